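"""Simulate one tumor under the three feedback protocols and score TTP.

The tumor has a resistant clone at 1% of the initial burden growing at
66% of the sensitive rate, starting at half the carrying capacity.
"""

import therapyopt as t

theta = t.ThetaTwoPop(d_hat_D=1.5, d_hat_T=0.0, r_hat_R=0.66, f_hat_0=0.01, n0=0.5)
horizon = 1000 * t.DEFAULT_R_S  # 1000 days in normalized time

for name in ("mtd", "on_off_at", "off_on_at"):
    policy = t.get_policy(name, n0=0.5)
    traj = t.simulate_policy(theta, policy, horizon)
    summary = t.compute_ttp(traj, n0=0.5)
    days = summary.days(policy.ttp_variant)[0]
    print(f"{name:>10}: progression after {days} days "
          f"(dose on {100 * traj.controls.mean():.0f}% of the time)")

print(
    "\nContinuous dosing (mtd) drives the sensitive clone extinct and the"
    "\nresistant clone takes over; both adaptive protocols keep sensitive"
    "\ncells alive as competitors and delay progression by 1-3 months."
)
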