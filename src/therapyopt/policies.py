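"""Feedback therapy protocols as finite-state controllers.

A policy observes only the total normalized burden ``n = s + r`` — in
the clinic the sensitive/resistant split is not separately measurable —
and maps it, together with an internal treat/vacation mode, to a dose
level.  The protocols implemented here:

* ``mtd`` — Maximum Tolerated Dose, full dose forever.
* ``on_off_at`` — classical adaptive therapy: treat from the start,
  pause once the burden halves, resume once it regrows to its initial
  value.
* ``off_on_at`` — surveillance-first adaptive therapy: withhold
  treatment until the burden reaches the progression threshold
  ``1.2·n0``, then treat until it halves, and repeat.

Threshold comparisons are inclusive: equality triggers the switch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable

import numpy as np

from .model import InvalidParameterError

__all__ = [
    "Mode",
    "PolicyState",
    "Policy",
    "OpenLoopPolicy",
    "ConstantDose",
    "MTD",
    "ThresholdPolicy",
    "OnOffAT",
    "OffOnAT",
    "SchedulePolicy",
    "mtd",
    "on_off_at",
    "off_on_at",
    "get_policy",
]


class Mode(Enum):
    TREAT = "treat"
    VACATION = "vacation"


@dataclass(frozen=True)
class PolicyState:
    """Internal controller state: current mode and its thresholds."""

    mode: Mode
    lower: float
    upper: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidParameterError(
                f"policy thresholds must satisfy lower < upper, got {self.lower} >= {self.upper}"
            )


class Policy:
    """Base class: maps (observed burden, state) -> (dose, new state)."""

    name: str = "policy"
    #: which progression statistic is the fair score for this protocol
    ttp_variant: str = "ttp"

    def initial_state(self) -> PolicyState | None:
        return None

    def step(self, n: float, state: PolicyState | None) -> tuple[float, PolicyState | None]:
        raise NotImplementedError


class OpenLoopPolicy(Policy):
    """A policy that ignores the observation."""

    def dose_at(self, k: int) -> float:
        raise NotImplementedError

    def step(self, n, state):
        raise NotImplementedError  # handled positionally by the simulator


class ConstantDose(OpenLoopPolicy):
    def __init__(self, level: float):
        if not 0.0 <= level <= 1.0:
            raise InvalidParameterError(f"dose level must lie in [0, 1], got {level!r}")
        self.level = float(level)
        self.name = f"constant:{level:g}"

    def dose_at(self, k: int) -> float:
        return self.level

    def step(self, n, state):
        return self.level, state


class MTD(ConstantDose):
    """Maximum Tolerated Dose: ``u ≡ 1``."""

    def __init__(self):
        super().__init__(1.0)
        self.name = "mtd"


class ThresholdPolicy(Policy):
    """Two-threshold bang-bang feedback controller.

    TREAT emits ``u = 1`` until ``n <= lower``; VACATION emits ``u = 0``
    until ``n >= upper``.
    """

    def __init__(self, lower: float, upper: float, initial_mode: Mode, name: str):
        if not lower < upper:
            raise InvalidParameterError("need lower < upper")
        self.lower = float(lower)
        self.upper = float(upper)
        self.initial_mode = initial_mode
        self.name = name

    def initial_state(self) -> PolicyState:
        return PolicyState(self.initial_mode, self.lower, self.upper, self.name)

    def step(self, n: float, state: PolicyState) -> tuple[float, PolicyState]:
        mode = state.mode
        if mode is Mode.TREAT and n <= self.lower:
            mode = Mode.VACATION
        elif mode is Mode.VACATION and n >= self.upper:
            mode = Mode.TREAT
        if mode is not state.mode:
            state = replace(state, mode=mode)
        return (1.0 if mode is Mode.TREAT else 0.0), state


class OnOffAT(ThresholdPolicy):
    """Classical adaptive therapy: start treating; pause at ``n0/2``,
    resume at ``n0``."""

    def __init__(self, n0: float):
        super().__init__(n0 / 2.0, n0, Mode.TREAT, "on_off_at")
        self.n0 = n0


class OffOnAT(ThresholdPolicy):
    """Surveillance-first adaptive therapy: start on vacation; treat at
    the progression threshold ``1.2·n0``, pause at ``n0/2``.

    Because the vacation phase rides the progression threshold by
    construction, the fair score is the last-exit statistic TTP'.
    """

    ttp_variant = "ttp_prime"

    def __init__(self, n0: float):
        super().__init__(n0 / 2.0, 1.2 * n0, Mode.VACATION, "off_on_at")
        self.n0 = n0


class SchedulePolicy(OpenLoopPolicy):
    """Open-loop replay of a stored piecewise-constant schedule."""

    def __init__(self, control):
        from .simulate import ControlGrid  # local import to avoid a cycle

        if not isinstance(control, ControlGrid):
            raise InvalidParameterError("SchedulePolicy expects a ControlGrid")
        self.control = control
        self.name = "schedule"

    def dose_at(self, k: int) -> float:
        return float(self.control.values[min(k, len(self.control.values) - 1)])


# --------------------------------------------------------------------------
# Functional interface and registry
# --------------------------------------------------------------------------

def mtd(n: float) -> float:
    """Maximum Tolerated Dose rule: full dose regardless of burden."""
    return 1.0


def on_off_at(n: float, state: PolicyState, n0: float) -> tuple[float, PolicyState]:
    """One evaluation of the On-Off adaptive rule."""
    return OnOffAT(n0).step(n, state)


def off_on_at(n: float, state: PolicyState, n0: float) -> tuple[float, PolicyState]:
    """One evaluation of the Off-On adaptive rule."""
    return OffOnAT(n0).step(n, state)


def get_policy(name: str, n0: float | None = None) -> Policy:
    """Look up a policy by registry name.

    Recognized names: ``mtd``, ``on_off_at``, ``off_on_at``,
    ``constant:<level>`` and ``schedule:<csv-path>``.  The adaptive
    policies require ``n0``.
    """
    if name == "mtd":
        return MTD()
    if name in ("on_off_at", "off_on_at"):
        if n0 is None:
            raise InvalidParameterError(f"policy {name!r} requires n0")
        return OnOffAT(n0) if name == "on_off_at" else OffOnAT(n0)
    if name.startswith("constant:"):
        return ConstantDose(float(name.split(":", 1)[1]))
    if name.startswith("schedule:"):
        from .io import read_control_csv

        return SchedulePolicy(read_control_csv(name.split(":", 1)[1]))
    raise InvalidParameterError(f"unknown policy {name!r}")
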