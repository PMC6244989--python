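"""Continuous within-run variation of model parameters.

Ramping the turn increment ``beta`` down during a run makes successive
loops larger (higher radial maxima); ramping the backward factor ``b`` down
— possibly below zero — makes the returns shallower (higher radial minima).
Both mimic a search that widens in its later stages.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._engine import integrate
from .model_core import ModelParams, Trajectory

__all__ = ["ParamSchedule", "value_at", "simulate_scheduled"]

_SCHEDULABLE = ("beta", "b")


@dataclasses.dataclass(frozen=True)
class ParamSchedule:
    """Linear ramp of one model parameter over the whole run."""

    param: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.param not in _SCHEDULABLE:
            raise ValueError(
                f"schedulable parameters are {_SCHEDULABLE}, got {self.param!r}"
            )
        if self.param == "b" and max(self.start, self.end) >= 1:
            raise ValueError("scheduled b must stay below 1")


def value_at(schedule: ParamSchedule, step: int, n_steps: int) -> float:
    """Linearly interpolated parameter value at a step index.

    ``value_at(sch, 0, N) == sch.start`` and
    ``value_at(sch, N, N) == sch.end``.
    """
    if not 0 <= step <= n_steps:
        raise ValueError(f"step {step} outside 0..{n_steps}")
    return schedule.start + (schedule.end - schedule.start) * step / n_steps


def simulate_scheduled(
    params: ModelParams, schedules: Sequence[ParamSchedule]
) -> Trajectory:
    """Simulate with ``beta`` and/or ``b`` evaluated per step from ramps.

    Unscheduled parameters keep their constant values; noise (``f > 0``)
    works exactly as in the unscheduled simulator.  An empty schedule list
    reproduces the unscheduled simulator bit-for-bit.
    """
    names = [sch.param for sch in schedules]
    if len(names) != len(set(names)):
        raise ValueError(f"schedules must reference distinct parameters, got {names}")

    beta_of = None
    b_of = None
    steps = np.arange(params.n_steps + 1)
    for sch in schedules:
        ramp = sch.start + (sch.end - sch.start) * steps / params.n_steps
        if sch.param == "beta":
            beta_of = ramp
        else:
            b_of = ramp
    return integrate(params, with_noise=True, beta_of=beta_of, b_of=b_of)
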