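"""Derived quantities for comparing simulated searches.

Provides the 5-step moving average used to de-jitter simulated paths, the
distance-to-origin series (the r/t view of a search), and a loop
segmentation that detects returns to the origin as qualifying minima of the
smoothed distance series.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np
from scipy.signal import find_peaks

from .model_core import Trajectory

__all__ = [
    "DistanceSeries",
    "LoopSummary",
    "smooth",
    "distance_series",
    "segment_loops",
]


@dataclasses.dataclass
class DistanceSeries:
    """Ordered ``(step, r)`` pairs of distance to the origin."""

    step: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        if len(self.step) != len(self.r):
            raise ValueError("step and r must have equal length")
        if len(self.r) and np.any(self.r < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.step)


@dataclasses.dataclass
class LoopSummary:
    """Loop structure of one search: return events and per-loop extrema.

    A loop spans from the previous return event (or the series start) to
    the next return event, so ``n_loops == len(return_events)``.
    """

    return_events: np.ndarray
    loop_maxima: np.ndarray
    loop_minima: np.ndarray
    n_loops: int


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    # summing ones then dividing keeps a constant series exactly constant
    return np.convolve(values, np.ones(window), mode="valid") / window


def smooth(trajectory: Trajectory, window: int = 5) -> Trajectory:
    """Centred moving average of the trajectory coordinates.

    Both raw and perturbed coordinates are averaged over ``window``
    successive records; the output is ``window - 1`` records shorter and its
    step indices are the window centres.  ``window = 1`` is the identity.
    The smoothed path is for output/analysis only and never feeds back into
    the dynamics.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if len(trajectory) < window:
        raise ValueError(
            f"trajectory of length {len(trajectory)} is shorter than "
            f"window {window}"
        )
    if window == 1:
        return trajectory
    half = window // 2
    sl = slice(half, len(trajectory) - half)
    return Trajectory(
        step=trajectory.step[sl],
        x=_moving_average(trajectory.x, window),
        y=_moving_average(trajectory.y, window),
        gamma=trajectory.gamma[sl],
        x_pert=_moving_average(trajectory.x_pert, window),
        y_pert=_moving_average(trajectory.y_pert, window),
        params=trajectory.params,
    )


def distance_series(trajectory: Trajectory) -> DistanceSeries:
    """Distance to the origin per step, taken from the perturbed path."""
    return DistanceSeries(step=trajectory.step.copy(), r=trajectory.r_pert)


def segment_loops(
    series: DistanceSeries,
    return_threshold: Optional[float] = 0.2,
    *,
    min_separation: int = 5,
    smooth_window: int = 5,
) -> LoopSummary:
    """Segment a distance series into loops at origin-return events.

    A return event is a local minimum of the smoothed series that lies
    below ``return_threshold`` times the running maximum of the smoothed
    series (running, so that growing searches still register their early
    returns).  Pass ``return_threshold=None`` to accept every separated
    local minimum as a loop boundary, e.g. for searches whose returns stay
    far from the origin.  Candidate minima closer than ``min_separation``
    samples are merged to suppress jitter doubles.

    Per-loop extrema are computed on the raw (unsmoothed) series between
    consecutive boundaries.
    """
    if len(series) == 0:
        raise ValueError("cannot segment an empty distance series")
    if return_threshold is not None and not 0 < return_threshold < 1:
        raise ValueError(
            f"return_threshold must lie in (0, 1), got {return_threshold}"
        )

    r = np.asarray(series.r, dtype=float)
    if smooth_window > 1 and len(r) >= smooth_window:
        rs = _moving_average(r, smooth_window)
        offset = smooth_window // 2
    else:
        rs = r
        offset = 0

    minima, _ = find_peaks(-rs, distance=max(1, min_separation))
    if return_threshold is not None:
        running_max = np.maximum.accumulate(rs)
        minima = minima[rs[minima] < return_threshold * running_max[minima]]

    events_idx = minima + offset  # positions in the original series
    boundaries = np.concatenate(([0], events_idx))
    loop_max: List[float] = []
    loop_min: List[float] = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = r[a : b + 1]
        loop_max.append(float(seg.max()))
        loop_min.append(float(seg.min()))

    return LoopSummary(
        return_events=series.step[events_idx],
        loop_maxima=np.asarray(loop_max),
        loop_minima=np.asarray(loop_min),
        n_loops=len(events_idx),
    )
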