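"""Deterministic centred-loop dynamics.

The simulator moves a point by small integration steps of fixed length
``s``.  The step direction is described by the angle ``gamma`` between the
current radial direction (toward/away from the origin) and the step vector;
``gamma`` grows by a constant increment ``beta`` every step, which bends the
path into loops.  A backward factor ``b`` shortens outbound radial motion and
lengthens inbound radial motion, so that each loop curves back through the
neighbourhood of the origin.

Two formulations of the same movement are provided:

* the Cartesian integrator (:func:`simulate_noiseless`), the production path;
* a polar-bookkeeping integrator (:func:`simulate_noiseless_polar`) that
  tracks ``(r, phi)`` directly and serves as an independent cross-check.

The polar single-step update exists in two flavours: :func:`polar_step` is
the first-order local-frame form (``dphi = s*sin(gamma)/r``), while
:func:`polar_step_exact` re-projects the displaced position exactly
(``hypot``/``atan2``) and therefore reproduces the Cartesian integrator to
floating-point accuracy.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "OriginSingularityError",
    "ModelParams",
    "Trajectory",
    "update_gamma",
    "radial_factor",
    "unit_vectors",
    "cartesian_step",
    "polar_step",
    "polar_step_exact",
    "simulate_noiseless",
    "simulate_noiseless_polar",
]

#: column order of the trajectory CSV interchange format
CSV_COLUMNS = ["step", "x", "y", "x_pert", "y_pert", "gamma_deg", "r", "r_pert"]


class OriginSingularityError(ValueError):
    """Raised when a step would have to be computed from the origin.

    The radial direction is undefined at ``(0, 0)``, so the integrator cannot
    proceed from there.
    """


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Full configuration of one simulation run.

    Parameters
    ----------
    alpha : float
        Initial step-direction angle ``gamma_0`` in degrees.
    beta : float
        Constant per-step increment of ``gamma`` in degrees.
    s : float
        Integration step length (length units per step); must be positive.
    b : float
        Backward factor subtracting ``|cos(gamma)|*b`` from the radial step
        component; must satisfy ``b < 1`` (may be negative).
    f : float
        Random perturbation factor (length units); ``f = 0`` disables noise.
    n : int
        Number of integration steps over which one random perturbation
        vector is active.
    x0, y0 : float
        Initial position; must not be the origin.
    n_steps : int
        Number of integration steps to simulate.
    seed : int or None
        Seed for the perturbation RNG; ``None`` draws fresh entropy.
    perturbation_mode : str
        ``"transient"`` (default) keeps the accumulated position noiseless
        and lets the perturbation act through the step geometry only;
        ``"persistent"`` folds the perturbation offset into the state.
    """

    alpha: float = 10.0
    beta: float = 3.0
    s: float = 0.12
    b: float = 0.2
    f: float = 0.0
    n: int = 3
    x0: float = 0.01
    y0: float = 0.0
    n_steps: int = 5000
    seed: Optional[int] = None
    perturbation_mode: str = "transient"

    def __post_init__(self) -> None:
        if not self.b < 1:
            raise ValueError(f"backward factor must satisfy b < 1, got b={self.b}")
        if not self.s > 0:
            raise ValueError(f"step length must be positive, got s={self.s}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"block length n must be a positive integer, got n={self.n}")
        if self.f < 0:
            raise ValueError(f"perturbation factor must be non-negative, got f={self.f}")
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ValueError(f"n_steps must be a positive integer, got {self.n_steps}")
        if self.x0 == 0.0 and self.y0 == 0.0:
            raise OriginSingularityError(
                "the initial position must not be the origin: the radial "
                "direction is undefined at (0, 0)"
            )
        if self.perturbation_mode not in ("transient", "persistent"):
            raise ValueError(
                f"perturbation_mode must be 'transient' or 'persistent', "
                f"got {self.perturbation_mode!r}"
            )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class Trajectory:
    """Per-step simulation records with ``dt = 1`` per record.

    Holds ``n_steps + 1`` records including the initial state.  The raw
    columns ``x, y`` carry the accumulated position; ``x_pert, y_pert`` carry
    the perturbed position actually analysed and plotted (equal to the raw
    columns when ``f = 0``).
    """

    step: np.ndarray
    x: np.ndarray
    y: np.ndarray
    gamma: np.ndarray
    x_pert: np.ndarray
    y_pert: np.ndarray
    params: Optional[ModelParams] = None

    def __post_init__(self) -> None:
        lens = {len(a) for a in (self.step, self.x, self.y, self.gamma,
                                 self.x_pert, self.y_pert)}
        if len(lens) != 1:
            raise ValueError("all trajectory columns must have equal length")

    def __len__(self) -> int:
        return len(self.step)

    @property
    def r(self) -> np.ndarray:
        """Distance of the raw position to the origin."""
        return np.hypot(self.x, self.y)

    @property
    def r_pert(self) -> np.ndarray:
        """Distance of the perturbed position to the origin."""
        return np.hypot(self.x_pert, self.y_pert)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "x": self.x,
                "y": self.y,
                "x_pert": self.x_pert,
                "y_pert": self.y_pert,
                "gamma_deg": self.gamma,
                "r": self.r,
                "r_pert": self.r_pert,
            }
        )

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV at full (round-tripping) precision.

        Float cells use Python's shortest-repr formatting, which parses back
        to the identical IEEE-754 double, so write-then-read is bit-exact.
        """
        r = self.r
        r_pert = self.r_pert
        with open(path, "w") as fh:
            fh.write(",".join(CSV_COLUMNS) + "\n")
            for i in range(len(self)):
                fh.write(
                    f"{int(self.step[i])},{float(self.x[i])!r},"
                    f"{float(self.y[i])!r},{float(self.x_pert[i])!r},"
                    f"{float(self.y_pert[i])!r},{float(self.gamma[i])!r},"
                    f"{float(r[i])!r},{float(r_pert[i])!r}\n"
                )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV is missing columns: {missing}")
        return cls(
            step=df["step"].to_numpy(dtype=np.int64),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            gamma=df["gamma_deg"].to_numpy(),
            x_pert=df["x_pert"].to_numpy(),
            y_pert=df["y_pert"].to_numpy(),
        )


def update_gamma(gamma: float, beta: float) -> float:
    """Advance the step-direction angle by the increment ``beta`` (degrees).

    The result is wrapped into ``[0, 360)``; wrapping is trigonometric
    identity and only keeps the state bounded.
    """
    g = (gamma + beta) % 360.0
    return 0.0 if g == 360.0 else g  # fp modulo can round up to the period


def radial_factor(gamma: float, b: float) -> float:
    """Radial step fraction ``cos(gamma) - |cos(gamma)|*b``.

    For inbound motion (``cos(gamma) = -a``) this gives ``-a*(1 + b)``: the
    approach is faster and straighter.  For outbound motion (``+a``) it gives
    ``a*(1 - b)``: the retreat is slower and curvier.  This asymmetry is what
    re-centres each loop on the origin.
    """
    c = math.cos(math.radians(gamma))
    return c - abs(c) * b


def unit_vectors(u: Tuple[float, float]) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Local radial and tangential unit vectors at position ``u``.

    Returns ``(e_r, e_phi)`` where ``e_r`` points away from the origin along
    ``u`` and ``e_phi`` is ``e_r`` rotated 90 degrees counter-clockwise.

    Raises
    ------
    OriginSingularityError
        If ``u`` is the zero vector.
    """
    x, y = u
    norm = math.hypot(x, y)
    if norm == 0.0:
        raise OriginSingularityError(
            "cannot compute radial/tangential directions at the origin"
        )
    return (x / norm, y / norm), (-y / norm, x / norm)


def cartesian_step(
    u: Tuple[float, float], gamma: float, params: ModelParams
) -> Tuple[float, float]:
    """Displacement of one integration step taken from position ``u``.

    The step of length ``s`` decomposes into a radial part
    ``s * (cos(gamma) - |cos(gamma)|*b)`` along ``e_r`` and a tangential
    part ``s * sin(gamma)`` along ``e_phi``.
    """
    e_r, e_phi = unit_vectors(u)
    s_r = params.s * radial_factor(gamma, params.b)
    s_phi = params.s * math.sin(math.radians(gamma))
    return (s_r * e_r[0] + s_phi * e_phi[0], s_r * e_r[1] + s_phi * e_phi[1])


def polar_step(
    r: float, phi: float, gamma: float, params: ModelParams
) -> Tuple[float, float]:
    """One integration step in first-order polar bookkeeping.

    ``dr = s * (cos(gamma) - |cos(gamma)|*b)`` and
    ``dphi = s * sin(gamma) / r`` (radians): the tangential displacement is
    divided by ``r`` to convert the unequal metric of polar coordinates, so
    turning is more rapid close to the origin.  ``phi`` is kept in radians.

    This form treats the local frame as flat during the step and is accurate
    only to first order in ``s / r``; use :func:`polar_step_exact` when the
    polar track must match the Cartesian vector sum.

    Raises
    ------
    OriginSingularityError
        If ``r <= 0`` before or after the step.
    """
    if r <= 0.0:
        raise OriginSingularityError("polar step requires r > 0")
    dr = params.s * radial_factor(gamma, params.b)
    dphi = params.s * math.sin(math.radians(gamma)) / r
    r_new = r + dr
    if r_new <= 0.0:
        raise OriginSingularityError(
            f"first-order polar step crossed the origin (r = {r_new})"
        )
    return r_new, phi + dphi


def polar_step_exact(
    r: float, phi: float, gamma: float, params: ModelParams
) -> Tuple[float, float]:
    """One integration step in polar bookkeeping, exact re-projection.

    The step vector (radial component ``dr``, tangential component ``dt``)
    is added to the position and the result is re-expressed in polar
    coordinates: ``r' = hypot(r + dr, dt)`` and
    ``phi' = phi + atan2(dt, r + dr)``.  This lands on exactly the same
    point as :func:`cartesian_step` followed by the vector sum, so a run
    integrated this way is an independent oracle for the Cartesian
    integrator.
    """
    if r <= 0.0:
        raise OriginSingularityError("polar step requires r > 0")
    dr = params.s * radial_factor(gamma, params.b)
    dt = params.s * math.sin(math.radians(gamma))
    r_new = math.hypot(r + dr, dt)
    if r_new == 0.0:
        raise OriginSingularityError("polar step landed exactly on the origin")
    return r_new, phi + math.atan2(dt, r + dr)


def simulate_noiseless(params: ModelParams) -> Trajectory:
    """Integrate the deterministic loop dynamics in the Cartesian frame.

    ``gamma`` starts at ``alpha``; every step first advances ``gamma`` by
    ``beta`` and then adds the step displacement to the position.  The
    perturbation factor ``f`` is ignored.  Output is bit-reproducible for
    identical parameters.
    """
    from ._engine import integrate

    return integrate(params, with_noise=False)


def simulate_noiseless_polar(params: ModelParams, exact: bool = True) -> Trajectory:
    """Integrate the deterministic dynamics in polar bookkeeping.

    With ``exact=True`` (default) uses :func:`polar_step_exact` and tracks
    the same trajectory as :func:`simulate_noiseless` to floating-point
    accuracy; with ``exact=False`` uses the first-order :func:`polar_step`,
    which drifts from the Cartesian track at second order in the step
    length.
    """
    step_fn = polar_step_exact if exact else polar_step
    n_rec = params.n_steps + 1
    r = math.hypot(params.x0, params.y0)
    if r == 0.0:
        raise OriginSingularityError("initial position must not be the origin")
    phi = math.atan2(params.y0, params.x0)
    g = params.alpha % 360.0

    x = np.empty(n_rec)
    y = np.empty(n_rec)
    gam = np.empty(n_rec)
    x[0] = params.x0
    y[0] = params.y0
    gam[0] = g
    for t in range(1, n_rec):
        g = update_gamma(g, params.beta)
        r, phi = step_fn(r, phi, g, params)
        x[t] = r * math.cos(phi)
        y[t] = r * math.sin(phi)
        gam[t] = g
    return Trajectory(
        step=np.arange(n_rec, dtype=np.int64),
        x=x,
        y=y,
        gamma=gam,
        x_pert=x.copy(),
        y_pert=y.copy(),
        params=params,
    )
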