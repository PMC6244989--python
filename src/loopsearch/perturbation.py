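"""Block random perturbations of the loop dynamics.

Noise is not injected at every step.  Instead one Gaussian displacement
vector ``p = (f*psi_k, f*psi_{k+1})`` is drawn per block of ``n`` steps and
added to the position with a sine envelope ``sin(i*pi/(n+1))`` that rises
and falls over the block, keeping the perturbed path free of sharp turns.
The perturbed position feeds back into the step geometry, so a single block
can enlarge or shrink the loop it lands in.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Tuple

import numpy as np

from ._engine import integrate
from .model_core import ModelParams, Trajectory

__all__ = [
    "PerturbationBlock",
    "draw_block",
    "envelope",
    "apply_perturbation",
    "simulate_perturbed",
]


@dataclasses.dataclass
class PerturbationBlock:
    """One random displacement vector with its within-block position.

    ``p`` stays fixed for ``n`` consecutive steps while the envelope index
    ``i`` runs from 1 to ``n``.
    """

    p: Tuple[float, float]
    n: int
    i: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"block length must be >= 1, got n={self.n}")
        if not 1 <= self.i <= self.n:
            raise ValueError(f"block index i={self.i} outside 1..{self.n}")


def draw_block(f: float, n: int, rng: np.random.Generator) -> PerturbationBlock:
    """Draw a fresh perturbation vector ``p = (f*psi_k, f*psi_{k+1})``.

    Exactly two standard-normal numbers are consumed from ``rng``, the first
    for the x-component, the second for the y-component.
    """
    if f < 0:
        raise ValueError(f"perturbation factor must be non-negative, got f={f}")
    psi_x = rng.standard_normal()
    psi_y = rng.standard_normal()
    return PerturbationBlock(p=(f * psi_x, f * psi_y), n=n)


def envelope(i: int, n: int) -> float:
    """Sine envelope ``sin(i*pi/(n+1))`` of the block perturbation.

    Strictly positive and symmetric over ``i = 1..n``: the perturbation
    ramps up to the block midpoint and back down, so the offset is transient
    within each block.
    """
    if not 1 <= i <= n:
        raise ValueError(f"envelope index i={i} outside 1..{n}")
    return math.sin(i * math.pi / (n + 1))


def apply_perturbation(
    u: Tuple[float, float], block: PerturbationBlock
) -> Tuple[float, float]:
    """Perturbed position ``u' = u + sin(sigma_i) * p``."""
    env = envelope(block.i, block.n)
    return (u[0] + env * block.p[0], u[1] + env * block.p[1])


def simulate_perturbed(params: ModelParams) -> Trajectory:
    """Run the full stochastic simulation.

    Each step advances ``gamma`` by ``beta``, perturbs the position with the
    active block, evaluates the step geometry (unit vectors and 1/r turning)
    at the perturbed position, and accumulates the displacement.  Blocks
    tile the run back to back; a new ``p`` is drawn every ``n`` steps, two
    normal draws each, in temporal order — with the seed fixed, the output
    is fully reproducible.  With ``f = 0`` the result is bit-identical to
    :func:`loopsearch.model_core.simulate_noiseless`.
    """
    return integrate(params, with_noise=True)
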