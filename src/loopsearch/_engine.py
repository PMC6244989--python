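"""Shared step-by-step integrator behind the public simulate_* functions.

One code path serves the noiseless, perturbed and scheduled simulators so
that disabling a feature (``f = 0``, constant schedules) reduces to the
simpler simulator bit-for-bit.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .model_core import ModelParams, OriginSingularityError, Trajectory


def integrate(
    params: ModelParams,
    *,
    with_noise: bool = True,
    beta_of: Optional[np.ndarray] = None,
    b_of: Optional[np.ndarray] = None,
) -> Trajectory:
    """Run the centred-loop integrator.

    Parameters
    ----------
    params : ModelParams
        Run configuration.
    with_noise : bool
        If false, the perturbation machinery is skipped entirely (``f`` is
        ignored).  If true and ``params.f > 0``, one Gaussian displacement
        vector ``p = (f*psi_k, f*psi_{k+1})`` is drawn per ``n``-step block
        (x-component first) and applied with the sine envelope
        ``sin(i*pi/(n+1))``, ``i = 1..n``.
    beta_of, b_of : ndarray or None
        Optional per-step parameter values indexed by step (length
        ``n_steps + 1``); ``None`` uses the constant from ``params``.

    Notes
    -----
    Per step: advance ``gamma`` by ``beta``; form the perturbed position
    ``u' = u + sin(sigma_i) * p``; evaluate the radial/tangential unit
    vectors and the radius at ``u'``; add the resulting displacement to the
    accumulated position ``u``; advance the block, drawing a fresh ``p``
    every ``n`` steps.  Both ``u`` and ``u'`` are recorded.  In
    ``persistent`` mode the offset is folded into ``u`` instead.
    """
    p = params
    n_rec = p.n_steps + 1
    x = np.empty(n_rec)
    y = np.empty(n_rec)
    gam = np.empty(n_rec)
    xp = np.empty(n_rec)
    yp = np.empty(n_rec)

    ux, uy = p.x0, p.y0
    if ux == 0.0 and uy == 0.0:
        raise OriginSingularityError("initial position must not be the origin")
    g = p.alpha % 360.0
    x[0] = xp[0] = ux
    y[0] = yp[0] = uy
    gam[0] = g

    noisy = with_noise and p.f > 0.0
    rng = np.random.default_rng(p.seed) if noisy else None
    persistent = noisy and p.perturbation_mode == "persistent"
    n_block = p.n

    beta_const = p.beta
    b_const = p.b
    f = p.f
    s = p.s
    px = py = 0.0
    block_i = 0  # steps already consumed from the active block

    hypot = math.hypot
    radians = math.radians
    sin = math.sin
    cos = math.cos
    pi = math.pi

    for t in range(1, n_rec):
        bt = beta_const if beta_of is None else beta_of[t]
        bb = b_const if b_of is None else b_of[t]
        g = (g + bt) % 360.0
        if g == 360.0:  # fp modulo can round up to the period
            g = 0.0

        if noisy:
            if block_i == 0:
                px = f * rng.standard_normal()
                py = f * rng.standard_normal()
            block_i += 1
            env = sin(block_i * pi / (n_block + 1))
            ox = env * px
            oy = env * py
            if block_i == n_block:
                block_i = 0
        else:
            ox = 0.0
            oy = 0.0

        wx = ux + ox
        wy = uy + oy
        r = hypot(wx, wy)
        if r == 0.0:
            # below the guard radius the step is still taken from the
            # pre-step direction vectors; only an exact zero is fatal
            raise OriginSingularityError(
                f"position reached the origin exactly at step {t}"
            )

        grad = radians(g)
        cg = cos(grad)
        s_r = s * (cg - abs(cg) * bb)
        s_phi = s * sin(grad)
        erx = wx / r
        ery = wy / r
        dx = s_r * erx - s_phi * ery
        dy = s_r * ery + s_phi * erx

        if persistent:
            ux = wx + dx
            uy = wy + dy
            x[t] = xp[t] = ux
            y[t] = yp[t] = uy
        else:
            ux += dx
            uy += dy
            x[t] = ux
            y[t] = uy
            xp[t] = ux + ox
            yp[t] = uy + oy
        gam[t] = g

    return Trajectory(
        step=np.arange(n_rec, dtype=np.int64),
        x=x,
        y=y,
        gamma=gam,
        x_pert=xp,
        y_pert=yp,
        params=p,
    )
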