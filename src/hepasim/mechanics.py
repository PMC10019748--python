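"""Overdamped off-lattice cell mechanics.

Cells interact through a piecewise-quadratic pair force: an elastic
repulsion active while cells overlap (centre distance below the sum of
radii R) and a compact-support adhesion active up to a maximum adhesion
distance R_A = R_A_factor · R.  Under the inertialess (low-Reynolds)
assumption velocities are forces divided by the drag coefficient; positions
are advanced with the two-step Adams–Bashforth method (forward Euler on a
cell's first step).

Neighbor search delegates to :class:`scipy.spatial.cKDTree`; every pair
within interaction range is enumerated exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SphereMembrane",
    "MechanicsParams",
    "neighbor_pairs",
    "pair_force",
    "pairwise_forces",
    "net_velocities",
    "membrane_force",
    "step_positions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SphereMembrane:
    """Confining spherical basement membrane (zero force inside)."""

    center: tuple[float, float, float]
    radius: float
    stiffness: float = 1.0


@dataclass(frozen=True)
class MechanicsParams:
    """Pair-interaction and drag coefficients.

    With the drag coefficient ``nu`` absorbed into force units (nu = 1 by
    default), ``c_adh`` and ``c_rep`` are in µm/min: they are the speeds of
    a cell at full adhesive stretch / full overlap.
    """

    c_adh: float = 0.06
    c_rep: float = 1.0
    R_A_factor: float = 1.25
    nu: float = 1.0
    membrane: SphereMembrane | None = None

    def __post_init__(self):
        if self.c_adh < 0 or self.c_rep < 0:
            raise ValueError("c_adh and c_rep must be >= 0")
        if self.R_A_factor < 1.0:
            raise ValueError("R_A_factor must be >= 1")
        if self.nu <= 0:
            raise ValueError("drag coefficient nu must be positive")


def neighbor_pairs(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """All index pairs (i < j) with ‖x_i − x_j‖ ≤ cutoff, each exactly once."""
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(np.asarray(positions, dtype=float))
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.astype(np.int64, copy=False)


def _force_magnitudes(d, R, R_A, c_adh, c_rep, adh_scale_pair=None):
    """Net radial force magnitude along (x_i - x_j): repulsion − adhesion."""
    rep = np.where(d < R, c_rep * (1.0 - d / R) ** 2, 0.0)
    adh = np.where(d < R_A, c_adh * (1.0 - d / R_A) ** 2, 0.0)
    if adh_scale_pair is not None:
        adh = adh * adh_scale_pair
    return rep - adh


def pair_force(
    xi, ri: float, xj, rj: float, params: MechanicsParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Force on cell i from cell j (Newton's third law gives the negation).

    Repulsion ``c_rep (1 − d/R)²`` for d < R; adhesion ``c_adh (1 − d/R_A)²``
    for d < R_A; zero beyond R_A.  Coincident centres get the repulsion along
    a random unit vector (logged).
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    delta = xi - xj
    d = float(np.linalg.norm(delta))
    R = ri + rj
    R_A = params.R_A_factor * R
    if d == 0.0:
        log.warning("coincident cell centres; applying repulsion along random direction")
        rng = rng or np.random.default_rng(0)
        delta = rng.normal(size=3)
        delta /= np.linalg.norm(delta)
        return params.c_rep * delta
    mag = float(_force_magnitudes(d, R, R_A, params.c_adh, params.c_rep))
    return mag * delta / d


def pairwise_forces(
    positions: np.ndarray,
    radii: np.ndarray,
    params: MechanicsParams,
    adhesion_scale: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Total pair force on every cell (n, 3); sums to zero over the population.

    ``adhesion_scale`` is an optional per-cell factor in [0, 1] (dying cells
    keep repulsion but lose adhesion); a pair's adhesion is scaled by the
    product of the two factors.
    """
    n = len(positions)
    forces = np.zeros((n, 3))
    if n < 2:
        return forces
    r_max = 2.0 * params.R_A_factor * float(np.max(radii))
    pairs = neighbor_pairs(positions, r_max)
    if pairs.size == 0:
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    delta = positions[i] - positions[j]
    d = np.linalg.norm(delta, axis=1)
    zero = d == 0.0
    if np.any(zero):
        log.warning("%d coincident cell pairs; random separation directions", zero.sum())
        rng = rng or np.random.default_rng(0)
        rnd = rng.normal(size=(int(zero.sum()), 3))
        rnd /= np.linalg.norm(rnd, axis=1, keepdims=True)
        delta[zero] = rnd
        d[zero] = 1e-12
    R = radii[i] + radii[j]
    R_A = params.R_A_factor * R
    scale = None
    if adhesion_scale is not None:
        scale = adhesion_scale[i] * adhesion_scale[j]
    mag = _force_magnitudes(d, R, R_A, params.c_adh, params.c_rep, scale)
    f = (mag / d)[:, None] * delta
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return forces


def membrane_force(
    positions: np.ndarray, radii: np.ndarray, membrane: SphereMembrane
) -> np.ndarray:
    """Inward linear restoring force on cells penetrating the membrane."""
    delta = np.atleast_2d(positions) - np.asarray(membrane.center)
    dist = np.linalg.norm(delta, axis=1)
    pen = dist + np.atleast_1d(radii) - membrane.radius
    out = np.zeros_like(np.atleast_2d(positions), dtype=float)
    active = pen > 0
    if np.any(active):
        direction = delta[active] / np.where(dist[active] > 0, dist[active], 1.0)[:, None]
        out[active] = -membrane.stiffness * pen[active, None] * direction
    return out


def net_velocities(
    positions: np.ndarray,
    radii: np.ndarray,
    params: MechanicsParams,
    adhesion_scale: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inertialess velocities v = (pair forces + membrane force) / nu."""
    f = pairwise_forces(positions, radii, params, adhesion_scale, rng)
    if params.membrane is not None:
        f = f + membrane_force(positions, radii, params.membrane)
    return f / params.nu


def step_positions(
    positions: np.ndarray,
    velocities: np.ndarray,
    v_prev: np.ndarray,
    has_prev: np.ndarray,
    dt: float,
    max_radius: float | None = None,
) -> np.ndarray:
    """Second-order Adams–Bashforth position update (in place).

    ``x ← x + dt (1.5 v − 0.5 v_prev)``; cells without velocity history take
    a forward-Euler step.  Returns the displacement actually applied; a
    displacement above one cell radius triggers a warning (time step too
    large for the current force scale).
    """
    v_eff = np.where(has_prev[:, None], 1.5 * velocities - 0.5 * v_prev, velocities)
    disp = dt * v_eff
    if max_radius is not None:
        step = np.linalg.norm(disp, axis=1)
        if np.any(step > max_radius):
            log.warning(
                "mechanics step moved %d cells more than one radius (max %.2f µm)",
                int(np.count_nonzero(step > max_radius)),
                float(step.max()),
            )
    positions += disp
    v_prev[...] = velocities
    has_prev[...] = True
    return disp


def relax(
    positions: np.ndarray,
    radii: np.ndarray,
    params: MechanicsParams,
    dt: float = 0.5,
    speed_tol: float = 0.02,
    max_steps: int = 2000,
) -> int:
    """Relax a packing until the fastest cell is slower than ``speed_tol``.

    Plain forward-Euler pseudo-time iteration used for initial-condition
    construction; returns the number of steps taken.
    """
    for step in range(max_steps):
        v = net_velocities(positions, radii, params)
        vmax = float(np.max(np.linalg.norm(v, axis=1))) if len(v) else 0.0
        if vmax < speed_tol:
            return step
        positions += dt * v
    return max_steps
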