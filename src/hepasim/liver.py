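"""Liver scenario: baseline construction, partial hepatectomy, growth-factor
regulation and vessel recruitment.

The baseline liver is a sphere of confluent hepatocytes threaded by a
hexagonal lattice of portal-triad vessel columns (oxygen Dirichlet nodes),
the idealized lobule architecture.  A partial hepatectomy removes a planar
half-space of tissue so that the resected cell-volume fraction matches the
requested degree.  Surviving hepatocytes then secrete an abstract growth
factor in proportion to the injury; its local concentration gates
hypertrophy (raised volume targets) below the proliferation threshold and
cycle entry above it.  Tissue that densifies over voxels tagged as
potential vessels recruits new Dirichlet nodes (angiogenesis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig
from .mesh import VoxelMesh
from .microenv import Microenvironment, Substrate
from .population import CellPopulation, HEPATOCYTE, VolumeParams
from . import mechanics

__all__ = [
    "LobuleLattice",
    "hcp_positions",
    "build_liver",
    "perform_hepatectomy",
    "gf_secretion_rate",
    "cycle_entry_rate",
    "hypertrophy_factor",
    "angiogenesis_update",
]

log = logging.getLogger(__name__)

OXYGEN = "oxygen"
GROWTH_FACTOR = "growth_factor"


# ---------------------------------------------------------------- lattice
@dataclass(frozen=True)
class LobuleLattice:
    """Hexagonal portal-triad lattice extruded along one axis.

    Triads live on a 2-D triangular lattice of constant ``triad_spacing``
    in the plane perpendicular to ``axis``; every voxel column through a
    lattice point is tagged as a *potential* vessel.  Columns inside the
    initial liver become the baseline portal-triad Dirichlet nodes; the
    rest may be recruited later by angiogenesis.
    """

    triad_spacing: float = 90.0
    axis: int = 2  # z

    def lattice_points(self, mesh: VoxelMesh) -> np.ndarray:
        """Triangular-lattice points covering the mesh footprint, shape (m, 2)."""
        s = self.triad_spacing
        ext = mesh.extent
        u, v = [a for a in range(3) if a != self.axis]
        lo = np.asarray(mesh.origin)[[u, v]]
        hi = lo + ext[[u, v]]
        a1 = np.array([s, 0.0])
        a2 = np.array([0.5 * s, 0.5 * np.sqrt(3.0) * s])
        # anchor the lattice at the domain centre so triads straddle it
        centre = 0.5 * (lo + hi)
        n_max = int(np.ceil(np.max(hi - lo) / s)) + 2
        pts = []
        for i in range(-n_max, n_max + 1):
            for j in range(-n_max, n_max + 1):
                p = centre + i * a1 + j * a2
                if np.all(p >= lo) and np.all(p <= hi):
                    pts.append(p)
        return np.array(pts) if pts else np.empty((0, 2))

    def tagged_voxel_mask(self, mesh: VoxelMesh) -> np.ndarray:
        """Boolean (nx, ny, nz) mask of potential-vessel voxels (full columns)."""
        mask = np.zeros(mesh.shape, dtype=bool)
        pts = self.lattice_points(mesh)
        if pts.size == 0:
            return mask
        u, v = [a for a in range(3) if a != self.axis]
        lo = np.asarray(mesh.origin)[[u, v]]
        iu = np.floor((pts[:, 0] - lo[0]) / mesh.dx).astype(int)
        iv = np.floor((pts[:, 1] - lo[1]) / mesh.dx).astype(int)
        shp = mesh.shape
        ok = (iu >= 0) & (iu < shp[u]) & (iv >= 0) & (iv < shp[v])
        for a, b in zip(iu[ok], iv[ok]):
            sel = [slice(None)] * 3
            sel[u] = a
            sel[v] = b
            mask[tuple(sel)] = True
        return mask


# ---------------------------------------------------------------- packing
def hcp_positions(
    sphere_radius: float,
    spacing: float,
    center,
    rng: np.random.Generator | None = None,
    jitter: float = 0.02,
) -> np.ndarray:
    """Hexagonal-close-packed positions filling a sphere, lightly jittered."""
    center = np.asarray(center, dtype=float)
    n = int(np.ceil(sphere_radius / spacing)) + 1
    pts = []
    for k in range(-n, n + 1):
        for j in range(-int(1.2 * n), int(1.2 * n) + 1):
            for i in range(-int(1.2 * n), int(1.2 * n) + 1):
                x = (2 * i + (j + k) % 2) * 0.5 * spacing
                y = np.sqrt(3.0) * (j + (k % 2) / 3.0) * 0.5 * spacing
                z = np.sqrt(6.0) / 3.0 * k * spacing
                p = np.array([x, y, z])
                if np.linalg.norm(p) <= sphere_radius:
                    pts.append(p)
    pos = np.array(pts) + center
    if rng is not None and jitter > 0 and len(pos):
        pos = pos + rng.normal(scale=jitter * spacing, size=pos.shape)
    return pos


# ------------------------------------------------------------ construction
def build_environment(config: ScenarioConfig) -> Microenvironment:
    d = config.domain
    n = int(round(d.size / d.dx))
    mesh = VoxelMesh(n, n, n, d.dx)
    substrates = [
        Substrate(
            OXYGEN,
            D=config.oxygen.D,
            lam=config.oxygen.lam,
            dirichlet_value=config.oxygen.dirichlet_value,
            initial_value=config.oxygen.initial_value,
        ),
        Substrate(
            GROWTH_FACTOR,
            D=config.growth_factor.D,
            lam=config.growth_factor.lam,
            dirichlet_value=config.growth_factor.dirichlet_value,
            initial_value=config.growth_factor.initial_value,
        ),
    ]
    return Microenvironment(mesh, substrates)


def build_liver(
    config: ScenarioConfig,
    table,
    rng: np.random.Generator,
    relax_steps: int = 60,
) -> tuple[CellPopulation, Microenvironment, LobuleLattice, np.ndarray]:
    """Construct the baseline liver.

    Hepatocytes are packed HCP at their mechanical equilibrium spacing
    inside a sphere centred in the domain, lightly jittered, then relaxed
    mechanically; portal-triad columns inside the sphere become oxygen
    Dirichlet nodes; the growth-factor field starts at zero.

    Returns ``(population, microenvironment, lattice, tagged_mask)`` where
    ``tagged_mask`` marks potential-vessel voxels still available.
    """
    env = build_environment(config)
    mesh = env.mesh
    radius = config.liver.radius
    vp = VolumeParams()
    cell_r = (3.0 * vp.V_total / (4.0 * np.pi)) ** (1.0 / 3.0)
    if radius < 4.0 * cell_r:
        raise ValueError("liver radius must be at least two cell diameters")
    mech = mechanics.MechanicsParams(
        c_adh=config.mechanics.c_adh,
        c_rep=config.mechanics.c_rep,
        R_A_factor=config.mechanics.R_A_factor,
        nu=config.mechanics.nu,
    )
    spacing = equilibrium_separation(mech) * 2.0 * cell_r
    pos = hcp_positions(radius, spacing, mesh.center, rng)
    pop = CellPopulation(table, n_substrates=env.n_substrates)
    pop.add_cells(pos, cell_type=HEPATOCYTE, phase="Ki67-", volume=vp)
    radii = pop.radius
    mechanics.relax(pop.position, radii, mech, dt=1.0, speed_tol=0.05,
                    max_steps=relax_steps)

    lattice = LobuleLattice(config.liver.triad_spacing)
    tagged = lattice.tagged_voxel_mask(mesh)
    centers = mesh.centers()
    inside = np.linalg.norm(centers - mesh.center, axis=-1) <= radius
    o2 = env.substrate_index(OXYGEN)
    for ijk in np.argwhere(tagged & inside):
        env.add_dirichlet_node(tuple(ijk), {OXYGEN: env.substrates[o2].dirichlet_value})
    return pop, env, lattice, tagged


def equilibrium_separation(params: mechanics.MechanicsParams) -> float:
    """Two-cell equilibrium centre distance as a fraction of combined radii.

    Root of c_rep (1 − x)² = c_adh (1 − x/R_A_factor)² on x < 1; cells at
    contact still attract, so confluent tissue sits slightly compressed.
    """
    if params.c_adh == 0:
        return 1.0
    from scipy.optimize import brentq

    f = lambda x: (
        params.c_rep * (1.0 - x) ** 2
        - params.c_adh * (1.0 - x / params.R_A_factor) ** 2
    )
    return float(brentq(f, 1e-6, 1.0 - 1e-9))


# ------------------------------------------------------------- hepatectomy
def perform_hepatectomy(
    pop: CellPopulation,
    env: Microenvironment,
    fraction: float,
    tagged_mask: np.ndarray,
    axis: int = 0,
    tol: float = 0.01,
) -> float:
    """Planar resection of ``fraction`` of the cell volume (clean cut).

    The cut plane is perpendicular to ``axis``; its offset is found by
    bisection so the removed cell-volume fraction matches ``fraction``
    within ``tol``.  Cells beyond the plane are removed instantly and the
    vessel (Dirichlet) nodes there are deactivated.  The potential-vessel
    *tags* — the lobule-architecture blueprint — stay in place, so tissue
    regrowing across the resection margin can recruit vessels there again.
    Returns the removed fraction actually achieved.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    coords = pop.position[:, axis]
    volumes = pop.V
    total = volumes.sum()
    lo, hi = coords.min() - 1.0, coords.max() + 1.0

    def removed(offset):
        return volumes[coords > offset].sum() / total

    # removed() decreases in offset: bisect
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        r = removed(mid)
        if abs(r - fraction) <= tol:
            break
        if r > fraction:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
        r = removed(mid)
    if abs(r - fraction) > 0.05:
        raise ValueError(
            f"could not achieve resected fraction {fraction} (best {r:.3f})"
        )
    cut = pop.position[:, axis] > mid
    pop.remove(cut)

    centers = env.mesh.centers()
    gone = centers[..., axis] > mid
    for vox in list(env.dirichlet_voxels):
        if gone[vox]:
            env.remove_dirichlet_node(vox)
    return float(r)


# --------------------------------------------------------------- regulation
def gf_secretion_rate(
    fraction: float, secretion_per_injury: float, recovery: float = 0.0
) -> float:
    """Per-cell growth-factor secretion rate after an injury of ``fraction``.

    Proportional to the resected fraction, and shut down linearly as the
    liver regrows: multiplied by max(0, 1 − recovery) where ``recovery`` is
    V(t) / V_target.
    """
    return secretion_per_injury * fraction * max(0.0, 1.0 - recovery)


def cycle_entry_rate(gf, gf_prol: float, gf_star: float, t_Kneg: float):
    """Growth-factor–gated cycle entry rate (1/min).

    r = (1/t_Kneg) · clamp((GF − GF_prol) / (GF* − GF_prol), 0, 1);
    piecewise linear and continuous, zero at the proliferation threshold,
    maximal (1/t_Kneg) at the saturation value.
    """
    if gf_star <= gf_prol:
        raise ValueError("gf_star must exceed gf_prol")
    if t_Kneg <= 0:
        raise ValueError("t_Kneg must be positive")
    x = (np.asarray(gf, dtype=float) - gf_prol) / (gf_star - gf_prol)
    return np.clip(x, 0.0, 1.0) / t_Kneg


def hypertrophy_factor(gf, gf_hyp: float, gf_hyp_sat: float, h_max: float):
    """Target-volume scale factor h(GF) ∈ [1, h_max].

    Ramps linearly from 1 at the hypertrophy threshold to ``h_max`` at the
    hypertrophy saturation value (below the proliferation threshold, so a
    mild injury produces pure hypertrophy).
    """
    if gf_hyp_sat <= gf_hyp:
        raise ValueError("gf_hyp_sat must exceed gf_hyp")
    x = (np.asarray(gf, dtype=float) - gf_hyp) / (gf_hyp_sat - gf_hyp)
    return 1.0 + (h_max - 1.0) * np.clip(x, 0.0, 1.0)


def oxygen_entry_factor(o2, o2_prol: float, o2_sat: float):
    """Multiplicative oxygen modulation of cycle entry, clamped linear."""
    x = (np.asarray(o2, dtype=float) - o2_prol) / (o2_sat - o2_prol)
    return np.clip(x, 0.0, 1.0)


# -------------------------------------------------------------- angiogenesis
def angiogenesis_update(
    pop: CellPopulation,
    env: Microenvironment,
    tagged_mask: np.ndarray,
    cell_threshold: int = 5,
    oxygen_value: float | None = None,
) -> int:
    """Recruit vessels where tagged voxels hold ``cell_threshold``+ cells.

    Every potential-vessel voxel that is not yet a Dirichlet node and whose
    contained live-cell count reaches the threshold becomes a permanent
    oxygen Dirichlet node.  Returns the number of nodes added.
    """
    if len(pop) == 0:
        return 0
    live = pop.alive
    idx = env.mesh.voxel_of(pop.position[live])
    counts = np.zeros(env.mesh.n_voxels, dtype=np.int64)
    np.add.at(counts, np.ravel_multi_index(idx.T, env.mesh.shape), 1)
    counts = counts.reshape(env.mesh.shape)
    if oxygen_value is None:
        oxygen_value = env.substrates[env.substrate_index(OXYGEN)].dirichlet_value
    added = 0
    for ijk in np.argwhere(tagged_mask & (counts >= cell_threshold)):
        vox = tuple(ijk)
        if not env.is_dirichlet(vox):
            env.add_dirichlet_node(vox, {OXYGEN: oxygen_value})
            added += 1
    return added
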