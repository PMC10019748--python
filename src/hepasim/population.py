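"""Vectorized off-lattice cell-agent container.

Cells are stored struct-of-arrays for speed: one row per agent holding
position, the three volume compartments (fluid, nuclear solid, cytoplasmic
solid), per-cell volume targets and relaxation rates, phase pointer and
time-in-phase, per-substrate secretion/uptake rates, lineage generation and
cell type.  All per-step operations (phase advance, volume relaxation,
division, removal) are NumPy-vectorized over the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycles import PhaseTable

__all__ = ["VolumeParams", "CellPopulation", "HEPATOCYTE", "CANCER"]

HEPATOCYTE = 0
CANCER = 1

_TARGET_KEYS = ("f_F", "V_NS_star", "f_CN", "r_F", "r_N", "r_C")


@dataclass(frozen=True)
class VolumeParams:
    """Homeostatic three-compartment volume model parameters.

    Defaults describe a ~2494 µm³ parenchymal cell: 75% fluid, 540 µm³
    nucleus (135 µm³ nuclear solid), cytoplasmic:nuclear solid ratio chosen
    so the compartments are at their joint fixed point.  Rates are 1/min.
    """

    V_total: float = 2494.0
    f_F: float = 0.75
    V_NS_star: float = 135.0
    f_CN: float = 3.6185
    r_F: float = 0.05
    r_N: float = 0.0033
    r_C: float = 0.0033

    def initial_compartments(self) -> tuple[float, float, float]:
        """(V_F, V_NS, V_CS) at the model's fixed point for these targets."""
        v_ns = self.V_NS_star
        v_cs = self.f_CN * v_ns
        v_s = v_ns + v_cs
        v = v_s / (1.0 - self.f_F) if self.f_F < 1.0 else v_s
        return (v - v_s, v_ns, v_cs)


def radius_from_volume(V):
    """Radius of the sphere of volume ``V`` (µm)."""
    return np.cbrt(3.0 * np.asarray(V) / (4.0 * np.pi))


class CellPopulation:
    """All cell agents of a simulation, in struct-of-arrays form."""

    _FLOAT_FIELDS = (
        "V_F", "V_NS", "V_CS",
        "f_F", "V_NS_star", "f_CN", "r_F", "r_N", "r_C",
        "V_NS_star_base", "t_phase", "entry_rate", "hypoxic_time", "dur_scale",
        "hyper_h", "hyper_peak",
    )

    def __init__(self, table: PhaseTable, n_substrates: int = 0):
        self.table = table
        self.n_substrates = n_substrates
        self._next_id = 0
        self.id = np.empty(0, dtype=np.int64)
        self.cell_type = np.empty(0, dtype=np.int8)
        self.position = np.empty((0, 3))
        self.v_prev = np.empty((0, 3))
        self.has_prev = np.empty(0, dtype=bool)
        self.phase = np.empty(0, dtype=np.int64)
        self.generation = np.empty(0, dtype=np.int64)
        self.alive = np.empty(0, dtype=bool)
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.empty(0))
        self.secretion = np.empty((0, n_substrates))
        self.uptake = np.empty((0, n_substrates))
        self.rho_star = np.empty((0, n_substrates))
        #: cumulative division events by cell type
        self.cum_divisions = {HEPATOCYTE: 0, CANCER: 0}

    # ------------------------------------------------------------ properties
    def __len__(self) -> int:
        return self.position.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    @property
    def V_S(self) -> np.ndarray:
        return self.V_NS + self.V_CS

    @property
    def V(self) -> np.ndarray:
        return self.V_F + self.V_NS + self.V_CS

    @property
    def V_N(self) -> np.ndarray:
        """Total nuclear volume (nuclear solid plus its share of fluid)."""
        v_s = self.V_S
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(v_s > 0, self.V_NS / np.where(v_s > 0, v_s, 1.0), 0.0)
        return self.V_NS + share * self.V_F

    @property
    def V_C(self) -> np.ndarray:
        return self.V - self.V_N

    @property
    def radius(self) -> np.ndarray:
        return radius_from_volume(self.V)

    def phase_name(self, i: int) -> str:
        return self.table.names[self.phase[i]]

    def phase_mask(self, name: str) -> np.ndarray:
        return self.phase == self.table.index(name)

    # -------------------------------------------------------------- building
    def add_cells(
        self,
        positions,
        cell_type: int = HEPATOCYTE,
        phase: str | int = 0,
        volume: VolumeParams | None = None,
        generation: int = 0,
    ) -> np.ndarray:
        """Append cells at ``positions`` (m, 3); returns their ids."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        m = positions.shape[0]
        vp = volume or VolumeParams()
        v_f, v_ns, v_cs = vp.initial_compartments()
        phase_idx = self.table.index(phase) if isinstance(phase, str) else int(phase)
        ids = np.arange(self._next_id, self._next_id + m, dtype=np.int64)
        self._next_id += m

        self.id = np.concatenate([self.id, ids])
        self.cell_type = np.concatenate(
            [self.cell_type, np.full(m, cell_type, dtype=np.int8)]
        )
        self.position = np.vstack([self.position, positions])
        self.v_prev = np.vstack([self.v_prev, np.zeros((m, 3))])
        self.has_prev = np.concatenate([self.has_prev, np.zeros(m, dtype=bool)])
        self.phase = np.concatenate([self.phase, np.full(m, phase_idx, dtype=np.int64)])
        self.generation = np.concatenate(
            [self.generation, np.full(m, generation, dtype=np.int64)]
        )
        self.alive = np.concatenate([self.alive, np.ones(m, dtype=bool)])
        new = {
            "V_F": np.full(m, v_f),
            "V_NS": np.full(m, v_ns),
            "V_CS": np.full(m, v_cs),
            "f_F": np.full(m, vp.f_F),
            "V_NS_star": np.full(m, vp.V_NS_star),
            "f_CN": np.full(m, vp.f_CN),
            "r_F": np.full(m, vp.r_F),
            "r_N": np.full(m, vp.r_N),
            "r_C": np.full(m, vp.r_C),
            "V_NS_star_base": np.full(m, vp.V_NS_star),
            "t_phase": np.zeros(m),
            "entry_rate": np.zeros(m),
            "hypoxic_time": np.zeros(m),
            "dur_scale": np.ones(m),
            "hyper_h": np.ones(m),
            "hyper_peak": np.ones(m),
        }
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.concatenate([getattr(self, name), new[name]]))
        zeros = np.zeros((m, self.n_substrates))
        self.secretion = np.vstack([self.secretion, zeros])
        self.uptake = np.vstack([self.uptake, zeros.copy()])
        self.rho_star = np.vstack([self.rho_star, zeros.copy()])
        return ids

    # --------------------------------------------------------------- volumes
    def update_volume(self, dt: float) -> None:
        """Forward-Euler relaxation of the three compartments to their targets.

        dV_F/dt  = r_F (f_F V - V_F)
        dV_NS/dt = r_N (V_NS* - V_NS)
        dV_CS/dt = r_C (f_CN V_NS - V_CS)
        """
        v = self.V
        dV_F = self.r_F * (self.f_F * v - self.V_F)
        dV_NS = self.r_N * (self.V_NS_star - self.V_NS)
        dV_CS = self.r_C * (self.f_CN * self.V_NS - self.V_CS)
        self.V_F = np.maximum(self.V_F + dt * dV_F, 0.0)
        self.V_NS = np.maximum(self.V_NS + dt * dV_NS, 0.0)
        self.V_CS = np.maximum(self.V_CS + dt * dV_CS, 0.0)

    def set_hypertrophy(self, factor, mask=None) -> None:
        """Scale nuclear-solid targets by ``factor`` (cytoplasm follows f_CN)."""
        if mask is None:
            self.V_NS_star = self.V_NS_star_base * factor
        else:
            self.V_NS_star[mask] = (self.V_NS_star_base * factor)[mask]

    # ---------------------------------------------------------------- phases
    def _apply_entry_targets(self, idx: np.ndarray, phase_idx: int) -> None:
        targets = self.table.entry_targets[phase_idx]
        for key, value in targets.items():
            getattr(self, key)[idx] = value

    def _enter_phase(self, idx: np.ndarray, new_phase: np.ndarray) -> None:
        self.phase[idx] = new_phase
        self.t_phase[idx] = 0.0
        for ph in np.unique(new_phase):
            sub = idx[new_phase == ph]
            self._apply_entry_targets(sub, int(ph))

    def start_death(self, idx: np.ndarray, phase: str) -> None:
        """Move cells into a death cycle (apoptotic or necrotic_swelling)."""
        idx = np.atleast_1d(np.asarray(idx, dtype=np.int64))
        if idx.size == 0:
            return
        ph = self.table.index(phase)
        self.alive[idx] = False
        self._enter_phase(idx, np.full(idx.size, ph, dtype=np.int64))

    def advance_phase(self, dt: float, rng: np.random.Generator) -> int:
        """One phenotype step: fire due transitions, divide, remove.

        Fixed-duration edges fire when time-in-phase reaches the duration;
        stochastic edges fire with probability ``1 - exp(-rate dt)`` (exact
        for exponential dwell).  Returns the number of division events.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        n = len(self)
        if n == 0:
            return 0
        t = self.table
        self.t_phase += dt
        dur = t.duration[self.phase]
        dur = np.where(t.scalable[self.phase], dur * self.dur_scale, dur)
        fire_fixed = ~np.isnan(dur) & (self.t_phase >= dur - 1e-9)
        rate = np.where(t.regulated[self.phase], self.entry_rate, t.rate[self.phase])
        stoch = ~np.isnan(rate) & (rate > 0)
        u = rng.random(n)
        fire_stoch = stoch & (u < -np.expm1(-rate * dt))
        fire = fire_fixed | fire_stoch

        divide_mask = fire & t.divides[self.phase]
        remove_mask = fire & t.removes[self.phase]
        trans_mask = fire & ~divide_mask & ~remove_mask

        idx = np.flatnonzero(trans_mask)
        if idx.size:
            self._enter_phase(idx, t.next_index[self.phase[idx]])

        n_div = int(np.count_nonzero(divide_mask))
        if n_div:
            div_idx = np.flatnonzero(divide_mask)
            for ct in (HEPATOCYTE, CANCER):
                self.cum_divisions[ct] += int(
                    np.count_nonzero(self.cell_type[div_idx] == ct)
                )
            self.divide(div_idx, rng)
            remove_mask = np.concatenate(
                [remove_mask, np.zeros(len(self) - n, dtype=bool)]
            )
        if np.any(remove_mask):
            self.remove(remove_mask)
        return n_div

    # --------------------------------------------------------------- divide
    def divide(self, indices: np.ndarray, rng: np.random.Generator) -> None:
        """Split each indexed cell into two daughters.

        Every volume compartment is halved (exact conservation); daughters
        are placed at parent ± (r_parent/2)·û with û uniform on the sphere;
        generation increments by one; both daughters enter the parent
        phase's successor (Ki-67+ post-mitotic for the proliferative cycle).
        """
        indices = np.atleast_1d(np.asarray(indices, dtype=np.int64))
        m = indices.size
        if m == 0:
            return
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        offset = 0.5 * self.radius[indices][:, None] * u
        parent_pos = self.position[indices].copy()

        # clone rows for daughter 2
        self.id = np.concatenate(
            [self.id, np.arange(self._next_id, self._next_id + m, dtype=np.int64)]
        )
        self._next_id += m
        grow2 = lambda a: np.concatenate([a, a[indices]])
        self.cell_type = grow2(self.cell_type)
        self.position = np.vstack([self.position, parent_pos])
        self.v_prev = np.vstack([self.v_prev, np.zeros((m, 3))])
        self.has_prev = np.concatenate([self.has_prev, np.zeros(m, dtype=bool)])
        self.phase = grow2(self.phase)
        self.generation = grow2(self.generation)
        self.alive = grow2(self.alive)
        for name in self._FLOAT_FIELDS:
            setattr(self, name, grow2(getattr(self, name)))
        self.secretion = np.vstack([self.secretion, self.secretion[indices]])
        self.uptake = np.vstack([self.uptake, self.uptake[indices]])
        self.rho_star = np.vstack([self.rho_star, self.rho_star[indices]])

        new_idx = np.arange(len(self) - m, len(self), dtype=np.int64)
        both = np.concatenate([indices, new_idx])
        for arr_name in ("V_F", "V_NS", "V_CS"):
            arr = getattr(self, arr_name)
            arr[indices] *= 0.5
            arr[new_idx] = arr[indices]
        self.position[indices] = parent_pos + offset
        self.position[new_idx] = parent_pos - offset
        self.generation[both] += 1
        self.has_prev[both] = False
        next_phase = self.table.next_index[self.phase[both]]
        self._enter_phase(both, next_phase)

    # --------------------------------------------------------------- removal
    def remove(self, mask: np.ndarray) -> None:
        """Delete the masked cells from every registry."""
        keep = ~np.asarray(mask, dtype=bool)
        self.id = self.id[keep]
        self.cell_type = self.cell_type[keep]
        self.position = self.position[keep]
        self.v_prev = self.v_prev[keep]
        self.has_prev = self.has_prev[keep]
        self.phase = self.phase[keep]
        self.generation = self.generation[keep]
        self.alive = self.alive[keep]
        for name in self._FLOAT_FIELDS:
            setattr(self, name, getattr(self, name)[keep])
        self.secretion = self.secretion[keep]
        self.uptake = self.uptake[keep]
        self.rho_star = self.rho_star[keep]
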