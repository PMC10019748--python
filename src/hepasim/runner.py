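"""Simulation clock, scheduler and scenario driver.

The main loop interleaves three cadences: substrate diffusion at
``dt_diffusion``, cell mechanics (pair forces + Adams–Bashforth positions)
whenever the mechanics due-time is reached, and cell processes (regulation,
volume relaxation, phase transitions, divisions/removals, necrosis
triggers, angiogenesis) at ``dt_cycle``; state snapshots are recorded every
``dt_save``.  The hepatectomy (and optional tumor seeding) fire once at
their configured simulation minute.

All randomness flows from one seed through named ``SeedSequence``
substreams (build / cycle / mechanics / tumor), so identical configuration
and seed reproduce bitwise-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import liver as liver_mod
from . import mechanics
from .config import DAY, ScenarioConfig
from .cycles import build_ki67_cycle, build_phase_table
from .liver import GROWTH_FACTOR, OXYGEN
from .population import CANCER, HEPATOCYTE, CellPopulation

__all__ = ["Schedule", "Simulation", "run_regeneration", "make_fixture"]

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class Schedule:
    """Step sizes (min), horizon, and the next-due times the loop tracks."""

    dt_diffusion: float
    dt_mech: float
    dt_cycle: float
    dt_save: float
    t_end: float
    t_mech: float = field(init=False)
    t_cycle: float = field(init=False)
    t_save: float = field(init=False)

    def __post_init__(self):
        if not (0 < self.dt_diffusion <= self.dt_mech <= self.dt_cycle):
            raise ValueError("need 0 < dt_diffusion <= dt_mech <= dt_cycle")
        self.t_mech = self.dt_mech
        self.t_cycle = self.dt_cycle
        self.t_save = self.dt_save

    @classmethod
    def from_config(cls, sc) -> "Schedule":
        return cls(sc.dt_diffusion, sc.dt_mech, sc.dt_cycle, sc.dt_save, sc.t_end)


class Simulation:
    """One scenario run: liver construction, events, main loop, time series."""

    def __init__(self, config: ScenarioConfig, seed: int | None = None):
        self.config = config
        seed = config.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        build_ss, cycle_ss, mech_ss, tumor_ss = ss.spawn(4)
        self.rng_build = np.random.default_rng(build_ss)
        self.rng_cycle = np.random.default_rng(cycle_ss)
        self.rng_mech = np.random.default_rng(mech_ss)
        self.rng_tumor = np.random.default_rng(tumor_ss)

        hep = config.hepatocyte
        cycle = build_ki67_cycle(
            t_pre=hep.t_pre, t_post=hep.t_post, total_cycle=hep.total_cycle
        )
        self.table = build_phase_table(cycle)
        self.t_Kneg_hep = hep.total_cycle - hep.t_pre - hep.t_post
        can = config.cancer
        self.t_Kneg_cancer = can.total_cycle - can.t_pre - can.t_post
        #: fixed-duration scale for cancer cycle phases relative to hepatocyte
        self.cancer_dur_scale = can.t_pre / hep.t_pre

        self.pop, self.env, self.lattice, self.tagged = liver_mod.build_liver(
            config, self.table, self.rng_build
        )
        self.mech = mechanics.MechanicsParams(
            c_adh=config.mechanics.c_adh,
            c_rep=config.mechanics.c_rep,
            R_A_factor=config.mechanics.R_A_factor,
            nu=config.mechanics.nu,
        )
        self.schedule = Schedule.from_config(config.schedule)
        self.t = 0.0
        self.injury_fraction = 0.0
        self.v_pre: float | None = None
        self.n_remnant: int | None = None
        self.divisions_at_cut = 0
        self.initial_vessels = len(self.env.dirichlet_voxels)
        self.vessels_added = 0
        self.records: list[dict] = []
        self._o2_idx = self.env.substrate_index(OXYGEN)
        self._gf_idx = self.env.substrate_index(GROWTH_FACTOR)
        self._set_uptake()
        self._hepatectomy_done = False
        self._tumor_seeded = False
        self._refresh_sources()

    # ----------------------------------------------------------- set-up bits
    def _set_uptake(self) -> None:
        pop, cfg = self.pop, self.config
        hep_mask = pop.cell_type == HEPATOCYTE
        pop.uptake[hep_mask, self._o2_idx] = cfg.hepatocyte.o2_uptake
        pop.uptake[~hep_mask, self._o2_idx] = cfg.cancer.o2_uptake
        pop.uptake[~pop.alive, :] = 0.0

    def _refresh_sources(self) -> None:
        """Re-derive voxel indices + source arrays after cells moved/changed."""
        pop = self.pop
        if len(pop) == 0:
            self._src = None
            return
        self._clip_to_domain()
        vox = self.env.mesh.voxel_of(pop.position)
        self._src = (vox, pop.V.copy(), pop.secretion, pop.rho_star, pop.uptake)

    def _clip_to_domain(self) -> None:
        lo = np.asarray(self.env.mesh.origin) + _EPS
        hi = lo + self.env.mesh.extent - 2 * _EPS
        np.clip(self.pop.position, lo, hi, out=self.pop.position)

    # --------------------------------------------------------------- metrics
    def liver_volume(self) -> float:
        pop = self.pop
        mask = pop.alive & (pop.cell_type == HEPATOCYTE)
        return float(pop.V[mask].sum())

    def tumor_volume(self) -> float:
        pop = self.pop
        mask = pop.alive & (pop.cell_type == CANCER)
        return float(pop.V[mask].sum())

    def ki67_fraction(self) -> float:
        pop = self.pop
        hep = pop.alive & (pop.cell_type == HEPATOCYTE)
        if not np.any(hep):
            return 0.0
        pos = pop.phase_mask("Ki67+pre") | pop.phase_mask("Ki67+post")
        return float(np.count_nonzero(pos & hep) / np.count_nonzero(hep))

    # ----------------------------------------------------------------- events
    def _fire_hepatectomy(self) -> None:
        cfg = self.config
        pop = self.pop
        self.v_pre = self.liver_volume()
        self.divisions_at_cut = pop.cum_divisions[HEPATOCYTE]
        achieved = liver_mod.perform_hepatectomy(
            pop, self.env, cfg.hepatectomy.fraction, self.tagged
        )
        self.injury_fraction = achieved
        self.n_remnant = int(np.count_nonzero(pop.alive & (pop.cell_type == HEPATOCYTE)))
        self._hepatectomy_done = True
        log.info(
            "hepatectomy at t=%.0f min: removed %.3f of liver volume, %d cells remain",
            self.t, achieved, len(pop),
        )
        if cfg.tumor.enabled and not self._tumor_seeded:
            seed_time = cfg.tumor.seed_time
            if seed_time is None or seed_time <= cfg.hepatectomy.time:
                self._fire_tumor_seed()
        self._refresh_sources()

    def _fire_tumor_seed(self) -> None:
        from .tumor import seed_tumor  # deferred: tumor builds on this module

        seed_tumor(
            self.pop,
            self.env,
            self.config.tumor,
            rng=self.rng_tumor,
            dur_scale=self.cancer_dur_scale,
        )
        self._set_uptake()
        self._tumor_seeded = True

    # ------------------------------------------------------------- regulation
    def _regulate(self) -> None:
        cfg = self.config
        pop = self.pop
        reg = cfg.regulation
        live = pop.alive
        hep = live & (pop.cell_type == HEPATOCYTE)
        can = live & (pop.cell_type == CANCER)
        if not np.any(live):
            return
        o2 = self.env.sample_many(pop.position, OXYGEN)
        gf = self.env.sample_many(pop.position, GROWTH_FACTOR)

        # hepatocytes: GF-driven hypertrophy and cycle entry, modulated by O2.
        # Enlargement follows rising GF promptly; enlargement up to
        # h_perm_cap is retained for good (ploidy-like committed growth),
        # while swelling beyond the cap reverses on the h_decay_time scale —
        # the observed partial shrink-back of regenerated hepatocytes.
        if np.any(hep):
            h_inst = liver_mod.hypertrophy_factor(
                gf, reg.gf_hyp, reg.gf_hyp_sat, reg.h_max
            )
            pop.hyper_peak = np.maximum(pop.hyper_peak, h_inst)
            h_floor = np.minimum(pop.hyper_peak, reg.h_perm_cap)
            target = np.maximum(h_inst, h_floor)
            decay = cfg.schedule.dt_cycle / reg.h_decay_time
            h_new = np.maximum(target, pop.hyper_h - decay * (pop.hyper_h - target))
            pop.hyper_h[hep] = h_new[hep]
            pop.set_hypertrophy(pop.hyper_h, mask=hep)
            rate = liver_mod.cycle_entry_rate(
                gf, reg.gf_prol, reg.gf_star, self.t_Kneg_hep
            )
            rate = rate * liver_mod.oxygen_entry_factor(
                o2, cfg.hepatocyte.o2_prol, cfg.hepatocyte.o2_sat
            )
            pop.entry_rate[hep] = rate[hep]

        # cancer cells: oxygen-gated entry only (no GF response)
        if np.any(can):
            crate = liver_mod.oxygen_entry_factor(
                o2, cfg.cancer.o2_prol, cfg.cancer.o2_sat
            ) / self.t_Kneg_cancer
            pop.entry_rate[can] = crate[can]

        # GF secretion by surviving hepatocytes, scaled by injury and shut
        # down as the liver volume approaches its regrowth set point
        if self._hepatectomy_done and self.v_pre:
            v_target = reg.v_target_factor(self.injury_fraction) * self.v_pre
            recovery = self.liver_volume() / v_target
            s = liver_mod.gf_secretion_rate(
                self.injury_fraction, reg.secretion_per_injury, recovery
            )
            pop.secretion[:, self._gf_idx] = np.where(hep, s, 0.0)
            pop.rho_star[:, self._gf_idx] = 1.0

        # necrosis on sustained critical hypoxia
        hypoxic = o2 < reg.o2_necrosis
        pop.hypoxic_time = np.where(hypoxic, pop.hypoxic_time + cfg.schedule.dt_cycle, 0.0)
        doomed = live & (pop.hypoxic_time > reg.necrosis_grace)
        if np.any(doomed):
            pop.start_death(np.flatnonzero(doomed), "necrotic_swelling")
            pop.uptake[doomed, :] = 0.0
            pop.secretion[doomed, :] = 0.0

    # -------------------------------------------------------------- main loop
    def _cycle_step(self) -> None:
        dt = self.config.schedule.dt_cycle
        pop = self.pop
        self._regulate()
        pop.update_volume(dt)
        pop.advance_phase(dt, self.rng_cycle)
        self._clip_to_domain()
        self._set_uptake()
        self.vessels_added += liver_mod.angiogenesis_update(
            pop, self.env, self.tagged & ~self._dirichlet_mask(),
            self.config.angiogenesis.cell_threshold,
        )
        self._refresh_sources()

    def _dirichlet_mask(self) -> np.ndarray:
        mask = np.zeros(self.env.mesh.shape, dtype=bool)
        for vox in self.env.dirichlet_voxels:
            mask[vox] = True
        return mask

    def _mechanics_step(self) -> None:
        pop = self.pop
        if len(pop) == 0:
            return
        dt = self.config.schedule.dt_mech
        # dying (not yet lysed) cells lose adhesion but keep repulsion;
        # lysed cells stop interacting entirely
        lysed = pop.phase == self.table.index("necrotic_lysed")
        adh_scale = np.where(pop.alive, 1.0, 0.0)
        radii = pop.radius
        active = ~lysed
        v = np.zeros((len(pop), 3))
        idx = np.flatnonzero(active)
        if idx.size:
            v[idx] = mechanics.net_velocities(
                pop.position[idx], radii[idx], self.mech,
                adhesion_scale=adh_scale[idx], rng=self.rng_mech,
            )
        mechanics.step_positions(
            pop.position, v, pop.v_prev, pop.has_prev, dt,
            max_radius=float(radii.max()) if len(pop) else None,
        )
        self._clip_to_domain()
        self._refresh_sources()

    def _diffusion_step(self) -> None:
        dt = self.config.schedule.dt_diffusion
        if self._src is not None:
            vox, vol, S, rho, U = self._src
            self.env.apply_cell_sources(vox, vol, S, rho, U, dt)
        self.env.step_diffusion(dt)

    def _record(self) -> None:
        pop = self.pop
        hep = pop.alive & (pop.cell_type == HEPATOCYTE)
        lv = self.liver_volume()
        hep_v = pop.V[hep]
        row = {
            "t_min": self.t,
            "t_day": self.t / DAY,
            "n_hepatocytes": int(np.count_nonzero(hep)),
            "n_cancer": int(np.count_nonzero(pop.alive & (pop.cell_type == CANCER))),
            "liver_volume": lv,
            "tumor_volume": self.tumor_volume(),
            "fold_level": lv / self.v_pre if self.v_pre else np.nan,
            "mean_cell_volume": float(hep_v.mean()) if hep_v.size else np.nan,
            "mean_cell_area": float(
                np.mean(np.pi * (3.0 * hep_v / (4.0 * np.pi)) ** (2.0 / 3.0))
            ) if hep_v.size else np.nan,
            "ki67_fraction": self.ki67_fraction(),
            "cum_divisions": pop.cum_divisions[HEPATOCYTE] - self.divisions_at_cut,
            "cum_divisions_cancer": pop.cum_divisions[CANCER],
            "vessel_count": len(self.env.dirichlet_voxels),
            "mean_gf": self.env.mean_concentration(GROWTH_FACTOR),
            "mean_o2": self.env.mean_concentration(OXYGEN),
        }
        self.records.append(row)

    def run(self) -> pd.DataFrame:
        sched = self.schedule
        cfg = self.config
        self._record()
        n_steps = int(round(sched.t_end / sched.dt_diffusion))
        for k in range(1, n_steps + 1):
            if (not self._hepatectomy_done) and self.t + sched.dt_diffusion >= (
                cfg.hepatectomy.time - _EPS
            ):
                self._fire_hepatectomy()
            self._diffusion_step()
            self.t = k * sched.dt_diffusion
            if self.t >= sched.t_mech - _EPS:
                self._mechanics_step()
                sched.t_mech += sched.dt_mech
            if self.t >= sched.t_cycle - _EPS:
                self._cycle_step()
                sched.t_cycle += sched.dt_cycle
            if self.t >= sched.t_save - _EPS:
                self._record()
                sched.t_save += sched.dt_save
        if not self.records or self.records[-1]["t_min"] < self.t - _EPS:
            self._record()
        return self.series()

    def series(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)


def run_regeneration(config: ScenarioConfig, seed: int | None = None) -> Simulation:
    """Run a partial-hepatectomy scenario; returns the finished simulation."""
    sim = Simulation(config, seed=seed)
    sim.run()
    return sim


# ------------------------------------------------------------------ fixtures
def make_fixture(name: str, seed: int = 0):
    """Small deterministic scenes for tests and examples.

    ``"two-cell"``       two overlapping cells (mechanics relaxation);
    ``"one-voxel"``      a single-voxel microenvironment (source/sink ODE);
    ``"mini-lobule"``    a ~0.2 mm liver with one triad ring;
    ``"toy-hepatectomy"``the mini lobule after a 50% resection.
    """
    from .config import (DomainConfig, HepatectomyConfig, LiverConfig,
                         ScheduleConfig)
    from .cycles import build_phase_table
    from .mesh import VoxelMesh
    from .microenv import Microenvironment, Substrate

    rng = np.random.default_rng(seed)
    if name == "two-cell":
        table = build_phase_table()
        pop = CellPopulation(table, n_substrates=0)
        pop.add_cells([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        return pop
    if name == "one-voxel":
        mesh = VoxelMesh(1, 1, 1, 10.0)
        return Microenvironment(mesh, [Substrate("tracer", D=0.0, lam=0.0)])
    if name in ("mini-lobule", "toy-hepatectomy"):
        cfg = ScenarioConfig(
            domain=DomainConfig(size=210.0, dx=30.0),
            liver=LiverConfig(radius=72.0, triad_spacing=60.0),
            hepatectomy=HepatectomyConfig(fraction=0.5, time=30.0),
            schedule=ScheduleConfig(dt_diffusion=2.0, dt_mech=6.0, dt_cycle=6.0,
                                    dt_save=60.0, t_end=60.0),
            seed=seed,
        )
        sim = Simulation(cfg)
        if name == "toy-hepatectomy":
            sim._fire_hepatectomy()
        return sim
    raise ValueError(f"unknown fixture {name!r}")
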