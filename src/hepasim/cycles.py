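"""Cell cycle and death cycles as directed phase graphs.

Phases are nodes; edges fire either after a fixed dwell time or
stochastically with exponential dwell (per-step probability
``1 - exp(-rate * dt)``).  The proliferative cycle follows the Ki-67
immunostain decomposition: a quiescent Ki-67− phase with a regulated
stochastic entry rate, a fixed-duration Ki-67+ pre-mitotic phase (S + G2 +
M) that ends in division, and a fixed-duration Ki-67+ post-mitotic phase
(residual Ki-67 degrading over roughly two half-lives) that both daughters
enter.  Death is modelled the same way: apoptosis is a single shrinking
phase removed at exit; necrosis swells, lyses stochastically, then
degrades and is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Phase",
    "CycleModel",
    "build_ki67_cycle",
    "build_death_models",
    "build_phase_table",
    "PhaseTable",
    "REGULATED",
]

#: sentinel rate meaning "per-cell rate supplied by the regulation layer"
REGULATED = "regulated"


@dataclass(frozen=True)
class Phase:
    """One node of a cycle/death graph.

    Exactly one of ``duration`` (fixed dwell, min) or ``rate`` (stochastic
    exit rate, 1/min, or :data:`REGULATED`) must be given; a phase with
    neither is absorbing.  ``entry_targets`` are volume-model overrides
    applied when a cell enters the phase (keys: ``f_F``, ``V_NS_star``,
    ``f_CN``, ``r_F``, ``r_N``, ``r_C``).
    """

    name: str
    duration: float | None = None
    rate: float | str | None = None
    next_phase: str | None = None
    division_at_exit: bool = False
    removal_at_exit: bool = False
    entry_targets: dict = field(default_factory=dict)
    #: fixed duration scales with the cell's per-type cycle-duration factor
    scalable: bool = False

    def __post_init__(self):
        if self.duration is not None and self.rate is not None:
            raise ValueError(f"phase {self.name!r}: give duration or rate, not both")
        if self.duration is not None and self.duration <= 0:
            raise ValueError(f"phase {self.name!r}: duration must be positive")
        if isinstance(self.rate, (int, float)) and self.rate < 0:
            raise ValueError(f"phase {self.name!r}: rate must be >= 0")
        if self.division_at_exit and self.removal_at_exit:
            raise ValueError(f"phase {self.name!r}: division and removal are exclusive")
        exits = self.duration is not None or self.rate is not None
        if (self.division_at_exit or self.removal_at_exit or self.next_phase) and not exits:
            raise ValueError(f"phase {self.name!r}: exit flags on an absorbing phase")


@dataclass(frozen=True)
class CycleModel:
    """A named directed graph of phases."""

    name: str
    phases: tuple[Phase, ...]

    def __post_init__(self):
        names = [p.name for p in self.phases]
        if len(set(names)) != len(names):
            raise ValueError("phase names must be unique")
        for p in self.phases:
            if p.next_phase is not None and p.next_phase not in names:
                raise ValueError(f"phase {p.name!r} points to unknown {p.next_phase!r}")
        # every phase reachable from the first
        reach = {names[0]}
        frontier = [names[0]]
        lookup = {p.name: p for p in self.phases}
        while frontier:
            nxt = lookup[frontier.pop()].next_phase
            if nxt is not None and nxt not in reach:
                reach.add(nxt)
                frontier.append(nxt)
        if reach != set(names):
            raise ValueError(f"cycle {self.name!r}: unreachable phases {set(names) - reach}")

    def phase_index(self, name: str) -> int:
        for i, p in enumerate(self.phases):
            if p.name == name:
                return i
        raise KeyError(name)


def build_ki67_cycle(
    t_pre: float = 780.0,
    t_post: float = 150.0,
    t_Kneg_mean: float | None = None,
    total_cycle: float | None = None,
) -> CycleModel:
    """Three-phase Ki-67 proliferative cycle.

    ``Ki67-`` exits with a regulated stochastic rate (set per cell by the
    growth-factor/oxygen regulation; its saturated value is
    ``1 / t_Kneg_mean``); ``Ki67+pre`` lasts ``t_pre`` minutes and divides at
    exit; both daughters enter ``Ki67+post`` which lasts ``t_post`` minutes
    (about two Ki-67 half-lives of 60–90 min).  If ``total_cycle`` is given
    instead of ``t_Kneg_mean``, the quiescent mean dwell at maximal entry is
    ``total_cycle - t_pre - t_post``, so the expected saturated cycle time is
    exactly ``total_cycle``.
    """
    if t_pre <= 0 or t_post <= 0:
        raise ValueError("phase durations must be positive")
    if total_cycle is not None:
        t_Kneg_mean = total_cycle - t_pre - t_post
    if t_Kneg_mean is None or t_Kneg_mean <= 0:
        raise ValueError("t_Kneg_mean must be positive (t_pre + t_post < total cycle)")
    phases = (
        Phase("Ki67-", rate=REGULATED, next_phase="Ki67+pre", scalable=True),
        Phase("Ki67+pre", duration=t_pre, next_phase="Ki67+post",
              division_at_exit=True, scalable=True),
        Phase("Ki67+post", duration=t_post, next_phase="Ki67-", scalable=True),
    )
    model = CycleModel("ki67", phases)
    object.__setattr__(model, "t_Kneg_mean", t_Kneg_mean)
    return model


def build_death_models(
    apoptosis_duration: float = 516.0,
    swelling_lysis_rate: float = 1.0 / 360.0,
    lysed_duration: float = 1440.0,
    swollen_fluid_fraction: float = 0.95,
) -> tuple[CycleModel, CycleModel]:
    """Apoptosis and necrosis death cycles.

    Apoptosis: one fixed-duration phase whose entry drives every target
    volume to zero (the cell shrinks until removal).  Necrosis: a swelling
    phase (elevated target fluid fraction, nuclear solids degrading) with a
    stochastic lysis edge, then a fixed degradation phase, removed at exit.
    """
    apoptosis = CycleModel(
        "apoptosis",
        (
            Phase(
                "apoptotic",
                duration=apoptosis_duration,
                removal_at_exit=True,
                entry_targets={"f_F": 0.0, "V_NS_star": 0.0, "f_CN": 0.0, "r_F": 0.05},
            ),
        ),
    )
    necrosis = CycleModel(
        "necrosis",
        (
            Phase(
                "necrotic_swelling",
                rate=swelling_lysis_rate,
                next_phase="necrotic_lysed",
                entry_targets={"f_F": swollen_fluid_fraction, "V_NS_star": 0.0},
            ),
            Phase(
                "necrotic_lysed",
                duration=lysed_duration,
                removal_at_exit=True,
                entry_targets={"f_F": 0.0, "V_NS_star": 0.0, "f_CN": 0.0},
            ),
        ),
    )
    return apoptosis, necrosis


class PhaseTable:
    """Flat array view of one or more cycle models, for vectorized stepping.

    Concatenates the phases of the given models into index space and exposes
    per-phase arrays (``duration``, ``rate``, ``next_index``, flags).  A NaN
    duration and NaN rate with ``regulated`` False marks an absorbing phase;
    ``regulated`` True means the exit rate is the cell's own regulated entry
    rate.
    """

    def __init__(self, models: list[CycleModel]):
        self.models = list(models)
        self.names: list[str] = []
        offsets = {}
        for m in self.models:
            offsets[m.name] = len(self.names)
            self.names.extend(p.name for p in m.phases)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("phase names collide across models")
        self.duration = np.full(n, np.nan)
        self.rate = np.full(n, np.nan)
        self.scalable = np.zeros(n, dtype=bool)
        self.regulated = np.zeros(n, dtype=bool)
        self.next_index = np.full(n, -1, dtype=np.int64)
        self.divides = np.zeros(n, dtype=bool)
        self.removes = np.zeros(n, dtype=bool)
        self.entry_targets: list[dict] = []
        k = 0
        for m in self.models:
            for p in m.phases:
                if p.duration is not None:
                    self.duration[k] = p.duration
                self.scalable[k] = p.scalable
                if p.rate == REGULATED:
                    self.regulated[k] = True
                elif p.rate is not None:
                    self.rate[k] = p.rate
                if p.next_phase is not None:
                    self.next_index[k] = offsets[m.name] + m.phase_index(p.next_phase)
                self.divides[k] = p.division_at_exit
                self.removes[k] = p.removal_at_exit
                self.entry_targets.append(dict(p.entry_targets))
                k += 1

    def index(self, phase_name: str) -> int:
        return self.names.index(phase_name)

    def __len__(self) -> int:
        return len(self.names)


def build_phase_table(
    cycle: CycleModel | None = None,
    total_cycle: float = 2016.0,
    **death_kwargs,
) -> PhaseTable:
    """Standard table: Ki-67 cycle followed by apoptosis and necrosis phases."""
    if cycle is None:
        cycle = build_ki67_cycle(total_cycle=total_cycle)
    apo, nec = build_death_models(**death_kwargs)
    return PhaseTable([cycle, apo, nec])
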