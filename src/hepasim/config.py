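"""Run configuration: nested dataclasses, YAML round-trip, validation.

All lengths are µm, times minutes, oxygen in mmHg, growth factor in
arbitrary units normalized so its secretion saturation density is 1.
The defaults are the calibrated reference scenario (see docs/methods.md);
every value can be overridden from a YAML file or programmatically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import yaml

__all__ = ["ScenarioConfig", "load_config", "DAY"]

DAY = 1440.0  # minutes


@dataclass(frozen=True)
class DomainConfig:
    size: float = 396.0       # cubic domain edge, µm
    dx: float = 36.0          # voxel edge, µm


@dataclass(frozen=True)
class SubstrateConfig:
    D: float
    lam: float
    dirichlet_value: float = 0.0
    initial_value: float = 0.0


@dataclass(frozen=True)
class CellTypeConfig:
    total_cycle: float          # mean cycle time at saturated entry, min
    t_pre: float = 780.0        # Ki-67+ pre-mitotic (S+G2+M), min
    t_post: float = 150.0       # Ki-67+ post-mitotic (two Ki-67 half-lives), min
    o2_uptake: float = 1.0      # 1/min
    o2_prol: float = 5.0        # mmHg, below which cycle entry stops
    o2_sat: float = 30.0        # mmHg, above which entry is not oxygen-limited


@dataclass(frozen=True)
class LiverConfig:
    radius: float = 130.0          # initial liver sphere radius, µm
    triad_spacing: float = 90.0    # portal-triad lattice constant, µm
    settle_time: float = 60.0      # pre-hepatectomy homeostasis, min


@dataclass(frozen=True)
class RegulationConfig:
    """Growth-factor regulation of hypertrophy and cycle entry.

    Hypertrophy targets ramp from 1 to ``h_max`` between ``gf_hyp`` and
    ``gf_hyp_sat``; the cycle-entry rate ramps from 0 to ``1/t_Kneg``
    between ``gf_prol`` and ``gf_star``.  The hypertrophy ramp sits below
    the proliferation ramp (``gf_hyp < gf_prol``, ``gf_hyp_sat`` of the
    order of ``gf_prol``), so mild injuries hypertrophy without
    proliferating while severe ones do both.
    """

    gf_hyp: float = 0.008
    gf_hyp_sat: float = 0.06
    gf_prol: float = 0.032
    gf_star: float = 0.037
    secretion_per_injury: float = 0.02    # per-cell GF secretion rate per unit resected fraction, 1/min
    h_max: float = 2.4                    # maximal target-volume scale factor
    h_decay_time: float = 1440.0          # min; transient-hypertrophy reversal time
    h_perm_cap: float = 1.35              # permanently retained enlargement cap
    # regrowth set point as a multiple of the pre-hepatectomy volume,
    # decreasing with injury severity: v_target = (intercept - slope * f) V_pre
    v_target_intercept: float = 1.22
    v_target_slope: float = 0.6
    o2_necrosis: float = 2.0              # mmHg
    necrosis_grace: float = 720.0         # min below threshold before necrosis

    def v_target_factor(self, fraction: float) -> float:
        return self.v_target_intercept - self.v_target_slope * fraction


@dataclass(frozen=True)
class HepatectomyConfig:
    fraction: float = 0.7
    time: float = 60.0     # simulation minute of the resection


@dataclass(frozen=True)
class TumorConfig:
    enabled: bool = False
    n_cells: int = 1
    placement: str = "random_surface"   # or "fixed"
    position: tuple[float, float, float] | None = None
    seed_time: float | None = None      # default: at hepatectomy


@dataclass(frozen=True)
class MechanicsConfig:
    c_adh: float = 0.06
    c_rep: float = 1.0
    R_A_factor: float = 1.25
    nu: float = 1.0


@dataclass(frozen=True)
class ScheduleConfig:
    dt_diffusion: float = 2.0
    dt_mech: float = 6.0
    dt_cycle: float = 6.0
    dt_save: float = 360.0
    t_end: float = 10 * DAY

    def __post_init__(self):
        if not (0 < self.dt_diffusion <= self.dt_mech <= self.dt_cycle):
            raise ValueError("need 0 < dt_diffusion <= dt_mech <= dt_cycle")
        if self.dt_save <= 0 or self.t_end < 0:
            raise ValueError("dt_save must be positive and t_end >= 0")


@dataclass(frozen=True)
class AngiogenesisConfig:
    cell_threshold: int = 5    # cells per tagged voxel that recruit a vessel


@dataclass(frozen=True)
class ScenarioConfig:
    domain: DomainConfig = field(default_factory=DomainConfig)
    oxygen: SubstrateConfig = field(
        default_factory=lambda: SubstrateConfig(
            D=2000.0, lam=0.01, dirichlet_value=60.0, initial_value=38.0
        )
    )
    growth_factor: SubstrateConfig = field(
        default_factory=lambda: SubstrateConfig(D=600.0, lam=0.006)
    )
    hepatocyte: CellTypeConfig = field(
        default_factory=lambda: CellTypeConfig(total_cycle=2016.0)
    )
    cancer: CellTypeConfig = field(
        default_factory=lambda: CellTypeConfig(
            total_cycle=2316.0, o2_prol=14.0, o2_sat=40.0
        )
    )
    liver: LiverConfig = field(default_factory=LiverConfig)
    regulation: RegulationConfig = field(default_factory=RegulationConfig)
    hepatectomy: HepatectomyConfig = field(default_factory=HepatectomyConfig)
    tumor: TumorConfig = field(default_factory=TumorConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    angiogenesis: AngiogenesisConfig = field(default_factory=AngiogenesisConfig)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.hepatectomy.fraction < 1.0):
            raise ValueError("hepatectomy fraction must lie in (0, 1)")
        r = self.regulation
        if not (0.0 <= r.gf_hyp < r.gf_hyp_sat and r.gf_hyp < r.gf_prol < r.gf_star):
            raise ValueError(
                "need 0 <= gf_hyp < gf_hyp_sat and gf_hyp < gf_prol < gf_star"
            )
        for ct in (self.hepatocyte, self.cancer):
            if ct.total_cycle <= ct.t_pre + ct.t_post:
                raise ValueError("total cycle must exceed t_pre + t_post")

    # ------------------------------------------------------------- mutation
    def with_overrides(self, **sections) -> "ScenarioConfig":
        """Replace whole sections, e.g. ``with_overrides(tumor=TumorConfig(...))``."""
        return replace(self, **sections)

    def with_scaled_parameter(self, name: str, factor: float) -> "ScenarioConfig":
        """Scale one named sensitivity input by ``factor`` (e.g. 0.9 or 1.1)."""
        if name == "hepatocyte_o2_uptake":
            sec = replace(self.hepatocyte, o2_uptake=self.hepatocyte.o2_uptake * factor)
            return replace(self, hepatocyte=sec)
        if name == "cancer_o2_uptake":
            sec = replace(self.cancer, o2_uptake=self.cancer.o2_uptake * factor)
            return replace(self, cancer=sec)
        if name == "hepatocyte_cycle_duration":
            sec = _scale_cycle(self.hepatocyte, factor)
            return replace(self, hepatocyte=sec)
        if name == "cancer_cycle_duration":
            sec = _scale_cycle(self.cancer, factor)
            return replace(self, cancer=sec)
        if name == "adhesion":
            sec = replace(self.mechanics, c_adh=self.mechanics.c_adh * factor)
            return replace(self, mechanics=sec)
        if name == "repulsion":
            sec = replace(self.mechanics, c_rep=self.mechanics.c_rep * factor)
            return replace(self, mechanics=sec)
        raise ValueError(f"unknown parameter {name!r}")

    # ---------------------------------------------------------------- (de)io
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        section_types = {
            "domain": DomainConfig,
            "oxygen": SubstrateConfig,
            "growth_factor": SubstrateConfig,
            "hepatocyte": CellTypeConfig,
            "cancer": CellTypeConfig,
            "liver": LiverConfig,
            "regulation": RegulationConfig,
            "hepatectomy": HepatectomyConfig,
            "tumor": TumorConfig,
            "mechanics": MechanicsConfig,
            "schedule": ScheduleConfig,
            "angiogenesis": AngiogenesisConfig,
        }
        for key, value in data.items():
            if key in section_types:
                typ = section_types[key]
                known = {f.name for f in dataclasses.fields(typ)}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
                if key == "tumor" and value.get("position") is not None:
                    value = dict(value, position=tuple(value["position"]))
                kwargs[key] = typ(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _scale_cycle(ct: CellTypeConfig, factor: float) -> CellTypeConfig:
    return replace(
        ct,
        total_cycle=ct.total_cycle * factor,
        t_pre=ct.t_pre * factor,
        t_post=ct.t_post * factor,
    )


def load_config(path_or_none=None, **overrides) -> ScenarioConfig:
    cfg = ScenarioConfig.from_yaml(path_or_none) if path_or_none else ScenarioConfig()
    return cfg.with_overrides(**overrides) if overrides else cfg
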