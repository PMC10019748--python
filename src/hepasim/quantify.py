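"""Scenario metrics: fold-recovery, plateau detection, hypertrophy and
proliferation statistics, and the ±10% parameter-sensitivity driver."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import CellPopulation, HEPATOCYTE

__all__ = [
    "fold_level",
    "detect_plateau",
    "mean_divisions",
    "mean_cell_area",
    "mean_cell_volume",
    "SensitivityResult",
    "run_sensitivity",
    "SENSITIVITY_PARAMETERS",
]

log = logging.getLogger(__name__)


def fold_level(volumes, v_pre: float) -> np.ndarray:
    """Liver volume trajectory as a fraction of the pre-hepatectomy volume."""
    if v_pre <= 0:
        raise ValueError("pre-hepatectomy volume must be positive")
    return np.asarray(volumes, dtype=float) / v_pre


def detect_plateau(t_days, values, tol_per_day: float = 0.005):
    """First day after which the relative change per day stays below tol.

    Returns ``(day, level)`` where ``level`` is the mean value from the
    plateau day to the end of the series.  If the series never settles a
    sentinel ``(nan, nan)`` is returned with a warning.
    """
    t = np.asarray(t_days, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.size < 2:
        raise ValueError("need matching t/value series of length >= 2")
    dt = np.diff(t)
    scale = np.maximum(np.abs(v[1:]), 1e-300)
    rel_rate = np.abs(np.diff(v)) / scale / dt
    quiet = rel_rate < tol_per_day
    # last index where the rate still exceeded tol
    noisy = np.flatnonzero(~quiet)
    if noisy.size == 0:
        start = 0
    elif noisy[-1] == len(quiet) - 1:
        log.warning("series never plateaus below %.3g/day", tol_per_day)
        return (math.nan, math.nan)
    else:
        start = noisy[-1] + 1
    return (float(t[start]), float(np.mean(v[start:])))


def mean_divisions(
    n_initial: int, n_final: int, division_events: int
) -> dict[str, float]:
    """Divisions per initial remnant cell, by two conventions.

    ``events`` counts cumulative division events divided by the remnant
    population; ``log2_ratio`` is log2 of the population fold-increase,
    which matches the event count when divisions are near-synchronous and
    no cells are lost.
    """
    if n_initial <= 0:
        raise ValueError("n_initial must be positive")
    return {
        "events": division_events / n_initial,
        "log2_ratio": math.log2(n_final / n_initial) if n_final > 0 else -math.inf,
    }


def _equivalent_area(volumes: np.ndarray) -> np.ndarray:
    """Equatorial cross-section of the volume-equivalent sphere, µm²."""
    return np.pi * (3.0 * np.asarray(volumes) / (4.0 * np.pi)) ** (2.0 / 3.0)


def mean_cell_area(pop_or_volumes, cell_type: int = HEPATOCYTE) -> float:
    """Mean equivalent-sphere cross-section area of live cells (µm²)."""
    v = _live_volumes(pop_or_volumes, cell_type)
    return float(np.mean(_equivalent_area(v))) if v.size else math.nan


def mean_cell_volume(pop_or_volumes, cell_type: int = HEPATOCYTE) -> float:
    v = _live_volumes(pop_or_volumes, cell_type)
    return float(np.mean(v)) if v.size else math.nan


def _live_volumes(pop_or_volumes, cell_type: int) -> np.ndarray:
    if isinstance(pop_or_volumes, CellPopulation):
        pop = pop_or_volumes
        mask = pop.alive & (pop.cell_type == cell_type)
        return pop.V[mask]
    return np.asarray(pop_or_volumes, dtype=float)


# --------------------------------------------------------------- sensitivity

#: the scanned inputs: oxygen uptake of both cell types, both cycle
#: durations, and the two mechanics coefficients
SENSITIVITY_PARAMETERS = (
    "hepatocyte_o2_uptake",
    "cancer_o2_uptake",
    "hepatocyte_cycle_duration",
    "cancer_cycle_duration",
    "adhesion",
    "repulsion",
)


@dataclass
class SensitivityResult:
    """Relative change of the day-30 tumor size under one parameter nudge."""

    parameter: str
    direction: str  # "+10%" or "-10%"
    mean_change_pct: float
    sd_change_pct: float
    n: int
    mean_final_volume: float = math.nan


def run_sensitivity(
    config,
    params_to_vary=SENSITIVITY_PARAMETERS,
    delta: float = 0.10,
    n_reps: int = 4,
    seed: int = 0,
    baseline_stats: tuple[float, float] | None = None,
) -> list[SensitivityResult]:
    """±delta parameter scan of the recurrence scenario.

    Re-runs the hepatectomy-plus-tumor-clone simulation ``n_reps`` times per
    parameter and direction (fresh seeds per replicate, shared across arms
    so arms are paired) and reports the relative change of the final tumor
    volume against the baseline mean.  ``baseline_stats`` may supply a
    precomputed (mean, sd) of the baseline final volume to avoid re-running
    it.
    """
    from .tumor import run_recurrence_replicates  # local import to avoid cycle

    for p in params_to_vary:
        if p not in SENSITIVITY_PARAMETERS:
            raise ValueError(f"unknown sensitivity parameter {p!r}")
    if baseline_stats is None:
        base = run_recurrence_replicates(config, n_reps=n_reps, seed=seed)
        baseline_stats = (base["mean"], base["sd"])
    base_mean, base_sd = baseline_stats
    results = []
    for p in params_to_vary:
        for sign, tag in ((+1.0, "+10%"), (-1.0, "-10%")):
            varied = config.with_scaled_parameter(p, 1.0 + sign * delta)
            rep = run_recurrence_replicates(varied, n_reps=n_reps, seed=seed)
            finals = np.asarray(rep["finals"])
            change = (finals - base_mean) / base_mean * 100.0
            results.append(
                SensitivityResult(
                    parameter=p,
                    direction=tag,
                    mean_change_pct=float(change.mean()),
                    sd_change_pct=float(change.std(ddof=1)) if len(finals) > 1 else 0.0,
                    n=len(finals),
                    mean_final_volume=float(finals.mean()),
                )
            )
    return results


def sensitivity_table(results: list[SensitivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "direction": [r.direction for r in results],
            "mean_change_pct": [r.mean_change_pct for r in results],
            "sd_change_pct": [r.sd_change_pct for r in results],
            "n": [r.n for r in results],
        }
    )
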