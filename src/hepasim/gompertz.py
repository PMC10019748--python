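"""Gompertz tumor-growth law and specific-growth-rate estimation.

The Gompertz model

    V(t) = K · exp[ ln(V0/K) · exp(−α t) ]

describes saturating tumor growth toward a carrying capacity ``K`` (here
taken as the volume of the largest transplant-eligible tumor, a 50 mm
sphere, under the Milan criteria) from an initial volume ``V0`` with
specific growth rate ``α`` (1/day).  The two-point specific growth rate is

    α = ln(V2/V1) / (t2 − t1),

conventionally printed in %/day; the interface accepts "%/day" strings and
converts, so all arithmetic is done in 1/day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GompertzModel",
    "gompertz_volume",
    "specific_growth_rate",
    "time_to_volume",
    "sphere_volume",
    "parse_rate",
]


def parse_rate(alpha) -> float:
    """Normalize a growth rate to 1/day.

    Accepts a plain number (already 1/day) or a string like ``"0.053 %/day"``
    / ``"0.053%/day"`` which is divided by 100.
    """
    if isinstance(alpha, str):
        text = alpha.strip().lower()
        percent = "%" in text
        for token in ("%/day", "% / day", "%", "/day", "1/day", "per day"):
            text = text.replace(token, "")
        value = float(text.strip())
        return value / 100.0 if percent else value
    return float(alpha)


def sphere_volume(diameter_mm: float) -> float:
    """Volume (mm³) of a sphere given its diameter in mm."""
    return np.pi * diameter_mm**3 / 6.0


@dataclass(frozen=True)
class GompertzModel:
    """Gompertz growth law with carrying capacity K, initial volume V0 (mm³)
    and specific growth rate alpha (1/day; "%/day" strings accepted)."""

    K: float
    V0: float
    alpha: float

    def __post_init__(self):
        object.__setattr__(self, "alpha", parse_rate(self.alpha))
        if self.K <= 0 or self.V0 <= 0:
            raise ValueError("K and V0 must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def volume(self, t) -> np.ndarray | float:
        return gompertz_volume(self, t)

    def time_to_volume(self, v_target: float) -> float:
        return time_to_volume(self, v_target)


def gompertz_volume(model: GompertzModel, t) -> np.ndarray | float:
    """Evaluate V(t) = K exp[ln(V0/K) exp(−α t)] for t in days (t ≥ 0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = model.K * np.exp(np.log(model.V0 / model.K) * np.exp(-model.alpha * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def specific_growth_rate(V1: float, V2: float, t1: float, t2: float) -> float:
    """Two-point specific growth rate α = ln(V2/V1)/(t2 − t1), in 1/day.

    Invariant to rescaling both volumes by a common factor.
    """
    if V1 <= 0 or V2 <= 0:
        raise ValueError("volumes must be positive")
    if t2 == t1:
        raise ValueError("measurement times must differ")
    if t2 < t1:
        raise ValueError("t2 must be later than t1")
    return float(np.log(V2 / V1) / (t2 - t1))


def time_to_volume(model: GompertzModel, v_target: float) -> float:
    """Invert the growth law: the day at which V(t) = v_target.

    Valid for V0 ≤ v_target < K (growth scenarios); exact closed form
    t = −(1/α) ln[ ln(v_target/K) / ln(V0/K) ].
    """
    if not (model.V0 <= v_target < model.K):
        raise ValueError(
            f"target volume must lie in [V0, K) = [{model.V0}, {model.K})"
        )
    ratio = np.log(v_target / model.K) / np.log(model.V0 / model.K)
    return float(-np.log(ratio) / model.alpha)
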