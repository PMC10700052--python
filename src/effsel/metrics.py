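"""Summary statistics for fluctuating-selection trajectories.

Two single-number fitness summaries are compared throughout the package:

* **geometric mean fitness** f_G = (prod f_i)^(1/n), the classical summary,
  computed from the fitness values alone;
* **effective fitness** f_E = (0.5 + Δ̄s) / (0.5 - Δ̄s), the fitness that would
  produce the trajectory's mean per-generation selection change Δ̄s at
  frequency 0.5 — it uses the frequency trajectory through the Δs terms.

The **relative selection effect** C = ΣΔs / (|ΣΔs| + |ΣΔd|) measures the
signed share of selection in the total frequency change; |C| below a cutoff
(0.05 by default) defines effective neutrality of the realized process.
Undefined values (zero denominator) are represented as NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .wfsim import Trajectory

__all__ = [
    "MetricsSummary",
    "geometric_mean_fitness",
    "effective_fitness",
    "mean_delta_s_from_fe",
    "relative_selection_effect",
    "is_effectively_neutral",
    "predict_freq_from_fg",
    "predict_freq_from_fe",
    "summarize",
]


def geometric_mean_fitness(fitnesses) -> float:
    """Geometric mean of per-generation relative fitnesses, in log space."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one fitness value")
    if np.any(f <= 0):
        raise ValueError("all fitness values must be strictly positive")
    return float(np.exp(np.mean(np.log(f))))


def effective_fitness(delta_s_seq) -> float:
    """Effective fitness f_E = (0.5 + Δ̄s)/(0.5 - Δ̄s) from a Δs sequence."""
    ds = np.asarray(delta_s_seq, dtype=float)
    if ds.size == 0:
        raise ValueError("need at least one Δs value")
    m = float(np.mean(ds))
    if not -0.5 < m < 0.5:
        raise ValueError(f"mean Δs must lie in (-0.5, 0.5), got {m}")
    return (0.5 + m) / (0.5 - m)


def mean_delta_s_from_fe(f_e: float) -> float:
    """Inverse of :func:`effective_fitness`: Δ̄s = (f_E - 1) / (2 (f_E + 1))."""
    if f_e <= 0:
        raise ValueError("f_e must be strictly positive")
    return (f_e - 1.0) / (2.0 * (f_e + 1.0))


def relative_selection_effect(sum_delta_s: float, sum_delta_d: float) -> float:
    """C = ΣΔs / (|ΣΔs| + |ΣΔd|); NaN when the denominator is zero."""
    denom = abs(sum_delta_s) + abs(sum_delta_d)
    if denom == 0.0:
        return math.nan
    return sum_delta_s / denom


def is_effectively_neutral(c: float, cutoff: float = 0.05) -> Optional[bool]:
    """Whether |C| < cutoff (strict); None when C is undefined (NaN)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if c is None or (isinstance(c, float) and math.isnan(c)):
        return None
    if not -1.0 <= c <= 1.0:
        raise ValueError(f"C must lie in [-1, 1], got {c}")
    return abs(c) < cutoff


def predict_freq_from_fg(q0: float, f_g: float, n: int) -> float:
    """Frequency after n generations of constant selection f_g, no drift.

    q_G = q0 f_g^n / (1 + q0 (f_g^n - 1)); by the multiplicability of relative
    fitness this equals the no-drift outcome of any fitness sequence whose
    geometric mean is f_g.
    """
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must lie strictly in (0, 1)")
    if f_g <= 0:
        raise ValueError("f_g must be strictly positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    ratio = q0 / (1.0 - q0) * f_g ** n
    return ratio / (1.0 + ratio)


def predict_freq_from_fe(q0: float, f_e: float, n: int) -> float:
    """Linear predictor q_E = q0 + n Δ̄s with Δ̄s = (f_e - 1)/(2 (f_e + 1)).

    Deliberately NOT clamped to [0, 1]: the predictor is linear by definition
    and clamping would silently bias downstream error comparisons.  A warning
    is emitted when the prediction leaves [0, 1].
    """
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must lie strictly in (0, 1)")
    if n < 0:
        raise ValueError("n must be >= 0")
    pred = q0 + n * mean_delta_s_from_fe(f_e)
    if not 0.0 <= pred <= 1.0:
        warnings.warn(
            f"f_E-based frequency prediction {pred:.4g} lies outside [0, 1]",
            RuntimeWarning, stacklevel=2)
    return pred


@dataclass(frozen=True)
class MetricsSummary:
    """Per-trajectory summary: f_G, f_E, selection/drift sums, C, outcome."""

    n_generations: int
    f_g: float
    mean_delta_s: float
    f_e: float
    sum_delta_s: float
    sum_delta_d: float
    c_value: float  # NaN when undefined
    outcome: str

    @property
    def c_defined(self) -> bool:
        return not math.isnan(self.c_value)

    def to_dict(self) -> dict:
        d = {
            "n_generations": self.n_generations,
            "f_g": self.f_g,
            "mean_delta_s": self.mean_delta_s,
            "f_e": self.f_e,
            "sum_delta_s": self.sum_delta_s,
            "sum_delta_d": self.sum_delta_d,
            "c_value": None if math.isnan(self.c_value) else self.c_value,
            "outcome": self.outcome,
        }
        return d


def summarize(trajectory: Trajectory) -> MetricsSummary:
    """Compute all summary statistics for one trajectory.

    ΣΔd is taken as (q_final - q0) - ΣΔs, the drift-sum identity; with the
    simulator's exact per-generation decomposition this equals the sum of the
    recorded Δd terms.  The final (absorbing) generation's Δs, computed from
    the last interior frequency, is included.
    """
    if trajectory.n_generations < 1:
        raise ValueError("trajectory must contain at least one generation")
    sum_ds = float(np.sum(trajectory.delta_s))
    sum_dd = (trajectory.q_final - trajectory.q0) - sum_ds
    return MetricsSummary(
        n_generations=trajectory.n_generations,
        f_g=geometric_mean_fitness(trajectory.fitness),
        mean_delta_s=sum_ds / trajectory.n_generations,
        f_e=effective_fitness(trajectory.delta_s),
        sum_delta_s=sum_ds,
        sum_delta_d=sum_dd,
        c_value=relative_selection_effect(sum_ds, sum_dd),
        outcome=trajectory.outcome,
    )
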