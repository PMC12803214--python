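"""Limited-proteolysis kinetics and proteolysis-vs-HDX stability comparisons.

Intact-protein loss under limited proteolysis is summarized three ways:
a single-exponential decay fit F(t) = A exp(-k t) (amplitude bounded near 1
to absorb densitometry baseline drift), a trapezoidal area under the
fraction-intact curve as a fit-free protease-sensitivity metric, and a
single-timepoint protection delta under optimized conditions.  Per-protein
summaries from proteolysis and HDX are then compared by Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from scipy import stats

from .errors import UsageError, ValidationError

__all__ = [
    "ProteolysisTimecourse",
    "ExponentialDecayModel",
    "DecayFit",
    "StabilityComparison",
    "fit_exponential_decay",
    "timecourse_auc",
    "protection_single_timepoint",
    "pearson_correlation",
]


@dataclass
class ProteolysisTimecourse:
    """Fraction of intact protein versus incubation time (hours)."""

    protein: str
    condition: str  # "vehicle" or "stabilizer"
    times: list[float]
    fractions: list[float]
    clipped: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.shape != f.shape:
            raise ValidationError("times and fractions must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValidationError("fractions must lie in [0, 1] (clip before building)")


@dataclass
class DecayFit:
    """Results of a single-exponential proteolysis fit."""

    rate: float  # 1/h
    amplitude: float
    rate_stderr: float | None
    amplitude_stderr: float | None
    residual_norm: float
    converged: bool
    message: str = ""

    @property
    def half_life(self) -> float:
        return math.inf if self.rate == 0 else math.log(2.0) / self.rate

    def predict(self, times):
        return self.amplitude * np.exp(-self.rate * np.asarray(times, dtype=float))

    def summary(self) -> str:
        se = "--" if self.rate_stderr is None else f"{self.rate_stderr:.3g}"
        lines = [
            "Single-exponential proteolysis fit",
            "=" * 40,
            f"rate k (1/h):     {self.rate:.5g} +/- {se}",
            f"amplitude A:      {self.amplitude:.5g}",
            f"half-life (h):    {self.half_life:.5g}",
            f"residual norm:    {self.residual_norm:.3g}",
            f"converged:        {self.converged}",
        ]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


class ExponentialDecayModel:
    """F(t) = A exp(-k t) least-squares model for a proteolysis timecourse.

    A is free within [0.8, 1.2] (baseline drift); k >= 0.  Data that rise
    with time violate the decay model and are flagged, not raised, because
    not every protein's timecourse supports a rate estimate.
    """

    def __init__(self, times: Sequence[float], fractions: Sequence[float]) -> None:
        self.times = np.asarray(times, dtype=float)
        self.fractions = np.asarray(fractions, dtype=float)
        if self.times.size < 3:
            raise UsageError("need at least 3 timepoints to fit a decay")

    @classmethod
    def from_timecourse(cls, tc: ProteolysisTimecourse) -> "ExponentialDecayModel":
        return cls(tc.times, tc.fractions)

    def fit(self) -> DecayFit:
        t, f = self.times, self.fractions
        # crude slope-based initial rate
        positive = f > 0.05
        if positive.sum() >= 2 and f[positive].min() < f[positive].max():
            span = t[positive].max() - t[positive].min()
            drop = math.log(f[positive].max() / f[positive].min())
            k_init = max(drop / max(span, 1e-9), 1e-6)
        else:
            k_init = 0.1
        params = lmfit.Parameters()
        params.add("amplitude", value=min(max(float(f[0]), 0.8), 1.2), min=0.8, max=1.2)
        params.add("rate", value=k_init, min=0.0)

        def residual(p):
            return p["amplitude"].value * np.exp(-p["rate"].value * t) - f

        result = lmfit.minimize(residual, params, method="leastsq")
        p = result.params
        resid = residual(p)
        converged = bool(result.success)
        message = ""
        # rising data: the decay model is wrong regardless of optimizer status
        slope = np.polyfit(t, f, 1)[0]
        if slope > 0 and f[-1] > f[0]:
            converged = False
            message = "fractions increase with time; decay model implausible"
        elif not result.success:
            message = str(result.message)
        return DecayFit(
            rate=p["rate"].value,
            amplitude=p["amplitude"].value,
            rate_stderr=p["rate"].stderr,
            amplitude_stderr=p["amplitude"].stderr,
            residual_norm=float(np.linalg.norm(resid)),
            converged=converged,
            message=message,
        )


def fit_exponential_decay(tc: ProteolysisTimecourse) -> DecayFit:
    return ExponentialDecayModel.from_timecourse(tc).fit()


def timecourse_auc(tc: ProteolysisTimecourse) -> float:
    """Trapezoidal area under fraction-intact vs time, in fraction*hours."""
    if len(tc.times) < 2:
        raise UsageError("need at least 2 timepoints for an AUC")
    return float(np.trapezoid(tc.fractions, tc.times))


def protection_single_timepoint(vehicle: float, stabilized: float) -> float:
    """Protection delta: fraction intact with stabilizer minus vehicle."""
    for v in (vehicle, stabilized):
        if not 0.0 <= v <= 1.0:
            raise ValidationError("fractions must lie in [0, 1]")
    return stabilized - vehicle


@dataclass
class StabilityComparison:
    """Pearson comparison of two per-protein stability metrics."""

    proteins: list[str]
    x: list[float]
    y: list[float]
    x_label: str
    y_label: str
    pearson_r: float
    p_value: float


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and two-sided p value, with pairwise deletion of NaNs."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise UsageError("x and y must have equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise UsageError("need at least 3 paired finite values")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("correlation undefined: zero variance in an input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def compare_stability_metrics(
    proteins: Sequence[str],
    x: Sequence[float],
    y: Sequence[float],
    x_label: str = "proteolysis",
    y_label: str = "hdx",
) -> StabilityComparison:
    r, p = pearson_correlation(x, y)
    return StabilityComparison(
        proteins=list(proteins), x=list(map(float, x)), y=list(map(float, y)),
        x_label=x_label, y_label=y_label, pearson_r=r, p_value=p,
    )
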