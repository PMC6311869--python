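"""Derived immunological statistics and two-group comparisons.

Implements the T-cell exhaustion score, the macrophage polarization
profile and ratio, caliper tumor volume, antibody dosing, and the
pooled-variance two-sample Student's t-test (from raw values or from
summary statistics) with Bonferroni family-wise correction.

The pooled-variance (equal-variance) form of the t-test is used
throughout, not the Welch form: only the pooled form reproduces the
published p-values from the printed group summaries. Two degenerate
conventions are fixed for zero pooled variance: equal means give p = 1,
unequal means give p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .exceptions import ConfigurationError, InferenceError, UndefinedScoreError

__all__ = [
    "TCESInputs",
    "GroupSummary",
    "ComparisonResult",
    "MacrophageProfile",
    "TumorMeasurement",
    "compute_tces",
    "pooled_t_test_summary",
    "pooled_t_test_raw",
    "bonferroni_threshold",
    "compare_panels",
    "compare_group_summaries",
    "m1m2_ratio",
    "tumor_volume",
    "dose_micrograms",
    "summarize",
    "round_sig",
]


def round_sig(x: float, figures: int) -> float:
    """Round ``x`` to ``figures`` significant figures (0 and non-finite pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, figures - 1 - math.floor(math.log10(abs(x))))


def _check_pct(name: str, value: float) -> None:
    if not 0.0 <= value <= 100.0:
        raise ConfigurationError(f"{name} must lie in [0, 100], got {value}")


@dataclass(frozen=True)
class TCESInputs:
    """The six percentages entering the exhaustion score.

    Marker percentages (``pct_PD1_*``, ``pct_Tim3_*``) are percent of the
    corresponding T-cell subset positive for the marker; ``pct_CTL`` and
    ``pct_Th`` are the subsets' percent populations of the leukocyte gate.
    """

    pct_PD1_CTL: float
    pct_Tim3_CTL: float
    pct_PD1_Th: float
    pct_Tim3_Th: float
    pct_CTL: float
    pct_Th: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _check_pct(name, getattr(self, name))


def compute_tces(inputs: TCESInputs) -> float:
    """Exhaustion score: summed PD-1/Tim-3 marker percentages over summed
    T-cell percent populations. Undefined (raises) when no T cells."""
    denominator = inputs.pct_CTL + inputs.pct_Th
    if denominator <= 0.0:
        raise UndefinedScoreError("exhaustion score undefined: no T-cell population")
    numerator = (
        inputs.pct_PD1_CTL + inputs.pct_PD1_Th + inputs.pct_Tim3_CTL + inputs.pct_Tim3_Th
    )
    return numerator / denominator


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("SD must be >= 0")
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")


def summarize(values: Sequence[float]) -> GroupSummary:
    """Bessel-corrected mean/SD summary of raw per-animal values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ConfigurationError("cannot summarize an empty sample")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def pooled_t_test_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Two-tailed pooled-variance Student's t-test from summary statistics.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``. Zero pooled
    variance: p = 1 for equal means, p = 0 (infinite t) otherwise.
    """
    df = a.n + b.n - 2
    if df < 1:
        raise InferenceError("pooled t-test requires n_a + n_b >= 3")
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    diff = a.mean - b.mean
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df))
    return t, df, p


def pooled_t_test_raw(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled t-test on raw samples; identical to summarizing then testing."""
    if len(values_a) < 2 and len(values_b) < 2:
        raise InferenceError("pooled t-test requires at least one group with n >= 2")
    return pooled_t_test_summary(summarize(values_a), summarize(values_b))


def bonferroni_threshold(family_size: int, family_alpha: float = 0.05) -> float:
    """Per-comparison alpha after Bonferroni correction."""
    if family_size < 1:
        raise ConfigurationError("family_size must be >= 1")
    if not 0.0 < family_alpha <= 1.0:
        raise ConfigurationError("family_alpha must lie in (0, 1]")
    return family_alpha / family_size


@dataclass(frozen=True)
class ComparisonResult:
    """One row of a comparison table."""

    label: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    corrected_alpha: float
    significant: bool


def _compare(
    summaries_a: Mapping[str, GroupSummary],
    summaries_b: Mapping[str, GroupSummary],
    family_size: int | None,
    family_alpha: float,
) -> list[ComparisonResult]:
    if set(summaries_a) != set(summaries_b):
        only_a = sorted(set(summaries_a) - set(summaries_b))
        only_b = sorted(set(summaries_b) - set(summaries_a))
        raise ConfigurationError(
            f"population sets differ (only in A: {only_a}; only in B: {only_b})"
        )
    m = family_size if family_size is not None else len(summaries_a)
    alpha = bonferroni_threshold(m, family_alpha)
    results = []
    for label in summaries_a:
        a, b = summaries_a[label], summaries_b[label]
        t, df, p = pooled_t_test_summary(a, b)
        results.append(
            ComparisonResult(
                label=label,
                summary_a=a,
                summary_b=b,
                t_statistic=t,
                degrees_of_freedom=df,
                p_value=p,
                corrected_alpha=alpha,
                significant=p < alpha,
            )
        )
    return results


def compare_panels(
    cohort_a: Mapping[str, Sequence[float]],
    cohort_b: Mapping[str, Sequence[float]],
    family_size: int | None = None,
    family_alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Bonferroni-corrected pooled t-tests over per-animal percentage tables.

    ``cohort_a``/``cohort_b`` map population label to the per-animal values
    of that population. The family size defaults to the number of
    populations compared.
    """
    return _compare(
        {label: summarize(v) for label, v in cohort_a.items()},
        {label: summarize(v) for label, v in cohort_b.items()},
        family_size,
        family_alpha,
    )


def compare_group_summaries(
    summaries_a: Mapping[str, GroupSummary],
    summaries_b: Mapping[str, GroupSummary],
    family_size: int | None = None,
    family_alpha: float = 0.05,
) -> list[ComparisonResult]:
    """As :func:`compare_panels`, but directly from printed summary statistics."""
    return _compare(dict(summaries_a), dict(summaries_b), family_size, family_alpha)


@dataclass(frozen=True)
class MacrophageProfile:
    """Percent of the monocyte/macrophage gate positive for each marker.

    Cxcl9 and Nos2 are the pro-inflammatory (M1-like) markers; Tgm2 and
    Arg1 the anti-inflammatory (M2-like) markers.
    """

    pct_Tgm2: float
    pct_Arg1: float
    pct_Cxcl9: float
    pct_Nos2: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _check_pct(name, getattr(self, name))


def m1m2_ratio(profile: MacrophageProfile) -> float:
    """Summed M1 marker percentages over summed M2 marker percentages.

    The combining rule (sum of marker percentages per arm) is a
    documented convention of this package; swap this function to change it.
    """
    m2 = profile.pct_Tgm2 + profile.pct_Arg1
    if m2 <= 0.0:
        raise UndefinedScoreError("M1:M2 ratio undefined: no M2 marker expression")
    return (profile.pct_Cxcl9 + profile.pct_Nos2) / m2


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement in cm: greatest length and greatest width."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ConfigurationError("tumor dimensions must be positive")


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoidal caliper volume in cm^3: length x width^2 / 2."""
    return m.length * m.width**2 / 2.0


def dose_micrograms(mass_kg: float, dose_rate_mg_per_kg: float) -> float:
    """Antibody dose in micrograms for an animal of ``mass_kg`` kilograms."""
    if mass_kg <= 0:
        raise ConfigurationError("animal mass must be positive")
    if dose_rate_mg_per_kg < 0:
        raise ConfigurationError("dose rate must be >= 0")
    return mass_kg * dose_rate_mg_per_kg * 1000.0
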