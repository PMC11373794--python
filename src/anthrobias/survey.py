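"""Survey data-quality assessment for child anthropometry.

Reads per-child survey tables (columns ``age``, ``haz``, ``whz``, ``waz``,
``wt``), computes survey-weighted z-score moments per indicator, applies the
bias relationship to estimate the plausible prevalence-bias range, and runs
the age-quality diagnostics: the age-heaping ratio (fraction of children
reported within one month of 24, 36 or 48 months; 9/60 = 15% under a uniform
age distribution) and chi-square digit-preference tests.  Across a
collection of surveys, the Pearson correlation between the heaping ratio and
the height-for-age SD quantifies whether inflated SDs track age estimation.

Weighted moments use the population form with the sum of weights as
denominator: survey weights are expansion weights, and any common rescaling
leaves both moments unchanged.  Missing z-scores are dropped per indicator,
not listwise.  The bias estimate is a data-quality diagnostic only; it must
not be applied as a correction to reported prevalence, since it assumes the
distribution mean itself is accurate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .biasmap import REFERENCE_SD_RANGE, estimate_bias, realistic_bias_range
from .core import DEFAULT_THRESHOLD, NormalParams, prevalence_closed_form
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    SchemaError,
    UndefinedCorrelationError,
)

REQUIRED_COLUMNS = ("age", "haz", "whz", "waz", "wt")
INDICATORS = ("haz", "whz", "waz")
#: indicator names by conventional epidemiological label
INDICATOR_LABELS = {"haz": "stunting", "whz": "wasting", "waz": "underweight"}
DEFAULT_HEAPING_TARGETS = (24, 36, 48)
#: months eligible for survey inclusion: [0, 60)
AGE_RANGE_MONTHS = (0.0, 60.0)


@dataclass(frozen=True)
class SurveyTable:
    """Per-child records of one survey plus its identifying label."""

    data: pd.DataFrame
    survey_id: str

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class IndicatorSummary:
    """Weighted moments and estimated bias range for one indicator."""

    indicator: str
    weighted_mean: float
    weighted_sd: float
    estimated_prevalence: float
    bias_point: float
    bias_interval: Tuple[float, float]
    n_used: int
    n_missing: int

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "weighted_mean": self.weighted_mean,
            "weighted_sd": self.weighted_sd,
            "estimated_prevalence": self.estimated_prevalence,
            "bias_point": self.bias_point,
            "bias_interval": list(self.bias_interval),
            "n_used": self.n_used,
            "n_missing": self.n_missing,
        }


@dataclass(frozen=True)
class HeapingResult:
    """Age-heaping ratio and its configuration."""

    ratio: float
    qualifying_count: int
    total_count: int
    target_ages: Tuple[int, ...]
    window_halfwidth: int
    uniform_expectation: float

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "qualifying_count": self.qualifying_count,
            "total_count": self.total_count,
            "target_ages": list(self.target_ages),
            "window_halfwidth": self.window_halfwidth,
            "uniform_expectation": self.uniform_expectation,
        }


@dataclass(frozen=True)
class DigitPreferenceResult:
    """Observed digit/month frequencies with a uniform-null chi-square test."""

    counts: Dict[int, int]
    statistic: float
    p_value: float
    kind: str

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "counts": {str(k): v for k, v in self.counts.items()},
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two cross-survey statistics."""

    rho: float
    n_surveys: int
    x_label: str
    y_label: str


def read_survey(
    path,
    survey_id: Optional[str] = None,
    filter_age: bool = True,
    plausibility_filter: bool = False,
) -> SurveyTable:
    """Load a per-child CSV with columns exactly ``age,haz,whz,waz,wt``.

    Missing z-scores are preserved as NaN.  Rows outside the [0, 60)-month
    eligibility window are dropped when ``filter_age`` is set.  The optional
    ``plausibility_filter`` blanks z-scores beyond the conventional
    biological-plausibility limits (|haz| > 6, |whz| > 5, |waz| > 6); it is
    off by default since the assessment itself defines no such exclusion.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in REQUIRED_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = coerced
    if (df["wt"].isna() | (df["wt"] <= 0)).any():
        row = int(np.flatnonzero((df["wt"].isna() | (df["wt"] <= 0)).to_numpy())[0])
        raise SchemaError(f"{path}: non-positive or missing survey weight at row {row}")
    if df["age"].isna().any():
        row = int(np.flatnonzero(df["age"].isna().to_numpy())[0])
        raise SchemaError(f"{path}: missing age at row {row}")
    if filter_age:
        lo, hi = AGE_RANGE_MONTHS
        df = df[(df["age"] >= lo) & (df["age"] < hi)].reset_index(drop=True)
    if plausibility_filter:
        limits = {"haz": 6.0, "whz": 5.0, "waz": 6.0}
        for col, lim in limits.items():
            df.loc[df[col].abs() > lim, col] = np.nan
    if survey_id is None:
        import os

        survey_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SurveyTable(data=df, survey_id=survey_id)


def weighted_moments(table: SurveyTable, indicator: str) -> Tuple[float, float, int]:
    """Survey-weighted mean and SD of one indicator.

    mean = sum(w z) / sum(w);  sd = sqrt(sum(w (z - mean)^2) / sum(w)).
    """
    if indicator not in INDICATORS:
        raise InvalidInputError(f"unknown indicator {indicator!r}; expected one of {INDICATORS}")
    z = table.data[indicator].to_numpy(dtype=float)
    w = table.data["wt"].to_numpy(dtype=float)
    keep = ~np.isnan(z)
    z, w = z[keep], w[keep]
    if z.size < 2:
        raise InsufficientDataError(
            f"survey {table.survey_id!r}: need >= 2 non-missing {indicator} values, "
            f"got {z.size}"
        )
    wsum = w.sum()
    mean = float((w * z).sum() / wsum)
    sd = float(math.sqrt((w * (z - mean) ** 2).sum() / wsum))
    return mean, sd, int(z.size)


def assess_indicator(
    table: SurveyTable,
    indicator: str,
    threshold: float = DEFAULT_THRESHOLD,
    reference_sd: float = 1.0,
    reference_range: Tuple[float, float] = REFERENCE_SD_RANGE,
) -> IndicatorSummary:
    """Weighted moments plus the implied prevalence and bias range."""
    mean, sd, n_used = weighted_moments(table, indicator)
    prev = prevalence_closed_form(NormalParams(mean, sd), threshold).value
    bias_point = estimate_bias(mean, sd, threshold, reference_sd)
    rng = realistic_bias_range(mean, sd, threshold, reference_range)
    n_missing = int(table.data[indicator].isna().sum())
    return IndicatorSummary(
        indicator=indicator,
        weighted_mean=mean,
        weighted_sd=sd,
        estimated_prevalence=prev,
        bias_point=bias_point,
        bias_interval=rng.interval,
        n_used=n_used,
        n_missing=n_missing,
    )


def age_heaping_ratio(
    table: SurveyTable,
    target_ages: Sequence[int] = DEFAULT_HEAPING_TARGETS,
    window: int = 1,
    excluded_ages: Sequence[int] = (),
) -> HeapingResult:
    """Fraction of children with rounded age within ``window`` months of a target.

    Targets default to 24, 36 and 48 months; 12 months is not a target
    because many activity designs treat under-18-month children differently,
    so a 12-month cluster can reflect eligibility rather than estimation.
    The denominator counts every child in the survey; pass
    ``excluded_ages=(12,)`` to also drop children near an excluded cluster
    from the denominator.  The ratio is defined on raw counts and ignores
    survey weights.  Under a uniform 0-59-month age distribution the
    expected ratio is 9/60 = 15%.
    """
    if table.n == 0:
        raise InvalidInputError(f"survey {table.survey_id!r} has no records")
    months = np.rint(table.data["age"].to_numpy(dtype=float)).astype(int)
    qualifying = np.zeros(months.shape, dtype=bool)
    for t in target_ages:
        qualifying |= np.abs(months - t) <= window
    excluded = np.zeros(months.shape, dtype=bool)
    for t in excluded_ages:
        excluded |= np.abs(months - t) <= window
    qualifying &= ~excluded
    lo, hi = AGE_RANGE_MONTHS
    eligible_months = np.arange(int(lo), int(hi))
    q_months = np.zeros(eligible_months.shape, dtype=bool)
    for t in target_ages:
        q_months |= np.abs(eligible_months - t) <= window
    x_months = np.zeros(eligible_months.shape, dtype=bool)
    for t in excluded_ages:
        x_months |= np.abs(eligible_months - t) <= window
    q_months &= ~x_months
    total = int(np.count_nonzero(~excluded))
    denom_months = int(np.count_nonzero(~x_months))
    uniform_expectation = (
        0.0 if denom_months == 0 else int(np.count_nonzero(q_months)) / denom_months
    )
    if total == 0:
        raise InvalidInputError("heaping-ratio denominator is empty")
    return HeapingResult(
        ratio=int(np.count_nonzero(qualifying)) / total,
        qualifying_count=int(np.count_nonzero(qualifying)),
        total_count=total,
        target_ages=tuple(int(t) for t in target_ages),
        window_halfwidth=int(window),
        uniform_expectation=float(uniform_expectation),
    )


def digit_preference_test(values: Iterable[float], kind: str) -> DigitPreferenceResult:
    """Chi-square goodness-of-fit of digit frequencies against a uniform null.

    ``terminal_digit`` bins the first decimal digit (0-9) of each value, the
    usual check for rounded height/weight readings; ``integer_month`` bins
    rounded ages over the 0-59-month range.  The uniform null is a stated
    modelling choice for "no preference"; a small p-value flags clustering.
    """
    values = np.asarray(list(values), dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise InvalidInputError("digit preference test needs at least one value")
    if values.size < 30:
        import warnings

        warnings.warn(
            f"digit preference test on only {values.size} values; chi-square "
            "approximation is unreliable below ~30",
            stacklevel=2,
        )
    if kind == "terminal_digit":
        digits = np.rint(values * 10).astype(np.int64) % 10
        bins = np.arange(10)
    elif kind == "integer_month":
        digits = np.rint(values).astype(np.int64)
        bins = np.arange(int(AGE_RANGE_MONTHS[0]), int(AGE_RANGE_MONTHS[1]))
    else:
        raise InvalidInputError(f"unknown kind {kind!r}")
    counts = {int(b): int(np.count_nonzero(digits == b)) for b in bins}
    observed = np.array([counts[int(b)] for b in bins], dtype=float)
    stat, p = stats.chisquare(observed)
    return DigitPreferenceResult(
        counts=counts, statistic=float(stat), p_value=float(p), kind=kind
    )


def heaping_sd_correlation(
    pairs: Sequence[Tuple[HeapingResult, IndicatorSummary]],
    x_label: str = "age_heaping_ratio",
    y_label: str = "haz_weighted_sd",
) -> CorrelationResult:
    """Pearson correlation of heaping ratio vs height-for-age SD across surveys."""
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"correlation needs >= 3 surveys, got {len(pairs)}"
        )
    x = np.array([h.ratio for h, _ in pairs], dtype=float)
    y = np.array([s.weighted_sd for _, s in pairs], dtype=float)
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        raise UndefinedCorrelationError(
            "correlation undefined: (near-)zero variance in heaping ratio or SD"
        )
    rho = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(rho=rho, n_surveys=len(pairs), x_label=x_label, y_label=y_label)


def assess_survey(
    table: SurveyTable,
    threshold: float = DEFAULT_THRESHOLD,
    reference_sd: float = 1.0,
    reference_range: Tuple[float, float] = REFERENCE_SD_RANGE,
    heaping_targets: Sequence[int] = DEFAULT_HEAPING_TARGETS,
) -> dict:
    """Full per-survey report: three indicator summaries plus age diagnostics.

    Indicators with fewer than two non-missing values are reported as
    unavailable rather than aborting the whole survey.
    """
    indicators = {}
    for ind in INDICATORS:
        try:
            indicators[ind] = assess_indicator(
                table, ind, threshold, reference_sd, reference_range
            ).to_dict()
        except InsufficientDataError as exc:
            indicators[ind] = {"error": str(exc)}
    heaping = age_heaping_ratio(table, target_ages=heaping_targets)
    age_digits = digit_preference_test(table.data["age"], kind="integer_month")
    return {
        "survey_id": table.survey_id,
        "n_children": table.n,
        "indicators": indicators,
        "age_heaping": heaping.to_dict(),
        "age_digit_preference": age_digits.to_dict(),
    }


def assess_collection(
    tables: Sequence[SurveyTable],
    threshold: float = DEFAULT_THRESHOLD,
    reference_sd: float = 1.0,
) -> Tuple[pd.DataFrame, CorrelationResult]:
    """Cross-survey summary table plus the heaping-vs-HAZ-SD correlation."""
    rows = []
    pairs = []
    for table in tables:
        heaping = age_heaping_ratio(table)
        summary = assess_indicator(table, "haz", threshold, reference_sd)
        pairs.append((heaping, summary))
        rows.append(
            {
                "survey_id": table.survey_id,
                "n_children": table.n,
                "heaping_ratio": heaping.ratio,
                "haz_weighted_mean": summary.weighted_mean,
                "haz_weighted_sd": summary.weighted_sd,
                "haz_bias_point": summary.bias_point,
                "haz_bias_low": summary.bias_interval[0],
                "haz_bias_high": summary.bias_interval[1],
            }
        )
    corr = heaping_sd_correlation(pairs)
    return pd.DataFrame(rows), corr
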