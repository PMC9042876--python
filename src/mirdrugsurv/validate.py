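"""External-cohort validation of discovered markers by median split.

A global threshold learned on one platform's scale is meaningless on
another (e.g., RNA-seq vs microarray), so validation cohorts are split at
each cohort's own per-feature median: samples above the median form the
highly-expressed class, the rest the lowly-expressed class, and a log-rank
test measures whether the marker stratifies the cohort's survival
endpoint. The endpoint (OS / DFS / DRFS ...) is metadata only — any
(time, event) pair is handled identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import NoValidThreshold
from .io import ExpressionMatrix
from .stats import LogrankResult, SurvivalSample, better_survival_class, logrank_test

__all__ = ["ValidationCohort", "ValidationResult", "median_split", "validate_marker"]


@dataclass
class ValidationCohort:
    """An independent cohort: platform-native log-scale expression plus one
    survival endpoint per sample."""

    expression: ExpressionMatrix
    samples: Mapping[str, SurvivalSample]  # keyed by sample id
    endpoint_label: str = "OS"


@dataclass
class ValidationResult:
    feature_id: str
    endpoint_label: str
    available: bool
    tested: bool
    n_low: int = 0
    n_high: int = 0
    logrank: LogrankResult | None = None
    direction: str | None = None  # 'high_better' | 'low_better'
    note: str = ""


def median_split(values) -> dict[str, str]:
    """Split samples at the median of their values: 'high' strictly above,
    'low' at or below. Missing values are unlabeled; an all-equal vector
    has no valid split and raises :class:`NoValidThreshold`."""
    s = pd.Series(values, dtype=float)
    s = s.dropna()
    if s.size < 2:
        raise NoValidThreshold(f"need >= 2 non-missing values, got {s.size}")
    med = float(s.median())
    if s.min() == s.max():
        raise NoValidThreshold("all values equal: no valid median split")
    return {str(k): ("high" if v > med else "low") for k, v in s.items()}


def validate_marker(feature_id: str, cohort: ValidationCohort) -> ValidationResult:
    """Median-split + log-rank for one marker in one cohort.

    Markers absent from the cohort's expression matrix (platform coverage
    differs) are reported as unavailable rather than raising; degenerate
    splits (constant expression, or an empty class) are reported untested.
    """
    if feature_id not in cohort.expression:
        return ValidationResult(
            feature_id, cohort.endpoint_label, available=False, tested=False,
            note="feature not present in cohort expression",
        )
    vals = cohort.expression.feature_values(feature_id)
    vals = vals[[s in cohort.samples for s in vals.index]]
    try:
        labels = median_split(vals)
    except NoValidThreshold as exc:
        return ValidationResult(
            feature_id, cohort.endpoint_label, available=True, tested=False,
            note=str(exc),
        )
    low = [cohort.samples[s] for s, c in labels.items() if c == "low"]
    high = [cohort.samples[s] for s, c in labels.items() if c == "high"]
    if not low or not high:
        return ValidationResult(
            feature_id, cohort.endpoint_label, available=True, tested=False,
            n_low=len(low), n_high=len(high), note="empty class after split",
        )
    lr = logrank_test(low, high)
    direction = (
        "high_better" if better_survival_class(low, high) == "high" else "low_better"
    )
    return ValidationResult(
        feature_id,
        cohort.endpoint_label,
        available=True,
        tested=True,
        n_low=len(low),
        n_high=len(high),
        logrank=lr,
        direction=direction,
    )
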