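"""Global step-function binarization of expression features.

Each feature's expression values across *all* patients are sorted and a
one-step (two-level) function is fitted by least squares: for every
breakpoint b the fitted curve is (mean of the first b sorted values, mean
of the remaining n-b). The breakpoint minimizing the total squared error
defines a global threshold — the midpoint of the two segment means — used
to split patients into lowly- and highly-expressed classes. Because the
threshold is derived from all patients across all cancer types it gives a
robust, cohort-wide definition of "high" and "low" for that feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import NoValidThreshold

__all__ = ["StepThreshold", "fit_step_threshold", "fit_all_thresholds", "assign_classes"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepThreshold:
    """A fitted step-function threshold for one feature.

    ``breakpoint_index`` is the number of sorted values in the low segment;
    ``sse`` the total within-segment squared error at that breakpoint;
    ``n_used`` the number of non-missing values the fit saw.
    """

    feature_id: str
    threshold: float
    breakpoint_index: int
    sse: float
    n_used: int


def fit_step_threshold(values, feature_id: str = "") -> StepThreshold:
    """Least-squares one-step fit on the sorted non-missing values.

    Ties in SSE break toward the smallest breakpoint. Raises
    :class:`NoValidThreshold` for fewer than two non-missing values or a
    constant vector.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise NoValidThreshold(
            f"feature {feature_id!r}: need >= 2 non-missing values, got {n}"
        )
    xs = np.sort(x)
    if xs[0] == xs[-1]:
        raise NoValidThreshold(f"feature {feature_id!r}: all values equal")

    cs = np.cumsum(xs)
    cs2 = np.cumsum(xs * xs)
    b = np.arange(1, n)  # candidate breakpoints: low segment sizes 1..n-1
    left_sum, left_sum2 = cs[b - 1], cs2[b - 1]
    right_sum, right_sum2 = cs[-1] - left_sum, cs2[-1] - left_sum2
    sse = (left_sum2 - left_sum**2 / b) + (right_sum2 - right_sum**2 / (n - b))
    best = int(np.argmin(sse))  # argmin takes the first minimum: smallest b
    bi = best + 1
    mean_low = left_sum[best] / bi
    mean_high = right_sum[best] / (n - bi)
    return StepThreshold(
        feature_id=feature_id,
        threshold=float((mean_low + mean_high) / 2.0),
        breakpoint_index=bi,
        sse=float(max(sse[best], 0.0)),
        n_used=n,
    )


def fit_all_thresholds(expression) -> dict[str, StepThreshold]:
    """Fit a global threshold for every feature of an expression matrix.

    Degenerate features (constant, or < 2 non-missing values) are skipped
    and logged; downstream screens simply never test them.
    """
    out: dict[str, StepThreshold] = {}
    for i, fid in enumerate(expression.feature_ids):
        try:
            out[fid] = fit_step_threshold(expression.values[i], feature_id=fid)
        except NoValidThreshold as exc:
            log.info("skipping feature without a valid threshold: %s", exc)
    return out


def assign_classes(values: Mapping[str, float] | pd.Series, t: StepThreshold) -> dict[str, str]:
    """Label each sample 'high' (value > threshold) or 'low' (<= threshold).

    Missing values leave the sample unlabeled (absent from the result).
    """
    if isinstance(values, pd.Series):
        items = values.items()
    else:
        items = values.items()
    out = {}
    for sid, v in items:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        out[sid] = "high" if v > t.threshold else "low"
    return out
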