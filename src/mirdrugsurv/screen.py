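"""Cancer-drug group construction and the drug-specific survival screen.

Patients sharing one cancer type and one standardized drug form a
cancer-drug group (a patient belongs to every group they qualify for).
Within each group of at least ``min_group_size`` patients, every feature is
split into highly- and lowly-expressed classes by its *global* step
threshold; features with fewer than ``min_class_size`` patients in either
class are gated out, the rest are tested by log-rank, and the resulting
p-values are Benjamini-Hochberg adjusted within the group. A marker is
drug-specific when it is group-significant (FDR below threshold) but the
identical test run on all patients of the cancer type — same global
threshold, same class gate, FDR over all features tested cancer-wide — is
not significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .binarize import StepThreshold
from .io import UNMAPPED, ClinicalRecord, DrugRecord, ExpressionMatrix
from .stats import (
    LogrankResult,
    _better_class_arrays,
    _logrank_arrays,
    bh_adjust,
)

__all__ = [
    "CancerDrugGroup",
    "MarkerResult",
    "build_groups",
    "enumerate_combinations",
    "screen_group",
    "test_features_in_group",
    "drug_specific_filter",
    "group_census",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_GROUP_SIZE = 15
DEFAULT_MIN_CLASS_SIZE = 5
DEFAULT_FDR_THRESHOLD = 0.1


@dataclass(frozen=True)
class CancerDrugGroup:
    """All eligible patients of one cancer type exposed to one drug."""

    cancer_type: str
    drug: str
    patient_ids: frozenset[str]

    def __len__(self):
        return len(self.patient_ids)


@dataclass
class MarkerResult:
    """Screen outcome for one (feature, cancer-drug group) combination."""

    feature_id: str
    cancer_type: str
    drug: str
    n_low: int
    n_high: int
    gated: bool = False
    logrank: LogrankResult | None = None
    p_value: float | None = None
    fdr: float | None = None
    cancer_level_p: float | None = None
    drug_specific: bool | None = None
    better_survival_class: str | None = None

    @property
    def tested(self) -> bool:
        return not self.gated and self.logrank is not None

    def significant(self, fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> bool:
        return self.tested and self.fdr is not None and self.fdr < fdr_threshold


def build_groups(
    clinical: Iterable[ClinicalRecord],
    drugs: Iterable[DrugRecord],
    expression: ExpressionMatrix,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> list[CancerDrugGroup]:
    """One group per (cancer type, standardized drug) with at least
    ``min_group_size`` patients having clinical outcome, that drug exposure,
    and an expression profile. Exposure uses set semantics: repeated records
    of one drug for one patient count once."""
    by_patient = {r.patient_id: r for r in clinical}
    samples = set(expression.sample_ids)
    membership: dict[tuple[str, str], set[str]] = {}
    for d in drugs:
        if d.standardized_name == UNMAPPED:
            continue
        rec = by_patient.get(d.patient_id)
        if rec is None or d.patient_id not in samples:
            continue
        membership.setdefault((rec.cancer_type, d.standardized_name), set()).add(
            d.patient_id
        )
    groups = [
        CancerDrugGroup(c, drug, frozenset(pids))
        for (c, drug), pids in membership.items()
        if len(pids) >= min_group_size
    ]
    groups.sort(key=lambda g: (g.cancer_type, g.drug))
    return groups


def enumerate_combinations(
    groups: Sequence[CancerDrugGroup], feature_ids: Sequence[str]
) -> tuple[int, Iterator[tuple[str, CancerDrugGroup]]]:
    """Count and iterate the Cartesian product of features and groups — the
    number of combinations examined before the class-size gate."""
    count = len(groups) * len(feature_ids)

    def _iter():
        for g in groups:
            for f in feature_ids:
                yield f, g

    return count, _iter()


def _survival_arrays(
    patient_ids: Sequence[str], clinical_by_id: Mapping[str, ClinicalRecord]
) -> tuple[np.ndarray, np.ndarray]:
    recs = [clinical_by_id[p] for p in patient_ids]
    return (
        np.array([r.survival_time for r in recs], dtype=float),
        np.array([r.event for r in recs], dtype=int),
    )


def test_features_in_group(
    group: CancerDrugGroup,
    expression: ExpressionMatrix,
    thresholds: Mapping[str, StepThreshold],
    clinical_by_id: Mapping[str, ClinicalRecord],
    feature_ids: Sequence[str] | None = None,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> list[MarkerResult]:
    """Screen a set of features within one group.

    Classes come from each feature's global threshold restricted to group
    members; features failing the class-size gate are recorded as gated;
    tested features get a log-rank p, a survival-direction call by the
    restricted-mean comparator, and (after all features) a BH-adjusted FDR
    computed across the tested features of this call.
    """
    members = sorted(group.patient_ids & set(expression.sample_ids))
    if feature_ids is None:
        feature_ids = [f for f in expression.feature_ids if f in thresholds]
    sub = expression.sample_columns(members)  # features x members
    times, events = _survival_arrays(members, clinical_by_id)
    fidx = {f: i for i, f in enumerate(expression.feature_ids)}

    results: list[MarkerResult] = []
    tested_idx: list[int] = []
    for fid in feature_ids:
        t = thresholds.get(fid)
        if t is None or fid not in fidx:
            continue
        vals = sub[fidx[fid]]
        present = ~np.isnan(vals)
        is_high = present & (vals > t.threshold)
        is_low = present & ~is_high
        n_low, n_high = int(is_low.sum()), int(is_high.sum())
        res = MarkerResult(fid, group.cancer_type, group.drug, n_low, n_high)
        if n_low < min_class_size or n_high < min_class_size:
            res.gated = True
        else:
            lr = _logrank_arrays(
                times[is_low], events[is_low], times[is_high], events[is_high]
            )
            res.logrank = lr
            res.p_value = lr.p_value
            res.better_survival_class = _better_class_arrays(
                times[is_low], events[is_low], times[is_high], events[is_high]
            )
            tested_idx.append(len(results))
        results.append(res)

    if tested_idx:
        fdrs = bh_adjust([results[i].p_value for i in tested_idx])
        for i, q in zip(tested_idx, fdrs):
            results[i].fdr = float(q)
    return results


def screen_group(
    group: CancerDrugGroup,
    expression: ExpressionMatrix,
    thresholds: Mapping[str, StepThreshold],
    clinical_by_id: Mapping[str, ClinicalRecord],
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> list[MarkerResult]:
    """Screen every thresholded feature of ``expression`` within one group."""
    return test_features_in_group(
        group, expression, thresholds, clinical_by_id, None, min_class_size
    )


def drug_specific_filter(
    group_results: Iterable[MarkerResult],
    clinical: Iterable[ClinicalRecord],
    expression: ExpressionMatrix,
    thresholds: Mapping[str, StepThreshold],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    mode: str = "adjusted",
    cancer_alpha: float = 0.05,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> list[MarkerResult]:
    """Flag group-significant markers that are *not* significant cancer-wide.

    The cancer-wide comparison reruns the identical stratified test on all
    patients of the cancer type that have clinical and expression data
    (drug records not required), with FDR over all features tested
    cancer-wide. ``mode='adjusted'`` compares the cancer-wide BH value
    against ``fdr_threshold``; ``mode='raw'`` compares the raw cancer-wide p
    against ``cancer_alpha``. A feature gated cancer-wide counts as not
    significant there.
    """
    if mode not in ("adjusted", "raw"):
        raise ValueError("mode must be 'adjusted' or 'raw'")
    group_results = list(group_results)
    clinical = list(clinical)
    clinical_by_id = {r.patient_id: r for r in clinical}
    samples = set(expression.sample_ids)

    cancers_needed = {
        r.cancer_type for r in group_results if r.significant(fdr_threshold)
    }
    cancer_tables: dict[str, dict[str, MarkerResult]] = {}
    for cancer in sorted(cancers_needed):
        pids = frozenset(
            r.patient_id
            for r in clinical
            if r.cancer_type == cancer and r.patient_id in samples
        )
        pseudo = CancerDrugGroup(cancer, "__all__", pids)
        cw = test_features_in_group(
            pseudo, expression, thresholds, clinical_by_id, None, min_class_size
        )
        cancer_tables[cancer] = {r.feature_id: r for r in cw}

    for res in group_results:
        if not res.significant(fdr_threshold):
            res.drug_specific = False if res.tested else None
            continue
        cw = cancer_tables[res.cancer_type].get(res.feature_id)
        if cw is None or not cw.tested:
            # gated (or unthresholded) cancer-wide: cannot be significant there
            res.cancer_level_p = None
            res.drug_specific = True
            continue
        if mode == "adjusted":
            res.cancer_level_p = cw.fdr
            res.drug_specific = cw.fdr >= fdr_threshold
        else:
            res.cancer_level_p = cw.p_value
            res.drug_specific = cw.p_value >= cancer_alpha
    return group_results


def group_census(groups: Sequence[CancerDrugGroup]):
    """Patient counts per (cancer type, drug) — the group-size table."""
    import pandas as pd

    return pd.DataFrame(
        [(g.cancer_type, g.drug, len(g)) for g in groups],
        columns=["cancer_type", "drug", "n_patients"],
    )
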