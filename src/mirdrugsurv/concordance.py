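"""Target-gene screening and miRNA-target survival-direction concordance.

For every drug-specific miRNA marker, the target genes of that miRNA are
screened in the same cancer-drug group with the same global-threshold /
class-gate / log-rank machinery, with BH adjustment across the target genes
tested within the group. A significant miRNA paired with one of its
significant target genes in the same group forms an miRNA-mediated
gene-cancer-drug combination; each combination is then checked for
expression correlation (OLS of gene on miRNA over the group's patients) and
for consistency between the pair's regulatory direction and the two
survival directions: an inhibitory pair is consistent when the directions
are opposite, an activating pair when they agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .binarize import StepThreshold
from .io import ClinicalRecord, ExpressionMatrix, TargetPair
from .screen import (
    DEFAULT_MIN_CLASS_SIZE,
    CancerDrugGroup,
    MarkerResult,
    test_features_in_group,
)

__all__ = [
    "ConcordanceRecord",
    "MediatedCombination",
    "screen_targets",
    "mediated_combinations",
    "expression_correlation",
    "classify_consistency",
    "build_concordance_records",
]

log = logging.getLogger(__name__)

DEFAULT_GENE_FDR = 0.01
DEFAULT_CORR_ALPHA = 0.05


@dataclass(frozen=True)
class MediatedCombination:
    """A significant miRNA and one of its significant target genes within
    the same cancer-drug group."""

    mirna_id: str
    gene_id: str
    cancer_type: str
    drug: str
    mirna_fdr: float
    gene_fdr: float
    regulation: str
    mirna_direction: str  # 'high_better' | 'low_better'
    gene_direction: str


@dataclass
class ConcordanceRecord:
    """A mediated combination with its expression correlation and the
    survival-direction consistency verdict."""

    mirna_id: str
    gene_id: str
    cancer_type: str
    drug: str
    regulation: str
    corr_slope: float | None
    corr_p: float | None
    corr_significant: bool | None
    mirna_direction: str
    gene_direction: str
    verdict: str  # 'consistent' | 'inconsistent' | 'unknown'


def _direction(res: MarkerResult) -> str:
    return "high_better" if res.better_survival_class == "high" else "low_better"


def screen_targets(
    markers: Iterable[MarkerResult],
    pairs: Iterable[TargetPair],
    gene_expression: ExpressionMatrix,
    gene_thresholds: Mapping[str, StepThreshold],
    clinical_by_id: Mapping[str, ClinicalRecord],
    groups: Mapping[tuple[str, str], CancerDrugGroup],
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> list[MarkerResult]:
    """Screen the target genes of the given miRNA markers in their groups.

    Returns gene-level results (gated ones included) with FDR adjusted
    across the target genes tested within each group; the gene-significance
    cut is applied later by :func:`mediated_combinations`. Markers whose
    miRNA has no known targets contribute nothing (logged).
    """
    targets_of: dict[str, list[str]] = {}
    for p in pairs:
        targets_of.setdefault(p.mirna_id, []).append(p.gene_id)

    by_group: dict[tuple[str, str], list[MarkerResult]] = {}
    for m in markers:
        by_group.setdefault((m.cancer_type, m.drug), []).append(m)

    out: list[MarkerResult] = []
    for key, group_markers in sorted(by_group.items()):
        group = groups.get(key)
        if group is None:
            log.warning("no group found for %s; skipping its target screen", key)
            continue
        genes: list[str] = []
        seen: set[str] = set()
        for m in group_markers:
            tg = targets_of.get(m.feature_id)
            if not tg:
                log.info("miRNA %s has no known targets", m.feature_id)
                continue
            for g in tg:
                if g not in seen and g in gene_expression and g in gene_thresholds:
                    seen.add(g)
                    genes.append(g)
        if not genes:
            continue
        out.extend(
            test_features_in_group(
                group,
                gene_expression,
                gene_thresholds,
                clinical_by_id,
                genes,
                min_class_size,
            )
        )
    return out


def mediated_combinations(
    mirna_markers: Iterable[MarkerResult],
    gene_results: Iterable[MarkerResult],
    pairs: Iterable[TargetPair],
    gene_fdr: float = DEFAULT_GENE_FDR,
) -> list[MediatedCombination]:
    """Pair each significant miRNA with its significant target genes within
    the same group. A gene significant for two miRNAs of one group yields
    two combinations."""
    pair_lookup = {(p.mirna_id, p.gene_id): p for p in pairs}
    genes_by_group: dict[tuple[str, str], list[MarkerResult]] = {}
    for g in gene_results:
        if g.tested and g.fdr is not None and g.fdr < gene_fdr:
            genes_by_group.setdefault((g.cancer_type, g.drug), []).append(g)

    combos: list[MediatedCombination] = []
    for m in mirna_markers:
        for g in genes_by_group.get((m.cancer_type, m.drug), []):
            p = pair_lookup.get((m.feature_id, g.feature_id))
            if p is None:
                continue
            combos.append(
                MediatedCombination(
                    mirna_id=m.feature_id,
                    gene_id=g.feature_id,
                    cancer_type=m.cancer_type,
                    drug=m.drug,
                    mirna_fdr=float(m.fdr),
                    gene_fdr=float(g.fdr),
                    regulation=p.regulation,
                    mirna_direction=_direction(m),
                    gene_direction=_direction(g),
                )
            )
    combos.sort(key=lambda c: (c.cancer_type, c.drug, c.mirna_id, c.gene_id))
    return combos


def expression_correlation(mirna_values, gene_values) -> tuple[float, float]:
    """OLS simple linear fit of gene on miRNA expression over paired samples.

    Returns (slope, two-sided p for zero slope). Requires at least three
    complete pairs and a non-constant predictor.
    """
    x = np.asarray(mirna_values, dtype=float)
    y = np.asarray(gene_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("miRNA expression is constant: slope undefined")
    fit = _sps.linregress(x, y)
    return float(fit.slope), float(fit.pvalue)


def classify_consistency(regulation: str, mirna_direction: str, gene_direction: str) -> str:
    """Survival-direction consistency verdict for one miRNA-target pair.

    inhibit: consistent iff the survival directions are opposite (high
    miRNA with low gene favoring survival, or vice versa); activate:
    consistent iff they agree; unknown regulation: verdict unknown.
    """
    if regulation == "unknown":
        return "unknown"
    if regulation not in ("inhibit", "activate"):
        raise ValueError(f"unknown regulation label {regulation!r}")
    for d in (mirna_direction, gene_direction):
        if d not in ("high_better", "low_better"):
            raise ValueError(f"bad survival direction {d!r}")
    same = mirna_direction == gene_direction
    if regulation == "inhibit":
        return "inconsistent" if same else "consistent"
    return "consistent" if same else "inconsistent"


def build_concordance_records(
    combos: Sequence[MediatedCombination],
    mirna_expression: ExpressionMatrix,
    gene_expression: ExpressionMatrix,
    groups: Mapping[tuple[str, str], CancerDrugGroup],
    corr_alpha: float = DEFAULT_CORR_ALPHA,
) -> list[ConcordanceRecord]:
    """Correlation + consistency classification for each combination.

    The correlation is computed over the combination's own group patients.
    Pairs whose correlation is not significant at ``corr_alpha`` are flagged
    but retained. Correlation failures (too few pairs, constant predictor)
    leave slope/p unset.
    """
    records = []
    for c in combos:
        group = groups[(c.cancer_type, c.drug)]
        members = sorted(
            group.patient_ids
            & set(mirna_expression.sample_ids)
            & set(gene_expression.sample_ids)
        )
        mv = mirna_expression.feature_values(c.mirna_id).loc[members]
        gv = gene_expression.feature_values(c.gene_id).loc[members]
        try:
            slope, p = expression_correlation(mv.to_numpy(), gv.to_numpy())
            sig = p < corr_alpha
        except ValueError as exc:
            log.warning("correlation failed for %s/%s: %s", c.mirna_id, c.gene_id, exc)
            slope = p = sig = None
        records.append(
            ConcordanceRecord(
                mirna_id=c.mirna_id,
                gene_id=c.gene_id,
                cancer_type=c.cancer_type,
                drug=c.drug,
                regulation=c.regulation,
                corr_slope=slope,
                corr_p=p,
                corr_significant=sig,
                mirna_direction=c.mirna_direction,
                gene_direction=c.gene_direction,
                verdict=classify_consistency(
                    c.regulation, c.mirna_direction, c.gene_direction
                ),
            )
        )
    return records
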