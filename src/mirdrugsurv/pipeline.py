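"""End-to-end orchestration: config, stage sequencing, and table output.

``run_pipeline`` wires the stages together — global step thresholds, group
building, the per-group miRNA screen, the drug-specificity contrast, the
target-gene screen, mediated combinations, and correlation/consistency —
and writes every table plus a run manifest. Identical config and inputs
produce identical outputs (timestamps appear only in the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import binarize, concordance, io, screen
from .errors import MirDrugSurvError, PipelineError
from .stats import SurvivalSample, bh_adjust

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All inputs, thresholds and switches for one run.

    Default constants: groups need at least 15 patients, each expression
    class at least 5; miRNA markers at FDR < 0.1; target genes at
    FDR < 0.01; expression correlations flagged at p >= 0.05.
    """

    clinical: str = ""
    drugs: str = ""
    drug_mapping: str = ""
    mirna_expression: str = ""
    gene_expression: str = ""
    target_pairs: list[str] = field(default_factory=list)
    out_dir: str = "mirdrugsurv_out"
    clinical_columns: dict[str, str] = field(default_factory=dict)
    min_group_size: int = 15
    min_class_size: int = 5
    mirna_fdr: float = 0.1
    gene_fdr: float = 0.01
    corr_alpha: float = 0.05
    fdr_scope: str = "per_group"  # or "global"
    cancer_specificity_mode: str = "adjusted"  # or "raw"
    cancer_alpha: float = 0.05
    seed: int = 0
    plots: bool = True

    def __post_init__(self):
        for name in ("mirna_fdr", "gene_fdr", "corr_alpha", "cancer_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise MirDrugSurvError(f"{name} must be in [0, 1], got {v}")
        if self.min_group_size < 1 or self.min_class_size < 1:
            raise MirDrugSurvError("group/class sizes must be >= 1")
        if self.fdr_scope not in ("per_group", "global"):
            raise MirDrugSurvError("fdr_scope must be 'per_group' or 'global'")
        if self.cancer_specificity_mode not in ("adjusted", "raw"):
            raise MirDrugSurvError("cancer_specificity_mode must be 'adjusted' or 'raw'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _require(path: str, what: str):
    if not path or not Path(path).exists():
        raise PipelineError("inputs", f"missing {what} file: {path!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages and write outputs under ``config.out_dir``.

    Returns the manifest (paths, counts, gate tallies). Any stage error
    aborts with a stage-tagged :class:`PipelineError` and removes the
    partial outputs of this run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run(config, out, created)
    except PipelineError:
        _cleanup(created)
        raise
    except Exception as exc:  # tag unexpected failures with their stage too
        _cleanup(created)
        raise PipelineError("pipeline", str(exc)) from exc


def _cleanup(created: list[Path]):
    for p in created:
        try:
            p.unlink(missing_ok=True)
        except OSError:
            pass


def _write(df: pd.DataFrame, path: Path, created: list[Path]):
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    created.append(path)


def _run(config: PipelineConfig, out: Path, created: list[Path]) -> dict[str, Any]:
    # ---- load ------------------------------------------------------------
    try:
        _require(config.clinical, "clinical")
        _require(config.drugs, "drug records")
        _require(config.drug_mapping, "drug mapping")
        _require(config.mirna_expression, "miRNA expression")
        cols = io.ClinicalColumns(**config.clinical_columns) if config.clinical_columns else None
        clinical, clin_report = io.read_clinical(config.clinical, cols)
        raw_drugs = io.read_drug_records(config.drugs)
        mapping = io.read_drug_mapping(config.drug_mapping)
        drugs = io.standardize_drugs(raw_drugs, mapping)
        mirna, mirna_report = io.read_expression(config.mirna_expression)
    except MirDrugSurvError as exc:
        raise PipelineError("load", str(exc)) from exc

    have_genes = bool(config.gene_expression)
    genes = gene_report = None
    pairs: list[io.TargetPair] = []
    if have_genes:
        try:
            _require(config.gene_expression, "gene expression")
            genes, gene_report = io.read_expression(config.gene_expression)
            for p in config.target_pairs:
                _require(p, "target pairs")
            pairs, _pair_log = io.read_target_pairs(config.target_pairs)
        except MirDrugSurvError as exc:
            raise PipelineError("load", str(exc)) from exc

    clinical_by_id = {r.patient_id: r for r in clinical}

    # ---- binarize --------------------------------------------------------
    try:
        mirna_thresholds = binarize.fit_all_thresholds(mirna)
        gene_thresholds = binarize.fit_all_thresholds(genes) if have_genes else {}
    except MirDrugSurvError as exc:
        raise PipelineError("binarize", str(exc)) from exc
    _write(_threshold_table(mirna_thresholds), out / "thresholds_mirna.tsv", created)
    if have_genes:
        _write(_threshold_table(gene_thresholds), out / "thresholds_gene.tsv", created)

    # ---- groups ----------------------------------------------------------
    groups = screen.build_groups(clinical, drugs, mirna, config.min_group_size)
    group_map = {(g.cancer_type, g.drug): g for g in groups}
    _write(screen.group_census(groups), out / "group_census.tsv", created)

    feature_ids = [f for f in mirna.feature_ids if f in mirna_thresholds]
    n_enumerated, _ = screen.enumerate_combinations(groups, feature_ids)

    # ---- miRNA screen ----------------------------------------------------
    all_results: list[screen.MarkerResult] = []
    for g in groups:
        all_results.extend(
            screen.screen_group(g, mirna, mirna_thresholds, clinical_by_id,
                                config.min_class_size)
        )
    if config.fdr_scope == "global":
        tested = [r for r in all_results if r.tested]
        if tested:
            for r, q in zip(tested, bh_adjust([r.p_value for r in tested])):
                r.fdr = float(q)

    all_results = screen.drug_specific_filter(
        all_results, clinical, mirna, mirna_thresholds,
        fdr_threshold=config.mirna_fdr,
        mode=config.cancer_specificity_mode,
        cancer_alpha=config.cancer_alpha,
        min_class_size=config.min_class_size,
    )
    markers = [
        r for r in all_results if r.significant(config.mirna_fdr) and r.drug_specific
    ]
    _write(_marker_table(all_results), out / "markers.tsv", created)
    _write(_marker_table(markers), out / "drug_specific_markers.tsv", created)

    # ---- target genes / concordance -------------------------------------
    gene_results: list[screen.MarkerResult] = []
    combos: list[concordance.MediatedCombination] = []
    records: list[concordance.ConcordanceRecord] = []
    if have_genes and markers:
        gene_results = concordance.screen_targets(
            markers, pairs, genes, gene_thresholds, clinical_by_id, group_map,
            config.min_class_size,
        )
        combos = concordance.mediated_combinations(
            markers, gene_results, pairs, config.gene_fdr
        )
        records = concordance.build_concordance_records(
            combos, mirna, genes, group_map, config.corr_alpha
        )
    if have_genes:
        _write(_marker_table(gene_results), out / "gene_results.tsv", created)
        _write(_combo_table(combos), out / "combinations.tsv", created)
        _write(_concordance_table(records), out / "concordance.tsv", created)
        _write(_concordance_summary(records), out / "concordance_summary.tsv", created)

    # ---- KM exports for the drug-specific markers ------------------------
    km_dir = out / "km"
    if markers:
        km_dir.mkdir(exist_ok=True)
    for m in markers:
        _export_km(m, group_map[(m.cancer_type, m.drug)], mirna,
                   mirna_thresholds, clinical_by_id, km_dir, created,
                   plots=config.plots)

    # ---- manifest --------------------------------------------------------
    tested = sum(1 for r in all_results if r.tested)
    gated = sum(1 for r in all_results if r.gated)
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "counts": {
            "patients_loaded": len(clinical),
            "clinical_rows_dropped": clin_report.n_dropped,
            "expression_missing_cells": mirna_report.missing_cells,
            "unmapped_drug_records": sum(
                1 for d in drugs if d.standardized_name == io.UNMAPPED
            ),
            "features_thresholded": len(feature_ids),
            "features_skipped_no_threshold": len(mirna.feature_ids) - len(feature_ids),
            "groups": len(groups),
            "combinations_enumerated": n_enumerated,
            "combinations_tested": tested,
            "combinations_gated": gated,
            "group_significant_markers": sum(
                1 for r in all_results if r.significant(config.mirna_fdr)
            ),
            "drug_specific_markers": len(markers),
            "target_genes_tested": sum(1 for r in gene_results if r.tested),
            "target_genes_gated": sum(1 for r in gene_results if r.gated),
            "gene_significant": sum(
                1 for r in gene_results
                if r.tested and r.fdr is not None and r.fdr < config.gene_fdr
            ),
            "mediated_combinations": len(combos),
            "verdict_consistent": sum(1 for r in records if r.verdict == "consistent"),
            "verdict_inconsistent": sum(1 for r in records if r.verdict == "inconsistent"),
            "verdict_unknown": sum(1 for r in records if r.verdict == "unknown"),
        },
        "outputs": {p.name: str(p) for p in created},
        "output_names": sorted(str(p.relative_to(out)) for p in created),
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    created.append(manifest_path)
    return manifest


def _threshold_table(thresholds) -> pd.DataFrame:
    rows = [
        (t.feature_id, t.threshold, t.breakpoint_index, t.sse, t.n_used)
        for t in thresholds.values()
    ]
    df = pd.DataFrame(
        rows, columns=["feature_id", "threshold", "breakpoint_index", "sse", "n_used"]
    )
    return df.sort_values("feature_id").reset_index(drop=True)


def _marker_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "cancer_type": r.cancer_type,
                "drug": r.drug,
                "feature_id": r.feature_id,
                "n_low": r.n_low,
                "n_high": r.n_high,
                "gated": r.gated,
                "logrank_stat": r.logrank.statistic if r.logrank else np.nan,
                "p_value": r.p_value if r.p_value is not None else np.nan,
                "fdr": r.fdr if r.fdr is not None else np.nan,
                "cancer_level_p": r.cancer_level_p if r.cancer_level_p is not None else np.nan,
                "drug_specific": r.drug_specific,
                "better_survival_class": r.better_survival_class or "",
            }
        )
    cols = [
        "cancer_type", "drug", "feature_id", "n_low", "n_high", "gated",
        "logrank_stat", "p_value", "fdr", "cancer_level_p", "drug_specific",
        "better_survival_class",
    ]
    return pd.DataFrame(rows, columns=cols)


def _combo_table(combos) -> pd.DataFrame:
    return pd.DataFrame(
        [asdict(c) for c in combos],
        columns=[
            "cancer_type", "drug", "gene_id", "gene_fdr", "mirna_id", "mirna_fdr",
            "regulation", "mirna_direction", "gene_direction",
        ],
    )


def _concordance_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [asdict(r) for r in records],
        columns=[
            "cancer_type", "drug", "mirna_id", "gene_id", "regulation",
            "corr_slope", "corr_p", "corr_significant", "mirna_direction",
            "gene_direction", "verdict",
        ],
    )


def _concordance_summary(records) -> pd.DataFrame:
    counts = {"consistent": 0, "inconsistent": 0, "unknown": 0}
    for r in records:
        counts[r.verdict] += 1
    return pd.DataFrame(
        {"verdict": list(counts), "n": list(counts.values()),
         "total": [len(records)] * 3}
    )


def _export_km(marker, group, expression, thresholds, clinical_by_id, km_dir,
               created, plots=True):
    from .stats import km_estimate

    t = thresholds[marker.feature_id]
    vals = expression.feature_values(marker.feature_id)
    members = sorted(group.patient_ids & set(expression.sample_ids))
    stem = f"{marker.cancer_type}_{marker.drug}_{marker.feature_id}".replace("/", "-")
    curves = {}
    for label in ("low", "high"):
        samples = [
            SurvivalSample(clinical_by_id[p].survival_time, clinical_by_id[p].event)
            for p in members
            if not np.isnan(vals[p])
            and (("high" if vals[p] > t.threshold else "low") == label)
        ]
        if samples:
            curves[label] = km_estimate(samples)
    frames = []
    for label, curve in curves.items():
        tab = curve.to_table()
        tab.insert(0, "class", label)
        frames.append(tab)
    if frames:
        df = pd.concat(frames, ignore_index=True)
        path = km_dir / f"{stem}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        created.append(path)
    if plots and curves:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for label, curve in curves.items():
            xs = np.concatenate([[0.0], curve.times])
            ys = np.concatenate([[1.0], curve.survival])
            ax.step(xs, ys, where="post", label=f"{label} (n at risk {int(curve.n_at_risk[0]) if curve.n_at_risk.size else 0})")
        ax.set_xlabel("days")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"{marker.feature_id} in {marker.cancer_type}-{marker.drug}")
        ax.legend()
        fig.tight_layout()
        path = km_dir / f"{stem}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        created.append(path)
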