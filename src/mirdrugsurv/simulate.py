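"""Synthetic TCGA-like cohort with planted drug-specific survival markers.

The generator emulates the statistical structure the screening pipeline
assumes in real data: a multi-cancer cohort where each patient carries a
list of standardized drug exposures; miRNA features that are either null
(unimodal Gaussian on the log scale) or planted markers (two-component
Gaussian mixtures whose high/low component shifts the death hazard only for
patients inside one specific cancer-drug group); inhibitory target genes
generated as decreasing affine functions of their miRNA plus noise; and
exponential survival with independent exponential censoring.

All randomness flows from a single ``numpy`` generator seeded by
``SimConfig.seed``, so identical configurations yield identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ClinicalRecord, DrugRecord, ExpressionMatrix, TargetPair

__all__ = ["PlantedMarker", "SimConfig", "Cohort", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class PlantedMarker:
    """A marker miRNA whose expression class shifts the hazard inside one
    cancer-drug group; hazard_ratio > 1 means the high class dies faster."""

    cancer_type: str
    drug: str
    mirna_id: str
    hazard_ratio: float
    target_gene_ids: tuple[str, ...] = ()


def _default_markers():
    return [PlantedMarker("CT1", "drugA", "mir-plant-1", 4.0, ("gene-plant-1",))]


@dataclass
class SimConfig:
    """Cohort design. Defaults give a compact cohort with one strong planted
    marker (hazard ratio 4 inside its group) and one inhibitory target gene;
    bimodal components are four standard deviations apart, censoring is
    light so most follow-ups end in an observed event."""

    n_cancer_types: int = 3
    patients_per_cancer: int = 400
    drugs_per_cancer: int = 3
    drug_exposure_prob: float = 0.12
    n_mirnas: int = 60
    n_genes: int = 80
    planted_markers: list[PlantedMarker] = field(default_factory=_default_markers)
    # (low_mean, high_mean, sd, high_fraction) of the marker mixture
    bimodal_params: tuple[float, float, float, float] = (2.0, 6.0, 1.0, 0.5)
    baseline_hazard: float = 1.0 / 500.0  # deaths per day
    censoring_rate: float = 1.0 / 2000.0  # censorings per day
    target_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        low, high, sd, frac = self.bimodal_params
        if not low < high:
            raise ValueError("bimodal low_mean must be < high_mean")
        if not 0 < frac < 1:
            raise ValueError("high_fraction must be in (0, 1)")
        if sd <= 0 or self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("sd and rates must be > 0")
        if not 0 < self.drug_exposure_prob <= 1:
            raise ValueError("drug_exposure_prob must be in (0, 1]")
        for m in self.planted_markers:
            if m.hazard_ratio <= 0:
                raise ValueError(f"hazard_ratio must be > 0 for {m.mirna_id}")

    @property
    def cancer_types(self) -> list[str]:
        return [f"CT{i + 1}" for i in range(self.n_cancer_types)]

    @property
    def drugs(self) -> list[str]:
        return [f"drug{chr(ord('A') + j)}" for j in range(self.drugs_per_cancer)]


@dataclass
class Cohort:
    """Everything generate_cohort emits, in the pipeline's own data model."""

    clinical: list[ClinicalRecord]
    drugs: list[DrugRecord]
    mirna: ExpressionMatrix
    genes: ExpressionMatrix
    pairs: list[TargetPair]
    truth: pd.DataFrame  # one row per planted marker


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full synthetic cohort from ``config`` (reproducible from seed)."""
    rng = np.random.default_rng(config.seed)
    cancers = config.cancer_types
    drugs = config.drugs

    for m in config.planted_markers:
        if m.cancer_type not in cancers:
            raise ValueError(f"planted marker references unknown cancer {m.cancer_type!r}")
        if m.drug not in drugs:
            raise ValueError(f"planted marker references unknown drug {m.drug!r}")

    patient_ids: list[str] = []
    patient_cancer: dict[str, str] = {}
    for c in cancers:
        for k in range(config.patients_per_cancer):
            pid = f"{c}-P{k:04d}"
            patient_ids.append(pid)
            patient_cancer[pid] = c
    n = len(patient_ids)

    # drug exposure: independent Bernoulli per (patient, drug in the cancer panel)
    exposure = rng.random((n, len(drugs))) < config.drug_exposure_prob
    drug_records = [
        DrugRecord(pid, drugs[j], drugs[j])
        for i, pid in enumerate(patient_ids)
        for j in range(len(drugs))
        if exposure[i, j]
    ]

    low, high, sd, frac = config.bimodal_params
    mid = (low + high) / 2.0

    planted_ids = [m.mirna_id for m in config.planted_markers]
    if len(set(planted_ids)) != len(planted_ids):
        raise ValueError("planted marker miRNA ids must be distinct")
    n_null_mirna = config.n_mirnas - len(planted_ids)
    if n_null_mirna < 0:
        raise ValueError("n_mirnas smaller than number of planted markers")
    mirna_ids = planted_ids + [f"mir-null-{i:04d}" for i in range(n_null_mirna)]

    mirna_vals = np.empty((config.n_mirnas, n))
    marker_class = {}  # mirna_id -> bool array (high component)
    for r, m in enumerate(config.planted_markers):
        z = rng.random(n) < frac
        marker_class[m.mirna_id] = z
        mirna_vals[r] = np.where(z, high, low) + rng.normal(0.0, sd, n)
    mirna_vals[len(planted_ids):] = rng.normal(mid, sd, (n_null_mirna, n))

    # target genes: decreasing affine function of the miRNA plus noise
    planted_gene_ids: list[str] = []
    gene_rows: list[np.ndarray] = []
    pairs: list[TargetPair] = []
    for r, m in enumerate(config.planted_markers):
        for gid in m.target_gene_ids:
            planted_gene_ids.append(gid)
            gene_rows.append(
                (low + high) - mirna_vals[r] + rng.normal(0.0, config.target_noise_sd, n)
            )
            pairs.append(TargetPair(m.mirna_id, gid, "inhibit", "synthetic-truth"))
    if len(set(planted_gene_ids)) != len(planted_gene_ids):
        raise ValueError("planted target gene ids must be distinct")
    n_null_gene = config.n_genes - len(planted_gene_ids)
    if n_null_gene < 0:
        raise ValueError("n_genes smaller than number of planted target genes")
    null_gene_ids = [f"gene-null-{i:04d}" for i in range(n_null_gene)]
    gene_ids = planted_gene_ids + null_gene_ids
    if n_null_gene:
        gene_rows.append(rng.normal(mid, sd, (n_null_gene, n)))
    gene_vals = np.vstack(gene_rows) if gene_rows else np.empty((0, n))

    # decoy pairs: planted miRNAs also listed against a couple of null genes
    for m in config.planted_markers:
        for gid in null_gene_ids[: min(2, n_null_gene)]:
            pairs.append(TargetPair(m.mirna_id, gid, "unknown", "synthetic-decoy"))

    # survival: exponential death hazard, multiplicative marker effects
    # confined to the marker's cancer-drug group; independent exponential
    # censoring; observed time is the earlier of the two
    hazard = np.full(n, config.baseline_hazard)
    drug_idx = {d: j for j, d in enumerate(drugs)}
    cancer_of = np.array([patient_cancer[p] for p in patient_ids])
    for m in config.planted_markers:
        in_group = (cancer_of == m.cancer_type) & exposure[:, drug_idx[m.drug]]
        z = marker_class[m.mirna_id]
        hazard = hazard * np.where(in_group & z, m.hazard_ratio, 1.0)
    t_death = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    time = np.minimum(t_death, t_cens)
    event = (t_death <= t_cens).astype(int)

    clinical = [
        ClinicalRecord(pid, patient_cancer[pid], float(time[i]), int(event[i]))
        for i, pid in enumerate(patient_ids)
    ]

    truth = pd.DataFrame(
        {
            "cancer_type": [m.cancer_type for m in config.planted_markers],
            "drug": [m.drug for m in config.planted_markers],
            "mirna_id": [m.mirna_id for m in config.planted_markers],
            "hazard_ratio": [m.hazard_ratio for m in config.planted_markers],
            "target_gene_ids": [";".join(m.target_gene_ids) for m in config.planted_markers],
        }
    )

    return Cohort(
        clinical=clinical,
        drugs=drug_records,
        mirna=ExpressionMatrix(mirna_ids, patient_ids, mirna_vals),
        genes=ExpressionMatrix(gene_ids, patient_ids, gene_vals),
        pairs=pairs,
        truth=truth,
    )


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the cohort in the TSV dialects the loaders read; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.tsv",
        "drugs": outdir / "drugs.tsv",
        "drug_mapping": outdir / "drug_mapping.tsv",
        "mirna": outdir / "mirna_expression.tsv",
        "genes": outdir / "gene_expression.tsv",
        "target_pairs": outdir / "target_pairs.tsv",
        "truth": outdir / "truth.tsv",
    }
    pd.DataFrame(
        [
            (r.patient_id, r.cancer_type, r.survival_time, r.event)
            for r in cohort.clinical
        ],
        columns=["patient_id", "cancer_type", "survival_time", "event"],
    ).to_csv(paths["clinical"], sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(
        [(r.patient_id, r.raw_name) for r in cohort.drugs],
        columns=["patient_id", "drug_name"],
    ).to_csv(paths["drugs"], sep="\t", index=False)
    drugs = sorted({r.raw_name for r in cohort.drugs})
    pd.DataFrame({"raw_name": drugs, "canonical_name": drugs}).to_csv(
        paths["drug_mapping"], sep="\t", index=False
    )
    cohort.mirna.to_frame().to_csv(
        paths["mirna"], sep="\t", index_label="feature_id", float_format="%.6f"
    )
    cohort.genes.to_frame().to_csv(
        paths["genes"], sep="\t", index_label="feature_id", float_format="%.6f"
    )
    pd.DataFrame(
        [(p.mirna_id, p.gene_id, p.regulation, p.source) for p in cohort.pairs],
        columns=["mirna_id", "gene_id", "regulation", "source"],
    ).to_csv(paths["target_pairs"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
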