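"""Data model and tab-separated I/O for the screening pipeline.

All inputs and outputs are UTF-8 TSV with a header row. Column names for the
clinical table are configurable because TCGA and GEO exports differ; the
expression dialect is fixed (first column feature id, remaining columns
samples, log-scale values).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MirDrugSurvError

__all__ = [
    "UNMAPPED",
    "ClinicalRecord",
    "DrugRecord",
    "ExpressionMatrix",
    "TargetPair",
    "ClinicalColumns",
    "LoadReport",
    "read_clinical",
    "standardize_drugs",
    "read_drug_records",
    "read_drug_mapping",
    "read_expression",
    "write_expression",
    "read_target_pairs",
]

log = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"

REGULATIONS = ("inhibit", "activate", "unknown")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's cancer type and survival outcome (days; event 1 = death)."""

    patient_id: str
    cancer_type: str
    survival_time: float
    event: int

    def __post_init__(self):
        if self.survival_time < 0:
            raise ValueError(
                f"patient {self.patient_id}: survival_time must be >= 0"
            )
        if self.event not in (0, 1):
            raise ValueError(f"patient {self.patient_id}: event must be 0 or 1")


@dataclass(frozen=True)
class DrugRecord:
    """One drug exposure; ``standardized_name`` is UNMAPPED when the raw
    name is absent from the standardization map."""

    patient_id: str
    raw_name: str
    standardized_name: str = UNMAPPED


@dataclass(frozen=True)
class TargetPair:
    """An miRNA->target-gene relation with its regulatory direction."""

    mirna_id: str
    gene_id: str
    regulation: str = "unknown"
    source: str = ""

    def __post_init__(self):
        if self.regulation not in REGULATIONS:
            raise ValueError(f"regulation must be one of {REGULATIONS}")


@dataclass
class LoadReport:
    """Bookkeeping from a loader: rows dropped and cells coerced to missing."""

    dropped_rows: list[int] = field(default_factory=list)
    missing_cells: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_rows)


@dataclass(frozen=True)
class ClinicalColumns:
    """Column-name mapping for clinical tables (TCGA/GEO dialects differ)."""

    patient: str = "patient_id"
    cancer_type: str = "cancer_type"
    time: str = "survival_time"
    event: str = "event"


class ExpressionMatrix:
    """Log-scale expression values, features x samples, NaN for missing."""

    def __init__(self, feature_ids: Sequence[str], sample_ids: Sequence[str], values):
        feature_ids = list(feature_ids)
        sample_ids = list(sample_ids)
        values = np.asarray(values, dtype=float)
        if len(set(feature_ids)) != len(feature_ids):
            raise MirDrugSurvError("duplicate feature ids in expression matrix")
        if len(set(sample_ids)) != len(sample_ids):
            raise MirDrugSurvError("duplicate sample ids in expression matrix")
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise MirDrugSurvError(
                f"shape {values.shape} inconsistent with "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self.values = values
        self._fidx = {f: i for i, f in enumerate(feature_ids)}
        self._sidx = {s: j for j, s in enumerate(sample_ids)}

    @property
    def shape(self):
        return self.values.shape

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._fidx

    def feature_values(self, feature_id: str) -> pd.Series:
        """Values of one feature keyed by sample id."""
        return pd.Series(
            self.values[self._fidx[feature_id]], index=self.sample_ids, name=feature_id
        )

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Submatrix (features x selected samples)."""
        idx = [self._sidx[s] for s in sample_ids]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_clinical(
    path, columns: ClinicalColumns | None = None
) -> tuple[list[ClinicalRecord], LoadReport]:
    """Read a clinical TSV into records; rows with missing time or event are
    dropped and counted in the returned :class:`LoadReport`."""
    columns = columns or ClinicalColumns()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [columns.patient, columns.cancer_type, columns.time, columns.event]
    for col in required:
        if col not in df.columns:
            raise MirDrugSurvError(f"clinical table {path}: missing column {col!r}")
    report = LoadReport()
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        t_raw, e_raw = row[columns.time], row[columns.event]
        if _is_blank(t_raw) or _is_blank(e_raw):
            report.dropped_rows.append(int(i))
            continue
        try:
            t = float(t_raw)
            e = int(float(e_raw))
        except ValueError:
            report.dropped_rows.append(int(i))
            report.messages.append(f"row {i}: non-numeric time/event")
            continue
        if t < 0:
            raise MirDrugSurvError(f"clinical table {path}: negative time at row {i}")
        pid = str(row[columns.patient])
        if pid in seen:
            raise MirDrugSurvError(f"clinical table {path}: duplicate patient {pid}")
        seen.add(pid)
        records.append(ClinicalRecord(pid, str(row[columns.cancer_type]), t, e))
    return records, report


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""


_WS = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Lowercase, trim, collapse internal whitespace, strip trailing punctuation."""
    s = _WS.sub(" ", str(name).strip().lower())
    return s.rstrip(".,;:")


def read_drug_mapping(path) -> dict[str, str]:
    """Read a two-column (raw, canonical) TSV into a normalized lookup map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MirDrugSurvError(f"drug mapping {path}: need raw and canonical columns")
    raw_col, canon_col = df.columns[:2]
    return build_drug_mapping(zip(df[raw_col], df[canon_col]))


def build_drug_mapping(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    """Normalize raw keys; conflicting duplicates after normalization are a
    hard error (same normalized raw name mapping to two canonical names)."""
    mapping: dict[str, str] = {}
    for raw, canon in pairs:
        key = normalize_drug_name(raw)
        canon = str(canon).strip()
        if key in mapping and mapping[key] != canon:
            raise MirDrugSurvError(
                f"drug mapping conflict for {key!r}: {mapping[key]!r} vs {canon!r}"
            )
        mapping[key] = canon
    return mapping


def read_drug_records(path) -> list[DrugRecord]:
    """Read raw drug-exposure records (patient_id, drug_name[, ...])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "drug_name"):
        if col not in df.columns:
            raise MirDrugSurvError(f"drug table {path}: missing column {col!r}")
    return [
        DrugRecord(str(r.patient_id), str(r.drug_name))
        for r in df.itertuples(index=False)
    ]


def standardize_drugs(
    records: Iterable[DrugRecord], mapping: Mapping[str, str]
) -> list[DrugRecord]:
    """Attach a canonical drug name to every record.

    Raw names are normalized before lookup; names absent from the map become
    UNMAPPED (excluded from group building downstream). Idempotent: records
    whose raw name already equals a canonical name re-map to it, and already
    standardized records are left unchanged.
    """
    canonical = set(mapping.values())
    out = []
    for rec in records:
        key = normalize_drug_name(rec.raw_name)
        if key in mapping:
            std = mapping[key]
        elif rec.standardized_name != UNMAPPED:
            std = rec.standardized_name  # already standardized: no-op
        elif rec.raw_name in canonical:
            std = rec.raw_name
        else:
            std = UNMAPPED
        out.append(DrugRecord(rec.patient_id, rec.raw_name, std))
    return out


def read_expression(path) -> tuple[ExpressionMatrix, LoadReport]:
    """Read a feature-by-sample TSV; non-numeric cells become missing and
    are counted; duplicate feature ids are a hard error."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MirDrugSurvError(f"expression table {path}: empty")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise MirDrugSurvError(f"expression table {path}: duplicate feature ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    report = LoadReport()
    report.missing_cells = int(numeric.isna().sum().sum())
    mat = ExpressionMatrix(
        [str(f) for f in df.index], [str(s) for s in df.columns], numeric.to_numpy()
    )
    return mat, report


def write_expression(matrix: ExpressionMatrix, path, float_format: str = "%.6g"):
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format=float_format)


def read_target_pairs(paths: Sequence | str) -> tuple[list[TargetPair], list[str]]:
    """Union of miRNA-target tables, de-duplicated on (mirna, gene).

    Conflicting regulation labels for the same pair resolve to ``unknown``
    and are reported in the returned log. Malformed rows are skipped and
    logged. Tables need ``mirna_id`` and ``gene_id`` columns; ``regulation``
    and ``source`` are optional.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    merged: dict[tuple[str, str], TargetPair] = {}
    logmsgs: list[str] = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("mirna_id", "gene_id"):
            if col not in df.columns:
                raise MirDrugSurvError(f"target table {path}: missing column {col!r}")
        has_reg = "regulation" in df.columns
        has_src = "source" in df.columns
        for i, row in df.iterrows():
            if _is_blank(row["mirna_id"]) or _is_blank(row["gene_id"]):
                logmsgs.append(f"{path} row {i}: malformed, skipped")
                continue
            reg = str(row["regulation"]).strip().lower() if has_reg and not _is_blank(row.get("regulation")) else "unknown"
            if reg not in REGULATIONS:
                logmsgs.append(f"{path} row {i}: bad regulation {reg!r}, set unknown")
                reg = "unknown"
            src = str(row["source"]) if has_src and not _is_blank(row.get("source")) else str(path)
            pair = TargetPair(str(row["mirna_id"]), str(row["gene_id"]), reg, src)
            key = (pair.mirna_id, pair.gene_id)
            if key in merged:
                prev = merged[key]
                if prev.regulation != pair.regulation:
                    logmsgs.append(
                        f"conflicting regulation for {key}: "
                        f"{prev.regulation} vs {pair.regulation} -> unknown"
                    )
                    merged[key] = TargetPair(key[0], key[1], "unknown", prev.source)
            else:
                merged[key] = pair
    for m in logmsgs:
        log.info(m)
    return list(merged.values()), logmsgs
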