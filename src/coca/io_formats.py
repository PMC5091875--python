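"""Flat-file I/O for the pipeline's standard formats.

Conventions
-----------
* SEG files are tab-delimited with columns ``Sample, Chromosome, Start, End,
  Segment_Mean``; coordinates are treated as 1-based inclusive (the common
  SEG dialect).
* BED gene models are 0-based half-open on disk and converted to 1-based
  inclusive on read, so SEG/BED overlaps line up.
* Chromosome names are normalized by stripping a leading ``chr`` prefix.
* Matrix TSVs are feature x sample with a single header row; missing cells
  are written as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import PlatformMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SegmentRecord",
    "GeneInterval",
    "ClinicalTable",
    "read_seg_file",
    "read_bed_genes",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "afp_class",
    "stage_class",
    "child_pugh_class",
]

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Segment_Mean"]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment: log2 tumor/normal ratio over an interval.

    Coordinates are 1-based inclusive.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if not np.isfinite(self.seg_mean):
            raise ValueError("seg_mean must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


def read_seg_file(path: str | Path) -> list[SegmentRecord]:
    """Parse a SEG file into segment records.

    Rows whose ``Segment_Mean`` does not parse as a finite number are
    skipped; the skip count is logged so no sample silently loses data.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in SEG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"SEG file {path} is missing required column {col!r}")
    if df.empty:
        logger.warning("SEG file %s contains a header but no data rows", path)
        return []
    records: list[SegmentRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            mean = float(getattr(row, "Segment_Mean"))
            if not np.isfinite(mean):
                raise ValueError
        except (TypeError, ValueError):
            skipped += 1
            continue
        records.append(
            SegmentRecord(
                sample_id=str(row.Sample),
                chrom=normalize_chrom(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                seg_mean=mean,
            )
        )
    if skipped:
        logger.warning(
            "SEG file %s: skipped %d rows with non-numeric Segment_Mean (%d kept)",
            path, skipped, len(records),
        )
    return records


def read_bed_genes(path: str | Path) -> list[GeneInterval]:
    """Read a gene model from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise FormatError("gene BED requires at least 4 columns (chrom, start, end, name)")
    genes = [
        GeneInterval(
            gene_id=str(r[3]),
            chrom=normalize_chrom(r[0]),
            start=int(r[1]) + 1,
            end=int(r[2]),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise FormatError(f"duplicate gene ids in BED: {dupes[:5]}")
    return genes


def read_matrix_tsv(path: str | Path, kind: str) -> PlatformMatrix:
    """Read a feature x sample TSV into a raw :class:`PlatformMatrix`.

    The first column holds feature IDs; ``NA`` cells become missing values.
    Duplicate feature or sample IDs and ragged rows are format errors.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise FormatError(f"matrix file {path} is empty")
    header = lines[0].split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"duplicate sample columns in {path}")
    n_cols = len(header)
    features, rows = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise FormatError(f"ragged row at line {i} of {path}: {len(parts)} fields, expected {n_cols}")
        features.append(parts[0])
        rows.append([np.nan if p in ("NA", "", "NaN", "nan") else float(p) for p in parts[1:]])
    if len(set(features)) != len(features):
        dupes = sorted({f for f in features if features.count(f) > 1})
        raise FormatError(f"duplicate feature rows in {path}: {dupes[:5]}")
    data = pd.DataFrame(rows, index=features, columns=samples, dtype=float)
    return PlatformMatrix(kind=kind, data=data, state="raw")


def write_matrix_tsv(matrix: PlatformMatrix, path: str | Path) -> None:
    """Write a matrix as tab-delimited UTF-8 with NA for missing cells."""
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8")


# ---------------------------------------------------------------------------
# Clinical table

CLINICAL_LEVELS: Mapping[str, tuple[str, str]] = {
    "gender": ("Female", "Male"),
    "alcohol": ("NO", "YES"),
    "child_pugh": ("Low(1)", "High(>1)"),
    "afp": ("Low(<20)", "High(>20)"),
    "ajcc_stage": ("1", ">1"),
    "hcv": ("No", "Yes"),
    "vascular_invasion": ("NO", "YES"),
}


def afp_class(value: float | str) -> str:
    """Dichotomize serum alpha-fetoprotein at 20 ng/ml."""
    v = float(value)
    return "Low(<20)" if v < 20 else "High(>20)"


def stage_class(value: str | int) -> str:
    """Dichotomize AJCC primary-tumor stage as 1 vs >1 (accepts 'T2', '2', 2)."""
    s = str(value).strip().upper().lstrip("T")
    first = s[:1]
    if not first.isdigit():
        raise ValueError(f"unparseable AJCC stage {value!r}")
    return "1" if first == "1" else ">1"


def child_pugh_class(value: str | int) -> str:
    """Dichotomize Child-Pugh grade as 1 vs >1."""
    s = str(value).strip()
    if s in CLINICAL_LEVELS["child_pugh"]:
        return s
    grade = int(s)
    return "Low(1)" if grade <= 1 else "High(>1)"


@dataclass
class ClinicalTable:
    """Per-sample survival and categorical covariates.

    ``data`` is indexed by sample id with columns ``survival_time`` (days),
    ``event`` (1=death, 0=censored) and any categorical covariate columns.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if "survival_time" not in self.data.columns or "event" not in self.data.columns:
            raise ValueError("clinical table requires survival_time and event columns")
        bad = self.data.index[self.data["survival_time"] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive survival times for samples: {bad}")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("survival_time", "event")]

    def covariate(self, name: str) -> pd.Series:
        return self.data[name]

    def subset(self, samples: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[samples].copy())


def read_clinical_tsv(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV, mapping raw fields onto the binary groupings.

    Numeric AFP is classed at 20, AJCC T stage as 1 vs >1, and Child-Pugh
    grade as 1 vs >1; already-classed string levels pass through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    df["survival_time"] = df["survival_time"].astype(float)
    df["event"] = df["event"].astype(int)
    if "afp" in df.columns:
        df["afp"] = [v if v in CLINICAL_LEVELS["afp"] else afp_class(v) for v in df["afp"]]
    if "ajcc_stage" in df.columns:
        df["ajcc_stage"] = [
            v if v in CLINICAL_LEVELS["ajcc_stage"] else stage_class(v) for v in df["ajcc_stage"]
        ]
    if "child_pugh" in df.columns:
        df["child_pugh"] = [child_pugh_class(v) for v in df["child_pugh"]]
    return ClinicalTable(df)


def write_clinical_tsv(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8")
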