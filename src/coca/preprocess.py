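"""Per-platform feature construction and variance filtering.

Each platform is reduced to a feature x sample matrix of the most variable
features:

* CNV: segments are collapsed to gene-level scores (length-weighted mean of
  overlapping log2 segment means), clipped to +/-2; genes with
  across-sample SD <= 0.2 are dropped.
* Methylation: CpG loci with any missing beta value are dropped; the 10000
  highest-SD loci are kept.
* mRNA: genes detected in all samples are log2-transformed with a floor at
  -26; the 6000 highest-SD genes are kept.
* miRNA: RPM values are log2-transformed with a floor at 0; the 80
  highest-SD miRNAs are kept.
* Mutation: gene x sample 0/1 matrix; never-mutated genes are dropped.

SD is the sample standard deviation (n-1 denominator) throughout, and
top-N selection breaks SD ties lexicographically by feature ID so runs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneInterval, SegmentRecord
from .types import PlatformMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "gene_level_cnv",
    "prep_methylation",
    "prep_expression",
    "prep_mirna",
    "build_mutation_matrix",
]


@dataclass
class PreprocessConfig:
    """Thresholds for per-platform preprocessing (defaults as published)."""

    cnv_clip: float = 2.0
    cnv_sd_min: float = 0.2
    cnv_length_weighted: bool = True
    meth_top_n: int = 10000
    mrna_floor: float = -26.0
    mrna_top_n: int = 6000
    mirna_floor: float = 0.0
    mirna_top_n: int = 80

    def __post_init__(self) -> None:
        if self.cnv_clip <= 0:
            raise ValueError("cnv_clip must be positive")
        for name in ("meth_top_n", "mrna_top_n", "mirna_top_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _row_sd(df: pd.DataFrame) -> pd.Series:
    return df.std(axis=1, ddof=1)


def _top_by_sd(df: pd.DataFrame, n: int) -> pd.DataFrame:
    """Keep the n highest-SD rows; ties broken lexicographically by id."""
    sd = _row_sd(df)
    order = sorted(df.index, key=lambda f: (-sd[f], str(f)))
    return df.loc[order[: min(n, len(order))]]


def gene_level_cnv(
    segments: Iterable[SegmentRecord],
    genes: Sequence[GeneInterval],
    config: PreprocessConfig | None = None,
) -> PlatformMatrix:
    """Collapse copy-number segments to gene-level scores.

    Each gene's score in a sample is the mean of the log2 segment means of
    the segments overlapping its interval, weighted by overlap length in
    base pairs (or unweighted if ``config.cnv_length_weighted`` is False).
    Scores are clipped to ``[-cnv_clip, +cnv_clip]``; genes not covered in
    some sample are dropped, then genes with SD <= ``cnv_sd_min`` across
    samples are removed.
    """
    config = config or PreprocessConfig()
    genes = list(genes)
    if not genes:
        raise ValueError("gene model is empty")
    segs = list(segments)
    if not segs:
        raise ValueError("no segments supplied")

    by_sample_chrom: dict[tuple[str, str], list[SegmentRecord]] = defaultdict(list)
    for s in segs:
        by_sample_chrom[(s.sample_id, s.chrom)].append(s)
    samples = sorted({s.sample_id for s in segs})

    values = np.full((len(genes), len(samples)), np.nan)
    for gi, gene in enumerate(genes):
        for si, sample in enumerate(samples):
            overlaps = [
                (min(gene.end, s.end) - max(gene.start, s.start) + 1, s.seg_mean)
                for s in by_sample_chrom.get((sample, gene.chrom), [])
                if s.start <= gene.end and s.end >= gene.start
            ]
            if not overlaps:
                continue
            w = np.array([o[0] for o in overlaps], dtype=float)
            m = np.array([o[1] for o in overlaps], dtype=float)
            if not config.cnv_length_weighted:
                w = np.ones_like(w)
            values[gi, si] = float(np.average(m, weights=w))

    df = pd.DataFrame(values, index=[g.gene_id for g in genes], columns=samples)
    uncovered = df.index[df.isna().any(axis=1)]
    if len(uncovered):
        logger.warning(
            "dropping %d genes without segment coverage in every sample (e.g. %s)",
            len(uncovered), list(uncovered[:3]),
        )
        df = df.drop(index=uncovered)
    df = df.clip(-config.cnv_clip, config.cnv_clip)
    df = df[_row_sd(df) > config.cnv_sd_min]
    if df.empty:
        raise ValueError("no genes survive CNV coverage and SD filtering")
    return PlatformMatrix("cnv", df, state="preprocessed")


def prep_methylation(matrix: PlatformMatrix, config: PreprocessConfig | None = None) -> PlatformMatrix:
    """Drop CpG loci with any missing beta, keep the top-SD loci."""
    config = config or PreprocessConfig()
    df = matrix.data.dropna(axis=0)
    if df.empty:
        raise ValueError("every methylation locus contains at least one NA")
    v = df.to_numpy()
    if v.min() < 0 or v.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    df = _top_by_sd(df, config.meth_top_n)
    return PlatformMatrix("meth", df, state="preprocessed")


def _log2_floor(df: pd.DataFrame, floor: float) -> pd.DataFrame:
    with np.errstate(divide="ignore"):
        logged = np.log2(df.to_numpy(dtype=float))
    return pd.DataFrame(np.maximum(logged, floor), index=df.index, columns=df.columns)


def prep_expression(matrix: PlatformMatrix, config: PreprocessConfig | None = None) -> PlatformMatrix:
    """log2 mRNA abundances with a floor, keep genes detected everywhere."""
    config = config or PreprocessConfig()
    df = matrix.data.dropna(axis=0)
    if df.empty:
        raise ValueError("no genes detected in all samples")
    if (df.to_numpy() < 0).any():
        raise ValueError("expression estimates must be nonnegative")
    df = _log2_floor(df, config.mrna_floor)
    df = _top_by_sd(df, config.mrna_top_n)
    return PlatformMatrix("mrna", df, state="preprocessed")


def prep_mirna(matrix: PlatformMatrix, config: PreprocessConfig | None = None) -> PlatformMatrix:
    """log2 miRNA RPM with a floor at 0, keep the top-SD miRNAs."""
    config = config or PreprocessConfig()
    df = matrix.data.dropna(axis=0)
    if df.empty:
        raise ValueError("no miRNAs detected in all samples")
    if (df.to_numpy() < 0).any():
        raise ValueError("RPM values must be nonnegative")
    df = _log2_floor(df, config.mirna_floor)
    df = _top_by_sd(df, config.mirna_top_n)
    return PlatformMatrix("mirna", df, state="preprocessed")


def build_mutation_matrix(
    calls: Iterable[tuple[str, str]], samples: Sequence[str]
) -> PlatformMatrix:
    """Build a dense gene x sample 0/1 somatic-mutation matrix.

    ``calls`` are (gene, sample) pairs; duplicates are idempotent. Genes
    with no mutation in any sample are excluded.
    """
    samples = list(samples)
    sample_set = set(samples)
    hits: dict[str, set[str]] = defaultdict(set)
    for gene, sample in calls:
        if sample not in sample_set:
            raise ValueError(f"mutation call references unknown sample {sample!r}")
        hits[gene].add(sample)
    genes = sorted(hits)
    values = np.zeros((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        for s in hits[g]:
            values[gi, samples.index(s)] = 1.0
    df = pd.DataFrame(values, index=genes, columns=samples)
    return PlatformMatrix("mut", df, state="preprocessed")
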