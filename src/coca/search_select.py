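"""Survival-guided selection of sub-cluster counts and final subgroups.

The search loops over combinations of per-platform sub-cluster counts.
For each combination it rebuilds the combined indicator matrix, consensus-
clusters the samples at every candidate subgroup count, and log-rank-tests
the resulting subgroups against survival. Significant combinations are
kept; the most recurrent sub-cluster count per platform wins, and the
final subgroups are called by consensus clustering at those counts with
the subgroup number chosen from the consensus-CDF delta-area curve.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coc_core import (
    COCMatrix,
    ConsensusResult,
    IndicatorRow,
    assemble_coc_matrix,
    binary_distance_matrix,
    consensus_sweep,
    indicator_rows_for_platform,
    select_k_delta_area,
    subcluster_features,
)
from .io_formats import ClinicalTable
from .survival_stats import logrank_test
from .types import PLATFORM_ORDER, PlatformMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "GridPoint",
    "SearchResult",
    "survival_guided_grid_search",
    "recurrence_mode_select",
    "finalize_subgroups",
    "loocv_accuracy",
]


@dataclass
class SearchConfig:
    """Grid ranges and knobs for the survival-guided search.

    Ranges are inclusive (lo, hi) per platform; ``budget`` caps the number
    of sub-cluster-count combinations evaluated (None = exhaustive, with
    seeded uniform subsampling otherwise). ``consensus_reps`` during the
    search is deliberately modest; the final call should use more.
    """

    ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"cnv": (2, 15), "mrna": (2, 15), "mirna": (2, 7), "meth": (2, 15)}
    )
    subgroup_range: tuple[int, int] = (2, 7)
    p_threshold: float = 0.05
    budget: int | None = 50
    consensus_reps: int = 30
    sample_fraction: float = 0.8
    min_group_size: int = 10
    stability_threshold: float = 0.05
    bh_correct: bool = False


@dataclass(frozen=True)
class GridPoint:
    """One (sub-cluster counts, subgroup count) combination and its test."""

    k_cnv: int
    k_mrna: int
    k_mirna: int
    k_meth: int
    k_subgroups: int
    logrank_p: float
    significant: bool

    def counts(self) -> dict[str, int]:
        return {"cnv": self.k_cnv, "mrna": self.k_mrna, "mirna": self.k_mirna, "meth": self.k_meth}


@dataclass
class SearchResult:
    evaluated: list[GridPoint]
    selected: dict[str, int]
    final_labels: pd.Series = field(repr=False)
    final_k: int = 0
    diagnostics: list[ConsensusResult] = field(default_factory=list, repr=False)


class _IndicatorCache:
    """Caches sub-clusterings and indicator rows per (platform, k)."""

    def __init__(self, platforms: Mapping[str, PlatformMatrix], min_group_size: int, seed: int):
        self.platforms = platforms
        self.min_group_size = min_group_size
        self.seed = seed
        self._rows: dict[tuple[str, int], list[IndicatorRow]] = {}

    def rows(self, kind: str, k: int) -> list[IndicatorRow]:
        key = (kind, k)
        if key not in self._rows:
            sc = subcluster_features(self.platforms[kind], k, seed=self.seed)
            self._rows[key] = indicator_rows_for_platform(
                self.platforms[kind], sc, min_group_size=self.min_group_size
            )
        return self._rows[key]

    def matrix(self, counts: Mapping[str, int], universe: Sequence[str]) -> COCMatrix:
        rows: list[IndicatorRow] = []
        for kind in PLATFORM_ORDER:
            rows.extend(self.rows(kind, counts[kind]))
        return assemble_coc_matrix(rows, universe)


def _common_samples(
    platforms: Mapping[str, PlatformMatrix], clinical: ClinicalTable
) -> list[str]:
    common = set(clinical.sample_ids)
    for pm in platforms.values():
        common &= set(pm.sample_ids)
    if not common:
        raise ValueError("no samples shared by all platforms and the clinical table")
    # keep the clinical table's order for determinism
    return [s for s in clinical.sample_ids if s in common]


def _clamped_ranges(
    config: SearchConfig, platforms: Mapping[str, PlatformMatrix]
) -> dict[str, tuple[int, int]]:
    out = {}
    for kind, (lo, hi) in config.ranges.items():
        nf = platforms[kind].n_features
        if hi > nf:
            logger.warning("%s: grid upper bound %d capped at feature count %d", kind, hi, nf)
            hi = nf
        if lo < 2 or lo > hi:
            raise ValueError(f"invalid sub-cluster range for {kind}: ({lo}, {hi})")
        out[kind] = (lo, hi)
    return out


def survival_guided_grid_search(
    platforms: Mapping[str, PlatformMatrix],
    clinical: ClinicalTable,
    config: SearchConfig | None = None,
    seed: int = 0,
) -> list[GridPoint]:
    """Evaluate sub-cluster-count combinations against survival.

    Returns one :class:`GridPoint` per (combination, subgroup count). The
    set of evaluated combinations, all clustering and all resampling are
    deterministic given ``(config, seed)``.
    """
    config = config or SearchConfig()
    samples = _common_samples(platforms, clinical)
    platforms = {k: pm.subset_samples(samples) for k, pm in platforms.items()}
    clin = clinical.subset(samples)
    ranges = _clamped_ranges(config, platforms)

    combos = list(
        itertools.product(*(range(lo, hi + 1) for lo, hi in (ranges[k] for k in PLATFORM_ORDER)))
    )
    rng = np.random.default_rng(seed)
    if config.budget is not None and config.budget < len(combos):
        pick = rng.choice(len(combos), size=config.budget, replace=False)
        combos = [combos[i] for i in sorted(pick)]

    cache = _IndicatorCache(platforms, config.min_group_size, seed)
    lo_k, hi_k = config.subgroup_range
    points: list[GridPoint] = []
    for combo in combos:
        counts = dict(zip(PLATFORM_ORDER, combo))
        coc = cache.matrix(counts, samples)
        sweep_seed = int(rng.integers(2**31))
        results = consensus_sweep(
            coc,
            range(lo_k, hi_k + 1),
            reps=config.consensus_reps,
            sample_fraction=config.sample_fraction,
            seed=sweep_seed,
        )
        for res in results:
            p = logrank_test(clin, res.labels).p_value
            points.append(
                GridPoint(
                    k_cnv=counts["cnv"],
                    k_mrna=counts["mrna"],
                    k_mirna=counts["mirna"],
                    k_meth=counts["meth"],
                    k_subgroups=res.k,
                    logrank_p=p,
                    significant=bool(p < config.p_threshold),
                )
            )
    if config.bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [pt.logrank_p for pt in points], alpha=config.p_threshold, method="fdr_bh"
        )
        points = [
            GridPoint(pt.k_cnv, pt.k_mrna, pt.k_mirna, pt.k_meth, pt.k_subgroups,
                      pt.logrank_p, bool(r))
            for pt, r in zip(points, reject)
        ]
    return points


def recurrence_mode_select(points: Sequence[GridPoint]) -> dict[str, int]:
    """Per-platform modal sub-cluster count among significant grid points.

    Ties are broken toward the smaller count. The result is invariant to
    the order of the grid points.
    """
    sig = [p for p in points if p.significant]
    if not sig:
        raise ValueError(
            "no significant grid point; widen the grid, raise the budget, "
            "or relax the significance threshold"
        )
    selected: dict[str, int] = {}
    for kind in PLATFORM_ORDER:
        counts = pd.Series([p.counts()[kind] for p in sig]).value_counts()
        top = counts[counts == counts.max()].index
        chosen = int(min(top))
        if len(top) > 1:
            logger.info("%s: modal count tie among %s; choosing %d", kind, sorted(top), chosen)
        selected[kind] = chosen
    return selected


def finalize_subgroups(
    platforms: Mapping[str, PlatformMatrix],
    selected: Mapping[str, int],
    subgroup_range: tuple[int, int] = (2, 7),
    seed: int = 0,
    reps: int = 1000,
    sample_fraction: float = 0.8,
    min_group_size: int = 10,
    stability_threshold: float = 0.05,
) -> SearchResult:
    """Call final subgroups at the selected per-platform sub-cluster counts.

    Rebuilds the combined indicator matrix, consensus-clusters over the
    subgroup range, and picks the subgroup count by the delta-area rule.
    """
    universe = None
    for pm in platforms.values():
        s = set(pm.sample_ids)
        universe = s if universe is None else universe & s
    samples = [s for s in next(iter(platforms.values())).sample_ids if s in universe]
    platforms = {k: pm.subset_samples(samples) for k, pm in platforms.items()}

    cache = _IndicatorCache(platforms, min_group_size, seed)
    coc = cache.matrix(dict(selected), samples)
    lo_k, hi_k = subgroup_range
    results = consensus_sweep(
        coc, range(lo_k, hi_k + 1), reps=reps, sample_fraction=sample_fraction, seed=seed
    )
    k = select_k_delta_area(results, threshold=stability_threshold)
    chosen = next(r for r in results if r.k == k)
    return SearchResult(
        evaluated=[],
        selected=dict(selected),
        final_labels=chosen.labels,
        final_k=k,
        diagnostics=results,
    )


def loocv_accuracy(matrix: COCMatrix, labels: Mapping[str, int] | pd.Series) -> float:
    """Leave-one-out nearest-centroid accuracy on the indicator matrix.

    Each sample is re-assigned to the nearest subgroup centroid (computed
    without it) under the NA-tolerant mean absolute difference over
    indicator rows, and compared with its own label. Samples in singleton
    subgroups are skipped (their centroid would be empty) and removed from
    the denominator.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample in the matrix needs a label")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups")

    X = matrix.values.to_numpy(dtype=float)  # rows x samples
    n = X.shape[1]
    lab = labels.to_numpy()
    sizes = pd.Series(lab).value_counts()
    skipped = [g for g in groups if sizes[g] < 2]
    if skipped:
        logger.warning("skipping singleton subgroups in LOOCV: %s", skipped)

    correct = total = 0
    for i in range(n):
        if lab[i] in skipped:
            continue
        dists = []
        for g in groups:
            members = np.where((lab == g) & (np.arange(n) != i))[0]
            if members.size == 0:
                dists.append(np.inf)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NA rows
                centroid = np.nanmean(X[:, members], axis=1)
            diff = np.abs(X[:, i] - centroid)
            ok = ~np.isnan(diff)
            dists.append(float(np.mean(diff[ok])) if ok.any() else np.inf)
        pred = groups[int(np.argmin(dists))]
        correct += int(pred == lab[i])
        total += 1
    if total == 0:
        raise ValueError("no sample eligible for LOOCV")
    return correct / total
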