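"""Cluster-of-clusters core: feature sub-clustering, binary indicators,
matrix assembly and resampling consensus clustering.

The integration works in three moves:

1. Features on each platform are grouped into k "sub-clusters"
   (hierarchical clustering with correlation distance by default).
2. Each sub-cluster's member features split the samples into two groups
   (Ward 2-cut). The split becomes a 0/1 indicator row over samples —
   unless either side has fewer than ``min_group_size`` samples, in which
   case the whole row is NA and carries no information.
3. The stacked indicator rows from all platforms form one binary matrix,
   and the samples are clustered on it by resampling consensus clustering
   with an NA-tolerant Hamming distance. The number of subgroups is read
   off the consensus CDF's delta-area curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import PLATFORM_ORDER, PlatformMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSubclusters",
    "IndicatorRow",
    "COCMatrix",
    "ConsensusResult",
    "subcluster_features",
    "indicator_from_subcluster",
    "indicator_rows_for_platform",
    "assemble_coc_matrix",
    "binary_distance_matrix",
    "consensus_cluster",
    "consensus_sweep",
    "select_k_delta_area",
]


@dataclass
class FeatureSubclusters:
    """Assignment of one platform's features to k sub-clusters (1..k)."""

    platform: str
    k: int
    assignment: Mapping[str, int]

    def members(self, index: int) -> list[str]:
        return [f for f, c in self.assignment.items() if c == index]

    def __post_init__(self) -> None:
        got = set(self.assignment.values())
        if got != set(range(1, self.k + 1)):
            raise ValueError(f"sub-cluster indices {sorted(got)} != 1..{self.k}")


@dataclass
class IndicatorRow:
    """Per-sample 0/1 labels from one sub-cluster's two-way sample split.

    ``labels`` is indexed by sample id with values 0.0, 1.0 or NaN. A row is
    either entirely NA (the split violated the minimum group size) or fully
    labeled with both groups at least ``min_group_size`` strong.
    """

    platform: str
    subcluster_index: int
    labels: pd.Series = field(repr=False)

    @property
    def is_all_na(self) -> bool:
        return bool(self.labels.isna().all())


@dataclass
class COCMatrix:
    """Stacked indicator rows over the common sample universe."""

    values: pd.DataFrame = field(repr=False)  # rows x samples, {0,1,NaN}
    row_meta: list[tuple[str, int]] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass
class ConsensusResult:
    """Consensus clustering output for one candidate subgroup count."""

    k: int
    consensus: np.ndarray = field(repr=False)
    labels: pd.Series = field(repr=False)
    cdf_area: float = 0.0
    delta_area: float = float("nan")

    def validate(self) -> None:
        c = self.consensus
        assert np.allclose(c, c.T), "consensus matrix not symmetric"
        assert np.allclose(np.diag(c), 1.0), "consensus diagonal != 1"
        assert c.min() >= 0 and c.max() <= 1 + 1e-12, "consensus outside [0,1]"


# ---------------------------------------------------------------------------
# Step 1: feature sub-clustering


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; zero-variance rows get r=0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    return np.clip((dist + dist.T) / 2.0, 0.0, None)


def subcluster_features(
    matrix: PlatformMatrix,
    k: int,
    seed: int = 0,
    method: str = "hierarchical",
) -> FeatureSubclusters:
    """Divide a platform's features into k sub-clusters.

    Default is average-linkage hierarchical clustering with correlation
    distance (1 - Pearson across samples); ``method="kmeans"`` uses
    seeded k-means on the feature vectors instead. The result is
    deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.n_features:
        raise ValueError(f"k={k} exceeds feature count {matrix.n_features}")
    features = matrix.feature_ids
    if k == matrix.n_features:
        return FeatureSubclusters(matrix.kind, k, {f: i + 1 for i, f in enumerate(features)})

    values = matrix.data.to_numpy(dtype=float)
    if method == "hierarchical":
        dist = _correlation_distance(values)
        Z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(Z, t=k, criterion="maxclust")
        raw = _repair_cluster_count(raw, dist, k)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(values) + 1
        raw = _repair_cluster_count(np.asarray(raw), None, k)
    else:
        raise ValueError(f"unknown method {method!r}")

    # renumber clusters 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    assignment = {}
    for f, c in zip(features, raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        assignment[f] = remap[c]
    return FeatureSubclusters(matrix.kind, k, assignment)


def _repair_cluster_count(labels: np.ndarray, dist: np.ndarray | None, k: int) -> np.ndarray:
    """Ensure exactly k nonempty clusters by peeling members off the largest.

    Degenerate tie structures can make a maxclust cut return fewer than k
    clusters; the farthest member of the largest cluster (or the last one,
    without a distance matrix) is promoted to a fresh singleton until the
    count is right.
    """
    labels = labels.copy()
    while len(set(labels)) < k:
        sizes = pd.Series(labels).value_counts()
        big = sizes.index[0]
        members = np.where(labels == big)[0]
        if dist is not None:
            within = dist[np.ix_(members, members)].sum(axis=1)
            move = members[int(np.argmax(within))]
        else:
            move = members[-1]
        labels[move] = max(labels) + 1
    return labels


# ---------------------------------------------------------------------------
# Steps 2-4: indicator rows


def indicator_from_subcluster(
    matrix: PlatformMatrix,
    members: Sequence[str],
    min_group_size: int = 10,
    subcluster_index: int = 1,
) -> IndicatorRow:
    """Split the samples in two by one sub-cluster's features.

    Samples are clustered (Ward, Euclidean) on the member-feature
    submatrix and cut at 2. If either group has fewer than
    ``min_group_size`` samples the row is entirely NA. Otherwise the group
    with the higher mean feature value is labeled 1.
    """
    members = [m for m in members if m in matrix.data.index]
    if not members:
        raise ValueError("sub-cluster members not found in matrix")
    sub = matrix.data.loc[members]
    n = sub.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples to split")

    X = sub.to_numpy(dtype=float).T  # samples x features
    Z = linkage(X, method="ward")
    halves = fcluster(Z, t=2, criterion="maxclust")

    samples = list(sub.columns)
    sizes = np.bincount(halves)[1:]
    if sizes.min() < min_group_size:
        labels = pd.Series(np.nan, index=samples)
        return IndicatorRow(matrix.kind, subcluster_index, labels)

    means = [X[halves == g].mean() for g in (1, 2)]
    if means[0] == means[1]:  # deterministic tie-break: group of lowest sample id wins
        first = min(range(n), key=lambda i: str(samples[i]))
        one = halves[first]
    else:
        one = 1 if means[0] > means[1] else 2
    labels = pd.Series((halves == one).astype(float), index=samples)
    return IndicatorRow(matrix.kind, subcluster_index, labels)


def indicator_rows_for_platform(
    matrix: PlatformMatrix,
    subclusters: FeatureSubclusters,
    min_group_size: int = 10,
) -> list[IndicatorRow]:
    """One indicator row per sub-cluster, in sub-cluster order."""
    return [
        indicator_from_subcluster(
            matrix, subclusters.members(i), min_group_size=min_group_size, subcluster_index=i
        )
        for i in range(1, subclusters.k + 1)
    ]


# ---------------------------------------------------------------------------
# Step 5: assembly


def assemble_coc_matrix(rows: Iterable[IndicatorRow], sample_universe: Sequence[str]) -> COCMatrix:
    """Stack indicator rows into the combined binary matrix.

    Rows are ordered by platform (CNV, mRNA, miRNA, methylation) and then
    sub-cluster index. All rows must be indexed over exactly the sample
    universe; all-NA rows are retained (they carry no information but
    preserve the row accounting).
    """
    universe = list(sample_universe)
    uset = set(universe)
    rows = list(rows)
    for r in rows:
        rset = set(r.labels.index)
        if rset != uset:
            missing = sorted(uset - rset)[:5]
            extra = sorted(rset - uset)[:5]
            raise ValueError(
                f"indicator row {r.platform}{r.subcluster_index} sample set mismatch; "
                f"missing={missing} extra={extra}"
            )
    order = {p: i for i, p in enumerate(PLATFORM_ORDER)}
    rows.sort(key=lambda r: (order.get(r.platform, len(order)), r.subcluster_index))
    values = pd.DataFrame(
        [r.labels.reindex(universe).to_numpy() for r in rows],
        index=[f"{r.platform}{r.subcluster_index}" for r in rows],
        columns=universe,
        dtype=float,
    )
    return COCMatrix(values=values, row_meta=[(r.platform, r.subcluster_index) for r in rows])


# ---------------------------------------------------------------------------
# Steps 6 & 9: consensus clustering


def binary_distance_matrix(matrix: COCMatrix) -> np.ndarray:
    """Pairwise NA-tolerant Hamming distance between samples.

    The distance between two samples is the mismatch fraction over the
    indicator rows where both are non-NA; pairs with no mutually observed
    row get the maximally ambiguous value 0.5.
    """
    X = matrix.values.to_numpy(dtype=float)
    O = (~np.isnan(X)).astype(float)
    B = np.nan_to_num(X, nan=0.0)
    both = O.T @ O
    mism = B.T @ O + O.T @ B - 2.0 * (B.T @ B)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(both > 0, mism / np.maximum(both, 1), 0.5)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    if vals.size == 0:
        return 0.0
    xs = np.concatenate(([0.0], vals, [1.0]))
    F = np.arange(0, vals.size + 1) / vals.size
    F = np.concatenate((F, [1.0]))
    return float(np.sum(np.diff(xs) * F[:-1]))


def consensus_cluster(
    matrix: COCMatrix,
    k: int,
    reps: int = 1000,
    sample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampling consensus clustering of samples at one subgroup count."""
    return consensus_sweep(matrix, [k], reps=reps, sample_fraction=sample_fraction, seed=seed)[0]


def consensus_sweep(
    matrix: COCMatrix,
    ks: Sequence[int],
    reps: int = 1000,
    sample_fraction: float = 0.8,
    seed: int = 0,
) -> list[ConsensusResult]:
    """Consensus clustering over several subgroup counts.

    Each rep draws ``floor(sample_fraction * n)`` samples without
    replacement, builds one average-linkage tree on the NA-tolerant binary
    distance, and cuts it at every k — sharing the tree across k keeps the
    per-k consensus matrices mutually consistent and the sweep tractable.
    Consensus(i, j) is the co-clustering count over the co-sampling count;
    final labels cut an average-linkage tree on 1 - consensus.
    """
    n = len(matrix.sample_ids)
    ks = sorted(set(int(k) for k in ks))
    if min(ks) < 2:
        raise ValueError("subgroup count must be >= 2")
    if max(ks) > n:
        raise ValueError(f"k={max(ks)} exceeds sample count {n}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0 < sample_fraction <= 1):
        raise ValueError("sample_fraction must be in (0, 1]")

    D = binary_distance_matrix(matrix)
    m = int(np.floor(sample_fraction * n))
    m = max(m, max(ks))
    rng = np.random.default_rng(seed)

    co = {k: np.zeros((n, n)) for k in ks}
    counted = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        counted[np.ix_(idx, idx)] += 1
        for k in ks:
            part = fcluster(Z, t=k, criterion="maxclust")
            for g in np.unique(part):
                members = idx[part == g]
                co[k][np.ix_(members, members)] += 1

    never = (counted == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning(
            "%d sample pairs never co-sampled (reps too low); consensus set to 0",
            int(never.sum()) // 2,
        )
    results = []
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(counted > 0, co[k] / np.maximum(counted, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        # Ward-style cut favors balanced subgroups; degenerate near-singleton
        # subgroups are both biologically meaningless and break the
        # chi-square approximation of the downstream log-rank test.
        Zc = linkage(squareform(np.clip(1.0 - cons, 0, None), checks=False), method="ward")
        lab = fcluster(Zc, t=k, criterion="maxclust")
        labels = pd.Series(lab, index=matrix.sample_ids)
        results.append(ConsensusResult(k=k, consensus=cons, labels=labels, cdf_area=_cdf_area(cons)))
    for i, res in enumerate(results):
        if i == 0 and res.k == 2:
            res.delta_area = res.cdf_area
        elif i > 0 and results[i - 1].k == res.k - 1:
            prev = results[i - 1].cdf_area
            res.delta_area = (res.cdf_area - prev) / prev if prev > 0 else 0.0
    return results


def _ambiguous_fraction(consensus: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    iu = np.triu_indices(consensus.shape[0], k=1)
    v = consensus[iu]
    return float(((v > lo) & (v < hi)).mean()) if v.size else 0.0


def select_k_delta_area(
    results: Sequence[ConsensusResult],
    threshold: float = 0.05,
    ambiguity_threshold: float = 0.4,
) -> int:
    """Choose the subgroup count from the consensus-CDF delta-area curve.

    The chosen k is the largest whose relative delta-area exceeds the
    stability threshold — the elbow after which adding clusters stops
    changing the consensus distribution. If the consensus matrix at that k
    is still mostly ambiguous (more than ``ambiguity_threshold`` of its
    entries strictly between 0.1 and 0.9), no k is genuinely stable — on
    unstructured data the delta-area curve decays too slowly to ever fall
    below the threshold — and the minimum k is returned with a warning.
    """
    results = sorted(results, key=lambda r: r.k)
    if len(results) == 1:
        logger.warning("single candidate k supplied; returning it")
        return results[0].k
    ks = [r.k for r in results]
    if ks != list(range(ks[0], ks[0] + len(ks))):
        raise ValueError("results must cover consecutive k")
    stable = [r for r in results if np.isfinite(r.delta_area) and r.delta_area > threshold]
    if not stable:
        logger.warning("no k exceeds the delta-area threshold; structure looks unstable")
        return results[0].k
    best = max(stable, key=lambda r: r.k)
    if _ambiguous_fraction(best.consensus) > ambiguity_threshold:
        logger.warning(
            "consensus at k=%d is mostly ambiguous; no stable subgroup structure, "
            "returning minimum k", best.k,
        )
        return results[0].k
    return best.k
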