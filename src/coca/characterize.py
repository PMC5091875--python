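"""Subgroup characterization: contingency associations, proportions,
one-vs-rest AUC biomarker ranking and differential signature tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import PlatformMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "AUCRecord",
    "association_test",
    "subgroup_proportions",
    "feature_auc_onevsrest",
    "subgroup_signature_table",
]


@dataclass
class AssociationResult:
    covariate: str
    contingency: pd.DataFrame = field(repr=False)  # groups x levels
    test: str = "fisher"
    p_value: float = float("nan")


@dataclass(frozen=True)
class AUCRecord:
    feature_id: str
    subgroup: object
    auc: float
    direction_free_auc: float


def _as_series(mapping: Mapping[str, object] | pd.Series, name: str) -> pd.Series:
    s = pd.Series(dict(mapping) if not isinstance(mapping, pd.Series) else mapping)
    if s.isna().any():
        raise ValueError(f"{name} contains missing values")
    return s


def association_test(
    labels: Mapping[str, object] | pd.Series,
    covariate: Mapping[str, object] | pd.Series,
    test: str = "fisher",
    name: str = "covariate",
    seed: int = 0,
    n_simulations: int = 20000,
) -> AssociationResult:
    """Test association between subgroup labels and a categorical covariate.

    ``test="fisher"`` uses the exact hypergeometric test for 2x2 tables and
    a seeded Monte Carlo permutation of the covariate (chi-square statistic)
    for larger tables; ``test="chi_square"`` uses the asymptotic chi-square
    test throughout.
    """
    lab = _as_series(labels, "labels")
    cov = _as_series(covariate, "covariate").reindex(lab.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some labeled samples")
    table = pd.crosstab(lab, cov)
    if table.shape[0] < 2:
        raise ValueError("need at least 2 subgroups")
    if table.shape[1] < 2:
        raise ValueError(f"covariate {name!r} has a single level")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")

    if test == "chi_square":
        p = float(stats.chi2_contingency(table.to_numpy())[1])
    elif test == "fisher":
        if table.shape == (2, 2):
            p = float(stats.fisher_exact(table.to_numpy())[1])
        else:
            p = _permutation_chi2_p(lab, cov, seed=seed, n=n_simulations)
    else:
        raise ValueError(f"unknown test {test!r}")
    return AssociationResult(covariate=name, contingency=table, test=test, p_value=p)


def _chi2_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _permutation_chi2_p(lab: pd.Series, cov: pd.Series, seed: int, n: int) -> float:
    """Monte Carlo p for RxC tables: permute the covariate, compare chi2."""
    rng = np.random.default_rng(seed)
    li = pd.factorize(lab)[0]
    ci = pd.factorize(cov)[0]
    nl, nc = li.max() + 1, ci.max() + 1

    def table(c):
        return np.bincount(li * nc + c, minlength=nl * nc).reshape(nl, nc).astype(float)

    observed = _chi2_stat(table(ci))
    ci = ci.copy()
    hits = 0
    for _ in range(n):
        rng.shuffle(ci)
        hits += _chi2_stat(table(ci)) >= observed - 1e-12
    return (hits + 1) / (n + 1)


def subgroup_proportions(
    labels: Mapping[str, object] | pd.Series,
    covariate: Mapping[str, object] | pd.Series,
    focus_groups: Iterable[object],
    focus_level: object,
) -> tuple[float, int]:
    """Percentage of focus-level samples within the focus subgroups.

    Returns ``(percentage, rounded_percent)`` — the unrounded value and its
    nearest-integer display form.
    """
    lab = _as_series(labels, "labels")
    cov = _as_series(covariate, "covariate").reindex(lab.index)
    focus = set(focus_groups)
    if not focus:
        raise ValueError("focus group set is empty")
    mask = lab.isin(focus)
    denom = int(mask.sum())
    if denom == 0:
        raise ValueError("no samples in the focus subgroups")
    count = int((cov[mask] == focus_level).sum())
    pct = 100.0 * count / denom
    return pct, int(round(pct))


def feature_auc_onevsrest(
    values: Mapping[str, float] | pd.Series,
    labels: Mapping[str, object] | pd.Series,
    subgroup: object,
    feature_id: str = "feature",
) -> AUCRecord:
    """One-vs-rest ROC AUC of a feature for one subgroup.

    Orientation is fixed (higher value scores the subgroup as positive);
    tied values contribute 1/2, i.e. the Mann-Whitney U identity
    AUC = U / (n_pos * n_neg). ``direction_free_auc`` is max(AUC, 1-AUC).
    """
    vals = _as_series(values, "values").astype(float)
    lab = _as_series(labels, "labels").reindex(vals.index)
    pos = (lab == subgroup).to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("subgroup must be a proper nonempty subset of the samples")
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(pos.astype(int), vals.to_numpy()))
    return AUCRecord(feature_id=feature_id, subgroup=subgroup, auc=auc,
                     direction_free_auc=max(auc, 1.0 - auc))


def subgroup_signature_table(
    platforms: Mapping[str, PlatformMatrix] | Sequence[PlatformMatrix],
    labels: Mapping[str, object] | pd.Series,
    alpha: float = 0.05,
    top_n: int = 10,
) -> pd.DataFrame:
    """Per-subgroup differential features across platforms.

    For every subgroup and platform, each feature is tested subgroup vs
    rest with the Wilcoxon rank-sum test; p-values are Benjamini-Hochberg
    adjusted within (platform, subgroup). Returns a tidy table of the
    significant features (q < alpha, at most ``top_n`` per cell) with the
    effect direction (sign of the median difference).
    """
    if not isinstance(platforms, Mapping):
        platforms = {pm.kind: pm for pm in platforms}
    lab = _as_series(labels, "labels")
    rows = []
    for kind, pm in platforms.items():
        common = [s for s in pm.sample_ids if s in lab.index]
        data = pm.data[common]
        groups = lab.reindex(common)
        for g in sorted(groups.unique()):
            mask = (groups == g).to_numpy()
            if mask.sum() == 0 or mask.all():
                continue
            X = data.to_numpy(dtype=float)
            inside, outside = X[:, mask], X[:, ~mask]
            stat_p = stats.ranksums(inside, outside, axis=1)
            pvals = np.asarray(stat_p.pvalue)
            reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
            direction = np.sign(np.median(inside, axis=1) - np.median(outside, axis=1))
            for idx in np.argsort(pvals):
                if not reject[idx]:
                    continue
                rows.append(
                    {
                        "platform": kind,
                        "subgroup": g,
                        "feature_id": data.index[idx],
                        "p_value": float(pvals[idx]),
                        "q_value": float(qvals[idx]),
                        "direction": "up" if direction[idx] > 0 else "down",
                    }
                )
            # cap per (platform, subgroup)
            cell = [r for r in rows if r["platform"] == kind and r["subgroup"] == g]
            if len(cell) > top_n:
                keep = set(id(r) for r in cell[:top_n])
                rows = [r for r in rows
                        if not (r["platform"] == kind and r["subgroup"] == g and id(r) not in keep)]
    return pd.DataFrame(
        rows, columns=["platform", "subgroup", "feature_id", "p_value", "q_value", "direction"]
    )
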