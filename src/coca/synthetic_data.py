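"""Synthetic multi-omics generator with planted sample subgroups.

The generator emulates the statistical structure the cluster-of-clusters
analysis assumes: each platform's features come in correlated blocks, and
each block is "active" in a subset of the sample subgroups — active
samples get a mean shift of ``effect`` (in units of the per-feature noise
SD). Block activation patterns cycle through the subgroups (singletons
first, then adjacent pairs), so the stacked block indicators jointly
identify every subgroup.

Platform value scales mimic their real counterparts: CNV is emitted as
per-sample segment records in log2-ratio units (so the gene-overlap code
path is exercised), methylation betas are a logistic map of the Gaussian
latent, and mRNA/miRNA are emitted as 2**latent abundances so the log2
preprocessing recovers the latent scale. Survival is exponential with
per-subgroup log-hazard offsets; censoring is independent exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import ClinicalTable, GeneInterval, SegmentRecord, afp_class
from .preprocess import (
    PreprocessConfig,
    build_mutation_matrix,
    gene_level_cnv,
    prep_expression,
    prep_methylation,
    prep_mirna,
)
from .types import PlatformMatrix

__all__ = [
    "PlatformSpec",
    "SurvivalSpec",
    "MutationSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_multiomics",
    "simulate_survival",
]


@dataclass(frozen=True)
class PlatformSpec:
    """Block-model parameters for one platform.

    ``effect`` is the active-subgroup mean shift in noise-SD units;
    ``block_sd`` is the SD of the per-(block, sample) shared latent that
    makes features within a block correlated.
    """

    n_features: int
    n_blocks: int
    effect: float
    noise_sd: float = 1.0
    block_sd: float = 0.8
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential survival model with per-subgroup log-hazard offsets."""

    baseline_hazard: float = 1.0 / 400.0  # events per day
    log_hazard_offsets: tuple[float, ...] | None = None  # default: spread for HR 3
    hazard_ratio_extremes: float = 3.0
    censoring_rate: float = 0.3

    def offsets(self, n_subgroups: int) -> np.ndarray:
        if self.log_hazard_offsets is not None:
            if len(self.log_hazard_offsets) != n_subgroups:
                raise ValueError("log_hazard_offsets length must equal n_subgroups")
            return np.asarray(self.log_hazard_offsets, dtype=float)
        half = np.log(self.hazard_ratio_extremes) / 2.0
        return np.linspace(half, -half, n_subgroups)


@dataclass(frozen=True)
class MutationSpec:
    n_genes: int = 30
    baseline_rate: float = 0.05
    enriched_rate: float = 0.45
    enriched_per_subgroup: int = 2


@dataclass
class SyntheticConfig:
    """Full study configuration; defaults give a clearly separable study.

    The defaults plant 5 subgroups of equal size with per-platform block
    effects of 2 noise-SD (CNV uses log2-ratio units with the same 2-SD
    effect-to-noise ratio) and an extreme-to-extreme hazard ratio of 3.
    """

    n_samples: int = 250
    n_subgroups: int = 5
    proportions: tuple[float, ...] | None = None  # default: equal
    cnv: PlatformSpec = field(default_factory=lambda: PlatformSpec(
        n_features=100, n_blocks=5, effect=0.5, noise_sd=0.25, block_sd=0.0,
        baseline_mean=0.0, baseline_sd=0.0))
    mrna: PlatformSpec = field(default_factory=lambda: PlatformSpec(
        n_features=300, n_blocks=10, effect=2.0, baseline_mean=5.0, baseline_sd=2.0))
    mirna: PlatformSpec = field(default_factory=lambda: PlatformSpec(
        n_features=80, n_blocks=5, effect=2.0, baseline_mean=6.0, baseline_sd=1.5))
    meth: PlatformSpec = field(default_factory=lambda: PlatformSpec(
        n_features=240, n_blocks=8, effect=2.0, baseline_mean=0.0, baseline_sd=1.5))
    prot: PlatformSpec = field(default_factory=lambda: PlatformSpec(
        n_features=40, n_blocks=5, effect=1.5, baseline_mean=0.0, baseline_sd=0.5))
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    mutation: MutationSpec = field(default_factory=MutationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroups < 2:
            raise ValueError("need at least 2 subgroups")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if len(p) != self.n_subgroups:
                raise ValueError("proportions length must equal n_subgroups")
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("proportions must be nonnegative and sum to 1")
        if self.survival.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not (0 <= self.survival.censoring_rate < 1):
            raise ValueError("censoring rate must be in [0, 1)")
        for spec in (self.cnv, self.mrna, self.mirna, self.meth, self.prot):
            if spec.effect < 0 or spec.noise_sd <= 0:
                raise ValueError("effect must be >= 0 and noise_sd > 0")
            if spec.n_blocks > spec.n_features:
                raise ValueError("more blocks than features")

    def null(self) -> "SyntheticConfig":
        """A copy with no planted structure: zero effects, equal hazards."""
        return replace(
            self,
            cnv=replace(self.cnv, effect=0.0),
            mrna=replace(self.mrna, effect=0.0),
            mirna=replace(self.mirna, effect=0.0),
            meth=replace(self.meth, effect=0.0),
            prot=replace(self.prot, effect=0.0),
            survival=replace(self.survival, hazard_ratio_extremes=1.0, log_hazard_offsets=None),
            mutation=replace(self.mutation, enriched_rate=self.mutation.baseline_rate),
        )


@dataclass
class SyntheticDataset:
    """One simulated study: four platforms plus mutation, protein, clinical."""

    sample_ids: list[str]
    true_labels: pd.Series = field(repr=False)
    cnv_segments: list[SegmentRecord] = field(repr=False)
    gene_model: list[GeneInterval] = field(repr=False)
    meth: PlatformMatrix = field(repr=False)
    mrna: PlatformMatrix = field(repr=False)
    mirna: PlatformMatrix = field(repr=False)
    mutation: PlatformMatrix = field(repr=False)
    protein: PlatformMatrix = field(repr=False)
    clinical: ClinicalTable = field(repr=False)

    def preprocessed_platforms(
        self, config: PreprocessConfig | None = None
    ) -> dict[str, PlatformMatrix]:
        """Run the standard preprocessing on all four integrated platforms."""
        config = config or PreprocessConfig()
        return {
            "cnv": gene_level_cnv(self.cnv_segments, self.gene_model, config),
            "mrna": prep_expression(self.mrna, config),
            "mirna": prep_mirna(self.mirna, config),
            "meth": prep_methylation(self.meth, config),
        }


def _block_active_sets(n_blocks: int, n_subgroups: int) -> list[frozenset[int]]:
    """Cycle singleton subgroups, then adjacent pairs, as block activations."""
    sets = []
    for b in range(n_blocks):
        if b < n_subgroups or n_subgroups == 1:
            sets.append(frozenset({b % n_subgroups}))
        else:
            g = b % n_subgroups
            sets.append(frozenset({g, (g + 1) % n_subgroups}))
    return sets


def _block_latent(
    spec: PlatformSpec, labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[frozenset[int]], np.ndarray]:
    """Feature x sample latent Gaussian matrix under the block model."""
    n = labels.size
    n_subgroups = int(labels.max()) + 1
    active = _block_active_sets(spec.n_blocks, n_subgroups)
    block_of = np.repeat(np.arange(spec.n_blocks), int(np.ceil(spec.n_features / spec.n_blocks)))
    block_of = block_of[: spec.n_features]
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_features)
    shared = rng.normal(0.0, spec.block_sd, size=(spec.n_blocks, n))
    is_active = np.array(
        [[1.0 if labels[i] in active[b] else 0.0 for i in range(n)] for b in range(spec.n_blocks)]
    )
    shift = spec.effect * spec.noise_sd * is_active + shared
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_features, n))
    latent = baseline[:, None] + shift[block_of] + noise
    return latent, active, block_of


def simulate_survival(
    labels: Sequence[int] | pd.Series, config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Exponential survival with subgroup-specific hazards.

    Returns a DataFrame (indexed like ``labels`` if it is a Series) with
    ``survival_time`` in days and ``event``. The censoring distribution is
    exponential with its rate set so the expected censored fraction is
    approximately ``censoring_rate``.
    """
    if isinstance(labels, pd.Series):
        index, lab = labels.index, labels.to_numpy()
    else:
        lab = np.asarray(labels)
        index = pd.RangeIndex(len(lab))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    offsets = config.survival.offsets(config.n_subgroups)
    rates = config.survival.baseline_hazard * np.exp(offsets[lab])
    t_event = rng.exponential(1.0 / rates)
    c = config.survival.censoring_rate
    if c > 0:
        censor_rate = float(np.mean(rates)) * c / (1.0 - c)
        t_censor = rng.exponential(1.0 / censor_rate, size=lab.size)
    else:
        t_censor = np.full(lab.size, np.inf)
    time = np.maximum(np.minimum(t_event, t_censor), 0.5)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({"survival_time": time, "event": event}, index=index)


def _simulate_cnv_segments(
    spec: PlatformSpec, labels: np.ndarray, sample_ids: Sequence[str], rng: np.random.Generator
) -> tuple[list[SegmentRecord], list[GeneInterval]]:
    """Emit per-sample segments whose gene-level means follow the block model.

    Genes sit on one chromosome at 10 kb spacing; each block's region is
    emitted as two segments per sample split at a random gene boundary, so
    the overlap-averaging code sees multi-segment genespans.
    """
    n_subgroups = int(labels.max()) + 1
    active = _block_active_sets(spec.n_blocks, n_subgroups)
    gpb = int(np.ceil(spec.n_features / spec.n_blocks))
    genes = [
        GeneInterval(f"gene_{g:04d}", "1", g * 10_000 + 1, g * 10_000 + 6_000)
        for g in range(spec.n_features)
    ]
    segments: list[SegmentRecord] = []
    for si, sample in enumerate(sample_ids):
        for b in range(spec.n_blocks):
            lo = b * gpb
            hi = min((b + 1) * gpb, spec.n_features) - 1
            if lo > hi:
                continue
            value = spec.effect * (1.0 if labels[si] in active[b] else 0.0)
            value += rng.normal(0.0, spec.noise_sd)
            start = genes[lo].start
            end = genes[hi].end + 4_000  # pad to the next gene boundary
            if hi > lo:
                split_gene = int(rng.integers(lo, hi))
                mid = genes[split_gene].end + 4_000
                jit = rng.normal(0.0, 0.02, size=2)
                segments.append(SegmentRecord(sample, "1", start, mid, value + jit[0]))
                segments.append(SegmentRecord(sample, "1", mid + 1, end, value + jit[1]))
            else:
                segments.append(SegmentRecord(sample, "1", start, end, value))
    return segments, genes


def _simulate_clinical_covariates(
    labels: np.ndarray, n_subgroups: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Categorical covariates with subgroup-biased level frequencies."""
    last_two = {n_subgroups - 2, n_subgroups - 1}
    ends = {0, n_subgroups - 1}
    best = min(2, n_subgroups - 1)  # the "good prognosis" subgroup
    n = labels.size
    p_female = np.where(np.isin(labels, list(last_two)), 0.65, 0.25)
    p_alcohol = np.where(np.isin(labels, list(ends)), 0.55, 0.30)
    afp_mu = np.where(labels == best, 2.2, 3.6)
    p_stage1 = np.where(np.isin(labels, list(ends)), 0.12, 0.45)
    return pd.DataFrame(
        {
            "gender": np.where(rng.random(n) < p_female, "Female", "Male"),
            "alcohol": np.where(rng.random(n) < p_alcohol, "YES", "NO"),
            "afp": [afp_class(v) for v in np.exp(rng.normal(afp_mu, 1.0))],
            "ajcc_stage": np.where(rng.random(n) < p_stage1, "1", ">1"),
            "child_pugh": np.where(rng.random(n) < 0.85, "Low(1)", "High(>1)"),
            "hcv": np.where(rng.random(n) < 0.8, "Yes", "No"),
            "vascular_invasion": np.where(rng.random(n) < 0.35, "YES", "NO"),
        }
    )


def simulate_multiomics(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full simulated study; bit-identical for a given config."""
    rng = np.random.default_rng(config.seed)
    n, G = config.n_samples, config.n_subgroups
    sample_ids = [f"P{i:04d}" for i in range(n)]
    if config.proportions is None:
        labels = np.arange(n) % G  # balanced, deterministic
    else:
        labels = rng.choice(G, size=n, p=np.asarray(config.proportions))
    labels = np.sort(labels)
    true_labels = pd.Series(labels + 1, index=sample_ids, name="subgroup")

    segments, genes = _simulate_cnv_segments(config.cnv, labels, sample_ids, rng)

    mrna_latent, _, _ = _block_latent(config.mrna, labels, rng)
    mrna = PlatformMatrix(
        "mrna",
        pd.DataFrame(
            np.power(2.0, mrna_latent),
            index=[f"gene_mrna_{i:04d}" for i in range(config.mrna.n_features)],
            columns=sample_ids,
        ),
        state="raw",
    )
    mirna_latent, _, _ = _block_latent(config.mirna, labels, rng)
    mirna = PlatformMatrix(
        "mirna",
        pd.DataFrame(
            np.power(2.0, mirna_latent),
            index=[f"hsa-mir-{i:03d}" for i in range(config.mirna.n_features)],
            columns=sample_ids,
        ),
        state="raw",
    )
    meth_latent, _, _ = _block_latent(config.meth, labels, rng)
    meth = PlatformMatrix(
        "meth",
        pd.DataFrame(
            expit(meth_latent),
            index=[f"cg{i:08d}" for i in range(config.meth.n_features)],
            columns=sample_ids,
        ),
        state="raw",
    )
    prot_latent, _, _ = _block_latent(config.prot, labels, rng)
    protein = PlatformMatrix(
        "prot",
        pd.DataFrame(
            prot_latent,
            index=[f"protein_{i:03d}" for i in range(config.prot.n_features)],
            columns=sample_ids,
        ),
        state="preprocessed",
    )

    mut = config.mutation
    calls: list[tuple[str, str]] = []
    for gi in range(mut.n_genes):
        enriched_for = (gi // mut.enriched_per_subgroup) if gi < G * mut.enriched_per_subgroup else -1
        rate = np.where(labels == enriched_for, mut.enriched_rate, mut.baseline_rate)
        hit = rng.random(n) < rate
        calls.extend((f"mut_gene_{gi:03d}", sample_ids[i]) for i in np.where(hit)[0])
    mutation = build_mutation_matrix(calls, sample_ids)

    surv = simulate_survival(true_labels - 1, config, seed=int(rng.integers(2**31)))
    covars = _simulate_clinical_covariates(labels, G, rng)
    covars.index = sample_ids
    clinical = ClinicalTable(pd.concat([surv, covars], axis=1))

    return SyntheticDataset(
        sample_ids=sample_ids,
        true_labels=true_labels,
        cnv_segments=segments,
        gene_model=genes,
        meth=meth,
        mrna=mrna,
        mirna=mirna,
        mutation=mutation,
        protein=protein,
        clinical=clinical,
    )
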