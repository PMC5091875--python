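"""Null calibration of the survival-guided search.

Under a global null — no planted block structure and exchangeable
survival — a grid point's subgroups are independent of survival, so its
log-rank p-value is uniform and the significance flag fires at the
nominal level. Grid points evaluated within one dataset share the
platform noise and the survival draw and are therefore strongly
positively correlated; a binomial check of the significant fraction is
only valid over points from independent datasets. This module evaluates
exactly one grid point per independently simulated null study.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .search_select import SearchConfig, survival_guided_grid_search
from .synthetic_data import PlatformSpec, SyntheticConfig, simulate_multiomics

__all__ = ["null_significant_fraction"]

_SMALL_PLATFORMS = dict(
    cnv=PlatformSpec(40, 4, 0.0, 0.25, 0.0, 0.0, 0.0),
    mrna=PlatformSpec(80, 8, 0.0, 1.0, 0.8, 5.0, 2.0),
    mirna=PlatformSpec(40, 4, 0.0, 1.0, 0.8, 6.0, 1.5),
    meth=PlatformSpec(60, 6, 0.0, 1.0, 0.8, 0.0, 1.5),
)


def null_significant_fraction(
    n_points: int = 72,
    seed: int = 0,
    n_samples: int = 300,
    consensus_reps: int = 10,
    p_threshold: float = 0.05,
) -> tuple[float, int]:
    """Fraction of significant grid points over independent null studies.

    Each point comes from its own simulated structure-free study (one
    random sub-cluster-count combination, one subgroup count cycling over
    2..7), so the points are mutually independent and the fraction is
    binomial(n_points, alpha) under correct calibration. Returns
    ``(fraction, n_points)``.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    for i in range(n_points):
        s = int(rng.integers(2**31))
        k_sub = 2 + i % 6
        cfg = SyntheticConfig(
            n_samples=n_samples, n_subgroups=5, seed=s, **_SMALL_PLATFORMS
        ).null()
        ds = simulate_multiomics(cfg)
        points = survival_guided_grid_search(
            ds.preprocessed_platforms(),
            ds.clinical,
            SearchConfig(
                budget=1,
                consensus_reps=consensus_reps,
                subgroup_range=(k_sub, k_sub),
                p_threshold=p_threshold,
            ),
            seed=s,
        )
        assert len(points) == 1
        n_sig += int(points[0].significant)
    return n_sig / n_points, n_points
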