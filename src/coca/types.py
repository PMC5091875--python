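"""Shared container types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLATFORM_KINDS = ("cnv", "meth", "mrna", "mirna", "mut", "prot")

# Row order used when stacking indicator rows across platforms.
PLATFORM_ORDER = ("cnv", "mrna", "mirna", "meth")


@dataclass
class PlatformMatrix:
    """A feature x sample numeric matrix tagged with platform kind and state.

    ``data`` rows are features, columns are samples. ``state`` is ``raw``
    until the platform-specific preprocessing has been applied.
    """

    kind: str
    data: pd.DataFrame = field(repr=False)
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in PLATFORM_KINDS:
            raise ValueError(f"unknown platform kind {self.kind!r}; expected one of {PLATFORM_KINDS}")
        if self.state not in ("raw", "preprocessed"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: list[str]) -> "PlatformMatrix":
        return PlatformMatrix(self.kind, self.data[list(samples)].copy(), self.state)

    def validate_preprocessed(self) -> None:
        """Check the per-platform value invariants of the preprocessed state."""
        v = self.data.to_numpy()
        if self.kind == "cnv":
            assert np.nanmax(np.abs(v)) <= 2 + 1e-12, "CNV values exceed clip range"
        elif self.kind == "meth":
            assert not np.isnan(v).any(), "methylation matrix contains missing values"
            assert v.min() >= 0 and v.max() <= 1, "beta values outside [0, 1]"
        elif self.kind == "mrna":
            assert np.nanmin(v) >= -26 - 1e-12, "mRNA values below the -26 floor"
        elif self.kind == "mirna":
            assert np.nanmin(v) >= 0, "miRNA values below 0"
        elif self.kind == "mut":
            assert np.isin(v, [0.0, 1.0]).all(), "mutation matrix must be 0/1"
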