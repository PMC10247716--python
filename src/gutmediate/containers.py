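"""Shared in-memory containers for omics tables.

Every stage of the pipeline consumes and produces :class:`FeatureTable`:
a features x samples numeric matrix with per-sample group labels. The same
container holds genus-level counts, metabolite peak intensities and the
hormone panel; ``kind`` records which rules apply (counts must be
non-negative integers, intensities merely non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_KINDS = ("counts", "intensity", "hormone")


class TableValidationError(ValueError):
    """Raised when a table violates its structural contract."""


@dataclass
class FeatureTable:
    """Features x samples matrix plus sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids.
    groups
        Series mapping sample id -> group label (2-level factor such as
        control/hypoxia). Must cover every sample column.
    kind
        One of ``counts``, ``intensity``, ``hormone``.
    """

    values: pd.DataFrame
    groups: pd.Series
    kind: str = "intensity"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise TableValidationError(f"unknown table kind {self.kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise TableValidationError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableValidationError("table values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise TableValidationError("table contains non-finite values")
        if self.kind == "counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise TableValidationError(
                    "counts tables must hold non-negative integers"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    def group_columns(self, level: str) -> pd.DataFrame:
        """Sub-matrix of samples belonging to one group."""
        cols = [s for s in self.sample_ids if self.groups[s] == level]
        return self.values[cols]

    def group_indicator(self, positive: str = "hypoxia") -> np.ndarray:
        """0/1 treatment vector in sample order (1 = ``positive`` group)."""
        return (self.groups.to_numpy() == positive).astype(float)

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(feature_ids)], self.groups, self.kind)

    def relative_abundance(self) -> "FeatureTable":
        """Per-sample total-sum scaling to proportions (counts -> intensity)."""
        totals = self.values.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise TableValidationError(f"all-zero samples: {bad}")
        return FeatureTable(self.values / totals, self.groups, "intensity")

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.groups.copy(), self.kind)


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, non-increasing
    proportion_explained: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        eig = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(eig) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if self.proportion_explained is None:
            tot = eig.sum()
            self.proportion_explained = eig / tot if tot > 0 else eig * 0.0
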