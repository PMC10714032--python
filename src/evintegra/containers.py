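"""Core in-memory containers shared across the pipeline stages.

All tabular data is held in pandas objects: an intensity matrix is a
``DataFrame`` of features (rows) by samples (columns), missing values are
``NaN``, and group membership is a ``Series`` mapping sample id to one of
two group labels (by convention ``"control"`` and ``"case"``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"


def _check_two_groups(groups: pd.Series, columns: Sequence[str]) -> pd.Series:
    groups = pd.Series(groups)
    missing = [c for c in columns if c not in groups.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    groups = groups.loc[list(columns)]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(
            f"groups must partition samples into exactly two non-empty sets, got {list(levels)}"
        )
    return groups


@dataclass
class IntensityMatrix:
    """Feature x sample matrix of log2 intensities with group labels.

    Parameters
    ----------
    values
        DataFrame, rows = features, columns = samples. Missing entries are NaN.
    groups
        Series mapping sample id -> group label (exactly two levels).
    original_mask
        Missing-value indicator recorded before imputation (True = was
        missing). Kept as provenance; ``values`` itself is NaN-free after
        imputation.
    stages
        Ordered provenance flags of the preprocessing steps already applied.
    """

    values: pd.DataFrame
    groups: pd.Series
    original_mask: pd.DataFrame | None = None
    stages: tuple[str, ...] = ("log2",)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.groups = _check_two_groups(self.groups, self.values.columns)
        if self.original_mask is not None:
            if self.original_mask.shape != self.values.shape:
                raise ValueError("original_mask must be conformal with values")

    @property
    def mask(self) -> pd.DataFrame:
        """Current missing-value indicator (True = missing)."""
        return self.values.isna()

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    @property
    def group_levels(self) -> tuple[str, str]:
        levels = list(pd.unique(self.groups))
        # stable convention: control first when present
        if CONTROL in levels:
            levels = [CONTROL] + [g for g in levels if g != CONTROL]
        return levels[0], levels[1]

    def with_values(self, values: pd.DataFrame, stage: str | None = None,
                    original_mask: pd.DataFrame | None = None) -> "IntensityMatrix":
        stages = self.stages + ((stage,) if stage else ())
        mask = original_mask if original_mask is not None else self.original_mask
        if mask is not None:
            mask = mask.loc[values.index, values.columns]
        return IntensityMatrix(values=values, groups=self.groups.loc[values.columns],
                               original_mask=mask, stages=stages)


@dataclass
class SimTruth:
    """Ground truth of a simulated EV proteome cohort.

    ``proportions`` holds the true cell-type fractions (samples x cell types,
    each row non-negative and summing to one); ``de_features`` maps spiked
    feature ids to their true group log2 fold change (case minus control).
    """

    proportions: pd.DataFrame
    de_features: dict[str, float]
    dropout_rate: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        rows = self.proportions.to_numpy()
        if (rows < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        sums = rows.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each sample's proportions must sum to 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "proportions_by_sample": {
                s: dict(zip(self.proportions.columns, map(float, row)))
                for s, row in zip(self.proportions.index, self.proportions.to_numpy())
            },
            "de_features": {k: float(v) for k, v in self.de_features.items()},
            "dropout_rate": float(self.dropout_rate),
            "noise_sd": float(self.noise_sd),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimTruth":
        props = pd.DataFrame.from_dict(d["proportions_by_sample"], orient="index")
        return cls(proportions=props, de_features=dict(d["de_features"]),
                   dropout_rate=d["dropout_rate"], noise_sd=d["noise_sd"],
                   seed=d["seed"])


@dataclass
class CellMatrix:
    """Single-cell count matrix (genes x cells) with cell-type labels."""

    counts: pd.DataFrame
    labels: pd.Series
    dispersion: pd.Series | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        unlabelled = [c for c in self.counts.columns if c not in self.labels.index]
        if unlabelled:
            raise ValueError(f"cells without a label: {unlabelled[:5]}")
        self.labels = self.labels.loc[self.counts.columns]

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.labels))

    def cells_of(self, cell_type: str) -> list[str]:
        return list(self.labels.index[self.labels == cell_type])


@dataclass
class CtThresholds:
    """Reliability thresholds for Ct arrays.

    The instrument vendor does not publish universal cutoffs; a Ct ceiling of
    35 cycles and a minimum amplification score of 1.24 are common practice
    and are logged whenever a matrix is filtered.
    """

    ct_max: float = 35.0
    amp_min: float = 1.24
    max_unreliable: int = 3


@dataclass
class CtMatrix:
    """miRNA x sample cycle-threshold matrix with amplification scores."""

    ct: pd.DataFrame
    amp_score: pd.DataFrame
    groups: pd.Series
    thresholds: CtThresholds = field(default_factory=CtThresholds)

    def __post_init__(self) -> None:
        if self.amp_score.shape != self.ct.shape:
            raise ValueError("amp_score must be conformal with ct")
        self.groups = _check_two_groups(self.groups, self.ct.columns)


@dataclass
class ScaledMatrix:
    """Feature-wise min-max scaled matrix with scaling provenance.

    Rows with ``x_max == x_min`` map to all-zeros and are flagged degenerate
    rather than dropped.
    """

    X_scaled: pd.DataFrame
    x_min: pd.Series
    x_max: pd.Series
    degenerate: pd.Series  # bool per feature


@dataclass
class EnrichmentResult:
    """Result of one preranked gene-set enrichment run."""

    es: float
    nes: float
    p: float
    leading_edge: list[str]
    n_perm: int
    size: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReceptorModule:
    """Receptors reachable from one direction of differentially expressed ligands."""

    direction: str  # "up" or "down"
    receptors: list[str]
    source_ligands: list[str]
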