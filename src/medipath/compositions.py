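"""OTU count preprocessing: sparsity filtering, zero replacement, CLR transform.

Microbial features enter the mediation models as centered log-ratio (CLR)
abundances. Raw rarefied counts are compositional: only relative information
is meaningful, and log-ratio methods require strictly positive entries. The
preprocessing chain is therefore

    filter_otus -> replace_zeros -> clr_transform

Sparse features (low total count, or absent from most samples) are removed
first; remaining zeros are imputed by multiplicative replacement; the CLR
transform then maps each sample composition to unconstrained real coordinates
that sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "OtuTable",
    "filter_otus",
    "replace_zeros",
    "clr_transform",
    "OtuPreprocessor",
]


@dataclass
class OtuTable:
    """A samples x features microbial abundance table at one sampling stage.

    ``kind`` tracks where the table sits in the preprocessing chain:
    ``"counts"`` (non-negative integers), ``"proportions"`` (strictly
    positive rows summing to one, after zero replacement) or ``"clr"``
    (real rows summing to zero).
    """

    data: pd.DataFrame
    stage: str = "S2"
    kind: str = "counts"
    removed_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "counts":
            values = self.data.to_numpy()
            if (values < 0).any():
                raise ValueError("count table contains negative entries")
            if not np.allclose(values, np.round(values)):
                raise ValueError("count table contains non-integer entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def presence(self) -> pd.Series:
        """Fraction of samples in which each feature has a nonzero value."""
        return (self.data > 0).mean(axis=0)

    def check_rarefied(self) -> bool:
        """True if all row sums are equal (counts rarefied upstream)."""
        totals = self.data.sum(axis=1)
        return bool((totals == totals.iloc[0]).all())


def filter_otus(
    table: OtuTable,
    min_total: int = 1200,
    max_zero_fraction: float = 0.80,
) -> OtuTable:
    """Drop sparse features from a count table.

    A feature is retained iff its total count over all samples is at least
    ``min_total`` AND it is zero in at most ``max_zero_fraction`` of the
    samples. Both rules are evaluated jointly on the original counts. The
    sample set is unchanged; removed feature ids are recorded on the result.
    """
    if table.kind != "counts":
        raise ValueError("filter_otus expects a count table, got kind=%r" % table.kind)
    totals = table.data.sum(axis=0)
    zero_frac = (table.data == 0).mean(axis=0)
    keep = (totals >= min_total) & (zero_frac <= max_zero_fraction)
    removed = [f for f, k in keep.items() if not k]
    return OtuTable(
        data=table.data.loc[:, keep],
        stage=table.stage,
        kind="counts",
        removed_features=removed,
    )


def replace_zeros(table: OtuTable, delta_fraction: float = 0.65) -> OtuTable:
    """Multiplicative zero replacement on row proportions.

    Each zero cell in a row is set to ``delta_fraction * (1 / row_total)``
    (a configurable fraction of one count at that row's sequencing depth);
    nonzero cells are shrunk by the common factor that keeps the row summing
    to one. Output rows are strictly positive compositions.
    """
    if table.kind != "counts":
        raise ValueError("replace_zeros expects a count table, got kind=%r" % table.kind)
    counts = table.data.to_numpy(dtype=float)
    row_totals = counts.sum(axis=1, keepdims=True)
    if (row_totals == 0).any():
        bad = [table.sample_ids[i] for i in np.where(row_totals.ravel() == 0)[0]]
        raise ValueError(f"all-zero rows cannot form a composition: {bad}")
    props = counts / row_totals
    is_zero = counts == 0
    delta = delta_fraction / row_totals  # per-row imputed proportion
    zero_mass = is_zero.sum(axis=1, keepdims=True) * delta
    if (zero_mass >= 1).any():
        raise ValueError(
            "imputed zero mass reaches the whole composition; "
            "row depth too small for this delta_fraction"
        )
    out = np.where(is_zero, np.broadcast_to(delta, props.shape), props * (1.0 - zero_mass))
    return OtuTable(
        data=pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        stage=table.stage,
        kind="proportions",
        removed_features=list(table.removed_features),
    )


def clr_transform(table: OtuTable) -> OtuTable:
    """Centered log-ratio transform: x -> log(x) - mean(log(x)) per row."""
    if table.kind == "clr":
        raise ValueError("table is already CLR-transformed")
    values = table.data.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError(
            "CLR requires strictly positive entries; run replace_zeros first"
        )
    transformed = _skbio_clr(values)
    return OtuTable(
        data=pd.DataFrame(transformed, index=table.data.index, columns=table.data.columns),
        stage=table.stage,
        kind="clr",
        removed_features=list(table.removed_features),
    )


class OtuPreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer chaining filter, zero replacement and CLR.

    Parameters
    ----------
    min_total : int
        Minimum total count for a feature to be retained.
    max_zero_fraction : float
        Maximum tolerated fraction of zero-count samples per feature.
    delta_fraction : float
        Fraction of one count (at the row's depth) used to impute zeros.

    Attributes
    ----------
    feature_ids_ : list of str
        Features retained by the sparsity filter, fixed at fit time.
    removed_features_ : list of str
        Features dropped by the filter.
    """

    def __init__(
        self,
        min_total: int = 1200,
        max_zero_fraction: float = 0.80,
        delta_fraction: float = 0.65,
    ):
        self.min_total = min_total
        self.max_zero_fraction = max_zero_fraction
        self.delta_fraction = delta_fraction

    def fit(self, X: pd.DataFrame, y=None) -> "OtuPreprocessor":
        table = X if isinstance(X, OtuTable) else OtuTable(pd.DataFrame(X))
        filtered = filter_otus(table, self.min_total, self.max_zero_fraction)
        self.feature_ids_ = filtered.feature_ids
        self.removed_features_ = filtered.removed_features
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "feature_ids_"):
            raise ValueError("OtuPreprocessor is not fitted")
        table = X if isinstance(X, OtuTable) else OtuTable(pd.DataFrame(X))
        kept = OtuTable(
            table.data.loc[:, self.feature_ids_], stage=table.stage, kind="counts",
            removed_features=list(self.removed_features_),
        )
        return clr_transform(replace_zeros(kept, self.delta_fraction)).data
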