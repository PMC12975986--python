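"""Mixed-trait dissimilarity matrices.

The core-sampling objectives operate on a pairwise dissimilarity matrix over
accessions. The default metric is Gower's coefficient, the standard choice
for germplasm trait data because it handles quantitative and qualitative
traits together:

* quantitative trait t: ``|x_i - x_j| / range_t`` (range over the collection);
* qualitative trait t: 0 if the states match, 1 otherwise;
* the distance is the average of per-trait contributions, with pairwise
  deletion of missing values (the divisor counts only traits observed in both
  accessions).

All entries lie in [0, 1]. A Euclidean option on standardized quantitative
traits is provided for hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, SchemaError
from .traits import validate_descriptor_set

_CHUNK = 512  # rows per block when accumulating the pairwise sums


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with an accession index."""

    values: np.ndarray
    ids: tuple
    metric: str = "gower"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = tuple(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise SchemaError("distance matrix shape does not match id count")
        self._pos = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        return np.array([self._pos[a] for a in ids], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric: str = "gower"):
        return cls(df.to_numpy(dtype=float), tuple(df.index), metric)


def _trait_arrays(table: pd.DataFrame, descriptors, subset):
    """Split the trait table into usable quantitative/qualitative arrays."""
    validate_descriptor_set(descriptors)
    by_name = {d.name: d for d in descriptors}
    names = list(subset) if subset is not None else list(table.columns)
    for name in names:
        if name not in by_name:
            raise SchemaError(f"trait {name!r} has no descriptor")
        if name not in table.columns:
            raise SchemaError(f"trait {name!r} missing from the trait table")

    quant, qual = [], []
    for name in names:
        d = by_name[name]
        if d.is_quantitative:
            col = pd.to_numeric(table[name], errors="coerce").to_numpy(dtype=float)
            rng = np.nanmax(col) - np.nanmin(col) if np.isfinite(col).any() else 0.0
            if not np.isfinite(rng) or rng <= 0:
                warnings.warn(
                    f"quantitative trait {name!r} has zero range; excluded "
                    "from the distance computation",
                    stacklevel=3,
                )
                continue
            quant.append((name, col, rng))
        else:
            codes = pd.Categorical(table[name]).codes.astype(float)  # -1 = missing
            codes[codes < 0] = np.nan
            if len(pd.unique(table[name].dropna())) < 1:
                warnings.warn(f"qualitative trait {name!r} is all-missing; excluded",
                              stacklevel=3)
                continue
            qual.append((name, codes))
    return quant, qual


def gower_matrix(table: pd.DataFrame, descriptors, subset=None) -> DistanceMatrix:
    """Gower dissimilarity over a (accession x trait) table.

    Parameters
    ----------
    table : DataFrame
        Indexed by accession id; one column per trait. Missing values allowed.
    descriptors : sequence of TraitDescriptor
        Must cover every column used.
    subset : sequence of str, optional
        Restrict the computation to these traits (default: all columns).

    Raises
    ------
    ComputationError
        If every trait is constant, or some accession has no observed value
        on the selected traits.
    """
    quant, qual = _trait_arrays(table, descriptors, subset)
    if not quant and not qual:
        raise ComputationError("all selected traits are constant or missing")

    n = len(table)
    num = np.zeros((n, n))
    den = np.zeros((n, n))

    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        for _, col, rng in quant:
            a = col[start:stop, None]
            b = col[None, :]
            ok = np.isfinite(a) & np.isfinite(b)
            contrib = np.abs(a - b) / rng
            num[start:stop] += np.where(ok, contrib, 0.0)
            den[start:stop] += ok
        for _, codes in qual:
            a = codes[start:stop, None]
            b = codes[None, :]
            ok = np.isfinite(a) & np.isfinite(b)
            num[start:stop] += np.where(ok, (a != b).astype(float), 0.0)
            den[start:stop] += ok

    if (den.diagonal() == 0).any():
        bad = [table.index[i] for i in np.nonzero(den.diagonal() == 0)[0]]
        raise ComputationError(f"accessions with all-missing trait values: {bad[:5]}")
    if (den == 0).any():
        warnings.warn("some accession pairs share no observed trait; their "
                      "distance is set to the maximum (1.0)", stacklevel=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against fp noise
    return DistanceMatrix(d, tuple(table.index), "gower")


def euclidean_matrix(table: pd.DataFrame, descriptors, subset=None,
                     standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance on (optionally standardized) quantitative traits."""
    quant, _ = _trait_arrays(table, descriptors, subset)
    if not quant:
        raise ComputationError("no usable quantitative traits")
    x = np.column_stack([col for _, col, _ in quant])
    if np.isnan(x).any():
        # mean imputation keeps the matrix defined; flagged to the caller
        warnings.warn("missing values mean-imputed for euclidean distance",
                      stacklevel=2)
        mu = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = mu[idx[1]]
    if standardize:
        sd = x.std(axis=0, ddof=1)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    sq = (x ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(d, tuple(table.index), "euclidean")
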