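"""PCA, hierarchical clustering and trait correlation structure.

PCA is performed on the trait correlation matrix (traits standardized to
unit variance), the right choice when traits carry heterogeneous units; the
eigenvalues then sum to the number of traits and each component's variance
share is 100*lambda/p. Loading signs are fixed so the largest-magnitude
loading of every component is positive (PCA signs are otherwise arbitrary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .distance import DistanceMatrix
from .errors import ComputationError

LINKAGES = ("ward", "average", "complete")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame   # trait x component
    scores: pd.DataFrame     # accession x component
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray

    @property
    def sdev(self) -> np.ndarray:
        return np.sqrt(np.clip(self.eigenvalues, 0, None))

    def table(self) -> pd.DataFrame:
        """Eigenvalue / variance-share summary, one column per component."""
        cols = list(self.loadings.columns)
        head = pd.DataFrame(
            [self.sdev, self.eigenvalues, self.variance_pct,
             self.cumulative_pct],
            index=["sdev", "eigenvalue", "variance_pct", "cumulative_pct"],
            columns=cols)
        return pd.concat([head, self.loadings])


def variance_share(eigenvalue: float, n_traits: int) -> float:
    """Percent variance explained by one component of a correlation PCA."""
    if n_traits <= 0:
        raise ComputationError("n_traits must be positive")
    return 100.0 * eigenvalue / n_traits


def pca(table: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of an accession x quantitative-trait table.

    Constant traits are dropped with a warning; missing values are imputed by
    the trait mean with a warning.
    """
    x = table.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    names = list(table.columns)
    sd = np.nanstd(x, axis=0, ddof=1)
    keep = [j for j in range(len(names)) if np.isfinite(sd[j]) and sd[j] > 0]
    dropped = [names[j] for j in range(len(names)) if j not in keep]
    if dropped:
        warnings.warn(f"constant traits dropped from PCA: {dropped}",
                      stacklevel=2)
    if len(keep) < 2:
        raise ComputationError("PCA needs >= 2 traits with non-zero variance")
    x = x[:, keep]
    names = [names[j] for j in keep]
    if np.isnan(x).any():
        warnings.warn("missing values imputed by trait means for PCA",
                      stacklevel=2)
        mu = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = mu[idx[1]]

    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    p = z.shape[1]
    corr = (z.T @ z) / (len(z) - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    for j in range(p):  # sign convention
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    scores = z @ v
    comp = [f"PC{i + 1}" for i in range(p)]
    pct = 100.0 * w / p
    return PCAResult(
        eigenvalues=w,
        loadings=pd.DataFrame(v, index=names, columns=comp),
        scores=pd.DataFrame(scores, index=table.index, columns=comp),
        variance_pct=pct,
        cumulative_pct=np.cumsum(pct))


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree over accessions."""

    linkage_matrix: np.ndarray  # scipy linkage format
    ids: tuple
    linkage: str

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage_matrix, n_clusters,
                                    criterion="maxclust")
        return pd.Series(labels, index=list(self.ids), name="cluster")

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hier_cluster(d: DistanceMatrix, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering of a distance matrix."""
    if linkage not in LINKAGES:
        raise ComputationError(f"linkage must be one of {LINKAGES}")
    if d.n < 2:
        raise ComputationError("need >= 2 accessions")
    condensed = d.values[np.triu_indices(d.n, k=1)]
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(z, d.ids, linkage)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlation_matrix(table: pd.DataFrame):
    """Pearson correlations with two-sided t-based p-values.

    Pairs involving a constant trait get nan r and p (flagged by warning).
    """
    x = table.apply(pd.to_numeric, errors="coerce")
    n = len(x)
    if n < 3:
        raise ComputationError("need >= 3 accessions")
    r = x.corr(method="pearson")
    sd = x.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant traits give undefined correlations: "
                      f"{constant}", stacklevel=2)
    rv = r.to_numpy(copy=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1.0 - rv ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    np.fill_diagonal(p.values, 0.0)
    np.fill_diagonal(r.values, 1.0)
    return r, p
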