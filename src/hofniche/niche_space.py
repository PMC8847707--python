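"""Analytics on the OTU x variable niche-optimum matrix.

Each OTU is summarized by its vector of niche optima across the environmental
variables (all on the common 1-100 scale).  Ecological divergence between two
OTUs is the Euclidean distance between their optimum vectors; ecological
*groups* are communities in a Spearman-correlation network over those vectors,
detected by multi-level (Louvain) modularity optimization; PCA ordinates the
whole matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ecological_distance",
    "spearman_network",
    "detect_groups",
    "rho_sweep",
    "pca_ordination",
    "DEFAULT_RHO_GRID",
]

# correlation strengths explored when choosing the network cutoff
DEFAULT_RHO_GRID = (0.4, 0.5, 0.6, 0.7, 0.725, 0.75, 0.775, 0.8, 0.825, 0.85,
                    0.875, 0.8875, 0.9, 0.9125, 0.925, 0.9375, 0.95, 0.96,
                    0.975, 0.98, 0.99)


def ecological_distance(v1, v2) -> float:
    """Euclidean distance between two complete niche-optimum vectors.

    With optima on the 1-100 scale, the theoretical maximum over 41 variables
    is 99 * sqrt(41) ~= 634.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing entries: restrict to shared complete variables first")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def spearman_network(optima: pd.DataFrame, rho_cutoff: float = 0.85,
                     min_shared: int = 3) -> nx.Graph:
    """Build the Spearman correlation network over OTU optimum vectors.

    An undirected edge joins two OTUs when the Spearman rank correlation of
    their optimum vectors (over pairwise-complete variables) is >= the cutoff.
    OTUs with fewer than ``min_shared`` usable variables are excluded with a
    logged warning.

    Parameters
    ----------
    optima : DataFrame, OTU x variable
        Niche optima; NaN marks undefined optima (flat responses).
    """
    counts = optima.notna().sum(axis=1)
    dropped = counts[counts < min_shared].index.tolist()
    if dropped:
        logger.warning("excluding %d OTU(s) with < %d usable variables: %s",
                       len(dropped), min_shared, dropped[:10])
    kept = optima.loc[counts >= min_shared]
    g = nx.Graph()
    g.add_nodes_from(kept.index)
    if kept.shape[0] < 2:
        return g
    mat = kept.to_numpy(dtype=float)
    eps = 1e-12   # guard against float round-off at the cutoff
    if not np.isnan(mat).any():
        # complete case: one vectorized rank-correlation pass
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(mat, axis=1).statistic
        rho = np.atleast_2d(rho)
        idx = list(kept.index)
        ii, jj = np.where(np.triu(rho >= rho_cutoff - eps, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(idx[i], idx[j], weight=float(rho[i, j]))
        return g
    idx = list(kept.index)
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            a, b = mat[i], mat[j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < min_shared:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(a[ok], b[ok]).statistic
            if np.isfinite(rho) and rho >= rho_cutoff - eps:
                g.add_edge(idx[i], idx[j], weight=float(rho))
    return g


def detect_groups(network: nx.Graph, seed: int = 0,
                  min_size: int = 2) -> tuple[pd.Series, float]:
    """Multi-level (Louvain) modularity community detection.

    Returns ``(labels, modularity)``.  Nodes in communities smaller than
    ``min_size`` (isolated OTUs are not 'groups of similar OTUs') get label
    -1.  Deterministic under the seed.
    """
    if network.number_of_nodes() == 0:
        return pd.Series(dtype=int), 0.0
    comms = nx.community.louvain_communities(network, weight="weight", seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    labels = {}
    gid = 0
    for comm in comms:
        if len(comm) >= min_size:
            for node in comm:
                labels[node] = gid
            gid += 1
        else:
            for node in comm:
                labels[node] = -1
    modularity = nx.community.modularity(network, comms, weight="weight") \
        if network.number_of_edges() > 0 else 0.0
    return pd.Series(labels).reindex(network.nodes), float(modularity)


def rho_sweep(optima: pd.DataFrame, rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
              seed: int = 0) -> pd.DataFrame:
    """Group counts across a grid of correlation cutoffs.

    For each rho the network is rebuilt, communities detected, and groups of
    size >= 2 counted; the table reports how many OTUs belong to any group and
    their fraction of all OTUs.
    """
    if any(not 0 < r < 1 for r in rho_grid):
        raise ValueError("rho grid values must lie in (0, 1)")
    n_total = optima.shape[0]
    rows = []
    for rho in sorted(rho_grid):
        g = spearman_network(optima, rho_cutoff=rho)
        labels, _ = detect_groups(g, seed=seed)
        grouped = labels[labels >= 0]
        rows.append((rho, int(grouped.nunique()), int(grouped.size),
                     grouped.size / n_total if n_total else 0.0))
    return pd.DataFrame(rows, columns=["rho", "n_groups", "n_otus_in_groups",
                                       "fraction"])


@dataclass
class PCAResult:
    scores: pd.DataFrame            # OTU x component
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame          # variable x component


def pca_ordination(optima: pd.DataFrame, n_components: Optional[int] = None,
                   impute: bool = True) -> PCAResult:
    """Principal component ordination of the optimum matrix.

    Column-centered SVD; missing optima are replaced by the per-variable mean
    when ``impute`` (consistent with the trait-matrix imputation rule).
    Explained-variance fractions sum to 1 over all components.
    """
    if optima.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    mat = optima.to_numpy(dtype=float).copy()
    if np.isnan(mat).any():
        if not impute:
            raise ValueError("missing values present and impute=False")
        col_means = np.nanmean(mat, axis=0)
        ii, jj = np.where(np.isnan(mat))
        mat[ii, jj] = col_means[jj]
    centered = mat - mat.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    if n_components is None:
        n_components = s.size
    scores = u[:, :n_components] * s[:n_components]
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=optima.index, columns=comp_names),
        explained_variance_ratio=ratio[:n_components],
        loadings=pd.DataFrame(vt[:n_components].T, index=optima.columns,
                              columns=comp_names),
    )
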