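"""Cultivated-species comparison: trait matrices, NMDS, Procrustes concordance.

Physiological trait matrices compiled from species descriptions (utilization
tests coded 1 = negative, 2 = weak, 3 = positive; complex growth traits such
as optimum pH/temperature, NaCl tolerance, oxygen relation) are sparse; they
are iteratively pruned, missing niche optima mean-imputed, pairwise
Bray-Curtis dissimilarities computed with per-pair complete traits, ordinated
by non-metric multidimensional scaling (NMDS), and ordinations compared by
the symmetric Procrustes correlation with a permutation (protest) test whose
p-value is averaged over repeated permutation runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _procrustes
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

__all__ = [
    "sparsity_prune",
    "impute_mean_optima",
    "bray_curtis",
    "nmds",
    "procrustes_protest",
    "OrdinationResult",
    "ProcrustesResult",
]


def sparsity_prune(matrix: pd.DataFrame, row_min: float = 0.70,
                   col_min: float = 0.50) -> pd.DataFrame:
    """Iteratively remove sparse rows then columns until both thresholds hold.

    Rows (species) must have data for at least ``row_min`` of the columns and
    columns (traits) for at least ``col_min`` of the rows.  Each iteration
    removes failing rows first, then failing columns, and repeats until the
    result is a fixed point.

    Raises
    ------
    ValueError
        If the matrix empties out, with a diagnostic of the last shape.
    """
    m = matrix.copy()
    while True:
        if m.size == 0:
            raise ValueError(
                f"sparsity pruning removed everything (thresholds row>={row_min}, "
                f"col>={col_min}; input shape {matrix.shape})")
        row_frac = m.notna().mean(axis=1)
        m2 = m.loc[row_frac >= row_min]
        if m2.size == 0:
            m = m2
            continue
        col_frac = m2.notna().mean(axis=0)
        m2 = m2.loc[:, col_frac >= col_min]
        if m2.shape == m.shape and m2.index.equals(m.index) \
                and m2.columns.equals(m.columns):
            return m2
        m = m2


def impute_mean_optima(optima: pd.DataFrame, max_missing: int = 2):
    """Complete a species x variable optimum matrix by mean imputation.

    Species with more than ``max_missing`` missing optima are dropped (their
    responses were too often flat to place them in niche space); remaining
    gaps are filled with the per-variable column mean of the retained species.

    Returns ``(completed matrix, list of dropped species)``.
    """
    n_missing = optima.isna().sum(axis=1)
    dropped = optima.index[n_missing > max_missing].tolist()
    kept = optima.loc[n_missing <= max_missing].copy()
    all_missing = kept.columns[kept.isna().all(axis=0)].tolist()
    if all_missing:
        raise ValueError(f"variable(s) missing for every species: {all_missing}")
    kept = kept.fillna(kept.mean(axis=0))
    return kept, dropped


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity with pairwise-complete traits.

    BC(i, j) = sum_t |x_it - x_jt| / sum_t (x_it + x_jt), the sums running
    over traits t observed in *both* rows; traits missing in either row of a
    pair are omitted from both sums for that pair only.

    Raises
    ------
    ValueError
        If some pair shares no complete trait.
    """
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    out = np.zeros((n, n))
    present = ~np.isnan(x)
    for i in range(n):
        for j in range(i + 1, n):
            ok = present[i] & present[j]
            if not ok.any():
                raise ValueError(
                    f"rows {matrix.index[i]!r} and {matrix.index[j]!r} share no "
                    "complete trait")
            num = np.abs(x[i, ok] - x[j, ok]).sum()
            den = (x[i, ok] + x[j, ok]).sum()
            out[i, j] = out[j, i] = num / den if den > 0 else 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


@dataclass
class OrdinationResult:
    """NMDS configuration with Kruskal stress-1."""

    scores: pd.DataFrame
    stress: float
    converged: bool
    k: int


def _stress1(dist: np.ndarray, embedded: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding: isotonic (monotone) regression of the
    configuration distances on the input dissimilarities supplies the
    disparities d-hat, and stress-1 = sqrt(sum (d - d-hat)^2 / sum d^2)."""
    iu = np.triu_indices(dist.shape[0], k=1)
    dij = dist[iu]
    eij = embedded[iu]
    order = np.argsort(dij, kind="mergesort")
    iso = IsotonicRegression(increasing=True)
    dhat = iso.fit_transform(dij[order], eij[order])
    num = float(np.sum((eij[order] - dhat) ** 2))
    den = float(np.sum(eij**2))
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def nmds(dissimilarity: pd.DataFrame, k: int = 6, n_starts: int = 20,
         seed: int = 0, max_iter: int = 300) -> OrdinationResult:
    """Non-metric multidimensional scaling by SMACOF majorization.

    Minimizes Kruskal stress-1 with monotone (isotonic) regression of the
    configuration distances on the dissimilarity ranks; the best of
    ``n_starts`` random initializations is kept and the configuration is
    centered and rotated to its principal axes.
    """
    n = dissimilarity.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    d = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(n_components=k, metric="precomputed", metric_mds=False,
                  n_init=n_starts, max_iter=max_iter, random_state=seed,
                  normalized_stress=True, eps=1e-9)
        coords = mds.fit_transform(d)
    # center and principal-axis rotate
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    stress = _stress1(d, emb)
    return OrdinationResult(
        scores=pd.DataFrame(coords, index=dissimilarity.index,
                            columns=[f"NMDS{i + 1}" for i in range(k)]),
        stress=stress, converged=bool(mds.n_iter_ < max_iter), k=k)


@dataclass
class ProcrustesResult:
    """Symmetric Procrustes concordance of two ordinations."""

    correlation: float            # sqrt(1 - m^2)
    m2: float                     # minimized sum of squares
    p_value: Optional[float]      # mean permutation p over repeats
    p_values: Optional[np.ndarray] = None


def _procrustes_corr(a: np.ndarray, b: np.ndarray) -> float:
    _, _, m2 = _procrustes(a, b)
    return float(np.sqrt(max(0.0, 1.0 - m2)))


def procrustes_protest(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                       n_perm: int = 999, n_repeat: int = 100,
                       seed: int = 0) -> ProcrustesResult:
    """Symmetric Procrustes correlation with a protest permutation test.

    Both configurations are centered and scaled to unit trace; the
    correlation is sqrt(1 - m^2) with m^2 the minimized sum of squared
    differences after optimal rotation/scaling.  The null distribution comes
    from row permutations of the second configuration; because a permutation
    p-value is itself noisy, the test is repeated ``n_repeat`` times with
    independent permutations and the mean p reported.
    """
    if not scores_a.index.sort_values().equals(scores_b.index.sort_values()):
        raise ValueError("score matrices must cover the same species")
    b_aligned = scores_b.loc[scores_a.index]
    a = scores_a.to_numpy(dtype=float)
    b = b_aligned.to_numpy(dtype=float)
    corr = _procrustes_corr(a, b)
    if n_perm <= 0 or n_repeat <= 0:
        return ProcrustesResult(correlation=corr, m2=1.0 - corr**2, p_value=None)
    rng = np.random.default_rng(seed)
    ps = np.empty(n_repeat)
    n = a.shape[0]
    for r in range(n_repeat):
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _procrustes_corr(a, b[perm]) >= corr:
                count += 1
        ps[r] = (1 + count) / (1 + n_perm)
    return ProcrustesResult(correlation=corr, m2=1.0 - corr**2,
                            p_value=float(ps.mean()), p_values=ps)
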