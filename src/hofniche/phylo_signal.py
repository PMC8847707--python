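"""Phylogenetic signal of niche optima: Blomberg's K and PSR curves/areas.

Blomberg's K compares the observed trait similarity of relatives with the
expectation under Brownian motion (BM) on the given ultrametric tree: K = 1
matches BM, K < 1 means relatives resemble each other less than expected
(overdispersion / convergent evolution), K > 1 more.  Significance comes from
permuting trait values across tips and comparing the variance of
phylogenetically independent contrasts.

Phylogenetic eigenvector regression (PVR) extracts principal-coordinate
eigenvectors from the patristic distance matrix and regresses the trait on
the first j of them; plotting R^2_j against the accumulated eigenvalue
fraction gives the phylogenetic signal-representation (PSR) curve.  The signed
area between the curve and the 45-degree diagonal is ~0 under BM, negative
for traits evolving faster than BM, positive for slower.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "phylo_covariance",
    "blomberg_k",
    "psr_area",
    "psr_basis",
    "pic_variance",
    "SignalResult",
]


@dataclass
class SignalResult:
    """Phylogenetic-signal summary for one trait."""

    k: Optional[float] = None
    p_value: Optional[float] = None
    psr_curve: Optional[np.ndarray] = None   # (cum eigenvalue fraction, R^2) rows
    psr_area: Optional[float] = None


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _align_trait(tree: dendropy.Tree, trait) -> tuple[list[str], np.ndarray]:
    labels = _tip_labels(tree)
    if isinstance(trait, pd.Series):
        missing = [t for t in labels if t not in trait.index]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        y = trait.loc[labels].to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if y.size != len(labels):
            raise ValueError("trait length does not match tip count")
    if np.isnan(y).any():
        raise ValueError("trait contains missing values")
    if np.allclose(y, y[0]):
        raise ValueError("constant trait: signal undefined")
    return labels, y


def phylo_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic covariance matrix V: shared root-to-MRCA path lengths.

    For an ultrametric tree of height h, V[i, j] = h - d(i, j)/2 where d is
    the patristic distance; the diagonal equals the tree height.
    """
    labels = _tip_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    depths = {}
    for node in tree.preorder_node_iter():
        depths[node] = (0.0 if node.parent_node is None
                        else depths[node.parent_node] + (node.edge.length or 0.0))
    height = float(np.mean([depths[lf] for lf in tree.leaf_node_iter()]))
    v = height - d / 2.0
    return pd.DataFrame(v, index=labels, columns=labels)


def pic_variance(tree: dendropy.Tree, trait) -> float:
    """Variance (mean square) of Felsenstein's phylogenetically independent
    contrasts — the permutation statistic for the K test."""
    labels, y = _align_trait(tree, trait)
    state: dict = {}
    for lf, value in zip(tree.leaf_node_iter(), y):
        state[lf] = (value, lf.edge.length or 0.0)
    contrasts = []
    for node in tree.postorder_internal_node_iter():
        children = node.child_nodes()
        # reduce polytomies pairwise in child order
        xs = [state[c] for c in children]
        while len(xs) > 1:
            (x1, b1), (x2, b2) = xs.pop(0), xs.pop(0)
            contrasts.append((x1 - x2) / np.sqrt(b1 + b2))
            xm = (x1 / b1 + x2 / b2) / (1.0 / b1 + 1.0 / b2) if b1 > 0 and b2 > 0 \
                else 0.5 * (x1 + x2)
            bm = (b1 * b2) / (b1 + b2) if b1 + b2 > 0 else 0.0
            xs.insert(0, (xm, bm))
        xm, bm = xs[0]
        state[node] = (xm, bm + (node.edge.length or 0.0))
    c = np.asarray(contrasts)
    return float(np.mean(c**2))


def blomberg_k(tree: dendropy.Tree, trait, n_perm: int = 999,
               seed: int = 0, v: Optional[pd.DataFrame] = None) -> SignalResult:
    """Blomberg's K with a permutation test.

    K is the ratio of the observed MSE0/MSE (phylogenetically corrected mean,
    ordinary vs V-weighted mean squares) to its BM expectation on the tree:

        K = (MSE0 / MSE) / [(tr V - n / sum(V^-1)) / (n - 1)]

    The p-value counts tip-label permutations whose independent-contrast
    variance is <= the observed one (low contrast variance = strong signal):
    p = (1 + #{perm <= obs}) / (1 + n_perm).  ``n_perm=0`` skips the test.
    """
    labels, y = _align_trait(tree, trait)
    if v is None:
        v = phylo_covariance(tree)
    vm = v.loc[labels, labels].to_numpy(dtype=float)
    n = len(labels)
    cho = linalg.cho_factor(vm)
    ones = np.ones(n)
    vinv_1 = linalg.cho_solve(cho, ones)
    one_vinv_one = float(ones @ vinv_1)
    ahat = float(vinv_1 @ y) / one_vinv_one
    resid = y - ahat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ linalg.cho_solve(cho, resid)) / (n - 1)
    expected = (np.trace(vm) - n / one_vinv_one) / (n - 1)
    k = (mse0 / mse) / expected

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        series = pd.Series(y, index=labels)
        obs = pic_variance(tree, series)
        count = 0
        for _ in range(n_perm):
            perm = pd.Series(rng.permutation(y), index=labels)
            if pic_variance(tree, perm) <= obs:
                count += 1
        p = (1 + count) / (1 + n_perm)
    return SignalResult(k=float(k), p_value=p)


def psr_basis(tree: dendropy.Tree, eig_tol: float = 1e-10):
    """Eigendecomposition backing the PSR curve, reusable across traits.

    Returns ``(labels, eigenvalues, eigenvectors)`` from classical scaling of
    the patristic distance matrix (see :func:`psr_area` for why the distances
    are treated as squared distances).
    """
    labels = _tip_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    jmat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * jmat @ d @ jmat
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 0:
        raise ValueError("degenerate distance matrix")
    neg = eigval < -eig_tol * eigval[0]
    if neg.any():
        import warnings
        warnings.warn(f"truncating {int(neg.sum())} negative eigenvalue(s)")
    keep = eigval > eig_tol * eigval[0]
    return labels, eigval[keep], eigvec[:, keep]


def psr_area(tree: dendropy.Tree, trait, eig_tol: float = 1e-10,
             basis=None) -> SignalResult:
    """PSR curve and signed area from phylogenetic eigenvector regression.

    Principal coordinates of the patristic distance matrix supply orthogonal
    eigenvectors; the trait is regressed (OLS with intercept) on the first j
    eigenvectors for j = 1..m and R^2_j plotted against the cumulative
    eigenvalue fraction, with (0, 0) prepended.  The area is the trapezoidal
    integral of (curve - diagonal); ~0 under BM.
    """
    labels_t, y = _align_trait(tree, trait)
    if len(labels_t) < 4:
        raise ValueError("need at least 4 tips")
    # The patristic distance is treated as the *squared* trait-space distance:
    # under Brownian motion Var(y_i - y_j) = sigma^2 D_ij, so the Gower-
    # centered -D/2 equals the centered phylogenetic covariance and the PSR
    # curve tracks the diagonal in expectation for a BM trait.
    if basis is None:
        basis = psr_basis(tree, eig_tol=eig_tol)
    labels, eigval, eigvec = basis
    if labels != labels_t:
        y = pd.Series(y, index=labels_t).loc[labels].to_numpy()

    # eigenvectors are centered and orthonormal, so sequential OLS R^2 is a
    # cumulative sum of squared projections of the centered trait
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    proj = eigvec.T @ yc
    r2 = np.cumsum(proj**2) / ss_tot
    cum_eig = np.cumsum(eigval) / eigval.sum()
    curve = np.column_stack([np.concatenate([[0.0], cum_eig]),
                             np.concatenate([[0.0], r2])])
    area = float(np.trapezoid(curve[:, 1] - curve[:, 0], curve[:, 0]))
    return SignalResult(psr_curve=curve, psr_area=area)


def signal_table(tree: dendropy.Tree, traits: pd.DataFrame, n_perm: int = 999,
                 seed: int = 0) -> pd.DataFrame:
    """Per-variable loop: K, permutation p, and PSR area for every column of a
    tip x variable trait table."""
    v = phylo_covariance(tree)
    basis = psr_basis(tree)
    rng = np.random.default_rng(seed)
    rows = []
    for col in traits.columns:
        sub = int(rng.integers(0, 2**31 - 1))
        kb = blomberg_k(tree, traits[col], n_perm=n_perm, seed=sub, v=v)
        ps = psr_area(tree, traits[col], basis=basis)
        rows.append((col, kb.k, kb.p_value, ps.psr_area))
    return pd.DataFrame(rows, columns=["variable", "K", "p", "psr_area"])
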