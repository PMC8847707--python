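"""Ecological divergence vs 16S sequence divergence in terminal clades.

Recently diverged OTU pairs — cherries of the phylogeny whose 16S sequences
differ by at most 5% — capture the onset of speciation.  Their ecological
divergence (Euclidean distance between 41-dimensional niche-optimum vectors)
is regressed on 16S dissimilarity with a clade (subdivision) term, with and
without an interaction, the two fits compared by ANOVA F-test and AIC, and
subdivision intercepts compared by simultaneous max-|t| contrasts.

The 16S dissimilarity enters the design in percent, so a slope reads as
"ecological-divergence units per percent sequence change".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "terminal_pairs",
    "fit_divergence_models",
    "group_contrasts",
    "predict_with_ci",
    "DivergenceModels",
]


def terminal_pairs(tree: dendropy.Tree, dissimilarity: pd.DataFrame,
                   max_dissim: float = 0.05) -> pd.DataFrame:
    """Cherry pairs (two tips sharing an immediate ancestor) with 16S
    dissimilarity <= ``max_dissim``.

    Within a polytomy every tip pair is considered a cherry and flagged in the
    ``polytomy`` column.

    Parameters
    ----------
    dissimilarity : DataFrame
        Symmetric tip x tip sequence dissimilarity (fractions in [0, 1]).

    Returns
    -------
    DataFrame with columns ``otu1, otu2, dissimilarity, polytomy``.
    """
    rows = []
    for node in tree.postorder_internal_node_iter():
        children = node.child_nodes()
        leaves = [c for c in children if c.is_leaf()]
        if len(leaves) < 2 or len(leaves) != len(children):
            continue
        poly = len(leaves) > 2
        for i in range(len(leaves)):
            for j in range(i + 1, len(leaves)):
                a = leaves[i].taxon.label
                b = leaves[j].taxon.label
                d = float(dissimilarity.loc[a, b])
                if d <= max_dissim:
                    rows.append((a, b, d, poly))
    return pd.DataFrame(rows, columns=["otu1", "otu2", "dissimilarity", "polytomy"])


@dataclass
class DivergenceModels:
    """OLS fits of ecological divergence on 16S dissimilarity + subdivision."""

    additive: sm.regression.linear_model.RegressionResultsWrapper
    interaction: sm.regression.linear_model.RegressionResultsWrapper
    anova: pd.DataFrame           # F-test of the interaction terms
    aic_additive: float
    aic_interaction: float

    @property
    def interaction_f(self) -> float:
        return float(self.anova.loc[1, "F"])

    @property
    def interaction_p(self) -> float:
        return float(self.anova.loc[1, "Pr(>F)"])


def fit_divergence_models(pairs: pd.DataFrame) -> DivergenceModels:
    """Fit additive and interaction linear models and compare them.

    ``pairs`` needs columns ``divergence`` (ecological divergence),
    ``dissimilarity`` (16S fraction, converted to percent internally) and
    ``subdivision``.  The additive model is
    ``divergence ~ dissimilarity_pct + C(subdivision)``; the interaction model
    adds ``dissimilarity_pct : C(subdivision)``.  Both are compared via the
    ANOVA F-test for the interaction terms and via AIC.
    """
    df = pairs.copy()
    required = {"divergence", "dissimilarity", "subdivision"}
    if not required <= set(df.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    counts = df.groupby("subdivision").size()
    if len(counts) < 2:
        raise ValueError("need at least 2 subdivisions")
    if (counts < 3).any():
        raise ValueError("need at least 3 pairs per subdivision")
    df["dissim_pct"] = df["dissimilarity"] * 100.0
    additive = smf.ols("divergence ~ dissim_pct + C(subdivision)", data=df).fit()
    inter = smf.ols("divergence ~ dissim_pct * C(subdivision)", data=df).fit()
    anova = sm.stats.anova_lm(additive, inter)
    anova = anova.rename(columns={"Pr(>F)": "Pr(>F)"}).reset_index(drop=True)
    return DivergenceModels(
        additive=additive, interaction=inter, anova=anova,
        aic_additive=float(additive.aic), aic_interaction=float(inter.aic),
    )


def group_contrasts(models: DivergenceModels, method: str = "single-step",
                    n_mc: int = 50_000, seed: int = 0) -> pd.DataFrame:
    """Simultaneous pairwise comparisons of subdivision intercepts.

    For the additive (no-interaction) model, all pairwise contrasts of the
    subdivision means (at common slope) are tested with familywise-error
    control.  ``method="single-step"`` uses the max-|t| distribution of the
    joint multivariate-t of the contrast estimates, evaluated by seeded
    Monte-Carlo (exact Student-t when there is a single contrast);
    ``method="holm"`` applies the Holm step-down correction instead.

    Returns a table with estimate, SE, t, raw and adjusted p per contrast.
    """
    res = models.additive
    exog_names = res.model.exog_names
    level_terms = [nm for nm in exog_names if nm.startswith("C(subdivision)")]
    levels = ["<ref>"] + level_terms
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 subdivisions for contrasts")
    # effect vectors: intercept-shift of each level relative to the reference
    eff = np.zeros((k, len(exog_names)))
    for i, nm in enumerate(level_terms, start=1):
        eff[i, exog_names.index(nm)] = 1.0
    contrasts, names = [], []
    ref_name = res.model.data.frame["subdivision"].astype("category").cat.categories[0] \
        if hasattr(res.model.data, "frame") else "ref"
    labels = [str(ref_name)] + [nm.split("[T.")[1].rstrip("]") for nm in level_terms]
    for i in range(k):
        for j in range(i + 1, k):
            contrasts.append(eff[j] - eff[i])
            names.append(f"{labels[j]} - {labels[i]}")
    cmat = np.vstack(contrasts)
    est = cmat @ res.params.to_numpy()
    cov = cmat @ res.cov_params().to_numpy() @ cmat.T
    se = np.sqrt(np.diag(cov))
    tvals = est / se
    dfree = res.df_resid
    p_raw = 2.0 * stats.t.sf(np.abs(tvals), dfree)

    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty_like(p_raw)
        running = 0.0
        m = len(p_raw)
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(1.0, running)
    elif method == "single-step":
        if len(p_raw) == 1:
            adj = p_raw.copy()
        else:
            corr = cov / np.outer(se, se)
            rng = np.random.default_rng(seed)
            # sample max-|t|: correlated normals scaled by a shared chi draw
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(se)))
            z = rng.standard_normal((n_mc, len(se))) @ chol.T
            scale = np.sqrt(rng.chisquare(dfree, size=n_mc) / dfree)
            maxabs = np.abs(z).max(axis=1) / scale
            adj = np.array([(1 + np.sum(maxabs >= abs(t))) / (1 + n_mc)
                            for t in tvals])
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({"contrast": names, "estimate": est, "se": se,
                         "t": tvals, "p_raw": p_raw, "p_adj": adj})


def predict_with_ci(models: DivergenceModels, n_sim_per_group: int = 50,
                    seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Predicted divergence with pointwise confidence bands per subdivision.

    Dissimilarity values are drawn uniformly over each subdivision's observed
    range (``n_sim_per_group`` per subdivision) and the additive model's mean
    prediction and (1 - alpha) confidence band evaluated there.
    """
    res = models.additive
    frame = res.model.data.frame
    rng = np.random.default_rng(seed)
    out = []
    for sd, grp in frame.groupby("subdivision", observed=True):
        lo, hi = grp["dissim_pct"].min(), grp["dissim_pct"].max()
        xs = np.sort(rng.uniform(lo, hi, size=n_sim_per_group))
        new = pd.DataFrame({"dissim_pct": xs, "subdivision": sd})
        pred = res.get_prediction(new).summary_frame(alpha=alpha)
        out.append(pd.DataFrame({
            "subdivision": sd, "dissim_pct": xs,
            "predicted": pred["mean"].to_numpy(),
            "ci_lo": pred["mean_ci_lower"].to_numpy(),
            "ci_hi": pred["mean_ci_upper"].to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)
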