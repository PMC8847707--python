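"""Self-contained validation experiments on fully synthetic data.

Each function simulates data with known truth under the package's standard
study conditions (150 sites, sequencing depth 10^4, 41-variable gradient
ranges, bootstrap = 50), runs the corresponding pipeline stage, and measures
how well the truth is recovered.  They back both the statistical acceptance
tests and the reproduction script; all are deterministic given a seed.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import divergence as dv
from . import environment as env_mod
from . import niche_space as ns
from . import phylo_signal as ps
from . import synthetic as syn
from . import traits as tr
from .hof import NicheModel

__all__ = [
    "hof_recovery",
    "flat_model_control",
    "blomberg_calibration",
    "psr_neutrality",
    "network_recovery",
    "interaction_test_size",
    "protest_calibration",
]


def _sub(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def hof_recovery(n_otus: int = 200, n_sites: int = 150, depth: int = 10_000,
                 n_bootstrap: int = 50, seed: int = 0) -> dict:
    """Niche-optimum recovery on unimodal (model IV) truth.

    Simulates ``n_otus`` OTUs with known interior optima along one gradient,
    runs full model selection per OTU, and reports the median absolute
    optimum error (scaled units) and the fraction of OTUs assigned a unimodal
    shape (IV or V).
    """
    rng = np.random.default_rng(seed)
    cfg = syn.SimulationConfig(n_sites=n_sites, n_otus=n_otus,
                               read_depth=depth, rng_seed=_sub(rng))
    env = syn.generate_env(cfg)
    truth = syn.planted_optima(cfg)
    x = env_mod.rescale_variable(env["pH"].to_numpy())
    counts = syn.sample_reads(syn.generate_responses(x, truth), depth,
                              seed=_sub(rng),
                              background_mass=cfg.background_mass)
    counts = counts.drop(index="background")
    totals = np.full(n_sites, float(depth))
    errors, unimodal = [], 0
    for i in range(n_otus):
        nm = NicheModel(n_bootstrap=n_bootstrap, random_state=_sub(rng))
        nm.fit(x, counts.iloc[i].to_numpy(), totals=totals)
        if nm.model_type_ in ("IV", "V"):
            unimodal += 1
        if nm.optimum_.defined and np.isfinite(truth.optima[i]):
            errors.append(abs(nm.optimum_.optimum - truth.optima[i]))
    return {
        "median_abs_optimum_error": float(np.median(errors)),
        "frac_unimodal_selected": unimodal / n_otus,
        "n": n_otus,
    }


def flat_model_control(n_datasets: int = 100, n_sites: int = 150,
                       depth: int = 10_000, n_bootstrap: int = 50,
                       seed: int = 0) -> dict:
    """Type-I control: fraction of flat-truth datasets where the flat model I
    is (correctly) selected, i.e. no spurious optimum is reported."""
    rng = np.random.default_rng(seed)
    flat = 0
    for _ in range(n_datasets):
        cfg = syn.SimulationConfig(n_sites=n_sites, n_otus=1,
                                   read_depth=depth, rng_seed=_sub(rng))
        env = syn.generate_env(cfg)
        truth = syn.planted_optima(cfg, models=["I"])
        x = env_mod.rescale_variable(env["pH"].to_numpy())
        counts = syn.sample_reads(syn.generate_responses(x, truth), depth,
                                  seed=_sub(rng),
                                  background_mass=cfg.background_mass)
        nm = NicheModel(n_bootstrap=n_bootstrap, random_state=_sub(rng))
        nm.fit(x, counts.iloc[0].to_numpy(), totals=np.full(n_sites, float(depth)))
        flat += nm.model_type_ == "I"
    return {"flat_selection_rate": flat / n_datasets, "n": n_datasets}


def blomberg_calibration(n_reps: int = 200, n_tips: int = 100,
                         seed: int = 0) -> dict:
    """K on a star phylogeny (analytically 1) and the mean K of BM traits on
    a random ultrametric tree (expectation 1)."""
    rng = np.random.default_rng(seed)
    star = dendropy.Tree.get(
        data="(" + ",".join(f"t{i}:1.0" for i in range(1, 21)) + ");",
        schema="newick")
    star_trait = pd.Series(rng.standard_normal(20),
                           index=[f"t{i}" for i in range(1, 21)])
    star_k = ps.blomberg_k(star, star_trait, n_perm=0).k
    tree = syn.generate_tree(n_tips, seed=_sub(rng))
    v = ps.phylo_covariance(tree)
    ks = [ps.blomberg_k(tree, syn.evolve_trait(tree, "BM", seed=_sub(rng)),
                        n_perm=0, v=v).k
          for _ in range(n_reps)]
    return {"star_k": float(star_k), "mean_bm_k": float(np.mean(ks)),
            "n": n_reps}


def psr_neutrality(n_reps: int = 200, n_tips: int = 100, seed: int = 0) -> dict:
    """Mean PSR area of BM traits (expectation ~0: BM tracks the diagonal)."""
    rng = np.random.default_rng(seed)
    tree = syn.generate_tree(n_tips, seed=_sub(rng))
    basis = ps.psr_basis(tree)
    areas = [ps.psr_area(tree, syn.evolve_trait(tree, "BM", seed=_sub(rng)),
                         basis=basis).psr_area
             for _ in range(n_reps)]
    return {"mean_bm_psr_area": float(np.mean(areas)), "n": n_reps}


def network_recovery(n_groups: int = 4, group_size: int = 50,
                     n_variables: int = 41, jitter: float = 2.0,
                     rho_cutoff: float = 0.85, seed: int = 0) -> dict:
    """Adjusted Rand index between planted ecological groups (distinct
    optimum profiles) and the communities detected at the standard cutoff."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(10, 90, size=(n_groups, n_variables))
    rows, labels = [], []
    for g in range(n_groups):
        for _ in range(group_size):
            rows.append(np.clip(centers[g] + rng.normal(0, jitter, n_variables),
                                1, 100))
            labels.append(g)
    optima = pd.DataFrame(rows, index=[f"OTU{i:04d}" for i in range(len(rows))])
    graph = ns.spearman_network(optima, rho_cutoff=rho_cutoff)
    detected, _ = ns.detect_groups(graph, seed=_sub(rng))
    ari = adjusted_rand_score(labels, detected.to_numpy())
    return {"adjusted_rand_index": float(ari), "n": len(rows)}


def interaction_test_size(n_reps: int = 1000, n_per_group: int = 40,
                          n_groups: int = 3, alpha: float = 0.05,
                          seed: int = 0) -> dict:
    """Type-I error of the interaction F-test when the truth has a common
    slope across subdivisions."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        rows = []
        for g in range(n_groups):
            x = rng.uniform(0.0, 0.05, n_per_group)
            y = 100.0 + 50.0 * g + 22.0 * (x * 100) \
                + rng.normal(0, 30.0, n_per_group)
            rows.extend((xi, yi, f"SD{g + 1}") for xi, yi in zip(x, y))
        pairs = pd.DataFrame(rows, columns=["dissimilarity", "divergence",
                                            "subdivision"])
        models = dv.fit_divergence_models(pairs)
        rejections += models.interaction_p < alpha
    return {"interaction_rejection_rate": rejections / n_reps, "n": n_reps}


def protest_calibration(n_null: int = 500, n_species: int = 29, k: int = 6,
                        n_perm: int = 199, alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Protest size: self-comparison correlation (1 by construction) and the
    rejection rate across independent Gaussian configurations (~alpha)."""
    rng = np.random.default_rng(seed)
    idx = [f"sp{i}" for i in range(n_species)]
    ref = pd.DataFrame(rng.standard_normal((n_species, k)), index=idx)
    self_res = tr.procrustes_protest(ref, ref.copy(), n_perm=n_perm,
                                     n_repeat=1, seed=_sub(rng))
    rejections = 0
    for _ in range(n_null):
        a = pd.DataFrame(rng.standard_normal((n_species, k)), index=idx)
        b = pd.DataFrame(rng.standard_normal((n_species, k)), index=idx)
        res = tr.procrustes_protest(a, b, n_perm=n_perm, n_repeat=1,
                                    seed=_sub(rng))
        rejections += res.p_value < alpha
    return {
        "self_correlation": float(self_res.correlation),
        "self_p": float(self_res.p_value),
        "null_rejection_rate": rejections / n_null,
        "n": n_null,
    }
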