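"""Shared fixtures: small synthetic surveys, trees, and planted optima."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from hofniche import environment as env_mod
from hofniche import synthetic as syn


@pytest.fixture(scope="session")
def small_survey():
    """A 150-site survey with 30 model-IV OTUs at depth 10^4 (one gradient)."""
    cfg = syn.SimulationConfig(n_sites=150, n_otus=30, rng_seed=11)
    env = syn.generate_env(cfg)
    truth = syn.planted_optima(cfg)
    x = env_mod.rescale_variable(env["pH"].to_numpy())
    expected = syn.generate_responses(x, truth)
    counts = syn.sample_reads(expected, cfg.read_depth, seed=12,
                              background_mass=cfg.background_mass,
                              site_names=list(env.index))
    counts = counts.drop(index="background")
    totals = np.full(cfg.n_sites, float(cfg.read_depth))
    return {"config": cfg, "env": env, "truth": truth, "x": x,
            "counts": counts, "totals": totals}


@pytest.fixture(scope="session")
def yule_tree_100():
    return syn.generate_tree(100, seed=3)


@pytest.fixture(scope="session")
def star_tree_20():
    newick = "(" + ",".join(f"t{i}:1.0" for i in range(1, 21)) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture(scope="session")
def planted_optima_matrix():
    """Four ecological groups of 50 OTUs each with distinct 41-variable
    optimum profiles plus small within-group jitter."""
    rng = np.random.default_rng(21)
    centers = rng.uniform(10, 90, size=(4, 41))
    rows, labels = [], []
    for g in range(4):
        for _ in range(50):
            rows.append(np.clip(centers[g] + rng.normal(0, 2.0, 41), 1, 100))
            labels.append(g)
    optima = pd.DataFrame(
        rows, index=[f"OTU{i:03d}" for i in range(len(rows))],
        columns=[f"var{j:02d}" for j in range(41)])
    return optima, np.array(labels)
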