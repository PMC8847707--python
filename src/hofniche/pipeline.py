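"""Pipeline driver chaining the analysis stages with a provenance log.

The configuration is a flat mapping (JSON on disk): stage toggles under
``stages``, file paths under ``paths``, stage parameters under ``params``
(every random stage takes an explicit seed).  Outputs are TSV files in the
output directory; ``provenance.json`` records package and library versions,
the configuration hash, and all seeds and parameters used.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, environment, hof, io, niche_space, phylo_signal
from . import divergence as divergence_mod
from . import traits as traits_mod

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "default_config"]

STAGE_ORDER = ("env", "assign", "fit_hof", "network", "ordinate",
               "phylosignal", "divergence", "traits")


def default_config(outdir: str = "hofniche_out") -> dict:
    return {
        "outdir": outdir,
        "stages": {s: False for s in STAGE_ORDER},
        "paths": {},
        "params": {
            "identity_cutoff": 0.99,
            "min_sites": 25,
            "n_bootstrap": 50,
            "rho": 0.85,
            "n_perm": 999,
            "n_repeat": 100,
            "nmds_k": 6,
            "max_dissim": 0.05,
            "seed": 0,
        },
    }


def _require(paths: dict, key: str, stage: str) -> Path:
    if key not in paths:
        raise ValueError(f"stage {stage!r} needs config path {key!r}")
    p = Path(paths[key])
    if not p.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: input {p} is missing — did an upstream stage run?")
    return p


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in order; returns the provenance record."""
    outdir = Path(config.get("outdir", "hofniche_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    paths = dict(config.get("paths", {}))
    params = {**default_config()["params"], **config.get("params", {})}
    seed = int(params["seed"])
    chash = io.config_hash(config)
    produced: dict[str, str] = {}

    def emit(df: pd.DataFrame, name: str, index: bool = True) -> Path:
        p = outdir / name
        io.write_table(df, p, index=index)
        produced[name] = str(p)
        return p

    if stages.get("env"):
        raw = io.read_table(_require(paths, "env_raw", "env"), "environment")
        rescaled = environment.rescale_table(raw)
        screen = environment.correlation_screen(raw)
        emit(rescaled, "env_rescaled.tsv")
        emit(screen.pairs, "env_correlations.tsv", index=False)
        paths.setdefault("env_rescaled", str(outdir / "env_rescaled.tsv"))
        logger.info("env: %d sites x %d variables; %d pairs, mean |r|=%.3f",
                    *rescaled.shape, screen.n_pairs, screen.mean_abs_r)

    if stages.get("assign"):
        from . import assign as assign_mod
        refs = io.read_fasta(_require(paths, "references", "assign"))
        reads_fa = io.read_fasta(_require(paths, "reads", "assign"))
        records = []
        for rid, seq in reads_fa.items():
            site = "site001"
            for token in rid.split("|"):
                if token.startswith("site="):
                    site = token[5:]
            records.append((rid, site, seq))
        table = assign_mod.assign_reads(records, refs,
                                        cutoff=float(params["identity_cutoff"]))
        emit(table, "abundance.tsv")
        paths.setdefault("abundance", str(outdir / "abundance.tsv"))

    if stages.get("fit_hof"):
        abundance = io.read_table(_require(paths, "abundance", "fit_hof"), "abundance")
        env = io.read_table(_require(paths, "env_rescaled", "fit_hof"), "environment")
        optima = hof.optimum_matrix(abundance, env,
                                    min_sites=int(params["min_sites"]),
                                    n_bootstrap=int(params["n_bootstrap"]),
                                    seed=seed)
        emit(optima, "optima.tsv", index=False)
        paths.setdefault("optima", str(outdir / "optima.tsv"))

    wide = None
    if any(stages.get(s) for s in ("network", "ordinate", "phylosignal")):
        long = io.read_table(_require(paths, "optima", "network"), "optima")
        wide = hof.optima_wide(long)

    if stages.get("network"):
        g = niche_space.spearman_network(wide, rho_cutoff=float(params["rho"]))
        labels, modularity = niche_space.detect_groups(g, seed=seed)
        edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
            columns=["otu1", "otu2", "rho"])
        emit(edges, "network_edges.tsv", index=False)
        emit(labels.rename("group").rename_axis("otu").to_frame(),
             "network_groups.tsv")
        logger.info("network: %d edges, modularity %.3f", len(edges), modularity)

    if stages.get("ordinate"):
        pca = niche_space.pca_ordination(wide)
        emit(pca.scores, "pca_scores.tsv")

    if stages.get("phylosignal"):
        tree = io.read_tree(_require(paths, "tree", "phylosignal"))
        table = phylo_signal.signal_table(tree, wide,
                                          n_perm=int(params["n_perm"]), seed=seed)
        emit(table, "phylosignal.tsv", index=False)

    if stages.get("divergence"):
        tree = io.read_tree(_require(paths, "tree", "divergence"))
        dissim = io.read_table(_require(paths, "dissimilarity", "divergence"),
                               "matrix")
        long = io.read_table(_require(paths, "optima", "divergence"), "optima")
        wide_d = hof.optima_wide(long)
        sd = pd.read_csv(_require(paths, "subdivisions", "divergence"),
                         sep="\t", index_col=0).iloc[:, 0]
        pairs = divergence_mod.terminal_pairs(tree, dissim,
                                              max_dissim=float(params["max_dissim"]))
        div = [niche_space.ecological_distance(wide_d.loc[r.otu1],
                                               wide_d.loc[r.otu2])
               for r in pairs.itertuples()]
        pairs["divergence"] = div
        pairs["subdivision"] = sd.reindex(pairs["otu1"]).to_numpy()
        models = divergence_mod.fit_divergence_models(pairs)
        contrasts = divergence_mod.group_contrasts(models, seed=seed)
        emit(pairs, "divergence_pairs.tsv", index=False)
        emit(contrasts, "divergence_contrasts.tsv", index=False)
        summary = pd.DataFrame({
            "model": ["additive", "interaction"],
            "aic": [models.aic_additive, models.aic_interaction],
            "interaction_F": [np.nan, models.interaction_f],
            "interaction_p": [np.nan, models.interaction_p],
        })
        emit(summary, "divergence_models.tsv", index=False)

    if stages.get("traits"):
        ta = io.read_table(_require(paths, "traits_a", "traits"), "traits")
        tb = io.read_table(_require(paths, "traits_b", "traits"), "traits")
        k = int(params["nmds_k"])
        results = []
        scores = {}
        for name, mat in (("a", ta), ("b", tb)):
            pruned = traits_mod.sparsity_prune(mat)
            bc = traits_mod.bray_curtis(pruned)
            ord_res = traits_mod.nmds(bc, k=min(k, bc.shape[0] - 2), seed=seed)
            scores[name] = ord_res.scores
            results.append((name, ord_res.stress))
            emit(ord_res.scores, f"nmds_scores_{name}.tsv")
        shared = scores["a"].index.intersection(scores["b"].index)
        pro = traits_mod.procrustes_protest(
            scores["a"].loc[shared], scores["b"].loc[shared],
            n_perm=int(params["n_perm"]), n_repeat=int(params["n_repeat"]),
            seed=seed)
        emit(pd.DataFrame({
            "comparison": ["a_vs_b"], "correlation": [pro.correlation],
            "p": [pro.p_value],
            "stress_a": [results[0][1]], "stress_b": [results[1][1]],
        }), "protest.tsv", index=False)

    provenance = {
        "config_hash": chash,
        "hofniche_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "params": params,
        "stages_run": [s for s in STAGE_ORDER if stages.get(s)],
        "outputs": produced,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return provenance
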