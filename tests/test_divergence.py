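import dendropy
import numpy as np
import pandas as pd
import pytest

from hofniche import divergence as dv
from hofniche import synthetic as syn


def _full_dissim(labels, value=0.02):
    d = pd.DataFrame(value, index=labels, columns=labels)
    np.fill_diagonal(d.values, 0.0)
    return d


def _simulate_pairs(rng, slopes, intercepts, n_per=40, noise=30.0):
    rows = []
    for sd, (slope, inter) in enumerate(zip(slopes, intercepts)):
        x = rng.uniform(0.0, 0.05, n_per)
        y = inter + slope * (x * 100) + rng.normal(0, noise, n_per)
        for xi, yi in zip(x, y):
            rows.append((xi, yi, f"SD{sd + 1}"))
    return pd.DataFrame(rows, columns=["dissimilarity", "divergence",
                                       "subdivision"])


class TestTerminalPairs:
    def test_balanced_four_tip_tree(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                                 schema="newick")
        pairs = dv.terminal_pairs(tree, _full_dissim(list("ABCD")))
        got = {frozenset((r.otu1, r.otu2)) for r in pairs.itertuples()}
        assert got == {frozenset("AB"), frozenset("CD")}

    def test_dissimilar_cherry_excluded(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                                 schema="newick")
        d = _full_dissim(list("ABCD"))
        d.loc["C", "D"] = d.loc["D", "C"] = 0.06
        pairs = dv.terminal_pairs(tree, d, max_dissim=0.05)
        assert len(pairs) == 1 and pairs.iloc[0]["otu1"] == "A"

    def test_polytomy_pairs_flagged(self):
        tree = dendropy.Tree.get(data="((A:1,B:1,C:1):1,D:2);",
                                 schema="newick")
        pairs = dv.terminal_pairs(tree, _full_dissim(list("ABCD")))
        assert len(pairs) == 3
        assert pairs["polytomy"].all()

    def test_matches_brute_force_cherry_enumeration(self):
        tree = syn.generate_tree(100, seed=17)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        pairs = dv.terminal_pairs(tree, _full_dissim(labels, 0.01))
        # oracle: every unordered leaf pair sharing a parent node
        leaves = list(tree.leaf_node_iter())
        brute = {
            frozenset((a.taxon.label, b.taxon.label))
            for i, a in enumerate(leaves) for b in leaves[i + 1:]
            if a.parent_node is b.parent_node
        }
        got = {frozenset((r.otu1, r.otu2)) for r in pairs.itertuples()}
        assert got == brute


class TestDivergenceModels:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(0)
        df = _simulate_pairs(rng, [20.0] * 3, [80.0, 150.0, 240.0], noise=0.0)
        m = dv.fit_divergence_models(df)
        params = m.additive.params
        assert params["dissim_pct"] == pytest.approx(20.0)
        assert params["Intercept"] == pytest.approx(80.0)
        assert params["C(subdivision)[T.SD2]"] == pytest.approx(70.0)
        assert params["C(subdivision)[T.SD3]"] == pytest.approx(160.0)

    def test_nesting_rss_inequality(self):
        rng = np.random.default_rng(1)
        df = _simulate_pairs(rng, [22.0, 18.0, 25.0], [80.0, 150.0, 240.0])
        m = dv.fit_divergence_models(df)
        assert m.interaction.ssr <= m.additive.ssr + 1e-9

    def test_label_encoding_invariance(self):
        rng = np.random.default_rng(2)
        df = _simulate_pairs(rng, [20.0] * 3, [80.0, 150.0, 240.0])
        m1 = dv.fit_divergence_models(df)
        relabeled = df.assign(subdivision=df["subdivision"].map(
            {"SD1": "z", "SD2": "m", "SD3": "a"}))
        m2 = dv.fit_divergence_models(relabeled)
        assert m1.aic_additive == pytest.approx(m2.aic_additive)
        assert m1.interaction_f == pytest.approx(m2.interaction_f)

    def test_distinct_slopes_favor_interaction_model(self):
        """With genuinely different per-subdivision slopes, AIC prefers the
        interaction model in almost all replicates at n = 120."""
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(100):
            df = _simulate_pairs(rng, [5.0, 25.0, 45.0],
                                 [100.0, 100.0, 100.0], noise=20.0)
            m = dv.fit_divergence_models(df)
            wins += m.aic_interaction < m.aic_additive
        assert wins > 90

    def test_requires_enough_groups_and_pairs(self):
        df = pd.DataFrame({"dissimilarity": [0.01] * 4,
                           "divergence": [1.0, 2.0, 3.0, 4.0],
                           "subdivision": ["a"] * 4})
        with pytest.raises(ValueError):
            dv.fit_divergence_models(df)


class TestGroupContrasts:
    def test_two_groups_adjusted_equals_raw(self):
        rng = np.random.default_rng(4)
        df = _simulate_pairs(rng, [20.0, 20.0], [80.0, 150.0])
        m = dv.fit_divergence_models(df)
        c = dv.group_contrasts(m, seed=0)
        assert len(c) == 1
        assert c["p_adj"].iloc[0] == pytest.approx(c["p_raw"].iloc[0])

    def test_huge_separation_all_significant(self):
        rng = np.random.default_rng(5)
        df = _simulate_pairs(rng, [20.0] * 3, [0.0, 300.0, 600.0], noise=30.0)
        m = dv.fit_divergence_models(df)
        c = dv.group_contrasts(m, seed=0)
        assert (c["p_adj"] < 1e-4).all()  # floor is 1/(n_mc + 1)

    def test_familywise_error_controlled(self):
        """Equal true intercepts: any adjusted p < 0.05 in at most ~5% of
        replicates (plus Monte-Carlo slack)."""
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            df = _simulate_pairs(rng, [20.0] * 3, [100.0] * 3, n_per=20)
            m = dv.fit_divergence_models(df)
            c = dv.group_contrasts(m, n_mc=4000, seed=rep)
            hits += (c["p_adj"] < 0.05).any()
        assert hits / n_rep <= 0.08

    def test_holm_fallback(self):
        rng = np.random.default_rng(7)
        df = _simulate_pairs(rng, [20.0] * 3, [80.0, 150.0, 240.0])
        m = dv.fit_divergence_models(df)
        c = dv.group_contrasts(m, method="holm")
        assert (c["p_adj"] >= c["p_raw"] - 1e-12).all()


class TestPredictWithCI:
    def test_prediction_at_group_mean(self):
        rng = np.random.default_rng(8)
        df = _simulate_pairs(rng, [20.0] * 3, [80.0, 150.0, 240.0])
        m = dv.fit_divergence_models(df)
        frame = m.additive.model.data.frame
        grp = frame[frame["subdivision"] == "SD2"]
        new = pd.DataFrame({"dissim_pct": [grp["dissim_pct"].mean()],
                            "subdivision": ["SD2"]})
        pred = float(m.additive.get_prediction(new).predicted_mean[0])
        assert pred == pytest.approx(float(grp["divergence"].mean()), rel=0.02)

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        widths = {}
        for n in (30, 300):
            df = _simulate_pairs(rng, [20.0] * 2, [80.0, 150.0], n_per=n)
            m = dv.fit_divergence_models(df)
            pred = dv.predict_with_ci(m, n_sim_per_group=50, seed=0)
            widths[n] = (pred["ci_hi"] - pred["ci_lo"]).mean()
        assert widths[300] < widths[30]

    def test_band_covers_true_line(self):
        """~95% pointwise coverage of the true mean line."""
        rng = np.random.default_rng(10)
        cover = []
        for rep in range(200):
            df = _simulate_pairs(rng, [20.0] * 2, [80.0, 150.0], n_per=40)
            m = dv.fit_divergence_models(df)
            pred = dv.predict_with_ci(m, n_sim_per_group=10, seed=rep)
            truth = np.where(pred["subdivision"] == "SD1", 80.0, 150.0) \
                + 20.0 * pred["dissim_pct"].to_numpy()
            cover.append(np.mean((pred["ci_lo"] <= truth) & (truth <= pred["ci_hi"])))
        assert 0.90 < np.mean(cover) < 0.99
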