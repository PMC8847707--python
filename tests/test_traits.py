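import numpy as np
import pandas as pd
import pytest

from hofniche import synthetic as syn
from hofniche import traits as tr


class TestSparsityPrune:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(1, 4, (8, 6)).astype(float))
        pd.testing.assert_frame_equal(tr.sparsity_prune(m), m)

    def test_single_sparse_row_removed(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.integers(1, 4, (10, 10)).astype(float),
                         index=[f"sp{i}" for i in range(10)])
        m.iloc[0, :4] = np.nan  # 60% complete < 70% threshold
        pruned = tr.sparsity_prune(m)
        assert list(pruned.index) == [f"sp{i}" for i in range(1, 10)]
        assert pruned.shape[1] == 10

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(1, 4, (15, 8)).astype(float))
        mask = rng.random(m.shape) < 0.25
        m = m.mask(mask)
        once = tr.sparsity_prune(m)
        twice = tr.sparsity_prune(once)
        pd.testing.assert_frame_equal(once, twice)
        assert (once.notna().mean(axis=1) >= 0.70).all()
        assert (once.notna().mean(axis=0) >= 0.50).all()

    def test_empty_result_raises_with_diagnostics(self):
        m = pd.DataFrame(np.nan, index=["a", "b"], columns=["t1", "t2"])
        with pytest.raises(ValueError, match="shape"):
            tr.sparsity_prune(m)


class TestImputeMeanOptima:
    @pytest.fixture
    def optima(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(1, 100, (10, 41)),
                         index=[f"sp{i}" for i in range(10)])
        m.iloc[0, :2] = np.nan   # 2 missing: retained and imputed
        m.iloc[1, :4] = np.nan   # 4 missing: dropped
        return m

    def test_impute_and_drop_rules(self, optima):
        completed, dropped = tr.impute_mean_optima(optima, max_missing=2)
        assert dropped == ["sp1"]
        assert "sp0" in completed.index
        assert not completed.isna().any().any()
        col_mean = optima.drop(index="sp1")[0].mean()
        assert completed.loc["sp0", 0] == pytest.approx(col_mean)

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.uniform(1, 100, (5, 41)))
        completed, dropped = tr.impute_mean_optima(m)
        assert dropped == []
        pd.testing.assert_frame_equal(completed, m)

    def test_variable_missing_everywhere_rejected(self):
        m = pd.DataFrame(np.ones((4, 3)))
        m[1] = np.nan
        with pytest.raises(ValueError):
            tr.impute_mean_optima(m, max_missing=3)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], dtype=float)
        assert tr.bray_curtis(m).iloc[0, 1] == 0.0

    def test_hand_computed_value(self):
        m = pd.DataFrame([[1, 1, 1], [3, 3, 3]], dtype=float)
        assert tr.bray_curtis(m).iloc[0, 1] == pytest.approx(0.5)

    def test_missing_trait_omitted_pairwise(self):
        m = pd.DataFrame([[1.0, np.nan, 3.0], [2.0, 3.0, 3.0]])
        # only traits 0 and 2 shared: |1-2|+|3-3| / (3+6) = 1/9
        assert tr.bray_curtis(m).iloc[0, 1] == pytest.approx(1 / 9)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(1, 4, (12, 9)).astype(float))
        bc = tr.bray_curtis(m).to_numpy()
        assert bc.min() >= 0.0 and bc.max() <= 1.0

    def test_no_shared_trait_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="share"):
            tr.bray_curtis(m)


class TestNMDS:
    def test_exact_embedding_recovered(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(15, 3))
        d = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)))
        res = tr.nmds(d, k=3, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_full_dimensional_embedding_near_zero_stress(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0.2, 1.0, (8, 8))
        d = pd.DataFrame(np.triu(m, 1) + np.triu(m, 1).T)
        res = tr.nmds(d, k=7, n_starts=10, seed=0)
        assert res.stress < 0.05

    def test_duplicated_species_coincide(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        pts[1] = pts[0]
        d = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)))
        res = tr.nmds(d, k=2, n_starts=8, seed=0)
        s = res.scores.to_numpy()
        assert np.linalg.norm(s[0] - s[1]) < 0.05 * np.abs(s).max()

    def test_k_validation(self):
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError):
            tr.nmds(d, k=4)


@pytest.fixture()
def scores():
    rng = np.random.default_rng(9)
    idx = [f"sp{i}" for i in range(20)]
    return pd.DataFrame(rng.normal(size=(20, 4)), index=idx)


class TestProtest:

    def test_self_comparison(self, scores):
        res = tr.procrustes_protest(scores, scores, n_perm=99, n_repeat=5,
                                    seed=0)
        assert res.correlation == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_rotation_and_scale_invariance(self, scores):
        th = 0.9
        rot = np.eye(4)
        rot[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        other = pd.DataFrame(scores.to_numpy() @ rot * 2.5 + 7.0,
                             index=scores.index)
        res = tr.procrustes_protest(scores, other, n_perm=49, n_repeat=2,
                                    seed=1)
        assert res.correlation == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 50)

    def test_mismatched_species_rejected(self, scores):
        other = scores.copy()
        other.index = [f"x{i}" for i in range(20)]
        with pytest.raises(ValueError):
            tr.procrustes_protest(scores, other)

    def test_repeat_averaging_stabilizes_p(self, scores):
        rng = np.random.default_rng(10)
        other = pd.DataFrame(rng.normal(size=scores.shape), index=scores.index)
        res = tr.procrustes_protest(scores, other, n_perm=99, n_repeat=10,
                                    seed=2)
        assert res.p_values.std() >= 0.0
        assert res.p_value == pytest.approx(res.p_values.mean())


class TestEndToEndConcordance:
    def test_coupled_matrices_concordant(self):
        a, b, _ = syn.plant_trait_matrices(n_species=30, n_traits=12,
                                           n_groups=3, missing_fraction=0.1,
                                           seed=5)
        pa, pb = tr.sparsity_prune(a), tr.sparsity_prune(b)
        shared = pa.index.intersection(pb.index)
        sa = tr.nmds(tr.bray_curtis(pa.loc[shared]), k=6, seed=1).scores
        sb = tr.nmds(tr.bray_curtis(pb.loc[shared]), k=6, seed=2).scores
        res = tr.procrustes_protest(sa, sb, n_perm=199, n_repeat=5, seed=3)
        assert res.p_value < 0.05

    def test_decoupled_matrices_not_concordant(self):
        """Destroying the shared species-group assignment (row relabeling)
        removes the concordance signal."""
        a, b, _ = syn.plant_trait_matrices(n_species=30, n_traits=12,
                                           n_groups=3, seed=6)
        rng = np.random.default_rng(8)
        b = pd.DataFrame(b.to_numpy()[rng.permutation(len(b))],
                         index=b.index, columns=b.columns)
        pa, pb = tr.sparsity_prune(a), tr.sparsity_prune(b)
        shared = pa.index.intersection(pb.index)
        sa = tr.nmds(tr.bray_curtis(pa.loc[shared]), k=6, seed=1).scores
        sb = tr.nmds(tr.bray_curtis(pb.loc[shared]), k=6, seed=2).scores
        res = tr.procrustes_protest(sa, sb, n_perm=199, n_repeat=5, seed=3)
        assert res.p_value > 0.01
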