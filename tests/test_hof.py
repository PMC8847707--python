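import math

import numpy as np
import pandas as pd
import pytest

from hofniche import environment as env_mod
from hofniche import synthetic as syn
from hofniche.hof import (
    MODEL_ORDER,
    HOFCurve,
    HOFFit,
    NicheModel,
    _best_by_aicc,
    extract_optimum,
    fit_hof_model,
    niche_width,
    optima_wide,
    optimum_matrix,
    prevalence_filter,
)


def _sim_curve(model, params, x, depth, seed, background=2.0):
    """Counts from a single true curve plus constant background."""
    curve = HOFFit(model, np.asarray(params, float), 1.0, np.nan, np.nan, 0)
    expected = curve.predict(x)[None, :]
    table = syn.sample_reads(expected, depth, seed=seed, background_mass=background)
    return table.iloc[0].to_numpy(), np.full(x.size, float(depth)), curve


class TestFitHofModel:
    def test_flat_model_recovers_constant_ratio(self):
        x = np.linspace(1, 100, 150)
        totals = np.full(150, 5000.0)
        counts = np.full(150, 250.0)  # exact ratio 0.05
        fit = fit_hof_model(x, counts, totals, model_type="I")
        assert fit.predict(np.array([50.0]))[0] == pytest.approx(0.05, rel=1e-4)

    def test_likelihood_nesting_up_the_hierarchy(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 100, 150)
        counts, totals, _ = _sim_curve("II", [2.0, -6.0], x, 10_000, seed=5)
        fits = {m: fit_hof_model(x, counts, totals, model_type=m)
                for m in MODEL_ORDER}
        assert fits["II"].loglik >= fits["I"].loglik - 1e-6
        for m in ("III", "IV", "V"):
            assert fits[m].loglik >= fits["II"].loglik - 1e-6

    def test_model_iv_curve_recovery(self):
        """Median fitted-curve RMSE against the true model-IV curve is small
        across 200 replicate fits."""
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 100, 150)
        grid = np.linspace(1, 100, 1000)
        rmses = []
        for rep in range(200):
            counts, totals, curve = _sim_curve("IV", [-2.0, 10.0, 6.0], x,
                                               10_000, seed=1000 + rep)
            fit = fit_hof_model(x, counts, totals, model_type="IV")
            # the observable proportion is e/(e + background)
            target = curve.predict(grid) / (curve.predict(grid) + 2.0)
            rmses.append(float(np.sqrt(np.mean(
                (fit.predict(grid) - target) ** 2))))
        assert np.median(rmses) < 0.005

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_hof_model(np.linspace(1, 100, 30), np.zeros(30),
                          np.full(30, 100.0), model_type="I")

    def test_gaussian_family_fits_proportions(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 100, 100)
        counts, totals, curve = _sim_curve("IV", [-2.0, 10.0, 6.0], x, 10_000,
                                           seed=8)
        fit = fit_hof_model(x, counts, totals, model_type="IV",
                            family="gaussian")
        assert fit.family == "gaussian"
        opt = extract_optimum(fit)
        assert opt.defined


class TestSelection:
    def test_equally_good_band_prefers_simpler(self):
        def mk(model, aicc):
            return HOFFit(model, np.zeros(4), 1.0, 0.0, aicc, 150)
        fits = {"I": mk("I", 101.5), "II": mk("II", 100.0), "V": mk("V", 99.0)}
        # all within 2 of the minimum 99 except none: I at +2.5 is out
        assert _best_by_aicc(fits) == "II"
        fits["I"] = mk("I", 100.9)
        assert _best_by_aicc(fits) == "I"

    def test_equal_complexity_tie_goes_to_better_fit(self):
        def mk(model, aicc):
            return HOFFit(model, np.zeros(4), 1.0, 0.0, aicc, 150)
        fits = {"III": mk("III", 100.5), "IV": mk("IV", 100.0)}
        assert _best_by_aicc(fits) == "IV"

    def test_strong_unimodal_truth_selected_with_support(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 100, 150)
        counts, totals, _ = _sim_curve("IV", [-2.0, 10.0, 6.0], x, 10_000,
                                       seed=10)
        nm = NicheModel(n_bootstrap=50, random_state=0).fit(x, counts, totals)
        assert nm.model_type_ in ("IV", "V")
        assert nm.bootstrap_support_ > 0.5

    def test_site_order_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 100, 120)
        counts, totals, _ = _sim_curve("IV", [-1.0, 9.0, 5.0], x, 5_000, seed=13)
        nm1 = NicheModel(n_bootstrap=20, random_state=1).fit(x, counts, totals)
        perm = rng.permutation(120)
        nm2 = NicheModel(n_bootstrap=20, random_state=1).fit(
            x[perm], counts[perm], totals[perm])
        assert nm1.model_type_ == nm2.model_type_
        assert nm1.optimum_.optimum == pytest.approx(nm2.optimum_.optimum,
                                                     abs=1e-9)


class TestOptimumExtraction:
    def test_flat_model_has_no_optimum(self):
        fit = HOFFit("I", np.array([2.0]), 1.0, 0.0, 0.0, 100)
        assert not extract_optimum(fit).defined

    def test_symmetric_iv_peaks_at_midpoint(self):
        fit = HOFFit("IV", np.array([2.0, 8.0, 2.0]), 1.0, 0.0, 0.0, 100)
        assert extract_optimum(fit).optimum == pytest.approx(50.5)

    def test_monotone_models_peak_at_gradient_end(self):
        down = HOFFit("II", np.array([0.0, 5.0]), 1.0, 0.0, 0.0, 100)
        up = HOFFit("II", np.array([0.0, -5.0]), 1.0, 0.0, 0.0, 100)
        assert extract_optimum(down).optimum == 1.0
        assert extract_optimum(up).optimum == 100.0

    def test_model_v_argmax_matches_grid(self):
        fit = HOFFit("V", np.array([6.0, -14.0, -3.0, 9.0]), 1.0, 0.0, 0.0, 100)
        grid = np.linspace(1, 100, 990_001)  # 1e-4 scaled-unit steps
        oracle = grid[np.argmax(fit.predict(grid))]
        assert extract_optimum(fit).optimum == pytest.approx(oracle, abs=1e-3)

    def test_closed_form_iv(self):
        a, b, c = -1.5, 11.0, 4.0
        fit = HOFFit("IV", np.array([a, b, c]), 1.0, 0.0, 0.0, 100)
        internal = (c - a) / (2 * b)
        assert extract_optimum(fit).optimum == pytest.approx(50.5 + 99 * internal)


class TestNicheWidth:
    def test_narrow_curve_has_smaller_width(self):
        narrow = HOFFit("IV", np.array([-6.0, 24.0, 18.0]), 1.0, 0.0, 0.0, 100)
        broad = HOFFit("IV", np.array([-1.5, 6.0, 4.5]), 1.0, 0.0, 0.0, 100)
        wn = niche_width(narrow)
        wb = niche_width(broad)
        assert (wn.hi - wn.lo) < (wb.hi - wb.lo)

    def test_symmetric_interval_around_optimum(self):
        fit = HOFFit("IV", np.array([2.0, 10.0, 2.0]), 1.0, 0.0, 0.0, 100)
        w = niche_width(fit)
        assert w.optimum - w.lo == pytest.approx(w.hi - w.optimum, abs=1e-6)

    def test_model_v_bounds_match_grid_scan(self):
        fit = HOFFit("V", np.array([6.0, -14.0, -3.0, 9.0]), 1.0, 0.0, 0.0, 100)
        w = niche_width(fit)
        grid = np.linspace(1, 100, 99_001)
        resp = fit.predict(grid)
        thr = math.exp(-0.5) * resp.max()
        inside = grid[resp >= thr]
        assert w.lo == pytest.approx(inside.min(), abs=1e-2)
        assert w.hi == pytest.approx(inside.max(), abs=1e-2)

    def test_interval_clipped_to_gradient(self):
        fit = HOFFit("IV", np.array([0.5, 3.0, 0.5]), 1.0, 0.0, 0.0, 100)
        w = niche_width(fit)
        assert w.lo >= 1.0 and w.hi <= 100.0


class TestOptimumMatrix:
    def test_prevalence_filter_boundaries(self):
        rng = np.random.default_rng(14)
        table = pd.DataFrame(0.0, index=["a", "b", "c"],
                             columns=[f"s{i}" for i in range(150)])
        table.iloc[0, :25] = 1.0   # exactly 25 sites: retained
        table.iloc[1, :24] = 1.0   # 24 sites: removed
        table.iloc[2, :] = 1.0
        kept = prevalence_filter(table, min_sites=25)
        assert list(kept.index) == ["a", "c"]
        pd.testing.assert_frame_equal(prevalence_filter(kept, 25), kept)
        with pytest.raises(ValueError):
            prevalence_filter(table, min_sites=151)

    def test_bookkeeping_and_missing_iff_flat(self, small_survey):
        counts = small_survey["counts"].iloc[:4]
        env = pd.DataFrame({
            "pH": small_survey["x"],
            "flatvar": np.linspace(1, 100, 150),  # unrelated gradient
        }, index=counts.columns)
        # make occupancy certain: add background-level pseudo reads
        long = optimum_matrix(counts + 1.0, env, min_sites=25, n_bootstrap=10,
                              seed=0)
        assert len(long) == 8  # 4 OTUs x 2 variables
        flat = long["model"] == "I"
        assert long.loc[flat, "optimum"].isna().all()
        assert long.loc[~flat, "optimum"].notna().all()
        wide = optima_wide(long)
        assert wide.shape == (4, 2)
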