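"""Evaluation battery: tSNR, t-maps, version statistics, profiles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nordicvaso import (ComplexSeries, DenoiseConfig, GFactorMap, StatsConfig,
                        StrategySpec, boco, compare_versions, denoise_series,
                        holm_bonferroni, laminar_profile, make_design,
                        removed_structure, simulate_run, split_half_selection,
                        split_interleaved, subsample_profiles,
                        trial_series_correlation, tsnr_map, tvalue_map,
                        PhantomSpec, run_strategy, trial_psc, trial_psc_map)
from nordicvaso.evaluate import roi_metrics


class TestTsnrMap:
    def test_constant_plus_noise(self):
        rng = np.random.default_rng(1)
        vals = 100.0 + 2.0 * rng.standard_normal((4, 4, 2, 500))
        tsnr = tsnr_map(vals, detrend_order=0)
        assert np.nanmean(tsnr) == pytest.approx(50.0, rel=0.05)

    def test_exact_linear_drift_flagged(self):
        t = np.arange(20, dtype=float)
        vals = np.broadcast_to(5.0 + 2.0 * t, (2, 2, 1, 20)).copy()
        tsnr = tsnr_map(vals, detrend_order=1)
        assert np.isnan(tsnr).all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = 50.0 + rng.standard_normal((3, 3, 2, 60))
        np.testing.assert_allclose(tsnr_map(vals), tsnr_map(7.0 * vals),
                                   rtol=1e-9)

    def test_denoising_increases_tsnr_paired_runs(self):
        # thermal-dominated phantom: ROI tSNR rises in every one of 6 runs
        spec = PhantomSpec(grid_dims=(24, 24, 12), n_runs=6,
                           volumes_per_contrast_per_run=48, seed=13)
        cfg = DenoiseConfig(patch_dims=(8, 8, 8), seed=1)
        gains = []
        for r in range(6):
            series, truth = simulate_run(spec, r)
            nulled, _ = split_interleaved(series)
            res = denoise_series(nulled, cfg, truth.g_map)
            before = np.nanmean(tsnr_map(nulled)[truth.roi_mask])
            after = np.nanmean(tsnr_map(res.denoised)[truth.roi_mask])
            gains.append(after - before)
        assert all(g > 0 for g in gains)


class TestTvalueMap:
    def test_zero_variance_flagged(self):
        t = tvalue_map(np.ones((2, 2, 1, 4)))
        assert np.isnan(t).all()

    def test_hand_computed(self):
        t = tvalue_map(np.array([[[[2.0, 0.0, 2.0, 0.0]]]]))
        assert t[0, 0, 0] == pytest.approx(1.7321, abs=1e-4)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            tvalue_map(np.ones((2, 2, 1, 1)))


class TestVersionComparison:
    def test_holm_worked_example(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def _table(self, b_offset):
        rows = []
        rng = np.random.default_rng(3)
        base = 10.0 + rng.random(6)
        for run in range(6):
            rows.append({"version": "a", "run": run, "tsnr": base[run],
                         "abs_t": 2.0, "psc": 1.0})
            rows.append({"version": "b", "run": run,
                         "tsnr": base[run] + b_offset, "abs_t": 2.0,
                         "psc": 1.0})
        return pd.DataFrame(rows)

    def test_identical_versions_p_one(self):
        res = compare_versions(self._table(0.0))
        assert (res["p"] == 1.0).all()
        assert not res["significant"].any()

    def test_constant_nonzero_difference_p_zero(self):
        res = compare_versions(self._table(1.0))
        tsnr_row = res[res.metric == "tsnr"].iloc[0]
        assert tsnr_row["p"] == 0.0 and tsnr_row["significant"]

    def test_single_run_rejected(self):
        table = self._table(1.0)
        with pytest.raises(ValueError, match="2 paired runs"):
            compare_versions(table[table.run == 0])

    def test_real_difference_detected_with_holm(self):
        rng = np.random.default_rng(4)
        rows = []
        for run in range(8):
            base = 10.0 + rng.standard_normal() * 0.1
            rows.append({"version": "raw", "run": run, "tsnr": base,
                         "abs_t": 2.0 + 0.01 * rng.standard_normal(),
                         "psc": 1.0 + 0.01 * rng.standard_normal()})
            rows.append({"version": "den", "run": run, "tsnr": base + 5.0,
                         "abs_t": 2.5 + 0.01 * rng.standard_normal(),
                         "psc": 0.9 + 0.01 * rng.standard_normal()})
        res = compare_versions(pd.DataFrame(rows))
        tsnr = res[res.metric == "tsnr"].iloc[0]
        assert tsnr["significant"] and tsnr["p_adj"] <= 0.05

    def test_roi_metrics_row_shape(self, small_run):
        series, truth = small_run
        nulled, notnulled = split_interleaved(series)
        psc = trial_psc(boco(nulled, notnulled), truth.roi_mask, truth.design)
        row = roi_metrics("control", 0, nulled, psc, truth.roi_mask)
        assert set(row) == {"version", "run", "tsnr", "abs_t", "psc"}
        assert np.isfinite(row["tsnr"]) and np.isfinite(row["abs_t"])


class TestSplitHalfSelection:
    def test_strong_responders_all_selected(self):
        rng = np.random.default_rng(5)
        resp = 5.0 + 0.1 * rng.standard_normal((4, 4, 2, 36))
        labels = np.repeat(np.arange(6), 6)
        mask = split_half_selection(resp, labels, first_runs={0, 1, 2})
        assert mask.all()

    def test_mask_independent_of_second_half(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((6, 6, 2, 24))
        labels = np.repeat(np.arange(4), 6)
        m1 = split_half_selection(vals, labels, first_runs={0, 1})
        permuted = vals.copy()
        permuted[..., 12:] = rng.permutation(permuted[..., 12:], axis=-1)
        m2 = split_half_selection(permuted, labels, first_runs={0, 1})
        assert np.array_equal(m1, m2)

    def test_null_selection_near_tail_fraction(self):
        # pure-noise trials: t>2 selects roughly the one-sided tail mass
        from scipy import stats
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((40, 40, 6, 36))
        labels = np.repeat(np.arange(6), 6)
        mask = split_half_selection(vals, labels, first_runs={0, 1, 2})
        expected = stats.t.sf(2.0, 17)  # 18 first-half trials
        assert mask.mean() == pytest.approx(expected, abs=0.01)

    def test_empty_selection_warns(self):
        vals = np.zeros((3, 3, 1, 12))
        vals += np.linspace(-1, 1, 12) * 0.0
        rng = np.random.default_rng(8)
        vals = -5.0 + 0.1 * rng.standard_normal((3, 3, 1, 12))
        labels = np.repeat([0, 1], 6)
        with pytest.warns(UserWarning, match="empty"):
            mask = split_half_selection(vals, labels, first_runs={0})
        assert not mask.any()


class TestTrialCorrelation:
    def test_identity_and_inversion(self):
        a = np.array([1.0, 2.0, 3.0, 2.5])
        assert trial_series_correlation(a, a) == pytest.approx(1.0)
        assert trial_series_correlation(a, -a) == pytest.approx(-1.0)

    def test_small_added_noise(self):
        # independent noise at 10% of SD(a): r ~ 1/sqrt(1.01) ~ 0.995
        rng = np.random.default_rng(9)
        a = rng.standard_normal(5000)
        b = a + 0.1 * rng.standard_normal(5000)
        assert trial_series_correlation(a, b) == pytest.approx(
            1 / np.sqrt(1.01), abs=0.003)

    def test_zero_variance_flagged(self):
        assert np.isnan(trial_series_correlation(np.ones(5),
                                                 np.arange(5.0)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            trial_series_correlation(np.ones(3), np.ones(4))


class TestRemovedStructure:
    def test_zero_removed(self):
        removed = ComplexSeries(np.zeros((6, 6, 3, 24)), contrast="nulled",
                                validate=False)
        design = make_design(24, 6, 6)
        gmap = GFactorMap(np.ones((6, 6, 3)))
        mean_img, _, delta = removed_structure(removed, gmap,
                                               np.ones((6, 6, 3), bool), design)
        assert np.all(mean_img == 0)
        np.testing.assert_allclose(delta, 0.0)

    def test_pure_noise_removed_is_unstructured(self):
        rng = np.random.default_rng(10)
        g = 1.0 + rng.random((16, 16, 8)) * 0.5
        noise = g[..., None] * rng.standard_normal((16, 16, 8, 200))
        removed = ComplexSeries(noise, contrast="nulled", validate=False)
        _, autocorr, _ = removed_structure(removed, GFactorMap(g),
                                           np.ones((16, 16, 8), bool))
        assert abs(autocorr) < 0.1

    def test_task_locked_component_detected(self):
        design = make_design(48, 6, 6)
        task = design.task_indicator().astype(float)
        d = 0.7
        vals = np.broadcast_to(d * task, (8, 8, 4, 48)).copy()
        removed = ComplexSeries(vals, contrast="nulled", validate=False)
        gmap = GFactorMap(np.ones((8, 8, 4)))
        _, _, delta = removed_structure(removed, gmap,
                                        np.ones((8, 8, 4), bool), design)
        np.testing.assert_allclose(delta, d, atol=1e-10)


class TestLaminarProfiles:
    def _depth(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        depth = rng.random((n, 1, 1))
        return depth

    def test_uniform_delta_flat_profile(self):
        depth = self._depth()
        delta = np.full((500, 1, 1), 3.0)
        prof = laminar_profile(delta, depth, np.ones((500, 1, 1), bool), 10)
        np.testing.assert_allclose(prof.delta_mean, 3.0)
        assert np.all(prof.delta_se == 0)

    def test_degenerate_binning_drops_empty_bins(self):
        depth = np.array([0.1, 0.9]).reshape(2, 1, 1)
        delta = np.array([1.0, 2.0]).reshape(2, 1, 1)
        with pytest.warns(UserWarning, match="empty"):
            prof = laminar_profile(delta, depth, np.ones((2, 1, 1), bool), 50)
        assert len(prof.bin_centers) == 2

    def test_phantom_profile_shape_recovered_72_trials(self):
        # six standard runs (72 trials): binned deltas track the generating
        # mid-depth-peaked profile (r > 0.9), even without denoising
        from nordicvaso import trial_delta_map
        from nordicvaso.phantom import default_profile_shape
        spec = PhantomSpec(seed=17)
        deltas = []
        for r in range(6):
            series, truth = simulate_run(spec, r)
            nulled, notnulled = split_interleaved(series)
            vaso = boco(nulled, notnulled)
            deltas.append(trial_delta_map(vaso, truth.design))
        mean_delta = np.concatenate(deltas, axis=-1).mean(axis=-1)
        prof = laminar_profile(mean_delta, truth.depth_map, truth.roi_mask, 11)
        generating = default_profile_shape(prof.bin_centers)
        r = np.corrcoef(prof.delta_mean, generating)[0, 1]
        assert r > 0.9

    def test_subsampling_schemes(self):
        rng = np.random.default_rng(11)
        depth = rng.random((200, 1, 1))
        trials = rng.standard_normal((200, 1, 1, 72)) + 1.0
        roi = np.ones((200, 1, 1), bool)
        out = subsample_profiles(trials, depth, roi, factors=(1, 2, 6), n_bins=5)
        assert len(out[1]["profiles"]) == 1
        assert len(out[2]["profiles"]) == 2
        assert len(out[6]["profiles"]) == 6
        assert out[1]["dispersion"] == 0.0
        assert out[6]["dispersion"] > out[2]["dispersion"] > 0

    def test_factor_exceeding_trials_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="exceeds"):
            subsample_profiles(rng.standard_normal((10, 1, 1, 6)),
                               rng.random((10, 1, 1)), np.ones((10, 1, 1), bool),
                               factors=(7,))

    def test_tsnr_and_t_orderings_reported_independently(self, small_run):
        # the harness reports both metrics rather than assuming they agree
        series, truth = small_run
        cfg = DenoiseConfig(patch_dims=(8, 8, 8), seed=1)
        rows = []
        for strat in (StrategySpec.control(), StrategySpec()):
            res_n, res_nn = run_strategy(series, strat, cfg, truth.g_map)
            vaso = boco(res_n.denoised, res_nn.denoised)
            psc = trial_psc(vaso, truth.roi_mask, truth.design)
            rows.append(roi_metrics(strat.name, 0, res_n.denoised, psc,
                                    truth.roi_mask))
        table = pd.DataFrame(rows)
        assert {"tsnr", "abs_t"} <= set(table.columns)
        assert table.set_index("version").loc["separate-noisevol-magnitude",
                                              "tsnr"] > \
            table.set_index("version").loc["control", "tsnr"]


class TestPlotting:
    def test_profile_and_removed_plots_render(self, small_run, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from nordicvaso import DenoiseConfig, denoise_series, trial_delta_map
        series, truth = small_run
        nulled, notnulled = split_interleaved(series)
        res = denoise_series(nulled, DenoiseConfig(patch_dims=(8, 8, 8), seed=1),
                             truth.g_map)
        ax = res.plot_removed_mean()
        assert ax.get_title().startswith("mean removed")
        delta = trial_delta_map(boco(nulled, notnulled), truth.design).mean(-1)
        prof = laminar_profile(delta, truth.depth_map, truth.roi_mask, 8)
        ax2 = prof.plot(label="raw")
        assert ax2.get_ylabel() == "response delta"
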