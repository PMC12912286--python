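import numpy as np
import pandas as pd
import pytest

import shortsep as ss
from shortsep.glm import (
    CONDITIONS,
    EXPECTED_NUISANCE_COUNT,
    DegenerateFitError,
    DesignError,
    PIPELINES,
    PipelineConfig,
    build_nuisance,
    build_task_design,
    canonical_hrf,
    condition_regressor,
    fit_ols,
    run_pipeline,
    sc_pca_components,
)
from shortsep.preprocess import preprocess_session

from .oracles import ols_normal_equations

FS = 7.81


class TestHrf:
    def test_zero_at_origin(self):
        h = canonical_hrf(FS)
        assert h[0] == 0.0

    def test_peak_location_and_normalization(self):
        h = canonical_hrf(100.0)  # dense grid
        t = np.arange(h.size) / 100.0
        assert 4.0 <= t[np.argmax(h)] <= 7.0
        assert h.max() == pytest.approx(1.0)

    def test_tail_small_at_kernel_end(self):
        h = canonical_hrf(100.0)
        assert abs(h[-1]) < 0.01


class TestTaskDesign:
    def test_empty_schedule_zero_columns(self):
        sched = ss.EventSchedule(np.array([]), np.array([]), [])
        design = build_task_design(sched, FS, 500, design_band=None)
        for cond in CONDITIONS:
            assert np.allclose(design.columns[cond], 0.0)
        assert np.allclose(design.columns["intercept"], 1.0)

    def test_single_event_only_its_column_nonzero(self):
        sched = ss.EventSchedule(np.array([10.0]), np.array([10.0]), ["A"])
        design = build_task_design(sched, FS, 800, design_band=None)
        assert np.allclose(design.columns["V"], 0.0)
        assert np.allclose(design.columns["AV"], 0.0)
        a = design.columns["A"]
        # zero before onset, one dominant positive lobe (HRF undershoot may dip)
        assert np.allclose(a[: int(10 * FS) - 1], 0.0)
        assert a.max() > 0.5
        assert a.min() > -0.2 * a.max()

    def test_default_schedule_column_count(self):
        sched = ss.generate_schedule(ss.SessionSpec(), seed=0)
        n = int((sched.end_time + 30) * FS)
        design = build_task_design(sched, FS, n)
        assert design.matrix().shape[1] == 4  # 3 conditions + intercept

    def test_event_beyond_series_rejected(self):
        sched = ss.EventSchedule(np.array([100.0]), np.array([10.0]), ["A"])
        with pytest.raises(DesignError):
            build_task_design(sched, FS, 200)


class TestPipelineRegistry:
    def test_ten_pipelines(self):
        assert sorted(PIPELINES) == list(range(1, 11))
        labels = {p.label for p in PIPELINES.values()}
        assert len(labels) == 10

    def test_limited_pooled_raw_invalid(self):
        with pytest.raises(DesignError):
            PipelineConfig(99, "limited", "pooled_raw")

    def test_scope_none_requires_method_none(self):
        with pytest.raises(DesignError):
            PipelineConfig(99, "none", "mean")


@pytest.fixture(scope="module")
def noisy_hemo(montage):
    spec = ss.SessionSpec(n_trials_per_condition=4, baseline_duration=20, tail_duration=20)
    truth = ss.default_ground_truth(montage)
    raw, sched = ss.simulate_session(spec, truth, ss.NoiseSpec(), montage, seed=12)
    return preprocess_session(raw), sched


class TestNuisance:
    def test_counts_match_strategy_for_all_channels(self, noisy_hemo, montage):
        hemo, _ = noisy_hemo
        for config in PIPELINES.values():
            expected = EXPECTED_NUISANCE_COUNT[(config.sc_scope, config.method)]
            for ch in montage.analyzed_channels:
                for chromo in ("HbO", "HbR"):
                    y = hemo.trace(f"L{ch.id}", chromo)
                    nuis = build_nuisance(config, hemo, ch, chromo, y, montage)
                    assert nuis.count == expected, (config.id, ch.id, chromo)

    def test_mean_method_labels(self, noisy_hemo, montage):
        hemo, _ = noisy_hemo
        ch = montage.channel(5)
        nuis = build_nuisance(PIPELINES[8], hemo, ch, "HbO", hemo.trace("L5", "HbO"), montage)
        assert nuis.names == ["mean-HbO", "mean-HbR"]

    def test_nearest_uses_same_chromophore_sc(self, noisy_hemo, montage):
        hemo, _ = noisy_hemo
        ch = montage.channel(7)  # occipital, source O1 -> SC4 (full), POz SC (limited)
        nuis_full = build_nuisance(PIPELINES[6], hemo, ch, "HbR", None, montage)
        assert nuis_full.names == ["SC4-HbR"]
        nuis_lim = build_nuisance(PIPELINES[2], hemo, ch, "HbO", None, montage)
        sc_poz = montage.limited_subset["occipital"]
        assert nuis_lim.names == [f"SC{sc_poz}-HbO"]

    def test_correlated_picks_argmax_pearson(self, noisy_hemo, montage):
        hemo, _ = noisy_hemo
        ch = montage.channel(3)
        y = hemo.trace("L3", "HbO")
        nuis = build_nuisance(PIPELINES[7], hemo, ch, "HbO", y, montage)
        rs = {i: np.corrcoef(y, hemo.trace(f"S{i}", "HbO"))[0, 1] for i in range(1, 9)}
        best = max(sorted(rs), key=lambda i: rs[i])
        assert nuis.names == [f"SC{best}-HbO"]

    def test_pca_components_orthogonal_ordered_span(self, noisy_hemo):
        hemo, _ = noisy_hemo
        scores, names = sc_pca_components(hemo, list(range(1, 9)))
        assert scores.shape[1] == 16
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))
        var = np.var(scores, axis=0)
        assert np.all(np.diff(var) <= 1e-12)  # decreasing explained variance
        # span equals span of the centered raw SC matrix
        X = np.column_stack(
            [hemo.trace(f"S{i}", ch) for ch in ("HbO", "HbR") for i in range(1, 9)]
        )
        Xc = X - X.mean(axis=0)
        Q, _ = np.linalg.qr(scores)
        resid = Xc - Q @ (Q.T @ Xc)
        assert np.max(np.abs(resid)) < 1e-8 * np.max(np.abs(Xc))

    def test_missing_sc_rejected(self, noisy_hemo, montage):
        hemo, _ = noisy_hemo
        lc_only = ss.HemoSeries(
            hemo.values[:16], hemo.fs, [n for n in hemo.channel_names if n.startswith("L")]
        )
        ch = montage.channel(1)
        with pytest.raises(DesignError):
            build_nuisance(PIPELINES[6], lc_only, ch, "HbO", None, montage)


class TestFitOls:
    def test_exact_interpolation_in_span(self):
        sched = ss.EventSchedule(np.array([5.0]), np.array([5.0]), ["A"])
        design = build_task_design(sched, FS, 300, design_band=None)
        y = 2.0 * design.columns["A"] + 0.5
        fit = fit_ols(y, design, ss.NuisanceSet([], np.empty((0, 0))))
        assert fit.condition_betas["A"] == pytest.approx(2.0, abs=1e-10)
        rss = fit.residual_variance * fit.dof
        assert rss < 1e-16 * float(y @ y)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        sched = ss.EventSchedule(
            np.array([0.3, 1.5, 3.0]), np.array([1.0, 1.0, 1.0]), ["A", "V", "AV"]
        )
        design = build_task_design(sched, FS, n, design_band=None)
        nuis = ss.NuisanceSet(["z1", "z2"], rng.normal(size=(n, 2)))
        y = rng.normal(size=n)
        fit = fit_ols(y, design, nuis)
        X = np.column_stack([design.matrix(), nuis.columns])
        ref = ols_normal_equations(X, y)
        got = np.array([fit.beta[k] for k in list(design.names) + nuis.names])
        assert np.allclose(got, ref, atol=1e-10)

    def test_orthonormal_design_gives_inner_products(self):
        rng = np.random.default_rng(4)
        n = 64
        M = np.linalg.qr(rng.normal(size=(n, 4)))[0]
        sched = ss.EventSchedule(np.array([]), np.array([]), [])
        design = build_task_design(sched, FS, n, design_band=None)
        design.columns = dict(zip(["A", "V", "AV", "intercept"], M.T))
        y = rng.normal(size=n)
        fit = fit_ols(y, design, ss.NuisanceSet([], np.empty((0, 0))))
        for k, cond in enumerate(CONDITIONS):
            assert fit.condition_betas[cond] == pytest.approx(float(M[:, k] @ y), abs=1e-10)

    def test_degenerate_fit_rejected(self):
        sched = ss.EventSchedule(np.array([]), np.array([]), [])
        design = build_task_design(sched, FS, 30, design_band=None)
        design.columns["intercept"] = np.zeros(30)
        with pytest.raises(DegenerateFitError):
            fit_ols(np.zeros(30), design, ss.NuisanceSet([], np.empty((0, 0))))

    def test_dof_accounts_for_all_regressors(self):
        rng = np.random.default_rng(5)
        n = 100
        sched = ss.EventSchedule(np.array([1.0]), np.array([2.0]), ["A"])
        design = build_task_design(sched, FS, n, design_band=None)
        nuis = ss.NuisanceSet(["z"], rng.normal(size=(n, 1)))
        fit = fit_ols(rng.normal(size=n), design, nuis)
        assert fit.dof == n - 5


class TestRunPipeline:
    def test_pooled_raw_equals_pooled_pca(self, noisy_hemo, montage):
        """Identical column spans (with intercept) -> identical condition betas."""
        hemo, sched = noisy_hemo
        b9 = run_pipeline([hemo], PIPELINES[9], montage, [sched])
        b10 = run_pipeline([hemo], PIPELINES[10], montage, [sched])
        merged = b9.merge(b10, on=["subject", "channel", "condition", "chromophore"])
        scale = merged.beta_x.abs().max()
        assert np.max(np.abs(merged.beta_x - merged.beta_y)) < 1e-8 * scale

    def test_zero_noise_recovers_truth(self, montage):
        spec = ss.SessionSpec(
            n_trials_per_condition=4, baseline_duration=20, tail_duration=20, n_subjects=1
        )
        truth = ss.default_ground_truth(montage, between_subject_sd=0.0)
        cohort = ss.make_cohort(spec, truth, ss.ZERO_NOISE, seed=3, montage=montage)
        hemo = preprocess_session(cohort.sessions[0])
        betas = run_pipeline([hemo], PIPELINES[1], montage, cohort.schedules)
        merged = betas.merge(truth.beta, on=["channel", "condition", "chromophore"],
                             suffixes=("_hat", "_true"))
        nz = merged[merged.beta_true != 0]
        rel = np.abs(nz.beta_hat - nz.beta_true) / np.abs(nz.beta_true)
        assert rel.max() < 0.02

    def test_hbr_betas_negative_for_negative_truth(self, montage):
        spec = ss.SessionSpec(
            n_trials_per_condition=4, baseline_duration=20, tail_duration=20, n_subjects=1
        )
        truth = ss.default_ground_truth(montage, between_subject_sd=0.0)
        cohort = ss.make_cohort(spec, truth, ss.ZERO_NOISE, seed=5, montage=montage)
        hemo = preprocess_session(cohort.sessions[0])
        betas = run_pipeline([hemo], PIPELINES[1], montage, cohort.schedules)
        occ_v = betas[(betas.roi == "occipital") & (betas.condition == "V")]
        assert (occ_v[occ_v.chromophore == "HbR"].beta < 0).all()
        assert (occ_v[occ_v.chromophore == "HbO"].beta > 0).all()

    def test_nesting_monotonicity_of_rss(self, noisy_hemo, montage):
        """Adding nuisance regressors never increases the residual sum of squares."""
        hemo, sched = noisy_hemo
        n = hemo.values.shape[-1]
        design = build_task_design(sched, hemo.fs, n)
        ch = montage.channel(6)
        y = hemo.trace("L6", "HbO")
        rss = {}
        for pid in (1, 8, 9):
            nuis = build_nuisance(PIPELINES[pid], hemo if pid > 1 else None, ch, "HbO", y, montage)
            fit = fit_ols(y, design, nuis)
            rss[pid] = fit.residual_variance * fit.dof
        assert rss[8] <= rss[1] + 1e-9
        assert rss[9] <= rss[8] + 1e-9

    def test_beta_table_complete_index(self, noisy_hemo, montage):
        hemo, sched = noisy_hemo
        betas = run_pipeline([hemo], PIPELINES[4], montage, [sched])
        assert len(betas) == 15 * 3 * 2
        assert set(betas.channel.unique()) == {ch.id for ch in montage.analyzed_channels}


class TestScCorrectionBenefit:
    def test_pooled_pca_beats_no_sc_across_seeds(self, montage):
        """With shared superficial noise, the no-SC pipeline's HbO beta RMSE
        strictly exceeds the full pooled-PCA pipeline's (paired by seed)."""
        spec = ss.SessionSpec(
            n_trials_per_condition=4, baseline_duration=20, tail_duration=20, n_subjects=1
        )
        truth = ss.default_ground_truth(montage, between_subject_sd=0.0)
        noise = ss.NoiseSpec(motion_rate_per_min=0.0)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort = ss.make_cohort(spec, truth, noise, seed=seed, montage=montage)
            hemo = preprocess_session(cohort.sessions[0])
            rmse = {}
            for pid in (1, 10):
                betas = run_pipeline([hemo], PIPELINES[pid], montage, cohort.schedules)
                merged = betas.merge(truth.beta, on=["channel", "condition", "chromophore"],
                                     suffixes=("_hat", "_true"))
                hbo = merged[merged.chromophore == "HbO"]
                rmse[pid] = np.sqrt(np.mean((hbo.beta_hat - hbo.beta_true) ** 2))
            wins += rmse[1] > rmse[10]
        assert wins == n_seeds

    def test_rmse_increases_with_superficial_share(self, montage):
        """No-SC HbO beta RMSE grows monotonically in the superficial share."""
        spec = ss.SessionSpec(
            n_trials_per_condition=4, baseline_duration=20, tail_duration=20, n_subjects=1
        )
        truth = ss.default_ground_truth(montage, between_subject_sd=0.0)
        rmses = []
        for share in (0.2, 0.5, 0.9):
            noise = ss.NoiseSpec(superficial_share=share, motion_rate_per_min=0.0, white_sd=0.0)
            vals = []
            for seed in (0, 1, 2):
                cohort = ss.make_cohort(spec, truth, noise, seed=seed, montage=montage)
                hemo = preprocess_session(cohort.sessions[0])
                betas = run_pipeline([hemo], PIPELINES[1], montage, cohort.schedules)
                merged = betas.merge(truth.beta, on=["channel", "condition", "chromophore"],
                                     suffixes=("_hat", "_true"))
                hbo = merged[merged.chromophore == "HbO"]
                vals.append(np.sqrt(np.mean((hbo.beta_hat - hbo.beta_true) ** 2)))
            rmses.append(np.mean(vals))
        assert rmses[0] < rmses[1] < rmses[2]
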