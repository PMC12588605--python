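import numpy as np
import pandas as pd
import pytest

from rhythmoscan.glm_rhythm import rhythm_scan
from rhythmoscan.prevalence_contrast import (
    average_prevalence, band_flags, bootstrap_prevalence, compute_eye_metrics,
    contrast_conditions, cooccurrence_correlation, difficulty_drift,
    dual_task_summary, median_split,
)
from rhythmoscan.synthetic_data import (
    DesignConfig, EyeParams, ObserverParams, RhythmComponent, generate_design,
    simulate_eye_traces, simulate_observer,
)
from rhythmoscan.trial_data import filter_outliers, reference_delays, transform_rt


def _null_scan(rng, P=5, n=80, n_perm=150, freqs=np.array([2.0, 3.0, 4.0])):
    data = [(rng.uniform(0, 1.2, n), rng.normal(size=n)) for _ in range(P)]
    return rhythm_scan(data, freqs=freqs, n_perm=n_perm, seed=int(rng.integers(2**31)))


class TestBootstrapPrevalence:
    def test_identical_participants_strong_effect_prevalence_one(self, rng):
        t = rng.uniform(0, 1.2, 150)
        y = np.sin(2 * np.pi * 4.0 * t)  # noiseless rhythm
        data = [(t, y)] * 6
        res = rhythm_scan(data, freqs=np.array([3.0, 4.0]), n_perm=200, seed=0)
        prev = bootstrap_prevalence(res.actual_vs, res.perm_vs, threshold=0.05,
                                    n_boot=200, seed=1, freqs_hz=res.freqs_hz)
        assert prev.prevalence[1] == 1.0

    def test_null_cohort_low_prevalence(self, rng):
        res = _null_scan(rng, P=8, n=100, n_perm=300)
        prev = bootstrap_prevalence(res.actual_vs, res.perm_vs, threshold=0.05 / 3,
                                    n_boot=300, seed=2, freqs_hz=res.freqs_hz)
        assert prev.prevalence.max() < 0.5

    def test_seed_reproducibility(self, rng):
        res = _null_scan(rng)
        a = bootstrap_prevalence(res.actual_vs, res.perm_vs, 0.05, n_boot=100, seed=3)
        b = bootstrap_prevalence(res.actual_vs, res.perm_vs, 0.05, n_boot=100, seed=3)
        np.testing.assert_array_equal(a.flags, b.flags)

    def test_matches_full_refit_exactly_with_shared_streams(self, rng):
        """Precomputed-surrogate bootstrap == refit bootstrap when the refit
        reuses the same per-participant permutation streams."""
        P = 5
        data = [(rng.uniform(0, 1.2, 60),
                 0.4 * np.sin(2 * np.pi * 3.0 * rng.uniform(0, 1.2, 60)))
                for _ in range(P)]
        data = [(t, 0.4 * np.sin(2 * np.pi * 3.0 * t) + rng.normal(0, 0.4, 60))
                for t, _ in data]
        freqs = np.array([2.0, 3.0])
        scan = rhythm_scan(data, freqs=freqs, n_perm=200, seed=11)
        n_boot = 50
        prev = bootstrap_prevalence(scan.actual_vs, scan.perm_vs, 0.05,
                                    n_boot=n_boot, seed=7, freqs_hz=freqs)
        # full refit: per bootstrap cohort, regenerate each drawn participant's
        # null with the same master seed => identical per-participant streams
        rng_b = np.random.default_rng(7)
        draws = rng_b.integers(0, P, size=(n_boot, P))
        for b in range(min(n_boot, 10)):
            idx = draws[b]
            group_actual = scan.actual_vs[idx].mean(axis=0)
            group_perm = scan.perm_vs[idx].mean(axis=0)  # (F, n_perm)
            p = (1 + (group_perm >= group_actual[:, None]).sum(axis=1)) / 201
            np.testing.assert_array_equal(prev.flags[b], p <= 0.05)

    def test_matches_fresh_refit_statistically(self, rng):
        """Prevalence from precomputed surrogates agrees with a full refit that
        draws fresh permutations (small instance, Monte-Carlo tolerance)."""
        P = 5
        t0 = rng.uniform(0, 1.2, 60)
        data = [(t0, 0.5 * np.sin(2 * np.pi * 3.0 * t0) + rng.normal(0, 0.5, 60))
                for _ in range(P)]
        freqs = np.array([3.0])
        scan = rhythm_scan(data, freqs=freqs, n_perm=200, seed=0)
        prev = bootstrap_prevalence(scan.actual_vs, scan.perm_vs, 0.05,
                                    n_boot=200, seed=1, freqs_hz=freqs)
        rng_b = np.random.default_rng(2)
        hits = 0
        n_refit = 60
        for b in range(n_refit):
            idx = rng_b.integers(0, P, size=P)
            res = rhythm_scan([data[i] for i in idx], freqs=freqs, n_perm=200,
                              seed=int(rng_b.integers(2**31)))
            hits += res.p[0] <= 0.05
        assert abs(prev.prevalence[0] - hits / n_refit) < 0.2

    def test_monotone_in_effect_amplitude(self, rng):
        prevs = []
        for amp in (0.0, 0.4, 1.0):
            data = []
            for _ in range(6):
                t = rng.uniform(0, 1.2, 80)
                data.append((t, amp * np.sin(2 * np.pi * 4.0 * t)
                             + rng.normal(0, 0.8, 80)))
            scan = rhythm_scan(data, freqs=np.array([4.0]), n_perm=200, seed=5)
            prev = bootstrap_prevalence(scan.actual_vs, scan.perm_vs, 0.05,
                                        n_boot=300, seed=6)
            prevs.append(prev.prevalence[0])
        assert prevs[0] <= prevs[1] + 0.1
        assert prevs[1] <= prevs[2] + 0.1
        assert prevs[2] > prevs[0]

    def test_shape_validation(self, rng):
        with pytest.raises(ValueError, match="surrogates"):
            bootstrap_prevalence(np.zeros((3, 2)), np.zeros((3, 3, 5)), 0.05)


class TestAveragePrevalence:
    def test_elementwise_mean(self, rng):
        res = [_null_scan(rng) for _ in range(3)]
        prevs = [bootstrap_prevalence(r.actual_vs, r.perm_vs, 0.1, n_boot=50,
                                      seed=i, freqs_hz=r.freqs_hz)
                 for i, r in enumerate(res)]
        avg = average_prevalence(prevs)
        oracle = (prevs[0].prevalence + prevs[1].prevalence
                  + prevs[2].prevalence) / 3
        np.testing.assert_allclose(avg.prevalence, oracle)
        same = average_prevalence([prevs[0]] * 3)
        np.testing.assert_allclose(same.prevalence, prevs[0].prevalence)

    def test_grid_mismatch_rejected(self, rng):
        a = _null_scan(rng)
        b = _null_scan(rng, freqs=np.array([2.0, 3.0, 5.0]))
        pa = bootstrap_prevalence(a.actual_vs, a.perm_vs, 0.1, n_boot=20,
                                  seed=0, freqs_hz=a.freqs_hz)
        pb = bootstrap_prevalence(b.actual_vs, b.perm_vs, 0.1, n_boot=20,
                                  seed=0, freqs_hz=b.freqs_hz)
        with pytest.raises(ValueError, match="grid"):
            average_prevalence([pa, pb])


class TestCoOccurrence:
    def test_identical_flags_r_one(self):
        f = np.array([0, 1, 1, 0, 1, 0, 1, 1], dtype=bool)
        res = cooccurrence_correlation(f, f)
        assert res.r == pytest.approx(1.0)

    def test_independent_flags_near_zero(self, rng):
        small = 0
        for _ in range(20):
            a = rng.random(5000) < 0.3
            b = rng.random(5000) < 0.4
            res = cooccurrence_correlation(a, b)
            small += abs(res.r) < 0.05
        assert small >= 19

    def test_constant_flag_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            res = cooccurrence_correlation(np.zeros(10, bool),
                                           np.array([0, 1] * 5, dtype=bool))
        assert not res.defined and np.isnan(res.r)

    def test_band_flags(self, rng):
        res = _null_scan(rng)
        prev = bootstrap_prevalence(res.actual_vs, res.perm_vs, 0.2, n_boot=50,
                                    seed=0, freqs_hz=res.freqs_hz)
        flags = band_flags(prev, (2.5, 4.5))
        np.testing.assert_array_equal(flags, prev.flags[:, 1:].any(axis=1))
        with pytest.raises(ValueError, match="band"):
            band_flags(prev, (10.0, 11.0))


def _eye_setup(n_trials=8, seed=0, eye_params=None):
    d = generate_design(DesignConfig(n_blocks=1, trials_per_block=n_trials,
                                     seed=seed))
    tr = simulate_eye_traces(d, eye_params or EyeParams(blink_rate_hz=0.0),
                             seed=seed + 1)
    return d, tr


class TestEyeMetrics:
    def test_constant_gaze_and_pupil(self):
        d, tr = _eye_setup(eye_params=EyeParams(
            jitter_sd_mean_deg=0.0, jitter_sd_sd_deg=0.0, drift_sd_deg_per_s=0.0,
            pupil_slow_sd=0.0, pupil_trial_sd=0.0, blink_rate_hz=0.0))
        with pytest.warns(UserWarning, match="constant pupil"):
            m = compute_eye_metrics(tr, d, min_valid_trials=1)
        assert m.per_trial["fixation_stability"].abs().max() < 1e-12
        assert m.per_trial["pupil_mean_z"].abs().max() < 1e-12

    def test_stability_matches_direct_computation(self):
        d, tr = _eye_setup(seed=3)
        m = compute_eye_metrics(tr, d, min_valid_trials=1)
        delays = d.df["delay_s"].to_numpy()
        for _, row in m.per_trial.iterrows():
            seg = tr[(tr["trial_id"] == row["trial_id"])
                     & (tr["t_s"] >= 0) & (tr["t_s"] <= delays[int(row["trial_id"])])]
            oracle = (seg["x_deg"].std(ddof=0) + seg["y_deg"].std(ddof=0)) / 2
            assert row["fixation_stability"] == pytest.approx(oracle, abs=1e-9)

    def test_single_invalid_sample_rejects_epoch(self):
        d, tr = _eye_setup(seed=5)
        victim = tr.index[tr["trial_id"] == 2][100]
        tr.loc[victim, "valid"] = False
        m = compute_eye_metrics(tr, d, min_valid_trials=1)
        row = m.per_trial[m.per_trial["trial_id"] == 2].iloc[0]
        assert not row["valid"] and np.isnan(row["pupil_mean_z"])

    def test_gaze_limit_flags_epoch(self):
        d, tr = _eye_setup(seed=6)
        victim = tr.index[tr["trial_id"] == 1][50]
        tr.loc[victim, "x_deg"] = 15.0
        m = compute_eye_metrics(tr, d, min_valid_trials=1)
        assert not m.per_trial.loc[m.per_trial["trial_id"] == 1, "valid"].iloc[0]

    def test_inclusion_threshold(self):
        d, tr = _eye_setup(n_trials=8)
        m = compute_eye_metrics(tr, d, min_valid_trials=600)
        assert not m.report["included"].any()
        m2 = compute_eye_metrics(tr, d, min_valid_trials=4)
        assert m2.report["included"].all()


class TestMedianSplit:
    def _metrics(self, values, pid="p0"):
        return pd.DataFrame({
            "trial_id": np.arange(len(values)), "participant_id": pid,
            "pupil_mean_z": values, "fixation_stability": values,
            "valid": True})

    def test_simple_split(self):
        m = self._metrics(np.arange(1, 11, dtype=float))
        low, high = median_split(m, "fixation_stability", min_per_half=1)
        assert sorted(low["fixation_stability"]) == [1, 2, 3, 4, 5]
        assert sorted(high["fixation_stability"]) == [6, 7, 8, 9, 10]
        # exact partition
        assert len(low) + len(high) == 10
        assert not set(low["trial_id"]) & set(high["trial_id"])

    def test_all_tied_goes_low_with_warning(self):
        m = self._metrics(np.ones(6))
        with pytest.warns(UserWarning, match="tied"):
            low, high = median_split(m, "pupil_mean_z", min_per_half=1)
        assert len(low) == 6 and len(high) == 0

    def test_trial_minimum_excludes_participant(self):
        m = self._metrics(np.arange(10, dtype=float))
        with pytest.warns(UserWarning, match="excluded"):
            low, high = median_split(m, "pupil_mean_z", min_per_half=400)
        assert low.empty and high.empty

    def test_two_population_recovery(self, rng):
        """Median split recovers trial populations with distinct jitter SDs."""
        sd = np.r_[np.full(200, 0.2), np.full(200, 0.6)]
        vals = np.abs(rng.normal(0, sd))  # stability-like metric
        m = self._metrics(vals)
        low, high = median_split(m, "fixation_stability", min_per_half=1)
        labels_low = (low["trial_id"] >= 200).mean()
        labels_high = (high["trial_id"] >= 200).mean()
        assert labels_high - labels_low > 0.4


def _prepared(table):
    return reference_delays(transform_rt(filter_outliers(table)))


class TestContrastConditions:
    def _cohort(self, rhythm_b, n=6, seed=0):
        a_tabs, b_tabs = [], []
        for i in range(n):
            cfg = dict(experiment="exp1", seed=seed + i)
            da = generate_design(DesignConfig(participant_id=f"p{i}", **cfg))
            db = generate_design(DesignConfig(participant_id=f"p{i}",
                                              seed=seed + 100 + i))
            obs_a = ObserverParams(d0=1.5, lapse_rate=0.0)
            obs_b = ObserverParams(d0=1.5, lapse_rate=0.0, rhythm=rhythm_b)
            a_tabs.append(_prepared(simulate_observer(da, obs_a, seed=i)))
            b_tabs.append(_prepared(simulate_observer(db, obs_b, seed=100 + i)))
        a = a_tabs[0].copy_with(pd.concat([t.df for t in a_tabs], ignore_index=True))
        b = b_tabs[0].copy_with(pd.concat([t.df for t in b_tabs], ignore_index=True))
        return a, b

    def test_self_contrast_is_zero(self, flat_cohort):
        t = flat_cohort[0]
        both = t.copy_with(pd.concat(
            [tab.df for tab in flat_cohort[:4]], ignore_index=True))
        res = contrast_conditions(both, both, metric="dprime")
        np.testing.assert_allclose(res.mean_diff, 0.0, atol=1e-14)
        np.testing.assert_allclose(res.vs_a, res.vs_b)
        assert not (res.p_bh <= 0.05).any()

    def test_injected_contrast_recovered(self):
        rhythm = [RhythmComponent("dprime", 4.0, 1.4)]
        a, b = self._cohort(rhythm_b=rhythm, n=8)
        res = contrast_conditions(a, b, metric="dprime")
        near = np.abs(res.freqs_hz - 4.0) <= 0.3
        sig = res.p_bh <= 0.05
        assert sig[near].any()
        assert res.mean_diff[near].min() < 0  # B exceeds A near 4 Hz

    def test_bh_adjustment_matches_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.02, 0.04, 0.8])
        adj = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.004, 0.04, 0.05333333, 0.8], atol=1e-8)


class TestDescriptiveReports:
    def test_dual_task_summary_shape(self):
        d = generate_design(DesignConfig(experiment="exp4", seed=0))
        t = simulate_observer(d, ObserverParams(d0=1.2), seed=1)
        rep = dual_task_summary(t)
        assert set(rep["metric"]) == {"dprime", "bias", "mean_rt_s"}

    def test_difficulty_drift_db(self):
        d = generate_design(DesignConfig(seed=0))
        df = d.df.copy()
        # stimulus halves over the session: -6.02 dB per track
        order = df.sort_values(["block", "trial_index"]).index
        ramp = np.linspace(1.0, 0.5, len(df))
        df.loc[order, "stim_param"] = ramp
        t = d.copy_with(df)
        rep = difficulty_drift(t)
        assert rep["drift_db"].iloc[0] == pytest.approx(20 * np.log10(0.5), abs=0.25)
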