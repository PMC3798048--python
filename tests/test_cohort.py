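"""Synthetic cohort generator: boxcar, networks, neuronal simulation,
motion, behaviour scores and full-cohort contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from causalbold import (
    CohortConfig,
    generate_boxcar,
    generate_cohort,
    generate_ground_truth_networks,
    generate_motion_trace,
    generate_scalar_features,
    simulate_neuronal_subject,
)
from causalbold.cohort import (
    draw_subject_weights,
    simulate_neuronal_series,
    spectral_radius,
)
from causalbold.qc import framewise_displacement


class TestBoxcar:
    def test_empty_event_list_gives_all_zero(self):
        u = generate_boxcar([], total_duration=30, dt=1.0)
        assert len(u.values) == 30
        assert not u.values.any()

    def test_eleven_second_vignette_covers_samples_5_to_15(self):
        u = generate_boxcar([(5, 11)], total_duration=30, dt=1.0)
        assert np.array_equal(np.flatnonzero(u.values), np.arange(5, 16))

    def test_sample_count_matches_event_durations_at_half_second_grid(self):
        u = generate_boxcar([(2, 3), (10, 2)], total_duration=20, dt=0.5)
        assert u.values.sum() == (3 + 2) / 0.5

    def test_overlapping_events_are_merged(self):
        u = generate_boxcar([(2, 4), (4, 4)], total_duration=20, dt=1.0)
        assert np.array_equal(np.flatnonzero(u.values), np.arange(2, 8))

    def test_event_outside_run_raises(self):
        with pytest.raises(ValueError):
            generate_boxcar([(25, 10)], total_duration=30, dt=1.0)

    @given(
        onset=st.integers(0, 20),
        duration=st.integers(1, 10),
        dt=st.sampled_from([0.25, 0.5, 1.0]),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_active_sample_count_equals_duration_over_dt(self, onset, duration, dt):
        u = generate_boxcar([(onset, duration)], total_duration=40, dt=dt)
        assert u.values.sum() == pytest.approx(duration / dt)


class TestGroundTruth:
    def test_zero_effect_gives_identical_group_matrices(self):
        truth = generate_ground_truth_networks(CohortConfig(effect_size=0.0, seed=3))
        assert np.array_equal(
            truth.weights_by_group["TD"], truth.weights_by_group["ASD"]
        )

    def test_default_config_designates_19_distinct_directed_paths(self):
        truth = generate_ground_truth_networks(CohortConfig(seed=5))
        assert len(truth.discriminative_paths) == 19
        assert len(set(truth.discriminative_paths)) == 19
        assert all(src != snk for src, snk in truth.discriminative_paths)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_both_group_processes_are_stationary(self, seed):
        truth = generate_ground_truth_networks(CohortConfig(seed=seed))
        for w in truth.weights_by_group.values():
            assert spectral_radius(w) < 1.0

    def test_group_difference_is_effect_size_times_spread_on_designated_paths(self):
        config = CohortConfig(seed=5, effect_size=1.5)
        truth = generate_ground_truth_networks(config)
        diff = truth.weights_by_group["TD"] - truth.weights_by_group["ASD"]
        nz = diff[np.abs(diff) > 1e-15]
        assert len(nz) == 19
        assert np.allclose(nz, config.effect_size * config.path_weight_sd)
        for source, sink in truth.discriminative_paths:
            assert (
                truth.weights_by_group["ASD"][sink, source]
                < truth.weights_by_group["TD"][sink, source]
            )


class TestNeuronalSimulation:
    def test_decoupled_zero_matrix_yields_white_noise(self, small_config, rng):
        from causalbold.cohort import ExogenousInput

        u = ExogenousInput(values=np.zeros(2000), dt=0.1)
        h = simulate_neuronal_series(np.zeros((2, 2)), u, small_config, rng)
        # no lag-1 autocorrelation and no cross-correlation beyond noise
        for row in h:
            r = np.corrcoef(row[:-1], row[1:])[0, 1]
            assert abs(r) < 0.1
        assert abs(np.corrcoef(h[0], h[1])[0, 1]) < 0.1

    def test_lag1_coefficient_recovered_by_least_squares(self, small_config):
        from causalbold.cohort import ExogenousInput

        w = np.array([[0.5, 0.0], [0.5, 0.4]])  # a21 = 0.5 in lag-1 terms
        u = ExogenousInput(values=np.zeros(20000), dt=0.1)
        h = simulate_neuronal_series(w, u, small_config, np.random.default_rng(0))
        # independent normal-equations oracle on the recursion
        x = h[:, :-1].T
        y = h[1, 1:]
        coef = np.linalg.solve(x.T @ x, x.T @ y)
        assert coef[0] == pytest.approx(0.5, abs=0.05)

    def test_same_seed_reproduces_series(self, small_config):
        truth = generate_ground_truth_networks(small_config)
        from causalbold.cohort import ExogenousInput

        u = ExogenousInput(values=np.zeros(1200), dt=0.1)
        h1 = simulate_neuronal_subject(truth, "TD", u, small_config, seed=42)
        h2 = simulate_neuronal_subject(truth, "TD", u, small_config, seed=42)
        assert np.array_equal(h1, h2)

    def test_no_divergence_over_ten_times_run_length(self, small_config):
        from causalbold.cohort import ExogenousInput

        truth = generate_ground_truth_networks(small_config)
        u = ExogenousInput(values=np.zeros(12000), dt=0.1)
        h = simulate_neuronal_subject(truth, "ASD", u, small_config, seed=0)
        assert np.isfinite(h).all()
        assert np.abs(h).max() < 50


class TestMotionTrace:
    def test_zero_magnitude_gives_zero_trace_and_zero_fd(self):
        trace = generate_motion_trace(100, magnitude=0.0, seed=0)
        assert not trace.data.any()
        assert not framewise_displacement(trace).values.any()

    def test_default_magnitude_stays_under_screening_threshold(self):
        # 0.2 mm excursion scale must stay below the 0.5 mm screen in
        # at least 95% of seeds
        ok = sum(
            generate_motion_trace(460, magnitude=0.2, seed=s).max_excursion() < 0.5
            for s in range(100)
        )
        assert ok >= 95

    def test_same_seed_reproduces_trace(self):
        t1 = generate_motion_trace(50, 0.3, seed=9)
        t2 = generate_motion_trace(50, 0.3, seed=9)
        assert np.array_equal(t1.data, t2.data)


class TestScalarFeatures:
    def test_zero_coupling_gives_scores_independent_of_weights(self):
        config = CohortConfig(seed=2, behaviour_coupling=0.0)
        truth = generate_ground_truth_networks(config)
        rng = np.random.default_rng(0)
        aqs, wbars = [], []
        for _ in range(60):
            w = draw_subject_weights(truth, "TD", config, rng)
            aq, _, _ = generate_scalar_features(w, truth, config, "TD", rng)
            aqs.append(aq)
            wbars.append(
                np.mean([w[snk, src] for src, snk in truth.discriminative_paths])
            )
        rho, p = stats.spearmanr(aqs, wbars)
        assert p > 0.01  # no detectable coupling

    def test_strong_coupling_gives_significant_negative_aq_correlation(self):
        config = CohortConfig(seed=2, behaviour_coupling=0.9)
        truth = generate_ground_truth_networks(config)
        rng = np.random.default_rng(1)
        aqs, wbars = [], []
        for group in ("ASD", "TD"):
            for _ in range(15):
                w = draw_subject_weights(truth, group, config, rng)
                aq, _, _ = generate_scalar_features(w, truth, config, group, rng)
                aqs.append(aq)
                wbars.append(
                    np.mean([w[snk, src] for src, snk in truth.discriminative_paths])
                )
        rho, p = stats.spearmanr(aqs, wbars)
        assert rho < 0
        assert p < 0.05

    def test_scores_stay_within_configured_ranges(self, small_cohort):
        subjects, _ = small_cohort
        for s in subjects:
            assert 4.0 <= s.aq <= 38.0
            assert 15.0 <= s.rme <= 24.0
            assert 0.0 <= s.fa <= 1.0


class TestCohort:
    def test_default_cohort_has_30_subjects_with_18x460_series(self, default_cohort):
        subjects, _ = default_cohort
        assert len(subjects) == 30
        assert sum(s.group == "ASD" for s in subjects) == 15
        for s in subjects[:3]:
            assert s.roi_series.shape == (18, 460)
            assert s.neuronal_truth.shape == (18, 4600)
            assert s.roi_labels[0] == "SMA" and s.roi_labels[-1] == "RTPJ"

    def test_cohort_is_reproducible_from_seed(self, small_config):
        a, _ = generate_cohort(small_config)
        b, _ = generate_cohort(small_config)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.roi_series, sb.roi_series)
            assert np.array_equal(sa.motion.data, sb.motion.data)
            assert (sa.aq, sa.rme, sa.fa) == (sb.aq, sb.rme, sb.fa)

    def test_bold_snr_is_near_target(self, default_cohort):
        # variance-ratio SNR: total BOLD variance over noise variance ~ 2.
        # Reconstruct the noise-free BOLD from the stored latent truth and
        # per-subject hemodynamic parameters.
        from causalbold.hemodynamics import balloon_forward

        subjects, _ = default_cohort
        config = CohortConfig(seed=11)
        s = subjects[0]
        clean = balloon_forward(
            s.neuronal_truth, s.hemodynamic_params, dt=config.fine_dt, tr=config.tr
        )
        noise_var = (s.roi_series - clean).var(axis=1)
        snr = s.roi_series.var(axis=1) / noise_var
        assert np.median(snr) == pytest.approx(config.snr_target, rel=0.2)

    def test_discriminative_true_weights_significant_at_design_effect(self):
        subjects, truth = generate_cohort(CohortConfig(seed=3, effect_size=1.5))
        paths = truth.discriminative_paths
        alpha = 0.05 / len(paths)
        n_sig = 0
        for src, snk in paths:
            asd = [s.true_weights[snk, src] for s in subjects if s.group == "ASD"]
            td = [s.true_weights[snk, src] for s in subjects if s.group == "TD"]
            t, p = stats.ttest_ind(td, asd)
            if p < alpha and t > 0:
                n_sig += 1
        # effect size 1.5 per path gives ~96% power at Bonferroni level
        assert n_sig >= len(paths) // 2

    def test_null_cohort_true_weights_not_significant_after_bonferroni(self):
        subjects, truth = generate_cohort(
            CohortConfig(seed=4, effect_size=0.0, behaviour_coupling=0.0)
        )
        k = truth.n_rois
        alpha = 0.05 / (k * (k - 1))
        for src in range(k):
            for snk in range(k):
                if src == snk:
                    continue
                asd = [s.true_weights[snk, src] for s in subjects if s.group == "ASD"]
                td = [s.true_weights[snk, src] for s in subjects if s.group == "TD"]
                _, p = stats.ttest_ind(td, asd)
                assert p >= alpha

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_rois=0)
        with pytest.raises(ValueError):
            CohortConfig(effect_size=-1)
        with pytest.raises(ValueError):
            CohortConfig(n_rois=3, n_discriminative_paths=7)
        with pytest.raises(ValueError):
            CohortConfig(snr_target=0.5)
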