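"""Synthetic-cohort generator: determinism, bookkeeping and moment checks."""

import numpy as np
import pandas as pd
import pytest

from macula_hbm.cleaning import apply_cleaning
from macula_hbm.grid_io import analysis_labels, parse_label, validate_long_table
from macula_hbm.params import GlobalHyperparams, reference_hyperparams, transform_array
from macula_hbm.simulate import (
    ArtifactConfig,
    CohortDesign,
    SpatialEffectModel,
    build_pca_fixture,
    draw_superpixel_params,
    grid_correlation,
    inject_artifacts,
    simulate_cohort,
)

from conftest import make_params, small_design, small_effect_model, small_labels


class TestGridCorrelation:
    def test_unit_diagonal_symmetric_psd(self):
        for r in (0.8, 0.5, 0.35, 0.3):
            C = grid_correlation(r)
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-8)
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() >= -1e-8

    def test_adjacent_decay_and_meridian_attenuation(self):
        labels = analysis_labels()
        C = grid_correlation(0.8)
        idx = {lab: i for i, lab in enumerate(labels)}
        # same-side adjacent pair ~ r; straddling temporal pair ~ r/2
        assert C[idx["3.2"], idx["4.2"]] == pytest.approx(0.8, abs=0.01)
        assert C[idx["4.2"], idx["5.2"]] == pytest.approx(0.4, abs=0.01)
        # nasal-side pairs are not attenuated
        assert C[idx["4.6"], idx["5.6"]] == pytest.approx(0.8, abs=0.01)

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError):
            grid_correlation(1.5)


class TestDrawSuperpixelParams:
    def test_zero_variance_limit_collapses_to_means(self):
        hyp0 = reference_hyperparams()
        hyp = GlobalHyperparams(
            mu_c=hyp0.mu_c,
            Sigma_c=1e-18 * np.eye(3),
            mu_ind=hyp0.mu_ind,
            tau_ind=1e-9 * np.ones(4),
        )
        params = draw_superpixel_params(hyp, K=5, seed=0)
        ref = np.array([p.to_interpretable() for p in params])
        assert np.ptp(ref, axis=0).max() < 1e-6

    def test_across_superpixel_spread_matches_prior(self):
        # alpha0 is untransformed: its across-superpixel SD must equal the
        # prior SD (13.29) on average, within 3 standard errors over 50 seeds
        hyp = reference_hyperparams()
        sds = []
        for seed in range(50):
            params = draw_superpixel_params(hyp, K=49, seed=seed)
            sds.append(np.std([p.alpha0 for p in params], ddof=1))
        se = 13.29 / np.sqrt(2 * 48) / np.sqrt(50)
        assert np.mean(sds) == pytest.approx(13.29, abs=3 * se + 0.05)

    def test_seeded_determinism(self):
        hyp = reference_hyperparams()
        a = draw_superpixel_params(hyp, 10, seed=4)
        b = draw_superpixel_params(hyp, 10, seed=4)
        c = draw_superpixel_params(hyp, 10, seed=5)
        assert [p.alpha0 for p in a] == [p.alpha0 for p in b]
        assert [p.alpha0 for p in a] != [p.alpha0 for p in c]


class TestSimulateCohort:
    def test_record_count_is_visits_times_superpixels(self):
        model = small_effect_model()
        table, truth = simulate_cohort(model, small_design(6), seed=1)
        expected = sum(len(t) for t in truth.visit_times) * len(model.labels)
        assert len(table) == expected

    def test_deterministic_under_seed(self):
        model = small_effect_model()
        t1, _ = simulate_cohort(model, small_design(5), seed=9)
        t2, _ = simulate_cohort(model, small_design(5), seed=9)
        t3, _ = simulate_cohort(model, small_design(5), seed=10)
        pd.testing.assert_frame_equal(t1, t2)
        assert not t1["thickness_um"].equals(t3["thickness_um"])

    def test_degenerate_limit_recovers_population_line(self):
        labels = small_labels(2, 2)
        model = SpatialEffectModel(
            params=make_params(4, ri_sd=1e-4, rs_sd=1e-4, sigma_m=1e-6, sigma_s=1e-9),
            C_int=grid_correlation(0.8, labels=labels),
            C_slope=grid_correlation(0.5, labels=labels),
            C_logsd=grid_correlation(0.35, labels=labels),
            C_res=grid_correlation(0.3, labels=labels),
            labels=labels,
        )
        table, _ = simulate_cohort(model, small_design(4), seed=2)
        p = model.params[0]
        expected = p.alpha0 + p.alpha1 * table["time_years"]
        np.testing.assert_allclose(table["thickness_um"], expected, atol=1e-3)

    def test_law_of_large_numbers_intercept_variance(self):
        labels = ["4.4"]
        model = SpatialEffectModel(
            params=make_params(1, ri_sd=15.0),  # D00 = 225
            C_int=np.ones((1, 1)),
            C_slope=np.ones((1, 1)),
            C_logsd=np.ones((1, 1)),
            C_res=np.ones((1, 1)),
            labels=labels,
        )
        _, truth = simulate_cohort(model, CohortDesign(n_subjects=10_000), seed=3)
        assert truth.beta0.var() == pytest.approx(225.0, rel=0.02)

    def test_cross_superpixel_latent_correlations(self):
        # empirical correlations of latent draws converge to the target
        labels = ["4.4", "4.5"]
        r = 0.8
        model = SpatialEffectModel(
            params=make_params(2),
            C_int=np.array([[1, r], [r, 1]]),
            C_slope=np.eye(2),
            C_logsd=np.eye(2),
            C_res=np.eye(2),
            labels=labels,
        )
        _, truth = simulate_cohort(model, CohortDesign(n_subjects=10_000), seed=5)
        got = np.corrcoef(truth.beta0[:, 0], truth.beta0[:, 1])[0, 1]
        se = (1 - r**2) / np.sqrt(10_000)
        assert got == pytest.approx(r, abs=3 * se)

    def test_visit_schedule_respects_design_limits(self):
        model = small_effect_model()
        _, truth = simulate_cohort(model, small_design(40), seed=6)
        for times in truth.visit_times:
            assert 4 <= len(times) <= 10
            assert times[0] == 0.0
            assert times[-1] <= 4.2
            assert times[-1] >= 2.0
            assert np.diff(times).min() > 0.2

    def test_generated_table_valid_and_clean(self):
        # low-noise cohorts sail through cleaning untouched
        model = small_effect_model(low_noise=True)
        table, _ = simulate_cohort(model, small_design(10), seed=7)
        validate_long_table(table)
        _, report = apply_cleaning(table)
        assert report.n_removed == 0

    def test_non_psd_correlation_rejected(self):
        labels = ["4.4", "4.5"]
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError, match="C_int"):
            SpatialEffectModel(
                params=make_params(2),
                C_int=bad,
                C_slope=np.eye(2),
                C_logsd=np.eye(2),
                C_res=np.eye(2),
                labels=labels,
            )


class TestInjectArtifacts:
    def test_zero_count_bookkeeping(self):
        model = small_effect_model(low_noise=True)
        table, _ = simulate_cohort(model, small_design(8), seed=1)
        corrupted, truth = inject_artifacts(
            table, ArtifactConfig(n_zeros=7, n_single_spikes=0, n_double_spike_profiles=0), seed=2
        )
        assert (corrupted["thickness_um"] == 0).sum() == 7
        assert len(truth.zeros) == 7

    def test_empty_config_identity(self):
        model = small_effect_model(low_noise=True)
        table, _ = simulate_cohort(model, small_design(4), seed=1)
        out, truth = inject_artifacts(
            table, ArtifactConfig(n_zeros=0, n_single_spikes=0, n_double_spike_profiles=0), seed=3
        )
        pd.testing.assert_frame_equal(out, table)
        assert len(truth.single_spikes) == 0

    def test_excessive_counts_rejected(self):
        model = small_effect_model(low_noise=True)
        table, _ = simulate_cohort(model, small_design(3), seed=1)
        with pytest.raises(ValueError):
            inject_artifacts(table, ArtifactConfig(n_double_spike_profiles=10_000), seed=1)


class TestPCAFixture:
    def test_single_fraction_is_rank_one(self):
        fx = build_pca_fixture([1.0], K=49, n_draws=50, seed=1)
        # all draws proportional to the global (uniform) eigenvector
        v1 = fx.eigenvectors[:, 0]
        proj = fx.samples - np.outer(fx.samples @ v1, v1)
        assert np.abs(proj).max() < 1e-8
        cov = np.cov(fx.samples, rowvar=False)
        w = np.linalg.eigvalsh(cov)
        assert w[-1] / w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_population_covariance_reconstructs_fractions(self):
        fr = [0.516, 0.227, 0.096]
        fx = build_pca_fixture(fr, K=49, n_draws=10, seed=2)
        w = np.sort(np.linalg.eigvalsh(fx.covariance))[::-1]
        np.testing.assert_allclose(w[:3] / w.sum(), fr, atol=1e-10)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            build_pca_fixture([0.8, 0.5], K=49, n_draws=10, seed=1)
        with pytest.raises(ValueError):
            build_pca_fixture([-0.1], K=49, n_draws=10, seed=1)

    def test_structured_eigenvectors_orthonormal(self):
        fx = build_pca_fixture([0.5, 0.3], K=49, n_draws=5, seed=3)
        V = fx.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(49), atol=1e-10)
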