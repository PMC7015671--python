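"""Quantitative assay fitters: recovery, degeneracies, estimator API."""

import numpy as np
import pytest

from mtrecon.assays import (
    CensoredExponentialFitter,
    GaussianMixture1D,
    MichaelisMentenEstimator,
    OverlapForceRegressor,
    fit_force_per_overlap,
    fit_gaussian_mixture,
    fit_michaelis_menten,
    fit_runlength,
    roi_intensity_ratio,
)
from mtrecon.simulate import gen_mm_dataset, gen_motility_dataset, gen_roi_image


class TestMichaelisMenten:
    def test_noiseless_recovery_to_four_significant_figures(self):
        d = gen_mm_dataset(7.1, 680.0, np.geomspace(68.0, 13600.0, 8), 0.0)
        fit = fit_michaelis_menten(d.mt_conc_nM, d.rate_per_s)
        assert fit.kcat_ == pytest.approx(7.1, rel=1e-4)
        assert fit.km_ == pytest.approx(680.0, rel=1e-4)
        assert fit.converged_

    def test_two_point_algebraic_solution(self):
        # v(Km) = kcat/2 and a near-saturating point pin both parameters
        s = np.array([680.0, 680000.0, 68.0])
        v = 7.1 * s / (680.0 + s)
        fit = fit_michaelis_menten(s, v)
        assert fit.kcat_ == pytest.approx(7.1, rel=1e-6)
        assert fit.km_ == pytest.approx(680.0, rel=1e-5)

    def test_saturated_only_data_flags_km_unidentifiable(self):
        fit = MichaelisMentenEstimator().fit([1e5, 2e5, 4e5], [7.1, 7.1, 7.1])
        assert not fit.km_identifiable_
        assert np.isnan(fit.km_)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([100.0, 700.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_michaelis_menten([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])

    def test_sklearn_estimator_api(self):
        est = MichaelisMentenEstimator()
        assert est.get_params()["max_nfev"] == 10000
        est.set_params(max_nfev=500)
        d = gen_mm_dataset(5.0, 100.0, np.geomspace(10, 2000, 6), 0.0)
        est.fit(d.mt_conc_nM, d.rate_per_s)
        assert est.predict([100.0])[0] == pytest.approx(2.5, rel=1e-6)

    def test_order_invariance(self):
        d = gen_mm_dataset(7.1, 680.0, np.geomspace(68, 13600, 8), 0.03, seed=2)
        a = fit_michaelis_menten(d.mt_conc_nM, d.rate_per_s)
        perm = np.random.default_rng(0).permutation(8)
        b = fit_michaelis_menten(d.mt_conc_nM[perm], d.rate_per_s[perm])
        assert a.kcat_ == pytest.approx(b.kcat_, abs=1e-12)
        assert a.km_ == pytest.approx(b.km_, abs=1e-9)


class TestGaussianMixture:
    def test_bic_prefers_single_component(self):
        """On unimodal samples (n=400) k=1 wins in >=95% of 100 seeds."""
        wins = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(24.0, 4.0, size=400)
            fit = GaussianMixture1D().fit(x)
            wins += fit.k_ == 1
        assert wins >= 95

    def test_bimodal_weight_recovery(self):
        d = gen_motility_dataset([(24.0, 5.0, 0.6), (41.0, 4.0, 0.4)], n=149, seed=3)
        fit = fit_gaussian_mixture(d.velocities_nm_s, k=2)
        assert fit.weights_[1] == pytest.approx(0.40, abs=0.08)
        assert fit.means_[0] == pytest.approx(24.0, abs=2.5)
        assert fit.means_[1] == pytest.approx(41.0, abs=2.5)

    def test_identical_components_collapse_to_k1(self):
        x = np.random.default_rng(0).normal(30.0, 3.0, size=300)
        fit = GaussianMixture1D(n_components=None).fit(x)
        assert fit.k_ == 1

    def test_likelihood_never_decreases(self):
        d = gen_motility_dataset([(24.0, 5.0, 0.6), (41.0, 4.0, 0.4)], n=200, seed=5)
        fit = fit_gaussian_mixture(d.velocities_nm_s, k=2)
        assert np.all(np.diff(fit.ll_trace_) > -1e-8)

    def test_matches_sklearn_mixture_oracle(self):
        """Independent cross-check against sklearn's EM on the same sample."""
        from sklearn.mixture import GaussianMixture

        d = gen_motility_dataset([(24.0, 5.0, 0.6), (41.0, 4.0, 0.4)], n=400, seed=6)
        x = d.velocities_nm_s
        ours = fit_gaussian_mixture(x, k=2)
        ref = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        assert ours.means_ == pytest.approx(ref.means_.ravel()[order], abs=0.5)
        assert ours.weights_ == pytest.approx(ref.weights_[order], abs=0.03)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_mixture(np.arange(15.0), k=2)


class TestRunLength:
    def test_uncensored_mean_is_sample_mean(self):
        x = np.array([2.0, 5.0, 9.0, 1.5])
        fit = fit_runlength(x, np.zeros(4, dtype=bool))
        assert fit.mean_um_ == pytest.approx(x.mean())
        assert fit.half_length_um_ == pytest.approx(x.mean() * np.log(2))

    def test_censored_mle_beats_naive_mean(self):
        """At ~30% censoring the censored MLE has strictly smaller bias than
        the naive uncensored mean, across 100 seeded replicates."""
        mle_err, naive_err = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            raw = rng.exponential(8.0, size=200)
            limit = np.quantile(raw, 0.7)
            cens = raw >= limit
            obs = np.where(cens, limit, raw)
            fit = CensoredExponentialFitter().fit(obs, cens)
            mle_err.append(fit.mean_um_ - 8.0)
            naive_err.append(obs[~cens].mean() - 8.0)
        assert abs(np.mean(mle_err)) < abs(np.mean(naive_err))
        assert abs(np.mean(mle_err)) < 0.4  # near-unbiased

    def test_recovery_under_25um_censoring(self):
        d = gen_motility_dataset([(36.0, 5.0, 1.0)], n=200, runlen_mean_um=8.0,
                                 censor_limit_um=25.0, seed=123)
        fit = fit_runlength(d.run_lengths_um, d.censored, 25.0)
        assert fit.mean_um_ == pytest.approx(8.0, rel=0.10)

    def test_all_censored_is_error(self):
        with pytest.raises(ValueError, match="censored"):
            fit_runlength(np.full(5, 25.0), np.ones(5, dtype=bool))

    def test_matches_lifelines_oracle(self):
        from lifelines import ExponentialFitter

        rng = np.random.default_rng(9)
        raw = rng.exponential(8.0, size=300)
        cens = raw >= 20.0
        obs = np.where(cens, 20.0, raw)
        ours = fit_runlength(obs, cens)
        ref = ExponentialFitter().fit(obs, event_observed=~cens)
        assert ours.mean_um_ == pytest.approx(ref.lambda_, rel=1e-6)


class TestForcePerOverlap:
    def test_exact_line_recovered_to_machine_precision(self):
        x = np.linspace(1.0, 8.0, 20)
        fit = fit_force_per_overlap(x, 4.0 * x + 1.0)
        assert fit.slope_ == pytest.approx(4.0, abs=1e-12)
        assert fit.intercept_ == pytest.approx(1.0, abs=1e-10)

    def test_through_origin_constraint(self):
        x = np.linspace(1.0, 8.0, 20)
        fit = fit_force_per_overlap(x, 4.0 * x, through_origin=True)
        assert fit.slope_ == pytest.approx(4.0, abs=1e-12)
        assert fit.intercept_ == 0.0

    def test_pure_noise_ci_contains_zero(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(1.0, 8.0, 30)
            y = rng.normal(0.0, 2.0, 30)
            fit = OverlapForceRegressor(random_state=seed, n_boot=400).fit(x, y)
            hits += fit.ci_low_ <= 0.0 <= fit.ci_high_
        assert hits >= 18  # >= 90% coverage

    def test_ci_brackets_slope_and_is_seed_stable(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1.0, 8.0, 30)
        y = 4.0 * x + rng.normal(0.0, 3.0, 30)
        a = fit_force_per_overlap(x, y, seed=11)
        b = fit_force_per_overlap(x, y, seed=11)
        assert a.ci_low_ <= a.slope_ <= a.ci_high_
        assert (a.ci_low_, a.ci_high_) == (b.ci_low_, b.ci_high_)

    def test_degenerate_overlaps_rejected(self):
        with pytest.raises(ValueError):
            fit_force_per_overlap([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestRoiRatio:
    def test_uniform_image_ratio_one(self):
        img = gen_roi_image(50.0, 50.0, 50.0 - 30.0, noise_sd=0.0)
        r = roi_intensity_ratio(img.pixels, img.spindle_mask, img.cell_mask,
                                img.background_rois)
        assert r.ratio == pytest.approx(1.0)

    def test_recovery_with_noise(self):
        b, c = 20.0, 120.0
        s = 2.39 * (c - b) + b
        img = gen_roi_image(s, c, b, noise_sd=0.02 * c, seed=6)
        r = roi_intensity_ratio(img.pixels, img.spindle_mask, img.cell_mask,
                                img.background_rois)
        # noise-propagated SE on the ratio is well below 0.03 at this size
        assert r.ratio == pytest.approx(2.39, abs=0.05)

    def test_empty_spindle_is_error(self):
        img = gen_roi_image(100.0, 80.0, 10.0)
        with pytest.raises(ValueError, match="empty"):
            roi_intensity_ratio(img.pixels, np.zeros_like(img.spindle_mask),
                                img.cell_mask, img.background_rois)

    def test_cyto_below_background_flags_undefined(self):
        img = gen_roi_image(100.0, 5.0, 10.0, noise_sd=0.0)
        r = roi_intensity_ratio(img.pixels, img.spindle_mask, img.cell_mask,
                                img.background_rois)
        assert r.undefined and np.isnan(r.ratio)
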