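import numpy as np
import pytest

from agemix.densities import NormalParams, SNPParams, sample_density
from agemix.errors import DegenerateDataError, DegenerateFitError, ParameterError
from agemix.fitting import (
    FitConfig,
    MixtureParams,
    _em_from_responsibilities,
    fit_mixture_normal_em,
    fit_mixture_snp,
    fit_single_normal,
    fit_single_snp,
)
from conftest import truncated_mixture_sample

FAST = FitConfig(seed=1, n_random_starts=4)


class TestSingleNormal:
    def test_two_point_mle(self):
        r = fit_single_normal(np.array([40.0, 50.0]))
        assert r.params.mu == pytest.approx(45.0)
        assert r.params.sigma == pytest.approx(5.0)
        assert r.k == 2

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateDataError):
            fit_single_normal(np.array([45.0, 45.0, 45.0]))

    def test_sampling_oracle(self):
        x = np.random.default_rng(10).normal(50, 10, 10_000)
        r = fit_single_normal(x)
        assert 49.5 < r.params.mu < 50.5
        assert 9.5 < r.params.sigma < 10.5

    def test_loglik_is_exact_normal_loglik(self):
        x = np.array([42.0, 48.0, 55.0, 61.0])
        r = fit_single_normal(x)
        mu, sd = x.mean(), x.std()
        oracle = float(
            np.sum(
                -0.5 * ((x - mu) / sd) ** 2
                - np.log(sd)
                - 0.5 * np.log(2 * np.pi)
            )
        )
        assert r.loglik == pytest.approx(oracle, abs=1e-12)


class TestSingleSnp:
    def test_degree_zero_reduces_to_normal(self):
        x = np.random.default_rng(11).normal(50, 10, 500)
        rn = fit_single_normal(x)
        rs = fit_single_snp(x, 0, FAST)
        assert rs.loglik == pytest.approx(rn.loglik, abs=1e-9)
        assert rs.params.mu == pytest.approx(rn.params.mu, abs=1e-9)

    def test_normal_data_keeps_coeffs_small(self):
        x = np.random.default_rng(3).normal(50, 10, 5000)
        rs = fit_single_snp(x, 2, FAST)
        rn = fit_single_normal(x)
        assert rs.loglik - rn.loglik < 3.0
        assert all(abs(c) < 0.3 for c in rs.params.coeffs[1:])

    def test_parameter_recovery(self):
        truth = SNPParams(50, 10, (1.0, 0.8))
        x = sample_density(truth, 10_000, seed=42)
        r = fit_single_snp(x, 1, FAST)
        assert r.params.coeffs[1] == pytest.approx(0.8, abs=0.1)

    def test_nested_above_normal(self, bimodal_ages):
        rn = fit_single_normal(bimodal_ages)
        rs = fit_single_snp(bimodal_ages, 2, FAST)
        assert rs.loglik >= rn.loglik - 1e-6
        assert rs.k == 4

    def test_degree_validation(self):
        with pytest.raises(ParameterError):
            fit_single_snp(np.arange(20.0), 4, FAST)


class TestMixtureNormalEm:
    def test_parameter_recovery(self, bimodal_ages):
        r = fit_mixture_normal_em(bimodal_ages, FAST)
        assert 0.65 <= r.params.pi_early <= 0.75
        assert r.params.comp_early.mu == pytest.approx(45, abs=1.5)
        assert r.params.comp_late.mu == pytest.approx(65, abs=1.5)
        assert r.k == 5

    def test_no_overfit_on_unimodal(self, unimodal_ages):
        rm = fit_mixture_normal_em(unimodal_ages, FAST)
        rn = fit_single_normal(unimodal_ages)
        assert rm.loglik - rn.loglik < 5.0

    def test_deterministic(self, bimodal_ages):
        a = fit_mixture_normal_em(bimodal_ages, FAST)
        b = fit_mixture_normal_em(bimodal_ages, FAST)
        assert a == b

    def test_monotone_loglik(self, bimodal_ages):
        trace = []
        n = bimodal_ages.size
        cut = np.percentile(bimodal_ages, 50)
        hard = (bimodal_ages <= cut).astype(float)
        gamma = np.column_stack([0.9 * hard + 0.05, 0.95 - 0.9 * hard])
        _em_from_responsibilities(bimodal_ages, gamma, FAST, trace=trace)
        diffs = np.diff(np.asarray(trace))
        assert trace, "EM recorded no iterations"
        assert np.all(diffs >= -1e-10)

    def test_component_ordering(self, bimodal_ages):
        r = fit_mixture_normal_em(bimodal_ages, FAST)
        assert r.params.comp_early.mode < r.params.comp_late.mode

    def test_all_starts_collapse(self):
        # nonzero variance, but any weighted component SD sits far below
        # the 0.5-year floor, so every start collapses
        ages = np.array([50.0] * 11 + [50.4])
        with pytest.raises(DegenerateFitError):
            fit_mixture_normal_em(ages, FAST)

    def test_truncated_recovery_mean(self):
        # [20,74]-truncated mixture, weight 0.72: the replicate-mean of
        # the truncated-ML weight lands within +-0.03 of truth
        cfg = FitConfig(seed=1, n_random_starts=4, truncation=(20, 74))
        pis = []
        for rep in range(20):
            ages, _ = truncated_mixture_sample(2860, 0.72, seed=500 + rep)
            pis.append(fit_mixture_normal_em(ages, cfg).params.pi_early)
        assert abs(np.mean(pis) - 0.72) < 0.03


class TestMixtureSnp:
    def test_degree_zero_matches_em(self, bimodal_ages):
        cfg = FitConfig(seed=1, n_random_starts=4, tol=1e-11)
        em = fit_mixture_normal_em(bimodal_ages, cfg)
        ms = fit_mixture_snp(bimodal_ages, 0, cfg)
        assert ms.loglik == pytest.approx(em.loglik, abs=1e-4)

    def test_parameter_recovery(self):
        truth = MixtureParams(
            SNPParams(45, 8, (1.0, 0.3)),
            SNPParams(65, 6, (1.0, -0.2)),
            0.7,
        )
        x = np.concatenate(
            [
                sample_density(truth.comp_early, 3500, seed=11),
                sample_density(truth.comp_late, 1500, seed=12),
            ]
        )
        r = fit_mixture_snp(x, 1, FAST)
        assert r.params.pi_early == pytest.approx(0.7, abs=0.05)

    def test_small_sample_never_crashes(self):
        x = np.random.default_rng(6).normal(50, 8, 50)
        r = fit_mixture_snp(x, 1, FAST)
        assert isinstance(r.converged, bool)

    def test_k_count(self, bimodal_ages):
        r = fit_mixture_snp(bimodal_ages, 2, FAST)
        assert r.k == 2 * (2 + 2) + 1


class TestInvariants:
    def test_nesting_chain(self, bimodal_ages):
        slack = 1e-4
        cfg = FAST
        sn = fit_single_normal(bimodal_ages)
        ss = fit_single_snp(bimodal_ages, 2, cfg)
        mn = fit_mixture_normal_em(bimodal_ages, cfg)
        ms = fit_mixture_snp(bimodal_ages, 2, cfg)
        assert sn.loglik <= ss.loglik + slack
        assert ss.loglik <= ms.loglik + slack
        assert sn.loglik <= mn.loglik + slack
        assert mn.loglik <= ms.loglik + slack

    @pytest.mark.parametrize("fitter", ["normal", "snp", "em", "msnp"])
    def test_aic_identity(self, bimodal_ages, fitter):
        fits = {
            "normal": lambda: fit_single_normal(bimodal_ages),
            "snp": lambda: fit_single_snp(bimodal_ages, 1, FAST),
            "em": lambda: fit_mixture_normal_em(bimodal_ages, FAST),
            "msnp": lambda: fit_mixture_snp(bimodal_ages, 1, FAST),
        }
        r = fits[fitter]()
        assert r.aic == pytest.approx(2 * r.k - 2 * r.loglik, abs=1e-9)

    def test_label_invariance(self, bimodal_ages):
        # reversing the data (and hence every initial hard assignment
        # derived from it) leaves the ordered components unchanged
        a = fit_mixture_normal_em(bimodal_ages, FAST)
        b = fit_mixture_normal_em(bimodal_ages[::-1].copy(), FAST)
        assert a.params.comp_early.mu == pytest.approx(
            b.params.comp_early.mu, abs=1e-6
        )
        assert a.params.pi_early == pytest.approx(b.params.pi_early, abs=1e-6)

    def test_pi_bounds_validated(self):
        with pytest.raises(ParameterError):
            MixtureParams(NormalParams(45, 9), NormalParams(65, 7), 1.0)
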