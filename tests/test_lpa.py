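"""Constrained mixture EM: densities, M-step constraints, FIML, multistart."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from actiprofiles.lpa import (INDICATOR_COLS, FitError, ProfileSet,
                              as_arrays, fit_em, fit_with_fixed_profiles,
                              loglik_child, multistart_fit, posterior_probs)
from actiprofiles.synth import sample_compositions


def dense_cov(profiles, k):
    """Full 4x4 covariance of profile k (block diagonal over day types)."""
    B = np.array([[profiles.var_m[k], profiles.cov[k]],
                  [profiles.cov[k], profiles.var_s[k]]])
    S = np.zeros((4, 4))
    S[:2, :2] = B
    S[2:, 2:] = B
    return S


class TestLoglikChild:
    def test_standard_normal_at_mode(self):
        prof = ProfileSet(mu=[[0.0, 0.0, 0.0, 0.0]], var_m=[1.0],
                          var_s=[1.0], cov=[0.0], mixing=[1.0])
        ll = loglik_child([0.0, 0.0, 0.0, 0.0], prof)
        assert ll == pytest.approx(-2.0 * np.log(2 * np.pi), abs=1e-12)

    def test_label_collapse_equals_single_component(self):
        p1 = ProfileSet(mu=[[0.1, 0.6, 0.1, 0.6]], var_m=[1e-3],
                        var_s=[4e-3], cov=[-1e-3], mixing=[1.0])
        p2 = ProfileSet(mu=np.tile([0.1, 0.6, 0.1, 0.6], (2, 1)),
                        var_m=[1e-3, 1e-3], var_s=[4e-3, 4e-3],
                        cov=[-1e-3, -1e-3], mixing=[0.5, 0.5])
        y = [0.12, 0.55, 0.09, 0.7]
        assert loglik_child(y, p2) == pytest.approx(loglik_child(y, p1),
                                                    abs=1e-12)

    def test_matches_dense_multivariate_normal_oracle(self, rng,
                                                      two_profile_separated):
        """Block-structured density equals a dense 4x4 MVN mixture."""
        prof = two_profile_separated
        for _ in range(3):
            y = rng.uniform(0.02, 0.6, 4)
            direct = np.logaddexp.reduce([
                np.log(prof.mixing[k])
                + multivariate_normal.logpdf(y, prof.mu[k], dense_cov(prof, k))
                for k in range(prof.K)])
            assert loglik_child(y, prof) == pytest.approx(direct, abs=1e-10)

    def test_missing_weekend_uses_weekday_marginal(self,
                                                   two_profile_separated):
        prof = two_profile_separated
        y = [0.12, 0.55, np.nan, np.nan]
        direct = np.logaddexp.reduce([
            np.log(prof.mixing[k])
            + multivariate_normal.logpdf(y[:2], prof.mu[k, :2],
                                         dense_cov(prof, k)[:2, :2])
            for k in range(prof.K)])
        assert loglik_child(y, prof) == pytest.approx(direct, abs=1e-10)

    def test_fully_missing_rejected(self, two_profile_separated):
        with pytest.raises(ValueError):
            loglik_child([np.nan] * 4, two_profile_separated)


class TestFitEM:
    def test_single_component_recovers_truth(self, rng, single_profile):
        frame, _ = sample_compositions(single_profile, 2000, rng)
        fit = fit_em(frame, 1, single_profile)
        assert fit.converged
        se_m = np.sqrt(single_profile.var_m[0] / 2000)
        assert abs(fit.profiles.mu[0, 0]
                   - single_profile.mu[0, 0]) < 3 * se_m

    def test_posterior_rows_sum_to_one(self, rng, two_profile_separated):
        frame, _ = sample_compositions(two_profile_separated, 400, rng)
        fit = multistart_fit(frame, 2, n_starts=4, seed=0)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-12)

    def test_constraints_hold_after_fit(self, rng, two_profile_separated):
        """Shared day-type variance and PD covariance blocks by
        construction after every fit."""
        frame, _ = sample_compositions(two_profile_separated, 500, rng,
                                       weekend_missing_rate=0.1)
        fit = multistart_fit(frame, 2, n_starts=4, seed=1)
        p = fit.profiles
        assert np.all(p.cov**2 < p.var_m * p.var_s)
        assert p.mixing.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unconstrained_oracle_agreement(self, rng):
        """When weekday and weekend truths coincide and there is no
        missingness, the constrained MLE matches moment estimates computed
        by pooling day types (closed-form oracle for K=1)."""
        prof = ProfileSet(mu=[[0.1, 0.6, 0.1, 0.6]], var_m=[8e-4],
                          var_s=[3e-3], cov=[-8e-4], mixing=[1.0])
        frame, _ = sample_compositions(prof, 3000, rng)
        fit = fit_em(frame, 1, prof, tol=1e-12)
        Y = frame.to_numpy()
        mu_hat = Y.mean(axis=0)
        dm = np.r_[Y[:, 0] - mu_hat[0], Y[:, 2] - mu_hat[2]]
        ds = np.r_[Y[:, 1] - mu_hat[1], Y[:, 3] - mu_hat[3]]
        assert fit.profiles.mu[0] == pytest.approx(mu_hat, abs=1e-9)
        assert fit.profiles.var_m[0] == pytest.approx(np.mean(dm * dm),
                                                      rel=1e-6)
        assert fit.profiles.cov[0] == pytest.approx(np.mean(dm * ds),
                                                    rel=1e-5)

    def test_fiml_weekday_estimates_stable_under_mcar_deletion(self, rng):
        prof = ProfileSet(
            mu=np.array([[0.12, 0.55, 0.14, 0.50],
                         [0.06, 0.70, 0.05, 0.72]]),
            var_m=np.array([4e-4, 2e-4]), var_s=np.array([2e-3, 1.5e-3]),
            cov=np.array([-4e-4, -2e-4]), mixing=np.array([0.5, 0.5]))
        frame, _ = sample_compositions(prof, 3000, rng)
        fit_full = multistart_fit(frame, 2, n_starts=4, seed=2)
        frame_mis = frame.copy()
        drop = rng.random(len(frame)) < 0.3
        frame_mis.loc[drop, ["p_mvpa_we", "p_sed_we"]] = np.nan
        fit_mis = multistart_fit(frame_mis, 2, n_starts=4, seed=2)
        se = np.sqrt(prof.var_m.max() / (0.5 * 3000))
        assert np.all(np.abs(fit_full.profiles.mu[:, :2]
                             - fit_mis.profiles.mu[:, :2]) < 3 * se)

    def test_too_few_observations_rejected(self, two_profile_separated):
        frame = pd.DataFrame([[0.1, 0.6, 0.1, 0.6]], columns=INDICATOR_COLS)
        with pytest.raises(ValueError):
            fit_em(frame, 2, two_profile_separated)


class TestMultistart:
    def test_same_seed_reproduces_fit(self, rng, two_profile_separated):
        frame, _ = sample_compositions(two_profile_separated, 300, rng)
        a = multistart_fit(frame, 2, n_starts=4, seed=7)
        b = multistart_fit(frame, 2, n_starts=4, seed=7)
        assert a.loglik == b.loglik
        assert np.array_equal(a.profiles.mu, b.profiles.mu)

    def test_well_separated_starts_agree_and_replicate(self, rng,
                                                       two_profile_separated):
        frame, _ = sample_compositions(two_profile_separated, 400, rng)
        fit = multistart_fit(frame, 2, n_starts=6, seed=3)
        assert fit.best_ll_replicated
        assert np.ptp(fit.start_logliks) < 1e-3

    def test_best_loglik_is_max_over_starts(self, rng):
        prof = ProfileSet(
            mu=np.array([[0.10, 0.60, 0.10, 0.60],
                         [0.07, 0.66, 0.06, 0.67]]),
            var_m=np.array([6e-4, 6e-4]), var_s=np.array([3e-3, 3e-3]),
            cov=np.array([-5e-4, -5e-4]), mixing=np.array([0.5, 0.5]))
        frame, _ = sample_compositions(prof, 400, rng)
        fit = multistart_fit(frame, 2, n_starts=8, seed=4)
        assert fit.loglik >= max(fit.start_logliks) - 1e-12

    def test_canonical_order_descending_mvpa(self, rng,
                                             two_profile_separated):
        frame, _ = sample_compositions(two_profile_separated, 400, rng)
        fit = multistart_fit(frame, 2, n_starts=4, seed=5)
        wm = fit.profiles.weighted_mvpa_mean()
        assert wm[0] > wm[1]

    def test_requires_two_starts(self, rng, two_profile_separated):
        frame, _ = sample_compositions(two_profile_separated, 100, rng)
        with pytest.raises(ValueError):
            multistart_fit(frame, 2, n_starts=1)


class TestFixedProfileFit:
    def test_recovers_mixing_with_known_measurement(self, rng):
        prof = ProfileSet(
            mu=np.array([[0.12, 0.55, 0.14, 0.50],
                         [0.06, 0.70, 0.05, 0.72]]),
            var_m=np.array([4e-4, 2e-4]), var_s=np.array([2e-3, 1.5e-3]),
            cov=np.array([-4e-4, -2e-4]), mixing=np.array([0.7, 0.3]))
        frame, z = sample_compositions(prof, 4000, rng)
        fit = fit_with_fixed_profiles(frame, prof)
        se = np.sqrt(0.7 * 0.3 / 4000)
        assert abs(fit.profiles.mixing[0] - 0.7) < 3 * se + 0.01
        # measurement untouched
        assert np.array_equal(fit.profiles.mu, prof.mu)


class TestDataIngestion:
    def test_incoherent_missingness_rejected(self):
        frame = pd.DataFrame(
            [[0.1, 0.6, np.nan, 0.6],      # half-missing weekend: dropped
             [0.1, 0.6, 0.1, 0.6]], columns=INDICATOR_COLS)
        Y, we = as_arrays(frame)
        assert Y.shape[0] == 1

    def test_all_rows_unusable_raises(self):
        frame = pd.DataFrame([[np.nan, 0.6, 0.1, 0.6]],
                             columns=INDICATOR_COLS)
        with pytest.raises(ValueError):
            as_arrays(frame)
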