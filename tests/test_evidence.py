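"""Evidence module: AR(1) whitening, conjugate updates, cvLME.

The log-evidence closed form is checked against brute-force numerical
integration of the normal-gamma marginal likelihood on tiny instances.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from chronoglm.design import build_model_space
from chronoglm.evidence import (EvidenceMaps, NoisePrewhitener,
                                NormalGammaPosterior, SubjectEvidenceModel,
                                bayes_glm_update, cv_log_evidence,
                                estimate_ar1, log_evidence,
                                subject_evidence_maps, _cvlme_many_voxels)


def quadrature_log_evidence(y, X, prior):
    """Brute-force oracle: numerically integrate the marginal likelihood.

    Computes log of the integral over (beta, tau) of
    N(y | X beta, I/tau) * N(beta | mu, (tau Lambda)^-1) * Gamma(tau | a, b),
    independently of the conjugate algebra under test.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    post = bayes_glm_update(y, X, prior)  # only to centre the grid

    from scipy.special import gammaln

    _, prior_ld = np.linalg.slogdet(prior.Lambda)

    def log_integrand(tau, beta):
        beta = np.asarray(beta)
        resid = y - X @ beta
        ll = 0.5 * n * np.log(tau / (2 * np.pi)) - 0.5 * tau * resid @ resid
        diff = beta - prior.mu
        lp_beta = 0.5 * (prior_ld + p * np.log(tau) - p * np.log(2 * np.pi)) \
            - 0.5 * tau * diff @ prior.Lambda @ diff
        lp_tau = prior.a * np.log(prior.b) + (prior.a - 1) * np.log(tau) \
            - prior.b * tau - gammaln(prior.a)
        return ll + lp_beta + lp_tau

    offset = log_integrand(post.a / post.b, post.mu)
    sd = np.sqrt(np.diag(np.linalg.inv(post.Lambda)) * post.b / post.a)
    tau_lo = stats.gamma.ppf(1e-10, post.a, scale=1 / post.b)
    tau_hi = stats.gamma.ppf(1 - 1e-10, post.a, scale=1 / post.b)
    half = 12.0

    if p == 1:
        val, _ = integrate.dblquad(
            lambda tau, b0: np.exp(
                log_integrand(tau, np.array([b0])) - offset),
            post.mu[0] - half * sd[0], post.mu[0] + half * sd[0],
            tau_lo, tau_hi, epsabs=1e-12, epsrel=1e-10)
    elif p == 2:
        val, _ = integrate.tplquad(
            lambda tau, b1, b0: np.exp(
                log_integrand(tau, np.array([b0, b1])) - offset),
            post.mu[0] - half * sd[0], post.mu[0] + half * sd[0],
            post.mu[1] - half * sd[1], post.mu[1] + half * sd[1],
            tau_lo, tau_hi, epsabs=1e-12, epsrel=1e-8)
    else:
        raise NotImplementedError
    return offset + np.log(val)


class TestAR1:
    def test_white_noise_near_zero(self, rng):
        x = rng.normal(size=10_000)
        assert abs(estimate_ar1(x)) < 0.05

    def test_recovers_simulated_coefficient(self, rng):
        n, rho = 10_000, 0.5
        e = rng.normal(size=n)
        x = np.empty(n)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + e[t]
        assert abs(estimate_ar1(x) - rho) < 0.05

    def test_constant_residuals_warn_and_zero(self):
        with pytest.warns(UserWarning):
            assert estimate_ar1(np.full(100, 3.0)) == 0.0

    def test_whitening_removes_lag1_autocorrelation(self, rng):
        n, rho = 20_000, 0.6
        e = rng.normal(size=n)
        x = np.empty(n)
        x[0] = e[0] / np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + e[t]
        w = NoisePrewhitener(rho).whiten(x)
        assert abs(estimate_ar1(w)) < 0.05


class TestConjugateUpdate:
    def test_intercept_only_posterior_mean(self, rng):
        y = rng.normal(2.0, 1.0, size=17)
        post = bayes_glm_update(y, np.ones((17, 1)))
        assert post.mu[0] == pytest.approx(y.mean())

    def test_shape_bookkeeping_and_residual_b(self):
        y = np.array([1.0, 2.0, 3.0])
        post = bayes_glm_update(y, np.ones((3, 1)))
        assert post.a == pytest.approx(1.5)  # n/2 from a=0
        assert post.b == pytest.approx(1.0)  # half the centred sum of squares

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.integers(2, 5), st.integers(6, 12))
    def test_chain_rule_over_row_partitions(self, seed, split, n):
        """Sequential conjugate updates equal the joint update."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        prior = NormalGammaPosterior(mu=np.zeros(2), Lambda=np.eye(2),
                                     a=1.5, b=1.0)
        joint = bayes_glm_update(y, X, prior)
        seq = bayes_glm_update(y[split:], X[split:],
                               bayes_glm_update(y[:split], X[:split], prior))
        assert np.allclose(seq.mu, joint.mu, atol=1e-8)
        assert np.allclose(seq.Lambda, joint.Lambda, atol=1e-8)
        assert seq.a == pytest.approx(joint.a)
        assert seq.b == pytest.approx(joint.b, abs=1e-8)

    def test_rank_deficiency_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            bayes_glm_update(np.array([1.0]), np.ones((1, 2)))


class TestLogEvidence:
    prior1 = NormalGammaPosterior(mu=np.array([0.5]),
                                  Lambda=np.array([[2.0]]), a=2.0, b=1.5)
    prior2 = NormalGammaPosterior(mu=np.array([0.2, -0.4]),
                                  Lambda=np.diag([1.5, 3.0]), a=3.0, b=2.0)

    @pytest.mark.parametrize("case", [
        (np.array([0.7]), np.array([[1.0]]), "prior1"),
        (np.array([0.3, -0.9, 1.4]), np.array([[1.0], [0.5], [-1.0]]), "prior1"),
        (np.array([0.5, 1.1, -0.2, 0.8]),
         np.array([[1.0, 0.2], [0.4, -1.0], [1.0, 1.0], [-0.3, 0.5]]), "prior2"),
    ])
    def test_matches_quadrature_oracle(self, case):
        y, X, prior_name = case
        prior = getattr(self, prior_name)
        closed = log_evidence(y, X, prior)
        oracle = quadrature_log_evidence(y, X, prior)
        assert closed == pytest.approx(oracle, abs=1e-4)

    def test_chain_rule_identity(self, rng):
        y = rng.normal(size=10)
        X = rng.normal(size=(10, 2))
        prior = self.prior2
        lhs = log_evidence(y[:6], X[:6], prior) + log_evidence(
            y[6:], X[6:], bayes_glm_update(y[:6], X[:6], prior))
        rhs = log_evidence(y, X, prior)
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_joint_scaling_preserves_ranking(self, rng):
        X1 = rng.normal(size=(30, 2))
        X2 = rng.normal(size=(30, 3))
        y = X1 @ np.array([1.0, -0.5]) + 0.3 * rng.normal(size=30)
        r1 = cv_log_evidence(y, X1) - cv_log_evidence(y, X2)
        s = 7.3
        r2 = cv_log_evidence(s * y, s * X1) - cv_log_evidence(s * y, s * X2)
        assert np.sign(r1) == np.sign(r2)

    def test_improper_prior_rejected(self):
        with pytest.raises(ValueError, match="cv_log_evidence"):
            log_evidence(np.ones(3), np.ones((3, 1)),
                         NormalGammaPosterior.noninformative(1))


class TestCvLogEvidence:
    def test_deterministic(self, rng):
        y = rng.normal(size=24)
        X = rng.normal(size=(24, 3))
        assert cv_log_evidence(y, X) == cv_log_evidence(y, X)

    def test_true_model_beats_intercept_under_signal(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(40), rng.normal(size=40)])
            y = X @ np.array([0.0, 1.0]) + rng.normal(size=40)  # SNR 1
            wins += cv_log_evidence(y, X) > cv_log_evidence(y, X[:, :1])
        assert wins >= 95

    def test_complexity_penalty_for_noise_regressor(self):
        diffs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X = np.column_stack([np.ones(40), rng.normal(size=40)])
            y = X @ np.array([0.5, 1.0]) + rng.normal(size=40)
            X_aug = np.column_stack([X, rng.normal(size=40)])
            diffs.append(cv_log_evidence(y, X_aug) - cv_log_evidence(y, X))
        assert np.mean(diffs) < 0

    def test_fold_order_invariance(self, rng):
        """cvLME is a sum over folds: permuting rows within a fold of both
        y and X leaves it unchanged."""
        n = 24
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 3))
        base = cv_log_evidence(y, X, n_folds=2)
        perm = np.r_[rng.permutation(12), 12 + rng.permutation(12)]
        assert cv_log_evidence(y[perm], X[perm]) == pytest.approx(base, abs=1e-9)

    def test_vectorised_path_matches_scalar(self, rng):
        Y = rng.normal(size=(30, 7))
        X = rng.normal(size=(30, 3))
        vec = _cvlme_many_voxels(Y, X)
        scal = [cv_log_evidence(Y[:, i], X) for i in range(7)]
        assert np.allclose(vec, scal, atol=1e-10)

    def test_too_few_training_rows_raises(self, rng):
        with pytest.raises(ValueError, match="training complement"):
            cv_log_evidence(rng.normal(size=4), rng.normal(size=(4, 3)))


class TestSubjectEvidenceMaps:
    def test_empty_mask_yields_empty_map(self, small_trials):
        bold = np.zeros((2, 2, 2, 60)) + 100.0
        mask = np.zeros((2, 2, 2), dtype=bool)
        ev = subject_evidence_maps(bold, mask, small_trials, TR_s=1.0)
        assert ev.cvlme.shape == (1, 4, 0)

    def test_nonfinite_voxel_dropped(self, small_trials, rng):
        bold = 100 + rng.normal(size=(2, 2, 1, 60))
        bold[0, 0, 0, 10] = np.nan
        mask = np.ones((2, 2, 1), dtype=bool)
        with pytest.warns(UserWarning, match="non-finite"):
            ev = subject_evidence_maps(bold, mask, small_trials, TR_s=1.0)
        assert ev.cvlme.shape[2] == 3
        assert not ev.mask[0, 0, 0]

    def test_generative_voxels_recovered_at_modest_snr(self, rng):
        """Voxels following the stimulus-locked process prefer it over the
        response-locked alternatives."""
        from chronoglm.simulate import (SimConfig, generate_group_dataset)
        cfg = SimConfig(n_subjects=1, n_sessions=1, n_trials=48,
                        grid_shape=(6, 6, 6), block_size=2, sigma=0.5)
        ds = generate_group_dataset(cfg, seed=7)
        sub = ds.subjects[0]
        mask = np.ones(cfg.grid_shape, dtype=bool)
        ev = subject_evidence_maps(sub.bold[0], mask, sub.trials[0],
                                   motion=sub.motion[0], TR_s=cfg.TR_s)
        proc = ds.ground_truth.process_map.ravel()
        winners = np.argmax(ev.cvlme[0], axis=0) + 1
        block1 = proc == 1
        assert np.mean(winners[block1] == 1) >= 0.8

    def test_estimator_follows_sklearn_conventions(self, small_trials, rng):
        from sklearn.base import clone
        est = SubjectEvidenceModel(TR_s=1.0, n_folds=2)
        assert clone(est).get_params()["n_folds"] == 2
        bold = 100 + rng.normal(size=(2, 1, 1, 60))
        est.fit(bold, trials=small_trials)
        assert est.evidence_maps_.cvlme.shape == (1, 4, 2)
        assert 0.0 <= est.rho_ <= 0.95

    def test_noise_voxels_show_no_locking_preference(self, rng):
        """On pure noise, stimulus- vs response-locked winners split evenly
        and the evidence's dimensionality penalty favours the simpler,
        unmodulated models (complexity control)."""
        n = 120
        space = build_model_space(False)
        from chronoglm.design import TrialTable, build_design_matrix
        onsets = 6.0 + 6.0 * np.arange(8)
        trials = TrialTable(onset_s=onsets,
                            rt_s=rng.uniform(0.3, 0.5, 8),
                            condition=np.array(["neutral"] * 8, dtype=object),
                            correct=np.ones(8, dtype=bool),
                            isi_s=np.full(8, 6.0))
        designs = [build_design_matrix(trials, m, TR_s=1.0, n_scans=n,
                                       hp_cutoff_s=None) for m in space]
        Y = rng.normal(size=(n, 200))
        L = np.stack([_cvlme_many_voxels(Y, d.values) for d in designs])
        winners = np.argmax(L, axis=0)
        early = np.isin(winners, (0, 1)).mean()
        assert abs(early - 0.5) <= 0.10
        unmodulated = np.isin(winners, (0, 2)).mean()
        assert unmodulated > 0.8
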