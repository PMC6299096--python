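import numpy as np
import pytest
from scipy import integrate, stats

from kinclock.emg import EMGParams
from kinclock.inference import (
    CompetingRisksModel,
    cause_log_density,
    conditional_copula_survival,
    dataset_loglik,
    fit_model,
    gaussian_copula_cdf,
    gaussian_copula_density,
    inferred_underlying,
    overall_log_survival,
    overall_survival,
    pair_loglikelihood,
    sample_pairs_from_model,
)
from kinclock.inference import _pairs_loglik
from kinclock.lineage import Fate, PairObservation, Relation


@pytest.fixture(scope="module")
def mild_model(mild_model_params):
    div, die = mild_model_params
    return CompetingRisksModel(theta_div=div, theta_die=die, z=0.55)


class TestCopula:
    def test_independence(self, rng):
        u = rng.uniform(size=(20, 2))
        assert np.allclose(gaussian_copula_density(u[:, 0], u[:, 1], 0.0), 1.0)

    def test_center_closed_form(self):
        z = 0.71
        assert gaussian_copula_density(0.5, 0.5, z) == pytest.approx(
            1.0 / np.sqrt(1 - z * z))

    def test_symmetry(self, rng):
        u = rng.uniform(size=(50, 2))
        a = gaussian_copula_density(u[:, 0], u[:, 1], 0.4)
        b = gaussian_copula_density(u[:, 1], u[:, 0], 0.4)
        assert np.allclose(a, b)

    def test_density_integrates_to_one(self):
        val, _ = integrate.dblquad(
            lambda u, v: gaussian_copula_density(u, v, 0.6), 0, 1, 0, 1,
            epsabs=1e-9)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_z(self):
        with pytest.raises(ValueError):
            gaussian_copula_density(0.5, 0.5, 1.0)

    @pytest.mark.parametrize("rho", [-0.8, 0.0, 0.3, 0.95])
    def test_cdf_against_scipy_bivariate_normal(self, rho):
        pts = [(-1.2, 0.3), (0.5, 0.5), (2.0, -0.7), (0.0, 1.0), (-2.0, -2.0)]
        for x, y in pts:
            ours = gaussian_copula_cdf(stats.norm.cdf(x), stats.norm.cdf(y), rho)
            ref = stats.multivariate_normal.cdf(
                [x, y], mean=[0, 0], cov=[[1, rho], [rho, 1]])
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_conditional_survival_complements_partial_cdf(self, rng):
        # d C / d u1 + conditional survival = 1
        z = 0.6
        u1, u2 = 0.3, 0.7
        x, y = stats.norm.ppf(u1), stats.norm.ppf(u2)
        partial = stats.norm.cdf((y - z * x) / np.sqrt(1 - z * z))
        assert conditional_copula_survival(u1, u2, z) == pytest.approx(1 - partial)


class TestCompetingRisks:
    def test_overall_survival_product(self, mild_model):
        t = np.linspace(0, 40, 50)
        div_only = CompetingRisksModel(theta_div=mild_model.theta_div)
        assert np.allclose(
            overall_survival(t, mild_model),
            overall_survival(t, div_only)
            * np.exp(overall_log_survival(t, CompetingRisksModel(
                theta_div=mild_model.theta_die))),
        )
        assert overall_survival(0.0, div_only) == pytest.approx(
            float(np.exp(mild_model.theta_div.frozen().logsf(0.0))))

    def test_death_disabled(self, mild_model_params):
        div, _ = mild_model_params
        m = CompetingRisksModel(theta_div=div)
        t = np.linspace(-5, 40, 50)
        assert np.allclose(overall_survival(t, m), div.frozen().sf(t))
        with pytest.raises(ValueError):
            cause_log_density(5.0, m, Fate.DIED)

    def test_total_cause_probability(self, mild_model):
        f = lambda t: (np.exp(cause_log_density(t, mild_model, Fate.DIVIDED))
                       + np.exp(cause_log_density(t, mild_model, Fate.DIED)))
        val, _ = integrate.quad(f, -30, 150, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestPairLikelihood:
    def test_independent_collapse(self, mild_model_params):
        """At z = 0 with the death clock off, the pair density factorizes
        into the product of the (positivity-conditioned) lifetime densities."""
        div, _ = mild_model_params
        m = CompetingRisksModel(theta_div=div, z=0.0)
        pair = PairObservation(9.0, 14.0, Fate.DIVIDED, Fate.DIVIDED, Relation.SISTER)
        fr = div.frozen()
        expected = (fr.logpdf(9.0) + fr.logpdf(14.0) - 2 * fr.logsf(0.0))
        assert pair_loglikelihood(pair, m) == pytest.approx(float(expected))

    def test_both_censored_independent(self, mild_model_params):
        div, _ = mild_model_params
        m = CompetingRisksModel(theta_div=div, z=0.0)
        c = 8.0
        pair = PairObservation(c, c, Fate.CENSORED, Fate.CENSORED, Relation.SISTER)
        fr = div.frozen()
        expected = 2 * (fr.logsf(c) - fr.logsf(0.0))
        assert pair_loglikelihood(pair, m) == pytest.approx(float(expected), abs=1e-6)

    def test_negative_lifetime_rejected(self, mild_model):
        with pytest.raises(ValueError):
            pair_loglikelihood(
                PairObservation(-1.0, 5.0, Fate.DIVIDED, Fate.DIVIDED, Relation.SISTER),
                mild_model)

    def test_normalization_over_fates_and_times(self, mild_model):
        """The pair density sums to 1 over fates x (conditioned) times."""
        t = np.linspace(0.0, 120.0, 900)
        T1, T2 = np.meshgrid(t, t)
        a = np.zeros(T1.size)
        tot = 0.0
        for e1 in (0, 1):
            for e2 in (0, 1):
                ll = _pairs_loglik(T1.ravel(), T2.ravel(),
                                   np.full(T1.size, e1), np.full(T1.size, e2),
                                   mild_model, a, a)
                tot += np.trapezoid(
                    np.trapezoid(np.exp(ll).reshape(T1.shape), t, axis=1), t)
        assert tot == pytest.approx(1.0, abs=1e-4)

    def test_dataset_invariant_to_pair_order(self, mild_model, rng):
        pairs = sample_pairs_from_model(mild_model, 40, rng, censor_horizon=25.0)
        a = dataset_loglik(pairs, [], mild_model)
        b = dataset_loglik(list(reversed(pairs)), [], mild_model)
        assert a == pytest.approx(b)

    def test_singleton_terms(self, mild_model):
        ll = dataset_loglik([], [(7.0, Fate.DIVIDED), (9.0, Fate.CENSORED)],
                            mild_model)
        expected = (
            float(cause_log_density(7.0, mild_model, Fate.DIVIDED))
            + float(overall_log_survival(9.0, mild_model))
            - 2 * float(overall_log_survival(0.0, mild_model))
        )
        assert ll == pytest.approx(expected)

    def test_empty_dataset_raises(self, mild_model):
        with pytest.raises(ValueError):
            dataset_loglik([], [], mild_model)


class TestFit:
    def test_parameter_recovery(self, rng):
        true = CompetingRisksModel(
            theta_div=EMGParams(17.0, 5.0, 1 / 12.0),
            theta_die=EMGParams(20.0, 7.0, 1 / 9.0),
            z=0.6, censor_horizon=72.0)
        pairs = sample_pairs_from_model(true, 500, rng, censor_horizon=72.0)
        fit = fit_model(pairs, [], init=true, n_restarts=2, seed=0)
        assert fit.converged
        assert abs(fit.model.z - 0.6) < 0.1
        assert fit.model.theta_div.mean == pytest.approx(true.theta_div.mean, rel=0.05)
        assert fit.model.theta_die.mean == pytest.approx(true.theta_die.mean, rel=0.05)
        assert all(v > 0 for v in fit.se.values() if np.isfinite(v))

    def test_nested_models(self, rng):
        true = CompetingRisksModel(
            theta_div=EMGParams(17.0, 5.0, 1 / 12.0),
            theta_die=EMGParams(20.0, 7.0, 1 / 9.0),
            z=0.6, censor_horizon=72.0)
        pairs = sample_pairs_from_model(true, 200, rng, censor_horizon=72.0)
        free = fit_model(pairs, [], init=true, n_restarts=1, seed=0)
        fixed = fit_model(pairs, [], init=true, fixed_params={"z": 0.0},
                          n_restarts=1, seed=0)
        assert free.loglik >= fixed.loglik

    def test_copula_margins_uniform(self, mild_model, rng):
        """Simulated event times have uniform conditional-CDF margins."""
        pairs = sample_pairs_from_model(mild_model, 800, rng)
        t = np.array([p.t1 for p in pairs])
        u = 1.0 - np.exp(overall_log_survival(t, mild_model)
                         - overall_log_survival(0.0, mild_model))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_inferred_underlying_closed_forms(self, rng):
        true = CompetingRisksModel(
            theta_div=EMGParams(17.0, 5.0, 1 / 12.0),
            theta_die=EMGParams(20.0, 7.0, 1 / 9.0), z=0.5)
        pairs = sample_pairs_from_model(true, 300, rng)
        fit = fit_model(pairs, [], init=true, n_restarts=1, seed=0)
        tdiv, tdie, summary = inferred_underlying(fit)
        assert summary["imt"][0] == pytest.approx(tdiv.mu + 1 / tdiv.lam)
        assert summary["imt"][1] == pytest.approx(
            np.sqrt(tdiv.sigma**2 + 1 / tdiv.lam**2))

    def test_unconverged_fit_refused(self, mild_model):
        from kinclock.inference import FitResult

        bad = FitResult(model=mild_model, loglik=-1, se={}, converged=False,
                        n_pairs=0, n_singletons=0)
        with pytest.raises(ValueError):
            inferred_underlying(bad)


class TestCompetitionBias:
    def test_observed_division_mean_below_latent(self, mild_model, rng):
        """Min-competition bias: observed divisions are earlier than the
        latent division clock whenever the death clock overlaps."""
        pairs = sample_pairs_from_model(mild_model, 2000, rng)
        divided = [t for p in pairs for t, e in ((p.t1, p.e1), (p.t2, p.e2))
                   if e is Fate.DIVIDED]
        assert np.mean(divided) < mild_model.theta_div.mean
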