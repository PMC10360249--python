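import numpy as np
import pytest
from scipy import stats

from bymap.bym_inference import (
    BYMData,
    BYMFit,
    BYMModelSpec,
    dic,
    fit,
    icar_quadratic,
    log_joint,
    spatial_variance_fraction,
    summarize_fixed_effects,
)
from bymap.synthetic_city import generate_lattice, sample_populations
from tests.conftest import FAST_FIT


def make_fit(alpha, beta, u, st, spec=None, names=None):
    """Hand-built BYMFit for summary/DIC oracle tests."""
    alpha = np.asarray(alpha, float)
    m = alpha.size
    return BYMFit(
        spec=spec or BYMModelSpec(covariate_names=names or []),
        alpha=alpha,
        beta=np.asarray(beta, float).reshape(m, -1),
        u=np.asarray(u, float).reshape(m, -1),
        st=np.asarray(st, float).reshape(m, -1),
        tau_u=np.ones(m),
        tau_st=np.ones(m),
        n_chains=1,
        n_draws=m,
        rhat={},
        n_divergent=0,
        covariate_names=names or [],
    )


def toy_data(n=12, seed=0, rate=0.2):
    lat = generate_lattice(n, seed=seed)
    pops = sample_populations(n, seed=seed).astype(float)
    rng = np.random.default_rng(seed)
    y = rng.poisson(pops * rate)
    return BYMData(y, pops, np.zeros((n, 0)), lat, [])


class TestLogJoint:
    def test_poisson_term_matches_pointwise_oracle(self):
        data = toy_data(10, seed=1)
        spec = BYMModelSpec(include_u=False, include_st=False)
        a = np.log(0.17)
        got = log_joint({"alpha": a}, data, spec)
        oracle = stats.poisson.logpmf(data.y, data.population *
                                      np.exp(a)).sum()
        oracle -= 0.5 * spec.fixed_effect_precision * a**2
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_icar_term_invariant_to_constant_shift(self, grid5_rook):
        rng = np.random.default_rng(2)
        st = rng.normal(size=25)
        q1 = icar_quadratic(st, grid5_rook)
        q2 = icar_quadratic(st + 7.3, grid5_rook)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_tau_doubling_closed_form(self):
        data = toy_data(15, seed=3)
        spec = BYMModelSpec(include_u=False, soft_sum_zero_sd=None)
        rng = np.random.default_rng(3)
        st = rng.normal(size=15)
        st -= st.mean()
        tau = 1.7
        base = dict(alpha=-1.5, st=st)
        lo = log_joint({**base, "log_tau_st": np.log(tau)}, data, spec)
        hi = log_joint({**base, "log_tau_st": np.log(2 * tau)}, data, spec)
        n = 15
        quad = icar_quadratic(st, data.lattice)
        a, b = spec.prior_st
        expected = (0.5 * (n - 1) * np.log(2) - 0.5 * tau * quad
                    + a * np.log(2) - b * tau)
        assert hi - lo == pytest.approx(expected, abs=1e-10)

    def test_mismatched_dimensions_rejected(self):
        data = toy_data(8, seed=0)
        spec = BYMModelSpec()
        with pytest.raises(Exception):
            log_joint({"alpha": 0.0, "st": np.zeros(5)}, data, spec)


class TestFitConjugateOracle:
    def test_matches_poisson_gamma_posterior(self):
        data = toy_data(30, seed=5, rate=0.3)
        spec = BYMModelSpec(include_u=False, include_st=False)
        f = fit(data, spec, seed=1, **FAST_FIT)
        e_alpha = np.exp(f.alpha)
        oracle = data.y.sum() / data.population.sum()  # flat-prior limit
        assert abs(e_alpha.mean() - oracle) < 2 * e_alpha.std()


class TestFitStructure:
    def test_sum_to_zero_every_draw(self, small_fit):
        assert np.abs(small_fit.st.sum(axis=1)).max() < 1e-8

    def test_rhat_reported_and_reasonable(self, small_fit):
        assert set(small_fit.rhat) >= {"alpha", "log_tau_u", "log_tau_st"}
        assert all(np.isfinite(v) for v in small_fit.rhat.values())

    def test_recovers_simulated_effects(self, small_city, small_fit):
        truth = np.exp(small_city.truth.beta)
        est = np.exp(small_fit.beta).mean(axis=0)
        np.testing.assert_allclose(est, truth, atol=0.05)

    def test_label_invariance(self, small_city):
        from bymap.spatial_lattice import build_adjacency

        c = small_city
        n = c.lattice.n
        names = list(c.covariates.columns)
        data_a = BYMData(c.cases, c.populations, c.covariates.to_numpy(),
                         c.lattice, names)
        # relabel so canonical (sorted) order is reversed
        new_ids = [f"Z{n - 1 - i:03d}" for i in range(n)]
        lat_b = build_adjacency(new_ids, list(c.lattice.polygons),
                                "queen", warn_islands=False)
        rev = slice(None, None, -1)
        data_b = BYMData(c.cases[rev], c.populations[rev],
                         c.covariates.to_numpy()[rev], lat_b, names)
        spec = BYMModelSpec(covariate_names=names)
        fa = fit(data_a, spec, seed=9, **FAST_FIT)
        fb = fit(data_b, spec, seed=9, **FAST_FIT)
        np.testing.assert_allclose(np.exp(fa.beta).mean(axis=0),
                                   np.exp(fb.beta).mean(axis=0), atol=0.01)
        np.testing.assert_allclose(fa.u.mean(axis=0),
                                   fb.u.mean(axis=0)[rev], atol=0.06)

    def test_validation(self):
        data = toy_data(8)
        with pytest.raises(ValueError, match="population"):
            BYMData(data.y, np.zeros(8), data.X, data.lattice)
        with pytest.raises(ValueError, match="integer"):
            BYMData(data.y.astype(float), data.population, data.X,
                    data.lattice)
        with pytest.raises(ValueError, match="positive"):
            BYMModelSpec(prior_u=(0, 1))


class TestSummarizeFixedEffects:
    def test_degenerate_draws(self):
        f = make_fit(np.zeros(50), np.full((50, 1), np.log(2.0)),
                     np.zeros((50, 3)), np.zeros((50, 3)), names=["x"])
        s = summarize_fixed_effects(f)
        row = s.loc["x"]
        assert row["exp_mean"] == pytest.approx(2.0)
        assert row["q2.5"] == pytest.approx(2.0)
        assert row["q97.5"] == pytest.approx(2.0)
        assert row["credible"]

    def test_symmetric_draws_not_credible(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1, size=(2000, 1))
        f = make_fit(np.zeros(2000), b, np.zeros((2000, 2)),
                     np.zeros((2000, 2)), names=["x"])
        assert not summarize_fixed_effects(f).loc["x", "credible"]

    def test_lognormal_quantile_oracle(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0.07, 0.01, size=200_000)
        f = make_fit(np.zeros(draws.size), draws.reshape(-1, 1),
                     np.zeros((draws.size, 1)), np.zeros((draws.size, 1)),
                     names=["x"])
        row = summarize_fixed_effects(f).loc["x"]
        assert row["exp_mean"] == pytest.approx(
            np.exp(0.07 + 0.5 * 0.01**2), abs=2e-4)
        assert row["q2.5"] == pytest.approx(np.exp(0.07 - 1.96 * 0.01),
                                            abs=3e-4)
        assert row["q97.5"] == pytest.approx(np.exp(0.07 + 1.96 * 0.01),
                                             abs=3e-4)

    def test_credibility_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0.3, 0.05, size=(1000, 1))
        f1 = make_fit(np.zeros(1000), b, np.zeros((1000, 1)),
                      np.zeros((1000, 1)), names=["x"])
        # order-preserving transform of draws keeps the flag
        f2 = make_fit(np.zeros(1000), np.sort(b, axis=0),
                      np.zeros((1000, 1)), np.zeros((1000, 1)), names=["x"])
        s1, s2 = summarize_fixed_effects(f1), summarize_fixed_effects(f2)
        assert s1.loc["x", "credible"] == s2.loc["x", "credible"]


class TestDIC:
    def test_single_draw_pd_zero(self):
        data = toy_data(6, seed=2)
        f = make_fit([0.1], np.zeros((1, 0)), 0.01 * np.ones((1, 6)),
                     np.zeros((1, 6)))
        d, p_d = dic(f, data)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        eta = 0.1 + np.log(data.population) + 0.01
        oracle = -2 * stats.poisson.logpmf(data.y, np.exp(eta)).sum()
        assert d == pytest.approx(oracle, abs=1e-8)

    def test_three_area_toy_matches_hand_oracle(self):
        from bymap.spatial_lattice import build_adjacency
        from shapely.geometry import box

        lat = build_adjacency(
            ["a", "b", "c"],
            [box(0, 0, 1, 1), box(1, 0, 2, 1), box(2, 0, 3, 1)])
        data = BYMData(np.array([4, 9, 2]), np.array([50.0, 80.0, 30.0]),
                       np.zeros((3, 0)), lat, [])
        alphas = np.array([-2.0, -2.2])
        us = np.array([[0.1, -0.05, 0.0], [0.0, 0.2, -0.1]])
        f = make_fit(alphas, np.zeros((2, 0)), us, np.zeros((2, 3)))
        d, p_d = dic(f, data)
        # scalar log-pmf oracle
        devs = []
        for a, u in zip(alphas, us):
            lam = data.population * np.exp(a + u)
            devs.append(-2 * stats.poisson.logpmf(data.y, lam).sum())
        d_bar = np.mean(devs)
        eta_bar = np.mean([a + u for a, u in zip(alphas, us)], axis=0) + \
            np.log(data.population)
        d_hat = -2 * stats.poisson.logpmf(data.y, np.exp(eta_bar)).sum()
        assert d == pytest.approx(2 * d_bar - d_hat, abs=1e-10)
        assert p_d == pytest.approx(d_bar - d_hat, abs=1e-10)


class TestSpatialVarianceFraction:
    def test_zero_when_structured_silent(self):
        rng = np.random.default_rng(0)
        f = make_fit(np.zeros(10), np.zeros((10, 0)),
                     rng.normal(size=(10, 5)), np.zeros((10, 5)))
        assert spatial_variance_fraction(f) == 0.0

    def test_one_when_unstructured_silent(self):
        rng = np.random.default_rng(0)
        st = rng.normal(size=(10, 5))
        st -= st.mean(axis=1, keepdims=True)
        f = make_fit(np.zeros(10), np.zeros((10, 0)),
                     np.zeros((10, 5)), st)
        assert spatial_variance_fraction(f) == 1.0

    def test_direction_with_dominant_unstructured(self, small_city_data):
        # tau_u << tau_st: unstructured noise dominates the truth
        from bymap.synthetic_city import generate_city

        city = generate_city(n_areas=50, seed=21, tau_u=5.0, tau_st=200.0)
        names = list(city.covariates.columns)
        data = BYMData(city.cases, city.populations,
                       city.covariates.to_numpy(), city.lattice, names)
        f = fit(data, BYMModelSpec(covariate_names=names), seed=2,
                **FAST_FIT)
        assert spatial_variance_fraction(f) < 0.5
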