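"""Conjugate family oracles: updates, predictives, engines vs references."""

import numpy as np
import pytest
from scipy import integrate, stats

from mapdp.exp_family import (
    BernoulliFamily,
    BetaPrior,
    BinomialFamily,
    CategoricalFamily,
    ComponentModel,
    DirichletPrior,
    EllipticalModel,
    Feature,
    FeatureSchema,
    FullGaussianFamily,
    FullGaussianModel,
    GammaPrior,
    NIWPrior,
    PoissonFamily,
    SphericalGaussianFamily,
    SphericalGaussianModel,
    SphericalGaussianPrior,
    SupportError,
    elliptical_log_predictive,
    family_for,
)

LOG_2PI = np.log(2 * np.pi)


class TestSphericalGaussian:
    fam = SphericalGaussianFamily()

    def test_empty_update_is_identity(self):
        prior = SphericalGaussianPrior(np.zeros(2), 2.0, 1.0)
        post = self.fam.posterior_update(prior, [])
        np.testing.assert_array_equal(post.mu0, prior.mu0)
        assert post.var0 == prior.var0

    def test_single_point_update(self):
        # mu0=0, var0=1, var=1, one point at 2: var -> 1/2, mean -> 1
        prior = SphericalGaussianPrior(np.zeros(1), 1.0, 1.0)
        post = self.fam.posterior_update(prior, [[2.0]])
        assert post.var0 == pytest.approx(0.5)
        assert post.mu0[0] == pytest.approx(1.0)

    def test_predictive_at_mean_unit_variance(self):
        # composite variance var0 + var = 1: only the 2*pi constant remains
        hyper = SphericalGaussianPrior(np.array([3.0, -1.0]), 0.25, 0.75)
        lp = self.fam.log_predictive(hyper, hyper.mu0)
        assert lp == pytest.approx(-0.5 * 2 * LOG_2PI)

    def test_conjugacy_identity_against_quadrature(self):
        # log f(x | posterior) must equal the marginal-likelihood ratio,
        # with marginals computed by direct numerical integration over
        # the latent mean.
        prior = SphericalGaussianPrior(np.array([0.5]), 1.3, 0.8)
        pts = [-0.2, 0.9, 1.4]
        x = 0.3

        def marginal(points):
            def integrand(mu):
                val = stats.norm.pdf(mu, prior.mu0[0], np.sqrt(prior.var0))
                for p in points:
                    val *= stats.norm.pdf(p, mu, np.sqrt(prior.var))
                return val

            out, _ = integrate.quad(integrand, -20, 20)
            return out

        post = self.fam.posterior_update(prior, [[p] for p in pts])
        lhs = self.fam.log_predictive(post, [x])
        rhs = np.log(marginal(pts + [x])) - np.log(marginal(pts))
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_support_error(self):
        with pytest.raises(SupportError):
            self.fam.log_predictive(SphericalGaussianPrior(np.zeros(1), 1, 1), [np.nan])


class TestBetaBernoulli:
    fam = BernoulliFamily()

    def test_count_update(self):
        post = self.fam.posterior_update(BetaPrior(1, 1), [1, 1, 0])
        assert (post.a, post.b) == (3, 2)

    def test_uniform_prior_predictive(self):
        assert self.fam.log_predictive(BetaPrior(1, 1), 1) == pytest.approx(np.log(0.5))

    def test_conjugacy_identity_closed_form(self):
        from scipy.special import betaln

        prior = BetaPrior(2.0, 3.0)
        pts = [1, 0, 1, 1]

        def log_marginal(points):
            h = sum(points)
            return betaln(prior.a + h, prior.b + len(points) - h) - betaln(prior.a, prior.b)

        post = self.fam.posterior_update(prior, pts)
        for x in (0, 1):
            assert self.fam.log_predictive(post, x) == pytest.approx(
                log_marginal(pts + [x]) - log_marginal(pts), abs=1e-12
            )

    def test_normalization(self):
        hyper = BetaPrior(2.7, 0.4)
        total = sum(np.exp(self.fam.log_predictive(hyper, x)) for x in (0, 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_support(self):
        with pytest.raises(SupportError):
            self.fam.posterior_update(BetaPrior(1, 1), [2])


class TestBetaBinomial:
    fam = BinomialFamily(n_trials=5)

    def test_update(self):
        post = self.fam.posterior_update(BetaPrior(1, 1), [3, 5])
        assert (post.a, post.b) == (9, 3)

    def test_normalization(self):
        hyper = BetaPrior(1.4, 2.2)
        total = sum(np.exp(self.fam.log_predictive(hyper, x)) for x in range(6))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_against_quadrature(self):
        hyper = BetaPrior(2.0, 1.5)
        for x in (0, 2, 5):
            val, _ = integrate.quad(
                lambda p: stats.binom.pmf(x, 5, p) * stats.beta.pdf(p, hyper.a, hyper.b),
                0, 1,
            )
            assert self.fam.log_predictive(hyper, x) == pytest.approx(np.log(val), abs=1e-8)


class TestDirichletCategorical:
    fam = CategoricalFamily(n_levels=4)

    def test_update(self):
        post = self.fam.posterior_update(DirichletPrior(np.ones(4)), [0, 2, 2])
        np.testing.assert_array_equal(post.alpha, [2, 1, 3, 1])

    def test_normalization(self):
        hyper = DirichletPrior(np.array([0.4, 1.1, 2.0, 0.2]))
        total = sum(np.exp(self.fam.log_predictive(hyper, x)) for x in range(4))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(SupportError):
            self.fam.log_predictive(DirichletPrior(np.ones(4)), 4)


class TestGammaPoisson:
    fam = PoissonFamily()

    def test_update(self):
        post = self.fam.posterior_update(GammaPrior(1.0, 1.0), [3, 0, 2])
        assert (post.a, post.b) == (6.0, 4.0)

    def test_against_quadrature(self):
        # integrate Poisson(lambda) against Gamma(2, 1) numerically
        hyper = GammaPrior(2.0, 1.0)
        for x in (0, 1, 4):
            val, _ = integrate.quad(
                lambda lam: stats.poisson.pmf(x, lam) * stats.gamma.pdf(lam, 2.0, scale=1.0),
                0, 60,
            )
            assert self.fam.log_predictive(hyper, x) == pytest.approx(np.log(val), abs=1e-8)

    def test_zero_count_value(self):
        # Gamma(2,1) -> NB(r=2, p=1/2): P(0) = (1/2)^2
        assert self.fam.log_predictive(GammaPrior(2.0, 1.0), 0) == pytest.approx(np.log(0.25))

    def test_truncated_normalization(self):
        hyper = GammaPrior(3.0, 0.7)
        total = sum(np.exp(self.fam.log_predictive(hyper, x)) for x in range(400))
        assert total == pytest.approx(1.0, abs=1e-8)


class TestFullGaussian:
    fam = FullGaussianFamily()

    def test_empty_update_identity(self):
        prior = NIWPrior(np.zeros(2), 1.0, 4.0, np.eye(2))
        post = self.fam.posterior_update(prior, [])
        assert post is prior

    def test_posterior_parameters(self, rng):
        prior = NIWPrior(np.array([1.0, -1.0]), 2.0, 5.0, np.eye(2) * 2)
        pts = rng.normal(size=(6, 2))
        post = self.fam.posterior_update(prior, pts)
        assert post.kappa0 == pytest.approx(8.0)
        assert post.nu0 == pytest.approx(11.0)
        xbar = pts.mean(axis=0)
        np.testing.assert_allclose(post.m0, (2 * prior.m0 + 6 * xbar) / 8)

    def test_predictive_1d_dense_grid(self):
        # 1-D toy: integrate N(x | mu, s2) against the normal-inverse-
        # chi-squared posterior on a dense (mu, s2) grid and compare to
        # the closed-form Student-t at 1e-4 relative tolerance.
        prior = NIWPrior(np.array([0.3]), 1.5, 3.0, np.array([[0.8]]))
        m0, k0, n0, S0 = prior.m0[0], prior.kappa0, prior.nu0, prior.S0[0, 0]
        xs = [0.0, 1.2, -2.0]
        s2 = np.geomspace(1e-4, 2e4, 6000)  # heavy IG tail needs range
        mu = np.linspace(-400, 400, 8001)
        # inverse-gamma density for s2 with shape n0/2, scale S0/2
        ig = stats.invgamma.pdf(s2, n0 / 2, scale=S0 / 2)
        for x in xs:
            inner = np.empty_like(s2)
            for i, v in enumerate(s2):
                dens = stats.norm.pdf(mu, m0, np.sqrt(v / k0)) * stats.norm.pdf(x, mu, np.sqrt(v))
                inner[i] = np.trapezoid(dens, mu)
            val = np.trapezoid(inner * ig, s2)
            assert np.exp(self.fam.log_predictive(prior, [x])) == pytest.approx(val, rel=1e-4)

    def test_predictive_2d_monte_carlo(self, rng):
        prior = NIWPrior(np.array([0.0, 1.0]), 2.0, 6.0, np.array([[1.5, 0.4], [0.4, 1.0]]))
        x = np.array([0.5, 0.5])
        draws = 30_000
        sigmas = stats.invwishart.rvs(df=prior.nu0, scale=prior.S0, size=draws,
                                      random_state=np.random.RandomState(0))
        vals = np.empty(draws)
        for i in range(draws):
            mu = rng.multivariate_normal(prior.m0, sigmas[i] / prior.kappa0)
            vals[i] = stats.multivariate_normal.pdf(x, mu, sigmas[i])
        mc = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(draws)
        assert abs(np.exp(self.fam.log_predictive(prior, x)) - mc) < 4 * se

    def test_invariants(self):
        with pytest.raises(ValueError):
            NIWPrior(np.zeros(2), 1.0, 0.5, np.eye(2))  # nu0 <= D - 1
        with pytest.raises(ValueError):
            NIWPrior(np.zeros(2), -1.0, 4.0, np.eye(2))


class TestElliptical:
    def test_single_feature_equals_family(self):
        fam = BernoulliFamily()
        theta = BetaPrior(2, 1)
        assert elliptical_log_predictive([fam], [theta], [1]) == pytest.approx(
            fam.log_predictive(theta, 1)
        )

    def test_two_gaussians_sum(self):
        fam = SphericalGaussianFamily()
        t1 = SphericalGaussianPrior(np.array([0.0]), 1.0, 1.0)
        t2 = SphericalGaussianPrior(np.array([2.0]), 0.5, 1.0)
        lp = elliptical_log_predictive([fam, fam], [t1, t2], [0.3, 1.9])
        expect = fam.log_predictive(t1, [0.3]) + fam.log_predictive(t2, [1.9])
        assert lp == pytest.approx(expect)

    def test_all_missing_is_zero(self):
        fam = SphericalGaussianFamily()
        t = SphericalGaussianPrior(np.array([0.0]), 1.0, 1.0)
        assert elliptical_log_predictive([fam, fam], [t, t], [np.nan, np.nan]) == 0.0

    def test_length_mismatch(self):
        fam = BernoulliFamily()
        with pytest.raises(ValueError):
            elliptical_log_predictive([fam], [BetaPrior(1, 1)], [1, 0])


# ---------------------------------------------------------------------------
# Engine layer vs scalar layer
# ---------------------------------------------------------------------------


def mixed_schema_and_priors():
    schema = FeatureSchema(
        [
            Feature("g", "gaussian_full"),
            Feature("s", "gaussian_spherical"),
            Feature("b", "bernoulli"),
            Feature("o", "binomial", n_trials=4),
            Feature("c", "categorical", n_levels=3),
            Feature("p", "poisson"),
        ]
    )
    priors = [
        NIWPrior(np.array([0.0]), 1.0, 3.0, np.array([[1.0]])),
        SphericalGaussianPrior(np.array([0.0]), 2.0, 1.0),
        BetaPrior(1.0, 2.0),
        BetaPrior(0.5, 0.5),
        DirichletPrior(np.array([1.0, 2.0, 0.5])),
        GammaPrior(2.0, 1.0),
    ]
    return schema, priors


def random_mixed_rows(rng, n):
    return np.column_stack(
        [
            rng.normal(size=n),
            rng.normal(size=n),
            rng.integers(0, 2, n).astype(float),
            rng.integers(0, 5, n).astype(float),
            rng.integers(0, 3, n).astype(float),
            rng.poisson(3.0, n).astype(float),
        ]
    )


class TestEngines:
    def test_spherical_engine_matches_scalar(self, rng):
        prior = SphericalGaussianPrior(np.array([0.5, -0.5]), 1.7, 0.9)
        model = SphericalGaussianModel(prior)
        fam = SphericalGaussianFamily()
        X = rng.normal(size=(20, 2))
        z = rng.integers(0, 3, size=20)
        stats_obj = model.init_stats(X, z, 3)
        x = rng.normal(size=2)
        costs = model.costs(stats_obj, x)
        for k in range(3):
            post = fam.posterior_update(prior, X[z == k])
            assert costs[k] == pytest.approx(-fam.log_predictive(post, x), rel=1e-10)
        assert model.cost_prior(x) == pytest.approx(-fam.log_predictive(prior, x), rel=1e-10)

    def test_niw_engine_matches_scalar(self, rng):
        prior = NIWPrior(np.array([0.0, 0.0]), 1.3, 4.5, np.array([[2.0, 0.3], [0.3, 1.0]]))
        model = FullGaussianModel(prior)
        fam = FullGaussianFamily()
        X = rng.normal(size=(25, 2))
        z = rng.integers(0, 4, size=25)
        stats_obj = model.init_stats(X, z, 4)
        x = rng.normal(size=2)
        costs = model.costs(stats_obj, x)
        for k in range(4):
            post = fam.posterior_update(prior, X[z == k])
            assert costs[k] == pytest.approx(-fam.log_predictive(post, x), rel=1e-8)

    def test_elliptical_engine_matches_scalar(self, rng):
        schema, priors = mixed_schema_and_priors()
        model = EllipticalModel(schema, priors)
        X = random_mixed_rows(rng, 15)
        z = rng.integers(0, 2, size=15)
        stats_obj = model.init_stats(X, z, 2)
        x = random_mixed_rows(rng, 1)[0]
        costs = model.costs(stats_obj, x)
        fams = [family_for(f) for f in schema]
        for k in range(2):
            expect = 0.0
            for m, fam in enumerate(fams):
                pts = X[z == k, m]
                if schema[m].kind in ("gaussian_full", "gaussian_spherical"):
                    pts = pts[:, None]
                post = fam.posterior_update(priors[m], pts)
                val = x[m] if schema[m].kind not in ("gaussian_full", "gaussian_spherical") else [x[m]]
                expect += fam.log_predictive(post, val)
            assert costs[k] == pytest.approx(-expect, rel=1e-8)

    @pytest.mark.parametrize("which", ["spherical", "niw", "elliptical"])
    def test_remove_then_add_restores(self, rng, which):
        if which == "spherical":
            model = SphericalGaussianModel(SphericalGaussianPrior(np.zeros(2), 1.0, 1.0))
            X = rng.normal(size=(12, 2))
        elif which == "niw":
            model = FullGaussianModel(NIWPrior(np.zeros(2), 1.0, 4.0, np.eye(2)))
            X = rng.normal(size=(12, 2))
        else:
            schema, priors = mixed_schema_and_priors()
            model = EllipticalModel(schema, priors)
            X = random_mixed_rows(rng, 12)
        z = rng.integers(0, 2, size=12)
        stats_obj = model.init_stats(X, z, 2)
        before = {k: v.copy() for k, v in stats_obj.arrays.items()}
        for i in range(12):
            model.remove(stats_obj, int(z[i]), X[i])
            model.add(stats_obj, int(z[i]), X[i])
        for k, v in stats_obj.arrays.items():
            np.testing.assert_allclose(v, before[k], atol=1e-10)

    def test_incremental_equals_batch(self, rng):
        model = FullGaussianModel(NIWPrior(np.zeros(2), 1.0, 4.0, np.eye(2)))
        X = rng.normal(size=(30, 2))
        z = rng.integers(0, 3, size=30)
        incremental = model.init_stats(X[:1], z[:1] * 0, 1)
        for _ in range(2):
            model.new_cluster(incremental)
        for i in range(1, 30):
            model.add(incremental, int(z[i]), X[i])
        model.remove(incremental, 0, X[0])
        model.add(incremental, int(z[0]), X[0])
        batch = model.init_stats(X, z, 3)
        for name in batch.arrays:
            np.testing.assert_allclose(
                incremental.arrays[name][:3], batch.arrays[name][:3], atol=1e-8
            )

    def test_elliptical_nan_marginalized(self, rng):
        schema, priors = mixed_schema_and_priors()
        model = EllipticalModel(schema, priors)
        X = random_mixed_rows(rng, 10)
        z = np.zeros(10, dtype=int)
        stats_obj = model.init_stats(X, z, 1)
        x = random_mixed_rows(rng, 1)[0]
        full = model.costs(stats_obj, x)[0]
        x_missing = x.copy()
        x_missing[0] = np.nan
        partial = model.costs(stats_obj, x_missing)[0]
        assert partial != pytest.approx(full)
        # the dropped feature's contribution accounts for the difference
        fam = family_for(schema[0])
        post = fam.posterior_update(priors[0], X[:, :1])
        assert full - partial == pytest.approx(-fam.log_predictive(post, [x[0]]), rel=1e-8)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=40, deadline=None)
@given(
    points=st.lists(st.integers(0, 1), min_size=0, max_size=12),
    extra=st.integers(0, 1),
    a=st.floats(0.1, 5.0),
    b=st.floats(0.1, 5.0),
)
def test_beta_update_add_remove_property(points, extra, a, b):
    """Batch update equals incremental add; removing the point restores it."""
    fam = BernoulliFamily()
    prior = BetaPrior(a, b)
    base = fam.posterior_update(prior, points)
    together = fam.posterior_update(prior, points + [extra])
    incremental = fam.posterior_update(base, [extra])
    assert incremental.a == pytest.approx(together.a, abs=1e-10)
    assert incremental.b == pytest.approx(together.b, abs=1e-10)
    restored = BetaPrior(incremental.a - extra, incremental.b - (1 - extra))
    assert restored.a == pytest.approx(base.a, abs=1e-10)
    assert restored.b == pytest.approx(base.b, abs=1e-10)


@settings(max_examples=30, deadline=None)
@given(
    pts=st.lists(st.floats(-5, 5), min_size=0, max_size=8),
    x=st.floats(-5, 5),
    var0=st.floats(0.1, 4.0),
    var=st.floats(0.1, 4.0),
)
def test_spherical_predictive_finite_and_conjugate(pts, x, var0, var):
    fam = SphericalGaussianFamily()
    prior = SphericalGaussianPrior(np.array([0.0]), var0, var)
    post = fam.posterior_update(prior, [[p] for p in pts])
    lp = fam.log_predictive(post, [x])
    assert np.isfinite(lp)
    # one more point through either route gives the same posterior
    a = fam.posterior_update(post, [[x]])
    b = fam.posterior_update(prior, [[p] for p in pts] + [[x]])
    assert a.mu0[0] == pytest.approx(b.mu0[0], abs=1e-10)
    assert a.var0 == pytest.approx(b.var0, abs=1e-10)


class TestSchema:
    def test_roundtrip(self, tmp_path):
        schema, _ = mixed_schema_and_priors()
        path = tmp_path / "schema.yaml"
        import yaml

        path.write_text(yaml.safe_dump(schema.to_list()))
        loaded = FeatureSchema.from_file(path)
        assert loaded.names == schema.names
        assert [f.kind for f in loaded] == [f.kind for f in schema]

    def test_json_sidecar(self, tmp_path):
        import json

        path = tmp_path / "schema.json"
        path.write_text(json.dumps([{"name": "a", "kind": "poisson", "params": {}}]))
        loaded = FeatureSchema.from_file(path)
        assert loaded[0].kind == "poisson"

    def test_invalid_entries(self):
        with pytest.raises(ValueError):
            Feature("x", "gaussian")
        with pytest.raises(ValueError):
            Feature("x", "binomial")  # missing n_trials
        with pytest.raises(ValueError):
            Feature("x", "categorical", n_levels=1)
        with pytest.raises(ValueError):
            FeatureSchema([Feature("a", "poisson"), Feature("a", "bernoulli")])
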