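import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vpop import (
    Cohort,
    VariableSchema,
    build_rule,
    default_rules,
    discretize,
    fit,
    generate,
    make_cohort,
    sample_latent,
    smartool_like,
)
from vpop.errors import SchemaError, VpopError
from vpop.generator import DiscretizationRule, crv
from vpop.joint_model import FittedJointModel


class TestSampleLatent:
    def test_zero_draws_gives_empty(self):
        assert sample_latent(3, 0, seed=1).shape == (0, 3)

    def test_same_seed_is_deterministic(self):
        assert np.array_equal(sample_latent(4, 10, seed=9), sample_latent(4, 10, seed=9))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sample_latent(3, -1, seed=0)

    def test_standard_normal_moments(self):
        z = sample_latent(1, 100_000, seed=2)
        assert abs(z.mean()) < 0.02
        assert abs(z.std() - 1.0) < 0.02


class TestCriticalValues:
    def test_midpoint_rule_for_binary(self, toy_cohort):
        rule = build_rule("smoker", "midpoint", toy_cohort)
        assert rule.boundaries.tolist() == [1.5]

    def test_crv_at_median_is_exp_mu(self):
        assert crv(0.0, 1.0, 0.5) == pytest.approx(1.0)

    def test_crv_one_sigma_above(self):
        # NORMINV(0.8413...) = 1, so CrV = e^2
        assert crv(0.0, 2.0, 0.8413447460685429) == pytest.approx(
            np.exp(2.0), rel=1e-9
        )

    def test_quantile_rule_uses_empirical_proportions(self, toy_cohort):
        rule = build_rule("smoker", "lognormal_quantile", toy_cohort)
        logs = np.log([2.0, 1.0, 2.0])
        expected = crv(logs.mean(), logs.std(ddof=1), 1.0 / 3.0)
        assert rule.boundaries[0] == pytest.approx(expected)

    def test_quantile_rule_degenerate_for_unobserved_category(self):
        schemas = [VariableSchema(name="c", kind="categorical",
                                  categories=["a", "b"])]
        cohort = Cohort(schemas=schemas, values=np.ones((3, 1)),
                        mask=np.zeros((3, 1), dtype=bool))
        with pytest.raises(VpopError, match="zero observations"):
            build_rule("c", "lognormal_quantile", cohort)

    def test_continuous_variable_rejected(self, toy_cohort):
        with pytest.raises(SchemaError):
            build_rule("ldl", "midpoint", toy_cohort)


class TestDiscretize:
    RULE = DiscretizationRule(variable="x", method="midpoint",
                              boundaries=np.array([1.5]))

    def test_value_in_unit_window_maps_to_one(self):
        assert discretize(0.9, self.RULE) == 1

    def test_boundary_tie_goes_to_upper_code(self):
        assert discretize(1.5, self.RULE) == 2

    def test_lower_tail_clamped(self):
        assert discretize(-3.7, self.RULE) == 1

    @given(st.floats(min_value=0.5, max_value=1.4999999))
    @settings(deadline=None, max_examples=50)
    def test_whole_midpoint_window_maps_to_one(self, value):
        assert discretize(value, self.RULE) == 1

    @given(st.floats(min_value=-50, max_value=50))
    @settings(deadline=None, max_examples=100)
    def test_total_function_with_valid_code(self, value):
        rule = DiscretizationRule(variable="x", method="midpoint",
                                  boundaries=np.array([1.5, 2.5, 3.5]))
        assert discretize(value, rule) in (1, 2, 3, 4)


def _identity_model(p=2):
    schemas = [VariableSchema(name=f"x{j}", kind="continuous") for j in range(p)]
    return FittedJointModel(
        mu=np.zeros(p), sigma=np.eye(p), U=np.eye(p),
        Lambda=np.ones(p), K=np.eye(p), schemas=schemas, n_source=2,
    )


class TestGenerate:
    def test_degenerate_model_yields_exp_mu_exactly(self):
        p = 3
        schemas = [VariableSchema(name=f"x{j}", kind="continuous") for j in range(p)]
        mu = np.array([0.0, 1.0, 2.0])
        model = FittedJointModel(
            mu=mu, sigma=np.zeros((p, p)), U=np.eye(p),
            Lambda=np.zeros(p), K=np.zeros((p, p)), schemas=schemas, n_source=5,
        )
        cohort = generate(model, 7, seed=0)
        assert np.allclose(cohort.values, np.exp(mu)[np.newaxis, :])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            generate(_identity_model(), -1, seed=0)

    def test_every_value_finite_and_positive(self, source_model):
        cohort = generate(source_model, 500, seed=3)
        cont = [j for j, s in enumerate(cohort.schemas) if not s.is_categorical]
        assert np.isfinite(cohort.values).all()
        assert (cohort.values[:, cont] > 0).all()

    def test_same_seed_reproduces_cohort(self, source_model):
        assert generate(source_model, 50, seed=4) == generate(source_model, 50, seed=4)

    def test_log_space_covariance_recovered_at_10k(self, source_model):
        cohort = generate(source_model, 10_000, seed=5)
        cont = [j for j, s in enumerate(cohort.schemas) if not s.is_categorical]
        logs = np.log(cohort.values[:, cont])
        sample_sigma = np.cov(logs, rowvar=False)
        target = source_model.sigma[np.ix_(cont, cont)]
        bound = 5 * source_model.sigma.diagonal().max() / np.sqrt(10_000)
        assert np.max(np.abs(sample_sigma - target)) < bound


@pytest.fixture(scope="module")
def big_pair():
    """A large ground-truth draw and a regenerated cohort of equal size."""
    truth = smartool_like()
    source = make_cohort(truth, 10_000, seed=21)
    model = fit(source)
    quantile_rules = {
        s.name: build_rule(s.name, "lognormal_quantile", source)
        for s in source.schemas if s.is_categorical
    }
    virtual = generate(model, 10_000, seed=22, rules=quantile_rules)
    return source, virtual


class TestDistributionalRecovery:
    """Fit on a large ground-truth draw, regenerate, compare distributions."""

    def test_continuous_ks_below_noise_scale(self, big_pair):
        from vpop import ks_gof

        source, virtual = big_pair
        for s in source.schemas:
            if not s.is_categorical:
                assert ks_gof(source.column(s.name), virtual.column(s.name)) < 0.05

    def test_categorical_proportions_within_three_points(self, big_pair):
        source, virtual = big_pair
        for s in source.schemas:
            if s.is_categorical:
                for code in s.codes:
                    ps = (source.column(s.name) == code).mean()
                    pv = (virtual.column(s.name) == code).mean()
                    assert abs(ps - pv) < 0.03, s.name

    def test_strong_correlation_signs_preserved(self, big_pair):
        source, virtual = big_pair
        from vpop.core_data import encode
        from vpop.joint_model import log_transform

        def corr(c):
            return np.corrcoef(log_transform(*encode(c)), rowvar=False)

        rs, rv = corr(source), corr(virtual)
        strong = np.abs(rs) > 0.3
        np.fill_diagonal(strong, False)
        assert (np.sign(rs[strong]) == np.sign(rv[strong])).all()


def test_default_rules_cover_every_categorical(source_cohort):
    rules = default_rules(source_cohort)
    cats = {s.name for s in source_cohort.schemas if s.is_categorical}
    assert set(rules) == cats
    assert all(r.method == "midpoint" for r in rules.values())
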