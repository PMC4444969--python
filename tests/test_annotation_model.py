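"""Closed-form model computations: densities, posteriors, odds ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from funcscore import (
    AnnotationEntry,
    AnnotationMatrix,
    AnnotationSchema,
    ModelError,
    ModelParameters,
    class_log_density,
    group_posterior,
    marginal_odds_ratio,
    parameter_count,
    posterior_score,
    posterior_scores,
    simulate_dataset,
    validate_parameters,
)
from funcscore.synthetic_data import default_parameters

from conftest import naive_posterior, random_instance


def single_binary_params(pi=0.5, p0=0.2, p1=0.8):
    schema = AnnotationSchema((AnnotationEntry("b", "binary", "other"),))
    return ModelParameters(schema=schema, pi=pi, mu0=[], sigma0=[], mu1=[],
                           sigma1=[], p0=np.array([p0]), p1=np.array([p1]))


def single_continuous_params(pi=0.5, mu0=0.0, mu1=0.0, sigma=1.0):
    schema = AnnotationSchema((AnnotationEntry("c", "continuous", "conservation"),))
    return ModelParameters(schema=schema, pi=pi, mu0=np.array([mu0]),
                           sigma0=np.array([sigma]), mu1=np.array([mu1]),
                           sigma1=np.array([sigma]), p0=[], p1=[])


class TestSchema:
    @pytest.mark.parametrize("n_cont,n_bin,expected", [
        (2, 20, 49),   # the default layout
        (0, 0, 1),     # prior alone
        (1, 1, 7),
    ])
    def test_parameter_count(self, n_cont, n_bin, expected):
        entries = [AnnotationEntry(f"c{i}", "continuous", "conservation") for i in range(n_cont)]
        entries += [AnnotationEntry(f"b{i}", "binary", "other") for i in range(n_bin)]
        assert parameter_count(AnnotationSchema(tuple(entries))) == expected

    def test_default_schema_composition(self, default_schema):
        assert len(default_schema) == 22
        assert len(default_schema.group_names("conservation")) == 2
        assert len(default_schema.group_names("open_chromatin")) == 2
        assert len(default_schema.group_names("histone")) == 8
        assert len(default_schema.group_names("tfbs")) == 10
        assert default_schema.n_continuous == 2
        assert default_schema.n_binary == 20
        assert parameter_count(default_schema) == 49

    def test_duplicate_names_rejected(self):
        with pytest.raises(ModelError):
            AnnotationSchema((AnnotationEntry("x", "binary", "other"),
                              AnnotationEntry("x", "binary", "other")))


class TestClassLogDensity:
    def test_single_binary_positive(self):
        params = single_binary_params(p1=0.8)
        got = class_log_density(np.array([1.0]), np.array([True]), params, z=1)
        assert got == pytest.approx(math.log(0.8), rel=1e-12)

    def test_single_continuous_at_mean(self):
        params = single_continuous_params()
        got = class_log_density(np.array([0.0]), np.array([True]), params, z=0)
        assert got == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi)), rel=1e-12)

    def test_mixed_row_matches_per_term_product(self, mixed_params):
        from scipy.stats import norm
        row = np.array([0.7, 1.0, 0.0])
        mask = np.ones(3, dtype=bool)
        for z in (0, 1):
            mu = mixed_params.mu1 if z else mixed_params.mu0
            sd = mixed_params.sigma1 if z else mixed_params.sigma0
            p = mixed_params.p1 if z else mixed_params.p0
            oracle = (norm.pdf(0.7, mu[0], sd[0]) * p[0] * (1 - p[1]))
            got = class_log_density(row, mask, mixed_params, z)
            assert got == pytest.approx(math.log(oracle), rel=1e-12)

    def test_all_missing_row_errors(self, mixed_params):
        with pytest.raises(ModelError, match="observed"):
            class_log_density(np.zeros(3), np.zeros(3, dtype=bool), mixed_params, 0)

    def test_invalid_z_errors(self, mixed_params):
        with pytest.raises(ModelError, match="z must"):
            class_log_density(np.array([0.0, 1.0, 0.0]), np.ones(3, dtype=bool),
                              mixed_params, 2)


class TestPosterior:
    def test_symmetric_classes_return_prior(self):
        params = single_continuous_params(pi=0.5, mu0=1.0, mu1=1.0)
        assert posterior_score(np.array([3.0]), np.array([True]), params) == 0.5

    def test_single_binary_bayes(self):
        # 0.5*0.8 / (0.5*0.8 + 0.5*0.2)
        params = single_binary_params()
        got = posterior_score(np.array([1.0]), np.array([True]), params)
        assert got == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("pi,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_prior(self, pi, expected):
        params = single_binary_params(pi=pi)
        assert posterior_score(np.array([1.0]), np.array([True]), params) == expected

    def test_batch_matches_scalar_and_is_deterministic(self, mixed_params):
        row = np.array([0.3, 1.0, 1.0])
        values = np.tile(row, (5, 1))
        matrix = AnnotationMatrix(mixed_params.schema, values,
                                  np.ones_like(values, dtype=bool))
        scores = posterior_scores(matrix, mixed_params)
        scalar = posterior_score(row, np.ones(3, dtype=bool), mixed_params)
        assert np.all(scores == scores[0])
        assert scores[0] == scalar

    def test_separated_classes_give_high_auc(self):
        # means 4 SDs apart -> near-perfect ranking of true labels
        schema = AnnotationSchema((
            AnnotationEntry("c1", "continuous", "conservation"),
            AnnotationEntry("c2", "continuous", "conservation"),
        ))
        params = ModelParameters(schema=schema, pi=0.4,
                                 mu0=np.zeros(2), sigma0=np.ones(2),
                                 mu1=np.full(2, 4.0), sigma1=np.ones(2),
                                 p0=[], p1=[])
        ds = simulate_dataset(params, 10_000, seed=42)
        scores = posterior_scores(ds.matrix, params)
        from funcscore import evaluate_classification
        report = evaluate_classification(scores, ds.labels, cutoff=0.5)
        assert report.auc > 0.99

    def test_missing_policy_choice(self, mixed_params):
        # marginalize drops the cell; neutral-0 imputation scores it as 0
        values = np.array([[np.nan, 1.0, 0.0]])
        mask = np.array([[False, True, True]])
        matrix = AnnotationMatrix(mixed_params.schema, values, mask)
        marg = posterior_scores(matrix, mixed_params)[0]
        imputed = posterior_scores(matrix.impute_neutral_zero(), mixed_params)[0]
        zero_row = AnnotationMatrix(mixed_params.schema,
                                    np.array([[0.0, 1.0, 0.0]]),
                                    np.ones((1, 3), dtype=bool))
        assert imputed == posterior_scores(zero_row, mixed_params)[0]
        assert marg != imputed


class TestGroupPosterior:
    def test_full_subset_equals_posterior(self, mixed_params):
        row = np.array([0.2, 1.0, 0.0])
        mask = np.ones(3, dtype=bool)
        full = group_posterior(row, mask, mixed_params, ["cons", "peakA", "peakB"])
        assert full == posterior_score(row, mask, mixed_params)

    def test_single_binary_subset(self):
        schema = AnnotationSchema((AnnotationEntry("c", "continuous", "conservation"),
                                   AnnotationEntry("b", "binary", "other")))
        params = ModelParameters(schema=schema, pi=0.5,
                                 mu0=np.array([0.0]), sigma0=np.array([1.0]),
                                 mu1=np.array([2.0]), sigma1=np.array([1.0]),
                                 p0=np.array([0.2]), p1=np.array([0.8]))
        got = group_posterior(np.array([5.0, 1.0]), np.ones(2, dtype=bool),
                              params, ["b"])
        assert got == pytest.approx(0.8, abs=1e-12)

    def test_group_decomposition_in_range(self, default_params):
        ds = simulate_dataset(default_params, 1, seed=5)
        row, mask = ds.matrix.row(0)
        schema = default_params.schema
        for group in ("conservation", "open_chromatin", "histone", "tfbs"):
            p = group_posterior(row, mask, default_params,
                                schema.group_names(group))
            assert 0.0 <= p <= 1.0

    def test_errors(self, mixed_params):
        row = np.array([0.2, 1.0, 0.0])
        mask = np.ones(3, dtype=bool)
        with pytest.raises(ModelError):
            group_posterior(row, mask, mixed_params, [])
        with pytest.raises(ModelError):
            group_posterior(row, mask, mixed_params, ["nope"])


class TestOddsRatio:
    def test_uninformative_is_one(self):
        params = single_binary_params(p0=0.4, p1=0.4)
        assert marginal_odds_ratio(params, "b") == 1.0

    def test_near_uninformative_histone_mark(self, default_params):
        # p1=0.80, p0=0.72 -> (0.80*0.28)/(0.72*0.20) = 14/9
        got = marginal_odds_ratio(default_params, "H3K27me3")
        assert got == pytest.approx(14.0 / 9.0, abs=1e-9)

    def test_strong_annotation(self):
        params = single_binary_params(p0=0.1, p1=0.9)
        assert marginal_odds_ratio(params, "b") == pytest.approx(81.0, rel=1e-12)

    def test_continuous_name_rejected(self, mixed_params):
        with pytest.raises(ModelError):
            marginal_odds_ratio(mixed_params, "cons")

    def test_posterior_odds_consistency(self):
        """Posterior odds(y=1) / odds(y=0) equals the marginal odds ratio."""
        params = single_binary_params(pi=0.3, p0=0.25, p1=0.6)
        mask = np.array([True])
        s1 = posterior_score(np.array([1.0]), mask, params)
        s0 = posterior_score(np.array([0.0]), mask, params)
        odds_ratio = (s1 / (1 - s1)) / (s0 / (1 - s0))
        assert odds_ratio == pytest.approx(marginal_odds_ratio(params, "b"), rel=1e-12)


class TestValidation:
    def test_default_params_valid(self, default_params, default_schema):
        assert validate_parameters(default_params, default_schema) == []

    def test_zero_sigma_named(self, mixed_params, mixed_schema):
        bad = ModelParameters(schema=mixed_schema, pi=mixed_params.pi,
                              mu0=mixed_params.mu0, sigma0=mixed_params.sigma0,
                              mu1=mixed_params.mu1, sigma1=np.array([0.0]),
                              p0=mixed_params.p0, p1=mixed_params.p1)
        report = validate_parameters(bad, mixed_schema)
        assert any("cons" in line and "sigma1" in line for line in report)

    def test_count_mismatch_reported(self, default_schema):
        short = ModelParameters(schema=default_schema, pi=0.4,
                                mu0=np.zeros(2), sigma0=np.ones(2),
                                mu1=np.zeros(2), sigma1=np.ones(2),
                                p0=np.full(19, 0.2), p1=np.full(20, 0.6))
        report = validate_parameters(short, default_schema)
        assert any("expected 20" in line for line in report)


class TestSerialization:
    def test_roundtrip_bit_exact(self, tmp_path, default_params):
        # perturb to awkward decimal representations
        params = default_params.with_pi(0.4271828182845905)
        path = tmp_path / "params.txt"
        params.save(path)
        back = ModelParameters.load(path)
        assert back.pi == params.pi
        for f in ("mu0", "sigma0", "mu1", "sigma1", "p0", "p1"):
            np.testing.assert_array_equal(getattr(back, f), getattr(params, f))
        assert back.schema.names == params.schema.names
        assert back.schema.kinds == params.schema.kinds


class TestProperties:
    @settings(derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_posterior_bounds_and_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        _, params, row, mask = random_instance(rng)
        got = posterior_score(row, mask, params)
        assert 0.0 <= got <= 1.0
        expected = naive_posterior(row, mask, params)
        assert got == pytest.approx(expected, rel=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_posterior_monotone_in_pi(self, seed):
        rng = np.random.default_rng(seed)
        _, params, row, mask = random_instance(rng)
        pis = np.sort(rng.uniform(0.01, 0.99, size=5))
        scores = [posterior_score(row, mask, params.with_pi(pi)) for pi in pis]
        assert np.all(np.diff(scores) >= -1e-15)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_masking_equals_schema_dropping(self, seed):
        """Marginalizing an annotation out is the same as removing it."""
        rng = np.random.default_rng(seed)
        schema, params, row, mask = random_instance(rng, n_cont=2, n_bin=2)
        mask = np.ones(4, dtype=bool)
        drop = int(rng.integers(0, 4))
        masked = mask.copy()
        masked[drop] = False
        keep_names = [n for i, n in enumerate(schema.names) if i != drop]
        sub_params = params.subset(keep_names)
        sub_row = np.delete(row, drop)
        got_masked = posterior_score(row, masked, params)
        got_dropped = posterior_score(sub_row, np.ones(3, dtype=bool), sub_params)
        assert got_masked == pytest.approx(got_dropped, rel=1e-12)

    def test_prior_recovered_when_uninformative(self):
        params = single_binary_params(pi=0.37, p0=0.5, p1=0.5)
        assert posterior_score(np.array([1.0]), np.array([True]), params) == \
            pytest.approx(0.37, abs=1e-15)


class TestMatrixValidation:
    def test_missing_binary_rejected(self, mixed_schema):
        values = np.array([[0.0, np.nan, 1.0]])
        mask = np.array([[True, False, True]])
        with pytest.raises(ModelError, match="binary"):
            AnnotationMatrix(mixed_schema, values, mask)

    def test_nonbinary_value_rejected(self, mixed_schema):
        values = np.array([[0.0, 0.5, 1.0]])
        with pytest.raises(ModelError, match="0/1"):
            AnnotationMatrix(mixed_schema, values, np.ones((1, 3), dtype=bool))

    def test_default_parameters_count(self, default_params, default_schema):
        assert parameter_count(default_schema) == 49
        assert len(default_params.p0) == 20 and len(default_params.mu0) == 2
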