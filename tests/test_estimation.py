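"""Fitting, goodness of fit, standard errors and model comparison."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from lineup2ht import (
    FIXTURE_NAMES,
    GroupParameters,
    LineupCounts,
    ModelSpec,
    NotNestedError,
    TwoHTModel,
    category_probabilities,
    expected_frequencies,
    g_squared,
    likelihood_ratio_test,
    load_fixture,
    saturated_spec,
)
from oracles import direct_g2, finite_difference_hessian, grid_min_g2


def single_condition(cp, ca, k=6, cond="a"):
    return [LineupCounts(cond, k, *cp, *ca)]


class TestGSquared:
    def test_zero_when_observed_equals_expected(self):
        assert g_squared([30, 20, 10], [30, 20, 10]) == 0.0

    def test_matches_direct_evaluation(self):
        # 2 * (30 ln(30/25) + 20 ln(20/25)) evaluated independently
        assert g_squared([30, 20], [25, 25]) == pytest.approx(2.0136, abs=5e-4)
        assert g_squared([30, 20], [25, 25]) == pytest.approx(
            direct_g2([30, 20], [25, 25]), abs=1e-12
        )

    def test_zero_observed_categories_contribute_nothing(self):
        assert g_squared([30, 0], [25, 5]) == pytest.approx(
            2 * 30 * np.log(30 / 25), abs=1e-12
        )

    def test_positive_observed_with_zero_expected_is_infinite(self):
        assert g_squared([30, 1], [31, 0]) == float("inf")


class TestFitting:
    def test_saturated_fit_recovers_generating_parameters_exactly(self):
        # counts are exact expected frequencies at (dP=.5, b=.2, g=.5, dA=.1)
        theta = GroupParameters(dP=0.5, b=0.2, g=0.5, dA=0.1)
        expected = expected_frequencies(category_probabilities(theta, 6), 300, 100)
        assert np.allclose(expected, np.round(expected))  # integers by design
        data = single_condition(expected[:3].astype(int), expected[3:].astype(int))
        result = TwoHTModel(data).fit()
        assert result.g_squared <= 1e-8
        assert result.df == 0
        for name, truth in [("dP_a", 0.5), ("b_a", 0.2), ("g_a", 0.5), ("dA_a", 0.1)]:
            assert result.estimates[name] == pytest.approx(truth, abs=1e-6)

    def test_zero_g2_means_expected_equals_observed(self):
        data = single_condition((60, 20, 20), (10, 30, 60))
        result = TwoHTModel(data).fit()
        assert result.g_squared <= 1e-8
        np.testing.assert_allclose(
            result.expected()["a"], data[0].observed(), atol=1e-6
        )

    def test_saturated_estimates_match_moment_equation_oracle(self):
        # with G2 = 0 the estimates solve the moment equations; solve those
        # independently with a root finder and compare
        data = single_condition((60, 20, 20), (10, 30, 60))
        result = TwoHTModel(data).fit()

        def equations(x):
            dP, b, g, dA = x
            k = 6.0
            return [
                dP + (1 - dP) * b + (1 - dP) * (1 - b) * g / k - 0.6,
                (1 - dP) * (1 - b) * g * (k - 1) / k - 0.2,
                (1 - dA) * b + (1 - dA) * (1 - b) * g / k - 0.1,
                (1 - dA) * (1 - b) * g * (k - 1) / k - 0.3,
            ]

        oracle = fsolve(equations, [0.5, 0.1, 0.5, 0.3], full_output=False)
        for name, value in zip(("dP_a", "b_a", "g_a", "dA_a"), oracle):
            assert result.estimates[name] == pytest.approx(value, abs=1e-3)

    @pytest.mark.parametrize(
        "cp, ca",
        [
            ((60, 20, 20), (10, 30, 60)),
            ((50, 40, 30), (20, 60, 80)),
            ((90, 5, 25), (15, 25, 100)),
        ],
    )
    def test_fit_attains_grid_search_minimum(self, cp, ca):
        """The ML fit is at least as good as a 0.005-step grid scan."""
        result = TwoHTModel(single_condition(cp, ca)).fit(compute_se=False)
        oracle = grid_min_g2(cp, ca, k=6, step=0.005)
        assert result.g_squared <= oracle + 1e-3

    def test_em_loglikelihood_monotone_on_fixtures(self):
        for name in FIXTURE_NAMES:
            fixture = load_fixture(name)
            model = TwoHTModel(fixture.data, fixture.comparison_spec)
            _, _, _, _, trajectory = model._compiled.run_em(
                model._heuristic_start(), max_iter=2000, trace=True
            )
            diffs = np.diff(trajectory)
            assert diffs.min() >= -1e-10, name

    def test_em_loglikelihood_monotone_on_random_instances(self):
        rng = np.random.default_rng(20220804)
        for i in range(100):
            theta = GroupParameters(*rng.uniform(0.05, 0.95, 4))
            k = int(rng.choice([2, 5, 6, 8]))
            probs = category_probabilities(theta, k)
            n_cp, n_ca = rng.integers(20, 200, 2)
            cp = rng.multinomial(n_cp, probs.p_cp)
            ca = rng.multinomial(n_ca, probs.p_ca)
            model = TwoHTModel(single_condition(cp, ca, k=k))
            start = rng.uniform(0.05, 0.95, 4)
            _, _, _, _, trajectory = model._compiled.run_em(
                start, max_iter=1000, trace=True
            )
            diffs = np.diff(trajectory)
            assert diffs.min() >= -1e-10, f"instance {i}"

    def test_em_agrees_with_quasi_newton_on_all_fixtures(self, study_fits):
        for name, entry in study_fits.items():
            gap = entry["comparison"].diagnostics["em_optimizer_gap"]
            assert gap < 1e-4, name

    def test_restricted_never_beats_general(self, study_fits):
        for name, entry in study_fits.items():
            g_general = entry["comparison"].g_squared
            for rname, rfit in entry["restricted"].items():
                assert rfit.g_squared >= g_general - 1e-6, (name, rname)

    def test_nonconvergence_is_flagged(self):
        data = single_condition((60, 20, 20), (10, 30, 60))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            result = TwoHTModel(data).fit(
                max_iter=1, n_restarts=0, cross_check=False, compute_se=False
            )
        assert not result.converged

    def test_p_value_and_statistic_ranges(self, study_fits):
        for entry in study_fits.values():
            fit = entry["comparison"]
            assert fit.g_squared >= 0
            assert fit.df >= 0
            assert 0.0 <= fit.p_value <= 1.0


class TestStandardErrors:
    def test_match_finite_difference_hessian_oracle(self):
        data = single_condition((60, 20, 20), (10, 30, 60))
        model = TwoHTModel(data)
        result = model.fit()

        info = -finite_difference_hessian(model.loglike, result.params, h=1e-4)
        oracle = np.sqrt(np.diag(np.linalg.inv(info)))
        for name, se in zip(model.free_parameters, oracle):
            assert result.standard_errors[name] == pytest.approx(se, abs=1e-4)

    def test_fixed_parameters_have_no_se_entry(self):
        data = single_condition((60, 20, 20), (10, 30, 60))
        spec = saturated_spec(["a"]).restrict(fix={"dA_a": 0.0})
        result = TwoHTModel(data, spec).fit()
        assert "dA_a" not in result.standard_errors
        assert set(result.standard_errors) == set(spec.free_parameters)

    def test_boundary_estimates_are_flagged_but_reported(self, study_fits):
        result = study_fits["memon2003"]["comparison"]
        assert result.boundary["dA"]  # dA converges to 0 for these data
        assert np.isfinite(result.standard_errors["dA"])
        assert not result.boundary["g_long"]


class TestIdentifiability:
    def test_saturated_single_condition_has_full_rank(self):
        data = single_condition((60, 20, 20), (10, 30, 60))
        result = TwoHTModel(data).fit(compute_se=False)
        report = result.identifiability()
        assert report["rank"] == 4 and report["identifiable"]

    def test_memon_spec_is_identified_at_its_solution(self, study_fits):
        report = study_fits["memon2003"]["comparison"].identifiability()
        assert report["rank"] == report["n_free"] == 6

    def test_rank_deficiency_is_flagged(self):
        # condition "a" has only culprit-absent observations, so its private
        # dP_a never enters any observable category: the Jacobian column for
        # dP_a is zero and the model is not locally identifiable
        data = [
            LineupCounts("a", 6, 0, 0, 0, 10, 30, 60),
            LineupCounts("b", 6, 60, 20, 20, 10, 30, 60),
        ]
        spec = ModelSpec(
            conditions=("a", "b"),
            bind={
                ("a", "dP"): "dP_a",
                ("b", "dP"): "dP_b",
                ("a", "b"): "b",
                ("b", "b"): "b",
                ("a", "g"): "g",
                ("b", "g"): "g",
                ("a", "dA"): "dA",
                ("b", "dA"): "dA",
            },
        )
        model = TwoHTModel(data, spec)
        report = model.identifiability_check([0.5, 0.5, 0.2, 0.5, 0.3])
        assert report["rank"] < report["n_free"]
        assert not report["identifiable"]


class TestLikelihoodRatio:
    def test_comparing_a_fit_with_itself_is_refused(self, study_fits):
        fit = study_fits["smith2014"]["comparison"]
        with pytest.raises(NotNestedError, match="ddf"):
            likelihood_ratio_test(fit, fit)

    def test_non_nested_specs_are_refused(self, study_fits):
        entry = study_fits["memon2003"]
        general = entry["comparison"]
        restricted = entry["restricted"]["equal_dP"]
        with pytest.raises(NotNestedError):
            likelihood_ratio_test(general, restricted)  # arguments swapped

    def test_mismatched_data_is_refused(self, study_fits):
        memon = study_fits["memon2003"]["restricted"]["equal_dP"]
        smith = study_fits["smith2014"]["comparison"]
        with pytest.raises(ValueError, match="identical data"):
            likelihood_ratio_test(memon, smith)

    def test_delta_statistics_are_consistent(self, study_fits):
        entry = study_fits["karageorge_zajac"]
        lr = likelihood_ratio_test(entry["restricted"]["equal_dA"], entry["comparison"])
        assert lr.delta_df == 1
        assert lr.delta_g_squared == pytest.approx(
            entry["restricted"]["equal_dA"].g_squared
            - entry["comparison"].g_squared,
            abs=1e-9,
        )
        assert 0.0 <= lr.p_value <= 1.0
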