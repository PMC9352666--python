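"""Tree equations: category probabilities and expected frequencies."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lineup2ht import (
    CategoryProbabilities,
    GroupParameters,
    category_probabilities,
    expected_frequencies,
)
from oracles import path_enumeration_probs

probability = st.floats(0.0, 1.0, allow_nan=False)


def probs(dP, b, g, dA, k):
    return category_probabilities(GroupParameters(dP=dP, b=b, g=g, dA=dA), k)


class TestCategoryProbabilities:
    @pytest.mark.parametrize(
        "theta, k, expected_cp, expected_ca",
        [
            # no detection, no selection: certain rejection in both trees
            ((0, 0, 0, 0), 6, (0, 0, 1), (0, 0, 1)),
            # certain detection of presence and of absence
            ((1, 0, 0, 1), 6, (1, 0, 0), (0, 0, 1)),
            # pure guessing lands on the suspect 1/k of the time
            ((0, 0, 1, 0), 6, (1 / 6, 5 / 6, 0), (1 / 6, 5 / 6, 0)),
        ],
    )
    def test_degenerate_parameter_corners(self, theta, k, expected_cp, expected_ca):
        p = probs(*theta, k)
        np.testing.assert_allclose(p.p_cp, expected_cp, atol=1e-15)
        np.testing.assert_allclose(p.p_ca, expected_ca, atol=1e-15)

    def test_interior_point_against_enumeration_oracle(self):
        # frozen values computed by summing branch products over all
        # root-to-leaf paths at (dP=.5, b=.2, g=.5, dA=.1), k=6
        p = probs(0.5, 0.2, 0.5, 0.1, 6)
        np.testing.assert_allclose(
            p.p_cp, (0.633333333333, 0.166666666667, 0.2), atol=1e-12
        )
        np.testing.assert_allclose(p.p_ca, (0.24, 0.30, 0.46), atol=1e-12)

    def test_agrees_with_enumeration_oracle_on_grid(self):
        values = np.linspace(0.0, 1.0, 5)
        for k in (2, 5, 6, 8):
            for dP in values:
                for b in values:
                    for g in values:
                        for dA in values:
                            p = probs(dP, b, g, dA, k)
                            p_cp, p_ca = path_enumeration_probs(dP, b, g, dA, k)
                            np.testing.assert_allclose(p.p_cp, p_cp, atol=1e-12)
                            np.testing.assert_allclose(p.p_ca, p_ca, atol=1e-12)

    @given(probability, probability, probability, probability, st.integers(2, 12))
    def test_each_tree_sums_to_one(self, dP, b, g, dA, k):
        p = probs(dP, b, g, dA, k)
        assert abs(sum(p.p_cp) - 1.0) < 1e-12
        assert abs(sum(p.p_ca) - 1.0) < 1e-12
        assert all(0.0 <= x <= 1.0 for x in p.p_cp + p.p_ca)

    def test_culprit_identification_monotone_in_dp_b_g(self):
        grid = np.linspace(0.0, 1.0, 11)
        base = dict(dP=0.3, b=0.2, g=0.4, dA=0.3)
        for moving in ("dP", "b", "g"):
            series = [
                probs(**{**base, moving: v}, k=6).p_cp[0] for v in grid
            ]
            assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(series, series[1:]))
        rejections = [probs(**{**base, "dA": v}, k=6).p_ca[2] for v in grid]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(rejections, rejections[1:]))

    @given(probability, probability, st.integers(2, 10))
    def test_one_high_threshold_variant(self, b, g, k):
        """dA = 0 reduces the culprit-absent tree to b + (1-b) g / k."""
        p = probs(0.7, b, g, 0.0, k)
        assert abs(p.p_ca[0] - (b + (1 - b) * g / k)) < 1e-12

    @pytest.mark.parametrize(
        "bad_call",
        [
            lambda: probs(0.5, 0.5, 0.5, 0.5, 1),
            lambda: probs(1.5, 0.5, 0.5, 0.5, 6),
            lambda: probs(0.5, -0.1, 0.5, 0.5, 6),
        ],
    )
    def test_invalid_inputs_rejected(self, bad_call):
        with pytest.raises(ValueError):
            bad_call()


class TestExpectedFrequencies:
    def test_scales_probabilities_by_tree_totals(self):
        p = CategoryProbabilities(p_cp=(1, 0, 0), p_ca=(1 / 6, 5 / 6, 0))
        expected = expected_frequencies(p, n_cp=21, n_ca=60)
        np.testing.assert_allclose(expected, [21, 0, 0, 10, 50, 0], atol=1e-12)

    def test_interior_point_scaling(self):
        p = probs(0.5, 0.2, 0.5, 0.1, 6)
        expected = expected_frequencies(p, 100, 100)
        np.testing.assert_allclose(
            expected, [63.3333, 16.6667, 20.0, 24.0, 30.0, 46.0], atol=1e-3
        )
        assert abs(expected[:3].sum() - 100) < 1e-9
        assert abs(expected[3:].sum() - 100) < 1e-9

    def test_negative_totals_rejected(self):
        p = probs(0.5, 0.2, 0.5, 0.1, 6)
        with pytest.raises(ValueError):
            expected_frequencies(p, -1, 10)
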