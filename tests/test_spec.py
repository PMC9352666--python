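"""Model specifications, parameter binding and degrees-of-freedom accounting."""

import pytest

from lineup2ht import (
    LineupCounts,
    ModelSpec,
    degrees_of_freedom,
    free_parameter_count,
    independent_category_count,
    load_fixture,
    saturated_spec,
)


def two_condition_spec(**overrides):
    bind = {
        ("a", "dP"): "dP_a",
        ("b", "dP"): "dP_b",
        ("a", "g"): "g",
        ("b", "g"): "g",
        ("a", "b"): "b",
        ("b", "b"): "b",
        ("a", "dA"): "dA",
        ("b", "dA"): "dA",
    }
    bind.update(overrides.pop("bind", {}))
    return ModelSpec(conditions=("a", "b"), bind=bind, **overrides)


class TestModelSpecStructure:
    def test_every_slot_must_be_bound_exactly_once(self):
        with pytest.raises(ValueError, match="unbound"):
            ModelSpec(conditions=("a",), bind={("a", "dP"): "dP"})
        with pytest.raises(ValueError, match="both bound and fixed"):
            ModelSpec(
                conditions=("a",),
                bind={("a", p): p for p in ("dP", "b", "g", "dA")},
                fix={("a", "dA"): 0.0},
            )

    def test_fixed_constants_must_be_probabilities(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ModelSpec(
                conditions=("a",),
                bind={("a", p): p for p in ("dP", "b", "g")},
                fix={("a", "dA"): 1.5},
            )

    def test_one_high_threshold_variant_via_fixing(self):
        spec = two_condition_spec().restrict(fix={"dA": 0.0})
        assert spec.n_free == 4
        assert spec.fix[("a", "dA")] == 0.0
        assert spec.is_nested_in(two_condition_spec())

    def test_json_round_trip(self, tmp_path):
        spec = two_condition_spec(description="shared g, b, dA")
        path = tmp_path / "spec.json"
        spec.to_json(path)
        loaded = ModelSpec.from_json(path)
        assert loaded == spec

    def test_from_dict_reports_missing_keys(self):
        with pytest.raises(ValueError, match="conditions"):
            ModelSpec.from_dict({"bind": {}})


class TestNesting:
    def test_merge_restriction_is_nested(self):
        general = two_condition_spec()
        restricted = general.restrict(merge={"dP": ["dP_a", "dP_b"]})
        assert restricted.n_free == general.n_free - 1
        assert restricted.is_nested_in(general)
        assert not general.is_nested_in(restricted)

    def test_splitting_a_shared_parameter_is_not_nested(self):
        shared_g = two_condition_spec()
        split_g = two_condition_spec(bind={("a", "g"): "g_a", ("b", "g"): "g_b"})
        assert shared_g.is_nested_in(split_g)
        assert not split_g.is_nested_in(shared_g)

    def test_fixture_restrictions_are_nested_in_comparison(self):
        for name in ("memon2003", "colloff", "wilcock_bull"):
            fixture = load_fixture(name)
            for spec in fixture.restriction_specs.values():
                assert spec.is_nested_in(fixture.comparison_spec)

    def test_unknown_parameter_in_restrict(self):
        with pytest.raises(KeyError):
            two_condition_spec().restrict(merge={"x": ["nope"]})


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "name, expected_df",
        [
            ("memon2003", 10),
            ("smith2014", 2),
            ("wetmore", 9),
            ("colloff", 9),
            ("malpass_devine", 2),
            ("lampinen", 6),
            ("karageorge_zajac", 1),
            ("wilcock_bull", 1),
        ],
    )
    def test_comparison_specs_reproduce_published_df(self, name, expected_df):
        fixture = load_fixture(name)
        df = degrees_of_freedom(fixture.comparison_spec, fixture.data)
        assert df == expected_df

    def test_saturated_model_has_zero_df(self):
        data = [LineupCounts("a", 6, 10, 5, 5, 3, 7, 10)]
        spec = saturated_spec(["a"])
        assert free_parameter_count(spec) == 4
        assert independent_category_count(data) == 4
        assert degrees_of_freedom(spec, data) == 0

    def test_empty_tree_contributes_no_categories(self):
        data = [LineupCounts("a", 6, 0, 0, 0, 3, 7, 10)]
        assert independent_category_count(data) == 2

    def test_strict_df_subtracts_reconstructed_categories(self):
        fixture = load_fixture("memon2003")  # four reconstructed CA trees
        lax = degrees_of_freedom(fixture.comparison_spec, fixture.data)
        strict = degrees_of_freedom(
            fixture.comparison_spec, fixture.data, strict_df=True
        )
        assert lax - strict == 4

    def test_condition_mismatch_raises(self):
        fixture = load_fixture("smith2014")
        with pytest.raises(ValueError, match="do not match"):
            degrees_of_freedom(fixture.comparison_spec, fixture.data[::-1])
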