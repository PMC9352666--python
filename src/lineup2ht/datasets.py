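"""Bundled frequency tables and model specs for eight published lineup studies.

Each fixture carries the per-condition 2 x 3 frequency tables of one
eyewitness identification experiment, the comparison-standard model used
as the baseline for hypothesis tests, one restricted spec per equality
restriction of interest, and the published reference numbers (G², ΔG²,
parameter estimates and standard errors) for side-by-side reproduction
reports.

Data-reconstruction conventions used by several of the fixtures:

* Studies without a designated innocent suspect report only the pooled
  number of false identifications in culprit-absent lineups; the
  innocent-suspect count is estimated as that total divided by the lineup
  size (rounded half up) and the filler count as the remainder
  (`split_false_identifications`).
* When per-condition sample sizes are unreported, the total sample is
  divided equally across conditions (`equal_cell_counts`).

The frequencies are stored as literal integers exactly as published; they
are not re-derived at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .spec import ModelSpec
from .trees import PARAM_NAMES, LineupCounts

__all__ = [
    "Fixture",
    "FIXTURE_NAMES",
    "load_fixture",
    "split_false_identifications",
    "equal_cell_counts",
]


def split_false_identifications(
    total_false: int, lineup_size: int
) -> tuple[int, int]:
    """Split pooled culprit-absent false identifications into suspect/filler.

    The innocent-suspect count is ``total_false / lineup_size`` rounded
    half up (a fair lineup gives each member the same chance of being
    picked); the filler count is the remainder.
    """
    if total_false < 0:
        raise ValueError("total_false must be non-negative")
    if lineup_size < 2:
        raise ValueError("lineup_size must be >= 2")
    suspect = (2 * total_false + lineup_size) // (2 * lineup_size)
    return int(suspect), int(total_false - suspect)


def equal_cell_counts(total_n: int, n_conditions: int) -> int:
    """Per-condition sample size under equal assignment to conditions."""
    if total_n < 0 or n_conditions < 1:
        raise ValueError("totals and condition counts must be positive")
    if total_n % n_conditions:
        raise ValueError(
            f"total n = {total_n} is not divisible by {n_conditions} conditions; "
            "supply explicit per-condition counts"
        )
    return total_n // n_conditions


@dataclass(frozen=True)
class Fixture:
    """One study's data, model specs and published reference values."""

    name: str
    data: tuple[LineupCounts, ...]
    comparison_spec: ModelSpec
    restriction_specs: Mapping[str, ModelSpec]
    provenance: str
    published: Mapping = field(default_factory=dict)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(d.condition_id for d in self.data)


def _spec(
    conditions: Sequence[str],
    layout: Mapping[str, Mapping[str, str] | str],
    description: str,
) -> ModelSpec:
    """Build a spec from a per-parameter layout.

    ``layout[param]`` is either one shared free-parameter name or a map
    from condition to free-parameter name.
    """
    bind = {}
    for param in PARAM_NAMES:
        entry = layout[param]
        for cond in conditions:
            bind[(cond, param)] = entry if isinstance(entry, str) else entry[cond]
    return ModelSpec(conditions=tuple(conditions), bind=bind, description=description)


def _counts(rows, lineup_size, ca_reconstructed):
    return tuple(
        LineupCounts(cond, lineup_size, *cells, ca_reconstructed=ca_reconstructed)
        for cond, cells in rows
    )


def _memon2003() -> Fixture:
    # age (younger/older) x exposure duration (long/short); n = 21 per
    # younger cell (84 / 4) and 20 per older cell (80 / 4); culprit-absent
    # suspect/filler splits reconstructed by the 1/6 rule.
    data = _counts(
        [
            ("younger_long", (20, 1, 0, 2, 7, 12)),
            ("younger_short", (6, 9, 6, 3, 16, 2)),
            ("older_long", (17, 2, 1, 2, 8, 10)),
            ("older_short", (7, 9, 4, 3, 13, 4)),
        ],
        lineup_size=6,
        ca_reconstructed=True,
    )
    conditions = [d.condition_id for d in data]
    layout = {
        "dP": {
            "younger_long": "dP_long",
            "older_long": "dP_long",
            "younger_short": "dP_short",
            "older_short": "dP_short",
        },
        "g": {
            "younger_long": "g_long",
            "older_long": "g_long",
            "younger_short": "g_short",
            "older_short": "g_short",
        },
        "b": "b",
        "dA": "dA",
    }
    comparison = _spec(
        conditions,
        layout,
        "Memon et al. comparison standard: dP and g per exposure duration, "
        "b and dA shared",
    )
    restrictions = {
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_long", "dP_short"]},
            description="dP equal across exposure durations",
        ),
        "equal_g": comparison.restrict(
            merge={"g": ["g_long", "g_short"]},
            description="g equal across exposure durations",
        ),
    }
    published = {
        "g_squared": 8.19,
        "df": 10,
        "delta_g_squared": {"equal_dP": 34.33, "equal_g": 10.24},
        "estimates": {"b": 0.02, "g_long": 0.48, "g_short": 0.78, "dA": 0.00},
        "standard_errors": {"b": 0.04, "g_long": 0.09, "g_short": 0.06, "dA": 0.12},
    }
    return Fixture(
        name="memon2003",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance=(
            "Reconstructed from Table 1 of Memon, Hope & Bull (2003), "
            "Br J Psychol 94, exposure-duration experiment"
        ),
        published=published,
    )


def _smith2014() -> Fixture:
    # viewing conditions at encoding (clear/degraded); suspect/filler
    # splits in culprit-absent lineups reconstructed by the 1/6 rule.
    data = _counts(
        [
            ("clear", (79, 9, 20, 9, 43, 153)),
            ("degraded", (17, 35, 47, 18, 89, 96)),
        ],
        lineup_size=6,
        ca_reconstructed=True,
    )
    conditions = [d.condition_id for d in data]
    layout = {
        "dP": {"clear": "dP_clear", "degraded": "dP_degraded"},
        "g": {"clear": "g_clear", "degraded": "g_degraded"},
        "b": "b",
        "dA": "dA",
    }
    comparison = _spec(
        conditions,
        layout,
        "Smith comparison standard: dP and g per viewing condition, b and dA shared",
    )
    restrictions = {
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_clear", "dP_degraded"]},
            description="dP equal across viewing conditions",
        ),
        "equal_g": comparison.restrict(
            merge={"g": ["g_clear", "g_degraded"]},
            description="g equal across viewing conditions",
        ),
    }
    published = {
        "g_squared": 1.81,
        "df": 2,
        "delta_g_squared": {"equal_dP": 74.73, "equal_g": 32.02},
        "estimates": {"b": 0.00, "g_clear": 0.26, "g_degraded": 0.51, "dA": 0.00},
        "standard_errors": {"b": 0.01, "g_clear": 0.04, "g_degraded": 0.05, "dA": 0.12},
    }
    return Fixture(
        name="smith2014",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance="Reconstructed from Table 1 of Smith (2014), viewing-condition data",
        published=published,
    )


def _wetmore() -> Fixture:
    # lineup fairness (fair/unfair) x delay (immediate/delayed); lineup arm
    # only; the two designated innocent suspects are aggregated.
    data = _counts(
        [
            ("immediate_fair", (41, 6, 13, 31, 74, 54)),
            ("immediate_unfair", (57, 2, 11, 56, 37, 58)),
            ("delayed_fair", (59, 13, 14, 22, 59, 38)),
            ("delayed_unfair", (54, 4, 14, 48, 31, 39)),
        ],
        lineup_size=6,
        ca_reconstructed=False,
    )
    conditions = [d.condition_id for d in data]

    def by_fairness(name):
        return {
            "immediate_fair": f"{name}_fair",
            "delayed_fair": f"{name}_fair",
            "immediate_unfair": f"{name}_unfair",
            "delayed_unfair": f"{name}_unfair",
        }

    layout = {
        "dP": by_fairness("dP"),
        "g": by_fairness("g"),
        "b": by_fairness("b"),
        "dA": "dA",
    }
    comparison = _spec(
        conditions,
        layout,
        "Wetmore et al. comparison standard: dP, g and b per fairness "
        "(shared across delay), dA shared",
    )
    restrictions = {
        "equal_b": comparison.restrict(
            merge={"b": ["b_fair", "b_unfair"]},
            description="b equal across fair and unfair lineups",
        ),
        "equal_g": comparison.restrict(
            merge={"g": ["g_fair", "g_unfair"]},
            description="g equal across fair and unfair lineups",
        ),
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_fair", "dP_unfair"]},
            description="dP equal across fair and unfair lineups",
        ),
    }
    published = {
        "g_squared": 14.10,
        "df": 9,
        "delta_g_squared": {"equal_b": 31.84, "equal_g": 15.42, "equal_dP": 0.19},
        "estimates": {
            "dP_fair": 0.61,
            "g_fair": 0.61,
            "dA": 0.00,
            "dP_unfair": 0.64,
            "g_unfair": 0.42,
        },
        "standard_errors": {
            "dP_fair": 0.05,
            "g_fair": 0.05,
            "dA": 0.07,
            "dP_unfair": 0.06,
            "g_unfair": 0.05,
        },
    }
    return Fixture(
        name="wetmore",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance=(
            "Reconstructed from the proportions in Table 2 of Wetmore et al. "
            "(2015), lineup arm only"
        ),
        published=published,
    )


def _colloff() -> Fixture:
    # lineup type: three fair techniques (block, pixelation, replication)
    # vs unfair; designated innocent suspects, so no suspect/filler split.
    data = _counts(
        [
            ("block", (323, 390, 414, 101, 503, 534)),
            ("pixelation", (320, 411, 414, 102, 512, 510)),
            ("replication", (347, 382, 396, 105, 523, 513)),
            ("unfair", (629, 206, 275, 364, 219, 434)),
        ],
        lineup_size=6,
        ca_reconstructed=False,
    )
    conditions = [d.condition_id for d in data]

    def by_type(name):
        return {
            "block": f"{name}_fair",
            "pixelation": f"{name}_fair",
            "replication": f"{name}_fair",
            "unfair": f"{name}_unfair",
        }

    layout = {
        "dP": by_type("dP"),
        "g": by_type("g"),
        "b": by_type("b"),
        "dA": "dA",
    }
    comparison = _spec(
        conditions,
        layout,
        "Colloff et al. comparison standard: dP, g and b shared across the "
        "three fair conditions and separate for unfair, dA shared",
    )
    restrictions = {
        "equal_b": comparison.restrict(
            merge={"b": ["b_fair", "b_unfair"]},
            description="b equal across fair and unfair lineups",
        ),
        "equal_g": comparison.restrict(
            merge={"g": ["g_fair", "g_unfair"]},
            description="g equal across fair and unfair lineups",
        ),
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_fair", "dP_unfair"]},
            description="dP equal across fair and unfair lineups",
        ),
    }
    published = {
        "g_squared": 12.92,
        "df": 9,
        "delta_g_squared": {"equal_b": 418.89, "equal_g": 48.99, "equal_dP": 8.37},
        "estimates": {
            "dP_fair": 0.22,
            "g_fair": 0.55,
            "dA": 0.02,
            "dP_unfair": 0.32,
            "g_unfair": 0.43,
        },
        "standard_errors": {
            "dP_fair": 0.01,
            "g_fair": 0.01,
            "dA": 0.02,
            "dP_unfair": 0.03,
            "g_unfair": 0.02,
        },
    }
    return Fixture(
        name="colloff",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance="From Table 2 of Colloff, Wade & Strange (2016)",
        published=published,
    )


def _malpass_devine() -> Fixture:
    # pre-lineup instructions (one-sided/two-sided); five-person lineup;
    # 100 participants total (cells 28/22/23/27); suspect/filler splits
    # reconstructed by the 1/5 rule.
    data = _counts(
        [
            ("one_sided", (21, 7, 0, 3, 14, 5)),
            ("two_sided", (19, 0, 4, 2, 7, 18)),
        ],
        lineup_size=5,
        ca_reconstructed=True,
    )
    conditions = [d.condition_id for d in data]
    layout = {
        "dP": {"one_sided": "dP_one_sided", "two_sided": "dP_two_sided"},
        "g": {"one_sided": "g_one_sided", "two_sided": "g_two_sided"},
        "b": "b",
        "dA": "dA",
    }
    comparison = _spec(
        conditions,
        layout,
        "Malpass & Devine comparison standard: dP and g per instruction "
        "condition, b and dA shared",
    )
    restrictions = {
        "equal_g": comparison.restrict(
            merge={"g": ["g_one_sided", "g_two_sided"]},
            description="g equal across instruction conditions",
        ),
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_one_sided", "dP_two_sided"]},
            description="dP equal across instruction conditions",
        ),
    }
    published = {
        "g_squared": 3.35,
        "df": 2,
        "delta_g_squared": {"equal_g": 20.95, "equal_dP": 0.88},
        "estimates": {"dP_one_sided": 0.68, "b": 0.01, "dA": 0.21, "dP_two_sided": 0.81},
        "standard_errors": {
            "dP_one_sided": 0.11,
            "b": 0.06,
            "dA": 0.30,
            "dP_two_sided": 0.09,
        },
    }
    return Fixture(
        name="malpass_devine",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance=(
            "Reconstructed from Table 1 of Malpass & Devine (1981); "
            "five-person lineup"
        ),
        published=published,
    )


def _lampinen() -> Fixture:
    # pre-lineup instructions: one-sided vs standard and detailed two-sided
    # (the two two-sided variants share dP and g); suspect/filler splits
    # reconstructed by the 1/6 rule.
    data = _counts(
        [
            ("one_sided", (68, 88, 10, 25, 126, 15)),
            ("standard_two_sided", (60, 85, 22, 19, 97, 50)),
            ("detailed_two_sided", (56, 76, 32, 20, 100, 46)),
        ],
        lineup_size=6,
        ca_reconstructed=True,
    )
    conditions = [d.condition_id for d in data]
    layout = {
        "dP": {
            "one_sided": "dP_one_sided",
            "standard_two_sided": "dP_two_sided",
            "detailed_two_sided": "dP_two_sided",
        },
        "g": {
            "one_sided": "g_one_sided",
            "standard_two_sided": "g_two_sided",
            "detailed_two_sided": "g_two_sided",
        },
        "b": "b",
        "dA": "dA",
    }
    comparison = _spec(
        conditions,
        layout,
        "Lampinen et al. comparison standard: dP and g per instruction type "
        "(two-sided variants combined), b and dA shared",
    )
    restrictions = {
        "equal_g": comparison.restrict(
            merge={"g": ["g_one_sided", "g_two_sided"]},
            description="g equal across one-sided and two-sided instructions",
        ),
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_one_sided", "dP_two_sided"]},
            description="dP equal across one-sided and two-sided instructions",
        ),
    }
    published = {
        "g_squared": 4.86,
        "df": 6,
        "delta_g_squared": {"equal_g": 36.39, "equal_dP": 0.69},
        "estimates": {"dP_one_sided": 0.30, "b": 0.00, "dA": 0.04, "dP_two_sided": 0.26},
        "standard_errors": {
            "dP_one_sided": 0.05,
            "b": 0.02,
            "dA": 0.03,
            "dP_two_sided": 0.03,
        },
    }
    return Fixture(
        name="lampinen",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance=(
            "Calculated from the proportions in Table 1 of Lampinen et al. "
            "(Experiment 1); equal assignment of the total sample to six cells"
        ),
        published=published,
    )


def _karageorge_zajac() -> Fixture:
    # wildcard (silhouette 'mystery man') vs control, collapsed over age and
    # delay; choosing the wildcard is scored as a lineup rejection.
    data = _counts(
        [
            ("wildcard", (31, 10, 7, 2, 6, 41)),
            ("control", (36, 8, 9, 25, 13, 16)),
        ],
        lineup_size=6,
        ca_reconstructed=False,
    )
    conditions = [d.condition_id for d in data]
    layout = {
        "dP": {"wildcard": "dP_wildcard", "control": "dP_control"},
        "g": {"wildcard": "g_wildcard", "control": "g_control"},
        "dA": {"wildcard": "dA_wildcard", "control": "dA_control"},
        "b": "b",
    }
    comparison = _spec(
        conditions,
        layout,
        "Karageorge & Zajac comparison standard: dP, g and dA per condition, "
        "b shared",
    )
    restrictions = {
        "equal_dA": comparison.restrict(
            merge={"dA": ["dA_wildcard", "dA_control"]},
            description="dA equal across wildcard and control conditions",
        ),
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_wildcard", "dP_control"]},
            description="dP equal across wildcard and control conditions",
        ),
        "equal_g": comparison.restrict(
            merge={"g": ["g_wildcard", "g_control"]},
            description="g equal across wildcard and control conditions",
        ),
    }
    published = {
        "g_squared": 3.58,
        "df": 1,
        "delta_g_squared": {"equal_dA": 29.79, "equal_dP": 0.21, "equal_g": 1.44},
        "estimates": {
            "dP_wildcard": 0.37,
            "b": 0.37,
            "g_wildcard": 0.67,
            "dP_control": 0.45,
            "g_control": 0.51,
        },
        "standard_errors": {
            "dP_wildcard": 0.15,
            "b": 0.09,
            "g_wildcard": 0.10,
            "dP_control": 0.14,
            "g_control": 0.11,
        },
    }
    return Fixture(
        name="karageorge_zajac",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance=(
            "Reconstructed from Table 1 of Karageorge & Zajac (2011), "
            "collapsed over age and delay"
        ),
        published=published,
    )


def _wilcock_bull() -> Fixture:
    # culprit-absent practice lineup vs control; suspect/filler splits
    # reconstructed by the 1/6 rule.
    data = _counts(
        [
            ("practice", (24, 21, 5, 2, 12, 36)),
            ("control", (20, 20, 10, 7, 36, 7)),
        ],
        lineup_size=6,
        ca_reconstructed=True,
    )
    conditions = [d.condition_id for d in data]
    layout = {
        "dP": {"practice": "dP_practice", "control": "dP_control"},
        "g": {"practice": "g_practice", "control": "g_control"},
        "dA": {"practice": "dA_practice", "control": "dA_control"},
        "b": "b",
    }
    comparison = _spec(
        conditions,
        layout,
        "Wilcock & Bull comparison standard: dP, g and dA per condition, b shared",
    )
    restrictions = {
        "equal_dA": comparison.restrict(
            merge={"dA": ["dA_practice", "dA_control"]},
            description="dA equal across practice and control conditions",
        ),
        "equal_dP": comparison.restrict(
            merge={"dP": ["dP_practice", "dP_control"]},
            description="dP equal across practice and control conditions",
        ),
        "equal_g": comparison.restrict(
            merge={"g": ["g_practice", "g_control"]},
            description="g equal across practice and control conditions",
        ),
    }
    published = {
        "g_squared": 2.92,
        "df": 1,
        "delta_g_squared": {"equal_dA": 23.42, "equal_dP": 0.58, "equal_g": 0.18},
        "estimates": {
            "dP_practice": 0.40,
            "b": 0.00,
            "g_practice": 0.83,
            "dP_control": 0.31,
            "g_control": 0.80,
        },
        "standard_errors": {
            "dP_practice": 0.09,
            "b": 0.05,
            "g_practice": 0.07,
            "dP_control": 0.09,
            "g_control": 0.06,
        },
    }
    return Fixture(
        name="wilcock_bull",
        data=data,
        comparison_spec=comparison,
        restriction_specs=restrictions,
        provenance="From Table 3 of Wilcock & Bull (Experiment 2)",
        published=published,
    )


_REGISTRY = {
    "memon2003": _memon2003,
    "smith2014": _smith2014,
    "wetmore": _wetmore,
    "colloff": _colloff,
    "malpass_devine": _malpass_devine,
    "lampinen": _lampinen,
    "karageorge_zajac": _karageorge_zajac,
    "wilcock_bull": _wilcock_bull,
}

FIXTURE_NAMES = tuple(_REGISTRY)


def load_fixture(name: str) -> Fixture:
    """Load one of the eight bundled study fixtures by name."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()
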