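"""Model specifications: binding latent-parameter slots to free parameters.

A multi-condition 2-HT model is defined by how the four parameter slots of
each condition (``dP``, ``b``, ``g``, ``dA``) are tied together.  Each slot
is bound either to a *named free parameter* — possibly shared across
conditions, which imposes an equality restriction — or fixed to a constant
(e.g. ``dA = 0`` for the one-high-threshold variant).  Hypotheses are
tested by comparing a model against a nested model whose binding is a
coarsening of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .trees import PARAM_NAMES, LineupCounts

__all__ = [
    "Slot",
    "ModelSpec",
    "saturated_spec",
    "free_parameter_count",
    "independent_category_count",
    "degrees_of_freedom",
]

#: A (condition label, parameter name) pair addressing one latent slot.
Slot = tuple[str, str]


def _slot_key(slot: Slot) -> str:
    return f"{slot[0]}.{slot[1]}"


def _parse_slot(key: str) -> Slot:
    condition, _, param = key.rpartition(".")
    if not condition or param not in PARAM_NAMES:
        raise ValueError(
            f"slot key {key!r} must have the form '<condition>.<param>' with "
            f"param one of {PARAM_NAMES}"
        )
    return condition, param


@dataclass(frozen=True)
class ModelSpec:
    """Binding of every (condition, parameter) slot of a 2-HT model.

    Parameters
    ----------
    conditions
        Ordered condition labels; the order fixes report layout.
    bind
        Map from slot to the name of a free parameter.
    fix
        Map from slot to a constant in [0, 1].
    free_parameters
        Ordered names of the free parameters.  Defaults to the names in
        ``bind`` in first-appearance order (conditions outer, canonical
        parameter order inner).
    description
        Free text describing the hypothesis the spec encodes.
    """

    conditions: tuple[str, ...]
    bind: Mapping[Slot, str]
    fix: Mapping[Slot, float] = field(default_factory=dict)
    free_parameters: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        conditions = tuple(self.conditions)
        if len(set(conditions)) != len(conditions):
            raise ValueError("condition labels must be unique")
        bind = dict(self.bind)
        fix = {slot: float(v) for slot, v in self.fix.items()}
        object.__setattr__(self, "conditions", conditions)
        object.__setattr__(self, "bind", bind)
        object.__setattr__(self, "fix", fix)

        slots = self.slots()
        bound = set(bind) | set(fix)
        missing = [s for s in slots if s not in bound]
        if missing:
            raise ValueError(f"unbound slots: {[_slot_key(s) for s in missing]}")
        extra = bound - set(slots)
        if extra:
            raise ValueError(f"bindings for unknown slots: {sorted(map(_slot_key, extra))}")
        if set(bind) & set(fix):
            doubled = sorted(_slot_key(s) for s in set(bind) & set(fix))
            raise ValueError(f"slots both bound and fixed: {doubled}")
        for slot, value in fix.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"fixed constant for {_slot_key(slot)} must lie in [0, 1]"
                )

        if self.free_parameters:
            free = tuple(self.free_parameters)
            if set(free) != set(bind.values()):
                raise ValueError(
                    "free_parameters must name exactly the parameters used in bind"
                )
        else:
            seen: dict[str, None] = {}
            for slot in slots:
                if slot in bind:
                    seen.setdefault(bind[slot], None)
            free = tuple(seen)
        object.__setattr__(self, "free_parameters", free)

    # -- structure ---------------------------------------------------------

    def slots(self) -> list[Slot]:
        """All (condition, parameter) slots in canonical order."""
        return [(c, p) for c in self.conditions for p in PARAM_NAMES]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    def assignment(self, slot: Slot) -> str | float:
        """Free-parameter name or fixed constant bound to ``slot``."""
        if slot in self.bind:
            return self.bind[slot]
        return self.fix[slot]

    def is_nested_in(self, general: "ModelSpec") -> bool:
        """Whether this spec is a coarsening of ``general``.

        A restricted spec is nested in a general one when its assignment is
        constant on every equivalence class of the general binding: slots
        sharing a free parameter in the general spec must share an
        assignment here, and slots fixed in the general spec must be fixed
        to the same constant here.
        """
        if tuple(self.conditions) != tuple(general.conditions):
            return False
        class_map: dict[str, str | float] = {}
        for slot in general.slots():
            general_assignment = general.assignment(slot)
            restricted_assignment = self.assignment(slot)
            if isinstance(general_assignment, float):
                if (
                    not isinstance(restricted_assignment, float)
                    or restricted_assignment != general_assignment
                ):
                    return False
            else:
                if general_assignment in class_map:
                    if class_map[general_assignment] != restricted_assignment:
                        return False
                else:
                    class_map[general_assignment] = restricted_assignment
        return True

    def restrict(
        self,
        merge: Mapping[str, Sequence[str]] | None = None,
        fix: Mapping[str, float] | None = None,
        description: str = "",
    ) -> "ModelSpec":
        """Derive a nested spec by merging or fixing free parameters.

        ``merge`` maps a new free-parameter name to the general names it
        replaces; ``fix`` pins general free parameters to constants.
        """
        merge = dict(merge or {})
        fix = dict(fix or {})
        rename: dict[str, str] = {}
        for new_name, old_names in merge.items():
            for old in old_names:
                if old not in self.free_parameters:
                    raise KeyError(f"unknown free parameter {old!r}")
                rename[old] = new_name
        for old in fix:
            if old not in self.free_parameters:
                raise KeyError(f"unknown free parameter {old!r}")
            if old in rename:
                raise ValueError(f"parameter {old!r} both merged and fixed")
        new_bind: dict[Slot, str] = {}
        new_fix: dict[Slot, float] = dict(self.fix)
        for slot, name in self.bind.items():
            if name in fix:
                new_fix[slot] = float(fix[name])
            else:
                new_bind[slot] = rename.get(name, name)
        return ModelSpec(
            conditions=self.conditions,
            bind=new_bind,
            fix=new_fix,
            description=description or self.description,
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "free_parameters": list(self.free_parameters),
            "bind": {_slot_key(s): name for s, name in self.bind.items()},
            "fix": {_slot_key(s): value for s, value in self.fix.items()},
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ModelSpec":
        try:
            conditions = tuple(payload["conditions"])
            bind = {_parse_slot(k): v for k, v in payload.get("bind", {}).items()}
            fix = {_parse_slot(k): float(v) for k, v in payload.get("fix", {}).items()}
        except KeyError as exc:
            raise ValueError(f"model spec is missing key {exc.args[0]!r}") from None
        return cls(
            conditions=conditions,
            bind=bind,
            fix=fix,
            free_parameters=tuple(payload.get("free_parameters", ())),
            description=payload.get("description", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def saturated_spec(conditions: Iterable[str], description: str = "") -> ModelSpec:
    """One free parameter per slot: the zero-degrees-of-freedom model."""
    conditions = tuple(conditions)
    bind = {(c, p): f"{p}_{c}" for c in conditions for p in PARAM_NAMES}
    return ModelSpec(
        conditions=conditions,
        bind=bind,
        description=description or "saturated (per-condition) model",
    )


# -- degrees-of-freedom accounting ----------------------------------------


def free_parameter_count(spec: ModelSpec) -> int:
    return spec.n_free


def _check_conditions(spec: ModelSpec, data: Sequence[LineupCounts]) -> None:
    data_labels = [d.condition_id for d in data]
    if list(spec.conditions) != data_labels:
        raise ValueError(
            f"spec conditions {list(spec.conditions)} do not match data "
            f"conditions {data_labels}"
        )


def independent_category_count(
    data: Sequence[LineupCounts], strict_df: bool = False
) -> int:
    """Independent multinomial categories: 2 per tree with a positive total.

    With ``strict_df=True`` one category is subtracted for every
    culprit-absent tree whose suspect/filler split was reconstructed from a
    pooled false-identification count, as a sensitivity analysis for data
    sets without a designated innocent suspect.
    """
    n = 0
    for d in data:
        if d.n_cp > 0:
            n += 2
        if d.n_ca > 0:
            n += 2
            if strict_df and d.ca_reconstructed:
                n -= 1
    return n


def degrees_of_freedom(
    spec: ModelSpec, data: Sequence[LineupCounts], strict_df: bool = False
) -> int:
    """df = independent categories − free parameters (0 means saturated)."""
    _check_conditions(spec, data)
    df = independent_category_count(data, strict_df=strict_df) - spec.n_free
    if df < 0:
        raise ValueError(
            f"model has more free parameters ({spec.n_free}) than independent "
            f"categories ({independent_category_count(data, strict_df=strict_df)})"
        )
    return df
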