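"""Core tree structure of the two-high-threshold (2-HT) lineup identification model.

The model is a multinomial processing tree (MPT) over the 2 x 3 data
structure of a lineup identification task.  Each witness sees either a
culprit-present or a culprit-absent lineup and makes one of three
responses: suspect identification, filler identification, or lineup
rejection.  Four latent-process probabilities generate these responses:

``dP``
    detection of the culprit's presence (culprit-present lineups only);
    leads directly to a correct culprit identification.
``dA``
    detection of the culprit's absence (culprit-absent lineups only);
    leads directly to a correct lineup rejection.
``b``
    biased selection of the suspect when no detection occurs, e.g. because
    the suspect stands out from the fillers in an unfair lineup.
``g``
    guessing-based selection of some lineup member when neither detection
    nor biased selection occurs; the guess lands on the suspect with
    probability ``1/k`` and on a filler with probability ``(k-1)/k``,
    where ``k`` is the lineup size.

Setting ``dA = 0`` yields the one-high-threshold variant of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "CP_CATEGORIES",
    "CA_CATEGORIES",
    "GroupParameters",
    "LineupCounts",
    "CategoryProbabilities",
    "category_probabilities",
    "expected_frequencies",
]

#: Latent-process parameters of one experimental condition, in canonical order.
PARAM_NAMES = ("dP", "b", "g", "dA")

CP_CATEGORIES = ("cp_culprit", "cp_filler", "cp_reject")
CA_CATEGORIES = ("ca_suspect", "ca_filler", "ca_reject")


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"parameter {name!r} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class GroupParameters:
    """The four latent-process probabilities of one condition."""

    dP: float
    b: float
    g: float
    dA: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class LineupCounts:
    """Observed 2 x 3 frequency table of one condition plus its lineup size.

    ``ca_reconstructed`` records whether the culprit-absent suspect/filler
    split was reconstructed from a pooled false-identification count rather
    than observed directly (relevant for the ``strict_df`` sensitivity
    option of the degrees-of-freedom accounting).
    """

    condition_id: str
    lineup_size: int
    cp_culprit: int
    cp_filler: int
    cp_reject: int
    ca_suspect: int
    ca_filler: int
    ca_reject: int
    ca_reconstructed: bool = False

    def __post_init__(self) -> None:
        if int(self.lineup_size) != self.lineup_size or self.lineup_size < 2:
            raise ValueError(
                f"lineup_size must be an integer >= 2, got {self.lineup_size!r}"
            )
        object.__setattr__(self, "lineup_size", int(self.lineup_size))
        for field in CP_CATEGORIES + CA_CATEGORIES:
            value = getattr(self, field)
            if int(value) != value or value < 0:
                raise ValueError(f"count {field!r} must be a non-negative integer")
            object.__setattr__(self, field, int(value))
        if self.n_cp == 0 and self.n_ca == 0:
            raise ValueError(
                f"condition {self.condition_id!r} has no observations in either tree"
            )

    @property
    def n_cp(self) -> int:
        """Total number of witnesses shown the culprit-present lineup."""
        return self.cp_culprit + self.cp_filler + self.cp_reject

    @property
    def n_ca(self) -> int:
        """Total number of witnesses shown the culprit-absent lineup."""
        return self.ca_suspect + self.ca_filler + self.ca_reject

    def observed(self) -> np.ndarray:
        """The six counts as an array, culprit-present tree first."""
        return np.array(
            [getattr(self, f) for f in CP_CATEGORIES + CA_CATEGORIES], dtype=float
        )


@dataclass(frozen=True)
class CategoryProbabilities:
    """Model-implied response probabilities, one triple per tree."""

    p_cp: tuple[float, float, float]
    p_ca: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, triple in (("p_cp", self.p_cp), ("p_ca", self.p_ca)):
            if len(triple) != 3 or any(not 0.0 <= p <= 1.0 for p in triple):
                raise ValueError(f"{name} must be three probabilities in [0, 1]")
            if abs(sum(triple) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {sum(triple)!r}")

    def as_array(self) -> np.ndarray:
        return np.array(self.p_cp + self.p_ca, dtype=float)


def category_probabilities(
    theta: GroupParameters, lineup_size: int
) -> CategoryProbabilities:
    """Map latent-process probabilities to the six response probabilities.

    Reading the two processing trees from root to leaves (``k`` denotes the
    lineup size)::

        p_cp(culprit) = dP + (1-dP)*b + (1-dP)*(1-b)*g*(1/k)
        p_cp(filler)  = (1-dP)*(1-b)*g*((k-1)/k)
        p_cp(reject)  = (1-dP)*(1-b)*(1-g)

        p_ca(suspect) = (1-dA)*b + (1-dA)*(1-b)*g*(1/k)
        p_ca(filler)  = (1-dA)*(1-b)*g*((k-1)/k)
        p_ca(reject)  = dA + (1-dA)*(1-b)*(1-g)

    The ``1/k`` and ``(k-1)/k`` weights are structural constants of the
    design, not parameters; they are formed as exact rationals.
    """
    if int(lineup_size) != lineup_size or lineup_size < 2:
        raise ValueError(f"lineup_size must be an integer >= 2, got {lineup_size!r}")
    k = int(lineup_size)
    w_suspect = float(Fraction(1, k))
    w_filler = float(Fraction(k - 1, k))
    dP, b, g, dA = theta.dP, theta.b, theta.g, theta.dA

    p_cp = (
        dP + (1.0 - dP) * b + (1.0 - dP) * (1.0 - b) * g * w_suspect,
        (1.0 - dP) * (1.0 - b) * g * w_filler,
        (1.0 - dP) * (1.0 - b) * (1.0 - g),
    )
    p_ca = (
        (1.0 - dA) * b + (1.0 - dA) * (1.0 - b) * g * w_suspect,
        (1.0 - dA) * (1.0 - b) * g * w_filler,
        dA + (1.0 - dA) * (1.0 - b) * (1.0 - g),
    )
    # guard against floating-point drift before the container validates sums
    p_cp = tuple(min(1.0, max(0.0, p)) for p in p_cp)
    p_ca = tuple(min(1.0, max(0.0, p)) for p in p_ca)
    return CategoryProbabilities(p_cp=p_cp, p_ca=p_ca)


def expected_frequencies(
    probs: CategoryProbabilities, n_cp: int, n_ca: int
) -> np.ndarray:
    """Expected counts for the six categories given the two tree totals."""
    if n_cp < 0 or n_ca < 0:
        raise ValueError("tree totals must be non-negative")
    return np.concatenate(
        [n_cp * np.asarray(probs.p_cp), n_ca * np.asarray(probs.p_ca)]
    )
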