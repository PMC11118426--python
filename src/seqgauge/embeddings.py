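"""Model specifications, one-hot and simplex feature embeddings.

A linear sequence-function model is ``f(s; theta) = theta . x(s)`` where the
embedding ``x`` is a direct sum, over an ordered family of position sets
``A_1, ..., A_J``, of Kronecker products of single-position encodings of the
characters at the positions in each set.  Two single-position encodings are
supported:

* **one-hot** — the ``alpha``-dimensional indicator vector of the character;
* **simplex** — the zero-centered ``(alpha-1)``-dimensional encoding in which
  character ``c_i`` (``i < alpha``) maps to the ``i``-th standard basis vector
  and the last character maps to the all ``-1`` vector.

Generalized one-hot models (direct sums of Kronecker products of one-hot
encodings) are the common Potts-style models with interactions of arbitrary
order; their features are redundant, which is the source of gauge freedoms.
Simplex models over distinct position sets carry no redundancy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np

from .errors import EnumerationCapError, ValidationError
from .sequence_space import (
    DEFAULT_ENUMERATION_CAP,
    Alphabet,
    enumerate_sequences,
    validate_sequence,
)

ONE_HOT = "one-hot"
SIMPLEX = "simplex"
FLAVORS = (ONE_HOT, SIMPLEX)

PRESET_NAMES = (
    "constant",
    "additive",
    "pairwise",
    "nearest-neighbor",
    "all-order",
    "all-adjacent",
    "K-order",
    "hierarchical-K-order",
    "K-adjacent",
    "hierarchical-K-adjacent",
)


def subset_sort_key(subset: tuple[int, ...]) -> tuple:
    """Canonical subset order: by size, then lexicographic by positions."""
    return (len(subset), subset)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a linear equivariant model.

    Parameters
    ----------
    alphabet:
        The ordered character alphabet.
    L:
        Sequence length.
    flavor:
        ``"one-hot"`` or ``"simplex"`` — the single-position encoding used in
        every Kronecker factor.
    position_sets:
        Ordered family of position sets (1-based positions, each set given in
        ascending order).  Sets may repeat; the empty set denotes the constant
        feature.  An empty *family* (``J = 0``) is the degenerate
        zero-dimensional model and is accepted only so the enumeration of
        equivariant model classes is closed; it cannot be embedded.
    """

    alphabet: Alphabet
    L: int
    flavor: str
    position_sets: tuple[tuple[int, ...], ...]

    def __init__(
        self,
        alphabet: Alphabet | str,
        L: int,
        flavor: str,
        position_sets: Iterable[Iterable[int]],
    ):
        if not isinstance(alphabet, Alphabet):
            alphabet = Alphabet(alphabet)
        if flavor not in FLAVORS:
            raise ValidationError(f"flavor must be one of {FLAVORS}, got {flavor!r}")
        if L < 1:
            raise ValidationError(f"sequence length must be positive, got {L}")
        sets = []
        for j, A in enumerate(position_sets):
            A = tuple(sorted(int(l) for l in A))
            if len(set(A)) != len(A):
                raise ValidationError(f"position set #{j + 1} has repeated positions: {A}")
            for l in A:
                if not 1 <= l <= L:
                    raise ValidationError(
                        f"position set #{j + 1} contains position {l}, outside 1..{L}"
                    )
            sets.append(A)
        object.__setattr__(self, "alphabet", alphabet)
        object.__setattr__(self, "L", int(L))
        object.__setattr__(self, "flavor", flavor)
        object.__setattr__(self, "position_sets", tuple(sets))

    @property
    def J(self) -> int:
        """Number of position sets (interaction terms)."""
        return len(self.position_sets)

    @property
    def block_dims(self) -> tuple[int, ...]:
        """Dimension contributed by each position set."""
        base = self.alphabet.alpha if self.flavor == ONE_HOT else self.alphabet.alpha - 1
        return tuple(base ** len(A) for A in self.position_sets)

    @property
    def n_features(self) -> int:
        """Total embedding dimension M (exact integer arithmetic)."""
        return sum(self.block_dims)

    def with_flavor(self, flavor: str) -> "ModelSpec":
        """Same position sets, other encoding flavor."""
        return ModelSpec(self.alphabet, self.L, flavor, self.position_sets)


# ---------------------------------------------------------------------------
# Single-position encodings
# ---------------------------------------------------------------------------

def onehot_single(c: str, alphabet: Alphabet) -> np.ndarray:
    """One-hot indicator vector of character ``c`` (length ``alpha``)."""
    v = np.zeros(alphabet.alpha, dtype=np.int64)
    v[alphabet.index(c)] = 1
    return v


def simplex_single(c: str, alphabet: Alphabet) -> np.ndarray:
    """Simplex encoding of ``c`` (length ``alpha - 1``).

    Characters ``c_1 .. c_{alpha-1}`` map to standard basis vectors; the last
    character maps to the all ``-1`` vector, so the encodings of all
    characters sum to zero.
    """
    i = alphabet.index(c)
    if i == alphabet.alpha - 1:
        return -np.ones(alphabet.alpha - 1, dtype=np.int64)
    v = np.zeros(alphabet.alpha - 1, dtype=np.int64)
    v[i] = 1
    return v


def _single(spec: ModelSpec, c: str) -> np.ndarray:
    if spec.flavor == ONE_HOT:
        return onehot_single(c, spec.alphabet)
    return simplex_single(c, spec.alphabet)


# ---------------------------------------------------------------------------
# Feature labels and parameter vectors
# ---------------------------------------------------------------------------

def _block_labels(spec: ModelSpec, A: tuple[int, ...]) -> list[str]:
    """Labels for one position-set block, in Kronecker (row-major) order."""
    if not A:
        return ["theta_0"]
    pos = ",".join(str(l) for l in A)
    if spec.flavor == ONE_HOT:
        choices = itertools.product(spec.alphabet.chars, repeat=len(A))
        return [f"theta_{pos}:{''.join(chars)}" for chars in choices]
    idx = itertools.product(range(1, spec.alphabet.alpha), repeat=len(A))
    return [f"theta_{pos}:{','.join(str(i) for i in t)}" for t in idx]


def feature_labels(spec: ModelSpec) -> list[str]:
    """Unique labels of the M features, in embedding order.

    Repeated position sets get a ``#<ordinal>`` suffix from the second
    occurrence on, keeping labels unique.  The label syntax is contractual
    for parameter TSV files.
    """
    seen: dict[tuple[int, ...], int] = {}
    labels: list[str] = []
    for A in spec.position_sets:
        seen[A] = seen.get(A, 0) + 1
        suffix = f"#{seen[A]}" if seen[A] > 1 else ""
        labels.extend(lbl + suffix for lbl in _block_labels(spec, A))
    if len(set(labels)) != len(labels):  # pragma: no cover - guarded by suffixing
        raise ValidationError("internal error: feature labels are not unique")
    return labels


@dataclass
class ParameterVector:
    """Named model parameters, one value per feature label."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __init__(self, labels: TypingSequence[str], values: TypingSequence[float]):
        labels = tuple(labels)
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or len(labels) != values.shape[0]:
            raise ValidationError(
                f"got {len(labels)} labels but {values.shape} values"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("parameter values must be finite")
        self.labels = labels
        self.values = values

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "ParameterVector":
        labels = feature_labels(spec)
        return cls(labels, np.zeros(len(labels)))

    @classmethod
    def from_mapping(cls, spec: ModelSpec, mapping: Mapping[str, float]) -> "ParameterVector":
        """Build from a label->value mapping; unnamed features default to 0."""
        labels = feature_labels(spec)
        unknown = set(mapping) - set(labels)
        if unknown:
            raise ValidationError(f"unknown feature labels: {sorted(unknown)}")
        return cls(labels, [mapping.get(lbl, 0.0) for lbl in labels])

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        try:
            return float(self.values[self.labels.index(label)])
        except ValueError:
            raise KeyError(label) from None


def _as_theta(spec: ModelSpec, theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        values = theta.values
    else:
        values = np.asarray(theta, dtype=float)
    if values.shape != (spec.n_features,):
        raise ValidationError(
            f"parameter vector has shape {values.shape}, expected ({spec.n_features},)"
        )
    return values


# ---------------------------------------------------------------------------
# Embedding, design matrix, model evaluation
# ---------------------------------------------------------------------------

def embed_sequence(spec: ModelSpec, s: str) -> np.ndarray:
    """The M-dimensional feature embedding of sequence ``s``.

    Direct sum over position sets (in listed order) of the Kronecker product,
    over positions in ascending order, of the single-position encodings; the
    empty set contributes the 1-dimensional constant feature ``(1,)``.
    """
    validate_sequence(s, spec.alphabet, spec.L)
    parts = []
    for A in spec.position_sets:
        block = np.ones(1, dtype=np.int64)
        for l in A:
            block = np.kron(block, _single(spec, s[l - 1]))
        parts.append(block)
    if not parts:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(parts)


def design_matrix(
    spec: ModelSpec, cap: int = DEFAULT_ENUMERATION_CAP
) -> np.ndarray:
    """The ``alpha**L x M`` matrix whose rows are sequence embeddings.

    Rows follow the lexicographic sequence enumeration order; columns follow
    the feature label order.  Raises :class:`EnumerationCapError` when the
    sequence space exceeds ``cap``.
    """
    seqs = enumerate_sequences(spec.alphabet, spec.L, cap=cap)
    if spec.n_features == 0:
        return np.zeros((len(seqs), 0), dtype=np.int64)
    return np.stack([embed_sequence(spec, s) for s in seqs])


def evaluate_model(spec: ModelSpec, theta, s: str) -> float:
    """Model prediction ``f(s; theta) = theta . x(s)``."""
    values = _as_theta(spec, theta)
    return float(values @ embed_sequence(spec, s))


# ---------------------------------------------------------------------------
# Model presets
# ---------------------------------------------------------------------------

def _windows(L: int, k: int) -> list[tuple[int, ...]]:
    return [tuple(range(start, start + k)) for start in range(1, L - k + 2)]


def _subsets(L: int, k: int) -> list[tuple[int, ...]]:
    return [tuple(c) for c in itertools.combinations(range(1, L + 1), k)]


def preset_position_sets(name: str, L: int, K: int | None = None) -> list[tuple[int, ...]]:
    """Position-set family of a named model preset.

    Families are listed in canonical order: the empty set first (where
    present), then sets of increasing size, lexicographic within a size.
    """
    needs_K = name in ("K-order", "hierarchical-K-order", "K-adjacent", "hierarchical-K-adjacent")
    if needs_K:
        if K is None:
            raise ValidationError(f"preset {name!r} requires an interaction order K")
        lo = 1 if "adjacent" in name else 0
        if not lo <= K <= L:
            raise ValidationError(f"preset {name!r} requires {lo} <= K <= L={L}, got {K}")
    elif K is not None:
        raise ValidationError(f"preset {name!r} does not take an interaction order K")

    if name == "constant":
        return [()]
    if name == "additive":
        return [()] + _subsets(L, 1)
    if name == "pairwise":
        return [()] + _subsets(L, 1) + _subsets(L, 2)
    if name == "nearest-neighbor":
        return [()] + _subsets(L, 1) + _windows(L, 2)
    if name == "all-order":
        return [s for k in range(L + 1) for s in _subsets(L, k)]
    if name == "all-adjacent":
        return [()] + [w for k in range(1, L + 1) for w in _windows(L, k)]
    if name == "K-order":
        return _subsets(L, K)
    if name == "hierarchical-K-order":
        return [s for k in range(K + 1) for s in _subsets(L, k)]
    if name == "K-adjacent":
        return _windows(L, K)
    if name == "hierarchical-K-adjacent":
        return [()] + [w for k in range(1, K + 1) for w in _windows(L, k)]
    raise ValidationError(f"unknown preset {name!r}; known presets: {PRESET_NAMES}")


def model_preset(
    name: str,
    alphabet: Alphabet | str,
    L: int,
    K: int | None = None,
    flavor: str = ONE_HOT,
) -> ModelSpec:
    """A :class:`ModelSpec` for one of the standard model families."""
    return ModelSpec(alphabet, L, flavor, preset_position_sets(name, L, K))
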