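"""Sequence space and its position-specific character permutation symmetries.

Sequences of length ``L`` over an alphabet of ``alpha`` characters form a
space on which the group of position-specific character permutations (PSCP)
acts: an element applies an independent permutation of the alphabet at each
position.  This group preserves Hamming distances between sequences and is
the symmetry group under which the models in this package are equivariant.

Sequences themselves are represented as plain Python strings; the
:class:`Alphabet` fixes the character order, which in turn fixes feature
indexing and the row order of design matrices everywhere in the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence as TypingSequence

import numpy as np

from .errors import EnumerationCapError, ValidationError

#: Default bound on the number of sequences that may be fully enumerated.
DEFAULT_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class Alphabet:
    """An ordered alphabet of distinct characters.

    The order of ``chars`` is contractual: it determines the indexing of
    one-hot and simplex features, and the *last* character is the simplex
    reference character (the one embedded as the all ``-1`` vector).
    """

    chars: tuple[str, ...]

    def __init__(self, chars: TypingSequence[str] | str):
        chars = tuple(chars)
        if len(chars) < 2:
            raise ValidationError(
                f"alphabet must have at least 2 characters, got {len(chars)}"
            )
        if len(set(chars)) != len(chars):
            raise ValidationError(f"alphabet characters must be distinct: {chars!r}")
        for c in chars:
            if not isinstance(c, str) or len(c) != 1:
                raise ValidationError(f"alphabet entries must be single characters: {c!r}")
        object.__setattr__(self, "chars", chars)

    @property
    def alpha(self) -> int:
        """Number of characters."""
        return len(self.chars)

    @property
    def reference(self) -> str:
        """The simplex reference character (last in the alphabet order)."""
        return self.chars[-1]

    def index(self, c: str) -> int:
        """0-based index of character ``c``; raises on unknown character."""
        try:
            return self.chars.index(c)
        except ValueError:
            raise ValidationError(f"character {c!r} not in alphabet {''.join(self.chars)!r}") from None

    def __len__(self) -> int:
        return len(self.chars)

    def __iter__(self) -> Iterator[str]:
        return iter(self.chars)

    def __contains__(self, c: object) -> bool:
        return c in self.chars

    def __str__(self) -> str:
        return "".join(self.chars)


def validate_sequence(s: str, alphabet: Alphabet, L: int) -> str:
    """Check that ``s`` has length ``L`` and only alphabet characters."""
    if len(s) != L:
        raise ValidationError(f"sequence {s!r} has length {len(s)}, expected {L}")
    for c in s:
        if c not in alphabet:
            raise ValidationError(
                f"sequence {s!r} contains {c!r}, not in alphabet {alphabet}"
            )
    return s


def enumerate_sequences(
    alphabet: Alphabet, L: int, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[str]:
    """All ``alpha**L`` sequences, lexicographic in alphabet-character order.

    This order is contractual: it is the row order of every design matrix.
    Raises :class:`EnumerationCapError` when the space exceeds ``cap``.
    """
    if L < 0:
        raise ValidationError(f"sequence length must be non-negative, got {L}")
    if alphabet.alpha**L > cap:
        raise EnumerationCapError(alphabet.alpha, L, cap)
    return ["".join(t) for t in itertools.product(alphabet.chars, repeat=L)]


@dataclass(frozen=True)
class PSCPElement:
    """A position-specific character permutation.

    ``perms[l]`` is the permutation applied at position ``l+1`` (positions
    are 1-based in user-facing labels), stored as a mapping on alphabet
    characters so that elements are independent of character order.
    """

    perms: tuple[Mapping[str, str], ...] = field(hash=False)

    def __init__(self, perms: TypingSequence[Mapping[str, str]]):
        frozen = []
        for i, p in enumerate(perms):
            if set(p.keys()) != set(p.values()):
                raise ValidationError(f"position {i + 1}: mapping {p!r} is not a permutation")
            frozen.append(dict(p))
        object.__setattr__(self, "perms", tuple(frozen))

    @property
    def L(self) -> int:
        return len(self.perms)

    @classmethod
    def identity(cls, alphabet: Alphabet, L: int) -> "PSCPElement":
        return cls([{c: c for c in alphabet} for _ in range(L)])

    def __call__(self, s: str) -> str:
        return apply_pscp(self, s)

    def compose(self, other: "PSCPElement") -> "PSCPElement":
        """Elementwise composition ``self∘other`` (first ``other``, then ``self``)."""
        if self.L != other.L:
            raise ValidationError("cannot compose PSCP elements of different lengths")
        return PSCPElement(
            [
                {c: p_self[p_other[c]] for c in p_other}
                for p_self, p_other in zip(self.perms, other.perms)
            ]
        )

    def inverse(self) -> "PSCPElement":
        return PSCPElement([{v: k for k, v in p.items()} for p in self.perms])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSCPElement):
            return NotImplemented
        return self.perms == other.perms


def apply_pscp(h: PSCPElement, s: str) -> str:
    """Apply ``h`` to sequence ``s``: position ``l`` is permuted by ``h.perms[l]``."""
    if len(s) != h.L:
        raise ValidationError(
            f"sequence length {len(s)} does not match group element length {h.L}"
        )
    try:
        return "".join(p[c] for p, c in zip(h.perms, s))
    except KeyError as exc:
        raise ValidationError(f"character {exc.args[0]!r} not moved by this PSCP element") from exc


def random_pscp(
    alphabet: Alphabet, L: int, seed: int | np.random.Generator
) -> PSCPElement:
    """Uniform random element of the PSCP group ``H_1 x ... x H_L``.

    Deterministic given ``seed``; a ``numpy.random.Generator`` may be passed
    directly to draw several elements from one stream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = []
    for _ in range(L):
        images = list(alphabet.chars)
        rng.shuffle(images)
        perms.append(dict(zip(alphabet.chars, images)))
    return PSCPElement(perms)


def hamming(s: str, t: str) -> int:
    """Hamming distance between two equal-length sequences."""
    if len(s) != len(t):
        raise ValidationError("Hamming distance requires equal-length sequences")
    return sum(a != b for a, b in zip(s, t))
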