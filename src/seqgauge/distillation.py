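"""Embedding distillation: change of basis exposing gauge freedoms.

The single-position one-hot encoding decomposes, under the PSCP group, into
a trivial (constant) part and a simplex part; the change of basis is the
``alpha x alpha`` similarity matrix ``T`` returned by :func:`similarity_T`.
Applying ``T`` factor-by-factor to a generalized one-hot embedding expands
each Kronecker block over a position set ``A_j`` into ``2**|A_j|``
sub-blocks, one per subset ``B`` of ``A_j``; the sub-block for ``B``
transforms as the Kronecker product of simplex encodings over ``B`` and, on
every sequence embedding, *equals* that product.  Sub-blocks with the same
``B`` arising from different position sets are therefore identical on all
sequences, and this redundancy is the entire source of gauge freedoms.

Distillation is the cumulative similarity transformation

    ``Tdist = Tsort . Tthin . Tdecom``

where ``Tdecom`` performs the per-block expansion, ``Tthin`` subtracts the
first-kept copy of each repeated sub-block from the later copies (zeroing
them on every sequence embedding), and ``Tsort`` permutes the kept
sub-blocks to the top.  The result satisfies, for every sequence ``s``,

    ``Tdist . x(s) = x_dist(s) ⊕ 0_gamma``

with ``x_dist`` the simplex embedding over the distinct subsets ``B_k`` and
``gamma`` the number of gauge freedoms:

    ``gamma = M - sum_k (alpha-1)**|B_k| = sum_k (Q_k - 1)(alpha-1)**|B_k|``

where ``Q_k`` is the number of position sets containing ``B_k``.  The last
``gamma`` rows of ``Tdist`` form a sparse basis of the gauge space with
entries in {-1, 0, +1}.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .embeddings import (
    ONE_HOT,
    SIMPLEX,
    ModelSpec,
    feature_labels,
    subset_sort_key,
)
from .errors import ValidationError
from .sequence_space import Alphabet


# ---------------------------------------------------------------------------
# Single-position similarity transformation
# ---------------------------------------------------------------------------

def similarity_T(alphabet: Alphabet) -> tuple[np.ndarray, np.ndarray]:
    """The ``alpha x alpha`` matrix ``T`` splitting one-hot into trivial ⊕ simplex.

    Row 0 is all ones; row ``i`` (``i = 1 .. alpha-1``) has ``+1`` in column
    ``i-1`` and ``-1`` in the last column, so that
    ``T . onehot(c) = (1,) ⊕ simplex(c)`` for every character ``c``.

    Returns ``(T, T_inverse)``; ``T`` is integer-valued, its inverse has
    entries that are integer multiples of ``1/alpha``.
    """
    alpha = alphabet.alpha
    T = np.zeros((alpha, alpha), dtype=np.int64)
    T[0, :] = 1
    T[1:, :-1] = np.eye(alpha - 1, dtype=np.int64)
    T[1:, -1] = -1
    T_inv = np.full((alpha, alpha), -1.0 / alpha)
    T_inv[:, 0] = 1.0 / alpha
    T_inv[: alpha - 1, 1:] += np.eye(alpha - 1)
    return T, T_inv


# ---------------------------------------------------------------------------
# Block bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One irreducible sub-block of the decomposed embedding."""

    source: int                 # index j of the position set it came from
    source_set: tuple[int, ...]  # A_j
    subset: tuple[int, ...]      # B ⊆ A_j; the sub-block transforms as ⊗_{l∈B} simplex
    dim: int                     # (alpha-1)**|B|
    offset: int                  # first coordinate of the sub-block after Tdecom


@dataclass(frozen=True)
class BlockStructure:
    """Ordered sub-blocks of the decomposed embedding, with offsets."""

    blocks: tuple[Block, ...]
    M: int

    def kept_copies(self) -> dict[tuple[int, ...], Block]:
        """First-occurring copy of each distinct subset, in block order."""
        kept: dict[tuple[int, ...], Block] = {}
        for b in self.blocks:
            kept.setdefault(b.subset, b)
        return kept


def _expand_position_set(
    spec: ModelSpec, A: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, list[tuple[tuple[int, ...], int]]]:
    """Per-set decomposition matrix, its inverse, and the subset layout.

    The Kronecker product of ``T`` over the positions of ``A`` (ascending) is
    composed with the permutation that groups output coordinates by the
    subset ``B`` of positions carrying a simplex component, ordered by size
    then lexicographically.  Returns ``(D, D_inv, layout)`` where ``layout``
    lists ``(B, dim)`` in output order.
    """
    alpha = spec.alphabet.alpha
    T, T_inv = similarity_T(spec.alphabet)
    n = len(A)
    K = np.ones((1, 1), dtype=np.int64)
    K_inv = np.ones((1, 1))
    for _ in range(n):
        K = np.kron(K, T)
        K_inv = np.kron(K_inv, T_inv)
    # Decode each kron output coordinate into per-position components:
    # component 0 is the trivial part, components 1..alpha-1 the simplex part.
    keys = []
    for i in range(alpha**n):
        digits = []
        rem = i
        for _ in range(n):
            rem, d = divmod(rem, alpha)
            digits.append(d)
        digits.reverse()  # kron order: first factor is the most significant
        B = tuple(pos for pos, d in zip(A, digits) if d > 0)
        keys.append((len(B), B, i))
    order = [i for (_, _, i) in sorted(keys)]
    D = K[order, :]
    D_inv = K_inv[:, order]
    layout: list[tuple[tuple[int, ...], int]] = []
    for _, B, _ in sorted(keys):
        if layout and layout[-1][0] == B:
            layout[-1] = (B, layout[-1][1] + 1)
        else:
            layout.append((B, 1))
    return D, D_inv, layout


def _decomposition(spec: ModelSpec) -> tuple[sp.csr_matrix, sp.csr_matrix, BlockStructure]:
    """``Tdecom``, its inverse, and the resulting block structure."""
    mats, inv_mats, blocks = [], [], []
    offset = 0
    for j, A in enumerate(spec.position_sets):
        if spec.flavor == ONE_HOT:
            D, D_inv, layout = _expand_position_set(spec, A)
        else:
            # Simplex blocks are already irreducible: no expansion needed.
            dim = (spec.alphabet.alpha - 1) ** len(A)
            D = np.eye(dim, dtype=np.int64)
            D_inv = np.eye(dim)
            layout = [(A, dim)]
        mats.append(sp.csr_matrix(D))
        inv_mats.append(sp.csr_matrix(D_inv))
        for B, dim in layout:
            blocks.append(Block(j, A, B, dim, offset))
            offset += dim
    M = offset
    if M == 0:
        empty = sp.csr_matrix((0, 0))
        return empty, empty.copy(), BlockStructure((), 0)
    Tdecom = sp.block_diag(mats, format="csr")
    Tdecom_inv = sp.block_diag(inv_mats, format="csr")
    return Tdecom, Tdecom_inv, BlockStructure(tuple(blocks), M)


def build_Tdecom(spec: ModelSpec) -> tuple[sp.csr_matrix, BlockStructure]:
    """The decomposition matrix ``Tdecom`` and its block structure."""
    Tdecom, _, blocks = _decomposition(spec)
    return Tdecom, blocks


def _thin_pair(blocks: BlockStructure, sign: int) -> sp.csr_matrix:
    M = blocks.M
    kept = blocks.kept_copies()
    rows = list(range(M))
    cols = list(range(M))
    data = [1] * M
    for b in blocks.blocks:
        keep = kept[b.subset]
        if keep.offset == b.offset:
            continue
        for i in range(b.dim):
            rows.append(b.offset + i)
            cols.append(keep.offset + i)
            data.append(sign)
    return sp.csr_matrix((data, (rows, cols)), shape=(M, M))


def build_Tthin(blocks: BlockStructure) -> sp.csr_matrix:
    """The thinning matrix: later copies of each repeated sub-block become
    (copy) − (first-kept copy), which vanishes on every sequence embedding."""
    return _thin_pair(blocks, -1)


def build_Tthin_inverse(blocks: BlockStructure) -> sp.csr_matrix:
    """Inverse of :func:`build_Tthin` (re-adds the kept copy)."""
    return _thin_pair(blocks, +1)


def build_Tsort(blocks: BlockStructure) -> sp.csr_matrix:
    """Permutation moving kept sub-blocks to the top.

    Kept sub-blocks are ordered by subset size then lexicographically by
    positions; the zeroed copies follow in their original order.
    """
    kept = blocks.kept_copies()
    top: list[int] = []
    for B in sorted(kept, key=subset_sort_key):
        b = kept[B]
        top.extend(range(b.offset, b.offset + b.dim))
    bottom = [
        i
        for b in blocks.blocks
        if kept[b.subset].offset != b.offset
        for i in range(b.offset, b.offset + b.dim)
    ]
    order = top + bottom
    M = blocks.M
    return sp.csr_matrix(
        (np.ones(M, dtype=np.int64), (np.arange(M), np.array(order, dtype=np.int64))),
        shape=(M, M),
    )


# ---------------------------------------------------------------------------
# Counting (pure integer arithmetic, no matrices)
# ---------------------------------------------------------------------------

def distinct_subsets_with_multiplicity(
    spec: ModelSpec,
) -> tuple[list[tuple[int, ...]], list[int]]:
    """The distinct irreducible subsets ``B_k`` and their multiplicities ``Q_k``.

    For one-hot flavor every subset of every position set occurs; ``Q_k`` is
    the number of position sets containing ``B_k``.  For simplex flavor the
    position sets themselves are the irreducible subsets and ``Q_k`` counts
    repetitions.
    """
    counts: dict[tuple[int, ...], int] = {}
    for A in spec.position_sets:
        if spec.flavor == ONE_HOT:
            for r in range(len(A) + 1):
                for B in itertools.combinations(A, r):
                    counts[B] = counts.get(B, 0) + 1
        else:
            counts[A] = counts.get(A, 0) + 1
    subsets = sorted(counts, key=subset_sort_key)
    return subsets, [counts[B] for B in subsets]


def count_params(spec: ModelSpec) -> int:
    """Number of model parameters M = Σ_j base**|A_j| (base = alpha or alpha-1)."""
    return spec.n_features


def count_gauge(spec: ModelSpec) -> int:
    """Number of gauge freedoms, by exact combinatorial counting.

    Evaluates both ``M - Σ_k (alpha-1)**|B_k|`` and
    ``Σ_k (Q_k - 1)(alpha-1)**|B_k|`` and checks that they agree.
    """
    beta = spec.alphabet.alpha - 1
    subsets, mult = distinct_subsets_with_multiplicity(spec)
    distilled_dim = sum(beta ** len(B) for B in subsets)
    gamma_rank = count_params(spec) - distilled_dim
    gamma_mult = sum((Q - 1) * beta ** len(B) for B, Q in zip(subsets, mult))
    if gamma_rank != gamma_mult:  # pragma: no cover - algebraic identity
        raise AssertionError(
            f"gauge counts disagree: {gamma_rank} (dimension) vs {gamma_mult} (multiplicity)"
        )
    return gamma_rank


# ---------------------------------------------------------------------------
# Full distillation
# ---------------------------------------------------------------------------

@dataclass
class DistillationResult:
    """Outcome of distilling a model embedding.

    ``Tdist`` is the M x M change of basis with entries in {-1, 0, +1};
    applied to any sequence embedding it yields the distilled simplex
    embedding over the distinct subsets ``B_k`` followed by ``gamma`` zeros.
    """

    spec: ModelSpec
    Tdist: sp.csr_matrix = field(repr=False)
    Tdist_inverse: sp.csr_matrix = field(repr=False)
    gamma: int
    distinct_subsets: tuple[tuple[int, ...], ...]
    multiplicities: tuple[int, ...]
    blocks: BlockStructure = field(repr=False)

    @property
    def M(self) -> int:
        return self.spec.n_features

    @property
    def distilled_dim(self) -> int:
        return self.M - self.gamma

    @property
    def distilled_spec(self) -> ModelSpec:
        """Simplex-flavor model over the distinct subsets (the distilled model)."""
        return ModelSpec(self.spec.alphabet, self.spec.L, SIMPLEX, self.distinct_subsets)

    @property
    def distilled_labels(self) -> list[str]:
        return feature_labels(self.distilled_spec)


def distill(spec: ModelSpec) -> DistillationResult:
    """Distill a model embedding: ``Tdist = Tsort . Tthin . Tdecom``.

    One-hot specs are fully decomposed; simplex specs (already built from
    irreducible blocks) only need thinning of repeated position sets and
    sorting.  The inverse is assembled from the closed-form inverses of the
    three factors, never by numerical inversion.
    """
    if spec.J == 0:
        empty = sp.csr_matrix((0, 0))
        return DistillationResult(spec, empty, empty.copy(), 0, (), (), BlockStructure((), 0))
    Tdecom, Tdecom_inv, blocks = _decomposition(spec)
    Tthin = build_Tthin(blocks)
    Tthin_inv = build_Tthin_inverse(blocks)
    Tsort = build_Tsort(blocks)
    Tdist = (Tsort @ Tthin @ Tdecom).tocsr()
    Tdist.eliminate_zeros()
    Tdist_inv = (Tdecom_inv @ Tthin_inv @ Tsort.T).tocsr()
    Tdist_inv.eliminate_zeros()
    subsets, mult = distinct_subsets_with_multiplicity(spec)
    gamma = count_gauge(spec)
    return DistillationResult(
        spec, Tdist, Tdist_inv, gamma, tuple(subsets), tuple(mult), blocks
    )


# ---------------------------------------------------------------------------
# Enumeration of equivariant model classes
# ---------------------------------------------------------------------------

def enumerate_model_classes(
    L: int, alphabet: Alphabet | str = "AB", max_L: int = 4
) -> list[ModelSpec]:
    """All inequivalent equivariant linear models on sequences of length ``L``.

    Each position can contribute either the trivial or the simplex
    irreducible encoding, giving ``2**L`` irreducible embeddings — one per
    subset of positions — and every equivariant model class is a subset of
    these, so there are ``2**(2**L)`` classes.  Each class is returned as a
    simplex-flavor :class:`ModelSpec` over its distinct subsets (the empty
    family is the degenerate zero model); every class has zero gauge
    freedoms.
    """
    if L > max_L:
        raise ValidationError(
            f"class enumeration produces 2**(2**L) classes; L={L} exceeds max_L={max_L}"
        )
    subsets = sorted(
        (s for r in range(L + 1) for s in itertools.combinations(range(1, L + 1), r)),
        key=subset_sort_key,
    )
    classes = []
    for mask in range(2 ** len(subsets)):
        family = [B for i, B in enumerate(subsets) if mask >> i & 1]
        classes.append(ModelSpec(alphabet, L, SIMPLEX, family))
    return classes
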