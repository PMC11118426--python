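"""Matrix representations of the PSCP group on embeddings and parameters.

A representation assigns to each group element ``h`` an invertible matrix
``R(h)`` with ``R(h1 h2) = R(h1) R(h2)``.  The one-hot encoding transforms
under the permutation (defining) representation of the symmetric group at
each position; the simplex encoding transforms under the standard
representation.  Model embeddings, being direct sums of Kronecker products
of single-position encodings, transform under the matching direct sums of
Kronecker products, and equivariance means ``x(hs) = R(h) x(s)`` for every
sequence ``s``.  Parameter vectors transform contragrediently, by
``(R(h)^-1)^T``, which leaves all model predictions unchanged.

All matrices here are integer-valued, so representation identities are
checked exactly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .embeddings import ONE_HOT, ModelSpec, ParameterVector, _as_theta, simplex_single
from .sequence_space import Alphabet, PSCPElement


def perm_rep_single(h_l: Mapping[str, str], alphabet: Alphabet) -> np.ndarray:
    """The ``alpha x alpha`` permutation matrix of one character permutation.

    Satisfies ``R . onehot(c) = onehot(h_l(c))``: column ``i`` carries the
    one-hot vector of the image of character ``c_i``.
    """
    alpha = alphabet.alpha
    R = np.zeros((alpha, alpha), dtype=np.int64)
    for i, c in enumerate(alphabet.chars):
        R[alphabet.index(h_l[c]), i] = 1
    return R


def simplex_rep_single(h_l: Mapping[str, str], alphabet: Alphabet) -> np.ndarray:
    """The ``(alpha-1) x (alpha-1)`` matrix of ``h_l`` on simplex encodings.

    The unique matrix with ``R . simplex(c) = simplex(h_l(c))`` for every
    character; it is found by solving against the ``alpha - 1`` linearly
    independent simplex vectors of the non-reference characters.
    """
    basis = np.stack(
        [simplex_single(c, alphabet) for c in alphabet.chars[:-1]], axis=1
    )  # identity by construction, kept explicit so the solve is generic
    images = np.stack(
        [simplex_single(h_l[c], alphabet) for c in alphabet.chars[:-1]], axis=1
    )
    R = np.linalg.solve(basis.astype(float).T, images.astype(float).T).T
    R_int = np.rint(R).astype(np.int64)
    assert np.allclose(R, R_int), "simplex representation must be integer-valued"
    return R_int


def model_rep(spec: ModelSpec, h: PSCPElement) -> np.ndarray:
    """The ``M x M`` matrix by which the model embedding transforms under ``h``.

    Direct sum over position sets of Kronecker products, over positions in
    ascending order, of the single-position representation matrices
    (flavor-matched); the empty set contributes the 1x1 trivial block.
    """
    if h.L != spec.L:
        raise ValueError(f"group element length {h.L} does not match model L={spec.L}")
    single = perm_rep_single if spec.flavor == ONE_HOT else simplex_rep_single
    M = spec.n_features
    R = np.zeros((M, M), dtype=np.int64)
    offset = 0
    for A, dim in zip(spec.position_sets, spec.block_dims):
        block = np.ones((1, 1), dtype=np.int64)
        for l in A:
            block = np.kron(block, single(h.perms[l - 1], spec.alphabet))
        R[offset : offset + dim, offset : offset + dim] = block
        offset += dim
    return R


def transform_parameters(spec: ModelSpec, h: PSCPElement, theta) -> ParameterVector:
    """Parameters compensating a sequence transformation: ``(R(h)^-1)^T theta``.

    Guarantees ``f(s; theta) = f(hs; transformed)`` for every sequence.  The
    inverse representation matrix is obtained exactly as ``R(h^-1)``.
    """
    values = _as_theta(spec, theta)
    R_inv = model_rep(spec, h.inverse())
    out = R_inv.T @ values
    from .embeddings import feature_labels

    return ParameterVector(feature_labels(spec), out)


def check_maschke_single(alphabet: Alphabet, h_l: Mapping[str, str]) -> bool:
    """Verify the single-position Maschke decomposition for one permutation.

    Checks, in exact integer arithmetic, that the similarity matrix ``T``
    conjugates the permutation representation into the block diagonal of the
    trivial (1x1) and simplex representations:
    ``T R_ohe(h) = (R_triv(h) ⊕ R_sim(h)) T``.
    """
    from .distillation import similarity_T

    T, _ = similarity_T(alphabet)
    R_ohe = perm_rep_single(h_l, alphabet)
    R_sim = simplex_rep_single(h_l, alphabet)
    block = np.zeros((alphabet.alpha, alphabet.alpha), dtype=np.int64)
    block[0, 0] = 1
    block[1:, 1:] = R_sim
    return bool(np.array_equal(T @ R_ohe, block @ T))
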