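"""Gauge-space bases, membership tests, and gauge-fixing projections.

A gauge freedom is a parameter direction ``g`` with ``g . x(s) = 0`` for
every sequence ``s``: adding ``g`` to the parameters changes no prediction.
The gauge space is spanned by the last ``gamma`` rows of the distillation
matrix, giving a sparse basis with entries in {-1, 0, +1} without ever
forming the design matrix.

Gauge fixing restricts parameters to a complement of the gauge space via an
idempotent projection ``P`` that preserves all predictions.  The projection
built here zeroes the redundant coordinates of ``(Tdist^-1)^T theta``; its
image is one valid linear gauge (not, in general, the zero-sum gauge, for
which a separate structural check is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .distillation import DistillationResult
from .embeddings import (
    ModelSpec,
    ParameterVector,
    _as_theta,
    design_matrix,
    feature_labels,
    preset_position_sets,
)
from .errors import ValidationError
from .sequence_space import DEFAULT_ENUMERATION_CAP


@dataclass
class GaugeBasis:
    """A sparse basis of the gauge space: ``gamma`` row vectors of length M."""

    vectors: sp.csr_matrix = field(repr=False)
    source: DistillationResult = field(repr=False)

    @property
    def gamma(self) -> int:
        return self.vectors.shape[0]

    def toarray(self) -> np.ndarray:
        return self.vectors.toarray()


def gauge_basis(distres: DistillationResult) -> GaugeBasis:
    """The last ``gamma`` rows of ``Tdist``: a sparse ±1/0 gauge-space basis."""
    M, gamma = distres.M, distres.gamma
    vectors = distres.Tdist[M - gamma :, :].tocsr() if gamma else sp.csr_matrix((0, M))
    return GaugeBasis(vectors, distres)


def is_gauge_vector(
    spec: ModelSpec,
    g,
    cap: int = DEFAULT_ENUMERATION_CAP,
    tol: float = 1e-9,
) -> bool:
    """Whether ``g . x(s) = 0`` for every sequence in the (capped) enumeration.

    The test is exact for integer vectors and uses an absolute tolerance
    otherwise.
    """
    g = np.asarray(sp.csr_matrix(g).todense()).ravel() if sp.issparse(g) else np.asarray(g).ravel()
    if g.shape != (spec.n_features,):
        raise ValidationError(
            f"vector has length {g.shape[0]}, expected M={spec.n_features}"
        )
    X = design_matrix(spec, cap=cap)
    residuals = X @ g
    if np.issubdtype(g.dtype, np.integer):
        return bool(np.all(residuals == 0))
    return bool(np.all(np.abs(residuals) <= tol))


def projection_matrix(distres: DistillationResult) -> sp.csr_matrix:
    """Gauge-fixing projection ``P = Tdist^T . D . (Tdist^-1)^T``.

    ``D`` is the diagonal selector of the first ``M - gamma`` (distilled)
    coordinates.  ``P`` is idempotent, annihilates every gauge vector, and
    ``P^T x(s) = x(s)`` for every sequence, so predictions are preserved.
    """
    M, gamma = distres.M, distres.gamma
    d = np.ones(M)
    if gamma:
        d[M - gamma :] = 0.0
    D = sp.diags(d)
    P = (distres.Tdist.T @ D @ distres.Tdist_inverse.T).tocsr()
    P.eliminate_zeros()
    return P


def project_parameters(distres: DistillationResult, theta) -> ParameterVector:
    """Project parameters into the distilled gauge: ``theta_fixed = P theta``."""
    values = _as_theta(distres.spec, theta)
    fixed = projection_matrix(distres) @ values
    return ParameterVector(feature_labels(distres.spec), fixed)


def zero_sum_check(spec: ModelSpec, theta, tol: float = 1e-9) -> bool:
    """Whether pairwise one-hot parameters satisfy the zero-sum gauge.

    Requires ``spec`` to be the pairwise one-hot preset.  Checks that the
    additive parameters at every position sum to zero over characters, and
    that every pairwise block sums to zero over either position's characters
    with the other held fixed.
    """
    if spec.flavor != "one-hot" or spec.position_sets != tuple(
        preset_position_sets("pairwise", spec.L)
    ):
        raise ValidationError("zero_sum_check applies to the pairwise one-hot preset only")
    values = _as_theta(spec, theta)
    alpha = spec.alphabet.alpha
    offset = 1  # skip the constant feature
    for _ in range(spec.L):
        if abs(values[offset : offset + alpha].sum()) > tol:
            return False
        offset += alpha
    n_pairs = spec.L * (spec.L - 1) // 2
    for _ in range(n_pairs):
        block = values[offset : offset + alpha * alpha].reshape(alpha, alpha)
        if np.any(np.abs(block.sum(axis=0)) > tol) or np.any(np.abs(block.sum(axis=1)) > tol):
            return False
        offset += alpha * alpha
    return True
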