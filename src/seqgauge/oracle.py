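"""Brute-force certification against the full design matrix.

Everything here is computed from the enumerated ``alpha**L x M`` design
matrix by standard numerical linear algebra — rank, null space, column-span
comparison — with no reference to the distillation machinery, so it serves
as an independent check on the analytic results.  It only works while the
sequence space fits under the enumeration cap; scaling beyond that is
exactly what distillation provides.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .embeddings import ModelSpec, design_matrix
from .errors import ValidationError
from .sequence_space import DEFAULT_ENUMERATION_CAP

#: Relative singular-value cutoff for rank decisions.  Design-matrix entries
#: are in {-1, 0, 1} and true singular values are well separated at the
#: sizes this module handles, so the choice is not delicate.
RANK_TOL = 1e-9


def nullspace_dim(spec: ModelSpec, cap: int = DEFAULT_ENUMERATION_CAP) -> int:
    """``M - rank(design matrix)``: the number of gauge freedoms, by brute force."""
    X = design_matrix(spec, cap=cap).astype(float)
    if X.shape[1] == 0:
        return 0
    rank = np.linalg.matrix_rank(X, tol=RANK_TOL * max(X.shape) * np.abs(X).max())
    return X.shape[1] - int(rank)


def nullspace_basis(spec: ModelSpec, cap: int = DEFAULT_ENUMERATION_CAP) -> np.ndarray:
    """Orthonormal basis of the design-matrix null space (columns)."""
    X = design_matrix(spec, cap=cap).astype(float)
    if X.shape[1] == 0:
        return np.zeros((0, 0))
    return scipy.linalg.null_space(X, rcond=RANK_TOL)


def span_equal(
    specA: ModelSpec,
    specB: ModelSpec,
    cap: int = DEFAULT_ENUMERATION_CAP,
    tol: float = 1e-9,
) -> bool:
    """Whether two design matrices have the same column span.

    Both models must share alphabet and length.  Each matrix's columns are
    projected onto an orthonormal basis of the other's column space; spans
    are equal iff all residuals vanish.
    """
    if specA.alphabet != specB.alphabet or specA.L != specB.L:
        raise ValidationError("span comparison requires matching alphabet and length")
    XA = design_matrix(specA, cap=cap).astype(float)
    XB = design_matrix(specB, cap=cap).astype(float)
    QA = scipy.linalg.orth(XA, rcond=RANK_TOL) if XA.shape[1] else np.zeros((XA.shape[0], 0))
    QB = scipy.linalg.orth(XB, rcond=RANK_TOL) if XB.shape[1] else np.zeros((XB.shape[0], 0))
    scale = max(1.0, np.abs(XA).max(initial=0.0), np.abs(XB).max(initial=0.0))
    res_B_in_A = XB - QA @ (QA.T @ XB)
    res_A_in_B = XA - QB @ (QB.T @ XA)
    return bool(
        np.all(np.abs(res_B_in_A) <= tol * scale * max(XB.shape, default=1))
        and np.all(np.abs(res_A_in_B) <= tol * scale * max(XA.shape, default=1))
    )
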