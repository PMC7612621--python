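"""Batched tensor algebra for Lagrangian continuum mechanics.

All routines operate on arrays whose last axes are tensor axes; any number of
leading batch axes is allowed.  Second-order tensors are ``(..., 3, 3)``,
fourth-order tensors ``(..., 3, 3, 3, 3)``.  Fourth-order tensors map
symmetric second-order tensors to symmetric second-order tensors via double
contraction over the trailing index pair, ``(A : B)_ij = A_ijkl B_kl``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "I2",
    "I4_SYM",
    "VOIGT_PAIRS",
    "det3",
    "inv3",
    "sym",
    "dyad",
    "odot",
    "ddot42",
    "ddot44",
    "to_voigt",
    "from_voigt_index",
]

I2 = np.eye(3)

#: Symmetrized fourth-order identity, Isym_ijkl = (d_ik d_jl + d_il d_jk)/2.
I4_SYM = 0.5 * (
    np.einsum("ik,jl->ijkl", I2, I2) + np.einsum("il,jk->ijkl", I2, I2)
)

#: Voigt ordering (11, 22, 33, 12, 23, 13).
VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


def det3(A: np.ndarray) -> np.ndarray:
    """Determinant of a batch of 3x3 matrices."""
    return np.linalg.det(A)


def inv3(A: np.ndarray) -> np.ndarray:
    """Inverse of a batch of 3x3 matrices."""
    return np.linalg.inv(A)


def sym(A: np.ndarray) -> np.ndarray:
    """Symmetric part ``(A + A^T)/2`` over the trailing two axes."""
    return 0.5 * (A + np.swapaxes(A, -1, -2))


def dyad(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Dyadic product ``(A (x) B)_ijkl = A_ij B_kl``."""
    return np.einsum("...ij,...kl->...ijkl", A, B)


def odot(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Symmetrized dyadic ``(A . B)_ijkl = (A_ik B_jl + A_il B_jk)/2``.

    For ``A = B = C^{-1}`` this is the negative derivative of ``C^{-1}``
    with respect to ``C``.
    """
    return 0.5 * (
        np.einsum("...ik,...jl->...ijkl", A, B)
        + np.einsum("...il,...jk->...ijkl", A, B)
    )


def ddot42(A4: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Double contraction ``(A : B)_ij = A_ijkl B_kl``."""
    return np.einsum("...ijkl,...kl->...ij", A4, B2)


def ddot44(A4: np.ndarray, B4: np.ndarray) -> np.ndarray:
    """Double contraction ``(A : B)_ijmn = A_ijkl B_klmn``."""
    return np.einsum("...ijkl,...klmn->...ijmn", A4, B4)


def to_voigt(C4: np.ndarray) -> np.ndarray:
    """Collapse a (minor-symmetric) fourth-order tensor to a Voigt 6x6 matrix."""
    out = np.empty(C4.shape[:-4] + (6, 6), dtype=C4.dtype)
    for a, (i, j) in enumerate(VOIGT_PAIRS):
        for b, (k, l) in enumerate(VOIGT_PAIRS):
            out[..., a, b] = C4[..., i, j, k, l]
    return out


def from_voigt_index(a: int) -> tuple[int, int]:
    """Tensor index pair of Voigt slot ``a``."""
    return VOIGT_PAIRS[a]
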