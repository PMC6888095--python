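"""Gram-matrix construction and matrix-based Renyi α-order entropy.

The central object is a trace-normalized RBF Gram matrix ``A`` built from a
block of (possibly delay-embedded) samples.  Entropy-like functionals are
evaluated directly on the eigenvalue spectrum of ``A``:

    H_alpha(A) = (1 / (1 - alpha)) * log2( sum_i  lambda_i ** alpha ),

which behaves like a Renyi entropy of order ``alpha`` without any density
estimation: it is invariant under orthonormal conjugation, additive over
Kronecker products, bounded by ``log2(n)``, and tends to the von Neumann
entropy ``-sum lambda log2 lambda`` as ``alpha -> 1``.  Joint entropies of
several variables use the Hadamard product of their Gram matrices,
renormalized to unit trace.  All entropies are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateDataError, InputError, ParameterError

__all__ = [
    "GramMatrix",
    "median_bandwidth",
    "rbf_gram",
    "renyi_entropy",
    "joint_renyi_entropy",
    "conditional_entropy",
    "mutual_information",
]


@dataclass(frozen=True)
class GramMatrix:
    """A trace-normalized kernel (Gram) matrix.

    Attributes
    ----------
    entries
        The ``n x n`` symmetric PSD matrix, already divided by ``n`` so that
        ``trace(entries) == 1``.
    bandwidth
        RBF bandwidth sigma used to build the matrix.
    """

    entries: np.ndarray
    bandwidth: float

    @property
    def n(self) -> int:
        return self.entries.shape[0]


def _as_block(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise InputError("sample block must be 1-D or 2-D (n points x d coordinates)")
    if x.shape[0] < 2:
        raise InputError("sample block needs at least 2 points")
    if not np.all(np.isfinite(x)):
        raise InputError("sample block contains non-finite values")
    return x


def median_bandwidth(block) -> float:
    """Median of the pairwise Euclidean distances of a sample block.

    Self-distances (the zero diagonal) are excluded; including them would
    bias the bandwidth towards zero. Raises :class:`DegenerateDataError` if
    all points coincide, since a zero bandwidth makes the RBF kernel
    ill-defined.
    """
    x = _as_block(block)
    d = pdist(x)
    med = float(np.median(d))
    if med <= 0.0:
        raise DegenerateDataError(
            "median pairwise distance is zero (all points identical)"
        )
    return med


def rbf_gram(block, sigma: float) -> GramMatrix:
    """Trace-normalized Gaussian RBF Gram matrix of a sample block.

    ``k_ij = exp(-||a_i - a_j||^2 / (2 sigma^2))``, then divided by ``n``.
    """
    x = _as_block(block)
    if not (sigma > 0):
        raise ParameterError("sigma must be positive")
    n = x.shape[0]
    sq = squareform(pdist(x, "sqeuclidean"))
    k = np.exp(-sq / (2.0 * sigma * sigma))
    # exact symmetry guards eigvalsh against asymmetric round-off
    k = 0.5 * (k + k.T)
    return GramMatrix(entries=k / n, bandwidth=float(sigma))


def _entries(a) -> np.ndarray:
    return a.entries if isinstance(a, GramMatrix) else np.asarray(a, dtype=float)


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if alpha == 1.0:
        raise ParameterError(
            "alpha = 1 is undefined for this functional; use e.g. alpha = 1.01"
        )
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    return alpha


def _spectrum(m: np.ndarray) -> np.ndarray:
    """Eigenvalues of a trace-normalized Gram matrix, clipped and renormalized.

    Round-off can yield eigenvalues around -1e-15 whose non-integer power is
    undefined, so the spectrum is clipped at 0 and rescaled to sum to 1.
    """
    lam = np.linalg.eigvalsh(m)
    lam = np.clip(lam, 0.0, None)
    s = lam.sum()
    if s <= 0:
        raise DegenerateDataError("matrix has no positive spectrum")
    return lam / s

def entropy_from_eigenvalues(lam: np.ndarray, alpha: float) -> float:
    """H_alpha (bits) from a clipped, sum-to-one eigenvalue spectrum."""
    alpha = _check_alpha(alpha)
    pos = lam[lam > 0.0]
    return float(np.log2(np.sum(pos**alpha)) / (1.0 - alpha))


def renyi_entropy(a, alpha: float) -> float:
    """Matrix-based Renyi entropy ``H_alpha(A)`` in bits.

    ``A`` must be trace-normalized (``tr(A) = 1`` within 1e-8).
    """
    m = _entries(a)
    if abs(np.trace(m) - 1.0) > 1e-8:
        raise InputError("Gram matrix must be trace-normalized (tr(A) = 1)")
    return entropy_from_eigenvalues(_spectrum(m), alpha)


def hadamard_joint(matrices: Iterable) -> np.ndarray:
    """Trace-normalized Hadamard product of two or more Gram matrices."""
    mats = [_entries(m) for m in matrices]
    if len(mats) < 2:
        raise InputError("joint entropy needs at least two Gram matrices")
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise InputError("Gram matrices must share a common size")
    prod = mats[0].copy()
    for m in mats[1:]:
        prod *= m
    tr = np.trace(prod)
    if tr <= 0:
        raise DegenerateDataError("Hadamard product has non-positive trace")
    return prod / tr


def joint_renyi_entropy(matrices: Sequence, alpha: float) -> float:
    """Joint entropy ``H_alpha(A, B, ...)`` via the normalized Hadamard product."""
    return entropy_from_eigenvalues(_spectrum(hadamard_joint(matrices)), alpha)


def conditional_entropy(a, b, alpha: float) -> float:
    """``H_alpha(A | B) = H_alpha(A, B) - H_alpha(B)``."""
    return joint_renyi_entropy([a, b], alpha) - renyi_entropy(b, alpha)


def mutual_information(a, b, alpha: float) -> float:
    """``I_alpha(A; B) = H_alpha(A) + H_alpha(B) - H_alpha(A, B)``."""
    return (
        renyi_entropy(a, alpha)
        + renyi_entropy(b, alpha)
        - joint_renyi_entropy([a, b], alpha)
    )
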