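"""Effective-connectivity estimators.

Four directed measures between a source series ``x`` and a target series
``y`` are provided:

``te_kernel_alpha``
    Kernel-matrix Renyi transfer entropy TE_κα: TE written as a sum of
    Renyi α-order entropies and each entropy evaluated on a trace-normalized
    RBF Gram matrix of the embedded data (no density estimation). Bits.
``te_ksg``
    Kraskov-Stögbauer-Grassberger nearest-neighbor transfer entropy with a
    Theiler window, the standard k-NN estimator of neuroscience practice.
    Nats.
``te_symbolic``
    Plug-in Shannon transfer entropy on ordinal-pattern symbols. Bits.
``granger``
    Bivariate linear Granger causality, the log ratio of restricted and
    full autoregression residual variances. Nats.

All four share the time-indexing convention of :mod:`renyite.embedding`:
the present target sample is conditioned on the target past embedded at
``t - 1`` and the source past embedded at ``t - u``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import digamma

from . import kernels
from .embedding import EmbeddedBlock, EmbeddingSpec, align_te_blocks, takens_embed
from .exceptions import DegenerateDataError, InputError, ParameterError

__all__ = [
    "TEResult",
    "te_kernel_alpha",
    "te_ksg",
    "ordinal_symbolize",
    "te_symbolic",
    "granger",
]


@dataclass(frozen=True)
class TEResult:
    """A single directed-measure estimate with full parameter provenance."""

    value: float
    method: str  # kernel_alpha | ksg | symbolic | granger
    params: dict = field(default_factory=dict)
    n_effective: int = 0


def _check_series(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    for s, name in ((x, "source"), (y, "target")):
        if np.ptp(s) == 0.0:
            raise DegenerateDataError(f"{name} series is constant")
    return x, y


# ---------------------------------------------------------------------------
# kernel-matrix Renyi TE
# ---------------------------------------------------------------------------

def kernel_te_spectra(x, y, spec: EmbeddingSpec):
    """Eigenvalue spectra of the four Gram-matrix combinations TE_κα needs.

    Builds RBF Gram matrices for the present target sample, the target past
    and the source past (each with its own median-distance bandwidth) and
    returns the clipped unit-sum spectra of
    ``(target_past ∘ source_past)``, ``(target ∘ target_past ∘ source_past)``,
    ``(target ∘ target_past)`` and ``target_past``, plus the sample count.
    Factoring this out lets several α values share the eigendecompositions.
    """
    x, y = _check_series(x, y)
    target, target_past, source_past = align_te_blocks(x, y, spec, spec)
    grams = []
    for block in (target, target_past, source_past):
        sigma = kernels.median_bandwidth(block)
        grams.append(kernels.rbf_gram(block, sigma).entries)
    k_t, k_tp, k_sp = grams
    spectra = (
        kernels._spectrum(kernels.hadamard_joint([k_tp, k_sp])),
        kernels._spectrum(kernels.hadamard_joint([k_t, k_tp, k_sp])),
        kernels._spectrum(kernels.hadamard_joint([k_t, k_tp])),
        kernels._spectrum(k_tp),
    )
    return spectra, target.shape[0]


def te_kernel_alpha(
    x, y, spec: EmbeddingSpec, alpha: Union[float, tuple, list] = 2.0
):
    """Kernel-matrix Renyi α-order transfer entropy TE_κα(x→y) in bits.

    ``alpha`` may be a scalar (returns one :class:`TEResult`) or a sequence
    (returns a list, reusing the same eigendecompositions, which dominate the
    cost).  Finite-sample estimates may be slightly negative; values are not
    clipped — significance is the job of the surrogate test.
    """
    spectra, n = kernel_te_spectra(x, y, spec)
    alphas = np.atleast_1d(np.asarray(alpha, dtype=float))
    results = []
    for a in alphas:
        h = [kernels.entropy_from_eigenvalues(lam, a) for lam in spectra]
        value = h[0] - h[1] + h[2] - h[3]
        results.append(
            TEResult(
                value=float(value),
                method="kernel_alpha",
                params={"d": spec.d, "tau": spec.tau, "u": spec.u, "alpha": float(a)},
                n_effective=n,
            )
        )
    return results[0] if np.isscalar(alpha) else results


# ---------------------------------------------------------------------------
# KSG nearest-neighbor TE
# ---------------------------------------------------------------------------

def _chebyshev(a: np.ndarray) -> np.ndarray:
    return cdist(a, a, "chebyshev")


def te_ksg(x, y, spec: EmbeddingSpec, K: int = 4, theiler: int | None = None) -> TEResult:
    """Kraskov-Stögbauer-Grassberger transfer entropy TE_KSG(x→y) in nats.

    The number of neighbors ``K`` is fixed in the joint space
    (present target, target past, source past) under the Chebyshev norm, and
    the distance to the K-th neighbor is projected to the marginal spaces
    where strictly closer points are counted.  Samples within ``theiler``
    time steps of the reference point are excluded from searches and counts
    (Theiler correction; defaults to the embedding delay, i.e. one ACT under
    the usual convention).
    """
    x, y = _check_series(x, y)
    if K < 1:
        raise ParameterError("K must be >= 1")
    if theiler is None:
        theiler = spec.tau
    if theiler < 0:
        raise ParameterError("theiler must be >= 0")
    target, target_past, source_past = align_te_blocks(x, y, spec, spec)
    n = target.shape[0]
    if K >= n:
        raise ParameterError(f"K={K} must be smaller than n_effective={n}")

    d_t = _chebyshev(target)
    d_tp = _chebyshev(target_past)
    d_sp = _chebyshev(source_past)
    d_joint = np.maximum(np.maximum(d_t, d_tp), d_sp)

    idx = np.arange(n)
    excl = np.abs(idx[:, None] - idx[None, :]) <= theiler  # includes diagonal
    d_joint_m = np.where(excl, np.inf, d_joint)
    eps = np.partition(d_joint_m, K - 1, axis=1)[:, K - 1]
    if not np.all(np.isfinite(eps)):
        raise ParameterError("Theiler window leaves fewer than K neighbors")

    def count(dm):
        return ((dm < eps[:, None]) & ~excl).sum(axis=1)

    n_tp = count(d_tp)
    n_t_tp = count(np.maximum(d_t, d_tp))
    n_tp_sp = count(np.maximum(d_tp, d_sp))

    value = digamma(K) + np.mean(
        digamma(n_tp + 1) - digamma(n_t_tp + 1) - digamma(n_tp_sp + 1)
    )
    return TEResult(
        value=float(value),
        method="ksg",
        params={"d": spec.d, "tau": spec.tau, "u": spec.u, "K": K, "theiler": theiler},
        n_effective=n,
    )


# ---------------------------------------------------------------------------
# symbolic (ordinal-pattern) TE
# ---------------------------------------------------------------------------

def ordinal_symbolize(block) -> np.ndarray:
    """Ordinal-pattern symbols of an embedded block.

    For each row ``(x(t), x(t-tau), ..., x(t-(d-1)tau))`` the symbol is the
    permutation ``(r_1, ..., r_d)`` of delay indices that sorts the
    amplitudes ascending; amplitude ties are broken by the smaller delay
    index first (stable sort).
    """
    rows = block.rows if isinstance(block, EmbeddedBlock) else np.asarray(block)
    if rows.ndim != 2:
        raise InputError("expected a 2-D embedded block")
    return np.argsort(rows, axis=1, kind="stable")


def _encode(symbols: np.ndarray) -> np.ndarray:
    """Pack permutation symbols into integers (base-d positional code)."""
    d = symbols.shape[1]
    weights = d ** np.arange(d)
    return symbols @ weights


def _shannon(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def te_symbolic(x, y, spec: EmbeddingSpec) -> TEResult:
    """Symbolic transfer entropy TE_Sym(x→y) in bits.

    Both series are delay-embedded and ordinal-symbolized; the plug-in
    Shannon TE over the joint distribution of (next target symbol, current
    target symbol, source symbol lagged by u-1) is evaluated through the
    four-entropy decomposition, with probabilities from symbol counts.
    """
    x, y = _check_series(x, y)
    u = spec.u
    sx = _encode(ordinal_symbolize(takens_embed(x, spec.d, spec.tau)))
    sy = _encode(ordinal_symbolize(takens_embed(y, spec.d, spec.tau)))
    t0 = (spec.d - 1) * spec.tau  # first time index with a defined symbol
    l = x.size
    # triples (s^y_{t+1}, s^y_t, s^x_{t+1-u}) over valid t
    t_first = max(t0, t0 + u - 1)
    t_last = l - 2
    n = t_last - t_first + 1
    if n < 10:
        raise InputError("series too short for symbolic TE at these parameters")
    t = np.arange(t_first, t_last + 1)
    y_next = sy[t + 1 - t0]
    y_now = sy[t - t0]
    x_past = sx[t + 1 - u - t0]

    base = int(max(y_next.max(), y_now.max(), x_past.max())) + 1
    h_yx = _shannon(y_now * base + x_past)
    h_nyx = _shannon((y_next * base + y_now) * base + x_past)
    h_ny = _shannon(y_next * base + y_now)
    h_y = _shannon(y_now)
    return TEResult(
        value=h_yx - h_nyx + h_ny - h_y,
        method="symbolic",
        params={"d": spec.d, "tau": spec.tau, "u": spec.u},
        n_effective=n,
    )


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

def granger(x, y, order: int = 3) -> TEResult:
    """Bivariate Granger causality GC(x→y) in nats.

    Fits, by ordinary least squares over the same sample range, a restricted
    autoregression of ``y`` on its own ``order`` lags and a full bivariate
    model that adds the lags of ``x``; returns
    ``ln(var(e_restricted) / var(e_full))``, nonnegative up to round-off.
    """
    x, y = _check_series(x, y)
    if order < 1:
        raise ParameterError("order must be >= 1")
    l = y.size
    if l <= 10 * order:
        raise InputError(f"series of length {l} too short for order {order}")
    t = np.arange(order, l)
    y_resp = y[t]
    y_lags = np.column_stack([y[t - k] for k in range(1, order + 1)])
    x_lags = np.column_stack([x[t - k] for k in range(1, order + 1)])
    const = np.ones((t.size, 1))

    def residual_var(design):
        coef, _, rank, _ = np.linalg.lstsq(design, y_resp, rcond=None)
        if rank < design.shape[1]:
            raise DegenerateDataError("rank-deficient autoregression design")
        resid = y_resp - design @ coef
        return float(resid @ resid) / resid.size

    var_r = residual_var(np.hstack([const, y_lags]))
    var_f = residual_var(np.hstack([const, y_lags, x_lags]))
    if var_f <= 0:
        raise DegenerateDataError("full model fits the target exactly")
    return TEResult(
        value=float(np.log(var_r / var_f)),
        method="granger",
        params={"order": order},
        n_effective=int(t.size),
    )
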