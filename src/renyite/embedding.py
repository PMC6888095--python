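"""Delay embedding and the time-index bookkeeping of transfer entropy.

A scalar series ``x`` is reconstructed in state space by Takens delay
embedding: the state at time ``t`` is the vector
``(x(t), x(t - tau), ..., x(t - (d-1) tau))`` (most-recent first), with
embedding dimension ``d`` and delay ``tau``.  The embedding delay is
conventionally set to one autocorrelation time (ACT), the first lag at which
the sample autocorrelation drops to 1/e.

Transfer entropy from ``x`` to ``y`` with interaction delay ``u`` conditions
the present target sample ``y_t`` on the target past (embedded at ``t - 1``)
and the source past (embedded at ``t - u``); :func:`align_te_blocks` builds
the three row-aligned blocks over the common valid time range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, InputError, InsufficientDataError

__all__ = [
    "EmbeddingSpec",
    "EmbeddedBlock",
    "autocorrelation_time",
    "takens_embed",
    "align_te_blocks",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """State-space reconstruction parameters.

    ``d``: embedding dimension, ``tau``: embedding delay in samples,
    ``u``: interaction delay (driver-to-driven lag) in samples.
    """

    d: int = 3
    tau: int = 1
    u: int = 1

    def __post_init__(self):
        if self.d < 1 or self.tau < 1 or self.u < 1:
            raise InputError("EmbeddingSpec requires d >= 1, tau >= 1, u >= 1")


@dataclass(frozen=True)
class EmbeddedBlock:
    """Delay-embedded samples: one row per valid time index.

    ``t0`` is the first valid 0-based time index of the original series;
    row ``i`` corresponds to time ``t0 + i``.
    """

    rows: np.ndarray
    t0: int

    @property
    def d(self) -> int:
        return self.rows.shape[1]


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise InputError("time series must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise InputError("time series contains non-finite values")
    return x


def autocorrelation_time(x) -> int:
    """First lag at which the sample ACF falls to <= 1/e, capped at l/4.

    The signed ACF value is used (an ACF of -1 at lag 1 therefore counts as a
    crossing).  Raises :class:`DegenerateDataError` for constant series.
    """
    x = _as_series(x)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        raise DegenerateDataError("constant series has no autocorrelation time")
    cap = max(1, x.size // 4)
    thresh = 1.0 / np.e
    for k in range(1, cap + 1):
        rho = float(xc[:-k] @ xc[k:]) / denom
        if rho <= thresh:
            return k
    return cap


def takens_embed(x, d: int, tau: int) -> EmbeddedBlock:
    """Takens delay embedding with dimension ``d`` and delay ``tau``.

    Row for time ``t`` is ``(x(t), x(t - tau), ..., x(t - (d-1) tau))``.
    """
    x = _as_series(x)
    if d < 1 or tau < 1:
        raise InputError("embedding requires d >= 1 and tau >= 1")
    t0 = (d - 1) * tau
    if x.size <= t0:
        raise InputError(
            f"series of length {x.size} too short for d={d}, tau={tau}; "
            f"need at least {t0 + 1} samples"
        )
    cols = [x[t0 - j * tau : x.size - j * tau] for j in range(d)]
    return EmbeddedBlock(rows=np.column_stack(cols), t0=t0)


def align_te_blocks(x, y, spec_x: EmbeddingSpec, spec_y: EmbeddingSpec):
    """Row-aligned blocks (y_t, past of y at t-1, past of x at t-u).

    The first valid 0-based index is
    ``max(1 + (dy-1) tau_y, u + (dx-1) tau_x)`` so that every delayed sample
    exists.  Returns ``(target, target_past, source_past)``, each with one
    row per time index; ``target`` is an (n, 1) column.
    """
    x = _as_series(x)
    y = _as_series(y)
    if x.size != y.size:
        raise InputError("source and target series must have equal length")
    l = x.size
    u = spec_x.u
    t_first = max(1 + (spec_y.d - 1) * spec_y.tau, u + (spec_x.d - 1) * spec_x.tau)
    n = l - t_first
    if n < 10:
        raise InsufficientDataError(
            f"only {max(n, 0)} aligned samples (need >= 10); series too short "
            f"for d=({spec_x.d},{spec_y.d}), tau=({spec_x.tau},{spec_y.tau}), u={u}"
        )
    t = np.arange(t_first, l)
    target = y[t][:, None]
    target_past = np.column_stack(
        [y[t - 1 - j * spec_y.tau] for j in range(spec_y.d)]
    )
    source_past = np.column_stack(
        [x[t - u - j * spec_x.tau] for j in range(spec_x.d)]
    )
    return target, target_past, source_past
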