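"""Synthetic validation data generators.

Two benchmark systems are provided:

* A unidirectional bivariate VAR(3) pair ``z_t = c + sum_i Q_i z_{t-i} + eps_t``
  whose coupling direction is imposed by zeroing the cross-coefficients of
  the non-causal direction; the remaining coefficients are drawn at random
  and rejected until the companion matrix is comfortably stable.  A noise
  mixer then replaces a fraction ``gamma`` of the (Frobenius-normalized)
  signal with an instantaneous random mixture of three independent AR(3)
  noise sources, emulating volume conduction.

* The modified linear Kus 5-channel network: an EEG-like input drives
  channel 1; channels 2-4 are scaled (0.4), delayed (4 or 8 samples) copies
  down a chain; channel 5 is pure noise.  Scaled internal noise and external
  white Gaussian noise (variance equal to the scale factor v, a quarter of
  the driving series' variance) contaminate every channel.

All generators are deterministic given a seed or a ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GenerationError, InputError, ParameterError

__all__ = [
    "VARModelSpec",
    "NetworkTruth",
    "sample_var_spec",
    "simulate_var",
    "mix_noise",
    "surrogate_eeg",
    "simulate_kus",
    "kus_truth",
]

BURN_IN = 200
STABILITY_RADIUS = 0.95
MAX_DRAWS = 1000


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class VARModelSpec:
    """Unidirectional bivariate VAR(3) parameters.

    ``Q`` has shape (3, 2, 2); state order is (x, y).  ``direction`` is
    'x_to_y' (the x-row cross-coefficients Q[:, 0, 1] are zero) or 'y_to_x'
    (Q[:, 1, 0] zero).
    """

    Q: np.ndarray
    c: np.ndarray
    noise_sd: float = 1.0
    direction: str = "x_to_y"

    def companion(self) -> np.ndarray:
        top = np.hstack([self.Q[0], self.Q[1], self.Q[2]])
        bottom = np.hstack([np.eye(4), np.zeros((4, 2))])
        return np.vstack([top, bottom])

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))


@dataclass(frozen=True)
class NetworkTruth:
    """Ground-truth directed couplings of a simulated network (1-based pairs)."""

    positives: frozenset
    n_channels: int = 5

    @property
    def negatives(self) -> frozenset:
        allpairs = {
            (i, j)
            for i in range(1, self.n_channels + 1)
            for j in range(1, self.n_channels + 1)
            if i != j
        }
        return frozenset(allpairs - set(self.positives))

    def to_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_channels, self.n_channels), dtype=bool)
        for i, j in self.positives:
            m[i - 1, j - 1] = True
        return m


def _stable_companion_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a univariate AR(p)."""
    p = coeffs.size
    comp = np.zeros((p, p))
    comp[0] = coeffs
    comp[1:, :-1] = np.eye(p - 1)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def sample_var_spec(direction: str = "x_to_y", seed=None) -> VARModelSpec:
    """Draw a random, stable, unidirectional VAR(3) specification.

    Coefficients and constants are uniform on [-1, 1]; the cross-coefficients
    of the non-causal direction are zeroed, and draws are rejected until the
    companion spectral radius is below 0.95.
    """
    if direction not in ("x_to_y", "y_to_x"):
        raise ParameterError("direction must be 'x_to_y' or 'y_to_x'")
    rng = _rng(seed)
    for _ in range(MAX_DRAWS):
        Q = rng.uniform(-1.0, 1.0, size=(3, 2, 2))
        if direction == "x_to_y":
            Q[:, 0, 1] = 0.0  # x receives nothing from y
        else:
            Q[:, 1, 0] = 0.0  # y receives nothing from x
        c = rng.uniform(-1.0, 1.0, size=2)
        spec = VARModelSpec(Q=Q, c=c, direction=direction)
        if spec.spectral_radius() < STABILITY_RADIUS:
            return spec
    raise GenerationError("no stable VAR(3) specification found in 1000 draws")


def simulate_var(spec: VARModelSpec, l: int, seed=None) -> np.ndarray:
    """Iterate the VAR(3) recursion; returns a 2 x l array after burn-in."""
    if l < 100:
        raise InputError("l must be >= 100")
    rng = _rng(seed)
    total = l + BURN_IN
    eps = rng.normal(0.0, spec.noise_sd, size=(total, 2))
    z = np.zeros((total + 3, 2))
    for t in range(3, total + 3):
        z[t] = (
            spec.c
            + spec.Q[0] @ z[t - 1]
            + spec.Q[1] @ z[t - 2]
            + spec.Q[2] @ z[t - 3]
            + eps[t - 3]
        )
    out = z[3 + BURN_IN :].T
    if not np.all(np.isfinite(out)) or np.max(np.abs(out)) > 1e8:
        raise GenerationError("VAR simulation diverged (unstable specification)")
    return out


def _sample_ar3(rng: np.random.Generator, l: int) -> np.ndarray:
    """One realization of a random stable AR(3) process (unit innovations)."""
    for _ in range(MAX_DRAWS):
        a = rng.uniform(-1.0, 1.0, size=3)
        if _stable_companion_radius(a) < STABILITY_RADIUS:
            break
    else:
        raise GenerationError("no stable AR(3) noise model found")
    total = l + BURN_IN
    eps = rng.normal(size=total)
    s = np.zeros(total + 3)
    for t in range(3, total + 3):
        s[t] = a[0] * s[t - 1] + a[1] * s[t - 2] + a[2] * s[t - 3] + eps[t - 3]
    return s[3 + BURN_IN :]


def mix_noise(Z: np.ndarray, gamma, seed=None) -> np.ndarray:
    """Convex combination of normalized signal and mixed AR(3) noise.

    ``out = (1 - gamma) Z/||Z||_F + gamma (Theta Xi)/||Theta Xi||_F`` with
    ``Theta`` a random 2x3 instantaneous mixing matrix and ``Xi`` three
    independent AR(3) noise series.  A scalar ``gamma`` applies symmetric
    noise; a 2-vector applies its entries row-wise (asymmetric noise).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != 2:
        raise InputError("Z must be a 2 x l array")
    g = np.asarray(gamma, dtype=float)
    if g.ndim not in (0, 1) or (g.ndim == 1 and g.size != 2):
        raise ParameterError("gamma must be a scalar or a 2-vector")
    if np.any(g < 0) or np.any(g > 1):
        raise ParameterError("gamma must lie in [0, 1]")
    rng = _rng(seed)
    l = Z.shape[1]
    theta = rng.uniform(-1.0, 1.0, size=(2, 3))
    xi = np.vstack([_sample_ar3(rng, l) for _ in range(3)])
    noise = theta @ xi
    zn = Z / np.linalg.norm(Z)
    nn = noise / np.linalg.norm(noise)
    gcol = g if g.ndim == 0 else g[:, None]
    return (1.0 - gcol) * zn + gcol * nn


def surrogate_eeg(l: int, seed=None, fs: float = 250.0) -> np.ndarray:
    """Synthetic EEG-like input series (stand-in for a real scalp channel).

    1/f-weighted Gaussian noise with an added 8-12 Hz narrowband (alpha)
    component at a nominal ``fs`` Hz sampling rate, standardized to zero
    mean and unit variance.
    """
    if l < 256:
        raise InputError("l must be >= 256")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(l, d=1.0 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    weight = np.zeros_like(freqs)
    nz = freqs > 0
    weight[nz] = 1.0 / np.sqrt(freqs[nz])  # 1/f power
    weight += 0.5 * np.exp(-0.5 * ((freqs - 10.0) / 1.5) ** 2)  # alpha bump
    x = np.fft.irfft(spec * weight, n=l)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise GenerationError("degenerate surrogate EEG draw")
    return x / sd


#: directed couplings of the modified Kus network: delay 4 for 1→2 and 2→3,
#: delay 8 for 2→4; channel 5 is uncoupled noise
KUS_COUPLING = 0.4
KUS_DELAYS = {(1, 2): 4, (2, 3): 4, (2, 4): 8}


def simulate_kus(input_series, seed=None) -> np.ndarray:
    """Generate one trial of the modified linear Kus 5-channel network.

    ``ch1 = beta + v*eta1``; ``ch2 = 0.4*ch1(t-4) + v2*eta2``;
    ``ch3 = 0.4*ch2(t-4) + v3*eta3``; ``ch4 = 0.4*ch2(t-8) + v4*eta4``;
    ``ch5 = v*eta5``; each equation's scale factor v is a quarter of the
    variance of its driving series (the input series for channels 1 and 5).
    External white Gaussian noise with variance v (input-series based) is
    then added to every channel, and the first 8 samples (the longest
    delay) are trimmed so all channels are aligned.  Returns 5 x (l - 8).
    """
    beta = np.asarray(input_series, dtype=float).ravel()
    l = beta.size
    if l < 64:
        raise InputError("input series must have at least 64 samples")
    rng = _rng(seed)
    v0 = 0.25 * float(np.var(beta))
    if v0 <= 0:
        raise InputError("input series must not be constant")
    eta = rng.normal(size=(5, l))

    def shifted(s, delay):
        out = np.zeros(l)
        out[delay:] = s[:-delay]
        return out

    x1 = beta + v0 * eta[0]
    v2 = 0.25 * float(np.var(x1))
    x2 = KUS_COUPLING * shifted(x1, 4) + v2 * eta[1]
    v3 = 0.25 * float(np.var(x2))
    x3 = KUS_COUPLING * shifted(x2, 4) + v3 * eta[2]
    x4 = KUS_COUPLING * shifted(x2, 8) + 0.25 * float(np.var(x2)) * eta[3]
    x5 = v0 * eta[4]
    channels = np.vstack([x1, x2, x3, x4, x5])
    channels += rng.normal(0.0, np.sqrt(v0), size=channels.shape)
    return channels[:, 8:]


def kus_truth() -> NetworkTruth:
    """Ground truth of the modified Kus network (direct + indirect couplings).

    Direct: 1→2, 2→3, 2→4.  Indirect: 1→3, 1→4 (chain), 3→4 (common driver
    with lead: channel 3 precedes channel 4 by 4 samples).  Everything
    touching channel 5 is a true negative.
    """
    return NetworkTruth(
        positives=frozenset({(1, 2), (2, 3), (2, 4), (1, 3), (1, 4), (3, 4)})
    )
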