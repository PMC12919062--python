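"""Deterministic generative model of vascular waveforms.

A recording is modeled as the convolution of an impulse train at the pulse
onset times ``z`` with a single parametric impulse response ``h`` (the pulse
shape), plus a low-frequency baseline drift and additive white Gaussian
noise::

    y(t) = sum_i h(t - z_i) + b(t) + eps(t)

The impulse response is a windowed Fourier series,

    h(t) = a * gamma(t) * (w . phi(t) + 1)

where ``gamma`` is a product of two sigmoids (left/right temporal bounds on
the pulse) and ``phi`` stacks sine/cosine harmonics of a fundamental ``f_h``.
All time coordinates are continuous and in seconds; nothing in the model is
tied to sample indices, so irregular sampling is supported throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


__all__ = [
    "WaveformObservation",
    "PulseShape",
    "BaselineDrift",
    "PulseTiming",
    "window",
    "fourier_basis",
    "impulse_response",
    "impulse_response_deriv",
    "drift_basis",
    "baseline",
    "interval_map",
    "times_from_intervals",
    "intervals_of",
    "anchor_index",
    "clean_signal",
    "synthesize",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class WaveformObservation:
    """One recording: sample times ``t`` (s) and values ``y``.

    The grid need not be uniform, but times must be strictly increasing.
    """

    t: np.ndarray
    y: np.ndarray
    fs_nominal: float | None = None

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.y = _as_float_array(self.y, "y")
        if self.t.ndim != 1 or self.y.ndim != 1 or len(self.t) != len(self.y):
            raise ValueError("t and y must be 1-D with equal length")
        if len(self.t) < 2:
            raise ValueError("need at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def fs_median(self) -> float:
        return float(1.0 / np.median(np.diff(self.t)))


@dataclass
class PulseShape:
    """Windowed-Fourier impulse response parameters.

    ``a`` scales the pulse; ``w`` holds K Fourier weights (K/2 harmonics of
    ``f_h``, sine/cosine interleaved); ``g1..g4`` parameterize the sigmoid
    window: left steepness/center, right steepness/center (support roughly
    the interval (g2, g4)).
    """

    a: float
    w: np.ndarray
    f_h: float
    g1: float
    g2: float
    g3: float
    g4: float

    def __post_init__(self) -> None:
        self.w = _as_float_array(self.w, "w")
        if self.w.ndim != 1 or len(self.w) % 2 != 0 or len(self.w) < 2:
            raise ValueError("w must be 1-D with even length >= 2")
        if not (self.g1 > 0 and self.g3 > 0):
            raise ValueError("window steepness g1, g3 must be positive")
        if not self.g2 < self.g4:
            raise ValueError("window requires g2 < g4")
        if not self.f_h > 0:
            raise ValueError("f_h must be positive")

    @property
    def K(self) -> int:
        return len(self.w)

    @property
    def support(self) -> tuple[float, float]:
        """Interval outside which the window (hence the pulse) is negligible."""
        return (self.g2 - 12.0 / self.g1, self.g4 + 12.0 / self.g3)


@dataclass
class BaselineDrift:
    """Slow additive drift: weights over (1, t, sin/cos harmonics of f_b)."""

    b: np.ndarray
    f_b: float

    def __post_init__(self) -> None:
        self.b = _as_float_array(self.b, "b")
        if self.b.ndim != 1 or len(self.b) < 1:
            raise ValueError("b must be a non-empty 1-D vector")
        if not self.f_b > 0:
            raise ValueError("f_b must be positive")

    @property
    def B(self) -> int:
        return len(self.b)

    @classmethod
    def none(cls, duration: float = 11.0) -> "BaselineDrift":
        return cls(b=np.zeros(1), f_b=1.0 / max(duration, 1e-6))


def anchor_index(M: int) -> int:
    """1-based anchor index m = floor(M/2), clamped to [1, M]."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return min(max(M // 2, 1), M)


@dataclass
class PulseTiming:
    """Pulse onset times with the anchor convention.

    The anchor pulse ``z[m-1]`` (1-based index ``m = floor(M/2)``) is the
    first pulse at or after the reference time ``t0`` (center of the
    observed window); its position within the preceding inter-pulse interval
    is the only absolute-time degree of freedom.
    """

    z: np.ndarray
    t0: float
    m: int | None = None

    def __post_init__(self) -> None:
        self.z = _as_float_array(self.z, "z")
        if self.z.ndim != 1 or len(self.z) < 1:
            raise ValueError("z must be non-empty 1-D")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if self.m is None:
            self.m = anchor_index(len(self.z))
        if not 1 <= self.m <= len(self.z):
            raise ValueError("anchor index m out of range")

    @property
    def M(self) -> int:
        return len(self.z)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.z)

    @property
    def f_hr(self) -> float:
        """Average heart rate (Hz) implied by the mean inter-pulse interval."""
        if self.M < 2:
            raise ValueError("need at least 2 pulses for a heart rate")
        return float(1.0 / np.mean(self.intervals))


# ---------------------------------------------------------------------------
# Forward-model operations


def window(t_query, shape: PulseShape) -> np.ndarray:
    """Sigmoid-product window gamma(t) in (0, 1)."""
    t = _as_float_array(t_query, "t_query")
    return expit(shape.g1 * (t - shape.g2)) * expit(-shape.g3 * (t - shape.g4))


def fourier_basis(t_query, K: int, f_h: float) -> np.ndarray:
    """phi(t): (..., K) array of interleaved sin/cos harmonics of f_h."""
    t = np.asarray(t_query, dtype=float)
    k = np.arange(1, K // 2 + 1)
    ang = 2.0 * np.pi * f_h * t[..., None] * k
    out = np.empty(t.shape + (K,), dtype=float)
    out[..., 0::2] = np.sin(ang)
    out[..., 1::2] = np.cos(ang)
    return out


def impulse_response(t_query, shape: PulseShape) -> np.ndarray:
    """Single-pulse shape h(t) = a * gamma(t) * (w . phi(t) + 1)."""
    t = _as_float_array(t_query, "t_query")
    phi = fourier_basis(t, shape.K, shape.f_h)
    return shape.a * window(t, shape) * (phi @ shape.w + 1.0)


def impulse_response_deriv(t_query, shape: PulseShape) -> np.ndarray:
    """Analytic time derivative h'(t)."""
    t = _as_float_array(t_query, "t_query")
    s1 = expit(shape.g1 * (t - shape.g2))
    s2 = expit(-shape.g3 * (t - shape.g4))
    gam = s1 * s2
    dgam = gam * (shape.g1 * (1.0 - s1) - shape.g3 * (1.0 - s2))
    phi = fourier_basis(t, shape.K, shape.f_h)
    # derivative of the Fourier sum: rotate weights by the harmonic frequency
    k = np.arange(1, shape.K // 2 + 1)
    omega = 2.0 * np.pi * shape.f_h * k
    wt = np.empty_like(shape.w)
    wt[0::2] = -omega * shape.w[1::2]
    wt[1::2] = omega * shape.w[0::2]
    return shape.a * (dgam * (phi @ shape.w + 1.0) + gam * (phi @ wt))


def drift_basis(t_query, B: int, f_b: float) -> np.ndarray:
    """beta(t): (..., B) array (1, t, sin/cos harmonics of f_b)."""
    t = np.asarray(t_query, dtype=float)
    out = np.empty(t.shape + (B,), dtype=float)
    out[..., 0] = 1.0
    if B > 1:
        out[..., 1] = t
    if B > 2:
        n_harm = (B - 2 + 1) // 2
        k = np.arange(1, n_harm + 1)
        ang = 2.0 * np.pi * f_b * t[..., None] * k
        trig = np.empty(t.shape + (2 * n_harm,), dtype=float)
        trig[..., 0::2] = np.sin(ang)
        trig[..., 1::2] = np.cos(ang)
        out[..., 2:] = trig[..., : B - 2]
    return out


def baseline(t_query, drift: BaselineDrift) -> np.ndarray:
    """Drift value b . beta(t)."""
    t = _as_float_array(t_query, "t_query")
    return drift_basis(t, drift.B, drift.f_b) @ drift.b


def interval_map(M: int, m: int) -> np.ndarray:
    """Affine map D_m from intervals to times: z = z' @ D_m + z_m * 1.

    ``D_m`` has shape (M-1, M); column j (1-based) holds +1 for intervals
    m..j-1 and -1 for intervals j..m-1, so cumulative sums run outward from
    the anchor pulse.
    """
    if not 1 <= m <= M:
        raise ValueError("anchor index m out of range")
    D = np.zeros((max(M - 1, 0), M))
    for j in range(1, M + 1):
        if j > m:
            D[m - 1 : j - 1, j - 1] = 1.0
        elif j < m:
            D[j - 1 : m - 1, j - 1] = -1.0
    return D


def times_from_intervals(intervals, z_m: float, m: int) -> np.ndarray:
    """Rebuild pulse times from intervals and the anchor time (fast path)."""
    zp = _as_float_array(intervals, "intervals")
    M = len(zp) + 1
    if not 1 <= m <= M:
        raise ValueError("anchor index m out of range")
    z = np.empty(M)
    z[m - 1] = z_m
    if m < M:
        z[m:] = z_m + np.cumsum(zp[m - 1 :])
    if m > 1:
        z[: m - 1] = z_m - np.cumsum(zp[: m - 1][::-1])[::-1]
    return z


def intervals_of(z) -> np.ndarray:
    return np.diff(_as_float_array(z, "z"))


def clean_signal(t_query, timing: PulseTiming, shape: PulseShape) -> np.ndarray:
    """Noiseless signal: superposition of shifted impulse responses."""
    t = _as_float_array(t_query, "t_query")
    tau = t[..., None] - timing.z
    phi = fourier_basis(tau, shape.K, shape.f_h)
    h = shape.a * window(tau, shape) * (phi @ shape.w + 1.0)
    return h.sum(axis=-1)


def synthesize(
    t_query,
    timing: PulseTiming,
    shape: PulseShape,
    drift: BaselineDrift | None = None,
    sigma_eps: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Clean signal + drift + white Gaussian noise; deterministic given seed."""
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be >= 0")
    t = _as_float_array(t_query, "t_query")
    y = clean_signal(t, timing, shape)
    if drift is not None:
        y = y + baseline(t, drift)
    if sigma_eps > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma_eps, size=t.shape)
    return y
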