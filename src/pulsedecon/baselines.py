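"""Traditional vascular-waveform analysis pipeline: filters, heuristic
timing markers, and segmentation-averaging shape extraction.

These are the reference algorithms the deconvolution method is compared
against: linear IIR bandpass filters (Butterworth and Chebyshev type II,
0.5-12 Hz), per-beat heuristic markers (systolic peak SP, onset ON, peak
first derivative U, peak second derivative A), and pulse-shape extraction by
segmenting between consecutive markers and averaging, which ignores overlap
between adjacent pulses (its documented weakness).

The widely used Python PPG toolboxes ship Butterworth-family bandpasses as
their default filters and apply them zero-phase (forward-backward), so that
is the default here; a single-pass option retains the phase distortion of a
causal IIR application for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ExtractedShape",
    "bandpass_filter",
    "detect_marker",
    "segment_average_shape",
    "MARKERS",
]

MARKERS = ("SP", "ON", "U", "A")

#: minimum beat separation (s) used by the adaptive cycle detector: 150 BPM
MIN_BEAT_SEPARATION = 60.0 / 150.0


@dataclass
class ExtractedShape:
    """Averaged pulse shape on a uniform grid relative to the pulse anchor."""

    t_rel: np.ndarray
    values: np.ndarray
    n_pulses: int

    def __post_init__(self) -> None:
        self.t_rel = np.asarray(self.t_rel, float)
        self.values = np.asarray(self.values, float)
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        dt = np.diff(self.t_rel)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("t_rel must be uniform")


def bandpass_filter(
    y,
    fs: float,
    family: str = "butterworth",
    band: tuple[float, float] = (0.5, 12.0),
    zero_phase: bool = True,
) -> np.ndarray:
    """0.5-12 Hz IIR bandpass (2nd-order Butterworth or 4th-order Chebyshev II).

    Zero-phase (``sosfiltfilt``) by default, matching how the standard PPG
    toolboxes apply their filters; ``zero_phase=False`` gives the causal
    single-pass application, whose phase distortion is instructive in
    ablations.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if band[1] >= fs / 2.0:
        raise ValueError(f"band edge {band[1]} Hz >= Nyquist {fs / 2.0} Hz")
    if family in ("butterworth", "butter"):
        sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    elif family in ("chebyshev2", "cheby2"):
        sos = signal.cheby2(4, 20.0, band, btype="bandpass", fs=fs, output="sos")
    else:
        raise ValueError(f"unknown filter family: {family!r}")
    if zero_phase:
        return signal.sosfiltfilt(sos, y)
    return signal.sosfilt(sos, y)


def _find_cycles(y: np.ndarray, fs: float) -> np.ndarray:
    """Systolic-peak indices from adaptive peak detection."""
    dist = max(int(MIN_BEAT_SEPARATION * fs), 1)
    prom = 0.5 * float(np.std(y))
    peaks, _ = signal.find_peaks(y, distance=dist, prominence=prom)
    if len(peaks) == 0:
        peaks, _ = signal.find_peaks(y, distance=dist)
    return peaks


def detect_marker(y_filtered, t, marker: str = "U") -> np.ndarray:
    """Per-beat heuristic timing markers (one time per detected cycle).

    SP: local signal maximum (systolic peak); ON: local minimum preceding
    SP (onset); U: local maximum of the first derivative; A: local maximum
    of the second derivative.  Cycles come from adaptive peak detection
    with a minimum separation of 0.4 s (150 BPM).  Derivatives are central
    finite differences on the (assumed near-uniform) grid.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}; choose from {MARKERS}")
    y = np.asarray(y_filtered, float)
    t = np.asarray(t, float)
    fs = 1.0 / float(np.median(np.diff(t)))
    sp_idx = _find_cycles(y, fs)
    if len(sp_idx) == 0:
        import warnings

        warnings.warn("no pulse cycles detected", RuntimeWarning, stacklevel=2)
        return np.array([])
    if marker == "SP":
        return t[sp_idx]
    dy = np.gradient(y, t)
    d2y = np.gradient(dy, t)
    med_iv = np.median(np.diff(sp_idx)) if len(sp_idx) > 1 else int(0.8 * fs)
    out = []
    for k, p in enumerate(sp_idx):
        start = sp_idx[k - 1] if k > 0 else max(p - int(med_iv), 0)
        start = max(start, 0)
        if p - start < 2:
            continue
        seg = slice(start, p + 1)
        if marker == "ON":
            out.append(t[start + int(np.argmin(y[seg]))])
        elif marker == "U":
            out.append(t[start + int(np.argmax(dy[seg]))])
        else:  # A
            out.append(t[start + int(np.argmax(d2y[seg]))])
    return np.asarray(out)


def segment_average_shape(y_filtered, t, pulse_times) -> ExtractedShape:
    """Average pulse shape by segmenting between consecutive pulse anchors.

    Segments are resampled to the median segment length and averaged; no
    attempt is made to correct overlap or truncation between adjacent
    pulses — that limitation is intrinsic to the method.
    """
    y = np.asarray(y_filtered, float)
    t = np.asarray(t, float)
    pt = np.sort(np.asarray(pulse_times, float))
    if len(pt) < 1:
        raise ValueError("need at least 1 pulse time")
    if len(pt) == 1:
        sel = t >= pt[0]
        return ExtractedShape(t_rel=t[sel] - pt[0], values=y[sel], n_pulses=1)
    dt = float(np.median(np.diff(t)))
    segments = []
    for z0, z1 in zip(pt[:-1], pt[1:]):
        sel = (t >= z0) & (t < z1)
        if sel.sum() >= 2:
            segments.append(y[sel])
    if not segments:
        raise ValueError("no usable segments between pulse times")
    n_med = int(np.median([len(s) for s in segments]))
    grid = np.arange(n_med) / max(n_med - 1, 1)
    resampled = [
        np.interp(grid, np.arange(len(s)) / max(len(s) - 1, 1), s)
        for s in segments
    ]
    avg = np.mean(resampled, axis=0)
    return ExtractedShape(t_rel=grid * (n_med - 1) * dt, values=avg,
                          n_pulses=len(segments))
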