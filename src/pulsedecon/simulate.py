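"""Labeled synthetic vascular waveforms drawn from the generative priors.

The default protocol produces 11-second windows sampled uniformly at 64 Hz
with unit pulse amplitude, zero baseline drift, and white Gaussian noise
whose power is -20 dB relative to the mean-removed clean-signal power
(i.e., SNR = +20 dB).  Every record carries its ground truth: the noiseless
signal, the pulse times, and the pulse shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PulseShape, PulseTiming, WaveformObservation, clean_signal
from .priors import LatentState, PriorSet, sample_prior

__all__ = ["SimulatedWaveform", "simulate_waveform", "simulate_batch"]


@dataclass
class SimulatedWaveform:
    """One simulated recording plus its ground truth."""

    observation: WaveformObservation
    clean: np.ndarray
    timing: PulseTiming
    shape: PulseShape
    state: LatentState
    sigma_eps: float
    noise_db: float

    @property
    def true_times_in_window(self) -> np.ndarray:
        t = self.observation.t
        z = self.timing.z
        return z[(z >= t[0]) & (z <= t[-1])]


def simulate_waveform(
    priors: PriorSet,
    duration_s: float = 11.0,
    fs_hz: float = 64.0,
    noise_db: float = -20.0,
    seed: int | np.random.Generator | None = 0,
    a: float = 1.0,
) -> SimulatedWaveform:
    """Sample one labeled waveform from the generative model.

    ``noise_db`` sets the white-noise power relative to the AC (mean-removed)
    power of the clean signal; pass ``-inf`` for a noiseless record.
    Deterministic given ``seed``.
    """
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    state = sample_prior((float(t[0]), float(t[-1])), priors, seed=rng, a=a)
    timing = state.timing
    shape = state.pulse_shape(priors)
    clean = clean_signal(t, timing, shape)
    ac_power = float(np.mean((clean - clean.mean()) ** 2))
    if np.isneginf(noise_db):
        sigma = 0.0
        y = clean.copy()
    else:
        sigma = float(np.sqrt(ac_power * 10.0 ** (noise_db / 10.0)))
        y = clean + rng.normal(0.0, sigma, size=n)
    state.sigma_eps = sigma
    obs = WaveformObservation(t=t, y=y, fs_nominal=fs_hz)
    return SimulatedWaveform(observation=obs, clean=clean, timing=timing,
                             shape=shape, state=state, sigma_eps=sigma,
                             noise_db=noise_db)


def simulate_batch(
    n: int,
    priors: PriorSet,
    duration_s: float = 11.0,
    fs_hz: float = 64.0,
    noise_db: float = -20.0,
    base_seed: int = 0,
) -> list[SimulatedWaveform]:
    """Simulate ``n`` independent waveforms with per-waveform seeds base_seed+i."""
    return [
        simulate_waveform(priors, duration_s=duration_s, fs_hz=fs_hz,
                          noise_db=noise_db, seed=base_seed + i)
        for i in range(n)
    ]
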