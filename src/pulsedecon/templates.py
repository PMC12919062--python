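"""Synthetic pulse templates and the packaged default prior set.

The multivariate-Gaussian shape prior is meant to be fitted to a corpus of
averaged pulse shapes from real recordings.  When no such corpus is at hand,
this module builds a synthetic stand-in: a family of analytically
constructed, physiologically plausible arterial pulse templates (a dominant
systolic wave followed by a smaller dicrotic wave, with jittered amplitudes,
latencies, widths, and overall duration), run through the same
``fit_shape_prior`` procedure used for real data.  The resulting prior is
shipped as a small JSON file and regenerated deterministically by
``build_default_priors``.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

from .priors import PriorSet, fit_shape_prior, solve_heart_rate_prior

__all__ = [
    "synthetic_pulse_templates",
    "build_default_priors",
    "default_priors",
]

#: fixed seed for the synthetic template family (a fixture, not an analysis)
_TEMPLATE_SEED = 1234
#: default beat-to-beat variability of normalized intervals: sd = 1/sqrt(300)
DEFAULT_ALPHA_ZPP = 300.0


def _pulse_template(t, amp_sys, t_sys, w_sys, amp_dic, t_dic, w_dic,
                    amp_dia, tau_dia, scale):
    """Arterial pulse: systolic wave + dicrotic wave + diastolic decay.

    The diastolic component is the windkessel-style exponential runoff that
    follows systole and persists over most of the cycle, which is what makes
    adjacent pulses overlap at ordinary heart rates; it is tapered to zero
    near the end of the template support.
    """
    ts = t / scale
    v = amp_sys * np.exp(-0.5 * ((ts - t_sys) / w_sys) ** 2)
    v += amp_dic * np.exp(-0.5 * ((ts - t_dic) / w_dic) ** 2)
    onset = 1.0 / (1.0 + np.exp(-(ts - t_sys) / 0.04))
    taper = 1.0 / (1.0 + np.exp((ts - 1.15) / 0.05))
    v += amp_dia * onset * taper * np.exp(-np.maximum(ts - t_sys, 0.0) / tau_dia)
    return v


def synthetic_pulse_templates(
    n: int = 30,
    dt: float = 1.0 / 128.0,
    t_max: float = 1.35,
    seed: int = _TEMPLATE_SEED,
):
    """Build ``n`` jittered pulse templates on a common grid.

    Returns a list of ``(t_rel, values)`` pairs in the format consumed by
    ``fit_shape_prior``.  Nominal morphology: systolic peak near 0.18 s with
    ~65 ms width, dicrotic wave near 0.42 s at roughly a third of the
    systolic amplitude, and an exponential diastolic decay (time constant
    ~0.6 s) so the pulse support spans ~1.3 s — at ordinary heart rates the
    tail of one pulse overlaps the next beat, as in arterial recordings.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max, dt)
    shapes = []
    for _ in range(n):
        params = dict(
            amp_sys=rng.uniform(0.9, 1.1),
            t_sys=rng.normal(0.18, 0.015),
            w_sys=rng.normal(0.065, 0.006),
            amp_dic=rng.uniform(0.25, 0.50),
            t_dic=rng.normal(0.42, 0.03),
            w_dic=rng.normal(0.11, 0.012),
            amp_dia=rng.uniform(0.3, 0.5),
            tau_dia=rng.normal(0.6, 0.06),
            scale=rng.uniform(0.9, 1.1),
        )
        shapes.append((t, _pulse_template(t, **params)))
    return shapes


def build_default_priors(
    alpha_zpp: float = DEFAULT_ALPHA_ZPP,
    K: int = 24,
    f_h: float = 0.5,
) -> PriorSet:
    """Recompute the packaged priors from scratch (deterministic)."""
    timing = solve_heart_rate_prior(alpha_zpp=alpha_zpp)
    shape = fit_shape_prior(synthetic_pulse_templates(), K=K, f_h=f_h)
    return PriorSet(timing=timing, shape=shape)


@lru_cache(maxsize=1)
def default_priors() -> PriorSet:
    """Load the packaged default prior set (synthetic shape corpus)."""
    ref = resources.files("pulsedecon").joinpath("data/default_priors.json")
    with resources.as_file(ref) as path:
        return PriorSet.load(path)
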