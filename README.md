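# pulsedecon

Bayesian pulse deconvolution for vascular waveforms — photoplethysmography,
applanation tonometry, intravascular pressure, and similar signals that
measure bulk flow in blood vessels.

Analyzing these waveforms involves three interdependent tasks: filtering
noise, detecting per-beat pulse timing, and extracting the pulse shape.
Conventional pipelines do them sequentially (a linear bandpass filter, then
heuristic markers such as the systolic peak or the peak first derivative,
then segment-and-average shape extraction), and each stage's errors
propagate into the next. `pulsedecon` solves all three jointly by Bayesian
inference in one generative model,

```
y(t) = Σᵢ h(t − zᵢ) + b(t) + ε(t),        h(t) = a · γ(t) · (wᵀφ(t) + 1)
```

an impulse train at pulse onsets `z` convolved with a parametric pulse
shape `h` (a Fourier series `φ` under a sigmoid-product window `γ`), plus
low-frequency drift `b(t)` and white Gaussian noise. Domain knowledge
enters through priors: heart rate `f_hr ~ Γ(α_hr, λ_hr)` confined to
30–150 beats/min, heart-rate-normalized beat intervals
`z″ ~ Γ(α, rate=α)` (mean exactly 1), an anchor-pulse uniform prior that
makes the model time-shift invariant, and a multivariate Gaussian over the
shape weights `w`. The maximum a posteriori (MAP) fit simultaneously
denoises the signal, locates every pulse in continuous time (below the
sample period), and returns the full pulse shape as an analytic function;
the No-U-Turn sampler provides joint posterior uncertainty over all of it.

The package also ships the traditional baselines (Butterworth / Chebyshev II
bandpasses, SP/ON/U/A markers, segmentation averaging), a prior-based
waveform simulator, and the three evaluation metrics (Hann-weighted noise
attenuation, matched beat-interval RMSE, percent-area shape error), so the
whole comparison study can be rerun end to end.

## Worked example

```python
from pulsedecon import simulate_waveform, map_fit, FitConfig, default_priors
from pulsedecon.evaluation import noise_attenuation_db, interval_rmse

priors = default_priors()
sim = simulate_waveform(priors, duration_s=11.0, fs_hz=64.0,
                        noise_db=-20.0, seed=7)       # labeled synthetic PPG
est = map_fit(sim.observation, priors, FitConfig(restarts=8, seed=0))

print(f"true heart rate:      {sim.state.f_hr*60:.1f} BPM")
print(f"estimated heart rate: {est.f_hr*60:.1f} BPM")
print(f"noise attenuation:    "
      f"{noise_attenuation_db(sim.observation.y, est.clean_fit, sim.clean):.1f} dB")
print(f"beat-interval RMSE:   "
      f"{interval_rmse(est.timing.z, sim.true_times_in_window):.2f} ms")
print(f"noise sd: fitted {est.sigma_eps:.4f} vs true {sim.sigma_eps:.4f}")
```

prints

```
true heart rate:      74.6 BPM
estimated heart rate: 75.2 BPM
noise attenuation:    33.2 dB
beat-interval RMSE:   0.83 ms
noise sd: fitted 0.0766 vs true 0.0827
```

The attenuation (20·log10 of the Hann-weighted pre/post error-power ratio
against the known clean signal) says the fit removed nearly all of the
added noise; the interval RMSE shows beat-to-beat timing recovered more
than an order of magnitude below the 15.6 ms sample period; the fitted
noise sd matches the injected value. `est.timing.M` can exceed the number
of in-window pulses because pulses just outside the window whose tails
reach into it are retained. Posterior uncertainty on top of the fit:

```python
from pulsedecon import posterior_sample, credible_intervals
post = posterior_sample(sim.observation, priors, est, n_samples=2000, seed=0)
ci = credible_intervals(post, level=0.99)   # signal bands + per-pulse times
```

Everything is also reachable from a CLI (`pulsedecon simulate | fit-priors |
fit | uq | baseline | benchmark | denoise`); every subcommand takes
`--seed` and is run-to-run reproducible. Fitting is CSV in
(`time_s,value`), JSON out. Because the fitted model is an analytic
function of continuous time, `denoise` evaluates it on any grid —
resampling, interpolation, and extrapolation come for free.

## Default priors

`default_priors()` loads a packaged prior set whose shape component was
fitted (by the same `fit_shape_prior` estimator a user would apply to real
averaged pulses) on a **synthetic** corpus of analytically constructed
arterial pulse templates — systolic wave, dicrotic wave, exponential
diastolic decay; see `docs/methods.md`. To fit priors from your own data:

```bash
pulsedecon fit-priors --shapes-dir my_pulses/ --intervals-csv rr.csv --out priors.json
```

For evaluation against external references (e.g., ECG R-peak times), the
metrics accept any reference time vector — see
`pulsedecon.evaluation.match_pulses` / `interval_rmse` and
`pulsedecon.io.read_ref_times`.

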