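# spikeosc

Bias-aware detection and quantification of oscillations in single-unit
spike trains.

## The problem

Neuronal oscillations (beta-band bursting in the Parkinsonian basal
ganglia, movement-related gamma, …) are usually detected from the power
spectrum of a spike train: a peak at the oscillation frequency is compared,
in standard-deviation units, against a high-frequency noise floor.  But a
spike train is a stochastic point process realised from its underlying rate
function λ(t) = r₀·(1 + m·cos(2π·f₀·t)), and the expected spectrum of a
finite inhomogeneous Poisson process,

    S(f₀)      = r₀·(1 + r₀·T·m²/4)      (peak)
    S(f ≠ f₀)  = r₀                       (flat baseline)

makes the peak SNR grow *linearly with the firing rate r₀*, *linearly with
the recording duration T* (in √N_wins steps under Welch averaging), and
quadratically with the modulation depth m.  Two neurons with identical
modulation but different rates therefore get different "oscillation
scores", and comparisons across regions, cell types, behavioural states or
recording protocols are systematically biased.

## The modulation index

Inverting the peak-power expression gives a rate- and duration-free
estimate of the modulation depth itself:

    m̂ = 2·√( (Ŝ(f₀) − r̂₀) / (r̂₀²·T) )

with r̂₀ = N/T.  `spikeosc` implements the full pipeline around this
estimator:

* **simulate** — inhomogeneous-Poisson generator (1 ms Bernoulli bins) with
  optional absolute refractory period and frequency jitter;
* **spectral** — Welch spectra of binned trains (non-overlapping 1000-bin
  Hamming segments), the noise-band SNR statistic, the closed-form
  finite-T spectrum, and the correction mapping Welch peak power onto the
  analytic scale (density rescaling, segment-count correction, window
  coherent-gain correction);
* **modindex** — m̂ with a Monte-Carlo significance threshold (null mean +
  2 SD at matched rate and duration), an iterative correction for the
  refractory-period bias, rate-function reconstruction, and the (biased)
  autocorrelogram SNR for comparison;
* **planning** — the required recording duration for a target peak SNR,
  T̂ = 16·SNR²/(wl·r̂₀²·m̂⁴);
* **io / cli** — plain-text and CSV spike-time formats, YAML run configs,
  a batch runner, and a thin `spikeosc` command-line interface.

## Worked example

```python
from spikeosc import OscillatoryRateParams, assess, generate_train

params = OscillatoryRateParams(r0=60, m=0.5, f0=12)
train = generate_train(params, T=300.0, seed=7)
result = assess(train, f_band=(10, 15), n_null=300, seed=8)
```

prints (see `examples/02_modulation_index.py`):

```
r0_hat = 59.6 sp/s, f_peak = 12 Hz
m_hat = 0.494 (true 0.5)
null threshold = 0.090 -> significant
reconstructed rate over one cycle (sp/s): [89.1 59.6 30.2 59.6 89.1]
```

The estimator recovers the generator's modulation (0.494 vs 0.5) and the
reconstruction r̂₀·(1 + m̂·cos(2π·f̂₀·t)) describes the full rate function.
The other scripts in `examples/` cover the spectral SNR, the refractory
correction (raw 0.427 → corrected 0.498 for a true 0.5 with a 2 ms dead
time), duration planning, and the window-size/jitter trade-off.

From the shell:

```sh
spikeosc simulate --r0 60 --m 0.5 -T 300 --seed 7 --out unit.txt
spikeosc modindex --in unit.txt --band 10 15
spikeosc plan --r0 75 --m 0.25 --snr 5
```

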