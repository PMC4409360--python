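# Methods

## Model

Spiking is modelled as an inhomogeneous Poisson process with rate

    λ(t) = r0 · (1 + m · cos(2π f0 t + φ0)),

where r0 > 0 is the baseline rate (sp/s), m ∈ [0, 1] the modulation index,
f0 the oscillation frequency (Hz) and φ0 the phase at t = 0 (default 0).
The expected spectrum of a finite realisation on [0, T] is

    S(f) = (1/T) [ ∫λ dt + |∫λ e^{−i2πft} dt|² ],

which expands, for the cosine rate, into an eight-term closed form in
normalised sinc functions (`analytic_psd` evaluates it exactly).  For
f0·T ≫ 1 it collapses to the peak/baseline pair S(f0) = r0(1 + r0Tm²/4),
S(f≠f0) = r0, which underlies everything else in the package.

## Simulator

Trains are generated by per-bin Bernoulli thinning at Δt = 1 ms: bin k
fires with probability λ(t_k)Δt, t_k the bin centre.  This reproduces the
discrete generator standard in this literature and its spectra; it caps
representable rates at 1/Δt = 1000 sp/s (a `SaturationError` beyond that,
and a warning with clipping if the modulation peak alone reaches the cap).
Two consequences worth knowing:

* the per-bin variance is p(1−p) rather than p, so the spectral baseline
  sits a factor (1 − r0Δt) below r0 — about 3% at 30 sp/s.  The analytic
  agreement checks at these rates pass within their tolerances with this
  suppression included;
* ISIs are multiples of Δt; the exponential-ISI property holds in the
  geometric limit.

An absolute refractory period τ_ref zeroes the rate for round(τ_ref/Δt)
bins after each spike (dead-time thinning), so the minimum ISI is
τ_ref + Δt and the realised rate is r0/(1 + r0·τ_ref) in expectation —
exactly the relation inverted by the Poisson-equivalent rate
r_p = N/(T − τ_ref·N).

Frequency jitter (the `jitter_band` option) is a bounded random walk: the
instantaneous frequency is constant over each oscillation cycle, steps
uniformly by at most a quarter band-width at cycle boundaries, reflects at
the band edges, and the phase accumulates continuously.  The mechanism is
a modelling choice (any phase-continuous wander inside the band produces
the same ~band-wide spectral spread); only the band edges are treated as
data-constrained.

## Spectral estimation and the analytic scale

`welch_psd` uses scipy's Welch estimator with non-overlapping segments
(default 1000 bins → 1 Hz resolution, 500 Hz Nyquist), a periodic Hamming
taper, no detrending, one-sided per-Hz density; a trailing partial segment
is discarded (N_wins = ⌊T/wl_s⌋).  Counts are not mean-subtracted: the DC
structure belongs to the f = 0 bin, which every peak search and noise-band
statistic excludes.  Note the tapered DC component leaks into the first
couple of bins; search bands should start above the DC mainlobe (the
defaults do).

The SNR spectrum is snr(f) = (P(f) − μ)/σ with μ, σ the mean and SD of the
density over 100–500 Hz (endpoints included).  Peak search returns the
highest-SNR bin in the requested band, ties to the lower frequency.

Mapping a Welch peak onto the analytic scale applies three corrections in
order:

1. **density scale** — multiply by Fs²/2.  For a one-sided per-Hz density
   of a binned Poisson train the baseline expectation is 2r0/Fs², so this
   restores the analytic flat level r0.  (Formulations of this correction
   that multiply by Fs/2 assume a per-cycle-per-bin density; the constant
   is convention-dependent and pinned here by the invariant tests.)
2. **resolution** — peak·N_wins − (N_wins−1)·r̂0 converts the per-segment
   peak r0(1 + r0·wl_s·m²/4) to the full-duration peak.
3. **window gain** — multiply by mean(w)·wl/(wᵀw), undoing the coherent
   gain loss of the taper at a spectral line (≈ 1.36 for Hamming).

The window term is a *line* correction: applied to broadband baseline power
it would overshoot by the same 1.36, so baseline/noise-band power is mapped
with step 1 alone (`to_analytic_scale`).  Corrected peaks may be negative
(no excess power); they are passed through unclamped and clamp to m̂ = 0
only inside the index estimator.

## Modulation index

m̂ = 2·√((Ŝ(f0) − r̂0)/(r̂0²T)) with r̂0 = N/T, clamped to [0, 1] (a warning
on the upper clamp).  Two extraction modes, selected by the band argument:

* **band search** (e.g. (10, 15) Hz) for data whose oscillation frequency
  is unknown: the peak bin is the band argmax.  The corresponding null
  threshold is computed with the *same* argmax, so the selection bias of
  taking a maximum over bins is present identically under the null and the
  rule stays calibrated.
* **fixed frequency** (degenerate band (f, f)) when the frequency is known
  (simulation studies, the refractory-correction inner loop): no selection
  bias, and mean m̂ recovers the true m within ±0.05 across the tested
  r0 × m grid down to m = 0.1 at 10 sp/s.  Recovery curves are flat in the
  firing rate — the property the estimator exists for.

Significance: the threshold is the null mean + 2 SD of m̂ over `n_null`
homogeneous trains simulated at the unit's own (r̂0, T) with the same
estimator settings (cached per parameter set; the batch runner buckets
rates into 5 sp/s bins to share nulls).  Under the null the rule fires on
roughly 2–4% of trains (≤ 5% asserted), versus ≲ 1% for the SNR ≥ 5 rule.

## Refractory correction

Dead time clips spikes preferentially near the oscillation peak, biasing
m̂ low, increasingly so at high rates (tested: mean m̂ ≈ 0.45 at 20 sp/s vs
≈ 0.39 at 100 sp/s for a true m = 0.5, τ_ref = 2 ms).  The correction
inverts the forward distortion by search: compute r_p from the dead-time
budget, then find the generator modulation m_p ∈ [m̂, 1] whose simulated
refractory trains (n_sim = 100 per iteration, common random numbers across
iterations) reproduce the observed m̂ at the already-identified peak
frequency.  The forward map is monotone in m_p, so bisection converges;
tolerance 0.01 on the index, 20 iterations cap, saturation at m_p = 1
reported with a warning.  τ_ref can be supplied or read from the leading
gap of the 1 ms ISI histogram (first bin exceeding 5% of the modal count);
the explicit value always wins.  Recovered m_p for a true 0.5 at 60 sp/s,
T = 300 s is within ±0.07 (tested at 15 correction replicates; the
estimator itself is deterministic given seeds).

## Duration planning

Per-segment SNR r0·wl_s·m²/4 times √(T/wl_s) inverts to
T̂ = 16·SNR²/(wl_s·r̂0²·m̂⁴) (reported as ∞ for m̂ = 0 — an unmodulated
train is undetectable at any duration).  The round trip
`predicted_welch_snr(plan, required_duration(plan)) == target` holds to
machine precision.  The identity deliberately omits the Hamming
coherent-gain factor, so empirical mean peak SNRs at T̂ land ~25% below the
target (measured ≈ 3.7–4.2 for a target of 5); the planner therefore also
offers `simulated_detection_probability`, and practical advice is to plan
with a ~2× margin.  Detection at the planned duration is inherently
stochastic either way.

## Problem sizes and determinism

All quantitative tests regenerate their data; no fixtures are stored.
Rep counts are chosen to make Monte-Carlo standard errors small against
the asserted tolerances: 500 trains per detection cell (binomial SE < 2.3
points), 200 per spectral-agreement and fit cell, 100 per recovery cell,
30/15 for the refractory sweeps.  Every stochastic path takes an explicit
seed (integers or numpy Generators); identical seeds give identical
trains, thresholds and reports.

## What the simulations do not cover

The generator realises exactly the model the estimators assume (cosine
modulation, Poisson firing, at most absolute refractoriness, stationary
parameters).  Passing tests therefore demonstrate estimator correctness
under the model, not robustness to bursting, relative refractoriness,
non-sinusoidal or non-stationary modulation, multi-frequency rhythms, or
spike-sorting contamination — all of which real recordings contain.  The
refractory correction cannot recover a modulation the dead time has erased
entirely (observed m̂ = 0), and the ISI-histogram τ_ref reading is coarse;
supply a measured refractory period when one is available.
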