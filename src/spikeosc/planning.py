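"""Analytic SNR prediction and recording-duration planning.

For a cosine-modulated Poisson train, the expected spectral SNR at the
oscillation frequency grows linearly with the rate and duration and
quadratically with the modulation:

    SNR(f0) ~= r0 * T * m^2 / 4          (single segment, large T)

Welch averaging over N = T/wl non-overlapping segments multiplies the
per-segment SNR by sqrt(N), giving the planning identity

    SNR_hat(T) = (r0 * wl * m^2 / 4) * sqrt(T / wl)

whose inversion yields the recording duration required to reach a target
SNR:

    T_hat = 16 * SNR^2 / (wl * r0^2 * m^4)

These formulas let an experimenter size a recording session from a short
pilot estimate of the firing rate and modulation index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .simulate import OscillatoryRateParams, bin_train, generate_train
from .spectral import (DEFAULT_NOISE_BAND, DEFAULT_WINDOW, DEFAULT_WL,
                       find_peak, snr_spectrum, welch_psd)


@dataclass(frozen=True)
class PlanInputs:
    """Pilot estimates and targets for recording-duration planning.

    wl_s is the Welch window length in seconds (1 s -> 1 Hz resolution).
    """

    r0_hat: float
    m_hat: float
    target_snr: float
    wl_s: float = 1.0
    f0: float = 12.0

    def __post_init__(self) -> None:
        if self.r0_hat <= 0 or self.target_snr <= 0 or self.wl_s <= 0 \
                or self.f0 <= 0:
            raise ParameterError("all plan inputs must be positive")
        if not 0 <= self.m_hat <= 1:
            raise ParameterError(f"m_hat must lie in [0, 1], got {self.m_hat}")


def analytic_snr(params: OscillatoryRateParams, T: float) -> float:
    """Exact expected SNR at f0 for a single unwindowed segment of length T.

    Evaluates the full finite-T expression (all sinc cross-terms); use
    ``analytic_snr_large_T`` for the simplified form.
    """
    if T <= 0:
        raise ParameterError(f"T must be positive, got {T}")
    r0, m, f0 = params.r0, params.m, params.f0
    s1 = np.sinc(f0 * T)
    s2 = np.sinc(2.0 * f0 * T)
    num = r0**2 * T**2 * (s1**2
                          + m * s1
                          + m * s1 * s2
                          + m**2 / 4.0
                          + (m**2 / 4.0) * s2**2
                          + (m**2 / 2.0) * s2)
    den = r0 * T * (1.0 + m * s2)
    return float(num / den)


def analytic_snr_large_T(params: OscillatoryRateParams, T: float) -> float:
    """Large-T limit r0*T*m^2/4 of the analytic SNR at f0."""
    if T <= 0:
        raise ParameterError(f"T must be positive, got {T}")
    return params.r0 * T * params.m**2 / 4.0


def predicted_welch_snr(plan: PlanInputs, T: float) -> float:
    """Predicted Welch peak SNR for a recording of duration T.

    Per-segment SNR (duration wl_s) times sqrt(number of segments).
    """
    if T < plan.wl_s:
        raise ParameterError(
            f"T = {T} s is shorter than one Welch segment ({plan.wl_s} s)")
    per_window = plan.r0_hat * plan.wl_s * plan.m_hat**2 / 4.0
    return per_window * math.sqrt(T / plan.wl_s)


def required_duration(plan: PlanInputs) -> float:
    """Recording duration needed to reach the target Welch peak SNR.

    T_hat = 16*SNR^2 / (wl * r0^2 * m^4); decreasing in rate and modulation,
    increasing in the target.  A zero modulation index is undetectable at
    any duration, reported as ``math.inf`` rather than an exception.
    """
    if plan.m_hat == 0:
        return math.inf
    return (16.0 * plan.target_snr**2
            / (plan.wl_s * plan.r0_hat**2 * plan.m_hat**4))


def peak_snr_samples(params: OscillatoryRateParams, T: float, n_reps: int,
                     seed, band: tuple[float, float] = (10.0, 15.0),
                     *, wl: int = DEFAULT_WL,
                     window_name: str = DEFAULT_WINDOW,
                     dt: float = 0.001,
                     noise_band: tuple[float, float] = DEFAULT_NOISE_BAND) -> np.ndarray:
    """Empirical Welch peak SNRs of ``n_reps`` simulated trains.

    The workhorse behind detection-probability estimates and the planner's
    simulation check.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        train = generate_train(params, T, rng, dt=dt)
        ps = welch_psd(bin_train(train, dt), wl=wl, window_name=window_name)
        snr = snr_spectrum(ps, noise_band=noise_band)
        out[i] = find_peak(snr, ps, band).peak_snr
    return out


def simulated_detection_probability(plan: PlanInputs, T: float, n_reps: int,
                                    seed,
                                    band: tuple[float, float] = (10.0, 15.0),
                                    **kwargs) -> float:
    """Fraction of simulated trains whose peak SNR exceeds the target.

    A stochastic companion to ``required_duration``: SNR-threshold crossing
    at the planned duration is a coin flip near probability 1/2, not a
    certainty.
    """
    params = OscillatoryRateParams(r0=plan.r0_hat, m=plan.m_hat, f0=plan.f0)
    snrs = peak_snr_samples(params, T, n_reps, seed, band=band, **kwargs)
    return float(np.mean(snrs > plan.target_snr))
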