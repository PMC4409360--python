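"""Spectral estimation for binned spike trains.

Implements the Welch power spectrum of a binned spike train (non-overlapping
Hamming-tapered segments), the closed-form power spectrum of a finite
cosine-modulated Poisson process, the noise-band SNR statistic, and the
mapping of Welch-estimated peak power onto the analytic scale.

Conventions
-----------
The expected spectrum of a finite inhomogeneous Poisson process over [0, T]
is

    S(f) = (1/T) * [ integral(lambda) + |integral(lambda * exp(-i*2*pi*f*t))|^2 ]

which for lambda(t) = r0*(1 + m*cos(2*pi*f0*t)) gives, at large T,

    S(f0)      = r0 * (1 + r0*T*m^2/4)        (spectral peak)
    S(f != f0) = r0                            (flat baseline)

``welch_psd`` returns scipy's one-sided *per-Hz* density; under that
convention the baseline maps to the analytic scale as ``power * Fs**2 / 2``
(see ``to_analytic_scale``), and a Welch-estimated spectral peak maps via the
three-step correction in ``welch_to_analytic``: density scale, resolution
(number of segments), and coherent window gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (DegenerateNoiseBandError, InsufficientDataError,
                     ParameterError)
from .simulate import BinnedTrain, OscillatoryRateParams, SpikeTrain

DEFAULT_WL = 1000           # bins per Welch segment -> 1 Hz resolution at 1 ms
DEFAULT_WINDOW = "hamming"
DEFAULT_NOISE_BAND = (100.0, 500.0)  # Hz


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided Welch power spectral density with its estimation metadata."""

    freqs: np.ndarray          # Hz
    power: np.ndarray          # density, (counts)^2 / Hz
    Fs: float                  # sampling frequency, Hz
    wl: int                    # segment length, bins
    n_wins: int                # number of non-overlapping segments used
    window: np.ndarray         # taper vector, length wl
    window_name: str

    @property
    def df(self) -> float:
        """Frequency resolution in Hz."""
        return self.Fs / self.wl


@dataclass(frozen=True)
class SnrSpectrum:
    """Per-frequency SNR in standard deviations of the noise-band power."""

    freqs: np.ndarray
    snr: np.ndarray
    noise_band: tuple[float, float]
    noise_mean: float
    noise_std: float


@dataclass(frozen=True)
class SpectralPeak:
    """Highest-SNR frequency within a search band."""

    f_peak: float
    peak_power: float          # analytic-scale power (see welch_to_analytic)
    peak_snr: float
    band: tuple[float, float]


def welch_psd(binned: BinnedTrain, wl: int = DEFAULT_WL,
              window_name: str = DEFAULT_WINDOW) -> PowerSpectrum:
    """Welch PSD of a binned train: non-overlapping tapered segments.

    A trailing partial segment is discarded.  Counts are not mean-subtracted;
    the DC structure of the rate belongs to the f=0 bin, which all peak and
    noise-band computations exclude.
    """
    n = binned.n_bins
    n_wins = n // wl
    if n_wins < 1:
        raise InsufficientDataError(
            f"train has {n} bins, shorter than one {wl}-bin Welch segment")
    x = binned.counts[:n_wins * wl].astype(float)
    w = signal.get_window(window_name, wl)
    freqs, power = signal.welch(
        x, fs=binned.Fs, window=w, nperseg=wl, noverlap=0,
        detrend=False, scaling="density", return_onesided=True)
    return PowerSpectrum(freqs=freqs, power=power, Fs=binned.Fs, wl=wl,
                         n_wins=n_wins, window=w, window_name=window_name)


def analytic_psd(params: OscillatoryRateParams, T: float,
                 freqs: np.ndarray) -> np.ndarray:
    """Exact expected spectrum of the finite cosine-modulated Poisson process.

    Evaluates the full eight-term closed form (sinc(x) = sin(pi*x)/(pi*x),
    sinc(0) = 1) with no large-T simplification.  Only valid for the pure
    Poisson model (``tau_ref == 0``, no jitter).
    """
    if params.tau_ref > 0:
        raise ParameterError(
            "analytic_psd assumes a pure Poisson model (tau_ref == 0)")
    if params.jitter_band is not None:
        raise ParameterError("analytic_psd assumes a fixed frequency")
    f = np.asarray(freqs, dtype=float)
    r0, m, f0 = params.r0, params.m, params.f0
    sm = np.sinc((f - f0) * T)   # numpy sinc is the normalised sinc
    sp = np.sinc((f + f0) * T)
    sf = np.sinc(f * T)
    s2 = np.sinc(2.0 * f0 * T)
    return (r0
            + r0 * m * s2
            + r0**2 * T * sf**2
            + r0**2 * T * m * sf * sm
            + r0**2 * T * m * sf * sp
            + r0**2 * T * (m**2 / 4.0) * sm**2
            + r0**2 * T * (m**2 / 4.0) * sp**2
            + r0**2 * T * (m**2 / 2.0) * sm * sp)


def peak_power_large_T(params: OscillatoryRateParams, T: float) -> float:
    """Large-T spectral peak r0*(1 + r0*T*m^2/4)."""
    return params.r0 * (1.0 + params.r0 * T * params.m**2 / 4.0)


def snr_spectrum(ps: PowerSpectrum,
                 noise_band: tuple[float, float] = DEFAULT_NOISE_BAND) -> SnrSpectrum:
    """Normalise a spectrum to SNR units against a high-frequency noise band.

    snr(f) = (power(f) - mean_band) / std_band, with the band statistics
    taken over all frequency bins inside ``noise_band`` (endpoints included,
    f = 0 excluded).
    """
    lo, hi = noise_band
    mask = (ps.freqs >= lo) & (ps.freqs <= hi) & (ps.freqs > 0)
    if mask.sum() < 10:
        raise ParameterError(
            f"noise band {noise_band} covers only {int(mask.sum())} bins "
            "(need >= 10)")
    band = ps.power[mask]
    mu = float(band.mean())
    sd = float(band.std(ddof=1))
    if sd == 0.0:
        raise DegenerateNoiseBandError(
            f"noise band {noise_band} has zero power variance "
            f"(mean power {mu}); SNR is undefined")
    return SnrSpectrum(freqs=ps.freqs, snr=(ps.power - mu) / sd,
                       noise_band=noise_band, noise_mean=mu, noise_std=sd)


def find_peak(snr: SnrSpectrum, ps: PowerSpectrum,
              band: tuple[float, float],
              r0_hat: float | None = None) -> SpectralPeak:
    """Highest-SNR frequency within ``band`` (ties go to the lower frequency).

    ``peak_power`` is reported on the analytic scale: the full Welch
    correction when ``r0_hat`` is supplied, otherwise the plain density
    rescaling (no resolution/window correction).
    """
    lo, hi = band
    mask = (snr.freqs >= lo) & (snr.freqs <= hi) & (snr.freqs > 0)
    if not mask.any():
        raise ParameterError(f"band {band} contains no frequency bins")
    idx = np.nonzero(mask)[0]
    best = idx[int(np.argmax(snr.snr[idx]))]   # argmax -> first/lowest freq on ties
    peak_welch = float(ps.power[best])
    if r0_hat is None:
        peak_power = to_analytic_scale(peak_welch, ps.Fs)
    else:
        peak_power = welch_to_analytic(peak_welch, ps, r0_hat)
    return SpectralPeak(f_peak=float(snr.freqs[best]), peak_power=peak_power,
                        peak_snr=float(snr.snr[best]), band=(lo, hi))


def to_analytic_scale(power, Fs: float):
    """Rescale a per-Hz Welch density to the analytic baseline scale.

    For a homogeneous Poisson train the one-sided per-Hz density away from DC
    has expectation 2*r0/Fs^2, so multiplying by Fs^2/2 recovers the analytic
    flat level r0.  This is the correct scaling for *baseline* (noise-band)
    power; spectral peaks additionally need the resolution and window-gain
    corrections of ``welch_to_analytic``.
    """
    return power * Fs**2 / 2.0


def welch_to_analytic(peak_welch: float, ps: PowerSpectrum,
                      r0_hat: float) -> float:
    """Map a Welch-estimated spectral peak onto the analytic full-T scale.

    Three corrections, in order:

    1. density scale: ``peak * Fs^2 / 2`` (per-Hz one-sided density to
       analytic units; see module docstring for the convention),
    2. resolution: the per-segment peak r0*(1 + r0*wl_s*m^2/4) is converted
       to the full-duration peak by ``peak*n_wins - (n_wins - 1)*r0``,
    3. window gain: multiply by ``mean(w)*wl / (w . w)``, undoing the
       coherent-gain loss of the taper at the spectral line.

    The result may be negative (no excess peak power); it is passed through
    unclamped — clamping is the modulation-index estimator's responsibility.
    """
    if ps.n_wins < 1:
        raise ParameterError("power spectrum reports no Welch segments")
    w = ps.window
    scaled = to_analytic_scale(peak_welch, ps.Fs)
    full_t = scaled * ps.n_wins - (ps.n_wins - 1) * r0_hat
    window_term = float(w.mean()) * ps.wl / float(w @ w)
    return full_t * window_term


def estimate_rate(train: SpikeTrain) -> float:
    """Mean firing rate n_spikes / T in spikes/s (0.0 for an empty train)."""
    if train.T <= 0:
        raise ParameterError("train duration must be positive")
    return train.n_spikes / train.T


def band_power_analytic(ps: PowerSpectrum,
                        band: tuple[float, float]) -> float:
    """Mean analytic-scale power over a frequency band (f = 0 excluded)."""
    lo, hi = band
    mask = (ps.freqs >= lo) & (ps.freqs <= hi) & (ps.freqs > 0)
    if not mask.any():
        raise ParameterError(f"band {band} contains no frequency bins")
    return float(to_analytic_scale(ps.power[mask], ps.Fs).mean())
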