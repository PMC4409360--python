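"""Inhomogeneous-Poisson spike-train simulation with cosine rate modulation.

The generator realises the rate function

    lambda(t) = r0 * (1 + m * cos(2*pi*f0*t))

as a discrete-time Bernoulli process at resolution ``dt`` (1 ms by default):
each bin fires with probability ``lambda(t)*dt``, independently of the past.
An absolute refractory period is modelled by forcing the rate to zero for
``tau_ref`` seconds after every spike.  An optional jittered variant lets the
instantaneous frequency wander inside a band, with continuous phase.

This module is both the core of the refractory-correction engine and the
package's own fixture generator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from numba import njit

from .errors import ParameterError, SaturationError

DEFAULT_DT = 0.001  # s; 1 ms bins throughout


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillatoryRateParams:
    """Parameters of the cosine-modulated rate function.

    Attributes
    ----------
    r0 : float
        Baseline firing rate, spikes/s.  Must be positive.
    m : float
        Modulation index in [0, 1]; relative depth of the cosine modulation.
    f0 : float
        Oscillation frequency, Hz.
    jitter_band : tuple of float, optional
        (f_lo, f_hi) in Hz.  When given, the instantaneous frequency performs
        a bounded random walk within the band (see ``generate_jittered_train``).
    tau_ref : float
        Absolute refractory period in seconds; 0 means pure Poisson firing.
    phase0 : float
        Cosine phase at t = 0, radians.  Defaults to 0 so that the rate peaks
        at the start of the recording.
    """

    r0: float
    m: float
    f0: float
    jitter_band: tuple[float, float] | None = None
    tau_ref: float = 0.0
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ParameterError(f"r0 must be positive, got {self.r0}")
        if not 0.0 <= self.m <= 1.0:
            raise ParameterError(f"m must lie in [0, 1], got {self.m}")
        if not self.f0 > 0:
            raise ParameterError(f"f0 must be positive, got {self.f0}")
        if self.tau_ref < 0:
            raise ParameterError(f"tau_ref must be >= 0, got {self.tau_ref}")
        if self.jitter_band is not None:
            f_lo, f_hi = self.jitter_band
            if f_lo > f_hi:
                raise ParameterError(
                    f"jitter band is inverted: ({f_lo}, {f_hi})")
            if not (f_lo <= self.f0 <= f_hi):
                raise ParameterError(
                    f"f0={self.f0} outside jitter band ({f_lo}, {f_hi})")
            if f_lo <= 0:
                raise ParameterError("jitter band must be strictly positive")

    def rate(self, t: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous firing rate lambda(t) in spikes/s."""
        return self.r0 * (1.0 + self.m * np.cos(
            2.0 * np.pi * self.f0 * np.asarray(t) + self.phase0))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times on [0, T).

    ``times`` are in seconds, strictly increasing; ``T`` is the total
    recording duration in seconds.
    """

    times: np.ndarray
    T: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.T <= 0:
            raise ParameterError(f"T must be positive, got {self.T}")
        if times.size:
            if times[0] < 0 or times[-1] >= self.T:
                raise ParameterError("spike times must lie in [0, T)")
            if np.any(np.diff(times) <= 0):
                raise ParameterError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)


@dataclass(frozen=True)
class BinnedTrain:
    """Spike counts in contiguous half-open bins [k*dt, (k+1)*dt)."""

    counts: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "counts",
                           np.asarray(self.counts, dtype=np.int64))

    @property
    def Fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.dt

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


# ---------------------------------------------------------------------------
# sampling kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _bernoulli_dead_time(u: np.ndarray, p: np.ndarray, dead_bins: int) -> np.ndarray:
    """Sequential Bernoulli thinning with an absolute dead time.

    A spike in bin i suppresses firing in the following ``dead_bins`` bins
    (rate forced to zero), reproducing an absolute refractory period of
    dead_bins*dt seconds.
    """
    out = np.empty(u.size, dtype=np.int64)
    k = 0
    next_allowed = 0
    for i in range(u.size):
        if i >= next_allowed and u[i] < p[i]:
            out[k] = i
            k += 1
            next_allowed = i + dead_bins + 1
    return out[:k]


def _sample_bins(p: np.ndarray, tau_ref: float, dt: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw spike bin indices for per-bin probabilities ``p``."""
    u = rng.random(p.size)
    if tau_ref > 0:
        dead_bins = int(round(tau_ref / dt))
        if dead_bins > 0:
            return _bernoulli_dead_time(u, p, dead_bins)
    return np.nonzero(u < p)[0]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _check_probabilities(params: OscillatoryRateParams, dt: float,
                         p: np.ndarray) -> np.ndarray:
    if params.r0 * dt >= 1.0:
        raise SaturationError(
            f"baseline rate {params.r0} sp/s is unrepresentable at "
            f"dt={dt} s (per-bin probability >= 1)")
    if np.any(p >= 1.0):
        warnings.warn(
            "per-bin spike probability reaches 1 at the modulation peak; "
            "rates are clipped and the realised train will be distorted",
            RuntimeWarning, stacklevel=3)
        p = np.minimum(p, 1.0)
    return p


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_train(params: OscillatoryRateParams, T: float, seed,
                   dt: float = DEFAULT_DT) -> SpikeTrain:
    """Generate one inhomogeneous-Poisson spike train of duration ``T``.

    Spike times are placed at bin centres ``(k + 1/2)*dt``.  With
    ``params.tau_ref > 0`` the instantaneous rate is held at zero for
    ``tau_ref`` seconds after each spike, so no ISI is shorter than
    ``tau_ref``.  ``seed`` may be an integer or a ``numpy.random.Generator``
    (the latter is consumed in place, which lets callers run many trains off
    one reproducible stream).
    """
    if T <= 0:
        raise ParameterError(f"T must be positive, got {T}")
    if params.jitter_band is not None:
        return generate_jittered_train(params, T, seed, dt=dt)
    rng = _as_rng(seed)
    n_bins = int(round(T / dt))
    t = (np.arange(n_bins) + 0.5) * dt
    p = params.rate(t) * dt
    p = _check_probabilities(params, dt, p)
    idx = _sample_bins(p, params.tau_ref, dt, rng)
    return SpikeTrain(times=(idx + 0.5) * dt, T=T)


def _jittered_phase(params: OscillatoryRateParams, n_bins: int, dt: float,
                    rng: np.random.Generator):
    """Phase at bin centres for a frequency random walk within the band.

    The instantaneous frequency is piecewise constant over oscillation
    cycles; at each cycle boundary it takes a uniform step of at most a
    quarter band-width and is reflected into [f_lo, f_hi].  The phase is the
    running integral of 2*pi*f, hence continuous by construction.

    Returns (phase at bin centres, per-bin instantaneous frequency).
    """
    f_lo, f_hi = params.jitter_band
    step = (f_hi - f_lo) / 4.0
    phase = np.empty(n_bins)
    freq = np.empty(n_bins)
    f = float(params.f0)
    phi = params.phase0  # phase at the start of the current cycle
    i = 0
    while i < n_bins:
        n_cycle = max(1, int(round(1.0 / (f * dt))))
        n_cycle = min(n_cycle, n_bins - i)
        dphi = 2.0 * np.pi * f * dt
        phase[i:i + n_cycle] = phi + dphi * (np.arange(n_cycle) + 0.5)
        freq[i:i + n_cycle] = f
        phi += dphi * n_cycle
        i += n_cycle
        if step > 0:
            f += rng.uniform(-step, step)
            # reflect into the band
            if f < f_lo:
                f = 2 * f_lo - f
            if f > f_hi:
                f = 2 * f_hi - f
    return phase, freq


def generate_jittered_train(params: OscillatoryRateParams, T: float, seed,
                            dt: float = DEFAULT_DT) -> SpikeTrain:
    """Generate a train whose oscillation frequency wanders inside a band.

    Requires ``params.jitter_band``.  The frequency trajectory stays within
    [f_lo, f_hi] and the oscillation phase is continuous, so the spectral
    peak spreads over the band instead of jumping between frequencies.
    """
    if params.jitter_band is None:
        raise ParameterError("generate_jittered_train requires jitter_band")
    if T <= 0:
        raise ParameterError(f"T must be positive, got {T}")
    rng = _as_rng(seed)
    n_bins = int(round(T / dt))
    phase, _ = _jittered_phase(params, n_bins, dt, rng)
    lam = params.r0 * (1.0 + params.m * np.cos(phase))
    p = _check_probabilities(params, dt, lam * dt)
    idx = _sample_bins(p, params.tau_ref, dt, rng)
    return SpikeTrain(times=(idx + 0.5) * dt, T=T)


def bin_train(train: SpikeTrain, dt: float = DEFAULT_DT) -> BinnedTrain:
    """Bin a spike train into counts over half-open bins [k*dt, (k+1)*dt).

    The total count is conserved: ``sum(counts) == train.n_spikes``.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    n_bins = int(np.ceil(round(train.T / dt, 9)))
    idx = np.floor(train.times / dt).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)  # guards float fuzz at the last edge
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedTrain(counts=counts, dt=dt)


def expected_count(params: OscillatoryRateParams, T: float) -> float:
    """Expected number of spikes in [0, T]: r0*T*(1 + m*sinc(2*f0*T))."""
    return params.r0 * T * (1.0 + params.m * np.sinc(2.0 * params.f0 * T))


# ---------------------------------------------------------------------------
# fixture grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureGridConfig:
    """Cartesian grid of simulation conditions with deterministic seeding."""

    r0_values: Sequence[float]
    m_values: Sequence[float]
    durations: Sequence[float]
    reps: int
    base_seed: int
    f0: float = 12.0
    tau_ref: float = 0.0
    dt: float = DEFAULT_DT


def iter_fixture_grid(config: FixtureGridConfig) -> Iterator[tuple[OscillatoryRateParams, float, int, SpikeTrain]]:
    """Yield (params, T, seed, train) for every grid cell and repetition.

    Seeds are ``base_seed + running_index`` so the full grid is reproducible
    and cells are mutually independent.
    """
    k = 0
    for r0 in config.r0_values:
        for m in config.m_values:
            for T in config.durations:
                params = OscillatoryRateParams(
                    r0=r0, m=m, f0=config.f0, tau_ref=config.tau_ref)
                for _ in range(config.reps):
                    seed = config.base_seed + k
                    k += 1
                    yield params, T, seed, generate_train(
                        params, T, seed, dt=config.dt)


def make_fixture_grid(config: FixtureGridConfig,
                      out_dir: str | Path | None = None):
    """Materialise a fixture grid and its JSON manifest.

    Returns ``(records, manifest)`` where each record is
    ``(params, T, seed, SpikeTrain)``.  When ``out_dir`` is given, spike
    times are written as plain text (one per line) and the manifest as
    ``manifest.json`` alongside them; the manifest is byte-stable for a
    fixed config.
    """
    records = list(iter_fixture_grid(config))
    manifest = {
        "f0": config.f0,
        "tau_ref": config.tau_ref,
        "dt": config.dt,
        "base_seed": config.base_seed,
        "reps": config.reps,
        "cells": [],
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for params, T, seed, train in records:
        name = f"r0_{params.r0:g}_m_{params.m:g}_T_{T:g}_seed_{seed}.txt"
        entry = {"r0": params.r0, "m": params.m, "T": T, "seed": seed,
                 "n_spikes": train.n_spikes, "file": name}
        manifest["cells"].append(entry)
        if out_path is not None:
            write_spike_times_txt(train, out_path / name)
    if out_path is not None:
        (out_path / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return records, manifest


def write_spike_times_txt(train: SpikeTrain, path: str | Path) -> None:
    """Write spike times as plain text, one time in seconds per line."""
    Path(path).write_text(
        "".join(f"{t:.6f}\n" for t in train.times))
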