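"""Spike-train readers/writers, report output, and the batch runner.

External time unit is always seconds; bins exist only inside the spectral
machinery.  Supported formats:

* plain text — one spike time per line, seconds, written at 1 us precision;
* CSV — columns ``unit_id,time_s``, multiple units per file.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ParameterError
from .modindex import (RefractoryModel, assess, correct_for_refractoriness,
                       estimate_tau_ref, significance_threshold)
from .simulate import SpikeTrain

log = logging.getLogger("spikeosc")


def _make_train(times: np.ndarray, T: float | None, label: str) -> SpikeTrain:
    if np.any(times < 0):
        raise ParameterError(f"{label}: negative spike times in input")
    if np.any(np.diff(times) < 0):
        warnings.warn(f"{label}: input times were unsorted; sorting",
                      RuntimeWarning, stacklevel=3)
        times = np.sort(times)
    dup = np.diff(times) == 0
    if np.any(dup):
        warnings.warn(
            f"{label}: {int(dup.sum())} duplicate spike times dropped",
            RuntimeWarning, stacklevel=3)
        times = np.concatenate([times[:1], times[1:][~dup]])
    if T is None:
        tmax = times[-1] if times.size else 0.0
        # round the duration up to the next millisecond past the last spike
        T = float(np.ceil((tmax + 1e-9) * 1000.0) / 1000.0) or 0.001
    if times.size and times[-1] >= T:
        raise ParameterError(
            f"{label}: spike at {times[-1]} s is outside duration T={T} s")
    return SpikeTrain(times=times, T=T)


def read_spike_times(path: str | Path, T: float | None = None,
                     fmt: str | None = None) -> dict[str, SpikeTrain]:
    """Read spike trains from plain text or CSV.

    Returns ``{unit_id: SpikeTrain}``; plain-text files yield a single unit
    named after the file stem.  ``T`` overrides the recording duration
    (default: last spike rounded up to the next millisecond).  Unsorted
    input is sorted with a warning; duplicated times are dropped with a
    warning; negative times are a format error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "txt"
    if fmt == "txt":
        text = path.read_text().split()
        times = np.array([float(v) for v in text], dtype=float)
        return {path.stem: _make_train(times, T, path.name)}
    if fmt == "csv":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ParameterError(
                f"{path.name}: CSV must have a time_s column")
        if "unit_id" not in df.columns:
            df["unit_id"] = path.stem
        out = {}
        for unit, sub in df.groupby("unit_id", sort=True):
            out[str(unit)] = _make_train(
                sub["time_s"].to_numpy(dtype=float), T,
                f"{path.name}:{unit}")
        return out
    raise ParameterError(f"unknown format {fmt!r}")


def write_spike_times(trains: dict[str, SpikeTrain] | SpikeTrain,
                      path: str | Path, fmt: str | None = None) -> None:
    """Write spike trains as plain text (single unit) or CSV (any number)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "txt"
    if isinstance(trains, SpikeTrain):
        trains = {path.stem: trains}
    if fmt == "txt":
        if len(trains) != 1:
            raise ParameterError("plain-text format holds a single unit")
        (train,) = trains.values()
        path.write_text("".join(f"{t:.6f}\n" for t in train.times))
        return
    if fmt == "csv":
        rows = [(unit, f"{t:.6f}") for unit, train in trains.items()
                for t in train.times]
        pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
            path, index=False)
        return
    raise ParameterError(f"unknown format {fmt!r}")


def write_spectrum_csv(ps, snr, path: str | Path) -> None:
    """Spectrum as CSV (freq_hz, power, snr) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"freq_hz": ps.freqs, "power": ps.power})
    if snr is not None:
        df["snr"] = snr.snr
    df.to_csv(path, index=False)
    meta = {"Fs": ps.Fs, "wl": ps.wl, "window_name": ps.window_name,
            "n_wins": ps.n_wins}
    if snr is not None:
        meta.update(noise_band=list(snr.noise_band),
                    noise_mean=snr.noise_mean, noise_std=snr.noise_std)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n")


# rate bin width (sp/s) for sharing null thresholds across units
RATE_BIN = 5.0


def run_batch(paths, config: RunConfig, T: float | None = None) -> pd.DataFrame:
    """Assess every unit in ``paths`` and return one report row per unit.

    Null significance thresholds are computed at the unit's rate rounded to
    the nearest ``RATE_BIN`` sp/s (and its exact duration), so units with
    similar rates share one Monte-Carlo null.  Per-unit failures are logged
    and reported in the ``error`` column; the batch continues.
    """
    rows = []
    for path in paths:
        try:
            units = read_spike_times(path, T=T)
        except Exception as exc:  # noqa: BLE001 — batch must survive bad files
            log.warning("failed to read %s: %s", path, exc)
            rows.append({"unit_id": Path(path).stem, "path": str(path),
                         "error": str(exc)})
            continue
        for unit, train in units.items():
            try:
                rows.append(_assess_unit(unit, path, train, config))
            except Exception as exc:  # noqa: BLE001
                log.warning("failed to assess %s: %s", unit, exc)
                rows.append({"unit_id": unit, "path": str(path),
                             "error": str(exc)})
    columns = ["unit_id", "path", "r0_hat", "f_peak", "m_hat", "threshold",
               "significant", "peak_snr", "tau_ref", "m_p_hat", "error"]
    return pd.DataFrame(rows).reindex(columns=columns)


def _assess_unit(unit: str, path, train: SpikeTrain,
                 config: RunConfig) -> dict:
    result = assess(train, config.search_band, wl=config.wl,
                    window_name=config.window_name, dt=config.bin_dt,
                    noise_band=config.noise_band,
                    compute_significance=False)
    r0_binned = max(RATE_BIN, round(result.r0_hat / RATE_BIN) * RATE_BIN)
    threshold = significance_threshold(
        r0_binned, train.T, config.search_band, n_sim=config.n_null,
        seed=config.seed, wl=config.wl, window_name=config.window_name,
        dt=config.bin_dt, noise_band=config.noise_band)
    tau_ref = None
    m_p_hat = None
    if config.tau_ref_mode != "zero":
        tau_ref = (config.tau_ref if config.tau_ref_mode == "fixed"
                   else estimate_tau_ref(train))
        if tau_ref > 0 and result.m_hat > 0:
            model = RefractoryModel(tau_ref=tau_ref)
            m_p_hat = correct_for_refractoriness(
                train, result, model, seed=config.seed, wl=config.wl,
                window_name=config.window_name, dt=config.bin_dt,
                noise_band=config.noise_band)
        else:
            m_p_hat = result.m_hat
    return {"unit_id": unit, "path": str(path), "r0_hat": result.r0_hat,
            "f_peak": result.f_peak, "m_hat": result.m_hat,
            "threshold": threshold,
            "significant": bool(result.m_hat > threshold),
            "peak_snr": result.peak_snr, "tau_ref": tau_ref,
            "m_p_hat": m_p_hat, "error": None}


def write_report(df: pd.DataFrame, path: str | Path,
                 config: RunConfig) -> None:
    """Write the batch report CSV plus a JSON sidecar with the full config."""
    path = Path(path)
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"config": config.to_dict()}, indent=1, sort_keys=True)
        + "\n")
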