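"""Run configuration shared by the assessment pipeline, batch runner and CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    """Analysis settings; the defaults reproduce the standard pipeline:
    1 ms bins, 1000-bin non-overlapping Hamming Welch segments (1 Hz
    resolution, 500 Hz Nyquist), 100-500 Hz noise band, SNR threshold of 5
    standard deviations, and a 1000-train Monte-Carlo null for the
    modulation-index significance threshold.
    """

    bin_dt: float = 0.001
    wl: int = 1000
    window_name: str = "hamming"
    search_band: tuple[float, float] = (10.0, 15.0)
    noise_band: tuple[float, float] = (100.0, 500.0)
    snr_threshold: float = 5.0
    n_null: int = 1000
    seed: int = 0
    tau_ref_mode: str = "zero"     # "zero" | "auto" | "fixed"
    tau_ref: float = 0.002         # used when tau_ref_mode == "fixed"

    def __post_init__(self) -> None:
        nyquist = 0.5 / self.bin_dt
        for name, band in (("search_band", self.search_band),
                           ("noise_band", self.noise_band)):
            lo, hi = band
            if not (0 <= lo < hi <= nyquist):
                raise ParameterError(
                    f"{name}={band} must lie within (0, {nyquist}] Hz")
        if self.tau_ref_mode not in ("zero", "auto", "fixed"):
            raise ParameterError(
                f"tau_ref_mode must be zero/auto/fixed, got {self.tau_ref_mode}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["search_band"] = list(self.search_band)
        d["noise_band"] = list(self.noise_band)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("search_band", "noise_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))
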