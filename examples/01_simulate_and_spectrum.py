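"""Simulate an oscillatory spike train and inspect its spectral SNR.

A 12 Hz cosine modulation of depth m=0.5 on a 40 sp/s baseline is clearly
visible in the Welch spectrum of a 5-minute recording: the peak at 12 Hz
stands tens of standard deviations above the 100-500 Hz noise floor.
"""

import numpy as np

from spikeosc import (OscillatoryRateParams, bin_train, estimate_rate,
                      find_peak, generate_train, snr_spectrum, welch_psd)

params = OscillatoryRateParams(r0=40, m=0.5, f0=12)
train = generate_train(params, T=300.0, seed=1)
print(f"simulated {train.n_spikes} spikes over {train.T:.0f} s "
      f"(mean rate {estimate_rate(train):.1f} sp/s)")

ps = welch_psd(bin_train(train))           # 1000-bin Hamming segments, 1 Hz
snr = snr_spectrum(ps)                     # SD units vs the 100-500 Hz band
peak = find_peak(snr, ps, band=(10, 15), r0_hat=estimate_rate(train))

print(f"spectral peak at {peak.f_peak:g} Hz, SNR {peak.peak_snr:.1f} SD")
print(f"corrected peak power {peak.peak_power:.0f} "
      f"(closed-form expectation {40 * (1 + 40 * 300 * 0.25 / 4):.0f})")
# The SNR in SD units is what detection thresholds (e.g. SNR >= 5) act on;
# the corrected peak power is on the analytic scale used by the
# modulation-index estimator.
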