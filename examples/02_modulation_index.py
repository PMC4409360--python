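"""Estimate the modulation index and its significance for one spike train.

The raw spectral SNR grows with the firing rate and recording duration, but
the modulation index recovers the generator's modulation depth directly:
here a train simulated with m = 0.5 yields m_hat close to 0.5, well above
the Monte-Carlo null threshold for its firing rate.
"""

import numpy as np

from spikeosc import (OscillatoryRateParams, assess, generate_train,
                      reconstruct_rate)

params = OscillatoryRateParams(r0=60, m=0.5, f0=12)
train = generate_train(params, T=300.0, seed=7)

result = assess(train, f_band=(10, 15), n_null=300, seed=8)
print(f"r0_hat = {result.r0_hat:.1f} sp/s, f_peak = {result.f_peak:g} Hz")
print(f"m_hat = {result.m_hat:.3f} (true 0.5)")
print(f"null threshold = {result.threshold:.3f} -> "
      f"{'significant' if result.significant else 'not significant'}")

t = np.linspace(0, 1 / 12, 5)
print("reconstructed rate over one cycle (sp/s):",
      np.round(reconstruct_rate(result, t), 1))
# The reconstruction r0_hat*(1 + m_hat*cos(2*pi*f_peak*t)) fully describes
# the estimated rate function: peak near 90 sp/s, trough near 30 sp/s.
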