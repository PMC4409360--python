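"""Plan the recording duration needed to detect an oscillation.

From pilot estimates of the firing rate and modulation index, the planner
inverts the Welch SNR growth law SNR(T) = (r0*wl*m^2/4)*sqrt(T/wl) for the
duration at which a target peak SNR is reached.  For a 75 sp/s neuron with
m = 0.25, less than half a minute suffices for SNR 5.
"""

from spikeosc import (PlanInputs, predicted_welch_snr, required_duration,
                      simulated_detection_probability)

plan = PlanInputs(r0_hat=75, m_hat=0.25, target_snr=5.0, wl_s=1.0)
T_hat = required_duration(plan)
print(f"required duration for SNR 5: {T_hat:.1f} s")
print(f"round trip: predicted SNR at T_hat = "
      f"{predicted_welch_snr(plan, T_hat):.2f}")

plan7 = PlanInputs(r0_hat=75, m_hat=0.25, target_snr=7.0, wl_s=1.0)
print(f"required duration for SNR 7: {required_duration(plan7):.1f} s")

p = simulated_detection_probability(plan, T_hat, n_reps=200, seed=5)
print(f"simulated detection probability at T_hat: {p:.2f}")
# Crossing the threshold at the planned duration is stochastic (roughly a
# coin flip by construction), and the Hamming taper costs some coherent
# gain, so plan with margin: recording ~2x the planned duration makes
# detection reliable.
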