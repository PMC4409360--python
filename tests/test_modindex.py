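"""Modulation-index estimation, significance, refractory correction,
rate reconstruction and the autocorrelogram comparison measure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeosc import (DegenerateInputError, InsufficientDataError,
                      ModIndexResult, OscillatoryRateParams, ParameterError,
                      RefractoryModel, SpikeTrain, assess, autocorr_snr,
                      correct_for_refractoriness, estimate_tau_ref,
                      generate_train, modulation_index,
                      poisson_equivalent_rate, raw_modulation_index,
                      reconstruct_rate, significance_threshold)

F0_BIN = (12.0, 12.0)  # extraction at the known simulation frequency


# --------------------------------------------------------- modulation_index

def test_modulation_index_inverts_peak_power():
    # forward: 20*(1 + 20*60*0.3^2/4) = 560; inversion recovers 0.3
    assert modulation_index(560.0, 20.0, 60.0) == pytest.approx(0.3)


def test_modulation_index_clamps():
    assert modulation_index(20.0, 20.0, 60.0) == 0.0
    assert modulation_index(5.0, 20.0, 60.0) == 0.0       # below baseline
    with pytest.warns(RuntimeWarning):
        assert modulation_index(1e9, 20.0, 60.0) == 1.0   # above unity


def test_modulation_index_rejects_bad_inputs():
    with pytest.raises(ParameterError):
        modulation_index(10.0, 0.0, 60.0)
    with pytest.raises(ParameterError):
        modulation_index(10.0, 20.0, 0.0)


@given(m=st.floats(min_value=0.01, max_value=0.999),
       r0=st.floats(min_value=1.0, max_value=150.0),
       T=st.floats(min_value=1.0, max_value=3600.0))
@settings(deadline=None, max_examples=100)
def test_modulation_index_round_trip(m, r0, T):
    peak = r0 * (1 + r0 * T * m**2 / 4)
    assert modulation_index(peak, r0, T) == pytest.approx(m, rel=1e-9)


# ------------------------------------------------------------------- assess

def test_assess_recovers_modulation(rng):
    # mean m_hat over reps close to the generator's m (r0=60, m=0.5, T=300)
    p = OscillatoryRateParams(r0=60, m=0.5, f0=12)
    m_hats = []
    for _ in range(20):
        train = generate_train(p, 300.0, rng)
        res = assess(train, F0_BIN, compute_significance=False)
        m_hats.append(res.m_hat)
        assert res.f_peak == 12.0
    assert np.mean(m_hats) == pytest.approx(0.5, abs=0.05)


def test_assess_null_rarely_significant(rng):
    # homogeneous trains: mean+2SD rule fires in well under half the reps
    p = OscillatoryRateParams(r0=30, m=0.0, f0=12)
    flags = []
    for _ in range(40):
        train = generate_train(p, 60.0, rng)
        res = assess(train, F0_BIN, n_null=200, seed=900)
        flags.append(res.significant)
    assert np.mean(flags) <= 0.15


def test_assess_invariant_under_circular_shift(rng):
    # m_hat changes only by Monte-Carlo noise when the train is rotated
    p = OscillatoryRateParams(r0=60, m=0.5, f0=12)
    train = generate_train(p, 300.0, seed=31)
    shift = 17.2
    rolled = np.sort((train.times + shift) % train.T)
    shifted = SpikeTrain(times=rolled, T=train.T)
    m_a, *_ = raw_modulation_index(train, F0_BIN)
    m_b, *_ = raw_modulation_index(shifted, F0_BIN)
    assert m_b == pytest.approx(m_a, abs=0.05)


# ----------------------------------------------------- significance threshold

def test_threshold_positive_and_deterministic():
    a = significance_threshold(20.0, 60.0, F0_BIN, n_sim=50, seed=5,
                               use_cache=False)
    b = significance_threshold(20.0, 60.0, F0_BIN, n_sim=50, seed=5,
                               use_cache=False)
    assert a == b > 0


def test_threshold_cached():
    kw = dict(n_sim=30, seed=6)
    a = significance_threshold(25.0, 60.0, F0_BIN, **kw)
    b = significance_threshold(25.0, 60.0, F0_BIN, **kw)
    assert a is not None and a == b


def test_threshold_decreases_with_rate():
    # more spikes -> tighter null; monotone trend over a rate ladder
    thresholds = [significance_threshold(r0, 60.0, F0_BIN, n_sim=150,
                                         seed=8, use_cache=False)
                  for r0 in (10.0, 30.0, 60.0, 100.0)]
    assert thresholds[0] > thresholds[-1]
    assert all(t > 0 for t in thresholds)


# ------------------------------------------------------- refractory handling

def test_poisson_equivalent_rate_formula():
    train = SpikeTrain(times=np.linspace(0.001, 59.9, 3000), T=60.0)
    assert poisson_equivalent_rate(train, 0.0) == pytest.approx(50.0)
    assert poisson_equivalent_rate(train, 0.002) == pytest.approx(3000 / 54)
    with pytest.raises(DegenerateInputError):
        poisson_equivalent_rate(train, 0.02)  # tau*N == T


def test_estimate_tau_ref_on_simulated_trains():
    p = OscillatoryRateParams(r0=60, m=0.0, f0=12, tau_ref=0.002)
    train = generate_train(p, 600.0, seed=41)
    tau = estimate_tau_ref(train)
    assert 0.001 <= tau <= 0.003
    pure = generate_train(OscillatoryRateParams(r0=60, m=0.0, f0=12),
                          600.0, seed=42)
    assert estimate_tau_ref(pure) == 0.0
    with pytest.raises(InsufficientDataError):
        estimate_tau_ref(SpikeTrain(times=np.arange(10) * 0.1, T=2.0))


def test_correction_identity_without_refractoriness():
    result = ModIndexResult(r0_hat=40.0, f_peak=12.0, m_hat=0.4,
                            threshold=0.1, significant=True, peak_snr=8.0,
                            T=60.0)
    train = SpikeTrain(times=np.linspace(0.001, 59.9, 2400), T=60.0)
    model = RefractoryModel(tau_ref=0.0)
    assert correct_for_refractoriness(train, result, model) == 0.4


def test_correction_recovers_true_modulation():
    # ground truth m=0.5 with a 2 ms refractory period: raw m_hat is biased
    # low, the corrected index comes back near 0.5 and never below m_hat
    p = OscillatoryRateParams(r0=60, m=0.5, f0=12, tau_ref=0.002)
    train = generate_train(p, 300.0, seed=55)
    res = assess(train, F0_BIN, compute_significance=False)
    assert res.m_hat < 0.5
    model = RefractoryModel(tau_ref=0.002, n_sim=40)
    m_p = correct_for_refractoriness(train, res, model, seed=56)
    assert m_p >= res.m_hat
    assert m_p == pytest.approx(0.5, abs=0.07)


# --------------------------------------------------------- rate reconstruction

def test_reconstruct_rate_shape():
    res = ModIndexResult(r0_hat=5.0, f_peak=12.0, m_hat=0.5, threshold=0.1,
                         significant=True, peak_snr=10.0, T=60.0)
    t = np.linspace(0, 1 / 12, 1201)
    lam = reconstruct_rate(res, t)
    assert lam[0] == pytest.approx(7.5)
    assert lam.min() == pytest.approx(2.5, abs=1e-6)
    # mean over one full period equals the baseline rate
    period = np.linspace(0, 1 / 12, 1200, endpoint=False)
    assert reconstruct_rate(res, period).mean() == pytest.approx(5.0, rel=1e-6)
    flat = ModIndexResult(r0_hat=5.0, f_peak=12.0, m_hat=0.0, threshold=0.1,
                          significant=False, peak_snr=0.0, T=60.0)
    assert np.all(reconstruct_rate(flat, t) == 5.0)


def test_reconstruct_rate_prefers_corrected_index():
    res = ModIndexResult(r0_hat=5.0, f_peak=12.0, m_hat=0.3, threshold=0.1,
                         significant=True, peak_snr=10.0, T=60.0,
                         m_p_hat=0.5, tau_ref=0.002)
    assert reconstruct_rate(res, np.array([0.0]))[0] == pytest.approx(7.5)


# ------------------------------------------------------------- autocorrelogram

def test_autocorr_peak_near_oscillation_period(rng):
    p = OscillatoryRateParams(r0=30, m=0.5, f0=12)
    train = generate_train(p, 300.0, rng)
    res = autocorr_snr(train, max_lag=0.2)
    assert res.lag == pytest.approx(1 / 12, abs=0.01)   # ~83 ms
    assert res.snr > 0.5


def test_autocorr_snr_grows_with_rate(rng):
    # the autocorrelogram SNR shares the firing-rate bias of the spectral SNR
    means = []
    for r0 in (5.0, 15.0, 30.0):
        vals = []
        for _ in range(10):
            p = OscillatoryRateParams(r0=r0, m=0.5, f0=12)
            train = generate_train(p, 300.0, rng)
            vals.append(autocorr_snr(train, max_lag=0.2).snr)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
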