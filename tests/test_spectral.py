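"""Tests for the linearised spectral forward model and Welch estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamdcm.microcircuit import (CONNECTIONS, DEFAULT_KAPPA,
                                 MicrocircuitParams, default_params, drift,
                                 fixed_point, integrate)
from lamdcm.spectral import (InputSpectrum, LeadField, NoiseSpectrum,
                             default_grid, is_stable, jacobian, predict_csd,
                             shaped_noise, transfer_functions, welch_csd)


def zero_amp_params(**kw):
    return MicrocircuitParams(amplitudes={c: 0.0 for c in CONNECTIONS}, **kw)


TWO_CH = LeadField(gains=(1.0, 1.0), assignment=(4, 3))


# ----------------------------------------------------------------------
# lead field / spectra containers
# ----------------------------------------------------------------------

def test_lead_field_validation():
    with pytest.raises(ValueError):
        LeadField(gains=(1.0,), assignment=(1, 2))
    with pytest.raises(ValueError):
        LeadField(gains=(0.0, 1.0), assignment=(1, 2))
    with pytest.raises(ValueError):
        LeadField(gains=(1.0, 1.0), assignment=(1, 5))
    with pytest.raises(ValueError):
        LeadField(gains=(1.0, 1.0), assignment=(3, 3))


def test_lead_field_swap():
    assert TWO_CH.swapped().assignment == (3, 4)
    L = TWO_CH.matrix()
    assert L.shape == (2, 4)
    assert L[0, 3] == 1.0 and L[1, 2] == 1.0 and L.sum() == 2.0


def test_input_spectrum_form():
    gu = InputSpectrum(amp=2.0, exponent=1.0, bump_height=0.0)
    f = np.array([1.0, 2.0, 4.0])
    assert np.allclose(gu(f), 2.0 / f)
    with pytest.raises(ValueError):
        InputSpectrum(amp=-1.0)
    with pytest.raises(ValueError):
        InputSpectrum(bump_height=1.0, bump_width=-1.0)


def test_noise_spectrum_structure():
    gn = NoiseSpectrum(channel_amps=(0.1, 0.2), channel_exps=(1.0, 0.5),
                       common_amp=0.05, common_exp=1.0)
    f = np.array([1.0, 10.0])
    G = gn(f)
    assert G.shape == (2, 2, 2)
    # off-diagonal carries only the common part
    assert G[0, 0, 1] == pytest.approx(0.05)
    assert G[1, 0, 1] == pytest.approx(0.005)
    assert G[0, 0, 0] == pytest.approx(0.1 + 0.05)


# ----------------------------------------------------------------------
# jacobian
# ----------------------------------------------------------------------

def test_jacobian_uncoupled_blocks():
    p = zero_amp_params()
    J = jacobian(p)
    k = np.asarray(DEFAULT_KAPPA)
    assert np.allclose(J[:4, 4:], np.eye(4))
    assert np.allclose(J[:4, :4], 0.0)
    assert np.allclose(J[4:, :4], np.diag(-k ** 2))
    assert np.allclose(J[4:, 4:], np.diag(-2.0 * k))


def test_jacobian_finite_difference_oracle():
    rng = np.random.default_rng(5)
    amps = {c: float(rng.uniform(0.0, 1.0)) for c in CONNECTIONS}
    p = MicrocircuitParams(amplitudes=amps)
    xs = fixed_point(p)
    J = jacobian(p, xs)
    x0 = xs.flatten()
    h = 1e-6
    Jfd = np.empty((8, 8))
    for j in range(8):
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        Jfd[:, j] = (drift(xp, p) - drift(xm, p)) / (2 * h)
    assert np.max(np.abs(J - Jfd)) < 1e-6


def test_prior_mean_is_stable():
    assert is_stable(jacobian(default_params()))


# ----------------------------------------------------------------------
# transfer functions
# ----------------------------------------------------------------------

def test_transfer_closed_form_uncoupled():
    p = zero_amp_params(input_gain=1.5)
    lf = LeadField(gains=(2.0,), assignment=(1,))
    grid = default_grid(1, 50, 0.5)
    T = transfer_functions(p, lf, grid)
    w = 2.0 * np.pi * grid / 1000.0
    k = DEFAULT_KAPPA[0]
    expected = 2.0 * 1.5 * k / np.abs((1j * w) ** 2 + 2 * k * (1j * w) + k ** 2)
    assert np.allclose(np.abs(T[:, 0]), expected, rtol=1e-10)


def test_transfer_no_path_population_three():
    p = zero_amp_params()
    lf = LeadField(gains=(1.0,), assignment=(3,))
    T = transfer_functions(p, lf, default_grid(1, 50, 0.5))
    assert np.allclose(T, 0.0)


def test_transfer_fft_impulse_oracle():
    """FFT of the simulated impulse response matches T(f) to < 1%."""
    p = default_params()
    dt = 0.05
    n = int(4000 / dt)
    u = np.zeros(n)
    u[0] = 1.0 / dt
    v = integrate(p, u, dt=dt)
    grid = default_grid(1, 50, 0.5)
    lf = TWO_CH
    T = transfer_functions(p, lf, grid)
    freqs_fft = np.fft.rfftfreq(n, d=dt / 1000.0)
    for c, pop in enumerate(lf.assignment):
        V = np.fft.rfft(v[:, pop - 1]) * dt
        Vg = np.interp(grid, freqs_fft, np.abs(V))
        rel = np.abs(Vg - np.abs(T[:, c])) / np.abs(T[:, c])
        assert rel.max() < 0.01


# ----------------------------------------------------------------------
# predict_csd
# ----------------------------------------------------------------------

def test_predict_csd_hermitian_and_positive():
    csd = predict_csd(default_params(), TWO_CH, InputSpectrum(amp=0.02),
                      NoiseSpectrum(), default_grid(1, 50, 0.5))
    assert csd.is_hermitian()
    assert np.all(csd.auto_spectrum(0) >= 0.0)
    assert np.all(csd.auto_spectrum(1) >= 0.0)


def test_predict_csd_noise_floor_limit():
    """With a vanishing input spectrum the prediction reduces to g_N."""
    gn = NoiseSpectrum(channel_amps=(0.1, 0.2), common_amp=0.03)
    grid = default_grid(1, 50, 0.5)
    csd = predict_csd(default_params(), TWO_CH, InputSpectrum(amp=1e-30), gn, grid)
    assert np.allclose(csd.values, gn(grid), rtol=1e-6, atol=1e-12)


def test_predict_csd_bump_peak():
    gu = InputSpectrum(amp=0.0005, exponent=1.0, bump_height=0.1,
                       bump_freq=10.0, bump_width=1.5)
    grid = default_grid(1, 50, 0.5)
    csd = predict_csd(default_params(), TWO_CH, gu, None, grid)
    for c in range(2):
        assert abs(grid[np.argmax(csd.auto_spectrum(c))] - 10.0) <= 0.5


def test_predict_csd_gain_scaling_quadratic():
    grid = default_grid(1, 30, 1.0)
    gu = InputSpectrum(amp=0.02)
    base = predict_csd(default_params(), TWO_CH, gu, None, grid)
    c = 3.0
    lf2 = LeadField(gains=(c, c), assignment=(4, 3))
    scaled = predict_csd(default_params(), lf2, gu, None, grid)
    assert np.allclose(scaled.values, c ** 2 * base.values, rtol=1e-12)


def test_predict_csd_reciprocity_swap():
    grid = default_grid(1, 30, 1.0)
    gu = InputSpectrum(amp=0.02)
    fwd = predict_csd(default_params(), TWO_CH, gu, None, grid)
    rev = predict_csd(default_params(), TWO_CH.swapped(), gu, None, grid)
    perm = [1, 0]
    assert np.allclose(rev.values, fwd.values[:, perm][:, :, perm], rtol=1e-12)


def test_predict_csd_channel_count_mismatch():
    gn = NoiseSpectrum(channel_amps=(0.1,), channel_exps=(1.0,))
    with pytest.raises(ValueError):
        predict_csd(default_params(), TWO_CH, InputSpectrum(), gn,
                    default_grid(1, 30, 1.0))


# ----------------------------------------------------------------------
# welch_csd / shaped noise
# ----------------------------------------------------------------------

def test_welch_duplicated_channel_unit_coherence():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(20000)
    csd = welch_csd(np.vstack([x, x]), fs=500.0, nperseg=1024)
    coh = np.abs(csd.values[:, 0, 1]) ** 2 / (csd.auto_spectrum(0) * csd.auto_spectrum(1))
    assert np.allclose(coh, 1.0, atol=1e-10)


def test_welch_white_noise_flat():
    rng = np.random.default_rng(1)
    fs = 500.0
    n = 400_000
    x = rng.standard_normal(n)
    nperseg = 1024
    csd = welch_csd(x[None, :], fs=fs, nperseg=nperseg)
    level = 1.0 / fs                       # two-sided variance density x2, one-sided
    auto = csd.auto_spectrum(0)
    # chi^2 sampling theory: relative SE ~ 1/sqrt(n_segments)
    nseg = n // (nperseg // 2) - 1
    se = 3.0 * 2.0 * level / np.sqrt(nseg)
    inside = np.abs(auto - 2.0 * level) <= se
    assert inside.mean() > 0.95


def test_welch_sinusoid_peak():
    fs = 500.0
    t = np.arange(100_000) / fs
    rng = np.random.default_rng(2)
    x = np.sin(2 * np.pi * 10.0 * t) + 0.01 * rng.standard_normal(t.size)
    csd = welch_csd(x[None, :], fs=fs, nperseg=2048)
    fpk = csd.freqs[np.argmax(csd.auto_spectrum(0))]
    assert abs(fpk - 10.0) <= fs / 2048


def test_welch_requires_two_segments():
    with pytest.raises(ValueError):
        welch_csd(np.zeros((1, 100)), fs=100.0, nperseg=90)


def test_welch_cross_phase_convention():
    """A delayed copy must show phase exp(-i w tau) in <x1 conj(x2)>."""
    fs = 1000.0
    f0 = 50.0
    t = np.arange(60000) / fs
    lag = 2  # samples; x2 lags x1
    x1 = np.sin(2 * np.pi * f0 * t)
    x2 = np.roll(x1, lag)
    csd = welch_csd(np.vstack([x1, x2]), fs=fs, nperseg=1000)
    i = np.argmin(np.abs(csd.freqs - f0))
    phase = np.angle(csd.values[i, 0, 1])
    assert phase == pytest.approx(2 * np.pi * f0 * lag / fs, abs=0.02)


def test_shaped_noise_matches_target_psd():
    gu = InputSpectrum(amp=0.5, exponent=0.0)    # flat target
    dt = 1.0
    rng = np.random.default_rng(4)
    x = shaped_noise(gu, 500_000, dt, rng)
    csd = welch_csd(x[None, :], fs=1000.0 / dt, nperseg=512)
    assert np.median(csd.auto_spectrum(0)) == pytest.approx(0.5, rel=0.05)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_welch_hermitian_property(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((2, 4096))
    csd = welch_csd(x, fs=250.0, nperseg=512)
    assert csd.is_hermitian()
    assert np.all(csd.auto_spectrum(0) >= 0)
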