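"""Unit and property tests for the neural mass microcircuit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamdcm.microcircuit import (CONNECTIONS, DEFAULT_KAPPA, IntegrationError,
                                 MicrocircuitParams, MicrocircuitState,
                                 SigmoidParams, default_params, drift,
                                 fixed_point, integrate, sigmoid_rate,
                                 sigmoid_slope)


def zero_amp_params(**kw) -> MicrocircuitParams:
    return MicrocircuitParams(amplitudes={c: 0.0 for c in CONNECTIONS}, **kw)


# ----------------------------------------------------------------------
# sigmoid
# ----------------------------------------------------------------------

def test_sigmoid_zero_centred():
    assert sigmoid_rate(0.0, SigmoidParams()) == 0.0


def test_sigmoid_value_at_one():
    # 1/(1+e^-0.6) - 0.5
    assert sigmoid_rate(1.0, SigmoidParams(r=0.6, eta=0.0)) == pytest.approx(
        1.0 / (1.0 + np.exp(-0.6)) - 0.5, abs=1e-12)
    assert sigmoid_rate(1.0, SigmoidParams()) == pytest.approx(0.1457, abs=5e-5)


def test_sigmoid_asymptote():
    assert sigmoid_rate(1e3, SigmoidParams(r=0.6, eta=0.0)) == pytest.approx(0.5, abs=1e-9)
    # general eta: upper asymptote 1 - 1/(1+exp(r eta))
    p = SigmoidParams(r=0.8, eta=2.0)
    assert sigmoid_rate(1e3, p) == pytest.approx(1.0 - 1.0 / (1.0 + np.exp(0.8 * 2.0)), abs=1e-9)


def test_sigmoid_slope_at_origin():
    p = SigmoidParams(r=0.6, eta=0.0)
    assert sigmoid_slope(0.0, p) == pytest.approx(0.6 / 4.0, abs=1e-12)


def test_sigmoid_invalid_slope():
    with pytest.raises(ValueError):
        SigmoidParams(r=-1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(-50, 50), st.floats(-50, 50))
def test_sigmoid_monotone(v1, v2):
    p = SigmoidParams()
    lo, hi = sorted((v1, v2))
    assert sigmoid_rate(lo, p) <= sigmoid_rate(hi, p)


# ----------------------------------------------------------------------
# drift
# ----------------------------------------------------------------------

def test_drift_origin_fixed_point():
    assert np.all(drift(np.zeros(8), default_params(), u=0.0) == 0.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.0, 5.0), min_size=10, max_size=10))
def test_drift_origin_fixed_point_any_amplitudes(amps):
    p = MicrocircuitParams(amplitudes=dict(zip(CONNECTIONS, amps)))
    assert np.linalg.norm(drift(np.zeros(8), p, u=0.0)) < 1e-14


def test_drift_uncoupled_restoring_term():
    # amplitudes 0, v1 = 1, vdot = 0 -> vddot1 = -kappa1^2 = -0.25
    p = zero_amp_params()
    x = np.zeros(8)
    x[0] = 1.0
    dx = drift(x, p, u=0.0)
    assert dx[4] == pytest.approx(-0.25, abs=1e-14)
    assert np.all(dx[[5, 6, 7]] == 0.0)


def test_drift_input_routing():
    p = zero_amp_params(input_gain=1.7)
    dx = drift(np.zeros(8), p, u=1.0)
    assert dx[4] == pytest.approx(DEFAULT_KAPPA[0] * 1.7, abs=1e-14)
    assert np.all(dx[[5, 6, 7]] == 0.0)
    assert np.all(dx[:4] == 0.0)


def test_drift_rejects_nonfinite():
    x = np.zeros(8)
    x[0] = np.nan
    with pytest.raises(IntegrationError):
        drift(x, default_params())


# ----------------------------------------------------------------------
# parameters container
# ----------------------------------------------------------------------

def test_params_roundtrip():
    p = default_params()
    q = MicrocircuitParams.from_dict(p.to_dict())
    assert q == p
    keys = set(p.to_dict())
    assert keys == {"kappa1", "kappa2", "kappa3", "kappa4", *CONNECTIONS,
                    "r", "eta", "input_gain"}


def test_params_scaled_and_with_amplitudes():
    p = default_params()
    q = p.scaled({"a44": 2.0})
    assert q.amplitudes["a44"] == pytest.approx(2.0 * p.amplitudes["a44"])
    r = p.with_amplitudes(a11=0.0)
    assert r.amplitudes["a11"] == 0.0
    assert r.amplitudes["a14"] == p.amplitudes["a14"]


def test_params_validation():
    with pytest.raises(ValueError):
        MicrocircuitParams(kappa=(1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        MicrocircuitParams(amplitudes={"a11": 1.0})
    bad = {c: 1.0 for c in CONNECTIONS}
    bad["a44"] = -0.1
    with pytest.raises(ValueError):
        MicrocircuitParams(amplitudes=bad)


def test_state_validation():
    with pytest.raises(ValueError):
        MicrocircuitState(v=[np.inf, 0, 0, 0], vdot=np.zeros(4))
    s = MicrocircuitState.zeros()
    assert np.all(MicrocircuitState.from_flat(s.flatten()).v == 0.0)


# ----------------------------------------------------------------------
# fixed point
# ----------------------------------------------------------------------

def test_fixed_point_origin():
    s = fixed_point(default_params(), u0=0.0)
    assert np.allclose(s.v, 0.0, atol=1e-12)
    assert np.all(s.vdot == 0.0)


def test_fixed_point_constant_input_uncoupled():
    # u0 = 0.5, amplitudes 0 -> v1* = 0.5 * input_gain / kappa1
    p = zero_amp_params(input_gain=2.0)
    s = fixed_point(p, u0=0.5)
    assert s.v[0] == pytest.approx(0.5 * 2.0 / DEFAULT_KAPPA[0], rel=1e-10)
    assert np.allclose(s.v[1:], 0.0, atol=1e-10)


def test_fixed_point_is_equilibrium():
    p = default_params()
    s = fixed_point(p, u0=0.3)
    assert np.max(np.abs(drift(s, p, u=0.3))) < 1e-10


# ----------------------------------------------------------------------
# integrate
# ----------------------------------------------------------------------

def test_integrate_zero_input_zero_output():
    v = integrate(default_params(), np.zeros(2000), dt=0.05)
    assert np.all(v == 0.0)


def test_integrate_dt_guard():
    with pytest.raises(ValueError):
        integrate(default_params(), np.zeros(10), dt=0.2)


def test_integrate_deterministic():
    rng = np.random.default_rng(3)
    u = rng.standard_normal(20000)
    p = default_params()
    v1 = integrate(p, u, dt=0.05)
    v2 = integrate(p, u.copy(), dt=0.05)
    assert np.array_equal(v1, v2)


def test_integrate_divergence_reported():
    # a bound below the response amplitude must trigger the divergence error
    p = zero_amp_params()
    u = np.zeros(4000)
    u[0] = 1000.0
    with pytest.raises(IntegrationError):
        integrate(p, u, dt=0.05, divergence_bound=1.0)


def test_integrate_impulse_matches_alpha_kernel():
    """Uncoupled impulse response is gain * kappa * t * exp(-kappa t)."""
    dt = 0.01
    p = zero_amp_params(input_gain=1.3)
    n = 8000
    u = np.zeros(n)
    u[0] = 1.0 / dt          # unit-area impulse under zero-order hold
    v = integrate(p, u, dt=dt)
    t = dt * np.arange(n)
    k = DEFAULT_KAPPA[0]
    # the zero-order-hold "impulse" is a box of width dt; its centroid lags
    # the ideal delta by dt/2, so compare against the half-step-shifted kernel
    ts = np.clip(t - dt / 2.0, 0.0, None)
    expected = 1.3 * k * ts * np.exp(-k * ts)
    err = np.max(np.abs(v[:, 0] - expected)) / expected.max()
    assert err < 1e-3
    assert np.allclose(v[:, 1:], 0.0)


def test_integrate_white_noise_variance_parseval():
    """Sample variance of v1 matches the integral of |H|^2 S_u (uncoupled)."""
    dt = 0.05
    p = zero_amp_params()
    rng = np.random.default_rng(12)
    sigma = 1.0
    n = int(120_000 / dt)  # 120 s
    u = sigma * rng.standard_normal(n)
    v = integrate(p, u, dt=dt)
    var = v[:, 0].var()
    # analytic: S_u two-sided = sigma^2 / fs; H(f) = k/((i w)^2 + 2k i w + k^2)
    fs = 1000.0 / dt
    f = np.linspace(0.0, fs / 2.0, 200001)
    w = 2.0 * np.pi * f / 1000.0
    k = DEFAULT_KAPPA[0]
    H2 = np.abs(k / ((1j * w) ** 2 + 2.0 * k * (1j * w) + k ** 2)) ** 2
    var_pred = 2.0 * np.trapezoid(H2 * sigma ** 2 / fs, f)
    assert var == pytest.approx(var_pred, rel=0.10)


def test_a44_variance_monotonicity():
    """Increasing superficial-PN self-inhibition reduces var(v4): 3-point probe."""
    rng = np.random.default_rng(7)
    dt = 0.05
    u = 0.05 * rng.standard_normal(int(40_000 / dt))
    variances = []
    for fac in (0.6, 1.0, 1.6):
        p = default_params().scaled({"a44": fac})
        v = integrate(p, u, dt=dt)
        variances.append(v[:, 3].var())
    assert variances[0] > variances[1] > variances[2]
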