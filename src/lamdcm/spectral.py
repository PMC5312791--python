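"""Linearised spectral forward model for laminar recordings.

Predicts the complex cross-spectral density (CSD) between laminar channels
from the microcircuit model: the state equations are linearised around
their fixed point, giving per-channel transfer functions

    T_i(omega) = phi_i e_{m(i)}^T (i omega I - J)^{-1} B

where J is the Jacobian of the drift, B routes the exogenous input into
population 1's acceleration, and the diagonal lead field assigns channel i
to population m(i) with gain phi_i.  The predicted CSD is

    g_Y(omega)_ij = T_i(omega) g_u(omega) conj(T_j(omega)) + g_N(omega)_ij

with a parameterised endogenous-input spectrum g_u (scale-free background
plus an optional Gaussian bump, e.g. a 10 Hz thalamic peak) and channel
noise g_N.  Frequencies are in Hz; the state equations run in ms, so
omega = 2 pi f / 1000 rad/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .csd import CrossSpectralDensity, validate_frequency_grid
from .microcircuit import (MicrocircuitParams, MicrocircuitState,
                           fixed_point, sigmoid_slope)

__all__ = [
    "LeadField", "InputSpectrum", "NoiseSpectrum",
    "default_grid", "jacobian", "is_stable", "transfer_functions",
    "predict_csd", "welch_csd", "shaped_noise",
]


def default_grid(fmin: float = 1.0, fmax: float = 100.0, df: float = 0.5) -> np.ndarray:
    """Default frequency grid: 1-100 Hz at 0.5 Hz."""
    n = int(round((fmax - fmin) / df)) + 1
    return validate_frequency_grid(fmin + df * np.arange(n))


@dataclass(frozen=True)
class LeadField:
    """Diagonal laminar lead field: one population per channel.

    ``assignment[i]`` is the 1-based population index recorded by channel i
    (injective), ``gains[i]`` its positive sensitivity phi_i.
    """

    gains: tuple
    assignment: tuple

    def __post_init__(self):
        if len(self.gains) != len(self.assignment):
            raise ValueError("gains and assignment must have equal length")
        if any(g <= 0 for g in self.gains):
            raise ValueError("lead-field gains must be positive")
        if not set(self.assignment) <= {1, 2, 3, 4}:
            raise ValueError("assignment must map into populations 1..4")
        if len(set(self.assignment)) != len(self.assignment):
            raise ValueError("assignment must be injective")

    @property
    def n_channels(self) -> int:
        return len(self.gains)

    def swapped(self) -> "LeadField":
        """Reverse the channel-to-population assignment (two channels)."""
        if self.n_channels != 2:
            raise ValueError("swapped() is defined for two channels")
        return replace(self, assignment=(self.assignment[1], self.assignment[0]))

    def matrix(self) -> np.ndarray:
        """(n_chan, 4) selection matrix picking assigned voltages x gains."""
        L = np.zeros((self.n_channels, 4))
        for i, (g, m) in enumerate(zip(self.gains, self.assignment)):
            L[i, m - 1] = g
        return L


@dataclass(frozen=True)
class InputSpectrum:
    """Endogenous-input spectrum: scale-free noise plus an optional bump.

    g_u(f) = amp * f^(-exponent) + bump_height * exp(-(f-bump_freq)^2 / (2 bump_width^2))
    """

    amp: float = 1.0
    exponent: float = 1.0
    bump_height: float = 0.0
    bump_freq: float = 10.0
    bump_width: float = 1.5

    def __post_init__(self):
        if self.amp <= 0 or self.exponent < 0 or self.bump_height < 0:
            raise ValueError("require amp > 0, exponent >= 0, bump_height >= 0")
        if self.bump_height > 0 and (self.bump_freq <= 0 or self.bump_width <= 0):
            raise ValueError("bump centre and width must be positive")

    def __call__(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        g = self.amp * f ** (-self.exponent)
        if self.bump_height > 0:
            g = g + self.bump_height * np.exp(-0.5 * ((f - self.bump_freq) / self.bump_width) ** 2)
        return g


@dataclass(frozen=True)
class NoiseSpectrum:
    """Channel-noise spectrum: per-channel and common scale-free components.

    The common component is shared across channels; by default it
    contributes to every entry of the noise CSD (``cross_common=True``),
    with the channel-specific components on the diagonal only.
    """

    channel_amps: tuple = (0.05, 0.05)
    channel_exps: tuple = (1.0, 1.0)
    common_amp: float = 0.02
    common_exp: float = 1.0
    cross_common: bool = True

    def __post_init__(self):
        if len(self.channel_amps) != len(self.channel_exps):
            raise ValueError("per-channel amplitudes and exponents must pair up")
        if any(a <= 0 for a in self.channel_amps) or self.common_amp < 0:
            raise ValueError("auto-spectral noise contributions must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_amps)

    def __call__(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        nc = self.n_channels
        out = np.zeros((f.size, nc, nc), dtype=complex)
        common = self.common_amp * f ** (-self.common_exp)
        if self.cross_common:
            out += common[:, None, None]
        for i in range(nc):
            out[:, i, i] += self.channel_amps[i] * f ** (-self.channel_exps[i])
            if not self.cross_common:
                out[:, i, i] += common
        return out


def jacobian(params: MicrocircuitParams, xstar: MicrocircuitState | None = None) -> np.ndarray:
    """Analytic 8x8 Jacobian of the drift at a fixed point.

    State ordering (v1..v4, v1'..v4').  With all amplitudes zero the matrix
    is block-reducible into four damped-oscillator blocks
    [[0, 1], [-kappa^2, -2 kappa]].
    """
    if xstar is None:
        xstar = fixed_point(params)
    v = xstar.v
    k = params.kappa_array
    a = params.amplitudes
    sp = sigmoid_slope(v, params.sigmoid)
    # dF_m/dv_j with the fixed sign structure
    C = np.zeros((4, 4))
    C[0, 3] = a["a14"] * sp[3]
    C[0, 0] = -a["a11"] * sp[0]
    C[1, 2] = a["a23"] * sp[2]
    C[1, 1] = -a["a22"] * sp[1]
    C[2, 1] = -a["a32"] * sp[1]
    C[2, 0] = -a["a31"] * sp[0]
    C[2, 2] = -a["a33"] * sp[2]
    C[2, 3] = a["a34"] * sp[3]
    C[3, 0] = -a["a41"] * sp[0]
    C[3, 3] = -a["a44"] * sp[3]
    J = np.zeros((8, 8))
    J[:4, 4:] = np.eye(4)
    J[4:, :4] = np.diag(-k ** 2) + k[:, None] * C
    J[4:, 4:] = np.diag(-2.0 * k)
    return J


def is_stable(J: np.ndarray) -> bool:
    """All Jacobian eigenvalues strictly in the left half-plane."""
    return bool(np.linalg.eigvals(J).real.max() < 0)


def transfer_functions(params: MicrocircuitParams, lf: LeadField,
                       freqs: np.ndarray, xstar: MicrocircuitState | None = None,
                       J: np.ndarray | None = None) -> np.ndarray:
    """Channel transfer functions T_i(f) from exogenous input to channels.

    Returns a complex (n_freq, n_chan) array.  T is the Fourier transform
    of the first-order (impulse-response) kernel of the linearised system.
    """
    f = validate_frequency_grid(freqs)
    if J is None:
        J = jacobian(params, xstar)
    B = np.zeros(8)
    B[4] = params.kappa_array[0] * params.input_gain
    omega = 2.0 * np.pi * f / 1000.0  # rad/ms
    A = (1j * omega)[:, None, None] * np.eye(8) - J[None, :, :]
    X = np.linalg.solve(A, np.broadcast_to(B[None, :, None], (f.size, 8, 1)).copy())
    Lx = lf.matrix()  # (n_chan, 4)
    return X[:, :4, 0] @ Lx.T


def predict_csd(params: MicrocircuitParams, lf: LeadField, gu: InputSpectrum,
                gn: NoiseSpectrum | None, freqs: np.ndarray,
                condition: str = "", channels: tuple = ()) -> CrossSpectralDensity:
    """Predicted CSD: g_Y = T g_u T^dagger + g_N (Hermitian by construction)."""
    f = validate_frequency_grid(freqs)
    T = transfer_functions(params, lf, f)
    g = gu(f)[:, None, None] * (T[:, :, None] * np.conj(T[:, None, :]))
    if gn is not None:
        if gn.n_channels != lf.n_channels:
            raise ValueError("noise spectrum channel count does not match lead field")
        g = g + gn(f)
    return CrossSpectralDensity(f, g, channels=channels, condition=condition).validate(1e-8)


def welch_csd(series: np.ndarray, fs: float, nperseg: int,
              noverlap: int | None = None, channels: tuple = (),
              condition: str = "", detrend: str = "constant") -> CrossSpectralDensity:
    """Welch estimate of the CSD matrix of a multichannel time series.

    Parameters
    ----------
    series
        Array (n_chan, n_samples); ``fs`` in Hz.
    nperseg, noverlap
        Welch segmentation; at least two segments are required.

    Returns a one-sided CSD (density units, per Hz) on the FFT grid
    excluding DC.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    nch, n = x.shape
    if noverlap is None:
        noverlap = nperseg // 2
    if n < nperseg + (nperseg - noverlap):
        raise ValueError("series shorter than two Welch segments")
    f, _ = signal.csd(x[0], x[0], fs=fs, nperseg=nperseg, noverlap=noverlap,
                      detrend=detrend)
    vals = np.empty((f.size, nch, nch), dtype=complex)
    for i in range(nch):
        for j in range(i, nch):
            _, gij = signal.csd(x[i], x[j], fs=fs, nperseg=nperseg,
                                noverlap=noverlap, detrend=detrend)
            # scipy's convention conjugates the first argument; store <x_i conj(x_j)>
            vals[:, i, j] = np.conj(gij)
            vals[:, j, i] = gij
        vals[:, i, i] = np.real(vals[:, i, i])
    keep = f > 0
    return CrossSpectralDensity(f[keep], vals[keep], channels=channels,
                                condition=condition)


def shaped_noise(gu: InputSpectrum, n: int, dt: float, rng: np.random.Generator,
                 fmax: float | None = None) -> np.ndarray:
    """Gaussian noise with one-sided spectral density g_u(f).

    White Gaussian noise is shaped in the frequency domain so its one-sided
    PSD matches g_u on (0, fmax]; used to drive the time-domain oracle of
    the spectral predictions.  ``dt`` in ms.
    """
    fs = 1000.0 / dt  # Hz
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(f)
    pos = f > 0
    amp[pos] = np.sqrt(gu(f[pos]) * fs / 2.0)
    if fmax is not None:
        amp[f > fmax] = 0.0
    return np.fft.irfft(W * amp, n=n)
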