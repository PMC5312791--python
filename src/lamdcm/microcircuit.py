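"""Four-population canonical-microcircuit neural mass model.

The mesoscopic model describes the mean depolarisation ``v_m`` of four
neuronal populations in a cortical column:

========  =======================================
index     population
========  =======================================
1         superficial inhibitory interneurons
2         deep inhibitory interneurons
3         deep pyramidal cells
4         superficial pyramidal cells
========  =======================================

Each population obeys a critically damped second-order (alpha-kernel)
synaptic convolution driven by the sigmoid-transformed firing of its
afferents::

    v''_m = -2 kappa_m v'_m - kappa_m^2 v_m + kappa_m f_m(sigma(v), U)

with ten signed intrinsic connections (all recurrent/self connections
inhibitory) and exogenous input U entering population 1 only.  Time is in
milliseconds throughout; rate constants ``kappa`` in 1/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize

__all__ = [
    "CONNECTIONS",
    "CONNECTION_SIGNS",
    "POPULATION_ROLES",
    "TABLE_AMPLITUDE_RATIOS",
    "DEFAULT_AMPLITUDE_SCALE",
    "SigmoidParams",
    "MicrocircuitParams",
    "MicrocircuitState",
    "sigmoid_rate",
    "default_params",
    "drift",
    "fixed_point",
    "integrate",
    "FixedPointError",
    "IntegrationError",
]

#: Canonical ordering of the ten intrinsic connection amplitudes.
CONNECTIONS = ("a11", "a14", "a22", "a23", "a31", "a32", "a33", "a34", "a41", "a44")

#: Sign with which each amplitude enters the presynaptic drive f_m.
#: Self connections and interneuron efferents are inhibitory.
CONNECTION_SIGNS = {
    "a11": -1, "a14": +1,
    "a22": -1, "a23": +1,
    "a31": -1, "a32": -1, "a33": -1, "a34": +1,
    "a41": -1, "a44": -1,
}

#: Fixed population-role convention (1-based indices).
POPULATION_ROLES = {
    1: "superficial inhibitory interneurons",
    2: "deep inhibitory interneurons",
    3: "deep pyramidal cells",
    4: "superficial pyramidal cells",
}

#: Published relative magnitudes of the intrinsic connection kernels.
TABLE_AMPLITUDE_RATIOS = {
    "a11": 4.0, "a14": 4.0, "a22": 4.0, "a23": 2.0, "a31": 4.0,
    "a32": 8.0, "a33": 4.0, "a34": 8.0, "a41": 4.0, "a44": 8.0,
}

#: Default uniform scaling of the published amplitude ratios.  The scale is
#: chosen so that the prior-mean circuit is linearly stable with its least
#: damped mode in the alpha band (~10 Hz); see docs/methods.md for the
#: stability analysis behind this choice.
DEFAULT_AMPLITUDE_SCALE = 0.15

#: Default postsynaptic rate constants (1/ms).
DEFAULT_KAPPA = (1.0 / 2.0, 1.0 / 36.0, 1.0 / 16.0, 1.0 / 28.0)


class FixedPointError(RuntimeError):
    """Fixed-point search failed; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


class IntegrationError(RuntimeError):
    """Numerical divergence during time integration."""


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the postsynaptic firing-rate function.

    ``slope`` (r, per mV) and ``threshold`` (eta, mV) of the zero-centred
    logistic; prior means 0.6 and 0.
    """

    r: float = 0.6
    eta: float = 0.0

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError(f"sigmoid slope r must be positive, got {self.r}")


def sigmoid_rate(v, p: SigmoidParams):
    """Zero-centred logistic firing rate.

    ``s(v) = 1/(1+exp(-r(v-eta))) - 1/(1+exp(r eta))`` so that s(0) = 0:
    the resting point of the circuit is the origin for eta = 0.  Strictly
    increasing and bounded.
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-p.r * (v - p.eta))) - 1.0 / (1.0 + np.exp(p.r * p.eta))
    return out if out.ndim else float(out)


def sigmoid_slope(v, p: SigmoidParams):
    """Derivative of :func:`sigmoid_rate` with respect to v."""
    v = np.asarray(v, dtype=float)
    s = 1.0 / (1.0 + np.exp(-p.r * (v - p.eta)))
    out = p.r * s * (1.0 - s)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MicrocircuitParams:
    """State-equation parameters of the four-population circuit.

    Parameters
    ----------
    kappa
        Four postsynaptic rate constants (1/ms).
    amplitudes
        The ten non-negative connection magnitudes keyed by
        :data:`CONNECTIONS`; signs are fixed by :data:`CONNECTION_SIGNS`.
    sigmoid
        Firing-rate function parameters.
    input_gain
        Scalar weight of the exogenous input U into population 1.
    """

    kappa: tuple = DEFAULT_KAPPA
    amplitudes: dict = field(default_factory=dict)
    sigmoid: SigmoidParams = SigmoidParams()
    input_gain: float = 1.0

    def __post_init__(self):
        if len(self.kappa) != 4 or any(k <= 0 for k in self.kappa):
            raise ValueError("kappa must be four positive rate constants")
        if set(self.amplitudes) != set(CONNECTIONS):
            missing = set(CONNECTIONS) - set(self.amplitudes)
            extra = set(self.amplitudes) - set(CONNECTIONS)
            raise ValueError(f"amplitudes must have exactly the ten connections; missing={sorted(missing)} extra={sorted(extra)}")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("connection amplitudes must be non-negative")

    @property
    def kappa_array(self) -> np.ndarray:
        return np.asarray(self.kappa, dtype=float)

    @property
    def amplitude_vector(self) -> np.ndarray:
        """Amplitudes in :data:`CONNECTIONS` order."""
        return np.array([self.amplitudes[c] for c in CONNECTIONS], dtype=float)

    def with_amplitudes(self, **updates) -> "MicrocircuitParams":
        amps = dict(self.amplitudes)
        amps.update(updates)
        return replace(self, amplitudes=amps)

    def scaled(self, factors: dict) -> "MicrocircuitParams":
        """Multiply a subset of connections by given factors."""
        amps = dict(self.amplitudes)
        for name, fac in factors.items():
            amps[name] = amps[name] * fac
        return replace(self, amplitudes=amps)

    # -- flat serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {f"kappa{i+1}": float(k) for i, k in enumerate(self.kappa)}
        d.update({c: float(self.amplitudes[c]) for c in CONNECTIONS})
        d.update(r=float(self.sigmoid.r), eta=float(self.sigmoid.eta),
                 input_gain=float(self.input_gain))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MicrocircuitParams":
        kappa = tuple(float(d[f"kappa{i+1}"]) for i in range(4))
        amps = {c: float(d[c]) for c in CONNECTIONS}
        return cls(kappa=kappa, amplitudes=amps,
                   sigmoid=SigmoidParams(float(d.get("r", 0.6)), float(d.get("eta", 0.0))),
                   input_gain=float(d.get("input_gain", 1.0)))


@dataclass
class MicrocircuitState:
    """Population depolarisations and their first derivatives."""

    v: np.ndarray
    vdot: np.ndarray

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float).reshape(4)
        self.vdot = np.asarray(self.vdot, dtype=float).reshape(4)
        if not (np.isfinite(self.v).all() and np.isfinite(self.vdot).all()):
            raise ValueError("state entries must be finite")

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.v, self.vdot])

    @classmethod
    def from_flat(cls, x: np.ndarray) -> "MicrocircuitState":
        x = np.asarray(x, dtype=float).reshape(8)
        return cls(v=x[:4], vdot=x[4:])

    @classmethod
    def zeros(cls) -> "MicrocircuitState":
        return cls(v=np.zeros(4), vdot=np.zeros(4))


def presynaptic_drive(v: np.ndarray, params: MicrocircuitParams, u: float) -> np.ndarray:
    """The four signed afferent terms f_m, including exogenous input to f_1."""
    a = params.amplitudes
    s = sigmoid_rate(np.asarray(v, dtype=float), params.sigmoid)
    f = np.empty(4)
    f[0] = a["a14"] * s[3] - a["a11"] * s[0] + params.input_gain * u
    f[1] = a["a23"] * s[2] - a["a22"] * s[1]
    f[2] = -a["a32"] * s[1] - a["a31"] * s[0] - a["a33"] * s[2] + a["a34"] * s[3]
    f[3] = -a["a41"] * s[0] - a["a44"] * s[3]
    return f


def drift(x, params: MicrocircuitParams, u: float = 0.0) -> np.ndarray:
    """State derivative of the flattened 8-dimensional system.

    Returns ``(v', v'')`` with ``v''_m = -2 k_m v'_m - k_m^2 v_m + k_m f_m``.
    """
    if isinstance(x, MicrocircuitState):
        x = x.flatten()
    x = np.asarray(x, dtype=float).reshape(8)
    if not np.isfinite(x).all():
        raise IntegrationError("non-finite state passed to drift (divergence)")
    v, vdot = x[:4], x[4:]
    k = params.kappa_array
    f = presynaptic_drive(v, params, u)
    vddot = -2.0 * k * vdot - k ** 2 * v + k * f
    return np.concatenate([vdot, vddot])


def fixed_point(params: MicrocircuitParams, u0: float = 0.0,
                x0: np.ndarray | None = None, tol: float = 1e-10,
                maxiter: int = 200) -> MicrocircuitState:
    """Equilibrium of the circuit under constant input u0.

    The equilibrium has ``v' = 0`` and solves ``kappa_m f_m = kappa_m^2 v_m``;
    used as the expansion point for the linearised transfer functions.
    """
    a = params

    def eq(v):
        return presynaptic_drive(v, a, u0) - a.kappa_array * v

    v0 = np.zeros(4) if x0 is None else np.asarray(x0, dtype=float).reshape(-1)[:4]
    sol = optimize.root(eq, v0, method="hybr", options={"maxfev": maxiter * 8})
    state = MicrocircuitState(v=sol.x, vdot=np.zeros(4))
    resid = np.max(np.abs(drift(state, params, u0)))
    if resid > tol:
        raise FixedPointError(
            f"fixed point not converged (max |drift| = {resid:.3e} > {tol:.1e})",
            last_iterate=state.flatten())
    return state


@njit(cache=True)
def _drift_kernel(x, k, amps, r, eta, gain, u):  # pragma: no cover - numba
    out = np.empty(8)
    s = np.empty(4)
    s0 = 1.0 / (1.0 + np.exp(r * eta))
    for m in range(4):
        s[m] = 1.0 / (1.0 + np.exp(-r * (x[m] - eta))) - s0
    # amps order: a11,a14,a22,a23,a31,a32,a33,a34,a41,a44
    f0 = amps[1] * s[3] - amps[0] * s[0] + gain * u
    f1 = amps[3] * s[2] - amps[2] * s[1]
    f2 = -amps[5] * s[1] - amps[4] * s[0] - amps[6] * s[2] + amps[7] * s[3]
    f3 = -amps[8] * s[0] - amps[9] * s[3]
    for m in range(4):
        out[m] = x[4 + m]
    out[4] = -2.0 * k[0] * x[4] - k[0] * k[0] * x[0] + k[0] * f0
    out[5] = -2.0 * k[1] * x[5] - k[1] * k[1] * x[1] + k[1] * f1
    out[6] = -2.0 * k[2] * x[6] - k[2] * k[2] * x[2] + k[2] * f2
    out[7] = -2.0 * k[3] * x[7] - k[3] * k[3] * x[3] + k[3] * f3
    return out


@njit(cache=True)
def _rk4_kernel(x0, k, amps, r, eta, gain, u, dt, bound):  # pragma: no cover
    n = u.shape[0]
    out = np.empty((n, 4))
    x = x0.copy()
    for i in range(n):
        for m in range(4):
            out[i, m] = x[m]
        ui = u[i]  # zero-order hold over the step
        k1 = _drift_kernel(x, k, amps, r, eta, gain, ui)
        k2 = _drift_kernel(x + 0.5 * dt * k1, k, amps, r, eta, gain, ui)
        k3 = _drift_kernel(x + 0.5 * dt * k2, k, amps, r, eta, gain, ui)
        k4 = _drift_kernel(x + dt * k3, k, amps, r, eta, gain, ui)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for m in range(4):
            if np.abs(x[m]) > bound or not np.isfinite(x[m]):
                return out, i + 1
    return out, -1


def integrate(params: MicrocircuitParams, inputs: np.ndarray, dt: float = 0.05,
              x0: MicrocircuitState | None = None,
              divergence_bound: float = 1e6) -> np.ndarray:
    """Fixed-step RK4 integration of the circuit driven by a sampled input.

    Parameters
    ----------
    inputs
        Exogenous input U sampled at ``dt`` (zero-order hold within a step).
    dt
        Step in ms; must be <= 0.1 ms (stability guard for kappa_1 = 1/2).

    Returns
    -------
    ndarray, shape (len(inputs), 4)
        Population voltages; sample ``i`` is the state at time ``i * dt``.
        Deterministic: identical inputs give bit-identical output.
    """
    if dt > 0.1:
        raise ValueError(f"dt = {dt} ms exceeds the 0.1 ms stability guard")
    u = np.ascontiguousarray(inputs, dtype=float)
    if u.ndim != 1:
        raise ValueError("inputs must be a 1-d time series")
    state = MicrocircuitState.zeros() if x0 is None else x0
    out, bad = _rk4_kernel(state.flatten(), params.kappa_array,
                           params.amplitude_vector,
                           params.sigmoid.r, params.sigmoid.eta,
                           params.input_gain, u, float(dt),
                           float(divergence_bound))
    if bad >= 0:
        raise IntegrationError(
            f"|v| exceeded {divergence_bound:g} mV at step {bad} (t = {bad * dt:.3f} ms)")
    return out


def default_params(amplitude_scale: float = DEFAULT_AMPLITUDE_SCALE,
                   kappa: tuple = DEFAULT_KAPPA,
                   sigmoid: SigmoidParams = SigmoidParams(),
                   input_gain: float = 1.0) -> MicrocircuitParams:
    """Prior-mean parameters: published rate constants and amplitude ratios.

    The published amplitude table carries a "(x200)" annotation; applied
    literally (or even ignored) it places the circuit beyond its Hopf
    bifurcation at the prior mean, where no stationary spectral response
    exists.  The default scale keeps the published ratios but sets the
    overall magnitude so the prior circuit is stable with an alpha-band
    resonance; see docs/methods.md.
    """
    amps = {c: v * amplitude_scale for c, v in TABLE_AMPLITUDE_RATIOS.items()}
    return MicrocircuitParams(kappa=kappa, amplitudes=amps, sigmoid=sigmoid,
                              input_gain=input_gain)
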