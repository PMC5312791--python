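"""Variational Laplace inversion of the spectral forward model.

The observed CSD matrices are vectorised into real coordinates (real parts
of all unique channel pairs, imaginary parts of the off-diagonal pairs) and
modelled as the forward prediction plus Gaussian noise whose log-precisions
``lambda`` (one per channel-pair block) carry their own Gaussian
hyperpriors.  Latent parameters are log-scalings of positive quantities
(rate constants, connection amplitudes, gains, spectral amplitudes) and
identity offsets otherwise, with Gaussian priors.

Writing z = (theta, lambda) and rho = z - prior mean, the Gibbs energy is
the log joint of data and parameters,

    G(z) = -1/2 e'S^-1 e - 1/2 ln|S| - (n_y/2) ln 2pi
           -1/2 rho'O^-1 rho - 1/2 ln|O| - (n_z/2) ln 2pi

(real and imaginary residuals weighted by the same precision), and the free
energy is its Laplace integral,

    F = G(mu) + 1/2 ln|C| + (n_z/2) ln 2pi,   C = (-d2G/dz2)^-1,

which approximates the log model evidence ln p(y|m) and is exact for
linear-Gaussian problems.  Optimisation alternates damped Gauss-Newton
proposals accepted only when F increases, so the free-energy trace is
non-decreasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .csd import CrossSpectralDensity
from .microcircuit import CONNECTIONS, MicrocircuitParams
from .spectral import InputSpectrum, LeadField, NoiseSpectrum, predict_csd

__all__ = [
    "SpectralModel", "PriorDensity", "HyperParams", "PosteriorDensity",
    "InversionSettings", "default_free_parameters", "prediction_error",
    "gibbs_energy", "invert", "invert_vector", "free_energy",
    "noise_covariance", "coordinate_grid",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: Default set of latent coordinates estimated from data.  The overall
#: input scale (input_gain, gu_amp) is fixed: it is redundant with the
#: lead-field gains, which are free.
DEFAULT_FREE = CONNECTIONS + (
    "kappa1", "kappa2", "kappa3", "kappa4",
    "phi1", "phi2",
    "gu_exp", "gu_bump_h",
    "gn_common_amp", "gn_amp_ch1", "gn_amp_ch2",
)


def default_free_parameters() -> tuple:
    return DEFAULT_FREE


def _latent_kind(name: str) -> str:
    """'log' for positive parameters, 'lin' for the sigmoid threshold."""
    return "lin" if name == "eta" else "log"


@dataclass
class SpectralModel:
    """Forward-model specification mapping latent coordinates to CSDs.

    Parameters
    ----------
    mc, lf, gu, gn
        Base (prior-mean) values of the microcircuit, lead field, input
        spectrum and channel-noise spectrum.
    freqs
        Frequency grid (Hz) on which predictions are made.
    free
        Names of the latent coordinates.
    modulated
        Connection names receiving a condition-specific log-scaling
        ``beta`` applied in the first condition; adds coordinates named
        ``beta_<connection>``.
    n_conditions
        1 for a single data set, 2 for an ON/OFF pair (ON first).
    """

    mc: MicrocircuitParams
    lf: LeadField
    gu: InputSpectrum
    gn: NoiseSpectrum
    freqs: np.ndarray
    free: tuple = DEFAULT_FREE
    modulated: tuple = ()
    n_conditions: int = 1
    tag: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        bad = [m for m in self.modulated if m not in CONNECTIONS]
        if bad:
            raise ValueError(f"modulated names must be connections, got {bad}")
        if self.modulated and self.n_conditions != 2:
            raise ValueError("condition modulations require n_conditions = 2")

    # ------------------------------------------------------------------
    @property
    def names(self) -> tuple:
        return tuple(self.free) + tuple(f"beta_{m}" for m in self.modulated)

    @property
    def n_latent(self) -> int:
        return len(self.names)

    def _apply(self, name: str, z: float, mcd: dict, lfg: list, gud: dict, gnd: dict):
        if name in mcd:  # kappa*, a*, r, eta, input_gain
            mcd[name] = mcd[name] * np.exp(z) if _latent_kind(name) == "log" else mcd[name] + z
        elif name.startswith("phi"):
            i = int(name[3:]) - 1
            lfg[i] = lfg[i] * np.exp(z)
        elif name == "gu_amp":
            gud["amp"] *= np.exp(z)
        elif name == "gu_exp":
            gud["exponent"] *= np.exp(z)
        elif name == "gu_bump_h":
            gud["bump_height"] *= np.exp(z)
        elif name == "gu_bump_f":
            gud["bump_freq"] *= np.exp(z)
        elif name == "gu_bump_w":
            gud["bump_width"] *= np.exp(z)
        elif name == "gn_common_amp":
            gnd["common_amp"] *= np.exp(z)
        elif name == "gn_common_exp":
            gnd["common_exp"] *= np.exp(z)
        elif name.startswith("gn_amp_ch"):
            i = int(name[9:]) - 1
            gnd["channel_amps"][i] *= np.exp(z)
        elif name.startswith("gn_exp_ch"):
            i = int(name[9:]) - 1
            gnd["channel_exps"][i] *= np.exp(z)
        else:
            raise KeyError(f"unknown latent coordinate {name!r}")

    def build(self, z: np.ndarray, condition: int = 0):
        """Parameter bundle (mc, lf, gu, gn) at latent point z."""
        z = np.asarray(z, dtype=float)
        mcd = self.mc.to_dict()
        lfg = list(self.lf.gains)
        gud = {"amp": self.gu.amp, "exponent": self.gu.exponent,
               "bump_height": self.gu.bump_height, "bump_freq": self.gu.bump_freq,
               "bump_width": self.gu.bump_width}
        gnd = {"channel_amps": list(self.gn.channel_amps),
               "channel_exps": list(self.gn.channel_exps),
               "common_amp": self.gn.common_amp, "common_exp": self.gn.common_exp}
        nfree = len(self.free)
        for name, zi in zip(self.free, z[:nfree]):
            self._apply(name, zi, mcd, lfg, gud, gnd)
        if condition == 0:
            for m, beta in zip(self.modulated, z[nfree:]):
                mcd[m] = mcd[m] * np.exp(beta)
        mc = MicrocircuitParams.from_dict(mcd)
        lf = replace(self.lf, gains=tuple(lfg))
        gu = InputSpectrum(**gud)
        gn = NoiseSpectrum(channel_amps=tuple(gnd["channel_amps"]),
                           channel_exps=tuple(gnd["channel_exps"]),
                           common_amp=gnd["common_amp"], common_exp=gnd["common_exp"],
                           cross_common=self.gn.cross_common)
        return mc, lf, gu, gn

    def predict(self, z: np.ndarray, condition: int = 0) -> CrossSpectralDensity:
        mc, lf, gu, gn = self.build(z, condition)
        return predict_csd(mc, lf, gu, gn, self.freqs)

    def predict_vector(self, z: np.ndarray) -> np.ndarray:
        """Stacked real prediction vector over all conditions."""
        return np.concatenate([
            csd_vector(self.predict(z, c).values) for c in range(self.n_conditions)])

    def calibrated(self) -> "SpectralModel":
        """Rescale lead-field gains so prior-mean auto power averages one.

        A deterministic function of the model alone; keeps predictions on
        the same scale as unit-normalised data.
        """
        pred = self.predict(np.zeros(self.n_latent), 0)
        # total power (signal + noise floor), matching the statistic used to
        # unit-normalise observed data: the prior-mean prediction then sits
        # on exactly the same scale as prior-mean data, with no systematic
        # offset pushed into the noise amplitudes
        power = np.mean(np.real(np.diagonal(pred.values, axis1=1, axis2=2)))
        factor = float(1.0 / np.sqrt(power))
        lf = replace(self.lf, gains=tuple(g * factor for g in self.lf.gains))
        # keep the model-internal signal-to-noise ratio: the noise floor
        # scales with the squared gain
        gn = replace(self.gn,
                     channel_amps=tuple(a * factor ** 2 for a in self.gn.channel_amps),
                     common_amp=self.gn.common_amp * factor ** 2)
        return replace(self, lf=lf, gn=gn)


# ----------------------------------------------------------------------
# CSD vectorisation
# ----------------------------------------------------------------------

def _pairs(nch: int):
    return [(i, j) for i in range(nch) for j in range(i, nch)]


def csd_vector(values: np.ndarray) -> np.ndarray:
    """Vectorise (nf, nch, nch) Hermitian matrices into real coordinates.

    Layout: for each unique pair (i<=j) the real part over all
    frequencies, then for each strict pair (i<j) the imaginary part.
    """
    nf, nch, _ = values.shape
    segs = [np.real(values[:, i, j]) for i, j in _pairs(nch)]
    segs += [np.imag(values[:, i, j]) for i, j in _pairs(nch) if i != j]
    return np.concatenate(segs)


def vector_blocks(nf: int, nch: int) -> list:
    """Noise-component blocks: per pair, the slices of its coordinates."""
    pairs = _pairs(nch)
    strict = [p for p in pairs if p[0] != p[1]]
    blocks = []
    for k, p in enumerate(pairs):
        idx = [np.arange(k * nf, (k + 1) * nf)]
        if p[0] != p[1]:
            off = len(pairs) * nf + strict.index(p) * nf
            idx.append(np.arange(off, off + nf))
        blocks.append((p, np.concatenate(idx)))
    return blocks


def prediction_error(z: np.ndarray, data, model: SpectralModel) -> np.ndarray:
    """Residual vector: prediction minus vectorised data, all conditions."""
    y = data_vector(data, model)
    return model.predict_vector(z) - y


def data_vector(data, model: SpectralModel) -> np.ndarray:
    csds = data if isinstance(data, (list, tuple)) else [data]
    if len(csds) != model.n_conditions:
        raise ValueError("number of data conditions does not match the model")
    for c in csds:
        if c.freqs.shape != model.freqs.shape or not np.allclose(c.freqs, model.freqs):
            raise ValueError("data frequency grid does not match the model grid")
    return np.concatenate([csd_vector(c.values) for c in csds])


# ----------------------------------------------------------------------
# Densities
# ----------------------------------------------------------------------

@dataclass
class PriorDensity:
    """Gaussian density over latent coordinates."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim == 1:
            self.cov = np.diag(self.cov)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("prior covariance shape mismatch")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-12:
            raise ValueError("prior covariance must be PSD")

    @classmethod
    def default(cls, model: SpectralModel, variance: float = 1.0 / 8.0,
                sigmoid_variance: float = 1.0 / 32.0) -> "PriorDensity":
        names = model.names
        var = np.array([sigmoid_variance if n in ("r", "eta") else variance
                        for n in names])
        return cls(np.zeros(len(names)), np.diag(var), names=names)


@dataclass
class HyperParams:
    """Log-precision hyperparameters: prior mean and variance per component."""

    mean: np.ndarray
    variance: float = 1.0 / 16.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        if not np.isfinite(self.mean).all():
            raise ValueError("hyperparameter means must be finite")


@dataclass
class PosteriorDensity:
    """Gaussian posterior with free energy and hyperposterior attached."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    names: tuple
    lambdas: np.ndarray
    lambda_cov: np.ndarray
    trace: list
    converged: bool
    prior: PriorDensity
    data_scale: float = 1.0
    n_iter: int = 0

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def coordinate(self, name: str) -> tuple:
        i = self.names.index(name)
        return float(self.mean[i]), float(self.sd()[i])

    def report(self) -> dict:
        sd = self.sd()
        prior_sd = np.sqrt(np.diag(self.prior.cov))
        return {
            "free_energy": float(self.free_energy),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "data_scale": float(self.data_scale),
            "parameters": {
                n: {"prior_mean": float(self.prior.mean[i]),
                    "prior_sd": float(prior_sd[i]),
                    "posterior_mean": float(self.mean[i]),
                    "posterior_sd": float(sd[i])}
                for i, n in enumerate(self.names)},
            "lambda": {"mean": [float(v) for v in self.lambdas],
                       "sd": [float(v) for v in np.sqrt(np.diag(self.lambda_cov))]},
            "free_energy_trace": [float(v) for v in self.trace],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)


@dataclass
class InversionSettings:
    maxiter: int = 128
    tol: float = 1e-2
    patience: int = 3
    fd_step: float = 1e-3
    init_damping: float = 1.0
    max_damping: float = 1e8
    seed: int = 0


# ----------------------------------------------------------------------
# Gibbs energy / free energy
# ----------------------------------------------------------------------

def coordinate_grid(model: SpectralModel) -> tuple:
    """Map vector coordinates onto a (condition x frequency, coordinate) grid.

    Returns ``(grid_idx, block_of, cond_rows)``: ``grid_idx[F, c]`` is the
    vector index of coordinate c at grid row F (one row per condition and
    frequency), ``block_of[F, c]`` the noise-component index of that
    coordinate, and ``cond_rows`` the row ranges belonging to each
    condition (frequency differences are taken within conditions only).
    """
    nf = model.freqs.size
    nch = model.lf.n_channels
    per = vector_blocks(nf, nch)
    m = len(_pairs(nch)) + len([p for p in _pairs(nch) if p[0] != p[1]])
    ncoord = sum(idx.size for _, idx in per)
    nblocks_per = len(per)
    rows = model.n_conditions * nf
    grid = np.empty((rows, m), dtype=np.intp)
    block_of = np.empty((rows, m), dtype=np.intp)
    pairs = _pairs(nch)
    strict = [p for p in pairs if p[0] != p[1]]
    for c in range(model.n_conditions):
        for f in range(nf):
            row = c * nf + f
            col = 0
            for k, p in enumerate(pairs):
                grid[row, col] = c * ncoord + k * nf + f
                block_of[row, col] = c * nblocks_per + k
                col += 1
            for s, p in enumerate(strict):
                grid[row, col] = c * ncoord + (len(pairs) + s) * nf + f
                block_of[row, col] = c * nblocks_per + pairs.index(p)
                col += 1
    cond_rows = [(c * nf, (c + 1) * nf) for c in range(model.n_conditions)]
    return grid, block_of, cond_rows


def noise_covariance(y: np.ndarray, grid_idx: np.ndarray, cond_rows: list,
                     window: int = 9, ridge: float = 1e-3) -> np.ndarray:
    """Local noise covariance across CSD coordinates, per frequency.

    CSD sampling noise is heteroscedastic and correlated across the
    entries of the matrix at one frequency (with a common driving input
    the channels are nearly coherent, so the real/imaginary parts of all
    pairs fluctuate together).  Each noise component is therefore a fixed
    frequency-resolved covariance Q scaled by one free log-precision per
    channel-pair block.  Q is estimated from first differences over
    frequency: for a smooth spectrum with independent noise of covariance
    V(f), successive differences have covariance ~2 V(f); a running mean
    of their outer products gives V(f), ridge-regularised for
    conditioning (degenerate coordinates, e.g. duplicated channels, are
    handled by the ridge).
    """
    rows, m = grid_idx.shape
    V = np.empty((rows, m, m))
    half = window // 2
    for lo, hi in cond_rows:
        R = y[grid_idx[lo:hi]]                      # (nf, m)
        d = np.diff(R, axis=0)                      # (nf-1, m)
        O = d[:, :, None] * d[:, None, :] / 2.0     # outer products
        nf = hi - lo
        for f in range(nf):
            a = max(0, f - half)
            b = min(O.shape[0], f + half)
            if b <= a:
                a, b = max(0, O.shape[0] - window), O.shape[0]
            Vf = O[a:b].mean(axis=0)
            tr = np.trace(Vf)
            V[lo + f] = Vf + max(ridge * tr / m, 1e-14) * np.eye(m)
    return V


class _Objective:
    """Gibbs energy, gradients and curvature for a fixed data vector.

    The noise model is Sigma(lambda) = D^-1/2 V D^-1/2 with V the fixed
    per-row (condition x frequency) coordinate covariance and
    D = diag(exp(lambda_k)) assigning one log-precision per channel-pair
    block; a flat V (identity) recovers ordinary weighted least squares.
    """

    def __init__(self, y, model, prior, hyper, blocks, settings,
                 grid_idx=None, block_of=None, cov=None):
        self.y = y
        self.model = model
        self.prior = prior
        self.hyper = hyper
        self.blocks = blocks
        self.settings = settings
        self.ny = y.size
        self.ntheta = model.n_latent
        self.nlam = len(blocks)
        if grid_idx is None:
            # one coordinate per row; blocks give the component of each coord
            grid_idx = np.arange(self.ny, dtype=np.intp)[:, None]
            block_of = np.empty((self.ny, 1), dtype=np.intp)
            for k, (_, idx) in enumerate(blocks):
                block_of[idx, 0] = k
        self.grid = grid_idx
        self.kof = block_of
        rows, m = grid_idx.shape
        if cov is None:
            cov = np.broadcast_to(np.eye(m), (rows, m, m)).copy()
        self.Vinv = np.linalg.inv(cov)
        sign, ld = np.linalg.slogdet(cov)
        self.ld_V = float(np.sum(ld))
        self.nk = np.array([idx.size for _, idx in blocks], dtype=float)
        # Fisher information of the log-precisions.  With
        # Sigma = D^-1/2 V D^-1/2 the elementwise product Sigma o Sigma^-1
        # equals V o V^-1 (the D factors cancel), so the lambda curvature
        # is constant and positive definite - unlike the observed partial
        # quadratic forms, which are indefinite for correlated V.
        M = cov * self.Vinv + np.eye(self.grid.shape[1])
        K = self.kof
        pair_idx = (K[:, :, None] * self.nlam + K[:, None, :]).ravel()
        fl = np.zeros(self.nlam * self.nlam)
        np.add.at(fl, pair_idx, 0.25 * M.ravel())
        self.fisher_lam = fl.reshape(self.nlam, self.nlam)
        self.iOm = np.linalg.inv(prior.cov)
        _, self.ld_Om = np.linalg.slogdet(prior.cov)
        self.hyper_var = hyper.variance

    def residual(self, theta):
        return self.model.predict_vector(theta) - self.y

    def jacobian_fd(self, theta):
        h = self.settings.fd_step
        J = np.empty((self.ny, self.ntheta))
        for i in range(self.ntheta):
            tp = theta.copy(); tp[i] += h
            tm = theta.copy(); tm[i] -= h
            J[:, i] = (self.model.predict_vector(tp) - self.model.predict_vector(tm)) / (2 * h)
        return J

    # -- whitened quantities ------------------------------------------------
    def _sqrtD(self, lam):
        return np.exp(0.5 * lam[self.kof])          # (rows, m)

    def _whiten(self, r, lam):
        """r' = D^1/2 r on the grid and V^-1 r'."""
        Rp = r[self.grid] * self._sqrtD(lam)
        ViR = np.einsum("fij,fj->fi", self.Vinv, Rp)
        return Rp, ViR

    def block_quads(self, r, lam):
        """s_k = sum over block k of r' (V^-1 r'): the lambda sensitivities."""
        Rp, ViR = self._whiten(r, lam)
        prod = Rp * ViR
        s = np.zeros(self.nlam)
        np.add.at(s, self.kof.ravel(), prod.ravel())
        return s

    def gibbs(self, theta, lam, r=None):
        """G(z): log joint of data and latent parameters (all constants kept)."""
        if r is None:
            r = self.residual(theta)
        Rp, ViR = self._whiten(r, lam)
        quad = float(np.sum(Rp * ViR))
        like = -0.5 * quad + 0.5 * np.sum(self.nk * lam) \
            - 0.5 * self.ld_V - 0.5 * self.ny * LOG2PI
        rho = theta - self.prior.mean
        pen = -0.5 * rho @ self.iOm @ rho - 0.5 * self.ld_Om \
            - 0.5 * self.ntheta * LOG2PI
        dl = lam - self.hyper.mean
        hpen = -0.5 * np.sum(dl ** 2) / self.hyper_var \
            - 0.5 * self.nlam * np.log(self.hyper_var) - 0.5 * self.nlam * LOG2PI
        return like + pen + hpen

    def curvature(self, J, r, lam):
        """Negative Hessian of G (Gauss-Newton in theta, observed in lambda)."""
        sD = self._sqrtD(lam)
        A = J[self.grid] * sD[:, :, None]           # (rows, m, ntheta)
        ViA = np.einsum("fij,fjt->fit", self.Vinv, A)
        Ht = np.einsum("fit,fis->ts", A, ViA) + self.iOm
        Hl = self.fisher_lam + np.eye(self.nlam) / self.hyper_var
        # mean-field Laplace between theta and lambda: the cross curvature
        # is dropped, keeping H positive definite throughout optimisation
        n = self.ntheta + self.nlam
        H = np.zeros((n, n))
        H[:self.ntheta, :self.ntheta] = 0.5 * (Ht + Ht.T)
        H[self.ntheta:, self.ntheta:] = Hl
        return H

    def gradient(self, J, r, theta, lam):
        Rp, ViR = self._whiten(r, lam)
        u = np.zeros(self.ny)
        u[self.grid.ravel()] = (self._sqrtD(lam) * ViR).ravel()
        gt = -(J.T @ u) - self.iOm @ (theta - self.prior.mean)
        s = self.block_quads(r, lam)
        gl = -0.5 * s + 0.5 * self.nk - (lam - self.hyper.mean) / self.hyper_var
        return np.concatenate([gt, gl])

    def free_energy_at(self, theta, lam, J=None, r=None):
        if r is None:
            r = self.residual(theta)
        if J is None:
            J = self.jacobian_fd(theta)
        G = self.gibbs(theta, lam, r=r)
        H = self.curvature(J, r, lam)
        sign, ld = np.linalg.slogdet(H)
        if sign <= 0:
            raise np.linalg.LinAlgError("negative curvature at evaluation point")
        n = self.ntheta + self.nlam
        F = G - 0.5 * ld + 0.5 * n * LOG2PI
        return F, G, H, J, r


def gibbs_energy(theta, lam, data, model: SpectralModel, prior: PriorDensity,
                 hyper: HyperParams | None = None,
                 profile: np.ndarray | None = None) -> float:
    """Gibbs energy G(theta, lambda): log joint density of data and latents.

    The noise covariance is Sigma = sum_k exp(-lambda_k) Q_k with Q_k
    diagonal on the coordinates of channel-pair block k, carrying the
    variance ``profile`` (flat by default); the same precision weights the
    real and imaginary residual parts.
    """
    y = data_vector(data, model)
    blocks = _condition_blocks(model)
    if hyper is None:
        hyper = HyperParams(np.zeros(len(blocks)))
    lam = np.asarray(lam, dtype=float).reshape(-1)
    if lam.size != len(blocks):
        raise ValueError(f"expected {len(blocks)} log-precisions, got {lam.size}")
    cov = None
    if profile is not None:
        cov = np.asarray(profile, float).reshape(-1, 1, 1)
    obj = _Objective(y, model, prior, hyper, blocks, InversionSettings(),
                     grid_idx=np.arange(y.size, dtype=np.intp)[:, None] if profile is not None else None,
                     block_of=_block_of_vector(blocks, y.size) if profile is not None else None,
                     cov=cov)
    return float(obj.gibbs(np.asarray(theta, dtype=float), lam))


def _block_of_vector(blocks, ny):
    out = np.empty((ny, 1), dtype=np.intp)
    for k, (_, idx) in enumerate(blocks):
        out[idx, 0] = k
    return out


def _condition_blocks(model: SpectralModel) -> list:
    nf = model.freqs.size
    nch = model.lf.n_channels
    per = vector_blocks(nf, nch)
    ncoord = sum(idx.size for _, idx in per)
    blocks = []
    for c in range(model.n_conditions):
        for p, idx in per:
            blocks.append(((c,) + p, idx + c * ncoord))
    return blocks


def invert(data, model: SpectralModel, prior: PriorDensity | None = None,
           hyper: HyperParams | None = None,
           settings: InversionSettings | None = None,
           normalise: bool = True) -> PosteriorDensity:
    """Maximise the free energy; return the Gaussian posterior.

    The data are scaled to unit mean auto power and the model's lead field
    calibrated to the same scale (both deterministic), so the noise
    log-precisions start near their hyperprior means.  Levenberg-Marquardt
    proposals on (theta, lambda) are accepted only when the free energy
    increases; the trace of accepted F values is therefore monotone.
    """
    settings = settings or InversionSettings()
    csds = data if isinstance(data, (list, tuple)) else [data]
    scale = 1.0
    if normalise:
        scale = float(np.mean([np.abs(np.diagonal(c.values, axis1=1, axis2=2)).mean()
                               for c in csds]))
        csds = [c.scaled(1.0 / scale) for c in csds]
        model = model.calibrated()
    y = data_vector(csds, model)
    blocks = _condition_blocks(model)
    if prior is None:
        prior = PriorDensity.default(model)
    if prior.mean.size != model.n_latent:
        raise ValueError("prior dimension does not match model latent space")
    grid_idx, block_of, cond_rows = coordinate_grid(model)
    cov = noise_covariance(y, grid_idx, cond_rows)
    if hyper is None:
        hyper = HyperParams(np.zeros(len(blocks)))
    return invert_vector(y, model, prior, hyper, blocks, settings,
                         data_scale=scale, grid_idx=grid_idx,
                         block_of=block_of, cov=cov)


def invert_vector(y: np.ndarray, predictor, prior: PriorDensity,
                  hyper: HyperParams, blocks: list,
                  settings: InversionSettings | None = None,
                  data_scale: float = 1.0, grid_idx=None, block_of=None,
                  cov=None) -> PosteriorDensity:
    """Optimise the free energy for any predictor with ``predict_vector``.

    ``blocks`` lists the noise components as (tag, coordinate-index) pairs;
    a near-zero hyperprior variance pins the corresponding log-precision
    (its Occam terms then cancel exactly, so fixed-noise problems such as
    the linear-Gaussian toy are handled by the same code path).
    """
    settings = settings or InversionSettings()
    obj = _Objective(y, predictor, prior, hyper, blocks, settings,
                     grid_idx=grid_idx, block_of=block_of, cov=cov)

    theta = prior.mean.copy()
    lam = hyper.mean.copy()
    F, G, H, J, r = obj.free_energy_at(theta, lam)
    trace = [F]
    damping = settings.init_damping
    still = 0
    converged = False
    it = 0
    for it in range(1, settings.maxiter + 1):
        g = obj.gradient(J, r, theta, lam)
        accepted = False
        while damping <= settings.max_damping:
            Hd = H + damping * np.diag(np.clip(np.diag(H), 1e-8, None))
            try:
                delta = np.linalg.solve(Hd, g)
            except np.linalg.LinAlgError:
                damping *= 4.0
                continue
            t_new = theta + delta[:obj.ntheta]
            l_new = lam + delta[obj.ntheta:]
            try:
                F_new, G_new, H_new, J_new, r_new = obj.free_energy_at(t_new, l_new)
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                damping *= 4.0
                continue
            # ties are accepted: near the optimum the true improvement of a
            # Newton step can underflow the floating-point resolution of F,
            # and the parameter polish is still worth keeping (termination
            # is guaranteed by the patience counter on sub-tol steps)
            if np.isfinite(F_new) and F_new >= F:
                dF = F_new - F
                theta, lam, F, G, H, J, r = t_new, l_new, F_new, G_new, H_new, J_new, r_new
                trace.append(F)
                damping = max(damping * 0.3, 1e-8)
                accepted = True
                still = still + 1 if dF < settings.tol else 0
                break
            damping *= 4.0
        if not accepted:
            # No step of any damped length improves F: the iterate is a
            # numerical local maximum, i.e. the optimisation has converged.
            converged = True
            break
        if still >= settings.patience:
            converged = True
            break

    C = np.linalg.inv(H)
    Ct = C[:obj.ntheta, :obj.ntheta]
    Cl = C[obj.ntheta:, obj.ntheta:]
    return PosteriorDensity(mean=theta, cov=0.5 * (Ct + Ct.T), free_energy=float(F),
                            names=tuple(predictor.names), lambdas=lam,
                            lambda_cov=0.5 * (Cl + Cl.T), trace=trace,
                            converged=converged, prior=prior, data_scale=data_scale,
                            n_iter=it)


def free_energy(posterior: PosteriorDensity) -> float:
    """The free-energy approximation to the log model evidence (nats)."""
    return float(posterior.free_energy)
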