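"""Workflow orchestration: fixture generation and prior derivation.

The validation loop runs: simulate a detailed (compartmental) column ->
estimate its two-channel laminar CSD -> fit the neural mass model to it ->
use the posterior as priors for fitting further (e.g. empirical) data ->
compare laminar assignments and condition effects.

Because the empirical optogenetics dataset is not distributed, the package
generates its own synthetic two-channel CSD fixtures: neural-mass spectra
with a 10 Hz input bump over scale-free background, observed through
finite-sample (Wishart) averaging noise as in trial-averaged Welch
estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .csd import CrossSpectralDensity
from .inversion import (HyperParams, InversionSettings, PosteriorDensity,
                        PriorDensity, SpectralModel, invert)
from .microcircuit import default_params
from .spectral import InputSpectrum, LeadField, NoiseSpectrum, predict_csd

__all__ = [
    "GroundTruth", "FixtureSet", "sample_observed_csd", "default_model",
    "make_fixtures", "derive_priors", "CONDITION_TRUTH",
]

#: Ground-truth ON/OFF connection scalings used in the condition fixtures:
#: self-inhibition of superficial pyramidal cells reduced by 32%, the
#: superficial-interneuron influence on deep pyramidal cells up 113%, the
#: superficial-to-deep pyramidal drive up 400%.
CONDITION_TRUTH = {"a44": 0.68, "a31": 2.13, "a34": 5.0}

#: Number of averaged segments emulated by the observation noise.
DEFAULT_SEGMENTS = 100


def default_grid_fixture() -> np.ndarray:
    """1-50 Hz at 0.5 Hz: the band containing the alpha peak."""
    return 1.0 + 0.5 * np.arange(99)


def default_model(freqs: np.ndarray | None = None, **kwargs) -> SpectralModel:
    """Two-channel laminar model at the package's prior-mean ground truth.

    Channels: 'superficial' -> population 4 (superficial pyramidal),
    'deep' -> population 3 (deep pyramidal).  The endogenous input carries
    a 10 Hz spectral bump over 1/f background.
    """
    if freqs is None:
        freqs = default_grid_fixture()
    defaults = dict(
        mc=default_params(),
        lf=LeadField(gains=(1.0, 1.0), assignment=(4, 3)),
        gu=InputSpectrum(amp=0.02, exponent=1.0, bump_height=0.1,
                         bump_freq=10.0, bump_width=1.5),
        gn=NoiseSpectrum(channel_amps=(0.002, 0.002), channel_exps=(1.0, 1.0),
                         common_amp=0.001, common_exp=1.0),
        freqs=freqs,
    )
    defaults.update(kwargs)
    return SpectralModel(**defaults)


def sample_observed_csd(truth: CrossSpectralDensity, n_segments: int,
                        rng: np.random.Generator) -> CrossSpectralDensity:
    """Finite-sample observation of a true CSD.

    Emulates averaging ``n_segments`` independent periodogram segments:
    at each frequency the sample CSD is a complex Wishart average
    (1/K) sum_k y y^H with y ~ CN(0, G); Hermitian with real non-negative
    diagonal by construction.
    """
    nf, nch, _ = truth.values.shape
    out = np.empty_like(truth.values)
    for i in range(nf):
        G = truth.values[i]
        # numerical guard: symmetrise before factorisation
        L = np.linalg.cholesky(0.5 * (G + G.conj().T) + 1e-14 * np.trace(G).real * np.eye(nch))
        z = (rng.standard_normal((nch, n_segments))
             + 1j * rng.standard_normal((nch, n_segments))) / np.sqrt(2.0)
        y = L @ z
        S = (y @ y.conj().T) / n_segments
        S = 0.5 * (S + S.conj().T)
        out[i] = S
    return CrossSpectralDensity(truth.freqs.copy(), out, channels=truth.channels,
                                condition=truth.condition)


@dataclass
class GroundTruth:
    """Generator record stored with every fixture."""

    seed: int
    params: dict
    lead_field: dict
    input_spectrum: dict
    noise_spectrum: dict
    n_segments: int
    perturbation: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "params": self.params,
            "lead_field": self.lead_field, "input_spectrum": self.input_spectrum,
            "noise_spectrum": self.noise_spectrum, "n_segments": self.n_segments,
            "perturbation": self.perturbation,
        }


@dataclass
class FixtureSet:
    """Seeded synthetic CSDs with their ground-truth records.

    * ``baseline`` — two-channel CSD under the forward laminar assignment;
    * ``swapped`` — the same data with channel labels/rows exchanged;
    * ``on`` / ``off`` — condition pair; OFF is exactly the baseline and ON
      applies the documented connection scalings.
    """

    seed: int
    baseline: CrossSpectralDensity
    swapped: CrossSpectralDensity
    on: CrossSpectralDensity
    off: CrossSpectralDensity
    truth: GroundTruth
    truth_on: GroundTruth

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline.to_hdf5(out / "baseline.h5")
        self.swapped.to_hdf5(out / "swapped.h5")
        self.on.to_hdf5(out / "condition_on.h5")
        self.off.to_hdf5(out / "condition_off.h5")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump({"baseline": self.truth.to_dict(),
                       "on": self.truth_on.to_dict()}, fh, indent=2)


def _truth_record(model: SpectralModel, seed: int, n_segments: int,
                  perturbation: dict) -> GroundTruth:
    return GroundTruth(
        seed=seed, params=model.mc.to_dict(),
        lead_field={"gains": list(model.lf.gains),
                    "assignment": list(model.lf.assignment)},
        input_spectrum={"amp": model.gu.amp, "exponent": model.gu.exponent,
                        "bump_height": model.gu.bump_height,
                        "bump_freq": model.gu.bump_freq,
                        "bump_width": model.gu.bump_width},
        noise_spectrum={"channel_amps": list(model.gn.channel_amps),
                        "channel_exps": list(model.gn.channel_exps),
                        "common_amp": model.gn.common_amp,
                        "common_exp": model.gn.common_exp},
        n_segments=n_segments, perturbation=perturbation)


def make_fixtures(seed: int, n_segments: int = DEFAULT_SEGMENTS,
                  perturb: dict | None = None,
                  model: SpectralModel | None = None) -> FixtureSet:
    """Deterministic synthetic fixture set for one seed.

    ``perturb`` optionally scales ground-truth connections in the baseline
    (used for parameter-recovery studies).
    """
    model = model or default_model()
    if perturb:
        model = type(model)(mc=model.mc.scaled(perturb), lf=model.lf, gu=model.gu,
                            gn=model.gn, freqs=model.freqs, free=model.free)
    rng = np.random.default_rng(seed)
    channels = ("superficial", "deep")
    true_base = predict_csd(model.mc, model.lf, model.gu, model.gn, model.freqs,
                            channels=channels, condition="baseline")
    baseline = sample_observed_csd(true_base, n_segments, rng)
    swapped = baseline.swap_channels()

    mc_on = model.mc.scaled(CONDITION_TRUTH)
    true_on = predict_csd(mc_on, model.lf, model.gu, model.gn, model.freqs,
                          channels=channels, condition="on")
    on = sample_observed_csd(true_on, n_segments, rng)
    off = CrossSpectralDensity(baseline.freqs.copy(), baseline.values.copy(),
                               channels=channels, condition="off")
    return FixtureSet(
        seed=seed, baseline=baseline, swapped=swapped, on=on, off=off,
        truth=_truth_record(model, seed, n_segments, perturb or {}),
        truth_on=_truth_record(
            type(model)(mc=mc_on, lf=model.lf, gu=model.gu, gn=model.gn,
                        freqs=model.freqs, free=model.free),
            seed, n_segments, dict(CONDITION_TRUTH)))


#: Lower bound on derived prior variances: a posterior that has collapsed
#: onto the simulated data must not over-constrain the second-stage fit.
PRIOR_VARIANCE_FLOOR = 1.0 / 32.0


def derive_priors(simulated_csd: CrossSpectralDensity, model: SpectralModel,
                  base_prior: PriorDensity | None = None,
                  settings: InversionSettings | None = None,
                  variance_floor: float = PRIOR_VARIANCE_FLOOR) -> tuple:
    """Fit the neural mass model to simulated data; repackage as priors.

    Returns ``(prior, posterior)``: the posterior means become the new
    prior means and the posterior variances are floored at
    ``variance_floor`` (off-diagonal covariance is dropped — derived
    priors stay diagonal and hence conservative).
    """
    post = invert(simulated_csd, model, prior=base_prior, settings=settings)
    if not post.converged:
        import warnings
        warnings.warn("prior-derivation inversion did not converge; "
                      "returning flagged prior", stacklevel=2)
    var = np.maximum(np.diag(post.cov), variance_floor)
    prior = PriorDensity(post.mean.copy(), np.diag(var), names=post.names)
    return prior, post
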