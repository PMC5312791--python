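# Methods

This note documents the modelling assumptions, parameter choices,
numerical methods and the main design decisions behind `lamdcm`, together
with known limitations. Quantitative statements about behaviour refer to
checks performed by the test suite (`tests/`) or by
`scripts/acceptance.py`.

## 1. Neural mass microcircuit

Four populations interact through ten intrinsic connections: superficial
pyramidal cells (population 4), deep pyramidal cells (3), superficial
interneurons (1) and deep interneurons (2). Each population's mean
membrane potential obeys a critically damped second-order synaptic
kernel,

    v̈_k = −2 κ_k v̇_k − κ_k² v_k + κ_k f_k(v),

with rate constants κ = (1/2, 1/36, 1/16, 1/28) ms⁻¹ for populations
1–4. Presynaptic influence enters through a zero-centred logistic
firing-rate function σ(v) = 1/(1+e^{−r(v−η)}) − 1/(1+e^{rη}) with slope
r = 0.6 and threshold η = 0, so the origin is always a fixed point. The
exogenous input drives population 1 through its κ-scaled kernel with a
free gain.

Connection strengths are parameterised as `amplitude ratio × scale`. The
ratios (a11:4, a14:4, a22:4, a23:2, a31:4, a32:8, a33:4, a34:8, a41:4,
a44:8) fix the relative wiring; the default scale is 0.15.

**Why 0.15:** a numerical stability analysis of the linearisation across
candidate scales showed the fixed point loses stability well below a
scale of 1 for this wiring; 0.15 places the prior mean comfortably inside
the stable regime while keeping all connections influential. The
prior-mean Jacobian is verified stable in the test suite, and posterior
excursions of ±2 prior SD remain integrable.

Inference operates on log-scaling latents: each free parameter
multiplies its default by e^z with z ~ N(0, 1/8) a priori (1/32 for the
sigmoid parameters), which enforces positivity and makes "±2 posterior
SD" a scale-free statement.

## 2. Spectral forward model

Linearising the drift around the stable fixed point gives the Jacobian
J; the transfer from input to the two recording channels is
T(f) = L (iωI − J)⁻¹ B with ω = 2πf/1000 (f in Hz, time in ms), L the
lead field mapping channels to the pyramidal populations (superficial
contact → population 4, deep contact → population 3) and B the input
vector. The predicted CSD is

    g_Y(f) = T(f) g_u(f) T(f)ᴴ + g_N(f),

with endogenous input spectrum g_u (power-law background plus a Gaussian
10 Hz bump) and channel noise g_N (per-channel and channel-common
power-law components; the common component provides the only
off-diagonal noise). The convention throughout is
g_ij = ⟨x_i x̄_j⟩; the Welch estimator stores the conjugate of the
scipy convention to match it.

The linearisation is validated against 200 s stochastic simulations of
the full nonlinear model driven in its small-signal regime: the test
suite requires < 10 % relative error in the band around the spectral
peak and < 20 % median error over 1–50 Hz per channel (observed ~3 % and
~6 % at the documented seed; Welch sampling noise at ~200 averaged
segments dominates the discrepancy). The peak error is measured on a
three-bin band average around the peak because a single 0.5 Hz bin of a
sharp resonance has ~7–12 % sampling scatter at this segment count.

## 3. Variational Laplace inversion

The latent vector concatenates log-scalings θ and noise log-precisions
λ (one per channel-pair block and condition). The Gibbs energy
G(θ, λ) is the full log joint with all 2π constants; the free energy is
F = G(μ) + ½ ln|C| + (n/2) ln 2π at the posterior mode μ with posterior
covariance C = H⁻¹. On a linear-Gaussian problem this is exact, which
the test suite verifies to 1e−6 (F) and 1e−8 (posterior).

Design decisions:

* **Per-frequency residual covariance (GLS).** Residual whitening uses a
  per-frequency covariance estimated from first differences of the data
  across frequency (window 9, ridge 1e−3) rather than an identity
  weighting. Smooth model-data mismatch is strongly correlated across
  neighbouring frequencies; ignoring that correlation drastically
  overstates the information in misfit and destabilises model
  comparison. The λ parameters scale the precision of each channel-pair
  block on top of this fixed profile.
* **Mean-field θ/λ curvature.** The Hessian is block-diagonal across θ
  and λ (Gauss–Newton in θ, a constant Fisher curvature in λ). The θ–λ
  cross-curvature is indefinite for correlated residual covariances and
  breaks the positive-definiteness the Laplace approximation requires;
  dropping it keeps H positive definite at every iterate.
* **Trust-region ascent with tie acceptance.** Damped Newton steps are
  accepted when they do not decrease F. Ties must be accepted: near the
  optimum the true improvement of a Newton step underflows the
  floating-point resolution of F (~1e−15 relative), and rejecting the
  final polish leaves the posterior mean ~1e−8 from the optimum —
  exactly at the exactness tolerance. Termination is guaranteed by a
  patience counter on sub-tolerance steps; a state from which no damped
  step improves F is reported as converged.
* **Scale calibration.** Observed data are normalised to unit mean auto
  power; `SpectralModel.calibrated()` rescales the lead-field gains (and
  the noise amplitudes, quadratically) so the prior-mean prediction has
  unit mean **total** power. Calibrating to signal-only power leaves a
  systematic offset in the noise-amplitude posteriors equal to the noise
  fraction (~1 %), detectable in noiseless self-consistency fits.

## 4. Model comparison and condition effects

Laminar assignment is compared by fitting the same model under the
forward and the swapped lead field; the relative log-evidence
B = F_fwd − F_rev with |B| > 3 nats read as strong evidence. The
validation suite requires B > 3 on ≥ 18/20 forward-generated fixtures
and a mean B inside (−3, 3) on channel-duplicated null data, which carry
no laminar information.

Condition effects are estimated by a joint ON/OFF inversion sharing all
parameters, with a log-scaling β ~ N(0, 1/8) applied to each masked
connection in the ON condition; effects are reported as
100 (e^β − 1) %. The fixture ground truth scales a44 × 0.68,
a31 × 2.13 and a34 × 5.0; the suite requires all three signs correct and
every ratio within a factor 2 of truth in ≥ 16/20 seeded pairs.

**Identifiability.** With two pyramidal channels, the deep-interneuron
self-connection a33 is structurally non-identifiable: noiseless fits
return its prior (posterior mean ≈ 0 with undiminished SD). Recovery
protocols therefore cycle over the nine identifiable connections. More
generally, posterior SDs are somewhat overconfident (~1.5×) because the
GLS whitening treats segment-averaged Welch noise as Gaussian with a
smooth covariance; the 2-SD recovery criterion absorbs this.

## 5. Compartmental column

The detailed generator is a symmetric column of 10 mini-columns, each
with one 8-compartment layer-2/3 pyramidal cell, one 9-compartment
layer-5 pyramidal cell and one single-compartment interneuron per layer
(40 cells, 190 compartments). Somata carry Traub-type Hodgkin–Huxley
sodium and delayed-rectifier channels plus an M-current; layer-5 somata
add a high-threshold calcium current and a calcium-dependent potassium
current fed by a calcium pool with 20 ms decay. Dendrites are passive.
Synapses are peak-normalised double exponentials (AMPA/NMDA,
GABA_A/GABA_B) delivered event-wise with delays.

Horizontal connectivity follows w(i,j) = w_max e^{−|i−j|²/C_s²} and
d(i,j) = d_min e^{+|i−j|²/C_d²}; synapses below 1e−4 relative weight are
pruned. Interneuron-sourced conductances are scaled by 0.3: the
symmetric column uses 10 interneurons per layer where the connection
conductances were specified for about a third as many, and unscaled
inhibition silences the column.

The recorded signal is the per-layer current dipole: axial current times
vertical compartment separation summed over pyramidal compartment pairs.
Two drive protocols are provided:

* **Evoked** — per-trial feedforward (~25 ms), feedback (~70 ms) and
  late-feedforward (~135 ms) inputs with Gaussian timing jitter,
  averaged over 25 trials. The suite checks the three net-dipole
  deflections occur in order within ±15 ms of their targets.
* **Alpha** — two-spike feedforward bursts every ~100 ms with 20 ms
  jitter and 5 ms-lagged feedback, at 0.4 nS (pyramidal) / 0.8 nS
  (interneuron) drive conductances. The published conductance figure in
  pS is three orders of magnitude below the noise floor implied by the
  stated stochastic current and cannot drive any response; it is read as
  nS. The suite checks both layer spectra peak in 8–12 Hz for seeds 0–9
  at 6 s duration with 2 s Welch segments. Across arbitrary seeds,
  occasional runs peak at harmonics instead, so the summary script
  reports the median peak and the in-band fraction.

Integration is exponential Euler at dt = 0.025 ms with semi-implicit
axial coupling, event-driven synapses via a binary heap, and uniform
per-compartment stochastic current; runs are bit-reproducible from a
seed (verified in the suite).

**Generator realism.** The column is deliberately a *different* model
class from the neural mass: conductance-based, spiking, spatially
extended, with calcium dynamics. Fitting the neural mass to column
spectra (the `derive-priors` path) is therefore a genuine cross-model
exercise rather than self-confirmation. The column's fidelity target is
qualitative — deflection ordering and spectral peak location — not
waveform-exact reproduction of any particular laboratory's implementation,
because reduced morphologies and channel densities are plausible
defaults, not measured quantities.

## 6. Synthetic fixtures

Because no empirical dataset ships with the package, validation data are
generated: neural-mass CSDs (with the documented 10 Hz input bump)
observed through complex-Wishart finite-sample noise emulating 100
averaged Welch segments. Every fixture records its complete ground truth
(seed, parameters, perturbations) alongside the data, and fixture
generation is byte-deterministic given the seed.

## 7. Limitations

* The a33 connection cannot be estimated from two pyramidal channels;
  its posterior is its prior.
* Posterior SDs are mildly overconfident (see §4); credible intervals
  should be read as approximate.
* The Laplace evidence is exact only for linear-Gaussian problems; for
  the nonlinear spectral model it is the usual local approximation.
* The λ-curvature uses a constant Fisher approximation, accurate near
  the mode but not guaranteed elsewhere.
* The column uses reduced morphologies, passive dendrites and somatic
  channels only; absolute dipole magnitudes are in arbitrary units and
  only ratios and timings are meaningful.
* Alpha-band behaviour of the column is seed-dependent at the tails
  (harmonic peaks on some seeds); conclusions should use multiple seeds.
* The inversion assumes a stable fixed point; parameter regions where
  the linearisation loses stability are rejected during optimisation
  rather than modelled (no limit-cycle spectra).
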