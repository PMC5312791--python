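"""Tests for the variational Laplace inversion machinery."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from lamdcm.csd import CrossSpectralDensity
from lamdcm.inversion import (HyperParams, InversionSettings, PriorDensity,
                              SpectralModel, _condition_blocks, csd_vector,
                              data_vector, gibbs_energy, invert, invert_vector,
                              prediction_error, vector_blocks)
from lamdcm.pipeline import default_model

LOG2PI = np.log(2.0 * np.pi)


def small_model(nf=3):
    m = default_model()
    return SpectralModel(mc=m.mc, lf=m.lf, gu=m.gu, gn=m.gn,
                         freqs=m.freqs[:nf], free=m.free)


# ----------------------------------------------------------------------
# vectorisation / residuals
# ----------------------------------------------------------------------

def test_vector_blocks_partition():
    nf, nch = 7, 2
    blocks = vector_blocks(nf, nch)
    all_idx = np.concatenate([idx for _, idx in blocks])
    total = nf * (3 + 1)          # 3 unique pairs re + 1 strict pair im
    assert sorted(all_idx.tolist()) == list(range(total))


def test_csd_vector_layout():
    vals = np.zeros((2, 2, 2), dtype=complex)
    vals[:, 0, 0] = [1, 2]
    vals[:, 1, 1] = [3, 4]
    vals[:, 0, 1] = [5 + 7j, 6 + 8j]
    vals[:, 1, 0] = np.conj(vals[:, 0, 1])
    v = csd_vector(vals)
    assert np.allclose(v, [1, 2, 5, 6, 3, 4, 7, 8])


def test_zero_residual_at_generating_point():
    model = small_model()
    z = np.zeros(model.n_latent)
    data = model.predict(z)
    r = prediction_error(z, data, model)
    assert np.allclose(r, 0.0, atol=1e-14)


def test_residual_length_and_locality():
    model = small_model(nf=5)
    z = np.zeros(model.n_latent)
    data = model.predict(z)
    r0 = prediction_error(z, data, model)
    assert r0.size == 5 * 4       # nf x (3 re pairs + 1 im pair)
    vals = data.values.copy()
    vals[2, 0, 0] += 1.0          # perturb one real datum
    data2 = CrossSpectralDensity(data.freqs, vals)
    r1 = prediction_error(z, data2, model)
    diff = r1 - r0
    changed = np.nonzero(diff)[0]
    assert changed.size == 1
    assert diff[changed[0]] == pytest.approx(-1.0, abs=1e-12)


def test_data_vector_grid_mismatch():
    model = small_model(nf=4)
    data = small_model(nf=3).predict(np.zeros(model.n_latent))
    with pytest.raises(ValueError):
        data_vector(data, model)


# ----------------------------------------------------------------------
# Gibbs energy: dense-matrix oracle
# ----------------------------------------------------------------------

def test_gibbs_energy_dense_oracle():
    """Agreement with a brute-force dense evaluation on a 3-frequency toy."""
    model = small_model(nf=3)
    rng = np.random.default_rng(8)
    z_true = 0.05 * rng.standard_normal(model.n_latent)
    data = model.predict(z_true)
    theta = 0.05 * rng.standard_normal(model.n_latent)
    blocks = _condition_blocks(model)
    lam = rng.standard_normal(len(blocks))
    prior = PriorDensity.default(model)
    hyper = HyperParams(np.zeros(len(blocks)), variance=1.0 / 16.0)

    got = gibbs_energy(theta, lam, data, model, prior, hyper)

    # dense oracle: Sigma = sum_k exp(-lambda_k) Q_k, Q_k identity on block k
    y = data_vector(data, model)
    r = model.predict_vector(theta) - y
    ny = y.size
    var = np.empty(ny)
    for k, (_, idx) in enumerate(blocks):
        var[idx] = np.exp(-lam[k])
    Sigma = np.diag(var)
    rho = theta - prior.mean
    dl = lam - hyper.mean
    expected = (-0.5 * r @ np.linalg.solve(Sigma, r)
                - 0.5 * np.linalg.slogdet(Sigma)[1] - 0.5 * ny * LOG2PI
                - 0.5 * rho @ np.linalg.solve(prior.cov, rho)
                - 0.5 * np.linalg.slogdet(prior.cov)[1]
                - 0.5 * theta.size * LOG2PI
                - 0.5 * np.sum(dl ** 2) / hyper.variance
                - 0.5 * lam.size * np.log(hyper.variance)
                - 0.5 * lam.size * LOG2PI)
    assert got == pytest.approx(expected, abs=1e-12 * max(1.0, abs(expected)))


def test_gibbs_quadratic_scaling():
    """Doubling one residual quadruples its quadratic contribution."""
    model = small_model(nf=3)
    z = np.zeros(model.n_latent)
    data = model.predict(z)
    blocks = _condition_blocks(model)
    lam = np.zeros(len(blocks))
    prior = PriorDensity.default(model)
    g0 = gibbs_energy(z, lam, data, model, prior)

    def with_offset(eps):
        vals = data.values.copy()
        vals[1, 0, 0] += eps
        return gibbs_energy(z, lam,
                            CrossSpectralDensity(data.freqs, vals), model, prior)

    d1 = g0 - with_offset(1.0)
    d2 = g0 - with_offset(2.0)
    assert d2 == pytest.approx(4.0 * d1, rel=1e-10)


# ----------------------------------------------------------------------
# linear-Gaussian toy: Laplace exactness
# ----------------------------------------------------------------------

class _IdentityPredictor:
    def __init__(self, n):
        self.names = tuple(f"t{i}" for i in range(n))
        self.n_latent = n

    def predict_vector(self, z):
        return np.asarray(z, dtype=float)


#: the linear-Gaussian toy checks Laplace *exactness* to 1e-8, so the
#: optimiser must be run to numerical convergence rather than the default
#: working tolerance
TOY_SETTINGS = InversionSettings(tol=1e-12)


def toy_problem(seed=0, n=5, noise_var=0.7):
    rng = np.random.default_rng(seed)
    phi = rng.normal(size=n)
    Om = np.diag(rng.uniform(0.5, 2.0, n))
    y = rng.normal(size=n)
    prior = PriorDensity(phi, Om)
    hyper = HyperParams(np.array([-np.log(noise_var)]), variance=1e-12)
    blocks = [(("all",), np.arange(n))]
    return y, prior, hyper, blocks, phi, Om, noise_var


def analytic_toy(y, phi, Om, v):
    n = y.size
    iS = np.eye(n) / v
    C = np.linalg.inv(iS + np.linalg.inv(Om))
    mu = C @ (iS @ y + np.linalg.solve(Om, phi))
    Sm = v * np.eye(n) + Om
    log_ev = (-0.5 * (y - phi) @ np.linalg.solve(Sm, y - phi)
              - 0.5 * np.linalg.slogdet(2 * np.pi * Sm)[1])
    return mu, C, log_ev


def test_toy_laplace_exactness():
    y, prior, hyper, blocks, phi, Om, v = toy_problem()
    post = invert_vector(y, _IdentityPredictor(y.size), prior, hyper, blocks,
                         TOY_SETTINGS)
    mu, C, log_ev = analytic_toy(y, phi, Om, v)
    assert post.free_energy == pytest.approx(log_ev, abs=1e-6)
    assert np.max(np.abs(post.mean - mu)) < 1e-8
    assert np.max(np.abs(post.cov - C)) < 1e-8
    assert post.converged


def test_toy_monotone_trace():
    y, prior, hyper, blocks, *_ = toy_problem(seed=4)
    post = invert_vector(y, _IdentityPredictor(y.size), prior, hyper, blocks,
                         TOY_SETTINGS)
    assert np.all(np.diff(post.trace) > -1e-12)


def test_toy_pinned_coordinate_evidence():
    """A near-delta prior on one coordinate still matches the analytic evidence."""
    y, prior, hyper, blocks, phi, Om, v = toy_problem(seed=2)
    Om2 = Om.copy()
    Om2[0, 0] = 1e-8
    prior2 = PriorDensity(phi, Om2)
    post = invert_vector(y, _IdentityPredictor(y.size), prior2, hyper, blocks,
                         TOY_SETTINGS)
    _, _, log_ev = analytic_toy(y, phi, Om2, v)
    assert post.free_energy == pytest.approx(log_ev, abs=1e-5)


@hsettings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000))
def test_toy_exactness_property(seed):
    y, prior, hyper, blocks, phi, Om, v = toy_problem(seed=seed)
    post = invert_vector(y, _IdentityPredictor(y.size), prior, hyper, blocks,
                         TOY_SETTINGS)
    _, _, log_ev = analytic_toy(y, phi, Om, v)
    assert post.free_energy == pytest.approx(log_ev, abs=1e-6)


# ----------------------------------------------------------------------
# full inversion behaviour
# ----------------------------------------------------------------------

def test_invert_maxiter_zero_returns_prior():
    model = default_model()
    data = model.predict(np.zeros(model.n_latent))
    post = invert(data, model, settings=InversionSettings(maxiter=0))
    assert np.array_equal(post.mean, np.zeros(model.n_latent))
    assert np.isfinite(post.free_energy)
    assert post.n_iter == 0


def test_invert_self_consistency_noiseless():
    """Noiseless data at the prior mean: every coordinate within 2 SD of it."""
    model = default_model()
    data = model.predict(np.zeros(model.n_latent))
    post = invert(data, model)
    sd = post.sd()
    assert np.all(np.abs(post.mean) <= 2.0 * np.maximum(sd, 1e-6))
    assert np.all(np.diff(post.trace) > -1e-9)
    # posterior covariance symmetric PSD
    assert np.allclose(post.cov, post.cov.T)
    assert np.linalg.eigvalsh(post.cov).min() > -1e-10


def test_invert_more_frequencies_shrink_posterior():
    """Doubling the number of fitted frequencies shrinks posterior SDs on average."""
    m_full = default_model()
    m_half = default_model(freqs=m_full.freqs[::2])
    z = np.zeros(m_full.n_latent)
    post_full = invert(m_full.predict(z), m_full)
    post_half = invert(m_half.predict(np.zeros(m_half.n_latent)), m_half)
    assert post_full.sd().mean() < post_half.sd().mean()


def test_prior_density_validation():
    with pytest.raises(ValueError):
        PriorDensity(np.zeros(2), np.array([[1.0, 0.5], [0.4, 1.0]]))
    with pytest.raises(ValueError):
        PriorDensity(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))
    with pytest.raises(ValueError):
        PriorDensity(np.zeros(2), np.eye(3))


def test_posterior_report_roundtrip(tmp_path):
    y, prior, hyper, blocks, *_ = toy_problem()
    post = invert_vector(y, _IdentityPredictor(y.size), prior, hyper, blocks,
                         InversionSettings())
    rep = post.report()
    assert set(rep) >= {"free_energy", "converged", "parameters", "lambda",
                        "free_energy_trace"}
    post.to_json(tmp_path / "post.json")
    import json
    with open(tmp_path / "post.json") as fh:
        assert json.load(fh)["free_energy"] == pytest.approx(post.free_energy)
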