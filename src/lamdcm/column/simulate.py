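"""Time integration of the compartmental column and its dipole output.

Hodgkin-Huxley-type somatic currents (fast sodium, delayed rectifier,
M-type potassium; high-threshold calcium and calcium-dependent potassium
in layer-5 cells, with a 20 ms calcium decay), passive dendrites, event-
driven double-exponential synapses and per-compartment stochastic current.
Membrane and gating equations advance by exponential Euler (default dt
0.025 ms); axial coupling is handled semi-implicitly through the
conductance form of the update.

The recorded signal is the current dipole: the sum over pyramidal
adjacent-compartment pairs of axial current times vertical separation,
reported per layer (superficial = L2/3, deep = L5); interneurons are
single-compartment and contribute nothing.  Evoked and rhythmic (alpha)
drive protocols are provided; both are reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from ..spectral import welch_csd
from .network import ColumnNetwork, double_exp_norm

__all__ = ["DipoleTrace", "simulate_evoked", "simulate_alpha", "layer_csd",
           "dipole_from_voltages", "ColumnSimulationError"]


class ColumnSimulationError(RuntimeError):
    """Numerical instability during column simulation."""


# ----------------------------------------------------------------------
# gating kinetics (Traub-type rate functions, mV / ms)
# ----------------------------------------------------------------------

@njit(cache=True, inline="always")
def _vtrap(x, y):  # pragma: no cover - numba
    # x / (exp(x/y) - 1) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (np.exp(x / y) - 1.0)


@njit(cache=True)
def _gate_steady(v):  # pragma: no cover - numba
    """Steady-state (m, h, n, p, q) at voltage v."""
    am = 0.32 * _vtrap(-(v + 54.0), 4.0)
    bm = 0.28 * _vtrap(v + 27.0, 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * _vtrap(-(v + 52.0), 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    p_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    q_inf = 1.0 / (1.0 + np.exp(-(v + 30.0) / 9.0))
    return am / (am + bm), ah / (ah + bh), an / (an + bn), p_inf, q_inf


@njit(cache=True)
def _heap_push(ht, hs, size, t, s):  # pragma: no cover - numba
    i = size
    ht[i] = t
    hs[i] = s
    while i > 0:
        par = (i - 1) // 2
        if ht[par] <= ht[i]:
            break
        ht[par], ht[i] = ht[i], ht[par]
        hs[par], hs[i] = hs[i], hs[par]
        i = par
    return size + 1


@njit(cache=True)
def _heap_pop(ht, hs, size):  # pragma: no cover - numba
    t, s = ht[0], hs[0]
    size -= 1
    ht[0], hs[0] = ht[size], hs[size]
    i = 0
    while True:
        l, r = 2 * i + 1, 2 * i + 2
        small = i
        if l < size and ht[l] < ht[small]:
            small = l
        if r < size and ht[r] < ht[small]:
            small = r
        if small == i:
            break
        ht[small], ht[i] = ht[i], ht[small]
        hs[small], hs[i] = hs[i], hs[small]
        i = small
    return t, s, size


@njit(cache=True)
def _run_column(n_steps, dt,
                cm, gleak, eleak, gna, gkdr, gm_, gca, gkca,
                ena, ek, eca, tau_ca, k_ca, kd_kca,
                edge_parent, edge_child, edge_g, edge_dz, edge_layer,
                syn_target, syn_wf, syn_d1, syn_d2, syn_erev,
                out_ptr, out_syn, out_delay,
                exo_step, exo_syn,
                soma, noise_amp, v_bound, spike_thr, refrac_steps,
                seed):  # pragma: no cover - numba
    np.random.seed(seed)
    nc = cm.size
    ns = syn_target.size
    ncell = soma.size
    ne = edge_g.size

    V = eleak.copy()
    m = np.empty(nc); h = np.empty(nc); n = np.empty(nc)
    p = np.empty(nc); q = np.empty(nc)
    for c in range(nc):
        mi, hi, ni, pi, qi = _gate_steady(V[c])
        m[c] = mi; h[c] = hi; n[c] = ni; p[c] = pi; q[c] = qi
    ca = np.zeros(nc)
    A = np.zeros(ns)
    B = np.zeros(ns)
    gsum = np.empty(nc)
    gE = np.empty(nc)

    cap = 500000
    heap_t = np.empty(cap, dtype=np.int64)
    heap_s = np.empty(cap, dtype=np.int64)
    heap_size = 0

    dip = np.zeros((n_steps, 2))
    spikes = np.zeros(ncell, dtype=np.int64)
    last_spike = np.full(ncell, -10 ** 9, dtype=np.int64)
    v_soma_prev = np.empty(ncell)
    for i in range(ncell):
        v_soma_prev[i] = V[soma[i]]

    # exponential decay of the M-current gate uses a voltage-dependent tau
    exo_ptr = 0
    n_exo = exo_step.size
    status = np.int64(-1)

    for t in range(n_steps):
        # 1. deliver due events
        while exo_ptr < n_exo and exo_step[exo_ptr] == t:
            s = exo_syn[exo_ptr]
            A[s] += 1.0
            B[s] += 1.0
            exo_ptr += 1
        while heap_size > 0 and heap_t[0] <= t:
            _, s, heap_size = _heap_pop(heap_t, heap_s, heap_size)
            A[s] += 1.0
            B[s] += 1.0

        # 2. synaptic state decay and conductance accumulation
        for c in range(nc):
            gsum[c] = gleak[c]
            gE[c] = gleak[c] * eleak[c]
        for s in range(ns):
            A[s] *= syn_d1[s]
            B[s] *= syn_d2[s]
            g = syn_wf[s] * (B[s] - A[s])
            if g > 0.0:
                tg = syn_target[s]
                gsum[tg] += g
                gE[tg] += g * syn_erev[s]

        # 3. active channels (somatic), exponential-Euler gate updates
        for c in range(nc):
            v = V[c]
            if gna[c] > 0.0:
                am = 0.32 * _vtrap(-(v + 54.0), 4.0)
                bm = 0.28 * _vtrap(v + 27.0, 5.0)
                ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
                bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
                tm = 1.0 / (am + bm)
                th = 1.0 / (ah + bh)
                m[c] = am * tm + (m[c] - am * tm) * np.exp(-dt / tm)
                h[c] = ah * th + (h[c] - ah * th) * np.exp(-dt / th)
                g = gna[c] * m[c] ** 3 * h[c]
                gsum[c] += g
                gE[c] += g * ena
            if gkdr[c] > 0.0:
                an = 0.032 * _vtrap(-(v + 52.0), 5.0)
                bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
                tn = 1.0 / (an + bn)
                n[c] = an * tn + (n[c] - an * tn) * np.exp(-dt / tn)
                g = gkdr[c] * n[c] ** 4
                gsum[c] += g
                gE[c] += g * ek
            if gm_[c] > 0.0:
                p_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
                tp = 1000.0 / (3.3 * (np.exp((v + 35.0) / 20.0)
                                      + np.exp(-(v + 35.0) / 20.0)))
                p[c] = p_inf + (p[c] - p_inf) * np.exp(-dt / tp)
                g = gm_[c] * p[c]
                gsum[c] += g
                gE[c] += g * ek
            if gca[c] > 0.0:
                q_inf = 1.0 / (1.0 + np.exp(-(v + 30.0) / 9.0))
                q[c] = q_inf + (q[c] - q_inf) * np.exp(-dt / 5.0)
                g = gca[c] * q[c] ** 2
                ica = g * (v - eca)
                gsum[c] += g
                gE[c] += g * eca
                ca[c] += dt * (-k_ca * ica - ca[c] / tau_ca)
                if ca[c] < 0.0:
                    ca[c] = 0.0
            if gkca[c] > 0.0:
                g = gkca[c] * ca[c] / (ca[c] + kd_kca)
                gsum[c] += g
                gE[c] += g * ek

        # 4. axial coupling (semi-implicit: neighbour voltage from this step)
        for e in range(ne):
            pa = edge_parent[e]
            ch = edge_child[e]
            ge = edge_g[e]
            gsum[pa] += ge
            gE[pa] += ge * V[ch]
            gsum[ch] += ge
            gE[ch] += ge * V[pa]

        # 5. membrane update with stochastic current
        for c in range(nc):
            inoise = noise_amp * (2.0 * np.random.random() - 1.0)
            vinf = (gE[c] + inoise) / gsum[c]
            V[c] = vinf + (V[c] - vinf) * np.exp(-dt * gsum[c] / cm[c])
            if not np.isfinite(V[c]) or abs(V[c]) > v_bound:
                status = t
                return dip, spikes, status

        # 6. dipole: axial current x vertical separation, per layer
        d0 = 0.0
        d1 = 0.0
        for e in range(ne):
            lay = edge_layer[e]
            if lay < 0:
                continue
            cur = edge_g[e] * (V[edge_parent[e]] - V[edge_child[e]])
            contrib = cur * edge_dz[e]
            if lay == 0:
                d0 += contrib
            else:
                d1 += contrib
        dip[t, 0] = d0
        dip[t, 1] = d1

        # 7. somatic threshold crossings trigger outgoing synaptic events
        for i in range(ncell):
            vs = V[soma[i]]
            if vs >= spike_thr and v_soma_prev[i] < spike_thr \
                    and t - last_spike[i] > refrac_steps:
                spikes[i] += 1
                last_spike[i] = t
                for k in range(out_ptr[i], out_ptr[i + 1]):
                    if heap_size < cap:
                        heap_size = _heap_push(heap_t, heap_s, heap_size,
                                               t + out_delay[k], out_syn[k])
            v_soma_prev[i] = vs

    return dip, spikes, status


# ----------------------------------------------------------------------
# python-side assembly
# ----------------------------------------------------------------------

@dataclass
class DipoleTrace:
    """Per-layer current-dipole time series (a.u.; time in ms)."""

    t: np.ndarray
    superficial: np.ndarray     # L2/3 pyramidal contribution
    deep: np.ndarray            # L5 pyramidal contribution
    spike_counts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    display_scale: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def net(self) -> np.ndarray:
        """Net dipole: exactly the sum of the layer contributions."""
        return self.superficial + self.deep

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.t,
                             "L23": self.superficial * self.display_scale,
                             "L5": self.deep * self.display_scale,
                             "net": self.net * self.display_scale})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _dt(net: ColumnNetwork) -> float:
    return float(net.config["integration"]["dt"])


def _kernel_args(net: ColumnNetwork, syn_extra: dict | None, dt: float):
    """Combined local + drive synapse arrays and static kernel arguments."""
    tgt = list(net.syn_target)
    wf = [w * double_exp_norm(t1, t2) for w, t1, t2 in
          zip(net.syn_weight, net.syn_tau1, net.syn_tau2)]
    d1 = [np.exp(-dt / t1) for t1 in net.syn_tau1]
    d2 = [np.exp(-dt / t2) for t2 in net.syn_tau2]
    erev = list(net.syn_erev)
    if syn_extra:
        tgt += list(syn_extra["target"])
        wf += [w * double_exp_norm(t1, t2) for w, t1, t2 in
               zip(syn_extra["weight"], syn_extra["tau1"], syn_extra["tau2"])]
        d1 += [np.exp(-dt / t1) for t1 in syn_extra["tau1"]]
        d2 += [np.exp(-dt / t2) for t2 in syn_extra["tau2"]]
        erev += list(syn_extra["erev"])

    # CSR of outgoing local synapses per cell (drive synapses have no source)
    order = np.argsort(net.syn_source, kind="stable")
    out_syn = order.astype(np.int64)
    out_delay = np.round(net.syn_delay[order] / dt).astype(np.int64)
    out_ptr = np.zeros(net.n_cells + 1, dtype=np.int64)
    for s in net.syn_source:
        out_ptr[s + 1] += 1
    out_ptr = np.cumsum(out_ptr)

    cfg = net.config
    rev = cfg["reversals"]
    cal = cfg["calcium"]
    integ = cfg["integration"]
    return dict(
        cm=net.cm, gleak=net.gleak, eleak=net.eleak, gna=net.gna,
        gkdr=net.gkdr, gm_=net.gm, gca=net.gca, gkca=net.gkca,
        ena=rev["na"], ek=rev["k"], eca=rev["ca"],
        tau_ca=cal["tau_ca"], k_ca=cal["k_ca"], kd_kca=cal["kd_kca"],
        edge_parent=net.edge_parent, edge_child=net.edge_child,
        edge_g=net.edge_g, edge_dz=net.edge_dz, edge_layer=net.edge_layer,
        syn_target=np.array(tgt, dtype=np.int64), syn_wf=np.array(wf),
        syn_d1=np.array(d1), syn_d2=np.array(d2), syn_erev=np.array(erev),
        out_ptr=out_ptr, out_syn=out_syn, out_delay=out_delay,
        soma=net.soma, noise_amp=float(cfg["noise_amplitude"]),
        v_bound=float(integ["v_bound"]), spike_thr=float(integ["spike_threshold"]),
        refrac_steps=np.int64(round(integ["refractory"] / dt)))


def _drive_synapses(net: ColumnNetwork, drives: dict) -> tuple:
    """Create one drive synapse per (drive class, cell, term).

    Returns the extra synapse arrays plus a registry mapping
    (drive class, term index) -> (synapse index, extra delay ms).
    """
    receptors = net.config["receptors"]
    extra = {k: [] for k in ("target", "weight", "tau1", "tau2", "erev")}
    registry = {}
    idx = net.n_synapses
    for cls, per_type in drives.items():
        for i, kind in enumerate(net.cell_type):
            for term in per_type.get(kind, []):
                rec, gmax, comp, xdelay = term
                tau1, tau2, erev = receptors[rec]
                extra["target"].append(net.comp_index[i][comp])
                extra["weight"].append(gmax)
                extra["tau1"].append(tau1)
                extra["tau2"].append(tau2)
                extra["erev"].append(erev)
                registry.setdefault(cls, []).append((idx, xdelay))
                idx += 1
    return extra, registry


def _event_arrays(events: list, dt: float, n_steps: int) -> tuple:
    """Sort (time ms, synapse) events into step-indexed kernel arrays."""
    steps = []
    syns = []
    for t_ms, s in events:
        step = int(round(t_ms / dt))
        if 0 <= step < n_steps:
            steps.append(step)
            syns.append(s)
    if not steps:
        return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))
    order = np.argsort(np.array(steps), kind="stable")
    return (np.array(steps, dtype=np.int64)[order],
            np.array(syns, dtype=np.int64)[order])


def _run(net: ColumnNetwork, n_steps: int, dt: float, syn_extra, events,
         seed: int):
    args = _kernel_args(net, syn_extra, dt)
    exo_step, exo_syn = _event_arrays(events, dt, n_steps)
    dip, spikes, status = _run_column(
        n_steps, dt, args["cm"], args["gleak"], args["eleak"], args["gna"],
        args["gkdr"], args["gm_"], args["gca"], args["gkca"],
        args["ena"], args["ek"], args["eca"], args["tau_ca"], args["k_ca"],
        args["kd_kca"], args["edge_parent"], args["edge_child"],
        args["edge_g"], args["edge_dz"], args["edge_layer"],
        args["syn_target"], args["syn_wf"], args["syn_d1"], args["syn_d2"],
        args["syn_erev"], args["out_ptr"], args["out_syn"], args["out_delay"],
        exo_step, exo_syn, args["soma"], args["noise_amp"], args["v_bound"],
        args["spike_thr"], args["refrac_steps"], np.int64(seed % (2 ** 31)))
    if status >= 0:
        raise ColumnSimulationError(
            f"membrane potential diverged at step {status} (t = {status * dt:.2f} ms)")
    return dip, spikes


def simulate_evoked(net: ColumnNetwork, n_trials: int = 25, seed: int = 0,
                    duration: float = 300.0) -> DipoleTrace:
    """Trial-averaged evoked response to the three-drive protocol.

    Each trial delivers one presynaptic spike per drive class (feedforward
    ~25 ms, feedback ~70 ms, late feedforward ~135 ms) with Gaussian
    across-trial timing jitter, on top of per-compartment noise current;
    the per-layer dipoles are averaged across trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    dt = _dt(net)
    n_steps = int(round(duration / dt))
    cfg = net.config
    base_delay = cfg["exogenous_delay"]
    syn_extra, registry = _drive_synapses(net, cfg["evoked_drives"])
    rng = np.random.default_rng(seed)
    acc = np.zeros((n_steps, 2))
    total_spikes = None
    for trial in range(n_trials):
        events = []
        for cls, (mean, sd) in cfg["evoked_timing"].items():
            t_ev = rng.normal(mean, sd)
            for s, xdelay in registry.get(cls, []):
                events.append((t_ev + base_delay + xdelay, s))
        dip, spikes = _run(net, n_steps, dt, syn_extra, events,
                           seed=int(rng.integers(2 ** 31)))
        acc += dip
        total_spikes = spikes if total_spikes is None else total_spikes + spikes
    acc /= n_trials
    t = dt * np.arange(n_steps)
    return DipoleTrace(t=t, superficial=acc[:, 0], deep=acc[:, 1],
                       spike_counts=total_spikes,
                       meta={"protocol": "evoked", "n_trials": n_trials,
                             "seed": seed})


def simulate_alpha(net: ColumnNetwork, duration: float = 3000.0,
                   seed: int = 0) -> DipoleTrace:
    """Ongoing rhythmic drive producing subthreshold alpha-band dipoles.

    Feedforward bursts (two spikes 10 ms apart) arrive every ~100 ms with
    20 ms Gaussian jitter; feedback bursts follow with a 5 ms lag.  Spiking
    is monitored (``spike_counts``), not clamped: with default conductances
    the column stays below threshold.
    """
    if duration < 200.0:
        raise ValueError("alpha protocol requires at least 200 ms")
    dt = _dt(net)
    n_steps = int(round(duration / dt))
    cfg = net.config
    al = cfg["alpha"]
    # unit-conductance drive synapses at the alpha targets
    drives = {}
    for cls, targets in cfg["alpha_targets"].items():
        drives[cls] = {}
        for kind, comp in targets.items():
            g = al["g_in"] if kind.endswith("IN") else al["g_pn"]
            drives[cls][kind] = [("AMPA", g, comp, 0.0)]
    syn_extra, registry = _drive_synapses(net, drives)
    rng = np.random.default_rng(seed)
    base_delay = cfg["exogenous_delay"]
    events = []
    n_bursts = int(duration / al["inter_burst_interval"]) + 2
    for b in range(n_bursts):
        t0 = b * al["inter_burst_interval"] + rng.normal(0.0, al["burst_sd"])
        for k in range(al["spikes_per_burst"]):
            t_spike = t0 + k * al["intra_burst_interval"]
            for s, xdelay in registry.get("FF", []):
                events.append((t_spike + base_delay + xdelay, s))
            for s, xdelay in registry.get("FB", []):
                events.append((t_spike + al["fb_lag"] + base_delay + xdelay, s))
    dip, spikes = _run(net, n_steps, dt, syn_extra, events, seed=seed)
    t = dt * np.arange(n_steps)
    return DipoleTrace(t=t, superficial=dip[:, 0], deep=dip[:, 1],
                       spike_counts=spikes,
                       meta={"protocol": "alpha", "duration": duration,
                             "seed": seed})


def layer_csd(trace: DipoleTrace, nperseg_ms: float = 1000.0,
              burn_in: float = 200.0, decimate: int = 8):
    """Two-channel CSD (superficial, deep) of the layer dipoles.

    Drops the initial transient, decimates (the dipole is slow relative to
    the integration step) and Welch-averages; ready for model inversion.
    """
    from scipy import signal as sps
    keep = trace.t >= burn_in
    x = np.vstack([trace.superficial[keep], trace.deep[keep]])
    if decimate > 1:
        x = sps.decimate(x, decimate, axis=1, zero_phase=True)
    fs = 1000.0 / (trace.dt * decimate)
    nperseg = int(round(nperseg_ms / 1000.0 * fs))
    return welch_csd(x, fs=fs, nperseg=nperseg,
                     channels=("superficial", "deep"),
                     condition=trace.meta.get("protocol", ""))


def dipole_from_voltages(net: ColumnNetwork, v: np.ndarray) -> dict:
    """Per-layer dipole of a static voltage configuration (test oracle)."""
    cur = net.edge_g * (v[net.edge_parent] - v[net.edge_child])
    contrib = cur * net.edge_dz
    return {"superficial": float(contrib[net.edge_layer == 0].sum()),
            "deep": float(contrib[net.edge_layer == 1].sum())}
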