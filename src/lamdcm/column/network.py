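"""Construction of the symmetric compartmental column network.

Cells are reduced multi-compartment neurons connected by double-exponential
conductance synapses.  Horizontal connectivity between mini-columns i and j
follows a Gaussian weight profile and an inverse-Gaussian delay profile,

    w(i, j) = w_max exp(-|i-j|^2 / C_s^2)
    d(i, j) = d_min exp(+|i-j|^2 / C_d^2)

so connections are stronger and faster between nearby mini-columns; every
mini-column has identical structure (the homogeneity that licenses the
mean-field reduction).  Synapses whose profile weight falls below a small
relative cutoff are pruned (their delays grow exponentially while their
weights vanish).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as P

__all__ = ["ColumnNetwork", "connection_profile", "synaptic_current",
           "double_exp_peak_time", "build_symmetric_column"]

CELL_TYPES = ("L23PN", "L5PN", "L23IN", "L5IN")

#: Relative weight below which profile-expanded synapses are dropped.
WEIGHT_CUTOFF = 1e-4


def connection_profile(i: int, j: int, w_max: float, c_s: float,
                       d_min: float, c_d: float) -> tuple:
    """Weight (uS) and delay (ms) between mini-columns i and j."""
    if c_s <= 0 or c_d <= 0:
        raise ValueError("space constants must be positive")
    r2 = float(abs(i - j)) ** 2
    return w_max * np.exp(-r2 / c_s ** 2), d_min * np.exp(r2 / c_d ** 2)


def double_exp_peak_time(tau1: float, tau2: float) -> float:
    """Peak time of exp(-t/tau2) - exp(-t/tau1) for tau2 > tau1."""
    return tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)


def double_exp_norm(tau1: float, tau2: float) -> float:
    """Factor f normalising the double exponential to unit peak."""
    ts = double_exp_peak_time(tau1, tau2)
    return 1.0 / (np.exp(-ts / tau2) - np.exp(-ts / tau1))


def synaptic_current(t: float, w: float, tau1: float, tau2: float,
                     e_rev: float, v: float) -> float:
    """Double-exponential synaptic current at time t after spike arrival.

    g(t) = w f (exp(-t/tau2) - exp(-t/tau1)) with f normalising the peak
    conductance to w; I = g (V - E).  g(0) = 0 and the peak occurs at
    t* = tau1 tau2 / (tau2 - tau1) ln(tau2/tau1).
    """
    if t < 0:
        raise ValueError("time since spike arrival must be non-negative")
    f = double_exp_norm(tau1, tau2)
    g = w * f * (np.exp(-t / tau2) - np.exp(-t / tau1))
    return g * (v - e_rev)


@dataclass
class ColumnNetwork:
    """Flattened arrays describing cells, compartments and synapses."""

    config: dict
    # compartments
    parent: np.ndarray            # (nc,) parent compartment index, -1 for roots
    cm: np.ndarray                # (nc,) nF
    gleak: np.ndarray             # (nc,) uS
    eleak: np.ndarray             # (nc,) mV
    gna: np.ndarray
    gkdr: np.ndarray
    gm: np.ndarray
    gca: np.ndarray
    gkca: np.ndarray
    # axial edges
    edge_parent: np.ndarray
    edge_child: np.ndarray
    edge_g: np.ndarray            # uS
    edge_dz: np.ndarray           # um (signed, apical positive)
    edge_layer: np.ndarray        # 0 = L2/3 PN, 1 = L5 PN, -1 = interneuron
    # cells
    cell_type: list
    cell_minicolumn: np.ndarray
    soma: np.ndarray              # (ncell,) soma compartment index
    comp_index: list              # per cell: dict name -> compartment index
    # local synapses
    syn_source: np.ndarray        # (ns,) source cell
    syn_target: np.ndarray        # (ns,) target compartment
    syn_weight: np.ndarray        # (ns,) uS (peak-normalised)
    syn_tau1: np.ndarray
    syn_tau2: np.ndarray
    syn_erev: np.ndarray
    syn_delay: np.ndarray         # ms

    @property
    def n_compartments(self) -> int:
        return self.parent.size

    @property
    def n_cells(self) -> int:
        return len(self.cell_type)

    @property
    def n_synapses(self) -> int:
        return self.syn_source.size

    def cells_of_type(self, kind: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.cell_type) if t == kind])


def _build_cell(kind: str, cfg: dict, arrays: dict, comp_maps: list) -> None:
    comps = cfg["compartments"][kind]
    mem = cfg["membrane"]
    chan = cfg["channels"][kind]
    dend_leak = cfg["dendrite_leak"].get(kind, chan["gleak"])
    base = len(arrays["cm"])
    index = {}
    order = list(comps.keys())
    for name in order:
        parent_name, length, diam, dz = comps[name]
        area = np.pi * (diam * 1e-4) * (length * 1e-4)          # cm2
        idx = len(arrays["cm"])
        index[name] = idx
        arrays["cm"].append(mem["cm"] * area * 1e3)             # nF
        is_soma = name == "soma"
        gl = chan["gleak"] if is_soma else dend_leak
        arrays["gleak"].append(gl * area * 1e6)                 # uS
        arrays["eleak"].append(chan["eleak"])
        for key in ("gna", "gkdr", "gm", "gca", "gkca"):
            arrays[key].append(chan[key] * area * 1e6 if is_soma else 0.0)
        arrays["parent"].append(-1 if parent_name is None else index[parent_name])
    # axial edges (parent -> child) with half-cylinder series resistance
    layer = {"L23PN": 0, "L5PN": 1}.get(kind, -1)
    for name in order:
        parent_name, length, diam, dz = comps[name]
        if parent_name is None:
            continue
        p_parent, lp, dp, _ = comps[parent_name]
        r_child = cfg["membrane"]["ra"] * (length * 1e-4 / 2) / (np.pi * (diam * 1e-4 / 2) ** 2)
        r_par = cfg["membrane"]["ra"] * (lp * 1e-4 / 2) / (np.pi * (dp * 1e-4 / 2) ** 2)
        g = 1.0 / (r_child + r_par) * 1e6                       # uS
        arrays["edge_parent"].append(index[parent_name])
        arrays["edge_child"].append(index[name])
        arrays["edge_g"].append(g)
        arrays["edge_dz"].append(dz)
        arrays["edge_layer"].append(layer)
    comp_maps.append(index)


def build_symmetric_column(config: dict | None = None) -> ColumnNetwork:
    """Build the 40-cell symmetric column from the (default) config.

    Expands every connection class of the local table over all cell pairs
    with the Gaussian weight / inverse-Gaussian delay profiles, applies the
    interneuron-source conductance scaling, and prunes negligible synapses.
    """
    cfg = P.default_config()
    if config:
        for key, val in config.items():
            if key not in cfg:
                raise ValueError(f"unknown config section {key!r}; "
                                 f"expected one of {sorted(cfg)}")
            if isinstance(cfg[key], dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val

    n_mc = cfg["n_minicolumns"]
    arrays = {k: [] for k in ("parent", "cm", "gleak", "eleak", "gna", "gkdr",
                              "gm", "gca", "gkca", "edge_parent", "edge_child",
                              "edge_g", "edge_dz", "edge_layer")}
    comp_maps: list = []
    cell_type: list = []
    cell_mc: list = []
    soma: list = []
    for mc in range(n_mc):
        for kind in CELL_TYPES:
            cell_type.append(kind)
            cell_mc.append(mc)
            _build_cell(kind, cfg, arrays, comp_maps)
            soma.append(comp_maps[-1]["soma"])

    # expand the connection table over cell pairs
    cells_by_type = {k: [i for i, t in enumerate(cell_type) if t == k]
                     for k in CELL_TYPES}
    receptors = cfg["receptors"]
    syn = {k: [] for k in ("source", "target", "weight", "tau1", "tau2",
                           "erev", "delay")}
    for src_t, tgt_t, terms, c_s, d_min, c_d in cfg["connections"]:
        scale = cfg["in_source_scale"] if src_t.endswith("IN") else 1.0
        for si in cells_by_type[src_t]:
            for ti in cells_by_type[tgt_t]:
                if si == ti:
                    continue  # no autapses within a connection class
                w_fac, delay = connection_profile(cell_mc[si], cell_mc[ti],
                                                  1.0, c_s, d_min, c_d)
                if w_fac < WEIGHT_CUTOFF:
                    continue
                for rec, gmax, comp in terms:
                    tau1, tau2, erev = receptors[rec]
                    syn["source"].append(si)
                    syn["target"].append(comp_maps[ti][comp])
                    syn["weight"].append(gmax * scale * w_fac)
                    syn["tau1"].append(tau1)
                    syn["tau2"].append(tau2)
                    syn["erev"].append(erev)
                    syn["delay"].append(delay)

    return ColumnNetwork(
        config=cfg,
        parent=np.array(arrays["parent"], dtype=np.int64),
        cm=np.array(arrays["cm"]), gleak=np.array(arrays["gleak"]),
        eleak=np.array(arrays["eleak"]), gna=np.array(arrays["gna"]),
        gkdr=np.array(arrays["gkdr"]), gm=np.array(arrays["gm"]),
        gca=np.array(arrays["gca"]), gkca=np.array(arrays["gkca"]),
        edge_parent=np.array(arrays["edge_parent"], dtype=np.int64),
        edge_child=np.array(arrays["edge_child"], dtype=np.int64),
        edge_g=np.array(arrays["edge_g"]), edge_dz=np.array(arrays["edge_dz"]),
        edge_layer=np.array(arrays["edge_layer"], dtype=np.int64),
        cell_type=cell_type, cell_minicolumn=np.array(cell_mc, dtype=np.int64),
        soma=np.array(soma, dtype=np.int64), comp_index=comp_maps,
        syn_source=np.array(syn["source"], dtype=np.int64),
        syn_target=np.array(syn["target"], dtype=np.int64),
        syn_weight=np.array(syn["weight"]),
        syn_tau1=np.array(syn["tau1"]), syn_tau2=np.array(syn["tau2"]),
        syn_erev=np.array(syn["erev"]), syn_delay=np.array(syn["delay"]))
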