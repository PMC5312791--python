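"""Default parameters of the symmetric compartmental column.

The network comprises 10 mini-columns, each contributing one layer-2/3
pyramidal neuron (8 compartments), one layer-5 pyramidal neuron (9
compartments) and one single-compartment interneuron per layer.  Published
sources for this model family specify the channel inventory (fast sodium,
delayed rectifier, M-type potassium and leak in pyramidal cells; calcium
and calcium-dependent potassium with a 20 ms calcium decay in layer-5
cells; sodium/potassium only in interneurons), the synaptic receptor
kinetics, the connection table and the drive protocols — but not the
reduced morphologies or channel densities themselves.  The geometry and
kinetics below are documented plausible defaults for reduced pyramidal
morphologies with standard Hodgkin-Huxley-type rate functions; every entry
can be overridden through the config dictionaries.  The fidelity target of
the simulator is qualitative (the ordering of evoked deflections, the
alpha-band spectral peak), not waveform-exact reproduction of any specific
published implementation.

Units: lengths um, conductance densities S/cm2, specific capacitance
uF/cm2, axial resistivity ohm cm, absolute conductances uS, times ms,
voltages mV, currents nA.
"""

from __future__ import annotations

import copy

#: Membrane and cytoplasm.
MEMBRANE = {
    "cm": 0.85,          # uF/cm2
    "ra": 200.0,         # ohm cm
}

#: Reversal potentials (mV).
REVERSALS = {"na": 50.0, "k": -90.0, "ca": 120.0}

#: Compartment tables: name -> (parent, length um, diam um, dz um).
#: dz is the vertical (somato-apical) extent used by the dipole; oblique
#: and basal side branches run diagonally or laterally.
L23PN_COMPARTMENTS = {
    "soma":           (None,           22.1, 23.4,    0.0),
    "apical_trunk":   ("soma",         35.0,  4.25,  35.0),
    "apical_1":       ("apical_trunk", 306.0, 4.08, 306.0),
    "apical_tuft":    ("apical_1",     238.0, 3.4,  238.0),
    "apical_oblique": ("apical_trunk", 340.0, 3.91,   0.0),
    "basal_trunk":    ("soma",         85.0,  4.25, -85.0),
    "basal_1":        ("basal_trunk",  255.0, 2.72, -180.0),
    "basal_2":        ("basal_trunk",  255.0, 2.72, -180.0),
}

L5PN_COMPARTMENTS = {
    "soma":           (None,           39.0, 28.9,    0.0),
    "apical_trunk":   ("soma",         102.0, 10.2, 102.0),
    "apical_1":       ("apical_trunk", 680.0,  7.48, 680.0),
    "apical_2":       ("apical_1",     680.0,  4.93, 680.0),
    "apical_tuft":    ("apical_2",     425.0,  3.4,  425.0),
    "apical_oblique": ("apical_trunk", 255.0,  5.1,    0.0),
    "basal_trunk":    ("soma",         85.0,   8.5,  -85.0),
    "basal_1":        ("basal_trunk",  255.0,  8.5, -180.0),
    "basal_2":        ("basal_trunk",  255.0,  8.5, -180.0),
}

IN_COMPARTMENTS = {
    "soma": (None, 39.0, 20.0, 0.0),
}

#: Somatic channel densities (S/cm2); dendrites are passive.
CHANNELS = {
    "L23PN": {"gna": 0.15, "gkdr": 0.10, "gm": 0.004, "gca": 0.0, "gkca": 0.0,
              "gleak": 4.26e-5, "eleak": -65.0},
    "L5PN":  {"gna": 0.16, "gkdr": 0.085, "gm": 0.004, "gca": 0.002, "gkca": 0.003,
              "gleak": 4.26e-5, "eleak": -72.0},
    "L23IN": {"gna": 0.15, "gkdr": 0.10, "gm": 0.0, "gca": 0.0, "gkca": 0.0,
              "gleak": 1.0e-4, "eleak": -65.0},
    "L5IN":  {"gna": 0.15, "gkdr": 0.10, "gm": 0.0, "gca": 0.0, "gkca": 0.0,
              "gleak": 1.0e-4, "eleak": -65.0},
}

#: Dendritic passive leak (S/cm2) for pyramidal cells.
DENDRITE_LEAK = {"L23PN": 4.26e-5, "L5PN": 4.26e-5}

#: Calcium pool: d[Ca]/dt = -k_ca I_Ca - [Ca]/tau_ca.
CALCIUM = {"tau_ca": 20.0, "k_ca": 10.0, "kd_kca": 1.0}

#: Synaptic receptor kinetics: (tau1 rise ms, tau2 decay ms, E mV).
RECEPTORS = {
    "AMPA":   (0.5, 5.0, 0.0),
    "NMDA":   (1.0, 20.0, 0.0),
    "GABA_A": (0.5, 5.0, -80.0),
    "GABA_B": (1.0, 20.0, -80.0),
}

#: Local connection table.  Each row: source type, target type, list of
#: (receptor, max conductance uS, target compartment), weight space
#: constant C_s, min delay ms, delay space constant C_d.  Slash-separated
#: conductance pairs in the published table are read as AMPA/NMDA
#: (excitatory sources) or GABA_A/GABA_B (inhibitory sources).
CONNECTION_TABLE = [
    ("L23PN", "L23PN", [("AMPA", 0.001, "basal_1"), ("NMDA", 0.0005, "basal_1")], 3.0, 1.0, 3.0),
    ("L23PN", "L23IN", [("AMPA", 0.003, "soma")], 3.0, 1.0, 3.0),
    ("L23PN", "L5PN",  [("AMPA", 0.00025, "apical_oblique")], 3.0, 3.0, 3.0),
    ("L23PN", "L5IN",  [("AMPA", 0.000075, "soma")], 3.0, 3.0, 3.0),
    ("L23IN", "L23PN", [("GABA_A", 0.015, "soma"), ("GABA_B", 0.015, "apical_trunk")], 5.0, 1.0, 5.0),
    ("L23IN", "L5PN",  [("GABA_A", 0.0003, "apical_tuft")], 5.0, 1.0, 5.0),
    ("L23IN", "L23IN", [("GABA_A", 0.0006, "soma")], 2.0, 1.0, 2.0),
    ("L5PN", "L5PN",   [("AMPA", 0.005, "basal_1"), ("NMDA", 0.0005, "basal_1")], 3.0, 1.0, 3.0),
    ("L5PN", "L5IN",   [("AMPA", 0.0003, "soma")], 3.0, 1.0, 3.0),
    ("L5IN", "L5PN",   [("GABA_A", 0.0075, "soma"), ("GABA_B", 0.0075, "apical_trunk")], 7.0, 1.0, 7.0),
    ("L5IN", "L5IN",   [("GABA_A", 0.0006, "soma")], 2.0, 1.0, 2.0),
]

#: Scaling of interneuron-sourced conductances: the symmetric column uses
#: 10 interneurons per layer instead of 3, so their efferent conductances
#: are scaled by 0.3 to keep total inhibition comparable.
IN_SOURCE_SCALE = 0.3

#: Exogenous drive targets: drive class -> cell type -> list of
#: (receptor, conductance uS, compartment, extra delay ms).  Feedforward
#: drives contact basal/oblique dendrites (granular-layer input), feedback
#: contacts the distal apical tuft; interneurons are driven at the soma.
#: The feedforward connection to layer 5 arrives delayed.
EVOKED_DRIVES = {
    "FF": {
        "L23PN": [("AMPA", 0.002, "basal_1", 0.0)],
        "L23IN": [("AMPA", 0.0012, "soma", 0.0)],
        "L5PN":  [("AMPA", 0.001, "basal_1", 1.0)],
        "L5IN":  [("AMPA", 0.0006, "soma", 1.0)],
    },
    "FB": {
        "L23PN": [("AMPA", 0.004, "apical_tuft", 0.0), ("NMDA", 0.004, "apical_tuft", 0.0)],
        "L23IN": [("AMPA", 0.0006, "soma", 0.0), ("NMDA", 0.0006, "soma", 0.0)],
        "L5PN":  [("AMPA", 0.004, "apical_tuft", 0.0), ("NMDA", 0.004, "apical_tuft", 0.0)],
    },
    "LFF": {
        "L23PN": [("AMPA", 0.08, "basal_1", 0.0)],
        "L23IN": [("AMPA", 0.024, "soma", 0.0)],
        "L5PN":  [("AMPA", 0.04, "basal_1", 1.0)],
        "L5IN":  [("AMPA", 0.012, "soma", 1.0)],
    },
}

#: Evoked protocol: drive class -> (mean onset ms, SD ms across trials).
EVOKED_TIMING = {"FF": (25.0, 2.5), "FB": (70.0, 6.0), "LFF": (135.0, 7.0)}

#: Alpha protocol: rhythmic feedforward burst drive with delayed feedback.
#: Conductances are read as nS (the published "pS" figure is three orders
#: of magnitude below the noise floor implied by the stated stochastic
#: current, so it cannot be what produced the reported oscillations).
ALPHA_PROTOCOL = {
    "spikes_per_burst": 2,
    "intra_burst_interval": 10.0,   # ms between the two spikes
    "inter_burst_interval": 100.0,  # ms, mean
    "burst_sd": 20.0,               # ms, SD of burst arrival times
    "fb_lag": 5.0,                  # ms delay of feedback re feedforward
    "g_pn": 4.0e-4,                 # uS (0.4 nS) onto pyramidal cells
    "g_in": 8.0e-4,                 # uS (0.8 nS) onto interneurons
}

#: Alpha drive placement (unit conductances; scaled by g_pn / g_in).
ALPHA_TARGETS = {
    "FF": {"L23PN": "basal_1", "L23IN": "soma", "L5PN": "basal_1", "L5IN": "soma"},
    "FB": {"L23PN": "apical_tuft", "L23IN": "soma", "L5PN": "apical_tuft"},
}

#: Stochastic current amplitude per compartment (uniform in [-a, a] nA,
#: redrawn every integration step).
NOISE_AMPLITUDE = 0.3

#: Base synaptic delay of exogenous drives (ms).
EXOGENOUS_DELAY = 1.0

#: Integration defaults.
INTEGRATION = {"dt": 0.025, "v_init": None, "v_bound": 200.0,
               "spike_threshold": 0.0, "refractory": 3.0}

#: Number of mini-columns and display scaling of the dipole.
N_MINICOLUMNS = 10
DIPOLE_DISPLAY_SCALE = 3000.0


def default_config() -> dict:
    """Deep copy of the full default configuration."""
    return copy.deepcopy({
        "membrane": MEMBRANE,
        "reversals": REVERSALS,
        "compartments": {"L23PN": L23PN_COMPARTMENTS, "L5PN": L5PN_COMPARTMENTS,
                         "L23IN": IN_COMPARTMENTS, "L5IN": IN_COMPARTMENTS},
        "channels": CHANNELS,
        "dendrite_leak": DENDRITE_LEAK,
        "calcium": CALCIUM,
        "receptors": RECEPTORS,
        "connections": CONNECTION_TABLE,
        "in_source_scale": IN_SOURCE_SCALE,
        "evoked_drives": EVOKED_DRIVES,
        "evoked_timing": EVOKED_TIMING,
        "alpha": ALPHA_PROTOCOL,
        "alpha_targets": ALPHA_TARGETS,
        "noise_amplitude": NOISE_AMPLITUDE,
        "exogenous_delay": EXOGENOUS_DELAY,
        "integration": INTEGRATION,
        "n_minicolumns": N_MINICOLUMNS,
    })
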