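"""Flat state-vector layout of the TRN cell model.

The full dynamical state is a single float64 vector with the stable
ordering given by ``STATE_NAMES``.  Indices are exported as module-level
constants (``IDX_VM`` etc.) so that both the Python API and the compiled
right-hand side address the same slots.
"""

from __future__ import annotations

import numpy as np

STATE_NAMES: tuple[str, ...] = (
    # membrane potential (mV)
    "Vm",
    # Hodgkin-Huxley gates (dimensionless)
    "m", "h", "j",
    # T-type gates (dimensionless)
    "m_CaT", "h_CaT",
    # Ca-activated gates: KCa (fast AHP) and CAN (slow afterdepolarization)
    "m_KCa", "m_CAN",
    # alpha7 nAChR kinetic states (occupancy fractions, sum to 1)
    "a7_C", "a7_A", "a7_O", "a7_D",
    # IP3 receptor inactivation gate (dimensionless)
    "h_IP3",
    # calcium pools (mM)
    "Ca_i", "Ca_local", "Ca_ER",
    # monovalent ion concentrations (mM)
    "Na_i", "Na_o", "K_i", "K_o", "Cl_i",
    # glial potassium buffer occupancy (extracellular-volume-equivalent mM)
    "K_glia",
    # network recovery variable (dimensionless; inert in cell-only runs)
    "y",
)

N_STATES = len(STATE_NAMES)
STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

IDX_VM = STATE_INDEX["Vm"]
IDX_M = STATE_INDEX["m"]
IDX_H = STATE_INDEX["h"]
IDX_J = STATE_INDEX["j"]
IDX_MT = STATE_INDEX["m_CaT"]
IDX_HT = STATE_INDEX["h_CaT"]
IDX_MKCA = STATE_INDEX["m_KCa"]
IDX_MCAN = STATE_INDEX["m_CAN"]
IDX_A7C = STATE_INDEX["a7_C"]
IDX_A7A = STATE_INDEX["a7_A"]
IDX_A7O = STATE_INDEX["a7_O"]
IDX_A7D = STATE_INDEX["a7_D"]
IDX_HIP3 = STATE_INDEX["h_IP3"]
IDX_CAI = STATE_INDEX["Ca_i"]
IDX_CAL = STATE_INDEX["Ca_local"]
IDX_CAER = STATE_INDEX["Ca_ER"]
IDX_NAI = STATE_INDEX["Na_i"]
IDX_NAO = STATE_INDEX["Na_o"]
IDX_KI = STATE_INDEX["K_i"]
IDX_KO = STATE_INDEX["K_o"]
IDX_CLI = STATE_INDEX["Cl_i"]
IDX_KG = STATE_INDEX["K_glia"]
IDX_Y = STATE_INDEX["y"]


def state_to_dict(vec: np.ndarray) -> dict[str, float]:
    return {name: float(vec[i]) for i, name in enumerate(STATE_NAMES)}


def dict_to_state(d: dict[str, float]) -> np.ndarray:
    vec = np.empty(N_STATES)
    for name, i in STATE_INDEX.items():
        vec[i] = d[name]
    return vec
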