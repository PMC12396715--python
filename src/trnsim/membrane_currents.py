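"""Membrane current evaluators and channel gating kinetics.

All currents are densities in μA/cm², positive outward.  The fast Na+ and
K+ channels follow Hodgkin-Huxley kinetics with exponential-linear rate
functions; the low-threshold T-type Ca2+ channel uses steady-state /
time-constant gating with squared activation and slow inactivation that
de-inactivates on hyperpolarization.  KCa and CAN carry Ca-activated
gates driven by the subspace calcium concentration: the gate opens at
rate alpha·Ca² and closes at a fixed rate, fast for KCa (the spike/burst
afterhyperpolarization) and slow for CAN (the afterdepolarization that
carries the tonic tail).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import kernels
from .params import ModelParameters


@dataclass
class GatingState:
    """Channel gating variables, each constrained to [0, 1]."""

    m: float
    h: float
    j: float
    m_CaT: float
    h_CaT: float

    def validate(self) -> None:
        for name in ("m", "h", "j", "m_CaT", "h_CaT"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gating variable {name}={v} outside [0, 1]")


def gating_rate_functions(vm: float) -> dict:
    """All opening/closing rates (1/ms) and T-type x_inf / tau at Vm.

    Keys: a_m, b_m, a_h, b_h, a_j, b_j, mT_inf, tau_mT, hT_inf, tau_hT.
    """
    return {
        "a_m": float(kernels.alpha_m(vm)),
        "b_m": float(kernels.beta_m(vm)),
        "a_h": float(kernels.alpha_h(vm)),
        "b_h": float(kernels.beta_h(vm)),
        "a_j": float(kernels.alpha_j(vm)),
        "b_j": float(kernels.beta_j(vm)),
        "mT_inf": float(kernels.t_type_m_inf(vm)),
        "tau_mT": float(kernels.t_type_tau_m(vm)),
        "hT_inf": float(kernels.t_type_h_inf(vm)),
        "tau_hT": float(kernels.t_type_tau_h(vm)),
    }


def steady_state_gates(vm: float) -> GatingState:
    r = gating_rate_functions(vm)
    return GatingState(
        m=r["a_m"] / (r["a_m"] + r["b_m"]),
        h=r["a_h"] / (r["a_h"] + r["b_h"]),
        j=r["a_j"] / (r["a_j"] + r["b_j"]),
        m_CaT=r["mT_inf"],
        h_CaT=r["hT_inf"],
    )


def sodium_current(vm: float, m: float, h: float, e_na: float,
                   params: ModelParameters) -> float:
    """G_Na·m³·h·(Vm−E_Na) + G_NaL·(Vm−E_Na)."""
    return float(kernels.sodium_current(vm, m, h, e_na,
                                        params.G_Na, params.G_NaL))


def potassium_current(vm: float, j: float, e_k: float,
                      params: ModelParameters) -> float:
    """G_K·j⁴·(Vm−E_K) + G_KL·(Vm−E_K)."""
    return float(kernels.potassium_current(vm, j, e_k,
                                           params.G_K, params.G_KL))


def chloride_leak(vm: float, e_cl: float, params: ModelParameters) -> float:
    return float(kernels.chloride_leak(vm, e_cl, params.G_ClL))


def t_type_current(vm: float, m_cat: float, h_cat: float, e_ca: float,
                   params: ModelParameters) -> float:
    """G_CaT·m_CaT²·h_CaT·(Vm−E_Ca); inward for Vm < E_Ca."""
    return float(kernels.t_type_current(vm, m_cat, h_cat, e_ca,
                                        params.G_CaT))


def ncx_current(vm: float, na_i: float, na_o: float, ca_i: float,
                ca_o: float, params: ModelParameters) -> float:
    """Na/Ca exchanger current (saturating-exponential formulation)."""
    if min(na_i, na_o, ca_i, ca_o) <= 0:
        raise ValueError("NCX requires strictly positive concentrations")
    return float(kernels.ncx_current(
        vm, na_i, na_o, ca_i, ca_o, params.I_NCX_max, params.ncx_gamma,
        params.Km_Na, params.Km_Ca, params.k_sat, params.temperature))


def kca_gate_steady(ca: float, params: ModelParameters) -> float:
    """Steady-state activation of the KCa gate at fixed calcium."""
    return float(kernels.ca_gate_steady(ca, params.kca_alpha,
                                        params.kca_beta))


def can_gate_steady(ca: float, params: ModelParameters) -> float:
    """Steady-state activation of the CAN gate at fixed calcium."""
    return float(kernels.ca_gate_steady(ca, params.can_alpha,
                                        params.can_beta))


def kca_current(vm: float, ca: float, e_k: float,
                params: ModelParameters) -> float:
    """Ca2+-dependent K+ current at the gate's steady state for ``ca``.

    The dynamical model integrates the activation gate m_KCa (opening
    rate kca_alpha·Ca², closing rate kca_beta); this evaluator reports
    the current with the gate equilibrated to the given calcium, which
    is zero at zero calcium and nondecreasing in it.
    """
    if ca < 0:
        raise ValueError("calcium concentration must be ≥ 0")
    m = kca_gate_steady(ca, params)
    return float(kernels.kca_current(vm, m, e_k, params.G_KCa))


def can_current(vm: float, ca: float, params: ModelParameters) -> float:
    """Ca2+-activated nonspecific cation current at gate steady state
    (depolarizing at rest; reversal E_CAN)."""
    if ca < 0:
        raise ValueError("calcium concentration must be ≥ 0")
    m = can_gate_steady(ca, params)
    return float(kernels.can_current(vm, m, params.G_CAN, params.E_CAN))


def alpha7_current(vm: float, open_fraction: float, e_ca: float,
                   params: ModelParameters) -> float:
    """expression · G_α7,max · open fraction · (Vm − E_Ca)."""
    if not 0.0 <= open_fraction <= 1.0:
        raise ValueError(f"open_fraction={open_fraction} outside [0, 1]")
    return float(kernels.alpha7_current(
        vm, open_fraction, e_ca, params.G_alpha7_max,
        params.expression_fraction))
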