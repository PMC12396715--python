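"""α7 nAChR kinetics and the ER calcium store subsystem.

The receptor scheme has four states, C ⇌ A ⇌ O → D → C (resting/closed,
agonist-bound, open, desensitized); occupancies sum to one and the open
state carries the Ca2+ current.  The store subsystem comprises RyR release
(Hill-activated by the subspace trigger Ca), IP3R release (Li-Rinzel
open probability with a slow Ca-inactivation gate), a Hill-form SERCA
pump, a passive ER leak, and first-order exchange between the subspace
and bulk cytosolic pools.  All store fluxes are expressed per cytosolic
volume (mM/ms) and are proportional to the lumen-cytosol gradient, so a
flux vanishes when the pools equilibrate or when its block factor is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .params import ModelParameters


@dataclass
class Alpha7KineticState:
    """Receptor state occupancies (fractions summing to 1)."""

    C: float = 1.0
    A: float = 0.0
    O: float = 0.0
    D: float = 0.0

    def validate(self, tol: float = 1e-6) -> None:
        occ = (self.C, self.A, self.O, self.D)
        if min(occ) < -tol:
            raise ValueError(f"negative receptor occupancy: {occ}")
        if abs(sum(occ) - 1.0) > tol:
            raise ValueError(f"receptor occupancies sum to {sum(occ)}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.A, self.O, self.D])


@dataclass
class StoreState:
    """ER release-channel gating and block factors."""

    h_IP3: float = 0.8
    block_ryr: float = 1.0
    block_ip3r: float = 1.0


def alpha7_state_derivatives(state: Alpha7KineticState, vm: float,
                             ca_local: float, params: ModelParameters,
                             ach: float | None = None) -> np.ndarray:
    """d/dt of (C, A, O, D); components sum to zero by construction."""
    state.validate(tol=1e-6)
    if ach is None:
        ach = params.ach
    dc, da, do, dd = kernels.alpha7_derivatives(
        state.C, state.A, state.O, state.D, float(ach), params.to_vector())
    return np.array([dc, da, do, dd])


def alpha7_steady_state(params: ModelParameters,
                        ach: float | None = None) -> Alpha7KineticState:
    """Stationary occupancies of the receptor scheme at fixed agonist."""
    if ach is None:
        ach = params.ach
    kb = params.a7_k_on * ach
    # solve the 4-state linear chain with conservation
    mat = np.array([
        [-kb, params.a7_k_off, 0.0, params.a7_k_rec],
        [kb, -(params.a7_k_off + params.a7_k_open), params.a7_k_close, 0.0],
        [0.0, params.a7_k_open, -(params.a7_k_close + params.a7_k_des), 0.0],
        [1.0, 1.0, 1.0, 1.0],
    ])
    rhs = np.array([0.0, 0.0, 0.0, 1.0])
    c, a, o, d = np.linalg.solve(mat, rhs)
    return Alpha7KineticState(C=float(c), A=float(a), O=float(o), D=float(d))


def ryr_flux(ca_trigger: float, ca_er: float, ca_i: float,
             params: ModelParameters, block: float | None = None) -> float:
    """RyR release flux (mM/ms): block · P_open(trigger) · (Ca_ER − Ca_i)."""
    if min(ca_trigger, ca_er, ca_i) < 0:
        raise ValueError("calcium concentrations must be ≥ 0")
    p = params if block is None else params.replace(block_ryr=block)
    return float(kernels.ryr_flux(ca_trigger, ca_er, ca_i, p.to_vector()))


def ryr_open_fraction(ca_trigger: float, params: ModelParameters) -> float:
    return float(kernels.ryr_open_fraction(ca_trigger, params.ryr_half))


def ip3r_flux(ca: float, ip3: float, h_ip3: float, ca_er: float,
              params: ModelParameters, block: float | None = None) -> float:
    """IP3R release flux gated by IP3 binding, fast Ca activation and the
    slow inactivation gate h_IP3."""
    if min(ca, ip3, ca_er) < 0:
        raise ValueError("concentrations must be ≥ 0")
    p = params if block is None else params.replace(block_ip3r=block)
    pv = p.replace(ip3_conc=ip3).to_vector()
    return float(kernels.ip3r_flux(ca, ip3, h_ip3, ca_er, pv))


def ip3r_gate_derivative(h_ip3: float, ca: float,
                         params: ModelParameters) -> float:
    """First-order relaxation of h_IP3 to its Ca-dependent steady state."""
    return float(kernels.ip3r_gate_derivative(h_ip3, ca, params.to_vector()))


def ip3r_gate_steady_state(ca: float, params: ModelParameters) -> float:
    q2 = params.ip3_d2 * (params.ip3_conc + params.ip3_d1) \
        / (params.ip3_conc + params.ip3_d3)
    return q2 / (q2 + ca)


def serca_flux(ca: float, params: ModelParameters) -> float:
    """Hill-form (n = 2) SERCA uptake from cytosol into the ER."""
    if ca < 0:
        raise ValueError("calcium concentration must be ≥ 0")
    return float(kernels.serca_flux(ca, params.serca_vmax,
                                    params.serca_half))


def calcium_pool_derivatives(ca_i: float, ca_local: float, ca_er: float,
                             i_ca_local: float, i_ca_bulk: float,
                             h_ip3: float, params: ModelParameters) -> dict:
    """d/dt of the three calcium pools (mM/ms).

    ``i_ca_local`` / ``i_ca_bulk`` are the membrane Ca current densities
    (μA/cm², positive outward) deposited into the subspace and bulk pools
    respectively.  With both set to zero the buffer-and-volume-weighted
    total Ca_i/f_i + vloc·Ca_local/f_loc + ver·Ca_ER is conserved by
    construction (the fast-buffer free fractions f divide out the scaling
    they apply to the free-concentration derivatives).
    """
    g = params.gamma_conv
    j_ryr = ryr_flux(ca_local, ca_er, ca_i, params)
    j_ip3r = ip3r_flux(ca_i, params.ip3_conc, h_ip3, ca_er, params)
    j_serca = serca_flux(ca_i, params)
    j_leak = params.er_leak * (ca_er - ca_i)
    j_exch = params.ca_exch * (ca_local - ca_i)
    d_local = params.ca_buffer_local * (
        -g / (2.0 * params.vloc_frac) * i_ca_local - j_exch)
    d_bulk = params.ca_buffer_i * (
        -g / 2.0 * i_ca_bulk + j_ryr + j_ip3r - j_serca + j_leak
        + params.vloc_frac * j_exch)
    d_er = (j_serca - j_ryr - j_ip3r - j_leak) / params.ver_frac
    return {"Ca_i": d_bulk, "Ca_local": d_local, "Ca_ER": d_er}


def block_store_channels(params: ModelParameters, *, block_ryr: bool = False,
                         block_ip3r: bool = False) -> ModelParameters:
    """Return parameters with the requested release channels blocked
    (their fluxes multiplied by zero).  Reversible: returns a new object.
    """
    return params.replace(
        block_ryr=0.0 if block_ryr else 1.0,
        block_ip3r=0.0 if block_ip3r else 1.0,
    )
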