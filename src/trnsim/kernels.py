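"""Compiled numerical kernels for the TRN cell model.

Every piece of model arithmetic lives here as an ``@njit`` function so the
same code path serves unit tests, trace export, and the stiff integrator.
The full right-hand side ``rhs(t, y, p, i_app)`` consumes the packed state
vector (see :mod:`trnsim.state`) and packed parameter vector (field order
of :class:`trnsim.params.ModelParameters`).

Sign convention: membrane currents are positive outward, and
``dVm/dt = -(sum of currents - I_app) / C_m``.  The Na/K-ATPase current is
carried inside the Na and K current totals (3 Na out : 2 K in) so that
charge bookkeeping and concentration dynamics are mutually consistent.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import FARADAY, GAS_CONSTANT
from .params import PARAM_INDEX
from .state import (
    IDX_VM, IDX_M, IDX_H, IDX_J, IDX_MT, IDX_HT, IDX_MKCA, IDX_MCAN,
    IDX_A7C, IDX_A7A, IDX_A7O, IDX_A7D,
    IDX_HIP3, IDX_CAI, IDX_CAL, IDX_CAER,
    IDX_NAI, IDX_NAO, IDX_KI, IDX_KO, IDX_CLI, IDX_KG, IDX_Y,
    N_STATES,
)

# parameter indices as module-level constants (resolved at jit time)
_g = globals()
for _name, _i in PARAM_INDEX.items():
    _g["P_" + _name.upper()] = _i
del _g, _name, _i

NB_OPTS = dict(cache=True, fastmath=False)


# ----------------------------------------------------------------------
# reversal potentials
# ----------------------------------------------------------------------
@njit(**NB_OPTS)
def nernst_potential(valence, conc_in, conc_out, temperature):
    """Nernst potential in mV: (R*T)/(z*F) * ln(conc_out/conc_in)."""
    rtf = 1000.0 * GAS_CONSTANT * temperature / FARADAY
    return rtf / valence * math.log(conc_out / conc_in)


# ----------------------------------------------------------------------
# Hodgkin-Huxley rate functions (exponential-linear forms; removable
# singularities evaluated by their analytic limits)
# ----------------------------------------------------------------------
@njit(**NB_OPTS)
def _exp_linear(x, scale):
    # scale * x / (1 - exp(-x)); limit at x -> 0 is scale
    if abs(x) < 1e-9:
        return scale * (1.0 + 0.5 * x)
    return scale * x / (-math.expm1(-x))


@njit(**NB_OPTS)
def alpha_m(v):
    return _exp_linear(0.1 * (v + 30.0), 1.0)


@njit(**NB_OPTS)
def beta_m(v):
    return 4.0 * math.exp(-(v + 55.0) / 18.0)


@njit(**NB_OPTS)
def alpha_h(v):
    return 0.07 * math.exp(-(v + 44.0) / 20.0)


@njit(**NB_OPTS)
def beta_h(v):
    return 1.0 / (1.0 + math.exp(-0.1 * (v + 14.0)))


# K-gate rates carry a 4x kinetic factor so spike repolarization is
# brief and the low-threshold envelope survives between fast spikes
@njit(**NB_OPTS)
def alpha_j(v):
    return 4.0 * _exp_linear(0.1 * (v + 34.0), 0.1)


@njit(**NB_OPTS)
def beta_j(v):
    return 0.5 * math.exp(-(v + 44.0) / 80.0)


# ----------------------------------------------------------------------
# T-type Ca channel steady states and time constants (ms)
# ----------------------------------------------------------------------
@njit(**NB_OPTS)
def t_type_m_inf(v):
    return 1.0 / (1.0 + math.exp(-(v + 52.0) / 7.4))


@njit(**NB_OPTS)
def t_type_tau_m(v):
    return 0.44 + 0.15 / (math.exp((v + 27.0) / 10.0)
                          + math.exp(-(v + 102.0) / 15.0))


@njit(**NB_OPTS)
def t_type_h_inf(v):
    return 1.0 / (1.0 + math.exp((v + 80.0) / 5.0))


@njit(**NB_OPTS)
def t_type_tau_h(v):
    # de-inactivation branch accelerated relative to the classic fit so a
    # 100 ms hyperpolarizing step recruits a usable fraction of channels
    return 22.7 + 0.1 / (math.exp((v + 48.0) / 4.0)
                         + math.exp(-(v + 407.0) / 50.0))


# ----------------------------------------------------------------------
# membrane currents (μA/cm², positive outward)
# ----------------------------------------------------------------------
@njit(**NB_OPTS)
def sodium_current(vm, m, h, e_na, g_na, g_nal):
    return g_na * m ** 3 * h * (vm - e_na) + g_nal * (vm - e_na)


@njit(**NB_OPTS)
def potassium_current(vm, j, e_k, g_k, g_kl):
    return g_k * j ** 4 * (vm - e_k) + g_kl * (vm - e_k)


@njit(**NB_OPTS)
def chloride_leak(vm, e_cl, g_cll):
    return g_cll * (vm - e_cl)


@njit(**NB_OPTS)
def t_type_current(vm, m_cat, h_cat, e_ca, g_cat):
    return g_cat * m_cat ** 2 * h_cat * (vm - e_ca)


@njit(**NB_OPTS)
def ncx_current(vm, na_i, na_o, ca_i, ca_o, i_max, gamma, km_na, km_ca,
                k_sat, temperature):
    """Saturating-exponential Na/Ca exchanger current.

    Positive values correspond to reverse-mode operation (net outward
    current, Ca entry); each unit of net charge moved corresponds to one
    Ca ion moved in the opposite sense to three Na ions.
    """
    vfrt = vm * 1e-3 * FARADAY / (GAS_CONSTANT * temperature)
    e1 = math.exp(gamma * vfrt)
    e2 = math.exp((gamma - 1.0) * vfrt)
    num = i_max * (e1 * na_i ** 3 * ca_o - e2 * na_o ** 3 * ca_i)
    den = ((km_na ** 3 + na_o ** 3) * (km_ca + ca_o)
           * (1.0 + k_sat * e2))
    return num / den


@njit(**NB_OPTS)
def hill2(ca, half):
    c2 = ca * ca
    return c2 / (c2 + half * half)


@njit(**NB_OPTS)
def ca_gate_derivative(m_gate, ca, alpha, beta):
    """Ca-activated gate: dm/dt = alpha*Ca^2*(1-m) - beta*m."""
    c = ca if ca > 0.0 else 0.0
    return alpha * c * c * (1.0 - m_gate) - beta * m_gate


@njit(**NB_OPTS)
def ca_gate_steady(ca, alpha, beta):
    c = ca if ca > 0.0 else 0.0
    a = alpha * c * c
    return a / (a + beta)


@njit(**NB_OPTS)
def kca_current(vm, m_gate, e_k, g_kca):
    return g_kca * m_gate * m_gate * (vm - e_k)


@njit(**NB_OPTS)
def can_current(vm, m_gate, g_can, e_can):
    return g_can * m_gate * m_gate * (vm - e_can)


@njit(**NB_OPTS)
def alpha7_current(vm, open_fraction, e_ca, g_max, expression):
    return expression * g_max * open_fraction * (vm - e_ca)


@njit(**NB_OPTS)
def pump_current(na_i, k_o, rho, na_half, na_slope, k_half):
    """Na/K-ATPase turnover expressed as a net outward current (μA/cm²)."""
    fna = 1.0 / (1.0 + math.exp((na_half - na_i) / na_slope))
    fk = 1.0 / (1.0 + math.exp(k_half - k_o))
    return rho * fna * fk


@njit(**NB_OPTS)
def kcc2_flux(k_i, cl_i, k_o, cl_o, rate):
    """Electroneutral K-Cl cotransport (mM/ms out of the cell).

    Zero exactly when [K]i[Cl]i = [K]o[Cl]o.
    """
    return rate * math.log((k_i * cl_i) / (k_o * cl_o))


@njit(**NB_OPTS)
def glial_uptake(k_o, glia_max, k_half, k_slope):
    return glia_max / (1.0 + math.exp((k_half - k_o) / k_slope))


@njit(**NB_OPTS)
def glial_vascular_fluxes(k_o, k_glia, p):
    """(flux into glia, flux into vasculature), both mM/ms removed from ECS."""
    j_glia = (glial_uptake(k_o, p[P_GLIA_MAX], p[P_GLIA_K_HALF],
                           p[P_GLIA_K_SLOPE])
              - p[P_GLIA_RELEASE] * k_glia)
    j_vasc = p[P_EPS_K] * (k_o - p[P_K_BATH])
    return j_glia, j_vasc


# ----------------------------------------------------------------------
# alpha7 nAChR kinetics: C <-> A <-> O -> D -> C
# ----------------------------------------------------------------------
@njit(**NB_OPTS)
def alpha7_derivatives(c, a, o, d, ach, p):
    kb = p[P_A7_K_ON] * ach
    dc = -kb * c + p[P_A7_K_OFF] * a + p[P_A7_K_REC] * d
    da = kb * c - (p[P_A7_K_OFF] + p[P_A7_K_OPEN]) * a + p[P_A7_K_CLOSE] * o
    do = p[P_A7_K_OPEN] * a - (p[P_A7_K_CLOSE] + p[P_A7_K_DES]) * o
    dd = p[P_A7_K_DES] * o - p[P_A7_K_REC] * d
    return dc, da, do, dd


# ----------------------------------------------------------------------
# ER store fluxes (mM/ms, referenced to cytosolic volume)
# ----------------------------------------------------------------------
@njit(**NB_OPTS)
def ryr_open_fraction(ca_trigger, half):
    c4 = ca_trigger ** 4
    return c4 / (c4 + half ** 4)


@njit(**NB_OPTS)
def ryr_flux(ca_trigger, ca_er, ca_i, p):
    return (p[P_BLOCK_RYR] * p[P_RYR_VMAX]
            * ryr_open_fraction(ca_trigger, p[P_RYR_HALF])
            * (ca_er - ca_i))


@njit(**NB_OPTS)
def ip3r_open_probability(ca, ip3, h_gate, p):
    m_inf = ip3 / (ip3 + p[P_IP3_D1])
    n_inf = ca / (ca + p[P_IP3_D5])
    x = m_inf * n_inf * h_gate
    return x * x * x


@njit(**NB_OPTS)
def ip3r_flux(ca, ip3, h_gate, ca_er, p):
    return (p[P_BLOCK_IP3R] * p[P_IP3R_VMAX]
            * ip3r_open_probability(ca, ip3, h_gate, p)
            * (ca_er - ca))


@njit(**NB_OPTS)
def ip3r_gate_derivative(h_gate, ca, p):
    q2 = p[P_IP3_D2] * (p[P_IP3_CONC] + p[P_IP3_D1]) \
        / (p[P_IP3_CONC] + p[P_IP3_D3])
    return p[P_IP3_A2] * (q2 * (1.0 - h_gate) - ca * h_gate)


@njit(**NB_OPTS)
def serca_flux(ca, vmax, half):
    if ca <= 0.0:
        return 0.0
    return vmax * hill2(ca, half)


# ----------------------------------------------------------------------
# full right-hand side
# ----------------------------------------------------------------------
@njit(**NB_OPTS)
def rhs(t, y, p, i_app):
    dy = np.zeros(N_STATES)

    vm = y[IDX_VM]
    m = y[IDX_M]
    h = y[IDX_H]
    jg = y[IDX_J]
    mt = y[IDX_MT]
    ht = y[IDX_HT]
    ca_i = y[IDX_CAI]
    ca_l = y[IDX_CAL]
    ca_er = y[IDX_CAER]
    na_i = y[IDX_NAI]
    na_o = y[IDX_NAO]
    k_i = y[IDX_KI]
    k_o = y[IDX_KO]
    cl_i = y[IDX_CLI]

    temp = p[P_TEMPERATURE]
    ca_o = p[P_CA_O]
    cl_o = p[P_CL_O]

    # reversal potentials from instantaneous concentrations
    e_na = nernst_potential(1.0, na_i, na_o, temp)
    e_k = nernst_potential(1.0, k_i, k_o, temp)
    e_cl = nernst_potential(-1.0, cl_i, cl_o, temp)
    ca_rev_src = ca_i if ca_i > 1e-9 else 1e-9
    e_ca = nernst_potential(2.0, ca_rev_src, ca_o, temp)

    # Ca driving the KCa / CAN activation gates (subspace by default)
    ca_kca = ca_i if p[P_CA_SENSOR_BULK] > 0.5 else ca_l
    ca_can = ca_i if p[P_CAN_SENSOR_LOCAL] > 0.5 else ca_l

    # membrane currents
    i_na_g = sodium_current(vm, m, h, e_na, p[P_G_NA], p[P_G_NAL])
    i_k_g = potassium_current(vm, jg, e_k, p[P_G_K], p[P_G_KL])
    i_cl = chloride_leak(vm, e_cl, p[P_G_CLL])
    i_t = t_type_current(vm, mt, ht, e_ca, p[P_G_CAT])
    i_ncx = ncx_current(vm, na_i, na_o, ca_i, ca_o, p[P_I_NCX_MAX],
                        p[P_NCX_GAMMA], p[P_KM_NA], p[P_KM_CA],
                        p[P_K_SAT], temp)
    i_kca = kca_current(vm, y[IDX_MKCA], e_k, p[P_G_KCA])
    i_can = can_current(vm, y[IDX_MCAN], p[P_G_CAN], p[P_E_CAN])
    i_a7 = alpha7_current(vm, y[IDX_A7O], e_ca, p[P_G_ALPHA7_MAX],
                          p[P_EXPRESSION_FRACTION])
    i_p = pump_current(na_i, k_o, p[P_RHO_PUMP], p[P_PUMP_NA_HALF],
                       p[P_PUMP_NA_SLOPE], p[P_PUMP_K_HALF])

    i_ncx_vm = i_ncx * p[P_C_M] if p[P_LITERAL_NCX_CM] > 0.5 else i_ncx

    i_total = (i_na_g + i_k_g + i_cl + i_t + i_ncx_vm + i_kca + i_a7
               + i_can + i_p - i_app)
    dy[IDX_VM] = -i_total / p[P_C_M]

    # HH gating
    dy[IDX_M] = alpha_m(vm) * (1.0 - m) - beta_m(vm) * m
    dy[IDX_H] = alpha_h(vm) * (1.0 - h) - beta_h(vm) * h
    dy[IDX_J] = alpha_j(vm) * (1.0 - jg) - beta_j(vm) * jg
    dy[IDX_MT] = (t_type_m_inf(vm) - mt) / t_type_tau_m(vm)
    dy[IDX_HT] = (t_type_h_inf(vm) - ht) / t_type_tau_h(vm)
    dy[IDX_MKCA] = ca_gate_derivative(y[IDX_MKCA], ca_kca,
                                      p[P_KCA_ALPHA], p[P_KCA_BETA])
    dy[IDX_MCAN] = ca_gate_derivative(y[IDX_MCAN], ca_can,
                                      p[P_CAN_ALPHA], p[P_CAN_BETA])

    # alpha7 receptor kinetics
    dc, da, do, dd = alpha7_derivatives(y[IDX_A7C], y[IDX_A7A], y[IDX_A7O],
                                        y[IDX_A7D], p[P_ACH], p)
    dy[IDX_A7C] = dc
    dy[IDX_A7A] = da
    dy[IDX_A7O] = do
    dy[IDX_A7D] = dd

    # IP3R inactivation gate
    dy[IDX_HIP3] = ip3r_gate_derivative(y[IDX_HIP3], ca_i, p)

    # store fluxes (per cytosolic volume)
    j_ryr = ryr_flux(ca_l, ca_er, ca_i, p)
    j_ip3r = ip3r_flux(ca_i, p[P_IP3_CONC], y[IDX_HIP3], ca_er, p)
    j_serca = serca_flux(ca_i, p[P_SERCA_VMAX], p[P_SERCA_HALF])
    j_leak = p[P_ER_LEAK] * (ca_er - ca_i)

    gamma = p[P_GAMMA_CONV]
    vloc = p[P_VLOC_FRAC]
    ver = p[P_VER_FRAC]

    # membrane Ca entry: T-type and alpha7 feed the subspace; NCX
    # exchanges with the bulk pool (2 units of Ca charge per net charge)
    j_ca_local_in = -gamma / (2.0 * vloc) * (i_t + i_a7)
    j_exch = p[P_CA_EXCH] * (ca_l - ca_i)
    dy[IDX_CAL] = p[P_CA_BUFFER_LOCAL] * (j_ca_local_in - j_exch)
    dy[IDX_CAI] = p[P_CA_BUFFER_I] * (gamma * i_ncx + j_ryr + j_ip3r
                                      - j_serca + j_leak + vloc * j_exch)
    dy[IDX_CAER] = (j_serca - j_ryr - j_ip3r - j_leak) / ver

    # monovalent ion bookkeeping
    i_na_total = i_na_g + 3.0 * i_p + 3.0 * i_ncx \
        + p[P_CAN_NA_FRAC] * i_can
    i_k_total = i_k_g - 2.0 * i_p + i_kca \
        + (1.0 - p[P_CAN_NA_FRAC]) * i_can

    j_kcc2 = kcc2_flux(k_i, cl_i, k_o, cl_o, p[P_KCC2_RATE])
    j_glia, j_vasc = glial_vascular_fluxes(k_o, y[IDX_KG], p)

    beta = p[P_VOL_RATIO]
    dy[IDX_NAI] = -gamma * i_na_total
    dy[IDX_NAO] = beta * gamma * i_na_total
    dy[IDX_KI] = -gamma * i_k_total - j_kcc2
    dy[IDX_KO] = beta * gamma * i_k_total + beta * j_kcc2 \
        - j_glia - j_vasc
    dy[IDX_CLI] = gamma * i_cl - j_kcc2
    dy[IDX_KG] = j_glia

    # network recovery variable
    alpha = p[P_FB_ALPHA] if vm > 0.0 else 0.0
    dy[IDX_Y] = -alpha * y[IDX_Y] + p[P_FB_BETA] * (1.0 - y[IDX_Y])

    return dy


@njit(**NB_OPTS)
def membrane_current_vector(t, y, p, i_app):
    """Per-current decomposition at a state point.

    Returns (I_Na, I_K, I_Cl, I_T, I_NCX, I_KCa, I_alpha7, I_CAN, I_pump,
    J_RyR, J_IP3R, J_SERCA) for trace export; current components in
    μA/cm², store fluxes in mM/ms.
    """
    vm = y[IDX_VM]
    ca_i = y[IDX_CAI]
    ca_l = y[IDX_CAL]
    ca_er = y[IDX_CAER]
    na_i = y[IDX_NAI]
    na_o = y[IDX_NAO]
    temp = p[P_TEMPERATURE]

    e_na = nernst_potential(1.0, na_i, na_o, temp)
    e_k = nernst_potential(1.0, y[IDX_KI], y[IDX_KO], temp)
    e_cl = nernst_potential(-1.0, y[IDX_CLI], p[P_CL_O], temp)
    ca_rev_src = ca_i if ca_i > 1e-9 else 1e-9
    e_ca = nernst_potential(2.0, ca_rev_src, p[P_CA_O], temp)
    i_na = sodium_current(vm, y[IDX_M], y[IDX_H], e_na, p[P_G_NA], p[P_G_NAL])
    i_k = potassium_current(vm, y[IDX_J], e_k, p[P_G_K], p[P_G_KL])
    i_cl = chloride_leak(vm, e_cl, p[P_G_CLL])
    i_t = t_type_current(vm, y[IDX_MT], y[IDX_HT], e_ca, p[P_G_CAT])
    i_ncx = ncx_current(vm, na_i, na_o, ca_i, p[P_CA_O], p[P_I_NCX_MAX],
                        p[P_NCX_GAMMA], p[P_KM_NA], p[P_KM_CA],
                        p[P_K_SAT], temp)
    i_kca = kca_current(vm, y[IDX_MKCA], e_k, p[P_G_KCA])
    i_a7 = alpha7_current(vm, y[IDX_A7O], e_ca, p[P_G_ALPHA7_MAX],
                          p[P_EXPRESSION_FRACTION])
    i_can = can_current(vm, y[IDX_MCAN], p[P_G_CAN], p[P_E_CAN])
    i_p = pump_current(na_i, y[IDX_KO], p[P_RHO_PUMP], p[P_PUMP_NA_HALF],
                       p[P_PUMP_NA_SLOPE], p[P_PUMP_K_HALF])
    j_ryr = ryr_flux(ca_l, ca_er, ca_i, p)
    j_ip3r = ip3r_flux(ca_i, p[P_IP3_CONC], y[IDX_HIP3], ca_er, p)
    j_serca = serca_flux(ca_i, p[P_SERCA_VMAX], p[P_SERCA_HALF])

    return (i_na, i_k, i_cl, i_t, i_ncx, i_kca, i_a7, i_can, i_p,
            j_ryr, j_ip3r, j_serca)
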