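"""Dynamic ion concentrations, reversal potentials, pumps and transport.

Intracellular and extracellular Na+, K+ and Cl- pools are dynamic, as are
the three calcium pools (bulk cytosol, membrane subspace, ER lumen).
Extracellular Ca2+ and Cl- are clamped bath concentrations.  Potassium is
additionally exchanged with a glial buffer and with the vasculature.

Membrane current densities (μA/cm²) convert to concentration rates
(mM/ms) through ``gamma_conv`` — the surface-to-volume factor of the
cytosolic compartment divided by Faraday's constant — divided by the ion
valence; extracellular changes are scaled by the intracellular-to-
extracellular volume ratio and carry the opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import kernels
from .params import ModelParameters

#: ion species labels accepted by :func:`ion_concentration_derivatives`
ION_SPECIES = ("Na", "K", "Cl", "Ca")
_VALENCE = {"Na": 1.0, "K": 1.0, "Cl": -1.0, "Ca": 2.0}


@dataclass
class IonState:
    """Ion concentrations (mM) in all compartments."""

    Na_i: float = 18.0
    Na_o: float = 144.0
    K_i: float = 140.0
    K_o: float = 3.0
    Cl_i: float = 6.0
    Cl_o: float = 130.0
    Ca_i: float = 1.0e-4
    Ca_o: float = 2.0
    Ca_local: float = 1.0e-4
    Ca_ER: float = 0.4
    K_glia: float = 20.0

    def validate(self) -> None:
        for name in ("Na_i", "Na_o", "K_i", "K_o", "Cl_i", "Cl_o",
                     "Ca_i", "Ca_o", "Ca_local", "Ca_ER", "K_glia"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration for {name}")

    def replace(self, **kw) -> "IonState":
        return replace(self, **kw)


@dataclass
class ReversalPotentials:
    E_Na: float
    E_K: float
    E_Cl: float
    E_Ca: float


def nernst_potential(valence: float, conc_in: float, conc_out: float,
                     temperature: float = 310.0, ion: str = "") -> float:
    """Nernst potential (mV) for an ion of the given valence.

    Raises ``ValueError`` naming the ion for non-positive concentrations.
    """
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if conc_in <= 0 or conc_out <= 0:
        label = ion or "ion"
        raise ValueError(
            f"non-positive concentration for {label}: "
            f"in={conc_in}, out={conc_out}")
    return float(kernels.nernst_potential(float(valence), float(conc_in),
                                          float(conc_out),
                                          float(temperature)))


def update_reversal_potentials(ions: IonState,
                               params: ModelParameters) -> ReversalPotentials:
    """Recompute all four reversal potentials from current concentrations."""
    t = params.temperature
    return ReversalPotentials(
        E_Na=nernst_potential(1, ions.Na_i, ions.Na_o, t, "Na"),
        E_K=nernst_potential(1, ions.K_i, ions.K_o, t, "K"),
        E_Cl=nernst_potential(-1, ions.Cl_i, ions.Cl_o, t, "Cl"),
        E_Ca=nernst_potential(2, ions.Ca_i, ions.Ca_o, t, "Ca"),
    )


def pump_and_cotransport_currents(ions: IonState, vm: float,
                                  params: ModelParameters) -> dict:
    """Na/K-ATPase per-ion currents (μA/cm²) and KCC2 flux (mM/ms).

    The ATPase moves 3 Na+ out per 2 K+ in, a net outward current.  KCC2
    is electroneutral: it appears only as a concentration flux (positive
    = K and Cl leaving the cell), never as a membrane current.
    """
    i_p = float(kernels.pump_current(
        ions.Na_i, ions.K_o, params.rho_pump, params.pump_na_half,
        params.pump_na_slope, params.pump_k_half))
    j_kcc2 = float(kernels.kcc2_flux(
        ions.K_i, ions.Cl_i, ions.K_o, ions.Cl_o, params.kcc2_rate))
    return {"Na": 3.0 * i_p, "K": -2.0 * i_p, "net": i_p, "KCC2": j_kcc2}


def glial_and_vascular_k_exchange(k_o: float, k_glia: float,
                                  params: ModelParameters
                                  ) -> tuple[float, float]:
    """(flux into glia, flux into vasculature) in mM/ms removed from ECS.

    The vascular term is diffusive, proportional to (K_o − bath); the
    glial term is a saturating uptake opposed by first-order release of
    the buffered pool.
    """
    if k_o < 0:
        raise ValueError("negative concentration for K_o")
    j_glia, j_vasc = kernels.glial_vascular_fluxes(
        float(k_o), float(k_glia), params.to_vector())
    return float(j_glia), float(j_vasc)


def ion_concentration_derivatives(ions: IonState,
                                  membrane_currents: dict,
                                  store_fluxes: dict,
                                  params: ModelParameters) -> dict:
    """Concentration derivatives (mM/ms) from per-ion current densities.

    ``membrane_currents`` maps ion species labels ("Na", "K", "Cl", "Ca")
    to total membrane current density carried by that species (μA/cm²,
    positive outward).  ``store_fluxes`` may provide "Ca_i", "Ca_local",
    "Ca_ER" source terms (mM/ms) from the ER subsystem, and "Ca_local_in"
    for the part of the Ca current deposited into the subspace.  Pump and
    cotransport contributions are expected to already be folded into the
    per-ion currents / fluxes by the caller; this function performs the
    pure charge-to-moles bookkeeping plus glial/vascular exchange.
    """
    for key in membrane_currents:
        if key not in ION_SPECIES:
            raise ValueError(f"unknown ion species label: {key!r}")
    g = params.gamma_conv
    beta = params.vol_ratio
    d = {name: 0.0 for name in (
        "Na_i", "Na_o", "K_i", "K_o", "Cl_i", "Cl_o",
        "Ca_i", "Ca_o", "Ca_local", "Ca_ER", "K_glia")}

    i_na = membrane_currents.get("Na", 0.0)
    i_k = membrane_currents.get("K", 0.0)
    i_cl = membrane_currents.get("Cl", 0.0)
    i_ca = membrane_currents.get("Ca", 0.0)

    d["Na_i"] = -g * i_na
    d["Na_o"] = beta * g * i_na
    d["K_i"] = -g * i_k
    d["K_o"] = beta * g * i_k
    d["Cl_i"] = g * i_cl  # valence −1
    # bath-clamped pools stay fixed
    d["Cl_o"] = 0.0
    d["Ca_o"] = 0.0

    # KCC2 (electroneutral) and glia/vasculature source terms
    j_kcc2 = store_fluxes.get("KCC2", 0.0)
    d["K_i"] -= j_kcc2
    d["K_o"] += beta * j_kcc2
    d["Cl_i"] -= j_kcc2
    j_glia = store_fluxes.get("glia", 0.0)
    j_vasc = store_fluxes.get("vasc", 0.0)
    d["K_o"] -= j_glia + j_vasc
    d["K_glia"] = j_glia

    # calcium: membrane flux splits between subspace and bulk targets
    i_ca_local = store_fluxes.get("Ca_current_local", i_ca)
    i_ca_bulk = i_ca - i_ca_local
    d["Ca_local"] = -g / (2.0 * params.vloc_frac) * i_ca_local \
        + store_fluxes.get("Ca_local", 0.0)
    d["Ca_i"] = -g / 2.0 * i_ca_bulk + store_fluxes.get("Ca_i", 0.0)
    d["Ca_ER"] = store_fluxes.get("Ca_ER", 0.0)
    return d
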