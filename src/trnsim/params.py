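"""Model parameters: conductances, kinetics, transport, geometry.

All membrane currents are in μA/cm², conductance densities in mS/cm²,
concentrations in mM, time in ms, voltage in mV.  ``ModelParameters`` is a
flat dataclass; its declared field order defines the layout of the packed
parameter vector consumed by the compiled right-hand side, and the field
set doubles as the manifest against which parameter files are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterator

import numpy as np
import yaml


@dataclass
class ModelParameters:
    # ---- physical / geometric ------------------------------------------
    #: temperature (K)
    temperature: float = 310.0
    #: μA/cm² → mM/ms conversion for the cytosolic volume, per unit valence
    #: (surface-to-volume factor divided by Faraday's constant)
    gamma_conv: float = 4.45e-5
    #: intracellular-to-extracellular volume ratio
    vol_ratio: float = 7.0
    #: subspace ("local") volume as a fraction of cytosolic volume
    vloc_frac: float = 0.1
    #: ER lumen volume as a fraction of cytosolic volume
    ver_frac: float = 0.05
    #: specific membrane capacitance (μF/cm²)
    C_m: float = 1.0

    # ---- maximal conductances (mS/cm²) ---------------------------------
    G_Na: float = 150.0
    G_K: float = 40.0
    G_NaL: float = 0.0429
    G_KL: float = 0.1283
    G_ClL: float = 0.0294
    G_CaT: float = 3.5
    G_KCa: float = 20.0
    G_CAN: float = 1.0
    #: maximal alpha7 nAChR conductance at 100% expression
    G_alpha7_max: float = 0.3
    #: alpha7 expression fraction (1.0 = wild type, 0.5 = hemizygous)
    expression_fraction: float = 1.0

    # ---- KCa / CAN activation ------------------------------------------
    #: KCa gate opening rate constant (1/(ms·mM²)); closes at kca_beta
    kca_alpha: float = 20.0
    #: KCa gate closing rate (1/ms); sets the fast-AHP decay (~30 ms)
    kca_beta: float = 0.02
    #: CAN gate opening rate constant (1/(ms·mM²))
    can_alpha: float = 60.0
    #: CAN gate closing rate (1/ms); sets the afterdepolarization decay
    can_beta: float = 2.7e-3
    #: reversal potential of the CAN current (mV)
    E_CAN: float = 10.0
    #: fraction of the CAN current carried by Na+ (remainder K+)
    can_na_frac: float = 0.75
    #: 1.0 → KCa senses bulk Ca_i instead of the local subspace
    ca_sensor_bulk: float = 0.0
    #: 1.0 → CAN senses the local subspace instead of bulk Ca_i
    can_sensor_local: float = 0.0

    # ---- NCX ------------------------------------------------------------
    I_NCX_max: float = 1000.0
    ncx_gamma: float = 0.35
    Km_Na: float = 87.5
    Km_Ca: float = 1.38
    k_sat: float = 0.1
    #: 1.0 reproduces the literal C_m-scaled NCX term of the membrane equation
    literal_ncx_cm: float = 0.0

    # ---- Na/K-ATPase, glia, vasculature, KCC2 --------------------------
    #: neuronal pump current scale (μA/cm²)
    rho_pump: float = 131.8
    pump_na_half: float = 25.0
    pump_na_slope: float = 3.0
    pump_k_half: float = 4.5
    #: glial uptake capacity (mM/ms); sigmoidal in K_o (glial Na/K-ATPase)
    glia_max: float = 0.066
    glia_k_half: float = 18.0
    glia_k_slope: float = 2.5
    #: first-order release of buffered glial K+ back to the ECS (1/ms)
    glia_release: float = 8.1e-6
    #: extracellular ↔ vasculature K+ diffusion constant (1/ms)
    eps_k: float = 5.0e-3
    #: perfusate / bath potassium (mM)
    k_bath: float = 3.0
    #: KCC2 cotransport rate (mM/ms per unit of ln driving force)
    kcc2_rate: float = 5.0e-5

    # ---- clamped bath concentrations (mM) ------------------------------
    Ca_o: float = 2.0
    Cl_o: float = 130.0

    # ---- alpha7 nAChR kinetics -----------------------------------------
    #: ambient acetylcholine concentration (mM)
    ach: float = 1.0e-3
    #: C→A agonist binding rate (1/(mM·ms))
    a7_k_on: float = 5.0
    #: A→C unbinding rate (1/ms)
    a7_k_off: float = 0.5
    #: A→O opening rate (1/ms)
    a7_k_open: float = 2.0
    #: O→A closing rate (1/ms)
    a7_k_close: float = 1.0
    #: O→D desensitization rate (1/ms)
    a7_k_des: float = 0.05
    #: D→C recovery rate (1/ms)
    a7_k_rec: float = 5.0e-3

    # ---- ER store: SERCA, RyR, IP3R, leak ------------------------------
    serca_vmax: float = 1.0e-3
    serca_half: float = 5.0e-4
    #: RyR maximal release rate (1/ms), flux ∝ (Ca_ER − Ca_i)
    ryr_vmax: float = 5.0e-3
    #: RyR half-activation by the local trigger Ca (mM, Hill n=4)
    ryr_half: float = 0.005
    #: IP3R maximal release rate (1/ms)
    ip3r_vmax: float = 2.0e-3
    #: cytosolic IP3 concentration (mM); constant in this model
    ip3_conc: float = 1.5e-4
    ip3_d1: float = 1.3e-4
    ip3_d2: float = 1.049e-3
    ip3_d3: float = 9.434e-4
    ip3_d5: float = 8.234e-5
    ip3_a2: float = 0.2
    #: passive ER leak rate (1/ms)
    er_leak: float = 5.0e-4
    #: local ↔ bulk first-order Ca exchange rate (1/ms)
    ca_exch: float = 1.0
    #: free fraction of bulk cytosolic Ca (fast-buffer approximation)
    ca_buffer_i: float = 0.02
    #: free fraction of subspace Ca (lightly buffered, fast)
    ca_buffer_local: float = 0.5
    #: store-channel block factors (1 = intact, 0 = blocked)
    block_ryr: float = 1.0
    block_ip3r: float = 1.0

    # ---- network recovery variable -------------------------------------
    #: decay rate of y while Vm > 0 (1/ms); large enough that a single
    #: action potential drives y close to zero
    fb_alpha: float = 5.0
    #: recovery rate of y (1/ms); models the GABA response duration
    fb_beta: float = 0.05

    # -------------------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)],
                        dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParameters":
        names = [f.name for f in fields(cls)]
        return cls(**{n: float(v) for n, v in zip(names, vec)})

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def validate(self) -> None:
        for name in ("C_m", "temperature", "gamma_conv", "vol_ratio",
                     "vloc_frac", "ver_frac", "Km_Na", "Km_Ca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite")
        for name in ("G_Na", "G_K", "G_NaL", "G_KL", "G_ClL", "G_CaT",
                     "G_KCa", "G_CAN", "G_alpha7_max", "expression_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be ≥ 0")
        if not 0.0 <= self.ncx_gamma <= 1.0:
            raise ValueError("ncx_gamma must lie in [0, 1]")


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ModelParameters))
PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)


def default_parameters() -> ModelParameters:
    return ModelParameters()


def load_parameters(path: str, *, strict: bool = True) -> ModelParameters:
    """Load parameters from a YAML file, validating against the manifest.

    Every key must name a known parameter; with ``strict`` every manifest
    symbol must be present, otherwise missing symbols fall back to the
    defaults.  Duplicate keys are rejected by the YAML loader below.
    """
    with open(path) as fh:
        raw = yaml.load(fh, Loader=_NoDuplicateLoader)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    unknown = sorted(set(raw) - set(PARAM_NAMES))
    if unknown:
        raise ValueError(f"unknown parameter name(s): {', '.join(unknown)}")
    missing = sorted(set(PARAM_NAMES) - set(raw))
    if strict and missing:
        raise ValueError(f"missing parameter name(s): {', '.join(missing)}")
    params = ModelParameters(**{k: float(v) for k, v in raw.items()})
    params.validate()
    return params


def save_parameters(params: ModelParameters, path: str) -> None:
    data = {f.name: float(getattr(params, f.name))
            for f in fields(ModelParameters)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


class _NoDuplicateLoader(yaml.SafeLoader):
    """SafeLoader variant that rejects duplicate mapping keys."""


def _no_dup_construct(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ValueError(f"duplicate key in parameter file: {key!r}")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_NoDuplicateLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_dup_construct)


def iter_params(params: ModelParameters) -> Iterator[tuple[str, float]]:
    for f in fields(params):
        yield f.name, getattr(params, f.name)
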