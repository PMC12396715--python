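"""Assembly and integration of the full single-compartment TRN model.

The flat state vector (see :mod:`trnsim.state`) is integrated with a
stiff, variable-order solver (LSODA by default, BDF available).  Stimulus
edges are exact integration breakpoints, and output is sampled on a dense
regular grid for spike extraction.  The standard experiments — control,
α7-removed, CAN-knockout and store-block — share one protocol: settle to
rest, then a hyperpolarizing pulse of −3.5 μA/cm² for 100 ms at t = 100 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import kernels, spike_analysis
from .calcium_signaling import alpha7_steady_state, ip3r_gate_steady_state
from .membrane_currents import steady_state_gates
from .params import ModelParameters, default_parameters
from .state import (
    IDX_VM, IDX_M, IDX_H, IDX_J, IDX_MT, IDX_HT, IDX_MKCA, IDX_MCAN,
    IDX_A7C, IDX_A7A, IDX_A7O, IDX_A7D, IDX_HIP3,
    IDX_CAI, IDX_CAL, IDX_CAER, IDX_NAI, IDX_NAO, IDX_KI, IDX_KO,
    IDX_CLI, IDX_KG, IDX_Y, N_STATES, STATE_NAMES, STATE_INDEX,
)

# control stimulus of the cell-level experiments
STIM_ONSET = 100.0   # ms
STIM_DUR = 100.0     # ms
STIM_AMP = -3.5      # μA/cm² (negative hyperpolarizes)

CURRENT_CHANNELS = ("I_Na", "I_K", "I_Cl", "I_T", "I_NCX", "I_KCa",
                    "I_alpha7", "I_CAN", "I_pump",
                    "J_RyR", "J_IP3R", "J_SERCA")


@dataclass
class StimulusProtocol:
    """Piecewise-constant applied current: (onset, duration, amplitude)."""

    segments: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        segs = sorted(self.segments)
        for (o1, d1, a1), (o2, _, _) in zip(segs, segs[1:]):
            if o1 + d1 > o2 + 1e-12:
                raise ValueError("stimulus segments overlap")
        for o, d, a in segs:
            if d < 0 or not np.isfinite(a):
                raise ValueError("invalid stimulus segment")
        self.segments = segs

    def i_app(self, t: float) -> float:
        total = 0.0
        for onset, dur, amp in self.segments:
            if onset <= t < onset + dur:
                total += amp
        return total

    def breakpoints(self) -> list[float]:
        pts = set()
        for onset, dur, _ in self.segments:
            pts.add(onset)
            pts.add(onset + dur)
        return sorted(pts)

    @classmethod
    def control_pulse(cls) -> "StimulusProtocol":
        return cls([(STIM_ONSET, STIM_DUR, STIM_AMP)])


@dataclass
class SolverConfig:
    """Stiff-integrator settings."""

    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    method: str = "LSODA"
    max_step: float = np.inf
    sample_dt: float = 0.05  # ms

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0 or self.sample_dt <= 0:
            raise ValueError("solver tolerances and sampling must be > 0")

    def atol_vector(self) -> np.ndarray:
        atol = np.full(N_STATES, self.atol)
        # calcium pools live at ~1e-4 mM; voltage at tens of mV
        for idx in (IDX_CAI, IDX_CAL):
            atol[idx] = min(self.atol, 1e-10)
        atol[IDX_VM] = max(self.atol, 1e-8)
        return atol


@dataclass
class SimulationTrace:
    """Time-stamped record of the full state along a trajectory."""

    t: np.ndarray
    y: np.ndarray  # shape (n_samples, N_STATES)
    params: ModelParameters

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time grid must be strictly increasing")
        if self.y.shape != (self.t.size, N_STATES):
            raise ValueError("state array shape does not match time grid")

    @property
    def vm(self) -> np.ndarray:
        return self.y[:, IDX_VM]

    def channel(self, name: str) -> np.ndarray:
        return self.y[:, STATE_INDEX[name]]

    def current_channels(self) -> dict[str, np.ndarray]:
        """Per-current (μA/cm²) and per-store-flux (mM/ms) time series."""
        pvec = self.params.to_vector()
        out = np.empty((self.t.size, len(CURRENT_CHANNELS)))
        for i in range(self.t.size):
            out[i] = kernels.membrane_current_vector(
                self.t[i], self.y[i], pvec, 0.0)
        return {name: out[:, k] for k, name in enumerate(CURRENT_CHANNELS)}

    def window(self, t0: float, t1: float) -> "SimulationTrace":
        sel = (self.t >= t0) & (self.t <= t1)
        return SimulationTrace(self.t[sel].copy(), self.y[sel].copy(),
                               self.params)


def initial_state(params: ModelParameters | None = None,
                  vm: float = -69.0) -> np.ndarray:
    """Nominal initial state: gates and receptor at steady state for vm,
    concentrations at their standard resting values."""
    if params is None:
        params = default_parameters()
    y = np.zeros(N_STATES)
    y[IDX_VM] = vm
    g = steady_state_gates(vm)
    y[IDX_M], y[IDX_H], y[IDX_J] = g.m, g.h, g.j
    y[IDX_MT], y[IDX_HT] = g.m_CaT, g.h_CaT
    from .membrane_currents import kca_gate_steady, can_gate_steady
    ca_loc0 = 1.0e-4
    y[IDX_MKCA] = kca_gate_steady(ca_loc0, params)
    y[IDX_MCAN] = can_gate_steady(ca_loc0, params)
    a7 = alpha7_steady_state(params)
    y[IDX_A7C], y[IDX_A7A] = a7.C, a7.A
    y[IDX_A7O], y[IDX_A7D] = a7.O, a7.D
    y[IDX_CAI] = 1.0e-4
    y[IDX_CAL] = 1.0e-4
    y[IDX_CAER] = 0.4
    y[IDX_HIP3] = ip3r_gate_steady_state(y[IDX_CAI], params)
    y[IDX_NAI], y[IDX_NAO] = 18.0, 144.0
    y[IDX_KI], y[IDX_KO] = 140.0, 3.0
    y[IDX_CLI] = 6.0
    y[IDX_KG] = 20.0
    y[IDX_Y] = 1.0
    return y


def assemble_rhs(state: np.ndarray, t: float, params: ModelParameters,
                 protocol: StimulusProtocol | None = None) -> np.ndarray:
    """Full model right-hand side with a non-finite diagnostic."""
    i_app = protocol.i_app(t) if protocol is not None else 0.0
    dy = kernels.rhs(t, np.asarray(state, dtype=float),
                     params.to_vector(), i_app)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise FloatingPointError(
            f"non-finite derivative for state(s): {', '.join(bad)} "
            f"at t={t}")
    return dy


class SolverError(RuntimeError):
    def __init__(self, message, t_last=None, y_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


def integrate(initial: np.ndarray, protocol: StimulusProtocol,
              t_span: tuple[float, float],
              params: ModelParameters | None = None,
              solver: SolverConfig | None = None) -> SimulationTrace:
    """Integrate the model over ``t_span``, honoring stimulus edges as
    breakpoints, and sample densely at ``solver.sample_dt``."""
    if params is None:
        params = default_parameters()
    if solver is None:
        solver = SolverConfig()
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 < t0:
        raise ValueError("t_span must be ordered")
    y0 = np.array(initial, dtype=float)
    if t1 == t0:
        return SimulationTrace(np.array([t0]), y0[None, :], params)

    pvec = params.to_vector()
    atol = solver.atol_vector()

    edges = [t0] + [b for b in protocol.breakpoints() if t0 < b < t1] + [t1]
    ts_out = [np.array([t0])]
    ys_out = [y0[None, :]]
    y = y0
    for a, b in zip(edges, edges[1:]):
        amp = protocol.i_app(0.5 * (a + b))
        n = max(1, int(np.ceil((b - a) / solver.sample_dt)))
        t_eval = np.linspace(a, b, n + 1)

        def fun(t, yy, _amp=amp):
            return kernels.rhs(t, yy, pvec, _amp)

        sol = solve_ivp(fun, (a, b), y, method=solver.method,
                        rtol=solver.rtol, atol=atol,
                        max_step=solver.max_step, t_eval=t_eval,
                        dense_output=False)
        if not sol.success:
            raise SolverError(
                f"solver failed in segment [{a}, {b}]: {sol.message}",
                t_last=sol.t[-1] if sol.t.size else a,
                y_last=sol.y[:, -1] if sol.t.size else y)
        ts_out.append(sol.t[1:])
        ys_out.append(sol.y.T[1:])
        y = sol.y[:, -1].copy()

    t = np.concatenate(ts_out)
    ys = np.vstack(ys_out)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return SimulationTrace(t[keep], ys[keep], params)


def settle_to_rest(params: ModelParameters | None = None,
                   duration: float = 2000.0,
                   solver: SolverConfig | None = None,
                   initial: np.ndarray | None = None,
                   dvdt_tol: float = 1.0e-3) -> tuple[np.ndarray, dict]:
    """Integrate without stimulus until the membrane settles.

    Returns the final state and diagnostics including the maximum
    |dVm/dt| (mV/ms) over the final 10% of the settling window; warns if
    the model has not reached a quiescent point.
    """
    if params is None:
        params = default_parameters()
    if solver is None:
        solver = SolverConfig(sample_dt=1.0)
    if initial is None:
        initial = initial_state(params)
    trace = integrate(initial, StimulusProtocol([]), (0.0, duration),
                      params, solver)
    tail = trace.t >= duration * 0.9
    dvdt = np.gradient(trace.vm[tail], trace.t[tail])
    max_dvdt = float(np.max(np.abs(dvdt)))
    diag = {"vm_rest": float(trace.vm[-1]), "max_dvdt_tail": max_dvdt,
            "duration": duration}
    if max_dvdt > dvdt_tol:
        warnings.warn(
            f"settle_to_rest: membrane not quiescent "
            f"(max |dVm/dt| = {max_dvdt:.2e} mV/ms over final 10%)")
    return trace.y[-1].copy(), diag


@dataclass
class CellRunResult:
    """A cell-level experiment: trace plus burst/spike summary."""

    label: str
    trace: SimulationTrace
    spikes: "spike_analysis.SpikeTrain"
    bursts: "spike_analysis.BurstSegmentation"
    rest_state: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.bursts.bursts)

    @property
    def n_tonic(self) -> int:
        return len(self.bursts.tonic_spikes)


def _run_protocol(params: ModelParameters, label: str,
                  settle_duration: float = 2000.0,
                  post_duration: float = 3000.0,
                  solver: SolverConfig | None = None) -> CellRunResult:
    rest, _ = settle_to_rest(params, settle_duration)
    protocol = StimulusProtocol.control_pulse()
    t_end = STIM_ONSET + STIM_DUR + post_duration
    trace = integrate(rest, protocol, (0.0, t_end), params, solver)
    spikes = spike_analysis.detect_spikes(trace)
    bursts = spike_analysis.segment_bursts(spikes)
    return CellRunResult(label=label, trace=trace, spikes=spikes,
                         bursts=bursts, rest_state=rest)


def run_control_protocol(params: ModelParameters | None = None,
                         **kw) -> CellRunResult:
    """Control experiment: burst response followed by tonic spiking."""
    if params is None:
        params = default_parameters()
    return _run_protocol(params, "control", **kw)


def run_alpha7_removed(params: ModelParameters | None = None,
                       **kw) -> CellRunResult:
    """Same protocol with the α7 nAChR removed (expression = 0)."""
    if params is None:
        params = default_parameters()
    return _run_protocol(params.replace(expression_fraction=0.0),
                         "no-alpha7", **kw)


def run_can_knockout(params: ModelParameters | None = None,
                     **kw) -> CellRunResult:
    """Same protocol with G_CAN = 0 (repeated bursts, no tonic tail)."""
    if params is None:
        params = default_parameters()
    return _run_protocol(params.replace(G_CAN=0.0), "can-ko", **kw)


def run_store_block(params: ModelParameters | None = None, *,
                    block_ryr: bool = True, block_ip3r: bool = True,
                    **kw) -> CellRunResult:
    """Same protocol with RyR and/or IP3R release multiplied by zero."""
    from .calcium_signaling import block_store_channels
    if params is None:
        params = default_parameters()
    blocked = block_store_channels(params, block_ryr=block_ryr,
                                   block_ip3r=block_ip3r)
    return _run_protocol(blocked, "store-block", **kw)
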