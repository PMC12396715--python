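"""Minimal thalamocortical loop around the TRN cell.

The thalamo-cortical return path is abstracted to a delayed depolarizing
current pulse onto the TRN cell ("inhibitory rebound excitation").  A
recovery variable y tracks TRN output: it decays rapidly while the
membrane is above 0 mV and recovers with rate β (the GABA-response
timescale).  When y crosses below the trigger threshold a rebound pulse
is scheduled ``rebound_delay`` ms later; the scheduler then disarms until
y recovers above the threshold (one event per excursion).

Wakefulness is set by the adenosine-activated potassium leak G_KL,
spanning 0.07 (rest ≈ −64 mV, wake) to 0.21 (rest ≈ −80 mV, deep sleep).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import kernels
from .params import ModelParameters, default_parameters
from .spike_analysis import SpikeTrain, detect_spikes
from .state import IDX_Y, N_STATES
from .trn_cell import (SolverConfig, SolverError, StimulusProtocol,
                       SimulationTrace, settle_to_rest)

logger = logging.getLogger(__name__)

#: printed calibration range of the adenosine leak knob
G_KL_RANGE = (0.07, 0.21)
ADENOSINE_LEVELS = {"low": 0.07, "intermediate": 0.14, "high": 0.21}

TRIGGER_THRESHOLD = 0.9

#: network initiation pulse: depolarizing, 100 ms (ignites the loop from
#: hyperpolarized sleep states as well as from the wake state)
NETWORK_STIM_AMP = 5.0

#: default reduced sleep-axis grids (outermost to innermost)
SWEEP_ADENOSINE = (0.07, 0.14, 0.21)
SWEEP_DELAYS = (120.0, 200.0)
SWEEP_STRENGTHS = (4.0, 6.0)
SWEEP_DURATIONS = (15.0, 30.0)


@dataclass
class RecoveryState:
    y: float = 1.0
    armed: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.y <= 1.0:
            raise ValueError(f"recovery variable y={self.y} outside [0, 1]")


@dataclass
class FeedbackParams:
    """Rebound-feedback loop parameters."""

    alpha_active: float = 5.0     # 1/ms, applied while Vm > 0
    beta: float = 0.05            # 1/ms, recovery rate of y
    trigger_threshold: float = TRIGGER_THRESHOLD
    rebound_amplitude: float = 4.0  # μA/cm², depolarizing
    rebound_duration: float = 15.0  # ms
    rebound_delay: float = 120.0    # ms

    def __post_init__(self):
        if self.alpha_active < 0 or self.beta < 0:
            raise ValueError("rates must be ≥ 0")
        if not 0.0 < self.trigger_threshold < 1.0:
            raise ValueError("trigger threshold must lie in (0, 1)")
        if self.rebound_amplitude < 0:
            raise ValueError("rebound amplitude must be depolarizing (≥ 0)")


@dataclass
class AdenosineParam:
    """Adenosine-activated K leak conductance with a named level tag."""

    g_kl: float
    level: str = "custom"

    def __post_init__(self):
        lo, hi = G_KL_RANGE
        if not lo - 1e-9 <= self.g_kl <= hi + 1e-9:
            raise ValueError(
                f"G_KL={self.g_kl} outside the configured range {G_KL_RANGE}")

    @classmethod
    def from_level(cls, level: str | float) -> "AdenosineParam":
        if isinstance(level, str):
            key = {"mid": "intermediate", "normal": "low"}.get(level, level)
            if key not in ADENOSINE_LEVELS:
                raise ValueError(f"unknown adenosine level {level!r}")
            return cls(ADENOSINE_LEVELS[key], key)
        return cls(float(level))


def recovery_derivative(y: float, vm: float,
                        params: FeedbackParams) -> float:
    """dy/dt = −α·y + β·(1−y) with α active only while Vm > 0."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"recovery variable y={y} outside [0, 1]")
    alpha = params.alpha_active if vm > 0.0 else 0.0
    return -alpha * y + params.beta * (1.0 - y)


def rebound_scheduler(t: np.ndarray, y: np.ndarray,
                      params: FeedbackParams
                      ) -> list[tuple[float, float, float]]:
    """Rebound events for a sampled y trajectory.

    Returns (start, duration, amplitude) pulses: one per sub-threshold
    excursion of y (hysteresis — the scheduler disarms at a downward
    crossing and re-arms only after y recovers above the threshold).
    Overlapping events are merged with a logged warning.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time base must be strictly increasing")
    thr = params.trigger_threshold
    events: list[tuple[float, float, float]] = []
    armed = y[0] >= thr
    for i in range(1, t.size):
        if armed and y[i] < thr <= y[i - 1]:
            frac = (y[i - 1] - thr) / (y[i - 1] - y[i])
            tc = t[i - 1] + frac * (t[i] - t[i - 1])
            events.append((tc + params.rebound_delay,
                           params.rebound_duration,
                           params.rebound_amplitude))
            armed = False
        elif not armed and y[i] >= thr:
            armed = True
    return _merge_overlaps(events)


def _merge_overlaps(events):
    merged: list[tuple[float, float, float]] = []
    for start, dur, amp in sorted(events):
        if merged and start < merged[-1][0] + merged[-1][1]:
            s0, d0, a0 = merged[-1]
            end = max(s0 + d0, start + dur)
            merged[-1] = (s0, end - s0, max(a0, amp))
            logger.warning("merged overlapping rebound events at t=%.1f",
                           start)
        else:
            merged.append((start, dur, amp))
    return merged


def apply_adenosine_level(params: ModelParameters,
                          level: "AdenosineParam | str | float"
                          ) -> ModelParameters:
    """Set the TRN cell's potassium leak to the adenosine level."""
    if not isinstance(level, AdenosineParam):
        level = AdenosineParam.from_level(level)
    return params.replace(G_KL=level.g_kl)


def run_network_trial(cell_params: ModelParameters | None = None,
                      feedback: FeedbackParams | None = None,
                      adenosine: "AdenosineParam | str | float" = "low",
                      record_duration: float = 20000.0,
                      settle_duration: float = 2000.0,
                      solver: SolverConfig | None = None,
                      stim_amplitude: float = NETWORK_STIM_AMP,
                      return_trace: bool = False):
    """One network trial: settle, 100 ms initiating injection, then the
    coupled cell + recovery system with scheduled rebound pulses.

    Returns the post-stimulus :class:`SpikeTrain` (and the full trace when
    ``return_trace`` is set).
    """
    if cell_params is None:
        cell_params = default_parameters()
    if feedback is None:
        feedback = FeedbackParams()
    if solver is None:
        solver = SolverConfig(sample_dt=0.1)
    params = apply_adenosine_level(cell_params, adenosine)
    params = params.replace(fb_alpha=feedback.alpha_active,
                            fb_beta=feedback.beta)

    rest, _ = settle_to_rest(params, settle_duration)
    rest = rest.copy()
    rest[IDX_Y] = 1.0

    stim_onset, stim_dur = 100.0, 100.0
    t_end = stim_onset + stim_dur + record_duration
    pulses = [(stim_onset, stim_dur, stim_amplitude)]

    t_grid, y_grid = _integrate_with_rebounds(
        rest, params, feedback, pulses, t_end, solver)

    trace = SimulationTrace(t_grid, y_grid, params)
    spikes = detect_spikes(trace)
    post = spikes.restrict(stim_onset + stim_dur, t_end)
    if return_trace:
        return post, trace
    return post


def _integrate_with_rebounds(y0, params, feedback, pulses, t_end, solver):
    """Piecewise integration with hysteretic rebound-event detection."""
    pvec = params.to_vector()
    atol = solver.atol_vector()
    thr = feedback.trigger_threshold

    ts = [np.array([0.0])]
    ys = [np.array(y0)[None, :]]
    t = 0.0
    y = np.array(y0, dtype=float)
    armed = y[IDX_Y] >= thr
    pulses = list(pulses)

    def edges_after(t_now):
        pts = {t_end}
        for onset, dur, _ in pulses:
            if onset > t_now:
                pts.add(onset)
            if onset + dur > t_now:
                pts.add(onset + dur)
        return sorted(pts)

    def amp_at(tm):
        return sum(a for (o, d, a) in pulses if o <= tm < o + d)

    guard = 0
    while t < t_end - 1e-9:
        guard += 1
        if guard > 100000:
            raise SolverError("rebound scheduling did not terminate", t, y)
        seg_end = edges_after(t)[0]
        amp = amp_at(0.5 * (t + seg_end))

        def fun(tt, yy, _amp=amp):
            return kernels.rhs(tt, yy, pvec, _amp)

        if armed:
            def event(tt, yy):
                return yy[IDX_Y] - thr
            event.terminal = True
            event.direction = -1.0
        else:
            def event(tt, yy):
                return yy[IDX_Y] - thr
            event.terminal = True
            event.direction = 1.0

        n = max(1, int(np.ceil((seg_end - t) / solver.sample_dt)))
        t_eval = np.linspace(t, seg_end, n + 1)
        sol = solve_ivp(fun, (t, seg_end), y, method=solver.method,
                        rtol=solver.rtol, atol=atol, t_eval=t_eval,
                        events=[event], max_step=solver.max_step)
        if not sol.success:
            raise SolverError(f"network solver failed: {sol.message}",
                              sol.t[-1] if sol.t.size else t, y)
        if sol.t_events[0].size:
            tc = float(sol.t_events[0][0])
            yc = sol.y_events[0][0]
            keep = sol.t < tc
            ts.append(sol.t[keep][1:] if sol.t[keep].size else sol.t[:0])
            ys.append(sol.y.T[keep][1:] if sol.t[keep].size
                      else sol.y.T[:0])
            ts.append(np.array([tc]))
            ys.append(yc[None, :])
            if armed:
                start = tc + feedback.rebound_delay
                if feedback.rebound_amplitude > 0 and start < t_end:
                    pulses.append((start, feedback.rebound_duration,
                                   feedback.rebound_amplitude))
                armed = False
            else:
                armed = True
            t, y = tc, np.array(yc)
        else:
            ts.append(sol.t[1:])
            ys.append(sol.y.T[1:])
            t, y = seg_end, sol.y[:, -1].copy()

    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    return t_all[keep], y_all[keep]
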