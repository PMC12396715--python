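"""Run manifests, columnar trace/histogram/matrix serialization, figure
reproduction, and deterministic test-fixture generation.

All outputs are text-first: whitespace-delimited columnar files with a
commented header naming every channel, plus JSON manifests carrying the
resolved parameters, solver configuration and software version — enough
to regenerate a result directory bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .params import ModelParameters, iter_params
from .spike_analysis import (RateHistogram, SpikeTrain, log_bin_edges)
from .trn_cell import SimulationTrace, SolverConfig
from .state import STATE_NAMES


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    protocol: str
    parameters: dict
    solver: dict
    software_version: str = _version
    timestamp: str = ""
    resolved_defaults: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    @property
    def parameter_digest(self) -> str:
        blob = json.dumps(self.parameters, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        data = dataclasses.asdict(self)
        data["parameter_digest"] = self.parameter_digest
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def for_run(cls, protocol: str, params: ModelParameters,
                solver: SolverConfig | None = None,
                **defaults) -> "RunManifest":
        solver = solver or SolverConfig()
        return cls(protocol=protocol,
                   parameters=dict(iter_params(params)),
                   solver=dataclasses.asdict(solver),
                   resolved_defaults=defaults)


# ----------------------------------------------------------------------
# columnar writers / readers (lossless at written precision)
# ----------------------------------------------------------------------
def write_trace(trace: SimulationTrace, path, channels=None) -> None:
    """Columnar text: time plus state channels (and derived currents)."""
    cols = {"t_ms": trace.t}
    for name in STATE_NAMES:
        cols[name] = trace.channel(name)
    if channels:
        cur = trace.current_channels()
        for name in channels:
            cols[name] = cur[name]
    header = " ".join(cols)
    np.savetxt(path, np.column_stack(list(cols.values())),
               header=header, fmt="%.17g")


def read_trace_columns(path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    data = np.loadtxt(path, ndmin=2)
    return {name: data[:, i] for i, name in enumerate(header)}


def write_spike_train(train: SpikeTrain, path) -> None:
    np.savetxt(path, train.times,
               header=f"spike_time_ms window {train.window[0]} "
                      f"{train.window[1]}", fmt="%.17g")


def read_spike_train(path) -> SpikeTrain:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    t0, t1 = float(header[-2]), float(header[-1])
    times = np.loadtxt(path, ndmin=1)
    return SpikeTrain(times, (t0, t1))


def write_histograms(hists: list[RateHistogram | None], path) -> None:
    """Histogram matrix: first row bin edges (Hz), one row of counts per
    histogram; gaps and empty histograms are flagged in the header."""
    valid = [h for h in hists if h is not None]
    edges = valid[0].edges if valid else log_bin_edges()
    rows = []
    flags = []
    for h in hists:
        if h is None:
            rows.append(np.full(edges.size - 1, np.nan))
            flags.append("gap")
        else:
            rows.append(h.counts)
            flags.append("empty" if h.empty else "ok")
    header = ("interspike rate histograms; row0 = bin edges (Hz), "
              "rows 1.. = counts; flags: " + ",".join(flags))
    mat = np.vstack([edges[None, :],
                     np.column_stack([np.array(rows),
                                      np.full((len(rows), 1), np.nan)])]) \
        if rows else edges[None, :]
    np.savetxt(path, mat, header=header, fmt="%.17g")


def read_histograms(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline()
    flags = header.rsplit("flags: ", 1)[-1].strip().split(",") \
        if "flags:" in header else []
    data = np.loadtxt(path, ndmin=2)
    edges = data[0]
    counts = data[1:, :-1] if data.shape[0] > 1 else np.empty((0, edges.size - 1))
    return edges, counts, flags


def write_matrix(mat: np.ndarray, path, label: str = "matrix") -> None:
    np.savetxt(path, np.asarray(mat), header=label, fmt="%.17g")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)


# ----------------------------------------------------------------------
# synthetic spike-train fixtures with attached ground truth
# ----------------------------------------------------------------------
@dataclass
class FixtureSpec:
    """Planted spike structure for analysis-layer testing.

    ``bursts`` is a list of (onset ms, n_spikes, isi ms); ``tonic`` is a
    list of (onset ms, n_spikes, isi ms) appended as the tonic tail.
    Jitter (uniform, ± jitter_ms/2) is applied with the given seed.
    """

    bursts: list[tuple[float, int, float]] = field(default_factory=list)
    tonic: list[tuple[float, int, float]] = field(default_factory=list)
    jitter_ms: float = 0.0
    seed: int = 0
    window: tuple[float, float] = (0.0, 5000.0)

    def ground_truth(self) -> dict:
        return {"n_bursts": len(self.bursts),
                "n_tonic": int(sum(n for _, n, _ in self.tonic))}


def generate_fixture(spec: FixtureSpec) -> SpikeTrain:
    """Deterministic synthetic spike train matching the planted spec."""
    rng = np.random.default_rng(spec.seed)
    times = []
    for onset, n, isi in list(spec.bursts) + list(spec.tonic):
        ts = onset + np.arange(n) * isi
        if spec.jitter_ms > 0:
            ts = ts + rng.uniform(-spec.jitter_ms / 2, spec.jitter_ms / 2,
                                  size=n)
        times.extend(ts.tolist())
    times = np.sort(np.asarray(times))
    times = np.clip(times, spec.window[0], spec.window[1])
    # enforce strictly increasing times
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + 1e-6
    return SpikeTrain(times, spec.window)


def planted_trace(spike_times, window=(0.0, 1000.0), dt=0.05,
                  baseline=-69.0, peak=30.0, width_ms=1.0) -> tuple:
    """(t, vm) arrays with stereotyped triangular spikes planted at the
    given times; for spike-detector testing."""
    t = np.arange(window[0], window[1] + dt / 2, dt)
    vm = np.full(t.size, baseline)
    half = width_ms / 2
    for ts in spike_times:
        sel = np.abs(t - ts) <= half
        vm[sel] = np.maximum(vm[sel],
                             peak - (peak - baseline)
                             * np.abs(t[sel] - ts) / half)
    return t, vm


# ----------------------------------------------------------------------
# figure reproduction
# ----------------------------------------------------------------------
def reproduce_figures(which: str, out_dir,
                      params: ModelParameters | None = None) -> Path:
    """Re-run a standard experiment and render its panels.

    ``which``: one of cell-control, cell-no-alpha7, cell-store-fluxes,
    cell-store-block, sweep-reduced, correlation-reduced.
    Quantitative summaries are written alongside each figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from . import trn_cell
    from .spike_analysis import (histogram_correlation_matrix,
                                 sleep_axis_sweep)
    from .tc_network import (FeedbackParams, run_network_trial,
                             SWEEP_ADENOSINE, SWEEP_DELAYS,
                             SWEEP_STRENGTHS, SWEEP_DURATIONS)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if params is None:
        from .params import default_parameters
        params = default_parameters()

    def cell_panels(result, stem, overlay=None):
        tr = result.trace
        cur = tr.current_channels()
        fig, axes = plt.subplots(5, 1, figsize=(8, 10), sharex=True)
        axes[0].plot(tr.t, tr.vm, lw=0.5, color="C3" if overlay else "C0")
        if overlay is not None:
            axes[0].plot(overlay.trace.t, overlay.trace.vm, lw=0.5,
                         color="C0", alpha=0.7)
        axes[0].set_ylabel("Vm (mV)")
        axes[1].plot(tr.t, cur["I_T"], lw=0.5)
        axes[1].set_ylabel("I_T (μA/cm²)")
        axes[2].plot(tr.t, tr.channel("Ca_i"), lw=0.8)
        axes[2].set_ylabel("[Ca]_i (mM)")
        axes[3].plot(tr.t, tr.channel("Ca_local"), lw=0.8)
        axes[3].set_ylabel("[Ca]_local (mM)")
        axes[4].plot(tr.t, cur["J_RyR"], lw=0.8, label="RyR")
        axes[4].plot(tr.t, cur["J_IP3R"], lw=0.8, label="IP3R")
        axes[4].set_ylabel("ER flux (mM/ms)")
        axes[4].set_xlabel("time (ms)")
        axes[4].legend()
        fig.tight_layout()
        fig.savefig(out / f"{stem}.png", dpi=120)
        plt.close(fig)
        write_trace(tr, out / f"{stem}_trace.txt",
                    channels=("I_T", "J_RyR", "J_IP3R"))
        summary = {
            "n_bursts": result.n_bursts,
            "n_tonic": result.n_tonic,
            "bursts": [[b.onset, b.duration, b.n_spikes]
                       for b in result.bursts.bursts],
        }
        (out / f"{stem}_summary.json").write_text(
            json.dumps(summary, indent=2))

    if which == "cell-control":
        cell_panels(trn_cell.run_control_protocol(params), "control")
    elif which == "cell-no-alpha7":
        ctrl = trn_cell.run_control_protocol(params)
        noa7 = trn_cell.run_alpha7_removed(params)
        cell_panels(noa7, "no_alpha7", overlay=ctrl)
    elif which == "cell-store-fluxes":
        cell_panels(trn_cell.run_control_protocol(params), "store_fluxes")
    elif which == "cell-store-block":
        ctrl = trn_cell.run_control_protocol(params)
        blk = trn_cell.run_store_block(params)
        cell_panels(blk, "store_block", overlay=ctrl)
    elif which in ("sweep-reduced", "correlation-reduced"):
        def runner(g_kl, delay, strength, duration):
            fb = FeedbackParams(rebound_amplitude=strength,
                                rebound_duration=duration,
                                rebound_delay=delay)
            return run_network_trial(params, fb, g_kl,
                                     record_duration=10000.0)
        grid = sleep_axis_sweep(SWEEP_ADENOSINE, SWEEP_DELAYS,
                                SWEEP_STRENGTHS, SWEEP_DURATIONS, runner)
        write_histograms(grid.histograms, out / "histograms.txt")
        heat = grid.heatmap_matrix()
        fig, ax = plt.subplots(figsize=(8, 5))
        ax.imshow(heat.T, aspect="auto", origin="lower",
                  interpolation="nearest")
        ax.set_xlabel("sleep-axis position")
        ax.set_ylabel("rate bin (log spaced)")
        fig.savefig(out / "sleep_axis_heatmap.png", dpi=120)
        plt.close(fig)
        mat = histogram_correlation_matrix(grid)
        write_matrix(mat, out / "correlation_matrix.txt",
                     "pearson correlation of rate histograms")
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
        fig.savefig(out / "correlation_matrix.png", dpi=120)
        plt.close(fig)
    else:
        raise ValueError(f"unknown figure target {which!r}")

    RunManifest.for_run(which, params).write(out / "manifest.json")
    return out
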