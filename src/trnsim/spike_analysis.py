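"""Spike extraction, burst segmentation, interspike-rate histograms,
the sleep-axis sweep, and wake/sleep state classification.

Instantaneous rates are reciprocal interspike intervals (1000/ISI in Hz).
Histograms use logarithmically spaced bins over 0.01–380 Hz by default so
the 0.01–45 Hz zoom view is a sub-range of the same edges.  Burst
segmentation groups maximal runs of spikes whose consecutive ISIs stay
below a threshold; defaults (30 ms, ≥3 spikes) reflect intraburst rates
of roughly 40–200 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SPIKE_THRESHOLD = 0.0   # mV; consistent with the network recovery rule
REFRACTORY = 2.0        # ms
INTRA_BURST_ISI_MAX = 30.0  # ms
MIN_SPIKES_PER_BURST = 3

FULL_RANGE = (0.01, 380.0)
ZOOM_RANGE = (0.01, 45.0)
N_BINS = 60

LOW_CUTOFF_HZ = 10.0
WAKE_BAND_HZ = (15.0, 30.0)


@dataclass
class SpikeTrain:
    """Strictly increasing spike times (ms) within a recording window."""

    times: np.ndarray
    window: tuple[float, float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        t0, t1 = self.window
        if self.times.size and (self.times[0] < t0 or self.times[-1] > t1):
            raise ValueError("spike times outside the recording window")

    def __len__(self) -> int:
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def restrict(self, t0: float, t1: float) -> "SpikeTrain":
        sel = (self.times >= t0) & (self.times <= t1)
        return SpikeTrain(self.times[sel], (t0, t1))


@dataclass
class Burst:
    onset: float
    offset: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BurstSegmentation:
    bursts: list[Burst]
    tonic_spikes: np.ndarray
    isi_max: float
    min_spikes: int


@dataclass
class RateHistogram:
    """Counts of instantaneous interspike rates over fixed bin edges."""

    edges: np.ndarray   # Hz, strictly increasing
    counts: np.ndarray
    overflow: int = 0
    underflow: int = 0

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("histogram edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be ≥ 0")

    @property
    def empty(self) -> bool:
        return self.counts.sum() == 0

    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def mass_below(self, cutoff_hz: float) -> float:
        """Fraction of total counts at rates below ``cutoff_hz``."""
        total = self.counts.sum()
        if total == 0:
            return 0.0
        frac = np.clip((cutoff_hz - self.edges[:-1])
                       / np.diff(self.edges), 0.0, 1.0)
        return float((self.counts * frac).sum() / total)

    def mass_in_band(self, lo_hz: float, hi_hz: float) -> float:
        return self.mass_below(hi_hz) - self.mass_below(lo_hz)

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.copy()


def log_bin_edges(lo: float = FULL_RANGE[0], hi: float = FULL_RANGE[1],
                  n_bins: int = N_BINS) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)


def detect_spikes(trace, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = REFRACTORY) -> SpikeTrain:
    """Upward threshold crossings with linear-interpolated crossing times,
    separated by at least ``refractory`` ms."""
    t = np.asarray(trace.t if hasattr(trace, "t") else trace[0], dtype=float)
    v = np.asarray(trace.vm if hasattr(trace, "vm") else trace[1],
                   dtype=float)
    if t.size == 0:
        return SpikeTrain(np.empty(0), (0.0, 0.0))
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -np.inf
    for i in idx:
        dv = v[i + 1] - v[i]
        frac = (threshold - v[i]) / dv if dv != 0 else 0.0
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return SpikeTrain(np.asarray(times), (float(t[0]), float(t[-1])))


def segment_bursts(train: SpikeTrain,
                   intra_burst_isi_max: float = INTRA_BURST_ISI_MAX,
                   min_spikes_per_burst: int = MIN_SPIKES_PER_BURST
                   ) -> BurstSegmentation:
    """Split spikes into bursts (maximal runs of short-ISI spikes) and a
    tonic tail; every spike is assigned to exactly one of the two."""
    times = train.times
    bursts: list[Burst] = []
    tonic: list[float] = []
    if times.size == 0:
        return BurstSegmentation(bursts, np.empty(0), intra_burst_isi_max,
                                 min_spikes_per_burst)
    # split where ISI exceeds the threshold
    gaps = np.flatnonzero(np.diff(times) > intra_burst_isi_max)
    groups = np.split(times, gaps + 1)
    for grp in groups:
        if grp.size >= min_spikes_per_burst:
            bursts.append(Burst(onset=float(grp[0]), offset=float(grp[-1]),
                                n_spikes=int(grp.size)))
        else:
            tonic.extend(grp.tolist())
    return BurstSegmentation(bursts, np.asarray(tonic), intra_burst_isi_max,
                             min_spikes_per_burst)


def interspike_rate_histogram(train: SpikeTrain,
                              edges: np.ndarray | None = None
                              ) -> RateHistogram:
    """Histogram of instantaneous rates (1000/ISI, Hz).

    Rates outside the edge range are tallied in overflow/underflow
    metadata; a train with fewer than two spikes yields an empty
    (flagged) histogram.
    """
    if edges is None:
        edges = log_bin_edges()
    edges = np.asarray(edges, dtype=float)
    if len(train) < 2:
        return RateHistogram(edges, np.zeros(edges.size - 1))
    rates = 1000.0 / train.isis()
    counts, _ = np.histogram(rates, bins=edges)
    return RateHistogram(
        edges, counts,
        overflow=int((rates >= edges[-1]).sum()),
        underflow=int((rates < edges[0]).sum()))


def classify_state(h: RateHistogram, low_cutoff: float = LOW_CUTOFF_HZ,
                   wake_band: tuple[float, float] = WAKE_BAND_HZ,
                   eps: float = 0.01) -> str:
    """Label a histogram wake-like, sleep-like, or indeterminate.

    Wake-like: at most ``eps`` of the mass below ``low_cutoff`` and the
    dominant mass inside the wake band.  Sleep-like: more than ``eps``
    below the cutoff (slow interburst components present).
    """
    if h.empty:
        return "indeterminate"
    low_mass = h.mass_below(low_cutoff)
    if low_mass > eps:
        return "sleep-like"
    band_mass = h.mass_in_band(*wake_band)
    if band_mass >= 0.5:
        return "wake-like"
    return "indeterminate"


@dataclass
class SleepAxisGrid:
    """Histograms ordered along the sleep axis.

    The nesting order, outermost to innermost, is adenosine level,
    rebound delay, rebound strength, rebound duration; the flattened
    position is the sleep-axis coordinate.
    """

    param_tuples: list[tuple]
    histograms: list[RateHistogram | None]
    nesting: tuple[str, ...] = ("adenosine", "delay", "strength", "duration")
    spike_trains: list[SpikeTrain | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.param_tuples)

    def heatmap_matrix(self, normalized: bool = True) -> np.ndarray:
        """(n_tuples, n_bins) matrix of histogram rows; gaps are NaN."""
        n_bins = next(h.counts.size for h in self.histograms
                      if h is not None)
        out = np.full((len(self), n_bins), np.nan)
        for i, h in enumerate(self.histograms):
            if h is not None:
                out[i] = h.normalized() if normalized else h.counts
        return out

    def third(self, which: int) -> list[int]:
        """Indices of the first (0), middle (1) or last (2) third."""
        n = len(self)
        lo = which * n // 3
        hi = (which + 1) * n // 3
        return list(range(lo, hi))


def sleep_axis_sweep(adenosine_levels: Sequence[float],
                     rebound_delays: Sequence[float],
                     rebound_strengths: Sequence[float],
                     rebound_durations: Sequence[float],
                     runner: Callable[[float, float, float, float],
                                      SpikeTrain],
                     edges: np.ndarray | None = None,
                     keep_trains: bool = False) -> SleepAxisGrid:
    """Run one network trial per parameter tuple in nested sleep-axis
    order and collect the interspike-rate histograms.

    A failed trial records a gap (``None``) without aborting the sweep.
    """
    if min(map(len, (adenosine_levels, rebound_delays, rebound_strengths,
                     rebound_durations))) == 0:
        raise ValueError("all parameter grids must be non-empty")
    if edges is None:
        edges = log_bin_edges()
    tuples, hists, trains = [], [], []
    for g_kl in adenosine_levels:
        for delay in rebound_delays:
            for strength in rebound_strengths:
                for duration in rebound_durations:
                    tuples.append((g_kl, delay, strength, duration))
                    try:
                        train = runner(g_kl, delay, strength, duration)
                        hists.append(
                            interspike_rate_histogram(train, edges))
                        trains.append(train if keep_trains else None)
                    except Exception:
                        logger.exception(
                            "network trial failed for %s", tuples[-1])
                        hists.append(None)
                        trains.append(None)
    return SleepAxisGrid(tuples, hists, spike_trains=trains)


def histogram_correlation_matrix(grid: SleepAxisGrid | Sequence[RateHistogram]
                                 ) -> np.ndarray:
    """Pearson correlation between histogram count vectors.

    Symmetric with unit diagonal.  Zero-variance histograms and sweep
    gaps yield NaN off-diagonal entries (flagged, excluded from block
    summaries).
    """
    hists = grid.histograms if isinstance(grid, SleepAxisGrid) else list(grid)
    valid = [h for h in hists if h is not None]
    if len(valid) < 2:
        raise ValueError("need at least two histograms")
    edges0 = valid[0].edges
    for h in valid[1:]:
        if h.edges.shape != edges0.shape or not np.allclose(h.edges, edges0):
            raise ValueError("histograms must share identical bin edges")
    n = len(hists)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    counts = [None if h is None else h.counts.astype(float) for h in hists]
    stds = [None if c is None else c.std() for c in counts]
    for i in range(n):
        if counts[i] is None or stds[i] == 0:
            continue
        for j in range(i + 1, n):
            if counts[j] is None or stds[j] == 0:
                continue
            r = np.corrcoef(counts[i], counts[j])[0, 1]
            mat[i, j] = mat[j, i] = r
    return mat


def block_mean_correlation(mat: np.ndarray, rows: Sequence[int],
                           cols: Sequence[int]) -> float:
    """Mean off-diagonal correlation between two index blocks,
    ignoring NaN sentinels."""
    vals = []
    for i in rows:
        for j in cols:
            if i != j and np.isfinite(mat[i, j]):
                vals.append(mat[i, j])
    return float(np.mean(vals)) if vals else np.nan


def compare_expression_levels(sweeps: dict[float, SleepAxisGrid],
                              low_cutoff: float = LOW_CUTOFF_HZ,
                              eps: float = 0.01) -> dict[float, dict]:
    """Per expression level, the fraction of low-adenosine tuples that are
    sleep-like, plus the mean wake-band mass — summarizing the drift of
    the wake island as expression falls."""
    out = {}
    for expr, grid in sorted(sweeps.items()):
        idx = grid.third(0)
        hists = [grid.histograms[i] for i in idx
                 if grid.histograms[i] is not None]
        labels = [classify_state(h, low_cutoff=low_cutoff, eps=eps)
                  for h in hists]
        sleep_frac = (np.mean([lb == "sleep-like" for lb in labels])
                      if labels else np.nan)
        wake_mass = (np.mean([h.mass_in_band(*WAKE_BAND_HZ) for h in hists])
                     if hists else np.nan)
        low_mass = (np.mean([h.mass_below(low_cutoff) for h in hists])
                    if hists else np.nan)
        out[expr] = {"sleep_like_fraction": float(sleep_frac),
                     "wake_band_mass": float(wake_mass),
                     "low_freq_mass": float(low_mass),
                     "n": len(hists)}
    return out
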