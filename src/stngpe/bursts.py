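"""LFP burst detection and burst-length statistics.

The order-parameter trace R(t) tracks the LFP amplitude envelope closely, so
bursts of elevated synchrony are detected on R(t): the trace is smoothed by
a centered 400 ms moving average evaluated every 10 ms, dual thresholds are
set at the 75th (upper) and 65th (lower) empirical percentiles of the
smoothed trace over the analysis window, and a burst runs from an upward
crossing of the upper threshold to the next downward crossing of the lower
one.  Bursts touching the window edges are discarded rather than censored.

Statistics reported per condition: mean and median burst length, the
fraction of bursts shorter than a cutoff (default 5 s), and a histogram.
Between-condition comparisons use the two-sided Mann-Whitney U rank test
(an exact permutation variant is available for small samples), appropriate
for the right-skewed length distributions bursting produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "BurstStats",
    "smooth_trace",
    "percentile_thresholds",
    "detect_lfp_bursts",
    "burst_statistics",
    "compare_burst_lengths",
]


@dataclass
class BurstStats:
    """Burst intervals and summary statistics (lengths in the time unit of
    the input trace; seconds in the standard pipeline)."""

    intervals: List[Tuple[float, float]] = field(default_factory=list)
    mean: Optional[float] = None
    median: Optional[float] = None
    fraction_short: Optional[float] = None
    cutoff: float = 5.0
    hist_counts: Optional[np.ndarray] = None
    hist_edges: Optional[np.ndarray] = None

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray([b - a for a, b in self.intervals])

    @property
    def n_bursts(self) -> int:
        return len(self.intervals)


def smooth_trace(trace: np.ndarray, dt: float, window: float = 400.0,
                 step: float = 10.0) -> Tuple[np.ndarray, np.ndarray]:
    """Centered moving average over ``window`` ms evaluated every ``step`` ms.

    ``dt`` is the sampling interval of ``trace`` in ms (must be <= step).
    Returns ``(times, smoothed)`` with times relative to the trace start.
    """
    trace = np.asarray(trace, dtype=float)
    if dt > step:
        raise ValueError("trace must be sampled at least as finely as the step")
    w = int(round(window / dt))
    if w < 1 or trace.size < w:
        raise ValueError("trace shorter than the smoothing window")
    kernel = np.ones(w) / w
    sm_full = np.convolve(trace, kernel, mode="valid")   # centered average
    t_full = (np.arange(sm_full.size) + (w - 1) / 2.0) * dt
    stride = max(1, int(round(step / dt)))
    return t_full[::stride], sm_full[::stride]


def percentile_thresholds(trace: np.ndarray, window_start: int = 0,
                          upper_pct: float = 75.0,
                          lower_pct: float = 65.0) -> Tuple[float, float]:
    """Empirical (linear-interpolation) percentiles of the smoothed trace
    from ``window_start`` (sample index) onward."""
    t = np.asarray(trace, dtype=float)[window_start:]
    if t.size == 0:
        raise ValueError("empty analysis window")
    upper = float(np.percentile(t, upper_pct))
    lower = float(np.percentile(t, lower_pct))
    return upper, lower


def detect_lfp_bursts(times: np.ndarray, smoothed: np.ndarray,
                      upper: float, lower: float) -> List[Tuple[float, float]]:
    """Burst intervals from dual-threshold crossing of the smoothed trace.

    A burst opens at an upward crossing of ``upper`` while no burst is open
    and closes at the next downward crossing of ``lower``.  A burst already
    open at the first sample, or still open at the last, is discarded.
    """
    if upper < lower:
        raise ValueError("upper threshold must be >= lower threshold")
    times = np.asarray(times, dtype=float)
    x = np.asarray(smoothed, dtype=float)
    intervals: List[Tuple[float, float]] = []
    in_burst = x[0] >= upper      # a burst open at start will be discarded
    discard_first = in_burst
    onset = times[0]
    for i in range(1, x.size):
        if not in_burst and x[i - 1] < upper <= x[i]:
            in_burst = True
            onset = times[i]
        elif in_burst and x[i - 1] >= lower > x[i]:
            in_burst = False
            if discard_first:
                discard_first = False
            else:
                intervals.append((onset, times[i]))
    return intervals            # a burst still open at the end is dropped


def burst_statistics(intervals: List[Tuple[float, float]], cutoff: float = 5.0,
                     bin_width: float = 1.0) -> BurstStats:
    """Mean/median length, fraction shorter than ``cutoff`` and a histogram.

    With no bursts the statistics are left undefined (None), not zero.
    """
    stats_out = BurstStats(intervals=list(intervals), cutoff=cutoff)
    if not intervals:
        return stats_out
    lengths = stats_out.lengths
    if np.any(lengths <= 0):
        raise ValueError("burst offsets must exceed onsets")
    stats_out.mean = float(lengths.mean())
    stats_out.median = float(np.median(lengths))
    stats_out.fraction_short = float(np.mean(lengths < cutoff))
    edges = np.arange(0.0, lengths.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(lengths, bins=edges)
    stats_out.hist_counts, stats_out.hist_edges = counts, edges
    return stats_out


def compare_burst_lengths(lengths_a, lengths_b, method: str = "mannwhitney") -> float:
    """Two-sided p-value for a difference between two burst-length samples.

    ``method='mannwhitney'`` uses the rank-based Mann-Whitney U test;
    ``method='permutation'`` enumerates an exact permutation distribution of
    the mean difference (small samples only).
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if method == "permutation":
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        n_a, total = a.size, pooled.size
        count = hits = 0
        for idx in combinations(range(total), n_a):
            mask = np.zeros(total, dtype=bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            hits += diff >= observed - 1e-12
            count += 1
        return hits / count
    raise ValueError(f"unknown method {method!r}")
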