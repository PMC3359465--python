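"""Dwell-time series: summary statistics, log-binned residence-time
histograms, and the chi-square figures used by the model-fit error.

A dwell series is the run-length encoding of a dichotomous gating trace:
ordered, strictly alternating (state, duration) events whose durations sum
to the trace length.  Durations are kept in steps; one step is ``dt``
seconds (5e-5 s for 20 kHz recordings), so milliseconds are recovered as
``steps * dt * 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_models import OPEN, GatingTrace

__all__ = [
    "DwellSeries",
    "DwellHistogram",
    "TailFitComparison",
    "open_probability",
    "mean_dwell",
    "dwell_histogram",
    "replicate_histogram",
    "chi2_exp",
    "chi2_sim",
    "tail_fit_comparison",
]


@dataclass
class DwellSeries:
    """Ordered alternating dwell events extracted from one trace."""

    states: np.ndarray      # int8, strictly alternating 0/1
    durations: np.ndarray   # int64 steps, all >= 1
    dt: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=np.int64)
        if len(self.states) != len(self.durations) or len(self.states) == 0:
            raise ValueError("states/durations must be equal-length, non-empty")
        if (self.durations < 1).any():
            raise ValueError("durations must be >= 1 step")
        if len(self.states) > 1 and (self.states[1:] == self.states[:-1]).any():
            raise ValueError("states must alternate")

    def __len__(self) -> int:
        return len(self.states)

    def of_state(self, state: int) -> np.ndarray:
        """Durations (steps) of all events in one state."""
        return self.durations[self.states == state]

    @property
    def durations_ms(self) -> np.ndarray:
        return self.durations * (self.dt * 1e3)


@dataclass
class DwellHistogram:
    """Normalized residence-time distribution on logarithmic bins.

    ``p`` is probability mass per bin (not density); ``sd`` holds the
    per-bin replicate standard deviation when aggregated from several
    series.
    """

    edges_ms: np.ndarray
    p: np.ndarray
    state: int
    sd: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.edges_ms = np.asarray(self.edges_ms, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.edges_ms) != len(self.p) + 1:
            raise ValueError("need len(edges) == len(p) + 1")
        if (np.diff(self.edges_ms) <= 0).any():
            raise ValueError("edges must increase strictly")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError("bin probabilities must sum to 1")

    @property
    def centers_ms(self) -> np.ndarray:
        """Geometric bin centres."""
        return np.sqrt(self.edges_ms[:-1] * self.edges_ms[1:])

    @property
    def widths_ms(self) -> np.ndarray:
        return np.diff(self.edges_ms)


def open_probability(gt: GatingTrace) -> float:
    """Fraction of samples spent in the open state."""
    return float(np.mean(gt.states == OPEN))


def mean_dwell(ds: DwellSeries, state: int) -> float:
    """Arithmetic mean dwell time of one state, in milliseconds."""
    dur = ds.of_state(state)
    if dur.size == 0:
        raise ValueError(f"no events in state {state}")
    return float(dur.mean() * ds.dt * 1e3)


def _log_edges(dur_ms: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(dur_ms.min()), float(dur_ms.max())
    if lo == hi:
        hi = lo * 1.0001 + 1e-12
    # nudge the top edge so the maximum falls inside the last bin
    return np.geomspace(lo, hi * (1 + 1e-9), n_bins + 1)


def dwell_histogram(ds: DwellSeries, state: int, n_bins: int = 20,
                    edges_ms: Optional[np.ndarray] = None) -> DwellHistogram:
    """Log-binned dwell-time distribution of one state, normalized to
    probability mass per bin."""
    dur_ms = ds.of_state(state) * (ds.dt * 1e3)
    if dur_ms.size == 0:
        raise ValueError(f"no events in state {state}")
    if edges_ms is None:
        edges_ms = _log_edges(dur_ms, n_bins)
    counts, edges_ms = np.histogram(dur_ms, bins=edges_ms)
    if counts.sum() == 0:
        raise ValueError("all events fall outside the supplied edges")
    p = counts / counts.sum()
    return DwellHistogram(edges_ms, p, state=state, counts=counts)


def replicate_histogram(series: Sequence[DwellSeries], state: int,
                        n_bins: int = 20,
                        edges_ms: Optional[np.ndarray] = None) -> DwellHistogram:
    """Aggregate >= 2 replicate series on shared bins: mean probability per
    bin with the per-bin population SD (the delta_i of the chi-square)."""
    if len(series) < 2:
        raise ValueError("need at least 2 replicate series")
    if edges_ms is None:
        pooled = np.concatenate([ds.of_state(state) * (ds.dt * 1e3)
                                 for ds in series])
        edges_ms = _log_edges(pooled, n_bins)
    hists = [dwell_histogram(ds, state, edges_ms=edges_ms) for ds in series]
    pmat = np.array([h.p for h in hists])
    p_mean = pmat.mean(axis=0)
    p_mean = p_mean / p_mean.sum()
    return DwellHistogram(edges_ms, p_mean, state=state,
                          sd=pmat.std(axis=0),
                          counts=np.sum([h.counts for h in hists], axis=0))


def _check_shared_bins(a: DwellHistogram, b: DwellHistogram) -> None:
    if len(a.p) != len(b.p) or not np.allclose(a.edges_ms, b.edges_ms):
        raise ValueError("histograms must share bin edges")


def chi2_exp(hists: Sequence[DwellHistogram]) -> float:
    """Replicate scatter: mean over bins of the squared per-bin SD of the
    replicate probabilities."""
    if len(hists) < 2:
        raise ValueError("need >= 2 replicate histograms")
    for h in hists[1:]:
        _check_shared_bins(hists[0], h)
    pmat = np.array([h.p for h in hists])
    return float(np.mean(pmat.std(axis=0) ** 2))


def chi2_sim(exp_hist: DwellHistogram, sim_hist: DwellHistogram) -> float:
    """Model mismatch: mean over bins of the squared probability
    difference between the reference and simulated histograms."""
    _check_shared_bins(exp_hist, sim_hist)
    return float(np.mean((exp_hist.p - sim_hist.p) ** 2))


# -- qualitative distribution shape ----------------------------------------

@dataclass
class TailFitComparison:
    """Least-squares comparison of power-law vs single-exponential decay on
    a log-binned dwell density."""

    r2_power: float
    r2_exponential: float
    n_points: int
    region: str

    @property
    def winner(self) -> str:
        return "power" if self.r2_power > self.r2_exponential else "exponential"


def tail_fit_comparison(ds: DwellSeries, state: int, *, n_bins: int = 30,
                        region: str = "tail", min_count: int = 6,
                        tail_start: float = 1.0) -> TailFitComparison:
    """Decide whether a dwell distribution decays like a power law or like a
    single exponential.

    The dwell density (probability mass / bin width on log-spaced bins) is
    fitted by straight lines in log-density space against ``log t`` (power
    law) and against ``t`` (exponential); the larger r-squared wins.
    ``region="full"`` uses every adequately populated bin, ``region="tail"``
    only bins beyond ``tail_start`` times the mean dwell time.
    """
    if region not in ("tail", "full"):
        raise ValueError("region must be 'tail' or 'full'")
    dur = ds.of_state(state).astype(float)
    if dur.size < 100:
        raise ValueError("too few events for a shape comparison")
    edges = np.geomspace(dur.min(), dur.max() * (1 + 1e-9), n_bins + 1)
    counts, edges = np.histogram(dur, bins=edges)
    dens = counts / counts.sum() / np.diff(edges)
    t = np.sqrt(edges[:-1] * edges[1:])
    keep = counts >= min_count
    if region == "tail":
        keep &= t > tail_start * dur.mean()
    t, dens = t[keep], dens[keep]
    if t.size < 5:
        raise ValueError("fewer than 5 usable bins in the requested region")
    logd = np.log(dens)

    def _r2(x: np.ndarray) -> float:
        coef = np.polyfit(x, logd, 1)
        resid = logd - np.polyval(coef, x)
        return float(1 - np.sum(resid ** 2) / np.sum((logd - logd.mean()) ** 2))

    return TailFitComparison(r2_power=_r2(np.log(t)), r2_exponential=_r2(t),
                             n_points=t.size, region=region)
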