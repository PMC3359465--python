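"""Rescaled-range (R/S) analysis of dwell-time sequences.

The input series is the temporally ordered sequence of alternating open and
closed dwell durations.  For a window of size ``w`` the series is split into
disjoint blocks; within each block the mean-adjusted cumulative sum is
formed, its range R (max - min) is divided by the block standard deviation
S, and R/S is averaged over blocks.  The Hurst exponent H is the
least-squares slope of ``log <R/S>`` against ``log w`` over geometric window
sizes (powers of two from 8 up to a quarter of the series length).

H = 0.5 marks a memoryless series; H > 0.5 persistent, trend-reinforcing
behaviour.  The plain estimator carries a small positive bias at finite
sample sizes (roughly +0.02..+0.05 here); the optional Anis-Lloyd
correction removes the i.i.d. expectation of R/S before regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["RSResult", "rescaled_range", "hurst_exponent", "shuffle_control"]


@dataclass
class RSResult:
    """Hurst estimate with its regression diagnostics."""

    h: float
    r2: float
    points: np.ndarray   # (k, 2) array of (log window, log mean R/S)
    n_events: int
    corrected: bool = False


def rescaled_range(x: np.ndarray, w: int) -> float:
    """Mean R/S over the disjoint windows of size ``w``.

    Windows with zero variance are skipped; if every window is degenerate a
    ``ValueError`` is raised.
    """
    x = np.asarray(x, dtype=float)
    if w < 4:
        raise ValueError("window size must be >= 4")
    m = len(x) // w
    if m < 1:
        raise ValueError("series shorter than one window")
    seg = x[: m * w].reshape(m, w)
    dev = seg - seg.mean(axis=1, keepdims=True)
    z = np.cumsum(dev, axis=1)
    r = z.max(axis=1) - z.min(axis=1)
    s = seg.std(axis=1)
    ok = s > 0
    if not ok.any():
        raise ValueError("all windows have zero variance")
    return float(np.mean(r[ok] / s[ok]))


def _expected_rs(w: int) -> float:
    """Anis-Lloyd expectation of R/S for an i.i.d. series of length w."""
    i = np.arange(1, w)
    tail = np.sum(np.sqrt((w - i) / i))
    if w <= 340:
        front = np.exp(gammaln((w - 1) / 2) - gammaln(w / 2)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(w * np.pi / 2)
    return front * tail * (w - 0.5) / w


def hurst_exponent(x: np.ndarray, *, min_window: int = 8,
                   corrected: bool = False) -> RSResult:
    """Estimate H from the log-log regression of mean R/S on window size.

    Window sizes are powers of two from ``min_window`` up to ``len(x) // 4``
    so that every size contributes at least four disjoint windows.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 64:
        raise ValueError("need at least 64 events for a Hurst estimate")
    ws, rs = [], []
    w = min_window
    while w <= n // 4:
        try:
            rs_w = rescaled_range(x, w)
        except ValueError:
            w *= 2
            continue
        if rs_w > 0:
            ws.append(w)
            rs.append(rs_w)
        w *= 2
    if len(ws) < 2:
        raise ValueError("not enough valid window sizes")
    if len(ws) < 4:
        warnings.warn("fewer than 4 window sizes; H estimate is fragile",
                      stacklevel=2)
    lw = np.log(np.asarray(ws, dtype=float))
    lr = np.log(np.asarray(rs, dtype=float))
    if corrected:
        lr = lr - np.log([_expected_rs(w) for w in ws])
    slope, intercept = np.polyfit(lw, lr, 1)
    resid = lr - (slope * lw + intercept)
    sst = np.sum((lr - lr.mean()) ** 2)
    r2 = float(1 - np.sum(resid ** 2) / sst) if sst > 0 else 0.0
    h = float(slope) + (0.5 if corrected else 0.0)
    if not 0 <= h <= 1:
        warnings.warn(f"H = {h:.3f} outside [0, 1]", stacklevel=2)
    return RSResult(h=h, r2=r2, points=np.column_stack([lw, lr]),
                    n_events=n, corrected=corrected)


def shuffle_control(x: np.ndarray, seed=0, **kwargs) -> RSResult:
    """Hurst estimate of a uniformly shuffled copy of the series.

    Shuffling preserves the value distribution but destroys temporal order,
    so a genuinely long-memory series drops to H close to 0.5 once
    shuffled, while a memoryless series is unaffected.
    """
    rng = np.random.default_rng(seed)
    return hurst_exponent(rng.permutation(np.asarray(x, dtype=float)),
                          **kwargs)
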