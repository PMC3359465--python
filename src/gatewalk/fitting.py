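"""Composite model-fit error and its coordinate-descent optimization.

A candidate configuration is scored against reference (experimental or
experiment-like) gating statistics through four relative-error terms: the
Hurst exponent, the open probability, and the chi-square figures of the
open and closed dwell-time histograms.  The total error is their sum; a fit
is accepted when every term is below 5 % and the sum below 10 %.

The objective is stochastic (each evaluation simulates), so evaluations
average several seeded runs with common random numbers, and the optimizer
is a derivative-free coordinate descent with a multiplicatively shrinking
step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_models import CLOSED, OPEN, ModelConfig, simulate
from .dwell_stats import (DwellHistogram, DwellSeries, chi2_exp, chi2_sim,
                          dwell_histogram, replicate_histogram)
from .event_detection import extract_dwells
from .hurst_rs import hurst_exponent

__all__ = [
    "FitSummary",
    "ReferenceTargets",
    "ErrorBreakdown",
    "OptimizeResult",
    "error_terms",
    "accept",
    "reference_targets_from_series",
    "evaluate_config",
    "optimize",
]


@dataclass
class FitSummary:
    """The four statistics entering the error functional."""

    h: float
    p_open: float
    chi2_open: float
    chi2_closed: float
    provenance: str = ""


@dataclass
class ReferenceTargets:
    """Reference summary plus the histograms simulated candidates are
    binned against."""

    summary: FitSummary
    open_hist: DwellHistogram
    closed_hist: DwellHistogram


@dataclass
class ErrorBreakdown:
    e_h: float
    e_pop: float
    e_dw_open: float
    e_dw_closed: float

    @property
    def e_total(self) -> float:
        return self.e_h + self.e_pop + self.e_dw_open + self.e_dw_closed

    def terms(self) -> Tuple[float, float, float, float]:
        return (self.e_h, self.e_pop, self.e_dw_open, self.e_dw_closed)


def _rel(name: str, ref: float, sim: float) -> float:
    if ref == 0:
        raise ValueError(f"reference {name} is zero; relative error undefined")
    return abs(ref - sim) / abs(ref)


def error_terms(exp: FitSummary, sim: FitSummary) -> ErrorBreakdown:
    """Absolute relative deviation of each statistic, simulated vs
    reference."""
    return ErrorBreakdown(
        e_h=_rel("H", exp.h, sim.h),
        e_pop=_rel("p_open", exp.p_open, sim.p_open),
        e_dw_open=_rel("chi2_open", exp.chi2_open, sim.chi2_open),
        e_dw_closed=_rel("chi2_closed", exp.chi2_closed, sim.chi2_closed),
    )


def accept(e: ErrorBreakdown, *, term_tol: float = 0.05,
           total_tol: float = 0.10) -> bool:
    """Stopping rule: every term under 5 % and the sum under 10 %."""
    return all(t < term_tol for t in e.terms()) and e.e_total < total_tol


# -- building summaries from data -------------------------------------------


def _dwell_series(cfg: ModelConfig, n_steps: int, seed) -> DwellSeries:
    return extract_dwells(simulate(cfg, n_steps, seed))


def reference_targets_from_series(series: Sequence[DwellSeries],
                                  n_bins: int = 20,
                                  provenance: str = "replicates"
                                  ) -> ReferenceTargets:
    """Summarize >= 2 replicate dwell series into fitting targets.

    H and the open probability are replicate means; the chi-square figures
    are the replicate-scatter statistics of the per-state histograms.
    """
    hs = [hurst_exponent(ds.durations).h for ds in series]
    po = [float(np.sum(ds.of_state(OPEN)) / np.sum(ds.durations))
          for ds in series]
    open_hist = replicate_histogram(series, OPEN, n_bins=n_bins)
    closed_hist = replicate_histogram(series, CLOSED, n_bins=n_bins)
    reps_open = [dwell_histogram(ds, OPEN, edges_ms=open_hist.edges_ms)
                 for ds in series]
    reps_closed = [dwell_histogram(ds, CLOSED, edges_ms=closed_hist.edges_ms)
                   for ds in series]
    summary = FitSummary(h=float(np.mean(hs)), p_open=float(np.mean(po)),
                         chi2_open=chi2_exp(reps_open),
                         chi2_closed=chi2_exp(reps_closed),
                         provenance=provenance)
    return ReferenceTargets(summary, open_hist, closed_hist)


def evaluate_config(cfg: ModelConfig, ref: ReferenceTargets, *,
                    n_steps: int = 200_000, seeds: Sequence = (0, 1, 2)
                    ) -> Tuple[FitSummary, ErrorBreakdown]:
    """Simulate a candidate configuration and score it against the
    reference targets."""
    hs, po = [], []
    p_open_bins, p_closed_bins = [], []
    for seed in seeds:
        ds = _dwell_series(cfg, n_steps, seed)
        hs.append(hurst_exponent(ds.durations).h)
        po.append(float(np.sum(ds.of_state(OPEN)) / np.sum(ds.durations)))
        p_open_bins.append(
            dwell_histogram(ds, OPEN, edges_ms=ref.open_hist.edges_ms).p)
        p_closed_bins.append(
            dwell_histogram(ds, CLOSED, edges_ms=ref.closed_hist.edges_ms).p)
    sim_open = DwellHistogram(ref.open_hist.edges_ms,
                              _renorm(np.mean(p_open_bins, axis=0)), OPEN)
    sim_closed = DwellHistogram(ref.closed_hist.edges_ms,
                                _renorm(np.mean(p_closed_bins, axis=0)), CLOSED)
    summary = FitSummary(h=float(np.mean(hs)), p_open=float(np.mean(po)),
                         chi2_open=chi2_sim(ref.open_hist, sim_open),
                         chi2_closed=chi2_sim(ref.closed_hist, sim_closed),
                         provenance=f"simulation model {cfg.model_id}")
    return summary, error_terms(ref.summary, summary)


def _renorm(p: np.ndarray) -> np.ndarray:
    s = p.sum()
    return p / s if s > 0 else p


# -- the chi-square reference trick -----------------------------------------
# The published error compares the reference's replicate-scatter chi-square
# with the candidate's mismatch chi-square; both are computed on the
# reference bin edges so the two are commensurable.


@dataclass
class OptimizeResult:
    config: ModelConfig
    breakdown: ErrorBreakdown
    accepted: bool
    n_evaluations: int
    history: List[Tuple[Dict[str, float], float]]


_TUNABLES = {
    1: ("u_barrier", "t_b", "f_d"),
    2: ("u_barrier", "t_df", "tp"),
}
_INTEGER_PARAMS = {"t_b", "t_df", "tp"}


def _get(cfg: ModelConfig, name: str) -> float:
    return getattr(cfg, name)


def _set(cfg: ModelConfig, name: str, value: float) -> Optional[ModelConfig]:
    if name in _INTEGER_PARAMS:
        value = int(round(value))
    try:
        return replace(cfg, **{name: value})
    except ValueError:
        return None  # violates config invariants -> rejected move


def optimize(cfg0: ModelConfig, exp: ReferenceTargets, budget: int = 100, *,
             tunables: Optional[Sequence[str]] = None,
             n_steps: int = 200_000, seeds: Sequence = (0, 1, 2),
             step_frac: float = 0.10, shrink: float = 0.5,
             min_step_frac: float = 0.01) -> OptimizeResult:
    """Finite-difference coordinate descent on the total error.

    Each tunable is perturbed up and down by a relative step (an absolute
    step of ``step_frac`` reference units for parameters whose start value
    is zero); any move lowering the best-so-far total error is kept.  When
    a full sweep yields no improvement the steps shrink by ``shrink``.
    Stops on :func:`accept`, on step underflow, or after ``budget``
    objective evaluations.  Returns the best configuration seen.
    """
    names = list(tunables if tunables is not None
                 else _TUNABLES[cfg0.model_id])
    steps = {}
    for name in names:
        v = abs(_get(cfg0, name))
        steps[name] = step_frac * v if v > 0 else step_frac * _default_scale(name)

    best_cfg = cfg0
    _, best_e = evaluate_config(cfg0, exp, n_steps=n_steps, seeds=seeds)
    evals = 1
    history = [({n: _get(cfg0, n) for n in names}, best_e.e_total)]
    while evals < budget and not accept(best_e):
        improved = False
        for name in names:
            if evals >= budget or accept(best_e):
                break
            for sign in (+1, -1):
                if evals >= budget:
                    break
                cand = _set(best_cfg, name,
                            _get(best_cfg, name) + sign * steps[name])
                if cand is None:
                    continue
                if name in _INTEGER_PARAMS and _get(cand, name) == _get(best_cfg, name):
                    continue
                _, e = evaluate_config(cand, exp, n_steps=n_steps, seeds=seeds)
                evals += 1
                history.append(({n: _get(cand, n) for n in names}, e.e_total))
                if e.e_total < best_e.e_total:
                    best_cfg, best_e = cand, e
                    improved = True
                    break
        if not improved:
            for name in names:
                steps[name] *= shrink
            scale = max(abs(_get(cfg0, n)) or _default_scale(n)
                        for n in names)
            if max(steps.values()) < min_step_frac * step_frac * scale:
                break
    return OptimizeResult(config=best_cfg, breakdown=best_e,
                          accepted=accept(best_e), n_evaluations=evals,
                          history=history)


def _default_scale(name: str) -> float:
    return {"f_d": 0.4, "tp": 7.0, "u_barrier": 1.0,
            "t_b": 600.0, "t_df": 1200.0}.get(name, 1.0)
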