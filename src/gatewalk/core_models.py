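"""Lattice random-walk engines for channel-gate dynamics with a slow,
synchronized modulation.

The gate's conformational coordinate (reaction coordinate, RC) performs a
discrete random walk on integer lattice nodes.  A threshold point (TP)
separates closed (RC < TP) from open (RC > TP) manifolds; the TP node itself
carries the peak of a small tent-shaped activation barrier and is not
occupiable, so the jump TP-1 <-> TP+1 crosses the barrier.  Two variants of
the slow process that endows the dwell-time series with long-term memory are
implemented:

* **Model 1** — the reflecting boundaries ``(-b, +b)`` of the conformational
  space perform their own unbiased random walk, synchronized in direction
  (both half-spaces shrink or grow together), one boundary move every
  ``t_b`` RC steps.  A constant drift force ``f_d`` (kT/rcu, the same slope
  on both sides of the barrier) models sensor bias: positive ``f_d`` tilts
  the landscape toward closed states.

* **Model 2** — boundaries are fixed and a drift slope ``A`` fluctuates
  instead, by ``+/- drift_step`` every ``t_df`` RC steps, reflected at
  ``+/- drift_max``.  The outer slopes are antisymmetric about TP (``+A``
  left of the barrier, ``-A`` right of it), so positive ``A`` pushes the RC
  away from the threshold on both sides and negative ``A`` pulls it in.
  Sensor bias is modelled by shifting TP off-centre.

Single-step hop probabilities follow the small-gradient diffusion rule
``p = 1/2 - dU/4kT``, ``q = 1/2 + dU/4kT`` with ``dU`` the potential
difference across one lattice step centred on the current node.  One step
corresponds to ``dt`` seconds (default 5e-5 s, i.e. 20 kHz sampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from ._kernels import sim_model1, sim_model2

__all__ = [
    "ModelConfig",
    "WalkerState",
    "GatingTrace",
    "ConfigError",
    "potential_m1",
    "potential_m2",
    "step_probabilities",
    "move_probability",
    "update_boundaries_m1",
    "update_drift_m2",
    "simulate",
]

CLOSED, OPEN = 0, 1


class ConfigError(ValueError):
    """Raised when a model configuration violates its invariants."""


@dataclass(frozen=True)
class ModelConfig:
    """Full parameter set of one model variant.

    Use the :meth:`model1` / :meth:`model2` constructors; they fill in the
    published defaults and only expose the knobs that vary between runs.
    """

    model_id: int
    b_max: int = 14           # Model 1: max half-width of the space (rcu)
    b1: int = -18             # Model 2: fixed left boundary (rcu)
    b2: int = 18              # Model 2: fixed right boundary (rcu)
    tp: int = 0               # threshold point (rcu)
    u_barrier: float = 1.0    # barrier height U(TP) - U(TP-1.5), kT
    f_d: float = 0.0          # Model 1 constant drift slope, kT/rcu
    drift_step: float = 0.005  # Model 2 slow-walk increment, kT/rcu
    drift_max: float = 0.20   # Model 2 slope reflection limit, kT/rcu
    t_b: int = 600            # RC steps per boundary move (Model 1)
    t_df: int = 1200          # RC steps per drift move (Model 2)
    rc_init: Optional[int] = None  # default: TP - 1
    dt: float = 5e-5          # seconds per RC step

    @classmethod
    def model1(cls, f_d: float = 0.0, *, b_max: int = 14, u_barrier: float = 1.0,
               t_b: int = 600, tp: int = 0, rc_init: Optional[int] = None,
               dt: float = 5e-5) -> "ModelConfig":
        """Fluctuating-boundary model with its published defaults."""
        return cls(model_id=1, b_max=b_max, tp=tp, u_barrier=u_barrier,
                   f_d=f_d, t_b=t_b, rc_init=rc_init, dt=dt)

    @classmethod
    def model2(cls, tp: int = 0, *, b1: int = -18, b2: int = 18,
               u_barrier: float = 0.2, drift_step: float = 0.005,
               drift_max: float = 0.20, t_df: int = 1200,
               rc_init: Optional[int] = None, dt: float = 5e-5) -> "ModelConfig":
        """Fluctuating-drift model with its published defaults."""
        return cls(model_id=2, b1=b1, b2=b2, tp=tp, u_barrier=u_barrier,
                   drift_step=drift_step, drift_max=drift_max, t_df=t_df,
                   rc_init=rc_init, dt=dt)

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2):
            raise ConfigError(f"model_id must be 1 or 2, got {self.model_id}")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.u_barrier < 0 or self.u_barrier > 6:
            raise ConfigError("u_barrier must lie in [0, 6] kT")
        if self.model_id == 1:
            if self.b_max < 2:
                raise ConfigError("b_max must be >= 2")
            if abs(self.f_d) > 2:
                raise ConfigError("|f_d| must be <= 2 kT/rcu")
            if self.tp != 0:
                raise ConfigError("Model 1 uses a centred threshold (tp = 0)")
            if self.t_b < 0:
                raise ConfigError("t_b must be >= 1 (or 0 to freeze)")
        else:
            if not (self.b1 < self.tp < self.b2):
                raise ConfigError("need b1 < tp < b2")
            if self.tp - self.b1 < 2 or self.b2 - self.tp < 2:
                raise ConfigError("each side of the threshold needs >= 1 node")
            if self.drift_step <= 0 or self.drift_max < 0:
                raise ConfigError("drift_step must be > 0 and drift_max >= 0")
            if self.drift_max > 2:
                raise ConfigError("drift_max must be <= 2 kT/rcu")
            if self.t_df < 0:
                raise ConfigError("t_df must be >= 1 (or 0 to freeze)")

    # -- derived quantities -------------------------------------------------

    @property
    def period(self) -> int:
        """Steps between slow-process updates (0 = frozen)."""
        return self.t_b if self.model_id == 1 else self.t_df

    @property
    def barrier_slope(self) -> float:
        """Tent slope B = u_barrier / 1.5, kT/rcu."""
        return self.u_barrier / 1.5

    @property
    def rc_start(self) -> int:
        """Initial RC node (the closed substate nearest the threshold)."""
        return self.tp - 1 if self.rc_init is None else self.rc_init

    def initial_state(self) -> "WalkerState":
        if self.model_id == 1:
            half = self.b_max // 2
            return WalkerState(rc=self.rc_start, b1=-half, b2=half,
                               drift_slope=self.f_d, step_index=0)
        return WalkerState(rc=self.rc_start, b1=self.b1, b2=self.b2,
                           drift_slope=0.0, step_index=0)

    def frozen(self) -> "ModelConfig":
        """Copy with the slow process disabled (negative control)."""
        if self.model_id == 1:
            return replace(self, t_b=0)
        return replace(self, t_df=0)


@dataclass
class WalkerState:
    """Instantaneous state of one walker."""

    rc: int
    b1: int
    b2: int
    drift_slope: float = 0.0
    step_index: int = 0

    def __post_init__(self) -> None:
        if not (self.b1 <= self.rc <= self.b2):
            raise ValueError(f"rc={self.rc} outside boundaries "
                             f"[{self.b1}, {self.b2}]")


@dataclass
class GatingTrace:
    """Dichotomous open/closed series at a fixed sampling interval.

    ``states`` holds 0 (closed) / 1 (open) per sample; the optional side
    channels, when recorded, are aligned sample-for-sample with ``states``.
    """

    states: np.ndarray
    dt: float
    rc_path: Optional[np.ndarray] = None
    boundary_path: Optional[np.ndarray] = None  # b2 per step (b1 = -b2, M1)
    drift_path: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.size == 0:
            raise ValueError("empty trace")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0/1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for side in (self.rc_path, self.boundary_path, self.drift_path):
            if side is not None and len(side) != len(self.states):
                raise ValueError("side channel length mismatch")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self) * self.dt


# -- potentials -------------------------------------------------------------

def _potential(x: float, tp: float, b1: float, b2: float, outer_left: float,
               outer_right: float, bslope: float) -> float:
    """Piecewise-linear landscape, continuous, with U(b1) = 0."""
    if x < b1 or x > b2:
        raise ValueError(f"x={x} outside [{b1}, {b2}]")
    u_tent_lo = (tp - 1.5 - b1) * outer_left   # U at TP - 1.5
    if x < tp - 1.5:
        return (x - b1) * outer_left
    if x < tp:
        return u_tent_lo + (x - (tp - 1.5)) * bslope
    u_tp = u_tent_lo + 1.5 * bslope
    if x <= tp + 1.5:
        return u_tp - (x - tp) * bslope
    return u_tent_lo + (x - (tp + 1.5)) * outer_right


def potential_m1(x: float, cfg: ModelConfig, state: WalkerState) -> float:
    """Model 1 landscape: constant drift slope ``f_d`` on both outer
    segments, tent barrier of height ``u_barrier`` at TP.  In kT."""
    return _potential(x, cfg.tp, state.b1, state.b2,
                      cfg.f_d, cfg.f_d, cfg.barrier_slope)


def potential_m2(x: float, cfg: ModelConfig, state: WalkerState) -> float:
    """Model 2 landscape: outer slopes ``+A`` (left) and ``-A`` (right) with
    ``A = state.drift_slope``; mirror-symmetric about TP.  In kT."""
    a = state.drift_slope
    return _potential(x, cfg.tp, state.b1, state.b2, a, -a,
                      cfg.barrier_slope)


def step_probabilities(du: float) -> Tuple[float, float]:
    """Hop probabilities (p, q) for a potential difference ``du`` (kT)
    across one lattice step: ``p = 1/2 - du/4``, ``q = 1/2 + du/4``.

    Values of ``|du| > 2`` fall outside the validity of the linearised
    rule; the result is clamped to {0, 1} and a warning is emitted.
    """
    if abs(du) > 2:
        warnings.warn(f"|dU| = {abs(du):.3g} kT exceeds 2 kT; "
                      "probabilities clamped", stacklevel=2)
        return (0.0, 1.0) if du > 0 else (1.0, 0.0)
    p = 0.5 - du / 4.0
    return p, 1.0 - p


def move_probability(cfg: ModelConfig, state: WalkerState) -> float:
    """Probability that the next RC move is in the +x direction.

    At barrier-adjacent nodes the decision is governed by the uphill
    half-step into the peak, ``dU = U(TP) - U(TP -/+ 1/2)``; elsewhere by the
    centred difference ``dU = U(x + 1/2) - U(x - 1/2)``.
    """
    pot = potential_m1 if cfg.model_id == 1 else potential_m2
    x, tp = state.rc, cfg.tp
    if x == tp - 1:
        du = pot(tp, cfg, state) - pot(tp - 0.5, cfg, state)
        return step_probabilities(du)[0]
    if x == tp + 1:
        du = pot(tp, cfg, state) - pot(tp + 0.5, cfg, state)
        # crossing is the - move here; p(+) is the complement
        return 1.0 - step_probabilities(du)[0]
    du = pot(x + 0.5, cfg, state) - pot(x - 0.5, cfg, state)
    return step_probabilities(du)[0]


# -- slow-process updates ---------------------------------------------------

def update_boundaries_m1(state: WalkerState, cfg: ModelConfig,
                         rng: np.random.Generator) -> WalkerState:
    """One synchronized boundary event: both half-spaces expand (prob 1/2)
    or shrink (prob 1/2); moves past ``b_max`` or below a half-width of 2
    are rejected.  The RC is clamped into the new range if stranded."""
    b2 = state.b2
    rc = state.rc
    if rng.random() < 0.5:
        if b2 + 1 <= cfg.b_max:
            b2 += 1
    else:
        if b2 - 1 >= 2:
            b2 -= 1
            rc = min(max(rc, -b2), b2)
    return WalkerState(rc=rc, b1=-b2, b2=b2, drift_slope=state.drift_slope,
                       step_index=state.step_index)


def update_drift_m2(state: WalkerState, cfg: ModelConfig,
                    rng: np.random.Generator) -> WalkerState:
    """One drift-slope event: ``+/- drift_step`` with prob 1/2 each, moves
    past ``+/- drift_max`` rejected.  Exact multiples of the increment are
    preserved (no floating-point creep at the limits)."""
    k = round(state.drift_slope / cfg.drift_step)
    kmax = round(cfg.drift_max / cfg.drift_step)
    if rng.random() < 0.5:
        if k + 1 <= kmax:
            k += 1
    else:
        if k - 1 >= -kmax:
            k -= 1
    return WalkerState(rc=state.rc, b1=state.b1, b2=state.b2,
                       drift_slope=k * cfg.drift_step,
                       step_index=state.step_index)


# -- simulation -------------------------------------------------------------

def _uniforms(seed, n_steps: int, period: int) -> np.ndarray:
    """Pre-draw the uniform stream a run consumes (RC draw each step plus
    one slow draw whenever the slow process fires)."""
    n_slow = n_steps // period if period > 0 else 0
    rng = np.random.default_rng(seed)
    return rng.random(n_steps + n_slow)


def simulate(cfg: ModelConfig, n_steps: int, seed=0, *,
             record_paths: bool = False, burn_in: int = 0) -> GatingTrace:
    """Run one gating simulation and return the dichotomous trace.

    Parameters
    ----------
    cfg
        Validated model configuration.
    n_steps
        Number of RC steps (samples) to generate, after any burn-in.
    seed
        Anything accepted by :func:`numpy.random.default_rng`.
    record_paths
        Also record the RC trajectory and the slow variable (boundary
        half-width for Model 1, drift slope for Model 2).
    burn_in
        Steps simulated and discarded before recording starts.  The walk
        starts one node below threshold, so burn-in is negligible at the
        study's trace lengths; it is off by default.
    """
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    if burn_in < 0:
        raise ConfigError("burn_in must be >= 0")
    st0 = cfg.initial_state()
    if cfg.rc_start == cfg.tp or not (st0.b1 <= cfg.rc_start <= st0.b2):
        raise ConfigError(f"rc_init={cfg.rc_start} is not an occupiable node")
    total = n_steps + burn_in
    u = _uniforms(seed, total, cfg.period)
    record = record_paths
    rc_out = np.empty(total if record else 1, dtype=np.int16)
    s_out = np.empty(total if record else 1, dtype=np.int16)
    if cfg.model_id == 1:
        st = cfg.initial_state()
        states = sim_model1(total, cfg.b_max, st.b2, cfg.tp, cfg.u_barrier,
                            cfg.f_d, cfg.t_b, st.rc, u, record, rc_out, s_out)
        if record:
            return GatingTrace(states[burn_in:], cfg.dt,
                               rc_path=rc_out[burn_in:].copy(),
                               boundary_path=s_out[burn_in:].copy())
        return GatingTrace(states[burn_in:], cfg.dt)
    kmax = round(cfg.drift_max / cfg.drift_step)
    states = sim_model2(total, cfg.b1, cfg.b2, cfg.tp, cfg.u_barrier,
                        0, cfg.drift_step, kmax, cfg.t_df, cfg.rc_start,
                        u, record, rc_out, s_out)
    if record:
        return GatingTrace(states[burn_in:], cfg.dt,
                           rc_path=rc_out[burn_in:].copy(),
                           drift_path=s_out[burn_in:] * cfg.drift_step)
    return GatingTrace(states[burn_in:], cfg.dt)
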