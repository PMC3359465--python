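"""Patch-clamp-like synthetic current traces.

Real single-channel recordings of this preparation are not publicly
deposited, so the idealization and Hurst stages are exercised on emulated
data: a gating simulation supplies the dichotomous state process, the open
level follows the Ohmic relation I = g (V - V_rev) with the channel's
~235.6 pS conductance, the closed level is 0 pA, and additive Gaussian
white noise models the recording noise.  Default sampling is 20 kHz; a
300 s recording therefore holds 6e6 samples.

The recording noise SD is not published (only the 5e-4 pA quantization
step); the default gives a signal-to-noise ratio of 10, at which
threshold idealization is essentially error-free while the analog stage is
still non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core_models import GatingTrace, ModelConfig, simulate
from .event_detection import CurrentTrace

__all__ = ["RecordingSpec", "render_current", "make_fixture"]


@dataclass
class RecordingSpec:
    """Recording conditions for rendering a gating trace into current."""

    voltage: float = 80.0          # mV
    conductance: float = 235.6     # pS
    reversal: float = 0.0          # mV
    noise_sd: Optional[float] = None  # pA; default open_level / 10 (SNR 10)
    sampling: float = 20_000.0     # Hz
    duration: float = 300.0        # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling <= 0 or self.duration <= 0:
            raise ValueError("sampling and duration must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def open_level(self) -> float:
        """Ohmic open-channel current, pA (g in pS, V in mV)."""
        return self.conductance * (self.voltage - self.reversal) * 1e-3

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling))

    def resolved_noise_sd(self) -> float:
        return (abs(self.open_level) / 10.0 if self.noise_sd is None
                else self.noise_sd)


def render_current(gt: GatingTrace, spec: RecordingSpec) -> CurrentTrace:
    """Render a dichotomous gating trace into a noisy analog current."""
    if abs(gt.dt - spec.dt) > 1e-12:
        raise ValueError(f"trace dt={gt.dt} inconsistent with "
                         f"sampling={spec.sampling} Hz")
    rng = np.random.default_rng(spec.seed)
    current = gt.states * spec.open_level
    sd = spec.resolved_noise_sd()
    if sd > 0:
        current = current + rng.normal(0.0, sd, size=len(gt))
    else:
        current = current.astype(float)
    return CurrentTrace(current, dt=gt.dt, voltage=spec.voltage)


def make_fixture(model: int = 1, *, n_samples: Optional[int] = None,
                 seed: int = 0, spec: Optional[RecordingSpec] = None,
                 f_d: float = 0.0, tp: int = 0,
                 cfg: Optional[ModelConfig] = None
                 ) -> Tuple[CurrentTrace, GatingTrace]:
    """Couple a gating simulation to the current renderer.

    Returns the noisy analog trace together with its ground-truth gating
    trace, for end-to-end tests of the idealization chain.  ``n_samples``
    defaults to the full recording length implied by the spec (6e6 at
    20 kHz x 300 s).
    """
    spec = spec or RecordingSpec(seed=seed)
    if cfg is None:
        cfg = (ModelConfig.model1(f_d=f_d, dt=spec.dt) if model == 1
               else ModelConfig.model2(tp=tp, dt=spec.dt))
    n = spec.n_samples if n_samples is None else int(n_samples)
    truth = simulate(cfg, n, seed)
    return render_current(truth, spec), truth
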