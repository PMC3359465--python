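"""Closed-form scale-bridging estimates: from lattice units and sampling
time to apparent diffusion coefficients, mass ratios, and membrane-patch
volumes.

The chain of reasoning: one reaction-coordinate unit corresponds to a
fraction of the channel vestibule diameter; with the sampling interval it
yields an apparent diffusion coefficient of the channel gate, D_CG =
delta^2 / (6 tau).  The slow/fast diffusion-coefficient ratio of the model
maps onto a mass ratio through m ~ (2kT/D)^(3/5), and comparing that mass
ratio with the gate/patch volume ratio says what fraction of the membrane
patch must fluctuate coherently to drive the gate.

Two evaluation modes are provided: ``formula_chain`` recomputes everything
from its inputs, while ``printed_chain`` replays the published numbers
(which contain two internal inconsistencies, kept deliberately; see the
methods note) so both variants can be compared side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np

__all__ = [
    "PhysicalScales",
    "PRINTED",
    "rcu_length",
    "apparent_diffusion",
    "mass_ratio_from_diffusion",
    "cylinder_volume",
    "slab_volume",
    "printed_chain",
    "formula_chain",
]


def rcu_length(d: float, lattice_span: float) -> float:
    """Physical length of one lattice unit: delta = d / (2 * lattice_span),
    with ``d`` the vestibule diameter (one helix sweeps d/2) in Angstrom."""
    if d < 0 or lattice_span <= 0:
        raise ValueError("need d >= 0 and lattice_span > 0")
    return d / (2.0 * lattice_span)


def apparent_diffusion(delta: float, tau: float) -> float:
    """Apparent diffusion coefficient delta^2 / (6 tau), SI units."""
    if delta < 0 or tau <= 0:
        raise ValueError("need delta >= 0 and tau > 0")
    return delta ** 2 / (6.0 * tau)


def mass_ratio_from_diffusion(d_fast: float, d_slow: float) -> float:
    """Mass ratio of the slow to the fast diffuser, (D_fast/D_slow)^(3/5).

    Follows from D ~ v * delta with tau ~ m^(-2/3) (collision rate scales
    with surface, m ~ S^(3/2)) and equipartition kT ~ m v^2 / 2.
    """
    if d_fast <= 0 or d_slow <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return (d_fast / d_slow) ** 0.6


def cylinder_volume(r: float, h: float) -> float:
    """Volume of a membrane-spanning cylinder (helix), Angstrom^3."""
    if r < 0 or h < 0:
        raise ValueError("need r, h >= 0")
    return np.pi * r * r * h


def slab_volume(s: float, h: float) -> float:
    """Volume of a membrane slab of area ``s`` and thickness ``h``."""
    if s < 0 or h < 0:
        raise ValueError("need s, h >= 0")
    return s * h


@dataclass(frozen=True)
class PhysicalScales:
    """Named physical scales of one evaluation of the chain."""

    delta_angstrom: float     # length of 1 rcu
    tau_s: float              # seconds per step
    d_cg: float               # apparent gate diffusion coefficient, m^2/s
    d_s: float                # surrounding (slow) diffusion coefficient
    d_helix: float            # lateral helix diffusion in membrane, m^2/s
    mass_ratio: float         # m_surrounding / m_gate
    v_gate: float             # helix cylinder volume, A^3
    v_patch: float            # whole patch volume, A^3
    volume_ratio: float       # v_patch / v_gate
    patch_fraction: float     # fraction of patch acting as the surrounding


# published inputs and intermediates, kept verbatim so the printed chain
# can be replayed exactly
PRINTED = MappingProxyType({
    "d_vestibule_angstrom": 20.0,
    "lattice_denominator": 80.0,   # as printed; 2 * 2 * B_MAX = 56 with B_MAX = 14
    "delta_angstrom": 0.25,
    "tau_s": 5e-5,
    "d_cg": 1.04e-17,              # as printed; delta^2/(6 tau) gives 2.08e-18
    "slow_factor": 600.0,          # Model 1 time-scale ratio D_RC / D_B
    "d_s": 1.73e-20,
    "d_helix": 4e-12,
    "mass_ratio": 1.04e5,
    "r_helix_angstrom": 2.5,
    "membrane_thickness_angstrom": 70.0,
    "patch_area_angstrom2": 1e8,
    "v_gate": 1374.0,
    "v_patch": 7e9,
    "volume_ratio": 5.09e6,
    "patch_fraction": 0.02,
})


def printed_chain() -> PhysicalScales:
    """Replay the published chain from its printed inputs.

    Downstream values (D_S, mass ratio, patch fraction) are recomputed from
    the printed D_CG, with which they are internally consistent.
    """
    p = PRINTED
    d_s = p["d_cg"] / p["slow_factor"]
    mass_ratio = mass_ratio_from_diffusion(p["d_helix"], d_s)
    v_gate = cylinder_volume(p["r_helix_angstrom"],
                             p["membrane_thickness_angstrom"])
    v_patch = slab_volume(p["patch_area_angstrom2"],
                          p["membrane_thickness_angstrom"])
    volume_ratio = v_patch / v_gate
    return PhysicalScales(
        delta_angstrom=p["delta_angstrom"], tau_s=p["tau_s"],
        d_cg=p["d_cg"], d_s=d_s, d_helix=p["d_helix"],
        mass_ratio=mass_ratio, v_gate=v_gate, v_patch=v_patch,
        volume_ratio=volume_ratio,
        patch_fraction=mass_ratio / volume_ratio,
    )


def formula_chain(b_max: int = 14, *, d_vestibule: float = 20.0,
                  tau: float = 5e-5, d_helix: float = 4e-12,
                  slow_factor: float = 600.0, r_helix: float = 2.5,
                  membrane_thickness: float = 70.0,
                  patch_area: float = 1e8) -> PhysicalScales:
    """Recompute the whole chain from first inputs (lattice geometry,
    sampling interval, literature helix diffusivity)."""
    delta = rcu_length(d_vestibule, 2.0 * b_max)     # Angstrom
    d_cg = apparent_diffusion(delta * 1e-10, tau)    # m^2/s
    d_s = d_cg / slow_factor
    mass_ratio = mass_ratio_from_diffusion(d_helix, d_s)
    v_gate = cylinder_volume(r_helix, membrane_thickness)
    v_patch = slab_volume(patch_area, membrane_thickness)
    volume_ratio = v_patch / v_gate
    return PhysicalScales(
        delta_angstrom=delta, tau_s=tau, d_cg=d_cg, d_s=d_s,
        d_helix=d_helix, mass_ratio=mass_ratio, v_gate=v_gate,
        v_patch=v_patch, volume_ratio=volume_ratio,
        patch_fraction=mass_ratio / volume_ratio,
    )
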