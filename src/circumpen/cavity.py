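"""Cavity-expansion decomposition of penetration force.

The axial force on a cone penetrometer is the sum of the force needed to
expand a cavity in the soil and the interfacial frictional force.  For a
stationary sample the radial stress on the cone, sigma_r,s, links the two:

    Fr_s = pi rc^2 cot(beta_c) sigma_rs     (radial cavity force)
    Fc_s = Fr_s tan(beta_c)                 (axial cavity-expansion force)
    Fz   = Fc_s [1 + mu cot(beta_c)]        (measured axial force)
    Ff_s = Fz - Fc_s                        (frictional force)

Orbital motion of the sample adds a unidirectional radial force
``Fro = delta_c * k`` from the bent shaft, which makes the radial load on
the cone asymmetric without changing the net cavity size; the asymmetry
index ``Iasym = Fro / Fr_s`` and the circumnutation intensity
``CI = Iasym * f / fmax`` quantify that asymmetry and, combined with the
assumption of unchanged cavity-expansion force, attribute the measured
resistance reduction to interfacial friction.

Units: forces N, lengths mm, stresses MPa (N/mm^2), angles degrees at the
interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .probe import ProbeSpec

__all__ = [
    "FrictionParams",
    "ForceDecomposition",
    "resistance_from_force",
    "force_from_resistance",
    "radial_stress_stationary",
    "stationary_decomposition",
    "orbital_radial_force",
    "radial_force_distribution",
    "moving_friction",
    "friction_rescale",
    "asymmetry_index",
    "circumnutation_intensity",
    "decompose_treatment",
    "NegativeFrictionWarning",
]


class NegativeFrictionWarning(UserWarning):
    """Measured axial force below the cavity-expansion force."""


def _cot(angle_deg: float) -> float:
    if angle_deg <= 0:
        raise ValueError("semi-opening angle must be positive (cot undefined at 0)")
    return 1.0 / np.tan(np.deg2rad(angle_deg))


@dataclass(frozen=True)
class FrictionParams:
    """Interfacial friction coefficients.

    ``mu`` is the metal-soil friction coefficient at which the measurement
    was made; ``mu_prime`` an alternative coefficient (e.g. a root-soil
    interface) to which forces may be rescaled.
    """

    mu: float = 0.5
    mu_prime: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if not 0.0 <= self.mu_prime <= 1.0:
            raise ValueError("mu_prime must be in [0, 1]")


@dataclass
class ForceDecomposition:
    """All force components for one treatment (material x frequency)."""

    Fz: float
    sigma_rs: float
    Fr_s: float
    Fc_s: float
    Ff_s: float
    Fro: float = 0.0
    Ff_m: float = float("nan")
    Iasym: float = 0.0
    CI: float = 0.0
    f: float = 0.0
    fmax: float = 10.0


def resistance_from_force(Fz, probe: ProbeSpec):
    """Mechanical resistance Q = Fz / (pi rc^2), MPa for Fz in N, rc in mm."""
    Fz = np.asarray(Fz, dtype=float)
    if np.any(Fz < 0):
        raise ValueError("Fz must be non-negative")
    out = Fz / probe.cone_base_area
    return float(out) if out.ndim == 0 else out


def force_from_resistance(Q, probe: ProbeSpec):
    """Inverse of :func:`resistance_from_force`: Fz = Q * pi rc^2."""
    out = np.asarray(Q, dtype=float) * probe.cone_base_area
    return float(out) if out.ndim == 0 else out


def radial_stress_stationary(
    Fz_mean: float, probe: ProbeSpec, fric: FrictionParams
) -> float:
    """Radial stress sigma_r,s (MPa) from the mean stationary axial force."""
    if Fz_mean <= 0:
        raise ValueError("Fz_mean must be positive")
    return Fz_mean / (
        probe.cone_base_area * (1.0 + fric.mu * _cot(probe.semi_opening_angle))
    )


def stationary_decomposition(
    sigma_rs: float, probe: ProbeSpec, fric: FrictionParams
) -> ForceDecomposition:
    """Forces on a stationary sample from the radial stress.

    The identity ``Fz = Fc_s + Ff_s`` holds exactly by construction.
    """
    if sigma_rs <= 0:
        raise ValueError("sigma_rs must be positive")
    cot = _cot(probe.semi_opening_angle)
    Fc_s = probe.cone_base_area * sigma_rs
    Fr_s = Fc_s * cot
    Fz = Fc_s * (1.0 + fric.mu * cot)
    return ForceDecomposition(
        Fz=Fz, sigma_rs=sigma_rs, Fr_s=Fr_s, Fc_s=Fc_s, Ff_s=Fz - Fc_s
    )


def orbital_radial_force(delta_c: float, probe: ProbeSpec) -> float:
    """Unidirectional radial force Fro = delta_c * k from the bent shaft, N."""
    if delta_c < 0:
        raise ValueError("delta_c must be non-negative")
    return delta_c * probe.bending_stiffness


def radial_force_distribution(Fr_s: float, Fro: float, gamma) -> np.ndarray | float:
    """Radial force around the cone circumference.

    ``F*_r(gamma) = Fr_s + cos(gamma) * Fro`` with the admissibility
    constraint ``Fr_s >= Fro`` so the force stays non-negative everywhere.
    ``gamma`` is the angle (radians) from the direction of ``Fro``.
    """
    if Fro < 0 or Fr_s < 0:
        raise ValueError("forces must be non-negative")
    if Fro > Fr_s:
        raise ValueError("asymmetry constraint violated: Fro > Fr_s")
    out = Fr_s + np.cos(np.asarray(gamma, dtype=float)) * Fro
    return float(out) if out.ndim == 0 else out


def moving_friction(Fz_moving: float, Fc_s: float) -> float:
    """Frictional force under orbital motion: Ff_m = Fz_moving - Fc_s.

    Assumes the cavity-expansion force is unchanged by the orbital motion
    (same net cavity size), so the whole change in axial force is frictional.
    A negative result is returned with a warning, not clipped.
    """
    Ff_m = Fz_moving - Fc_s
    if Ff_m < 0:
        warnings.warn(
            f"negative moving friction ({Ff_m:.3g} N): Fz below cavity force",
            NegativeFrictionWarning,
            stacklevel=2,
        )
    return Ff_m


def friction_rescale(
    Fz: float, fric: FrictionParams, probe: ProbeSpec, Fc_s: float
) -> tuple[float, float]:
    """Rescale the axial force to a different friction coefficient.

    Returns ``(Fz', Ff')`` with
    ``Fz'(mu') = Fz [1 + mu' cot beta_c] / [1 + mu cot beta_c]`` and
    ``Ff' = Fz' - Fc_s``.  ``Fz'`` is affine and increasing in ``mu'``;
    at ``mu' = 0`` it reduces to the pure cavity-expansion force.
    """
    cot = _cot(probe.semi_opening_angle)
    Fz_p = Fz * (1.0 + fric.mu_prime * cot) / (1.0 + fric.mu * cot)
    return Fz_p, Fz_p - Fc_s


def asymmetry_index(Fro: float, Fr_s: float) -> float:
    """Asymmetry of the radial force distribution, Iasym = Fro / Fr_s in [0, 1]."""
    if Fro < 0:
        raise ValueError("Fro must be non-negative")
    if Fr_s <= 0:
        raise ValueError("Fr_s must be positive")
    if Fro > Fr_s:
        raise ValueError("asymmetry constraint violated: Fro > Fr_s")
    return Fro / Fr_s


def circumnutation_intensity(Iasym: float, f: float, fmax: float = 10.0) -> float:
    """Circumnutation intensity CI = Iasym * f / fmax."""
    if fmax <= 0:
        raise ValueError("fmax must be positive")
    if not 0.0 <= f <= fmax:
        raise ValueError("f must be in [0, fmax]")
    return Iasym * f / fmax


def decompose_treatment(
    Fz_stationary_mean: float,
    Fz_moving_mean: float,
    delta_c: float,
    f: float,
    probe: ProbeSpec,
    fric: FrictionParams,
    fmax: float = 10.0,
) -> ForceDecomposition:
    """Full decomposition for one moving treatment.

    The cavity-expansion force is inherited from the stationary
    decomposition of the same shaft-material group (its mean axial force),
    mirroring the assumption that orbital motion leaves the cavity
    unchanged.
    """
    sigma_rs = radial_stress_stationary(Fz_stationary_mean, probe, fric)
    stat = stationary_decomposition(sigma_rs, probe, fric)
    Fro = orbital_radial_force(delta_c, probe)
    Iasym = asymmetry_index(Fro, stat.Fr_s)
    CI = circumnutation_intensity(Iasym, f, fmax)
    Ff_m = moving_friction(Fz_moving_mean, stat.Fc_s)
    return ForceDecomposition(
        Fz=Fz_moving_mean,
        sigma_rs=sigma_rs,
        Fr_s=stat.Fr_s,
        Fc_s=stat.Fc_s,
        Ff_s=stat.Ff_s,
        Fro=Fro,
        Ff_m=Ff_m,
        Iasym=Iasym,
        CI=CI,
        f=f,
        fmax=fmax,
    )
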