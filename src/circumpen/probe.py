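"""Probe deflection kinematics.

A cone penetrometer on a slender shaft is used as a root analogue while the
soil sample performs an orbital motion (radius ``r_o``, nominally 1 mm).
Because the shaft bends, the cone does not follow the full orbit: the
projected deflection angle of the shaft, measured from time-lapse images,
gives the average horizontal cone deflection ``delta_c``, and the
circumnutation amplitude is the orbit radius minus that deflection.

All angles at module interfaces are in degrees (the unit in which they are
measured on images); conversion to radians happens only inside trig calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeSpec",
    "DeflectionSeries",
    "DeflectionSummary",
    "STEEL",
    "BRASS",
    "segment_oscillations",
    "cone_deflection",
    "circumnutation_amplitude",
    "axial_force_correction",
    "relative_force_error",
    "summarize_deflection",
]


@dataclass(frozen=True)
class ProbeSpec:
    """Geometry and stiffness of the root-analogue penetrometer probe.

    Parameters
    ----------
    cone_base_radius : float
        Cone base radius ``rc`` in mm.
    semi_opening_angle : float
        Cone tip half-angle ``beta_c`` in degrees, in (0, 90).
    shaft_length : float
        Shaft length ``ls`` in mm.
    bending_stiffness : float
        Cantilever bending stiffness ``k`` in N/mm (numerically equal to kN/m).
    material : str
        Shaft material label.
    orbit_radius : float
        Radius of the imposed orbital motion in mm.
    """

    cone_base_radius: float = 2.5
    semi_opening_angle: float = 15.0
    shaft_length: float = 45.0
    bending_stiffness: float = 6.96
    material: str = "steel"
    orbit_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.cone_base_radius <= 0:
            raise ValueError("cone_base_radius must be positive")
        if not 0.0 < self.semi_opening_angle < 90.0:
            raise ValueError("semi_opening_angle must be in (0, 90) degrees")
        if self.shaft_length <= 0:
            raise ValueError("shaft_length must be positive")
        if self.bending_stiffness <= 0:
            raise ValueError("bending_stiffness must be positive")
        if self.orbit_radius < 0:
            raise ValueError("orbit_radius must be non-negative")

    @property
    def cone_base_area(self) -> float:
        """Cone base area in mm**2."""
        return float(np.pi * self.cone_base_radius**2)


#: Stiff steel-shaft probe (k = 6.96 kN/m).
STEEL = ProbeSpec(bending_stiffness=6.96, material="steel")
#: Flexible brass-shaft probe (k = 2.96 kN/m).
BRASS = ProbeSpec(bending_stiffness=2.96, material="brass")


@dataclass
class DeflectionSeries:
    """Projected deflection angles partitioned into oscillation windows.

    ``timestamps`` are minutes since the start of penetration, strictly
    increasing; ``angles`` are projected deflection angles to the vertical in
    degrees; ``oscillation_index[i]`` assigns sample ``i`` to one of ``R``
    contiguous windows (all -1 for a stationary run, where ``R == 0``).
    """

    timestamps: np.ndarray
    angles: np.ndarray
    oscillation_index: np.ndarray
    R: int

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.oscillation_index = np.asarray(self.oscillation_index, dtype=int)
        if self.timestamps.shape != self.angles.shape:
            raise ValueError("timestamps and angles must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.R < 0:
            raise ValueError("R must be non-negative")

    def angle_ranges(self) -> np.ndarray:
        """Per-oscillation angle range ``delta_alpha_i`` (max - min), degrees."""
        if self.R == 0:
            return np.empty(0)
        out = np.empty(self.R)
        for i in range(self.R):
            win = self.angles[self.oscillation_index == i]
            if win.size == 0:
                raise ValueError(f"oscillation window {i} is empty")
            out[i] = win.max() - win.min()
        return out


@dataclass
class DeflectionSummary:
    """Per-replicate deflection summary.

    ``delta_c`` is the horizontal cone deflection in mm, ``amplitude`` the
    circumnutation amplitude (orbit radius minus deflection; NaN for
    stationary runs), ``Fa_over_Fz`` the axial-force correction factor and
    ``erel`` the relative force-measurement error in percent.
    """

    delta_alpha: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta_c: float = 0.0
    amplitude: float = float("nan")
    Fa_over_Fz: float = 1.0
    erel: float = 0.0
    R: int = 0


def segment_oscillations(
    timestamps: np.ndarray,
    angles: np.ndarray,
    frequency: float,
    speed: float = 1.0,
    depth_cm: float = 1.0,
) -> DeflectionSeries:
    """Partition an angle time series into per-oscillation windows.

    The orbital rig imposes the oscillation period (``60 / (f * speed)``
    minutes for a frequency of ``f`` oscillations per cm at ``speed`` cm/h),
    so windows are derived from the nominal frequency, not detected from the
    signal.  ``R = f * depth_cm`` contiguous, equal-duration windows span the
    series.

    Parameters
    ----------
    timestamps : array
        Sample times in minutes, strictly increasing.
    angles : array
        Projected deflection angles in degrees.
    frequency : float
        Circumnutation frequency ``f`` in oscillations per cm (0 for
        stationary samples).
    speed : float
        Penetration speed in cm/h.
    depth_cm : float
        Total penetration depth in cm.

    Returns
    -------
    DeflectionSeries
    """
    t = np.asarray(timestamps, dtype=float)
    a = np.asarray(angles, dtype=float)
    if frequency < 0:
        raise ValueError("frequency must be non-negative")
    if frequency == 0:
        return DeflectionSeries(t, a, np.full(t.shape, -1, dtype=int), 0)
    R = int(round(frequency * depth_cm))
    if R < 1:
        raise ValueError("incomplete oscillation: f * depth < 1")
    span = t[-1] - t[0] + (t[-1] - t[0]) / max(t.size - 1, 1)
    period = span / R
    if t.size < 2 or span <= 0:
        raise ValueError("incomplete oscillation: series too short")
    idx = np.minimum(((t - t[0]) / period).astype(int), R - 1)
    return DeflectionSeries(t, a, idx, R)


def cone_deflection(series: DeflectionSeries, probe: ProbeSpec) -> float:
    """Average horizontal cone deflection ``delta_c`` in mm.

    ``delta_c = (ls / R) * sum_i sin(delta_alpha_i / 2)`` with
    ``delta_alpha_i`` the angle range (degrees) of oscillation ``i``.
    """
    if series.R < 1:
        raise ValueError("cone deflection undefined without oscillations")
    half = np.deg2rad(series.angle_ranges()) / 2.0
    return float(probe.shaft_length * np.mean(np.sin(half)))


def circumnutation_amplitude(delta_c: float, probe: ProbeSpec) -> float:
    """Circumnutation amplitude in mm: orbit radius minus cone deflection."""
    if delta_c < 0:
        raise ValueError("delta_c must be non-negative")
    if delta_c > probe.orbit_radius:
        raise ValueError("deflection exceeds orbit radius")
    return probe.orbit_radius - delta_c


def axial_force_correction(Fz, series: DeflectionSeries):
    """Actual axial force ``Fa`` from the measured vertical force ``Fz``.

    Shaft deflection tilts the probe so the load cells underestimate the
    axial force; the correction divides by the mean cosine of the
    half-ranges: ``Fa = Fz / mean_i cos(delta_alpha_i / 2)``.
    """
    if series.R < 1:
        raise ValueError("force correction undefined without oscillations")
    half = np.deg2rad(series.angle_ranges()) / 2.0
    factor = 1.0 / float(np.mean(np.cos(half)))
    return np.asarray(Fz, dtype=float) * factor if np.ndim(Fz) else float(Fz) * factor


def relative_force_error(Fa: float, Fz: float) -> float:
    """Relative force-measurement error ``(Fa - Fz)/Fz * 100`` in percent."""
    if Fz <= 0:
        raise ValueError("Fz must be positive")
    return (Fa - Fz) / Fz * 100.0


def summarize_deflection(
    series: DeflectionSeries, probe: ProbeSpec, Fz: float = 1.0
) -> DeflectionSummary:
    """Full per-replicate summary: delta_c, amplitude, correction and erel.

    Stationary series (``R == 0``) carry ``delta_c = 0`` and an undefined
    (NaN) amplitude: the amplitude is meaningless without orbital motion.
    """
    if series.R == 0:
        return DeflectionSummary(R=0)
    da = series.angle_ranges()
    dc = cone_deflection(series, probe)
    amp = circumnutation_amplitude(dc, probe)
    fa = axial_force_correction(Fz, series)
    return DeflectionSummary(
        delta_alpha=da,
        delta_c=dc,
        amplitude=amp,
        Fa_over_Fz=fa / Fz,
        erel=relative_force_error(fa, Fz),
        R=series.R,
    )
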