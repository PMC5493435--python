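"""Asymmetric division outcomes: segregation ratios and signed division angles.

One asymmetric SOP division yields two daughters whose fate-determinant
reporter intensities and relative placement quantify the division:

* the segregation ratio min/max of the two daughter intensities is 1 for a
  perfectly symmetric split and approaches 0 for all-or-nothing inheritance;
* the division angle is the signed angle between the anterior-posterior body
  axis and the daughter-daughter displacement axis, clockwise-positive in the
  viewer's frame (y-down image coordinates), in (-180, 180].

Population dispersion of the signed angles is summarized by the arithmetic
sample SD (the primary statistic, matching how the published SDs on signed
angles were computed) alongside the circular SD derived from the mean
resultant length, which is the statistically sounder quantity for strongly
dispersed angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polarity import PolarityScore, polarization_coefficient

__all__ = [
    "DivisionRecord",
    "DispersionSummary",
    "segregation_ratio",
    "division_angle",
    "angle_dispersion",
    "polarization_of_crescent",
]


@dataclass(frozen=True)
class DivisionRecord:
    """One asymmetric division event.

    ``daughter_axis`` is the displacement vector from the anterior to the
    posterior daughter centroid in image coordinates; ``ap_axis`` the
    anterior-posterior body axis reference. Which daughter is anterior is
    caller-declared metadata, not inferred.
    """

    cell_id: str
    intensity_a: float
    intensity_b: float
    daughter_axis: tuple[float, float]
    ap_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.intensity_a < 0 or self.intensity_b < 0:
            raise ValueError("daughter intensities must be nonnegative")
        if self.intensity_a == 0 and self.intensity_b == 0:
            raise ValueError("at least one daughter intensity must be positive")
        if np.hypot(*self.daughter_axis) == 0:
            raise ValueError("daughter_axis must be nonzero")
        if np.hypot(*self.ap_axis) == 0:
            raise ValueError("ap_axis must be nonzero")


@dataclass(frozen=True)
class DispersionSummary:
    n: int
    sd_arithmetic: float  # sample SD (n-1 denominator) of the signed angles
    sd_circular: float    # sqrt(-2 ln R) in degrees, R = mean resultant length
    mean_angle: float     # circular mean, degrees in (-180, 180]


def segregation_ratio(record: DivisionRecord) -> float:
    """min/max of the two daughter intensities; 1 means equal segregation.

    Symmetric in the daughters and invariant to common intensity scaling.
    Equal intensities (including the tie at any common positive value)
    return exactly 1.0.
    """
    i_min = min(record.intensity_a, record.intensity_b)
    i_max = max(record.intensity_a, record.intensity_b)
    if i_max == 0:
        raise ValueError("both daughter intensities are zero")
    if i_min == i_max:
        return 1.0
    return i_min / i_max


def division_angle(record: DivisionRecord) -> float:
    """Signed angle (degrees) from the A-P axis to the daughter axis.

    Clockwise in the viewer's frame (y down) is positive, giving values in
    (-180, 180] with 0 a division perfectly along the A-P axis. Negating
    the daughter axis (swapping daughter identity) shifts the angle by 180
    degrees, re-wrapped; the convention is atan2-based, never modular
    arithmetic on raw degrees.
    """
    ax, ay = record.ap_axis
    dx, dy = record.daughter_axis
    # y-down frame: cross > 0 is a clockwise rotation on screen
    cross = ax * dy - ay * dx
    dot = ax * dx + ay * dy
    ang = np.degrees(np.arctan2(cross, dot))
    # arctan2 returns [-180, 180]; fold -180 onto +180
    if ang <= -180.0:
        ang += 360.0
    return round(float(ang), 2)


def angle_dispersion(angles) -> DispersionSummary:
    """Dispersion of signed division angles (degrees).

    Arithmetic sample SD (denominator n-1) is the primary output; the
    circular SD sqrt(-2 ln R) and circular mean are reported alongside.
    Requires at least 2 angles.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need at least 2 angles")
    sd_arith = float(np.std(a, ddof=1))
    rad = np.deg2rad(a)
    C, S = np.cos(rad).mean(), np.sin(rad).mean()
    R = float(np.hypot(C, S))
    if R <= 0:
        sd_circ = float("inf")
    else:
        sd_circ = float(np.degrees(np.sqrt(-2.0 * np.log(min(R, 1.0)))))
    mean_angle = float(180.0 - np.mod(180.0 - np.degrees(np.arctan2(S, C)), 360.0))
    return DispersionSummary(n=a.size, sd_arithmetic=sd_arith, sd_circular=sd_circ, mean_angle=mean_angle)


def polarization_of_crescent(profile) -> PolarityScore:
    """Polarization coefficient of a division's cortical crescent profile.

    Re-export of :func:`sopquant.polarity.polarization_coefficient` for
    division-level reports.
    """
    return polarization_coefficient(profile)
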