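"""Paraxial thin-lens vergence engine for the pseudophakic eye.

The eye is modelled as two thin lenses in series: the cornea (power from
keratometry) and the capsular-bag IOL at the effective lens position (ELP)
behind the corneal apex, followed by a vitreous path of length ``AL - ELP``
to the retinal focal plane. A spherocylindrical refraction is handled per
principal meridian; meridians are assumed aligned (the toric IOL's steep
axis sits on the flat corneal meridian), so no crossed-cylinder algebra is
needed.

Two directions through the model matter:

* forward — given biometry, an IOL power and an ELP, predict the
  postoperative spherical-equivalent refraction at the spectacle plane
  (:func:`predicted_postop_se`);
* inverse — given the measured postoperative refraction, back-solve the ELP
  formula-independently (:func:`solve_elp`), then compute the per-meridian
  IOL powers that fully correct the cornea (:func:`emmetropizing_power`,
  :func:`full_correction_tiol`).

The ratio of the resulting IOL torus to the corneal astigmatism is the
translation ratio, the central quantity of the cohort analysis in
:mod:`toricratio.model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "DegeneratePropagationError",
    "ElpSolveError",
    "EyeRecord",
    "MeridionalPowers",
    "CaseResult",
    "keratometric_power",
    "spherical_equivalent",
    "re_reference_sphere",
    "propagate_vergence",
    "predicted_postop_se",
    "solve_elp",
    "emmetropizing_power",
    "full_correction_tiol",
    "ELP_BRACKET_MM",
]

#: bracket for the formula-independent ELP solve, in mm behind the apex
ELP_BRACKET_MM = (0.5, 8.0)


class DegeneratePropagationError(ArithmeticError):
    """A vergence was propagated onto (or across) its own focus."""


class ElpSolveError(ValueError):
    """No ELP inside the physiologic bracket reproduces the measured SE."""


@dataclass(frozen=True)
class EyeRecord:
    """One case: preoperative biometry, implanted IOL, postop refraction.

    Radii and lengths in mm, powers in dioptres. ``acd_phakic`` (phakic
    anterior chamber depth) is carried through for completeness but does
    not enter the vergence model. ``meas_distance_m`` is the lane length at
    which the postoperative refraction was taken; refractions taken at a
    lane other than the model's reference distance are re-referenced before
    use.
    """

    r_flat: float
    r_steep: float
    axial_length: float
    acd_phakic: float
    p_iol_implanted: float
    postop_sphere: float
    postop_cylinder: float
    case_id: Optional[str] = None
    meas_distance_m: Optional[float] = None

    def validation_error(self) -> Optional[str]:
        """Return a reason string if the record violates the biometric
        plausibility bounds, else None."""
        if not (self.r_steep <= self.r_flat):
            return "steep_radius_exceeds_flat"
        for r in (self.r_flat, self.r_steep):
            if not (5.0 < r < 11.0):
                return "corneal_radius_out_of_range"
        if not (15.0 < self.axial_length < 40.0):
            return "axial_length_out_of_range"
        if self.meas_distance_m is not None and not self.meas_distance_m > 0:
            return "nonpositive_measurement_distance"
        return None


@dataclass(frozen=True)
class MeridionalPowers:
    """Corneal powers in the two principal meridians [D]."""

    k_flat: float
    k_steep: float

    @property
    def k_equivalent(self) -> float:
        return 0.5 * (self.k_flat + self.k_steep)

    @property
    def astigmatism(self) -> float:
        return self.k_steep - self.k_flat

    @classmethod
    def from_radii(
        cls,
        r_flat_mm: float,
        r_steep_mm: float,
        constants: OpticalConstants = DEFAULT_CONSTANTS,
    ) -> "MeridionalPowers":
        return cls(
            k_flat=keratometric_power(r_flat_mm, constants),
            k_steep=keratometric_power(r_steep_mm, constants),
        )


@dataclass(frozen=True)
class CaseResult:
    """Derived quantities for one analyzed case.

    ``translation_ratio`` is the IOL torus divided by the corneal
    astigmatism; it is NaN (and the case flagged) when the astigmatism is
    zero. Invalid cases carry NaN derived fields and a reason code.
    """

    elp: float = math.nan
    p_flat_meridian: float = math.nan
    p_steep_meridian: float = math.nan
    p_equivalent: float = math.nan
    torus: float = math.nan
    corneal_astigmatism: float = math.nan
    translation_ratio: float = math.nan
    valid: bool = True
    reason: str = "ok"
    case_id: Optional[str] = field(default=None, compare=False)


def keratometric_power(
    radius_mm: float, constants: OpticalConstants = DEFAULT_CONSTANTS
) -> float:
    """Total corneal power [D] from the front radius via the keratometer
    index: ``(n_k - 1) / r`` with r in metres."""
    if not radius_mm > 0:
        raise ValueError(f"corneal radius must be positive, got {radius_mm}")
    return (constants.n_keratometer - 1.0) / (radius_mm / 1000.0)


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """Spherical equivalent: sphere + cylinder/2 [D]."""
    return sphere + 0.5 * cylinder


def re_reference_sphere(
    sphere: float, actual_distance_m: float, target_distance_m: float
) -> float:
    """Re-reference a sphere measured at one lane length to another.

    The quantity ``sphere - 1/d`` (vergence leaving the spectacle lens) is
    the lane-invariant property of the corrected eye, so
    ``sphere_target = sphere_actual + 1/d_target - 1/d_actual``.
    """
    if not actual_distance_m > 0 or not target_distance_m > 0:
        raise ValueError("measurement distances must be positive")
    return sphere + 1.0 / target_distance_m - 1.0 / actual_distance_m


def propagate_vergence(v: float, distance_m: float, n: float) -> float:
    """Transfer a vergence V [D] across an axial gap of ``distance_m`` [m]
    in a medium of index ``n``: ``V' = V / (1 - (d/n) V)``.

    Negative distances undo a forward propagation exactly. Raises
    :class:`DegeneratePropagationError` when the focus falls inside the gap
    (vanishing denominator).
    """
    denom = 1.0 - (distance_m / n) * v
    if abs(denom) < 1e-12:
        raise DegeneratePropagationError(
            f"vergence {v} D focuses inside the {distance_m} m gap"
        )
    return v / denom


def _se_from_record(
    record: EyeRecord, constants: OpticalConstants = DEFAULT_CONSTANTS
) -> float:
    """Measured postop SE re-referenced to the model's lane length."""
    sphere = record.postop_sphere
    if (
        record.meas_distance_m is not None
        and record.meas_distance_m != constants.measurement_distance
    ):
        sphere = re_reference_sphere(
            sphere, record.meas_distance_m, constants.measurement_distance
        )
    return spherical_equivalent(sphere, record.postop_cylinder)


def predicted_postop_se(
    k_eq: float,
    axial_length: float,
    p_iol: float,
    elp: float,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Forward model: spherical-equivalent spectacle correction [D] of a
    pseudophakic eye with corneal power ``k_eq``, axial length
    ``axial_length`` [mm], IOL power ``p_iol`` and lens position ``elp``
    [mm].

    Works backwards from the retina: the vergence leaving the IOL must be
    ``n_media / (AL - ELP)``; stripping the IOL, the intraocular path, the
    cornea and the vertex gap yields the vergence just behind the spectacle
    lens, whose excess over the lane's object vergence is the correction.
    """
    if not (0 < elp < axial_length):
        raise ValueError("elp must lie strictly between 0 and the axial length")
    n_med = constants.n_media
    v = n_med / ((axial_length - elp) / 1000.0) - p_iol
    v = propagate_vergence(v, -elp / 1000.0, n_med)
    v = v - k_eq
    v = propagate_vergence(v, -constants.vertex_distance, constants.n_air)
    return v + 1.0 / constants.measurement_distance


def solve_elp(
    record: EyeRecord,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    bracket_mm: tuple[float, float] = ELP_BRACKET_MM,
    xtol_mm: float = 1e-9,
) -> float:
    """Back-solve the effective lens position [mm] from the measured
    postoperative spherical equivalent, formula-independently.

    Finds the ELP in ``bracket_mm`` at which the forward model reproduces
    the measured SE. The forward SE is strictly monotone in ELP over the
    physiologic range, so a bracketing root find is exact and unique.
    Raises :class:`ElpSolveError` when no root exists in the bracket.
    """
    se_measured = _se_from_record(record, constants)
    powers = MeridionalPowers.from_radii(record.r_flat, record.r_steep, constants)
    k_eq = powers.k_equivalent
    lo, hi = bracket_mm
    hi = min(hi, record.axial_length - 0.5)
    if not lo < hi:
        raise ElpSolveError("empty ELP bracket for this axial length")

    def f(elp_mm: float) -> float:
        return (
            predicted_postop_se(
                k_eq, record.axial_length, record.p_iol_implanted, elp_mm, constants
            )
            - se_measured
        )

    try:
        f_lo, f_hi = f(lo), f(hi)
    except DegeneratePropagationError as exc:
        raise ElpSolveError(f"degenerate optics at bracket edge: {exc}") from exc
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ElpSolveError(
            "measured refraction unreachable for any ELP in "
            f"[{lo}, {hi}] mm (elp_out_of_range)"
        )
    return float(brentq(f, lo, hi, xtol=xtol_mm))


def emmetropizing_power(
    k_meridian: float,
    axial_length: float,
    elp: float,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> float:
    """IOL power [D] in one meridian that leaves the eye fully corrected
    (zero spectacle refraction) for a corneal power ``k_meridian``.

    Chains the lane's object vergence through the vertex gap and the
    cornea to the IOL plane; the required IOL power is the difference
    between the vergence that focuses on the retina and the arriving one.
    """
    if not (0 < elp < axial_length):
        raise ValueError("elp must lie strictly between 0 and the axial length")
    v = -1.0 / constants.measurement_distance
    v = propagate_vergence(v, constants.vertex_distance, constants.n_air)
    v = v + k_meridian
    v = propagate_vergence(v, elp / 1000.0, constants.n_media)
    return constants.n_media / ((axial_length - elp) / 1000.0) - v


def full_correction_tiol(
    r_flat_mm: float,
    r_steep_mm: float,
    axial_length_mm: float,
    elp_mm: float,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    case_id: Optional[str] = None,
) -> CaseResult:
    """Per-meridian powers, torus and translation ratio of the fully
    correcting toric IOL at a common lens position.

    The same ELP is used for both meridians — a meridian-dependent lens
    position would be physically meaningless for a single implant. With
    ``astigmatism = K_steep - K_flat >= 0`` the flat corneal meridian needs
    the higher IOL power, so ``torus = P(flat) - P(steep) >= 0`` and the
    translation ratio is a positive scalar. Zero corneal astigmatism leaves
    the ratio undefined and flags the case.
    """
    powers = MeridionalPowers.from_radii(r_flat_mm, r_steep_mm, constants)
    try:
        p_flat = emmetropizing_power(powers.k_flat, axial_length_mm, elp_mm, constants)
        p_steep = emmetropizing_power(
            powers.k_steep, axial_length_mm, elp_mm, constants
        )
    except DegeneratePropagationError:
        return CaseResult(
            elp=elp_mm,
            corneal_astigmatism=powers.astigmatism,
            valid=False,
            reason="degenerate_propagation",
            case_id=case_id,
        )
    torus = p_flat - p_steep
    astig = powers.astigmatism
    # exchanging the meridian labels flips torus and astigmatism together,
    # so the ratio is label-invariant; only exactly-zero astigmatism is
    # flagged as undefined
    if astig == 0.0:
        return CaseResult(
            elp=elp_mm,
            p_flat_meridian=p_flat,
            p_steep_meridian=p_steep,
            p_equivalent=0.5 * (p_flat + p_steep),
            torus=torus,
            corneal_astigmatism=astig,
            valid=False,
            reason="zero_astigmatism",
            case_id=case_id,
        )
    return CaseResult(
        elp=elp_mm,
        p_flat_meridian=p_flat,
        p_steep_meridian=p_steep,
        p_equivalent=0.5 * (p_flat + p_steep),
        torus=torus,
        corneal_astigmatism=astig,
        translation_ratio=torus / astig,
        valid=True,
        reason="ok",
        case_id=case_id,
    )
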