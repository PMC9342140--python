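"""Environment-independent ("basic") cardiovascular profile.

Derives the resting and maximal heart rate, stroke volume, cardiac output and
arteriovenous oxygen difference (AVO2diff) of an individual from age, mass,
height, sex and baseline maximal oxygen uptake, and evaluates the graded
exercise response in a thermoneutral, euhydrated, sea-level state.  Heart rate
and cardiac output are linear in the fraction of the V̇o2 reserve; stroke
volume follows from the cardiac-output principle CO = SV·HR and is therefore
mildly nonlinear.

All stroke volumes are mL·beat⁻¹, cardiac outputs L·min⁻¹, oxygen uptakes
L·min⁻¹ and oxygen extractions L[O2]·L[blood]⁻¹; every unit conversion is an
explicit factor of 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DomainError, ValidationError

__all__ = [
    "IndividualProfile",
    "BasicCardio",
    "resting_vo2",
    "max_stroke_volume",
    "resting_stroke_volume",
    "max_heart_rate",
    "resting_heart_rate",
    "derive_basic_cardio",
    "vo2_reserve_fraction",
    "basic_response",
]

#: Mean resting stroke volume (mL·beat⁻¹) across the aggregated study groups;
#: no usable fitness relation exists at rest, so a constant is used.
SV_REST_ML = 85.1

#: Default intercept of the resting-heart-rate vs. relative-fitness relation.
HR_REST_INTERCEPT = 90.93

Sex = Literal["male", "female"]
Vo2restDivisor = Literal["weir", "literal"]


@dataclass(frozen=True)
class IndividualProfile:
    """Anthropometric and fitness inputs of one simulated person.

    Parameters
    ----------
    age : float
        Age in years.
    mass : float
        Pre-exposure body mass in kg.
    height : float
        Stature in cm.
    sex : {"male", "female"}
    vo2max : float
        Baseline (sea-level, thermoneutral) maximal oxygen uptake, L·min⁻¹.
    rer : float
        Respiratory exchange ratio assumed at rest, default 0.7.
    """

    age: float
    mass: float
    height: float
    sex: Sex
    vo2max: float
    rer: float = 0.7

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if self.mass <= 0:
            raise ValidationError(f"mass must be positive, got {self.mass}")
        if self.height <= 0:
            raise ValidationError(f"height must be positive, got {self.height}")
        if self.vo2max <= 0:
            raise ValidationError(f"vo2max must be positive, got {self.vo2max}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 0.7 <= self.rer <= 1.0:
            raise ValidationError(f"rer must lie in [0.7, 1.0], got {self.rer}")


@dataclass(frozen=True)
class BasicCardio:
    """Derived environment-independent cardiovascular constants."""

    vo2max: float  # L·min⁻¹ (carried through for reserve calculations)
    vo2rest: float  # L·min⁻¹
    sv_rest: float  # mL·beat⁻¹
    sv_max: float  # mL·beat⁻¹
    hr_rest: float  # beats·min⁻¹
    hr_max: float  # beats·min⁻¹
    co_rest: float  # L·min⁻¹
    co_max: float  # L·min⁻¹
    avo2diff_rest: float  # L·L⁻¹
    avo2diff_max: float  # L·L⁻¹


def resting_vo2(
    profile: IndividualProfile, divisor: Vo2restDivisor = "weir"
) -> float:
    """Resting oxygen uptake (L·min⁻¹) from resting energy expenditure.

    Resting energy expenditure follows Mifflin–St Jeor
    (male: ``10·mass + 6.25·height − 5·age + 5`` kcal·day⁻¹; female: the same
    with ``−161``), converted to L[O2]·min⁻¹ via 1440 min·day⁻¹ and an oxygen
    energy equivalent.  With ``divisor="weir"`` (default) the equivalent is the
    Weir form ``3.941 + 1.106·RER`` kcal·L⁻¹, which yields a physiologically
    plausible resting V̇o2 of about 0.25 L·min⁻¹ for a 75-kg adult;
    ``divisor="literal"`` uses ``5.05·RER`` instead.
    """
    sex_const = 5.0 if profile.sex == "male" else -161.0
    ree_kcal_day = (
        10.0 * profile.mass + 6.25 * profile.height - 5.0 * profile.age + sex_const
    )
    if divisor == "weir":
        kcal_per_litre = 3.941 + 1.106 * profile.rer
    elif divisor == "literal":
        kcal_per_litre = 5.05 * profile.rer
    else:
        raise ValidationError(f"unknown vo2rest divisor {divisor!r}")
    return ree_kcal_day / 1440.0 / kcal_per_litre


def max_stroke_volume(vo2max: float) -> float:
    """Maximal stroke volume (mL·beat⁻¹), linear in absolute V̇o2max (L·min⁻¹)."""
    if vo2max < 0:
        raise ValidationError(f"vo2max must be non-negative, got {vo2max}")
    return 40.59 + 24.81 * vo2max


def resting_stroke_volume() -> float:
    """Resting stroke volume: the constant 85.1 mL·beat⁻¹ for every individual."""
    return SV_REST_ML


def max_heart_rate(age: float) -> float:
    """Maximal heart rate (beats·min⁻¹) from age (Tanaka relation)."""
    if age < 0:
        raise ValidationError(f"age must be non-negative, got {age}")
    return 208.0 - 0.7 * age


def resting_heart_rate(
    vo2max: float, mass: float, intercept: float = HR_REST_INTERCEPT
) -> float:
    """Resting heart rate (beats·min⁻¹) from mass-relative fitness.

    The predictor is relative V̇o2max in mL·kg⁻¹·min⁻¹, obtained here from the
    absolute value (L·min⁻¹) and body mass (kg).  ``intercept`` admits the
    recalibrated value 100.93 used by the ``adjusted`` preset.
    """
    if vo2max < 0:
        raise ValidationError(f"vo2max must be non-negative, got {vo2max}")
    if mass <= 0:
        raise ValidationError(f"mass must be positive, got {mass}")
    relative = vo2max / mass * 1000.0  # mL·kg⁻¹·min⁻¹
    return intercept - 0.64 * relative


def derive_basic_cardio(
    profile: IndividualProfile,
    vo2rest_divisor: Vo2restDivisor = "weir",
    hr_rest_intercept: float = HR_REST_INTERCEPT,
) -> BasicCardio:
    """Derive every basic cardiovascular constant for one individual.

    Raises
    ------
    DomainError
        If the predicted resting heart rate is not below the maximal heart
        rate (extreme age/fitness combinations outside the model's domain),
        or if the resting V̇o2 is not below V̇o2max.
    """
    vo2rest = resting_vo2(profile, divisor=vo2rest_divisor)
    sv_rest = resting_stroke_volume()
    sv_max = max_stroke_volume(profile.vo2max)
    hr_rest = resting_heart_rate(profile.vo2max, profile.mass, hr_rest_intercept)
    hr_max = max_heart_rate(profile.age)
    if hr_rest >= hr_max:
        raise DomainError(
            f"resting HR {hr_rest:.1f} >= maximal HR {hr_max:.1f}; "
            "profile outside model domain"
        )
    if not 0 < vo2rest < profile.vo2max:
        raise DomainError(
            f"resting V̇o2 {vo2rest:.3f} not within (0, vo2max={profile.vo2max})"
        )
    co_rest = sv_rest / 1000.0 * hr_rest
    co_max = sv_max / 1000.0 * hr_max
    return BasicCardio(
        vo2max=profile.vo2max,
        vo2rest=vo2rest,
        sv_rest=sv_rest,
        sv_max=sv_max,
        hr_rest=hr_rest,
        hr_max=hr_max,
        co_rest=co_rest,
        co_max=co_max,
        avo2diff_rest=vo2rest / co_rest,
        avo2diff_max=profile.vo2max / co_max,
    )


def vo2_reserve_fraction(vo2: float, basic: BasicCardio) -> float:
    """Workload as a fraction of the V̇o2 reserve (0 at rest, 1 at V̇o2max).

    Values above 1 (supramaximal demand) are returned unclamped; feasibility
    is adjudicated by the scenario simulator, not here.
    """
    if vo2 < basic.vo2rest:
        raise ValidationError(
            f"vo2 {vo2:.4f} below resting value {basic.vo2rest:.4f}: "
            "sub-resting workloads are undefined"
        )
    return (vo2 - basic.vo2rest) / (basic.vo2max - basic.vo2rest)


def basic_response(
    fraction: float, basic: BasicCardio
) -> tuple[float, float, float]:
    """Heart rate, cardiac output and stroke volume at a reserve fraction.

    HR and CO interpolate linearly between their resting and maximal values;
    SV = CO/HR·1000 follows from the cardiac-output principle.

    Returns
    -------
    (hr, co, sv) : beats·min⁻¹, L·min⁻¹, mL·beat⁻¹
    """
    if fraction < 0:
        raise ValidationError(f"reserve fraction must be >= 0, got {fraction}")
    hr = (basic.hr_max - basic.hr_rest) * fraction + basic.hr_rest
    co = (basic.co_max - basic.co_rest) * fraction + basic.co_rest
    sv = co / hr * 1000.0
    return hr, co, sv
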