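"""Cardiac heat strain index (CHSI) and heat/dehydration modulation.

Heat stress lowers cardiac filling pressure and stroke volume while raising
the cardiac output needed for thermoregulation; dehydration compounds the
strain.  Both are folded into a single dimensionless index on a °C-equivalent
scale that replaces the body-temperature elevation ΔT_body in the fitted heat
sensitivities:

* ``synergistic``: 0.433·D + 0.091·ΔT + 0.125·D·ΔT (fitted to endurance-trained
  runners; D is dehydration in % of body mass, ΔT in °C above 36.54 °C),
* ``additive``: 0.5·D + 0.5·ΔT (equal contributions; the variant that
  validated best against heterogeneous individuals and the default).

Per CHSI unit, resting SV rises by 2.5 % and resting CO by 31.3 %, while
maximal SV and CO both fall by 8.3 %.  Maximal heart rate is unaffected: the
equal sensitivity of maximal SV and CO means the decline at V̇o2max is wholly
inotropic, whereas at rest a chronotropic compensation (a raised resting HR)
follows from the diverging resting SV and CO.

The "(heat, altitude)"-style quantities produced here carry no altitude term
themselves; altitude enters the combined response only through the
altitude-compensated cardiac output in the reserve fraction and through the
attenuated maximal extraction in the environment-limited V̇o2max.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .errors import DomainError, ValidationError
from .profile import BasicCardio

__all__ = [
    "T_BODY_REFERENCE_C",
    "ThermalState",
    "CHSIValue",
    "HeatSensitivities",
    "EnvCardio",
    "dehydration_percent",
    "chsi",
    "modulate_cardio",
    "resting_hr_env",
    "reserve_fraction_env",
    "exercise_response_env",
    "vo2max_env",
]

#: Thermoneutral mean body temperature (°C) above which heat strain accrues.
T_BODY_REFERENCE_C = 36.54

CHSIVariant = Literal["synergistic", "additive"]


@dataclass(frozen=True)
class ThermalState:
    """Instantaneous thermal and hydration state.

    Mean body temperature is the mass-weighted 0.2·T_skin + 0.8·T_core unless
    supplied directly via ``t_body`` (used when only T_body is known).  The
    elevation above the 36.54 °C reference is floored at zero: the model was
    fitted for heat strain and a hypothermic state produces no (negative)
    cardiac heat strain.
    """

    t_core: float | None = None  # °C
    t_skin: float | None = None  # °C
    dehydration_pct: float = 0.0  # % of body mass lost
    t_body: float | None = None  # °C, overrides the 0.2/0.8 weighting

    def __post_init__(self) -> None:
        if self.t_body is None and (self.t_core is None or self.t_skin is None):
            raise ValidationError(
                "either t_body or both t_core and t_skin must be given"
            )
        if self.dehydration_pct < 0:
            raise ValidationError(
                f"dehydration_pct must be >= 0, got {self.dehydration_pct}"
            )

    @property
    def mean_body_temperature(self) -> float:
        if self.t_body is not None:
            return self.t_body
        return 0.2 * self.t_skin + 0.8 * self.t_core

    @property
    def delta_t_body(self) -> float:
        """Elevation of mean body temperature above reference, floored at 0 °C."""
        return max(0.0, self.mean_body_temperature - T_BODY_REFERENCE_C)


@dataclass(frozen=True)
class CHSIValue:
    """A cardiac heat strain index value with the variant that produced it."""

    value: float
    variant: CHSIVariant

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(f"CHSI must be >= 0, got {self.value}")


@dataclass(frozen=True)
class HeatSensitivities:
    """Relative change per CHSI unit of each modulated quantity.

    The ``published`` set is the default; ``adjusted`` scales the sensitivities
    by 1.5 (and is paired with a +10 beats·min⁻¹ resting-HR intercept) — an
    exploratory recalibration that removed the systematic HR underestimation
    in validation.
    """

    sv_max: float = -0.083
    co_max: float = -0.083
    sv_rest: float = 0.025
    co_rest: float = 0.313

    @classmethod
    def published(cls) -> "HeatSensitivities":
        return cls()

    @classmethod
    def adjusted(cls) -> "HeatSensitivities":
        return cls(sv_max=-0.125, co_max=-0.125, sv_rest=0.038, co_rest=0.47)


@dataclass(frozen=True)
class EnvCardio:
    """Heat/dehydration-modulated resting and maximal cardiovascular values."""

    sv_max_env: float  # mL·beat⁻¹
    sv_rest_env: float  # mL·beat⁻¹
    co_max_env: float  # L·min⁻¹
    co_rest_env: float  # L·min⁻¹
    hr_rest_env: float  # beats·min⁻¹
    domain_ok: bool = field(default=True)


def dehydration_percent(
    elapsed_exercise_min: float,
    total_exercise_min: float,
    total_mass_loss_kg: float,
    mass_kg: float,
) -> float:
    """Progressive dehydration (% of body mass) by linear interpolation.

    The final mass loss is spread linearly over exercise time; rest phases
    accrue nothing.  Elapsed time past the stated total holds at the full
    loss rather than extrapolating.
    """
    if elapsed_exercise_min < 0 or total_mass_loss_kg < 0:
        raise ValidationError("elapsed time and mass loss must be >= 0")
    if mass_kg <= 0:
        raise ValidationError(f"mass must be positive, got {mass_kg}")
    if elapsed_exercise_min == 0:
        return 0.0
    if total_exercise_min <= 0:
        raise ValidationError(
            "total_exercise_min must be positive when exercise time has elapsed"
        )
    time_fraction = min(elapsed_exercise_min / total_exercise_min, 1.0)
    return time_fraction * total_mass_loss_kg / mass_kg * 100.0


def chsi(thermal: ThermalState, variant: CHSIVariant = "additive") -> CHSIValue:
    """Cardiac heat strain index for a thermal state, floored at zero."""
    d = thermal.dehydration_pct
    dt = thermal.delta_t_body
    if variant == "synergistic":
        value = 0.433 * d + 0.091 * dt + 0.125 * d * dt
    elif variant == "additive":
        value = 0.5 * d + 0.5 * dt
    else:
        raise ValidationError(f"unknown CHSI variant {variant!r}")
    return CHSIValue(value=max(0.0, value), variant=variant)


def modulate_cardio(
    basic: BasicCardio,
    index: CHSIValue,
    sensitivities: HeatSensitivities | None = None,
) -> EnvCardio:
    """Apply the heat sensitivities to resting and maximal SV and CO.

    At CHSI = 0 every field equals its basic counterpart.  A strain severe
    enough that the modulated maximal CO no longer exceeds the modulated
    resting CO is flagged ``domain_ok=False`` rather than raised, so a
    simulation can report the offending timestep.
    """
    s = sensitivities or HeatSensitivities.published()
    c = index.value
    sv_max_env = (1.0 + c * s.sv_max) * basic.sv_max
    co_max_env = (1.0 + c * s.co_max) * basic.co_max
    sv_rest_env = (1.0 + c * s.sv_rest) * basic.sv_rest
    co_rest_env = (1.0 + c * s.co_rest) * basic.co_rest
    hr_rest_env = co_rest_env / (sv_rest_env / 1000.0)
    domain_ok = co_max_env > co_rest_env and sv_max_env > 0 and co_max_env > 0
    return EnvCardio(
        sv_max_env=sv_max_env,
        sv_rest_env=sv_rest_env,
        co_max_env=co_max_env,
        co_rest_env=co_rest_env,
        hr_rest_env=hr_rest_env,
        domain_ok=domain_ok,
    )


def resting_hr_env(env: EnvCardio) -> float:
    """Resting heart rate under strain: modulated resting CO over resting SV.

    The division carries an explicit ×1000 (L·min⁻¹ over mL·beat⁻¹).
    """
    if env.sv_rest_env <= 0:
        raise DomainError("modulated resting SV must be positive")
    return env.co_rest_env / env.sv_rest_env * 1000.0


def reserve_fraction_env(
    basic: BasicCardio, env: EnvCardio, co_altitude: float
) -> float:
    """Fraction of the cardiac reserve consumed under combined strain.

    The altitude-compensated cardiac output is referenced to the *basic*
    resting CO in the numerator and denominator (resting strain raises the
    resting CO but not the reserve origin); the ceiling is the heat-modulated
    maximal CO.  May exceed 1 — task failure is adjudicated downstream.
    """
    denom = env.co_max_env - basic.co_rest
    if denom <= 0:
        raise DomainError(
            "modulated maximal CO does not exceed basic resting CO; "
            "reserve fraction undefined"
        )
    return (co_altitude - basic.co_rest) / denom


def exercise_response_env(
    basic: BasicCardio, env: EnvCardio, fraction: float
) -> tuple[float, float, float]:
    """HR, CO and SV under strain at a given environment reserve fraction.

    HR interpolates from the strained resting HR to the (unmodulated) maximal
    HR; CO from the strained resting CO to the strained maximal CO; SV follows
    from the cardiac-output principle.

    Returns
    -------
    (hr, co, sv) : beats·min⁻¹, L·min⁻¹, mL·beat⁻¹
    """
    if fraction < 0:
        raise ValidationError(f"reserve fraction must be >= 0, got {fraction}")
    hr_rest = resting_hr_env(env)
    hr = (basic.hr_max - hr_rest) * fraction + hr_rest
    co = (env.co_max_env - env.co_rest_env) * fraction + env.co_rest_env
    sv = co / hr * 1000.0
    return hr, co, sv


def vo2max_env(avo2diff_max_altitude: float, co_max_env: float) -> float:
    """Environment-limited V̇o2max (L·min⁻¹), by the Fick principle.

    The product of the altitude-attenuated maximal extraction and the
    heat-attenuated maximal cardiac output; reduces to the basic V̇o2max at
    zero strain and sea level.
    """
    if avo2diff_max_altitude <= 0 or co_max_env <= 0:
        raise ValidationError("extraction and cardiac output must be positive")
    return avo2diff_max_altitude * co_max_env
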