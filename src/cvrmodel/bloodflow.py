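"""Regional partition of cardiac output and active-muscle oxygen extraction.

The environment-modulated cardiac output is split into core (viscera and
major organs), skin, and active-muscle flows:

* the core fraction declines quadratically with the relative cardiac demand
  FCO = CO/CO_max(env): ``0.86·FCO² − 1.79·FCO + 1.06``;
* skin flow is a thermoneutral baseline of 5 % of the basic resting CO plus
  the whole heat-excess cardiac output (CO(heat) − CO(altitude));
* muscle flow is the remainder, so the three flows sum to the total exactly.

Muscle flow then yields a workload-dependent active-muscle oxygen extraction,
(V̇o2 − V̇o2rest)/MusBF, in place of the fixed 0.2 L·L⁻¹ that older
thermophysiological models assume.  Extreme strain can drive the remainder
negative or the extraction above 1 L·L⁻¹; such rows are flagged out-of-domain
rather than clamped, which would silently break conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "BloodFlowPartition",
    "core_fraction",
    "core_blood_flow",
    "skin_blood_flow",
    "partition",
]


@dataclass(frozen=True)
class BloodFlowPartition:
    """Core/skin/muscle flows (L·min⁻¹) and active-muscle extraction for one state."""

    core_bf: float
    skin_bf: float
    muscle_bf: float
    fco: float  # fraction of the environment-modulated maximal CO
    active_muscle_avo2diff: float  # L[O2]·L[blood]⁻¹
    domain_ok: bool


def core_fraction(fco: float) -> float:
    """Fraction of CO directed to the core at relative cardiac demand ``fco``.

    The quadratic is kept unclamped; at the FCO = 0 extrapolation it exceeds 1,
    but resting demand in practice sits near FCO ≈ 0.2.
    """
    return 0.86 * fco * fco - 1.79 * fco + 1.06


def core_blood_flow(co_env: float, co_max_env: float) -> float:
    """Core blood flow (L·min⁻¹): total CO times the core fraction."""
    if co_max_env <= 0:
        raise ValidationError(f"co_max_env must be positive, got {co_max_env}")
    if co_env <= 0:
        raise ValidationError(f"co_env must be positive, got {co_env}")
    return co_env * core_fraction(co_env / co_max_env)


def skin_blood_flow(co_rest_basic: float, co_env: float, co_altitude: float) -> float:
    """Skin blood flow (L·min⁻¹): 5 % of basic resting CO plus the heat excess."""
    return 0.05 * co_rest_basic + (co_env - co_altitude)


def partition(
    co_env: float,
    co_max_env: float,
    co_rest_basic: float,
    co_altitude: float,
    vo2: float,
    vo2rest: float,
) -> BloodFlowPartition:
    """Partition one timestep's cardiac output and derive muscle extraction.

    At resting V̇o2 the active-muscle extraction is 0 by convention (zero
    numerator); a non-positive muscle flow or an extraction above 1 L·L⁻¹
    sets ``domain_ok=False``.
    """
    core = core_blood_flow(co_env, co_max_env)
    skin = skin_blood_flow(co_rest_basic, co_env, co_altitude)
    muscle = co_env - skin - core
    excess_vo2 = vo2 - vo2rest
    # every compartment flow must be non-negative in the supported domain
    domain_ok = skin >= 0 and core >= 0
    if muscle <= 0:
        domain_ok = False
        extraction = float("nan") if excess_vo2 > 0 else 0.0
    elif excess_vo2 <= 0:
        extraction = 0.0
    else:
        extraction = excess_vo2 / muscle
        if extraction > 1.0:
            domain_ok = False
    return BloodFlowPartition(
        core_bf=core,
        skin_bf=skin,
        muscle_bf=muscle,
        fco=co_env / co_max_env,
        active_muscle_avo2diff=extraction,
        domain_ok=domain_ok,
    )
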