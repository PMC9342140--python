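"""Time-series scenario simulation, fixtures, tabular I/O and validation harness.

A scenario is a pandas DataFrame with one row per evaluation time point.
Recognised columns (units in the names):

===================== ==========================================================
``time_min``          strictly increasing evaluation times (required)
``phase``             ``rest`` or ``exercise`` (required)
``workload_fraction`` exercise intensity as a fraction of V̇o2max
``workload_vo2_L_min`` absolute oxygen demand; exclusive with the fraction
``t_core_C``/``t_skin_C``  core and mean skin temperature
``t_body_C``          mean body temperature directly (overrides the 0.2/0.8 mix)
``altitude_km``       altitude above sea level (0–8 km)
``mass_loss_kg``      body-mass loss (final total, or cumulative; see SimConfig)
``dehydration_pct``   precomputed dehydration, overrides ``mass_loss_kg``
===================== ==========================================================

The model is algebraic: each row is evaluated independently except for
progressive dehydration, which accrues over exercise time only and is held
(never reset) through rest phases.  Rows are never clamped or truncated at
task failure; every row carries feasibility and domain flags and the summary
reports the first failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .altitude import (
    MAX_ALTITUDE_KM,
    altitude_attenuation,
    cardiac_output_at_altitude,
)
from .bloodflow import partition
from .config import SimConfig
from .errors import ValidationError
from .heat import (
    ThermalState,
    chsi,
    dehydration_percent,
    exercise_response_env,
    modulate_cardio,
    reserve_fraction_env,
    resting_hr_env,
    vo2max_env,
)
from .profile import BasicCardio, IndividualProfile, derive_basic_cardio

__all__ = [
    "SCENARIO_COLUMNS",
    "SimulationResult",
    "RegressionFit",
    "simulate",
    "check_feasibility",
    "reference_profile",
    "fixture_graded_test",
    "fixture_rest_exercise",
    "regress_predicted_vs_measured",
    "read_scenario",
    "write_scenario",
    "write_results",
]

logger = logging.getLogger(__name__)

TIME = "time_min"
PHASE = "phase"
FRACTION = "workload_fraction"
VO2 = "workload_vo2_L_min"
TCORE = "t_core_C"
TSKIN = "t_skin_C"
TBODY = "t_body_C"
ALTITUDE = "altitude_km"
MASS_LOSS = "mass_loss_kg"
DEHYDRATION = "dehydration_pct"

SCENARIO_COLUMNS = (
    TIME, PHASE, FRACTION, VO2, TCORE, TSKIN, TBODY, ALTITUDE, MASS_LOSS,
    DEHYDRATION,
)

#: Relative tolerance for feasibility comparisons.
FEASIBILITY_RTOL = 1e-9


@dataclass(frozen=True)
class SimulationResult:
    """Per-row predictions plus a task-failure summary."""

    table: pd.DataFrame
    first_failure_time_min: float | None
    limiting_factor: str  # vo2max_exceeded | hr_ceiling | domain_violation | none
    basic: BasicCardio | None = field(repr=False, default=None)


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares of measured on predicted heart rate."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def check_feasibility(
    required_vo2: float,
    vo2max_env_value: float,
    predicted_hr: float,
    hr_max: float,
    hr_ceiling: float | None = None,
) -> tuple[bool, str]:
    """Adjudicate task failure for one timestep.

    Checks run in fixed order — oxygen demand against the environment-limited
    V̇o2max, predicted HR against the maximal HR, then any user HR ceiling —
    and the first violation names the limiting factor.
    """
    if required_vo2 <= 0 or vo2max_env_value <= 0 or predicted_hr <= 0 or hr_max <= 0:
        raise ValidationError("feasibility inputs must be positive")
    tol = 1.0 + FEASIBILITY_RTOL
    if required_vo2 > vo2max_env_value * tol:
        return False, "vo2max_exceeded"
    if predicted_hr > hr_max * tol:
        return False, "hr_ceiling"
    if hr_ceiling is not None and predicted_hr > hr_ceiling * tol:
        return False, "hr_ceiling"
    return True, "none"


def _validate_scenario(scenario: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(scenario, pd.DataFrame):
        raise ValidationError("scenario must be a pandas DataFrame")
    for col in (TIME, PHASE):
        if col not in scenario.columns:
            raise ValidationError(f"scenario is missing mandatory column {col!r}")
    unknown = [c for c in scenario.columns if c not in SCENARIO_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown scenario columns: %s", unknown)
    df = scenario.reset_index(drop=True)
    times = df[TIME].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise ValidationError("non-numeric or missing values in time_min")
    if np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 1
        raise ValidationError(f"time_min must be strictly increasing (row {bad})")
    for i, phase in enumerate(df[PHASE]):
        if phase not in ("rest", "exercise"):
            raise ValidationError(f"row {i}: phase must be rest|exercise, got {phase!r}")
    has_frac = FRACTION in df.columns
    has_vo2 = VO2 in df.columns
    for i, row in df.iterrows():
        frac_given = has_frac and pd.notna(row[FRACTION])
        vo2_given = has_vo2 and pd.notna(row[VO2])
        if frac_given and vo2_given:
            raise ValidationError(
                f"row {i}: workload_fraction and workload_vo2_L_min are mutually "
                "exclusive on one row"
            )
        if row[PHASE] == "exercise" and not (frac_given or vo2_given):
            raise ValidationError(f"row {i}: exercise row has no resolvable workload")
        if ALTITUDE in df.columns and pd.notna(row[ALTITUDE]):
            km = float(row[ALTITUDE])
            if km < 0 or km > MAX_ALTITUDE_KM:
                raise ValidationError(
                    f"row {i}: altitude {km} km outside supported 0–"
                    f"{MAX_ALTITUDE_KM:g} km"
                )
    return df


def _exercise_clock(df: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Cumulative exercise minutes at each row and the total exercise time.

    The interval ending at a row counts as exercise when that row's phase is
    exercise, so the clock reaches the total on the final exercise row.
    """
    times = df[TIME].to_numpy(dtype=float)
    dt = np.diff(times, prepend=times[0])
    is_ex = (df[PHASE] == "exercise").to_numpy()
    elapsed = np.cumsum(np.where(is_ex, dt, 0.0))
    return elapsed, float(elapsed[-1])


def _row_dehydration(
    df: pd.DataFrame, mass_kg: float, mode: str
) -> np.ndarray:
    if DEHYDRATION in df.columns and df[DEHYDRATION].notna().all():
        return df[DEHYDRATION].to_numpy(dtype=float)
    if MASS_LOSS not in df.columns:
        return np.zeros(len(df))
    loss = df[MASS_LOSS].fillna(0.0).to_numpy(dtype=float)
    if mode == "cumulative":
        return loss / mass_kg * 100.0
    elapsed, total = _exercise_clock(df)
    final_loss = float(np.max(loss))
    if total <= 0 or final_loss <= 0:
        return np.zeros(len(df))
    return np.array([
        dehydration_percent(e, total, final_loss, mass_kg) for e in elapsed
    ])


def _row_thermal(row: pd.Series, dehyd: float) -> ThermalState:
    if TBODY in row.index and pd.notna(row.get(TBODY)):
        return ThermalState(t_body=float(row[TBODY]), dehydration_pct=dehyd)
    if pd.notna(row.get(TCORE)) and pd.notna(row.get(TSKIN)):
        return ThermalState(
            t_core=float(row[TCORE]),
            t_skin=float(row[TSKIN]),
            dehydration_pct=dehyd,
        )
    # no temperatures supplied: thermoneutral reference
    return ThermalState(t_body=36.54, dehydration_pct=dehyd)


def simulate(
    profile: IndividualProfile,
    scenario: pd.DataFrame,
    config: SimConfig | None = None,
) -> SimulationResult:
    """Run the cardiovascular model over a scenario time series.

    Each row yields the heat/dehydration/altitude-modulated heart rate,
    cardiac output, stroke volume and oxygen extraction, the regional
    blood-flow partition, the environment-limited V̇o2max, and feasibility
    flags.  Identical inputs give bit-identical outputs.
    """
    config = config or SimConfig()
    df = _validate_scenario(scenario)
    basic = derive_basic_cardio(
        profile,
        vo2rest_divisor=config.vo2rest_divisor,
        hr_rest_intercept=config.hr_rest_intercept,
    )
    sens = config.heat_sensitivities
    dehyd = _row_dehydration(df, profile.mass, config.mass_loss_mode)

    records = []
    first_failure: float | None = None
    first_limiting = "none"
    for i, row in df.iterrows():
        km = float(row[ALTITUDE]) if ALTITUDE in df.columns and pd.notna(
            row.get(ALTITUDE)
        ) else 0.0
        thermal = _row_thermal(row, float(dehyd[i]))
        index = chsi(thermal, config.chsi_variant)
        env = modulate_cardio(basic, index, sens)
        att = altitude_attenuation(km)
        avo2diff_max_alt = basic.avo2diff_max * (1.0 - att)
        vo2cap = vo2max_env(avo2diff_max_alt, env.co_max_env)

        if row[PHASE] == "rest":
            vo2 = basic.vo2rest
        elif VO2 in df.columns and pd.notna(row.get(VO2)):
            vo2 = float(row[VO2])
        else:
            frac = float(row[FRACTION])
            target = vo2cap if config.workload_relative_to_env else profile.vo2max
            vo2 = frac * target
        if vo2 < basic.vo2rest:
            raise ValidationError(
                f"row {i}: workload resolves to {vo2:.4f} L·min⁻¹, below the "
                f"resting V̇o2 {basic.vo2rest:.4f}"
            )

        co_alt = cardiac_output_at_altitude(basic, vo2, km)
        frac_env = reserve_fraction_env(basic, env, co_alt)
        hr, co, sv = exercise_response_env(basic, env, frac_env)
        bf = partition(co, env.co_max_env, basic.co_rest, co_alt, vo2, basic.vo2rest)
        feasible, limiting = check_feasibility(
            vo2, vo2cap, hr, basic.hr_max, config.hr_ceiling
        )
        if feasible and not (env.domain_ok and bf.domain_ok):
            feasible, limiting = False, "domain_violation"
        if not feasible and first_failure is None:
            first_failure = float(row[TIME])
            first_limiting = limiting

        records.append({
            TIME: float(row[TIME]),
            PHASE: row[PHASE],
            "vo2_L_min": vo2,
            "reserve_fraction": frac_env,
            DEHYDRATION: float(dehyd[i]),
            "delta_t_body_C": thermal.delta_t_body,
            "chsi": index.value,
            ALTITUDE: km,
            "hr_bpm": hr,
            "co_L_min": co,
            "sv_mL": sv,
            "avo2diff": vo2 / co,
            "co_altitude_L_min": co_alt,
            "vo2max_env_L_min": vo2cap,
            "hr_rest_env_bpm": resting_hr_env(env),
            "core_bf_L_min": bf.core_bf,
            "skin_bf_L_min": bf.skin_bf,
            "muscle_bf_L_min": bf.muscle_bf,
            "active_muscle_avo2diff": bf.active_muscle_avo2diff,
            "fco": bf.fco,
            "feasible": feasible,
            "limiting_factor": limiting,
            "domain_ok": env.domain_ok and bf.domain_ok,
        })

    table = pd.DataFrame.from_records(records)
    return SimulationResult(
        table=table,
        first_failure_time_min=first_failure,
        limiting_factor=first_limiting,
        basic=basic,
    )


# ---------------------------------------------------------------------------
# Fixture scenarios
# ---------------------------------------------------------------------------

#: Body-temperature / final-mass-loss / altitude presets for the graded test.
_GRADED_ENVIRONMENTS = {
    "thermoneutral": {"t_body": 36.6, "mass_loss": 0.25, "altitude": 0.0},
    "heated": {"t_body": 39.0, "mass_loss": 1.5, "altitude": 0.0},
    "sea_level": {"t_body": 36.6, "mass_loss": 0.25, "altitude": 0.0},
    "high_altitude": {"t_body": 36.6, "mass_loss": 0.25, "altitude": 5.0},
}

_FIT_LEVELS = {"fit": 4.0, "unfit": 2.5}


def reference_profile(fit_level: str = "fit") -> IndividualProfile:
    """The 25-yr, 75-kg, 175-cm male used in the graded-test simulations.

    ``fit`` has a V̇o2max of 4.0 L·min⁻¹, ``unfit`` 2.5 L·min⁻¹.
    """
    if fit_level not in _FIT_LEVELS:
        raise ValidationError(f"fit_level must be fit|unfit, got {fit_level!r}")
    return IndividualProfile(
        age=25.0, mass=75.0, height=175.0, sex="male", vo2max=_FIT_LEVELS[fit_level]
    )


def fixture_graded_test(
    fit_level: str = "fit", environment: str = "thermoneutral"
) -> pd.DataFrame:
    """Graded exercise test to exhaustion: rest, then 20–100 % V̇o2max.

    One rest row followed by nine 2-min exercise steps at fractions 0.2
    through 1.0 of the basic V̇o2max, with the environment (mean body
    temperature, final mass loss, altitude) held constant per the preset.
    The workload fractions do not depend on fitness; ``fit_level`` selects
    the matching :func:`reference_profile` and is validated here.
    """
    if fit_level not in _FIT_LEVELS:
        raise ValidationError(f"fit_level must be fit|unfit, got {fit_level!r}")
    if environment not in _GRADED_ENVIRONMENTS:
        raise ValidationError(
            f"environment must be one of {sorted(_GRADED_ENVIRONMENTS)}, "
            f"got {environment!r}"
        )
    env = _GRADED_ENVIRONMENTS[environment]
    rows = [{
        TIME: 0.0, PHASE: "rest", FRACTION: 0.0, TBODY: env["t_body"],
        ALTITUDE: env["altitude"], MASS_LOSS: 0.0,
    }]
    for step in range(9):
        rows.append({
            TIME: 2.0 * (step + 1),
            PHASE: "exercise",
            FRACTION: (step + 2) / 10.0,  # 0.2, 0.3, ... 1.0 as exact decimals
            TBODY: env["t_body"],
            ALTITUDE: env["altitude"],
            MASS_LOSS: env["mass_loss"],
        })
    return pd.DataFrame(rows)


def _rest_exercise_rows(
    rest_min: float,
    exercise_min: float,
    step_min: float,
    fractions: list[tuple[float, float]],
    t_body_start: float,
    t_body_end: float,
    total_mass_loss_kg: float,
    altitude_km: float,
) -> pd.DataFrame:
    """Rest + exercise skeleton with a linear body-temperature ramp."""
    rows = []
    t = 0.0
    end = rest_min + exercise_min
    while t <= end + 1e-9:
        if t <= rest_min:
            phase, frac, t_body = "rest", 0.0, t_body_start
        else:
            phase = "exercise"
            ex_elapsed = t - rest_min
            frac = next(f for limit, f in fractions if ex_elapsed <= limit + 1e-9)
            t_body = t_body_start + (t_body_end - t_body_start) * ex_elapsed / exercise_min
        rows.append({
            TIME: t, PHASE: phase, FRACTION: frac, TBODY: t_body,
            ALTITUDE: altitude_km,
            MASS_LOSS: total_mass_loss_kg if phase == "exercise" else 0.0,
        })
        t += step_min
    return pd.DataFrame(rows)


def fixture_rest_exercise(
    protocol: str,
    t_body_start: float = 36.6,
    t_body_end: float | None = None,
    total_mass_loss_kg: float | None = None,
) -> pd.DataFrame:
    """Rest-then-exercise validation-style protocol skeletons, 5-min resolution.

    Protocols
    ---------
    ``fixed_load_heat``
        30-min rest then 60-min fixed low-intensity exercise (35 % V̇o2max,
        approximating 60-W cycling) in the heat.
    ``graded_climates``
        30-min rest then 30 min at 25 % and 30 min at 45 % V̇o2max.
    ``altitude_absolute``
        30-min rest then 30 min at 35 % and 30 min at 50 % of *sea-level*
        V̇o2max at 4 km (the equivalent of 12.7 % inspired O2).
    ``altitude_relative``
        The same rows as ``altitude_absolute``; run it with
        ``SimConfig(workload_relative_to_env=True)`` so the fractions are
        taken against the altitude-attenuated V̇o2max.

    Temperature rises linearly from ``t_body_start`` over the exercise period
    to ``t_body_end`` (default 38.0 °C for heat protocols, 37.2 °C for the
    cool altitude protocols); mass loss defaults to 1.0 kg (heat) or 0.5 kg
    (altitude) and is interpolated over exercise time during simulation.
    """
    heat = protocol in ("fixed_load_heat", "graded_climates")
    if t_body_end is None:
        t_body_end = 38.0 if heat else 37.2
    if total_mass_loss_kg is None:
        total_mass_loss_kg = 1.0 if heat else 0.5
    if protocol == "fixed_load_heat":
        fractions = [(60.0, 0.35)]
        km = 0.0
    elif protocol == "graded_climates":
        fractions = [(30.0, 0.25), (60.0, 0.45)]
        km = 0.0
    elif protocol in ("altitude_absolute", "altitude_relative"):
        fractions = [(30.0, 0.35), (60.0, 0.50)]
        km = 4.0
    else:
        raise ValidationError(f"unknown protocol {protocol!r}")
    return _rest_exercise_rows(
        rest_min=30.0, exercise_min=60.0, step_min=5.0, fractions=fractions,
        t_body_start=t_body_start, t_body_end=t_body_end,
        total_mass_loss_kg=total_mass_loss_kg, altitude_km=km,
    )


# ---------------------------------------------------------------------------
# Validation harness
# ---------------------------------------------------------------------------

def regress_predicted_vs_measured(
    predicted, measured, strata=None
) -> dict[str, RegressionFit]:
    """OLS of measured on predicted heart rate, pooled and per stratum.

    Measured data are supplied by the caller; this is a harness only.  Each
    stratum needs at least three pairs and non-degenerate variance in the
    predicted values.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValidationError("predicted and measured must have equal length")
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "pooled": (predicted, measured)
    }
    if strata is not None:
        labels = np.asarray(strata)
        if labels.shape != predicted.shape:
            raise ValidationError("strata labels must match pair count")
        for label in pd.unique(labels):
            mask = labels == label
            groups[str(label)] = (predicted[mask], measured[mask])
    fits: dict[str, RegressionFit] = {}
    for name, (x, y) in groups.items():
        if x.size < 3:
            raise ValidationError(f"stratum {name!r} has fewer than 3 pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValidationError(f"stratum {name!r} has degenerate variance")
        res = stats.linregress(x, y)
        fits[name] = RegressionFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            n=int(x.size),
        )
    return fits


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_scenario(path) -> pd.DataFrame:
    """Read and validate a scenario CSV (comma-separated, decimal point)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise ValidationError(f"cannot read scenario {path}: {exc}") from exc
    for col in df.columns:
        if col in (PHASE,):
            continue
        if col in SCENARIO_COLUMNS and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad.index[0]) if len(bad) else "?"
            raise ValidationError(f"non-numeric value in column {col!r}, row {row}")
    return _validate_scenario(df)


def write_scenario(path, scenario: pd.DataFrame) -> None:
    """Write a scenario CSV; write-then-read round-trips exactly."""
    scenario.to_csv(path, index=False)


def write_results(path, result: SimulationResult) -> None:
    """Write the per-row prediction table of a simulation to CSV."""
    result.table.to_csv(path, index=False)
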