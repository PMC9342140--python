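"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import ValidationError
from .heat import HeatSensitivities
from .profile import HR_REST_INTERCEPT

__all__ = ["SimConfig"]


@dataclass(frozen=True)
class SimConfig:
    """Numeric and structural options for a simulation run.

    Attributes
    ----------
    chsi_variant : {"additive", "synergistic"}
        Cardiac heat strain index formulation; ``additive`` (default) is the
        variant that validated best on heterogeneous individuals.
    vo2rest_divisor : {"weir", "literal"}
        Oxygen energy-equivalent used to convert resting energy expenditure
        to L·min⁻¹; ``weir`` (3.941 + 1.106·RER kcal·L⁻¹, default) or the
        ``literal`` 5.05·RER form.
    calibration : {"published", "adjusted"}
        ``published`` uses the fitted heat sensitivities and resting-HR
        intercept as printed; ``adjusted`` scales the heat sensitivities by
        1.5 and raises the resting-HR intercept by 10 beats·min⁻¹.
    workload_relative_to_env : bool
        Interpret fractional workloads against the environment-limited
        V̇o2max instead of the basic one (relative-workload protocols).
    mass_loss_mode : {"total", "cumulative"}
        ``total``: the scenario's mass-loss column holds the final loss and
        progressive dehydration is interpolated linearly over exercise time;
        ``cumulative``: the column already holds the loss accrued by each row.
    hr_ceiling : float or None
        Optional user heart-rate ceiling (beats·min⁻¹) for task-failure
        adjudication, e.g. an occupational work-tolerability limit.
    """

    chsi_variant: Literal["additive", "synergistic"] = "additive"
    vo2rest_divisor: Literal["weir", "literal"] = "weir"
    calibration: Literal["published", "adjusted"] = "published"
    workload_relative_to_env: bool = False
    mass_loss_mode: Literal["total", "cumulative"] = "total"
    hr_ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.chsi_variant not in ("additive", "synergistic"):
            raise ValidationError(f"unknown CHSI variant {self.chsi_variant!r}")
        if self.vo2rest_divisor not in ("weir", "literal"):
            raise ValidationError(f"unknown vo2rest divisor {self.vo2rest_divisor!r}")
        if self.calibration not in ("published", "adjusted"):
            raise ValidationError(f"unknown calibration {self.calibration!r}")
        if self.mass_loss_mode not in ("total", "cumulative"):
            raise ValidationError(f"unknown mass_loss_mode {self.mass_loss_mode!r}")
        if self.hr_ceiling is not None and self.hr_ceiling <= 0:
            raise ValidationError("hr_ceiling must be positive when given")

    @property
    def hr_rest_intercept(self) -> float:
        return HR_REST_INTERCEPT + (10.0 if self.calibration == "adjusted" else 0.0)

    @property
    def heat_sensitivities(self) -> HeatSensitivities:
        if self.calibration == "adjusted":
            return HeatSensitivities.adjusted()
        return HeatSensitivities.published()
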