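"""From prescription to a concrete three-step preparation plan.

A continuous-infusion order in µg/kg/min is turned into the sequence a nurse
actually executes: (1) pick the drug, (2) dilute a stock volume into a final
syringe volume, (3) program the pump in ml/h.  The link between the two unit
systems is

    pump_rate [ml/h] = dose_rate [µg/kg/min] x weight [kg] x 60 / C [µg/ml]

where C is the concentration of the prepared syringe.  The planner chooses C
so that the pump rate lands in a comfortable band (default 1-20 ml/h),
preferring the conventional rate-table concentration C = 60 x scale x weight
so that round prescriptions map to round pump rates, and falling back to
scaling that concentration by 2/5/10 factors when it would leave the band or
exceed the stock strength.

The same module provides the inverse map (delivered dose from an executed
preparation), bolus volumes, and the deviation metrics used to score
medication errors, including the "lucky path" case where a miscalculated
preparation reaches the right final dose by chance.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .formulary import DoseMode, Drug, Patient

__all__ = [
    "PreparationPlan",
    "DeviationResult",
    "ErrorClass",
    "BolusVolume",
    "InfeasiblePlanError",
    "compute_infusion_plan",
    "delivered_dose_rate",
    "rate_from_concentration",
    "bolus_volume",
    "assess_deviation",
    "ERROR_TOLERANCE_STRICT_PCT",
    "ERROR_TOLERANCE_CLINICAL_PCT",
]

#: any deviation beyond this counts as a miscalculation (strict preset)
ERROR_TOLERANCE_STRICT_PCT = 5.0
#: deviation large enough to be considered clinically critical
ERROR_TOLERANCE_CLINICAL_PCT = 20.0

#: default comfortable pump-rate band, ml/h
DEFAULT_RATE_BAND = (1.0, 20.0)
#: default admissible syringe volumes, ml
DEFAULT_FINAL_VOLUMES = (20.0, 50.0)

# concentration scaling factors tried in order of increasing departure from
# the rate-table concentration; powers of 2, 5 and 10 keep mental arithmetic
# tractable at the bedside
_SCALE_FACTORS = sorted(
    {m * 10.0**e for m in (1.0, 2.0, 5.0) for e in range(-3, 4)},
    key=lambda f: (abs(math.log10(f)), f < 1.0),
)


class InfeasiblePlanError(ValueError):
    """No admissible concentration yields a pump rate in the configured band."""


class PreparationPlan(BaseModel):
    """The fully specified three-step preparation for one infusion order."""

    model_config = ConfigDict(frozen=True)

    drug: Drug
    weight: float  # kg
    prescribed_rate: float  # µg/kg/min
    stock_volume: float  # ml drawn from vials
    diluent_volume: float  # ml
    final_volume: float  # ml
    final_concentration: float  # µg/ml
    pump_rate: float  # ml/h
    vials_needed: int

    @model_validator(mode="after")
    def _invariants(self) -> "PreparationPlan":
        if abs(self.stock_volume + self.diluent_volume - self.final_volume) > 0.01:
            raise ValueError("stock_volume + diluent_volume != final_volume")
        mass_in = self.drug.stock_concentration * self.stock_volume
        mass_out = self.final_concentration * self.final_volume
        if mass_in > 0 and not math.isclose(mass_in, mass_out, rel_tol=1e-3):
            raise ValueError("mass not conserved between stock draw and final syringe")
        if self.pump_rate <= 0:
            raise ValueError("pump_rate must be > 0")
        return self

    @property
    def stock_mass(self) -> float:
        """µg of drug drawn from vials."""
        return self.drug.stock_concentration * self.stock_volume

    def rounded(self) -> "RoundedPlan":
        """Bedside presentation: volumes to 0.01 ml, pump rate to 0.1 ml/h.

        Rounding is applied only here, never inside invariant checks.
        """
        return RoundedPlan(
            drug=self.drug.name,
            weight=self.weight,
            prescribed_rate=self.prescribed_rate,
            stock_volume=round(self.stock_volume, 2),
            diluent_volume=round(self.diluent_volume, 2),
            final_volume=round(self.final_volume, 2),
            final_concentration=round(self.final_concentration, 1),
            pump_rate=round(self.pump_rate, 1),
            vials_needed=self.vials_needed,
        )


@dataclass(frozen=True)
class RoundedPlan:
    drug: str
    weight: float
    prescribed_rate: float
    stock_volume: float
    diluent_volume: float
    final_volume: float
    final_concentration: float
    pump_rate: float
    vials_needed: int

    def describe(self) -> str:
        return (
            f"{self.drug} {self.prescribed_rate} µg/kg/min for {self.weight} kg:\n"
            f"  1. draw {self.stock_volume} ml of stock ({self.vials_needed} vial(s))\n"
            f"  2. dilute with {self.diluent_volume} ml to {self.final_volume} ml "
            f"({self.final_concentration} µg/ml)\n"
            f"  3. run pump at {self.pump_rate} ml/h"
        )


class ErrorClass(str, enum.Enum):
    NONE = "none"
    UNDERDOSE = "underdose"
    OVERDOSE = "overdose"
    LUCKY_PATH = "lucky_path"


@dataclass(frozen=True)
class DeviationResult:
    """Deviation of a delivered dose from the prescription, in percent."""

    prescribed: float
    delivered: float
    deviation_pct: float
    abs_deviation_pct: float
    is_error: bool
    error_class: ErrorClass


@dataclass(frozen=True)
class BolusVolume:
    volume_ml: float
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __float__(self) -> float:
        return self.volume_ml


def compute_infusion_plan(
    patient: Patient,
    drug: Drug,
    dose_rate: float,
    final_volume: float = 50.0,
    *,
    rate_band: tuple[float, float] = DEFAULT_RATE_BAND,
    admissible_volumes: Sequence[float] = DEFAULT_FINAL_VOLUMES,
    max_vials: int = 10,
) -> PreparationPlan:
    """Plan a continuous infusion: dilution volumes, concentration, pump rate.

    Parameters
    ----------
    patient, drug, dose_rate, final_volume
        The order: a continuous-mode drug at ``dose_rate`` µg/kg/min, made up
        to ``final_volume`` ml (must be one of ``admissible_volumes``).
    rate_band
        Acceptable pump-rate interval in ml/h; concentrations are chosen so
        the programmed rate falls inside it.
    max_vials
        Refuse plans needing more stock vials than this.

    Raises
    ------
    InfeasiblePlanError
        If no candidate concentration satisfies the rate band, syringe
        capacity and vial budget simultaneously.
    """
    if drug.mode is not DoseMode.CONTINUOUS:
        raise ValueError(f"{drug.name} is not a continuous-infusion drug")
    if dose_rate <= 0:
        raise ValueError("dose_rate must be > 0")
    if not any(math.isclose(final_volume, v) for v in admissible_volumes):
        raise ValueError(
            f"final_volume {final_volume} ml not in admissible set {sorted(admissible_volumes)}"
        )

    weight = patient.weight
    if drug.shann_scale is not None:
        # rate-table concentration: 3 x scale x weight mg in 50 ml
        base_conc = 60.0 * drug.shann_scale * weight
    else:
        # no table convention for this drug: aim mid-band
        target_rate = math.sqrt(rate_band[0] * rate_band[1])
        base_conc = dose_rate * weight * 60.0 / target_rate

    for factor in _SCALE_FACTORS:
        conc = base_conc * factor
        rate = dose_rate * weight * 60.0 / conc
        if not rate_band[0] <= rate <= rate_band[1]:
            continue
        stock_volume = conc * final_volume / drug.stock_concentration
        if stock_volume > final_volume:
            continue
        vials = math.ceil(conc * final_volume / drug.vial_mass - 1e-9)
        if vials > max_vials:
            continue
        return PreparationPlan(
            drug=drug,
            weight=weight,
            prescribed_rate=dose_rate,
            stock_volume=stock_volume,
            diluent_volume=final_volume - stock_volume,
            final_volume=final_volume,
            final_concentration=conc,
            pump_rate=rate,
            vials_needed=vials,
        )
    raise InfeasiblePlanError(
        f"no concentration puts {drug.name} {dose_rate} µg/kg/min at {weight} kg "
        f"inside {rate_band} ml/h with <= {max_vials} vials"
    )


def rate_from_concentration(concentration: float, pump_rate: float, weight: float) -> float:
    """Dose rate (µg/kg/min) delivered by a syringe of given concentration."""
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return concentration * pump_rate / (60.0 * weight)


def delivered_dose_rate(plan_as_executed: PreparationPlan, pump_rate: float, weight: float) -> float:
    """Inverse of the planner's conversion: µg/kg/min actually delivered."""
    return rate_from_concentration(plan_as_executed.final_concentration, pump_rate, weight)


def bolus_volume(
    drug: Drug, dose: float, weight: float, *, syringe_max_ml: float = 60.0
) -> BolusVolume:
    """Volume (ml) of stock to push for a direct IV bolus of ``dose`` mg/kg."""
    if drug.mode is not DoseMode.BOLUS:
        raise ValueError(f"{drug.name} is not a bolus drug")
    if dose <= 0:
        raise ValueError("dose must be > 0")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    volume = dose * weight * 1000.0 / drug.stock_concentration
    warnings: tuple[str, ...] = ()
    if volume > syringe_max_ml:
        warnings = (
            f"bolus volume {volume:.1f} ml exceeds syringe maximum {syringe_max_ml} ml",
        )
    return BolusVolume(volume_ml=volume, warnings=warnings)


def assess_deviation(
    prescribed: float,
    executed_plan: PreparationPlan,
    reference_plan: PreparationPlan,
    tolerance_pct: float = ERROR_TOLERANCE_STRICT_PCT,
) -> DeviationResult:
    """Score an executed preparation against the prescription and reference.

    An observation is an error when the delivered dose deviates from the
    prescription by more than ``tolerance_pct`` percent (classified over- or
    underdose by sign), or when the final dose is right but an intermediate
    step (stock or diluent volume) departed from the reference plan by more
    than the tolerance — the right dosage reached by chance.
    """
    if prescribed == 0:
        raise ValueError("deviation undefined for a zero prescription")
    if tolerance_pct < 0:
        raise ValueError("tolerance_pct must be >= 0")
    delivered = delivered_dose_rate(
        executed_plan, executed_plan.pump_rate, executed_plan.weight
    )
    deviation_pct = 100.0 * (delivered - prescribed) / prescribed
    abs_dev = abs(deviation_pct)
    if abs_dev > tolerance_pct:
        cls = ErrorClass.OVERDOSE if deviation_pct > 0 else ErrorClass.UNDERDOSE
        return DeviationResult(prescribed, delivered, deviation_pct, abs_dev, True, cls)

    def step_off(executed: float, reference: float) -> bool:
        if reference == 0:
            return abs(executed) > 1e-9
        return abs(executed - reference) / abs(reference) * 100.0 > tolerance_pct

    if step_off(executed_plan.stock_volume, reference_plan.stock_volume) or step_off(
        executed_plan.diluent_volume, reference_plan.diluent_volume
    ):
        return DeviationResult(
            prescribed, delivered, deviation_pct, abs_dev, True, ErrorClass.LUCKY_PATH
        )
    return DeviationResult(
        prescribed, delivered, deviation_pct, abs_dev, False, ErrorClass.NONE
    )
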