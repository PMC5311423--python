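"""Conventional infusion-rate-table preparation (Frank Shann convention).

The rate table is the comparator method: for each drug a weight-scaled mass
is diluted to a fixed syringe volume so that the pump rate maps linearly to
the dose rate.  In the canonical 50 ml formulation, diluting

    mass = 3 x scale x weight   [mg]

gives a syringe in which 1 ml/h delivers exactly ``scale`` µg/kg/min; the
pump rate for any prescription is then dose_rate / scale ml/h, with no
further arithmetic.  ``scale`` is the drug's ``shann_scale`` formulary field
(1 for dopamine/dobutamine, 0.1 for the catecholamine pressors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .formulary import Drug, Formulary
from .preparation import PreparationPlan

__all__ = ["ShannEntry", "shann_entry", "shann_table"]


@dataclass(frozen=True)
class ShannEntry:
    """One row of the rate table, specialized to a patient weight."""

    drug: Drug
    weight: float  # kg
    mass_to_dilute: float  # mg
    final_volume: float  # ml
    rate_scale: float  # µg/kg/min per 1 ml/h

    @property
    def concentration(self) -> float:
        """µg/ml of the prepared syringe."""
        return self.mass_to_dilute * 1000.0 / self.final_volume

    @property
    def stock_volume(self) -> float:
        """ml of stock drawn to obtain ``mass_to_dilute``."""
        return self.mass_to_dilute * 1000.0 / self.drug.stock_concentration

    @property
    def vials_needed(self) -> int:
        return math.ceil(self.mass_to_dilute * 1000.0 / self.drug.vial_mass - 1e-9)

    def pump_rate_for(self, dose_rate: float) -> float:
        """ml/h for a prescription in µg/kg/min."""
        if dose_rate <= 0:
            raise ValueError("dose_rate must be > 0")
        return dose_rate / self.rate_scale

    def as_plan(self, dose_rate: float) -> PreparationPlan:
        """The table preparation expressed as an executable plan."""
        stock = self.stock_volume
        return PreparationPlan(
            drug=self.drug,
            weight=self.weight,
            prescribed_rate=dose_rate,
            stock_volume=stock,
            diluent_volume=self.final_volume - stock,
            final_volume=self.final_volume,
            final_concentration=self.concentration,
            pump_rate=self.pump_rate_for(dose_rate),
            vials_needed=self.vials_needed,
        )


def shann_entry(drug: Drug, weight: float, final_volume: float = 50.0) -> ShannEntry:
    """Rate-table row for one drug and patient weight."""
    if drug.shann_scale is None:
        raise ValueError(f"{drug.name} has no shann_scale; not on the rate table")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if final_volume <= 0:
        raise ValueError("final_volume must be > 0")
    # mass such that 1 ml/h delivers rate_scale µg/kg/min at this volume;
    # reduces to 3 x scale x weight mg at the conventional 50 ml
    mass_mg = 0.06 * drug.shann_scale * weight * final_volume
    return ShannEntry(
        drug=drug,
        weight=weight,
        mass_to_dilute=mass_mg,
        final_volume=final_volume,
        rate_scale=drug.shann_scale,
    )


def shann_table(formulary: Formulary, weight: float, final_volume: float = 50.0) -> list[ShannEntry]:
    """One entry per eligible drug, in deterministic name order."""
    eligible = sorted(
        (d for d in formulary if d.shann_scale is not None), key=lambda d: d.name
    )
    return [shann_entry(d, weight, final_volume) for d in eligible]
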