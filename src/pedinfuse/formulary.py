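"""Drug formulary: typed models of drugs, patients and prescriptions.

All quantities are stored in canonical units — micrograms (µg), millilitres
(ml), kilograms (kg), seconds (s), dose rates in µg/kg/min.  Working in µg
rather than mg removes the decimal-point shift that is the classic source of
tenfold paediatric dosing errors; any mg-denominated input is converted on
load.

The formulary file is a YAML document with a top-level ``drugs`` list of
key/value records (see ``data/formulary_schema.json`` for the published
schema).  A default formulary with six continuous-infusion vasoactive drugs
and nineteen direct-IV bolus drugs ships with the package.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

__all__ = [
    "DoseMode",
    "Drug",
    "Patient",
    "Prescription",
    "DoseWarning",
    "Formulary",
    "FormularyError",
    "load_formulary",
    "write_formulary",
    "default_formulary",
    "validate_prescription",
]

#: tolerance on the vial mass / concentration x volume consistency check
MASS_BALANCE_RTOL = 1e-3


class FormularyError(ValueError):
    """Raised for malformed or inconsistent formulary content."""


class DoseMode(str, enum.Enum):
    CONTINUOUS = "continuous"
    BOLUS = "bolus"


class Drug(BaseModel):
    """One formulary entry.

    Exactly the fields of the declared ``mode`` must be populated: a
    continuous-infusion drug carries a dose-rate range in µg/kg/min (and
    optionally the rate-table scale factor), a bolus drug carries a unit
    dose in mg/kg.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    mode: DoseMode
    stock_concentration: float  # µg/ml
    vial_volume: float  # ml
    vial_mass: Optional[float] = None  # µg per vial; derived when omitted
    dose_rate_min: Optional[float] = None  # µg/kg/min
    dose_rate_max: Optional[float] = None  # µg/kg/min
    bolus_dose_per_kg: Optional[float] = None  # mg/kg
    shann_scale: Optional[float] = None  # µg/kg/min delivered per 1 ml/h

    @field_validator("stock_concentration", "vial_volume")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @model_validator(mode="after")
    def _check_mode_fields(self) -> "Drug":
        if self.vial_mass is None:
            object.__setattr__(
                self, "vial_mass", self.stock_concentration * self.vial_volume
            )
        expected = self.stock_concentration * self.vial_volume
        if not math.isclose(self.vial_mass, expected, rel_tol=MASS_BALANCE_RTOL):
            raise ValueError(
                f"vial_mass {self.vial_mass} µg inconsistent with "
                f"stock_concentration x vial_volume = {expected} µg"
            )
        if self.mode is DoseMode.CONTINUOUS:
            if self.dose_rate_min is None or self.dose_rate_max is None:
                raise ValueError("continuous drug requires dose_rate_min and dose_rate_max")
            if self.dose_rate_min > self.dose_rate_max:
                raise ValueError("dose_rate_min > dose_rate_max")
            if self.bolus_dose_per_kg is not None:
                raise ValueError("bolus_dose_per_kg set on a continuous drug")
        else:
            if self.bolus_dose_per_kg is None:
                raise ValueError("bolus drug requires bolus_dose_per_kg")
            if self.bolus_dose_per_kg <= 0:
                raise ValueError("bolus_dose_per_kg must be > 0")
            if self.dose_rate_min is not None or self.dose_rate_max is not None:
                raise ValueError("dose-rate range set on a bolus drug")
            if self.shann_scale is not None:
                raise ValueError("shann_scale is only meaningful for continuous drugs")
        return self


class Patient(BaseModel):
    model_config = ConfigDict(frozen=True)

    weight: float  # kg
    age: Optional[float] = None  # years

    @field_validator("weight")
    @classmethod
    def _weight_range(cls, v: float) -> float:
        if not 0 < v <= 150:
            raise ValueError("weight must be in (0, 150] kg")
        return v


class Prescription(BaseModel):
    """An ordered dose: a rate in µg/kg/min (continuous) or mg/kg (bolus)."""

    model_config = ConfigDict(frozen=True)

    drug: str
    dose_rate: Optional[float] = None  # µg/kg/min
    dose: Optional[float] = None  # mg/kg
    issued_at: float = 0.0  # s since scenario start
    override: bool = False

    @model_validator(mode="after")
    def _one_dose(self) -> "Prescription":
        if (self.dose_rate is None) == (self.dose is None):
            raise ValueError("exactly one of dose_rate (continuous) or dose (bolus) required")
        return self


class DoseWarning(BaseModel):
    """Non-fatal advisory attached to a prescription check."""

    model_config = ConfigDict(frozen=True)

    drug: str
    message: str


class Formulary:
    """Ordered, name-unique collection of :class:`Drug` entries."""

    def __init__(self, drugs: Iterable[Drug]):
        self._drugs: dict[str, Drug] = {}
        for d in drugs:
            if d.name in self._drugs:
                raise FormularyError(f"duplicate drug name: {d.name!r}")
            self._drugs[d.name] = d
        if not self._drugs:
            raise FormularyError("no drugs defined")

    def __len__(self) -> int:
        return len(self._drugs)

    def __iter__(self):
        return iter(self._drugs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._drugs

    def __getitem__(self, name: str) -> Drug:
        try:
            return self._drugs[name]
        except KeyError:
            raise KeyError(f"unknown drug: {name!r}") from None

    def continuous(self) -> list[Drug]:
        return [d for d in self if d.mode is DoseMode.CONTINUOUS]

    def bolus(self) -> list[Drug]:
        return [d for d in self if d.mode is DoseMode.BOLUS]

    def __eq__(self, other) -> bool:
        return isinstance(other, Formulary) and list(self) == list(other)


# keys accepted in formulary files; mg-denominated variants are converted to µg
_FIELD_ALIASES = {
    "name": ("name", 1.0),
    "mode": ("mode", None),
    "stock_concentration_ug_per_ml": ("stock_concentration", 1.0),
    "stock_concentration_mg_per_ml": ("stock_concentration", 1000.0),
    "vial_volume_ml": ("vial_volume", 1.0),
    "vial_mass_ug": ("vial_mass", 1.0),
    "vial_mass_mg": ("vial_mass", 1000.0),
    "dose_rate_min": ("dose_rate_min", 1.0),
    "dose_rate_max": ("dose_rate_max", 1.0),
    "bolus_dose_mg_per_kg": ("bolus_dose_per_kg", 1.0),
    "shann_scale": ("shann_scale", 1.0),
}


def _parse_entry(raw: dict, index: int) -> Drug:
    if not isinstance(raw, dict):
        raise FormularyError(f"drug entry {index}: expected a key/value record")
    fields: dict = {}
    for key, value in raw.items():
        if key not in _FIELD_ALIASES:
            raise FormularyError(f"drug entry {index}: unknown field {key!r}")
        target, scale = _FIELD_ALIASES[key]
        if target in fields:
            raise FormularyError(
                f"drug entry {index}: field {target!r} given in more than one unit"
            )
        if scale is not None and value is not None and not isinstance(value, str):
            value = float(value) * scale
        fields[target] = value
    try:
        return Drug(**fields)
    except ValidationError as exc:
        err = exc.errors()[0]
        loc = ".".join(str(p) for p in err["loc"]) or "entry"
        raise FormularyError(
            f"drug entry {index} ({raw.get('name', '?')}): field {loc}: {err['msg']}"
        ) from exc


def load_formulary(path: Union[str, Path, None] = None) -> Formulary:
    """Read a YAML formulary; with no path, load the packaged default."""
    if path is None:
        text = (
            resources.files("pedinfuse").joinpath("data/default_formulary.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not doc or "drugs" not in doc or not doc["drugs"]:
        raise FormularyError("no drugs defined")
    drugs = [_parse_entry(raw, i) for i, raw in enumerate(doc["drugs"], start=1)]
    return Formulary(drugs)


def default_formulary() -> Formulary:
    return load_formulary(None)


def write_formulary(formulary: Formulary, path: Union[str, Path]) -> None:
    """Serialize back to YAML in canonical units (round-trips with load)."""
    entries = []
    for d in formulary:
        e: dict = {
            "name": d.name,
            "mode": d.mode.value,
            "stock_concentration_ug_per_ml": d.stock_concentration,
            "vial_volume_ml": d.vial_volume,
            "vial_mass_ug": d.vial_mass,
        }
        if d.mode is DoseMode.CONTINUOUS:
            e["dose_rate_min"] = d.dose_rate_min
            e["dose_rate_max"] = d.dose_rate_max
            if d.shann_scale is not None:
                e["shann_scale"] = d.shann_scale
        else:
            e["bolus_dose_mg_per_kg"] = d.bolus_dose_per_kg
        entries.append(e)
    Path(path).write_text(yaml.safe_dump({"drugs": entries}, sort_keys=False))


def validate_prescription(p: Prescription, formulary: Formulary) -> list[DoseWarning]:
    """Check an order against the drug's labelled dose range.

    Out-of-range doses produce warnings, never exceptions: resuscitation
    dosing intentionally exceeds labelled ranges at clinician discretion
    (set ``override=True`` to silence the warning).
    """
    drug = formulary[p.drug]
    warnings: list[DoseWarning] = []
    if drug.mode is DoseMode.CONTINUOUS:
        if p.dose_rate is None:
            raise FormularyError(f"{drug.name} is a continuous drug; prescription needs dose_rate")
        if p.override:
            return warnings
        if not drug.dose_rate_min <= p.dose_rate <= drug.dose_rate_max:
            warnings.append(
                DoseWarning(
                    drug=drug.name,
                    message=(
                        f"dose rate {p.dose_rate} µg/kg/min outside labelled range "
                        f"[{drug.dose_rate_min}, {drug.dose_rate_max}] µg/kg/min"
                    ),
                )
            )
    else:
        if p.dose is None:
            raise FormularyError(f"{drug.name} is a bolus drug; prescription needs dose (mg/kg)")
        if p.override:
            return warnings
        if not math.isclose(p.dose, drug.bolus_dose_per_kg, rel_tol=0.5):
            warnings.append(
                DoseWarning(
                    drug=drug.name,
                    message=(
                        f"bolus dose {p.dose} mg/kg differs from the usual "
                        f"{drug.bolus_dose_per_kg} mg/kg by more than 50%"
                    ),
                )
            )
    return warnings
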