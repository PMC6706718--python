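"""Model parameters: domain types, validation, config I/O and age lookups.

Every input of the cost-utility model lives here as a validated type:
fracture incidence by age band, excess-mortality relative risks after
fracture, fracture utility multipliers, treatment effect and persistence,
costs, economic settings, the post-fracture re-fracture elevation schedule,
and the probabilistic-sensitivity-analysis distribution catalogue.

Configuration is a single YAML document; :func:`load_model_config` /
:func:`save_model_config` round-trip it losslessly. The bundled
``default_iran_2018`` preset reproduces the published Iranian tariff and
epidemiology tables this package was built around.
"""

from __future__ import annotations

import enum
import importlib.resources
import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .life_tables import (
    BaselineUtilityCurve,
    GompertzParams,
    LifeTable,
    gompertz_life_table,
    read_life_table,
)


class FractureType(str, enum.Enum):
    """The four fracture sites the model distinguishes."""

    HIP = "hip"
    VERTEBRAL = "vertebral"
    WRIST = "wrist"
    OTHER = "other_nonvertebral"


FRACTURE_TYPES: tuple[FractureType, ...] = tuple(FractureType)

#: Mortality follow-up groups: wrist and other non-vertebral fractures share
#: the "other" excess-mortality column.
MortalitySite = Literal["hip", "vertebral", "other"]


def mortality_site_of(ftype: FractureType) -> str:
    return ftype.value if ftype in (FractureType.HIP, FractureType.VERTEBRAL) else "other"


class HealthStateLabel(str, enum.Enum):
    WELL = "well"
    ACUTE_FRACTURE = "acute_fracture"
    POST_HIP = "post_hip"
    POST_VERTEBRAL = "post_vertebral"
    DEAD = "dead"


class HealthState(BaseModel):
    """One of the model's seven states.

    ``acute_fracture`` carries the fracture-site tag; hip, vertebral and
    "other" acute fractures occupy distinct boxes in the state diagram, with
    wrist and other non-vertebral fractures sharing the "other" box but
    keeping their tag for cost and utility purposes.
    """

    label: HealthStateLabel
    fracture: Optional[FractureType] = None

    @model_validator(mode="after")
    def _check(self) -> "HealthState":
        if (self.label == HealthStateLabel.ACUTE_FRACTURE) != (self.fracture is not None):
            raise ValueError("HealthState: acute_fracture (and only it) carries a fracture tag")
        return self

    model_config = {"frozen": True}


def _band_label(band: tuple[int, Optional[int]]) -> str:
    lo, hi = band
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


class IncidenceTable(BaseModel):
    """Annual fracture incidence per 1000 women by 5-year age band.

    Bands are contiguous from age 50 and the last band is open-ended.
    Above the open band's anchor age, incidence is extrapolated along the
    straight line through the last two band anchors (band midpoints, the
    open band anchored one spacing beyond the previous midpoint).
    """

    bands: list[tuple[int, Optional[int]]]
    per_1000: dict[FractureType, list[float]]

    @model_validator(mode="after")
    def _check(self) -> "IncidenceTable":
        if not self.bands or self.bands[0][0] != 50:
            raise ValueError("incidence: bands must start at age 50")
        if self.bands[-1][1] is not None:
            raise ValueError("incidence: last band must be open-ended")
        for (lo, hi), (lo2, _) in zip(self.bands, self.bands[1:]):
            if hi is None or lo2 != hi + 1:
                raise ValueError("incidence: bands must be contiguous, ordered and non-overlapping")
        for ft in FRACTURE_TYPES:
            vals = self.per_1000.get(ft)
            if vals is None:
                raise ValueError(f"incidence: missing fracture type '{ft.value}'")
            if len(vals) != len(self.bands):
                raise ValueError(f"incidence[{ft.value}]: expected {len(self.bands)} band values")
            if any(v < 0 for v in vals):
                raise ValueError(f"incidence[{ft.value}]: values must be >= 0")
        return self

    def anchors(self) -> list[float]:
        """Band anchor ages: closed-band midpoints, open band one spacing on."""
        mids = [(lo + hi) / 2.0 for lo, hi in self.bands[:-1]]
        spacing = mids[-1] - mids[-2] if len(mids) >= 2 else 5.0
        return mids + [mids[-1] + spacing]


def incidence_lookup(age: float, ftype: FractureType, table: IncidenceTable) -> float:
    """Per-person annual fracture probability at ``age`` for ``ftype``.

    Piecewise constant within printed bands (band of the integer part of
    age); linear extrapolation through the last two band anchors above the
    open band's anchor, floored at 0 and capped at 1.
    """
    if not (50.0 <= age <= 100.0):
        raise ValueError(f"age {age} outside supported range [50, 100]")
    vals = table.per_1000[FractureType(ftype)]
    anchors = table.anchors()
    if age > anchors[-1]:
        x0, x1 = anchors[-2], anchors[-1]
        v = vals[-2] + (vals[-1] - vals[-2]) / (x1 - x0) * (age - x0)
    else:
        a = int(math.floor(age))
        v = vals[-1]
        for (lo, hi), val in zip(table.bands, vals):
            if hi is not None and lo <= a <= hi:
                v = val
                break
    return min(max(v / 1000.0, 0.0), 1.0)


class MortalityRiskTable(BaseModel):
    """Relative risk of death after fracture, by age band.

    ``first_year`` multipliers apply during the first year after a hip,
    vertebral or "other" fracture; ``subsequent`` multipliers apply while in
    the post-hip / post-vertebral states. Other fractures carry no excess
    mortality beyond the first year. Ages outside the printed bands clamp to
    the nearest band.
    """

    bands: list[tuple[int, int]]
    first_year: dict[str, list[float]]
    subsequent: dict[str, list[float]]

    @model_validator(mode="after")
    def _check(self) -> "MortalityRiskTable":
        if not self.bands:
            raise ValueError("mortality_rr: no age bands")
        for (lo, hi), (lo2, _) in zip(self.bands, self.bands[1:]):
            if lo2 != hi + 1:
                raise ValueError("mortality_rr: bands must be contiguous and ordered")
        for key in ("hip", "vertebral", "other"):
            if key not in self.first_year:
                raise ValueError(f"mortality_rr.first_year: missing '{key}'")
        for key in ("hip", "vertebral"):
            if key not in self.subsequent:
                raise ValueError(f"mortality_rr.subsequent: missing '{key}'")
        for name, cols in (("first_year", self.first_year), ("subsequent", self.subsequent)):
            for key, vals in cols.items():
                if len(vals) != len(self.bands):
                    raise ValueError(f"mortality_rr.{name}[{key}]: expected {len(self.bands)} values")
                if any(v < 1.0 for v in vals):
                    raise ValueError(f"mortality_rr.{name}[{key}]: multipliers must be >= 1")
        return self

    def _band_index(self, age: float) -> int:
        a = int(math.floor(age))
        if a < self.bands[0][0]:
            return 0
        for i, (lo, hi) in enumerate(self.bands):
            if lo <= a <= hi:
                return i
        return len(self.bands) - 1


def mortality_rr_lookup(
    age: float, site: str, years_since_fracture: float, table: MortalityRiskTable
) -> float:
    """Excess-mortality multiplier for ``site`` at ``age``.

    First-year column while ``years_since_fracture < 1``; afterwards the
    subsequent-years column for hip/vertebral and 1.0 for other fractures.
    """
    if age < 50:
        raise ValueError(f"age {age} below supported range")
    if years_since_fracture < 0:
        raise ValueError("years_since_fracture must be >= 0")
    if site not in ("hip", "vertebral", "other"):
        raise ValueError(f"unknown mortality site '{site}'")
    i = table._band_index(age)
    if years_since_fracture < 1.0:
        return table.first_year[site][i]
    if site == "other":
        return 1.0
    return table.subsequent[site][i]


class UtilityMultipliers(BaseModel):
    """Fracture utility multipliers: first year by site, later years for hip/vertebral."""

    first_year: dict[FractureType, float]
    subsequent_years: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "UtilityMultipliers":
        for ft in FRACTURE_TYPES:
            if ft not in self.first_year:
                raise ValueError(f"utilities.first_year: missing '{ft.value}'")
        for key in ("hip", "vertebral"):
            if key not in self.subsequent_years:
                raise ValueError(f"utilities.subsequent_years: missing '{key}'")
        for name, vals in (("first_year", self.first_year), ("subsequent_years", self.subsequent_years)):
            for key, v in vals.items():
                k = key.value if isinstance(key, FractureType) else key
                if not (0.0 < v <= 1.0):
                    raise ValueError(f"utilities.{name}[{k}]: multiplier must be in (0, 1]")
        for key in ("hip", "vertebral"):
            if self.first_year[FractureType(key)] > self.subsequent_years[key]:
                raise ValueError(f"utilities: first_year[{key}] must be <= subsequent_years[{key}]")
        return self


class TreatmentParams(BaseModel):
    """Anabolic treatment effect: per-site fracture relative risks during an
    18-month course, linear offset (taper) after stopping, and 1-year
    persistence."""

    rr: dict[FractureType, float]
    duration_months: float = Field(18.0, gt=0.0)
    offset_months_vertebral: float = Field(24.0, ge=0.0)
    offset_months_nonvertebral: float = Field(30.0, ge=0.0)
    annual_persistence: float = Field(0.703, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "TreatmentParams":
        for ft in FRACTURE_TYPES:
            if ft not in self.rr:
                raise ValueError(f"treatment.rr: missing '{ft.value}'")
            if self.rr[ft] <= 0:
                raise ValueError(f"treatment.rr[{ft.value}]: relative risk must be > 0")
        return self


#: Recurring-cost eligibility rules understood by the engine.
RecurringRule = Literal[
    "per_cycle",                  # every cycle, every living patient, both arms
    "every_second_cycle",         # annual item in a 6-month-cycle model
    "per_acute_cycle",            # each of the two acute cycles, listed sites
    "first_post_fracture_cycle",  # once, booked at the fracture event
    "first_year_once",            # once in the first year, booked at the event
]


class OneOffItem(BaseModel):
    amount: float = Field(..., ge=0.0)
    trigger: FractureType


class RecurringItem(BaseModel):
    amount: float = Field(..., ge=0.0)
    rule: RecurringRule
    sites: Optional[list[FractureType]] = None

    @model_validator(mode="after")
    def _check(self) -> "RecurringItem":
        if self.rule in ("per_acute_cycle", "first_post_fracture_cycle", "first_year_once"):
            if not self.sites:
                raise ValueError(f"recurring item with rule '{self.rule}' needs explicit sites")
        return self


class CostModel(BaseModel):
    """Fracture-management and drug costs in integer IRR (governmental tariff)."""

    acute_package: dict[FractureType, float]
    one_off_items: dict[str, OneOffItem] = {}
    recurring_items: dict[str, RecurringItem] = {}
    drug_cost_per_pen: float = Field(..., ge=0.0)
    pen_dose_days: float = Field(30.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CostModel":
        for ft in FRACTURE_TYPES:
            if ft not in self.acute_package:
                raise ValueError(f"costs.acute_package: missing '{ft.value}'")
            if self.acute_package[ft] < 0:
                raise ValueError(f"costs.acute_package[{ft.value}]: must be >= 0")
        return self

    def event_cost(self, ftype: FractureType) -> float:
        """One-off IRR booked at a fracture event of ``ftype``: the acute
        management package, triggered one-off items, and event-booked
        recurring items (first-cycle nursing, first-year physiotherapy)."""
        total = self.acute_package[FractureType(ftype)]
        for item in self.one_off_items.values():
            if item.trigger == ftype:
                total += item.amount
        for item in self.recurring_items.values():
            if item.rule in ("first_post_fracture_cycle", "first_year_once") and ftype in item.sites:
                total += item.amount
        return total

    def recurring_cycle_cost(self, cycle_index: int, acute_site: Optional[FractureType]) -> float:
        """Per-cycle IRR for a living patient at ``cycle_index`` (0-based),
        in an acute state of ``acute_site`` (or None)."""
        total = 0.0
        for item in self.recurring_items.values():
            if item.rule == "per_cycle":
                total += item.amount
            elif item.rule == "every_second_cycle" and cycle_index % 2 == 0:
                total += item.amount
            elif item.rule == "per_acute_cycle" and acute_site is not None and acute_site in item.sites:
                total += item.amount
        return total

    def drug_cost_per_cycle(self, cycle_years: float) -> float:
        """Teriparatide cost per cycle on treatment: pens consumed in one
        cycle at one dose-day per day, rounded to integer IRR."""
        return round(cycle_years * 365.0 / self.pen_dose_days * self.drug_cost_per_pen)


class EconParams(BaseModel):
    """Discounting, cycle length, horizon and willingness-to-pay settings."""

    discount_rate_costs: float = Field(0.072, ge=0.0)
    discount_rate_effects: float = Field(0.05, ge=0.0)
    cycle_years: float = Field(0.5, gt=0.0)
    max_age: float = Field(100.0, gt=0.0)
    gdp_per_capita: float = Field(..., gt=0.0)
    wtp_grid: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "EconParams":
        if self.wtp_grid is not None:
            if any(w < 0 for w in self.wtp_grid):
                raise ValueError("econ.wtp_grid: values must be >= 0")
            if sorted(self.wtp_grid) != list(self.wtp_grid):
                raise ValueError("econ.wtp_grid: values must be sorted")
        return self

    def effective_wtp_grid(self) -> list[float]:
        """Default grid: 0 to 3x GDP/capita in steps of GDP/20."""
        if self.wtp_grid is not None:
            return list(self.wtp_grid)
        step = self.gdp_per_capita / 20.0
        return [i * step for i in range(61)]


class FractureHistoryModifiers(BaseModel):
    """Multiplier on same-site fracture incidence by whole years since the
    last fracture at that site; highest in year 1, back to 1.0 after year 5.

    The published model cites this elevation without printing values, so the
    default schedule is a documented placeholder and fully configurable.
    """

    schedule: list[float] = [2.0, 1.5, 1.3, 1.2, 1.1]

    @model_validator(mode="after")
    def _check(self) -> "FractureHistoryModifiers":
        if len(self.schedule) != 5:
            raise ValueError("history.schedule: expected 5 yearly multipliers")
        if any(m < 1.0 for m in self.schedule):
            raise ValueError("history.schedule: multipliers must be >= 1")
        if any(b > a + 1e-12 for a, b in zip(self.schedule, self.schedule[1:])):
            raise ValueError("history.schedule: multipliers must be non-increasing")
        return self

    def multiplier(self, years_since_fracture: Optional[float]) -> float:
        if years_since_fracture is None:
            return 1.0
        year = int(math.floor(years_since_fracture)) + 1
        if 1 <= year <= len(self.schedule):
            return self.schedule[year - 1]
        return 1.0


class PSARecord(BaseModel):
    """One row of the PSA distribution catalogue.

    ``lower``/``upper`` are read as a central 95% interval; ``point`` anchors
    the log-normal median; ``target`` names the model parameter the draw
    replaces (dotted path, or the special ``surgery.<site>`` /
    ``start_age`` handles).
    """

    name: str
    family: Literal["normal", "gamma", "lognormal", "beta"]
    lower: float
    upper: float
    target: str
    point: Optional[float] = None
    truncate: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "PSARecord":
        if not self.lower < self.upper:
            raise ValueError(f"psa[{self.name}]: lower must be < upper")
        if self.family == "beta" and not (0.0 < self.lower and self.upper < 1.0):
            raise ValueError(f"psa[{self.name}]: beta bounds must lie within (0, 1)")
        if self.family == "lognormal":
            if self.lower <= 0:
                raise ValueError(f"psa[{self.name}]: lognormal bounds must be > 0")
            if self.point is not None and not (self.lower < self.point < self.upper):
                raise ValueError(f"psa[{self.name}]: point estimate outside (lower, upper)")
        return self


class PSASpec(BaseModel):
    records: list[PSARecord] = []

    @model_validator(mode="after")
    def _check(self) -> "PSASpec":
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("psa: duplicate record names")
        return self


class BackgroundModel(BaseModel):
    """Background mortality and baseline utility inputs (synthetic stand-ins).

    Mortality resolves, in order of precedence: an inline life table, a
    two-column text file, or the Gompertz-Makeham parameters.
    """

    gompertz: Optional[GompertzParams] = None
    life_table_inline: Optional[LifeTable] = None
    life_table_path: Optional[str] = None
    utility_curve: BaselineUtilityCurve = BaselineUtilityCurve()

    @model_validator(mode="after")
    def _check(self) -> "BackgroundModel":
        if self.gompertz is None and self.life_table_inline is None and self.life_table_path is None:
            raise ValueError("background: need gompertz parameters or a life table")
        return self

    def resolve_life_table(self) -> LifeTable:
        if self.life_table_inline is not None:
            return self.life_table_inline
        if self.life_table_path is not None:
            return read_life_table(self.life_table_path)
        return gompertz_life_table(self.gompertz)


class SimulationDefaults(BaseModel):
    start_age: float = Field(70.0, ge=50.0, lt=100.0)
    prevalent_vertebral_fraction: float = Field(0.0, ge=0.0, le=1.0)
    max_expanded_states: int = Field(200_000, gt=0)


class ModelParameters(BaseModel):
    """The complete validated parameter set of the cost-utility model."""

    incidence: IncidenceTable
    mortality_rr: MortalityRiskTable
    utilities: UtilityMultipliers
    treatment: TreatmentParams
    costs: CostModel
    econ: EconParams
    history: FractureHistoryModifiers = FractureHistoryModifiers()
    psa: PSASpec = PSASpec()
    background: BackgroundModel
    simulation: SimulationDefaults = SimulationDefaults()
    meta: dict[str, object] = {}

    @model_validator(mode="after")
    def _check(self) -> "ModelParameters":
        cycle_months = self.econ.cycle_years * 12.0
        if abs(self.treatment.duration_months / cycle_months
               - round(self.treatment.duration_months / cycle_months)) > 1e-9:
            raise ValueError("treatment.duration_months must be a whole number of cycles")
        return self

    def to_config_dict(self) -> dict:
        return self.model_dump(mode="json", exclude_none=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config_dict(), sort_keys=False))


def load_model_config(path: str | Path | None = None) -> ModelParameters:
    """Load and validate a model configuration.

    With no path, loads the bundled ``default_iran_2018`` preset. Raises
    a validation error naming the offending field on any invariant
    violation.
    """
    if path is None:
        resource = importlib.resources.files("osteosim.data") / "default_iran_2018.yaml"
        raw = yaml.safe_load(resource.read_text())
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"configuration file not found: {p}")
        raw = yaml.safe_load(p.read_text())
    return ModelParameters.model_validate(raw)


def save_model_config(params: ModelParameters, path: str | Path) -> None:
    params.save(path)


def default_parameters() -> ModelParameters:
    """The bundled ``default_iran_2018`` preset."""
    return load_model_config(None)
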