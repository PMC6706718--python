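"""Synthetic background mortality and baseline utility inputs.

The cost-utility model needs an age-specific all-cause mortality table for
women and an age-specific baseline utility curve. Neither is a published
model parameter, so this module generates transparent synthetic stand-ins:

* a Gompertz-Makeham life table, calibrated so that remaining life
  expectancy at a reference age hits a user-chosen target, and
* a linear-with-floor baseline utility curve resembling EQ-5D population
  norms for older women.

Both accept user-supplied replacements (a two-column ``age, qx`` text file
or an explicit age->utility table) so real national data can be dropped in
without touching the rest of the model.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator


class CalibrationError(RuntimeError):
    """Raised when the Gompertz calibration target is unattainable."""


class GompertzParams(BaseModel):
    """Gompertz-Makeham hazard ``h(x) = a + b * exp(c * x)`` per year of age."""

    makeham_a: float = Field(0.0, ge=0.0)
    gompertz_b: float = Field(..., gt=0.0)
    gompertz_c: float = Field(..., gt=0.0)


class LifeTable(BaseModel):
    """Annual death probabilities ``q_annual[i]`` for integer ``age[i]`` (women)."""

    age: list[int]
    q_annual: list[float]

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        if len(self.age) != len(self.q_annual):
            raise ValueError("life table: age and q_annual must have equal length")
        if any(b - a != 1 for a, b in zip(self.age, self.age[1:])):
            raise ValueError("life table: ages must be consecutive integers")
        if any(not (0.0 <= q <= 1.0) for q in self.q_annual):
            raise ValueError("life table: q_annual must lie in [0, 1]")
        qs = [q for a, q in zip(self.age, self.q_annual) if a >= 60]
        if any(b < a - 1e-12 for a, b in zip(qs, qs[1:])):
            raise ValueError("life table: q_annual must be non-decreasing above age 60")
        return self

    def q_at(self, age: float) -> float:
        """Annual death probability at ``floor(age)``, clamped to the table range.

        Ages past the end of the table are treated as certain death within
        the year (the simulation horizon ends there anyway).
        """
        a = int(math.floor(age))
        if a < self.age[0]:
            return self.q_annual[0]
        if a > self.age[-1]:
            return 1.0
        return self.q_annual[a - self.age[0]]


def gompertz_life_table(
    params: GompertzParams, ages: Sequence[int] = range(50, 101)
) -> LifeTable:
    """Deterministic life table with ``q(x) = 1 - exp(-(a + b * e^{c x}))``."""
    ages = list(ages)
    x = np.asarray(ages, dtype=float)
    hazard = params.makeham_a + params.gompertz_b * np.exp(params.gompertz_c * x)
    q = 1.0 - np.exp(-hazard)
    return LifeTable(age=ages, q_annual=np.minimum(q, 1.0).tolist())


def life_expectancy(table: LifeTable, from_age: int) -> float:
    """Remaining life expectancy in years, trapezoidal over the survival curve.

    Survival is followed to the end of the table; deaths are credited half a
    year within the year they occur (the standard mid-year convention).
    """
    if from_age < table.age[0] or from_age > table.age[-1]:
        raise ValueError(f"from_age {from_age} outside table range "
                         f"[{table.age[0]}, {table.age[-1]}]")
    start = from_age - table.age[0]
    q = np.asarray(table.q_annual[start:], dtype=float)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    return float(np.trapezoid(surv, dx=1.0))


def calibrate_gompertz(
    target_le: float = 14.0,
    fixed_a: float = 0.0,
    fixed_c: float = 0.095,
    at_age: int = 70,
    ages: Sequence[int] = range(50, 101),
    tol: float = 0.05,
) -> GompertzParams:
    """Find ``b`` so that remaining life expectancy at ``at_age`` hits ``target_le``.

    Deterministic bisection on log(b); life expectancy is strictly decreasing
    in b. The default target of 14 remaining years at age 70 is an assumption
    standing in for an unpublished national female life table, not a measured
    value.
    """
    ages = list(ages)

    def le(b: float) -> float:
        p = GompertzParams(makeham_a=fixed_a, gompertz_b=b, gompertz_c=fixed_c)
        return life_expectancy(gompertz_life_table(p, ages), at_age)

    lo_b, hi_b = 1e-12, 10.0
    le_hi, le_lo = le(lo_b), le(hi_b)  # le_hi: longest life (tiny hazard)
    if not (le_lo - tol <= target_le <= le_hi + tol):
        raise CalibrationError(
            f"target {target_le} y at age {at_age} outside achievable bracket "
            f"[{le_lo:.3f}, {le_hi:.3f}] for b in [{lo_b:g}, {hi_b:g}]"
        )
    b = math.sqrt(lo_b * hi_b)
    for _ in range(200):
        b = math.sqrt(lo_b * hi_b)
        val = le(b)
        if abs(val - target_le) <= tol * 0.5:
            break
        if val > target_le:
            lo_b = b
        else:
            hi_b = b
    if abs(le(b) - target_le) > tol:
        raise CalibrationError(
            f"bisection did not reach |LE - {target_le}| <= {tol}; "
            f"final bracket b in [{lo_b:g}, {hi_b:g}]"
        )
    return GompertzParams(makeham_a=fixed_a, gompertz_b=b, gompertz_c=fixed_c)


class BaselineUtilityCurve(BaseModel):
    """Age-specific baseline utility weight for women without fracture.

    Default is a synthetic linear curve ``u(age) = anchor - slope * (age -
    anchor_age)`` clamped to ``[floor, 1]``; an explicit ``table`` (parallel
    ``table_age``/``table_utility`` lists) overrides it.
    """

    anchor_age: float = 50.0
    anchor_utility: float = Field(0.86, gt=0.0, le=1.0)
    slope_per_year: float = Field(0.004, ge=0.0)
    floor: float = Field(0.4, gt=0.0, le=1.0)
    table_age: Optional[list[float]] = None
    table_utility: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "BaselineUtilityCurve":
        if (self.table_age is None) != (self.table_utility is None):
            raise ValueError("utility curve: table_age and table_utility go together")
        if self.table_age is not None:
            if len(self.table_age) != len(self.table_utility):
                raise ValueError("utility curve: table lengths differ")
            if any(not (0.0 < u <= 1.0) for u in self.table_utility):
                raise ValueError("utility curve: utilities must be in (0, 1]")
            pairs = sorted(zip(self.table_age, self.table_utility))
            if any(u2 > u1 + 1e-12 for (_, u1), (_, u2) in zip(pairs, pairs[1:])):
                raise ValueError("utility curve: utilities must be non-increasing with age")
        return self


def baseline_utility(age: float, curve: BaselineUtilityCurve) -> float:
    """Baseline (no-fracture) utility weight at ``age``; defined on [50, 100]."""
    if not (50.0 <= age <= 100.0):
        raise ValueError(f"age {age} outside supported range [50, 100]")
    if curve.table_age is not None:
        ages = np.asarray(curve.table_age, dtype=float)
        utils = np.asarray(curve.table_utility, dtype=float)
        order = np.argsort(ages)
        return float(np.interp(age, ages[order], utils[order]))
    u = curve.anchor_utility - curve.slope_per_year * (age - curve.anchor_age)
    return float(min(max(u, curve.floor), 1.0))


def read_life_table(path: str | Path) -> LifeTable:
    """Read a two-column delimited text file (age, annual death probability)."""
    ages: list[int] = []
    qs: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").replace("\t", " ").split()
        if parts[0].lower() in {"age", "x"}:
            continue
        ages.append(int(float(parts[0])))
        qs.append(float(parts[1]))
    return LifeTable(age=ages, q_annual=qs)


def write_life_table(table: LifeTable, path: str | Path) -> None:
    lines = ["age\tq_annual"]
    lines += [f"{a}\t{q:.10g}" for a, q in zip(table.age, table.q_annual)]
    Path(path).write_text("\n".join(lines) + "\n")
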