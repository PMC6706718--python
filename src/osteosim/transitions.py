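"""Per-cycle model mechanics for one simulated woman.

Given a patient's current state (health state, age, treatment status and
per-site time-since-fracture clocks) this module derives the 6-month-cycle
transition probabilities, the effective treatment relative risk including
the post-treatment offset (taper), and the cycle's utility and cost.

Conventions (shared with the vectorised engine so the deterministic cohort
trace is the exact expectation of the microsimulation):

* Annual probabilities convert to cycle probabilities via the complement
  power rule, i.e. a constant hazard within the year.
* Excess mortality is applied on the hazard scale so that relative risks
  well above 1 cannot push probabilities past 1.
* Within a cycle, death is resolved first; survivors sustain at most one
  fracture, its site drawn proportional to the per-site hazards.
* Costs and utilities are booked at cycle start; fracture event costs are
  booked in the cycle of the event. No half-cycle correction is applied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .life_tables import baseline_utility
from .params import (
    FRACTURE_TYPES,
    FractureType,
    HealthState,
    HealthStateLabel,
    ModelParameters,
    TreatmentParams,
    incidence_lookup,
    mortality_rr_lookup,
    mortality_site_of,
)


class Arm(str, enum.Enum):
    TERIPARATIDE = "teriparatide"
    NO_TREATMENT = "no_treatment"


@dataclass
class PatientState:
    """One simulated woman's current state at a cycle start.

    ``months_since_last_fracture`` holds, per site, the months elapsed since
    the most recent fracture at that site (None if never fractured there).
    ``treatment_stop_month`` is the model month at which treatment ceased,
    by completing the course or by non-persistence; None while still on.
    """

    age: float
    state: HealthState
    months_since_model_start: float = 0.0
    arm: Arm = Arm.NO_TREATMENT
    on_treatment: bool = False
    treatment_stop_month: Optional[float] = None
    months_since_last_fracture: dict[FractureType, Optional[float]] = field(
        default_factory=lambda: {ft: None for ft in FRACTURE_TYPES}
    )
    prevalent_fracture_at_baseline: bool = False

    @property
    def alive(self) -> bool:
        return self.state.label != HealthStateLabel.DEAD


@dataclass
class CycleHazards:
    """Cycle-scale transition probabilities for one patient-cycle.

    The induced multinomial (death, one fracture per site, stay) sums to
    one exactly: p_stay = (1 - p_death) * (1 - p_any_fracture).
    """

    p_death: float
    p_fracture: dict[FractureType, float]
    p_any_fracture: float

    def site_shares(self) -> dict[FractureType, float]:
        """P(site | a fracture occurs), proportional to per-site hazards."""
        hz = {ft: -math.log(1.0 - min(p, 1.0 - 1e-15)) for ft, p in self.p_fracture.items()}
        total = sum(hz.values())
        if total <= 0.0:
            return {ft: 0.0 for ft in self.p_fracture}
        return {ft: h / total for ft, h in hz.items()}


def annual_prob_to_cycle_prob(p_annual: float, cycle_years: float) -> float:
    """Convert an annual probability to a cycle probability assuming a
    constant hazard within the year: ``1 - (1 - p)**cycle_years``."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability {p_annual} outside [0, 1]")
    if cycle_years <= 0:
        raise ValueError("cycle_years must be > 0")
    return 1.0 - (1.0 - p_annual) ** cycle_years


def persistence_prob_per_cycle(annual_persistence: float, cycle_years: float) -> float:
    """Probability of remaining on treatment across one cycle, compounding
    to the annual persistence rate: ``annual ** cycle_years``."""
    if not (0.0 < annual_persistence <= 1.0):
        raise ValueError("annual persistence must be in (0, 1]")
    return annual_persistence ** cycle_years


def effective_fracture_rr(
    ftype: FractureType,
    month: float,
    stop_month: Optional[float],
    params: TreatmentParams,
) -> float:
    """Treatment relative risk for ``ftype`` at model ``month``.

    Full effect while on treatment; after stopping (course completed or
    dropped out) the effect wanes linearly to none over the offset time --
    24 months for vertebral, 30 months for non-vertebral fractures.
    """
    if month < 0:
        raise ValueError("month must be >= 0")
    rr = params.rr[FractureType(ftype)]
    stop = params.duration_months if stop_month is None else min(stop_month, params.duration_months)
    if month < stop:
        return rr
    offset = (
        params.offset_months_vertebral
        if ftype == FractureType.VERTEBRAL
        else params.offset_months_nonvertebral
    )
    if offset <= 0.0 or month - stop >= offset:
        return 1.0
    return rr + (1.0 - rr) * (month - stop) / offset


#: Fracture sites reachable from each health-state label. From the post-hip
#: state only new hip fractures can occur; from post-vertebral, vertebral and
#: hip; the well state and the acute (first-year) states allow all four.
def allowed_sites(state: HealthState) -> tuple[FractureType, ...]:
    if state.label == HealthStateLabel.POST_HIP:
        return (FractureType.HIP,)
    if state.label == HealthStateLabel.POST_VERTEBRAL:
        return (FractureType.HIP, FractureType.VERTEBRAL)
    if state.label == HealthStateLabel.DEAD:
        return ()
    return FRACTURE_TYPES


def _mortality_multiplier(patient: PatientState, params: ModelParameters) -> float:
    st = patient.state
    if st.label == HealthStateLabel.WELL:
        return 1.0
    if st.label == HealthStateLabel.ACUTE_FRACTURE:
        site = mortality_site_of(st.fracture)
        msf = patient.months_since_last_fracture[st.fracture] or 0.0
        return mortality_rr_lookup(patient.age, site, msf / 12.0, params.mortality_rr)
    if st.label == HealthStateLabel.POST_HIP:
        msf = patient.months_since_last_fracture[FractureType.HIP]
        return mortality_rr_lookup(
            patient.age, "hip", 1.0 if msf is None else max(msf / 12.0, 1.0), params.mortality_rr
        )
    if st.label == HealthStateLabel.POST_VERTEBRAL:
        msf = patient.months_since_last_fracture[FractureType.VERTEBRAL]
        return mortality_rr_lookup(
            patient.age, "vertebral", 1.0 if msf is None else max(msf / 12.0, 1.0), params.mortality_rr
        )
    raise ValueError("dead patients have no mortality multiplier")


def cycle_hazards(patient: PatientState, params: ModelParameters) -> CycleHazards:
    """Transition probabilities for the coming cycle of a living patient."""
    if not patient.alive:
        raise ValueError("cycle_hazards: patient is dead")
    cy = params.econ.cycle_years
    q_bg = params.background.resolve_life_table().q_at(patient.age)
    rr_mort = _mortality_multiplier(patient, params)
    if q_bg >= 1.0:
        p_death = 1.0
    else:
        h = -math.log(1.0 - q_bg)
        p_death = min(1.0 - math.exp(-rr_mort * h * cy), 1.0)

    sites = allowed_sites(patient.state)
    p_frac: dict[FractureType, float] = {}
    for ft in FRACTURE_TYPES:
        if ft not in sites:
            p_frac[ft] = 0.0
            continue
        rr_t = 1.0
        if patient.arm == Arm.TERIPARATIDE:
            rr_t = effective_fracture_rr(
                ft, patient.months_since_model_start, patient.treatment_stop_month,
                params.treatment,
            )
        msf = patient.months_since_last_fracture[ft]
        hist = params.history.multiplier(None if msf is None else msf / 12.0)
        annual = min(incidence_lookup(patient.age, ft, params.incidence) * rr_t * hist, 1.0)
        p_frac[ft] = annual_prob_to_cycle_prob(annual, cy)

    p_any = 1.0
    for p in p_frac.values():
        p_any *= 1.0 - p
    p_any = 1.0 - p_any
    return CycleHazards(p_death=p_death, p_fracture=p_frac, p_any_fracture=p_any)


def cycle_utility(patient: PatientState, params: ModelParameters) -> float:
    """Quality-adjusted years accrued this cycle: age-specific baseline
    utility times the fracture multiplier, times the cycle length.

    First-year multipliers apply during the two acute cycles; post-hip and
    post-vertebral states use the subsequent-years multipliers; wrist and
    other fractures revert to no decrement after the acute year.
    """
    if not patient.alive:
        raise ValueError("cycle_utility: patient is dead")
    st = patient.state
    if st.label == HealthStateLabel.ACUTE_FRACTURE:
        mult = params.utilities.first_year[st.fracture]
    elif st.label == HealthStateLabel.POST_HIP:
        mult = params.utilities.subsequent_years["hip"]
    elif st.label == HealthStateLabel.POST_VERTEBRAL:
        mult = params.utilities.subsequent_years["vertebral"]
    else:
        mult = 1.0
    u = baseline_utility(patient.age, params.background.utility_curve)
    return u * mult * params.econ.cycle_years


def cycle_cost(
    patient: PatientState,
    events: list[FractureType],
    params: ModelParameters,
    cycle_index: Optional[int] = None,
) -> float:
    """Undiscounted IRR booked this cycle: recurring items, drug cost while
    on treatment, and one-off event costs per fracture sustained."""
    if not patient.alive:
        raise ValueError("cycle_cost: patient is dead")
    if cycle_index is None:
        cycle_index = int(round(patient.months_since_model_start / (params.econ.cycle_years * 12.0)))
    acute_site = (
        patient.state.fracture
        if patient.state.label == HealthStateLabel.ACUTE_FRACTURE
        else None
    )
    total = params.costs.recurring_cycle_cost(cycle_index, acute_site)
    if patient.arm == Arm.TERIPARATIDE and patient.on_treatment:
        total += params.costs.drug_cost_per_cycle(params.econ.cycle_years)
    for ft in events:
        total += params.costs.event_cost(ft)
    if total < 0:
        raise ValueError("negative cycle cost")
    return total
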