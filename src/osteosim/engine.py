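"""Simulation engine: first-order Monte-Carlo microsimulation and the
deterministic cohort-trace oracle.

Both run over the same expanded-state transition kernel (see
``statespace``), so the trace is the exact expectation of the
microsimulation and serves as its verification oracle. Costs are discounted
at the cost rate and utilities/life-years at the effect rate, both measured
at cycle start; simulation ends at death or at the horizon (age 100 by
default).

Random-number contract: each patient-cycle consumes one block of four
uniforms in the order (persistence, death, fracture, site), drawn only
while the patient is alive. ``run_microsim(n=1, seed=s)`` therefore
reproduces ``simulate_individual`` with a fresh ``default_rng(s)`` bit for
bit, and two runs with the same seed are identical. Passing the same seed
to both arms yields common random numbers across arms; the default in all
higher-level drivers is independent streams per arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .life_tables import baseline_utility
from .params import (
    FRACTURE_TYPES,
    FractureType,
    ModelParameters,
    incidence_lookup,
    mortality_rr_lookup,
)
from .statespace import (
    CAP,
    MACRO_LABELS,
    SITE_OF_ACUTE,
    StateSpaceError,
    get_state_space,
)
from .transitions import Arm, effective_fracture_rr, persistence_prob_per_cycle

__all__ = [
    "ArmResult",
    "CohortTrace",
    "IndividualResult",
    "discount_factor",
    "run_cohort_trace",
    "run_microsim",
    "simulate_individual",
]


def discount_factor(rate: float, t: float) -> float:
    """Present-value factor ``(1 + rate)**(-t)`` for an amount at year ``t``."""
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be >= 0")
    return (1.0 + rate) ** (-t)


@dataclass
class ArmResult:
    """Aggregated microsimulation result for one strategy arm."""

    arm: str
    n: int
    seed: Optional[int]
    mean_cost: float
    mean_qaly: float
    mean_ly: float
    se_cost: float
    se_qaly: float
    fracture_counts: dict[str, float]  # mean undiscounted fractures/patient

    def to_json_dict(self) -> dict:
        return {
            "arm": self.arm, "n": self.n, "seed": self.seed,
            "mean_cost": self.mean_cost, "mean_qaly": self.mean_qaly,
            "mean_ly": self.mean_ly, "se_cost": self.se_cost,
            "se_qaly": self.se_qaly, "fracture_counts": self.fracture_counts,
        }


@dataclass
class IndividualResult:
    """One simulated trajectory with its discounted totals."""

    trajectory: pd.DataFrame  # cycle, age, state, cost, utility (undiscounted)
    total_cost: float
    total_qaly: float
    total_ly: float
    fracture_counts: dict[str, int]


@dataclass
class CohortTrace:
    """Deterministic expected state occupancy, cost and utility per cycle."""

    arm: str
    start_age: float
    cycle_years: float
    ages: np.ndarray                      # age at each cycle start, length K
    cost_per_cycle: np.ndarray            # discounted IRR, length K
    qaly_per_cycle: np.ndarray            # discounted QALYs, length K
    ly_per_cycle: np.ndarray              # discounted life-years, length K
    fracture_counts: dict[str, float]     # expected undiscounted events
    occupancy: Optional[np.ndarray] = None  # (K+1, n_substates)

    @property
    def mean_cost(self) -> float:
        return float(self.cost_per_cycle.sum())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly_per_cycle.sum())

    @property
    def mean_ly(self) -> float:
        return float(self.ly_per_cycle.sum())

    def macro_occupancy(self) -> pd.DataFrame:
        """Occupancy aggregated to the seven model states (+ acute split)."""
        if self.occupancy is None:
            raise ValueError("trace was run without occupancy storage")
        space = get_state_space()
        onehot = np.zeros((space.n, len(MACRO_LABELS)))
        onehot[np.arange(space.n), space.macro] = 1.0
        agg = self.occupancy @ onehot
        cycles = np.arange(agg.shape[0])
        out = pd.DataFrame(agg, columns=list(MACRO_LABELS))
        out.insert(0, "age", self.start_age + cycles * self.cycle_years)
        out.insert(0, "cycle", cycles)
        return out

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(len(self.ages))
        return pd.DataFrame({
            "cycle": k, "age": self.ages,
            "disc_cost": self.cost_per_cycle,
            "disc_qaly": self.qaly_per_cycle,
            "disc_ly": self.ly_per_cycle,
        })


class _RunContext:
    """Static arrays and per-cycle scalars for one engine run."""

    def __init__(
        self,
        params: ModelParameters,
        arm: Arm,
        start_age: Optional[float] = None,
        horizon_years: Optional[float] = None,
    ) -> None:
        self.space = get_state_space()
        if self.space.n > params.simulation.max_expanded_states:
            raise StateSpaceError(
                f"expanded state space ({self.space.n}) exceeds configured bound "
                f"({params.simulation.max_expanded_states})"
            )
        self.params = params
        self.arm = Arm(arm)
        self.cy = params.econ.cycle_years
        self.cm = self.cy * 12.0
        self.start_age = float(params.simulation.start_age if start_age is None else start_age)
        horizon_age = params.econ.max_age
        if horizon_years is not None:
            horizon_age = min(horizon_age, self.start_age + horizon_years)
        self.n_cycles = max(int(math.floor((horizon_age - self.start_age) / self.cy + 1e-9)), 0)
        self.life_table = params.background.resolve_life_table()

        space = self.space
        # same-site history elevation by clock (in cycles)
        sched = params.history.schedule
        mult_by_clock = np.array(
            [sched[int(c * self.cy)] if int(c * self.cy) < len(sched) else 1.0
             for c in range(CAP + 1)]
        )
        self.hist = np.where(space.site_allowed, mult_by_clock[space.clock], 0.0)

        ut = params.utilities
        self.util_by_class = np.array([
            1.0,
            ut.first_year[FractureType.HIP], ut.first_year[FractureType.VERTEBRAL],
            ut.first_year[FractureType.WRIST], ut.first_year[FractureType.OTHER],
            ut.subsequent_years["hip"], ut.subsequent_years["vertebral"],
        ])
        self.util_mult = np.where(space.alive, self.util_by_class[space.util_class], 0.0)

        costs = params.costs
        self.event_cost = np.array([costs.event_cost(ft) for ft in FRACTURE_TYPES])
        # recurring per-state costs: acute-state items (bed sores); flat and
        # annual items enter as scalars per cycle
        acute_cost = np.zeros(space.n)
        self.flat_cycle_cost = 0.0
        self.annual_cycle_cost = 0.0
        for item in costs.recurring_items.values():
            if item.rule == "per_cycle":
                self.flat_cycle_cost += item.amount
            elif item.rule == "every_second_cycle":
                self.annual_cycle_cost += item.amount
            elif item.rule == "per_acute_cycle":
                site_ids = [list(FRACTURE_TYPES).index(ft) for ft in item.sites]
                for macro, site in SITE_OF_ACUTE.items():
                    if site in site_ids:
                        acute_cost[space.macro == macro] += item.amount
        self.acute_cost = np.where(space.alive, acute_cost, 0.0)
        self.drug_cost_cycle = costs.drug_cost_per_cycle(self.cy)

        tr = params.treatment
        self.duration_cycles = int(round(tr.duration_months / self.cm))
        self.pi_cycle = persistence_prob_per_cycle(tr.annual_persistence, self.cy)
        self.rr = np.array([tr.rr[ft] for ft in FRACTURE_TYPES])
        self.offset = np.array([
            tr.offset_months_vertebral if ft == FractureType.VERTEBRAL
            else tr.offset_months_nonvertebral
            for ft in FRACTURE_TYPES
        ])

        rc, re = params.econ.discount_rate_costs, params.econ.discount_rate_effects
        t = np.arange(self.n_cycles) * self.cy
        self.df_cost = (1.0 + rc) ** (-t)
        self.df_eff = (1.0 + re) ** (-t)

        self._scalar_cache: dict[int, tuple] = {}

    # -- per-cycle scalar inputs ------------------------------------------
    def cycle_scalars(self, k: int) -> tuple[float, np.ndarray, np.ndarray, float]:
        """(age, incidence[4], mortality RR by class[6], baseline utility)."""
        got = self._scalar_cache.get(k)
        if got is not None:
            return got
        age = self.start_age + k * self.cy
        inc = np.array([incidence_lookup(age, ft, self.params.incidence) for ft in FRACTURE_TYPES])
        mt = self.params.mortality_rr
        mort = np.array([
            1.0,
            mortality_rr_lookup(age, "hip", 0.0, mt),
            mortality_rr_lookup(age, "vertebral", 0.0, mt),
            mortality_rr_lookup(age, "other", 0.0, mt),
            mortality_rr_lookup(age, "hip", 1.0, mt),
            mortality_rr_lookup(age, "vertebral", 1.0, mt),
        ])
        u_base = baseline_utility(age, self.params.background.utility_curve)
        got = (age, inc, mort, u_base)
        self._scalar_cache[k] = got
        return got

    def background_hazard(self, age: float) -> float:
        q = self.life_table.q_at(age)
        if q >= 1.0:
            return np.inf
        return -math.log(1.0 - q)

    def effective_rr_vec(self, month: float, stop_month: np.ndarray) -> np.ndarray:
        """Per-site effective treatment RR, vectorised over patients.

        ``stop_month`` may be +inf while still on treatment; the course never
        extends past its nominal duration.
        """
        if self.arm != Arm.TERIPARATIDE:
            raise ValueError("treatment effect applies to the teriparatide arm only")
        stop = np.minimum(stop_month, self.params.treatment.duration_months)
        out = np.empty((stop.shape[0], 4))
        for i in range(4):
            rr, off = self.rr[i], self.offset[i]
            if off > 0:
                frac = np.clip((month - stop) / off, 0.0, 1.0)
            else:
                frac = (month >= stop).astype(float)
            out[:, i] = np.where(month < stop, rr, rr + (1.0 - rr) * frac)
        return out

    def treatment_paths(self) -> list[tuple[float, Optional[float]]]:
        """(probability, stop month) for each persistence path.

        Non-persistence is evaluated at the start of each cycle after the
        first, within the treatment window; survivors of all checks complete
        the course.
        """
        if self.arm != Arm.TERIPARATIDE:
            return [(1.0, None)]
        if (self.rr == 1.0).all() and self.drug_cost_cycle == 0:
            # no pathway distinguishes the persistence paths; collapse the
            # mixture so the null-treatment identity holds exactly
            return [(1.0, self.params.treatment.duration_months)]
        d = self.duration_cycles
        pi = self.pi_cycle
        paths = [(pi ** (k - 1) * (1.0 - pi), k * self.cm) for k in range(1, d)]
        paths.append((pi ** (d - 1), self.params.treatment.duration_months))
        total = sum(w for w, _ in paths)
        return [(w / total, m) for w, m in paths]

    def transition_probs(
        self, k: int, idx: np.ndarray, rr_t: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(p_death, p_site, p_any) for expanded-state rows ``idx``.

        ``rr_t``: per-site treatment RR, broadcastable to ``(len(idx), 4)``.
        Death is applied on the hazard scale; per-site annual probabilities
        (incidence x treatment RR x history elevation) convert by complement
        power and combine as competing risks.
        """
        space = self.space
        age, inc, mort, _ = self.cycle_scalars(k)
        h_bg = self.background_hazard(age)
        with np.errstate(over="ignore", invalid="ignore"):
            rr_mort = mort[space.mort_class[idx]]
            if np.isfinite(h_bg):
                q_cycle = 1.0 - np.exp(-rr_mort * h_bg * self.cy)
            else:
                q_cycle = np.ones_like(rr_mort)
            p_death = np.where(space.alive[idx], q_cycle, 0.0)
            annual = np.clip(inc * rr_t * self.hist[idx], 0.0, 1.0)
            p_site = 1.0 - (1.0 - annual) ** self.cy
            p_any = 1.0 - np.prod(1.0 - p_site, axis=1)
        return p_death, p_site, p_any

    def state_cost(self, k: int, idx: np.ndarray) -> np.ndarray:
        """Recurring (non-drug, non-event) cost per living patient this cycle."""
        base = self.flat_cycle_cost + (self.annual_cycle_cost if k % 2 == 0 else 0.0)
        return np.where(self.space.alive[idx], base + self.acute_cost[idx], 0.0)


def _hazard_shares(p_site: np.ndarray) -> np.ndarray:
    """P(site | fracture): per-site hazard over the summed hazard."""
    hz = -np.log1p(-np.clip(p_site, 0.0, 1.0 - 1e-15))
    tot = hz.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(tot > 0, hz / np.where(tot > 0, tot, 1.0), 0.0)
    return shares


# ---------------------------------------------------------------------------
# microsimulation
# ---------------------------------------------------------------------------

def _simulate_cohort(
    params: ModelParameters,
    arm: Arm,
    n: int,
    rng: np.random.Generator,
    start_age: Optional[float] = None,
    horizon_years: Optional[float] = None,
    record_trajectory: bool = False,
):
    ctx = _RunContext(params, arm, start_age, horizon_years)
    space = ctx.space
    teri = ctx.arm == Arm.TERIPARATIDE

    idx = np.full(n, space.start_index, dtype=np.int32)
    rho = params.simulation.prevalent_vertebral_fraction
    if rho > 0:
        idx[rng.random(n) < rho] = space.prevalent_index
    stop = np.full(n, np.inf)
    stop_observed = np.full(n, np.inf)  # month non-persistence occurred, for reporting
    death_cycle = np.full(n, np.inf)    # cycle during which death occurred
    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    frac_counts = np.zeros(4)
    alive_pos = np.arange(n)
    rows = [] if record_trajectory else None

    for k in range(ctx.n_cycles):
        if alive_pos.size == 0:
            break
        cur = idx[alive_pos]
        m = alive_pos.size
        u = rng.random((m, 4))
        month = k * ctx.cm

        if teri and 1 <= k <= ctx.duration_cycles - 1:
            on = np.isinf(stop[alive_pos])
            quit_now = on & (u[:, 0] >= ctx.pi_cycle)
            stop[alive_pos[quit_now]] = month
            stop_observed[alive_pos[quit_now]] = month

        age, _, _, u_base = ctx.cycle_scalars(k)
        util_k = u_base * ctx.util_mult[cur] * ctx.cy
        cost_k = ctx.state_cost(k, cur)
        if teri:
            on_drug = month < np.minimum(stop[alive_pos], params.treatment.duration_months)
            cost_k = cost_k + ctx.drug_cost_cycle * on_drug
            rr_t = ctx.effective_rr_vec(month, stop[alive_pos])
        else:
            rr_t = np.ones((m, 4))

        p_death, p_site, p_any = ctx.transition_probs(k, cur, rr_t)
        died = u[:, 1] < p_death
        fract = ~died & (u[:, 2] < p_any)
        shares = _hazard_shares(p_site)
        cum = np.cumsum(shares, axis=1)
        site = (u[:, 3, None] >= cum).sum(axis=1).clip(0, 3)

        ev = np.zeros(m)
        if fract.any():
            ev[fract] = ctx.event_cost[site[fract]]
            frac_counts += np.bincount(site[fract], minlength=4)
        cost[alive_pos] += ctx.df_cost[k] * (cost_k + ev)
        qaly[alive_pos] += ctx.df_eff[k] * util_k
        ly[alive_pos] += ctx.df_eff[k] * ctx.cy

        if rows is not None:
            rows.append({
                "cycle": k, "age": age,
                "state": MACRO_LABELS[space.macro[cur[0]]],
                "cost": float(cost_k[0] + ev[0]), "utility": float(util_k[0]),
            })

        nxt = space.next_stay[cur].copy()
        if fract.any():
            nxt[fract] = space.next_frac[cur[fract], site[fract]]
        nxt[died] = space.dead_index
        idx[alive_pos] = nxt
        death_cycle[alive_pos[died]] = k
        alive_pos = alive_pos[~died]

    return ctx, cost, qaly, ly, frac_counts, stop, stop_observed, death_cycle, rows


def run_microsim(
    params: ModelParameters,
    arm: Arm | str,
    n: int,
    seed: int,
    start_age: Optional[float] = None,
    horizon_years: Optional[float] = None,
) -> ArmResult:
    """First-order Monte-Carlo simulation of ``n`` independent patients."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    arm = Arm(arm)
    _, cost, qaly, ly, counts, _, _, _, _ = _simulate_cohort(
        params, arm, n, rng, start_age, horizon_years
    )
    se = lambda x: float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ArmResult(
        arm=arm.value, n=n, seed=seed,
        mean_cost=float(cost.mean()), mean_qaly=float(qaly.mean()),
        mean_ly=float(ly.mean()),
        se_cost=se(cost), se_qaly=se(qaly),
        fracture_counts={
            ft.value: float(c / n) for ft, c in zip(FRACTURE_TYPES, counts)
        },
    )


def treatment_status_at(
    params: ModelParameters, arm: Arm | str, n: int, seed: int, month: float,
    start_age: Optional[float] = None,
) -> float:
    """Fraction of patients alive at ``month`` who are still on treatment.

    A patient is "on treatment" at ``month`` if every persistence check up to
    and including that month succeeded and the course has not yet completed.
    """
    rng = np.random.default_rng(seed)
    ctx, _, _, _, _, _, stop_observed, death_cycle, _ = _simulate_cohort(
        params, Arm(arm), n, rng, start_age
    )
    dur = params.treatment.duration_months
    alive_at = death_cycle * ctx.cm >= month
    if not alive_at.any():
        raise ValueError(f"no patients alive at month {month}")
    on = np.minimum(stop_observed, dur) > month
    return float(on[alive_at].mean())


def simulate_individual(
    params: ModelParameters,
    arm: Arm | str,
    start_age: Optional[float],
    rng: np.random.Generator,
    horizon_years: Optional[float] = None,
) -> IndividualResult:
    """Simulate one woman's trajectory from her starting age to death or the
    horizon, returning the per-cycle path and discounted totals."""
    _, cost, qaly, ly, counts, _, _, _, rows = _simulate_cohort(
        params, Arm(arm), 1, rng, start_age, horizon_years, record_trajectory=True
    )
    return IndividualResult(
        trajectory=pd.DataFrame(rows, columns=["cycle", "age", "state", "cost", "utility"]),
        total_cost=float(cost[0]), total_qaly=float(qaly[0]), total_ly=float(ly[0]),
        fracture_counts={ft.value: int(c) for ft, c in zip(FRACTURE_TYPES, counts)},
    )


# ---------------------------------------------------------------------------
# deterministic cohort trace
# ---------------------------------------------------------------------------

def run_cohort_trace(
    params: ModelParameters,
    arm: Arm | str,
    start_age: Optional[float] = None,
    horizon_years: Optional[float] = None,
    store_occupancy: bool = True,
) -> CohortTrace:
    """Exact expected occupancy, discounted cost and QALYs over the same
    transition kernel as the microsimulation; no randomness.

    The teriparatide arm is the probability mixture over the finitely many
    persistence paths (stop at each cycle boundary within the treatment
    window, or complete the course), each pushed forward deterministically.
    """
    arm = Arm(arm)
    ctx = _RunContext(params, arm, start_age, horizon_years)
    space = ctx.space
    k_cycles = ctx.n_cycles
    s_all = np.arange(space.n)
    rho = params.simulation.prevalent_vertebral_fraction

    cost_pc = np.zeros(k_cycles)
    qaly_pc = np.zeros(k_cycles)
    ly_pc = np.zeros(k_cycles)
    counts = np.zeros(4)
    occ_mix = np.zeros((k_cycles + 1, space.n)) if store_occupancy else None

    for weight, stop_month in ctx.treatment_paths():
        occ = np.zeros(space.n)
        occ[space.start_index] = 1.0 - rho
        occ[space.prevalent_index] += rho
        if occ_mix is not None:
            occ_mix[0] += weight * occ
        for k in range(k_cycles):
            month = k * ctx.cm
            _, _, _, u_base = ctx.cycle_scalars(k)
            if arm == Arm.TERIPARATIDE:
                rr_t = ctx.effective_rr_vec(month, np.array([stop_month]))
                on_drug = month < min(stop_month, params.treatment.duration_months)
            else:
                rr_t = np.ones((1, 4))
                on_drug = False
            p_death, p_site, p_any = ctx.transition_probs(k, s_all, rr_t)
            shares = _hazard_shares(p_site)

            alive_occ = occ * space.alive
            qaly_pc[k] += weight * ctx.df_eff[k] * u_base * ctx.cy * float(occ @ ctx.util_mult)
            ly_pc[k] += weight * ctx.df_eff[k] * ctx.cy * float(alive_occ.sum())
            cost_vec = ctx.state_cost(k, s_all)
            if on_drug:
                cost_vec = cost_vec + ctx.drug_cost_cycle * space.alive
            ev_w = occ * (1.0 - p_death) * p_any  # P(fracture this cycle)
            ev_site = ev_w[:, None] * shares
            cost_pc[k] += weight * ctx.df_cost[k] * (
                float(occ @ cost_vec) + float(ev_site.sum(axis=0) @ ctx.event_cost)
            )
            counts += weight * ev_site.sum(axis=0)

            p_stay = (1.0 - p_death) * (1.0 - p_any)
            occ_next = np.bincount(space.next_stay, weights=occ * p_stay, minlength=space.n)
            for i in range(4):
                w_i = occ * (1.0 - p_death) * p_any * shares[:, i]
                ok = space.next_frac[:, i] >= 0
                occ_next += np.bincount(
                    space.next_frac[ok, i], weights=w_i[ok], minlength=space.n
                )
            occ_next[space.dead_index] += float((occ * p_death).sum())
            occ = occ_next
            if occ_mix is not None:
                occ_mix[k + 1] += weight * occ

    return CohortTrace(
        arm=arm.value,
        start_age=ctx.start_age,
        cycle_years=ctx.cy,
        ages=ctx.start_age + np.arange(k_cycles) * ctx.cy,
        cost_per_cycle=cost_pc,
        qaly_per_cycle=qaly_pc,
        ly_per_cycle=ly_pc,
        fracture_counts={ft.value: float(c) for ft, c in zip(FRACTURE_TYPES, counts)},
        occupancy=occ_mix,
    )
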