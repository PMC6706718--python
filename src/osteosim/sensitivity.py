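"""Deterministic and probabilistic sensitivity analysis.

* :func:`run_owsa` — one-way deterministic sweeps (default +/-25% around the
  base case, explicit ranges where published) with tornado ranking by ICER
  span.
* :func:`run_scenarios` — the scenario battery: drug price +/-25%, restricted
  horizons, treatment RR +/-25%, start ages 60/80, undiscounted results, and
  optional treatment-duration / offset variants.
* :func:`run_psa` — second-order Monte-Carlo over the parameter distribution
  catalogue, producing the cost-effectiveness plane scatter and the
  cost-effectiveness acceptability curve (CEAC).

Distribution bounds are read as central 95% intervals. Relative risks are
log-normal anchored at the point estimate; utilities beta by method of
moments; costs gamma by exact quantile matching; the start age normal,
truncated to a plausible range.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .economics import IncrementalResult, cost_effectiveness_label, incremental
from .engine import run_cohort_trace, run_microsim
from .params import ModelParameters, PSARecord
from .transitions import Arm


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedDistribution:
    """A frozen sampling distribution for one uncertain parameter."""

    record: PSARecord
    dist: stats.rv_continuous  # frozen scipy distribution

    def sample(self, rng: np.random.Generator, size=None):
        return self.dist.rvs(size=size, random_state=rng)

    @property
    def mean(self) -> float:
        return float(self.dist.mean())


def fit_distribution(record: PSARecord) -> FittedDistribution:
    """Fit the sampling distribution for one catalogue row.

    ``(lower, upper)`` is interpreted as the central 95% interval:

    * normal: mean = midpoint, sd = (upper - lower) / 3.92, optionally
      truncated;
    * lognormal: median at the point estimate, sdlog = (ln upper - ln
      lower) / 3.92;
    * gamma: shape and scale solved so the 2.5th/97.5th percentiles equal
      the bounds exactly;
    * beta: method of moments from mean = midpoint, sd = (upper - lower)
      / 3.92 (the skew of the resulting narrow betas is negligible, so the
      bounds are still recovered as percentiles).
    """
    lo, up = record.lower, record.upper
    mid = 0.5 * (lo + up)
    sd = (up - lo) / 3.92
    if record.family == "normal":
        if record.truncate is not None:
            a, b = record.truncate
            dist = stats.truncnorm((a - mid) / sd, (b - mid) / sd, loc=mid, scale=sd)
        else:
            dist = stats.norm(loc=mid, scale=sd)
    elif record.family == "lognormal":
        point = record.point if record.point is not None else math.sqrt(lo * up)
        sdlog = (math.log(up) - math.log(lo)) / 3.92
        dist = stats.lognorm(s=sdlog, scale=point)
    elif record.family == "gamma":
        if lo <= 0:
            raise ValueError(f"psa[{record.name}]: gamma bounds must be > 0")
        ratio = up / lo

        def excess(log_k: float) -> float:
            k = math.exp(log_k)
            lo_q = stats.gamma.ppf(0.025, k)
            if lo_q <= 0.0:  # shape so small the lower percentile underflows
                return math.inf
            return stats.gamma.ppf(0.975, k) / lo_q - ratio

        log_k = brentq(excess, math.log(1e-3), math.log(1e8))
        k = math.exp(log_k)
        dist = stats.gamma(k, scale=up / stats.gamma.ppf(0.975, k))
    elif record.family == "beta":
        var = sd * sd
        common = mid * (1.0 - mid) / var - 1.0
        if common <= 0:
            raise ValueError(f"psa[{record.name}]: bounds too wide for a beta fit")
        dist = stats.beta(mid * common, (1.0 - mid) * common)
    else:  # pragma: no cover - family is validated upstream
        raise ValueError(f"unknown family '{record.family}'")
    return FittedDistribution(record=record, dist=dist)


# ---------------------------------------------------------------------------
# applying draws / perturbations to a parameter set
# ---------------------------------------------------------------------------

def _set_path(cfg: dict, path: str, value) -> None:
    keys = path.split(".")
    node = cfg
    for key in keys[:-1]:
        if key not in node:
            raise KeyError(f"unknown parameter path '{path}'")
        node = node[key]
    if keys[-1] not in node:
        raise KeyError(f"unknown parameter path '{path}'")
    node[keys[-1]] = value


def _get_path(cfg: dict, path: str):
    node = cfg
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            raise KeyError(f"unknown parameter path '{path}'")
        node = node[key]
    return node


def _scale_incidence(cfg: dict, factor: float) -> None:
    for ft, vals in cfg["incidence"]["per_1000"].items():
        cfg["incidence"]["per_1000"][ft] = [v * factor for v in vals]


def apply_psa_draws(
    params: ModelParameters, draws: dict[str, float]
) -> tuple[ModelParameters, Optional[float]]:
    """Return a parameter set with the drawn values substituted, plus the
    drawn start age (handled by the engine, not the config) if any.

    Surgery-cost draws shift the corresponding acute management package by
    the difference from the catalogue midpoint (the package's non-surgical
    component is held fixed).
    """
    cfg = params.model_dump(mode="json", exclude_none=True)
    start_age: Optional[float] = None
    by_name = {r.name: r for r in params.psa.records}
    for name, value in draws.items():
        rec = by_name[name]
        value = float(value)
        if rec.target == "start_age":
            start_age = value
        elif rec.target.startswith("surgery."):
            site = rec.target.split(".", 1)[1]
            mid = 0.5 * (rec.lower + rec.upper)
            cfg["costs"]["acute_package"][site] += value - mid
        else:
            _set_path(cfg, rec.target, value)
    try:
        return ModelParameters.model_validate(cfg), start_age
    except ValueError:
        # rare tail draws can put a first-year utility above the
        # subsequent-years value; clamp and revalidate
        fy = cfg["utilities"]["first_year"]
        sub = cfg["utilities"]["subsequent_years"]
        for site in ("hip", "vertebral"):
            fy[site] = min(fy[site], sub[site])
        return ModelParameters.model_validate(cfg), start_age


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class OWSAParameter:
    """One sweep definition: a config path plus the low/high inputs.

    Without explicit ``low``/``high``, the sweep is base value times
    ``1 -/+ perturbation``. ``cap_high`` clips the high input (e.g. utility
    multipliers at 1). ``path`` ``"incidence.scale"`` scales every incidence
    entry by the swept factor (base value 1)."""

    name: str
    path: str
    low: Optional[float] = None
    high: Optional[float] = None
    cap_low: Optional[float] = None
    cap_high: Optional[float] = None


DEFAULT_OWSA_PARAMETERS: list[OWSAParameter] = [
    OWSAParameter("drug_cost_per_pen", "costs.drug_cost_per_pen"),
    OWSAParameter("acute_package_hip", "costs.acute_package.hip"),
    OWSAParameter("acute_package_vertebral", "costs.acute_package.vertebral"),
    OWSAParameter("acute_package_wrist", "costs.acute_package.wrist"),
    OWSAParameter("acute_package_other", "costs.acute_package.other_nonvertebral"),
    OWSAParameter("treatment_rr_hip", "treatment.rr.hip"),
    OWSAParameter("treatment_rr_vertebral", "treatment.rr.vertebral"),
    OWSAParameter("treatment_rr_wrist", "treatment.rr.wrist"),
    OWSAParameter("treatment_rr_other", "treatment.rr.other_nonvertebral"),
    OWSAParameter("annual_persistence", "treatment.annual_persistence", cap_high=1.0),
    OWSAParameter("utility_vertebral_first_year", "utilities.first_year.vertebral"),
    OWSAParameter("utility_wrist_first_year", "utilities.first_year.wrist", cap_high=1.0),
    OWSAParameter("utility_other_first_year", "utilities.first_year.other_nonvertebral", cap_high=1.0),
    OWSAParameter("utility_hip_subsequent", "utilities.subsequent_years.hip", cap_high=1.0),
    OWSAParameter("utility_vertebral_subsequent", "utilities.subsequent_years.vertebral", cap_high=1.0),
    OWSAParameter("start_age", "simulation.start_age", low=60.0, high=80.0),
    OWSAParameter("discount_rate_costs", "econ.discount_rate_costs"),
    OWSAParameter("discount_rate_effects", "econ.discount_rate_effects"),
    OWSAParameter("incidence_scale", "incidence.scale"),
    OWSAParameter("background_mortality_b", "background.gompertz.gompertz_b"),
]


@dataclass
class OWSAResult:
    parameter: str
    low_value: float
    high_value: float
    icer_low: Optional[float]
    icer_high: Optional[float]
    span: float
    skipped: Optional[str] = None


def _trace_incremental(
    params: ModelParameters,
    start_age: Optional[float] = None,
    horizon_years: Optional[float] = None,
) -> tuple[IncrementalResult, float, float, float, float]:
    t1 = run_cohort_trace(params, Arm.TERIPARATIDE, start_age, horizon_years,
                          store_occupancy=False)
    t0 = run_cohort_trace(params, Arm.NO_TREATMENT, start_age, horizon_years,
                          store_occupancy=False)
    inc = incremental(t1.mean_cost, t0.mean_cost, t1.mean_qaly, t0.mean_qaly)
    return inc, t1.mean_cost, t0.mean_cost, t1.mean_qaly, t0.mean_qaly


def _perturbed_params(
    params: ModelParameters, p: OWSAParameter, value: float
) -> ModelParameters:
    cfg = params.model_dump(mode="json", exclude_none=True)
    if p.path == "incidence.scale":
        _scale_incidence(cfg, value)
    else:
        _set_path(cfg, p.path, value)
    return ModelParameters.model_validate(cfg)


def run_owsa(
    params: ModelParameters,
    parameters: Optional[Sequence[OWSAParameter]] = None,
    perturbation: float = 0.25,
    horizon_years: Optional[float] = None,
) -> list[OWSAResult]:
    """One-way sweeps re-running both arms in deterministic trace mode;
    results are sorted by descending ICER span (tornado order)."""
    if parameters is None:
        parameters = DEFAULT_OWSA_PARAMETERS
    results: list[OWSAResult] = []
    base_cfg = params.model_dump(mode="json", exclude_none=True)
    for p in parameters:
        try:
            base = 1.0 if p.path == "incidence.scale" else float(_get_path(base_cfg, p.path))
        except KeyError as err:
            results.append(OWSAResult(p.name, float("nan"), float("nan"), None, None,
                                      float("nan"), str(err)))
            continue
        lo = p.low if p.low is not None else base * (1.0 - perturbation)
        hi = p.high if p.high is not None else base * (1.0 + perturbation)
        if p.cap_low is not None:
            lo = max(lo, p.cap_low)
        if p.cap_high is not None:
            hi = min(hi, p.cap_high)
        icers: list[Optional[float]] = []
        skipped = None
        for v in (lo, hi):
            try:
                pp = _perturbed_params(params, p, v)
                inc, *_ = _trace_incremental(pp, horizon_years=horizon_years)
                icers.append(inc.icer)
            except (ValueError, KeyError) as err:
                skipped = f"{p.name}={v}: {err}"
                icers.append(None)
        if skipped is not None:
            results.append(OWSAResult(p.name, lo, hi, icers[0], icers[1],
                                      float("nan"), skipped))
            continue
        span = (
            abs(icers[1] - icers[0])
            if icers[0] is not None and icers[1] is not None
            else float("nan")
        )
        results.append(OWSAResult(p.name, lo, hi, icers[0], icers[1], span))
    results.sort(key=lambda r: (math.isnan(r.span), -r.span if not math.isnan(r.span) else 0.0))
    return results


def owsa_to_frame(results: Sequence[OWSAResult]) -> pd.DataFrame:
    columns = ["parameter", "low", "high", "icer_low", "icer_high", "span", "skipped"]
    return pd.DataFrame([{
        "parameter": r.parameter, "low": r.low_value, "high": r.high_value,
        "icer_low": r.icer_low, "icer_high": r.icer_high, "span": r.span,
        "skipped": r.skipped,
    } for r in results], columns=columns)


# ---------------------------------------------------------------------------
# scenario battery
# ---------------------------------------------------------------------------

#: the published one-way scenario set (plus base case); extra named
#: scenarios for treatment duration and offset-time variants
SCENARIOS: dict[str, dict] = {
    "base_case": {},
    "drug_cost_minus_25pct": {"scale": {"costs.drug_cost_per_pen": 0.75}},
    "drug_cost_plus_25pct": {"scale": {"costs.drug_cost_per_pen": 1.25}},
    "horizon_5y": {"horizon_years": 5.0},
    "horizon_10y": {"horizon_years": 10.0},
    "rr_plus_25pct": {"rr_scale": 1.25},
    "rr_minus_25pct": {"rr_scale": 0.75},
    "start_age_60": {"set": {"simulation.start_age": 60.0}},
    "start_age_80": {"set": {"simulation.start_age": 80.0}},
    "no_discounting": {
        "set": {"econ.discount_rate_costs": 0.0, "econ.discount_rate_effects": 0.0}
    },
    "duration_12m": {"set": {"treatment.duration_months": 12.0}},
    "duration_24m": {"set": {"treatment.duration_months": 24.0}},
    "offset_none": {
        "set": {
            "treatment.offset_months_vertebral": 0.0,
            "treatment.offset_months_nonvertebral": 0.0,
        }
    },
    "offset_double": {
        "set": {
            "treatment.offset_months_vertebral": 48.0,
            "treatment.offset_months_nonvertebral": 60.0,
        }
    },
}

DEFAULT_SCENARIO_SET = [
    "base_case",
    "drug_cost_minus_25pct", "drug_cost_plus_25pct",
    "horizon_5y", "horizon_10y",
    "rr_plus_25pct", "rr_minus_25pct",
    "start_age_60", "start_age_80",
    "no_discounting",
]


def _scenario_params(params: ModelParameters, spec: dict) -> tuple[ModelParameters, Optional[float]]:
    cfg = params.model_dump(mode="json", exclude_none=True)
    for path, factor in spec.get("scale", {}).items():
        _set_path(cfg, path, _get_path(cfg, path) * factor)
    for path, value in spec.get("set", {}).items():
        _set_path(cfg, path, value)
    if "rr_scale" in spec:
        for site, rr in cfg["treatment"]["rr"].items():
            cfg["treatment"]["rr"][site] = rr * spec["rr_scale"]
    return ModelParameters.model_validate(cfg), spec.get("horizon_years")


def run_scenarios(
    params: ModelParameters,
    scenarios: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Deterministic (cohort-trace) results for the named scenarios.

    Returns one row per scenario with per-arm totals, incrementals, the
    ICER, and cost-effectiveness labels at the 2x and 3x GDP/capita
    willingness-to-pay thresholds.
    """
    names = list(scenarios) if scenarios is not None else list(DEFAULT_SCENARIO_SET)
    unknown = [n for n in names if n not in SCENARIOS]
    if unknown:
        raise KeyError(
            f"unknown scenario name(s) {unknown}; available: {sorted(SCENARIOS)}"
        )
    rows = []
    for name in names:
        pp, horizon = _scenario_params(params, SCENARIOS[name])
        inc, c1, c0, e1, e0 = _trace_incremental(pp, horizon_years=horizon)
        rows.append({
            "scenario": name,
            "cost_teriparatide": c1, "cost_no_treatment": c0,
            "qaly_teriparatide": e1, "qaly_no_treatment": e0,
            "delta_cost": inc.delta_cost, "delta_effect": inc.delta_effect,
            "icer": inc.icer,
            "label": cost_effectiveness_label(inc, params.econ.gdp_per_capita),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Scatter of incremental (cost, effect) points plus the CEAC."""

    samples: pd.DataFrame      # one row per iteration: draws + outcomes
    ceac: pd.DataFrame         # columns: wtp, probability
    seed: int
    n_iterations: int
    engine: str

    def prob_cost_effective(self, wtp: float) -> float:
        dc = self.samples["delta_cost"].to_numpy()
        de = self.samples["delta_effect"].to_numpy()
        return float(np.mean(wtp * de - dc > 0.0))

    def summary(self) -> dict:
        def ci(col: str) -> dict:
            x = self.samples[col].to_numpy()
            return {
                "mean": float(x.mean()),
                "ci95_low": float(np.percentile(x, 2.5)),
                "ci95_high": float(np.percentile(x, 97.5)),
            }
        return {
            "seed": self.seed, "n_iterations": self.n_iterations,
            "engine": self.engine,
            "cost_teriparatide": ci("cost_teriparatide"),
            "cost_no_treatment": ci("cost_no_treatment"),
            "qaly_teriparatide": ci("qaly_teriparatide"),
            "qaly_no_treatment": ci("qaly_no_treatment"),
            "delta_cost": ci("delta_cost"),
            "delta_effect": ci("delta_effect"),
        }


def run_psa(
    params: ModelParameters,
    n_iterations: int = 1000,
    seed: int = 0,
    engine: str = "trace",
    n_individuals: int = 2000,
    wtp_grid: Optional[Sequence[float]] = None,
) -> PSAResult:
    """Second-order Monte-Carlo over the parameter distribution catalogue.

    Per iteration, one draw of every catalogue row (the start age is drawn
    per iteration, not per individual) is pushed through both arms. The
    default engine is the deterministic cohort trace, isolating parameter
    (second-order) uncertainty; ``engine="microsim"`` layers first-order
    sampling noise on top using ``n_individuals`` patients per arm with
    per-iteration sub-seeds, which widens the interval estimates.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if engine not in ("trace", "microsim"):
        raise ValueError("engine must be 'trace' or 'microsim'")
    samplers = [fit_distribution(r) for r in params.psa.records]
    master = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        draws = {s.record.name: float(s.sample(master)) for s in samplers}
        pp, start_age = apply_psa_draws(params, draws)
        if engine == "trace":
            inc, c1, c0, e1, e0 = _trace_incremental(pp, start_age=start_age)
        else:
            sub = master.integers(0, 2**31, size=2)
            a1 = run_microsim(pp, Arm.TERIPARATIDE, n_individuals, int(sub[0]), start_age)
            a0 = run_microsim(pp, Arm.NO_TREATMENT, n_individuals, int(sub[1]), start_age)
            inc = incremental(a1.mean_cost, a0.mean_cost, a1.mean_qaly, a0.mean_qaly)
            c1, c0, e1, e0 = a1.mean_cost, a0.mean_cost, a1.mean_qaly, a0.mean_qaly
        rows.append({
            "iteration": it, **draws,
            "cost_teriparatide": c1, "cost_no_treatment": c0,
            "qaly_teriparatide": e1, "qaly_no_treatment": e0,
            "delta_cost": inc.delta_cost, "delta_effect": inc.delta_effect,
        })
    samples = pd.DataFrame(rows)
    grid = list(wtp_grid) if wtp_grid is not None else params.econ.effective_wtp_grid()
    dc = samples["delta_cost"].to_numpy()
    de = samples["delta_effect"].to_numpy()
    ceac = pd.DataFrame({
        "wtp": grid,
        "probability": [float(np.mean(w * de - dc > 0.0)) for w in grid],
    })
    return PSAResult(samples=samples, ceac=ceac, seed=seed,
                     n_iterations=n_iterations, engine=engine)
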