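"""Engine behaviour: discounting, microsimulation contracts, and agreement
between the microsimulation and the deterministic cohort trace."""

from __future__ import annotations

import math

import numpy as np
import pytest

import osteosim as osm
from osteosim.engine import (
    _RunContext,
    discount_factor,
    run_cohort_trace,
    run_microsim,
    simulate_individual,
    treatment_status_at,
)
from osteosim.params import FRACTURE_TYPES, FractureType
from osteosim.statespace import get_state_space
from osteosim.transitions import Arm, PatientState, cycle_hazards, cycle_utility


def _zero_mortality(cfg):
    cfg["background"]["life_table_inline"] = {
        "age": list(range(50, 101)), "q_annual": [0.0] * 51,
    }


def _zero_incidence(cfg):
    for ft in cfg["incidence"]["per_1000"]:
        cfg["incidence"]["per_1000"][ft] = [0.0] * 8


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0.3, 0.0) == 1.0
        assert discount_factor(0.072, 1.0) == pytest.approx(1 / 1.072)
        assert discount_factor(0.05, 10.0) == pytest.approx(1.05 ** -10)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            discount_factor(-0.1, 1.0)


class TestSimulateIndividual:
    def test_no_events_survives_to_horizon(self, make_params):
        p = make_params(lambda c: (_zero_mortality(c), _zero_incidence(c)))
        res = simulate_individual(p, Arm.NO_TREATMENT, 70.0, np.random.default_rng(0))
        assert len(res.trajectory) == 60  # (100 - 70) / 0.5 cycles
        assert set(res.trajectory["state"]) == {"well"}
        expected_qaly = sum(
            1.05 ** (-k * 0.5) * osm.baseline_utility(70 + k * 0.5, p.background.utility_curve) * 0.5
            for k in range(60)
        )
        assert res.total_qaly == pytest.approx(expected_qaly, rel=1e-12)

    def test_certain_death_in_first_cycle(self, make_params):
        p = make_params(lambda c: c["background"].update(
            life_table_inline={"age": list(range(50, 101)), "q_annual": [1.0] * 51}))
        res = simulate_individual(p, Arm.NO_TREATMENT, 70.0, np.random.default_rng(3))
        assert len(res.trajectory) == 1
        assert res.total_ly == pytest.approx(0.5)

    def test_seed_determinism(self, params):
        a = simulate_individual(params, Arm.TERIPARATIDE, 70.0, np.random.default_rng(11))
        b = simulate_individual(params, Arm.TERIPARATIDE, 70.0, np.random.default_rng(11))
        assert a.total_cost == b.total_cost and a.total_qaly == b.total_qaly
        assert a.trajectory.equals(b.trajectory)


class TestRunMicrosim:
    def test_single_patient_matches_individual(self, params):
        for arm in (Arm.TERIPARATIDE, Arm.NO_TREATMENT):
            one = run_microsim(params, arm, n=1, seed=7)
            ind = simulate_individual(params, arm, None, np.random.default_rng(7))
            assert one.mean_cost == ind.total_cost
            assert one.mean_qaly == ind.total_qaly

    def test_reproducible_with_seed(self, params):
        a = run_microsim(params, Arm.TERIPARATIDE, 500, seed=5)
        b = run_microsim(params, Arm.TERIPARATIDE, 500, seed=5)
        assert a == b

    def test_se_shrinks_with_n(self, params):
        small = run_microsim(params, Arm.NO_TREATMENT, 4000, seed=2)
        large = run_microsim(params, Arm.NO_TREATMENT, 16000, seed=3)
        assert large.se_qaly == pytest.approx(small.se_qaly / 2.0, rel=0.15)
        assert large.se_cost == pytest.approx(small.se_cost / 2.0, rel=0.15)

    def test_qaly_never_exceeds_life_years(self, params):
        r = run_microsim(params, Arm.NO_TREATMENT, 2000, seed=4)
        assert 0 < r.mean_qaly <= r.mean_ly

    def test_treatment_reduces_fractures_on_matched_seeds(self, params):
        # common random numbers: same seed in both arms
        teri = run_microsim(params, Arm.TERIPARATIDE, 20000, seed=9)
        ctrl = run_microsim(params, Arm.NO_TREATMENT, 20000, seed=9)
        assert sum(teri.fracture_counts.values()) < sum(ctrl.fracture_counts.values())
        assert teri.fracture_counts["vertebral"] < ctrl.fracture_counts["vertebral"]

    def test_persistence_recovered_at_one_year(self, params):
        frac = treatment_status_at(params, Arm.TERIPARATIDE, 20000, seed=13, month=12.0)
        assert frac == pytest.approx(0.703, abs=0.02)


class TestKernelMatchesScalarModel:
    """The vectorised kernel and the per-patient functions are independent
    code paths over the same rules; they must agree state by state."""

    @pytest.mark.parametrize("arm,stop", [
        (Arm.NO_TREATMENT, None), (Arm.TERIPARATIDE, 18.0), (Arm.TERIPARATIDE, 6.0),
    ])
    def test_transition_probabilities_agree(self, params, arm, stop):
        space = get_state_space()
        ctx = _RunContext(params, arm, start_age=70.0)
        rng = np.random.default_rng(0)
        sample = rng.choice(np.flatnonzero(space.alive), size=40, replace=False)
        for k in (0, 1, 3, 7, 12):
            month = k * 6.0
            if arm == Arm.TERIPARATIDE:
                rr_t = ctx.effective_rr_vec(month, np.full(len(sample), stop))
            else:
                rr_t = np.ones((len(sample), 4))
            p_death, p_site, _ = ctx.transition_probs(k, sample, rr_t)
            for row, idx in enumerate(sample):
                patient = PatientState(
                    age=70.0 + k * 0.5,
                    state=space.health_state(int(idx)),
                    months_since_model_start=month,
                    arm=arm,
                    treatment_stop_month=stop,
                    months_since_last_fracture=space.months_since_fracture(int(idx), 6.0),
                )
                hz = cycle_hazards(patient, params)
                assert hz.p_death == pytest.approx(p_death[row], rel=1e-12)
                for j, ft in enumerate(FRACTURE_TYPES):
                    assert hz.p_fracture[ft] == pytest.approx(p_site[row, j], rel=1e-12, abs=1e-15)

    def test_cycle_utility_agrees(self, params):
        space = get_state_space()
        ctx = _RunContext(params, Arm.NO_TREATMENT, start_age=70.0)
        _, _, _, u_base = ctx.cycle_scalars(4)
        rng = np.random.default_rng(1)
        for idx in rng.choice(np.flatnonzero(space.alive), size=25, replace=False):
            patient = PatientState(
                age=72.0, state=space.health_state(int(idx)),
                months_since_last_fracture=space.months_since_fracture(int(idx), 6.0),
            )
            assert cycle_utility(patient, params) == pytest.approx(
                u_base * ctx.util_mult[idx] * 0.5, rel=1e-12
            )


class TestCohortTrace:
    def test_occupancy_conserved_and_death_monotone(self, params):
        for arm in (Arm.TERIPARATIDE, Arm.NO_TREATMENT):
            trace = run_cohort_trace(params, arm)
            sums = trace.occupancy.sum(axis=1)
            assert np.abs(sums - 1.0).max() < 1e-12
            dead = trace.occupancy[:, get_state_space().dead_index]
            assert (np.diff(dead) >= -1e-15).all()

    def test_null_treatment_arms_identical(self, make_params):
        p = make_params(lambda c: (
            c["treatment"]["rr"].update({k: 1.0 for k in c["treatment"]["rr"]}),
            c["costs"].update(drug_cost_per_pen=0.0),
        ))
        t1 = run_cohort_trace(p, Arm.TERIPARATIDE, store_occupancy=False)
        t0 = run_cohort_trace(p, Arm.NO_TREATMENT, store_occupancy=False)
        assert t1.mean_cost - t0.mean_cost == 0.0
        assert t1.mean_qaly - t0.mean_qaly == 0.0

    def test_microsim_agrees_with_trace(self, params):
        for arm in (Arm.TERIPARATIDE, Arm.NO_TREATMENT):
            trace = run_cohort_trace(params, arm, store_occupancy=False)
            sim = run_microsim(params, arm, 30000, seed=21)
            assert abs(sim.mean_cost - trace.mean_cost) < 3.5 * sim.se_cost
            assert abs(sim.mean_qaly - trace.mean_qaly) < 3.5 * sim.se_qaly

    def test_discounting_reduces_totals(self, params, make_params):
        undisc = make_params(lambda c: c["econ"].update(
            discount_rate_costs=0.0, discount_rate_effects=0.0))
        t_disc = run_cohort_trace(params, Arm.NO_TREATMENT, store_occupancy=False)
        t_undisc = run_cohort_trace(undisc, Arm.NO_TREATMENT, store_occupancy=False)
        assert t_undisc.mean_cost > t_disc.mean_cost
        assert t_undisc.mean_qaly > t_disc.mean_qaly

    def test_horizon_truncation(self, params):
        t5 = run_cohort_trace(params, Arm.NO_TREATMENT, horizon_years=5.0,
                              store_occupancy=False)
        assert len(t5.ages) == 10
        full = run_cohort_trace(params, Arm.NO_TREATMENT, store_occupancy=False)
        assert t5.mean_qaly < full.mean_qaly

    def test_prevalent_fraction_lowers_utility(self, params, make_params):
        prev = make_params(lambda c: c["simulation"].update(
            prevalent_vertebral_fraction=1.0))
        t_prev = run_cohort_trace(prev, Arm.NO_TREATMENT, store_occupancy=False)
        t_base = run_cohort_trace(params, Arm.NO_TREATMENT, store_occupancy=False)
        assert t_prev.mean_qaly < t_base.mean_qaly

    def test_expected_fracture_counts_positive(self, params):
        trace = run_cohort_trace(params, Arm.NO_TREATMENT, store_occupancy=False)
        assert all(v > 0 for v in trace.fracture_counts.values())


def test_trajectory_writer_columns(params, tmp_path):
    res = simulate_individual(params, Arm.TERIPARATIDE, 70.0, np.random.default_rng(2))
    f = tmp_path / "traj.csv"
    res.trajectory.to_csv(f, index=False)
    header = f.read_text().splitlines()[0]
    assert header == "cycle,age,state,cost,utility"
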