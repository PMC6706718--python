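"""Per-cycle mechanics: probability conversions, treatment effect taper,
state-dependent hazards, utilities and costs."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, strategies as st

import osteosim as osm
from osteosim.params import FractureType, HealthState, HealthStateLabel
from osteosim.transitions import (
    Arm,
    PatientState,
    allowed_sites,
    annual_prob_to_cycle_prob,
    cycle_cost,
    cycle_hazards,
    cycle_utility,
    effective_fracture_rr,
    persistence_prob_per_cycle,
)

HIP = FractureType.HIP
VERT = FractureType.VERTEBRAL
WRIST = FractureType.WRIST
OTHER = FractureType.OTHER

WELL = HealthState(label=HealthStateLabel.WELL)


def patient(state=WELL, age=72.0, arm=Arm.NO_TREATMENT, month=0.0, stop=None,
            msf=None, on_treatment=False):
    return PatientState(
        age=age, state=state, months_since_model_start=month, arm=arm,
        on_treatment=on_treatment, treatment_stop_month=stop,
        months_since_last_fracture={ft: (msf or {}).get(ft) for ft in FractureType},
    )


class TestProbabilityConversions:
    def test_endpoints(self):
        assert annual_prob_to_cycle_prob(0.0, 0.5) == 0.0
        assert annual_prob_to_cycle_prob(1.0, 0.5) == 1.0

    def test_half_year_value(self):
        # independent: 1 - sqrt(1 - 0.0047)
        assert annual_prob_to_cycle_prob(0.0047, 0.5) == pytest.approx(
            1.0 - math.sqrt(0.9953), rel=1e-12
        )
        assert annual_prob_to_cycle_prob(0.0047, 0.5) == pytest.approx(0.0023528, abs=5e-8)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            annual_prob_to_cycle_prob(1.2, 0.5)

    @given(st.floats(min_value=0, max_value=1))
    def test_two_half_cycles_compound_to_annual(self, p):
        c = annual_prob_to_cycle_prob(p, 0.5)
        assert 1.0 - (1.0 - c) ** 2 == pytest.approx(p, abs=1e-12)


class TestPersistence:
    def test_half_year_rate(self):
        assert persistence_prob_per_cycle(0.703, 0.5) == pytest.approx(0.703 ** 0.5)
        assert persistence_prob_per_cycle(1.0, 0.5) == 1.0

    def test_cycles_compound_to_annual(self):
        c = persistence_prob_per_cycle(0.703, 0.5)
        assert c * c == pytest.approx(0.703, rel=1e-12)


class TestEffectTaper:
    def test_full_effect_during_treatment(self, params):
        for month in (0, 6, 12, 17.9):
            assert effective_fracture_rr(VERT, month, None, params.treatment) == 0.35

    def test_linear_taper_after_stop(self, params):
        # 12 months past an 18-month stop, vertebral offset 24 months
        got = effective_fracture_rr(VERT, 30, 18, params.treatment)
        assert got == pytest.approx(0.35 + 0.65 * 12 / 24, rel=1e-12)

    def test_no_effect_after_offset(self, params):
        assert effective_fracture_rr(VERT, 42, 18, params.treatment) == 1.0
        assert effective_fracture_rr(VERT, 60, 18, params.treatment) == 1.0
        assert effective_fracture_rr(HIP, 48, 18, params.treatment) == 1.0

    def test_early_stop_starts_taper_immediately(self, params):
        assert effective_fracture_rr(VERT, 6, 6, params.treatment) == 0.35
        assert effective_fracture_rr(VERT, 18, 6, params.treatment) == pytest.approx(
            0.35 + 0.65 * 12 / 24
        )

    def test_zero_offset_is_step(self, params, make_params):
        p = make_params(lambda c: c["treatment"].update(
            offset_months_vertebral=0.0, offset_months_nonvertebral=0.0))
        assert effective_fracture_rr(VERT, 17.9, None, p.treatment) == 0.35
        assert effective_fracture_rr(VERT, 18, None, p.treatment) == 1.0

    @given(st.floats(min_value=0, max_value=80))
    def test_bounded_and_monotone_in_month(self, month):
        p = osm.default_parameters()
        rr = effective_fracture_rr(VERT, month, 18, p.treatment)
        assert 0.35 <= rr <= 1.0
        later = effective_fracture_rr(VERT, month + 1.0, 18, p.treatment)
        assert later >= rr - 1e-12


class TestCycleHazards:
    def test_dead_patient_rejected(self, params):
        dead = patient(state=HealthState(label=HealthStateLabel.DEAD))
        with pytest.raises(ValueError):
            cycle_hazards(dead, params)

    def test_well_patient_fracture_probability_composition(self, params):
        hz = cycle_hazards(patient(age=72), params)
        expected = annual_prob_to_cycle_prob(
            osm.incidence_lookup(72, HIP, params.incidence), 0.5
        )
        assert hz.p_fracture[HIP] == pytest.approx(expected, rel=1e-12)

    def test_post_hip_allows_only_new_hip(self, params):
        st_ph = HealthState(label=HealthStateLabel.POST_HIP)
        hz = cycle_hazards(patient(state=st_ph, msf={HIP: 24.0}), params)
        assert hz.p_fracture[VERT] == 0.0
        assert hz.p_fracture[WRIST] == 0.0
        assert hz.p_fracture[OTHER] == 0.0
        assert hz.p_fracture[HIP] > 0.0
        assert allowed_sites(st_ph) == (HIP,)

    def test_post_vertebral_allows_vertebral_and_hip(self, params):
        st_pv = HealthState(label=HealthStateLabel.POST_VERTEBRAL)
        hz = cycle_hazards(patient(state=st_pv, msf={VERT: 24.0}), params)
        assert hz.p_fracture[HIP] > 0 and hz.p_fracture[VERT] > 0
        assert hz.p_fracture[WRIST] == 0.0 and hz.p_fracture[OTHER] == 0.0

    def test_history_elevation_applies_same_site(self, params):
        base = cycle_hazards(patient(age=72), params).p_fracture[WRIST]
        recent = cycle_hazards(patient(age=72, msf={WRIST: 6.0}), params).p_fracture[WRIST]
        assert recent == pytest.approx(
            annual_prob_to_cycle_prob(
                min(osm.incidence_lookup(72, WRIST, params.incidence) * 2.0, 1.0), 0.5
            )
        )
        assert recent > base

    def test_multinomial_sums_to_one_exactly(self, params):
        for st_ in (
            WELL,
            HealthState(label=HealthStateLabel.ACUTE_FRACTURE, fracture=HIP),
            HealthState(label=HealthStateLabel.POST_VERTEBRAL),
        ):
            msf = {HIP: 0.0} if st_.label == HealthStateLabel.ACUTE_FRACTURE else {VERT: 30.0}
            hz = cycle_hazards(patient(state=st_, age=78, msf=msf), params)
            shares = hz.site_shares()
            total = hz.p_death
            total += (1 - hz.p_death) * hz.p_any_fracture * sum(shares.values())
            total += (1 - hz.p_death) * (1 - hz.p_any_fracture)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_null_treatment_rr_matches_control(self, params, make_params):
        p_null = make_params(lambda c: c["treatment"]["rr"].update(
            {k: 1.0 for k in c["treatment"]["rr"]}))
        teri = cycle_hazards(patient(arm=Arm.TERIPARATIDE, month=6.0), p_null)
        ctrl = cycle_hazards(patient(arm=Arm.NO_TREATMENT, month=6.0), p_null)
        assert teri == ctrl

    def test_acute_state_uses_first_year_mortality(self, params):
        acute = patient(
            state=HealthState(label=HealthStateLabel.ACUTE_FRACTURE, fracture=HIP),
            age=72, msf={HIP: 0.0},
        )
        post = patient(state=HealthState(label=HealthStateLabel.POST_HIP),
                       age=72, msf={HIP: 24.0})
        well = patient(age=72)
        q = [cycle_hazards(p, params).p_death for p in (acute, post, well)]
        assert q[0] > q[1] > q[2]


class TestCycleUtility:
    def test_well_at_70(self, params):
        assert cycle_utility(patient(age=70), params) == pytest.approx(0.78 * 1.0 * 0.5)

    def test_acute_vertebral_at_70(self, params):
        p = patient(
            state=HealthState(label=HealthStateLabel.ACUTE_FRACTURE, fracture=VERT),
            age=70, msf={VERT: 0.0},
        )
        assert cycle_utility(p, params) == pytest.approx(0.78 * 0.626 * 0.5)

    def test_post_hip_multiplier_time_invariant(self, params):
        u = [
            cycle_utility(
                patient(state=HealthState(label=HealthStateLabel.POST_HIP),
                        age=70, msf={HIP: m}), params)
            for m in (12.0, 60.0, 240.0)
        ]
        assert u[0] == u[1] == u[2] == pytest.approx(0.78 * 0.9 * 0.5)

    def test_never_exceeds_baseline(self, params):
        for st_, msf in [
            (WELL, {}),
            (HealthState(label=HealthStateLabel.ACUTE_FRACTURE, fracture=WRIST), {WRIST: 0.0}),
            (HealthState(label=HealthStateLabel.POST_VERTEBRAL), {VERT: 24.0}),
        ]:
            p = patient(state=st_, age=75, msf=msf)
            u_base = osm.baseline_utility(75, params.background.utility_curve)
            assert cycle_utility(p, params) <= u_base * 0.5 + 1e-15


class TestCycleCost:
    def test_well_cycle_recurring_items(self, params):
        # calcium/vitamin-D/naproxen every cycle; BMD on annual cycles
        assert cycle_cost(patient(), [], params, cycle_index=0) == 1_300_000 + 1_400_000
        assert cycle_cost(patient(), [], params, cycle_index=1) == 1_300_000

    def test_hip_event_includes_package_and_one_offs(self, params):
        got = cycle_cost(patient(), [HIP], params, cycle_index=1)
        # package + wheelchair + waving bed + nursing + physiotherapy
        assert got == 1_300_000 + 150_000_000 + 10_000_000 + 10_000_000 + 60_000_000 + 10_500_000

    def test_wrist_event_is_package_only(self, params):
        got = cycle_cost(patient(), [WRIST], params, cycle_index=1)
        assert got == 1_300_000 + 80_000_000

    def test_acute_state_bed_sore_cost(self, params):
        p = patient(
            state=HealthState(label=HealthStateLabel.ACUTE_FRACTURE, fracture=VERT),
            msf={VERT: 0.0},
        )
        assert cycle_cost(p, [], params, cycle_index=1) == 1_300_000 + 4_000_000

    def test_drug_cost_prorated_per_cycle(self, params):
        p = patient(arm=Arm.TERIPARATIDE, on_treatment=True)
        got = cycle_cost(p, [], params, cycle_index=1)
        assert got == 1_300_000 + 26_766_667
        assert params.costs.drug_cost_per_cycle(0.5) == round(182.5 / 30 * 4_400_000)
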