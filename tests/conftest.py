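"""Shared fixtures: the bundled parameter preset, config editing helpers,
and a generator of randomized valid parameter sets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from osteosim.params import ModelParameters, default_parameters

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_parameters()


def edit_params(base: ModelParameters, mutate) -> ModelParameters:
    """Apply ``mutate(cfg_dict)`` to a dumped config and revalidate."""
    cfg = base.model_dump(mode="json", exclude_none=True)
    mutate(cfg)
    return ModelParameters.model_validate(cfg)


@pytest.fixture(scope="session")
def make_params(params):
    def _make(mutate) -> ModelParameters:
        return edit_params(params, mutate)
    return _make


def random_valid_params(base: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """A randomized but invariant-respecting parameter set around the preset."""

    def mutate(cfg: dict) -> None:
        inc_scale = rng.uniform(0.3, 2.5)
        for ft, vals in cfg["incidence"]["per_1000"].items():
            cfg["incidence"]["per_1000"][ft] = [v * inc_scale for v in vals]
        for group in ("first_year", "subsequent"):
            for site, vals in cfg["mortality_rr"][group].items():
                cfg["mortality_rr"][group][site] = [
                    1.0 + (v - 1.0) * rng.uniform(0.5, 1.5) for v in vals
                ]
        for site in cfg["treatment"]["rr"]:
            cfg["treatment"]["rr"][site] = rng.uniform(0.2, 1.2)
        cfg["treatment"]["annual_persistence"] = rng.uniform(0.3, 1.0)
        cfg["treatment"]["duration_months"] = float(rng.choice([12, 18, 24]))
        cfg["treatment"]["offset_months_vertebral"] = rng.uniform(0, 48)
        cfg["treatment"]["offset_months_nonvertebral"] = rng.uniform(0, 60)
        sub_h = rng.uniform(0.7, 1.0)
        sub_v = rng.uniform(0.7, 1.0)
        cfg["utilities"]["subsequent_years"] = {"hip": sub_h, "vertebral": sub_v}
        cfg["utilities"]["first_year"] = {
            "hip": rng.uniform(0.4, sub_h),
            "vertebral": rng.uniform(0.4, sub_v),
            "wrist": rng.uniform(0.7, 1.0),
            "other_nonvertebral": rng.uniform(0.6, 1.0),
        }
        for site in cfg["costs"]["acute_package"]:
            cfg["costs"]["acute_package"][site] *= rng.uniform(0.5, 2.0)
        cfg["costs"]["drug_cost_per_pen"] *= rng.uniform(0.5, 2.0)
        cfg["econ"]["discount_rate_costs"] = rng.uniform(0.0, 0.12)
        cfg["econ"]["discount_rate_effects"] = rng.uniform(0.0, 0.12)
        base_mult = rng.uniform(1.0, 3.0)
        steps = np.sort(rng.uniform(0.0, 1.0, size=4))[::-1]
        cfg["history"]["schedule"] = [
            float(1.0 + (base_mult - 1.0) * m) for m in [1.0, *steps]
        ]
        cfg["background"]["gompertz"]["gompertz_b"] *= rng.uniform(0.5, 2.0)
        cfg["background"]["utility_curve"]["anchor_utility"] = rng.uniform(0.7, 1.0)
        cfg["background"]["utility_curve"]["slope_per_year"] = rng.uniform(0.0, 0.008)
        cfg["simulation"]["start_age"] = float(rng.uniform(55, 85))
        cfg["simulation"]["prevalent_vertebral_fraction"] = float(rng.choice([0.0, 0.0, 0.3]))

    return edit_params(base, mutate)
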