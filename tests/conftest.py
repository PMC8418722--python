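import dataclasses

import pytest

from pharmascreen.engine import ModelInputs
from pharmascreen.parameters import (CohortDefinition, CostInputs,
                                     HazardInputs, ParameterSet, Stratum,
                                     UtilityInputs, fixed)
from pharmascreen.synthetic import reference_inputs


@pytest.fixture(scope="session")
def ref_inputs() -> ModelInputs:
    """The synthetic base case (cached across the session)."""
    return reference_inputs(seed=2021)


@pytest.fixture(scope="session")
def small_inputs(ref_inputs) -> ModelInputs:
    """Two-stratum cohort for fast engine / PSA tests."""
    cohort = CohortDefinition(strata=(
        Stratum("women", 55, "15-19", 60),
        Stratum("men", 60, "12-14", 40)))
    return dataclasses.replace(ref_inputs, cohort=cohort)


def degenerate(inputs: ModelInputs) -> ModelInputs:
    """Same point values, every sampling distribution collapsed."""
    def fix_all(block):
        return type(block)(**{k: (fixed(v.point) if hasattr(v, "point") else v)
                              for k, v in block.__dict__.items()})

    p = inputs.params
    params = ParameterSet(
        costs=fix_all(p.costs),
        utilities=UtilityInputs(
            baseline={k: fixed(v.point) for k, v in p.utilities.baseline.items()},
            disutility_t2d=fixed(p.utilities.disutility_t2d.point),
            disutility_complications_weighted=fixed(
                p.utilities.disutility_complications_weighted.point)),
        hazards=fix_all(p.hazards),
        economics=p.economics)
    return dataclasses.replace(
        inputs, params=params,
        incidence_fit=dataclasses.replace(inputs.incidence_fit,
                                          covariance=None),
        complication_fit=dataclasses.replace(inputs.complication_fit,
                                             covariance=None))
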