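import numpy as np
import pytest

from crc_cea.params import (
    ComplianceParams,
    CostParams,
    EconSettings,
    ModelParameters,
    MortalityBand,
    MortalityTable,
    NaturalHistoryParams,
    TestCharacteristics,
    UtilityParams,
    default_parameters,
    default_strategies,
)


@pytest.fixture(scope="session")
def fixture_params():
    """The packaged fixture-hk2009 parameter set (session-wide, read-only)."""
    return default_parameters()


def make_toy_params(
    q_other: float = 0.0,
    disease: bool = False,
    zero_costs: bool = True,
    **overrides,
) -> ModelParameters:
    """A minimal valid parameter set for closed-form checks.

    Default: the whole cohort starts in normal epithelium, no disease
    transitions, other-cause death probability ``q_other`` per year, all
    utilities 1, zero costs.
    """
    nh = NaturalHistoryParams(
        p_normal_to_low=0.0, p_low_to_high=0.0, p_high_to_crc=0.0,
        p_stage_progress=[0.0, 0.0, 0.0], p_symptomatic=[0.0] * 4,
        m_crc=[0.0] * 4, initial_distribution=[1.0, 0.0, 0.0],
    )
    if disease:
        nh = NaturalHistoryParams(
            p_normal_to_low=0.02, p_low_to_high=0.03, p_high_to_crc=0.04,
            p_stage_progress=[0.3, 0.3, 0.3], p_symptomatic=[0.2, 0.3, 0.5, 0.8],
            m_crc=[0.01, 0.05, 0.15, 0.4], initial_distribution=[0.9, 0.08, 0.02],
        )
    bands = [MortalityBand(sex, lo, lo + 4, q_other, 0.0)
             for sex in ("male", "female") for lo in range(50, 80, 5)]
    cost_val = 0.0 if zero_costs else 100.0
    params = ModelParameters(
        natural_history=nh,
        mortality=MortalityTable(bands),
        tests={
            "g_fobt": TestCharacteristics("g_fobt", 0.05, 0.12, [0.5] * 4, 0.92),
            "i_fobt": TestCharacteristics("i_fobt", 0.10, 0.25, [0.75] * 4, 0.95),
            "colonoscopy": TestCharacteristics("colonoscopy", 1.0, 1.0, [1.0] * 4, 1.0),
        },
        compliance=ComplianceParams(),
        costs=CostParams(
            unit_cost={k: cost_val for k in (
                "g_fobt", "i_fobt", "colonoscopy", "polypectomy",
                "complication_bleed", "complication_perforation", "specialist_visit")},
            initial_cost=[cost_val] * 4,
            continuing_cost=[cost_val] * 4,
        ),
        utilities=UtilityParams(),
        econ=EconSettings(),
        strategies=default_strategies(),
    )
    for key, value in overrides.items():
        setattr(params, key, value)
    params.validate()
    return params


@pytest.fixture
def toy_params():
    return make_toy_params


#: Printed per-person outcomes of the published base case (whole-dollar
#: costs, four-decimal LY/QALY): the worked-example inputs for the CEA layer.
PRINTED_TABLE1 = {
    # name: (cost, ly, qaly)
    "no_screening": (2541, 15.6420, 14.7479),
    "biennial_gfobt": (4221, 15.6862, 15.0687),
    "annual_gfobt": (5394, 15.7104, 15.2339),
    "colonoscopy_10y": (4752, 15.7385, 15.3586),
    "biennial_ifobt": (4542, 15.7429, 15.4203),
    "annual_ifobt": (5068, 15.7650, 15.5491),
}


@pytest.fixture(scope="session")
def printed_outcomes():
    from crc_cea.engine import StrategyOutcome

    return [StrategyOutcome(name, c, ly, q) for name, (c, ly, q) in PRINTED_TABLE1.items()]
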