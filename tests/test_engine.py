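"""Cohort engine: transition structure, accrual conventions, oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from acscea import (
    accumulate_outcomes,
    default_parameters,
    discount_factor,
    microsimulate,
    run_cohort,
    transition_matrix,
)
from acscea.engine import DEAD, REMISSION1, RELAPSE1, STATES
from acscea.parameters import ParameterError, RiskSet, UtilitySet


def _arm(risks_2y=None, risks_5y=None, costs=None, utilities=None):
    base = default_parameters().usual_care
    return dataclasses.replace(
        base,
        **{
            k: v
            for k, v in dict(
                risks_2y=risks_2y, risks_5y=risks_5y, costs=costs, utilities=utilities
            ).items()
            if v is not None
        },
    )


ZERO_RISKS = RiskSet(0, 0, 0, 0, 0, 0, 0)


def risk_sets():
    p = st.floats(0.0, 0.45)
    return st.builds(RiskSet, p, p, p, p, p, p, p)


# -- transition matrix -------------------------------------------------------


def test_relapse1_row_matches_death_risk(base_params):
    P = transition_matrix(base_params.usual_care, base_params.settings, month=3)
    row = P[RELAPSE1]
    assert row[DEAD] == pytest.approx(0.0248)
    assert row[STATES.index("remission2")] == pytest.approx(0.9752)
    assert np.count_nonzero(row) == 2  # no self-loop in relapse


def test_risk_switch_at_month_24(base_params):
    for arm in (base_params.usual_care, base_params.pcc):
        P = transition_matrix(arm, base_params.settings, month=30)
        assert P[REMISSION1, RELAPSE1] == pytest.approx(0.0062)
    P23 = transition_matrix(base_params.pcc, base_params.settings, month=23)
    assert P23[REMISSION1, RELAPSE1] == pytest.approx(0.0093)


@given(r2=risk_sets(), r5=risk_sets(), month=st.integers(0, 70))
@hsettings(max_examples=50, deadline=None)
def test_rows_are_stochastic_for_any_valid_risks(r2, r5, month):
    arm = _arm(risks_2y=r2, risks_5y=r5)
    P = transition_matrix(arm, default_parameters().settings, month)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert (P >= 0).all()


def test_overfull_remission_row_raises():
    bad = dataclasses.replace(ZERO_RISKS, relapse1=0.7, death_after_remission1=0.5)
    with pytest.raises(ParameterError):
        transition_matrix(_arm(risks_2y=bad), default_parameters().settings, 0)


# -- cohort propagation ------------------------------------------------------


def test_zero_risks_cohort_stays_in_remission1(base_params):
    arm = _arm(risks_2y=ZERO_RISKS, risks_5y=ZERO_RISKS)
    s = dataclasses.replace(base_params.settings, horizon_months=24)
    trace = run_cohort(arm, s)
    assert np.allclose(trace.occupancy[:, REMISSION1], 1.0)
    assert trace.new_deaths.sum() == 0


def test_zero_risk_undiscounted_qalys_closed_form(base_params):
    # 24 months at remission weight 0.82: 24 * 0.82 / 12 = 1.64 QALYs
    arm = _arm(risks_2y=ZERO_RISKS, risks_5y=ZERO_RISKS)
    s = dataclasses.replace(
        base_params.settings,
        horizon_months=24,
        discount_rate_effects=0.0,
        discount_rate_costs=0.0,
    )
    q, ly, costs = accumulate_outcomes(run_cohort(arm, s), arm, s)
    assert q == pytest.approx(1.64, abs=1e-12)
    assert ly == pytest.approx(2.0, abs=1e-12)
    assert costs.mortality_productivity == 0.0


def test_conservation_and_dead_monotone(base_params):
    for arm in (base_params.usual_care, base_params.pcc):
        trace = run_cohort(arm, base_params.settings)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert (np.diff(trace.occupancy[:, DEAD]) >= -1e-15).all()
        assert (trace.occupancy >= -1e-15).all()


@pytest.mark.parametrize(
    "month,rate,expected",
    [(0, 0.03, 1.0), (12, 0.03, 1 / 1.03), (24, 0.03, 1 / 1.03**2), (7, 0.0, 1.0)],
)
def test_discount_factor(month, rate, expected):
    assert discount_factor(month, rate) == pytest.approx(expected, rel=1e-12)


def test_full_death_at_month_zero_productivity_loss(base_params):
    # whole cohort dies during cycle 0: loses 60 months of wage undiscounted
    risks = dataclasses.replace(ZERO_RISKS, death_after_remission1=1.0)
    arm = _arm(risks_2y=risks, risks_5y=risks)
    s = dataclasses.replace(
        base_params.settings,
        horizon_months=60,
        discount_rate_costs=0.0,
        discount_rate_effects=0.0,
    )
    _, _, costs = accumulate_outcomes(run_cohort(arm, s), arm, s)
    assert costs.mortality_productivity == pytest.approx(60 * 46_400, rel=1e-12)


def test_zero_discount_equals_trace_sums(base_params):
    arm = base_params.usual_care
    s = dataclasses.replace(
        base_params.settings, discount_rate_costs=0.0, discount_rate_effects=0.0
    )
    trace = run_cohort(arm, s)
    q, ly, costs = accumulate_outcomes(trace, arm, s)
    assert q == pytest.approx(trace.qaly.sum(), rel=1e-12)
    assert ly == pytest.approx(trace.life_years.sum(), rel=1e-12)
    assert costs.direct == pytest.approx(trace.direct_cost.sum(), rel=1e-12)
    assert costs.sick_leave == pytest.approx(trace.sick_leave_cost.sum(), rel=1e-12)
    assert costs.mortality_productivity == pytest.approx(
        trace.mortality_productivity_loss.sum(), rel=1e-9
    )


def test_mismatched_horizon_raises(base_params):
    arm = base_params.usual_care
    trace = run_cohort(arm, base_params.settings)
    other = dataclasses.replace(base_params.settings, horizon_months=24)
    with pytest.raises(ValueError, match="horizon"):
        accumulate_outcomes(trace, arm, other)


def test_cost_breakdown_total_consistency(base_params):
    arm = base_params.pcc
    _, _, costs = accumulate_outcomes(
        run_cohort(arm, base_params.settings), arm, base_params.settings
    )
    assert costs.total == pytest.approx(
        costs.direct + costs.sick_leave + costs.mortality_productivity, rel=1e-9
    )


# -- monotonicity and discount ordering -------------------------------------


def _qalys(arm, s):
    return accumulate_outcomes(run_cohort(arm, s), arm, s)[0]


def test_higher_death_risk_weakly_decreases_qalys(base_params):
    s = base_params.settings
    base_q = _qalys(base_params.usual_care, s)
    worse = _arm(
        risks_2y=dataclasses.replace(
            base_params.usual_care.risks_2y, death_after_remission1=0.05
        )
    )
    assert _qalys(worse, s) < base_q


def test_higher_remission_utility_weakly_increases_qalys(base_params):
    s = base_params.settings
    base_q = _qalys(base_params.usual_care, s)
    better = _arm(utilities=UtilitySet(relapse=0.67, remission=0.9))
    assert _qalys(better, s) > base_q


def test_discounting_ordering(base_params):
    arm = base_params.usual_care
    outcomes = {}
    for r in (0.0, 0.03, 0.05):
        s = dataclasses.replace(
            base_params.settings, discount_rate_effects=r, discount_rate_costs=r
        )
        q, ly, costs = accumulate_outcomes(run_cohort(arm, s), arm, s)
        outcomes[r] = (q, ly, costs.total)
    for i in range(3):
        assert outcomes[0.0][i] >= outcomes[0.03][i] >= outcomes[0.05][i]


# -- accrual conventions -----------------------------------------------------


def test_initial_event_month_costed_as_relapse(base_params):
    arm = base_params.usual_care
    s = dataclasses.replace(
        base_params.settings, include_initial_event_month=True, horizon_months=12
    )
    trace = run_cohort(arm, s)
    assert trace.occupancy[0, STATES.index("initial_event")] == 1.0
    # first cycle accrues the relapse cost and relapse utility weight
    assert trace.direct_cost[0] == pytest.approx(arm.costs.relapse1_cost)
    assert trace.qaly[0] == pytest.approx(arm.utilities.relapse / 12)


def test_half_cycle_correction_between_start_and_end(base_params):
    arm = base_params.usual_care
    variants = {}
    for flags in [
        {"half_cycle_correction": True},
        {"accrue_at_cycle_end": True},
        {},
    ]:
        s = dataclasses.replace(base_params.settings, **flags)
        variants[tuple(flags)] = _qalys(arm, s)
    start = variants[()]
    end = variants[("accrue_at_cycle_end",)]
    half = variants[("half_cycle_correction",)]
    assert min(start, end) <= half <= max(start, end)
    assert end < start  # occupancy of alive states declines over time


def test_annualized_cost_accrual_divides_direct_costs_by_12(base_params):
    arm = base_params.usual_care
    s0 = base_params.settings
    s12 = dataclasses.replace(s0, annualized_cost_accrual=True)
    _, _, c0 = accumulate_outcomes(run_cohort(arm, s0), arm, s0)
    _, _, c12 = accumulate_outcomes(run_cohort(arm, s12), arm, s12)
    assert c12.direct == pytest.approx(c0.direct / 12, rel=1e-12)
    assert c12.mortality_productivity == pytest.approx(
        c0.mortality_productivity / 12, rel=1e-12
    )


def test_exclude_sick_leave_flag(base_params):
    arm = base_params.usual_care
    s = dataclasses.replace(base_params.settings, include_sick_leave=False)
    _, _, costs = accumulate_outcomes(run_cohort(arm, s), arm, s)
    assert costs.sick_leave == 0.0


# -- microsimulation oracle --------------------------------------------------


def test_cohort_matches_microsimulation(base_params):
    """The deterministic trace is the large-n limit of individual paths."""
    arm = base_params.usual_care
    s = base_params.settings
    n = 200_000
    occ_mc = microsimulate(arm, s, n, seed=20200907)
    occ = run_cohort(arm, s).occupancy
    se = np.sqrt(np.maximum(occ * (1 - occ), 1e-12) / n)
    assert np.abs(occ_mc - occ).max() < np.maximum(3.5 * se, 1e-4).max()
    assert (np.abs(occ_mc - occ) <= np.maximum(4 * se, 5e-4)).all()
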