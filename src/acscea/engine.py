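"""Time-inhomogeneous Markov cohort engine.

Seven ordered states encode the relapse-count memory so the process is
Markov: InitialEvent, Remission1, Relapse1, Remission2, Relapse2,
Remission3, Dead.  A relapse occupies exactly one monthly cycle, from which
the cohort transits to the next remission or to Dead.  Once in the third
remission, patients remain there or die.  For cycles before
``settings.switch_month`` the (treatment-specific) 2-year risks apply;
thereafter the treatment-independent 2-5 year risks.

``run_cohort`` propagates state occupancy for ``horizon_months`` cycles and
records per-cycle undiscounted accruals; ``accumulate_outcomes`` applies
discounting and returns per-patient QALYs, life-years and a cost breakdown
(direct healthcare, sick-leave absenteeism, mortality-related productivity
losses valued by the human-capital method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ArmParameters, GlobalSettings, RiskSet

__all__ = [
    "STATES",
    "N_STATES",
    "CohortTrace",
    "CostBreakdown",
    "transition_matrix",
    "run_cohort",
    "discount_factor",
    "accumulate_outcomes",
]

STATES = (
    "initial_event",
    "remission1",
    "relapse1",
    "remission2",
    "relapse2",
    "remission3",
    "dead",
)
N_STATES = len(STATES)
INITIAL_EVENT, REMISSION1, RELAPSE1, REMISSION2, RELAPSE2, REMISSION3, DEAD = range(
    N_STATES
)
#: states in which patients are in a relapse-type month
RELAPSE_STATES = (INITIAL_EVENT, RELAPSE1, RELAPSE2)
REMISSION_STATES = (REMISSION1, REMISSION2, REMISSION3)
ALIVE_STATES = RELAPSE_STATES + REMISSION_STATES


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-patient costs in SEK, split by component."""

    direct: float
    sick_leave: float
    mortality_productivity: float

    @property
    def total(self) -> float:
        return self.direct + self.sick_leave + self.mortality_productivity

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.direct + other.direct,
            self.sick_leave + other.sick_leave,
            self.mortality_productivity + other.mortality_productivity,
        )

    def __sub__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.direct - other.direct,
            self.sick_leave - other.sick_leave,
            self.mortality_productivity - other.mortality_productivity,
        )

    def __mul__(self, k: float) -> "CostBreakdown":
        return CostBreakdown(
            self.direct * k, self.sick_leave * k, self.mortality_productivity * k
        )

    __rmul__ = __mul__


@dataclass(frozen=True)
class CohortTrace:
    """Month-by-month state occupancy with per-cycle undiscounted accruals.

    ``occupancy`` has shape (horizon + 1, 7); row ``m`` is the distribution
    at the start of cycle ``m``.  Accrual arrays have length ``horizon``;
    entry ``m`` is the amount accrued during cycle ``m`` (on start- or
    end-of-cycle occupancy according to the settings used).  ``new_deaths``
    is the occupancy fraction dying during cycle ``m``.
    """

    occupancy: np.ndarray
    qaly: np.ndarray
    life_years: np.ndarray
    direct_cost: np.ndarray
    sick_leave_cost: np.ndarray
    mortality_productivity_loss: np.ndarray
    new_deaths: np.ndarray
    horizon_months: int

    def to_frame(self):
        """Trace as a pandas DataFrame (one row per cycle)."""
        import pandas as pd

        h = self.horizon_months
        df = pd.DataFrame(self.occupancy[:h], columns=STATES)
        df.insert(0, "month", np.arange(h))
        for name in (
            "qaly",
            "life_years",
            "direct_cost",
            "sick_leave_cost",
            "mortality_productivity_loss",
            "new_deaths",
        ):
            df[name] = getattr(self, name)
        return df


def transition_matrix(
    params: ArmParameters, settings: GlobalSettings, month: int
) -> np.ndarray:
    """Row-stochastic 7x7 one-cycle transition matrix at cycle ``month``."""
    if month < 0:
        raise ValueError("month must be >= 0")
    r: RiskSet = params.risks_2y if month < settings.switch_month else params.risks_5y
    r.validate()
    P = np.zeros((N_STATES, N_STATES))
    # the initial event behaves as a relapse-type month feeding Remission1
    P[INITIAL_EVENT, DEAD] = r.death_after_relapse1
    P[INITIAL_EVENT, REMISSION1] = 1.0 - r.death_after_relapse1
    P[REMISSION1, RELAPSE1] = r.relapse1
    P[REMISSION1, DEAD] = r.death_after_remission1
    P[REMISSION1, REMISSION1] = 1.0 - r.relapse1 - r.death_after_remission1
    P[RELAPSE1, DEAD] = r.death_after_relapse1
    P[RELAPSE1, REMISSION2] = 1.0 - r.death_after_relapse1
    P[REMISSION2, RELAPSE2] = r.relapse2
    P[REMISSION2, DEAD] = r.death_after_remission2
    P[REMISSION2, REMISSION2] = 1.0 - r.relapse2 - r.death_after_remission2
    P[RELAPSE2, DEAD] = r.death_after_relapse2
    P[RELAPSE2, REMISSION3] = 1.0 - r.death_after_relapse2
    P[REMISSION3, DEAD] = r.death_after_remission3
    P[REMISSION3, REMISSION3] = 1.0 - r.death_after_remission3
    P[DEAD, DEAD] = 1.0
    return P


def discount_factor(month: int | np.ndarray, annual_rate: float) -> float | np.ndarray:
    """Continuous-per-cycle discount factor (1 + r)^(-month/12)."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    return (1.0 + annual_rate) ** (-np.asarray(month, dtype=float) / 12.0)


def _state_reward_vectors(params: ArmParameters, settings: GlobalSettings):
    """Per-state monthly utility weight and direct-cost vectors."""
    u = np.zeros(N_STATES)
    u[list(RELAPSE_STATES)] = params.utilities.relapse
    u[list(REMISSION_STATES)] = params.utilities.remission
    c = np.zeros(N_STATES)
    c[INITIAL_EVENT] = params.costs.relapse1_cost
    c[RELAPSE1] = params.costs.relapse1_cost
    c[RELAPSE2] = params.costs.relapse2_cost
    c[REMISSION1] = params.costs.remission1_cost
    c[REMISSION2] = params.costs.remission2_cost
    c[REMISSION3] = params.costs.remission3_cost
    return u, c


def run_cohort(params: ArmParameters, settings: GlobalSettings) -> CohortTrace:
    """Propagate a unit cohort and record per-cycle accruals.

    The cohort starts fully in Remission1 (or in InitialEvent when
    ``settings.include_initial_event_month`` is set).  Conservation of
    occupancy holds to 1e-12 at every cycle.
    """
    params.validate()
    settings.validate()
    H = settings.horizon_months
    u, c = _state_reward_vectors(params, settings)
    cost_div = 12.0 if settings.annualized_cost_accrual else 1.0

    occ = np.zeros((H + 1, N_STATES))
    start = INITIAL_EVENT if settings.include_initial_event_month else REMISSION1
    occ[0, start] = 1.0
    for m in range(H):
        P = transition_matrix(params, settings, m)
        occ[m + 1] = occ[m] @ P

    if settings.half_cycle_correction:
        basis = 0.5 * (occ[:H] + occ[1 : H + 1])
    elif settings.accrue_at_cycle_end:
        basis = occ[1 : H + 1]
    else:
        basis = occ[:H]

    alive = basis[:, list(ALIVE_STATES)].sum(axis=1)
    qaly = basis @ u / 12.0
    life_years = alive / 12.0
    direct = (basis @ c) / cost_div
    direct += alive * params.delivery_cost_per_month / cost_div
    sick = alive * params.costs.sick_leave_monthly / cost_div
    new_deaths = np.diff(occ[:, DEAD])

    # undiscounted productivity loss booked in the cycle of death: the gross
    # wage for every cycle from death to the horizon (human-capital method)
    months_lost = _productivity_months(H, settings)
    mort = new_deaths * settings.gross_monthly_income * months_lost / cost_div

    return CohortTrace(
        occupancy=occ,
        qaly=qaly,
        life_years=life_years,
        direct_cost=direct,
        sick_leave_cost=sick,
        mortality_productivity_loss=mort,
        new_deaths=new_deaths,
        horizon_months=H,
    )


def _productivity_months(H: int, settings: GlobalSettings) -> np.ndarray:
    """Number of wage months lost for a death during each cycle 0..H-1."""
    m = np.arange(H)
    if settings.accrue_at_cycle_end:
        # loss window [m + 1, H)
        return np.maximum(H - 1 - m, 0).astype(float)
    # loss window [m, H)
    return (H - m).astype(float)


def accumulate_outcomes(
    trace: CohortTrace, params: ArmParameters, settings: GlobalSettings
) -> tuple[float, float, CostBreakdown]:
    """Discount a trace into per-patient (QALYs, life-years, costs).

    Effects are discounted at ``discount_rate_effects`` and costs at
    ``discount_rate_costs``.  A death during cycle ``m`` incurs a
    productivity loss equal to the gross monthly wage for every remaining
    cycle of the horizon, each discounted at the cost rate.
    """
    if trace.horizon_months != settings.horizon_months:
        raise ValueError(
            f"trace horizon {trace.horizon_months} != settings horizon "
            f"{settings.horizon_months}"
        )
    H = settings.horizon_months
    t = np.arange(H, dtype=float)
    if settings.half_cycle_correction:
        t = t + 0.5
    elif settings.accrue_at_cycle_end:
        t = t + 1.0
    dfe = discount_factor(t, settings.discount_rate_effects)
    dfc = discount_factor(t, settings.discount_rate_costs)

    qalys = float(trace.qaly @ dfe)
    life_years = float(trace.life_years @ dfe)
    direct = float(trace.direct_cost @ dfc) + params.delivery_cost_fixed
    sick = float(trace.sick_leave_cost @ dfc) if settings.include_sick_leave else 0.0

    # discounted wage stream lost from the cycle of death to the horizon
    cost_div = 12.0 if settings.annualized_cost_accrual else 1.0
    wage = settings.gross_monthly_income / cost_div
    df_cycle = discount_factor(np.arange(H, dtype=float), settings.discount_rate_costs)
    # suffix[k] = sum of discount factors for months k .. H-1 (suffix[H] = 0)
    suffix = np.concatenate([np.cumsum(df_cycle[::-1])[::-1], [0.0]])
    if settings.accrue_at_cycle_end:
        # death during cycle m: wage lost over months m+1 .. H-1
        loss_per_death = suffix[1 : H + 1]
    else:
        # death during cycle m: wage lost over months m .. H-1
        loss_per_death = suffix[:H]
    mort = float(trace.new_deaths @ (wage * loss_per_death))

    return qalys, life_years, CostBreakdown(direct, sick, mort)
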