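"""Parameter estimation from register-like patient-level records.

These estimators mirror how the base-case parameter table is assembled from
trial-linked register data: 2-year relapse risks from event counts per arm,
relapse costs as mean inpatient cost per ACS event, remission costs as
non-inpatient cost per remission patient-month, and sick-leave indirect
costs by the human-capital method (each reimbursed spell is extended by the
14 uncompensated days, valued at the gross daily wage).  Death risks,
2-5 year risks and utility weights are literature-sourced constants and
pass through from the supplied defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .parameters import GlobalSettings, ModelParameters, default_parameters

__all__ = [
    "PatientRecord",
    "DEFAULT_RELAPSE_ICD_PREFIXES",
    "total_risk",
    "monthly_risk",
    "relapse_cost",
    "remission_cost",
    "sick_leave_monthly_cost",
    "fit_parameters",
]

#: ICD-10 chapter prefixes counted as an ACS-related relapse event
DEFAULT_RELAPSE_ICD_PREFIXES = ("I20", "I21", "I22", "I25", "I50")


@dataclass(frozen=True)
class PatientRecord:
    """One register-linked patient.

    ``relapse_months`` are the months (0-based, within follow-up) of
    inpatient ACS events; ``inpatient_event_costs`` aligns with them.
    ``non_inpatient_monthly_costs`` are the outpatient + primary care +
    pharmaceutical costs of each alive month.  ``sick_leave_spells`` hold
    reimbursed-day counts (reimbursement starts after 14 days, so every
    registered spell exceeded 14 days).  ``event_diagnoses`` optionally
    carries one ICD code per event for code-list filtering.
    """

    patient_id: str
    arm: str  # "usual_care" | "pcc"
    follow_up_months: int
    relapse_months: tuple[int, ...] = ()
    inpatient_event_costs: tuple[float, ...] = ()
    non_inpatient_monthly_costs: tuple[float, ...] = ()
    sick_leave_spells: tuple[int, ...] = ()
    death_month: Optional[int] = None
    permanent_sick_leave_start: Optional[int] = None
    pre_existing_permanent_sick_leave: bool = False
    event_diagnoses: tuple[str, ...] = ()

    def __post_init__(self):
        if self.arm not in ("usual_care", "pcc"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if any(m >= self.follow_up_months or m < 0 for m in self.relapse_months):
            raise ValueError("relapse months must fall inside the follow-up window")
        if any(c < 0 for c in self.inpatient_event_costs) or any(
            c < 0 for c in self.non_inpatient_monthly_costs
        ):
            raise ValueError("costs must be >= 0")
        if self.death_month is not None and not (
            0 <= self.death_month <= self.follow_up_months
        ):
            raise ValueError("death_month outside follow-up window")

    @property
    def alive_months(self) -> int:
        """Follow-up truncated at death."""
        if self.death_month is not None:
            return self.death_month
        return self.follow_up_months

    def qualifying_events(
        self, icd_prefixes: Sequence[str] = DEFAULT_RELAPSE_ICD_PREFIXES
    ) -> int:
        """Number of relapse events, filtered by ICD prefix when coded."""
        if not self.event_diagnoses:
            return len(self.relapse_months)
        return sum(
            1
            for code in self.event_diagnoses
            if any(code.startswith(p) for p in icd_prefixes)
        )


def _require(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    recs = list(records)
    if not recs:
        raise ValueError("empty patient group")
    return recs


def total_risk(
    records: Iterable[PatientRecord],
    event_type: str,
    icd_prefixes: Sequence[str] = DEFAULT_RELAPSE_ICD_PREFIXES,
) -> float:
    """Total relapse risk over the follow-up: events / number of patients.

    ``relapse1`` counts patients with at least one qualifying event;
    ``relapse2`` counts patients with a second event (conditional on a
    first having occurred).
    """
    recs = _require(records)
    need = {"relapse1": 1, "relapse2": 2}.get(event_type)
    if need is None:
        raise ValueError(f"unknown event_type {event_type!r}")
    count = sum(1 for r in recs if r.qualifying_events(icd_prefixes) >= need)
    return count / len(recs)


def monthly_risk(total: float, months: int, method: str = "constant_hazard") -> float:
    """Convert a cumulative risk over ``months`` to a per-month probability.

    ``constant_hazard``: 1 - (1 - total)^(1/months); ``linear``:
    total / months.
    """
    if months < 1:
        raise ValueError("months must be >= 1")
    if not 0.0 <= total <= 1.0:
        raise ValueError("total risk must be in [0, 1]")
    if method == "constant_hazard":
        if total == 1.0:
            raise ValueError("total risk of 1 implies an infinite hazard")
        return 1.0 - (1.0 - total) ** (1.0 / months)
    if method == "linear":
        return total / months
    raise ValueError(f"unknown method {method!r}")


def _relapse_hazard(
    records: Iterable[PatientRecord],
    event_type: str,
    icd_prefixes: Sequence[str] = DEFAULT_RELAPSE_ICD_PREFIXES,
) -> tuple[int, int]:
    """(events, person-months at risk) for a first or second relapse.

    Person-time is reconstructed from the event and death months: a patient
    is at risk of a first relapse from entry until the first event, death
    or end of follow-up, and at risk of a second relapse from the month
    after the first event.  The ratio is the maximum-likelihood monthly
    transition probability, unbiased under censoring by death (unlike the
    cumulative-risk inversion of :func:`monthly_risk`).
    """
    recs = _require(records)
    need = {"relapse1": 1, "relapse2": 2}[event_type]
    events = 0
    at_risk = 0
    for r in recs:
        months = sorted(
            m
            for m, ok in _qualifying_months(r, icd_prefixes)
            if ok
        )
        # last month at which a transition out of an alive state is observed
        last_transition = (
            r.death_month - 1 if r.death_month is not None else r.follow_up_months - 2
        )
        if need == 1:
            start = 0
            event_month = months[0] if months else None
        else:
            if not months:
                continue
            start = months[0] + 1
            event_month = months[1] if len(months) > 1 else None
        if event_month is not None:
            events += 1
            at_risk += max(event_month - start, 0)
        else:
            at_risk += max(last_transition - start + 1, 0)
    return events, at_risk


def _qualifying_months(
    r: PatientRecord, icd_prefixes: Sequence[str]
) -> list[tuple[int, bool]]:
    if not r.event_diagnoses:
        return [(m, True) for m in r.relapse_months]
    return [
        (m, any(code.startswith(p) for p in icd_prefixes))
        for m, code in zip(r.relapse_months, r.event_diagnoses)
    ]


def relapse_cost(records: Iterable[PatientRecord]) -> float:
    """Mean inpatient cost per ACS event: sum of event costs / events."""
    recs = _require(records)
    costs = [c for r in recs for c in r.inpatient_event_costs]
    if not costs:
        raise ValueError("no relapse events in group; relapse cost undefined")
    return sum(costs) / len(costs)


def remission_cost(records: Iterable[PatientRecord]) -> float:
    """Non-inpatient cost per remission patient-month.

    Patient-months count alive time only; each relapse is assumed to last
    one month and is excluded from the denominator.
    """
    recs = _require(records)
    total = sum(sum(r.non_inpatient_monthly_costs) for r in recs)
    months = sum(max(r.alive_months - len(r.relapse_months), 0) for r in recs)
    if months == 0:
        raise ValueError("no remission patient-months in group")
    return total / months


def sick_leave_monthly_cost(
    records: Iterable[PatientRecord], settings: GlobalSettings
) -> float:
    """Indirect absenteeism cost per alive patient-month (human capital).

    Each reimbursed spell contributes (reimbursed days + 14) times the
    daily production value (gross monthly income / working days per month).
    Months on permanent sick leave after the initial event are valued at
    the full monthly income; patients already on permanent sick leave
    before their event contribute nothing.
    """
    recs = _require(records)
    day_value = settings.gross_monthly_income / settings.working_days_per_month
    total = 0.0
    months = 0
    for r in recs:
        months += r.alive_months
        if r.pre_existing_permanent_sick_leave:
            continue
        total += sum((d + 14) * day_value for d in r.sick_leave_spells)
        if r.permanent_sick_leave_start is not None:
            perm_months = max(r.alive_months - r.permanent_sick_leave_start, 0)
            total += perm_months * settings.gross_monthly_income
    if months == 0:
        return 0.0
    return total / months


def fit_parameters(
    records: Iterable[PatientRecord],
    settings: GlobalSettings | None = None,
    defaults: ModelParameters | None = None,
    risk_period_months: int = 24,
    method: str = "at_risk",
    icd_prefixes: Sequence[str] = DEFAULT_RELAPSE_ICD_PREFIXES,
) -> ModelParameters:
    """Estimate the arm-specific parameters from patient records.

    Returns a :class:`ModelParameters` in which the 2-year relapse risks,
    state costs and sick-leave costs are replaced by their estimates per
    arm, while death risks, 2-5 year risks and utilities are carried over
    from ``defaults`` (literature-sourced).  Zero-event cost estimators
    fall back to 0 rather than failing the whole fit.

    ``method`` selects the relapse-risk estimator: ``at_risk`` (default)
    divides events by person-months at risk, which is unbiased when deaths
    censor follow-up; ``constant_hazard`` and ``linear`` convert the
    cumulative events-per-patient risk over ``risk_period_months`` via
    :func:`monthly_risk`.
    """
    recs = list(records)
    base = defaults if defaults is not None else default_parameters()
    if settings is None:
        settings = base.settings
    by_arm = {
        arm: [r for r in recs if r.arm == arm] for arm in ("usual_care", "pcc")
    }
    if not by_arm["usual_care"] or not by_arm["pcc"]:
        raise ValueError("records must cover both treatment arms")

    fitted = base
    from .parameters import set_param  # local to avoid cycle at import time

    for arm, group in by_arm.items():
        for event_type in ("relapse1", "relapse2"):
            if method == "at_risk":
                events, at_risk = _relapse_hazard(group, event_type, icd_prefixes)
                m = events / at_risk if at_risk else 0.0
            else:
                tot = total_risk(group, event_type, icd_prefixes)
                m = monthly_risk(tot, risk_period_months, method)
            fitted = set_param(fitted, f"{arm}.risks_2y.{event_type}", m)
        try:
            rel_cost = relapse_cost(group)
        except ValueError:
            rel_cost = 0.0
        try:
            rem_cost = remission_cost(group)
        except ValueError:
            rem_cost = 0.0
        sick = sick_leave_monthly_cost(group, settings)
        for f_name, v in (
            ("relapse1_cost", rel_cost),
            ("relapse2_cost", rel_cost),
            ("remission1_cost", rem_cost),
            ("remission2_cost", rem_cost),
            ("remission3_cost", rem_cost),
            ("sick_leave_monthly", sick),
        ):
            fitted = set_param(fitted, f"{arm}.costs.{f_name}", v)
    return replace(fitted, settings=settings).validate()
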