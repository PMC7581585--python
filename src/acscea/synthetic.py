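"""Synthetic register-like patient data.

The generator simulates each patient's monthly path through the seven-state
disease process under a ground-truth parameter set and dresses the path
with register-style observations: inpatient costs per ACS event
(log-normal around the arm's relapse cost), non-inpatient monthly costs
(log-normal around the remission cost), and reimbursed sick-leave spells
(per-month Bernoulli onset with geometric reimbursed-day counts).  It
emulates the structure of trial-linked register data — per-arm event
processes, costs by visit type, spells reimbursed beyond 14 days, deaths —
so the estimators can be validated end to end without any real data.

``microsimulate`` exposes the same transition rules as a stochastic
individual-level oracle for the deterministic cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import (
    ALIVE_STATES,
    DEAD,
    N_STATES,
    REMISSION1,
    RELAPSE1,
    RELAPSE2,
    transition_matrix,
)
from .estimation import PatientRecord
from .parameters import (
    ArmParameters,
    GlobalSettings,
    ModelParameters,
    default_parameters,
)

__all__ = ["GeneratorConfig", "generate_cohort", "make_trial_fixture", "microsimulate"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic register-data generator.

    ``sick_leave_spell_rate`` (spells per patient-year) defaults to None,
    meaning the monthly spell probability is calibrated per arm so that the
    expected absenteeism cost per patient-month equals the arm's
    ground-truth ``sick_leave_monthly`` value.
    """

    n_per_arm: int = 59
    ground_truth: ModelParameters = field(default_factory=default_parameters)
    event_cost_dispersion: float = 0.5  # CV of inpatient event costs
    monthly_cost_dispersion: float = 0.5  # CV of non-inpatient monthly costs
    sick_leave_spell_rate: Optional[float] = None
    mean_reimbursed_days: float = 10.0
    follow_up_months: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.event_cost_dispersion < 0 or self.monthly_cost_dispersion < 0:
            raise ValueError("cost dispersions must be >= 0")
        if self.mean_reimbursed_days < 1:
            raise ValueError("mean_reimbursed_days must be >= 1")
        if self.follow_up_months < 1:
            raise ValueError("follow_up_months must be >= 1")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Log-normal draws with the given arithmetic mean and CV."""
    if mean <= 0 or cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _simulate_paths(
    arm: ArmParameters,
    settings: GlobalSettings,
    n: int,
    months: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """State indices of ``n`` patients at months 0 .. months-1 (all start
    in Remission1); vectorized across patients via inverse-CDF draws."""
    paths = np.empty((n, months), dtype=np.int8)
    paths[:, 0] = REMISSION1
    state = np.full(n, REMISSION1, dtype=np.int8)
    for m in range(1, months):
        P = transition_matrix(arm, settings, m - 1)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n)
        state = (u[:, None] > cum[state]).sum(axis=1).astype(np.int8)
        paths[:, m] = state
    return paths


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate ``2 * n_per_arm`` patients; deterministic for a seed."""
    rng = np.random.default_rng(config.seed)
    gt = config.ground_truth
    settings = gt.settings
    day_value = settings.gross_monthly_income / settings.working_days_per_month
    records: list[PatientRecord] = []
    for arm_name in ("usual_care", "pcc"):
        arm = getattr(gt, arm_name)
        if config.sick_leave_spell_rate is None:
            expected_spell_cost = (config.mean_reimbursed_days + 14) * day_value
            p_spell = arm.costs.sick_leave_monthly / expected_spell_cost
        else:
            p_spell = config.sick_leave_spell_rate / 12.0
        p_spell = min(p_spell, 1.0)
        paths = _simulate_paths(
            arm, settings, config.n_per_arm, config.follow_up_months, rng
        )
        for i in range(config.n_per_arm):
            path = paths[i]
            relapse_months = tuple(
                int(m) for m in np.flatnonzero(np.isin(path, (RELAPSE1, RELAPSE2)))
            )
            dead = np.flatnonzero(path == DEAD)
            death_month = int(dead[0]) if dead.size else None
            alive_months = np.flatnonzero(np.isin(path, ALIVE_STATES))
            n_alive = alive_months.size

            event_costs = tuple(
                float(c)
                for c in _lognormal(
                    rng,
                    arm.costs.relapse1_cost,
                    config.event_cost_dispersion,
                    len(relapse_months),
                )
            )
            n_remission = n_alive - len(relapse_months)
            monthly_costs = tuple(
                float(c)
                for c in _lognormal(
                    rng,
                    arm.costs.remission1_cost,
                    config.monthly_cost_dispersion,
                    n_remission,
                )
            )
            n_spells = int(rng.binomial(n_alive, p_spell)) if n_alive else 0
            spells = tuple(
                int(d)
                for d in rng.geometric(1.0 / config.mean_reimbursed_days, n_spells)
            )
            records.append(
                PatientRecord(
                    patient_id=f"{arm_name}-{i:05d}",
                    arm=arm_name,
                    follow_up_months=config.follow_up_months,
                    relapse_months=relapse_months,
                    inpatient_event_costs=event_costs,
                    non_inpatient_monthly_costs=monthly_costs,
                    sick_leave_spells=spells,
                    death_month=death_month,
                )
            )
    return records


def make_trial_fixture(seed: int = 117) -> list[PatientRecord]:
    """Small fixed cohort shaped like the source trial (117 patients,
    59 usual care / 58 person-centred care, 2-year follow-up)."""
    cfg_uc = GeneratorConfig(n_per_arm=59, seed=seed)
    cfg_pc = GeneratorConfig(n_per_arm=58, seed=seed + 1)
    usual = [r for r in generate_cohort(cfg_uc) if r.arm == "usual_care"]
    pcc = [r for r in generate_cohort(cfg_pc) if r.arm == "pcc"]
    return usual + pcc


def microsimulate(
    arm: ArmParameters,
    settings: GlobalSettings,
    n_patients: int,
    seed: int = 0,
) -> np.ndarray:
    """Individual-level stochastic oracle for the cohort engine.

    Simulates ``n_patients`` through the same monthly transition rules and
    returns occupancy fractions of shape (horizon + 1, 7).  Patients are
    propagated as per-state counts with multinomial transition draws, which
    is exactly equivalent to simulating each patient separately and
    aggregating.  The occupancy estimate converges to
    :func:`acscea.engine.run_cohort` at the Monte Carlo rate n^(-1/2).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    H = settings.horizon_months
    start = 0 if settings.include_initial_event_month else REMISSION1
    counts = np.zeros((H + 1, N_STATES), dtype=np.int64)
    counts[0, start] = n_patients
    for m in range(H):
        P = transition_matrix(arm, settings, m)
        for s in range(N_STATES):
            c = counts[m, s]
            if c:
                counts[m + 1] += rng.multinomial(c, P[s])
    return counts / n_patients
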