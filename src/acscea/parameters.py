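"""Model parameters for the ACS care cost-effectiveness model.

The parameter set covers two treatment arms (usual care and person-centred
care) of a monthly-cycle Markov cohort model of acute coronary syndrome
(ACS) in working-age patients (< 65).  Each arm carries monthly transition
risks for the first two years after the initial event and for the 2-5 year
period, state-related monthly healthcare costs, indirect sick-leave costs,
and quality-of-life weights, plus global settings (discount rates, gross
wage, willingness-to-pay threshold, horizon, cycle-accounting conventions).

``default_parameters()`` returns the published base-case parameterization;
``load_parameters()`` reads a YAML/JSON config in which any omitted field
inherits that default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Iterator, Mapping, Union

import yaml

__all__ = [
    "RiskSet",
    "CostSet",
    "UtilitySet",
    "ArmParameters",
    "GlobalSettings",
    "ModelParameters",
    "ParameterError",
    "default_parameters",
    "table1_defaults",
    "publication_conventions",
    "load_parameters",
    "save_parameters",
    "get_param",
    "set_param",
    "iter_scalar_addresses",
]


class ParameterError(ValueError):
    """Raised when a parameter value violates its domain invariant."""


@dataclass(frozen=True)
class RiskSet:
    """Monthly transition probabilities for one period (< 2 y or 2-5 y).

    All entries are per-cycle (monthly) probabilities in [0, 1].
    """

    relapse1: float
    relapse2: float
    death_after_relapse1: float
    death_after_relapse2: float
    death_after_remission1: float
    death_after_remission2: float
    death_after_remission3: float

    def validate(self, prefix: str = "") -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(
                    f"{prefix}{f.name} = {v!r} is not a probability in [0, 1]"
                )
        # competing risks out of a remission state must not exceed 1
        for rel, dth in (
            ("relapse1", "death_after_remission1"),
            ("relapse2", "death_after_remission2"),
        ):
            if getattr(self, rel) + getattr(self, dth) > 1.0:
                raise ParameterError(
                    f"{prefix}{rel} + {dth} exceeds 1; remission row not stochastic"
                )


@dataclass(frozen=True)
class CostSet:
    """State-related monthly costs in SEK.

    Relapse costs are per relapse month (one relapse occupies exactly one
    cycle, so this equals the mean inpatient cost per ACS event); remission
    costs are monthly non-inpatient healthcare costs; ``sick_leave_monthly``
    is the indirect absenteeism cost per alive patient-month.
    """

    relapse1_cost: float
    relapse2_cost: float
    remission1_cost: float
    remission2_cost: float
    remission3_cost: float
    sick_leave_monthly: float

    def validate(self, prefix: str = "") -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ParameterError(f"{prefix}{f.name} = {v!r} must be >= 0")


@dataclass(frozen=True)
class UtilitySet:
    """Quality-of-life weights (QALY per life-year) by health state."""

    relapse: float
    remission: float

    def validate(self, prefix: str = "") -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(
                    f"{prefix}{f.name} = {v!r} is not a utility weight in [0, 1]"
                )


@dataclass(frozen=True)
class ArmParameters:
    """Full parameter block for one treatment arm."""

    risks_2y: RiskSet
    risks_5y: RiskSet
    costs: CostSet
    utilities: UtilitySet
    #: one-off cost of delivering the intervention, SEK per patient
    delivery_cost_fixed: float = 0.0
    #: recurring delivery cost, SEK per alive patient-month
    delivery_cost_per_month: float = 0.0

    def validate(self, prefix: str = "") -> None:
        self.risks_2y.validate(prefix + "risks_2y.")
        self.risks_5y.validate(prefix + "risks_5y.")
        self.costs.validate(prefix + "costs.")
        self.utilities.validate(prefix + "utilities.")
        if self.delivery_cost_fixed < 0 or self.delivery_cost_per_month < 0:
            raise ParameterError(prefix + "delivery costs must be >= 0")


@dataclass(frozen=True)
class GlobalSettings:
    """Arm-independent settings: discounting, wage, horizon, conventions.

    The three convention flags at the bottom exist to replicate the cycle
    accounting of the original spreadsheet implementation of this analysis
    (see docs/methods.md): rewards on end-of-cycle occupancy, cost streams
    spread at 1/12 of their monthly value per cycle, and the sick-leave
    stream excluded from accumulated costs.  All default to the standard
    textbook conventions.
    """

    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    gross_monthly_income: float = 46_400.0
    working_days_per_month: int = 20
    wtp_threshold: float = 500_000.0
    horizon_months: int = 60
    #: cycle index from which the 2-5 year risks apply ([0, switch) uses 2 y)
    switch_month: int = 24
    #: reporting multiplier (results per this many patients)
    cohort_scale: float = 1000.0
    include_initial_event_month: bool = False
    half_cycle_correction: bool = False
    #: accrue rewards on end-of-cycle instead of start-of-cycle occupancy
    accrue_at_cycle_end: bool = False
    #: spread monthly cost amounts (and the wage) at 1/12 per cycle
    annualized_cost_accrual: bool = False
    #: include the monthly sick-leave stream in accumulated costs
    include_sick_leave: bool = True

    def validate(self, prefix: str = "settings.") -> None:
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ParameterError(prefix + "discount rates must be >= 0")
        if self.horizon_months < 1:
            raise ParameterError(prefix + "horizon_months must be >= 1")
        if self.switch_month < 0:
            raise ParameterError(prefix + "switch_month must be >= 0")
        if self.gross_monthly_income < 0:
            raise ParameterError(prefix + "gross_monthly_income must be >= 0")
        if self.working_days_per_month < 1:
            raise ParameterError(prefix + "working_days_per_month must be >= 1")
        if self.wtp_threshold < 0:
            raise ParameterError(prefix + "wtp_threshold must be >= 0")
        if self.cohort_scale <= 0:
            raise ParameterError(prefix + "cohort_scale must be > 0")
        if self.half_cycle_correction and self.accrue_at_cycle_end:
            raise ParameterError(
                prefix + "half_cycle_correction and accrue_at_cycle_end are exclusive"
            )


@dataclass(frozen=True)
class ModelParameters:
    """Complete model parameterization: both arms plus global settings."""

    usual_care: ArmParameters
    pcc: ArmParameters
    settings: GlobalSettings = field(default_factory=GlobalSettings)

    def validate(self) -> "ModelParameters":
        self.usual_care.validate("usual_care.")
        self.pcc.validate("pcc.")
        self.settings.validate()
        return self


# ---------------------------------------------------------------------------
# Base-case defaults
# ---------------------------------------------------------------------------

_SHARED_2Y = dict(
    death_after_relapse1=0.0248,
    death_after_relapse2=0.0248,
    death_after_remission1=0.0106,
    death_after_remission2=0.0115,
    death_after_remission3=0.0115,
)
# 2-5 y risks are treatment independent
_RISKS_5Y = RiskSet(
    relapse1=0.0062,
    relapse2=0.0062,
    death_after_relapse1=0.0037,
    death_after_relapse2=0.0037,
    death_after_remission1=0.0022,
    death_after_remission2=0.0022,
    death_after_remission3=0.0022,
)
_UTILITIES = UtilitySet(relapse=0.67, remission=0.82)


def default_parameters() -> ModelParameters:
    """Published base-case parameter set (immutable).

    Monthly probabilities are stored exactly as printed in the source
    analysis; any hazard/probability conversion lives in
    :mod:`acscea.estimation`.
    """
    usual_care = ArmParameters(
        risks_2y=RiskSet(relapse1=0.0115, relapse2=0.0035, **_SHARED_2Y),
        risks_5y=_RISKS_5Y,
        costs=CostSet(
            relapse1_cost=45_307.0,
            relapse2_cost=45_307.0,
            remission1_cost=2_176.0,
            remission2_cost=2_176.0,
            remission3_cost=2_176.0,
            sick_leave_monthly=9_349.0,
        ),
        utilities=_UTILITIES,
    )
    pcc = ArmParameters(
        risks_2y=RiskSet(relapse1=0.0093, relapse2=0.0056, **_SHARED_2Y),
        risks_5y=_RISKS_5Y,
        costs=CostSet(
            relapse1_cost=39_824.0,
            relapse2_cost=39_824.0,
            remission1_cost=2_223.0,
            remission2_cost=2_223.0,
            remission3_cost=2_223.0,
            sick_leave_monthly=8_250.0,
        ),
        utilities=_UTILITIES,
    )
    return ModelParameters(usual_care=usual_care, pcc=pcc).validate()


#: alias kept for the tabular origin of the defaults
table1_defaults = default_parameters


def publication_conventions(params: ModelParameters) -> ModelParameters:
    """Switch a parameter set to the cycle-accounting conventions that
    reproduce the originally published results.

    Leaves every numeric parameter untouched; flips only the convention
    flags (end-of-cycle accrual, annualized 1/12 cost accrual, sick-leave
    stream excluded).  See docs/methods.md for the replication analysis
    behind this mode.
    """
    return replace(
        params,
        settings=replace(
            params.settings,
            accrue_at_cycle_end=True,
            annualized_cost_accrual=True,
            include_sick_leave=False,
            half_cycle_correction=False,
        ),
    )


# ---------------------------------------------------------------------------
# Dotted-path addressing
# ---------------------------------------------------------------------------


def get_param(params: Any, address: str) -> Any:
    """Resolve a dotted address such as ``'pcc.risks_2y.relapse1'``."""
    obj = params
    for part in address.split("."):
        if not dataclasses.is_dataclass(obj) or part not in {
            f.name for f in fields(obj)
        }:
            raise ParameterError(f"cannot resolve parameter address {address!r}")
        obj = getattr(obj, part)
    return obj


def set_param(params: ModelParameters, address: str, value: Any) -> ModelParameters:
    """Return a copy of ``params`` with the addressed field replaced.

    The returned object is re-validated, so out-of-range values raise a
    :class:`ParameterError` naming the offending field.
    """

    def _set(obj: Any, parts: list[str]) -> Any:
        name = parts[0]
        if not dataclasses.is_dataclass(obj) or name not in {
            f.name for f in fields(obj)
        }:
            raise ParameterError(f"cannot resolve parameter address {address!r}")
        if len(parts) == 1:
            return replace(obj, **{name: value})
        return replace(obj, **{name: _set(getattr(obj, name), parts[1:])})

    new = _set(params, address.split("."))
    return new.validate()


def iter_scalar_addresses(params: ModelParameters) -> Iterator[str]:
    """Yield every dotted address of a scalar field in ``params``."""

    def walk(obj: Any, prefix: str) -> Iterator[str]:
        for f in fields(obj):
            v = getattr(obj, f.name)
            addr = f"{prefix}{f.name}"
            if dataclasses.is_dataclass(v):
                yield from walk(v, addr + ".")
            else:
                yield addr

    yield from walk(params, "")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    return obj


def _merge(base: Any, overrides: Mapping[str, Any], prefix: str = "") -> Any:
    """Recursively apply a (possibly partial) mapping onto a dataclass."""
    known = {f.name for f in fields(base)}
    for key in overrides:
        if key not in known:
            raise ParameterError(f"unknown parameter field {prefix + key!r}")
    kwargs = {}
    for name in known:
        if name not in overrides:
            continue
        v = overrides[name]
        current = getattr(base, name)
        if dataclasses.is_dataclass(current):
            if not isinstance(v, Mapping):
                raise ParameterError(
                    f"field {prefix + name!r} must be a mapping, got {type(v).__name__}"
                )
            kwargs[name] = _merge(current, v, prefix + name + ".")
        else:
            if isinstance(v, Mapping):
                raise ParameterError(f"field {prefix + name!r} is scalar")
            kwargs[name] = v
    return replace(base, **kwargs)


def load_parameters(
    source: Union[str, Path, Mapping[str, Any], None],
    base: ModelParameters | None = None,
) -> ModelParameters:
    """Load a parameter configuration, inheriting defaults for absent fields.

    ``source`` may be a YAML/JSON file path, an already-parsed mapping, or
    None/empty (returning the base defaults).  Dotted override paths are
    accepted at the top level, e.g. ``{"pcc.risks_2y.relapse1": 0.01}``.
    """
    if base is None:
        base = default_parameters()
    if source is None:
        return base
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ParameterError(f"could not parse parameter file {source}: {exc}")
        if data is None:
            data = {}
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ParameterError("parameter config must be a mapping")
    # split dotted top-level keys from nested mappings
    nested: dict[str, Any] = {}
    dotted: list[tuple[str, Any]] = []
    for key, v in data.items():
        if "." in key:
            dotted.append((key, v))
        else:
            nested[key] = v
    params = _merge(base, nested)
    for addr, v in dotted:
        params = set_param(params, addr, v)
    return params.validate()


def save_parameters(params: ModelParameters, path: Union[str, Path]) -> None:
    """Write a parameter set as YAML; re-loading reproduces it exactly."""
    Path(path).write_text(
        yaml.safe_dump(_to_dict(params), sort_keys=False, default_flow_style=False)
    )
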