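"""Deterministic sensitivity analysis.

Three tools: a discount-rate scenario grid, one-way parameter sweeps, and a
bisection search for the parameter value at which net monetary benefit
crosses zero at a given willingness-to-pay (the value at which the ICER
reaches the threshold).  Sweeps and searches address parameters by dotted
path (e.g. ``'pcc.risks_2y.relapse1'``); several addresses may be tied so
that they move together (e.g. both relapse-cost rows).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .cea import CEResult, compare_arms
from .parameters import ModelParameters, get_param, set_param

__all__ = [
    "ThresholdResult",
    "NoCrossingError",
    "discount_scenarios",
    "one_way_sweep",
    "threshold_search",
]

#: discount-rate scenarios: label -> (effects rate, costs rate)
DISCOUNT_SCENARIOS = {
    "base_3pct": (0.03, 0.03),
    "effects_and_costs_0pct": (0.0, 0.0),
    "effects_and_costs_5pct": (0.05, 0.05),
    "effects_0pct_costs_5pct": (0.0, 0.05),
    "effects_5pct_costs_0pct": (0.05, 0.0),
}


class NoCrossingError(ValueError):
    """NMB does not change sign over the supplied bracket."""


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a bisection threshold search on one (tied) parameter."""

    address: tuple[str, ...]
    base_value: float
    threshold_value: float
    wtp: float
    horizon_months: int
    perspective: str
    converged: bool
    iterations: int
    nmb_at_threshold: float


def discount_scenarios(params: ModelParameters) -> dict[str, CEResult]:
    """Base case plus the four 0%/5% effect/cost rate combinations."""
    out = {}
    for label, (re_, rc) in DISCOUNT_SCENARIOS.items():
        p = replace(
            params,
            settings=replace(
                params.settings,
                discount_rate_effects=re_,
                discount_rate_costs=rc,
            ),
        )
        out[label] = compare_arms(p)
    return out


def _set_all(
    params: ModelParameters, addresses: Sequence[str], value: float
) -> ModelParameters:
    for a in addresses:
        params = set_param(params, a, value)
    return params


def _normalize(address: str | Sequence[str]) -> tuple[str, ...]:
    return (address,) if isinstance(address, str) else tuple(address)


def one_way_sweep(
    params: ModelParameters,
    address: str | Sequence[str],
    values: Iterable[float],
) -> list[tuple[float, CEResult]]:
    """Evaluate ``compare_arms`` at each value of one (tied) parameter."""
    addrs = _normalize(address)
    return [(v, compare_arms(_set_all(params, addrs, v))) for v in values]


def threshold_search(
    params: ModelParameters,
    address: str | Sequence[str],
    wtp: float | None = None,
    bracket: tuple[float, float] | None = None,
    perspective: str = "societal",
    nmb_tol: float = 1e-6,
    max_iter: int = 200,
) -> ThresholdResult:
    """Bisect one (tied) parameter to the value at which NMB crosses zero.

    ``bracket`` defaults to (base value, 100x base value or +0.99 for a
    probability-like base below 1).  The search is deterministic and stops
    when the per-patient |NMB| falls below ``nmb_tol`` SEK or the bracket
    width falls below 1e-10 of its initial scale.

    Raises :class:`NoCrossingError` when NMB has the same sign at both
    bracket ends.
    """
    s = params.settings
    if wtp is None:
        wtp = s.wtp_threshold
    addrs = _normalize(address)
    base_value = float(get_param(params, addrs[0]))

    def f(v: float) -> float:
        res = compare_arms(_set_all(params, addrs, v))
        # per-patient NMB keeps the tolerance scale-free
        return res.nmb_at(wtp, perspective) / res.cohort_scale

    if bracket is None:
        hi = min(base_value + 0.99 * (1 - base_value), 0.999) if base_value < 1 else base_value * 100
        bracket = (base_value, hi)
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo == hi:
        raise NoCrossingError(f"degenerate bracket {bracket!r} for {addrs}")
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return ThresholdResult(addrs, base_value, lo, wtp, s.horizon_months,
                               perspective, True, 0, flo)
    if fhi == 0.0:
        return ThresholdResult(addrs, base_value, hi, wtp, s.horizon_months,
                               perspective, True, 0, fhi)
    if flo * fhi > 0:
        raise NoCrossingError(
            f"NMB does not change sign over bracket {bracket!r} for {addrs} "
            f"(NMB per patient: {flo:.6g} and {fhi:.6g})"
        )
    scale = max(abs(lo), abs(hi), 1.0)
    converged = False
    it = 0
    mid, fm = lo, flo
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < nmb_tol or (hi - lo) < 1e-10 * scale:
            converged = True
            break
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return ThresholdResult(
        address=addrs,
        base_value=base_value,
        threshold_value=mid,
        wtp=wtp,
        horizon_months=s.horizon_months,
        perspective=perspective,
        converged=converged,
        iterations=it,
        nmb_at_threshold=fm,
    )
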