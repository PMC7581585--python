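"""Probabilistic sensitivity analysis.

Risks and utility weights are drawn from beta distributions and costs from
log-normal distributions, each moment-matched so the base-case value is the
arithmetic mean.  The default dispersion rule sets the standard deviation
to 20% of the mean (``sd_fraction_of_mean``); the alternative
``variance_fraction_of_mean`` rule (variance = fraction x mean) is also
available but is infeasible for utilities near 1 and raises rather than
clipping.

Each parameter-table row consumes exactly one uniform percentile per
replicate.  A row's percentile is mapped through each arm's own
moment-matched distribution, so arms are comonotone: rows whose base
values coincide in the two arms (death risks, the 2-5 year relapse risks,
utility weights) receive identical draws, and rows whose base values
differ (2-year relapse risks, costs) receive draws that preserve the
between-arm difference.  Fully independent per-arm draws are available via
``default_distribution_specs(arm_correlation="independent")``.  Draw
ordering is replicate-major and spec-order within a replicate, so a fixed
seed reproduces samples bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .cea import PERSPECTIVES, compare_arms, nmb
from .parameters import ModelParameters, ParameterError, get_param, set_param

__all__ = [
    "DistributionSpec",
    "PSASample",
    "beta_from_moments",
    "lognormal_from_moments",
    "default_distribution_specs",
    "draw_replicate",
    "run_psa",
    "ceac",
    "probability_cost_effective",
]


def beta_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a mean and variance.

    alpha = m (m(1-m)/v - 1), beta = (1-m) (m(1-m)/v - 1); requires
    0 < mean < 1 and 0 < variance < mean (1 - mean).
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must be in (0, 1), got {mean!r}")
    bound = mean * (1.0 - mean)
    if not 0.0 < variance < bound:
        raise ParameterError(
            f"beta variance {variance!r} infeasible for mean {mean!r}: "
            f"requires 0 < v < {bound:.6g}"
        )
    factor = bound / variance - 1.0
    return mean * factor, (1.0 - mean) * factor


def lognormal_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Log-scale (mu, sigma^2) whose log-normal has the given arithmetic
    mean and variance: sigma^2 = ln(1 + v/m^2), mu = ln(m) - sigma^2/2."""
    if mean <= 0:
        raise ParameterError(f"log-normal mean must be > 0, got {mean!r}")
    if variance < 0:
        raise ParameterError("variance must be >= 0")
    sigma2 = math.log1p(variance / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, sigma2


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled parameter-table row.

    Consumes one uniform percentile per replicate; each dotted address is
    assigned the inverse CDF of its own moment-matched distribution at
    that percentile (identical means therefore give identical values).
    ``means`` optionally overrides the base-case value per address.
    """

    addresses: tuple[str, ...]
    family: str  # "beta" | "lognormal" | "fixed"
    means: tuple[float, ...] | None = None  # default: base-case values
    rule: str = "sd_fraction_of_mean"
    fraction: float = 0.2

    def __post_init__(self):
        if self.means is not None and len(self.means) != len(self.addresses):
            raise ParameterError("means must align with addresses")

    def variance_for(self, mean: float) -> float:
        if self.rule == "sd_fraction_of_mean":
            return (self.fraction * mean) ** 2
        if self.rule == "variance_fraction_of_mean":
            return self.fraction * mean
        raise ParameterError(f"unknown dispersion rule {self.rule!r}")

    def value_at(self, mean: float, u: float) -> float:
        """Inverse-CDF value at percentile ``u`` for the given mean."""
        if self.family == "fixed":
            return mean
        v = self.variance_for(mean)
        if v == 0.0 or mean == 0.0:
            return mean
        if self.family == "beta":
            a, b = beta_from_moments(mean, v)
            return float(special.betaincinv(a, b, u))
        if self.family == "lognormal":
            mu, sigma2 = lognormal_from_moments(mean, v)
            return float(math.exp(mu + math.sqrt(sigma2) * special.ndtri(u)))
        raise ParameterError(f"unknown distribution family {self.family!r}")


def _spec(addresses: Sequence[str], family: str, **kw) -> DistributionSpec:
    return DistributionSpec(tuple(addresses), family, **kw)


_RISK_2Y_SHARED = (
    "death_after_relapse1",
    "death_after_relapse2",
    "death_after_remission1",
    "death_after_remission2",
    "death_after_remission3",
)
_RISK_5Y_ROWS = ("relapse1", "relapse2") + _RISK_2Y_SHARED
_COST_ROWS = (
    "relapse1_cost",
    "relapse2_cost",
    "remission1_cost",
    "remission2_cost",
    "remission3_cost",
    "sick_leave_monthly",
)


def default_distribution_specs(
    rule: str = "sd_fraction_of_mean",
    fraction: float = 0.2,
    arm_correlation: str = "comonotone",
) -> list[DistributionSpec]:
    """Distribution assignment mirroring the base-case parameter table.

    One spec per table row.  With ``arm_correlation="comonotone"``
    (default) a row's two arm columns share the random percentile; with
    ``"independent"`` arm-specific rows (2-year relapse risks, costs)
    become separate specs with their own draws.  Rows whose base values
    coincide behave identically under both settings.
    """
    if arm_correlation not in ("comonotone", "independent"):
        raise ParameterError(f"unknown arm_correlation {arm_correlation!r}")
    kw = dict(rule=rule, fraction=fraction)
    both = arm_correlation == "comonotone"

    def arm_row(fmt: str, family: str) -> list[DistributionSpec]:
        addrs = [fmt.format(arm=a) for a in ("usual_care", "pcc")]
        if both:
            return [_spec(addrs, family, **kw)]
        return [_spec([a], family, **kw) for a in addrs]

    specs: list[DistributionSpec] = []
    for name in ("relapse1", "relapse2"):
        specs += arm_row("{arm}.risks_2y." + name, "beta")
    for name in _RISK_2Y_SHARED:
        specs.append(
            _spec([f"usual_care.risks_2y.{name}", f"pcc.risks_2y.{name}"], "beta", **kw)
        )
    for name in _RISK_5Y_ROWS:
        specs.append(
            _spec([f"usual_care.risks_5y.{name}", f"pcc.risks_5y.{name}"], "beta", **kw)
        )
    for name in _COST_ROWS:
        specs += arm_row("{arm}.costs." + name, "lognormal")
    for name in ("relapse", "remission"):
        specs.append(
            _spec(
                [f"usual_care.utilities.{name}", f"pcc.utilities.{name}"], "beta", **kw
            )
        )
    return specs


def draw_replicate(
    params: ModelParameters,
    specs: Sequence[DistributionSpec],
    rng: np.random.Generator,
) -> ModelParameters:
    """Draw one parameter replicate, consuming one uniform per spec."""
    out = params
    for spec in specs:
        u = float(rng.random())
        means = spec.means
        if means is None:
            means = tuple(float(get_param(params, a)) for a in spec.addresses)
        for addr, mean in zip(spec.addresses, means):
            out = set_param(out, addr, spec.value_at(mean, u))
    return out


@dataclass(frozen=True)
class PSASample:
    """Monte Carlo incremental (cost, effect) pairs.

    ``delta_costs`` maps each perspective to an array of incremental costs;
    increments are per ``cohort_scale`` patients, as in
    :func:`acscea.cea.compare_arms`.
    """

    delta_qalys: np.ndarray
    delta_costs: dict[str, np.ndarray]
    seed: int
    n_draws: int
    cohort_scale: float

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"delta_qalys": self.delta_qalys})
        for p in PERSPECTIVES:
            df[f"delta_cost_{p}"] = self.delta_costs[p]
        return df


def run_psa(
    params: ModelParameters,
    specs: Sequence[DistributionSpec] | None = None,
    n_draws: int = 1000,
    seed: int = 20200907,
) -> PSASample:
    """Seeded Monte Carlo over the parameter distributions.

    Each replicate re-runs the full two-arm cohort comparison on the drawn
    parameter set and stores the incremental (cost, QALY) pair for every
    costing perspective.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if specs is None:
        specs = default_distribution_specs()
    rng = np.random.default_rng(seed)
    dq = np.empty(n_draws)
    dc = {p: np.empty(n_draws) for p in PERSPECTIVES}
    for i in range(n_draws):
        drawn = draw_replicate(params, specs, rng)
        res = compare_arms(drawn)
        dq[i] = res.delta_qalys
        for p in PERSPECTIVES:
            dc[p][i] = res.delta_cost_for(p)
    return PSASample(
        delta_qalys=dq,
        delta_costs=dc,
        seed=seed,
        n_draws=n_draws,
        cohort_scale=params.settings.cohort_scale,
    )


def probability_cost_effective(
    sample: PSASample, wtp: float, perspective: str = "societal"
) -> float:
    """Fraction of replicates with positive NMB at the given threshold."""
    vals = nmb(sample.delta_costs[perspective], sample.delta_qalys, wtp)
    return float(np.mean(vals > 0))


def ceac(
    sample: PSASample,
    wtp_grid: Sequence[float],
    perspective: str = "societal",
):
    """Cost-effectiveness acceptability curve over a WTP grid."""
    import pandas as pd

    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    probs = [probability_cost_effective(sample, w, perspective) for w in grid]
    return pd.DataFrame({"wtp": grid, "probability_cost_effective": probs})
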