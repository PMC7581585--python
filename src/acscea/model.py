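"""Model/Results front end.

:class:`MarkovCEAModel` bundles a full parameterization of the two-arm
Markov cohort comparison; :meth:`MarkovCEAModel.fit` runs both cohorts and
returns a :class:`CEAResults` carrying the incremental estimates, per-arm
traces, a ``summary()`` table, and entry points to the sensitivity
analyses (discount scenarios, one-way sweeps, threshold search, Monte
Carlo PSA) and plotting.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import cea, dsa, psa
from .engine import CohortTrace, run_cohort
from .estimation import PatientRecord, fit_parameters
from .parameters import (
    GlobalSettings,
    ModelParameters,
    default_parameters,
    load_parameters,
    publication_conventions,
)

__all__ = ["MarkovCEAModel", "CEAResults"]


class MarkovCEAModel:
    """Two-arm Markov cohort cost-effectiveness model.

    Parameters
    ----------
    params:
        Complete :class:`~acscea.parameters.ModelParameters`; defaults to
        the published base case.
    **settings_overrides:
        Convenience keyword overrides applied to ``params.settings``
        (e.g. ``horizon_months=24``).
    """

    def __init__(self, params: ModelParameters | None = None, **settings_overrides):
        if params is None:
            params = default_parameters()
        if settings_overrides:
            params = replace(
                params, settings=replace(params.settings, **settings_overrides)
            )
        self.params = params.validate()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_config(cls, path, **settings_overrides) -> "MarkovCEAModel":
        """Build from a YAML/JSON parameter file (defaults inherited)."""
        return cls(load_parameters(path), **settings_overrides)

    @classmethod
    def from_patient_data(
        cls,
        records: Iterable[PatientRecord],
        settings: GlobalSettings | None = None,
        **fit_kwargs,
    ) -> "MarkovCEAModel":
        """Estimate arm-specific parameters from register-like records."""
        return cls(fit_parameters(records, settings=settings, **fit_kwargs))

    def with_publication_conventions(self) -> "MarkovCEAModel":
        """Copy of the model under the original spreadsheet's cycle
        accounting (see docs/methods.md)."""
        return MarkovCEAModel(publication_conventions(self.params))

    # -- estimation --------------------------------------------------------
    def fit(self) -> "CEAResults":
        """Run both cohorts and return the incremental results."""
        result = cea.compare_arms(self.params)
        traces = {
            "usual_care": run_cohort(self.params.usual_care, self.params.settings),
            "pcc": run_cohort(self.params.pcc, self.params.settings),
        }
        return CEAResults(self, result, traces)


class CEAResults:
    """Fitted results of a :class:`MarkovCEAModel`.

    Attributes
    ----------
    increments : acscea.cea.CEResult
        Incremental QALYs, life-years and costs (per ``cohort_scale``
        patients), with ICER and NMB accessors.
    traces : dict[str, CohortTrace]
        Per-arm month-by-month occupancy and accrual traces.
    """

    def __init__(self, model: MarkovCEAModel, increments: cea.CEResult,
                 traces: dict[str, CohortTrace]):
        self.model = model
        self.increments = increments
        self.traces = traces

    # convenience passthroughs
    @property
    def delta_qalys(self) -> float:
        return self.increments.delta_qalys

    @property
    def delta_life_years(self) -> float:
        return self.increments.delta_life_years

    @property
    def icer(self) -> dict[str, cea.ICERValue]:
        return self.increments.icer_by_perspective

    def nmb(self, wtp: float | None = None, perspective: str = "societal") -> float:
        if wtp is None:
            wtp = self.model.params.settings.wtp_threshold
        return self.increments.nmb_at(wtp, perspective)

    def summary(self) -> pd.DataFrame:
        """Incremental results by costing perspective, one row each."""
        inc = self.increments
        rows = []
        for p in cea.PERSPECTIVES:
            dcost = inc.delta_cost_for(p)
            rows.append(
                {
                    "perspective": p,
                    "delta_qalys": inc.delta_qalys,
                    "delta_life_years": inc.delta_life_years,
                    "delta_cost_sek": dcost,
                    "icer_sek_per_qaly": inc.icer_by_perspective[p].value,
                    "dominance": inc.icer_by_perspective[p].label,
                    "nmb_at_wtp_sek": inc.nmb_at(
                        self.model.params.settings.wtp_threshold, p
                    ),
                }
            )
        df = pd.DataFrame(rows).set_index("perspective")
        df.attrs["cohort_scale"] = inc.cohort_scale
        df.attrs["horizon_months"] = self.model.params.settings.horizon_months
        return df

    def __str__(self) -> str:
        s = self.model.params.settings
        head = (
            f"Markov cohort CEA — horizon {s.horizon_months} months, "
            f"increments per {s.cohort_scale:g} patients\n"
        )
        return head + self.summary().to_string(float_format=lambda v: f"{v:,.2f}")

    # -- sensitivity analyses ---------------------------------------------
    def discount_scenarios(self) -> dict[str, cea.CEResult]:
        return dsa.discount_scenarios(self.model.params)

    def one_way_sweep(self, address, values) -> list[tuple[float, cea.CEResult]]:
        return dsa.one_way_sweep(self.model.params, address, values)

    def threshold_search(self, address, **kwargs) -> dsa.ThresholdResult:
        return dsa.threshold_search(self.model.params, address, **kwargs)

    def run_psa(
        self,
        specs: Sequence[psa.DistributionSpec] | None = None,
        n_draws: int = 1000,
        seed: int = 20200907,
    ) -> psa.PSASample:
        return psa.run_psa(self.model.params, specs, n_draws, seed)

    # -- plotting (thin, optional) ----------------------------------------
    def plot_ce_plane(self, sample: psa.PSASample, perspective: str = "societal",
                      ax=None):
        """Scatter the PSA incremental (effect, cost) pairs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(
            sample.delta_qalys, sample.delta_costs[perspective], s=8, alpha=0.5
        )
        ax.axhline(0, lw=0.8, color="k")
        ax.axvline(0, lw=0.8, color="k")
        ax.set_xlabel(f"Incremental QALYs (per {sample.cohort_scale:g} patients)")
        ax.set_ylabel("Incremental cost (SEK)")
        ax.set_title(f"Cost-effectiveness plane — {perspective}")
        return ax

    def plot_ceac(self, sample: psa.PSASample, wtp_grid=None,
                  perspective: str = "societal", ax=None):
        """Cost-effectiveness acceptability curve."""
        import matplotlib.pyplot as plt

        if wtp_grid is None:
            wtp_grid = np.linspace(0, 1_000_000, 101)
        curve = psa.ceac(sample, wtp_grid, perspective)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["wtp"], curve["probability_cost_effective"])
        ax.set_ylim(0, 1)
        ax.set_xlabel("Willingness to pay (SEK per QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_title(f"CEAC — {perspective}")
        return ax
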