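"""Strategy evaluation, incremental analysis and decision rules.

``evaluate_strategy`` composes the decision tree (initial states and year-0
costs) with the Markov projection to produce discounted cohort totals per
strategy.  The targeted strategy is a proportional application of universal
screening to a fixed fraction of the cohort, so its totals are exactly the
convex blend of the two pure strategies.  ``icer`` implements

    ICER = (C_comparator - C_reference) / (Q_comparator - Q_reference)

with dominance classification, net monetary benefit NMB(lambda) =
lambda * dQ - dC, and a verdict against the willingness-to-pay band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import decision_tree as dt
from . import markov as mk
from .parameters import ParameterSet

__all__ = [
    "StrategyResult",
    "IncrementalResult",
    "evaluate_strategy",
    "evaluate_all",
    "icer",
    "net_monetary_benefit",
    "wtp_verdict",
    "results_table",
]


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals for one strategy on the cohort scale."""

    strategy: str
    cost: float  # THB, cohort total
    qalys: float  # cohort total
    cohort_size: float
    accounting_mode: str
    trace: Optional[mk.CohortTrace] = field(default=None, compare=False)

    @property
    def cost_per_patient(self) -> float:
        return self.cost / self.cohort_size

    @property
    def qalys_per_patient(self) -> float:
        return self.qalys / self.cohort_size


@dataclass(frozen=True)
class IncrementalResult:
    """Comparator vs reference: increments, ICER, dominance and NMB."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: str  # dominant / dominated / tradeoff_NE / tradeoff_SW / none
    nmb: dict[float, float] = field(default_factory=dict)


def _detection_tolls(params: ParameterSet) -> dict[tuple[str, str], float]:
    """Work-up charged when an undiagnosed patient is detected on symptoms."""
    c = params.costs
    return {
        ("omg_delayed", "omg_early_dx"): c.achr_ab_test + c.chest_ct,
        ("hypothyroid_missed", "hypothyroid_treated"): c.tft_panel,
    }


def _evaluate_pure(params: ParameterSet, strategy: str, mode: str) -> StrategyResult:
    settings = params.settings
    matrix = mk.build_transition_matrix(params.transitions)
    init = dt.initial_state_distribution(params, strategy)
    spec = mk.MarkovSpec(matrix=matrix, initial=init)
    trace = mk.run_cohort(spec, settings.horizon_years, cohort_size=1.0)

    rate = settings.discount_rate_annual
    qalys = mk.accumulate_qalys(trace, params.utilities, rate, mode=mode)

    per_cycle = np.zeros(len(mk.STATES))
    per_cycle[mk.state_index("omg_early_dx")] = params.costs.annual_treatment_omg
    per_cycle[mk.state_index("generalized_mg")] = params.costs.annual_treatment_omg
    per_cycle[mk.state_index("hypothyroid_treated")] = params.costs.annual_treatment_hypothyroid

    visit_years = math.ceil(params.costs.visits_per_patient / 2) if params.costs.followup_visit else 0
    visits_per_year = (
        params.costs.visits_per_patient / visit_years if visit_years else 0.0
    )
    cost = mk.accumulate_costs(
        trace,
        one_time=dt.one_time_cost_per_patient(params, strategy),
        per_cycle_state_costs=per_cycle,
        rate=rate,
        visit_cost_per_year=visits_per_year * params.costs.followup_visit,
        visit_years=visit_years,
        transition_tolls=_detection_tolls(params),
        matrix=matrix,
    )

    n = settings.cohort_size
    return StrategyResult(
        strategy=strategy,
        cost=cost * n,
        qalys=qalys * n,
        cohort_size=n,
        accounting_mode=mode,
        trace=mk.CohortTrace(occupancy=trace.occupancy * n, cohort_size=n),
    )


def evaluate_strategy(
    params: ParameterSet, strategy: str, mode: str = "accumulated"
) -> StrategyResult:
    """Discounted cohort cost and QALYs for one strategy.

    ``targeted`` applies the universal pathway to ``targeted_fraction`` of
    the cohort and the no-screening pathway to the rest, so its totals are
    the exact convex combination of the pure strategies.
    """
    if mode not in mk.ACCOUNTING_MODES:
        raise ValueError(f"unknown accounting mode {mode!r}")
    if strategy not in dt.STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {dt.STRATEGIES}")
    if strategy in ("none", "universal"):
        return _evaluate_pure(params, strategy, mode)
    f = params.settings.targeted_fraction
    uni = _evaluate_pure(params, "universal", mode)
    non = _evaluate_pure(params, "none", mode)
    return StrategyResult(
        strategy="targeted",
        cost=f * uni.cost + (1.0 - f) * non.cost,
        qalys=f * uni.qalys + (1.0 - f) * non.qalys,
        cohort_size=params.settings.cohort_size,
        accounting_mode=mode,
        trace=mk.CohortTrace(
            occupancy=f * uni.trace.occupancy + (1.0 - f) * non.trace.occupancy,
            cohort_size=params.settings.cohort_size,
        ),
    )


def evaluate_all(params: ParameterSet, mode: str = "accumulated") -> dict[str, StrategyResult]:
    return {s: evaluate_strategy(params, s, mode=mode) for s in dt.STRATEGIES}


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB(lambda) = lambda * dQALY - dCost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def icer(
    ref: StrategyResult,
    comp: StrategyResult,
    wtp_values: tuple[float, ...] = (160_000.0, 200_000.0),
) -> IncrementalResult:
    """Incremental analysis of ``comp`` against reference ``ref``."""
    if ref.accounting_mode != comp.accounting_mode:
        raise ValueError(
            f"mixed accounting modes: {ref.accounting_mode!r} vs {comp.accounting_mode!r}"
        )
    if not math.isclose(ref.cohort_size, comp.cohort_size):
        raise ValueError("strategies evaluated on different cohort scales")
    dc = comp.cost - ref.cost
    dq = comp.qalys - ref.qalys

    if dc <= 0 and dq >= 0 and not (dc == 0 and dq == 0):
        dominance = "dominant"
    elif dc >= 0 and dq <= 0 and not (dc == 0 and dq == 0):
        dominance = "dominated"
    elif dc > 0 and dq > 0:
        dominance = "tradeoff_NE"
    elif dc < 0 and dq < 0:
        dominance = "tradeoff_SW"
    else:
        dominance = "none"

    ratio = dc / dq if dq != 0.0 else None
    nmb = {w: net_monetary_benefit(dc, dq, w) for w in wtp_values}
    return IncrementalResult(
        reference=ref.strategy,
        comparator=comp.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        icer=ratio,
        dominance=dominance,
        nmb=nmb,
    )


def wtp_verdict(inc: IncrementalResult, wtp_lower: float, wtp_upper: float) -> str:
    """Classify against the willingness-to-pay band.

    Dominant strategies are cost-effective and dominated ones are not,
    regardless of the (possibly undefined) ICER; otherwise the ICER is
    compared with the band.
    """
    if wtp_lower > wtp_upper:
        raise ValueError("wtp_lower must be <= wtp_upper")
    if inc.dominance == "dominant":
        return "cost_effective"
    if inc.dominance == "dominated":
        return "not_cost_effective"
    if inc.icer is None:
        raise ValueError("ICER undefined (delta QALY = 0) without dominance")
    if inc.dominance == "tradeoff_SW":
        # less effective and cheaper: acceptable only if savings per QALY
        # forgone exceed the upper threshold
        return "cost_effective" if inc.icer > wtp_upper else "not_cost_effective"
    if inc.icer < wtp_lower:
        return "cost_effective"
    if inc.icer <= wtp_upper:
        return "borderline"
    return "not_cost_effective"


def results_table(results: dict[str, StrategyResult], reference: str = "none") -> pd.DataFrame:
    """Strategy summary mirroring the published layout: discounted QALYs,
    total cost and ICER against the no-screening reference."""
    ref = results[reference]
    rows = []
    for name, res in results.items():
        if name == reference:
            icer_txt: float | str = "reference"
        else:
            inc = icer(ref, res)
            icer_txt = inc.icer if inc.icer is not None else inc.dominance
        rows.append(
            {
                "strategy": name,
                "discounted_qalys": res.qalys,
                "total_cost_thb": res.cost,
                "icer_vs_reference": icer_txt,
                "accounting_mode": res.accounting_mode,
            }
        )
    return pd.DataFrame(rows)
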