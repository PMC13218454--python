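"""Diagnostic decision tree for the first model year.

For each screening test the tree splits the cohort into true-positive (TP),
false-negative (FN), false-positive (FP) and true-negative (TN) branches from
disease prevalence and test accuracy, assigns every branch an initial Markov
health state, and prices the first-year pathway: the baseline test panel, the
MRI performed in every arm, confirmatory work-up for screen positives, and
extra follow-up visits for false positives.

The two tests are treated as conditionally independent and the two target
diseases (ocular myasthenia gravis and thyroid dysfunction) as mutually
exclusive at the observed prevalences; the tree therefore has parallel
branches per test with no joint-disease pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import STATES, state_index
from .parameters import CostTable, ParameterSet, Prevalence, TestAccuracy

__all__ = [
    "STRATEGIES",
    "OutcomeProbabilities",
    "PathwayAssignment",
    "outcome_probabilities",
    "positive_predictive_value",
    "expected_pathway_counts",
    "screening_cost_per_patient",
    "initial_state_distribution",
    "one_time_cost_per_patient",
    "pathway_table",
]

STRATEGIES = ("none", "targeted", "universal")

#: extra follow-up visits charged to a false positive during work-up
FP_EXTRA_VISITS = 2


@dataclass(frozen=True)
class OutcomeProbabilities:
    """Branch mass of one test: tp + fn + fp + tn = 1."""

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if abs(self.tp + self.fn + self.fp + self.tn - 1.0) > 1e-12:
            raise ValueError("outcome probabilities must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class PathwayAssignment:
    """One terminal branch: outcome, initial health state and its price."""

    test: str  # "achr_ab" or "tft"
    outcome: str  # tp / fn / fp / tn
    probability: float
    initial_state: str
    one_time_cost: float  # THB beyond the shared test panel + MRI


def outcome_probabilities(prev: Prevalence | float, acc: TestAccuracy) -> OutcomeProbabilities:
    """TP/FN/FP/TN branch mass from prevalence and test accuracy.

    tp = p*Se, fn = p*(1-Se), fp = (1-p)*(1-Sp), tn = (1-p)*Sp.
    """
    p = prev.value if isinstance(prev, Prevalence) else float(prev)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence {p} outside [0, 1]")
    se, sp = acc.sensitivity, acc.specificity
    return OutcomeProbabilities(
        tp=p * se,
        fn=p * (1.0 - se),
        fp=(1.0 - p) * (1.0 - sp),
        tn=(1.0 - p) * sp,
    )


def positive_predictive_value(op: OutcomeProbabilities) -> float:
    """tp / (tp + fp); undefined when no positives can occur."""
    denom = op.tp + op.fp
    if denom == 0.0:
        raise ValueError("positive predictive value undefined: tp + fp = 0")
    return op.tp / denom


def expected_pathway_counts(op: OutcomeProbabilities, cohort_size: float) -> dict[str, float]:
    """Expected patients per branch in a cohort of ``cohort_size``."""
    if cohort_size < 0:
        raise ValueError("cohort_size must be non-negative")
    return {k: cohort_size * v for k, v in op.as_dict().items()}


def screening_cost_per_patient(costs: CostTable, strategy: str) -> dict[str, float]:
    """Baseline per-patient screening spend for a strategy.

    Returns the ``test_component`` (the laboratory panel actually driven by
    the strategy), the ``mri`` every arm receives, and their ``total``.
    Work-up costs of individual branches are handled by
    :func:`one_time_cost_per_patient`.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    panel = costs.achr_ab_test + costs.tft_panel
    test_component = {"none": 0.0, "universal": panel, "targeted": panel}[strategy]
    return {
        "test_component": test_component,
        "mri": costs.mri_brain_orbit,
        "total": test_component + costs.mri_brain_orbit,
    }


def _pathways(params: ParameterSet, test: str) -> list[PathwayAssignment]:
    """Terminal branches of one test under universal screening."""
    costs = params.costs
    if test == "achr_ab":
        op = outcome_probabilities(params.prevalence_mg, params.achr_accuracy)
        # every serologic positive gets chest CT for thymoma evaluation;
        # false positives also accrue extra clinic visits during work-up
        branch = {
            "tp": ("omg_early_dx", costs.chest_ct),
            "fn": ("omg_delayed", 0.0),
            "fp": ("idiopathic_ace", costs.chest_ct + FP_EXTRA_VISITS * costs.followup_visit),
            "tn": ("idiopathic_ace", 0.0),
        }
    elif test == "tft":
        op = outcome_probabilities(params.prevalence_thyroid, params.tft_accuracy)
        branch = {
            "tp": ("hypothyroid_treated", 0.0),
            "fn": ("hypothyroid_missed", 0.0),
            "fp": ("idiopathic_ace", FP_EXTRA_VISITS * costs.followup_visit),
            "tn": ("idiopathic_ace", 0.0),
        }
    else:
        raise ValueError(f"unknown test {test!r}")
    return [
        PathwayAssignment(test, outcome, getattr(op, outcome), state, cost)
        for outcome, (state, cost) in branch.items()
    ]


def initial_state_distribution(params: ParameterSet, strategy: str) -> np.ndarray:
    """Per-patient initial Markov state occupancy for a strategy.

    Universal screening sorts diseased patients into early-diagnosed or
    delayed states according to test sensitivity; without screening every
    diseased patient starts in the delayed/missed state.  The targeted
    strategy is the proportional blend handled in
    :mod:`acescreen.economics` and maps here to the universal distribution
    for its screened fraction.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    m = params.prevalence_mg.value
    h = params.prevalence_thyroid.value
    if m + h > 1.0:
        raise ValueError("prevalences sum above 1")
    dist = np.zeros(len(STATES))
    if strategy == "none":
        dist[state_index("omg_delayed")] = m
        dist[state_index("hypothyroid_missed")] = h
    else:
        se_a = params.achr_accuracy.sensitivity
        se_t = params.tft_accuracy.sensitivity
        dist[state_index("omg_early_dx")] = m * se_a
        dist[state_index("omg_delayed")] = m * (1.0 - se_a)
        dist[state_index("hypothyroid_treated")] = h * se_t
        dist[state_index("hypothyroid_missed")] = h * (1.0 - se_t)
    dist[state_index("idiopathic_ace")] = 1.0 - dist.sum()
    return dist


def one_time_cost_per_patient(params: ParameterSet, strategy: str) -> float:
    """Expected year-0 cost per patient: MRI, test panel, branch work-up."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    cost = params.costs.mri_brain_orbit
    if strategy == "none":
        return cost
    cost += params.costs.achr_ab_test + params.costs.tft_panel
    for test in ("achr_ab", "tft"):
        for pw in _pathways(params, test):
            cost += pw.probability * pw.one_time_cost
    return cost


def pathway_table(params: ParameterSet) -> pd.DataFrame:
    """One row per strategy x test x outcome, for export and auditing."""
    n = params.settings.cohort_size
    rows = []
    for strategy in STRATEGIES:
        screened_fraction = {
            "none": 0.0,
            "targeted": params.settings.targeted_fraction,
            "universal": 1.0,
        }[strategy]
        for test in ("achr_ab", "tft"):
            for pw in _pathways(params, test):
                rows.append(
                    {
                        "strategy": strategy,
                        "test": pw.test,
                        "outcome": pw.outcome,
                        "probability": pw.probability,
                        "screened_fraction": screened_fraction,
                        "expected_count": n * screened_fraction * pw.probability,
                        "one_time_cost_thb": pw.one_time_cost,
                        "initial_state": pw.initial_state,
                    }
                )
    return pd.DataFrame(rows)
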