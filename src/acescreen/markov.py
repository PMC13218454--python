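"""Markov cohort projection over the 10-year horizon.

Seven health states with annual cycles: idiopathic esotropia, ocular
myasthenia gravis early-diagnosed or still undiagnosed (delayed), generalized
myasthenia, treated hypothyroidism, undetected (missed) hypothyroidism, and
death as the absorbing background-mortality state.  Undiagnosed patients can
be picked up by symptom-triggered testing, which moves them to the diagnosed
state and charges the diagnostic work-up at that cycle.

Costs and quality-adjusted life years are discounted annually and carry a
half-cycle correction: each cycle's contribution uses state occupancy
averaged over its two boundaries (trapezoidal rule), discounted with the
end-of-cycle factor, so with full utility and no mortality the discounted
QALY total per patient equals the textbook annuity (1 - (1+r)^-H) / r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import TransitionInputs, UtilityTable

__all__ = [
    "STATES",
    "ACCOUNTING_MODES",
    "state_index",
    "MarkovSpec",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "discount_factor",
    "state_utilities",
    "accumulate_qalys",
    "accumulate_costs",
]

STATES = (
    "idiopathic_ace",
    "omg_early_dx",
    "omg_delayed",
    "generalized_mg",
    "hypothyroid_treated",
    "hypothyroid_missed",
    "death",
)

ACCOUNTING_MODES = ("accumulated", "endpoint")

#: Markov state -> utility-table attribute
STATE_UTILITY_FIELDS = {
    "idiopathic_ace": "idiopathic_ace",
    "omg_early_dx": "early_dx_omg",
    "omg_delayed": "delayed_dx_omg",
    "generalized_mg": "generalized_mg",
    "hypothyroid_treated": "treated_hypothyroid",
    "hypothyroid_missed": "delayed_hypothyroid",
    "death": "death",
}


def state_index(name: str) -> int:
    try:
        return STATES.index(name)
    except ValueError as exc:
        raise KeyError(f"unknown Markov state {name!r}") from exc


@dataclass(frozen=True)
class MarkovSpec:
    """Transition matrix plus an initial distribution (per-patient scale)."""

    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        init = np.asarray(self.initial, dtype=float)
        n = len(STATES)
        if m.shape != (n, n):
            raise ValueError(f"matrix must be {n}x{n}")
        if (m < -1e-15).any():
            raise ValueError("matrix entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("matrix rows must sum to 1")
        death = state_index("death")
        if not (m[death, death] == 1.0 and np.all(m[death, :death] == 0.0)):
            raise ValueError("death must be absorbing")
        if init.shape != (n,) or (init < -1e-15).any() or abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must be a length-7 probability vector")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "initial", init)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at each cycle boundary, rows 0..horizon."""

    occupancy: np.ndarray  # (horizon+1, n_states)
    cohort_size: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1


def build_transition_matrix(t: TransitionInputs) -> np.ndarray:
    """Row-stochastic annual matrix realizing the model's transition graph.

    Edges: every alive state can die (background mortality); both ocular-MG
    states can generalize; undiagnosed states convert to their diagnosed
    counterpart at the symptom-triggered detection rate; idiopathic patients
    can develop incident disease (entering the undiagnosed state).  The
    residual probability is "stay".
    """
    mort = t.background_mortality
    n = len(STATES)
    m = np.zeros((n, n))
    edges: dict[str, dict[str, float]] = {
        "idiopathic_ace": {
            "omg_delayed": t.incident_omg,
            "hypothyroid_missed": t.incident_hypothyroid,
            "death": mort,
        },
        "omg_early_dx": {"generalized_mg": t.omg_to_generalized, "death": mort},
        "omg_delayed": {
            "omg_early_dx": t.symptom_triggered_detection,
            "generalized_mg": t.omg_to_generalized,
            "death": mort,
        },
        "generalized_mg": {"death": mort},
        "hypothyroid_treated": {"death": mort},
        "hypothyroid_missed": {
            "hypothyroid_treated": t.symptom_triggered_detection,
            "death": mort,
        },
        "death": {},
    }
    for state, outflows in edges.items():
        i = state_index(state)
        total = sum(outflows.values())
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"outflows from state {state!r} sum to {total:.6f} > 1"
            )
        for target, p in outflows.items():
            m[i, state_index(target)] = p
        m[i, i] = 1.0 - total
    return m


def run_cohort(spec: MarkovSpec, horizon: int, cohort_size: float = 1.0) -> CohortTrace:
    """Project occupancy over ``horizon`` annual cycles."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if cohort_size < 0:
        raise ValueError("cohort_size must be non-negative")
    occ = np.empty((horizon + 1, len(STATES)))
    occ[0] = spec.initial * cohort_size
    for k in range(horizon):
        occ[k + 1] = occ[k] @ spec.matrix
    return CohortTrace(occupancy=occ, cohort_size=cohort_size)


def discount_factor(year: float, rate: float) -> float:
    """(1 + rate) ** (-year); rate 0 means no discounting."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return float((1.0 + rate) ** (-year))


def _cycle_weights(horizon: int, rate: float) -> np.ndarray:
    """Discount weight of cycle k (spanning years k to k+1).

    End-of-cycle factors, so sum_k weight = (1 - (1+r)^-H) / r; the
    half-cycle correction lives in the trapezoidal occupancy averaging.
    """
    return np.array([discount_factor(k + 1.0, rate) for k in range(horizon)])


def state_utilities(utilities: UtilityTable) -> np.ndarray:
    """Utility vector in Markov state order."""
    out = np.empty(len(STATES))
    for i, state in enumerate(STATES):
        value = getattr(utilities, STATE_UTILITY_FIELDS[state])
        if value is None:
            raise ValueError(f"no utility defined for state {state!r}")
        out[i] = value
    return out


def accumulate_qalys(
    trace: CohortTrace,
    utilities: UtilityTable | np.ndarray,
    rate: float,
    mode: str = "accumulated",
) -> float:
    """Discounted QALYs for a trace under the chosen accounting rule.

    ``accumulated`` is the standard state-utility x time sum: each cycle
    contributes the trapezoidal average of adjacent occupancies times the
    state utilities, times the cycle discount weight.  ``endpoint`` divides
    that sum by the discounted horizon weight, i.e. it reports the
    discount-weighted average utility scaled to the cohort, bounded by the
    cohort size rather than cohort x horizon.  Both rules are exposed because
    published cohort totals for models of this kind appear on either scale.
    """
    if mode not in ACCOUNTING_MODES:
        raise ValueError(f"unknown accounting mode {mode!r}; expected one of {ACCOUNTING_MODES}")
    u = utilities if isinstance(utilities, np.ndarray) else state_utilities(utilities)
    occ = trace.occupancy
    weights = _cycle_weights(trace.horizon, rate)
    per_cycle = 0.5 * (occ[:-1] @ u + occ[1:] @ u)
    total = float(weights @ per_cycle)
    if mode == "endpoint":
        return total / float(weights.sum())
    return total


def accumulate_costs(
    trace: CohortTrace,
    one_time: float,
    per_cycle_state_costs: np.ndarray | None,
    rate: float,
    *,
    visit_cost_per_year: float = 0.0,
    visit_years: int = 0,
    transition_tolls: dict[tuple[str, str], float] | None = None,
    matrix: np.ndarray | None = None,
) -> float:
    """Discounted total cost for a trace.

    ``one_time`` is charged at year 0 undiscounted.  ``per_cycle_state_costs``
    (THB per person-year per state) and the time-limited follow-up visit
    schedule (``visit_cost_per_year`` over the first ``visit_years`` cycles,
    alive states only) use trapezoidal occupancy and cycle discount weights.
    ``transition_tolls`` charge a one-off amount per transition event, e.g.
    the diagnostic work-up when an undiagnosed patient presents with
    symptoms; they require the transition ``matrix`` to recover flows.
    """
    if one_time < 0 or visit_cost_per_year < 0:
        raise ValueError("costs must be non-negative")
    occ = trace.occupancy
    horizon = trace.horizon
    weights = _cycle_weights(horizon, rate)
    total = float(one_time)

    if per_cycle_state_costs is not None:
        c = np.asarray(per_cycle_state_costs, dtype=float)
        if (c < 0).any():
            raise ValueError("per-cycle state costs must be non-negative")
        per_cycle = 0.5 * (occ[:-1] @ c + occ[1:] @ c)
        total += float(weights @ per_cycle)

    if visit_cost_per_year > 0.0 and visit_years > 0:
        alive = np.ones(len(STATES))
        alive[state_index("death")] = 0.0
        per_cycle = 0.5 * (occ[:-1] @ alive + occ[1:] @ alive)
        k = min(visit_years, horizon)
        total += float(weights[:k] @ per_cycle[:k]) * visit_cost_per_year

    if transition_tolls:
        if matrix is None:
            raise ValueError("transition_tolls require the transition matrix")
        for (src, dst), toll in transition_tolls.items():
            if toll < 0:
                raise ValueError("transition tolls must be non-negative")
            i, j = state_index(src), state_index(dst)
            flows = occ[:-1, i] * matrix[i, j]  # events during cycle k
            total += float(weights @ flows) * toll

    return total
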