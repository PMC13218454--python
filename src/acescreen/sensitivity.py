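"""Deterministic and probabilistic sensitivity analyses.

One-way DSA varies each uncertain parameter by +/-20% around its base value
and reports the swing in net monetary benefit (NMB) of universal screening
versus no screening, sorted tornado-style.  Probabilities that sit near the
ceiling (test accuracies, utilities) are varied on their complement scale —
the error rate or disutility — so a +/-20% range never has to be clipped at
1.0 and "the utility decrement of undiagnosed disease" is a single varied
quantity; prevalences, transition rates and costs vary on their natural
scale, with any residual excursion outside [0, 1] clipped and logged.

The PSA draws every stochastic parameter independently (beta distributions
for probabilities and utilities, parameterized as alpha = p*n, beta =
(1-p)*n; gamma distributions for costs with a 20% coefficient of variation),
re-evaluates both strategies per draw, and summarizes the incremental
cost/QALY cloud, the ICER distribution, and the cost-effectiveness
acceptability curve.  The two-way threshold analysis maps the ICER over a
grid of antibody-test price against disease prevalence.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import economics as ec
from .parameters import ParameterSet, Prevalence

logger = logging.getLogger(__name__)

__all__ = [
    "BetaSpec",
    "GammaSpec",
    "PointMass",
    "beta_from_pn",
    "gamma_from_mu_sigma",
    "UncertainParameter",
    "default_registry",
    "TornadoEntry",
    "one_way_dsa",
    "PSAResult",
    "run_psa",
    "ceac",
    "ThresholdGrid",
    "two_way_threshold",
]

#: default effective sample size behind a beta distribution when no counts
#: are available for the parameter
DEFAULT_BETA_N = 100.0

#: default coefficient of variation of gamma-distributed costs
COST_CV = 0.20


@dataclass(frozen=True)
class BetaSpec:
    """Beta(alpha, beta) for probabilities and utilities."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class GammaSpec:
    """Gamma(shape k, scale theta) for costs."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=size)


@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution for parameters held fixed in the PSA."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def variance(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value)


def beta_from_pn(p: float, n: float) -> BetaSpec:
    """Moment parameterization alpha = p*n, beta = (1-p)*n.

    ``beta_from_pn(0.75, 100)`` gives alpha 75, beta 25.  Degenerate p in
    {0, 1} is rejected; use a :class:`PointMass` instead.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p = {p} is degenerate for a beta distribution; use a point mass")
    if n <= 0:
        raise ValueError("effective sample size n must be positive")
    return BetaSpec(alpha=p * n, beta=(1.0 - p) * n)


def gamma_from_mu_sigma(mu: float, sigma: float) -> GammaSpec:
    """Moment parameterization k = mu^2/sigma^2, theta = sigma^2/mu."""
    if mu <= 0 or sigma <= 0:
        raise ValueError("mu and sigma must be positive")
    return GammaSpec(shape=mu * mu / (sigma * sigma), scale=sigma * sigma / mu)


# ---------------------------------------------------------------------------
# uncertain-parameter registry


def _clip_probability(value: float, name: str) -> float:
    if 0.0 <= value <= 1.0:
        return value
    clipped = min(max(value, 0.0), 1.0)
    logger.warning("%s: varied value %.4f clipped to %.4f", name, value, clipped)
    return clipped


@dataclass(frozen=True)
class UncertainParameter:
    """One model input eligible for sensitivity analysis.

    ``dsa_scale`` controls how the +/-20% range is constructed: ``direct``
    multiplies the value itself, ``complement`` multiplies 1 - value (error
    rates, disutilities), ``cost`` multiplies a non-negative amount.
    """

    name: str
    getter: Callable[[ParameterSet], float]
    setter: Callable[[ParameterSet, float], ParameterSet]
    dsa_scale: str  # direct / complement / cost
    psa_dist: Callable[[ParameterSet], BetaSpec | GammaSpec | PointMass]

    def dsa_range(self, params: ParameterSet, variation: float) -> tuple[float, float]:
        base = self.getter(params)
        if self.dsa_scale == "complement":
            lo = 1.0 - (1.0 - base) * (1.0 + variation)
            hi = 1.0 - (1.0 - base) * (1.0 - variation)
        else:
            lo = base * (1.0 - variation)
            hi = base * (1.0 + variation)
        if self.dsa_scale in ("direct", "complement"):
            lo = _clip_probability(lo, self.name)
            hi = _clip_probability(hi, self.name)
        return lo, hi


def _set_prev(params: ParameterSet, which: str, value: float) -> ParameterSet:
    value = _clip_probability(value, f"{which}_prevalence")
    return params.replace(**{f"prevalence_{which}": Prevalence(value)})


def _set_accuracy(params: ParameterSet, test: str, fld: str, value: float) -> ParameterSet:
    attr = f"{test}_accuracy"
    acc = getattr(params, attr)
    value = _clip_probability(value, f"{test}_{fld}")
    return params.replace(**{attr: dataclasses.replace(acc, **{fld: value})})


def _set_cost(params: ParameterSet, fld: str, value: float) -> ParameterSet:
    return params.replace(costs=dataclasses.replace(params.costs, **{fld: max(value, 0.0)}))


def _set_tft_panel(params: ParameterSet, value: float) -> ParameterSet:
    # scale the three assay costs jointly, preserving their proportions
    base = params.costs.tft_panel
    ratio = value / base if base > 0 else 0.0
    return params.replace(
        costs=dataclasses.replace(
            params.costs,
            tsh=params.costs.tsh * ratio,
            ft3=params.costs.ft3 * ratio,
            ft4=params.costs.ft4 * ratio,
        )
    )


def _set_utility(params: ParameterSet, fields: tuple[str, ...], value: float) -> ParameterSet:
    value = _clip_probability(value, f"utility_{fields[0]}")
    # keep the admissible ordering early >= delayed when the two are varied
    # independently; out-of-domain draws are clipped like probabilities
    if "delayed_dx_omg" in fields and value > params.utilities.early_dx_omg:
        logger.debug(
            "utility_delayed_omg: draw %.4f capped at early-diagnosis utility %.4f",
            value,
            params.utilities.early_dx_omg,
        )
        value = params.utilities.early_dx_omg
    if "early_dx_omg" in fields and value < params.utilities.delayed_dx_omg:
        logger.debug(
            "utility_early_omg: draw %.4f raised to delayed-diagnosis utility %.4f",
            value,
            params.utilities.delayed_dx_omg,
        )
        value = params.utilities.delayed_dx_omg
    return params.replace(
        utilities=dataclasses.replace(params.utilities, **{f: value for f in fields})
    )


def _set_transition(params: ParameterSet, fld: str, value: float) -> ParameterSet:
    value = _clip_probability(value, f"transition_{fld}")
    return params.replace(
        transitions=dataclasses.replace(params.transitions, **{fld: value})
    )


def _beta_for_prevalence(which: str) -> Callable[[ParameterSet], BetaSpec]:
    def dist(params: ParameterSet) -> BetaSpec:
        prev: Prevalence = getattr(params, f"prevalence_{which}")
        n = prev.source_count[1] if prev.source_count else DEFAULT_BETA_N
        return beta_from_pn(prev.value, n)

    return dist


def _beta_direct(getter: Callable[[ParameterSet], float]) -> Callable:
    def dist(params: ParameterSet) -> BetaSpec | PointMass:
        p = getter(params)
        if p <= 0.0 or p >= 1.0:
            return PointMass(p)
        return beta_from_pn(p, DEFAULT_BETA_N)

    return dist


def _gamma_cv(getter: Callable[[ParameterSet], float]) -> Callable:
    def dist(params: ParameterSet) -> GammaSpec | PointMass:
        mu = getter(params)
        if mu <= 0:
            return PointMass(mu)
        return gamma_from_mu_sigma(mu, COST_CV * mu)

    return dist


def default_registry(include_transitions: bool = False) -> list[UncertainParameter]:
    """The uncertain parameters of the base analysis.

    The default list mirrors the published sensitivity set: disease
    prevalences, accuracy of both tests, unit costs, and health-state
    utilities.  Markov transition rates (which the source model leaves
    unprinted) can be appended with ``include_transitions=True``.
    """
    reg: list[UncertainParameter] = [
        UncertainParameter(
            "mg_prevalence",
            lambda p: p.prevalence_mg.value,
            lambda p, v: _set_prev(p, "mg", v),
            "direct",
            _beta_for_prevalence("mg"),
        ),
        UncertainParameter(
            "thyroid_prevalence",
            lambda p: p.prevalence_thyroid.value,
            lambda p, v: _set_prev(p, "thyroid", v),
            "direct",
            _beta_for_prevalence("thyroid"),
        ),
        UncertainParameter(
            "achr_sensitivity",
            lambda p: p.achr_accuracy.sensitivity,
            lambda p, v: _set_accuracy(p, "achr", "sensitivity", v),
            "complement",
            _beta_direct(lambda p: p.achr_accuracy.sensitivity),
        ),
        UncertainParameter(
            "achr_specificity",
            lambda p: p.achr_accuracy.specificity,
            lambda p, v: _set_accuracy(p, "achr", "specificity", v),
            "complement",
            _beta_direct(lambda p: p.achr_accuracy.specificity),
        ),
        UncertainParameter(
            "tft_sensitivity",
            lambda p: p.tft_accuracy.sensitivity,
            lambda p, v: _set_accuracy(p, "tft", "sensitivity", v),
            "complement",
            _beta_direct(lambda p: p.tft_accuracy.sensitivity),
        ),
        UncertainParameter(
            "tft_specificity",
            lambda p: p.tft_accuracy.specificity,
            lambda p, v: _set_accuracy(p, "tft", "specificity", v),
            "complement",
            _beta_direct(lambda p: p.tft_accuracy.specificity),
        ),
        UncertainParameter(
            "achr_test_cost",
            lambda p: p.costs.achr_ab_test,
            lambda p, v: _set_cost(p, "achr_ab_test", v),
            "cost",
            _gamma_cv(lambda p: p.costs.achr_ab_test),
        ),
        UncertainParameter(
            "tft_panel_cost",
            lambda p: p.costs.tft_panel,
            _set_tft_panel,
            "cost",
            _gamma_cv(lambda p: p.costs.tft_panel),
        ),
        UncertainParameter(
            "chest_ct_cost",
            lambda p: p.costs.chest_ct,
            lambda p, v: _set_cost(p, "chest_ct", v),
            "cost",
            _gamma_cv(lambda p: p.costs.chest_ct),
        ),
        UncertainParameter(
            "mri_cost",
            lambda p: p.costs.mri_brain_orbit,
            lambda p, v: _set_cost(p, "mri_brain_orbit", v),
            "cost",
            _gamma_cv(lambda p: p.costs.mri_brain_orbit),
        ),
        UncertainParameter(
            "followup_visit_cost",
            lambda p: p.costs.followup_visit,
            lambda p, v: _set_cost(p, "followup_visit", v),
            "cost",
            _gamma_cv(lambda p: p.costs.followup_visit),
        ),
        UncertainParameter(
            "utility_early_omg",
            lambda p: p.utilities.early_dx_omg,
            lambda p, v: _set_utility(p, ("early_dx_omg",), v),
            "complement",
            _beta_direct(lambda p: p.utilities.early_dx_omg),
        ),
        UncertainParameter(
            "utility_delayed_omg",
            lambda p: p.utilities.delayed_dx_omg,
            lambda p, v: _set_utility(p, ("delayed_dx_omg", "generalized_mg"), v),
            "complement",
            _beta_direct(lambda p: p.utilities.delayed_dx_omg),
        ),
        UncertainParameter(
            "utility_hypothyroid",
            lambda p: p.utilities.treated_hypothyroid,
            lambda p, v: _set_utility(p, ("treated_hypothyroid", "delayed_hypothyroid"), v),
            "complement",
            _beta_direct(lambda p: p.utilities.treated_hypothyroid),
        ),
        UncertainParameter(
            "utility_idiopathic",
            lambda p: p.utilities.idiopathic_ace,
            lambda p, v: _set_utility(p, ("idiopathic_ace",), v),
            "complement",
            _beta_direct(lambda p: p.utilities.idiopathic_ace),
        ),
    ]
    if include_transitions:
        for fld in (
            "background_mortality",
            "omg_to_generalized",
            "symptom_triggered_detection",
        ):
            reg.append(
                UncertainParameter(
                    f"transition_{fld}",
                    lambda p, fld=fld: getattr(p.transitions, fld),
                    lambda p, v, fld=fld: _set_transition(p, fld, v),
                    "direct",
                    _beta_direct(lambda p, fld=fld: getattr(p.transitions, fld)),
                )
            )
    return reg


# ---------------------------------------------------------------------------
# one-way DSA


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    nmb_low: float
    nmb_high: float

    @property
    def swing(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _incremental_nmb(params: ParameterSet, wtp: float, mode: str) -> float:
    non = ec.evaluate_strategy(params, "none", mode=mode)
    uni = ec.evaluate_strategy(params, "universal", mode=mode)
    return ec.net_monetary_benefit(uni.cost - non.cost, uni.qalys - non.qalys, wtp)


def one_way_dsa(
    params: ParameterSet,
    vary: Optional[Sequence[UncertainParameter | str]] = None,
    wtp: Optional[float] = None,
    mode: str = "accumulated",
) -> tuple[float, list[TornadoEntry]]:
    """One-way sensitivity analysis of universal-vs-none NMB.

    Returns ``(base_nmb, entries)`` with entries sorted by descending swing.
    ``vary`` accepts registry entries or their names; by default the full
    published parameter set is varied by the configured +/-20%.
    """
    registry = {p.name: p for p in default_registry(include_transitions=True)}
    if vary is None:
        chosen = [p for p in default_registry()]
    else:
        chosen = []
        for item in vary:
            if isinstance(item, UncertainParameter):
                chosen.append(item)
            elif item in registry:
                chosen.append(registry[item])
            else:
                raise KeyError(f"unknown parameter {item!r}")
    if wtp is None:
        wtp = params.settings.wtp_lower
    variation = params.settings.dsa_variation

    base_nmb = _incremental_nmb(params, wtp, mode)
    entries = []
    for up in chosen:
        lo, hi = up.dsa_range(params, variation)
        nmb_lo = _incremental_nmb(up.setter(params, lo), wtp, mode)
        nmb_hi = _incremental_nmb(up.setter(params, hi), wtp, mode)
        entries.append(TornadoEntry(up.name, lo, hi, nmb_lo, nmb_hi))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return base_nmb, entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Incremental cost/QALY cloud of universal screening vs no screening."""

    delta_cost: np.ndarray  # THB, cohort scale
    delta_qaly: np.ndarray
    draws: int
    seed: int
    accounting_mode: str
    parameter_names: tuple[str, ...]
    samples: dict[str, np.ndarray] = field(repr=False)

    @property
    def icers(self) -> np.ndarray:
        """Per-draw ICER; NaN where the QALY increment is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.delta_qaly != 0.0, self.delta_cost / self.delta_qaly, np.nan)

    def quadrant_shares(self) -> dict[str, float]:
        dc, dq = self.delta_cost, self.delta_qaly
        n = len(dc)
        return {
            "NE": float(np.mean((dq > 0) & (dc > 0))),
            "NW": float(np.mean((dq <= 0) & (dc > 0))),
            "SE": float(np.mean((dq > 0) & (dc <= 0))),
            "SW": float(np.mean((dq <= 0) & (dc <= 0))),
        } if n else {"NE": 0.0, "NW": 0.0, "SE": 0.0, "SW": 0.0}

    def ceac(self, lambda_grid: Sequence[float]) -> np.ndarray:
        return ceac(self, lambda_grid)

    def summary(self) -> dict[str, float]:
        finite = self.icers[np.isfinite(self.icers)]
        return {
            "mean_delta_cost": float(self.delta_cost.mean()),
            "mean_delta_qaly": float(self.delta_qaly.mean()),
            "mean_icer": float(finite.mean()) if finite.size else float("nan"),
            "median_icer": float(np.median(finite)) if finite.size else float("nan"),
            **{f"share_{k}": v for k, v in self.quadrant_shares().items()},
        }


def run_psa(
    params: ParameterSet,
    draws: Optional[int] = None,
    seed: int = 0,
    mode: str = "accumulated",
    registry: Optional[Sequence[UncertainParameter]] = None,
) -> PSAResult:
    """Monte-Carlo resampling of all stochastic parameters.

    Every parameter gets its own child random stream spawned from the root
    seed, so results are reproducible and adding a parameter does not
    perturb the draws of the others.
    """
    if draws is None:
        draws = params.settings.psa_draws
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if registry is None:
        registry = default_registry()

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(registry))
    samples: dict[str, np.ndarray] = {}
    for up, child in zip(registry, children):
        dist = up.psa_dist(params)
        samples[up.name] = dist.sample(np.random.default_rng(child), draws)

    delta_cost = np.empty(draws)
    delta_qaly = np.empty(draws)
    for i in range(draws):
        drawn = params
        for up in registry:
            drawn = up.setter(drawn, float(samples[up.name][i]))
        non = ec.evaluate_strategy(drawn, "none", mode=mode)
        uni = ec.evaluate_strategy(drawn, "universal", mode=mode)
        delta_cost[i] = uni.cost - non.cost
        delta_qaly[i] = uni.qalys - non.qalys

    return PSAResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        draws=draws,
        seed=seed,
        accounting_mode=mode,
        parameter_names=tuple(up.name for up in registry),
        samples=samples,
    )


def ceac(psa: PSAResult, lambda_grid: Sequence[float]) -> np.ndarray:
    """P(NMB(lambda) > 0) across the willingness-to-pay grid."""
    grid = np.asarray(list(lambda_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    nmb = grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return (nmb > 0).mean(axis=1)


def default_lambda_grid() -> np.ndarray:
    """0 to 500,000 THB/QALY in 10,000 steps."""
    return np.arange(0, 500_001, 10_000, dtype=float)


# ---------------------------------------------------------------------------
# two-way price-prevalence threshold analysis


@dataclass(frozen=True)
class ThresholdGrid:
    """ICER of universal screening over a price x prevalence grid."""

    price_grid: np.ndarray  # THB per antibody test
    prevalence_grid: np.ndarray
    icer: np.ndarray  # (len(prevalence_grid), len(price_grid)); NaN if dQ = 0
    cost_effective: np.ndarray  # bool mask at the analysis WTP
    wtp: float

    def price_threshold(self, prevalence: float) -> Optional[float]:
        """Highest grid price still cost-effective at a given prevalence."""
        row = int(np.argmin(np.abs(self.prevalence_grid - prevalence)))
        ok = self.cost_effective[row]
        if not ok.any():
            return None
        return float(self.price_grid[ok].max())

    def prevalence_threshold(self, price: float) -> Optional[float]:
        """Lowest grid prevalence that is cost-effective at a given price."""
        col = int(np.argmin(np.abs(self.price_grid - price)))
        ok = self.cost_effective[:, col]
        if not ok.any():
            return None
        return float(self.prevalence_grid[ok].min())


def default_price_grid() -> np.ndarray:
    return np.arange(0.0, 3001.0, 100.0)


def default_prevalence_grid() -> np.ndarray:
    return np.arange(0.005, 0.10001, 0.0025)


def two_way_threshold(
    params: ParameterSet,
    price_grid: Optional[Sequence[float]] = None,
    prevalence_grid: Optional[Sequence[float]] = None,
    wtp: Optional[float] = None,
    mode: str = "accumulated",
) -> ThresholdGrid:
    """Deterministic ICER surface over antibody-test price x MG prevalence.

    A cell is cost-effective when universal screening is dominant or its
    ICER falls below the willingness-to-pay threshold.
    """
    prices = np.asarray(
        default_price_grid() if price_grid is None else list(price_grid), dtype=float
    )
    prevs = np.asarray(
        default_prevalence_grid() if prevalence_grid is None else list(prevalence_grid),
        dtype=float,
    )
    if prices.size == 0 or prevs.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(prices) <= 0) or np.any(np.diff(prevs) <= 0):
        raise ValueError("grids must be strictly ascending")
    if wtp is None:
        wtp = params.settings.wtp_lower

    icer_grid = np.full((prevs.size, prices.size), np.nan)
    ce = np.zeros((prevs.size, prices.size), dtype=bool)
    for r, prev in enumerate(prevs):
        p_prev = _set_prev(params, "mg", float(prev))
        for c, price in enumerate(prices):
            p_cell = _set_cost(p_prev, "achr_ab_test", float(price))
            non = ec.evaluate_strategy(p_cell, "none", mode=mode)
            uni = ec.evaluate_strategy(p_cell, "universal", mode=mode)
            inc = ec.icer(non, uni)
            if inc.icer is not None:
                icer_grid[r, c] = inc.icer
            if inc.dominance == "dominant" or (inc.icer is not None and inc.icer < wtp):
                ce[r, c] = True
    return ThresholdGrid(
        price_grid=prices, prevalence_grid=prevs, icer=icer_grid, cost_effective=ce, wtp=wtp
    )
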