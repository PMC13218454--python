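"""Model inputs for the screening cost-utility analysis.

Every quantity the model reads lives in a :class:`ParameterSet`: disease
prevalences in the esotropia cohort, diagnostic accuracy of the two screening
tests (acetylcholine-receptor antibody serology and the thyroid function
panel), unit costs in 2024 Thai baht, health-state utilities, economic
settings (discounting, horizon, willingness-to-pay) and the annual Markov
transition probabilities.

Each numeric field carries a provenance label:

``paper``
    printed in the source cost-utility study (base case),
``default``
    chosen by this package because the study does not print a value,
``user``
    supplied by the caller through a parameter file or constructor.

Parameter files are YAML documents with nested sections mirroring the
dataclasses below; ``load_parameters`` validates every invariant and records
which fields fell back to defaults.  Probabilities may be written either as
proportions (``0.75``) or as explicit percent strings (``"75%"``) — bare
numbers above 1 are rejected so a percentage can never be mistaken for a
proportion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "TestAccuracy",
    "Prevalence",
    "CostTable",
    "UtilityTable",
    "EconomicSettings",
    "TransitionInputs",
    "ParameterSet",
    "load_parameters",
    "write_parameters",
    "load_default_parameters",
    "prevalence_from_counts",
]


class SchemaError(ValueError):
    """A required field is missing or a section is malformed."""


class ValidationError(ValueError):
    """A field value violates one of its invariants."""


def _as_probability(value: Any, name: str) -> float:
    """Coerce a YAML scalar to a probability in [0, 1].

    Accepts proportions and percent strings ("75%").  Bare numerics outside
    [0, 1] raise, which guards against silent 100x unit errors.
    """
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            try:
                value = float(text[:-1]) / 100.0
            except ValueError as exc:
                raise ValidationError(f"{name}: cannot parse percent string {value!r}") from exc
        else:
            try:
                value = float(text)
            except ValueError as exc:
                raise ValidationError(f"{name}: cannot parse {value!r}") from exc
    if not isinstance(value, (int, float)):
        raise ValidationError(f"{name}: expected a number, got {type(value).__name__}")
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(
            f"{name}: probability {value} outside [0, 1] "
            "(write percentages with an explicit '%' suffix)"
        )
    return value


def _check_nonnegative(value: float, name: str) -> float:
    value = float(value)
    if value < 0:
        raise ValidationError(f"{name}: must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity and specificity of one diagnostic test."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensitivity", _as_probability(self.sensitivity, "sensitivity"))
        object.__setattr__(self, "specificity", _as_probability(self.specificity, "specificity"))


@dataclass(frozen=True)
class Prevalence:
    """A disease prevalence, optionally backed by observed counts."""

    value: float
    source_count: Optional[tuple[int, int]] = None  # (cases, cohort size)

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", _as_probability(self.value, "prevalence"))
        if self.source_count is not None:
            cases, cohort = self.source_count
            if cohort <= 0:
                raise ValidationError("prevalence: cohort size must be positive")
            if not 0 <= cases <= cohort:
                raise ValidationError(
                    f"prevalence: cases ({cases}) must lie in [0, cohort={cohort}]"
                )
            # the stored value must agree with cases/cohort to printed precision
            if abs(self.value - cases / cohort) > 5e-4:
                raise ValidationError(
                    f"prevalence: value {self.value} inconsistent with counts "
                    f"{cases}/{cohort} = {cases / cohort:.4f}"
                )

    def render(self) -> str:
        """Percent string at the one-decimal precision used in reports."""
        return f"{100 * self.value:.1f}%"


def prevalence_from_counts(cases: int, cohort: int) -> Prevalence:
    """Build a :class:`Prevalence` from an observed case count.

    ``prevalence_from_counts(3, 110)`` gives 0.0273, rendered "2.7%".
    """
    if cohort <= 0:
        raise ValidationError("cohort size must be positive")
    if cases < 0 or cases > cohort:
        raise ValidationError(f"cases ({cases}) must lie in [0, cohort={cohort}]")
    return Prevalence(value=cases / cohort, source_count=(cases, cohort))


@dataclass(frozen=True)
class CostTable:
    """Unit costs in 2024 THB and the fixed follow-up visit schedule."""

    achr_ab_test: float = 1900.0
    tsh: float = 170.0
    ft3: float = 170.0
    ft4: float = 150.0
    chest_ct: float = 8200.0
    mri_brain_orbit: float = 16000.0
    followup_visit: float = 750.0
    visits_per_patient: int = 6  # two per year over three years
    annual_treatment_omg: float = 0.0
    annual_treatment_hypothyroid: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "visits_per_patient":
                if int(value) != value or value < 0:
                    raise ValidationError(
                        f"visits_per_patient must be a non-negative integer, got {value}"
                    )
                object.__setattr__(self, f.name, int(value))
            else:
                object.__setattr__(self, f.name, _check_nonnegative(value, f"costs.{f.name}"))

    @property
    def tft_panel(self) -> float:
        """Cost of the full thyroid panel (TSH + FT3 + FT4)."""
        return self.tsh + self.ft3 + self.ft4


@dataclass(frozen=True)
class UtilityTable:
    """Health-state utilities on the 0 (death) to 1 (full health) scale.

    ``missed_condition`` is the published weight for an underlying condition
    never suspected and managed as idiopathic esotropia; it is kept in the
    table for sensitivity work but the default Markov state mapping uses the
    delayed-diagnosis weights (see :mod:`acescreen.markov`).
    """

    early_dx_omg: float = 0.872
    delayed_dx_omg: float = 0.739
    treated_hypothyroid: float = 0.94
    delayed_hypothyroid: float = 0.94
    idiopathic_ace: float = 1.0
    missed_condition: float = 0.965
    generalized_mg: float = 0.739
    death: float = 0.0
    ted_severe: Optional[float] = None
    ted_mild: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            object.__setattr__(self, f.name, _as_probability(value, f"utilities.{f.name}"))
        if self.death != 0.0:
            raise ValidationError("utilities.death must be 0")
        if self.early_dx_omg < self.delayed_dx_omg:
            raise ValidationError(
                "utilities: early_dx_omg must be >= delayed_dx_omg "
                f"({self.early_dx_omg} < {self.delayed_dx_omg})"
            )


@dataclass(frozen=True)
class EconomicSettings:
    """Discounting, horizon, cohort scale and decision thresholds."""

    discount_rate_annual: float = 0.03
    horizon_years: int = 10
    cohort_size: int = 110
    wtp_lower: float = 160_000.0
    wtp_upper: float = 200_000.0
    targeted_fraction: float = 0.30
    psa_draws: int = 10_000
    dsa_variation: float = 0.20

    def __post_init__(self) -> None:
        if self.discount_rate_annual < 0:
            raise ValidationError("settings.discount_rate_annual must be >= 0")
        if self.horizon_years < 1:
            raise ValidationError("settings.horizon_years must be >= 1")
        if self.cohort_size < 1:
            raise ValidationError("settings.cohort_size must be >= 1")
        if not 0.0 <= self.targeted_fraction <= 1.0:
            raise ValidationError("settings.targeted_fraction must lie in [0, 1]")
        if self.psa_draws < 1:
            raise ValidationError("settings.psa_draws must be >= 1")
        if self.wtp_lower > self.wtp_upper:
            raise ValidationError("settings.wtp_lower must be <= wtp_upper")
        if self.dsa_variation < 0:
            raise ValidationError("settings.dsa_variation must be >= 0")


@dataclass(frozen=True)
class TransitionInputs:
    """Annual Markov transition probabilities.

    The study fixes the transition graph (stable / progression to generalized
    myasthenia / symptom-triggered detection / background death) but prints no
    rates, so every default here carries provenance ``default`` and is
    eligible for deterministic and probabilistic sensitivity analysis.
    """

    background_mortality: float = 0.005
    omg_to_generalized: float = 0.05
    incident_omg: float = 0.0
    incident_hypothyroid: float = 0.0
    symptom_triggered_detection: float = 0.25

    def __post_init__(self) -> None:
        for f in fields(self):
            object.__setattr__(
                self, f.name, _as_probability(getattr(self, f.name), f"transitions.{f.name}")
            )


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated input set for the cost-utility model."""

    prevalence_mg: Prevalence = field(
        default_factory=lambda: Prevalence(0.027, source_count=(3, 110))
    )
    prevalence_thyroid: Prevalence = field(
        default_factory=lambda: Prevalence(0.009, source_count=(1, 110))
    )
    achr_accuracy: TestAccuracy = field(default_factory=lambda: TestAccuracy(0.75, 0.98))
    tft_accuracy: TestAccuracy = field(default_factory=lambda: TestAccuracy(0.90, 0.92))
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    settings: EconomicSettings = field(default_factory=EconomicSettings)
    transitions: TransitionInputs = field(default_factory=TransitionInputs)
    provenance: dict = field(default_factory=dict, compare=False)

    def replace(self, **kwargs: Any) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def defaults_report(self) -> list[str]:
        """Names of fields whose value was not supplied by the user."""
        return sorted(k for k, v in self.provenance.items() if v in ("default", "paper"))


# canonical provenance of every base-case value: "paper" when the study prints
# the number, "default" when this package had to choose one
_PAPER_FIELDS = {
    "prevalence_mg",
    "prevalence_thyroid",
    "achr_accuracy.sensitivity",
    "achr_accuracy.specificity",
    "tft_accuracy.sensitivity",
    "tft_accuracy.specificity",
    "costs.achr_ab_test",
    "costs.tsh",
    "costs.ft3",
    "costs.ft4",
    "costs.chest_ct",
    "costs.mri_brain_orbit",
    "costs.followup_visit",
    "costs.visits_per_patient",
    "utilities.early_dx_omg",
    "utilities.delayed_dx_omg",
    "utilities.treated_hypothyroid",
    "utilities.delayed_hypothyroid",
    "utilities.idiopathic_ace",
    "utilities.missed_condition",
    "settings.discount_rate_annual",
    "settings.horizon_years",
    "settings.cohort_size",
    "settings.wtp_lower",
    "settings.wtp_upper",
    "settings.targeted_fraction",
    "settings.psa_draws",
    "settings.dsa_variation",
}

_SECTION_TYPES: dict[str, type] = {
    "costs": CostTable,
    "utilities": UtilityTable,
    "settings": EconomicSettings,
    "transitions": TransitionInputs,
}


def _default_provenance() -> dict[str, str]:
    prov: dict[str, str] = {}
    base = ParameterSet()
    for name, section in (
        ("achr_accuracy", base.achr_accuracy),
        ("tft_accuracy", base.tft_accuracy),
        ("costs", base.costs),
        ("utilities", base.utilities),
        ("settings", base.settings),
        ("transitions", base.transitions),
    ):
        for f in fields(section):
            key = f"{name}.{f.name}"
            prov[key] = "paper" if key in _PAPER_FIELDS else "default"
    prov["prevalence_mg"] = "paper"
    prov["prevalence_thyroid"] = "paper"
    return prov


def load_default_parameters() -> ParameterSet:
    """The base case exactly as printed in the source analysis, with
    package-chosen defaults (provenance ``default``) where it prints none."""
    return ParameterSet(provenance=_default_provenance())


def _prevalence_from_node(node: Any, name: str) -> Prevalence:
    if isinstance(node, dict):
        counts = None
        if "cases" in node or "cohort" in node:
            try:
                counts = (int(node["cases"]), int(node["cohort"]))
            except KeyError as exc:
                raise SchemaError(f"{name}: counts need both 'cases' and 'cohort'") from exc
        if "value" in node:
            return Prevalence(_as_probability(node["value"], name), source_count=counts)
        if counts is not None:
            return prevalence_from_counts(*counts)
        raise SchemaError(f"{name}: needs 'value' or ('cases', 'cohort')")
    return Prevalence(_as_probability(node, name))


def _accuracy_from_node(node: Any, name: str) -> TestAccuracy:
    if not isinstance(node, dict):
        raise SchemaError(f"{name}: expected a mapping with sensitivity/specificity")
    missing = {"sensitivity", "specificity"} - node.keys()
    if missing:
        raise SchemaError(f"{name}: missing required field(s) {sorted(missing)}")
    return TestAccuracy(node["sensitivity"], node["specificity"])


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a YAML parameter file.

    Omitted optional fields are filled from the base case and logged; a
    missing section simply takes all its defaults.  Raises
    :class:`SchemaError` for structural problems and
    :class:`ValidationError` for out-of-range values.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a mapping")

    canonical = _default_provenance()
    provenance: dict[str, str] = {}
    kwargs: dict[str, Any] = {}

    prev_section = doc.get("prevalence", {})
    if not isinstance(prev_section, dict):
        raise SchemaError("prevalence: expected a mapping")
    for key, param in (("mg", "prevalence_mg"), ("thyroid", "prevalence_thyroid")):
        if key in prev_section:
            kwargs[param] = _prevalence_from_node(prev_section[key], f"prevalence.{key}")
            provenance[param] = "user"
        else:
            provenance[param] = canonical[param]

    acc_section = doc.get("test_accuracy", {})
    if not isinstance(acc_section, dict):
        raise SchemaError("test_accuracy: expected a mapping")
    for key, param in (("achr_ab", "achr_accuracy"), ("tft", "tft_accuracy")):
        if key in acc_section:
            kwargs[param] = _accuracy_from_node(acc_section[key], f"test_accuracy.{key}")
            provenance[f"{param}.sensitivity"] = "user"
            provenance[f"{param}.specificity"] = "user"
        else:
            provenance[f"{param}.sensitivity"] = canonical[f"{param}.sensitivity"]
            provenance[f"{param}.specificity"] = canonical[f"{param}.specificity"]

    for section_name, cls in _SECTION_TYPES.items():
        node = doc.get(section_name, {})
        if not isinstance(node, dict):
            raise SchemaError(f"{section_name}: expected a mapping")
        node = dict(node)
        if section_name == "costs" and "annual_treatment" in node:
            treat = node.pop("annual_treatment")
            if not isinstance(treat, dict):
                raise SchemaError("costs.annual_treatment: expected a mapping")
            for k, v in treat.items():
                node[f"annual_treatment_{k}"] = v
        known = {f.name for f in fields(cls)}
        unknown = set(node) - known
        if unknown:
            raise SchemaError(f"{section_name}: unknown field(s) {sorted(unknown)}")
        section_kwargs = {}
        for f in fields(cls):
            key = f"{section_name}.{f.name}"
            if f.name in node:
                section_kwargs[f.name] = node[f.name]
                provenance[key] = "user"
            else:
                provenance[key] = canonical[key]
        kwargs[section_name if section_name != "transitions" else "transitions"] = cls(
            **section_kwargs
        )

    ps = ParameterSet(provenance=provenance, **kwargs)
    defaulted = ps.defaults_report()
    if defaulted:
        logger.info(
            "parameter file %s: %d field(s) filled with documented defaults: %s",
            path,
            len(defaulted),
            ", ".join(defaulted),
        )
    return ps


def _parameter_set_to_doc(ps: ParameterSet) -> dict:
    def prev_node(p: Prevalence) -> dict:
        node: dict[str, Any] = {"value": p.value}
        if p.source_count is not None:
            node["cases"], node["cohort"] = p.source_count
        return node

    doc: dict[str, Any] = {
        "prevalence": {
            "mg": prev_node(ps.prevalence_mg),
            "thyroid": prev_node(ps.prevalence_thyroid),
        },
        "test_accuracy": {
            "achr_ab": dataclasses.asdict(ps.achr_accuracy),
            "tft": dataclasses.asdict(ps.tft_accuracy),
        },
    }
    for section_name in _SECTION_TYPES:
        section = getattr(ps, section_name)
        node = {
            f.name: getattr(section, f.name)
            for f in fields(section)
            if getattr(section, f.name) is not None
        }
        doc[section_name] = node
    return doc


def write_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Serialize a :class:`ParameterSet` to YAML (round-trips with
    :func:`load_parameters` field-by-field)."""
    doc = _parameter_set_to_doc(ps)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
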