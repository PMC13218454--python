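"""Synthetic patient-level cohorts with the structure of the study sample.

The generator emulates the published cohort margins: 110 patients, equal sex
split, esotropia type split 7.2 / 46.4 / 46.4% (types 1-3), age from a
normal(30.3, 20.5) truncated to [3, 84] years, ocular-myasthenia prevalence
2.7% and thyroid-dysfunction prevalence 0.9% (mutually exclusive), and test
results drawn from true status through each test's sensitivity/specificity.
Refraction (spherical equivalent, diopters) and symptom-onset duration are
cosmetic covariates matched to the printed mean/median/range through
log-skewed families; the economic model never reads them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import ParameterSet, Prevalence, load_default_parameters

__all__ = [
    "COLUMNS",
    "CohortSummary",
    "generate_cohort",
    "summarize_cohort",
    "empirical_prevalence_recovery",
    "write_cohort",
    "read_cohort",
]

COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "ace_type",
    "true_mg",
    "true_thyroid",
    "achr_ab_positive",
    "tft_abnormal",
    "refraction_se_diopters",
    "onset_duration_years",
)

ACE_TYPE_PROBS = (0.072, 0.464, 0.464)
AGE_MEAN, AGE_SD, AGE_LO, AGE_HI = 30.3, 20.5, 3.0, 84.0

# refraction: SE = 3 - X with X lognormal matched to median -0.50 D and
# mean -1.90 D; onset duration lognormal matched to median 1.75 / mean 2.87 y
_REFRACTION_OFFSET = 3.0
_REFRACTION_MU = float(np.log(_REFRACTION_OFFSET + 0.50))
_REFRACTION_SIGMA = float(np.sqrt(2.0 * np.log((_REFRACTION_OFFSET + 1.90) / (_REFRACTION_OFFSET + 0.50))))
_REFRACTION_LO, _REFRACTION_HI = -24.0, 3.0
_ONSET_MU = float(np.log(1.75))
_ONSET_SIGMA = float(np.sqrt(2.0 * np.log(2.87 / 1.75)))
_ONSET_LO, _ONSET_HI = 0.01, 30.0


def generate_cohort(
    n: int, params: ParameterSet | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` synthetic patients; reproducible for a given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = load_default_parameters()
    rng = np.random.default_rng(seed)

    sex = rng.choice(np.array(["F", "M"]), size=n, p=[0.5, 0.5])
    ace_type = rng.choice(np.array([1, 2, 3]), size=n, p=ACE_TYPE_PROBS)

    a = (AGE_LO - AGE_MEAN) / AGE_SD
    b = (AGE_HI - AGE_MEAN) / AGE_SD
    age = stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=AGE_MEAN, scale=AGE_SD)

    # mutually exclusive disease statuses from one uniform draw
    m = params.prevalence_mg.value
    h = params.prevalence_thyroid.value
    if m + h > 1.0:
        raise ValueError("prevalences sum above 1")
    u = rng.uniform(size=n)
    true_mg = u < m
    true_thyroid = (u >= m) & (u < m + h)

    se_a, sp_a = params.achr_accuracy.sensitivity, params.achr_accuracy.specificity
    se_t, sp_t = params.tft_accuracy.sensitivity, params.tft_accuracy.specificity
    achr = np.where(true_mg, rng.uniform(size=n) < se_a, rng.uniform(size=n) < 1.0 - sp_a)
    tft = np.where(true_thyroid, rng.uniform(size=n) < se_t, rng.uniform(size=n) < 1.0 - sp_t)

    refraction = _REFRACTION_OFFSET - rng.lognormal(_REFRACTION_MU, _REFRACTION_SIGMA, size=n)
    refraction = np.clip(refraction, _REFRACTION_LO, _REFRACTION_HI)
    onset = np.clip(rng.lognormal(_ONSET_MU, _ONSET_SIGMA, size=n), _ONSET_LO, _ONSET_HI)

    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "sex": sex,
            "age_years": np.round(age, 1),
            "ace_type": ace_type,
            "true_mg": true_mg,
            "true_thyroid": true_thyroid,
            "achr_ab_positive": achr.astype(bool),
            "tft_abnormal": tft.astype(bool),
            "refraction_se_diopters": np.round(refraction, 2),
            "onset_duration_years": np.round(onset, 2),
        }
    )


@dataclass(frozen=True)
class CohortSummary:
    n: int
    female: int
    male: int
    type_counts: dict[int, int]
    achr_positive: int
    tft_abnormal: int
    age_mean: float
    age_sd: float
    age_median: float
    refraction_mean: float
    refraction_sd: float

    def render(self) -> str:
        lines = [
            f"N = {self.n}",
            f"Sex: Female {self.female} ({100 * self.female / self.n:.1f}%), "
            f"Male {self.male} ({100 * self.male / self.n:.1f}%)",
            "Type of ACE: "
            + ", ".join(
                f"Type {t}: {c} ({100 * c / self.n:.1f}%)"
                for t, c in sorted(self.type_counts.items())
            ),
            f"AChR-Ab positive: {self.achr_positive} ({100 * self.achr_positive / self.n:.1f}%)",
            f"Abnormal TFT: {self.tft_abnormal} ({100 * self.tft_abnormal / self.n:.1f}%)",
            f"Age (years): mean {self.age_mean:.1f} +/- {self.age_sd:.1f}, "
            f"median {self.age_median:.1f}",
            f"Refraction (D): mean {self.refraction_mean:.2f} +/- {self.refraction_sd:.2f}",
        ]
        return "\n".join(lines)


def summarize_cohort(patients: pd.DataFrame) -> CohortSummary:
    """Exact counts and moments of a patient table."""
    if len(patients) == 0:
        raise ValueError("cohort is empty")
    n = len(patients)
    type_counts = patients["ace_type"].value_counts().to_dict()
    return CohortSummary(
        n=n,
        female=int((patients["sex"] == "F").sum()),
        male=int((patients["sex"] == "M").sum()),
        type_counts={int(k): int(v) for k, v in sorted(type_counts.items())},
        achr_positive=int(patients["achr_ab_positive"].sum()),
        tft_abnormal=int(patients["tft_abnormal"].sum()),
        age_mean=float(patients["age_years"].mean()),
        age_sd=float(patients["age_years"].std(ddof=1)) if n > 1 else 0.0,
        age_median=float(patients["age_years"].median()),
        refraction_mean=float(patients["refraction_se_diopters"].mean()),
        refraction_sd=float(patients["refraction_se_diopters"].std(ddof=1)) if n > 1 else 0.0,
    )


def _wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def empirical_prevalence_recovery(patients: pd.DataFrame) -> dict[str, dict]:
    """Point estimates and Wilson 95% intervals for true-status prevalence
    and raw test-positivity (the two notions the source table conflates)."""
    if len(patients) == 0:
        raise ValueError("cohort is empty")
    n = len(patients)
    out = {}
    for name, column in (
        ("mg_prevalence", "true_mg"),
        ("thyroid_prevalence", "true_thyroid"),
        ("achr_positivity", "achr_ab_positive"),
        ("tft_abnormal_rate", "tft_abnormal"),
    ):
        k = int(patients[column].sum())
        lo, hi = _wilson_interval(k, n)
        out[name] = {
            "estimate": Prevalence(k / n, source_count=(k, n)),
            "count": k,
            "n": n,
            "ci95": (lo, hi),
        }
    return out


def write_cohort(patients: pd.DataFrame, path: str | Path) -> None:
    patients.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing column(s): {sorted(missing)}")
    return df
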