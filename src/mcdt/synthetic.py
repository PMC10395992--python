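"""Synthetic dual-task cohorts with the structure the analysis assumes.

The generator emulates a memory-clinic cohort of older adults split into
cognitively normal (CNA), subjective cognitive impairment (SCI), and mild
cognitive impairment (MCI) groups, by default 10/17/17 subjects. Each
subject carries a complete 32-feature x 4-load motor block (8 FTAP, 8
TTHP, 16 GAIT features) plus correct-response counts at loads 1-3, an
age, a Frontal Assessment Battery score, sex, and education level.

Generative model, per subject j with class severity sev in {0, 1, 2}
(CNA/SCI/MCI) and latent frailty u_j ~ N(0, 1):

* baseline feature  f_i(CL_0) ~ N(mu_i, 0.1 mu_i), floored away from 0;
* fractional load degradation
      d = k*load_slope + k*effect_size*sev*noise_sd
          + noise_sd*(0.5 u_j + sqrt(0.75) eps),   eps ~ N(0, 1),
  so that within a load the adjacent-class separation of d is about
  ``k * effect_size`` residual standard deviations, and the shared u_j
  term induces realistic positive correlation between features;
* dual-task value  f_i(CL_k) = f_i(CL_0) * (1 -/+ d)  with the sign set
  by the feature's orientation (half the features are generated
  "higher is better", half "higher is worse");
* correct responses  Nc ~ round(N(m, sd)) truncated at 0, with mean
  m = base[k] * (1 - class_drop*effect_size*sev - 0.1 u_j) shrinking
  with load (fewer responses counting by sevens than by ones) and with
  impairment.

Ages and FAB scores are drawn per class to match a typical memory-clinic
cohort (CNA younger, FAB ordered CNA > SCI > MCI with an 18-point
ceiling). With ``effect_size = 0`` the motor and count distributions are
identical across classes, giving an exact null for the downstream
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import (
    CLASSES,
    EXERCISES,
    FEATURE_IDS,
    TASK_LOADS,
    FeatureTable,
    SubjectRecord,
    exercise_of,
)

_SEVERITY = {"CNA": 0, "SCI": 1, "MCI": 2}

#: frailty loading shared across a subject's features (induces
#: inter-feature correlation of about 0.25 in the degradation noise)
_FRAILTY_SHARE = 0.5

_SEX_P_FEMALE = {"CNA": 0.60, "SCI": 0.41, "MCI": 0.76}
_EDUCATION_P = {
    "CNA": {"Primary": 0.0, "Secondary": 0.2, "Superior": 0.8},
    "SCI": {"Primary": 0.06, "Secondary": 0.23, "Superior": 0.71},
    "MCI": {"Primary": 0.18, "Secondary": 0.35, "Superior": 0.47},
}


class CohortSpecError(ValueError):
    """A cohort specification field is invalid."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` is the class separation of dual-task degradation in
    residual-SD units per load step (0 = exchangeable null);
    ``load_slope`` the mean fractional worsening per load step common to
    all classes; ``noise_sd`` the residual SD of fractional degradation.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"CNA": 10, "SCI": 17, "MCI": 17}
    )
    effect_size: float = 1.0
    load_slope: float = 0.05
    noise_sd: float = 0.05
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CNA": (63.0, 6.0), "SCI": (72.0, 9.0), "MCI": (73.0, 9.0)}
    )
    fab_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CNA": (17.8, 0.8), "SCI": (17.0, 1.0), "MCI": (15.0, 1.2)}
    )
    count_params: dict = field(
        default_factory=lambda: {"base": {1: 20.0, 2: 12.0, 3: 6.0}, "sd": 3.0, "class_drop": 0.15}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_class) - set(CLASSES)
        if unknown:
            raise CohortSpecError(f"n_per_class: unknown class labels {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_class.values()):
            raise CohortSpecError("n_per_class: counts must be >= 0")
        if self.effect_size < 0:
            raise CohortSpecError(f"effect_size: must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise CohortSpecError(f"noise_sd: must be > 0, got {self.noise_sd}")
        for name, params in (("age_params", self.age_params), ("fab_params", self.fab_params)):
            for cls, (loc, scale) in params.items():
                if cls not in CLASSES:
                    raise CohortSpecError(f"{name}: unknown class {cls!r}")
                if scale <= 0:
                    raise CohortSpecError(f"{name}: scale for {cls} must be > 0")
        cp = self.count_params
        if set(cp.get("base", {})) != set(TASK_LOADS):
            raise CohortSpecError(f"count_params: 'base' must give a mean for loads {TASK_LOADS}")
        if cp.get("sd", 0) <= 0:
            raise CohortSpecError("count_params: 'sd' must be > 0")

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """A generated cohort: subject records, feature table, and the truth."""

    subjects: list[SubjectRecord]
    features: FeatureTable
    truth: dict

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            {r.subject_id: r.diagnosis for r in self.subjects}, name="diagnosis"
        )


def feature_orientation() -> dict[str, bool]:
    """Generated orientation metadata: alternate higher-is-better flags.

    Half of the features are oriented "higher raw value = better
    functioning" (e.g. tapping frequency), half the opposite (e.g. stride
    duration variability), exercising the orientation stage downstream.
    """
    return {f: (i % 2 == 0) for i, f in enumerate(FEATURE_IDS)}


def _baseline_mean(idx: int) -> float:
    # deterministic per-feature scale, spanning an order of magnitude so
    # candidate variables genuinely differ in range
    return 10.0 * (1 + (idx * 3) % 8)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a complete synthetic cohort. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    orientation = feature_orientation()

    subjects: list[SubjectRecord] = []
    sev_list: list[int] = []
    for cls in CLASSES:
        n = spec.n_per_class.get(cls, 0)
        loc_a, sc_a = spec.age_params[cls]
        loc_f, sc_f = spec.fab_params[cls]
        for _ in range(n):
            sid = f"S{len(subjects) + 1:02d}"
            age = float(np.clip(rng.normal(loc_a, sc_a), 45.0, 95.0))
            fab = int(np.clip(np.round(rng.normal(loc_f, sc_f)), 0, 18))
            sex = "F" if rng.random() < _SEX_P_FEMALE[cls] else "M"
            edu_p = _EDUCATION_P[cls]
            education = str(rng.choice(list(edu_p), p=list(edu_p.values())))
            subjects.append(
                SubjectRecord(subject_id=sid, age=round(age, 1), fab=fab, diagnosis=cls, sex=sex, education=education)
            )
            sev_list.append(_SEVERITY[cls])

    n_sub = len(subjects)
    sev = np.array(sev_list, dtype=float)
    frailty = rng.normal(0.0, 1.0, size=n_sub)

    rows = []
    for fi, feat in enumerate(FEATURE_IDS):
        ex = exercise_of(feat)
        mu = _baseline_mean(fi)
        f0 = np.maximum(rng.normal(mu, 0.1 * mu, size=n_sub), 0.2 * mu)
        sign = -1.0 if orientation[feat] else 1.0  # degradation direction
        for s_idx, rec in enumerate(subjects):
            rows.append((rec.subject_id, ex, 0, feat, float(f0[s_idx])))
        for k in TASK_LOADS:
            eps = rng.normal(0.0, 1.0, size=n_sub)
            d = (
                k * spec.load_slope
                + k * spec.effect_size * sev * spec.noise_sd
                + spec.noise_sd
                * (_FRAILTY_SHARE * frailty + np.sqrt(1 - _FRAILTY_SHARE**2) * eps)
            )
            fk = f0 * np.maximum(1.0 + sign * d, 0.05)
            for s_idx, rec in enumerate(subjects):
                rows.append((rec.subject_id, ex, k, feat, float(fk[s_idx])))

    cp = spec.count_params
    count_rows = []
    for ex in EXERCISES:
        for k in TASK_LOADS:
            m = cp["base"][k] * np.clip(
                1.0 - cp["class_drop"] * spec.effect_size * sev - 0.1 * frailty, 0.05, None
            )
            nc = np.maximum(0, np.round(rng.normal(m, cp["sd"]))).astype(int)
            for s_idx, rec in enumerate(subjects):
                count_rows.append((rec.subject_id, ex, k, int(nc[s_idx])))

    features = FeatureTable(
        values=pd.DataFrame(rows, columns=["subject", "exercise", "load", "feature", "value"]),
        counts=pd.DataFrame(count_rows, columns=["subject", "exercise", "load", "nc"]),
        orientation=orientation,
    )
    truth = {"spec": spec.to_dict(), "frailty": {r.subject_id: float(u) for r, u in zip(subjects, frailty)}}
    return SyntheticCohort(subjects=subjects, features=features, truth=truth)


def cohort_to_tables(cohort: SyntheticCohort) -> tuple[FeatureTable, list[SubjectRecord]]:
    """Unpack a cohort into the exact schema the I/O layer consumes."""
    return cohort.features, cohort.subjects
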