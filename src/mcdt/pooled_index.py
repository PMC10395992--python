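"""Pooled-index (PI) construction by correlation-screened selection.

A pooled index summarizes a subject's dual-task degradation in one
number. Candidate variables are the weighted dual-task costs (DTC*) of
the motor features; five indices are built: one per exercise (FTAP,
TTHP, GAIT), TAPPING pooling both tapping tasks, and TOTAL pooling all
three exercises.

Selection proceeds by iterative elimination until at most
``max_components`` candidates remain that are mutually weakly
correlated (all pairwise Spearman |rho| below the threshold, default
0.4). At each step one candidate is deleted by the first applicable
criterion:

1. stop if the candidate set is small enough and mutually uncorrelated;
2. delete the single candidate with the largest number of
   above-threshold correlations to others;
3. on a tie, delete the tied candidate with the weakest class
   separation (smallest maximum pairwise Cohen's |d| over the CNA/SCI/
   MCI pairs);
4. on a further tie, fall back to a user-supplied priority list of
   identities to drop (standing in for clinical judgement), then to the
   lexicographically smallest identity, loudly logged.

The retained components are oriented so that a higher value always
means better functioning, normalized (min-max to [0, 1] by default),
and averaged with equal weights into the final per-subject score.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CLASSES, EXERCISES, exercise_of
from .dtc import DTCTable

#: The five indices, keyed by the exercises they pool.
PI_NAMES: dict[str, tuple[str, ...]] = {
    "FTAP": ("FTAP",),
    "TTHP": ("TTHP",),
    "GAIT": ("GAIT",),
    "TAPPING": ("FTAP", "TTHP"),
    "TOTAL": ("FTAP", "TTHP", "GAIT"),
}


@dataclass
class SelectionConfig:
    """Controls of the elimination procedure and of PI scoring."""

    rho_threshold: float = 0.4
    max_components: int = 6
    tie_break_manual: tuple[str, ...] = ()
    candidate_mode: str = "per_load"  # or "load_averaged"
    normalization: str = "minmax"  # or "zscore"

    def __post_init__(self) -> None:
        if not (0 < self.rho_threshold < 1):
            raise ValueError(f"rho_threshold must be in (0, 1), got {self.rho_threshold}")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if self.candidate_mode not in ("per_load", "load_averaged"):
            raise ValueError(f"unknown candidate_mode {self.candidate_mode!r}")
        if self.normalization not in ("minmax", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PooledIndexModel:
    """A fitted pooled index: components, orientations, normalization."""

    name: str
    components: list[str]
    signs: dict[str, int]
    norm_params: dict[str, tuple[float, float]]  # (lo, hi) or (mean, sd) of oriented values
    normalization: str
    audit_trail: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.name,
                "component": self.components,
                "sign": [self.signs[c] for c in self.components],
                "norm_lo_or_mean": [self.norm_params[c][0] for c in self.components],
                "norm_hi_or_sd": [self.norm_params[c][1] for c in self.components],
                "normalization": self.normalization,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "components": self.components,
                "signs": self.signs,
                "norm_params": {k: list(v) for k, v in self.norm_params.items()},
                "normalization": self.normalization,
                "audit_trail": self.audit_trail,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, blob: str) -> "PooledIndexModel":
        d = json.loads(blob)
        return cls(
            name=d["name"],
            components=list(d["components"]),
            signs={k: int(v) for k, v in d["signs"].items()},
            norm_params={k: (float(v[0]), float(v[1])) for k, v in d["norm_params"].items()},
            normalization=d["normalization"],
            audit_trail=list(d["audit_trail"]),
        )


@dataclass
class PooledIndexScores:
    """Per-subject scores for each fitted index (columns = index names)."""

    scores: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.scores.reset_index().rename(columns={"index": "subject"})


def candidate_id(feature: str, load: int | None) -> str:
    return feature if load is None else f"{feature}_CL{load}"


def candidate_feature(cid: str) -> str:
    """Feature identity behind a candidate id (strips any load suffix)."""
    return cid.rsplit("_CL", 1)[0] if "_CL" in cid else cid


def assemble_candidates(
    dtc: DTCTable,
    exercises: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Candidate matrix (subjects x DTC* variables) for the given exercises.

    ``per_load`` mode yields one candidate per (feature, load) pair;
    ``load_averaged`` averages DTC* over the three loads per feature.
    Cells flagged upstream (degenerate baselines) surface as NaN.
    """
    unknown = set(exercises) - set(EXERCISES)
    if unknown:
        raise ValueError(f"unknown exercises requested: {sorted(unknown)}")
    t = dtc.table[dtc.table["exercise"].isin(exercises)]
    if t.empty:
        raise ValueError(f"DTC table has no rows for exercises {list(exercises)}")
    if config.candidate_mode == "per_load":
        t = t.copy()
        t["candidate"] = t["feature"] + "_CL" + t["load"].astype(str)
        mat = t.pivot(index="subject", columns="candidate", values="dtc_star")
    else:
        mat = t.pivot_table(index="subject", columns="feature", values="dtc_star", aggfunc="mean")
    return mat.sort_index(axis=0).sort_index(axis=1)


def spearman_matrix(candidates: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation with average-rank tie handling.

    Uses pairwise-complete observations; a constant column's
    correlations are undefined (NaN) and are reported as such — the
    exceedance count treats them as above-threshold (worst case).
    """
    if candidates.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a rank correlation")
    if candidates.shape[1] < 2:
        raise ValueError("need at least 2 candidates")
    rho = candidates.corr(method="spearman", min_periods=3)
    np.fill_diagonal(rho.values, 1.0)
    constant = candidates.nunique(dropna=True) <= 1
    if constant.any():
        warnings.warn(
            f"constant candidate columns have undefined correlations: "
            f"{list(constant[constant].index)}",
            stacklevel=2,
        )
        for c in constant[constant].index:
            rho.loc[c, :] = np.nan
            rho.loc[:, c] = np.nan
            rho.loc[c, c] = 1.0
    return rho


def count_exceedances(rho: pd.DataFrame, threshold: float) -> pd.Series:
    """Per candidate, how many *other* candidates correlate at |rho| >= threshold.

    The boundary counts as exceeding (the keep condition is strict
    |rho| < threshold), with a 1e-9 guard so that rank correlations
    landing exactly on the threshold — exact rationals that different
    correlation routines round to opposite sides — are classified
    consistently. Undefined (NaN) correlations also count as exceeding,
    so uninformative candidates are eliminated rather than silently kept.
    """
    a = rho.to_numpy(dtype=float).copy()
    if a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrix must be square")
    np.fill_diagonal(a, np.nan)
    exceed = np.isnan(a)
    with np.errstate(invalid="ignore"):
        exceed |= np.abs(a) >= threshold - 1e-9
    np.fill_diagonal(exceed, False)
    return pd.Series(exceed.sum(axis=1), index=rho.index, name="n_exceed")


def cohens_d(values_a, values_b) -> float:
    """Cohen's d with the pooled (n-1)-weighted standard deviation."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values for Cohen's d")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 == 0:
        warnings.warn("zero pooled SD; Cohen's d set to 0", stacklevel=2)
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def _class_effect_size(values: pd.Series, labels: pd.Series) -> float:
    """Class-discriminating strength: max pairwise |d| over class pairs."""
    present = [c for c in CLASSES if (labels == c).sum() >= 2]
    if len(present) < 2:
        raise ValueError(
            "criterion-3 effect size needs at least two classes with >= 2 subjects"
        )
    best = 0.0
    for ca, cb in combinations(present, 2):
        best = max(best, abs(cohens_d(values[labels == ca], values[labels == cb])))
    return best


def select_components(
    candidates: pd.DataFrame,
    labels: pd.Series,
    config: SelectionConfig = SelectionConfig(),
    name: str = "PI",
    signs: Mapping[str, int] | None = None,
) -> PooledIndexModel:
    """Iterative elimination per the four selection criteria.

    ``labels`` maps subject -> diagnosis and must align with the
    candidate matrix rows. ``signs`` optionally maps candidate id to
    +1/-1 orientation (+1 = higher value is better functioning); default
    +1. Normalization parameters are fitted here on the full candidate
    matrix; use :func:`fit_normalization` to refit on a subset.
    """
    labels = labels.reindex(candidates.index)
    if labels.isna().any():
        raise ValueError("labels missing for some subjects in the candidate matrix")
    current = list(candidates.columns)
    signs = {c: int((signs or {}).get(c, 1)) for c in current}
    trail: list[dict] = []
    step = 0
    # deleting a candidate leaves the pairwise correlations of the others
    # unchanged, so the matrix is computed once and subset thereafter
    rho_full = spearman_matrix(candidates) if len(current) > 1 else None
    while len(current) > 1:
        rho = rho_full.loc[current, current]
        n_exceed = count_exceedances(rho, config.rho_threshold)
        if len(current) <= config.max_components and (n_exceed == 0).all():
            trail.append({"step": step, "action": "stop", "reason": "<=max_components and all |rho| below threshold"})
            break
        tied = n_exceed[n_exceed == n_exceed.max()].index.tolist()
        if len(tied) == 1:
            victim, criterion, extra = tied[0], 2, {"n_exceed": int(n_exceed[tied[0]])}
        else:
            es = {c: _class_effect_size(candidates[c], labels) for c in tied}
            weakest = min(es.values())
            es_tied = sorted(c for c, v in es.items() if v == weakest)
            if len(es_tied) == 1:
                victim, criterion, extra = es_tied[0], 3, {"effect_size": es[es_tied[0]]}
            else:
                manual = [c for c in config.tie_break_manual if c in es_tied]
                if manual:
                    victim, criterion, extra = manual[0], 4, {"tie_break": "manual"}
                else:
                    victim = sorted(es_tied)[0]
                    criterion, extra = 4, {"tie_break": "lexicographic"}
                    warnings.warn(
                        f"{name}: criterion-4 tie among {es_tied} resolved "
                        f"lexicographically -> dropping {victim}",
                        stacklevel=2,
                    )
            extra["n_exceed"] = int(n_exceed[victim])
        current.remove(victim)
        trail.append({"step": step, "action": "delete", "candidate": victim, "criterion": criterion, **extra, "n_remaining": len(current)})
        step += 1
    else:
        trail.append({"step": step, "action": "stop", "reason": "single candidate remains"})
    model = PooledIndexModel(
        name=name,
        components=sorted(current),
        signs={c: signs[c] for c in sorted(current)},
        norm_params={},
        normalization=config.normalization,
        audit_trail=trail,
    )
    fit_normalization(model, candidates)
    return model


def fit_normalization(model: PooledIndexModel, candidates: pd.DataFrame) -> PooledIndexModel:
    """Fit per-component normalization statistics on (oriented) values."""
    for c in model.components:
        v = candidates[c] * model.signs[c]
        if model.normalization == "minmax":
            lo, hi = float(v.min()), float(v.max())
            model.norm_params[c] = (lo, hi)
        else:
            model.norm_params[c] = (float(v.mean()), float(v.std(ddof=1)))
    return model


def score_pi(model: PooledIndexModel, candidates: pd.DataFrame) -> PooledIndexScores:
    """Per-subject PI: orient, normalize, and average the components.

    A subject missing any component value gets a missing PI (excluded
    from downstream models rather than silently imputed).
    """
    missing = [c for c in model.components if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidate matrix lacks model components: {missing}")
    normed = {}
    for c in model.components:
        v = candidates[c] * model.signs[c]
        p, q = model.norm_params[c]
        if model.normalization == "minmax":
            normed[c] = ((v - p) / (q - p)).clip(0.0, 1.0) if q > p else pd.Series(0.5, index=v.index)
        else:
            normed[c] = (v - p) / q if q > 0 else pd.Series(0.0, index=v.index)
    nd = pd.DataFrame(normed)
    pi = nd.mean(axis=1, skipna=False)
    n_missing = int(pi.isna().sum())
    if n_missing:
        warnings.warn(f"{model.name}: PI missing for {n_missing} subject(s)", stacklevel=2)
    return PooledIndexScores(scores=pi.to_frame(model.name))


def candidate_signs(columns: Sequence[str], orientation: Mapping[str, bool]) -> dict[str, int]:
    """Orientation sign of each DTC* candidate from its feature's polarity.

    For a "higher is better" feature a larger (less negative) cost means
    better-preserved functioning (sign +1); for a "higher is worse"
    feature an *increase* under load is degradation, so the sign flips.
    """
    out = {}
    for c in columns:
        feat = candidate_feature(c)
        if feat not in orientation:
            raise ValueError(f"no orientation metadata for feature {feat!r}")
        out[c] = 1 if orientation[feat] else -1
    return out


def build_all_pis(
    dtc: DTCTable,
    labels: pd.Series,
    config: SelectionConfig = SelectionConfig(),
    orientation: Mapping[str, bool] | None = None,
) -> tuple[dict[str, PooledIndexModel], PooledIndexScores]:
    """Fit the five pooled indices and score every subject on each.

    ``orientation`` defaults to the DTC table's effective (post-recoding)
    polarity map, under which every candidate is already higher-is-better.
    """
    if orientation is None and getattr(dtc, "effective_orientation", None):
        orientation = dtc.effective_orientation
    models: dict[str, PooledIndexModel] = {}
    cols = []
    for name, exercises in PI_NAMES.items():
        cand = assemble_candidates(dtc, exercises, config)
        signs = candidate_signs(cand.columns, orientation) if orientation else None
        model = select_components(cand, labels, config, name=name, signs=signs)
        models[name] = model
        cols.append(score_pi(model, cand).scores)
    scores = pd.concat(cols, axis=1)
    return models, PooledIndexScores(scores=scores)
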