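"""Dual-task cost (DTC) and its commitment-weighted variant DTC*.

The classical dual-task cost of a motor feature is its percent change
under cognitive load relative to the single-task baseline:

    DTC = (f(CL_k) - f(CL_0)) / f(CL_0) * 100 .

DTC alone ignores the cognitive side of the dual task: a subject who
simply stops counting shows an unchanged motor feature and a DTC near 0%,
indistinguishable from genuinely intact performance. The weighted variant
multiplies the dual-task feature value by a bounded rescaling of the
subject's correct-response count Nc before the cost is computed, so that
low cognitive commitment/efficiency drags the weighted cost towards
-100% instead of leaving it at 0%:

    Zc   = (b - a) * (Nc - min Nc) / (max Nc - min Nc) + a,   a=0.01, b=1,
    f*   = f(CL_k) * Zc,
    DTC* = (f* - f(CL_0)) / f(CL_0) * 100 ,

with the min/max of Nc taken across subjects separately for each
(exercise, load) condition, and the baseline left unweighted (no
cognitive task exists at CL_0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import TASK_LOADS, FeatureTable


class DegenerateBaselineError(ValueError):
    """Percent change is undefined for a zero baseline value."""


@dataclass(frozen=True)
class RescaleBounds:
    """Bounds of the rescaled response-count weight.

    ``a`` (default 0.01) keeps weights away from zero; ``b`` (default 1)
    makes the best counter's dual-task feature pass through unweighted.
    """

    a: float = 0.01
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.a < self.b):
            raise ValueError(f"require 0 < a < b, got a={self.a}, b={self.b}")


@dataclass
class DTCTable:
    """Per-cell classical and weighted dual-task costs.

    ``table`` holds one row per (subject, exercise, load >= 1, feature)
    with columns dtc, zc, f_star, dtc_star. ``flagged`` lists cells
    excluded for a degenerate (zero or unusable) baseline. ``recoded``
    names the features that were reciprocal-recoded to the
    higher-is-better orientation before the cost computation;
    ``effective_orientation`` is the post-recoding polarity map (True
    for every recoded feature).
    """

    table: pd.DataFrame
    bounds: RescaleBounds = field(default_factory=RescaleBounds)
    flagged: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["subject", "exercise", "load", "feature", "reason"]))
    recoded: frozenset = frozenset()
    effective_orientation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.table[~self.table["load"].isin(TASK_LOADS)]
        if len(bad):
            raise ValueError("DTC is defined only for loads >= 1")
        zc = self.table["zc"].to_numpy()
        if len(zc) and (np.nanmin(zc) < self.bounds.a - 1e-12 or np.nanmax(zc) > self.bounds.b + 1e-12):
            raise ValueError("rescaled weights escape the [a, b] bounds")


def compute_dtc(task_value: float, baseline_value: float) -> float:
    """Classical dual-task cost: percent change from baseline.

    Raises :class:`DegenerateBaselineError` for a zero baseline rather
    than returning an infinity.
    """
    if baseline_value == 0:
        raise DegenerateBaselineError("baseline value is 0; percent change undefined")
    return (task_value - baseline_value) / baseline_value * 100.0


def rescale_counts(nc, bounds: RescaleBounds = RescaleBounds()) -> np.ndarray:
    """Bounded min-max rescaling of correct-response counts.

    Maps the cohort's minimum count to ``a`` and maximum to ``b`` by an
    affine transform; despite being the weight's historical name of a
    "Z-scored" count, this is a bounded rescaling, not a standardization.
    All-equal counts are mapped to ``b`` (uniform performance treated as
    full commitment, keeping DTC* = DTC in the uninformative case).
    """
    nc = np.asarray(nc, dtype=float)
    if nc.size == 0:
        raise ValueError("empty count vector")
    if (nc < 0).any():
        raise ValueError("counts must be nonnegative")
    lo, hi = nc.min(), nc.max()
    if hi == lo:
        warnings.warn("all counts equal; weights set to the upper bound", stacklevel=2)
        return np.full(nc.shape, bounds.b)
    w = (bounds.b - bounds.a) * (nc - lo) / (hi - lo) + bounds.a
    # the extremes attain the bounds exactly by definition; snap them so
    # rounding in the affine map cannot leave them epsilon short
    w[nc == lo] = bounds.a
    w[nc == hi] = bounds.b
    return w


def weight_feature(f, zc, load: int | None = None):
    """Commitment-weighted feature value ``f* = f * Zc``.

    Defined only under a cognitive task (load >= 1); pass ``load`` to have
    the baseline misuse rejected explicitly.
    """
    if load is not None and load not in TASK_LOADS:
        raise ValueError(f"weighted feature undefined at load {load}: no cognitive task at baseline")
    return np.asarray(f, dtype=float) * np.asarray(zc, dtype=float)


def compute_dtc_star(
    features: FeatureTable,
    bounds: RescaleBounds = RescaleBounds(),
    orient_features: bool = True,
) -> DTCTable:
    """Compute classical DTC and weighted DTC* for every candidate cell.

    For each (exercise, load) condition the Nc vector over subjects is
    rescaled to [a, b]; each dual-task feature value is multiplied by the
    subject's weight and the cost computed against the *unweighted*
    baseline. Cells whose baseline is exactly zero are flagged and
    excluded (their dtc/dtc_star are NaN in the output).

    The weighting is only meaningful for variables where a *drop* means
    degradation: shrinking f* towards zero must read as "worse". With
    ``orient_features`` (default), features whose orientation metadata
    says "higher is worse" are therefore recoded as reciprocals (their
    values must be strictly positive; e.g. stride time -> cadence-like
    rate) so that every cost enters the pipeline with the
    higher-is-better polarity. Non-positive cells of such features are
    flagged and excluded.
    """
    features.check_complete()
    v = features.values
    recoded: frozenset = frozenset()
    extra_flags = []
    effective = dict(features.orientation)
    if orient_features:
        worse = {f for f, b in features.orientation.items() if not b}
        if worse:
            v = v.copy()
            m = v["feature"].isin(worse)
            bad = m & (v["value"] <= 0)
            if bad.any():
                flg = v.loc[bad, ["subject", "exercise", "load", "feature"]].copy()
                flg["reason"] = "non-positive value under reciprocal orientation"
                extra_flags.append(flg)
            with np.errstate(divide="ignore"):
                v.loc[m, "value"] = np.where(
                    v.loc[m, "value"] > 0, 1.0 / v.loc[m, "value"], np.nan
                )
            recoded = frozenset(worse)
            effective = {f: True for f in features.orientation}
    base = (
        v[v["load"] == 0]
        .rename(columns={"value": "baseline"})
        .drop(columns=["load"])
    )
    task = v[v["load"].isin(TASK_LOADS)].copy()

    # per-(exercise, load) rescaling of Nc over the subject dimension
    c = features.counts.copy()
    c["zc"] = np.nan
    for (_, _), idx in c.groupby(["exercise", "load"]).groups.items():
        c.loc[idx, "zc"] = rescale_counts(c.loc[idx, "nc"].to_numpy(), bounds)

    out = task.merge(base, on=["subject", "exercise", "feature"], how="left")
    out = out.merge(c[["subject", "exercise", "load", "zc"]], on=["subject", "exercise", "load"], how="left")

    degenerate = (out["baseline"] == 0) | out["baseline"].isna() | out["value"].isna()
    flagged = out.loc[out["baseline"] == 0, ["subject", "exercise", "load", "feature"]].copy()
    flagged["reason"] = "zero baseline"
    flag_frames = [flagged, *extra_flags]
    flagged = pd.concat(flag_frames, ignore_index=True).drop_duplicates(
        subset=["subject", "exercise", "load", "feature"]
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        out["dtc"] = (out["value"] - out["baseline"]) / out["baseline"] * 100.0
        out["f_star"] = weight_feature(out["value"], out["zc"])
        out["dtc_star"] = (out["f_star"] - out["baseline"]) / out["baseline"] * 100.0
    out.loc[degenerate, ["dtc", "dtc_star", "f_star"]] = np.nan

    cols = ["subject", "exercise", "load", "feature", "value", "baseline", "zc", "dtc", "f_star", "dtc_star"]
    return DTCTable(
        table=out[cols].reset_index(drop=True),
        bounds=bounds,
        flagged=flagged.reset_index(drop=True),
        recoded=recoded,
        effective_orientation=effective,
    )
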