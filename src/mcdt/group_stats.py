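"""Descriptive group comparisons for the three diagnostic classes.

Continuous variables (age, FAB) are summarized per group as median and
IQR and compared with a Kruskal-Wallis omnibus test followed by
Bonferroni-corrected pairwise Mann-Whitney post hocs; categorical
variables (sex, education) with counts/percentages and a Pearson chi^2
test. Nonparametric tests are used throughout because clinical cohorts
of this size rarely satisfy normality or homoscedasticity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CLASSES, SubjectRecord

#: pairwise contrasts in reporting order, with their significance flags
PAIRS: tuple[tuple[str, str, str], ...] = (
    ("a", "CNA", "SCI"),
    ("b", "CNA", "MCI"),
    ("c", "SCI", "MCI"),
)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All values identical across groups gives H = 0, p = 1 (scipy raises
    in that case; the no-variation limit is well defined).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_mannwhitney_bonferroni(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided U tests for the three class pairs, Bonferroni-adjusted.

    p_adj = min(1, 3p). The exact null distribution is used when both
    groups have n <= 8 and no ties straddle them; otherwise the
    tie-corrected normal approximation (with continuity correction).
    Returns one row per pair with the a/b/c flag set iff p_adj < alpha.
    """
    rows = []
    n_pairs = sum(1 for _, ga, gb in PAIRS if ga in groups and gb in groups)
    for flag, ga, gb in PAIRS:
        if ga not in groups or gb not in groups:
            continue
        a = np.asarray(groups[ga], dtype=float)
        b = np.asarray(groups[gb], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"pair {ga}-{gb}: both groups need >= 2 values")
        small = max(len(a), len(b)) <= 8
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if small and no_ties else "asymptotic"
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        p_adj = min(1.0, n_pairs * float(p))
        rows.append(
            {
                "flag": flag,
                "group_a": ga,
                "group_b": gb,
                "U": float(u),
                "p": float(p),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def chi_square(contingency) -> tuple[float, float]:
    """Pearson chi^2 of independence, no continuity correction.

    Degrees of freedom (r-1)(c-1); a zero marginal row or column makes
    the expected counts degenerate and is rejected.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold nonnegative integers")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero marginal row/column; drop the empty category first")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def iqr(values) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    return float(np.quantile(v, 0.75) - np.quantile(v, 0.25))


@dataclass
class DescriptivesReport:
    """Per-variable group summaries with omnibus and post-hoc results."""

    continuous: dict[str, dict] = field(default_factory=dict)
    categorical: dict[str, dict] = field(default_factory=dict)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, d in self.continuous.items():
            row = {"variable": var, "type": "continuous", "p_value": d["p"]}
            for cls, s in d["groups"].items():
                row[f"{cls}"] = f"{s['median']:g} ({s['iqr']:g})" if s else ""
            row["flags"] = "".join(
                r["flag"] for _, r in d["posthoc"].iterrows() if r["significant"]
            )
            rows.append(row)
        for var, d in self.categorical.items():
            for level, counts in d["levels"].items():
                row = {"variable": f"{var}={level}", "type": "categorical", "p_value": d["p"]}
                for cls, (n, pct) in counts.items():
                    row[cls] = f"{n} ({pct:.0f}%)"
                row["flags"] = ""
                rows.append(row)
        return pd.DataFrame(rows)


def summarize_cohort(
    subjects: Sequence[SubjectRecord],
    continuous: Sequence[str] = ("age", "fab"),
    categorical: Sequence[str] = ("sex", "education"),
    alpha: float = 0.05,
) -> DescriptivesReport:
    """Cohort descriptives with group tests, one entry per variable.

    Empty groups are reported as absent; omnibus/post-hoc tests refuse
    (with a clear error) when a present group has a single subject.
    """
    df = pd.DataFrame([dataclasses.asdict(s) for s in subjects])
    if "diagnosis" not in df.columns or df.empty:
        raise ValueError("subject records with diagnosis labels required")
    report = DescriptivesReport(alpha=alpha)
    present = [c for c in CLASSES if (df["diagnosis"] == c).any()]
    for var in continuous:
        if var not in df.columns or df[var].isna().all():
            continue
        groups = {c: df.loc[df["diagnosis"] == c, var].dropna().to_numpy() for c in present}
        singletons = [c for c, g in groups.items() if len(g) < 2]
        if singletons:
            raise ValueError(
                f"{var}: group(s) {singletons} have a single subject; "
                "omnibus and post-hoc tests are undefined"
            )
        _, p = kruskal_wallis(list(groups.values()))
        posthoc = pairwise_mannwhitney_bonferroni(groups, alpha=alpha)
        report.continuous[var] = {
            "groups": {
                c: {"median": float(np.median(g)), "iqr": iqr(g), "n": len(g)}
                for c, g in groups.items()
            },
            "p": p,
            "posthoc": posthoc,
        }
    for var in categorical:
        if var not in df.columns or df[var].isna().all():
            continue
        tab = pd.crosstab(df[var], df["diagnosis"]).reindex(columns=present, fill_value=0)
        tab = tab.loc[tab.sum(axis=1) > 0]
        p = np.nan
        if tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.sum(axis=0) > 0).all():
            _, p = chi_square(tab.to_numpy())
        totals = tab.sum(axis=0)
        report.categorical[var] = {
            "levels": {
                lvl: {
                    c: (int(tab.loc[lvl, c]), 100 * tab.loc[lvl, c] / totals[c] if totals[c] else 0.0)
                    for c in present
                }
                for lvl in tab.index
            },
            "p": float(p) if p == p else p,
        }
    return report
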