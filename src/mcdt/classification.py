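"""Leave-one-out cross-validated logistic model battery.

Ten logistic regression models are evaluated for each of two problems —
two-class (CNA vs MCI) and three-class (CNA vs SCI vs MCI) — crossing
the five pooled indices with two regressor sets: (PI, age) and (PI,
age, FAB). The three-class model is a single multinomial (softmax)
logit. Every model is validated by leave-one-out cross-validation: each
subject is predicted by a model trained on all the others, and the
pooled out-of-fold predictions form one confusion matrix per model.

Reported metrics mirror the usual screening-study table: sensitivity
(recall of MCI, the class the screen exists to find), specificity, and
accuracy for the two-class problem; per-class and support-weighted
recall, precision, and F1 plus overall accuracy for the three-class
problem. Percentages are only rounded at report time.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .data_io import CLASSES, SubjectRecord

REGRESSOR_SETS: tuple[tuple[str, ...], ...] = (("PI", "AGE"), ("PI", "AGE", "FAB"))
PROBLEMS: tuple[str, ...] = ("two_class", "three_class")


class FitError(RuntimeError):
    """Logistic fit failed (non-convergence or degenerate labels)."""


@dataclass
class ModelSpec:
    """One battery entry: which PI, which covariates, which problem."""

    pi_name: str
    regressors: tuple[str, ...] = ("PI", "AGE")
    problem: str = "two_class"
    ridge: float = 1e-6
    # near-separable folds need many lbfgs iterations before the tiny
    # ridge caps the coefficient norms
    max_iter: int = 20000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if "PI" not in self.regressors:
            raise ValueError("the pooled index must always be a regressor")
        unknown = set(self.regressors) - {"PI", "AGE", "FAB"}
        if unknown:
            raise ValueError(f"unknown regressors {sorted(unknown)}")
        if self.problem not in PROBLEMS:
            raise ValueError(f"problem must be one of {PROBLEMS}")

    @property
    def classes(self) -> tuple[str, ...]:
        return ("CNA", "MCI") if self.problem == "two_class" else CLASSES

    def label(self) -> str:
        return f"PI({self.pi_name})" + "".join(f", {r}" for r in self.regressors if r != "PI")


@dataclass
class FittedLogit:
    """Standardizing logistic model (binomial or multinomial)."""

    classes: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    estimator: LogisticRegression

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        return self.estimator.predict_proba(Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class probability; ties broken by canonical class order.

        ``classes`` follows the estimator's column order; the tie-break
        among (numerically) equal probabilities uses the canonical
        CNA < SCI < MCI order for determinism.
        """
        proba = self.predict_proba(X)
        best = np.isclose(proba, proba.max(axis=1, keepdims=True), rtol=0, atol=1e-12)
        picks = []
        for row in best:
            cand = [self.classes[i] for i in np.flatnonzero(row)]
            picks.append(min(cand, key=CLASSES.index))
        return np.array(picks)


def fit_logistic(X, y, spec: ModelSpec) -> FittedLogit:
    """Maximum-likelihood logit with a small L2 stabilizer.

    Regressors are standardized to training mean/SD before fitting (a
    constant column gets scale 1). Deterministic given inputs; raises
    :class:`FitError` with iteration diagnostics on non-convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing cells")
    present = np.unique(y)
    if len(present) < 2:
        raise FitError(f"need >= 2 classes to fit, got only {list(present)}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    est = LogisticRegression(
        C=1.0 / spec.ridge,
        solver="lbfgs",
        max_iter=spec.max_iter,
        tol=spec.tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(Z, y)
        except ConvergenceWarning as exc:
            raise FitError(
                f"logistic fit did not converge in {spec.max_iter} iterations: {exc}"
            ) from exc
    return FittedLogit(classes=tuple(est.classes_), mean=mean, scale=scale, estimator=est)


def loocv(
    X,
    y,
    spec: ModelSpec,
    refit: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Leave-one-out predictions pooled into one confusion matrix.

    Returns (confusion, flagged_folds). The confusion matrix is indexed
    by true class (rows) and predicted class (columns) over the classes
    of the problem. A fold whose training set loses an entire class is
    still predicted from the model restricted to the remaining classes,
    and its index is flagged.

    ``refit``, if given, maps a boolean training mask to a transformed
    (X_train_full,) pair: it receives the mask and must return the
    design matrix recomputed using training subjects only (both rows for
    training and the held-out row). This hook implements fold-safe PI
    construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < X.shape[1] + 2:
        raise ValueError("too few subjects for LOOCV with this many regressors")
    labels = list(spec.classes)
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    flagged: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi = refit(mask) if refit is not None else X
        fold_classes = np.unique(y[mask])
        if len(fold_classes) == 1:
            # degenerate fold: the restricted "model" can only predict
            # the one class it has seen
            flagged.append(i)
            pred = fold_classes[0]
        else:
            model = fit_logistic(Xi[mask], y[mask], spec)
            if len(model.classes) < len(labels):
                flagged.append(i)
            pred = model.predict(Xi[[i]])[0]
        confusion.loc[y[i], pred] += 1
    return confusion, flagged


def compute_metrics(confusion: pd.DataFrame, problem: str) -> dict:
    """Screening metrics from a pooled confusion matrix (fractions, not %).

    Two-class: MCI is the positive class (sensitivity = MCI recall).
    Three-class: one-vs-rest per-class recall/precision/F1 plus their
    support-weighted averages and the overall accuracy. Precision for a
    never-predicted class is 0.
    """
    cm = confusion.to_numpy(dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = np.trace(cm) / total
    out: dict = {"accuracy": float(acc), "n": int(total)}
    labels = list(confusion.index)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, np.diag(cm) / row, 0.0)
        precision = np.where(col > 0, np.diag(cm) / col, 0.0)
        f1 = np.where(recall + precision > 0, 2 * recall * precision / (recall + precision), 0.0)
    if problem == "two_class":
        i_pos, i_neg = labels.index("MCI"), labels.index("CNA")
        out["sensitivity"] = float(recall[i_pos])
        out["specificity"] = float(recall[i_neg])
    else:
        support = row / total
        out["per_class"] = {
            lab: {"recall": float(recall[i]), "precision": float(precision[i]), "f1": float(f1[i])}
            for i, lab in enumerate(labels)
        }
        out["recall_weighted"] = float(np.sum(support * recall))
        out["precision_weighted"] = float(np.sum(support * precision))
        out["f1_weighted"] = float(np.sum(support * f1))
    return out


@dataclass
class MetricsReport:
    """Battery results: one entry per (model, problem) evaluation."""

    entries: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout mirroring the usual screening-study results table.

        One row per model (PI x regressor set), two-class Sen/Spe/Acc
        and three-class weighted Rec/Prec/F1 and Acc side by side, in
        percent.
        """
        by_model: dict[tuple, dict] = {}
        for e in self.entries:
            key = (e["pi_name"], e["regressors"])
            row = by_model.setdefault(
                key, {"model": e["label"], "pi": e["pi_name"], "regressors": e["regressors"]}
            )
            m = e["metrics"]
            if e["problem"] == "two_class":
                row["Sen"] = 100 * m["sensitivity"]
                row["Spe"] = 100 * m["specificity"]
                row["Acc_2class"] = 100 * m["accuracy"]
            else:
                row["Rec"] = 100 * m["recall_weighted"]
                row["Prec"] = 100 * m["precision_weighted"]
                row["F1"] = 100 * m["f1_weighted"]
                row["Acc_3class"] = 100 * m["accuracy"]
        return pd.DataFrame(list(by_model.values()))

    def per_class_frame(self) -> pd.DataFrame:
        """Per-class recall/precision/F1 of the three-class models."""
        rows = []
        for e in self.entries:
            if e["problem"] != "three_class":
                continue
            for cls, m in e["metrics"]["per_class"].items():
                rows.append(
                    {
                        "model": e["label"],
                        "class": cls,
                        "recall": 100 * m["recall"],
                        "precision": 100 * m["precision"],
                        "f1": 100 * m["f1"],
                    }
                )
        return pd.DataFrame(rows)


def battery_specs(pi_names: Sequence[str]) -> list[ModelSpec]:
    """The 10 models x 2 problems = 20 evaluations of the battery."""
    return [
        ModelSpec(pi_name=pi, regressors=regs, problem=prob)
        for regs in REGRESSOR_SETS
        for pi in pi_names
        for prob in PROBLEMS
    ]


def design_matrix(
    spec: ModelSpec, pi_scores: pd.DataFrame, subjects: Sequence[SubjectRecord]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, subject_ids) for one model, dropping incomplete rows."""
    sub = pd.DataFrame([dataclasses.asdict(s) for s in subjects]).set_index("subject_id")
    keep = sub.index[sub["diagnosis"].isin(spec.classes)]
    cols = {"PI": pi_scores[spec.pi_name].reindex(keep)}
    if "AGE" in spec.regressors:
        cols["AGE"] = sub.loc[keep, "age"]
    if "FAB" in spec.regressors:
        cols["FAB"] = sub.loc[keep, "fab"]
    df = pd.DataFrame(cols)
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{spec.label()} [{spec.problem}]: dropped {n_dropped} subject(s) with missing values",
            stacklevel=2,
        )
    y = sub.loc[complete.index, "diagnosis"].to_numpy()
    return complete.to_numpy(dtype=float), y, list(complete.index)


def run_model_battery(
    pi_scores: pd.DataFrame | "PooledIndexScores",
    subjects: Sequence[SubjectRecord],
    specs: Sequence[ModelSpec] | None = None,
) -> MetricsReport:
    """Evaluate the full battery with LOOCV and collect all metrics."""
    from .pooled_index import PooledIndexScores

    if isinstance(pi_scores, PooledIndexScores):
        pi_scores = pi_scores.scores
    if specs is None:
        specs = battery_specs(list(pi_scores.columns))
    report = MetricsReport()
    for spec in specs:
        X, y, ids = design_matrix(spec, pi_scores, subjects)
        confusion, flagged = loocv(X, y, spec)
        metrics = compute_metrics(confusion, spec.problem)
        report.entries.append(
            {
                "pi_name": spec.pi_name,
                "regressors": "+".join(spec.regressors),
                "label": spec.label(),
                "problem": spec.problem,
                "n": len(y),
                "flagged_folds": flagged,
                "confusion": confusion.values.tolist(),
                "confusion_labels": list(confusion.index),
                "metrics": metrics,
            }
        )
    return report
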