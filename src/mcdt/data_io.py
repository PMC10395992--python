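"""Tabular input/output for motor-feature tables and subject records.

The analysis consumes per-subject motor features ``f_i(Ex, CL_k, s_j)``
measured during three instrumented exercises — forefinger tapping (FTAP),
toe tapping with the heel pinned (TTHP), and a 10 m walk (GAIT) — under
four cognitive-load conditions CL_0 (single task) to CL_3 (counting
backwards by sevens), together with the number of correct counting
responses Nc produced during each dual-task trial (loads 1-3 only).

Canonical storage is long format: one row per subject x exercise x load x
feature. Wide format (one row per subject, one column per feature-load
pair) is supported for spreadsheet interoperability; its per-feature
orientation metadata travels in a JSON sidecar / extra worksheet.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Exercises and how many kinematic features each contributes.
EXERCISES: dict[str, int] = {"FTAP": 8, "TTHP": 8, "GAIT": 16}

#: Cognitive-load levels: 0 = single task, 1/2/3 = counting backwards
#: by ones, threes, sevens.
LOADS: tuple[int, ...] = (0, 1, 2, 3)

#: Loads at which a concurrent cognitive task (and hence Nc) exists.
TASK_LOADS: tuple[int, ...] = (1, 2, 3)

#: Diagnostic classes in canonical order (used for tie-breaking).
CLASSES: tuple[str, ...] = ("CNA", "SCI", "MCI")


def _feature_ids() -> tuple[str, ...]:
    ids = []
    for ex, n in EXERCISES.items():
        ids.extend(f"{ex}_f{i:02d}" for i in range(1, n + 1))
    return tuple(ids)


#: The 32 feature identities, e.g. "GAIT_f03".
FEATURE_IDS: tuple[str, ...] = _feature_ids()

LONG_COLUMNS = ("subject", "exercise", "load", "feature", "value", "nc")


class SchemaError(ValueError):
    """Raised when an input table violates the documented schema."""


def exercise_of(feature_id: str) -> str:
    """Exercise a feature identity belongs to (``"GAIT_f03"`` -> ``"GAIT"``)."""
    ex = feature_id.split("_", 1)[0]
    if ex not in EXERCISES:
        raise SchemaError(f"unknown exercise prefix in feature id {feature_id!r}")
    return ex


@dataclass
class SubjectRecord:
    """Demographic and clinical covariates for one subject.

    ``fab`` is the Frontal Assessment Battery score (0-18, 18 = best
    executive functioning); ``diagnosis`` is one of CNA / SCI / MCI.
    """

    subject_id: str
    age: float
    fab: int
    diagnosis: str
    sex: str | None = None
    education: str | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in CLASSES:
            raise SchemaError(
                f"subject {self.subject_id!r}: diagnosis {self.diagnosis!r} "
                f"not one of {CLASSES}"
            )
        if not (0 <= self.fab <= 18):
            raise SchemaError(
                f"subject {self.subject_id!r}: FAB score {self.fab} outside [0, 18]"
            )
        if self.age <= 0:
            raise SchemaError(f"subject {self.subject_id!r}: age {self.age} must be positive")


@dataclass
class FeatureTable:
    """Validated container for the feature tensor and response counts.

    Attributes
    ----------
    values : DataFrame
        Long table with columns (subject, exercise, load, feature, value);
        one row per cell of ``f_i(Ex, CL_k, s_j)``.
    counts : DataFrame
        Long table with columns (subject, exercise, load, nc); the correct
        response counts, defined only for loads 1-3.
    orientation : dict
        Maps each feature identity to True if a *higher* raw value
        indicates greater functioning, False if lower is better.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    orientation: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.reset_index(drop=True)
        self.counts = self.counts.reset_index(drop=True)
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        v, c = self.values, self.counts
        missing = [col for col in ("subject", "exercise", "load", "feature", "value") if col not in v.columns]
        if missing:
            raise SchemaError(f"feature table missing columns: {missing}")
        missing = [col for col in ("subject", "exercise", "load", "nc") if col not in c.columns]
        if missing:
            raise SchemaError(f"count table missing columns: {missing}")

        bad_feat = sorted(set(v["feature"]) - set(FEATURE_IDS))
        if bad_feat:
            raise SchemaError(f"unknown feature identities: {bad_feat}")
        bad_load = sorted(set(v["load"]) - set(LOADS))
        if bad_load:
            raise SchemaError(f"unknown load levels in feature table: {bad_load}")
        if len(c):
            bad = c[~c["load"].isin(TASK_LOADS)]
            if len(bad):
                raise SchemaError(
                    "Nc given at loads without a cognitive task (Nc exists only "
                    f"for loads {TASK_LOADS}); offending rows: "
                    f"{bad[['subject', 'exercise', 'load']].to_dict('records')[:5]}"
                )
            if (c["nc"] < 0).any() or not np.allclose(c["nc"], np.round(c["nc"])):
                raise SchemaError("Nc must be a nonnegative integer")
        dup = v.duplicated(subset=["subject", "exercise", "load", "feature"])
        if dup.any():
            raise SchemaError(
                f"duplicated (subject, exercise, load, feature) cells: "
                f"{v.loc[dup, ['subject', 'exercise', 'load', 'feature']].to_dict('records')[:5]}"
            )
        if len(v) and not pd.api.types.is_numeric_dtype(v["value"]):
            raise SchemaError("feature values must be numeric")
        if len(v):
            mism = v[v.apply(lambda r: exercise_of(r["feature"]) != r["exercise"], axis=1)]
            if len(mism):
                raise SchemaError(
                    f"feature/exercise mismatch in rows: "
                    f"{mism[['subject', 'feature', 'exercise']].to_dict('records')[:5]}"
                )
        unknown_orient = sorted(set(self.orientation) - set(FEATURE_IDS))
        if unknown_orient:
            raise SchemaError(f"orientation given for unknown features: {unknown_orient}")

    # -- introspection ----------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.values["subject"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def feature_columns(self) -> list[tuple[str, str, int]]:
        """All 128 (exercise, feature, load) columns of the full design."""
        return [(exercise_of(f), f, k) for f in FEATURE_IDS for k in LOADS]

    def check_complete(self) -> None:
        """Raise if any subject lacks a full 32 x 4 block or any Nc cell."""
        subs = self.subjects
        want = {(s, f, k) for s in subs for f in FEATURE_IDS for k in LOADS}
        have = set(zip(self.values["subject"], self.values["feature"], self.values["load"]))
        gaps = sorted(want - have)
        if gaps:
            raise SchemaError(f"missing feature cells ({len(gaps)} total), first few: {gaps[:5]}")
        want_nc = {(s, ex, k) for s in subs for ex in EXERCISES for k in TASK_LOADS}
        have_nc = set(zip(self.counts["subject"], self.counts["exercise"], self.counts["load"]))
        gaps = sorted(want_nc - have_nc)
        if gaps:
            raise SchemaError(f"missing Nc cells ({len(gaps)} total), first few: {gaps[:5]}")

    # -- layout conversion -------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Single long DataFrame with nc and orientation merged in."""
        v = self.values.copy()
        v = v.merge(self.counts, on=["subject", "exercise", "load"], how="left")
        v["higher_is_better"] = v["feature"].map(
            {f: int(b) for f, b in self.orientation.items()}
        )
        return v.sort_values(["subject", "exercise", "load", "feature"]).reset_index(drop=True)

    def to_wide(self) -> pd.DataFrame:
        """One row per subject: 128 ``<feature>_CL<k>`` columns + 9 ``Nc_<Ex>_CL<k>``."""
        v = self.values.copy()
        v["col"] = v["feature"] + "_CL" + v["load"].astype(str)
        wide = v.pivot(index="subject", columns="col", values="value")
        c = self.counts.copy()
        c["col"] = "Nc_" + c["exercise"] + "_CL" + c["load"].astype(str)
        wide_nc = c.pivot(index="subject", columns="col", values="nc")
        out = wide.join(wide_nc)
        cols = [f"{f}_CL{k}" for f in FEATURE_IDS for k in LOADS]
        cols += [f"Nc_{ex}_CL{k}" for ex in EXERCISES for k in TASK_LOADS]
        return out.reindex(columns=[c for c in cols if c in out.columns]).reset_index()

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "FeatureTable":
        for col in ("subject", "exercise", "load", "feature", "value"):
            if col not in df.columns:
                raise SchemaError(f"long table missing mandatory column {col!r}")
        known = set(LONG_COLUMNS) | {"higher_is_better"}
        extra = [c for c in df.columns if c not in known]
        if extra:
            warnings.warn(f"ignoring unknown columns {extra}", stacklevel=2)
        df = df.copy()
        df["subject"] = df["subject"].astype(str)
        df["load"] = df["load"].astype(int)
        try:
            df["value"] = pd.to_numeric(df["value"])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric feature value: {exc}") from exc
        values = df[["subject", "exercise", "load", "feature", "value"]]
        counts = (
            df.loc[df["nc"].notna(), ["subject", "exercise", "load", "nc"]]
            .drop_duplicates()
            .astype({"nc": int})
            if "nc" in df.columns
            else pd.DataFrame(columns=["subject", "exercise", "load", "nc"])
        )
        # reject Nc at load 0 loudly rather than dropping it
        if "nc" in df.columns:
            bad = df[(df["load"] == 0) & df["nc"].notna()]
            if len(bad):
                raise SchemaError(
                    "Nc given at baseline load CL_0 where no cognitive task exists; "
                    f"offending rows: {bad[['subject', 'exercise']].to_dict('records')[:5]}"
                )
        orientation: dict[str, bool] = {}
        if "higher_is_better" in df.columns:
            om = df.loc[df["higher_is_better"].notna(), ["feature", "higher_is_better"]].drop_duplicates()
            if om["feature"].duplicated().any():
                raise SchemaError("conflicting orientation flags for the same feature")
            orientation = {f: bool(b) for f, b in om.itertuples(index=False)}
        return cls(values=values, counts=counts, orientation=orientation)

    @classmethod
    def from_wide(cls, df: pd.DataFrame, orientation: Mapping[str, bool] | None = None) -> "FeatureTable":
        if "subject" not in df.columns:
            raise SchemaError("wide table missing 'subject' column")
        recs, ncs = [], []
        for _, row in df.iterrows():
            s = str(row["subject"])
            for col in df.columns:
                if col == "subject" or pd.isna(row[col]):
                    continue
                if col.startswith("Nc_"):
                    _, ex, cl = col.split("_")
                    ncs.append((s, ex, int(cl[2:]), int(row[col])))
                elif "_CL" in col:
                    feat, cl = col.rsplit("_CL", 1)
                    recs.append((s, exercise_of(feat), int(cl), feat, float(row[col])))
                else:
                    warnings.warn(f"ignoring unknown column {col!r}", stacklevel=2)
        values = pd.DataFrame(recs, columns=["subject", "exercise", "load", "feature", "value"])
        counts = pd.DataFrame(ncs, columns=["subject", "exercise", "load", "nc"])
        return cls(values=values, counts=counts, orientation=dict(orientation or {}))


# -- file round-trip -------------------------------------------------------


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    format: str = "csv",
    schema: str = "long",
) -> None:
    """Write a feature table as CSV or XLSX in long or wide layout.

    Wide CSV stores the orientation map in a ``<path>.meta.json`` sidecar;
    wide XLSX uses a second ``orientation`` worksheet.
    """
    path = Path(path)
    if schema == "long":
        df = table.to_long()
        if format == "csv":
            df.to_csv(path, index=False)
        elif format == "xlsx":
            df.to_excel(path, index=False, sheet_name="features")
        else:
            raise ValueError(f"unknown format {format!r}")
    elif schema == "wide":
        df = table.to_wide()
        orient = pd.DataFrame(
            {"feature": list(table.orientation), "higher_is_better": [int(b) for b in table.orientation.values()]}
        )
        if format == "csv":
            df.to_csv(path, index=False)
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps({f: bool(b) for f, b in table.orientation.items()}, indent=1)
            )
        elif format == "xlsx":
            with pd.ExcelWriter(path) as xw:
                df.to_excel(xw, index=False, sheet_name="features")
                orient.to_excel(xw, index=False, sheet_name="orientation")
        else:
            raise ValueError(f"unknown format {format!r}")
    else:
        raise ValueError(f"unknown schema {schema!r}")


def read_feature_table(path: str | Path, format: str = "csv", schema: str = "long") -> FeatureTable:
    """Read and validate a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema == "long":
        if format == "csv":
            df = pd.read_csv(path)
        elif format == "xlsx":
            df = pd.read_excel(path, sheet_name="features")
        else:
            raise ValueError(f"unknown format {format!r}")
        return FeatureTable.from_long(df)
    if schema == "wide":
        orientation: dict[str, bool] = {}
        if format == "csv":
            df = pd.read_csv(path)
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            if sidecar.exists():
                orientation = {f: bool(b) for f, b in json.loads(sidecar.read_text()).items()}
        elif format == "xlsx":
            df = pd.read_excel(path, sheet_name="features")
            try:
                om = pd.read_excel(path, sheet_name="orientation")
                orientation = {f: bool(b) for f, b in om.itertuples(index=False)}
            except ValueError:
                orientation = {}
        else:
            raise ValueError(f"unknown format {format!r}")
        return FeatureTable.from_wide(df, orientation)
    raise ValueError(f"unknown schema {schema!r}")


def write_subject_records(records: Sequence[SubjectRecord], path: str | Path, format: str = "csv") -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False, sheet_name="subjects")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_subject_records(path: str | Path, format: str = "csv") -> list[SubjectRecord]:
    """Read demographic/clinical records; every row is validated on load."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "xlsx":
        df = pd.read_excel(path, sheet_name="subjects")
    else:
        raise ValueError(f"unknown format {format!r}")
    for col in ("subject_id", "age", "fab", "diagnosis"):
        if col not in df.columns:
            raise SchemaError(f"subject table missing mandatory column {col!r}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                fab=int(row["fab"]),
                diagnosis=str(row["diagnosis"]),
                sex=None if "sex" not in df.columns or pd.isna(row.get("sex")) else str(row["sex"]),
                education=None
                if "education" not in df.columns or pd.isna(row.get("education"))
                else str(row["education"]),
            )
        )
    return records


def _provenance(extra: Mapping | None = None) -> dict:
    from . import __version__

    prov = {"software": "mcdt", "version": __version__}
    if extra:
        prov.update(extra)
    return prov


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(report, path: str | Path, format: str = "csv", provenance: Mapping | None = None) -> None:
    """Write an analysis artifact as CSV plus a JSON sidecar.

    ``report`` may be a DataFrame or any object with a ``to_frame()``
    method (MetricsReport, DescriptivesReport, PooledIndexModel). The JSON
    sidecar carries the same rows plus provenance (software version and
    any caller-supplied keys such as config hash and seed).
    """
    path = Path(path)
    df = report if isinstance(report, pd.DataFrame) else report.to_frame()
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    sidecar = {
        "provenance": _provenance(provenance),
        "columns": list(df.columns),
        "rows": json.loads(df.to_json(orient="records")),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_report_sidecar(path: str | Path) -> pd.DataFrame:
    """Re-load the machine-readable JSON sidecar written by :func:`write_report`."""
    payload = json.loads(Path(path).with_suffix(Path(path).suffix + ".json").read_text())
    return pd.DataFrame(payload["rows"], columns=payload["columns"])
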