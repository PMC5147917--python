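"""Readers and writers for the pipeline's plain-text formats.

Trace files are headered CSV (``time_s, ml_cm, ap_cm``; ``#`` comments), one
per subject per eye condition.  A manifest CSV
(``subject_id, label, open_path, closed_path``) ties traces to the binary
faller label.  Feature tables are headered CSV with one row per subject.
All files are comma-separated, ``.`` decimal, UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector, SubjectRecord
from .signal import RawTrace

__all__ = ["read_trace", "write_trace", "read_manifest", "write_cohort",
           "read_feature_table", "write_feature_table"]

TRACE_COLUMNS = ["time_s", "ml_cm", "ap_cm"]
MANIFEST_COLUMNS = ["subject_id", "label", "open_path", "closed_path"]


def write_trace(trace: RawTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.timestamps, "ml_cm": trace.ml,
                       "ap_cm": trace.ap})
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_trace(path, condition: str = "open") -> RawTrace:
    """Load and validate one trace file; errors name the file and row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} lacks columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # line number of the offending (second) sample: 1-based + header line
        raise ValueError(
            f"non-increasing timestamp in {path} at data row {bad[0] + 3}")
    try:
        return RawTrace(timestamps=t, ml=df["ml_cm"].to_numpy(dtype=float),
                        ap=df["ap_cm"].to_numpy(dtype=float),
                        condition=condition)
    except ValueError as exc:
        raise ValueError(f"invalid trace file {path}: {exc}") from exc


def write_cohort(subjects, out_dir, config_echo: dict | None = None) -> Path:
    """Write per-record trace files, the manifest and a config echo."""
    out_dir = Path(out_dir)
    traces = out_dir / "traces"
    traces.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        paths = {}
        for cond, trace in (("open", s.open_trace), ("closed", s.closed_trace)):
            rel = Path("traces") / f"{s.subject_id}_{cond}.csv"
            write_trace(trace, out_dir / rel)
            paths[cond] = str(rel)
        rows.append({"subject_id": s.subject_id,
                     "label": "faller" if s.is_faller else "non_faller",
                     "open_path": paths["open"],
                     "closed_path": paths["closed"]})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, index=False, lineterminator="\n")
    if config_echo is not None:
        with open(out_dir / "cohort_config.json", "w", encoding="utf-8") as fh:
            json.dump(config_echo, fh, sort_keys=True, indent=1)
    return manifest


def _parse_label(value, path, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("faller", "1", "true"):
        return True
    if text in ("non_faller", "nonfaller", "non-faller", "0", "false"):
        return False
    raise ValueError(f"unrecognised label {value!r} in {path} at data row {row}")


def read_manifest(path) -> list:
    """Load all subjects referenced by a manifest, validating every trace."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    base = path.parent
    subjects = []
    for i, row in df.iterrows():
        for col in ("open_path", "closed_path"):
            if pd.isna(row[col]) or not str(row[col]).strip():
                raise ValueError(
                    f"subject {row['subject_id']!r} is missing its "
                    f"{col.split('_')[0]}-eyes trace in {path} at data row {i + 2}")
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            is_faller=_parse_label(row["label"], path, i + 2),
            open_trace=read_trace(base / row["open_path"], "open"),
            closed_trace=read_trace(base / row["closed_path"], "closed"),
        ))
    return subjects


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, comment="#")
    required = ["subject_id", "label", *FEATURE_NAMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} lacks columns {missing}")
    return df


def features_to_frame(subjects, vectors) -> pd.DataFrame:
    """Assemble the on-disk feature table from records and their vectors."""
    rows = []
    for s, fv in zip(subjects, vectors):
        row = {"subject_id": s.subject_id,
               "label": "faller" if s.is_faller else "non_faller"}
        row.update({n: getattr(fv, n) for n in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
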