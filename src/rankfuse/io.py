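"""Score-table file formats and report serialization.

Score tables are UTF-8 CSV with a ``sample_id`` column followed by one
column per class label; one row per sample, '.' decimal mark. The M files
of one run must share identical class headers (order included); rows are
aligned across files by sample id, in the order of the labels file, so a
reordered file never causes a silent column or row swap. Labels files
are CSV with columns ``sample_id,label``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fusion_core import EnsembleScoreSet, FusionResult

__all__ = [
    "read_score_table",
    "read_labels",
    "read_score_bank",
    "write_score_bank",
    "write_predictions",
    "read_predictions",
    "write_report_json",
]


def read_score_table(path) -> pd.DataFrame:
    """Read one classifier's score CSV into a frame indexed by sample_id."""
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    df = df.set_index("sample_id")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric confidence {df.iat[r, c]!r} for sample "
            f"{df.index[r]!r}, class {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value for sample {df.index[r]!r}, class {df.columns[c]!r}")
    return numeric


def read_labels(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValueError(f"{path}: labels file must have columns sample_id,label")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id")["label"]


def read_score_bank(paths, labels_path) -> tuple[EnsembleScoreSet, pd.Series]:
    """Read M score CSVs + a labels CSV into an aligned score set.

    Row order follows the labels file; every sample in the labels file
    must be present in every score file (missing ids are an error naming
    them), extra rows in score files are dropped. Class headers must be
    identical, order included, across the M files.
    """
    paths = [Path(p) for p in paths]
    labels = read_labels(labels_path)
    frames = [read_score_table(p) for p in paths]
    columns = list(frames[0].columns)
    for p, f in zip(paths[1:], frames[1:]):
        if list(f.columns) != columns:
            raise ValueError(
                f"{p}: class header {list(f.columns)} differs from "
                f"{paths[0]}: {columns}"
            )
    wanted = labels.index
    for p, f in zip(paths, frames):
        missing = wanted.difference(f.index)
        if len(missing) > 0:
            raise ValueError(
                f"{p}: missing sample id(s) present in the labels file: "
                f"{sorted(missing)[:10]}"
            )
    aligned = [f.loc[wanted] for f in frames]
    names = [p.stem for p in paths]
    sset = EnsembleScoreSet.from_dataframes(aligned, classifier_names=names)
    unknown = set(labels.unique()) - set(columns)
    if unknown:
        raise ValueError(f"labels file contains label(s) not in the class header: {sorted(unknown)}")
    return sset, labels


def write_score_bank(sset: EnsembleScoreSet, outdir, truth=None) -> list[Path]:
    """Write model_<i>.csv files (and labels.csv when truth is given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, frame in enumerate(sset.to_dataframes()):
        p = outdir / f"model_{i + 1}.csv"
        frame.to_csv(p, float_format="%.10g")
        written.append(p)
    if truth is not None:
        p = outdir / "labels.csv"
        pd.DataFrame({"sample_id": sset.sample_ids, "label": list(truth)}).to_csv(p, index=False)
        written.append(p)
    return written


def write_predictions(result: FusionResult, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "fused_label": str})
    if "sample_id" not in df.columns or "fused_label" not in df.columns:
        raise ValueError(f"{path}: predictions file needs sample_id and fused_label columns")
    return df.set_index("sample_id")


def write_report_json(report_dict: dict, path, config_echo: dict | None = None) -> Path:
    """JSON report with a config echo and tool version; no timestamps, so
    identical inputs produce byte-identical files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"tool": "rankfuse", "version": __version__}
    if config_echo is not None:
        payload["config"] = config_echo
    payload.update(report_dict)
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    return path
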