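"""Readers and writers for the package's plain-text formats."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .effectsize import GroupScores

__all__ = [
    "DataError",
    "read_scores_csv",
    "read_weight_vector",
    "read_json",
    "write_json",
    "example_studies_path",
]


class DataError(ValueError):
    """Malformed or out-of-range input data (as opposed to a numeric-domain error)."""


def read_scores_csv(path) -> GroupScores:
    """Read classifier scores: CSV with columns subject_id, label (0/1), score."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse scores CSV {path}: {exc}") from exc
    missing = {"subject_id", "label", "score"} - set(frame.columns)
    if missing:
        raise DataError(f"scores CSV {path} lacks columns: {sorted(missing)}")
    labels = frame["label"].to_numpy()
    if not np.all(np.isin(labels, (0, 1))):
        raise DataError("label column must be strictly binary (0 = control, 1 = patient)")
    try:
        return GroupScores(labels, frame["score"].to_numpy(dtype=float))
    except ValueError as exc:
        raise DataError(str(exc)) from exc


def read_weight_vector(path) -> np.ndarray:
    """Read a model weight vector.

    Accepts a single numeric column (CSV/TSV, with or without header) or a
    two-column feature_id,weight table.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=sep, header=None)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse weight file {path}: {exc}") from exc
    # drop a header row if the first row is not numeric
    first = frame.iloc[0]
    if not all(_is_number(v) for v in first[-1:]):
        frame = frame.iloc[1:]
    if frame.shape[1] == 1:
        col = frame.iloc[:, 0]
    elif frame.shape[1] == 2:
        col = frame.iloc[:, 1]
    else:
        raise DataError(f"weight file {path} must have 1 or 2 columns, found {frame.shape[1]}")
    try:
        weights = col.astype(float).to_numpy()
    except ValueError as exc:
        raise DataError(f"non-numeric weights in {path}") from exc
    if weights.size == 0:
        raise DataError(f"empty weight file {path}")
    return weights


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, default=float) + "\n")


def example_studies_path() -> Path:
    """Path of the bundled example study table.

    The table holds only the worked accuracy pairs quoted in published
    text (a 77%->84% train/test pair with 30+30 training subjects; 67% vs
    77% for the same sample scanned at 3 T vs 7 T; an 86.8%->69.1%
    top-10%-features sub-model pair); sample sizes that were never printed
    are left blank.
    """
    return Path(resources.files("mleffect") / "data" / "example_studies.csv")
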