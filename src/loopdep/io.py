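"""Trial-level CSV schema, second-level data loading, and serialization.

The canonical trial table has one row per retrieval trial with the columns
listed in ``TRIAL_COLUMNS``. Responses are 'correct', 'incorrect' or
'missing'; missing responses are recoded to incorrect at load time (with the
count logged), matching how non-responses enter both the accuracy and the
dependency analyses.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CATEGORIES, DIRECTIONS, direction_index
from .matrix import ResponseMatrix, administered_mask_for_events

logger = logging.getLogger("loopdep")

TRIAL_COLUMNS = [
    "experiment",
    "participant",
    "session",
    "block",
    "trial_index",
    "triplet_id",
    "loop_type",
    "common_category",
    "trial_kind",
    "cue_role",
    "target_role",
    "tested_at_T1",
    "response",
]

_ENUMS = {
    "session": {"T1", "T2"},
    "loop_type": {"closed", "open"},
    "trial_kind": {"direct", "inference"},
    "cue_role": set(CATEGORIES),
    "target_role": set(CATEGORIES),
    "response": {"correct", "incorrect", "missing"},
}


def _validate(frame: pd.DataFrame, path=None) -> pd.DataFrame:
    where = f" in {path}" if path else ""
    missing_cols = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"missing columns {missing_cols}{where}")
    unknown = [c for c in frame.columns if c not in TRIAL_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns {unknown}{where}")
    frame = frame.copy()
    frame["common_category"] = frame["common_category"].fillna("").astype(str)
    frame.loc[frame["common_category"] == "nan", "common_category"] = ""
    for col, allowed in _ENUMS.items():
        bad = ~frame[col].isin(allowed)
        if bad.any():
            row = int(frame.index[bad][0])
            raise ValueError(
                f"invalid {col} value {frame.loc[row, col]!r} at row {row}{where}"
            )
    bad_common = ~frame["common_category"].isin(set(CATEGORIES) | {""})
    if bad_common.any():
        row = int(frame.index[bad_common][0])
        raise ValueError(f"invalid common_category at row {row}{where}")
    return frame


def read_trials(path) -> pd.DataFrame:
    """Load a trial-level CSV, recoding missing responses to incorrect."""
    frame = pd.read_csv(path, dtype={"common_category": str}, keep_default_na=False)
    frame["common_category"] = frame["common_category"].replace({"": ""})
    frame["tested_at_T1"] = frame["tested_at_T1"].astype(str).str.lower().isin(
        ("true", "1")
    )
    frame = _validate(frame, path)
    n_missing = int((frame["response"] == "missing").sum())
    if n_missing:
        logger.info("recoded %d missing responses as incorrect", n_missing)
        frame.loc[frame["response"] == "missing", "response"] = "incorrect"
    return frame


def write_trials(frame: pd.DataFrame, path) -> None:
    _validate(frame)
    frame.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def matrices_to_trials(matrix: ResponseMatrix, experiment: int = 0) -> pd.DataFrame:
    """One row per administered direction (block/trial order is synthetic)."""
    rows = []
    idx = 1
    for i in range(matrix.n_events):
        ev = matrix.events.iloc[i]
        for d, (cue, tgt) in enumerate(DIRECTIONS):
            r = matrix.responses[i, d]
            if r < 0:
                continue
            rows.append(
                {
                    "experiment": experiment,
                    "participant": matrix.participant,
                    "session": matrix.session,
                    "block": 1 + d,
                    "trial_index": idx,
                    "triplet_id": ev["triplet_id"],
                    "loop_type": ev["loop_type"],
                    "common_category": ev["common_category"] or "",
                    "trial_kind": "direct",
                    "cue_role": cue,
                    "target_role": tgt,
                    "tested_at_T1": bool(ev["tested_at_T1"]),
                    "response": "correct" if r == 1 else "incorrect",
                }
            )
            idx += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def trials_to_matrices(trials: pd.DataFrame) -> list:
    """Rebuild per participant-session response matrices from trial rows.

    Inference trials are excluded (the dependency analysis operates on
    directly encoded associations only); missing responses must already be
    recoded, as ``read_trials`` does.
    """
    frame = trials[trials["trial_kind"] == "direct"].copy()
    frame.loc[frame["response"] == "missing", "response"] = "incorrect"
    matrices = []
    for (participant, session), g in frame.groupby(["participant", "session"]):
        events = (
            g[["triplet_id", "loop_type", "common_category", "tested_at_T1"]]
            .drop_duplicates("triplet_id")
            .sort_values("triplet_id")
            .reset_index(drop=True)
        )
        events["common_category"] = events["common_category"].replace({"": None})
        row_of = {tid: i for i, tid in enumerate(events["triplet_id"])}
        responses = np.full((len(events), len(DIRECTIONS)), -1, dtype=np.int8)
        for _, tr in g.iterrows():
            d = direction_index(tr["cue_role"], tr["target_role"])
            responses[row_of[tr["triplet_id"]], d] = 1 if tr["response"] == "correct" else 0
        matrices.append(ResponseMatrix(participant, session, responses, events))
    return matrices


#: required logical fields for second-level (per-participant summary) data
SECOND_LEVEL_FIELDS = (
    "participant",
    "dependency_T1",
    "dependency_T2",
)


def read_second_level(path, schema_map: dict) -> pd.DataFrame:
    """Load deposited per-participant summary data via an explicit column map.

    ``schema_map`` maps logical field names (``participant``,
    ``dependency_T1``, ``dependency_T2``, optionally ``accuracy_T1``,
    ``accuracy_T2``, ``experiment``, ``loop_type``) to the file's column
    names; the deposited layout is not standardized, so no guessing is done.
    """
    for field in SECOND_LEVEL_FIELDS:
        if field not in schema_map:
            raise ValueError(f"schema_map must map required field {field!r}")
    frame = pd.read_csv(path)
    out = {}
    for logical, column in schema_map.items():
        if column not in frame.columns:
            raise ValueError(f"column {column!r} (for {logical!r}) not in {path}")
        out[logical] = frame[column]
    return pd.DataFrame(out)


def write_manifest(path, **payload) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default, sort_keys=True)
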