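"""Tabular I/O.

All tables are UTF-8 tab-separated with a header row:

* ``spikes.tsv``:  unit_id, region, spike_time_s
* ``events.tsv``:  episode_id, enc_cue_onset_s, enc_assoc_onset_s,
  enc_response_s, ret_cue_onset_s, ret_response_s, remembered
* ``tuning.tsv``:  image_id, onset_s                     (optional)
* ``blocks.tsv``:  block_start_s, block_end_s            (optional)

Scalar summaries (group tests) are written as JSON, per-unit/per-episode
values as TSV; both round-trip losslessly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .session import (
    EpisodeEvents,
    SchemaError,
    Session,
    SpikeTrain,
    TuningEvents,
    ValidationError,
)

SPIKE_COLUMNS = ["unit_id", "region", "spike_time_s"]
EVENT_COLUMNS = [
    "episode_id",
    "enc_cue_onset_s",
    "enc_assoc_onset_s",
    "enc_response_s",
    "ret_cue_onset_s",
    "ret_response_s",
    "remembered",
]
TUNING_COLUMNS = ["image_id", "onset_s"]


def _read_table(path, required: list) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("unit_id", "episode_id", "image_id")})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def _drop_malformed(df: pd.DataFrame, cols: list, label: str) -> pd.DataFrame:
    """Coerce time columns to float and drop rows that fail, with a report."""
    coerced = df.copy()
    for col in cols:
        coerced[col] = pd.to_numeric(coerced[col], errors="coerce")
    bad = coerced[cols].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"{label}: dropped {int(bad.sum())} row(s) with malformed times "
            f"(rows {list(df.index[bad])})",
            stacklevel=3,
        )
    return coerced[~bad]


def read_session(
    spikes_path,
    events_path,
    tuning_path=None,
    blocks_path=None,
    session_id: Optional[str] = None,
) -> Session:
    """Read and validate a session from delimited tables."""
    spikes = _drop_malformed(_read_table(spikes_path, SPIKE_COLUMNS), ["spike_time_s"], "spikes")
    if (spikes["spike_time_s"] < 0).any():
        raise ValidationError("spikes: negative spike times")

    units = []
    for unit_id, grp in spikes.groupby("unit_id", sort=True):
        region = grp["region"].iloc[0]
        units.append(SpikeTrain(str(unit_id), str(region), grp["spike_time_s"].to_numpy()))

    ev = _read_table(events_path, EVENT_COLUMNS)
    ev = _drop_malformed(ev, EVENT_COLUMNS[1:6], "events")
    episodes = []
    for _, row in ev.iterrows():
        remembered = row["remembered"]
        if isinstance(remembered, str):
            remembered = remembered.strip().lower() in ("1", "true", "yes")
        episodes.append(
            EpisodeEvents(
                episode_id=str(row["episode_id"]),
                enc_cue_onset_s=float(row["enc_cue_onset_s"]),
                enc_assoc_onset_s=float(row["enc_assoc_onset_s"]),
                enc_response_s=float(row["enc_response_s"]),
                ret_cue_onset_s=float(row["ret_cue_onset_s"]),
                ret_response_s=float(row["ret_response_s"]),
                remembered=bool(remembered),
            )
        )

    tuning = None
    if tuning_path is not None and Path(tuning_path).exists():
        tu = _drop_malformed(_read_table(tuning_path, TUNING_COLUMNS), ["onset_s"], "tuning")
        tu = tu.sort_values("onset_s")
        tuning = TuningEvents(tu["image_id"].to_numpy(), tu["onset_s"].to_numpy())

    blocks = []
    if blocks_path is not None and Path(blocks_path).exists():
        bl = _read_table(blocks_path, ["block_start_s", "block_end_s"])
        blocks = [(float(a), float(b)) for a, b in zip(bl["block_start_s"], bl["block_end_s"])]
    elif episodes:
        # fall back to a single block spanning all encoding windows
        blocks = [
            (
                min(ep.enc_cue_onset_s for ep in episodes),
                max(ep.enc_response_s for ep in episodes),
            )
        ]

    if session_id is None:
        session_id = Path(events_path).resolve().parent.name or "session"
    return Session(session_id, units, episodes, tuning, blocks)


def read_session_dir(session_dir) -> Session:
    """Read ``spikes.tsv`` / ``events.tsv`` (+ optional tables) from a directory."""
    d = Path(session_dir)
    return read_session(
        d / "spikes.tsv",
        d / "events.tsv",
        tuning_path=d / "tuning.tsv",
        blocks_path=d / "blocks.tsv",
        session_id=d.name,
    )


def write_session(session: Session, session_dir) -> Path:
    """Write a session as a directory of TSV tables (inverse of read_session_dir)."""
    d = Path(session_dir)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for u in session.units:
        for t in u.spike_times:
            rows.append((u.unit_id, u.region, repr(float(t))))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(d / "spikes.tsv", sep="\t", index=False)

    ev = pd.DataFrame(
        [
            (
                ep.episode_id,
                repr(ep.enc_cue_onset_s),
                repr(ep.enc_assoc_onset_s),
                repr(ep.enc_response_s),
                repr(ep.ret_cue_onset_s),
                repr(ep.ret_response_s),
                int(ep.remembered),
            )
            for ep in session.episodes
        ],
        columns=EVENT_COLUMNS,
    )
    ev.to_csv(d / "events.tsv", sep="\t", index=False)

    if session.tuning is not None:
        pd.DataFrame(
            {"image_id": session.tuning.image_ids, "onset_s": [repr(float(t)) for t in session.tuning.onsets_s]}
        ).to_csv(d / "tuning.tsv", sep="\t", index=False)

    if session.block_boundaries:
        pd.DataFrame(
            [(repr(float(a)), repr(float(b))) for a, b in session.block_boundaries],
            columns=["block_start_s", "block_end_s"],
        ).to_csv(d / "blocks.tsv", sep="\t", index=False)
    return d


class _ArrayEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, set):
            return sorted(obj)
        return super().default(obj)


def write_results(result, path) -> Path:
    """Serialize a result object.

    Objects exposing ``to_frame()`` are written as TSV; objects exposing
    ``to_dict()`` (and plain mappings) as JSON.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(result, "to_frame"):
        result.to_frame().to_csv(path, sep="\t", index=False)
    elif hasattr(result, "to_dict") or isinstance(result, dict):
        payload = result.to_dict() if hasattr(result, "to_dict") else result
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, cls=_ArrayEncoder, indent=1)
    else:
        raise TypeError(f"do not know how to serialize {type(result).__name__}")
    return path


def read_results_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
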