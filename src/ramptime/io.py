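"""Session file schemas and result writing.

A session is a directory of UTF-8 tab-delimited tables with header rows and
``NA`` for missing values:

* ``trials.tsv``  -- trial_id, task, condition, direction, fp_on_ms,
  cue_on_ms, saccade_ms, landing_error_deg
* ``spikes.tsv``  -- trial_id, spike_ms
* ``eye.tsv``     -- trial_id, t_ms, x_deg, y_deg (optional)
* ``metadata.tsv``-- key/value pairs: neuron_id, structure, monkey, agent,
  schema_version

Times are integer milliseconds on the trial clock (canonical form: spike
times are rounded to the grid on write), angles decimal degrees.  A dataset
is a directory of session directories; reading validates referential
integrity of ``trial_id`` across tables and the closed condition/direction
vocabularies.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import SessionData, TrialRecord

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
TRIAL_COLUMNS = [
    "trial_id", "task", "condition", "direction",
    "fp_on_ms", "cue_on_ms", "saccade_ms", "landing_error_deg",
]

__all__ = ["read_session", "read_sessions", "write_session", "write_results"]


class SchemaError(ValueError):
    """A session file violates the table schema."""


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing table: {path}")
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_session(path: str | Path) -> SessionData:
    """Read one session directory into :class:`SessionData`."""
    path = Path(path)
    trials_df = _read_table(path / "trials.tsv", TRIAL_COLUMNS)
    spikes_df = _read_table(path / "spikes.tsv", ["trial_id", "spike_ms"])
    meta_df = _read_table(path / "metadata.tsv", ["key", "value"])
    meta = dict(zip(meta_df["key"].astype(str), meta_df["value"].astype(str)))
    for req in ("neuron_id", "structure"):
        if req not in meta:
            raise SchemaError(f"{path}/metadata.tsv: missing key {req!r}")

    trial_ids = set(trials_df["trial_id"].astype(int))
    bad = set(spikes_df["trial_id"].astype(int)) - trial_ids
    if bad:
        raise SchemaError(f"{path}/spikes.tsv: unknown trial_id values {sorted(bad)[:5]}")
    if (trials_df[["fp_on_ms", "cue_on_ms", "saccade_ms"]] < 0).any().any():
        raise SchemaError(f"{path}/trials.tsv: negative times")

    trials = []
    for row in trials_df.itertuples(index=False):
        try:
            trials.append(
                TrialRecord(
                    trial_id=int(row.trial_id),
                    task=str(row.task),
                    condition=str(row.condition),
                    direction=str(row.direction),
                    fp_on_ms=float(row.fp_on_ms),
                    cue_on_ms=float(row.cue_on_ms),
                    saccade_ms=float(row.saccade_ms),
                    landing_error_deg=float(row.landing_error_deg),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}/trials.tsv trial {row.trial_id}: {exc}") from exc

    spikes: dict[int, np.ndarray] = {tid: np.empty(0) for tid in trial_ids}
    for tid, grp in spikes_df.groupby("trial_id"):
        spikes[int(tid)] = np.sort(grp["spike_ms"].to_numpy(dtype=float))

    eye = None
    eye_path = path / "eye.tsv"
    if eye_path.exists():
        eye_df = _read_table(eye_path, ["trial_id", "t_ms", "x_deg", "y_deg"])
        bad = set(eye_df["trial_id"].astype(int)) - trial_ids
        if bad:
            raise SchemaError(f"{eye_path}: unknown trial_id values {sorted(bad)[:5]}")
        eye = {
            int(tid): grp[["t_ms", "x_deg", "y_deg"]].reset_index(drop=True)
            for tid, grp in eye_df.groupby("trial_id")
        }

    return SessionData(
        neuron_id=meta["neuron_id"],
        structure=meta["structure"],
        trials=trials,
        spikes=spikes,
        eye=eye,
    )


def read_sessions(path: str | Path) -> list[SessionData]:
    """Read every session directory under ``path`` (sorted by name)."""
    path = Path(path)
    dirs = sorted(p for p in path.iterdir() if (p / "trials.tsv").exists())
    if not dirs:
        raise SchemaError(f"no session directories under {path}")
    return [read_session(p) for p in dirs]


def write_session(
    session: SessionData,
    path: str | Path,
    *,
    monkey: str = "NA",
    agent: str = "NA",
) -> Path:
    """Write a session in canonical form (spike times rounded to 1 ms)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials_df = pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "task": t.task,
                "condition": t.condition,
                "direction": t.direction,
                "fp_on_ms": int(round(t.fp_on_ms)),
                "cue_on_ms": int(round(t.cue_on_ms)),
                "saccade_ms": int(round(t.saccade_ms)),
                "landing_error_deg": t.landing_error_deg,
            }
            for t in session.trials
        ],
        columns=TRIAL_COLUMNS,
    )
    trials_df.to_csv(path / "trials.tsv", sep="\t", index=False, na_rep="NA")

    rows = []
    for tid in sorted(session.spikes):
        for s in np.round(session.spikes[tid]).astype(int):
            rows.append((tid, s))
    pd.DataFrame(rows, columns=["trial_id", "spike_ms"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False
    )

    meta = pd.DataFrame(
        {
            "key": ["neuron_id", "structure", "monkey", "agent", "schema_version"],
            "value": [session.neuron_id, session.structure, monkey, agent, SCHEMA_VERSION],
        }
    )
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)

    if session.eye:
        frames = []
        for tid in sorted(session.eye):
            df = session.eye[tid].copy()
            df.insert(0, "trial_id", tid)
            df["t_ms"] = df["t_ms"].astype(int)
            frames.append(df)
        pd.concat(frames).to_csv(
            path / "eye.tsv", sep="\t", index=False, float_format="%.4f"
        )
    return path


def write_results(
    results: Mapping[str, pd.DataFrame],
    path: str | Path,
    manifest: Mapping[str, object] | None = None,
) -> Path:
    """Emit result tables as TSV plus a JSON run manifest.

    The manifest records config, seeds, package version and per-input
    counts; callers pass whatever run metadata applies.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        df.to_csv(path / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    from . import __version__

    payload = {"schema_version": SCHEMA_VERSION, "package_version": __version__}
    payload.update(manifest or {})
    (path / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))
    return path
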