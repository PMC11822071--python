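"""Long-format CSV persistence for recordings and derived tables.

One row per sample, columns::

    participant_id,trial_id,condition,task,load,time_s,gaze_x_px,gaze_y_px,
    pupil_mm,hrp,gsr_ohm,valid,baseline_pupil_mm

UTF-8, '.' decimal, header mandatory.  The round trip is lossless at the
written precision (17 significant digits, i.e. exact for float64).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import GROUP_OF_CONDITION
from .synthetic import RecordingStream

__all__ = ["write_recordings", "read_recordings", "RecordingParseError"]

_REQUIRED = [
    "participant_id",
    "trial_id",
    "condition",
    "time_s",
    "gaze_x_px",
    "gaze_y_px",
    "pupil_mm",
    "hrp",
    "gsr_ohm",
    "valid",
    "baseline_pupil_mm",
]


class RecordingParseError(ValueError):
    """Raised when a recordings CSV is malformed."""


def write_recordings(streams: list[RecordingStream], path: str | Path) -> None:
    """Write all streams to one long-format CSV."""
    frames = []
    for s in streams:
        group = GROUP_OF_CONDITION.get(s.condition, "")
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "trial_id": s.trial_id,
                    "condition": s.condition,
                    "task": "mental_calculation" if group.startswith("mc") else "visual_search",
                    "load": "low" if group.endswith("low") else "high",
                    "time_s": s.time,
                    "gaze_x_px": s.gaze_x,
                    "gaze_y_px": s.gaze_y,
                    "pupil_mm": s.pupil,
                    "hrp": s.hrp,
                    "gsr_ohm": s.gsr,
                    "valid": s.valid.astype(int),
                    "baseline_pupil_mm": s.baseline_pupil,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_recordings(path: str | Path) -> list[RecordingStream]:
    """Read a long-format recordings CSV back into streams.

    Raises :class:`RecordingParseError` for an empty file, missing columns,
    non-monotone time, or per-trial array inconsistencies, naming the
    offending trial where applicable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as e:
        raise RecordingParseError(f"cannot read recordings from {path}: {e}") from e
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise RecordingParseError(f"missing required columns: {missing}")
    if df.empty:
        raise RecordingParseError("recordings file contains no samples")

    streams = []
    for (pid, tid), g in df.groupby(["participant_id", "trial_id"], sort=False):
        t = g["time_s"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise RecordingParseError(f"non-monotone time in trial {pid}/{tid}")
        cond = g["condition"].iloc[0]
        streams.append(
            RecordingStream(
                participant_id=str(pid),
                trial_id=str(tid),
                condition=str(cond),
                time=t,
                gaze_x=g["gaze_x_px"].to_numpy(dtype=float),
                gaze_y=g["gaze_y_px"].to_numpy(dtype=float),
                pupil=g["pupil_mm"].to_numpy(dtype=float),
                hrp=g["hrp"].to_numpy(dtype=float),
                gsr=g["gsr_ohm"].to_numpy(dtype=float),
                valid=g["valid"].to_numpy(dtype=bool),
                baseline_pupil=float(g["baseline_pupil_mm"].iloc[0]),
            )
        )
    return streams
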