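"""Dispersion-based gaze event detection and outlier reduction.

Segments a raw gaze stream into fixations and saccades with the classic
I-DT (identification by dispersion threshold) algorithm: a sliding window
is grown while the spatial spread of its samples, measured as
``(max x - min x) + (max y - min y)``, stays at or below a dispersion
threshold; windows that span at least a minimum duration are emitted as
fixations.  Saccades are the transitions between consecutive fixation
centroids.  The module also provides the upper-tail winsorization used to
tame outlying fixation durations and saccade amplitudes: values above
``mean + 1*IQR`` are reduced to the highest non-outlying value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GazeSample",
    "Fixation",
    "Saccade",
    "EventParams",
    "px_per_degree",
    "detect_fixations",
    "saccades_between",
    "winsorize_upper",
]


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: time (s), screen position (px), pupil (mm), validity."""

    time: float
    x: float
    y: float
    pupil: float = float("nan")
    valid: bool = True


@dataclass(frozen=True)
class Fixation:
    """A stationary gaze event."""

    onset: float
    offset: float
    centroid_x: float
    centroid_y: float
    mean_pupil: float
    n_samples: int

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0


@dataclass(frozen=True)
class Saccade:
    """A ballistic transition between two consecutive fixations.

    Amplitude is the Euclidean distance between the fixation centroids, in px.
    """

    onset: float
    offset: float
    amplitude: float


@dataclass(frozen=True)
class EventParams:
    """I-DT parameters: dispersion threshold (px) and minimum duration (ms).

    Defaults correspond to 1.0 degree of visual angle at a 570 mm viewing
    distance on a 21.5-inch 1920x1080 display (~= 40 px) and the
    conventional 100 ms minimum fixation duration.
    """

    dispersion_threshold: float = 40.0
    min_duration: float = 100.0
    max_gap_samples: int = 3

    def __post_init__(self) -> None:
        if self.dispersion_threshold <= 0:
            raise ValueError("dispersion_threshold must be > 0")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")


def px_per_degree(
    screen_px: float = 1920.0,
    screen_mm: float = 476.0,
    viewing_distance_mm: float = 570.0,
) -> float:
    """Pixels subtended by one degree of visual angle at screen centre."""
    mm_per_deg = 2.0 * viewing_distance_mm * math.tan(math.radians(0.5))
    return screen_px / screen_mm * mm_per_deg


def _bridge_invalid(samples: list[GazeSample], max_gap: int) -> list[list[GazeSample]]:
    """Split the stream at long invalid runs; interpolate across short ones.

    Runs of at most ``max_gap`` consecutive invalid samples are bridged by
    linear interpolation of x, y and pupil between the flanking valid
    samples; longer runs (and leading/trailing invalid samples) terminate
    the current segment.
    """
    segments: list[list[GazeSample]] = []
    current: list[GazeSample] = []
    pending: list[GazeSample] = []
    for s in samples:
        if s.valid and np.isfinite(s.x) and np.isfinite(s.y):
            if pending:
                if current and len(pending) <= max_gap:
                    a = current[-1]
                    span = s.time - a.time
                    for g in pending:
                        w = (g.time - a.time) / span if span > 0 else 0.5
                        current.append(
                            GazeSample(
                                time=g.time,
                                x=a.x + w * (s.x - a.x),
                                y=a.y + w * (s.y - a.y),
                                pupil=a.pupil + w * (s.pupil - a.pupil),
                                valid=True,
                            )
                        )
                else:
                    if current:
                        segments.append(current)
                    current = []
                pending = []
            current.append(s)
        else:
            pending.append(s)
    if current:
        segments.append(current)
    return segments


def _dispersion(xs: np.ndarray, ys: np.ndarray, lo: int, hi: int) -> float:
    """(max x - min x) + (max y - min y) over samples lo..hi inclusive."""
    w = slice(lo, hi + 1)
    return float(xs[w].max() - xs[w].min() + ys[w].max() - ys[w].min())


def detect_fixations(
    samples: "list[GazeSample] | np.ndarray",
    params: EventParams | None = None,
) -> list[Fixation]:
    """Run I-DT over a time-ordered gaze stream.

    The window is initialised to cover ``min_duration``; if its dispersion
    is within threshold it is extended sample by sample until the threshold
    would be exceeded, then emitted as a fixation.  Otherwise the first
    sample is dropped and the window re-anchored.  Invalid-sample gaps are
    handled per :func:`_bridge_invalid`.

    Returns an empty list (with a warning) when fewer than two valid
    samples are available.
    """
    params = params or EventParams()
    samples = list(samples)
    n_valid = sum(1 for s in samples if s.valid and np.isfinite(s.x))
    if n_valid < 2:
        warnings.warn("fewer than 2 valid gaze samples; no fixations detected")
        return []

    min_dur_s = params.min_duration / 1000.0
    fixations: list[Fixation] = []
    for seg in _bridge_invalid(samples, params.max_gap_samples):
        t = np.array([s.time for s in seg])
        xs = np.array([s.x for s in seg])
        ys = np.array([s.y for s in seg])
        ps = np.array([s.pupil for s in seg])
        n = len(seg)
        i = 0
        while i < n:
            # initial window spanning at least min_duration
            j = i
            while j < n and t[j] - t[i] < min_dur_s:
                j += 1
            if j >= n:
                break  # remaining samples cannot span min_duration
            if _dispersion(xs, ys, i, j) <= params.dispersion_threshold:
                while j + 1 < n and _dispersion(xs, ys, i, j + 1) <= params.dispersion_threshold:
                    j += 1
                w = slice(i, j + 1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    mp = float(np.nanmean(ps[w]))
                fixations.append(
                    Fixation(
                        onset=float(t[i]),
                        offset=float(t[j]),
                        centroid_x=float(xs[w].mean()),
                        centroid_y=float(ys[w].mean()),
                        mean_pupil=mp,
                        n_samples=j - i + 1,
                    )
                )
                i = j + 1
            else:
                i += 1
    return fixations


def saccades_between(fixations: list[Fixation]) -> list[Saccade]:
    """Saccades implied by consecutive fixation centroids (n fixations -> n-1)."""
    out: list[Saccade] = []
    for a, b in zip(fixations, fixations[1:]):
        out.append(
            Saccade(
                onset=a.offset,
                offset=b.onset,
                amplitude=math.hypot(b.centroid_x - a.centroid_x, b.centroid_y - a.centroid_y),
            )
        )
    return out


def events_frame(fixations: list[Fixation], saccades: list[Saccade],
                 participant_id: str = "", trial_id: str = ""):
    """Long-format event table: one row per fixation or saccade.

    Columns: participant_id, trial_id, event_type, onset_s, offset_s,
    duration_ms, centroid_x_px, centroid_y_px, amplitude_px, mean_pupil_mm.
    """
    import pandas as pd

    rows = []
    for f in fixations:
        rows.append(
            {
                "participant_id": participant_id,
                "trial_id": trial_id,
                "event_type": "fixation",
                "onset_s": f.onset,
                "offset_s": f.offset,
                "duration_ms": f.duration_ms,
                "centroid_x_px": f.centroid_x,
                "centroid_y_px": f.centroid_y,
                "amplitude_px": np.nan,
                "mean_pupil_mm": f.mean_pupil,
            }
        )
    for s in saccades:
        rows.append(
            {
                "participant_id": participant_id,
                "trial_id": trial_id,
                "event_type": "saccade",
                "onset_s": s.onset,
                "offset_s": s.offset,
                "duration_ms": (s.offset - s.onset) * 1000.0,
                "centroid_x_px": np.nan,
                "centroid_y_px": np.nan,
                "amplitude_px": s.amplitude,
                "mean_pupil_mm": np.nan,
            }
        )
    cols = [
        "participant_id", "trial_id", "event_type", "onset_s", "offset_s",
        "duration_ms", "centroid_x_px", "centroid_y_px", "amplitude_px", "mean_pupil_mm",
    ]
    frame = pd.DataFrame(rows, columns=cols)
    return frame.sort_values("onset_s", kind="stable").reset_index(drop=True)


def winsorize_upper(values) -> np.ndarray:
    """Reduce upper outliers to the highest non-outlying value.

    A single pass: the bound is ``mean + 1*IQR`` computed on the input
    (quantiles by linear interpolation between order statistics); every
    value above the bound is replaced by the largest value at or below it.
    Order and length are preserved.  If no value lies at or below the bound
    the bound itself is substituted, with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("winsorize_upper: empty input")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    bound = v.mean() + (q3 - q1)
    out = v.copy()
    mask = out > bound
    if not mask.any():
        return out
    keep = out[~mask]
    if keep.size == 0:
        warnings.warn("all values outlying; replacing with the bound itself")
        ceiling = bound
    else:
        ceiling = keep.max()
    out[mask] = ceiling
    return out
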