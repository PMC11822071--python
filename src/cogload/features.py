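"""Per-trial oculometric and biometric predictors.

Seven physiological features per trial, plus the participant's backward
digit-span score and the condition labels:

* mean fixation duration (ms) and mean saccade amplitude (px) — first-order
  oculometrics from the I-DT events, upper-winsorized per participant x task;
* the K coefficient of ambient/focal attention — mean over a trial's
  (fixation, following saccade) pairs of the z-scored fixation duration minus
  the z-scored amplitude of the following saccade, standardized per
  participant x task (positive = focal, negative = ambient attention);
* LHIPA — the Low-High Index of Pupillary Activity, a wavelet index of the
  ratio of low- to high-frequency pupil oscillation;
* pupil dilation — percent change of mean trial pupil diameter vs. the
  pre-task baseline-screen diameter;
* HRV — the SDNN of 3-beat-smoothed inter-beat intervals recovered from the
  heart-rate pulse signal by local peak detection;
* GSR — mean skin resistance (Ohms) over the trial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import find_peaks

from .gaze import (
    EventParams,
    Fixation,
    GazeSample,
    Saccade,
    detect_fixations,
    saccades_between,
    winsorize_upper,
)

__all__ = [
    "StandardizationStats",
    "IbiSeries",
    "LhipaParams",
    "PeakParams",
    "k_coefficient",
    "lhipa",
    "pupil_dilation",
    "ibi_from_hrp",
    "hrv_sdnn",
    "gsr_level",
    "gsr_in_plausible_range",
    "build_feature_table",
    "FEATURE_COLUMNS",
    "GROUP_OF_CONDITION",
]

#: plausible skin-resistance range (Ohms)
GSR_PLAUSIBLE = (10_000.0, 2_000_000.0)

#: condition label -> four-group factor (task x load)
GROUP_OF_CONDITION = {
    "short_easy": "mc_low",
    "short_hard": "mc_low",
    "long_easy": "mc_high",
    "long_hard": "mc_high",
    "parallel_hit": "vs_low",
    "parallel_reject": "vs_low",
    "serial_hit": "vs_high",
    "serial_reject": "vs_high",
}

FEATURE_COLUMNS = [
    "fix_dur_ms",
    "sacc_amp_px",
    "k_coef",
    "hrv_s",
    "gsr_ohm",
    "lhipa",
    "pupil_dilation_pct",
    "dspan_backward",
]


@dataclass(frozen=True)
class StandardizationStats:
    """Fixation-duration and saccade-amplitude mean/SD for one participant x task.

    Computed over all (d_i, a_{i+1}) pairs in the scope so the K_i values
    average exactly to zero over the scope.
    """

    mu_d: float
    sigma_d: float
    mu_a: float
    sigma_a: float

    def __post_init__(self) -> None:
        if not (self.sigma_d > 0 and self.sigma_a > 0):
            raise ValueError("standardization SDs must be > 0")


def k_coefficient(
    durations_ms,
    amplitudes_px,
    stats: StandardizationStats,
) -> tuple[float, np.ndarray]:
    """K coefficient for one trial.

    ``durations_ms[i]`` is the duration of the i-th fixation, paired with the
    amplitude of the following saccade ``amplitudes_px[i]``.  Returns the
    trial K (mean of K_i) and the per-pair K_i.  With no pairs the trial
    value is NaN.
    """
    d = np.asarray(durations_ms, dtype=float)
    a = np.asarray(amplitudes_px, dtype=float)
    if d.shape != a.shape:
        raise ValueError("durations and amplitudes must pair one-to-one")
    if d.size == 0:
        return float("nan"), np.empty(0)
    k_i = (d - stats.mu_d) / stats.sigma_d - (a - stats.mu_a) / stats.sigma_a
    return float(k_i.mean()), k_i


# ---------------------------------------------------------------------------
# LHIPA


@dataclass(frozen=True)
class LhipaParams:
    """Wavelet settings for the Low-High Index of Pupillary Activity.

    ``wavelet`` is the discrete wavelet family used for the decomposition;
    the high-frequency band is the level-1 detail and the low-frequency band
    the detail at level ``floor(log2(n)/2)`` (capped at the maximal useful
    decomposition level).  The LF/HF coefficient ratio is reduced to its
    modulus maxima, maxima below the universal threshold
    ``sigma_hat * sqrt(2 ln n)`` (sigma_hat = MAD of the finest-detail
    coefficients / 0.6745) are discarded, and the surviving count is divided
    by the signal duration in seconds.
    """

    wavelet: str = "sym16"
    mode: str = "periodization"
    normalize_by_duration: bool = True


def _modulus_maxima(x: np.ndarray) -> np.ndarray:
    """Magnitudes at local maxima of |x|; zero elsewhere."""
    m = np.abs(x)
    out = np.zeros_like(m)
    for i in range(len(m)):
        left = m[i - 1] if i > 0 else m[i]
        right = m[i + 1] if i < len(m) - 1 else m[i]
        if left <= m[i] >= right and (left < m[i] or m[i] > right):
            out[i] = m[i]
    return out


def lhipa(
    pupil: np.ndarray,
    fs: float = 150.0,
    params: LhipaParams | None = None,
) -> float:
    """Low-High Index of Pupillary Activity of one trial's pupil trace.

    Returns NaN for series shorter than 16 samples; 0 (with a warning) for a
    signal with no countable oscillatory structure (e.g. constant input).
    """
    params = params or LhipaParams()
    x = np.asarray(pupil, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 16:
        warnings.warn("pupil series too short for LHIPA; flagged missing")
        return float("nan")

    if np.ptp(x) < 1e-12:
        warnings.warn("constant pupil signal; LHIPA = 0")
        return 0.0

    w = pywt.Wavelet(params.wavelet)
    hif = 1
    lof = max(int(math.log2(n) / 2), 2)

    with warnings.catch_warnings():
        # the band definition may exceed pywt's "useful" level; boundary
        # effects are part of the index as defined
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, w, mode=params.mode, level=max(lof, hif))
    # wavedec returns [cA_L, cD_L, ..., cD_1]
    cd_h = np.asarray(coeffs[-hif], dtype=float) / math.sqrt(2.0**hif)
    cd_l = np.asarray(coeffs[len(coeffs) - 1 - (lof - 1)], dtype=float) / math.sqrt(2.0**lof)

    # align the HF band to the LF band's coarser grid
    step = 2 ** (lof - hif)
    cd_h_ds = cd_h[::step][: cd_l.size]
    cd_l = cd_l[: cd_h_ds.size]
    eps = 1e-12 * max(float(np.abs(cd_h).max()), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(cd_h_ds) > eps, cd_l / cd_h_ds, 0.0)
    if not np.isfinite(ratio).all() or ratio.size == 0:
        warnings.warn("degenerate LF/HF ratio; LHIPA set to 0")
        return 0.0

    maxima = _modulus_maxima(ratio)
    sigma_hat = float(np.median(np.abs(cd_h - np.median(cd_h)))) / 0.6745
    lam = sigma_hat * math.sqrt(2.0 * math.log(n))
    count = int(np.count_nonzero(maxima > lam))
    if params.normalize_by_duration:
        return count / (n / fs)
    return float(count)


def pupil_dilation(pupil: np.ndarray, baseline_pupil: float) -> float:
    """Percent change of mean trial pupil diameter vs. the pre-task baseline."""
    if not baseline_pupil > 0:
        raise ValueError("baseline pupil diameter must be > 0")
    x = np.asarray(pupil, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    return 100.0 * (float(x.mean()) - baseline_pupil) / baseline_pupil


# ---------------------------------------------------------------------------
# Heart-rate pulse -> IBI -> HRV


@dataclass(frozen=True)
class PeakParams:
    """Pulse-peak detection settings.

    ``min_distance_s`` is the refractory spacing between peaks (0.33 s ~=
    180 bpm ceiling); prominence is adaptive, ``prominence_frac`` times the
    5th-95th percentile span of the trial's pulse signal.
    """

    min_distance_s: float = 0.33
    prominence_frac: float = 0.25


@dataclass
class IbiSeries:
    """Pulse-peak times (s), raw inter-beat intervals and their 3-beat smooth."""

    peak_times: np.ndarray
    ibis: np.ndarray
    smoothed_ibis: np.ndarray = field(default_factory=lambda: np.empty(0))


def _moving_average_3(x: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average, window shrinking to 2 at the edges."""
    n = x.size
    if n <= 2:
        return x.copy()
    out = np.empty(n)
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def ibi_from_hrp(hrp: np.ndarray, fs: float = 150.0, params: PeakParams | None = None) -> IbiSeries | None:
    """Inter-beat intervals from the unitless heart-rate pulse signal.

    Local maxima with a minimum spacing and adaptive prominence give beat
    times; successive differences give the IBIs, smoothed by a 3-beat
    centered moving average.  Returns None (missing) when fewer than two
    peaks are found.
    """
    params = params or PeakParams()
    x = np.asarray(hrp, dtype=float)
    if x.size < 2 * fs:
        warnings.warn("pulse series shorter than 2 s; IBI flagged missing")
        return None
    lo, hi = np.percentile(x, [5.0, 95.0])
    span = hi - lo
    if span <= 0:
        return None
    peaks, _ = find_peaks(
        x,
        distance=max(int(round(params.min_distance_s * fs)), 1),
        prominence=params.prominence_frac * span,
    )
    if peaks.size < 2:
        return None
    peak_times = peaks / fs
    ibis = np.diff(peak_times)
    return IbiSeries(peak_times=peak_times, ibis=ibis, smoothed_ibis=_moving_average_3(ibis))


def hrv_sdnn(ibi: IbiSeries | None) -> float:
    """Sample SD (ddof=1) of the smoothed IBIs; NaN with < 2 intervals."""
    if ibi is None or ibi.smoothed_ibis.size < 2:
        return float("nan")
    return float(np.std(ibi.smoothed_ibis, ddof=1))


def gsr_level(gsr: np.ndarray) -> float:
    """Mean skin resistance (Ohms) over the trial; NaN if no valid samples."""
    x = np.asarray(gsr, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    return float(x.mean())


def gsr_in_plausible_range(value: float) -> bool:
    """Whether a GSR level sits in the physiologically typical 10 kOhm - 2 MOhm."""
    return bool(GSR_PLAUSIBLE[0] <= value <= GSR_PLAUSIBLE[1])


# ---------------------------------------------------------------------------
# Feature table assembly


def _trial_events(stream, params: EventParams) -> tuple[list[Fixation], list[Saccade]]:
    samples = [
        GazeSample(time=t, x=x, y=y, pupil=p, valid=bool(v))
        for t, x, y, p, v in zip(stream.time, stream.gaze_x, stream.gaze_y, stream.pupil, stream.valid)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fixations = detect_fixations(samples, params)
    return fixations, saccades_between(fixations)


def build_feature_table(
    streams,
    participants: pd.DataFrame,
    event_params: EventParams | None = None,
    lhipa_params: LhipaParams | None = None,
    peak_params: PeakParams | None = None,
    fs: float = 150.0,
) -> pd.DataFrame:
    """Assemble the labelled per-trial feature table.

    ``streams`` is an iterable of recording streams (one per trial);
    ``participants`` maps ``participant_id`` to ``dspan_backward``.
    Winsorization of fixation durations and saccade amplitudes and the K
    standardization statistics are scoped per participant x task, pooling
    all of that participant's events in the task before the per-trial
    aggregation.  Missing features carry NaN plus a ``*_missing`` flag.
    """
    event_params = event_params or EventParams()
    streams = list(streams)
    ids = [(s.participant_id, s.trial_id) for s in streams]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate (participant_id, trial_id) in recordings")

    dspan = participants.set_index("participant_id")["dspan_backward"].to_dict()

    # per-trial event detection
    per_trial: list[dict] = []
    for s in streams:
        fixations, saccades = _trial_events(s, event_params)
        task = "mental_calculation" if s.condition.startswith(("short", "long")) else "visual_search"
        per_trial.append(
            {
                "stream": s,
                "task": task,
                "fixations": fixations,
                "saccades": saccades,
            }
        )

    # participant x task winsorization scope
    frame_rows = []
    scope_key = lambda rec: (rec["stream"].participant_id, rec["task"])  # noqa: E731
    scopes: dict[tuple, list[dict]] = {}
    for rec in per_trial:
        scopes.setdefault(scope_key(rec), []).append(rec)

    for (_pid, _task), recs in scopes.items():
        durations = np.array([f.duration_ms for rec in recs for f in rec["fixations"]])
        amplitudes = np.array([sc.amplitude for rec in recs for sc in rec["saccades"]])
        if durations.size:
            durations_w = winsorize_upper(durations)
        else:
            durations_w = durations
        if amplitudes.size:
            amplitudes_w = winsorize_upper(amplitudes)
        else:
            amplitudes_w = amplitudes

        # distribute winsorized values back to trials
        di = ai = 0
        for rec in recs:
            nf, ns = len(rec["fixations"]), len(rec["saccades"])
            rec["dur_w"] = durations_w[di : di + nf]
            rec["amp_w"] = amplitudes_w[ai : ai + ns]
            di += nf
            ai += ns

        # K standardization over the paired events of the scope
        pair_d = np.concatenate([rec["dur_w"][: len(rec["amp_w"])] for rec in recs]) if recs else np.empty(0)
        pair_a = np.concatenate([rec["amp_w"] for rec in recs]) if recs else np.empty(0)
        stats = None
        if pair_d.size >= 2 and pair_d.std(ddof=1) > 0 and pair_a.std(ddof=1) > 0:
            stats = StandardizationStats(
                mu_d=float(pair_d.mean()),
                sigma_d=float(pair_d.std(ddof=1)),
                mu_a=float(pair_a.mean()),
                sigma_a=float(pair_a.std(ddof=1)),
            )

        for rec in recs:
            s = rec["stream"]
            if s.condition not in GROUP_OF_CONDITION:
                raise ValueError(f"unknown condition label: {s.condition!r}")
            fix_dur = float(rec["dur_w"].mean()) if rec["dur_w"].size else float("nan")
            sacc_amp = float(rec["amp_w"].mean()) if rec["amp_w"].size else float("nan")
            if stats is not None and rec["amp_w"].size:
                k, _ = k_coefficient(rec["dur_w"][: rec["amp_w"].size], rec["amp_w"], stats)
            else:
                k = float("nan")
            pupil = np.asarray(s.pupil, dtype=float)
            pupil_valid = pupil[np.asarray(s.valid, dtype=bool)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lh = lhipa(pupil_valid, fs=fs, params=lhipa_params)
                dil = pupil_dilation(pupil_valid, s.baseline_pupil)
                hrv = hrv_sdnn(ibi_from_hrp(np.asarray(s.hrp, dtype=float), fs=fs, params=peak_params))
            gsr = gsr_level(np.asarray(s.gsr, dtype=float))

            row = {
                "participant_id": s.participant_id,
                "trial_id": s.trial_id,
                "condition": s.condition,
                "task": rec["task"],
                "load": "low" if GROUP_OF_CONDITION[s.condition].endswith("low") else "high",
                "group": GROUP_OF_CONDITION[s.condition],
                "fix_dur_ms": fix_dur,
                "sacc_amp_px": sacc_amp,
                "k_coef": k,
                "hrv_s": hrv,
                "gsr_ohm": gsr,
                "lhipa": lh,
                "pupil_dilation_pct": dil,
                "dspan_backward": float(dspan.get(s.participant_id, float("nan"))),
                "gsr_out_of_range": not gsr_in_plausible_range(gsr) if np.isfinite(gsr) else False,
            }
            frame_rows.append(row)

    table = pd.DataFrame(frame_rows)
    for col in FEATURE_COLUMNS:
        table[f"{col}_missing"] = ~np.isfinite(table[col].to_numpy(dtype=float))
    order = [s.participant_id + "\x00" + s.trial_id for s in streams]
    table["_order"] = [p + "\x00" + t for p, t in zip(table["participant_id"], table["trial_id"])]
    table = table.set_index("_order").loc[order].reset_index(drop=True)
    return table
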