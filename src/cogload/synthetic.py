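"""Synthetic multimodal cognitive-load recordings.

Emulates the study design the analysis pipeline expects: 33 participants,
each completing 24 mental-calculation trials (six per condition:
short-easy, short-hard, long-easy, long-hard; ~3000 ms answer windows) and
20 visual-search trials (parallel vs. serial search, hit vs. reject,
response-terminated durations), with gaze, pupil, heart-rate pulse and
skin-resistance streams sampled at 150 Hz.

Gaze alternates stationary fixation clusters (Gaussian scatter, durations
drawn per-condition from a lognormal) with short ballistic transitions
whose amplitudes are drawn from a per-condition lognormal.  The pupil trace
is the participant baseline plus a condition-dependent offset, a slow
(<= 0.5 Hz) sinusoid, band-limited 1.2-4 Hz noise and white measurement
noise.  The pulse channel is a raised-cosine pulse train with truncated-
normal inter-beat intervals; skin resistance is a condition level with slow
multiplicative drift.  Default condition parameters are calibrated to the
per-condition feature means the analysis is designed to resolve; an
effect-size multiplier scales every between-condition difference (0 gives
a null dataset in which all conditions share one set of generative
parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ConditionProfile",
    "ParticipantProfile",
    "RecordingStream",
    "SyntheticConfig",
    "ScreenGeometry",
    "default_profiles",
    "resolve_profiles",
    "generate_trial",
    "generate_dataset",
]

FS = 150.0  # Hz, eye tracker + biometric module sampling rate

MCT_CONDITIONS = ("short_easy", "short_hard", "long_easy", "long_hard")
VST_CONDITIONS = ("parallel_hit", "parallel_reject", "serial_hit", "serial_reject")


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry used to convert visual angle to pixels."""

    width_px: int = 1920
    height_px: int = 1080
    width_mm: float = 476.0
    viewing_distance_mm: float = 570.0

    def deg_to_px(self, deg: float) -> float:
        mm = 2.0 * self.viewing_distance_mm * math.tan(math.radians(deg / 2.0))
        return mm * self.width_px / self.width_mm


@dataclass(frozen=True)
class ConditionProfile:
    """Generative parameters of one experimental condition.

    Distribution locations/scales are on the natural scale: fixation
    durations (ms) and saccade amplitudes (px) are lognormal with the given
    mean and SD; IBIs are Normal(ibi_mean, ibi_sd) truncated positive.
    ``pupil_baseline_offset`` is the sustained dilation of the condition in
    percent of the participant's baseline diameter.
    """

    label: str
    task: str
    load: str
    n_trials: int
    trial_duration_ms: float
    trial_duration_jitter_ms: float
    fixation_duration_mean_ms: float
    fixation_duration_sd_ms: float
    saccade_amplitude_mean_px: float
    saccade_amplitude_sd_px: float
    pupil_baseline_offset_pct: float
    pupil_lf_amp_mm: float
    pupil_hf_amp_mm: float
    ibi_mean_s: float
    ibi_sd_s: float
    gsr_level_ohm: float

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for f in ("fixation_duration_mean_ms", "fixation_duration_sd_ms",
                  "saccade_amplitude_mean_px", "saccade_amplitude_sd_px",
                  "gsr_level_ohm"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        if not (0.4 <= self.ibi_mean_s <= 1.5):
            raise ValueError("ibi_mean_s must lie in [0.4, 1.5] s")


# numeric fields scaled by the effect-size multiplier
_EFFECT_FIELDS = (
    "trial_duration_ms",
    "trial_duration_jitter_ms",
    "fixation_duration_mean_ms",
    "fixation_duration_sd_ms",
    "saccade_amplitude_mean_px",
    "saccade_amplitude_sd_px",
    "pupil_baseline_offset_pct",
    "pupil_lf_amp_mm",
    "pupil_hf_amp_mm",
    "ibi_mean_s",
    "ibi_sd_s",
    "gsr_level_ohm",
)


def default_profiles() -> dict[str, ConditionProfile]:
    """Per-condition defaults calibrated to the study's feature-level means.

    Six trials per mental-calculation condition and five per visual-search
    condition (20 visual-search trials in total).  Mental-calculation answer
    windows are fixed at 3000 ms; visual-search trials are response-
    terminated, emulated with lognormal durations (serial slower than
    parallel).
    """
    rows = {
        #  label            dur    jit  fixm fixsd sacm sacsd   off%    lf     hf    ibim  ibisd     gsr
        "short_easy":     (3000.0,   0.0, 366., 180., 240., 110.,  1.52, 0.05, 0.065, 0.75, 0.30,  354849.0),
        "short_hard":     (3000.0,   0.0, 440., 180., 286., 110.,  2.80, 0.05, 0.045, 0.75, 0.22,  354764.0),
        "long_easy":      (3000.0,   0.0, 425., 180., 301., 110.,  3.30, 0.05, 0.042, 0.75, 0.23,  348591.0),
        "long_hard":      (3000.0,   0.0, 429., 180., 325., 110.,  4.72, 0.05, 0.028, 0.75, 0.17,  346919.0),
        "parallel_hit":   (2600.0, 500.0, 407., 190., 249., 115., -3.59, 0.05, 0.065, 0.75, 0.020, 603614.0),
        "parallel_reject":(2600.0, 500.0, 452., 190., 326., 115., -3.11, 0.05, 0.042, 0.75, 0.020, 1157920.0),
        "serial_hit":     (4200.0, 900.0, 546., 230., 284., 115., -2.26, 0.05, 0.040, 0.75, 0.020, 892198.0),
        "serial_reject":  (4200.0, 900.0, 529., 200., 305., 115., -3.19, 0.05, 0.025, 0.75, 0.020, 609290.0),
    }
    out = {}
    for label, r in rows.items():
        mct = label in MCT_CONDITIONS
        out[label] = ConditionProfile(
            label=label,
            task="mental_calculation" if mct else "visual_search",
            load="low" if label.startswith(("short", "parallel")) else "high",
            n_trials=6 if mct else 5,
            trial_duration_ms=r[0],
            trial_duration_jitter_ms=r[1],
            fixation_duration_mean_ms=r[2],
            fixation_duration_sd_ms=r[3],
            saccade_amplitude_mean_px=r[4],
            saccade_amplitude_sd_px=r[5],
            pupil_baseline_offset_pct=r[6],
            pupil_lf_amp_mm=r[7],
            pupil_hf_amp_mm=r[8],
            ibi_mean_s=r[9],
            ibi_sd_s=r[10],
            gsr_level_ohm=r[11],
        )
    return out


@dataclass(frozen=True)
class ParticipantProfile:
    """Stable participant characteristics and between-person random factors.

    The multiplicative factors have unit mean across the population and let
    a dataset carry realistic between-participant variance (which the
    split-half reliability stage depends on).
    """

    participant_id: str
    dspan_backward: int = 7
    pupil_baseline: float = 4.5
    seed_offset: int = 0
    fix_dur_factor: float = 1.0
    sacc_amp_factor: float = 1.0
    gsr_factor: float = 1.0
    ibi_factor: float = 1.0
    ibi_sd_factor: float = 1.0
    hf_pupil_factor: float = 1.0
    dilation_shift_pct: float = 0.0
    # participant x condition interaction multipliers (stable idiosyncratic
    # responses to specific conditions; give the z-scored K coefficient and
    # the other per-group features a between-person variance component)
    cond_fix_factors: dict | None = None
    cond_sacc_factors: dict | None = None

    def fix_factor(self, label: str) -> float:
        base = self.fix_dur_factor
        return base * (self.cond_fix_factors or {}).get(label, 1.0)

    def sacc_factor(self, label: str) -> float:
        base = self.sacc_amp_factor
        return base * (self.cond_sacc_factors or {}).get(label, 1.0)

    def __post_init__(self) -> None:
        if self.dspan_backward < 0:
            raise ValueError("dspan_backward must be >= 0")
        if not (2.0 <= self.pupil_baseline <= 8.0):
            raise ValueError("pupil_baseline must lie in [2, 8] mm")


@dataclass
class RecordingStream:
    """Per-sample multimodal time series of one trial."""

    participant_id: str
    trial_id: str
    condition: str
    time: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil: np.ndarray
    hrp: np.ndarray
    gsr: np.ndarray
    valid: np.ndarray
    baseline_pupil: float

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("gaze_x", "gaze_y", "pupil", "hrp", "gsr", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"sample array {name!r} length mismatch in trial {self.trial_id}")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError(f"time must be strictly increasing in trial {self.trial_id}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Dataset-level settings: cohort size, profiles, geometry, seed, effect size."""

    n_participants: int = 33
    profiles: dict[str, ConditionProfile] = field(default_factory=default_profiles)
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0
    effect_size: float = 1.0
    fixation_scatter_deg: float = 0.05
    invalid_rate: float = 0.002
    dspan_mean: float = 7.24
    dspan_sd: float = 1.02

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size multiplier must be >= 0")


def resolve_profiles(config: SyntheticConfig) -> dict[str, ConditionProfile]:
    """Apply the effect-size multiplier to the configured condition profiles.

    Every numeric generative parameter is blended toward the unweighted
    grand mean over conditions: ``m + effect_size * (value - m)``.  With
    multiplier 0 all conditions become generatively identical (the null);
    with 1 the configured profiles are returned unchanged.
    """
    profs = config.profiles
    if config.effect_size == 1.0:
        return dict(profs)
    means = {
        f: float(np.mean([getattr(p, f) for p in profs.values()])) for f in _EFFECT_FIELDS
    }
    out = {}
    for label, p in profs.items():
        out[label] = replace(
            p,
            **{
                f: means[f] + config.effect_size * (getattr(p, f) - means[f])
                for f in _EFFECT_FIELDS
            },
        )
    return out


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws parameterised by natural-scale mean and SD."""
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, rms: float) -> np.ndarray:
    """White noise band-passed to [lo, hi] Hz via an FFT mask, scaled to RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    cur = float(np.sqrt(np.mean(x**2)))
    return x * (rms / cur) if cur > 0 else x


def _gaze_track(
    rng: np.random.Generator,
    n: int,
    condition: ConditionProfile,
    participant: ParticipantProfile,
    screen: ScreenGeometry,
    scatter_px: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixation/saccade alternation: cluster scatter + 5-sample transitions."""
    margin = 100.0
    w, h = screen.width_px, screen.height_px
    x = np.empty(n)
    y = np.empty(n)
    cx = rng.uniform(w * 0.35, w * 0.65)
    cy = rng.uniform(h * 0.35, h * 0.65)
    i = 0
    transition = 5  # samples (~33 ms) per saccade
    while i < n:
        f = participant.fix_factor(condition.label)
        dur_ms = _lognormal(
            rng,
            condition.fixation_duration_mean_ms * f,
            condition.fixation_duration_sd_ms * f,
        )
        nf = min(int(round(dur_ms * FS / 1000.0)) + 1, n - i)
        nf = max(nf, 1)
        x[i : i + nf] = cx + rng.normal(0.0, scatter_px, nf)
        y[i : i + nf] = cy + rng.normal(0.0, scatter_px, nf)
        i += nf
        if i >= n:
            break
        g = participant.sacc_factor(condition.label)
        amp = float(
            _lognormal(
                rng,
                condition.saccade_amplitude_mean_px * g,
                condition.saccade_amplitude_sd_px * g,
            )
        )
        # pick a direction that keeps the next centroid on screen
        for _ in range(64):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            nx, ny = cx + amp * math.cos(theta), cy + amp * math.sin(theta)
            if margin <= nx <= w - margin and margin <= ny <= h - margin:
                break
        else:  # amplitude larger than any on-screen move: aim at centre
            theta = math.atan2(h / 2 - cy, w / 2 - cx)
            nx, ny = cx + amp * math.cos(theta), cy + amp * math.sin(theta)
        nt = min(transition, n - i)
        frac = np.arange(1, nt + 1) / (transition + 1)
        x[i : i + nt] = cx + frac * (nx - cx)
        y[i : i + nt] = cy + frac * (ny - cy)
        i += nt
        cx, cy = nx, ny
    return x, y


def _pulse_train(rng: np.random.Generator, n: int, ibi_mean: float, ibi_sd: float) -> np.ndarray:
    """Raised-cosine pulse per beat; IBIs ~ Normal truncated to [0.35, 1.5] s."""
    duration = n / FS
    t = np.arange(n) / FS
    beat = float(rng.uniform(0.05, 0.4))
    beats = []
    while beat < duration + 0.5:
        beats.append(beat)
        ibi = float(np.clip(rng.normal(ibi_mean, ibi_sd), 0.35, 1.5))
        beat += ibi
    x = np.zeros(n)
    width = 0.24  # s, pulse footprint
    for b in beats:
        sel = np.abs(t - b) < width / 2
        x[sel] += 0.5 * (1.0 + np.cos(2.0 * math.pi * (t[sel] - b) / width))
    return x + rng.normal(0.0, 0.02, n)


def generate_trial(
    participant: ParticipantProfile,
    condition: ConditionProfile,
    rng: np.random.Generator,
    trial_id: str = "t00",
    screen: ScreenGeometry | None = None,
    scatter_deg: float = 0.05,
    invalid_rate: float = 0.002,
    duration_ms: float | None = None,
) -> RecordingStream:
    """Simulate one trial's multimodal recording stream.

    The trial duration is drawn from the condition's mean + jitter (fixed
    when jitter is 0) unless given explicitly.  Same participant, condition
    and generator state reproduce the identical stream.
    """
    screen = screen or ScreenGeometry()
    if duration_ms is None:
        if condition.trial_duration_jitter_ms > 0:
            duration_ms = float(
                _lognormal(rng, condition.trial_duration_ms, condition.trial_duration_jitter_ms)
            )
            duration_ms = max(duration_ms, 2200.0)
        else:
            duration_ms = condition.trial_duration_ms
    if duration_ms <= 0:
        raise ValueError(f"trial duration must be positive, got {duration_ms} ms")
    n = int(round(duration_ms / 1000.0 * FS))
    t = np.arange(n) / FS

    scatter_px = screen.deg_to_px(scatter_deg)
    gx, gy = _gaze_track(rng, n, condition, participant, screen, scatter_px)

    level = participant.pupil_baseline * (
        1.0
        + (
            condition.pupil_baseline_offset_pct
            + participant.dilation_shift_pct
            + rng.normal(0.0, 4.0)  # trial-to-trial dilation jitter, %
        )
        / 100.0
    )
    lf_freq = rng.uniform(0.15, 0.45)
    pupil = (
        level
        + condition.pupil_lf_amp_mm * np.sin(2.0 * math.pi * lf_freq * t + rng.uniform(0, 2 * math.pi))
        + _band_limited_noise(
            rng, n, FS, 20.0, 70.0, condition.pupil_hf_amp_mm * participant.hf_pupil_factor
        )
        + rng.normal(0.0, 0.01, n)
    )

    hrp = _pulse_train(
        rng,
        n,
        condition.ibi_mean_s * participant.ibi_factor,
        condition.ibi_sd_s * participant.ibi_sd_factor,
    )

    drift = np.cumsum(rng.normal(0.0, 1.0, n))
    drift = drift / (np.abs(drift).max() + 1e-12)
    gsr_base = condition.gsr_level_ohm * participant.gsr_factor * float(_lognormal(rng, 1.0, 0.10))
    gsr = gsr_base * (1.0 + 0.02 * drift) + rng.normal(0.0, 0.002 * gsr_base, n)

    valid = rng.random(n) >= invalid_rate
    baseline_pupil = float(participant.pupil_baseline + rng.normal(0.0, 0.02))

    return RecordingStream(
        participant_id=participant.participant_id,
        trial_id=trial_id,
        condition=condition.label,
        time=t,
        gaze_x=gx,
        gaze_y=gy,
        pupil=pupil,
        hrp=hrp,
        gsr=gsr,
        valid=valid,
        baseline_pupil=baseline_pupil,
    )


def _draw_participants(config: SyntheticConfig, rng: np.random.Generator) -> list[ParticipantProfile]:
    # Global between-person spread is part of the study population, not of
    # the condition contrast, so the effect-size multiplier does not touch
    # it.  Participant x condition interactions DO encode condition
    # structure, so their spread scales with the multiplier (0 -> a clean
    # null in which every condition is generatively identical).
    labels = list(config.profiles)
    inter_fix_sd = 0.12 * min(config.effect_size, 1.0)
    inter_sacc_sd = 0.13 * min(config.effect_size, 1.0)

    def interaction(sd: float) -> dict:
        if sd <= 0:
            return {}
        return {lab: float(rng.lognormal(-sd**2 / 2, sd)) for lab in labels}

    out = []
    for i in range(config.n_participants):
        dspan = int(np.clip(round(rng.normal(config.dspan_mean, config.dspan_sd)), 0, 14))
        out.append(
            ParticipantProfile(
                participant_id=f"p{i + 1:02d}",
                dspan_backward=dspan,
                pupil_baseline=float(np.clip(rng.normal(4.5, 0.5), 2.2, 7.8)),
                seed_offset=i,
                fix_dur_factor=float(rng.lognormal(-0.18**2 / 2, 0.18)),
                sacc_amp_factor=float(rng.lognormal(-0.22**2 / 2, 0.22)),
                gsr_factor=float(rng.lognormal(-0.55**2 / 2, 0.55)),
                ibi_factor=float(rng.lognormal(-0.05**2 / 2, 0.05)),
                ibi_sd_factor=float(rng.lognormal(-0.35**2 / 2, 0.35)),
                hf_pupil_factor=float(rng.lognormal(-0.25**2 / 2, 0.25)),
                dilation_shift_pct=float(rng.normal(0.0, 5.0)),
                cond_fix_factors=interaction(inter_fix_sd),
                cond_sacc_factors=interaction(inter_sacc_sd),
            )
        )
    return out


def generate_dataset(config: SyntheticConfig) -> tuple[list[RecordingStream], "pd.DataFrame"]:
    """Simulate the full cohort: one stream per participant x trial.

    Returns the streams (24 mental-calculation + 20 visual-search trials per
    participant under defaults) and a participant table with the backward
    digit-span covariate (drawn Normal(7.24, 1.02), rounded).
    """
    import pandas as pd

    profiles = resolve_profiles(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants + 1)
    part_rng = np.random.Generator(np.random.PCG64(children[0]))
    participants = _draw_participants(config, part_rng)

    streams: list[RecordingStream] = []
    for participant, child in zip(participants, children[1:]):
        rng = np.random.Generator(np.random.PCG64(child))
        k = 0
        for label in (*MCT_CONDITIONS, *VST_CONDITIONS):
            prof = profiles[label]
            for j in range(prof.n_trials):
                k += 1
                streams.append(
                    generate_trial(
                        participant,
                        prof,
                        rng,
                        trial_id=f"t{k:02d}_{label}",
                        screen=config.screen,
                        scatter_deg=config.fixation_scatter_deg,
                        invalid_rate=config.invalid_rate,
                    )
                )
    table = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "dspan_backward": [p.dspan_backward for p in participants],
            "pupil_baseline_mm": [p.pupil_baseline for p in participants],
        }
    )
    return streams, table
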