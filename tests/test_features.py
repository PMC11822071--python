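"""Per-trial feature computations against hand and step-by-step oracles."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest

from cogload.features import (
    IbiSeries,
    StandardizationStats,
    _moving_average_3,
    build_feature_table,
    gsr_in_plausible_range,
    gsr_level,
    hrv_sdnn,
    ibi_from_hrp,
    k_coefficient,
    lhipa,
    pupil_dilation,
)
from cogload.synthetic import ParticipantProfile, default_profiles, generate_trial


class TestKCoefficient:
    STATS = StandardizationStats(mu_d=400.0, sigma_d=200.0, mu_a=20.0, sigma_a=10.0)

    def test_identity_case_is_zero(self):
        k, k_i = k_coefficient([400.0, 400.0], [20.0, 20.0], self.STATS)
        assert k == 0.0
        assert np.allclose(k_i, 0.0)

    def test_hand_computed_two_pair_example(self):
        # d=[600,600]: z=1; a=[10,20]: z=[-1,0] -> K_i=[2,1], K=1.5
        k, k_i = k_coefficient([600.0, 600.0], [10.0, 20.0], self.STATS)
        assert k_i.tolist() == pytest.approx([2.0, 1.0])
        assert k == pytest.approx(1.5)

    def test_swapping_series_roles_negates(self):
        swapped = StandardizationStats(mu_d=20.0, sigma_d=10.0, mu_a=400.0, sigma_a=200.0)
        k1, _ = k_coefficient([600.0, 500.0], [10.0, 25.0], self.STATS)
        k2, _ = k_coefficient([10.0, 25.0], [600.0, 500.0], swapped)
        assert k2 == pytest.approx(-k1)

    def test_affine_invariance_of_durations_and_amplitudes(self, rng):
        d = rng.lognormal(6, 0.4, 40)
        a = rng.lognormal(5, 0.5, 40)
        stats = StandardizationStats(d.mean(), d.std(ddof=1), a.mean(), a.std(ddof=1))
        k0, _ = k_coefficient(d[:10], a[:10], stats)
        alpha, beta = 3.7, 120.0
        d2 = alpha * d + beta
        stats2 = StandardizationStats(d2.mean(), d2.std(ddof=1), a.mean(), a.std(ddof=1))
        k1, _ = k_coefficient(d2[:10], a[:10], stats2)
        assert k1 == pytest.approx(k0, rel=1e-9)

    def test_mean_over_standardization_scope_is_zero(self, rng):
        d = rng.lognormal(6, 0.4, 60)
        a = rng.lognormal(5, 0.5, 60)
        stats = StandardizationStats(d.mean(), d.std(ddof=1), a.mean(), a.std(ddof=1))
        _, k_i = k_coefficient(d, a, stats)
        assert k_i.mean() == pytest.approx(0.0, abs=1e-12)

    def test_no_pairs_flagged_missing_and_zero_sigma_rejected(self):
        k, k_i = k_coefficient([], [], self.STATS)
        assert math.isnan(k) and k_i.size == 0
        with pytest.raises(ValueError):
            StandardizationStats(400.0, 0.0, 20.0, 10.0)


class TestLhipa:
    def test_constant_signal_gives_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert lhipa(np.full(256, 4.2)) == 0.0

    def test_too_short_series_flagged_missing(self):
        with pytest.warns(UserWarning):
            assert math.isnan(lhipa(np.full(8, 4.0)))

    def test_matches_step_by_step_wavelet_oracle(self):
        """Independent recomputation: downcoef-based transform, explicit MAD
        universal threshold and modulus-maxima count."""
        import pywt

        rng = np.random.default_rng(99)
        t = np.arange(256) / 150.0
        x = 4.5 + 0.08 * np.sin(2 * np.pi * 0.3 * t) + rng.normal(0, 0.02, 256)

        n = len(x)
        w = pywt.Wavelet("sym16")
        hif, lof = 1, int(math.log2(n) / 2)  # 4 for n=256
        cd_h = pywt.downcoef("d", x, w, mode="periodization", level=hif) / math.sqrt(2**hif)
        cd_l = pywt.downcoef("d", x, w, mode="periodization", level=lof) / math.sqrt(2**lof)
        step = 2 ** (lof - hif)
        den = cd_h[::step][: len(cd_l)]
        ratio = np.where(np.abs(den) > 0, cd_l[: len(den)] / den, 0.0)
        # modulus maxima by direct neighbour comparison
        m = np.abs(ratio)
        maxima = []
        for i in range(len(m)):
            left = m[i - 1] if i > 0 else m[i]
            right = m[i + 1] if i < len(m) - 1 else m[i]
            if left <= m[i] >= right and (left < m[i] or m[i] > right):
                maxima.append(m[i])
            else:
                maxima.append(0.0)
        sigma_hat = np.median(np.abs(cd_h - np.median(cd_h))) / 0.6745
        lam = sigma_hat * math.sqrt(2 * math.log(n))
        expected = sum(v > lam for v in maxima) / (n / 150.0)

        assert lhipa(x) == pytest.approx(expected, abs=1e-9)

    def test_added_high_frequency_power_decreases_index(self):
        """Monte-Carlo monotonicity: HF noise injected into the band the
        index designates as high lowers LHIPA in >= 95/100 repetitions."""
        from cogload.synthetic import _band_limited_noise

        n, fs = 450, 150.0
        t = np.arange(n) / fs
        wins = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            base = 4.5 + 0.05 * np.sin(2 * np.pi * 0.3 * t) + rng.normal(0, 0.01, n)
            noisy = base + _band_limited_noise(rng, n, fs, 20.0, 70.0, 0.05)
            if lhipa(base, fs) >= lhipa(noisy, fs):
                wins += 1
        assert wins >= 95


class TestPupilDilation:
    def test_arithmetic_examples(self):
        assert pupil_dilation(np.full(10, 4.2), 4.0) == pytest.approx(5.0)
        assert pupil_dilation(np.full(10, 4.0), 4.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pupil_dilation(np.full(10, 4.0), 0.0)
        assert math.isnan(pupil_dilation(np.array([np.nan, np.nan]), 4.0))

    def test_default_sign_structure_mct_positive_vst_negative(self, small_dataset):
        means = small_dataset["table"].groupby("task")["pupil_dilation_pct"].mean()
        assert means["mental_calculation"] > 0
        assert means["visual_search"] < 0


class TestIbiAndHrv:
    def test_exact_period_pulse_train_recovered(self):
        fs, period = 150.0, 0.75
        t = np.arange(int(20 * fs)) / fs
        x = np.zeros_like(t)
        for b in np.arange(0.3, t[-1], period):
            sel = np.abs(t - b) < 0.12
            x[sel] += 0.5 * (1 + np.cos(2 * np.pi * (t[sel] - b) / 0.24))
        series = ibi_from_hrp(x, fs)
        assert series is not None
        assert np.all(np.abs(series.ibis - period) <= 1.0 / fs + 1e-9)

    def test_constant_signal_flagged_missing(self):
        assert ibi_from_hrp(np.zeros(600), 150.0) is None
        assert math.isnan(hrv_sdnn(None))

    def test_moving_average_edge_rule(self):
        out = _moving_average_3(np.array([0.8, 0.9, 1.0]))
        assert out.tolist() == pytest.approx([0.85, 0.9, 0.95])

    def test_sdnn_hand_example_and_homogeneity(self):
        s = IbiSeries(
            peak_times=np.array([0.0, 1.0, 2.0, 3.0]),
            ibis=np.array([1.0, 1.0, 1.0]),
            smoothed_ibis=np.array([0.85, 0.90, 0.95]),
        )
        assert hrv_sdnn(s) == pytest.approx(0.05)
        s2 = replace_smoothed(s, s.smoothed_ibis * 3.0)
        assert hrv_sdnn(s2) == pytest.approx(0.15)

    def test_constant_ibis_give_zero(self):
        s = IbiSeries(
            peak_times=np.arange(5.0),
            ibis=np.ones(4),
            smoothed_ibis=np.ones(4),
        )
        assert hrv_sdnn(s) == 0.0


def replace_smoothed(s: IbiSeries, new):
    return IbiSeries(peak_times=s.peak_times, ibis=s.ibis, smoothed_ibis=np.asarray(new))


def replace_stream_hrp(stream, hrp):
    from dataclasses import replace as dc_replace

    return dc_replace(stream, hrp=hrp)


class TestGsr:
    def test_constant_and_ramp(self):
        assert gsr_level(np.full(100, 350000.0)) == 350000.0
        ramp = np.linspace(100000.0, 300000.0, 1000)
        assert gsr_level(ramp) == pytest.approx(200000.0, rel=1e-6)

    def test_plausible_range_flag(self):
        assert gsr_in_plausible_range(350000.0)
        assert not gsr_in_plausible_range(5000.0)
        assert not gsr_in_plausible_range(3e6)

    def test_all_invalid_missing(self):
        assert math.isnan(gsr_level(np.array([np.nan])))


class TestFeatureTable:
    def test_one_row_per_trial_with_labels(self, small_dataset):
        table = small_dataset["table"]
        assert len(table) == 6 * 44
        assert set(table["group"]) == {"mc_low", "mc_high", "vs_low", "vs_high"}
        mc = table[table["task"] == "mental_calculation"]
        assert (mc.groupby("participant_id").size() == 24).all()

    def test_duplicate_trial_ids_rejected(self, small_dataset):
        streams = small_dataset["streams"][:2]
        dup = [streams[0], streams[0]]
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(dup, small_dataset["participants"])

    def test_trial_without_pulse_peaks_keeps_row_with_missing_flag(self, small_dataset):
        streams = [small_dataset["streams"][0]]
        streams[0] = replace_stream_hrp(streams[0], np.zeros_like(streams[0].hrp))
        table = build_feature_table(streams, small_dataset["participants"])
        assert len(table) == 1
        assert bool(table["hrv_s_missing"].iloc[0])
        assert math.isnan(table["hrv_s"].iloc[0])

    def test_single_trial_features_match_hand_computation(self):
        """Build one trial and recompute every feature with the low-level
        functions directly (no winsorization effects: scope has one trial)."""
        participant = ParticipantProfile(participant_id="px", dspan_backward=8)
        prof = default_profiles()["short_easy"]
        stream = generate_trial(participant, prof, np.random.default_rng(21))
        import pandas as pd

        participants = pd.DataFrame({"participant_id": ["px"], "dspan_backward": [8]})
        table = build_feature_table([stream], participants)
        row = table.iloc[0]

        from cogload.gaze import EventParams, GazeSample, detect_fixations, saccades_between, winsorize_upper

        samples = [
            GazeSample(time=t, x=x, y=y, pupil=p, valid=bool(v))
            for t, x, y, p, v in zip(stream.time, stream.gaze_x, stream.gaze_y, stream.pupil, stream.valid)
        ]
        fixations = detect_fixations(samples, EventParams())
        saccades = saccades_between(fixations)
        durations = winsorize_upper([f.duration_ms for f in fixations])
        amplitudes = winsorize_upper([s.amplitude for s in saccades])
        assert row["fix_dur_ms"] == pytest.approx(durations.mean())
        assert row["sacc_amp_px"] == pytest.approx(amplitudes.mean())

        pupil = stream.pupil[stream.valid]
        assert row["pupil_dilation_pct"] == pytest.approx(pupil_dilation(pupil, stream.baseline_pupil))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert row["lhipa"] == pytest.approx(lhipa(pupil))
        assert row["hrv_s"] == pytest.approx(hrv_sdnn(ibi_from_hrp(stream.hrp)))
        assert row["gsr_ohm"] == pytest.approx(gsr_level(stream.gsr))
        assert row["dspan_backward"] == 8

    def test_per_scope_weighted_k_mean_is_zero(self, small_dataset):
        """The pair-weighted mean of per-trial K within one participant x
        task is 0 by the z-scoring construction; per-trial values are not."""
        table = small_dataset["table"]
        streams = {(s.participant_id, s.trial_id): s for s in small_dataset["streams"]}
        from cogload.gaze import EventParams, GazeSample, detect_fixations, saccades_between

        for (pid, task), sub in table.groupby(["participant_id", "task"]):
            weights, ks = [], []
            for _, r in sub.iterrows():
                s = streams[(pid, r["trial_id"])]
                samples = [
                    GazeSample(time=t, x=x, y=y, valid=bool(v))
                    for t, x, y, v in zip(s.time, s.gaze_x, s.gaze_y, s.valid)
                ]
                fixations = detect_fixations(samples, EventParams())
                n_pairs = max(len(fixations) - 1, 0)
                if np.isfinite(r["k_coef"]) and n_pairs:
                    ks.append(r["k_coef"])
                    weights.append(n_pairs)
            ks, weights = np.asarray(ks), np.asarray(weights, dtype=float)
            assert np.average(ks, weights=weights) == pytest.approx(0.0, abs=1e-9)
            assert np.abs(ks).max() > 1e-3  # per-trial values are nonzero
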