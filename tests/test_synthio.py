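"""Generator behaviour: turn-taking structure, breath-cycle coupling,
saturation, envelopes, and sulcus images, all against ground truth."""

import numpy as np
import pytest
from scipy import stats

from breathturn import ipu_segment, synthio
from breathturn.ipu_segment import INTERLOCUTOR, PARTICIPANT
from breathturn.resp_preproc import RespirationTrace
from breathturn.synthio import (
    METABOLIC,
    SPEECH_COUPLED,
    BreathCycleParams,
    LagModel,
    SulcusCurveSpec,
    TurnParams,
    apply_saturation,
    generate_conversation,
    generate_respiration,
    generate_sulcus_image,
    render_rms_envelope,
)


class TestGenerateConversation:
    def test_same_speaker_pauses_exceed_200ms(self, conversation):
        by_speaker = {}
        for ipu in conversation:
            by_speaker.setdefault(ipu.speaker, []).append(ipu)
        for ipus in by_speaker.values():
            for a, b in zip(ipus, ipus[1:]):
                assert b.onset - a.offset > 0.2

    def test_all_ipus_inside_duration(self, conversation):
        assert all(0 <= i.onset < i.offset <= 300.0 for i in conversation)

    def test_speakers_alternate_stochastically(self, conversation):
        speakers = {i.speaker for i in conversation}
        assert speakers == {PARTICIPANT, INTERLOCUTOR}

    def test_too_short_duration_gives_empty_list(self):
        assert generate_conversation(0.1, seed=0) == []

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_conversation(0.0)

    def test_expected_ipu_count_matches_closed_form(self):
        # E[count] ~ duration / (mean turn + mean gap)
        params = TurnParams(mean_turn=3.0, mean_gap=1.0)
        counts = [
            len(generate_conversation(600.0, params, seed=s)) for s in range(10)
        ]
        expected = 600.0 / (3.0 + 1.0)
        assert abs(np.mean(counts) - expected) < 0.15 * expected

    def test_seed_reproducibility(self):
        a = generate_conversation(120.0, seed=5)
        b = generate_conversation(120.0, seed=5)
        assert [(i.onset, i.offset, i.speaker) for i in a] == [
            (i.onset, i.offset, i.speaker) for i in b
        ]


class TestLagModel:
    def test_point_mass_is_degenerate(self):
        lm = LagModel(family="point_mass", mode=-0.2)
        x = lm.sample(100, np.random.default_rng(0))
        assert np.all(x == -0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_default_family_is_left_skewed(self, seed):
        lm = LagModel()
        x = lm.sample(1000, np.random.default_rng(seed))
        assert stats.skew(x) < 0

    def test_mode_parameter_sets_density_peak(self):
        # histogram mode of a large sample sits near the nominal mode
        lm = LagModel(mode=-0.2)
        x = lm.sample(200_000, np.random.default_rng(1))
        hist, edges = np.histogram(x, bins=400)
        peak = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(peak - (-0.2)) < 0.02

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            LagModel(family="cauchy")


class TestGenerateRespiration:
    def test_zero_coupling_yields_only_metabolic_peaks(self, conversation):
        _, truth = generate_respiration(conversation, coupled_fraction=0.0, seed=3)
        assert all(lab == METABOLIC for lab in truth.true_labels)

    def test_point_mass_lag_is_exact(self, conversation):
        lm = LagModel(family="point_mass", mode=-0.2)
        _, truth = generate_respiration(
            conversation, lag_model=lm, coupled_fraction=1.0, seed=4
        )
        lags = [l for l in truth.true_lags if l is not None]
        assert len(lags) > 0
        assert np.allclose(lags, -0.2)

    def test_coupled_peaks_sit_at_onset_plus_lag(self, respiration):
        _, truth = respiration
        for t, lab, lag, onset in zip(
            truth.true_peak_times, truth.true_labels, truth.true_lags,
            truth.true_ipu_onsets,
        ):
            if lab == SPEECH_COUPLED:
                assert t == pytest.approx(onset + lag, abs=1e-9)

    def test_metabolic_peaks_respect_onset_guard(self, respiration):
        _, truth = respiration
        onsets = np.array(
            [i.onset for i in truth.ipu_list if i.speaker == PARTICIPANT]
        )
        for t, lab in zip(truth.true_peak_times, truth.true_labels):
            if lab == METABOLIC:
                assert np.min(np.abs(onsets - t)) >= 1.0 - 1e-9

    def test_peak_count_matches_cycle_length_expectation(self):
        # mean cycle = mean inhale + mean exhale; count ~ duration / cycle
        bp = BreathCycleParams(exhale_dur_range=(1.5, 3.5))
        counts = []
        for seed in range(20):
            _, truth = generate_respiration(
                [], breath_params=bp, duration=600.0, seed=seed
            )
            counts.append(len(truth.true_peak_times))
        expected = 600.0 / (0.35 + 2.5)
        assert abs(np.mean(counts) - expected) < 0.15 * expected

    def test_clean_trace_argmax_at_true_peaks(self, conversation):
        bp = BreathCycleParams(baseline_drift_sd=0.0, noise_sd=0.0)
        trace, truth = generate_respiration(
            conversation, breath_params=bp, seed=5
        )
        x = trace.samples
        for t in truth.true_peak_times:
            i = int(round(t * trace.rate))
            lo, hi = max(0, i - 100), min(len(x), i + 100)
            assert abs(int(np.argmax(x[lo:hi])) + lo - i) <= 1

    def test_seed_reproducibility(self, conversation):
        t1, _ = generate_respiration(conversation, seed=9)
        t2, _ = generate_respiration(conversation, seed=9)
        np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_unsorted_ipus_rejected(self, conversation):
        with pytest.raises(ValueError):
            generate_respiration(list(reversed(conversation)), seed=0)


class TestApplySaturation:
    def test_rails_outside_range_are_identity(self, sine_trace):
        out, intervals = apply_saturation(sine_trace, -2.0, 2.0)
        np.testing.assert_array_equal(out.samples, sine_trace.samples)
        assert intervals == []

    def test_clip_widths_match_analytic_crossing_times(self, sine_trace):
        # sin(2 pi t / T) > 0.9 on windows of width (T/pi) * acos(0.9)
        out, intervals = apply_saturation(sine_trace, -0.9, 0.9)
        period, rate = 3.0, sine_trace.rate
        expected_width = (period / np.pi) * np.arccos(0.9) * rate
        widths = [stop - start for start, stop in intervals]
        assert len(widths) == 20  # one per half-cycle over 10 periods
        for w in widths:
            assert abs(w - expected_width) <= 2

    def test_high_rail_clips_at_maxima(self, sine_trace):
        out, intervals = apply_saturation(sine_trace, -2.0, 0.9)
        t = sine_trace.times
        for start, stop in intervals:
            center = t[(start + stop) // 2]
            # nearest true maximum of sin(2 pi t / 3) is at 0.75 + 3k
            assert abs((center - 0.75) % 3.0) < 0.1 or abs((center - 0.75) % 3.0) > 2.9

    def test_everything_saturated_is_error(self, sine_trace):
        with pytest.raises(ValueError):
            apply_saturation(sine_trace, 2.0, 3.0)

    def test_output_is_clamped_input(self, sine_trace):
        out, _ = apply_saturation(sine_trace, -0.5, 0.5)
        np.testing.assert_array_equal(
            out.samples, np.clip(sine_trace.samples, -0.5, 0.5)
        )


class TestRenderRmsEnvelope:
    def test_zero_noise_envelope_vanishes_outside_ipus(self, conversation):
        env = render_rms_envelope(
            conversation, duration=300.0, noise_level=0.0, seed=1
        )
        inside = np.zeros(len(env.times), dtype=bool)
        for ipu in conversation:
            inside |= (env.times >= ipu.onset - 0.0251) & (env.times <= ipu.offset + 0.0251)
        assert np.all(env.values[~inside] == 0.0)

    def test_mean_inside_exceeds_mean_outside(self, conversation):
        env = render_rms_envelope(conversation, duration=300.0, seed=2)
        inside = np.zeros(len(env.times), dtype=bool)
        for ipu in conversation:
            inside |= (env.times >= ipu.onset) & (env.times <= ipu.offset)
        assert env.values[inside].mean() > env.values[~inside].mean()

    def test_segmentation_round_trip_recovers_boundaries(self, conversation):
        participant = [i for i in conversation if i.speaker == PARTICIPANT]
        env = render_rms_envelope(
            participant, duration=300.0, speech_level=1.0, noise_level=0.1, seed=3
        )
        thr = ipu_segment.threshold_from_rms(env, 0.5)
        got = ipu_segment.segment_ipus(env, thr)
        ref = [b for i in participant for b in (i.onset, i.offset)]
        hyp = np.array([b for i in got for b in (i.onset, i.offset)])
        hits = sum(1 for r in ref if np.min(np.abs(hyp - r)) <= 0.025)
        assert hits / len(ref) >= 0.99

    def test_boundary_recall_monotone_in_snr(self, conversation):
        participant = [i for i in conversation if i.speaker == PARTICIPANT]
        ref = [b for i in participant for b in (i.onset, i.offset)]
        recalls = []
        for noise in (0.4, 0.2, 0.1, 0.05):
            env = render_rms_envelope(
                participant, duration=300.0, noise_level=noise, seed=4
            )
            thr = ipu_segment.threshold_from_rms(env, 0.5)
            got = ipu_segment.segment_ipus(env, thr)
            hyp = np.array([b for i in got for b in (i.onset, i.offset)])
            if len(hyp) == 0:
                recalls.append(0.0)
                continue
            recalls.append(
                sum(1 for r in ref if np.min(np.abs(hyp - r)) <= 0.025) / len(ref)
            )
        assert all(b >= a - 1e-9 for a, b in zip(recalls, recalls[1:]))

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            render_rms_envelope([], duration=1.0, speech_level=0.1, noise_level=0.2)


class TestGenerateSulcusImage:
    def test_path_darker_than_background_before_noise(self):
        image, path, _ = generate_sulcus_image(noise_sd=0.0, seed=0)
        xs, ys = zip(*path)
        on_path = image[list(ys), list(xs)]
        off = np.full(image.shape, True)
        off[list(ys), list(xs)] = False
        assert on_path.max() <= image[off].min() - 0.4 + 1e-9

    def test_path_is_8_connected_chain_without_repeats(self):
        _, path, _ = generate_sulcus_image(seed=1)
        assert len(set(path)) == len(path)
        for (xa, ya), (xb, yb) in zip(path, path[1:]):
            assert max(abs(xa - xb), abs(ya - yb)) == 1

    def test_straight_line_is_column_of_minimal_intensity(self):
        spec = SulcusCurveSpec(amplitude=0.0)
        image, path, _ = generate_sulcus_image(path_spec=spec, noise_sd=0.0, seed=2)
        row = path[0][1]
        assert all(y == row for _, y in path)
        for x, y in path:
            assert image[y, x] == image[:, x].min()

    def test_probe_points_carry_ground_truth_labels(self):
        _, path, probes = generate_sulcus_image(seed=3)
        assert probes["on_line"]["label"] == "ON_LINE"
        px, py = probes["near_seed"]["xy"]
        sx, sy = path[0]
        assert np.hypot(px - sx, py - sy) < 1.0
        assert probes["near_seed"]["label"] == "FUNDUS"
        assert {probes["anterior"]["label"], probes["posterior"]["label"]} == {
            "ANTERIOR", "POSTERIOR",
        }

    def test_noise_exceeding_contrast_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="breathturn.synthio"):
            generate_sulcus_image(depth_contrast=0.1, noise_sd=0.2, seed=4)
        assert any("not guaranteed" in r.message for r in caplog.records)

    def test_seed_reproducibility(self):
        a, _, _ = generate_sulcus_image(seed=7)
        b, _, _ = generate_sulcus_image(seed=7)
        np.testing.assert_array_equal(a, b)
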