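import numpy as np
import pytest

from vaeeg.core import BANDS, Event, EventSchedule, MONTAGE_16, Recording
from vaeeg.preprocess import (
    FilterSpec,
    bandpass_filter,
    blink_scores,
    decompose_ica,
    identify_artifact_components,
    preprocess_recording,
    remove_components,
)
from vaeeg.spectral import periodogram, segment_event, segment_scores
from vaeeg.stats import run_comparison_plan
from vaeeg.synth import SynthConfig, generate_session

SHORT_FILTER = FilterSpec(order=500)


def sinusoid_recording(freq, seconds=20.0, rate=125.0, channels=1):
    t = np.arange(int(seconds * rate)) / rate
    data = np.tile(np.sin(2 * np.pi * freq * t), (channels, 1))
    return Recording(data, rate, MONTAGE_16[:channels])


def trim(x, n):
    return x[n:-n]


class TestBandpassFilter:
    def test_dc_is_suppressed(self):
        rec = Recording(np.full((1, 4000), 5.0), 125.0, ["Fp1"])
        out = bandpass_filter(rec, SHORT_FILTER)
        assert np.abs(trim(out.data[0], 600)).max() < 0.05

    def test_passband_sinusoid_preserved_within_one_percent(self):
        rec = sinusoid_recording(10.0)
        out = bandpass_filter(rec, SHORT_FILTER)
        amplitude = np.abs(trim(out.data[0], 600)).max()
        assert amplitude == pytest.approx(1.0, abs=0.01)

    def test_linearity_scale_commutes_with_filter(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.normal(size=(2, 3000)), 125.0, ["Fp1", "Fp2"])
        scaled_then_filtered = bandpass_filter(
            Recording(3.0 * rec.data, 125.0, ["Fp1", "Fp2"]), SHORT_FILTER)
        filtered_then_scaled = bandpass_filter(rec, SHORT_FILTER)
        np.testing.assert_allclose(scaled_then_filtered.data,
                                   3.0 * filtered_then_scaled.data,
                                   rtol=1e-10, atol=1e-10)

    def test_filter_is_idempotent_in_the_passband(self):
        rec = sinusoid_recording(10.0, seconds=40.0)
        once = bandpass_filter(rec, SHORT_FILTER)
        twice = bandpass_filter(once, SHORT_FILTER)
        a1 = np.abs(trim(once.data[0], 1200)).max()
        a2 = np.abs(trim(twice.data[0], 1200)).max()
        assert abs(a2 - a1) / a1 < 0.02

    def test_recording_shorter_than_filter_rejected(self):
        rec = Recording(np.zeros((1, 100)), 125.0, ["Fp1"])
        with pytest.raises(ValueError, match="pad"):
            bandpass_filter(rec, FilterSpec(order=4142))

    def test_f_hi_above_nyquist_rejected(self):
        rec = Recording(np.zeros((1, 4000)), 80.0, ["Fp1"])
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, FilterSpec(f_hi=50.0, order=500))

    def test_explicit_high_order_honored_on_long_recordings(self):
        spec = FilterSpec(order=4142)
        assert spec.effective_order(125.0, 200_000) == 4142
        # short recordings fall back to a derivable order
        assert spec.effective_order(125.0, 3000) < 3000


class TestICA:
    def test_known_two_channel_mixture_recovered(self):
        rng = np.random.default_rng(1)
        t = np.arange(5000) / 125.0
        s1 = np.sin(2 * np.pi * 7.0 * t)
        s2 = rng.uniform(-1, 1, size=t.size)
        mix = np.array([[1.0, 0.4], [0.6, 1.0]])
        rec = Recording(mix @ np.vstack([s1, s2]), 125.0, ["Fp1", "Fp2"])
        decomp = decompose_ica(rec, seed=0)
        corr = np.abs(np.corrcoef(np.vstack([decomp.sources, s1, s2])))
        assert max(corr[0, 2], corr[1, 2]) > 0.95    # s1 found
        assert max(corr[0, 3], corr[1, 3]) > 0.95    # s2 found

    def test_reconstruction_without_removal_is_exact(self, blinky_session):
        _, blinky, _, _ = blinky_session
        decomp = decompose_ica(blinky, seed=0)
        recon = remove_components(decomp, set())
        rel = (np.linalg.norm(recon.data - blinky.data)
               / np.linalg.norm(blinky.data))
        assert rel < 1e-6

    def test_same_seed_same_decomposition(self, blinky_session):
        _, blinky, _, _ = blinky_session
        d1 = decompose_ica(blinky, seed=3)
        d2 = decompose_ica(blinky, seed=3)
        np.testing.assert_array_equal(d1.mixing, d2.mixing)
        np.testing.assert_array_equal(d1.sources, d2.sources)

    def test_canonical_sign_convention(self, blinky_session):
        _, blinky, _, _ = blinky_session
        decomp = decompose_ica(blinky, seed=3)
        for j in range(decomp.n_components):
            col = decomp.mixing[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_samples_rejected(self):
        rec = Recording(np.random.default_rng(2).normal(size=(16, 100)),
                        125.0, MONTAGE_16)
        with pytest.raises(ValueError, match="fewer components"):
            decompose_ica(rec)

    def test_rank_deficient_input_rejected(self):
        row = np.random.default_rng(3).normal(size=2000)
        rec = Recording(np.vstack([row, row, row]), 125.0,
                        ["Fp1", "Fp2", "F3"])
        with pytest.raises(ValueError, match="rank"):
            decompose_ica(rec, n_components=3)


class TestArtifactIdentification:
    def test_blink_component_found_and_correlates_with_truth(
            self, blinky_session):
        from vaeeg.synth import _raised_cosine

        clean, blinky, truth, config = blinky_session
        decomp = decompose_ica(blinky, seed=7)
        picked = identify_artifact_components(decomp)
        assert 1 <= len(picked) <= 2
        width = int(round(config.blink_duration * config.rate))
        truth_course = np.zeros(blinky.n_samples)
        pulse = _raised_cosine(width)
        for onset in truth:
            s = int(round(onset * config.rate))
            e = min(s + width, truth_course.size)
            truth_course[s:e] += pulse[: e - s]
        best = max(
            abs(np.corrcoef(decomp.sources[j], truth_course)[0, 1])
            for j in picked)
        assert best > 0.8

    def test_blink_free_session_yields_empty_set(self):
        schedule = EventSchedule([Event("MA1", 1, 0.0, 120.0)])
        for seed in range(5):
            rec = generate_session(SynthConfig(seed=seed), schedule)
            decomp = decompose_ica(rec, seed=seed)
            assert identify_artifact_components(decomp) == set()

    def test_max_remove_zero_always_empty(self, blinky_session):
        _, blinky, _, _ = blinky_session
        decomp = decompose_ica(blinky, seed=7)
        assert identify_artifact_components(decomp, max_remove=0) == set()

    def test_removing_three_components_rejected(self, blinky_session):
        _, blinky, _, _ = blinky_session
        decomp = decompose_ica(blinky, seed=7)
        with pytest.raises(ValueError, match="cap"):
            remove_components(decomp, {0, 1, 2})

    def test_cleanup_recovers_clean_frontal_channels(self, blinky_session):
        clean, blinky, _, _ = blinky_session
        decomp = decompose_ica(blinky, seed=7)
        picked = identify_artifact_components(decomp)
        out = remove_components(decomp, picked)
        for ch in ("Fp1", "Fp2", "F3", "F4", "F7", "F8"):
            i = clean.channel_index(ch)
            corr = np.corrcoef(out.data[i], clean.data[i])[0, 1]
            assert corr >= 0.95

    def test_cleanup_does_not_increase_total_power(self, blinky_session):
        _, blinky, _, _ = blinky_session
        decomp = decompose_ica(blinky, seed=7)
        picked = identify_artifact_components(decomp)
        out = remove_components(decomp, picked)
        centered_in = blinky.data - blinky.data.mean(axis=1, keepdims=True)
        centered_out = out.data - out.data.mean(axis=1, keepdims=True)
        assert (centered_out ** 2).sum() <= (centered_in ** 2).sum() * 1.001


class TestPreprocessingNeutrality:
    def test_preprocessing_rarely_flips_null_decisions(self):
        """Cleaning must not manufacture significance: on null sessions
        the per-comparison U-test decisions before and after
        preprocessing agree in >95% of cases."""
        events = ["MA1", "MA2", "VA1", "VA2", "VA3", "VA4"]
        schedule = EventSchedule([
            Event(name, 1, i * 30.0, 30.0) for i, name in enumerate(events)
        ])
        flips = total = 0
        for seed in range(10):
            cfg = SynthConfig(n_channels=8, seed=seed)
            rec = generate_session(cfg, schedule)
            cleaned, _ = preprocess_recording(rec, SHORT_FILTER, seed=seed)

            def decisions(r):
                scores = {
                    e: segment_scores(periodogram(segment_event(r, e)),
                                      BANDS["raw"]).S
                    for e in events
                }
                return [res.decision() for res in
                        run_comparison_plan(scores).values()]

            raw_d = decisions(rec)
            clean_d = decisions(cleaned)
            flips += sum(a != b for a, b in zip(raw_d, clean_d))
            total += len(raw_d)
        assert flips / total < 0.05
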