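"""Stimulus-feature contracts: envelope, onset trains, PHENV, onset readers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csepnet.features import (
    EPOCH_N_SAMPLES,
    EPOCH_ONSET_SAMPLE,
    FeatureSeries,
    PhonemeOnsets,
    extract_envelope,
    onset_impulse_train,
    phenv_product,
    read_onsets,
    round_half_away,
    to_epoch_timebase,
)
from csepnet.vocoder import AudioWaveform


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        audio = AudioWaveform(np.zeros(16000), 16000)
        env = extract_envelope(audio, 30.0, 256.0)
        assert len(env) == 256
        assert np.allclose(env.values, 0)

    def test_sine_envelope_is_mean_rectified_value(self):
        """|sin| has mean 2/pi; a 30 Hz low-pass of |sin(2*pi*1000 t)| sits there."""
        fs = 16000.0
        t = np.arange(int(2 * fs)) / fs
        audio = AudioWaveform(np.sin(2 * np.pi * 1000 * t), fs)
        env = extract_envelope(audio, 30.0, 256.0).values
        interior = env[64:-64]
        np.testing.assert_allclose(interior, 2 / np.pi, rtol=0.05)

    @pytest.mark.parametrize("dur_s,out_rate", [(1.8, 256.0), (1.23, 256.0), (0.7, 100.0)])
    def test_output_length_contract(self, dur_s, out_rate, rng):
        fs = 16000.0
        audio = AudioWaveform(rng.standard_normal(int(round(dur_s * fs))), fs)
        env = extract_envelope(audio, 30.0, out_rate)
        assert len(env) == int(round(len(audio.samples) / fs * out_rate))

    def test_cutoff_above_nyquist_rejected(self):
        audio = AudioWaveform(np.zeros(100), 100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            extract_envelope(audio, 60.0, 50.0)

    def test_nonnegative(self, speech_like_audio):
        env = extract_envelope(speech_like_audio, 30.0, 256.0)
        assert env.values.min() >= 0

    def test_concatenation_locality(self, rng):
        """ENV of a concatenation matches concatenated ENVs away from the seam."""
        fs = 16000.0
        a = rng.standard_normal(int(fs))
        b = rng.standard_normal(int(fs))
        env_ab = extract_envelope(AudioWaveform(np.r_[a, b], fs), 30.0, 256.0).values
        env_a = extract_envelope(AudioWaveform(a, fs), 30.0, 256.0).values
        env_b = extract_envelope(AudioWaveform(b, fs), 30.0, 256.0).values
        guard = 32  # 0.125 s around each junction/edge
        np.testing.assert_allclose(env_ab[guard : 256 - guard],
                                   env_a[guard : 256 - guard], rtol=0.05, atol=5e-3)
        np.testing.assert_allclose(env_ab[256 + guard : 512 - guard],
                                   env_b[guard : 256 - guard], rtol=0.05, atol=5e-3)


class TestOnsetTrain:
    def test_empty_onsets_zero_train(self):
        train = onset_impulse_train(PhonemeOnsets([]), 1.8, 256.0)
        assert train.values.sum() == 0
        assert len(train) == round_half_away(1.8 * 256)

    def test_known_sample_placement(self):
        train = onset_impulse_train(PhonemeOnsets([0.1, 0.5]), 1.8, 256.0)
        hot = np.flatnonzero(train.values)
        np.testing.assert_array_equal(hot, [26, 128])

    def test_onset_beyond_duration_named(self):
        with pytest.raises(ValueError, match="2.0"):
            onset_impulse_train(PhonemeOnsets([0.1, 2.0]), 1.8, 256.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.7, allow_nan=False), min_size=0, max_size=25,
                    unique=True))
    def test_sum_equals_distinct_onset_samples(self, times):
        onsets = PhonemeOnsets(np.sort(times))
        train = onset_impulse_train(onsets, 1.8, 256.0)
        distinct = len(set(int(round_half_away(t * 256)) for t in times))
        assert int(train.values.sum()) == distinct


class TestPhenv:
    def test_product_and_support(self, rng):
        env = FeatureSeries(np.abs(rng.standard_normal(100)), 256.0, "ENV")
        ph_vals = np.zeros(100)
        ph_vals[[3, 50, 97]] = 1
        ph = FeatureSeries(ph_vals, 256.0, "PH")
        phenv = phenv_product(env, ph)
        assert phenv.kind == "PHENV"
        np.testing.assert_array_equal(np.flatnonzero(phenv.values), [3, 50, 97])
        np.testing.assert_allclose(phenv.values[[3, 50, 97]], env.values[[3, 50, 97]])
        # sums identity: PHENV total = ENV sampled at onsets
        assert phenv.values.sum() == pytest.approx(env.values[[3, 50, 97]].sum())

    def test_misaligned_series_rejected(self, rng):
        env = FeatureSeries(np.abs(rng.standard_normal(100)), 256.0, "ENV")
        ph = FeatureSeries(np.zeros(99), 256.0, "PH")
        with pytest.raises(ValueError, match="misaligned"):
            phenv_product(env, ph)


class TestEpochTimebase:
    def test_onset_lands_at_sample_128(self):
        series = FeatureSeries(np.ones(400), 256.0, "ENV")
        padded = to_epoch_timebase(series)
        assert len(padded) == EPOCH_N_SAMPLES
        assert np.all(padded.values[:EPOCH_ONSET_SAMPLE] == 0)
        assert np.all(padded.values[EPOCH_ONSET_SAMPLE : EPOCH_ONSET_SAMPLE + 400] == 1)
        assert np.all(padded.values[EPOCH_ONSET_SAMPLE + 400 :] == 0)


class TestReadOnsets:
    def test_tsv(self, tmp_path):
        p = tmp_path / "onsets.tsv"
        p.write_text("0.50\n0.10\n0.10\n")
        onsets = read_onsets(p, dialect="tsv")
        np.testing.assert_allclose(onsets.onsets, [0.1, 0.5])  # sorted, deduplicated

    def test_tsv_malformed_row_locates_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0.10\nnot-a-number\n")
        with pytest.raises(ValueError, match="bad.tsv:2"):
            read_onsets(p, dialect="tsv")

    LONG_TG = """File type = "ooTextFile"
Object class = "TextGrid"
xmin = 0
xmax = 0.5
tiers? <exists>
size = 1
item []:
    item [1]:
        class = "IntervalTier"
        name = "phonemes"
        xmin = 0
        xmax = 0.5
        intervals: size = 3
        intervals [1]:
            xmin = 0
            xmax = 0.1
            text = ""
        intervals [2]:
            xmin = 0.1
            xmax = 0.3
            text = "k"
        intervals [3]:
            xmin = 0.3
            xmax = 0.5
            text = "a"
"""

    SHORT_TG = '''File type = "ooTextFile"
Object class = "TextGrid"
0
0.5
<exists>
1
"IntervalTier"
"phonemes"
0
0.5
3
0
0.1
""
0.1
0.3
"k"
0.3
0.5
"a"
'''

    @pytest.mark.parametrize("text", [LONG_TG, SHORT_TG], ids=["long", "short"])
    def test_textgrid_nonempty_interval_starts(self, tmp_path, text):
        p = tmp_path / "s.TextGrid"
        p.write_text(text)
        onsets = read_onsets(p)
        np.testing.assert_allclose(onsets.onsets, [0.1, 0.3])

    def test_textgrid_without_interval_tier_rejected(self, tmp_path):
        p = tmp_path / "x.TextGrid"
        p.write_text('File type = "ooTextFile"\nno tiers here\n')
        with pytest.raises(ValueError):
            read_onsets(p, dialect="textgrid")
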