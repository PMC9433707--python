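"""Synthetic-study generator contracts: stimulus statistics, score grid,
forward-model tracking, determinism."""

import numpy as np
import pytest

from csepnet.csep import compute_csep
from csepnet.features import EPOCH_N_SAMPLES
from csepnet.labels import EXCLUDED_SCORES, SCORE_GRID
from csepnet.montage import MONTAGE_LABELS
from csepnet.synthetic import (
    DEFAULT_INFORMATIVE_CHANNELS,
    ForwardModelParams,
    PsychometricParams,
    SyntheticStudyConfig,
    gen_behavioral_scores,
    gen_eeg_epochs,
    gen_sentence,
    make_study,
    scaled_study,
    sentence_features,
)

CFG = SyntheticStudyConfig(n_subjects=4, n_sentences=2, repeats_per_sentence=5, seed=0)


class TestSentences:
    def test_onset_count_always_within_bounds(self):
        for i in range(40):
            _, onsets = gen_sentence(CFG, f"s{i}", seed=i)
            assert 17 <= len(onsets) <= 22

    def test_deterministic_regeneration(self):
        a_audio, a_on = gen_sentence(CFG, "s0", seed=3)
        b_audio, b_on = gen_sentence(CFG, "s0", seed=3)
        np.testing.assert_array_equal(a_audio.samples, b_audio.samples)
        np.testing.assert_array_equal(a_on.onsets, b_on.onsets)

    def test_duration_distribution(self):
        durs = [gen_sentence(CFG, f"s{i}", seed=i)[0].duration for i in range(500)]
        assert np.mean(durs) == pytest.approx(1.8, abs=0.03)

    def test_features_on_epoch_time_base(self):
        audio, onsets = gen_sentence(CFG, "s0", seed=0)
        feats = sentence_features(audio, onsets)
        for kind in ("ENV", "PH", "PHENV"):
            assert len(feats[kind]) == EPOCH_N_SAMPLES
        assert feats["PH"].values.sum() == len(onsets)


class TestBehavioralScores:
    def test_scores_on_allowed_grid(self):
        cfg = SyntheticStudyConfig(n_subjects=60, seed=1)
        table = gen_behavioral_scores(cfg)
        for s in table.score:
            assert s in SCORE_GRID
            assert s not in EXCLUDED_SCORES

    def test_condition_means_near_calibration_anchors(self):
        cfg = SyntheticStudyConfig(n_subjects=87, seed=2)
        table = gen_behavioral_scores(cfg)
        means = table.groupby("condition").score.mean()
        assert abs(means["voc2"] - 7.5) <= 5.0
        assert abs(means["natural"] - 99.6) <= 5.0

    def test_zero_slope_collapses_conditions(self):
        cfg = SyntheticStudyConfig(n_subjects=40, seed=3)
        psych = PsychometricParams(slope=1e-9, subject_jitter_sd=0.0)
        table = gen_behavioral_scores(cfg, psych)
        voc = table[table.condition != "natural"]
        assert voc.groupby("condition").score.mean().nunique() == 1


class TestForwardModel:
    def test_zero_noise_zero_score_gives_zero_epochs(self):
        import pandas as pd

        audio, onsets = gen_sentence(CFG, "sent00", seed=0)
        feats = {"sent00": sentence_features(audio, onsets)}
        scores = pd.DataFrame([{"participant": "S000", "condition": "x", "score": 0.0}])
        fm = ForwardModelParams(noise_scale=0.0)
        pools = gen_eeg_epochs(CFG, fm, feats, scores, repeats=2)
        for e in pools[("S000", "x")]:
            assert np.allclose(e.data, 0)

    def test_csep_tracking_separates_zero_from_nonzero_score_noiseless(self):
        """With no background noise, a zero score yields zero (hence
        zero-correlation) epochs while any positive score tracks perfectly.
        Pearson-normalized correlation is scale-invariant, so all positive
        scores saturate at the same peak — the graded effect appears only
        against a fixed noise floor (covered by the gain-monotonicity test)."""
        import pandas as pd

        audio, onsets = gen_sentence(CFG, "sent00", seed=0)
        feats = {"sent00": sentence_features(audio, onsets)}
        fm = ForwardModelParams(noise_scale=0.0)
        inf_idx = [MONTAGE_LABELS.index(c) for c in DEFAULT_INFORMATIVE_CHANNELS]
        env = {"sent00": feats["sent00"]["ENV"]}
        peaks = []
        for score in (0.0, 25.0, 50.0, 75.0, 100.0):
            scores = pd.DataFrame([{"participant": "S000", "condition": "x",
                                    "score": score}])
            pools = gen_eeg_epochs(CFG, fm, feats, scores, seed=5, repeats=2)
            img = compute_csep(pools[("S000", "x")], env, n_avg=2,
                               rng=np.random.default_rng(0))
            peaks.append(np.abs(img.matrix[inf_idx]).max())
        assert peaks[0] == 0.0
        # substantial tracking (the biphasic kernel bounds the peak below 1)
        assert all(p > 0.6 for p in peaks[1:])
        # Pearson scale invariance: every positive score saturates equally
        np.testing.assert_allclose(peaks[1:], peaks[1], atol=1e-9)

    def test_noninformative_channels_consistent_with_surrogate_null(self, rng):
        """Non-informative rows' lagged-correlation peak stays within the null
        from phase-randomized surrogate features (spectrum-preserving null,
        appropriate for 1/f background noise)."""
        import pandas as pd

        audio, onsets = gen_sentence(CFG, "sent00", seed=0)
        feats = {"sent00": sentence_features(audio, onsets)}
        scores = pd.DataFrame([{"participant": "S000", "condition": "x",
                                "score": 100.0}])
        pools = gen_eeg_epochs(CFG, ForwardModelParams(), feats, scores,
                               seed=6, repeats=4)
        env = feats["sent00"]["ENV"]
        img = compute_csep(pools[("S000", "x")], {"sent00": env}, n_avg=4,
                           rng=np.random.default_rng(0))
        inf = set(MONTAGE_LABELS.index(c) for c in DEFAULT_INFORMATIVE_CHANNELS)
        noninf = [i for i in range(64) if i not in inf]
        observed = np.abs(img.matrix[noninf]).max(axis=1).mean()

        def phase_randomized(x):
            X = np.fft.rfft(x)
            phases = rng.uniform(0, 2 * np.pi, len(X))
            phases[0] = 0.0
            return np.fft.irfft(np.abs(X) * np.exp(1j * phases), n=len(x))

        nulls = []
        for _ in range(20):
            null_img = compute_csep(pools[("S000", "x")],
                                    {"sent00": phase_randomized(env.values)},
                                    n_avg=4, rng=np.random.default_rng(0))
            nulls.append(np.abs(null_img.matrix[noninf]).max(axis=1).mean())
        assert observed <= np.quantile(nulls, 0.95) * 1.1

    def test_same_seed_different_gains_share_noise(self):
        import pandas as pd

        audio, onsets = gen_sentence(CFG, "sent00", seed=0)
        feats = {"sent00": sentence_features(audio, onsets)}
        scores = pd.DataFrame([{"participant": "S000", "condition": "x",
                                "score": 100.0}])
        lo = gen_eeg_epochs(CFG, ForwardModelParams(tracking_gain_env=0.0,
                                                    tracking_gain_ph=0.0),
                            feats, scores, seed=7, repeats=1)
        hi = gen_eeg_epochs(CFG, ForwardModelParams(tracking_gain_env=2.0,
                                                    tracking_gain_ph=2.0),
                            feats, scores, seed=7, repeats=1)
        diff = hi[("S000", "x")][0].data - lo[("S000", "x")][0].data
        # the difference is the (noise-free) response: zero off the informative set
        noninf = [i for i in range(64)
                  if MONTAGE_LABELS[i] not in DEFAULT_INFORMATIVE_CHANNELS]
        assert np.allclose(diff[noninf], 0, atol=1e-4)
        assert np.abs(diff).max() > 0


class TestStudyBundles:
    def test_full_determinism_and_class_coverage(self):
        a = make_study(CFG, repeats=2)
        b = make_study(CFG, repeats=2)
        np.testing.assert_array_equal(a.pools[("S000", "voc2")][0].data,
                                      b.pools[("S000", "voc2")][0].data)
        assert a.scores.equals(b.scores)
        # every emitted score has at least one pool
        for (participant, condition), lab in a.labels.items():
            assert len(a.pools[(participant, condition)]) > 0

    def test_scaled_study_emits_exactly_the_requested_levels(self):
        study = scaled_study(seed=0, n_subjects=2, repeats=2, n_sentences=1)
        assert sorted(study.scores.score.unique()) == [0.0, 25.0, 50.0, 75.0, 100.0]
        assert len(study.pools) == 10
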