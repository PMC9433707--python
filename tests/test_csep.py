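"""CSEP/ERP feature-image contracts: lagged correlation, bootstrap, rendering."""

import numpy as np
import pytest

from csepnet.csep import (
    DEFAULT_LAGS,
    FeatureImage,
    bootstrap_dataset,
    compute_csep,
    compute_erp,
    load_images,
    render_image,
    save_images,
    xcorr_series,
)
from csepnet.features import EPOCH_N_SAMPLES, FeatureSeries
from csepnet.labels import ScoreLabel
from csepnet.montage import N_CHANNELS
from tests.conftest import make_epoch


def brute_force_lagged_pearson(x, s, lags, min_overlap=8):
    """O(N^2) per-lag Pearson oracle."""
    N = len(x)
    out = np.zeros(len(lags))
    for i, lag in enumerate(lags):
        t0, t1 = max(0, lag), N + min(0, lag)
        xs, ss = x[t0:t1], s[t0 - lag : t1 - lag]
        if len(xs) < min_overlap or xs.std() == 0 or ss.std() == 0:
            continue
        out[i] = np.corrcoef(xs, ss)[0, 1]
    return out


class TestXcorrSeries:
    def test_self_correlation_unity_at_zero_lag(self, rng):
        x = rng.standard_normal(768)
        r = xcorr_series(x, x)
        assert r[np.flatnonzero(DEFAULT_LAGS == 0)[0]] == pytest.approx(1.0)

    def test_delayed_copy_peaks_at_delay(self, rng):
        s = rng.standard_normal(768)
        x = np.zeros(768)
        x[32:] = s[:-32]  # response trails the stimulus by 32 samples
        r = xcorr_series(x, s)
        assert DEFAULT_LAGS[np.argmax(r)] == 32

    def test_orthogonal_sinusoids_zero_at_lag_zero(self):
        t = np.arange(768)
        r = xcorr_series(np.sin(2 * np.pi * 8 * t / 768),
                         np.cos(2 * np.pi * 8 * t / 768))
        assert abs(r[np.flatnonzero(DEFAULT_LAGS == 0)[0]]) < 1e-6

    def test_matches_brute_force_oracle(self, rng):
        worst = 0.0
        for _ in range(10):
            x = rng.standard_normal(768) * rng.uniform(0.1, 100) + rng.uniform(-50, 50)
            s = rng.standard_normal(768)
            worst = max(worst, np.max(np.abs(
                xcorr_series(x, s) - brute_force_lagged_pearson(x, s, DEFAULT_LAGS))))
        assert worst < 1e-10

    def test_short_overlap_and_zero_variance_give_zero(self, rng):
        x = rng.standard_normal(768)
        # lag 762 leaves a 6-sample overlap (< 8)
        r = xcorr_series(x, x, lags=np.array([762]))
        assert r[0] == 0.0
        # constant series: zero variance everywhere
        assert np.all(xcorr_series(np.ones(768), x) == 0)

    def test_sparse_impulse_feature_no_nan(self, rng):
        s = np.zeros(768)
        s[[200, 400, 600]] = 1.0
        r = xcorr_series(rng.standard_normal(768), s)
        assert np.all(np.isfinite(r))


class TestComputeErp:
    def test_identical_epochs_average_to_themselves(self, rng):
        data = rng.standard_normal((N_CHANNELS, EPOCH_N_SAMPLES))
        pool = [make_epoch(data, k=k) for k in range(5)]
        erp = compute_erp(pool, n_avg=80, rng=np.random.default_rng(0))
        np.testing.assert_allclose(erp.matrix, data, atol=1e-12)
        assert erp.kind == "ERP"

    def test_full_pool_mean_is_order_invariant(self, epoch_pool, rng):
        a = compute_erp(epoch_pool, n_avg=None)
        perm = [epoch_pool[i] for i in rng.permutation(len(epoch_pool))]
        b = compute_erp(perm, n_avg=None)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            compute_erp([])


class TestComputeCsep:
    def make_feature(self, values, kind="ENV"):
        return FeatureSeries(np.clip(values, 0, None) if kind != "PH" else values,
                             256.0, kind)

    def test_entries_bounded(self, epoch_pool, rng):
        feats = {"sent00": self.make_feature(np.abs(rng.standard_normal(768)))}
        img = compute_csep(epoch_pool, feats, n_avg=10, rng=np.random.default_rng(0))
        assert img.matrix.min() >= -1 and img.matrix.max() <= 1
        assert img.kind == "ENV"

    def test_single_epoch_equals_rowwise_xcorr(self, rng):
        data = rng.standard_normal((N_CHANNELS, EPOCH_N_SAMPLES))
        feat_vals = np.abs(rng.standard_normal(768))
        feats = {"sent00": self.make_feature(feat_vals)}
        img = compute_csep([make_epoch(data)], feats, n_avg=1,
                           rng=np.random.default_rng(0))
        for ch in (0, 31, 63):
            np.testing.assert_allclose(
                img.matrix[ch], xcorr_series(data[ch], feat_vals), atol=1e-12)

    def test_injected_channel_attains_peak(self, rng):
        """A feature injected into channel 7 dominates the CSEP peak there."""
        feat_vals = np.abs(rng.standard_normal(768))
        feats = {"sent00": self.make_feature(feat_vals)}
        pool = []
        for k in range(10):
            data = 0.2 * rng.standard_normal((N_CHANNELS, EPOCH_N_SAMPLES))
            data[7] += feat_vals
            pool.append(make_epoch(data, k=k))
        img = compute_csep(pool, feats, n_avg=10, rng=np.random.default_rng(0))
        peaks = np.abs(img.matrix).max(axis=1)
        assert np.argmax(peaks) == 7

    def test_missing_feature_names_sentence(self, epoch_pool):
        with pytest.raises(KeyError, match="sent00"):
            compute_csep(epoch_pool, {}, n_avg=2)


class TestBootstrapDataset:
    def make_pools(self, rng, scores=(0.0, 50.0, 100.0), n_epochs=10):
        pools, labels = {}, {}
        for i, score in enumerate(scores):
            key = (f"S{i:03d}", f"lvl{int(score)}")
            pools[key] = [
                make_epoch(rng.standard_normal((N_CHANNELS, EPOCH_N_SAMPLES)),
                           participant_id=key[0], condition_id=key[1], k=k)
                for k in range(n_epochs)
            ]
            labels[key] = ScoreLabel(score)
        return pools, labels

    def test_counts_and_disjointness(self, rng):
        pools, labels = self.make_pools(rng)
        split = bootstrap_dataset(pools, labels, n_train=40, n_test=10,
                                  kind="ERP", seed=0, n_avg=4)
        assert len(split.train) == 40 and len(split.test) == 10
        train_ids = set().union(*(im.source_epoch_ids for im in split.train))
        test_ids = set().union(*(im.source_epoch_ids for im in split.test))
        assert train_ids.isdisjoint(test_ids)

    def test_single_class_all_labels_that_class(self, rng):
        pools, labels = self.make_pools(rng, scores=(25.0,))
        split = bootstrap_dataset(pools, labels, n_train=8, n_test=4,
                                  kind="ERP", seed=0, n_avg=4)
        assert {im.label.score for im in split.train + split.test} == {25.0}

    def test_class_balance_over_observed_classes(self, rng):
        """With uniform class draws, per-class counts stay near n/k (binomial)."""
        pools, labels = self.make_pools(rng, scores=(0.0, 25.0, 50.0, 75.0, 100.0),
                                        n_epochs=6)
        split = bootstrap_dataset(pools, labels, n_train=500, n_test=5,
                                  kind="ERP", seed=1, n_avg=2)
        counts = {}
        for im in split.train:
            counts[im.label.score] = counts.get(im.label.score, 0) + 1
        n, k = 500, 5
        sigma = np.sqrt(n * (1 / k) * (1 - 1 / k))
        assert all(abs(c - n / k) < 5 * sigma for c in counts.values()), counts

    def test_missing_pool_for_label_rejected(self, rng):
        pools, labels = self.make_pools(rng)
        labels[("S999", "lvlX")] = ScoreLabel(10.0)
        with pytest.raises(KeyError):
            bootstrap_dataset(pools, labels, 4, 2, "ERP", seed=0, n_avg=2)


class TestRenderImage:
    def test_constant_matrix_renders_half_gray(self):
        img = FeatureImage(np.full((N_CHANNELS, EPOCH_N_SAMPLES), 3.7), "ERP")
        out = render_image(img)
        assert out.pixels.shape == (299, 299, 3)
        np.testing.assert_allclose(out.pixels, 0.5)

    def test_shape_range_and_channel_replication(self, rng):
        img = FeatureImage(rng.standard_normal((N_CHANNELS, EPOCH_N_SAMPLES)), "ERP")
        out = render_image(img)
        assert out.pixels.shape == (299, 299, 3)
        assert out.pixels.min() == pytest.approx(0.0, abs=1e-7)
        assert out.pixels.max() == pytest.approx(1.0, abs=1e-7)
        np.testing.assert_array_equal(out.pixels[:, :, 0], out.pixels[:, :, 1])
        np.testing.assert_array_equal(out.pixels[:, :, 0], out.pixels[:, :, 2])

    def test_nonfinite_rejected(self):
        mat = np.zeros((N_CHANNELS, EPOCH_N_SAMPLES))
        mat[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            render_image(FeatureImage(mat, "ERP"))


def test_image_container_roundtrip(tmp_path, rng):
    images = [
        FeatureImage(rng.standard_normal((N_CHANNELS, EPOCH_N_SAMPLES)).astype(np.float32),
                     "ERP", label=ScoreLabel(s), participant_id="S000",
                     condition_id="c")
        for s in (0.0, 52.5, 100.0)
    ]
    save_images(tmp_path / "imgs.npz", images, seed=3)
    back = load_images(tmp_path / "imgs.npz")
    assert [im.label.score for im in back] == [0.0, 52.5, 100.0]
    np.testing.assert_allclose(back[1].matrix, images[1].matrix, atol=1e-6)
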