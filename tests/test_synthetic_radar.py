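"""Signal-chain and dataset-generation checks.

The baseband simulator is checked against brute-force DFT oracles and the
analytic Doppler of a constant-velocity scatterer; the dataset generator
against its determinism, geometry and learnability contracts.
"""

import numpy as np
import pytest

from mdwhiten.synthetic_radar import (
    C_LIGHT, CLASSES, DatasetConfig, RadarParams, Scatterer,
    SignatureDataset, SpectrogramParams, compute_range_map,
    compute_spectrogram, default_templates, export_signature,
    generate_dataset, load_dataset, save_dataset_h5, save_dataset_png,
    simulate_baseband, spectrogram_frequencies, sum_range_bins,
)
from mdwhiten.whitening import ValidationError

SMALL = RadarParams(num_chirps=64, samples_per_chirp=32)


def brute_force_dft(col):
    n = len(col)
    k = np.arange(n)
    return np.array([np.sum(col * np.exp(-2j * np.pi * p * k / n)) for p in k])


class TestSimulateBaseband:
    def test_empty_scene_is_silent(self):
        s = simulate_baseband([], SMALL)
        assert s.shape == (32, 64)
        assert np.all(s == 0)

    def test_superposition_is_linear(self):
        sc1 = Scatterer(lambda t: 3.0 - 0.5 * t)
        sc2 = Scatterer(lambda t: 2.0 + 0.2 * np.sin(2 * np.pi * t),
                        lambda t: np.full_like(t, 0.5))
        joint = simulate_baseband([sc1, sc2], SMALL)
        parts = simulate_baseband([sc1], SMALL) + simulate_baseband([sc2], SMALL)
        assert np.array_equal(joint, parts)

    def test_static_scatterer_beat_bin_matches_dft_oracle(self):
        params = RadarParams()
        r0 = 3.0
        s = simulate_baseband([Scatterer(lambda t: np.full_like(t, r0))], params)
        spectrum = np.abs(brute_force_dft(s[:, 7]))
        expected_bin = int(round(float(params.beat_bin(r0))))
        assert int(np.argmax(spectrum)) == expected_bin

    def test_nonfinite_trajectory_rejected(self):
        bad = Scatterer(lambda t: np.where(t > 0.01, np.nan, 3.0))
        with pytest.raises(ValidationError):
            simulate_baseband([bad], SMALL)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValidationError):
            simulate_baseband([Scatterer(lambda t: 0.05 - t)], SMALL)


class TestRangeMap:
    def test_constant_signal_concentrates_in_bin_zero(self):
        s = np.ones((32, 64), dtype=complex)
        R = compute_range_map(s, SMALL).values
        assert np.allclose(R[0], 1.0)
        assert np.allclose(R[1:], 0.0, atol=1e-12)

    def test_complex_tone_lands_on_its_bin(self):
        # the forward-DFT kernel e^{-j2 pi p n1/N1} picks out the
        # conjugate tone e^{+j2 pi p0 n1/N1} at bin p0
        p0 = 5
        n1 = np.arange(32)
        s = np.exp(2j * np.pi * p0 * n1 / 32)[:, None] * np.ones(64)
        R = np.abs(compute_range_map(s, SMALL).values)
        assert np.allclose(R[p0], 1.0)
        mask = np.ones(32, dtype=bool)
        mask[p0] = False
        assert R[mask].max() < 1e-12

    def test_parseval_with_normalization(self, rng):
        s = rng.standard_normal((32, 64)) + 1j * rng.standard_normal((32, 64))
        R = compute_range_map(s, SMALL).values
        lhs = np.sum(np.abs(R) ** 2, axis=0)
        rhs = np.sum(np.abs(s) ** 2, axis=0) / 32
        assert np.allclose(lhs, rhs)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_range_map(np.ones((8, 8)), SMALL)


class TestSumRangeBins:
    def test_single_bin_returns_that_row(self, rng):
        R = compute_range_map(
            rng.standard_normal((32, 64)) + 0j, SMALL
        )
        assert np.array_equal(sum_range_bins(R, 4, 4), R.values[4])

    def test_full_span_of_constant_scene(self):
        R = compute_range_map(np.ones((32, 64), dtype=complex), SMALL)
        assert np.allclose(sum_range_bins(R, 0, 31), 1.0)

    def test_matches_explicit_loop(self, rng):
        values = rng.standard_normal((32, 64)) + 1j * rng.standard_normal((32, 64))
        R = compute_range_map(np.fft.ifft(values * 32, axis=0), SMALL)
        expected = np.zeros(64, dtype=complex)
        for p in range(3, 11):
            expected += R.values[p]
        assert np.allclose(sum_range_bins(R, 3, 10), expected)

    def test_inverted_bounds_rejected(self, rng):
        R = compute_range_map(np.ones((32, 64), dtype=complex), SMALL)
        with pytest.raises(ValidationError):
            sum_range_bins(R, 10, 3)


class TestSpectrogram:
    SP = SpectrogramParams(window=np.ones(16), hop=4, dft_size=32)

    def test_silence_yields_zero_power(self):
        D = compute_spectrogram(np.zeros(100, dtype=complex), self.SP)
        assert np.all(D == 0)

    def test_tone_peaks_at_its_frequency_bin(self):
        f0 = 0.25  # cycles per sample
        v = np.exp(2j * np.pi * f0 * np.arange(256))
        D = compute_spectrogram(v, self.SP)
        freqs = np.fft.fftshift(np.fft.fftfreq(self.SP.dft_size))
        expected = int(np.argmin(np.abs(freqs - f0)))
        assert np.all(D.argmax(axis=1) == expected)

    def test_matches_per_segment_dft_oracle(self, rng):
        v = rng.standard_normal(120) + 1j * rng.standard_normal(120)
        D = compute_spectrogram(v, self.SP)
        N, h, nfft = 16, 4, 32
        for k1 in range(D.shape[0]):
            seg = v[k1 * h : k1 * h + N] * self.SP.window
            ref = np.array([
                np.sum(seg * np.exp(-2j * np.pi * np.arange(N) * k2 / nfft))
                for k2 in range(nfft)
            ])
            assert np.allclose(D[k1], np.fft.fftshift(np.abs(ref) ** 2))

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValidationError):
            compute_spectrogram(np.zeros(8, dtype=complex), self.SP)


class TestExportSignature:
    def test_constant_spectrogram_maps_to_zero_image(self):
        sig = export_signature(np.full((40, 60), 2.5))
        assert sig.image.shape == (75, 75)
        assert np.all(sig.image == 0)

    @pytest.mark.parametrize("shape", [(100, 80), (75, 75), (300, 41)])
    def test_output_is_always_75x75(self, shape, rng):
        sig = export_signature(rng.random(shape))
        assert sig.image.shape == (75, 75)
        assert sig.image.dtype == np.uint8

    def test_nonconstant_input_spans_full_intensity_range(self, rng):
        sig = export_signature(rng.random((90, 90)) + 0.01)
        assert sig.image.min() == 0
        assert sig.image.max() == 255

    def test_empty_crop_rejected(self, rng):
        with pytest.raises(ValidationError):
            export_signature(rng.random((40, 40)), crop=(10, 10, 0, 40))


class TestDopplerFidelity:
    def test_constant_velocity_ridge_tracks_analytic_doppler(self):
        params = RadarParams()
        vr = 1.5  # m/s closing speed
        s = simulate_baseband([Scatterer(lambda t: 4.0 - vr * t)], params)
        R = compute_range_map(s, params)
        v = sum_range_bins(R, 0, params.samples_per_chirp - 1)
        sp = SpectrogramParams()
        D = compute_spectrogram(v, sp)
        freqs = spectrogram_frequencies(sp, 1.0 / params.chirp_duration)
        ridge = freqs[D.argmax(axis=1)]
        f_doppler = 2.0 * params.carrier_frequency * vr / C_LIGHT
        n = len(ridge)
        central = ridge[int(0.1 * n) : int(0.9 * n)]
        bin_width = (1.0 / params.chirp_duration) / sp.dft_size
        frac = np.mean(np.abs(central - f_doppler) <= bin_width)
        assert frac >= 0.8


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        cfg = DatasetConfig(n_subjects=2, signatures_per_class=4)
        a = generate_dataset(config=cfg, seed=9)
        b = generate_dataset(config=cfg, seed=9)
        assert len(a) == len(b)
        assert all(
            np.array_equal(x.image, y.image)
            and (x.class_label, x.subject_id, x.repetition_id)
            == (y.class_label, y.subject_id, y.repetition_id)
            for x, y in zip(a, b)
        )

    def test_default_geometry(self, default_dataset):
        ds = default_dataset
        assert len(ds) == 570
        assert len(np.unique(ds.subjects)) == 33
        counts = np.bincount(ds.labels)
        assert np.all(counts == 95)
        # repetitions per subject are 2 or 3 for every class
        for sid in np.unique(ds.subjects):
            for c in range(6):
                reps = np.sum((ds.subjects == sid) & (ds.labels == c))
                assert reps in (2, 3)

    def test_incompatible_geometry_rejected(self):
        with pytest.raises(ValidationError):
            generate_dataset(
                config=DatasetConfig(n_subjects=2, signatures_per_class=20),
                seed=0,
            )

    def test_subject_partition_is_disjoint(self, small_dataset):
        subs = np.unique(small_dataset.subjects)
        first, rest = set(subs[:4].tolist()), set(subs[4:].tolist())
        assert first.isdisjoint(rest)

    def test_classes_are_learnable_above_chance(self, small_dataset):
        """Nearest-centroid on raw pixels beats the 1/6 chance level."""
        from sklearn.neighbors import NearestCentroid

        ds = small_dataset
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(ds))
        half = len(ds) // 2
        X = ds.images.reshape(len(ds), -1).astype(float)
        clf = NearestCentroid().fit(X[idx[:half]], ds.labels[idx[:half]])
        acc = (clf.predict(X[idx[half:]]) == ds.labels[idx[half:]]).mean()
        assert acc > 1.0 / 6.0


class TestDatasetIO:
    def test_h5_roundtrip(self, small_dataset, tmp_path):
        path = str(tmp_path / "ds.h5")
        save_dataset_h5(small_dataset, path)
        back = load_dataset(path)
        assert np.array_equal(back.images, small_dataset.images)
        assert np.array_equal(back.labels, small_dataset.labels)
        assert np.array_equal(back.subjects, small_dataset.subjects)
        assert tuple(back.class_names) == tuple(small_dataset.class_names)

    def test_png_directory_roundtrip(self, small_dataset, tmp_path):
        sub = small_dataset.subset(np.arange(12))
        out = str(tmp_path / "pngs")
        save_dataset_png(sub, out)
        back = load_dataset(out)
        assert len(back) == 12
        # same multiset of (label name, image) pairs
        orig = {
            (sub.class_names[sub.labels[i]], sub.images[i].tobytes())
            for i in range(12)
        }
        readback = {
            (back.class_names[back.labels[i]], back.images[i].tobytes())
            for i in range(12)
        }
        assert orig == readback

    def test_templates_cover_all_classes(self):
        assert tuple(t.class_label for t in default_templates()) == CLASSES
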