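"""Synthetic scene generator: signature shapes, dataset statistics, cubes and
the separability contract that downstream acceptance checks rely on."""

import numpy as np
import pytest

from hsiband import (
    BandSubset,
    SpectralGrid,
    SyntheticSceneSpec,
    build_default_signatures,
    generate_cube,
    generate_dataset,
    preprocess_dataset,
    run_cross_validation,
)
from hsiband.types import UNLABELED


class TestSignatures:
    def test_four_models_with_grid_length(self, grid128):
        sigs = build_default_signatures(grid128)
        assert len(sigs) == 4
        assert all(s.mean_spectrum.size == 128 for s in sigs)
        assert all(np.all(s.stdev_spectrum >= 0) for s in sigs)

    def test_hemoglobin_valley_exists(self, grid128):
        """Blood-rich tissue reflects less at 560 nm than at 650 nm."""
        sigs = build_default_signatures(grid128)
        wl = grid128.wavelengths
        i560 = np.abs(wl - 560).argmin()
        i650 = np.abs(wl - 650).argmin()
        hyper = sigs[2]
        assert hyper.mean_spectrum[i560] < hyper.mean_spectrum[i650]
        # and the valley is deeper than in normal cortex
        assert hyper.mean_spectrum[i560] < sigs[0].mean_spectrum[i560]

    def test_local_minimum_in_540_580_window(self, grid128):
        wl = grid128.wavelengths
        window = (wl >= 520) & (wl <= 600)
        for sig in build_default_signatures(grid128)[:3]:
            inside = sig.mean_spectrum[window]
            edges = sig.mean_spectrum[np.abs(wl - 520).argmin()], sig.mean_spectrum[
                np.abs(wl - 600).argmin()
            ]
            assert inside.min() < min(edges)

    def test_background_variance_dominates(self, grid128):
        sigs = build_default_signatures(grid128)
        tissue_sd = np.mean([s.stdev_spectrum.mean() for s in sigs[:3]])
        assert sigs[3].stdev_spectrum.mean() > tissue_sd

    def test_deterministic_construction(self, grid128):
        a = build_default_signatures(grid128)
        b = build_default_signatures(grid128)
        for x, y in zip(a, b):
            assert np.array_equal(x.mean_spectrum, y.mean_spectrum)

    def test_zero_contrast_collapses_means(self, grid128):
        sigs = build_default_signatures(grid128, contrast=0.0)
        for sig in sigs[1:]:
            assert np.allclose(sig.mean_spectrum, sigs[0].mean_spectrum)

    def test_grid_outside_visible_range_rejected(self):
        with pytest.raises(ValueError, match="signatures undefined"):
            build_default_signatures(SpectralGrid.linear(900, 1700, 64))


class TestGenerateDataset:
    def test_pixel_count(self):
        spec = SyntheticSceneSpec(n_patients=4, pixels_per_class_per_patient=50, seed=0)
        data = generate_dataset(spec)
        assert data.n_pixels == 4 * 4 * 50
        assert np.bincount(data.labels).tolist() == [200, 200, 200, 200]

    def test_bitwise_reproducible(self):
        spec = SyntheticSceneSpec(n_patients=2, pixels_per_class_per_patient=20, seed=9)
        a, b = generate_dataset(spec), generate_dataset(spec)
        assert np.array_equal(a.spectra, b.spectra)
        assert np.array_equal(a.labels, b.labels)

    def test_no_negative_reflectance(self):
        spec = SyntheticSceneSpec(n_patients=3, pixels_per_class_per_patient=100, seed=4)
        assert generate_dataset(spec).spectra.min() >= 0

    def test_sample_mean_matches_signature(self, grid128):
        """Law of large numbers: pooled class mean within 3 standard errors of
        the model mean at every band (patient offsets average toward zero)."""
        spec = SyntheticSceneSpec(n_patients=10, pixels_per_class_per_patient=250, seed=7)
        sigs = build_default_signatures(spec.grid)
        data = generate_dataset(spec, sigs)
        sig = sigs[0]
        cls = data.spectra[data.labels == 0]
        n = cls.shape[0]
        # two variance components with different effective sample sizes:
        # per-pixel noise averages over all n pixels, but the smooth patient
        # offset is shared within a patient and only averages over n_patients
        se = np.sqrt(
            sig.stdev_spectrum**2 / n + sig.patient_offset_sd**2 / spec.n_patients
        )
        # clipping at zero never binds for the normal class, so the mean is unbiased
        assert np.all(np.abs(cls.mean(axis=0) - sig.mean_spectrum) < 3 * se + 0.05)

    def test_mismatched_signature_length_rejected(self):
        spec = SyntheticSceneSpec(n_patients=2, pixels_per_class_per_patient=5)
        sigs = build_default_signatures(SpectralGrid.linear(440, 902, 64))
        with pytest.raises(ValueError, match="does not match"):
            generate_dataset(spec, sigs)


class TestGenerateCube:
    def test_map_codes_and_dims(self):
        spec = SyntheticSceneSpec(n_patients=2, pixels_per_class_per_patient=10, seed=1)
        cube, gt = generate_cube(spec, height=40, width=32)
        assert cube.shape == (40, 32, 128)
        assert set(np.unique(gt.labels)) <= {0, 1, 2, 3, UNLABELED}
        assert gt.shape == (40, 32)

    def test_zero_glare_means_no_saturated_pixels(self):
        spec = SyntheticSceneSpec(
            n_patients=2, pixels_per_class_per_patient=10, glare_fraction=0.0, seed=1
        )
        cube, _ = generate_cube(spec, height=24, width=24)
        # glare pixels are flat near-100 spectra; none should exist
        flat = cube.values.std(axis=2) < 1e-9
        assert not flat.any()

    def test_glare_pixels_are_unlabeled(self):
        spec = SyntheticSceneSpec(
            n_patients=2, pixels_per_class_per_patient=10, glare_fraction=0.2, seed=1
        )
        cube, gt = generate_cube(spec, height=24, width=24)
        saturated = cube.values.min(axis=2) >= 90.0
        assert saturated.any()
        assert np.all(gt.labels[saturated] == UNLABELED)

    def test_tumor_share_approximately_met(self):
        spec = SyntheticSceneSpec(n_patients=2, pixels_per_class_per_patient=10, seed=2,
                                  glare_fraction=0.0)
        _, gt = generate_cube(spec, height=60, width=60, tumor_share=0.12,
                              labeled_fraction=1.0)
        labeled = gt.labels != UNLABELED
        share = (gt.labels == 1).sum() / labeled.sum()
        assert abs(share - 0.12) < 60 / (60 * 60)  # within one pixel row

    def test_too_small_scene_rejected(self):
        spec = SyntheticSceneSpec(n_patients=2, pixels_per_class_per_patient=10)
        with pytest.raises(ValueError, match="packing"):
            generate_cube(spec, height=8, width=8)


class TestSeparabilityContract:
    """The generator's central tunable: class separation scales with contrast."""

    def test_max_contrast_held_out_accuracy(self):
        spec = SyntheticSceneSpec(n_patients=4, pixels_per_class_per_patient=150, seed=5)
        data = preprocess_dataset(generate_dataset(spec))
        bands = BandSubset(np.arange(data.n_bands), data.grid)
        reports = run_cross_validation(data, bands)
        for report in reports.values():
            assert report.oa >= 0.95

    def test_zero_contrast_chance_accuracy(self):
        spec = SyntheticSceneSpec(
            n_patients=4, pixels_per_class_per_patient=150, seed=5, contrast=0.0
        )
        data = preprocess_dataset(generate_dataset(spec))
        bands = BandSubset(np.arange(data.n_bands), data.grid)
        reports = run_cross_validation(data, bands)
        mean_oa = np.mean([r.oa for r in reports.values()])
        assert abs(mean_oa - 0.25) < 0.05

    def test_flat_tumor_patient_breaks_tumor_detection(self):
        spec = SyntheticSceneSpec(
            n_patients=4, pixels_per_class_per_patient=150, seed=5, flat_tumor_patient=True
        )
        data = preprocess_dataset(generate_dataset(spec))
        bands = BandSubset(np.arange(data.n_bands), data.grid)
        reports = run_cross_validation(data, bands)
        flat_patient = sorted(reports)[-1]
        assert reports[flat_patient].sensitivity[1] < 0.5
        # other folds keep working
        others = [r.sensitivity[1] for p, r in reports.items() if p != flat_patient]
        assert min(others) > 0.9
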