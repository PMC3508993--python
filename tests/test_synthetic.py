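"""Generator contracts: density profiles, point-process sampling, rendering
and dataset round trips."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from conetop import (
    CalibratedImage,
    ConeMosaicTruth,
    GenerationError,
    ParameterError,
    make_density_profile,
    read_calibrated_tiff,
    render_field,
    render_montage,
    sample_mosaic,
    write_dataset,
)
from conetop.datatypes import DensityProfile

from conftest import uniform_truth


class TestDensityProfile:
    def test_rd10_st_defaults_span_printed_density_range(self):
        p = make_density_profile("rd10_st")
        assert p.d_min == 3_000 and p.d_max == 50_000
        assert p.scotoma_radius > 0

    def test_rd10_ee_margin_density_is_peak(self):
        p = make_density_profile("rd10_ee")
        assert p.density(p.retina_radius, 0.3) == pytest.approx(85_000)

    def test_uniform_profile_is_constant(self):
        p = make_density_profile("uniform", d_max=10_000.0)
        r = np.linspace(0, p.retina_radius - 1e-9, 50)
        th = np.linspace(0, 2 * np.pi, 50)
        assert np.allclose(p.density(r, th), 10_000.0)

    def test_density_rises_monotonically_through_surviving_zone(self):
        for kind in ("rd10_st", "rd10_ee", "wildtype"):
            p = make_density_profile(kind)
            r = np.linspace(p.scotoma_radius, p.retina_radius, 200)
            for theta in (0.0, 0.7, np.pi / 2):
                d = p.density(r, theta)
                assert np.all(np.diff(d) >= -1e-9)
                assert d[0] == pytest.approx(p.d_min, rel=1e-6)
                assert d[-1] == pytest.approx(p.d_max, rel=1e-6)

    def test_scotoma_density_is_zero(self):
        p = make_density_profile("rd10_st")
        assert p.density(0.25 * p.scotoma_radius) == 0.0

    def test_unknown_kind_and_bad_parameters_raise(self):
        with pytest.raises(ParameterError):
            make_density_profile("rd12")
        with pytest.raises(ParameterError):
            make_density_profile("custom", d_min=-5.0, d_max=10.0,
                                 scotoma_radius=0.1)
        with pytest.raises(ParameterError):
            make_density_profile("rd10_st", scotoma_radius=3.0)


class TestSampleMosaic:
    def test_uniform_count_matches_poisson_within_4sd(self):
        # 10,000 cones/mm² on a disc of 1 mm² (r = sqrt(1/pi))
        prof = make_density_profile(
            "uniform", d_max=10_000.0, d_min=10_000.0,
            retina_radius=float(np.sqrt(1 / np.pi)),
        )
        truth = sample_mosaic(prof, seed=11, exclusion_radius=0.0)
        assert abs(truth.true_total - 10_000) < 4 * np.sqrt(10_000)

    def test_zero_intensity_gives_empty_mosaic(self):
        prof = make_density_profile("uniform", d_max=0.0, d_min=0.0)
        truth = sample_mosaic(prof, seed=0)
        assert truth.true_total == 0

    def test_determinism_bit_for_bit(self):
        prof = make_density_profile("rd10_st", retina_radius=0.8,
                                    scotoma_radius=0.2)
        a = sample_mosaic(prof, seed=1)
        b = sample_mosaic(prof, seed=1)
        assert np.array_equal(a.positions, b.positions)

    def test_hard_core_minimum_spacing_holds(self):
        truth = uniform_truth(60_000, seed=3, exclusion=2.0)
        d, _ = cKDTree(truth.positions).query(truth.positions, k=2)
        assert d[:, 1].min() >= 2.0 / 1000.0 - 1e-12

    def test_infeasible_packing_raises_naming_density(self):
        prof = make_density_profile("rd10_ee", retina_radius=0.5)
        with pytest.raises(GenerationError, match="85000"):
            sample_mosaic(prof, seed=0, exclusion_radius=4.0)

    def test_density_fidelity_in_probe_windows(self):
        # counts in ~0.1 mm² windows match the density integral within
        # Poisson error (4 SD) in at least 95% of windows
        prof = make_density_profile("rd10_st", anisotropy_amp=0.0)
        truth = sample_mosaic(prof, seed=5)
        side = 0.316  # mm -> ~0.1 mm² windows
        ok = tot = 0
        for cx in np.arange(-1.6, 1.7, side):
            for cy in np.arange(-1.6, 1.7, side):
                if np.hypot(abs(cx) + side / 2, abs(cy) + side / 2) > 2.05:
                    continue
                xs = np.linspace(cx - side / 2, cx + side / 2, 21)
                ys = np.linspace(cy - side / 2, cy + side / 2, 21)
                xx, yy = np.meshgrid(xs, ys)
                lam = prof.density_xy(xx, yy).mean() * side ** 2
                n = truth.count_in_box((cx, cy), side * 1000.0)
                tot += 1
                if abs(n - lam) <= 4 * np.sqrt(max(lam, 1.0)):
                    ok += 1
        assert ok / tot >= 0.95


class TestRenderField:
    def test_empty_field_is_pure_background(self):
        truth = uniform_truth(0.0, seed=0)
        img = render_field(truth, (0.0, 0.0), background=0.1, snr=10)
        assert abs(img.pixels.mean() - 0.1) < 0.01
        assert img.pixels.std() < 0.2

    def test_grid_of_25_spots_renders_25_peaks_at_truth(self):
        # noiseless render: one local maximum per cone, within one pixel
        g = np.arange(-2, 3) * 0.025  # 25 µm pitch
        xx, yy = np.meshgrid(g, g)
        prof = make_density_profile("uniform", d_max=1000.0, retina_radius=0.2)
        truth = ConeMosaicTruth(
            positions=np.column_stack([xx.ravel(), yy.ravel()]),
            profile=prof, seed=0, exclusion_radius=0.0,
        )
        img = render_field(truth, (0.0, 0.0), snr=0, background=0.0)
        peaks = peak_local_max(img.pixels, min_distance=10, threshold_abs=0.5)
        assert len(peaks) == 25
        half = img.shape[0] // 2
        got = np.sort((peaks - half) * img.scale / 1000.0, axis=0)
        want = np.sort(np.column_stack([yy.ravel(), xx.ravel()]), axis=0)
        assert np.all(np.abs(got - want) <= img.scale / 1000.0 + 1e-9)

    def test_expected_cones_in_field_by_area_arithmetic(self):
        # 50,000 cones/mm² × (0.125 mm)² = 781.25 expected per field
        counts = [
            uniform_truth(50_000, seed=s).count_in_box((0, 0), 125.0)
            for s in range(6)
        ]
        assert abs(np.mean(counts) - 781.25) < 4 * np.sqrt(781.25 / len(counts))

    def test_field_outside_outline_raises(self):
        truth = uniform_truth(1000, seed=0, radius=0.15)
        with pytest.raises(ParameterError, match="outline"):
            render_field(truth, (0.12, 0.0))


class TestRenderMontage:
    def test_empty_mosaic_is_background(self):
        prof = make_density_profile("uniform", d_max=0.0, d_min=0.0)
        truth = sample_mosaic(prof, seed=0)
        m = render_montage(truth)
        inside = m.pixels[m.outline_mask]
        assert abs(inside.mean() - 0.05) < 0.02

    def test_uniform_mosaic_has_low_intensity_cv(self, ):
        truth = sample_mosaic(
            make_density_profile("uniform", d_max=10_000.0, retina_radius=1.0),
            seed=2,
        )
        m = render_montage(truth)
        # avoid the outline edge where the blur rolls off
        xx, yy = m.pixel_coords()
        core = xx ** 2 + yy ** 2 <= 0.8 ** 2
        vals = m.pixels[core]
        assert vals.std() / vals.mean() < 0.5

    def test_scotoma_darker_than_periphery(self, st_truth, st_montage):
        xx, yy = st_montage.pixel_coords()
        r = np.hypot(xx, yy)
        s = st_truth.profile.scotoma_radius
        dark = st_montage.pixels[r < 0.8 * s].mean()
        bright = st_montage.pixels[(r > 1.7) & (r < 2.0)].mean()
        assert dark < bright

    def test_montage_determinism(self, st_truth):
        a = render_montage(st_truth)
        b = render_montage(st_truth)
        assert np.array_equal(a.pixels, b.pixels)


class TestWriteDataset:
    @pytest.fixture()
    def dataset(self, tmp_path):
        truth = uniform_truth(3000, seed=4, radius=0.15)
        montage = render_montage(truth, scale=5.0, pad_mm=0.02)
        fields = [((0.0, 0.0), render_field(truth, (0.0, 0.0)))]
        files = write_dataset(truth, montage, fields, tmp_path)
        return truth, montage, fields, tmp_path, files

    def test_tiff_round_trip_is_exact(self, dataset):
        truth, montage, fields, d, _ = dataset
        back = read_calibrated_tiff(d / "field_000.tif")
        stored = np.round(fields[0][1].pixels * 10_000.0) / 10_000.0
        assert np.array_equal(back.pixels, stored)
        assert back.scale == fields[0][1].scale

    def test_manifest_lists_all_files(self, dataset):
        truth, montage, fields, d, files = dataset
        rows = (d / "manifest.csv").read_text().strip().splitlines()
        assert len(rows) - 1 == 1 + len(fields) + 2

    def test_truth_csv_rows_equal_true_total(self, dataset):
        truth, _, _, d, _ = dataset
        rows = (d / "truth.csv").read_text().strip().splitlines()
        assert len(rows) - 1 == truth.true_total
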