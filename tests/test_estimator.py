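"""Sampling-scheme geometry and the stratified total estimator."""

import numpy as np
import pytest

from conetop import (
    CalibratedImage,
    EstimationError,
    IsodensityPartition,
    ParameterError,
    SamplingScheme,
    SchemeError,
    estimate_total,
    make_density_profile,
    make_sampling_scheme,
    percent_of_wildtype,
    region_density,
    sample_mosaic,
    sampling_fraction,
    trace_isodensity,
)
from conetop.pipeline import analyze_mosaic

from test_topography import _disc_image


@pytest.fixture(scope="module")
def single_region_partition():
    return trace_isodensity(_disc_image(lambda r: r), 1)


@pytest.fixture(scope="module")
def annuli_partition():
    return trace_isodensity(_disc_image(lambda r: r), 5)


class TestSamplingScheme:
    def test_single_region_gets_16_meridian_locations(self, single_region_partition):
        scheme = make_sampling_scheme(single_region_partition)
        assert scheme.n_locations == 16
        assert sorted(set(scheme.meridians)) == ["DV", "NT"]
        for x, y in scheme.locations:
            assert single_region_partition.region_at(x, y) == 1
            # on-axis placement
            assert min(abs(x), abs(y)) < 1e-9

    def test_total_fields_and_sampled_area(self, single_region_partition):
        scheme = make_sampling_scheme(single_region_partition)
        assert scheme.n_fields == 32
        assert scheme.sampled_area_mm2() == pytest.approx(0.5)

    def test_every_annulus_holds_a_location(self, annuli_partition):
        scheme = make_sampling_scheme(annuli_partition)
        hit = {annuli_partition.region_at(x, y) for x, y in scheme.locations}
        assert hit == set(annuli_partition.region_ids)

    def test_scheme_is_deterministic(self, annuli_partition):
        a = make_sampling_scheme(annuli_partition)
        b = make_sampling_scheme(annuli_partition)
        assert np.array_equal(a.locations, b.locations)

    def test_unreachable_region_raises_naming_it(self):
        # a tiny fifth region tucked on the diagonal, ~700 µm off both
        # meridians: perpendicular adjustment cannot reach it
        img = _disc_image(lambda r: r)
        xx, yy = img.pixel_coords()
        r = np.hypot(xx, yy)
        labels = np.zeros(img.shape, dtype=np.int32)
        labels[img.outline_mask] = np.digitize(
            r[img.outline_mask], [0.5, 1.0, 1.5]
        ) + 1
        blob = np.hypot(xx - 1.0, yy - 1.0) < 0.15
        labels[blob & img.outline_mask] = 5
        part = IsodensityPartition(
            labels=labels,
            level_bounds=[(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)],
            scale=img.scale,
            origin=img.origin,
        )
        with pytest.raises(SchemeError, match="5"):
            make_sampling_scheme(part)


class TestRegionDensity:
    def test_uniform_locations_give_region_mean(self, single_region_partition):
        scheme = make_sampling_scheme(single_region_partition)
        dens = region_density(
            scheme, np.full(16, 10_000.0), single_region_partition
        )
        assert dens == {1: pytest.approx(10_000.0)}

    def test_two_location_region_averages(self, single_region_partition):
        scheme = make_sampling_scheme(single_region_partition)
        vals = np.full(16, 8_000.0)
        vals[1::2] = 12_000.0
        dens = region_density(scheme, vals, single_region_partition)
        assert dens[1] == pytest.approx(10_000.0)

    def test_wrong_length_raises(self, single_region_partition):
        scheme = make_sampling_scheme(single_region_partition)
        with pytest.raises(EstimationError):
            region_density(scheme, np.ones(7), single_region_partition)


def _toy_partition(areas_px, scale=100.0):
    """1-D strip partition with given pixel counts per region."""
    labels = np.concatenate(
        [np.full(n, i + 1, dtype=np.int32) for i, n in enumerate(areas_px)]
    ).reshape(1, -1)
    bounds = [(float(i), float(i + 1)) for i in range(len(areas_px))]
    return IsodensityPartition(labels=labels, level_bounds=bounds, scale=scale)


class TestEstimateTotal:
    def test_single_region_product(self):
        part = _toy_partition([100])  # 100 px × (0.1 mm)² = 1 mm²
        scheme = SamplingScheme(
            locations=np.zeros((1, 2)), meridians=["NT"], fields_per_location=2
        )
        est = estimate_total(part, {1: 10_000.0}, scheme)
        assert est.total == pytest.approx(10_000.0)

    def test_two_region_sum(self):
        part = _toy_partition([200, 50])  # 2 mm² and 0.5 mm²
        scheme = SamplingScheme(
            locations=np.zeros((2, 2)), meridians=["NT", "NT"]
        )
        est = estimate_total(part, {1: 5_000.0, 2: 20_000.0}, scheme)
        assert est.total == pytest.approx(20_000.0)
        assert est.contributions == pytest.approx([10_000.0, 10_000.0])

    def test_missing_region_density_raises(self):
        part = _toy_partition([10, 10])
        scheme = SamplingScheme(locations=np.zeros((1, 2)), meridians=["NT"])
        with pytest.raises(EstimationError, match="2"):
            estimate_total(part, {1: 5_000.0}, scheme)

    def test_exact_on_piecewise_constant_density(self, annuli_partition):
        # if the density field is constant on each region and the location
        # densities are set to those constants, the estimate equals the
        # integral exactly
        scheme = make_sampling_scheme(annuli_partition)
        region_truth = {rid: 1_000.0 * rid for rid in annuli_partition.region_ids}
        loc_d = np.array(
            [
                region_truth[annuli_partition.region_at(x, y)]
                for x, y in scheme.locations
            ]
        )
        dens = region_density(scheme, loc_d, annuli_partition)
        est = estimate_total(annuli_partition, dens, scheme)
        want = sum(
            region_truth[rid] * a
            for rid, a in zip(annuli_partition.region_ids,
                              annuli_partition.areas_mm2())
        )
        assert est.total == pytest.approx(want, abs=1e-9)


class TestSamplingFraction:
    def test_default_scheme_on_default_outline_is_3p8_percent(
        self, single_region_partition
    ):
        scheme = make_sampling_scheme(single_region_partition)
        frac = sampling_fraction(scheme, single_region_partition.outline_area_mm2())
        assert round(frac, 1) == 3.8

    def test_whole_outline_single_field_is_100(self):
        scheme = SamplingScheme(
            locations=np.zeros((1, 2)), meridians=["NT"],
            fields_per_location=1, field_side=1000.0,
        )
        assert sampling_fraction(scheme, 1.0) == pytest.approx(100.0)

    def test_32_fields_on_10_mm2(self):
        scheme = SamplingScheme(
            locations=np.zeros((16, 2)), meridians=["NT"] * 16
        )
        assert sampling_fraction(scheme, 10.0) == pytest.approx(5.0)


class TestPercentOfWildtype:
    def test_reference_equals_total(self):
        pct, rounded = percent_of_wildtype(180_000, 180_000)
        assert (pct, rounded) == (100.0, 100)

    @pytest.mark.parametrize(
        "total,raw,rounded", [(100_000, 55.6, 56), (80_000, 44.4, 44)]
    )
    def test_printed_roundings(self, total, raw, rounded):
        pct, r = percent_of_wildtype(total)
        assert round(pct, 1) == raw and r == rounded

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ParameterError):
            percent_of_wildtype(1000, 0.0)


class TestRecovery:
    def test_total_scales_linearly_with_profile(self):
        # doubling the generator profile doubles the recovered total within
        # sampling error
        base = make_density_profile("rd10_st")
        doubled = make_density_profile(
            "rd10_st", d_min=2 * base.d_min, d_max=2 * base.d_max
        )
        t1 = sample_mosaic(base, seed=21)
        t2 = sample_mosaic(doubled, seed=22)
        r1 = analyze_mosaic(t1, count_from_truth=True)
        r2 = analyze_mosaic(t2, count_from_truth=True)
        ratio = r2.estimate.total / r1.estimate.total
        assert ratio == pytest.approx(2.0, rel=0.10)
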