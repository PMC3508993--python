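"""Meridian sampling scheme and area-weighted stratified total.

The whole-mount total is estimated by stratified sampling: local densities
are measured on two 125×125 µm² fields at each of 16 locations spaced
along the dorso-ventral and naso-temporal meridians, every isodensity
region receives at least one location, the density of a region is the mean
over its sampled locations, and the total is Σ (region density × region
area).  At the default geometry the 32 fields cover ≈3.8% of the retinal
surface.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    EstimationError,
    IsodensityPartition,
    ParameterError,
    SamplingScheme,
    SchemeError,
    TotalEstimate,
)

__all__ = [
    "DEFAULT_WILDTYPE_TOTAL",
    "make_sampling_scheme",
    "region_density",
    "estimate_total",
    "sampling_fraction",
    "percent_of_wildtype",
]

# Cone population of a normal (wildtype) mouse retina, from the mouse-retina
# literature; exposed so a different reference can be configured.
DEFAULT_WILDTYPE_TOTAL = 180_000.0

# half-meridian directions: naso-temporal along ±x, dorso-ventral along ±y
_DIRECTIONS = [
    (np.array([1.0, 0.0]), "NT"),
    (np.array([0.0, 1.0]), "DV"),
    (np.array([-1.0, 0.0]), "NT"),
    (np.array([0.0, -1.0]), "DV"),
]


def _ray_extent(partition: IsodensityPartition, direction: np.ndarray) -> float:
    """Radial extent (mm) of the outline along a ray from the centre."""
    step = partition.scale / 2000.0
    r = 0.0
    extent = 0.0
    max_r = max(partition.labels.shape) * partition.scale / 1000.0
    while r <= max_r:
        x, y = direction * r
        if partition.region_at(x, y) > 0:
            extent = r
        r += step
    return extent


def make_sampling_scheme(
    partition: IsodensityPartition,
    inner_radius: float = 0.0,
    n_per_half: int = 4,
    inner_clearance_um: float = 340.0,
    edge_clearance_um: float = 100.0,
    max_shift_um: float = 200.0,
    field_side: float = 125.0,
) -> SamplingScheme:
    """Place sampling locations along the two principal meridians.

    ``n_per_half`` locations per half-meridian are evenly spaced between
    the inner sampling bound (``inner_radius`` — e.g. the cone-free-zone
    radius — plus a clearance that keeps fields on surviving tissue) and
    the retinal margin minus an edge clearance.  The four half-meridians
    are phase-staggered by a quarter step, so the union of radii covers
    the span densely and radially banded partitions are hit by every ring.
    Locations are then locally adjusted (perpendicular shifts up to
    ``max_shift_um``) until every isodensity region holds at least one.

    Raises
    ------
    SchemeError
        If some region cannot be reached after maximal adjustment.
    """
    n_total = 4 * n_per_half
    locations = np.zeros((n_total, 2))
    meridians: list[str] = []
    k = 0
    for j, (direction, name) in enumerate(_DIRECTIONS):
        extent = _ray_extent(partition, direction)
        r_out = extent - edge_clearance_um / 1000.0
        r_in = inner_radius + inner_clearance_um / 1000.0
        if r_out <= r_in:
            raise SchemeError(
                f"no room for sampling along the {name} half-meridian "
                f"(inner bound {r_in:.3f} mm, outer bound {r_out:.3f} mm)"
            )
        for i in range(n_per_half):
            u = (n_per_half * i + j + 0.5) / n_total
            locations[k] = direction * (r_in + u * (r_out - r_in))
            meridians.append(name)
            k += 1

    scheme = SamplingScheme(
        locations=locations, meridians=meridians, field_side=field_side
    )
    _adjust_for_coverage(scheme, partition, max_shift_um)

    for i, (x, y) in enumerate(scheme.locations):
        if partition.region_at(x, y) == 0:
            raise SchemeError(f"location {i} at ({x:.3f}, {y:.3f}) left the outline")
    return scheme


def _perpendicular(meridian: str) -> np.ndarray:
    return np.array([0.0, 1.0]) if meridian == "NT" else np.array([1.0, 0.0])


def _adjust_for_coverage(
    scheme: SamplingScheme, partition: IsodensityPartition, max_shift_um: float
) -> None:
    """Shift locations perpendicular to their meridian (≤ ``max_shift_um``)
    until every region holds at least one location; in-place."""
    step_mm = max(partition.scale / 1000.0, 0.02)
    max_shift_mm = max_shift_um / 1000.0
    for region in partition.region_ids:
        regions_now = [
            partition.region_at(x, y) for x, y in scheme.locations
        ]
        if region in regions_now:
            continue
        rows, cols = np.nonzero(partition.labels == region)
        rx = partition.origin[0] + cols * partition.scale / 1000.0
        ry = partition.origin[1] + rows * partition.scale / 1000.0
        moved = False
        # try the closest locations first, but never vacate a singleton region
        d2 = [
            min((rx - x) ** 2 + (ry - y) ** 2)
            for x, y in scheme.locations
        ]
        for i in np.argsort(d2):
            if regions_now.count(regions_now[i]) <= 1 and regions_now[i] != 0:
                continue
            perp = _perpendicular(scheme.meridians[i])
            shifts = np.arange(step_mm, max_shift_mm + 1e-9, step_mm)
            for s in shifts:
                for sgn in (1.0, -1.0):
                    cand = scheme.locations[i] + sgn * s * perp
                    if partition.region_at(*cand) == region:
                        scheme.locations[i] = cand
                        moved = True
                        break
                if moved:
                    break
            if moved:
                break
        if not moved:
            raise SchemeError(
                f"isodensity region {region} is unreachable from the meridians "
                f"after perpendicular shifts up to {max_shift_um:g} µm"
            )


def region_density(
    scheme: SamplingScheme,
    location_densities: np.ndarray,
    partition: IsodensityPartition,
) -> dict[int, float]:
    """Per-region density (cones/mm²) as the mean over the locations that
    fall inside each region.

    Raises
    ------
    EstimationError
        If a location is off the outline or a region has no sample.
    """
    location_densities = np.asarray(location_densities, dtype=float)
    if location_densities.shape[0] != scheme.n_locations:
        raise EstimationError("one density per sampling location required")
    groups: dict[int, list[float]] = {rid: [] for rid in partition.region_ids}
    for (x, y), dens in zip(scheme.locations, location_densities):
        rid = partition.region_at(x, y)
        if rid == 0:
            raise EstimationError(
                f"sampling location ({x:.3f}, {y:.3f}) lies outside the outline"
            )
        groups[rid].append(float(dens))
    empty = [rid for rid, vals in groups.items() if not vals]
    if empty:
        raise EstimationError(f"region(s) without a sampled location: {empty}")
    return {rid: float(np.mean(vals)) for rid, vals in groups.items()}


def estimate_total(
    partition: IsodensityPartition,
    region_densities: dict[int, float],
    scheme: SamplingScheme,
    reference_total: float | None = None,
) -> TotalEstimate:
    """Area-weighted stratified total: Σ region density × region area."""
    missing = [rid for rid in partition.region_ids if rid not in region_densities]
    if missing:
        raise EstimationError(f"missing density for region(s): {missing}")
    areas = partition.areas_mm2()
    densities = np.array([region_densities[rid] for rid in partition.region_ids])
    return TotalEstimate(
        region_ids=partition.region_ids,
        densities=densities,
        areas=areas,
        sampled_area=scheme.sampled_area_mm2(),
        outline_area=partition.outline_area_mm2(),
        reference_total=reference_total,
    )


def sampling_fraction(scheme: SamplingScheme, outline_area: float) -> float:
    """Sampled percentage of the retinal surface:
    ``100 × n_fields × (field_side mm)² / outline_area``."""
    if outline_area <= 0:
        raise ParameterError("outline_area must be positive")
    return 100.0 * scheme.sampled_area_mm2() / outline_area


def percent_of_wildtype(
    total: float, reference_total: float = DEFAULT_WILDTYPE_TOTAL
) -> tuple[float, int]:
    """Express a total as a percentage of the wildtype cone population.

    Returns ``(raw_percent, rounded_percent)``; e.g. a total of 100,000
    against the default reference gives ``(55.6, 56)``.
    """
    if reference_total <= 0:
        raise ParameterError("reference_total must be positive")
    pct = 100.0 * total / reference_total
    return pct, int(round(pct))
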