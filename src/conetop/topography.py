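"""Isodensity mapping of the whole-mount montage.

On a low-power montage of an opsin-stained whole mount, local brightness
is a monotone proxy of cone density: cone-rich areas are bright, cone-free
zones dark.  This module builds a background-corrected, smoothed brightness
map, thresholds cone-rich clusters, and partitions the mount into ordered
isodensity regions whose boundary curves can be exported as polylines.
The partition carries the region areas needed by the stratified estimator;
absolute densities come from field sampling, not from brightness.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as cc_label

from .datatypes import (
    CalibratedImage,
    IsodensityPartition,
    ParameterError,
    PartitionError,
)

__all__ = [
    "build_brightness_map",
    "threshold_clusters",
    "trace_isodensity",
    "region_areas",
    "estimate_scotoma_radius",
    "isodensity_contours",
    "export_contours_geojson",
    "save_partition",
    "load_partition",
]


def build_brightness_map(
    montage: CalibratedImage,
    smooth_scale: float = 100.0,
    background_scale: float = 500.0,
    background_mode: str = "dark",
) -> CalibratedImage:
    """Background-correct and smooth the montage at a physical scale.

    Background modes: ``dark`` (default) subtracts a constant robust dark
    level (0.5th percentile of a denoised copy of the masked pixels) —
    this never disturbs the brightness ordering that the isodensity
    partition is built on; ``rolling`` subtracts a grey-opening envelope
    with a ``background_scale`` µm window (for montages with slow staining
    or illumination gradients); ``none`` skips correction.  The corrected
    image is then smoothed by masked (normalised) Gaussian convolution
    with FWHM ``smooth_scale`` µm.  Values outside the outline mask are 0
    and undefined.  All steps are homogeneous of degree one, so scaling
    the montage intensity scales the map by the same factor.
    """
    scale = montage.scale
    if smooth_scale < 2.0 * scale:
        raise ParameterError(
            f"smooth_scale {smooth_scale:g} µm is below 2 pixels "
            f"({2 * scale:g} µm) — increase it or use a finer montage"
        )
    img = montage.pixels.astype(float)
    mask = montage.outline_mask

    if background_mode == "dark":
        pre = ndimage.gaussian_filter(img, 3.0)
        img = img - float(np.percentile(pre[mask], 0.5))
    elif background_mode == "rolling":
        k = int(round(background_scale / scale))
        if k >= 2:
            # estimate the envelope on a denoised copy, otherwise the min
            # filter tracks the noise floor rather than the background
            pre = ndimage.gaussian_filter(img, max(2.0, 0.05 * k))
            bg = ndimage.maximum_filter(ndimage.minimum_filter(pre, size=k), size=k)
            img = img - bg
    elif background_mode != "none":
        raise ParameterError(f"unknown background_mode {background_mode!r}")

    sigma_px = smooth_scale / (2.355 * scale)  # FWHM -> sigma
    num = ndimage.gaussian_filter(np.where(mask, img, 0.0), sigma_px)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mask, num / den, 0.0)
    return CalibratedImage(
        pixels=np.where(mask, out, 0.0),
        scale=scale,
        origin=montage.origin,
        outline_mask=mask,
    )


def threshold_clusters(brightness_map: CalibratedImage) -> np.ndarray:
    """Binary mask of cone-rich pixels by Otsu thresholding of the masked
    brightness values.  A degenerate (constant) map returns the whole
    outline as foreground, with a warning."""
    mask = brightness_map.outline_mask
    vals = brightness_map.pixels[mask]
    if vals.size == 0:
        raise ParameterError("brightness map has an empty outline mask")
    if np.ptp(vals) == 0 or np.unique(vals).size < 2:
        warnings.warn(
            "brightness map is constant; returning the whole outline as foreground",
            stacklevel=2,
        )
        return mask.copy()
    thr = threshold_otsu(vals)
    return mask & (brightness_map.pixels > thr)


def trace_isodensity(
    brightness_map: CalibratedImage, n_levels: int
) -> IsodensityPartition:
    """Partition the outline into ``n_levels`` isodensity regions.

    Levels are quantile (equal-pixel-mass) bins of the masked brightness
    values, ordered dark → bright; each region is the pixel set of one bin
    and may consist of several patches.  The bin boundaries are the traced
    isodensity levels.
    """
    if n_levels < 1:
        raise ParameterError("n_levels must be >= 1")
    mask = brightness_map.outline_mask
    vals = brightness_map.pixels[mask]
    if np.unique(vals).size < n_levels:
        raise PartitionError(
            f"n_levels={n_levels} exceeds the number of distinct intensities "
            f"({np.unique(vals).size})"
        )
    # quantile (equal-pixel-mass) cuts, snapped to midpoints between distinct
    # values so that heavily tied maps (e.g. step images) still yield
    # non-empty bins with boundaries between the plateaus
    uniq, counts = np.unique(vals, return_counts=True)
    cum = np.cumsum(counts) / vals.size
    edges = []
    prev = -1
    for k in range(1, n_levels):
        target = k / n_levels
        idx = int(np.argmin(np.abs(cum[:-1] - target)))
        idx = max(idx, prev + 1)
        if idx > len(uniq) - 2:
            raise PartitionError(
                f"cannot place {n_levels} non-empty levels on this map"
            )
        edges.append(0.5 * (uniq[idx] + uniq[idx + 1]))
        prev = idx
    edges = np.asarray(edges)
    labels = np.zeros(brightness_map.shape, dtype=np.int32)
    labels[mask] = np.digitize(brightness_map.pixels[mask], edges, right=True) + 1
    lo = [float(vals.min())] + [float(e) for e in edges]
    hi = [float(e) for e in edges] + [float(vals.max())]
    bounds = list(zip(lo, hi))
    try:
        return IsodensityPartition(
            labels=labels,
            level_bounds=bounds,
            scale=brightness_map.scale,
            origin=brightness_map.origin,
        )
    except PartitionError as exc:
        raise PartitionError(
            f"quantile binning produced an empty level (heavy intensity ties); "
            f"reduce n_levels ({exc})"
        ) from exc


def region_areas(
    partition: IsodensityPartition, scale: float | None = None
) -> np.ndarray:
    """Region areas (mm²) as pixel counts × (scale/1000)²."""
    if scale is None:
        scale = partition.scale
    px2 = (scale / 1000.0) ** 2
    counts = np.bincount(partition.labels.ravel(), minlength=partition.n_levels + 1)
    return counts[1:] * px2


def estimate_scotoma_radius(
    brightness_map: CalibratedImage, rel_threshold: float = 0.03
) -> float:
    """Equivalent radius (mm) of the central cone-free zone, from the
    near-zero-brightness component containing the retinal centre.

    Returns 0.0 when the centre is not dark (healthy topography).
    """
    mask = brightness_map.outline_mask
    vals = brightness_map.pixels[mask]
    thr = rel_threshold * float(np.percentile(vals, 99.0))
    dark = mask & (brightness_map.pixels < thr)
    row = int(round((0.0 - brightness_map.origin[1]) * 1000.0 / brightness_map.scale))
    col = int(round((0.0 - brightness_map.origin[0]) * 1000.0 / brightness_map.scale))
    if not (0 <= row < dark.shape[0] and 0 <= col < dark.shape[1]):
        raise ParameterError("retinal centre lies outside the montage frame")
    if not dark[row, col]:
        return 0.0
    comp = cc_label(dark, connectivity=2)
    area_px = int(np.count_nonzero(comp == comp[row, col]))
    area_mm2 = area_px * (brightness_map.scale / 1000.0) ** 2
    return float(np.sqrt(area_mm2 / np.pi))


def save_partition(partition: IsodensityPartition, directory) -> Path:
    """Write a partition as an indexed-label TIFF plus a CSV of
    ``region_id,level_lo,level_hi,area_mm2`` (georeferencing in the TIFF
    description)."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "scale_um_per_px": partition.scale,
        "origin_mm": list(partition.origin),
        "level_bounds": [list(b) for b in partition.level_bounds],
    }
    tifffile.imwrite(
        directory / "partition_labels.tif",
        partition.labels.astype(np.uint8),
        description=json.dumps(meta),
    )
    areas = partition.areas_mm2()
    with open(directory / "partition.csv", "w") as fh:
        fh.write("region_id,level_lo,level_hi,area_mm2\n")
        for rid, (lo, hi), a in zip(partition.region_ids,
                                    partition.level_bounds, areas):
            fh.write(f"{rid},{lo:.6g},{hi:.6g},{a:.6f}\n")
    return directory


def load_partition(directory) -> IsodensityPartition:
    """Read a partition written by :func:`save_partition`."""
    import tifffile

    directory = Path(directory)
    with tifffile.TiffFile(directory / "partition_labels.tif") as tf:
        page = tf.pages[0]
        labels = page.asarray()
        meta = json.loads(page.tags["ImageDescription"].value)
    return IsodensityPartition(
        labels=labels.astype(np.int32),
        level_bounds=[tuple(b) for b in meta["level_bounds"]],
        scale=float(meta["scale_um_per_px"]),
        origin=tuple(meta["origin_mm"]),
    )


def isodensity_contours(
    brightness_map: CalibratedImage, partition: IsodensityPartition
) -> list[tuple[float, np.ndarray]]:
    """Boundary polylines (mm) of the partition's internal levels.

    Returns ``(level, polyline)`` pairs where ``polyline`` is an (n, 2)
    array of ``(x_mm, y_mm)`` vertices.
    """
    mask = brightness_map.outline_mask
    vals = brightness_map.pixels[mask]
    floor = float(vals.min()) - 1.0
    filled = np.where(mask, brightness_map.pixels, floor)
    out: list[tuple[float, np.ndarray]] = []
    ox, oy = brightness_map.origin
    s = brightness_map.scale / 1000.0
    for lo, _hi in partition.level_bounds[1:]:
        for poly in find_contours(filled, level=lo):
            xy = np.column_stack([ox + poly[:, 1] * s, oy + poly[:, 0] * s])
            out.append((float(lo), xy))
    return out


def export_contours_geojson(
    contours: list[tuple[float, np.ndarray]], path
) -> Path:
    """Write isodensity boundary curves as GeoJSON LineStrings (mm coords)."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"level": level},
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in poly],
            },
        }
        for level, poly in contours
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path
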