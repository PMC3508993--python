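"""End-to-end runs: simulate → map → sample → count → estimate → report.

`analyze_mosaic` performs the whole-mount analysis in memory on a ground
truth mosaic; `run_pipeline` wraps it with config handling, file output
and logging so a complete reproducible run is one call (or one CLI
invocation).  Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CalibratedImage,
    ConeMosaicTruth,
    IsodensityPartition,
    SamplingScheme,
    TotalEstimate,
)
from .detect import DetectionParams, calibrate_detection, combine_location, count_field
from .estimator import (
    DEFAULT_WILDTYPE_TOTAL,
    estimate_total,
    make_sampling_scheme,
    region_density,
)
from .synthetic import (
    DEFAULT_EXCLUSION_UM,
    DEFAULT_FIELD_SCALE_UM,
    DEFAULT_MONTAGE_SCALE_UM,
    make_density_profile,
    render_field,
    render_montage,
    sample_mosaic,
    write_dataset,
)
from .topography import (
    build_brightness_map,
    estimate_scotoma_radius,
    export_contours_geojson,
    isodensity_contours,
    trace_isodensity,
)

log = logging.getLogger("conetop")

__all__ = ["RunConfig", "PipelineResult", "analyze_mosaic", "run_pipeline",
           "write_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON-serialisable)."""

    profile: str = "rd10_st"
    profile_overrides: dict = field(default_factory=dict)
    seed: int = 0
    exclusion_radius_um: float = DEFAULT_EXCLUSION_UM
    montage_scale_um: float = DEFAULT_MONTAGE_SCALE_UM
    field_scale_um: float = DEFAULT_FIELD_SCALE_UM
    smooth_scale_um: float = 100.0
    background_scale_um: float = 500.0
    n_levels: int = 5
    detection: dict = field(default_factory=dict)
    reference_total: float = DEFAULT_WILDTYPE_TOTAL
    out_dir: str = "conetop_run"
    save_images: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    truth: ConeMosaicTruth
    montage: CalibratedImage
    brightness_map: CalibratedImage
    partition: IsodensityPartition
    scheme: SamplingScheme
    scotoma_radius: float
    location_densities: np.ndarray
    location_flags: list[tuple[str, ...]]
    region_densities: dict[int, float]
    estimate: TotalEstimate
    fields: list


def analyze_mosaic(
    truth: ConeMosaicTruth,
    montage_scale_um: float = DEFAULT_MONTAGE_SCALE_UM,
    field_scale_um: float = DEFAULT_FIELD_SCALE_UM,
    smooth_scale_um: float = 100.0,
    background_scale_um: float = 500.0,
    n_levels: int = 5,
    detection: DetectionParams | None = None,
    reference_total: float | None = DEFAULT_WILDTYPE_TOTAL,
    count_from_truth: bool = False,
) -> PipelineResult:
    """Run the full whole-mount analysis on one mosaic.

    With ``count_from_truth=True`` the per-field counts are read from the
    ground-truth coordinates instead of rendered images — isolating the
    sampling/stratification error from detection error (used by the
    estimator-bias tests; ~50× faster).
    """
    montage = render_montage(truth, scale=montage_scale_um)
    bmap = build_brightness_map(
        montage, smooth_scale=smooth_scale_um, background_scale=background_scale_um
    )
    scotoma_r = estimate_scotoma_radius(bmap)
    partition = trace_isodensity(bmap, n_levels)
    scheme = make_sampling_scheme(partition, inner_radius=scotoma_r)

    centers = [c for i in range(scheme.n_locations) for c in scheme.field_centers(i)]
    side = scheme.field_side
    if count_from_truth:
        counts = [truth.count_in_box(c, side) for c in centers]
        k = scheme.fields_per_location
        dens = [
            float(np.mean(counts[i * k : (i + 1) * k])) / (side / 1000.0) ** 2
            for i in range(scheme.n_locations)
        ]
        location_densities = np.array(dens)
        location_flags = [() for _ in range(scheme.n_locations)]
        fields = []
    else:
        images = [
            render_field(truth, c, field_side=side, scale=field_scale_um)
            for c in centers
        ]
        params = calibrate_detection(images, detection)
        log.info(
            "detection calibrated: background=%.4f unit=%s",
            params.background,
            f"{params.unit_amplitude:.4f}" if params.unit_amplitude else "auto",
        )
        k = scheme.fields_per_location
        fields = [
            count_field(
                img,
                tuple(scheme.locations[i // k]),
                field_side=side,
                params=params,
            )
            for i, img in enumerate(images)
        ]
        location_densities = np.empty(scheme.n_locations)
        location_flags = []
        for i in range(scheme.n_locations):
            d, fl = combine_location(fields[i * k : (i + 1) * k])
            location_densities[i] = d
            location_flags.append(fl)

    region_dens = region_density(scheme, location_densities, partition)
    est = estimate_total(
        partition, region_dens, scheme, reference_total=reference_total
    )
    return PipelineResult(
        truth=truth,
        montage=montage,
        brightness_map=bmap,
        partition=partition,
        scheme=scheme,
        scotoma_radius=scotoma_r,
        location_densities=location_densities,
        location_flags=location_flags,
        region_densities=region_dens,
        estimate=est,
        fields=fields,
    )


def _summary_dict(result: PipelineResult, config: RunConfig | None) -> dict:
    est = result.estimate
    out = {
        "total_cones": round(est.total, 1),
        "true_total": result.truth.true_total,
        "relative_error_pct": round(
            100.0 * (est.total - result.truth.true_total)
            / max(result.truth.true_total, 1),
            2,
        ),
        "sampled_area_mm2": round(est.sampled_area, 6),
        "sampling_fraction_pct": round(est.sampling_fraction, 2),
        "outline_area_mm2": round(est.outline_area, 4),
        "scotoma_radius_mm": round(result.scotoma_radius, 4),
        "n_locations": result.scheme.n_locations,
        "n_fields": result.scheme.n_fields,
        "n_regions": result.partition.n_levels,
    }
    if est.percent_of_wildtype is not None:
        out["percent_of_wildtype"] = round(est.percent_of_wildtype, 1)
        out["percent_of_wildtype_rounded"] = int(round(est.percent_of_wildtype))
    if config is not None:
        out["seed"] = config.seed
        out["profile"] = config.profile
    return out


def write_report(result: PipelineResult, out_dir, config: RunConfig | None = None):
    """Write the per-region estimate CSV, the summary JSON, the partition
    label image + CSV, isodensity contours (GeoJSON) and a QC overlay."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    est = result.estimate

    pd.DataFrame(
        {
            "region_id": est.region_ids,
            "density_mm2": est.densities,
            "area_mm2": est.areas,
            "contribution": est.contributions,
        }
    ).to_csv(out_dir / "estimate.csv", index=False)

    rows = []
    for i, (x, y) in enumerate(result.scheme.locations):
        rows.append(
            {
                "location_x_mm": round(float(x), 5),
                "location_y_mm": round(float(y), 5),
                "meridian": result.scheme.meridians[i],
                "density_mm2": round(float(result.location_densities[i]), 2),
                "region_id": result.partition.region_at(x, y),
                "flags": ";".join(result.location_flags[i]),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "locations.csv", index=False)

    part = result.partition
    pd.DataFrame(
        {
            "region_id": part.region_ids,
            "level_lo": [b[0] for b in part.level_bounds],
            "level_hi": [b[1] for b in part.level_bounds],
            "area_mm2": part.areas_mm2(),
        }
    ).to_csv(out_dir / "partition.csv", index=False)

    import tifffile

    tifffile.imwrite(out_dir / "partition_labels.tif",
                     part.labels.astype(np.uint8))
    contours = isodensity_contours(result.brightness_map, part)
    export_contours_geojson(contours, out_dir / "isodensity_curves.geojson")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_summary_dict(result, config), fh, indent=2, sort_keys=True)

    _write_overlay(result, out_dir / "overlay.png")


def _write_overlay(result: PipelineResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = result.montage
    ny, nx = m.shape
    extent = (
        m.origin[0] - m.scale / 2000.0,
        m.origin[0] + (nx - 0.5) * m.scale / 1000.0,
        m.origin[1] - m.scale / 2000.0,
        m.origin[1] + (ny - 0.5) * m.scale / 1000.0,
    )
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(m.pixels, cmap="gray", origin="lower", extent=extent)
    for level, poly in isodensity_contours(result.brightness_map, result.partition):
        ax.plot(poly[:, 0], poly[:, 1], lw=0.5, color="cyan")
    locs = result.scheme.locations
    ax.plot(locs[:, 0], locs[:, 1], "r+", ms=8, mew=1.5)
    ax.set_xlabel("x (mm, nasal →)")
    ax.set_ylabel("y (mm, dorsal →)")
    ax.set_title("montage with isodensity curves and sampling locations")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full simulate→estimate run from a config; returns the
    summary dict and writes all report files to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True))

    stage = "simulate"
    try:
        t0 = time.time()
        profile = make_density_profile(config.profile, **config.profile_overrides)
        truth = sample_mosaic(
            profile, seed=config.seed, exclusion_radius=config.exclusion_radius_um
        )
        log.info("simulate: %d cones (%.1fs)", truth.true_total, time.time() - t0)

        stage = "analyze"
        t0 = time.time()
        detection = DetectionParams(**config.detection) if config.detection else None
        result = analyze_mosaic(
            truth,
            montage_scale_um=config.montage_scale_um,
            field_scale_um=config.field_scale_um,
            smooth_scale_um=config.smooth_scale_um,
            background_scale_um=config.background_scale_um,
            n_levels=config.n_levels,
            detection=detection,
            reference_total=config.reference_total,
        )
        log.info(
            "analyze: total %.0f vs truth %d (%.1fs)",
            result.estimate.total,
            truth.true_total,
            time.time() - t0,
        )

        stage = "report"
        write_report(result, out_dir, config)
        if config.save_images:
            centers = [
                c
                for i in range(result.scheme.n_locations)
                for c in result.scheme.field_centers(i)
            ]
            imgs = [(c, f.image) for c, f in zip(centers, result.fields)]
            write_dataset(truth, result.montage, imgs, out_dir / "images")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out_dir / "summary.json") as fh:
        return json.load(fh)
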