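"""Core containers shared across the pipeline.

Coordinate conventions
----------------------
Retina-centred coordinates in millimetres: ``x`` toward the nasal pole,
``y`` toward the dorsal pole.  Rasters use the pixel-centre convention:
pixel ``(row, col)`` of a :class:`CalibratedImage` sits at physical
position ``origin + (col, row) * scale / 1000`` mm, with ``y`` increasing
with the row index.  All raster areas are pixel counts times ``scale²``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConetopError",
    "ParameterError",
    "GenerationError",
    "PartitionError",
    "SchemeError",
    "EstimationError",
    "CalibratedImage",
    "DensityProfile",
    "ConeMosaicTruth",
    "FieldSample",
    "IsodensityPartition",
    "SamplingScheme",
    "TotalEstimate",
]


class ConetopError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(ConetopError, ValueError):
    """A parameter value violates its contract."""


class GenerationError(ConetopError, RuntimeError):
    """Synthetic mosaic generation failed (e.g. infeasible packing)."""


class PartitionError(ConetopError, ValueError):
    """An isodensity partition violates its invariants."""


class SchemeError(ConetopError, RuntimeError):
    """A sampling scheme cannot satisfy its coverage requirements."""


class EstimationError(ConetopError, ValueError):
    """The stratified estimator received inconsistent inputs."""


# --------------------------------------------------------------------------
# Images


@dataclass
class CalibratedImage:
    """Grayscale raster with a physical scale and a whole-mount outline mask.

    Parameters
    ----------
    pixels
        2-D non-negative intensity array (arbitrary units).
    scale
        Physical pixel pitch in µm/pixel.
    origin
        ``(x, y)`` position, in mm, of the centre of pixel ``(0, 0)``.
    outline_mask
        Boolean array of the same shape marking tissue; intensity outside
        the mask is undefined.
    """

    pixels: np.ndarray
    scale: float
    origin: tuple[float, float] = (0.0, 0.0)
    outline_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be a 2-D array")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ParameterError(f"scale must be positive, got {self.scale}")
        if self.outline_mask is None:
            self.outline_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.outline_mask = np.asarray(self.outline_mask, dtype=bool)
            if self.outline_mask.shape != self.pixels.shape:
                raise ParameterError("outline_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x_mm, y_mm)`` arrays giving pixel-centre positions."""
        ny, nx = self.pixels.shape
        x = self.origin[0] + np.arange(nx) * self.scale / 1000.0
        y = self.origin[1] + np.arange(ny) * self.scale / 1000.0
        return np.meshgrid(x, y)

    def to_index(self, x_mm: float | np.ndarray, y_mm: float | np.ndarray):
        """Map physical mm coordinates to (row, col) indices (rounded)."""
        col = np.rint((np.asarray(x_mm) - self.origin[0]) * 1000.0 / self.scale)
        row = np.rint((np.asarray(y_mm) - self.origin[1]) * 1000.0 / self.scale)
        return row.astype(int), col.astype(int)

    def mask_area_mm2(self) -> float:
        """Area of the outline mask in mm²."""
        return float(self.outline_mask.sum()) * (self.scale / 1000.0) ** 2


# --------------------------------------------------------------------------
# Synthetic ground truth


@dataclass
class DensityProfile:
    """Radial-plus-angular model of local cone density on a whole mount.

    The surviving zone spans ``scotoma_radius <= r <= retina_radius``;
    density rises monotonically from ``d_min`` at the inner edge to
    ``d_max`` at the margin (squared quintic smoothstep: flat just outside
    the degeneration border, where the wave of cone loss has most recently
    passed, then rising steeply toward the spared far periphery), with an
    optional angular modulation (``anisotropy_amp``) that bends the radial
    profile without moving its endpoints.  Inside the scotoma the density
    is zero.
    """

    kind: str
    retina_radius: float = 2.05       # mm
    scotoma_radius: float = 0.0       # mm
    d_min: float = 0.0                # cones/mm² at inner edge of surviving zone
    d_max: float = 0.0                # cones/mm² at the retinal margin
    anisotropy_amp: float = 0.0       # in [0, 1]

    def __post_init__(self) -> None:
        if self.d_min < 0 or self.d_max < 0:
            raise ParameterError("densities must be non-negative")
        if self.d_min > self.d_max:
            raise ParameterError("d_min must not exceed d_max")
        if not 0 <= self.anisotropy_amp <= 1:
            raise ParameterError("anisotropy_amp must lie in [0, 1]")
        if not 0 <= self.scotoma_radius < self.retina_radius:
            raise ParameterError("require 0 <= scotoma_radius < retina_radius")

    # quintic smoothstep: flat (zero slope and curvature) at both ends
    @staticmethod
    def _smootherstep(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, 1.0)
        return t * t * t * (t * (6.0 * t - 15.0) + 10.0)

    def density(self, r, theta=0.0) -> np.ndarray:
        """Local density (cones/mm²) at polar position ``(r mm, theta rad)``."""
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        span = self.retina_radius - self.scotoma_radius
        t = (r - self.scotoma_radius) / span
        base = self._smootherstep(t) ** 2
        if self.anisotropy_amp > 0:
            # exponent modulation: warps the mid-profile, keeps endpoints fixed
            p = 1.0 + self.anisotropy_amp * np.cos(2.0 * theta)
            base = base ** p
        dens = self.d_min + (self.d_max - self.d_min) * base
        inside = (r >= self.scotoma_radius) & (r <= self.retina_radius)
        return np.where(inside, dens, 0.0)

    def density_xy(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.density(np.hypot(x, y), np.arctan2(y, x))

    def peak_density(self) -> float:
        return float(self.d_max)

    def expected_count(self, n_r: int = 2048, n_theta: int = 256) -> float:
        """Numerically integrate the density over the whole mount."""
        r = (np.arange(n_r) + 0.5) * self.retina_radius / n_r
        th = (np.arange(n_theta) + 0.5) * 2.0 * np.pi / n_theta
        rr, tt = np.meshgrid(r, th, indexing="ij")
        dens = self.density(rr, tt)
        dr = self.retina_radius / n_r
        dth = 2.0 * np.pi / n_theta
        return float(np.sum(dens * rr) * dr * dth)

    def retina_area_mm2(self) -> float:
        return float(np.pi * self.retina_radius ** 2)


@dataclass
class ConeMosaicTruth:
    """Ground-truth cone coordinates for one synthetic whole mount."""

    positions: np.ndarray             # (N, 2) array of (x, y) in mm
    profile: DensityProfile
    seed: int
    exclusion_radius: float           # µm, hard-core minimum spacing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    @property
    def true_total(self) -> int:
        return int(self.positions.shape[0])

    def count_in_box(self, center: Sequence[float], side_um: float) -> int:
        """Number of ground-truth cones whose centres fall inside a square
        field of ``side_um`` µm centred at ``center`` (mm)."""
        half = side_um / 2000.0
        dx = np.abs(self.positions[:, 0] - center[0])
        dy = np.abs(self.positions[:, 1] - center[1])
        return int(np.count_nonzero((dx <= half) & (dy <= half)))


# --------------------------------------------------------------------------
# Measurement containers


@dataclass
class FieldSample:
    """One 125×125 µm² high-resolution field with its detection result."""

    location: tuple[float, float]     # sampling location (x, y) in mm
    field_side: float                 # µm
    image: CalibratedImage | None = None
    detections: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=float).reshape(-1, 2)
        if self.field_side <= 0:
            raise ParameterError("field_side must be positive")

    @property
    def count(self) -> int:
        return int(self.detections.shape[0])

    @property
    def density(self) -> float:
        """Local density in cones/mm²."""
        return self.count / (self.field_side / 1000.0) ** 2


@dataclass
class IsodensityPartition:
    """Disjoint isodensity regions covering the whole-mount outline.

    ``labels`` assigns every outline pixel a region id ``1..n_levels``
    ordered dark → bright; pixels outside the outline are 0.
    """

    labels: np.ndarray
    level_bounds: list[tuple[float, float]]
    scale: float                      # µm/pixel of the label raster
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise PartitionError("labels must be a 2-D array")
        if self.scale <= 0:
            raise PartitionError("scale must be positive")
        n = self.n_levels
        if n < 1:
            raise PartitionError("partition must contain at least one region")
        counts = np.bincount(self.labels.ravel(), minlength=n + 1)
        if np.any(counts[1 : n + 1] == 0):
            empty = [i for i in range(1, n + 1) if counts[i] == 0]
            raise PartitionError(f"empty region(s): {empty}")
        if len(self.level_bounds) != n:
            raise PartitionError("level_bounds must match the number of regions")
        los = [b[0] for b in self.level_bounds]
        his = [b[1] for b in self.level_bounds]
        if any(h < l for l, h in zip(los, his)) or los != sorted(los):
            raise PartitionError("level_bounds must be ordered dark→bright")

    @property
    def n_levels(self) -> int:
        return int(self.labels.max())

    @property
    def outline_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def region_ids(self) -> list[int]:
        return list(range(1, self.n_levels + 1))

    def areas_mm2(self) -> np.ndarray:
        """Region areas (mm²) by pixel counting; index i → region i+1."""
        px2 = (self.scale / 1000.0) ** 2
        counts = np.bincount(self.labels.ravel(), minlength=self.n_levels + 1)
        return counts[1:] * px2

    def outline_area_mm2(self) -> float:
        return float(self.outline_mask.sum()) * (self.scale / 1000.0) ** 2

    def region_at(self, x_mm: float, y_mm: float) -> int:
        """Region id at a physical position (0 if outside the outline)."""
        row = int(round((y_mm - self.origin[1]) * 1000.0 / self.scale))
        col = int(round((x_mm - self.origin[0]) * 1000.0 / self.scale))
        if not (0 <= row < self.labels.shape[0] and 0 <= col < self.labels.shape[1]):
            return 0
        return int(self.labels[row, col])


@dataclass
class SamplingScheme:
    """Meridian-based field-sampling layout.

    16 locations by default: four per half-meridian along the dorso-ventral
    and naso-temporal axes, two 125×125 µm² fields per location.
    """

    locations: np.ndarray             # (n, 2) in mm
    meridians: list[str]              # 'NT' or 'DV' per location
    fields_per_location: int = 2
    field_side: float = 125.0         # µm
    field_offset: float = 70.0        # µm, perpendicular offset of the two fields

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float).reshape(-1, 2)
        if len(self.meridians) != self.n_locations:
            raise SchemeError("one meridian label per location required")

    @property
    def n_locations(self) -> int:
        return int(self.locations.shape[0])

    @property
    def n_fields(self) -> int:
        return self.n_locations * self.fields_per_location

    def sampled_area_mm2(self) -> float:
        return self.n_fields * (self.field_side / 1000.0) ** 2

    def field_centers(self, i: int) -> list[tuple[float, float]]:
        """Centres (mm) of the fields imaged at location ``i``.

        The two fields sit side by side, offset perpendicular to the
        location's meridian so both stay at the same eccentricity.
        """
        x, y = self.locations[i]
        d = self.field_offset / 1000.0
        if self.meridians[i] == "NT":          # meridian along x → offset in y
            offs = [(0.0, -d), (0.0, d)]
        else:                                   # meridian along y → offset in x
            offs = [(-d, 0.0), (d, 0.0)]
        k = self.fields_per_location
        return [(x + ox, y + oy) for ox, oy in offs[:k]] if k <= 2 else NotImplemented


@dataclass
class TotalEstimate:
    """Area-weighted stratified estimate of the whole-mount cone total."""

    region_ids: list[int]
    densities: np.ndarray             # cones/mm² per region
    areas: np.ndarray                 # mm² per region
    sampled_area: float               # mm²
    outline_area: float               # mm²
    reference_total: float | None = None

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.densities.shape != self.areas.shape:
            raise EstimationError("densities and areas must align")
        if np.any(self.densities < 0) or np.any(self.areas <= 0):
            raise EstimationError("densities must be >=0 and areas >0")

    @property
    def contributions(self) -> np.ndarray:
        return self.densities * self.areas

    @property
    def total(self) -> float:
        return float(self.contributions.sum())

    @property
    def sampling_fraction(self) -> float:
        """Sampled fraction of the retinal surface, in percent."""
        return 100.0 * self.sampled_area / self.outline_area

    @property
    def percent_of_wildtype(self) -> float | None:
        if self.reference_total is None:
            return None
        return 100.0 * self.total / self.reference_total
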