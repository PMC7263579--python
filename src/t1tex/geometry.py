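"""Myocardial unwrapping: landmark-anchored polar-to-rectangular transform.

The delineated myocardium of a short-axis slice is resampled onto a
standardized rectangular grid: columns sweep the full circumference
clockwise (displayed-image convention, y axis pointing down) starting at
the angle of the RV-insertion landmark, rows sample equal fractional
depths across the wall from the endocardial to the epicardial border.
Five slices (base to apex) are stacked vertically into one map per
subject.

Conventions fixed here and relied on by the texture modules:

* row 0 = endocardial border, last row = epicardial border;
* angles are sampled at column centers, ``(c + 0.5) / cols`` of a full
  turn from the landmark angle; radial depths at ``(r + 0.5) / rows``,
  so all sample points are strictly interior to the wall;
* "clockwise" is in displayed-image orientation (y down), i.e. the
  mathematical angle ``atan2(dy, dx)`` increases;
* the LV center used for ray casting is the endocardial-contour centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

__all__ = [
    "Contour",
    "ContourError",
    "UnwrapError",
    "UnwrapConfig",
    "RectangularMap",
    "StackedMap",
    "RESOLUTION_PRESETS",
    "rasterize_myocardium",
    "unwrap_slice",
    "unwrap_subject",
    "stack_subject",
    "global_and_segmental_t1",
]

#: Rectangular-map resolution presets (rows, cols); cols = 6 * rows keeps
#: six 32x32-style segments per slice at every preset.
RESOLUTION_PRESETS: dict[str, tuple[int, int]] = {
    "R16": (16, 96),
    "R32": (32, 192),
    "R64": (64, 384),
}


class ContourError(ValueError):
    """Invalid or mutually inconsistent myocardial contours."""


class UnwrapError(ValueError):
    """The slice cannot be unwrapped (degenerate wall or ray failure)."""


@dataclass(frozen=True)
class Contour:
    """Closed, ordered planar contour in 0-based pixel coordinates (x=column, y=row)."""

    points: np.ndarray  # (N, 2) float, not repeating the first point
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ContourError("contour needs >= 8 (x, y) points")
        if not self.closed:
            raise ContourError("open contour")
        if not np.all(np.isfinite(pts)):
            raise ContourError("contour contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def polygon(self) -> Polygon:
        poly = Polygon(self.points)
        if not poly.is_valid:
            raise ContourError("self-intersecting contour")
        return poly

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + np.array([dx, dy]))


@dataclass(frozen=True)
class UnwrapConfig:
    """Sampling resolution of the rectangular map.

    ``cols`` must equal ``6 * rows`` so that each slice splits into six
    equal square-ish segments regardless of the preset.
    """

    rows: int = 32
    cols: int = 192

    def __post_init__(self) -> None:
        if self.rows < 2:
            raise ValueError("rows must be >= 2")
        if self.cols != 6 * self.rows:
            raise ValueError("cols must equal 6 * rows")

    @classmethod
    def from_preset(cls, name: str) -> "UnwrapConfig":
        try:
            rows, cols = RESOLUTION_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown resolution preset {name!r}; choose from {sorted(RESOLUTION_PRESETS)}"
            ) from None
        return cls(rows=rows, cols=cols)


@dataclass(frozen=True)
class RectangularMap:
    """One unwrapped slice: rows x cols of T1 values (ms), column 0 at the landmark."""

    values: np.ndarray
    slice_index: int
    config: UnwrapConfig = field(default_factory=UnwrapConfig)


@dataclass(frozen=True)
class StackedMap:
    """Five unwrapped slices stacked vertically, base (top) to apex (bottom)."""

    values: np.ndarray
    config: UnwrapConfig = field(default_factory=UnwrapConfig)


def rasterize_myocardium(
    endo: Contour, epi: Contour, grid_shape: tuple[int, int]
) -> np.ndarray:
    """Binary mask of the myocardial annulus on a pixel grid.

    A pixel belongs to the myocardium when its center lies strictly
    inside the epicardial polygon and not strictly inside the
    endocardial polygon.
    """
    endo_poly = endo.polygon()
    epi_poly = epi.polygon()
    # Tiny outward buffer tolerates shared/touching boundary points.
    if not epi_poly.buffer(1e-9).covers(endo_poly):
        raise ContourError("contours crossing: epicardium does not enclose endocardium")
    h, w = grid_shape
    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.ravel().astype(float)
    ys = ys.ravel().astype(float)
    in_epi = shapely.contains_xy(epi_poly, xs, ys)
    in_endo = shapely.contains_xy(endo_poly, xs, ys)
    return (in_epi & ~in_endo).reshape(h, w)


def _ray_radii(points: np.ndarray, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from ``center`` to a closed polyline along each ray direction.

    Returns the nearest positive intersection per angle, NaN where the
    ray misses the contour.
    """
    p0 = points
    p1 = np.roll(points, -1, axis=0)
    seg = p1 - p0                      # (N, 2)
    rel = p0 - center                  # (N, 2)
    d = np.column_stack([np.cos(angles), np.sin(angles)])  # (M, 2)

    # Solve center + t*d = p0 + u*seg via 2-D cross products.
    denom = d[:, None, 0] * seg[None, :, 1] - d[:, None, 1] * seg[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[None, :, 0] * seg[None, :, 1] - rel[None, :, 1] * seg[None, :, 0]) / denom
        u = (rel[None, :, 0] * d[:, None, 1] - rel[None, :, 1] * d[:, None, 0]) / denom
    valid = (np.abs(denom) > 1e-12) & (u >= 0.0) & (u < 1.0) & (t > 1e-9)
    t = np.where(valid, t, np.inf)
    radii = t.min(axis=1)
    radii[~np.isfinite(radii)] = np.nan
    return radii


def unwrap_slice(t1_slice, cfg: UnwrapConfig | None = None) -> RectangularMap:
    """Unwrap one delineated slice into a rows x cols rectangular T1 map.

    ``t1_slice`` provides ``pixel_grid`` (2-D ms values), ``endo``/``epi``
    contours, a ``landmark`` point, and optionally ``slice_index``.
    Values are bilinearly interpolated at the polar sample points.
    """
    cfg = cfg or UnwrapConfig()
    grid = np.asarray(t1_slice.pixel_grid, dtype=float)
    endo: Contour = t1_slice.endo
    epi: Contour = t1_slice.epi
    center = endo.centroid
    lx, ly = np.asarray(t1_slice.landmark, dtype=float)
    theta0 = np.arctan2(ly - center[1], lx - center[0])

    # Clockwise on screen (y down) == increasing atan2 angle.
    angles = theta0 + 2.0 * np.pi * (np.arange(cfg.cols) + 0.5) / cfg.cols
    r_endo = _ray_radii(endo.points, center, angles)
    r_epi = _ray_radii(epi.points, center, angles)
    for name, radii in (("endocardial", r_endo), ("epicardial", r_epi)):
        if np.any(np.isnan(radii)):
            bad = angles[np.isnan(radii)][0]
            deg = np.degrees((bad - theta0) % (2 * np.pi))
            raise UnwrapError(
                f"ray at {deg:.1f} deg from landmark fails to intersect the {name} contour"
            )
    wall = r_epi - r_endo
    if np.any(wall < 1.0):
        deg = np.degrees((angles[np.argmin(wall)] - theta0) % (2 * np.pi))
        raise UnwrapError(
            f"degenerate wall thickness {wall.min():.3f} px at {deg:.1f} deg from landmark"
        )

    depths = (np.arange(cfg.rows) + 0.5) / cfg.rows           # row 0 = endo side
    radii = r_endo[None, :] + depths[:, None] * wall[None, :]  # (rows, cols)
    xs = center[0] + radii * np.cos(angles)[None, :]
    ys = center[1] + radii * np.sin(angles)[None, :]
    values = map_coordinates(grid, [ys, xs], order=1, mode="nearest")
    return RectangularMap(
        values=values, slice_index=getattr(t1_slice, "slice_index", 0), config=cfg
    )


def stack_subject(maps: list[RectangularMap]) -> StackedMap:
    """Stack five unwrapped slices (base to apex) into one tall map."""
    if len(maps) != 5:
        raise ValueError(f"expected 5 rectangular maps, got {len(maps)}")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"mixed map shapes {sorted(shapes)}; all slices must share one config")
    return StackedMap(values=np.vstack([m.values for m in maps]), config=maps[0].config)


def unwrap_subject(subject, cfg: UnwrapConfig | None = None) -> StackedMap:
    """Unwrap and stack all five slices of a subject."""
    cfg = cfg or UnwrapConfig()
    maps = []
    for i, sl in enumerate(subject.slices):
        m = unwrap_slice(sl, cfg)
        maps.append(RectangularMap(values=m.values, slice_index=i, config=cfg))
    return stack_subject(maps)


def global_and_segmental_t1(
    subject, cfg: UnwrapConfig | None = None
) -> tuple[float, np.ndarray]:
    """Global mean T1 over the myocardium of 5 slices plus 30 segmental means.

    The global value averages actual myocardial pixels (rasterized
    annulus) of all slices; the 30 segmental means are averages of the
    six contiguous column blocks of each slice's unwrapped map, block 0
    starting at the landmark column, ordered slice-major base to apex.
    """
    cfg = cfg or UnwrapConfig()
    pixels = []
    segments = []
    width = cfg.cols // 6
    for sl in subject.slices:
        mask = rasterize_myocardium(sl.endo, sl.epi, np.asarray(sl.pixel_grid).shape)
        if not mask.any():
            raise UnwrapError("empty myocardial mask")
        pixels.append(np.asarray(sl.pixel_grid, dtype=float)[mask])
        unwrapped = unwrap_slice(sl, cfg).values
        for b in range(6):
            segments.append(unwrapped[:, b * width : (b + 1) * width].mean())
    return float(np.concatenate(pixels).mean()), np.asarray(segments)
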