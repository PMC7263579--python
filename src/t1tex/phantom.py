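"""Synthetic short-axis native T1-map phantoms for three cohorts.

Each synthetic subject consists of five short-axis slices (base to
apex) of an annular left-ventricular myocardium rendered on a pixel
grid, with endocardial/epicardial contours and one landmark point at
the inferior RV-insertion angle per slice — everything the unwrapping
stage needs, with no external data.

Cohort archetypes:

* ``control`` — homogeneous wall, global T1 ~ 1071 +/- 32 ms;
* ``HCM`` — regional patchy T1 elevation co-located with a thickened
  septal sector, global T1 ~ 1096 +/- 38 ms;
* ``DCM`` — diffusely elevated T1 (1123 +/- 38 ms) with irregular
  scattered clusters of further elevation.

The myocardial T1 field of a subject is a subject-level mean drawn from
the cohort distribution, plus the cohort texture component, plus
Gaussian pixel noise; after rendering, the field is shifted so the
subject's myocardial mean equals the drawn value exactly, so cohort
global-T1 statistics are recovered by construction. Texture values are
painted on a slightly dilated annulus (a few pixels beyond the
contours) so that bilinear interpolation near the borders never mixes
in background zeros; far background stays 0.

All randomness flows from one master seed through per-subject
``numpy.random.SeedSequence`` substreams keyed by (seed, subject
index), so each subject is reproducible independently of generation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Contour, rasterize_myocardium

__all__ = [
    "COHORTS",
    "CohortSpec",
    "GeometryParams",
    "T1Slice",
    "SubjectPhantom",
    "PhantomError",
    "cohort_defaults",
    "generate_subject",
    "generate_dataset",
]

COHORTS = ("control", "HCM", "DCM")


class PhantomError(ValueError):
    """Invalid phantom specification or unrenderable geometry."""


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of one cohort's T1 distribution and texture."""

    name: str
    t1_mean: float                       # ms, cohort mean of subject global T1
    t1_sd_between_subjects: float        # ms
    texture_kind: str                    # homogeneous | patchy | diffuse
    patch_count_range: tuple[int, int] | None = None   # HCM only
    patch_t1_elevation: float = 0.0      # ms, patch/cluster elevation
    diffuse_noise_sd: float = 0.0        # ms, extra uncorrelated noise (DCM)
    wall_thickness_range: tuple[float, float] = (8.0, 10.0)  # mm, remote wall

    def __post_init__(self) -> None:
        if self.name not in COHORTS:
            raise PhantomError(f"unknown cohort {self.name!r}; choose from {COHORTS}")
        if self.t1_mean <= 0:
            raise PhantomError("t1_mean must be positive")
        if min(self.t1_sd_between_subjects, self.diffuse_noise_sd) < 0:
            raise PhantomError("standard deviations must be >= 0")
        expected = {"control": "homogeneous", "HCM": "patchy", "DCM": "diffuse"}[self.name]
        if self.texture_kind != expected:
            raise PhantomError(
                f"cohort {self.name} requires texture_kind={expected!r}, got {self.texture_kind!r}"
            )
        if (self.texture_kind == "patchy") != (self.patch_count_range is not None):
            raise PhantomError("patch_count_range is required iff texture is patchy")


_DEFAULTS = {
    # Global native T1 (ms): control 1071+/-32, HCM 1096+/-38, DCM 1123+/-38.
    "control": dict(
        t1_mean=1071.0, t1_sd_between_subjects=32.0, texture_kind="homogeneous",
        wall_thickness_range=(8.0, 10.0),
    ),
    "HCM": dict(
        t1_mean=1096.0, t1_sd_between_subjects=38.0, texture_kind="patchy",
        patch_count_range=(2, 5), patch_t1_elevation=120.0,
        wall_thickness_range=(9.0, 12.0),
    ),
    "DCM": dict(
        t1_mean=1123.0, t1_sd_between_subjects=38.0, texture_kind="diffuse",
        patch_t1_elevation=60.0, diffuse_noise_sd=15.0,
        wall_thickness_range=(7.0, 9.0),
    ),
}


def cohort_defaults(name: str) -> CohortSpec:
    """Default :class:`CohortSpec` for ``control``, ``HCM`` or ``DCM``."""
    if name not in _DEFAULTS:
        raise PhantomError(f"unknown cohort {name!r}; choose from {COHORTS}")
    return CohortSpec(name=name, **_DEFAULTS[name])


@dataclass(frozen=True)
class GeometryParams:
    """Phantom geometry and rendering knobs (pixels unless noted)."""

    grid_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 2.1                      # mm
    n_contour_points: int = 96
    #: endocardial radius per slice, base to apex (mm)
    endo_radius_mm: tuple[float, ...] = (26.0, 24.0, 22.0, 20.0, 18.0)
    #: wall thickness taper base to apex (multiplies the sampled thickness)
    wall_taper: tuple[float, ...] = (1.0, 0.95, 0.9, 0.85, 0.8)
    eccentricity: float = 0.04
    landmark_angle: float = 2.2                  # rad, inferior RV insertion (y down)
    septal_width: float = 1.5                    # rad, thickened/patchy sector (HCM)
    septal_bump_mm: float = 7.0                  # extra septal thickness in HCM
    pixel_noise_sd: float = 25.0                 # ms
    paint_margin: float = 4.0                    # px painted beyond the contours

    def center(self, slice_index: int) -> tuple[float, float]:
        base = (self.grid_shape[1] - 1) / 2.0, (self.grid_shape[0] - 1) / 2.0
        # Mild deterministic per-slice drift of the LV center.
        dx = 0.6 * np.cos(1.7 * slice_index + 0.3)
        dy = 0.6 * np.sin(2.3 * slice_index + 1.1)
        return base[0] + dx, base[1] + dy


@dataclass(frozen=True)
class T1Slice:
    """One short-axis T1 map with its delineation."""

    pixel_grid: np.ndarray       # (H, W) ms, background 0
    pixel_size: float            # mm
    endo: Contour
    epi: Contour
    landmark: np.ndarray         # (x, y)
    slice_index: int = 0


@dataclass(frozen=True)
class SubjectPhantom:
    """Five simulated slices plus cohort label for one synthetic subject."""

    subject_id: str
    cohort: str
    slices: tuple[T1Slice, ...]
    seed: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.slices) != 5:
            raise PhantomError(f"expected 5 slices, got {len(self.slices)}")


def _angular_profile(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine window on the circle, 1 at ``center``, 0 outside ``width``."""
    d = np.angle(np.exp(1j * (phi - center)))
    out = np.zeros_like(d)
    inside = np.abs(d) < width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * d[inside] / width))
    return out


def _slice_geometry(spec: CohortSpec, params: GeometryParams, s: int, wall_mm: float):
    """Radius functions (px) of angle for slice ``s``; raises if wall too thin."""
    r0 = params.endo_radius_mm[s] / params.pixel_size
    wall_px = wall_mm * params.wall_taper[s] / params.pixel_size
    bump_px = (
        params.septal_bump_mm * params.wall_taper[s] / params.pixel_size
        if spec.texture_kind == "patchy"
        else 0.0
    )
    sector_center = params.landmark_angle + 1.9

    def r_endo(phi):
        return r0 * (1 + params.eccentricity * np.cos(2 * phi - 0.4 * s))

    def r_epi(phi):
        w = wall_px + bump_px * _angular_profile(phi, sector_center, params.septal_width)
        return r_endo(phi) + w

    if wall_px < 2.0:
        raise PhantomError(
            f"wall thickness {wall_px:.2f} px (< 2 px) at slice {s}: unwrappable at this grid"
        )
    return r_endo, r_epi, sector_center


def _rotated_gaussian(xx, yy, cx, cy, sig_t, sig_r, theta):
    ca, sa = np.cos(theta), np.sin(theta)
    dx, dy = xx - cx, yy - cy
    t = ca * dx + sa * dy
    r = -sa * dx + ca * dy
    return np.exp(-0.5 * ((t / sig_t) ** 2 + (r / sig_r) ** 2))


def generate_subject(
    spec: CohortSpec,
    params: GeometryParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str | None = None,
) -> SubjectPhantom:
    """Render one synthetic subject; deterministic for fixed (spec, params, seed)."""
    params = params or GeometryParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    seed_repr = int(ss.generate_state(1)[0])

    target_t1 = rng.normal(spec.t1_mean, spec.t1_sd_between_subjects)
    wall_mm = rng.uniform(*spec.wall_thickness_range)

    h, w = params.grid_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    phis = 2 * np.pi * np.arange(params.n_contour_points) / params.n_contour_points

    slices: list[T1Slice] = []
    patch_masks: list[np.ndarray] = []
    myo_masks: list[np.ndarray] = []
    for s in range(5):
        cx, cy = params.center(s)
        r_endo_f, r_epi_f, sector_center = _slice_geometry(spec, params, s, wall_mm)
        rho = np.hypot(xx - cx, yy - cy)
        phi = np.arctan2(yy - cy, xx - cx)
        re, rp = r_endo_f(phi), r_epi_f(phi)
        paint = (rho >= re - params.paint_margin) & (rho <= rp + params.paint_margin)

        fld = np.full((h, w), target_t1)
        pmask = np.zeros((h, w), dtype=bool)
        if spec.texture_kind == "patchy":
            lo, hi = spec.patch_count_range
            k = int(rng.integers(lo, hi + 1))
            # One patch per angular bin of the septal sector; tangential spread
            # is capped well below the bin arc so patches never merge.
            bin_w = params.septal_width / k
            for j in range(k):
                c_j = sector_center - params.septal_width / 2 + (j + 0.5) * bin_w
                alpha = c_j + rng.uniform(-0.08, 0.08) * bin_w
                depth = rng.uniform(0.35, 0.65)
                rc = r_endo_f(alpha) + depth * (r_epi_f(alpha) - r_endo_f(alpha))
                pcx, pcy = cx + rc * np.cos(alpha), cy + rc * np.sin(alpha)
                sig_t = min(rng.uniform(2.0, 3.5), 0.22 * bin_w * rc)  # tangential
                sig_r = rng.uniform(1.0, 1.8)                          # radial
                amp = spec.patch_t1_elevation * rng.uniform(0.8, 1.2)
                bump = amp * _rotated_gaussian(xx, yy, pcx, pcy, sig_t, sig_r, alpha + np.pi / 2)
                fld += bump
                pmask |= bump > 0.5 * amp
        elif spec.texture_kind == "diffuse":
            rough = gaussian_filter(rng.standard_normal((h, w)), 1.5)
            thr = np.quantile(rough[paint], 0.88)
            clusters = rough > thr
            fld += spec.patch_t1_elevation * clusters
            fld += rng.normal(0.0, spec.diffuse_noise_sd, (h, w))
            pmask = clusters

        fld += rng.normal(0.0, params.pixel_noise_sd, (h, w))

        endo = Contour(np.column_stack([cx + r_endo_f(phis) * np.cos(phis),
                                        cy + r_endo_f(phis) * np.sin(phis)]))
        epi = Contour(np.column_stack([cx + r_epi_f(phis) * np.cos(phis),
                                       cy + r_epi_f(phis) * np.sin(phis)]))
        la = params.landmark_angle
        landmark = np.array([cx + r_epi_f(la) * np.cos(la), cy + r_epi_f(la) * np.sin(la)])

        grid = np.where(paint, fld, 0.0)
        myo = rasterize_myocardium(endo, epi, (h, w))
        slices.append(T1Slice(grid, params.pixel_size, endo, epi, landmark, s))
        patch_masks.append(pmask & myo)
        myo_masks.append(myo)

    # Shift painted values so the subject's myocardial mean is exactly the draw.
    current = np.concatenate(
        [sl.pixel_grid[m] for sl, m in zip(slices, myo_masks)]
    ).mean()
    shift = target_t1 - current
    slices = [
        replace(sl, pixel_grid=np.where(sl.pixel_grid != 0.0, sl.pixel_grid + shift, 0.0))
        for sl in slices
    ]

    return SubjectPhantom(
        subject_id=subject_id or f"{spec.name}_{seed_repr:08x}",
        cohort=spec.name,
        slices=tuple(slices),
        seed=seed_repr,
        extras={
            "patch_masks": patch_masks,
            "myo_masks": myo_masks,
            "target_global_t1": float(target_t1),
        },
    )


def generate_dataset(
    sizes: tuple[int, int, int] | dict[str, int],
    seed: int = 0,
    params: GeometryParams | None = None,
    specs: dict[str, CohortSpec] | None = None,
) -> tuple[list[SubjectPhantom], list[str]]:
    """Generate a labeled three-cohort dataset.

    ``sizes`` gives per-cohort subject counts in (control, HCM, DCM)
    order or as a mapping. Subjects are seeded independently from the
    master seed via per-index substreams.
    """
    if isinstance(sizes, dict):
        counts = {c: int(sizes.get(c, 0)) for c in COHORTS}
    else:
        counts = dict(zip(COHORTS, (int(n) for n in sizes)))
    if any(n < 0 for n in counts.values()):
        raise PhantomError("cohort counts must be >= 0")
    if sum(counts.values()) == 0:
        raise PhantomError("at least one cohort count must be positive")
    specs = specs or {c: cohort_defaults(c) for c in COHORTS}

    subjects: list[SubjectPhantom] = []
    labels: list[str] = []
    gi = 0
    for cohort in COHORTS:
        for j in range(counts[cohort]):
            ss = np.random.SeedSequence(entropy=(int(seed), gi))
            subjects.append(
                generate_subject(specs[cohort], params, ss, subject_id=f"{cohort}_{j:03d}")
            )
            labels.append(cohort)
            gi += 1
    return subjects, labels
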