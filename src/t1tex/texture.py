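"""Texture descriptors of stacked rectangular T1 maps.

Four families, 152 features in total per subject:

* 10 histogram features — mean, population variance, skewness,
  kurtosis, and standardized central moments of order 5..10;
* 44 gray-level run-length (GLRLM) features — 11 statistics x 4
  directions (0/45/90/135 degrees);
* 60 gray-level co-occurrence (GLCM) features — 6 Haralick-type
  statistics x 10 pixel displacements, co-occurrence counts pooled over
  the 4 directions per displacement;
* 38 rotation-invariant uniform local-binary-pattern (LBP) histogram
  bins — P = 36 circular neighbors (P + 2 = 38 codes).

GLCM and GLRLM operate on a quantized copy of the map (equal-width
min-max binning per stacked map, 32 levels by default), which makes
them invariant to adding a constant to the map. LBP thresholds the raw
values directly (neighbor >= center, with a tiny relative tolerance so
exactly-equal neighbors of a constant map count as 1).

Degenerate-input conventions (all fixed so the extractor is total):
constant map -> all pixels quantize to level 0; zero-variance histogram
moments are 0; GLCM correlation is 0 when a marginal SD vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import StackedMap

__all__ = [
    "QuantizationConfig",
    "GLCMConfig",
    "GLRLMConfig",
    "LBPConfig",
    "quantize",
    "histogram_features",
    "glcm_features",
    "glrlm_features",
    "lbp_features",
    "extract_all",
    "feature_names",
    "HISTOGRAM_NAMES",
    "GLRLM_STATS",
    "GLCM_STATS",
    "DIRECTIONS_DEG",
]

DIRECTIONS_DEG = (0, 45, 90, 135)

HISTOGRAM_NAMES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "CentralMoment5", "CentralMoment6", "CentralMoment7",
    "CentralMoment8", "CentralMoment9", "CentralMoment10",
)

GLRLM_STATS = (
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)

GLCM_STATS = ("ASM", "Contrast", "Homogeneity2", "Entropy", "Correlation", "SumOfSquares")


@dataclass(frozen=True)
class QuantizationConfig:
    """Equal-width min-max gray-level binning applied per stacked map."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence displacements 1..10 px, counts pooled over 4 directions."""

    displacements: tuple[int, ...] = tuple(range(1, 11))


@dataclass(frozen=True)
class GLRLMConfig:
    """Run-length directions, degrees in image convention (y down)."""

    directions: tuple[int, ...] = DIRECTIONS_DEG


@dataclass(frozen=True)
class LBPConfig:
    """Rotation-invariant uniform LBP: P + 2 histogram bins."""

    n_points: int = 36
    radius: float = 2.0

    @property
    def n_bins(self) -> int:
        return self.n_points + 2


def _values(map_or_array) -> np.ndarray:
    if isinstance(map_or_array, StackedMap):
        return np.asarray(map_or_array.values, dtype=float)
    return np.asarray(map_or_array, dtype=float)


def quantize(map_or_array, q: QuantizationConfig | None = None) -> np.ndarray:
    """Integer gray levels 0..n_levels-1 by equal-width binning of [min, max].

    The maximum value is assigned to the top bin; a constant map maps
    entirely to level 0.
    """
    q = q or QuantizationConfig()
    v = _values(map_or_array)
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite values")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.zeros(v.shape, dtype=np.int64)
    levels = np.floor(q.n_levels * (v - vmin) / (vmax - vmin)).astype(np.int64)
    return np.clip(levels, 0, q.n_levels - 1)


def histogram_features(map_or_array) -> np.ndarray:
    """First-order statistics: mean, variance (1/N) and standardized moments 3..10."""
    v = _values(map_or_array).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 pixels")
    mean = v.mean()
    centered = v - mean
    var = np.mean(centered**2)
    out = np.empty(10)
    out[0], out[1] = mean, var
    if var == 0.0:
        out[2:] = 0.0
        return out
    sd = np.sqrt(var)
    for i, k in enumerate(range(3, 11)):
        out[2 + i] = np.mean(centered**k) / sd**k
    return out


def _glcm_stats_from_probs(p: np.ndarray) -> np.ndarray:
    """The six co-occurrence statistics from one normalized symmetric matrix."""
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    diff = i[:, None] - i[None, :]
    px = p.sum(axis=1)
    mu = (i * px).sum()
    sigma2 = ((i - mu) ** 2 * px).sum()
    asm = (p**2).sum()
    contrast = (diff**2 * p).sum()
    homog2 = (p / (1.0 + diff**2)).sum()
    nz = p[p > 0]
    entropy = -(nz * np.log2(nz)).sum()
    if sigma2 > 0:
        corr = ((i[:, None] * i[None, :] * p).sum() - mu * mu) / sigma2
    else:
        corr = 0.0
    sos = ((i - mu) ** 2 * px).sum()
    return np.array([asm, contrast, homog2, entropy, corr, sos])


def glcm_features(
    qmap: np.ndarray,
    cfg: GLCMConfig | None = None,
    n_levels: int | None = None,
) -> np.ndarray:
    """60 co-occurrence features: 6 statistics x 10 displacements.

    For each displacement, symmetric co-occurrence counts are pooled
    (summed) over the four directions, then normalized to a joint
    probability matrix. Ordering is statistic-major:
    ``ASM(d1..d10), Contrast(d1..d10), ...``.
    """
    cfg = cfg or GLCMConfig()
    qmap = np.asarray(qmap)
    L = int(n_levels if n_levels is not None else qmap.max() + 1)
    per_disp = []
    for d in cfg.displacements:
        pooled = _cooccurrence_counts(qmap, d, L)
        total = pooled.sum()
        if total == 0:
            raise ValueError(f"no pixel pairs at displacement {d}")
        per_disp.append(_glcm_stats_from_probs(pooled / total))
    stats = np.column_stack(per_disp)  # (6, 10)
    return stats.ravel()


def _cooccurrence_counts(q: np.ndarray, d: int, L: int) -> np.ndarray:
    """Symmetric co-occurrence counts at d pixel steps, pooled over 4 directions.

    Offsets are d unit steps along 0/45/90/135 degrees (image convention),
    i.e. (0, d), (-d, d), (-d, 0), (-d, -d) in (row, col) — the diagonal
    displacement moves d pixels along each axis, matching the run-length
    directions.
    """
    h, w = q.shape
    C = np.zeros((L, L))
    for dr, dc in ((0, d), (-d, d), (-d, 0), (-d, -d)):
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        C += np.bincount(a * L + b, minlength=L * L).reshape(L, L)
    return C + C.T


def _direction_lines(a: np.ndarray, direction: int) -> list[np.ndarray]:
    """1-D scan lines of a 2-D array along one of the four directions.

    0 degrees: rows (left to right); 90: columns (top to bottom);
    135: top-left to bottom-right diagonals; 45: bottom-left to
    top-right diagonals (image convention, y down).
    """
    h, w = a.shape
    if direction == 0:
        return [a[r] for r in range(h)]
    if direction == 90:
        return [a[:, c] for c in range(w)]
    if direction == 135:
        return [a.diagonal(k) for k in range(-(h - 1), w)]
    if direction == 45:
        fl = np.flipud(a)
        return [fl.diagonal(k) for k in range(-(h - 1), w)]
    raise ValueError(f"unsupported direction {direction}; use 0, 45, 90 or 135")


def _run_length_matrix(a: np.ndarray, direction: int, n_levels: int) -> np.ndarray:
    """Counts of maximal runs by (gray level, run length) along one direction."""
    max_len = max(a.shape)
    M = np.zeros((n_levels, max_len), dtype=float)
    for line in _direction_lines(a, direction):
        if line.size == 0:
            continue
        change = np.flatnonzero(np.diff(line) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [line.size - 1]])
        lengths = ends - starts + 1
        np.add.at(M, (line[starts], lengths - 1), 1.0)
    return M


def _glrlm_stats(M: np.ndarray, n_pixels: int) -> np.ndarray:
    n_runs = M.sum()
    j = np.arange(1, M.shape[1] + 1, dtype=float)      # run lengths
    iw = np.arange(1, M.shape[0] + 1, dtype=float)     # gray-level weight i+1
    rj = M.sum(axis=0)   # runs per length
    ri = M.sum(axis=1)   # runs per level
    sre = (rj / j**2).sum() / n_runs
    lre = (rj * j**2).sum() / n_runs
    gln = (ri**2).sum() / n_runs
    rln = (rj**2).sum() / n_runs
    rp = n_runs / n_pixels
    lgre = (ri / iw**2).sum() / n_runs
    hgre = (ri * iw**2).sum() / n_runs
    jw2 = np.outer(1.0 / iw**2, 1.0 / j**2)
    srlge = (M * jw2).sum() / n_runs
    srhge = (M * np.outer(iw**2, 1.0 / j**2)).sum() / n_runs
    lrlge = (M * np.outer(1.0 / iw**2, j**2)).sum() / n_runs
    lrhge = (M * np.outer(iw**2, j**2)).sum() / n_runs
    return np.array([sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge])


def glrlm_features(
    qmap: np.ndarray,
    cfg: GLRLMConfig | None = None,
    n_levels: int | None = None,
) -> np.ndarray:
    """44 run-length features: 11 statistics x 4 directions, statistic-major.

    Gray-level weights use ``i + 1`` with levels indexed from 0, so
    low-gray-level emphasis features never divide by zero.
    """
    cfg = cfg or GLRLMConfig()
    qmap = np.asarray(qmap)
    if qmap.size == 0:
        raise ValueError("empty map")
    L = int(n_levels if n_levels is not None else qmap.max() + 1)
    per_dir = [
        _glrlm_stats(_run_length_matrix(qmap, d, L), qmap.size) for d in cfg.directions
    ]
    return np.column_stack(per_dir).ravel()   # (11, 4) -> statistic-major


def _shifted_plane(v: np.ndarray, m: int, dy: float, dx: float) -> np.ndarray:
    """Bilinear sample of ``v`` at offset (dy, dx) from every interior pixel.

    The offset is constant across pixels, so the sample is a fixed
    2x2 stencil of shifted slices of the image.
    """
    h, w = v.shape
    hh, ww = h - 2 * m, w - 2 * m
    dy, dx = round(dy, 9), round(dx, 9)
    fy, fx = int(np.floor(dy)), int(np.floor(dx))
    ty, tx = dy - fy, dx - fx

    def block(ry: int, rx: int) -> np.ndarray:
        r0, c0 = m + ry, m + rx
        return v[r0 : r0 + hh, c0 : c0 + ww]

    out = (1 - ty) * (1 - tx) * block(fy, fx)
    if tx > 0:
        out = out + (1 - ty) * tx * block(fy, fx + 1)
    if ty > 0:
        out = out + ty * (1 - tx) * block(fy + 1, fx)
        if tx > 0:
            out = out + ty * tx * block(fy + 1, fx + 1)
    return out


def lbp_features(map_or_array, cfg: LBPConfig | None = None) -> np.ndarray:
    """Normalized riu2 LBP histogram over P + 2 codes.

    Codes are computed for every pixel whose full circular neighborhood
    lies inside the map; neighbors are sampled bilinearly. A neighbor
    counts as 1 when its value is >= the center up to a 1e-9 relative
    tolerance (so an exactly constant map yields the all-ones uniform
    code with mass 1).
    """
    cfg = cfg or LBPConfig()
    v = _values(map_or_array)
    m = int(np.ceil(cfg.radius))
    if v.shape[0] <= 2 * m or v.shape[1] <= 2 * m:
        raise ValueError(
            f"map of shape {v.shape} smaller than the {cfg.n_points}-point, "
            f"radius-{cfg.radius} neighborhood"
        )
    center = v[m:-m, m:-m]
    tol = 1e-9 * np.maximum(1.0, np.abs(center))
    P = cfg.n_points
    bits = []
    for p in range(P):
        ang = 2 * np.pi * p / P
        dx = cfg.radius * np.cos(ang)
        dy = -cfg.radius * np.sin(ang)
        nb = _shifted_plane(v, m, dy, dx)
        bits.append(nb - center >= -tol)
    bits = np.stack(bits)                       # (P, hh, ww)
    ones = bits.sum(axis=0)
    transitions = (bits != np.roll(bits, -1, axis=0)).sum(axis=0)
    codes = np.where(transitions <= 2, ones, P + 1)
    hist = np.bincount(codes.ravel(), minlength=P + 2).astype(float)
    return hist / hist.sum()


def feature_names(
    glrlm: GLRLMConfig | None = None,
    glcm: GLCMConfig | None = None,
    lbp: LBPConfig | None = None,
) -> list[str]:
    """Canonical ordered names of the 152 features.

    Order: histogram (10), GLRLM statistic-major over directions (44),
    GLCM statistic-major over displacements (60), LBP bins 1..38.
    """
    glrlm = glrlm or GLRLMConfig()
    glcm = glcm or GLCMConfig()
    lbp = lbp or LBPConfig()
    names = list(HISTOGRAM_NAMES)
    names += [f"{s}({d})" for s in GLRLM_STATS for d in glrlm.directions]
    names += [f"{s}(d{d})" for s in GLCM_STATS for d in glcm.displacements]
    names += [f"LBP({b})" for b in range(1, lbp.n_bins + 1)]
    return names


def extract_all(
    stacked: StackedMap | np.ndarray,
    quant: QuantizationConfig | None = None,
    glrlm: GLRLMConfig | None = None,
    glcm: GLCMConfig | None = None,
    lbp: LBPConfig | None = None,
) -> pd.Series:
    """All 152 named texture features of one stacked rectangular map."""
    quant = quant or QuantizationConfig()
    glrlm = glrlm or GLRLMConfig()
    glcm = glcm or GLCMConfig()
    lbp = lbp or LBPConfig()
    v = _values(stacked)
    q = quantize(v, quant)
    parts = [
        histogram_features(v),
        glrlm_features(q, glrlm, n_levels=quant.n_levels),
        glcm_features(q, glcm, n_levels=quant.n_levels),
        lbp_features(v, lbp),
    ]
    vec = np.concatenate(parts)
    names = feature_names(glrlm, glcm, lbp)
    if len(vec) != len(names):
        raise AssertionError("feature count does not match the canonical name list")
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value produced")
    return pd.Series(vec, index=names)
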