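"""Observer-variability statistics: ICC and Bland-Altman under re-contouring.

Re-contouring is emulated on phantoms by smooth seeded radial jitter of
the endocardial and epicardial contours followed by re-running the
unwrap + feature-extraction pipeline; the jitter SD (default 1 pixel)
is a free knob standing in for intra-/inter-observer drawing
variability.

The ICC uses the two-way model mean squares. The default is the
consistency, single-measure form

    ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k - 1) MS_error)

with the absolute-agreement single-measure variant available via
``absolute_agreement=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .geometry import Contour, UnwrapConfig, unwrap_subject
from .geometry import _ray_radii
from .texture import extract_all

__all__ = [
    "icc_two_way_mixed",
    "bland_altman",
    "jitter_contour",
    "recontour_subject",
    "feature_reproducibility",
]


def icc_two_way_mixed(table, absolute_agreement: bool = False) -> float:
    """Single-measure ICC from an (n_subjects x n_raters) rating table."""
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] < 3 or T.shape[1] < 2:
        raise ValueError("rating table needs >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(T)):
        raise ValueError("rating table has missing entries")
    n, k = T.shape
    grand = T.mean()
    ss_rows = k * ((T.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((T.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((T - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if absolute_agreement:
        denom = denom + k * (msc - mse) / n
    if denom <= 0:
        warnings.warn("zero between-subject variance; ICC defined as 0", stacklevel=2)
        return 0.0
    return float((msr - mse) / denom)


def bland_altman(a, b) -> tuple[float, float, float]:
    """Bias and 1.96-SD limits of agreement of paired measurements a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurement vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def jitter_contour(contour: Contour, sd: float, rng: np.random.Generator) -> Contour:
    """Smooth radial perturbation of a contour about its centroid.

    Per-point radial noise is smoothed along the contour (periodic
    Gaussian, sigma 3 points) and rescaled to the requested SD, which
    keeps the jittered contour closed and non-self-intersecting for
    realistic magnitudes (~1 px).
    """
    pts = contour.points
    c = contour.centroid
    rel = pts - c
    r = np.hypot(rel[:, 0], rel[:, 1])
    noise = rng.normal(0.0, 1.0, len(pts))
    smooth = gaussian_filter1d(noise, sigma=3.0, mode="wrap")
    s = smooth.std()
    if s > 0:
        smooth *= sd / s
    scale = (r + smooth) / r
    return Contour(c + rel * scale[:, None])


def _clamp_inside(endo: Contour, epi: Contour, min_wall: float = 1.5) -> Contour:
    """Pull endocardial points inward where they come too close to the epicardium."""
    c = endo.centroid
    rel = endo.points - c
    r = np.hypot(rel[:, 0], rel[:, 1])
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    r_epi = _ray_radii(epi.points, c, angles)
    r_epi = np.where(np.isnan(r_epi), np.inf, r_epi)
    r_new = np.minimum(r, r_epi - min_wall)
    return Contour(c + rel * (r_new / r)[:, None])


def recontour_subject(subject, sd: float = 1.0, seed: int = 0):
    """Copy of a subject with independently jittered endo/epi contours.

    The jittered endocardium is clamped to stay at least 1.5 px inside
    the jittered epicardium, as a human observer would never cross the
    borders; this keeps thin apical walls unwrappable.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0x7EC0)))
    new_slices = []
    for sl in subject.slices:
        epi = jitter_contour(sl.epi, sd, rng)
        endo = _clamp_inside(jitter_contour(sl.endo, sd, rng), epi)
        new_slices.append(replace(sl, endo=endo, epi=epi))
    return replace(subject, slices=tuple(new_slices))


def feature_reproducibility(
    subjects,
    cfg: UnwrapConfig | None = None,
    jitter_sd: float = 1.0,
    n_raters: int = 2,
    seed: int = 0,
    feature_subset: list[str] | None = None,
    **extract_kwargs,
) -> dict[str, pd.DataFrame]:
    """Rating tables (subjects x raters) per feature under re-contouring.

    Rater 0 uses the original contours; each further rater re-contours
    every subject with independent seeded jitter. Feed one feature's
    table to :func:`icc_two_way_mixed` for an ICC, or two of its columns
    to :func:`bland_altman`.
    """
    cfg = cfg or UnwrapConfig()
    per_rater = []
    for rater in range(n_raters):
        rows = []
        for si, subj in enumerate(subjects):
            cur = subj if rater == 0 else recontour_subject(
                subj, sd=jitter_sd, seed=hash((seed, rater, si)) % (2**31)
            )
            vec = extract_all(unwrap_subject(cur, cfg), **extract_kwargs)
            rows.append(vec)
        per_rater.append(pd.DataFrame(rows, index=[s.subject_id for s in subjects]))
    names = feature_subset or list(per_rater[0].columns)
    return {
        name: pd.DataFrame(
            {f"rater{r}": per_rater[r][name] for r in range(n_raters)}
        )
        for name in names
    }
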