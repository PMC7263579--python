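import numpy as np
import pytest

from t1tex.geometry import Contour
from t1tex.phantom import SubjectPhantom, T1Slice, generate_dataset


def make_annulus_slice(
    field=1100.0,
    shape=(64, 64),
    center=(31.6, 32.3),
    r_endo=8.3,
    r_epi=15.6,
    landmark_angle=2.0,
    n_pts=96,
    margin=2.5,
    slice_index=0,
):
    """Circular-annulus T1 slice with analytic contours.

    ``field`` is either a constant or a callable ``f(xx, yy) -> values``
    evaluated on the pixel grid; values are painted on the annulus plus
    a small margin so border interpolation never sees background zeros.
    """
    h, w = shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rho = np.hypot(xx - cx, yy - cy)
    paint = (rho >= max(r_endo - margin, 0.2)) & (rho <= r_epi + margin)
    vals = field(xx, yy) if callable(field) else np.full(shape, float(field))
    grid = np.where(paint, vals, 0.0)
    phis = 2 * np.pi * np.arange(n_pts) / n_pts
    endo = Contour(np.column_stack([cx + r_endo * np.cos(phis), cy + r_endo * np.sin(phis)]))
    epi = Contour(np.column_stack([cx + r_epi * np.cos(phis), cy + r_epi * np.sin(phis)]))
    landmark = np.array(
        [cx + r_epi * np.cos(landmark_angle), cy + r_epi * np.sin(landmark_angle)]
    )
    return T1Slice(grid, 2.1, endo, epi, landmark, slice_index)


def subject_from_slice(sl, subject_id="toy", cohort="control"):
    """Five identical slices wrapped as one subject."""
    slices = tuple(
        T1Slice(sl.pixel_grid, sl.pixel_size, sl.endo, sl.epi, sl.landmark, i)
        for i in range(5)
    )
    return SubjectPhantom(subject_id, cohort, slices, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """36 phantoms (12 per cohort), enough for 10-fold CV, reused across tests."""
    return generate_dataset((12, 12, 12), seed=11)
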