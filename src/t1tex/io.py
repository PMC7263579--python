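"""File formats: per-slice NIfTI T1 maps, JSON sidecars, feature CSVs, configs.

A subject on disk is five float32 NIfTI slices (ms values) plus one
JSON sidecar holding, per slice, the endo/epi contours as ordered
0-based (x, y) pixel-coordinate lists, the landmark point, and the
cohort label and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import Contour
from .phantom import SubjectPhantom, T1Slice

__all__ = [
    "SubjectIOError",
    "write_subject",
    "read_subject",
    "write_features",
    "read_features",
    "PipelineConfig",
]


class SubjectIOError(ValueError):
    """Malformed or incomplete subject files."""


def write_subject(subject: SubjectPhantom, out_dir) -> Path:
    """Write one subject (5 NIfTI slices + sidecar); returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {
        "subject_id": subject.subject_id,
        "cohort": subject.cohort,
        "seed": subject.seed,
        "pixel_size_mm": subject.slices[0].pixel_size,
        "slices": [],
    }
    for i, sl in enumerate(subject.slices):
        fname = f"{subject.subject_id}_slice{i}.nii"
        affine = np.diag([sl.pixel_size, sl.pixel_size, 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(sl.pixel_grid, dtype=np.float32), affine),
                 out_dir / fname)
        sidecar["slices"].append(
            {
                "file": fname,
                "endo": np.asarray(sl.endo.points).tolist(),
                "epi": np.asarray(sl.epi.points).tolist(),
                "closed": True,
                "landmark": np.asarray(sl.landmark, dtype=float).tolist(),
            }
        )
    path = out_dir / f"{subject.subject_id}.json"
    path.write_text(json.dumps(sidecar))
    return path


def read_subject(sidecar_path) -> SubjectPhantom:
    """Load a subject from its JSON sidecar; validates contours and landmark."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    slices_meta = meta.get("slices", [])
    if len(slices_meta) != 5:
        raise SubjectIOError(f"expected 5 slices, got {len(slices_meta)}")
    slices = []
    for i, sm in enumerate(slices_meta):
        f = sidecar_path.parent / sm["file"]
        if not f.exists():
            raise SubjectIOError(f"missing slice file {sm['file']}")
        if not sm.get("closed", True):
            raise SubjectIOError(f"open contour in slice {i}")
        grid = np.asanyarray(nib.load(f).dataobj).astype(float)
        lm = np.asarray(sm["landmark"], dtype=float)
        h, w = grid.shape
        if not (0 <= lm[0] < w and 0 <= lm[1] < h):
            raise SubjectIOError(f"landmark outside image in slice {i}")
        try:
            endo = Contour(np.asarray(sm["endo"], dtype=float))
            epi = Contour(np.asarray(sm["epi"], dtype=float))
        except ValueError as e:
            raise SubjectIOError(f"malformed contour in slice {i}: {e}") from e
        slices.append(
            T1Slice(grid, float(meta.get("pixel_size_mm", 2.1)), endo, epi, lm, i)
        )
    return SubjectPhantom(
        subject_id=meta["subject_id"],
        cohort=meta.get("cohort", "control"),
        slices=tuple(slices),
        seed=int(meta.get("seed", 0)),
    )


def write_features(vectors, subject_ids, labels, path) -> pd.DataFrame:
    """Write a feature table CSV: subject_id, label, then the 152 named features."""
    if len(set(subject_ids)) != len(list(subject_ids)):
        raise SubjectIOError("duplicate subject ids")
    df = pd.DataFrame(list(vectors), index=list(subject_ids))
    df.insert(0, "label", list(labels))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)
    return df.reset_index(drop=True)


def read_features(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a feature CSV back into (features, labels), indexed by subject id."""
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.set_index("subject_id")
    labels = df.pop("label")
    return df, labels


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings; YAML/JSON round-trippable."""

    preset: str = "R32"
    n_levels: int = 32
    lbp_points: int = 36
    lbp_radius: float = 2.0
    classifier: str = "linear-svm"
    folds: int = 10
    k: int = 7
    seed: int = 0
    paper_mode: bool = False
    out_dir: str = "results"

    def save(self, path) -> None:
        path = Path(path)
        d = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**d)
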