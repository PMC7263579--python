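"""Shared study conditions for the analysis drivers.

One fixed desk-scale dataset (30 subjects per cohort, master seed 20)
is used across all numbered scripts; the extracted feature table is
cached under scratch/ so later scripts can rerun without repeating the
extraction.
"""

from pathlib import Path

import pandas as pd

from t1tex.io import PipelineConfig
from t1tex.phantom import generate_dataset
from t1tex.pipeline import extract_dataset_features

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

DATA_SEED = 20
SIZES = (30, 30, 30)
CONFIG = PipelineConfig(k=7, folds=10, seed=DATA_SEED)


def get_dataset():
    return generate_dataset(SIZES, seed=DATA_SEED)


def get_features(subjects):
    """Feature table at R32, cached in scratch/."""
    cache = SCRATCH / "features_r32.csv"
    if cache.exists():
        df = pd.read_csv(cache, float_precision="round_trip", index_col=0)
        if list(df.index) == [s.subject_id for s in subjects]:
            return df
    SCRATCH.mkdir(exist_ok=True)
    df = extract_dataset_features(subjects, CONFIG)
    df.to_csv(cache)
    return df
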