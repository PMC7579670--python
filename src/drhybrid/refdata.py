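"""Loaders for the reference artifacts shipped with the package.

Two small CSV files live in ``drhybrid/data``: the published confusion
matrix of the Hybrid-c fuser on its 5,000-image fundus test set, and the
per-source DR-grade counts of the combined 39,988-image training corpus.
They feed the evaluation-metric tests and the class-imbalance profile of the
synthetic-data generators.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .metrics import ConfusionMatrix

__all__ = ["hybrid_c_confusion", "dataset_grade_counts", "grade_proportions"]


def _data_path(name: str):
    return resources.files("drhybrid.data").joinpath(name)


def hybrid_c_confusion() -> ConfusionMatrix:
    """Reference 5x5 confusion counts of the Hybrid-c fuser (total 5,000)."""
    with resources.as_file(_data_path("hybrid_c_confusion.csv")) as path:
        counts = np.loadtxt(path, delimiter=",", comments="#", dtype=np.int64)
    return ConfusionMatrix(counts)


def dataset_grade_counts() -> pd.DataFrame:
    """Per-source grade counts, one row per source dataset."""
    with resources.as_file(_data_path("dataset_grade_counts.csv")) as path:
        return pd.read_csv(path, comment="#")


def grade_proportions() -> np.ndarray:
    """Grade 0-4 proportions of the combined corpus (sums to 1)."""
    df = dataset_grade_counts()
    totals = df[[f"grade{g}" for g in range(5)]].sum(axis=0).to_numpy(dtype=float)
    return totals / totals.sum()
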