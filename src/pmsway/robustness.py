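"""Leave-one-subject-out cross-validation of eigenvector stability.

A principal movement is considered robust (and hence interpretable) when
its eigenvector's orientation in posture space changes by no more than a
threshold angle (default 15 degrees) when any single subject is excluded
from the pooled decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PostureMatrix
from .decomposition import PosturePCA
from .preprocess import concatenate

__all__ = ["CrossValReport", "vector_angle", "loo_crossval"]


@dataclass
class CrossValReport:
    """Per-component orientation changes across leave-one-out folds.

    ``table`` has columns ``k``, ``max_deg``, ``mean_deg``, ``robust``.
    """

    table: pd.DataFrame
    threshold_deg: float
    n_folds: int

    @property
    def robust_count(self) -> int:
        return int(self.table["robust"].sum())


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Sign-invariant angle between two directions, degrees in [0, 90].

    PCA eigenvector signs are arbitrary, so the angle is computed from
    |u . v|.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero vector has no direction")
    c = np.clip(abs(u @ v) / (nu * nv), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def loo_crossval(
    subjects: list[PostureMatrix],
    r: int,
    threshold: float = 15.0,
) -> CrossValReport:
    """Leave-one-subject-out stability of the first ``r`` eigenvectors.

    Each fold refits the pooled PCA on all-but-one subject and records the
    angle between the fold's PC_k and the full-data PC_k (matched by
    eigenvalue rank).  A component is robust when its worst-case angle over
    all folds stays within ``threshold`` degrees.  Folds whose rank falls
    below ``r`` contribute 90 degrees for the missing components.
    """
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for cross-validation")
    pooled, _ = concatenate(subjects)
    full = PosturePCA(n_components=None).fit(pooled)
    r_eff = min(r, full.n_components_)
    if r_eff < r:
        warnings.warn(f"full model has only {r_eff} nonzero components")

    angles = np.empty((len(subjects), r_eff))
    for fold, left_out in enumerate(subjects):
        rest = [s for s in subjects if s is not left_out]
        fold_pooled, _ = concatenate(rest)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_model = PosturePCA(n_components=None).fit(fold_pooled)
        for k in range(r_eff):
            if k < fold_model.n_components_:
                angles[fold, k] = vector_angle(
                    fold_model.components_[k], full.components_[k]
                )
            else:
                warnings.warn(
                    f"fold {fold} rank below {r_eff}; reporting 90 deg for k={k + 1}"
                )
                angles[fold, k] = 90.0

    table = pd.DataFrame(
        {
            "k": np.arange(1, r_eff + 1),
            "max_deg": angles.max(axis=0),
            "mean_deg": angles.mean(axis=0),
        }
    )
    table["robust"] = table["max_deg"] <= threshold
    return CrossValReport(table=table, threshold_deg=threshold, n_folds=len(subjects))
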