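"""Pooled posture-space PCA and derived quantities.

The pooled matrix of all subjects' normalized posture vectors is decomposed
by a singular value decomposition.  Eigenvectors PC_k define the principal
movements PM_k, eigenvalues EV_k their pooled variances, and per-subject
score series the principal positions PP_k(t).  Because every subject is
centered on their own mean posture before pooling, no additional centering
is applied here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import PostureMatrix, SubjectScores

__all__ = [
    "PosturePCA",
    "fit_pca",
    "project_subject",
    "relative_std",
    "pm_extreme_postures",
]


class PosturePCA(TransformerMixin, BaseEstimator):
    """PCA of pooled posture vectors without re-centering.

    Parameters
    ----------
    n_components : int or None
        Number of components to retain; ``None`` keeps every component with
        nonzero variance.  If the pooled matrix is rank-deficient below the
        request, only the nonzero components are kept (with a warning).

    Attributes
    ----------
    components_ : ndarray of shape (r, n_coords)
        Orthonormal eigenvectors PC_k, rows ordered by descending
        eigenvalue.  Sign convention: the entry of largest magnitude in each
        component is positive, which makes fitting deterministic.
    eigenvalues_ : ndarray of shape (r,)
        Pooled score variances EV_k (population 1/N convention), descending.
    explained_pct_ : ndarray of shape (r,)
        EV_k as a percentage of the total variance over *all* nonzero
        components.
    n_samples_ : int
        Number of pooled posture vectors used for the fit.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("pooled matrix must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("pooled matrix contains non-finite values")
        n, d = X.shape
        if self.n_components is not None and self.n_components > min(n, d):
            raise ValueError("n_components exceeds matrix rank bound")

        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        ev = s**2 / n
        # discard numerically-zero directions
        nonzero = ev > (ev[0] if ev.size else 0.0) * 1e-14
        ev = ev[nonzero]
        Vt = Vt[nonzero]
        total = ev.sum()

        r = ev.size if self.n_components is None else self.n_components
        if r > ev.size:
            warnings.warn(
                f"pooled matrix has only {ev.size} nonzero components; "
                f"retaining those instead of the requested {r}"
            )
            r = ev.size

        comp = Vt[:r]
        # deterministic sign: largest-|coefficient| entry of each PC positive
        flip = np.sign(comp[np.arange(r), np.argmax(np.abs(comp), axis=1)])
        comp = comp * flip[:, None]

        self.components_ = comp
        self.eigenvalues_ = ev[:r]
        self.explained_pct_ = 100.0 * ev[:r] / total
        self.total_variance_ = total
        self.n_samples_ = n
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError("coordinate dimension mismatch with fitted model")
        return X @ self.components_.T

    def inverse_transform(self, scores) -> np.ndarray:
        check_is_fitted(self)
        return np.asarray(scores, dtype=float) @ self.components_

    @property
    def n_components_(self) -> int:
        return self.components_.shape[0]


def fit_pca(pooled: np.ndarray, r: int | None = None) -> PosturePCA:
    """Fit the pooled posture PCA retaining ``r`` components."""
    return PosturePCA(n_components=r).fit(pooled)


def project_subject(subject: PostureMatrix, model: PosturePCA) -> SubjectScores:
    """Project one subject's posture matrix onto the pooled eigenvectors."""
    return SubjectScores(
        subject_id=subject.subject_id,
        pp=model.transform(subject.data),
        sample_rate=subject.sample_rate,
    )


def relative_std(scores: SubjectScores, r: int | None = None) -> pd.DataFrame:
    """Relative standard deviations rSTD_k (% of summed score SDs).

    rSTD_k = 100 * std(PP_k) / sum_{j<=r} std(PP_j) with the population
    (1/N) standard deviation over the trial.  Returns a tidy frame with
    columns ``subject_id``, ``k``, ``rSTD``.
    """
    r = scores.n_components if r is None else r
    if r < 1 or r > scores.n_components:
        raise ValueError("r out of range")
    sd = scores.pp[:, :r].std(axis=0, ddof=0)
    denom = sd.sum()
    if denom == 0.0:
        warnings.warn("all score series are constant; rSTD undefined")
        rstd = np.full(r, np.nan)
    else:
        rstd = 100.0 * sd / denom
    return pd.DataFrame(
        {"subject_id": scores.subject_id, "k": np.arange(1, r + 1), "rSTD": rstd}
    )


def pm_extreme_postures(
    model: PosturePCA,
    scores: SubjectScores,
    k: int,
    amplification: float,
    posture: PostureMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Lab-space postures at +/- ``amplification`` x max|PP_k|.

    Used to visualize what movement a component encodes: the score extreme is
    amplified, mapped back through the eigenvector, un-weighted,
    un-normalized and added to the subject's mean posture.  Returns two
    (n_markers, 3) coordinate arrays (positive and negative extreme), meters.
    """
    if not 1 <= k <= model.n_components_:
        raise ValueError("component index k out of range")
    excursion = amplification * np.max(np.abs(scores.pp[:, k - 1]))
    w3 = posture.coordinate_weights()
    out = []
    for sign in (+1.0, -1.0):
        vec = sign * excursion * model.components_[k - 1]
        normalized = vec / w3  # undo mass weighting
        lab = (posture.mean_posture + normalized) * posture.height
        out.append(lab.reshape(-1, 3))
    return out[0], out[1]
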