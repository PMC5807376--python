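"""Preprocessing chain: gap filling, mirroring, marker selection, normalization.

The chain mirrors common practice in posture-space kinematics: trajectories
are gap-filled by iterative low-rank reconstruction, left-foot-front trials
are mirrored so that every dataset describes a right-foot-front tandem
stance, non-symmetric markers are dropped, and each subject's data are
centered on the mean posture, divided by stature and weighted by relative
segment mass before pooling across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import body
from .containers import MarkerTrajectorySet, PostureMatrix
from .errors import (
    IncompatibleSubjectsError,
    LabelingError,
    SelectionError,
    UnrecoverableGapError,
)

__all__ = [
    "MarkerPolicy",
    "segment_weight_table",
    "fill_gaps",
    "mirror_left_front",
    "select_markers",
    "normalize_and_weight",
    "concatenate",
]


@dataclass(frozen=True)
class MarkerPolicy:
    """Which markers enter the analysis.

    ``drop`` labels are removed; if ``keep`` is given, only those labels are
    retained (after dropping). The default drops the non-symmetric
    mid-segment labels of the canonical set.
    """

    drop: tuple[str, ...] = field(default=body.NON_SYMMETRIC_LABELS)
    keep: tuple[str, ...] | None = None


def segment_weight_table(labels: list[str]) -> dict[str, float]:
    """Relative mass weight per marker for the given (selected) label set.

    Each body segment's mass fraction is split equally among the markers that
    represent it; fractions are renormalized over the segments actually
    present so the weights sum to 1 over the label set.
    """
    segments = [body.segment_of(lab) for lab in labels]
    present = sorted(set(segments))
    total = sum(body.SEGMENT_MASS_FRACTIONS[s] for s in present)
    counts = {s: segments.count(s) for s in present}
    return {
        lab: body.SEGMENT_MASS_FRACTIONS[seg] / total / counts[seg]
        for lab, seg in zip(labels, segments)
    }


def fill_gaps(
    traj: MarkerTrajectorySet,
    rank: int = 10,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> MarkerTrajectorySet:
    """Fill missing samples by iterative low-rank (PCA) reconstruction.

    Missing entries are initialized by per-coordinate linear interpolation,
    then repeatedly replaced by their rank-``rank`` PCA reconstruction of the
    frames x coordinates matrix until the RMS change of the imputed entries
    drops below ``tol`` (meters) or ``max_iter`` is reached.  Observed
    entries are never altered.
    """
    if not traj.has_gaps:
        return traj.copy()
    fully_missing = traj.missing.all(axis=0)
    if fully_missing.any():
        bad = [traj.marker_labels[i] for i in np.where(fully_missing)[0]]
        raise UnrecoverableGapError(f"markers never observed: {bad}")

    T, M = traj.n_frames, traj.n_markers
    X = traj.positions.reshape(T, 3 * M).copy()
    miss = np.repeat(traj.missing, 3, axis=1)
    r = min(rank, *X.shape)
    n_obs_per_frame = (~miss).sum(axis=1)
    if (n_obs_per_frame < r).any():
        warnings.warn("some frames observe fewer coordinates than the requested rank")

    # linear-interpolation initialization per column
    idx = np.arange(T)
    for j in range(X.shape[1]):
        mj = miss[:, j]
        if mj.any():
            X[mj, j] = np.interp(idx[mj], idx[~mj], X[~mj, j])

    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = (U[:, :r] * s[:r]) @ Vt[:r] + mu
        delta = recon[miss] - X[miss]
        X[miss] = recon[miss]
        if np.sqrt(np.mean(delta**2)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("gap filling did not converge; returning best iterate")

    out = traj.copy()
    out.positions = X.reshape(T, M, 3)
    out.missing = np.zeros((T, M), dtype=bool)
    return out


def _pair_map(labels: list[str]) -> dict[str, str]:
    """Map each lateral label to its contralateral partner.

    A label is lateral when it starts with ``L``/``R`` and its stem appears in
    the canonical pair list; such a label without a partner in ``labels`` is a
    labeling error.
    """
    label_set = set(labels)
    pairs: dict[str, str] = {}
    for lab in labels:
        if lab[0] in ("L", "R") and lab[1:] and lab not in body.MIDLINE_LABELS:
            partner = ("R" if lab[0] == "L" else "L") + lab[1:]
            if partner not in label_set:
                raise LabelingError(f"lateral marker {lab!r} has no partner")
            pairs[lab] = partner
    return pairs


def mirror_left_front(traj: MarkerTrajectorySet) -> MarkerTrajectorySet:
    """Mirror a left-foot-front trial into the right-foot-front convention.

    The y (mediolateral) coordinate is negated for every marker and lateral
    labels are swapped L<->R; unpaired labels keep their name.
    """
    if traj.front_foot != "left":
        raise ValueError("mirror_left_front expects a left-foot-front trial")
    pairs = _pair_map(traj.marker_labels)
    out = traj.copy()
    out.positions[:, :, 1] *= -1.0
    out.marker_labels = [pairs.get(lab, lab) for lab in traj.marker_labels]
    out.front_foot = "right"
    return out


def select_markers(
    traj: MarkerTrajectorySet, policy: MarkerPolicy | None = None
) -> MarkerTrajectorySet:
    """Apply a marker-selection policy; output label order is sorted.

    Deterministic ordering across subjects is what makes pooled matrices
    column-compatible, so the selected labels are returned alphabetically.
    """
    present = set(traj.marker_labels)
    if policy is None:
        # default: drop whichever non-symmetric labels this set contains
        policy = MarkerPolicy(
            drop=tuple(l for l in body.NON_SYMMETRIC_LABELS if l in present)
        )
    for lab in policy.drop:
        if lab not in present:
            raise SelectionError(f"policy drops absent label {lab!r}")
    keep = present.difference(policy.drop)
    if policy.keep is not None:
        for lab in policy.keep:
            if lab not in present:
                raise SelectionError(f"policy keeps absent label {lab!r}")
        keep &= set(policy.keep)
    if not keep:
        raise SelectionError("selection policy removes every marker")
    order = sorted(keep)
    cols = [traj.marker_labels.index(lab) for lab in order]
    out = traj.copy()
    out.marker_labels = order
    out.positions = traj.positions[:, cols]
    out.missing = traj.missing[:, cols]
    return out


def normalize_and_weight(
    traj: MarkerTrajectorySet, weights: dict[str, float] | None = None
) -> PostureMatrix:
    """Center on the mean posture, divide by stature, weight by segment mass.

    Produces the dimensionless posture vectors v(t) = w * (m(t) - mean) / h
    that are pooled for the decomposition.  ``weights`` defaults to the
    anthropometric table for the trajectory's marker set.
    """
    if traj.has_gaps:
        raise UnrecoverableGapError("fill gaps before normalizing")
    if weights is None:
        weights = segment_weight_table(traj.marker_labels)
    try:
        w = np.array([weights[lab] for lab in traj.marker_labels], dtype=float)
    except KeyError as exc:
        raise SelectionError(f"no mass weight for marker {exc}") from exc
    if (w <= 0).any():
        raise ValueError("mass weights must be positive")

    T, M = traj.n_frames, traj.n_markers
    mean = traj.positions.mean(axis=0)  # (M, 3)
    centered = (traj.positions - mean) / traj.height
    weighted = centered * w[None, :, None]
    return PostureMatrix(
        subject_id=traj.subject_id,
        data=weighted.reshape(T, 3 * M),
        mean_posture=(mean / traj.height).reshape(3 * M),
        marker_labels=list(traj.marker_labels),
        weights=w,
        height=traj.height,
        sample_rate=traj.sample_rate,
    )


def concatenate(
    subjects: list[PostureMatrix],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack subjects' posture matrices row-wise into one pooled matrix.

    Returns the pooled (sum of frames) x (3 M') matrix and an index frame
    mapping each pooled row back to (subject_id, frame).
    """
    if not subjects:
        raise IncompatibleSubjectsError("no subjects to concatenate")
    ref = subjects[0].marker_labels
    for s in subjects[1:]:
        if s.marker_labels != ref:
            raise IncompatibleSubjectsError(
                f"subject {s.subject_id!r} has a different marker set/order"
            )
    pooled = np.vstack([s.data for s in subjects])
    index = pd.DataFrame(
        {
            "subject_id": np.repeat(
                [s.subject_id for s in subjects], [s.n_frames for s in subjects]
            ),
            "frame": np.concatenate([np.arange(s.n_frames) for s in subjects]),
        }
    )
    return pooled, index
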