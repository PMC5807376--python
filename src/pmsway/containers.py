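"""In-memory containers for marker recordings and posture matrices.

Coordinate convention throughout: lab frame with x anterior, y leftward,
z up, units of meters.  Posture vectors are stored marker-major, i.e. the
flattened column order is (x, y, z) for marker 0, then marker 1, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MarkerTrajectorySet", "PostureMatrix", "SubjectScores"]


@dataclass
class MarkerTrajectorySet:
    """One subject's raw 3D marker recording plus metadata.

    Parameters
    ----------
    subject_id : str
    marker_labels : list of str
        Unique labels; bilateral markers carry an ``L``/``R`` prefix.
    positions : ndarray of shape (n_frames, n_markers, 3)
        Meters, lab frame. Entries flagged missing may be NaN.
    sample_rate : float
        Hz, > 0.
    missing : ndarray of shape (n_frames, n_markers), bool
        True where the marker was not observed.
    height : float
        Subject stature in meters.
    mass : float
        Body mass in kg.
    age_group : {"young", "old"}
    gender : {"female", "male"}
    front_foot : {"left", "right"}
        Foot placed in front during the tandem stance.
    """

    subject_id: str
    marker_labels: list[str]
    positions: np.ndarray
    sample_rate: float
    missing: np.ndarray | None = None
    height: float = 1.70
    mass: float = 70.0
    age_group: str = "young"
    gender: str = "female"
    front_foot: str = "right"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.marker_labels):
            raise ValueError("marker_labels length does not match positions")
        if len(set(self.marker_labels)) != len(self.marker_labels):
            raise ValueError("duplicate marker labels")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.missing is None:
            self.missing = np.zeros(self.positions.shape[:2], dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.positions.shape[:2]:
                raise ValueError("missing mask shape mismatch")
        observed = ~self.missing[:, :, None] & ~np.isfinite(self.positions)
        if observed.any():
            raise ValueError("non-finite positions outside the missing mask")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def has_gaps(self) -> bool:
        return bool(self.missing.any())

    def copy(self) -> "MarkerTrajectorySet":
        return replace(
            self,
            marker_labels=list(self.marker_labels),
            positions=self.positions.copy(),
            missing=self.missing.copy(),
        )


@dataclass
class PostureMatrix:
    """Centered, height-normalized, mass-weighted posture vectors of one subject.

    ``data`` holds one dimensionless posture vector per frame (marker-major
    column order). ``mean_posture`` is the subject's mean posture divided by
    height but *before* mass weighting, so lab-space postures can be
    reconstructed via ``mean + height * (vector / weights)``.
    """

    subject_id: str
    data: np.ndarray  # (n_frames, 3 * n_markers)
    mean_posture: np.ndarray  # (3 * n_markers,), normalized, pre-weighting
    marker_labels: list[str]
    weights: np.ndarray  # (n_markers,), per-marker mass fraction
    height: float
    sample_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mean_posture = np.asarray(self.mean_posture, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        m = len(self.marker_labels)
        if self.data.ndim != 2 or self.data.shape[1] != 3 * m:
            raise ValueError("data must have 3 columns per marker")
        if self.mean_posture.shape != (3 * m,):
            raise ValueError("mean_posture length mismatch")
        if self.weights.shape != (m,):
            raise ValueError("weights length mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_coords(self) -> int:
        return self.data.shape[1]

    def coordinate_weights(self) -> np.ndarray:
        """Per-coordinate weights (each marker weight repeated for x, y, z)."""
        return np.repeat(self.weights, 3)


@dataclass
class SubjectScores:
    """Principal-position time series PP_k(t) of one subject.

    Rows are frames, columns are components ordered by descending eigenvalue
    of the pooled decomposition (k = 1 corresponds to column 0).
    """

    subject_id: str
    pp: np.ndarray  # (n_frames, r)
    sample_rate: float
    component_index: np.ndarray = field(default=None)  # 1-based k per column

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.ndim != 2:
            raise ValueError("pp must be 2-D (frames x components)")
        if self.component_index is None:
            self.component_index = np.arange(1, self.pp.shape[1] + 1)
        else:
            self.component_index = np.asarray(self.component_index, dtype=int)

    @property
    def n_components(self) -> int:
        return self.pp.shape[1]

    @property
    def n_frames(self) -> int:
        return self.pp.shape[0]
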