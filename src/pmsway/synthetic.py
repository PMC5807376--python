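"""Synthetic motion-capture cohorts with planted modal structure.

Each synthetic subject's normalized posture trajectory is a sum of a small
number of orthonormal movement modes, each driven by a quasi-sinusoidal
score series with configurable amplitude, dominant frequency and
control-regularity jitter.  The normalization chain of the real pipeline is
inverted (un-weight, un-normalize by stature, add a mean standing posture)
so the generated lab-space recordings exercise preprocessing realistically;
group effects on selected modes provide planted ground truth for parameter
recovery and power studies.

The generator is geometric, not physics-based: modes are random orthonormal
directions, not biomechanical strategies, and score series are oscillators,
not output of a feedback controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import body
from .containers import MarkerTrajectorySet
from .errors import ConfigError
from .preprocess import MarkerPolicy, segment_weight_table, select_markers

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "make_base_posture",
    "make_modes",
    "make_score_series",
    "generate_cohort",
]

_AGE_GROUPS = ("young", "old")
_GENDERS = ("female", "male")

#: Default group effect: the older group's second mode is controlled at a
#: 10% lower crossing frequency and with 15% more jitter.
DEFAULT_GROUP_EFFECTS: dict[tuple[str, int], dict[str, float]] = {
    ("old", 2): {"frequency": 0.90, "jitter": 1.15},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    ``n_subjects_per_cell`` is either one integer for all four
    (age group x gender) cells or a mapping ``(age_group, gender) -> n``.
    Amplitudes are in normalized-posture units and must be strictly
    decreasing so the planted mode order is identifiable from the
    eigenvalue order; frequencies are the dominant oscillation frequencies
    in Hz; ``frequency_jitter`` sets the relative SD of each mode's
    instantaneous half-period.  ``group_effects`` maps
    ``(group, mode_k)`` to multiplicative modifiers on ``amplitude``,
    ``frequency`` and/or ``jitter`` applied to subjects in that group
    (groups: young/old/female/male; mode_k is 1-based).
    """

    n_subjects_per_cell: int | Mapping[tuple[str, str], int] = 5
    duration: float = 80.0
    sample_rate: float = 240.0
    n_markers: int = 37
    n_modes: int = 5
    mode_amplitudes: tuple[float, ...] = (0.0040, 0.0024, 0.00144, 0.00086, 0.00052)
    mode_frequencies: tuple[float, ...] = (1.2, 2.0, 2.5, 1.6, 2.8)
    frequency_jitter: tuple[float, ...] = (0.15, 0.15, 0.15, 0.15, 0.15)
    group_effects: Mapping[tuple[str, int], Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    measurement_noise_sd: float = 0.0005
    gap_fraction: float = 0.0
    heights: tuple[float, float] = (1.55, 1.90)
    subject_frequency_cv: float = 0.03
    subject_amplitude_cv: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        K = self.n_modes
        if self.n_markers < 4:
            raise ConfigError("n_markers must be >= 4")
        if K < 1:
            raise ConfigError("need at least one mode")
        for name in ("mode_amplitudes", "mode_frequencies", "frequency_jitter"):
            if len(getattr(self, name)) < K:
                raise ConfigError(f"{name} must list at least {K} values")
        amps = self.mode_amplitudes[:K]
        if any(a < 0 for a in amps):
            raise ConfigError("mode amplitudes must be non-negative")
        if any(a > 0 for a in amps):
            # strictly decreasing guarantees identifiable eigenvalue order;
            # an all-zero (static) cohort is the one permitted exception
            if any(a <= 0 for a in amps):
                raise ConfigError("mode amplitudes must all be positive or all zero")
            if any(a1 <= a2 for a1, a2 in zip(amps, amps[1:])):
                raise ConfigError("mode amplitudes must be strictly decreasing")
        nyq = self.sample_rate / 2.0
        if any(not 0 < f < nyq for f in self.mode_frequencies[:K]):
            raise ConfigError("mode frequencies must lie in (0, Nyquist)")
        if any(j < 0 for j in self.frequency_jitter[:K]):
            raise ConfigError("frequency jitter must be non-negative")
        if not 0 <= self.gap_fraction < 0.5:
            raise ConfigError("gap_fraction must lie in [0, 0.5)")
        if self.measurement_noise_sd < 0:
            raise ConfigError("measurement_noise_sd must be non-negative")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ConfigError("duration and sample_rate must be positive")
        for group, k in self.group_effects:
            if group not in _AGE_GROUPS + _GENDERS:
                raise ConfigError(f"unknown group {group!r} in group_effects")
            if not 1 <= k <= K:
                raise ConfigError(f"group effect on undefined mode {k}")

    def cell_sizes(self) -> dict[tuple[str, str], int]:
        if isinstance(self.n_subjects_per_cell, int):
            return {
                (a, g): self.n_subjects_per_cell
                for a in _AGE_GROUPS
                for g in _GENDERS
            }
        return {
            (a, g): int(self.n_subjects_per_cell[(a, g)])
            for a in _AGE_GROUPS
            for g in _GENDERS
        }


@dataclass
class GroundTruth:
    """Everything planted into a synthetic cohort.

    ``mode_matrix`` holds the orthonormal planted modes as columns, in the
    weighted-normalized posture space over ``analysis_labels`` (the
    bilaterally symmetric marker subset, sorted).  ``true_scores`` are the
    time-centered score series actually generated per subject, i.e. exactly
    what projecting the re-normalized noise-free data onto the modes
    returns.  ``expected_crossings`` is 2 * f * duration per subject and
    mode (the analytic acceleration zero-crossing count of a jitter-free
    oscillation).
    """

    mode_matrix: np.ndarray  # (3 * M_selected, K)
    analysis_labels: list[str]
    true_scores: dict[str, np.ndarray]  # subject_id -> (T, K)
    amplitudes: dict[str, np.ndarray]  # subject_id -> (K,)
    frequencies: dict[str, np.ndarray]
    jitters: dict[str, np.ndarray]
    expected_crossings: dict[str, np.ndarray]
    group_effects: dict
    config: SyntheticConfig


def make_base_posture(
    n_markers: int, seed: int
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """A fixed, plausible standing posture with labeled, segment-mapped markers.

    For 37 markers the canonical full-body set (15 bilateral pairs + 7
    unpaired labels) with template anatomy is returned; other counts get a
    generic subset/extension with the same pairing conventions.  A small
    seeded jitter (< 1 cm) individualizes coordinates while keeping them
    anatomically plausible.  Returns (positions (M, 3) in meters for a
    1.70 m stature, labels, label -> segment map).
    """
    if n_markers < 4:
        raise ConfigError("n_markers must be >= 4")
    rng = np.random.default_rng(seed)
    if n_markers == 37:
        labels = body.full_marker_labels()
    else:
        n_mid = 1 if n_markers % 2 else 2
        n_pairs = (n_markers - n_mid) // 2
        if n_pairs > len(body.PAIR_STEMS) or n_mid > len(body.MIDLINE_LABELS):
            raise ConfigError("n_markers exceeds the available label inventory")
        labels = []
        for stem in body.PAIR_STEMS[:n_pairs]:
            labels.append("L" + stem)
            labels.append("R" + stem)
        labels.extend(
            lab for lab in body.MIDLINE_LABELS
            if lab not in body.NON_SYMMETRIC_LABELS
        )
        labels = labels[: 2 * n_pairs] + labels[2 * n_pairs : 2 * n_pairs + n_mid]
    positions = body.template_posture(labels)
    positions = positions + rng.uniform(-0.008, 0.008, size=positions.shape)
    segment_map = {lab: body.segment_of(lab) for lab in labels}
    return positions, labels, segment_map


def make_modes(dim: int, n_modes: int, seed: int) -> np.ndarray:
    """Orthonormal mode matrix (dim x n_modes) from seeded random vectors."""
    if n_modes > dim:
        raise ConfigError("cannot fit more orthonormal modes than dimensions")
    if n_modes < 1:
        raise ConfigError("need at least one mode")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((dim, n_modes)))
    # deterministic sign: largest-|entry| positive per column
    flip = np.sign(Q[np.argmax(np.abs(Q), axis=0), np.arange(n_modes)])
    return Q * flip[None, :]


def make_score_series(
    amplitude: float,
    frequency: float,
    jitter: float,
    duration: float,
    sample_rate: float,
    seed: int,
    initial_phase: float | None = None,
) -> np.ndarray:
    """Quasi-sinusoidal score series with per-half-cycle period jitter.

    s(t) = amplitude * sin(phi(t)) where the phase advances by pi over each
    half-cycle whose duration is drawn from a mean-preserving log-normal
    with mean 1/(2 * frequency) and relative SD ``jitter``.  With
    ``jitter = 0`` the series is a pure sinusoid, whose acceleration has
    exactly 2 * frequency * duration zero crossings in expectation.
    """
    if amplitude < 0:
        raise ConfigError("amplitude must be non-negative")
    if jitter < 0:
        raise ConfigError("jitter must be non-negative")
    if not 0 < frequency < sample_rate / 2:
        raise ConfigError("frequency must lie in (0, Nyquist)")
    n_samples = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2 * np.pi) if initial_phase is None else initial_phase
    if amplitude == 0.0:
        return np.zeros(n_samples)

    mean_half = 1.0 / (2.0 * frequency)
    t = np.arange(n_samples) / sample_rate
    if jitter == 0.0:
        return amplitude * np.sin(phi0 + 2 * np.pi * frequency * t)

    sig2 = np.log1p(jitter**2)
    mu = np.log(mean_half) - sig2 / 2.0
    halves = int(np.ceil(2 * frequency * duration * (1.0 + 4.0 * jitter))) + 16
    durations = rng.lognormal(mu, np.sqrt(sig2), size=halves)
    while durations.sum() < duration:
        durations = np.concatenate(
            [durations, rng.lognormal(mu, np.sqrt(sig2), size=halves)]
        )
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    phases = phi0 + np.pi * np.arange(boundaries.size)
    return amplitude * np.sin(np.interp(t, boundaries, phases))


def _group_modifier(config, age_group: str, gender: str, k: int, which: str) -> float:
    mod = 1.0
    for group in (age_group, gender):
        eff = config.group_effects.get((group, k))
        if eff:
            mod *= float(eff.get(which, 1.0))
    return mod


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[MarkerTrajectorySet], GroundTruth]:
    """Generate a cohort of marker recordings plus its ground truth.

    For each subject the normalized-space trajectory sum_k s_k(t) * mode_k
    is un-weighted, un-normalized by the subject's stature, shifted to a
    standing mean posture, then degraded by i.i.d. Gaussian measurement
    noise and (optionally) occlusion gaps.  Subjects assigned a left foot
    in front are stored mirrored (y negated, labels swapped), exactly as a
    real recording of that stance would be.
    """
    config.validate()
    K = config.n_modes
    ss = np.random.SeedSequence(config.seed)
    base_seed, modes_seed, subjects_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    template, labels, _segment_map = make_base_posture(config.n_markers, base_seed)

    # analysis subset: bilaterally symmetric markers, sorted label order
    reference = MarkerTrajectorySet(
        subject_id="_template",
        marker_labels=labels,
        positions=template[None, :, :],
        sample_rate=config.sample_rate,
    )
    selected = select_markers(reference, None)
    analysis_labels = selected.marker_labels
    weights = segment_weight_table(analysis_labels)
    w3 = np.repeat([weights[lab] for lab in analysis_labels], 3)
    sel_idx = [labels.index(lab) for lab in analysis_labels]

    dim = 3 * len(analysis_labels)
    modes = make_modes(dim, K, modes_seed)

    n_samples = int(round(config.duration * config.sample_rate))
    master = np.random.default_rng(subjects_seed)

    subjects: list[MarkerTrajectorySet] = []
    truth = GroundTruth(
        mode_matrix=modes,
        analysis_labels=list(analysis_labels),
        true_scores={},
        amplitudes={},
        frequencies={},
        jitters={},
        expected_crossings={},
        group_effects=dict(config.group_effects),
        config=config,
    )

    counter = 0
    for (age_group, gender), n_cell in sorted(config.cell_sizes().items()):
        for i in range(n_cell):
            counter += 1
            sid = f"{age_group[0]}{gender[0]}{counter:03d}"
            rng = np.random.default_rng(master.integers(2**31))
            height = rng.uniform(*config.heights)
            mass = float(np.clip(rng.normal(72.0, 12.0), 45.0, 110.0))
            front_foot = "left" if rng.random() < 0.5 else "right"

            amps = np.empty(K)
            freqs = np.empty(K)
            jits = np.empty(K)
            scores = np.empty((n_samples, K))
            for k in range(K):
                amp = config.mode_amplitudes[k] * _group_modifier(
                    config, age_group, gender, k + 1, "amplitude"
                )
                if config.subject_amplitude_cv > 0:
                    amp *= rng.lognormal(0.0, config.subject_amplitude_cv)
                freq = config.mode_frequencies[k] * _group_modifier(
                    config, age_group, gender, k + 1, "frequency"
                )
                if config.subject_frequency_cv > 0:
                    freq *= 1.0 + config.subject_frequency_cv * rng.standard_normal()
                freq = float(np.clip(freq, 0.1, 0.45 * config.sample_rate))
                jit = config.frequency_jitter[k] * _group_modifier(
                    config, age_group, gender, k + 1, "jitter"
                )
                amps[k], freqs[k], jits[k] = amp, freq, jit
                scores[:, k] = make_score_series(
                    amp, freq, jit, config.duration, config.sample_rate,
                    seed=int(rng.integers(2**31)),
                )

            disp = scores @ modes.T  # (T, dim), weighted-normalized space
            lab_disp = disp / w3[None, :] * height
            positions = np.zeros((n_samples, len(labels), 3))
            positions[:] = template[None, :, :] * (height / body.TEMPLATE_HEIGHT)
            positions[:, sel_idx, :] += lab_disp.reshape(n_samples, -1, 3)
            if config.measurement_noise_sd > 0:
                positions += rng.normal(
                    0.0, config.measurement_noise_sd, size=positions.shape
                )

            missing = np.zeros((n_samples, len(labels)), dtype=bool)
            if config.gap_fraction > 0:
                mean_len = max(1, int(round(0.25 * config.sample_rate)))
                for m in range(len(labels)):
                    target = config.gap_fraction * n_samples
                    covered = 0
                    while covered < target:
                        start = int(rng.integers(n_samples))
                        length = min(
                            rng.geometric(1.0 / mean_len), n_samples - start
                        )
                        missing[start : start + length, m] = True
                        covered += length

            traj = MarkerTrajectorySet(
                subject_id=sid,
                marker_labels=list(labels),
                positions=positions,
                sample_rate=config.sample_rate,
                missing=missing,
                height=height,
                mass=mass,
                age_group=age_group,
                gender=gender,
                front_foot="right",
            )
            if front_foot == "left":
                # store as recorded: the raw trial is the mirror image
                traj.positions[:, :, 1] *= -1.0
                pairs = {}
                for lab in labels:
                    if lab[0] in "LR" and lab not in body.MIDLINE_LABELS:
                        pairs[lab] = ("R" if lab[0] == "L" else "L") + lab[1:]
                traj.marker_labels = [pairs.get(lab, lab) for lab in labels]
                traj.front_foot = "left"

            subjects.append(traj)
            truth.true_scores[sid] = scores - scores.mean(axis=0)
            truth.amplitudes[sid] = amps
            truth.frequencies[sid] = freqs
            truth.jitters[sid] = jits
            truth.expected_crossings[sid] = 2.0 * freqs * config.duration
    return subjects, truth
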