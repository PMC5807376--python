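import numpy as np
import pytest

from pmsway import (
    SyntheticConfig,
    concatenate,
    fit_pca,
    generate_cohort,
    preprocess_subject,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free 8-subject cohort, K=3 planted modes, 10 s trials."""
    config = SyntheticConfig(
        n_subjects_per_cell=2,
        duration=10.0,
        n_markers=8,
        n_modes=3,
        mode_amplitudes=(0.004, 0.0024, 0.00144),
        mode_frequencies=(1.2, 2.0, 2.5),
        frequency_jitter=(0.1, 0.1, 0.1),
        measurement_noise_sd=0.0,
        group_effects={},
        seed=7,
    )
    cohort, truth = generate_cohort(config)
    return cohort, truth


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    cohort, truth = small_cohort
    return [preprocess_subject(t) for t in cohort], truth


@pytest.fixture(scope="session")
def small_model(small_matrices):
    matrices, truth = small_matrices
    pooled, _ = concatenate(matrices)
    return fit_pca(pooled, None), matrices, truth


def well_separated_config(noise_sd=0.0, seed=11, duration=20.0):
    """20-subject, K=5, full-marker-set recovery benchmark.

    Identifiability by construction: amplitude ratios >= 1.5 separate the
    eigenvalues, and the low jitter (0.05) keeps each mode's spectral
    bandwidth (~ f * jitter ~ 0.1 Hz) well below the frequency separation
    (>= 0.3 Hz), so sample cross-correlations between score series — which
    rotate eigenvectors within the signal subspace — stay small.
    """
    return SyntheticConfig(
        n_subjects_per_cell=5,
        duration=duration,
        n_markers=37,
        n_modes=5,
        mode_amplitudes=(0.0040, 0.0024, 0.00144, 0.00086, 0.00052),
        mode_frequencies=(1.2, 2.0, 2.5, 1.6, 2.8),
        frequency_jitter=(0.05,) * 5,
        measurement_noise_sd=noise_sd,
        group_effects={},
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    """Noise-free well-separated cohort (4800 frames per subject)."""
    cohort, truth = generate_cohort(well_separated_config(noise_sd=0.0))
    matrices = [preprocess_subject(t) for t in cohort]
    return cohort, matrices, truth


@pytest.fixture(scope="session")
def stats_cohort_factory():
    """Factory for the scaled-down 25+25 (17F/8M) statistics cohorts."""

    def make(seed, planted=True, duration=20.0):
        effects = (
            {("old", 2): {"frequency": 0.90, "jitter": 1.15}} if planted else {}
        )
        return SyntheticConfig(
            n_subjects_per_cell={
                ("young", "female"): 17,
                ("young", "male"): 8,
                ("old", "female"): 17,
                ("old", "male"): 8,
            },
            duration=duration,
            n_markers=8,
            n_modes=3,
            mode_amplitudes=(0.004, 0.0024, 0.00144),
            mode_frequencies=(1.2, 2.0, 2.5),
            frequency_jitter=(0.15, 0.15, 0.15),
            group_effects=effects,
            seed=seed,
        )

    return make


def angle_between(u, v):
    c = abs(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(min(1.0, c)))
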