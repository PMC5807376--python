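"""End-to-end orchestration: simulate/load -> preprocess -> PCA -> control -> stats.

A single :class:`RunConfig` drives the whole chain; every stage writes its
artifact into the output directory and a manifest records inputs, seeds and
checksums so a run is reproducible bit-for-bit given the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import MarkerTrajectorySet, PostureMatrix
from .control import KinematicsSettings, compute_control_variables, compute_pa
from .decomposition import fit_pca, project_subject, relative_std
from .errors import ConfigError
from .group_stats import full_report
from .io import read_markers
from .preprocess import (
    MarkerPolicy,
    concatenate,
    fill_gaps,
    mirror_left_front,
    normalize_and_weight,
    select_markers,
)
from .robustness import loo_crossval
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_all", "preprocess_subject"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Either ``synthetic`` (cohort is generated) or ``input_dir`` (marker CSVs
    are read) must be set.  ``n_components`` limits the statistical
    analysis; the decomposition itself always retains every nonzero
    component so rSTD percentages are computed over the full basis.
    """

    out_dir: str | Path = "pmsway_run"
    synthetic: SyntheticConfig | None = None
    input_dir: str | Path | None = None
    kinematics: KinematicsSettings = field(default_factory=KinematicsSettings)
    n_components: int = 9
    crossval_threshold: float = 15.0
    run_crossval: bool = True
    gap_fill_rank: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            for key in ("mode_amplitudes", "mode_frequencies", "frequency_jitter",
                        "heights"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "group_effects" in syn and syn["group_effects"] is not None:
                syn["group_effects"] = {
                    (str(g), int(k)): dict(v)
                    for (g, k, v) in (
                        (e["group"], e["mode"], e.get("modifiers", {}))
                        for e in syn["group_effects"]
                    )
                }
            if "n_subjects_per_cell" in syn and isinstance(
                syn["n_subjects_per_cell"], dict
            ):
                syn["n_subjects_per_cell"] = {
                    tuple(key.split("/")): int(n)
                    for key, n in syn["n_subjects_per_cell"].items()
                }
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "kinematics" in kwargs and kwargs["kinematics"] is not None:
            kwargs["kinematics"] = KinematicsSettings(**kwargs["kinematics"])
        return cls(**kwargs)


def preprocess_subject(
    traj: MarkerTrajectorySet,
    policy: MarkerPolicy | None = None,
    gap_fill_rank: int = 10,
) -> PostureMatrix:
    """Gap-fill, mirror, select and normalize one subject."""
    if traj.has_gaps:
        traj = fill_gaps(traj, rank=gap_fill_rank)
    if traj.front_foot == "left":
        traj = mirror_left_front(traj)
    traj = select_markers(traj, policy)
    return normalize_and_weight(traj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_cohort(config: RunConfig) -> list[MarkerTrajectorySet]:
    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed != syn.seed:
            syn = dataclasses.replace(syn, seed=config.seed)
        cohort, _truth = generate_cohort(syn)
        return cohort
    if config.input_dir is None:
        raise ConfigError("config needs either `synthetic` or `input_dir`")
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise ConfigError(f"input directory not found: {input_dir}")
    paths = sorted(input_dir.glob("*.csv"))
    if not paths:
        raise ConfigError(f"no marker CSV files in {input_dir}")
    return [read_markers(p) for p in paths]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the results manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, index=False, float_format="%.12g")
        artifacts[name] = _sha256(path)
        return path

    cohort = _load_cohort(config)
    metadata = pd.DataFrame(
        [
            {
                "subject_id": t.subject_id,
                "age_group": t.age_group,
                "gender": t.gender,
                "height": t.height,
                "mass": t.mass,
                "front_foot": t.front_foot,
                "n_frames": t.n_frames,
                "sample_rate": t.sample_rate,
            }
            for t in cohort
        ]
    )
    save(metadata, "subjects.csv")

    matrices = [
        preprocess_subject(t, gap_fill_rank=config.gap_fill_rank) for t in cohort
    ]
    pooled, _index = concatenate(matrices)

    model = fit_pca(pooled, None)
    r = min(config.n_components, model.n_components_)
    if r < config.n_components:
        warnings.warn(
            f"only {r} nonzero components available "
            f"(requested {config.n_components})"
        )
    eigen = pd.DataFrame(
        {
            "k": np.arange(1, model.n_components_ + 1),
            "EV": model.eigenvalues_,
            "explained_pct": model.explained_pct_,
        }
    )
    save(eigen, "eigenvalues.csv")
    np.savez(
        out / "model.npz",
        components=model.components_,
        eigenvalues=model.eigenvalues_,
        marker_labels=np.asarray(matrices[0].marker_labels),
    )
    artifacts["model.npz"] = _sha256(out / "model.npz")

    control_tables = []
    rstd_tables = []
    for mat in matrices:
        scores = project_subject(mat, model)
        rstd = relative_std(scores)  # percentages over the full basis
        rstd_tables.append(rstd)
        head = type(scores)(
            subject_id=scores.subject_id,
            pp=scores.pp[:, :r],
            sample_rate=scores.sample_rate,
        )
        kin = compute_pa(head, config.kinematics)
        control_tables.append(
            compute_control_variables(kin, rstd[rstd["k"] <= r])
        )
    rstd_all = pd.concat(rstd_tables, ignore_index=True)
    control = pd.concat(control_tables, ignore_index=True)
    save(rstd_all, "rstd.csv")
    save(control, "control.csv")

    if config.run_crossval:
        report = loo_crossval(matrices, r, config.crossval_threshold)
        save(report.table, "crossval.csv")
        robust_count = report.robust_count
    else:
        robust_count = None

    anova, posthoc = full_report(
        control, metadata, components=tuple(range(1, r + 1))
    )
    save(anova, "anova.csv")
    save(posthoc, "posthoc.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_subjects": len(cohort),
        "n_components_stats": r,
        "n_components_total": int(model.n_components_),
        "robust_count": robust_count,
        "kinematics": dataclasses.asdict(config.kinematics),
        "crossval_threshold": config.crossval_threshold,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
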