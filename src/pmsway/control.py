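"""Posture-space kinematics and zero-crossing control variables.

Score series PP_k(t) are lowpass filtered (zero-phase Butterworth), then
differentiated twice with a linear-phase FIR differentiator to obtain the
principal velocities PV_k(t) and accelerations PA_k(t).  Each sign change
of PA_k marks a corrective intervention of the neuro-muscular controller;
the crossing count N_k measures how tightly and the standard deviation of
inter-crossing times sigma_k how regularly a component is controlled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SubjectScores

__all__ = [
    "KinematicsSettings",
    "PMKinematics",
    "ScoreKinematics",
    "spectrum",
    "lowpass",
    "design_fir_differentiator",
    "differentiate",
    "compute_pa",
    "zero_crossings",
    "crossing_interval_sd",
    "compute_control_variables",
    "filter_sensitivity_sweep",
]


@dataclass(frozen=True)
class KinematicsSettings:
    """Filtering and differentiation parameters.

    Defaults follow standard practice for 240 Hz postural data whose signal
    power sits below ~3 Hz: a 5th-order 7 Hz zero-phase Butterworth lowpass
    on the scores and an order-50 FIR differentiator passing 5 Hz and
    stopping 7 Hz.  ``edge_trim_s`` seconds are discarded at both ends of
    the trial to remove filter transients.
    """

    butterworth_order: int = 5
    cutoff_hz: float = 7.0
    fir_order: int = 50
    pass_hz: float = 5.0
    stop_hz: float = 7.0
    edge_trim_s: float = 0.5

    def validate(self, sample_rate: float) -> None:
        nyq = sample_rate / 2.0
        if not 0 < self.pass_hz < self.stop_hz < nyq:
            raise ValueError("need 0 < pass_hz < stop_hz < Nyquist")
        if not 0 < self.cutoff_hz < nyq:
            raise ValueError("cutoff_hz must lie below the Nyquist frequency")
        if self.butterworth_order < 1 or self.fir_order < 2:
            raise ValueError("filter orders out of range")
        if self.fir_order % 2:
            raise ValueError("fir_order must be even (type III differentiator)")
        if self.edge_trim_s < 0:
            raise ValueError("edge_trim_s must be non-negative")


@dataclass
class PMKinematics:
    """Filtered scores and their first/second derivatives for one subject.

    Arrays cover the valid window only (edge-trimmed); ``window_s`` is its
    duration in seconds.
    """

    subject_id: str
    pp_f: np.ndarray  # (n_valid, r)
    pv: np.ndarray  # (n_valid, r), units 1/s
    pa: np.ndarray  # (n_valid, r), units 1/s^2
    sample_rate: float
    window_s: float

    @property
    def n_components(self) -> int:
        return self.pa.shape[1]


def spectrum(
    series: np.ndarray, sample_rate: float, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of a score series.

    Hann window, 50% overlap; segment length defaults to 8 s (or the whole
    series if shorter).  Requires at least 2 s of data.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("spectrum expects a 1-D series")
    if series.size < 2 * sample_rate:
        raise ValueError("need at least 2 s of data for a PSD estimate")
    if nperseg is None:
        nperseg = min(series.size, int(8 * sample_rate))
    freqs, psd = signal.welch(series, fs=sample_rate, nperseg=nperseg)
    return freqs, psd


def lowpass(
    series: np.ndarray, sample_rate: float, settings: KinematicsSettings
) -> np.ndarray:
    """Zero-phase Butterworth lowpass (applied forward and backward)."""
    settings.validate(sample_rate)
    sos = signal.butter(
        settings.butterworth_order, settings.cutoff_hz, fs=sample_rate, output="sos"
    )
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


@lru_cache(maxsize=32)
def design_fir_differentiator(
    order: int, pass_hz: float, stop_hz: float, sample_rate: float
) -> np.ndarray:
    """Weighted least-squares linear-phase (type III) FIR differentiator.

    The antisymmetric impulse response of length ``order + 1`` approximates
    H(w) = j*w up to ``pass_hz`` and 0 beyond ``stop_hz`` (transition band
    unconstrained).  The passband is weighted heavily because derivative
    amplitude accuracy in the signal band matters more than stopband leakage
    once the series has been lowpassed.  Output units are per sample;
    :func:`differentiate` multiplies by the sample rate.
    """
    half = order // 2
    grid = np.linspace(0.0, np.pi, 160 * half)
    wp = 2 * np.pi * pass_hz / sample_rate
    ws = 2 * np.pi * stop_hz / sample_rate
    mask = (grid <= wp) | (grid >= ws)
    w = grid[mask]
    desired = np.where(w <= wp, w, 0.0)
    basis = 2.0 * np.sin(np.outer(w, np.arange(1, half + 1)))
    weight = np.where(desired > 0, 1000.0, 1.0)
    coef, *_ = np.linalg.lstsq(basis * weight[:, None], desired * weight, rcond=None)
    h = np.zeros(order + 1)
    h[half - np.arange(1, half + 1)] = coef
    h[half + np.arange(1, half + 1)] = -coef
    return h


def differentiate(
    series: np.ndarray, sample_rate: float, settings: KinematicsSettings
) -> np.ndarray:
    """Differentiate a series (or columns of a 2-D array), units per second.

    The FIR filter's group delay (``fir_order / 2`` samples) is compensated
    so the derivative is time-aligned with the input; samples within half a
    filter length of either end are edge-contaminated and should be trimmed.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] <= settings.fir_order:
        raise ValueError("series shorter than the differentiator")
    h = design_fir_differentiator(
        settings.fir_order, settings.pass_hz, settings.stop_hz, sample_rate
    )
    if series.ndim == 1:
        return np.convolve(series, h, mode="same") * sample_rate
    out = np.empty_like(series)
    for j in range(series.shape[1]):
        out[:, j] = np.convolve(series[:, j], h, mode="same") * sample_rate
    return out


class ScoreKinematics(TransformerMixin, BaseEstimator):
    """Transformer from score series to filtered kinematics.

    A stateless sklearn-style wrapper over the lowpass + double FIR
    differentiation chain; ``transform`` maps a :class:`SubjectScores` to a
    :class:`PMKinematics`.  Parameters mirror
    :class:`KinematicsSettings`.
    """

    def __init__(
        self,
        butterworth_order: int = 5,
        cutoff_hz: float = 7.0,
        fir_order: int = 50,
        pass_hz: float = 5.0,
        stop_hz: float = 7.0,
        edge_trim_s: float = 0.5,
    ):
        self.butterworth_order = butterworth_order
        self.cutoff_hz = cutoff_hz
        self.fir_order = fir_order
        self.pass_hz = pass_hz
        self.stop_hz = stop_hz
        self.edge_trim_s = edge_trim_s

    def _settings(self) -> KinematicsSettings:
        return KinematicsSettings(
            butterworth_order=self.butterworth_order,
            cutoff_hz=self.cutoff_hz,
            fir_order=self.fir_order,
            pass_hz=self.pass_hz,
            stop_hz=self.stop_hz,
            edge_trim_s=self.edge_trim_s,
        )

    def fit(self, X=None, y=None):
        return self

    def transform(self, scores: SubjectScores) -> PMKinematics:
        return compute_pa(scores, self._settings())


def compute_pa(
    scores: SubjectScores, settings: KinematicsSettings | None = None
) -> PMKinematics:
    """Filtered scores, principal velocities and principal accelerations.

    PP is lowpassed, differentiated once for PV and again for PA; the first
    and last ``edge_trim_s`` seconds are then discarded from all three.
    """
    settings = settings or KinematicsSettings()
    settings.validate(scores.sample_rate)
    pp_f = lowpass(scores.pp, scores.sample_rate, settings)
    pv = differentiate(pp_f, scores.sample_rate, settings)
    pa = differentiate(pv, scores.sample_rate, settings)
    trim = int(round(settings.edge_trim_s * scores.sample_rate))
    if 2 * trim >= scores.n_frames:
        raise ValueError("edge trim leaves no valid window")
    sl = slice(trim, scores.n_frames - trim)
    window_s = (scores.n_frames - 2 * trim) / scores.sample_rate
    return PMKinematics(
        subject_id=scores.subject_id,
        pp_f=pp_f[sl],
        pv=pv[sl],
        pa=pa[sl],
        sample_rate=scores.sample_rate,
        window_s=window_s,
    )


def zero_crossings(
    pa_series: np.ndarray, sample_rate: float
) -> tuple[np.ndarray, int]:
    """Zero-crossing times and count of one acceleration series.

    A crossing is a sign change between consecutive non-zero samples;
    crossing times are sub-sample estimates by linear interpolation.  Runs
    of exact zeros flanked by opposite signs collapse to a single crossing
    at the run center; flanked by equal signs they count as no crossing.
    """
    x = np.asarray(pa_series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("zero_crossings expects a non-empty 1-D series")
    idx = np.flatnonzero(x)
    if idx.size < 2:
        return np.empty(0), 0
    v = x[idx]
    change = np.flatnonzero(np.signbit(v[:-1]) != np.signbit(v[1:]))
    times = np.empty(change.size)
    for out_i, m in enumerate(change):
        i, j = idx[m], idx[m + 1]
        if j == i + 1:
            times[out_i] = (i + v[m] / (v[m] - v[m + 1])) / sample_rate
        else:
            times[out_i] = 0.5 * (i + j) / sample_rate  # zero-run center
    return times, int(times.size)


def crossing_interval_sd(crossing_times: np.ndarray) -> float:
    """Standard deviation (sample, n-1) of times between successive crossings.

    Returns NaN (with a warning) when fewer than 3 crossings — i.e. fewer
    than 2 intervals — are available.
    """
    t = np.asarray(crossing_times, dtype=float)
    if t.size < 3:
        warnings.warn("fewer than 3 crossings; sigma undefined")
        return float("nan")
    return float(np.diff(t).std(ddof=1))


def compute_control_variables(
    kin: PMKinematics, rstd: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tidy per-component table of N_k, sigma_k (and rSTD_k if provided).

    Columns: ``subject_id``, ``k``, ``N``, ``sigma``, ``window_s`` plus
    ``rSTD`` when a relative-amplitude table for the same subject is given.
    """
    rows = []
    for j in range(kin.n_components):
        times, n = zero_crossings(kin.pa[:, j], kin.sample_rate)
        if n >= 3:
            sig = crossing_interval_sd(times)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = crossing_interval_sd(times)
        rows.append(
            {"subject_id": kin.subject_id, "k": j + 1, "N": n,
             "sigma": sig, "window_s": kin.window_s}
        )
    table = pd.DataFrame(rows)
    if rstd is not None:
        if not (rstd["subject_id"] == kin.subject_id).all():
            raise ValueError("rSTD table belongs to a different subject")
        table = table.merge(rstd[["k", "rSTD"]], on="k", how="left")
        table = table[["subject_id", "k", "rSTD", "N", "sigma", "window_s"]]
    return table


def filter_sensitivity_sweep(
    cohort_scores: list[SubjectScores],
    settings_grid: list[KinematicsSettings],
    metadata: pd.DataFrame,
    variables: tuple[str, ...] = ("N", "sigma"),
    components: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Recompute control variables and group effects over a filter grid.

    For every grid point the control variables are recomputed from the raw
    scores and the two-way (age x gender) ANOVA re-run; the tidy result
    table (one row per setting x variable x component x effect) lets one
    inspect how stable the statistical conclusions are under the filtering
    choice.  Invalid grid entries are skipped with a warning.
    """
    from .group_stats import two_way_anova  # local import avoids cycle

    if not settings_grid:
        raise ValueError("empty settings grid")
    if not cohort_scores:
        raise ValueError("no subjects")
    fs = cohort_scores[0].sample_rate
    rows = []
    for st in settings_grid:
        try:
            st.validate(fs)
        except ValueError as exc:
            warnings.warn(f"skipping invalid grid entry {st}: {exc}")
            continue
        tables = []
        for sc in cohort_scores:
            tables.append(compute_control_variables(compute_pa(sc, st)))
        control = pd.concat(tables, ignore_index=True)
        merged = control.merge(
            metadata[["subject_id", "age_group", "gender"]], on="subject_id"
        )
        ks = components or tuple(sorted(control["k"].unique()))
        for var in variables:
            for k in ks:
                sub = merged[merged["k"] == k].dropna(subset=[var])
                if sub.empty:
                    continue
                res = two_way_anova(sub.rename(columns={var: "value"}))
                for _, erow in res.effects.iterrows():
                    rows.append(
                        {
                            "cutoff_hz": st.cutoff_hz,
                            "pass_hz": st.pass_hz,
                            "stop_hz": st.stop_hz,
                            "variable": var,
                            "k": k,
                            "effect": erow["effect"],
                            "F": erow["F"],
                            "p": erow["p"],
                        }
                    )
    if not rows:
        raise ValueError("no valid grid entries")
    return pd.DataFrame(rows)
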