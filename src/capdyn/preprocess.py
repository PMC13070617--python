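"""Temporal cleaning of resting-state runs.

Implements the per-run temporal preprocessing chain: nuisance regression
(polynomial trends, six rigid-body motion parameters, optional tissue and
global signals), discrete-cosine high-pass filtering, framewise displacement,
and motion-based subject exclusion.  Spatial preprocessing (realignment,
normalization, smoothing) is assumed to have happened upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import BoldRun

__all__ = [
    "ConfoundSet",
    "CleanRun",
    "compute_framewise_displacement",
    "regress_nuisance",
    "highpass_filter",
    "flag_high_motion_subject",
    "clean_run",
]

log = logging.getLogger(__name__)


@dataclass
class ConfoundSet:
    """Per-volume nuisance regressors for one run.

    ``motion6`` holds three translations (mm) and three rotations (radians);
    set ``rotations_in_degrees`` when the motion table uses degrees.  Tissue
    and global-signal columns are optional: pass ``None`` to omit one.
    """

    motion6: np.ndarray
    wm_signal: np.ndarray | None = None
    csf_signal: np.ndarray | None = None
    global_signal: np.ndarray | None = None
    trend_order: int = 2
    rotations_in_degrees: bool = False

    def design_matrix(self, n_volumes: int) -> np.ndarray:
        motion = np.asarray(self.motion6, dtype=float)
        if motion.ndim != 2 or motion.shape[1] != 6:
            raise ValueError("motion table must have exactly 6 columns")
        if motion.shape[0] != n_volumes:
            raise ValueError("motion table length must match the run")
        if self.rotations_in_degrees:
            motion = motion.copy()
            motion[:, 3:] = np.deg2rad(motion[:, 3:])
        t = np.linspace(-1.0, 1.0, n_volumes)
        cols = [np.ones(n_volumes)]
        for p in range(1, self.trend_order + 1):
            cols.append(t**p)
        cols.extend(motion.T)
        for name in ("wm_signal", "csf_signal", "global_signal"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=float)
                if col.shape[0] != n_volumes:
                    raise ValueError(f"{name} length must match the run")
                if np.any(~np.isfinite(col)):
                    raise ValueError(f"{name} contains missing values")
                cols.append(col)
        return np.column_stack(cols)


@dataclass
class CleanRun:
    """A temporally cleaned run plus its motion summary."""

    signal: np.ndarray  # (n_volumes, n_voxels), zero-mean voxel series
    fd: np.ndarray  # framewise displacement per volume (mm), fd[0] = 0
    tr_seconds: float
    seed_voxels: np.ndarray
    high_motion_fraction: float = 0.0


def compute_framewise_displacement(
    motion6: np.ndarray, head_radius: float = 50.0
) -> np.ndarray:
    """Framewise displacement: sum of absolute backward differences of the six
    rigid-body parameters, rotations converted to arc length on a sphere of
    ``head_radius`` mm.  The first volume has no predecessor and gets FD = 0.
    """
    motion = np.asarray(motion6, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def _drop_collinear(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Greedy left-to-right removal of linearly dependent design columns."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol * max(1.0, np.abs(trial).max())) == len(keep) + 1:
            keep.append(j)
        else:
            log.warning("dropping collinear nuisance column %d", j)
    return X[:, keep]


def regress_nuisance(run: BoldRun, confounds: ConfoundSet) -> CleanRun:
    """Replace every voxel series by its OLS residual against the confound
    design (trends + motion + tissue/global columns).

    Residuals are orthogonal to every retained design column; an all-constant
    voxel comes out identically zero (the intercept absorbs it).
    """
    Y = np.asarray(run.signal, dtype=float)
    X = confounds.design_matrix(Y.shape[0])
    X = _drop_collinear(X)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    fd = compute_framewise_displacement(
        np.asarray(confounds.motion6, dtype=float)
        if not confounds.rotations_in_degrees
        else np.column_stack(
            [
                np.asarray(confounds.motion6, dtype=float)[:, :3],
                np.deg2rad(np.asarray(confounds.motion6, dtype=float)[:, 3:]),
            ]
        )
    )
    return CleanRun(
        signal=resid,
        fd=fd,
        tr_seconds=run.tr_seconds,
        seed_voxels=run.seed_voxels,
    )


def dct_highpass_basis(n_volumes: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift regressors with frequencies below ``cutoff_hz``.

    Basis function k has frequency k / (2 * N * TR); all k with frequency
    strictly below the cutoff are returned (excluding the constant k = 0).
    """
    n_basis = int(np.floor(2.0 * n_volumes * tr_seconds * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def highpass_filter(
    run: CleanRun, cutoff_hz: float = 0.01, tr_seconds: float | None = None
) -> CleanRun:
    """High-pass filter by regressing out sub-cutoff discrete-cosine drifts.

    Chosen over recursive filters to avoid edge transients on short runs; the
    contract is spectral: sinusoids well below the cutoff are attenuated by
    >= 90 %, components well above it are preserved.
    """
    tr = run.tr_seconds if tr_seconds is None else tr_seconds
    if tr <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    Y = np.asarray(run.signal, dtype=float)
    X = dct_highpass_basis(Y.shape[0], tr, cutoff_hz)
    Y = Y - Y.mean(axis=0, keepdims=True)
    if X.shape[1]:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y = Y - X @ beta
    return CleanRun(
        signal=Y,
        fd=run.fd,
        tr_seconds=run.tr_seconds,
        seed_voxels=run.seed_voxels,
        high_motion_fraction=run.high_motion_fraction,
    )


def flag_high_motion_subject(
    fd: np.ndarray, fd_threshold: float = 0.5, max_fraction: float = 0.40
) -> bool:
    """True iff strictly more than ``max_fraction`` of volumes exceed the FD
    threshold (the subject-exclusion rule)."""
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD vector")
    if np.any(fd < 0):
        raise ValueError("FD must be non-negative")
    return float(np.mean(fd > fd_threshold)) > max_fraction


def clean_run(
    run: BoldRun,
    motion6: np.ndarray,
    use_gsr: bool = True,
    highpass_hz: float = 0.01,
    fd_threshold: float = 0.5,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> CleanRun:
    """Full temporal-cleaning chain in the fixed order: nuisance regression
    (trends, motion, tissue/global) -> high-pass filter."""
    gs = run.signal.mean(axis=1) if use_gsr else None
    confounds = ConfoundSet(
        motion6=motion6, wm_signal=wm_signal, csf_signal=csf_signal, global_signal=gs
    )
    cleaned = regress_nuisance(run, confounds)
    cleaned = highpass_filter(cleaned, cutoff_hz=highpass_hz)
    cleaned.high_motion_fraction = float(np.mean(cleaned.fd > fd_threshold))
    log.info(
        "cleaned run: %d volumes, %d voxels, high-motion fraction %.3f (order: "
        "detrend+nuisance -> high-pass)",
        cleaned.signal.shape[0],
        cleaned.signal.shape[1],
        cleaned.high_motion_fraction,
    )
    return cleaned
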