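"""The CAP engine: seed frame selection, PCA, consensus clustering, CAP map
construction, atlas overlap, and cross-group frame assignment.

A co-activation pattern (CAP) is a recurring whole-brain spatial map obtained
by clustering individual fMRI frames selected at moments of high seed
activity.  Frames from a reference population define the CAPs; frames from a
second population are assigned to them by spatial correlation against a
per-CAP 5th-percentile acceptance threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .preprocess import CleanRun

__all__ = [
    "NOT_RETAINED",
    "UNASSIGNED",
    "FrameSelection",
    "PcaModel",
    "ConsensusReport",
    "CapSet",
    "extract_seed_timecourse",
    "select_active_frames",
    "pca_reduce",
    "consensus_cluster",
    "cluster_caps",
    "build_cap_maps",
    "network_overlap",
    "match_frames_to_caps",
    "labels_to_volume_series",
    "match_caps_to_templates",
]

log = logging.getLogger(__name__)

#: volume-label code for frames dropped by thresholding/scrubbing
NOT_RETAINED = -1
#: volume-label code for retained frames not matching any CAP
UNASSIGNED = 0


@dataclass
class FrameSelection:
    """Outcome of seed-amplitude thresholding plus motion scrubbing."""

    retained_indices: np.ndarray  # sorted original volume indices
    seed_z: np.ndarray  # per-volume z-scored seed signal
    scrub_mask: np.ndarray  # per-volume boolean, True = scrubbed

    @property
    def n_retained(self) -> int:
        return int(self.retained_indices.size)


@dataclass
class PcaModel:
    """Orthonormal voxel-space basis retaining a target variance fraction."""

    components: np.ndarray  # (n_components, n_voxels)
    mean: np.ndarray  # (n_voxels,)
    explained_variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, frames: np.ndarray) -> np.ndarray:
        return (frames - self.mean) @ self.components.T

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        return reduced @ self.components + self.mean


@dataclass
class ConsensusReport:
    """Per-K consensus matrices and PAC values from consensus clustering."""

    k_candidates: list[int]
    consensus_matrices: dict[int, np.ndarray]
    pac: dict[int, float]
    k_optimal: int


@dataclass
class CapSet:
    """K spatially z-scored CAP maps with reference-frame memberships and
    per-CAP 5th-percentile assignment thresholds."""

    maps: np.ndarray  # (K, n_voxels), each row mean 0 / SD 1
    member_frames: list[np.ndarray]  # per CAP: indices into the reference frames
    match_thresholds: np.ndarray  # (K,) 5th percentile of member correlations
    pca: PcaModel | None = None
    seed_voxels: np.ndarray | None = None
    seed_mask_id: str = "seed"

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def extract_seed_timecourse(run: CleanRun, seed_voxels: np.ndarray | None = None) -> np.ndarray:
    """Mean signal over the seed voxels per volume, z-scored over time."""
    seed = run.seed_voxels if seed_voxels is None else np.asarray(seed_voxels)
    if seed is None or np.size(seed) == 0:
        raise ValueError("seed mask is empty")
    if np.max(seed) >= run.signal.shape[1]:
        raise ValueError("seed mask lies outside the brain mask")
    ts = run.signal[:, seed].mean(axis=1)
    sd = ts.std()
    if sd == 0:
        raise ValueError("seed time series has zero variance")
    return (ts - ts.mean()) / sd


def select_active_frames(
    seed_z: np.ndarray,
    fd: np.ndarray,
    z_threshold: float = 0.84,
    fd_threshold: float = 0.5,
) -> FrameSelection:
    """Retain high-seed-amplitude frames that survive motion scrubbing.

    A volume is scrubbed when its FD strictly exceeds ``fd_threshold`` or when
    an immediate (-1/+1) neighbour does; a volume is retained when its seed
    z-score strictly exceeds ``z_threshold`` and it is not scrubbed.
    """
    seed_z = np.asarray(seed_z, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if seed_z.shape != fd.shape:
        raise ValueError("seed_z and fd must have the same length")
    high = fd > fd_threshold
    scrub = high.copy()
    scrub[:-1] |= high[1:]
    scrub[1:] |= high[:-1]
    retained = np.nonzero((seed_z > z_threshold) & ~scrub)[0]
    return FrameSelection(retained_indices=retained, seed_z=seed_z, scrub_mask=scrub)


def pca_reduce(
    frames: np.ndarray, variance_target: float = 0.9
) -> tuple[PcaModel, np.ndarray]:
    """PCA on retained frames keeping the smallest component count whose
    cumulative explained variance reaches ``variance_target``."""
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must lie in (0, 1]")
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames for PCA")
    full = PCA(n_components=min(frames.shape), svd_solver="full").fit(frames)
    cum = np.cumsum(full.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, full.components_.shape[0])
    model = PcaModel(
        components=full.components_[:n_comp],
        mean=full.mean_,
        explained_variance_fractions=full.explained_variance_ratio_[:n_comp],
    )
    return model, model.transform(frames)


def pac_from_consensus(
    consensus: np.ndarray,
    lower: float = 0.1,
    upper: float = 0.9,
) -> float:
    """Proportion of ambiguously clustered pairs: off-diagonal pairs whose
    consensus index lies strictly inside (lower, upper).  Pairs never
    co-selected (NaN consensus) are excluded."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    defined = np.isfinite(vals)
    if not defined.any():
        return float("nan")
    v = vals[defined]
    return float(np.mean((v > lower) & (v < upper)))


def consensus_cluster(
    reduced: np.ndarray,
    k_range=(2, 3, 4, 5, 6),
    n_resamples: int = 100,
    subsample_fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
    pac_window: tuple[float, float] = (0.1, 0.9),
) -> ConsensusReport:
    """Consensus clustering over candidate K with the PAC criterion.

    For each K, the frames are repeatedly subsampled and k-means clustered;
    the consensus index of a pair is its co-assignment count divided by its
    co-selection count.  The optimal K minimizes PAC (ties -> smaller K).
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(reduced, dtype=float)
    n = X.shape[0]
    k_range = sorted(int(k) for k in k_range)
    if any(k < 2 for k in k_range):
        raise ValueError("candidate K must be >= 2")
    if any(k > n / 10 for k in k_range):
        raise ValueError("candidate K too large for the number of frames")
    m = int(np.floor(subsample_fraction * n))
    matrices: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    for k in k_range:
        together = np.zeros((n, n), dtype=np.float64)
        coselect = np.zeros((n, n), dtype=np.float64)
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            labels = KMeans(
                n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1))
            ).fit_predict(X[idx])
            coselect[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                mem = idx[labels == c]
                together[np.ix_(mem, mem)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = together / coselect
        never = coselect == 0
        if never[np.triu_indices(n, k=1)].any():
            log.warning("some frame pairs were never co-selected; excluded from PAC")
        consensus[never] = np.nan
        np.fill_diagonal(consensus, 1.0)
        matrices[k] = consensus
        pac[k] = pac_from_consensus(consensus, *pac_window)
    k_optimal = min(k_range, key=lambda k: (pac[k], k))
    return ConsensusReport(
        k_candidates=k_range, consensus_matrices=matrices, pac=pac, k_optimal=k_optimal
    )


def cluster_caps(
    reduced: np.ndarray,
    k: int,
    n_repeats: int = 50,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """K-means frame clustering, best of ``n_repeats`` random restarts.

    Returns labels 1..k renumbered by descending cluster size, so CAP 1 is the
    most frequent reference state.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(reduced, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] <= k:
        raise ValueError("need more frames than clusters")
    for attempt in range(5):
        km = KMeans(
            n_clusters=k, n_init=n_repeats, random_state=int(rng.integers(2**31 - 1))
        ).fit(X)
        sizes = np.bincount(km.labels_, minlength=k)
        if sizes.min() > 0:
            break
    else:  # pragma: no cover - scikit-learn relocates empty clusters
        raise RuntimeError("k-means produced an empty cluster in 5 attempts")
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[km.labels_]


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    return (M - mu) / sd


def _row_correlations(frames: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Pearson correlation of every frame (rows) with every map: (n, K)."""
    F = frames - frames.mean(axis=1, keepdims=True)
    M = maps - maps.mean(axis=1, keepdims=True)
    fn = np.linalg.norm(F, axis=1, keepdims=True)
    mn = np.linalg.norm(M, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (F @ M.T) / (fn * mn.T)


def build_cap_maps(
    frames: np.ndarray,
    labels: np.ndarray,
    pca: PcaModel,
    seed_voxels: np.ndarray | None = None,
    seed_mask_id: str = "seed",
) -> CapSet:
    """Construct spatially z-scored CAP maps and assignment thresholds.

    Each CAP map is the voxel-wise mean of its member frames after projecting
    through the PCA basis and back (reversing the dimensionality reduction),
    then z-scored across voxels.  The assignment threshold of CAP k is the 5th
    percentile of its member frames' spatial correlations with map k.
    """
    frames = np.asarray(frames, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != frames.shape[0]:
        raise ValueError("labels must cover all frames")
    caps = np.unique(labels)
    recon = pca.inverse_transform(pca.transform(frames))
    maps = []
    members: list[np.ndarray] = []
    for k in caps:
        idx = np.nonzero(labels == k)[0]
        if idx.size < 2:
            raise ValueError(f"CAP {k} has fewer than 2 member frames")
        maps.append(recon[idx].mean(axis=0))
        members.append(idx)
    maps = _zscore_rows(np.asarray(maps))
    exclude = None if seed_voxels is None else np.asarray(seed_voxels)
    thresholds = np.empty(len(members))
    for i, idx in enumerate(members):
        r = _pearson_excluding(frames[idx], maps[i][None, :], exclude)[:, 0]
        thresholds[i] = np.percentile(r, 5)
    return CapSet(
        maps=maps,
        member_frames=members,
        match_thresholds=thresholds,
        pca=pca,
        seed_voxels=exclude,
        seed_mask_id=seed_mask_id,
    )


def _pearson_excluding(
    frames: np.ndarray, maps: np.ndarray, exclude: np.ndarray | None
) -> np.ndarray:
    if exclude is not None and np.size(exclude):
        keep = np.setdiff1d(np.arange(frames.shape[1]), exclude)
        frames = frames[:, keep]
        maps = maps[:, keep]
    return _row_correlations(frames, maps)


def match_frames_to_caps(frames: np.ndarray, cap_set: CapSet) -> np.ndarray:
    """Assign target-group frames to CAPs by best spatial correlation.

    A frame gets the label of its best-correlating CAP if that correlation
    strictly exceeds the CAP's 5th-percentile reference threshold, otherwise
    :data:`UNASSIGNED`.  Correlations are computed over non-seed voxels.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[1] != cap_set.maps.shape[1]:
        raise ValueError("frames and CAP maps live in different voxel spaces")
    r = _pearson_excluding(frames, cap_set.maps, cap_set.seed_voxels)
    bad = ~np.isfinite(r).all(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance frames left unassigned")
        r[bad] = -np.inf
    best = np.argmax(r, axis=1)
    best_r = r[np.arange(r.shape[0]), best]
    labels = np.where(best_r > cap_set.match_thresholds[best], best + 1, UNASSIGNED)
    return labels.astype(int)


def labels_to_volume_series(
    n_volumes: int, selection: FrameSelection, frame_labels: np.ndarray
) -> np.ndarray:
    """Expand retained-frame labels to a per-original-volume label series.

    Non-retained volumes get :data:`NOT_RETAINED`; retained volumes carry the
    CAP label (1..K) or :data:`UNASSIGNED`.
    """
    if frame_labels.shape[0] != selection.n_retained:
        raise ValueError("one label per retained frame required")
    series = np.full(n_volumes, NOT_RETAINED, dtype=int)
    series[selection.retained_indices] = frame_labels
    return series


def network_overlap(
    cap_map: np.ndarray,
    atlas_labels: np.ndarray,
    z_cut: float,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-network percentages of supra-threshold voxels, split by tail.

    For the positive (negative) tail, voxels with map value > z_cut
    (< -z_cut) are counted per network and normalized to percentages summing
    to 100 within each non-empty tail.  Seed voxels can be excluded.
    """
    cap_map = np.asarray(cap_map, dtype=float)
    atlas = np.asarray(atlas_labels)
    if atlas.shape != cap_map.shape:
        raise ValueError("atlas must cover the map's voxels")
    keep = np.ones(cap_map.shape, dtype=bool)
    if exclude is not None and np.size(exclude):
        keep[np.asarray(exclude)] = False
    networks = np.unique(atlas[keep])
    rows = {}
    for tail, sel in (
        ("positive", (cap_map > z_cut) & keep),
        ("negative", (cap_map < -z_cut) & keep),
    ):
        counts = np.array([np.sum(sel & (atlas == nw)) for nw in networks], dtype=float)
        total = counts.sum()
        rows[tail] = counts / total * 100.0 if total > 0 else counts
    return pd.DataFrame(rows, index=pd.Index(networks, name="network"))


def match_caps_to_templates(
    cap_maps: np.ndarray, templates: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of recovered CAP maps to planted templates.

    Returns ``(template_index_per_cap, matched_correlations)`` maximizing the
    summed absolute spatial correlation.
    """
    r = _row_correlations(np.asarray(cap_maps), np.asarray(templates))
    ci, ti = linear_sum_assignment(-np.abs(r))
    order = np.argsort(ci)
    return ti[order], r[ci[order], ti[order]]
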