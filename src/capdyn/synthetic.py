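"""Synthetic resting-state cohort generator with known brain-state structure.

Emulates a two-group resting-state fMRI study (patients vs. controls) in which
recurring whole-brain co-(de)activation templates are gated by a hidden Markov
state sequence, the seed region carries extra amplitude whenever any state is
active, head motion follows a smooth random walk with occasional spikes, and a
behaviour/covariate table is latently coupled to the planted state dynamics in
the patient group only.  Every downstream stage of the CAP pipeline can be
validated against the returned :class:`GroundTruth`.

The generator works on "parcel-like" voxel vectors (default ~2000 voxels)
rather than full acquisition grids; a cubic NIfTI export is provided for
interoperability.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "BoldRun",
    "SubjectRecord",
    "Cohort",
    "default_transition_matrix",
    "stationary_distribution",
    "simulate_state_sequence",
    "render_bold_run",
    "simulate_motion",
    "simulate_behaviour_table",
    "simulate_cohort",
    "iter_subjects",
    "make_network_atlas",
    "write_cohort",
]

#: sampling times of the five morning cortisol samples, minutes after awakening
CORTISOL_TIMES = (0.0, 15.0, 30.0, 45.0, 60.0)

#: rise-and-fall template of the cortisol awakening response, one value per
#: sample; only its area matters downstream (trapezoid minus baseline = 36).
_CORTISOL_BUMP = np.array([0.0, 0.5, 1.0, 0.7, 0.4])
_CORTISOL_BUMP_AUC = float(
    np.trapezoid(_CORTISOL_BUMP, CORTISOL_TIMES)
    - _CORTISOL_BUMP[0] * (CORTISOL_TIMES[-1] - CORTISOL_TIMES[0])
)

# Group-specific behaviour means/SDs (patients, controls) for the scalar
# questionnaire and biomarker columns.
_BEHAVIOUR_SCALE = {
    "pss": ((24.5, 8.1), (12.7, 4.5)),
    "ctq_total": ((50.6, 21.0), (35.2, 10.9)),
    "alpha_amylase": ((168.0, 90.4), (197.0, 179.0)),
    "mood_score": ((71.8, 19.0), (38.4, 10.0)),
    "wpi": ((8.7, 3.9), (np.nan, np.nan)),
    "bpi_severity": ((4.6, 1.7), (np.nan, np.nan)),
    "bpi_interference": ((5.6, 2.0), (np.nan, np.nan)),
    "peg_algometry": ((4.79, 2.04), (3.06, 1.29)),
}
# cortisol-bump amplitude scale so that AUC_I has the group means/SDs above
_CAR_AUCI_SCALE = ((105.0, 104.0), (47.7, 93.2))


def default_transition_matrix(group: str, n_states: int = 3) -> np.ndarray:
    """Row-stochastic (K+1)x(K+1) transition matrix over {baseline, state 1..K}.

    Patients enter state 1 less often and state 2 more often than controls,
    which is the planted group difference recovered by the group-contrast
    models downstream.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if group not in ("control", "patient"):
        raise ValueError(f"unknown group {group!r}")
    K = n_states
    # baseline row: stay 0.80, remaining 0.20 split over states; the canonical
    # K=3 design plants the group manipulation on states 1 and 2
    if K == 3:
        entries = np.array([0.09, 0.06, 0.05]) if group == "control" else np.array([0.05, 0.10, 0.05])
    else:
        entries = np.full(K, 0.20 / K)
        if group == "patient" and K >= 2:
            shift = 0.4 * entries[0]
            entries[0] -= shift
            entries[1] += shift
    P = np.zeros((K + 1, K + 1))
    P[0, 0] = 1.0 - entries.sum()
    P[0, 1:] = entries
    # state rows: dwell 0.55, small cross-talk, remainder back to baseline
    cross = 0.05 / max(K - 1, 1) if K > 1 else 0.0
    for k in range(1, K + 1):
        P[k, 1:] = cross
        P[k, k] = 0.55
        P[k, 0] = 1.0 - P[k, 1:].sum()
    return P


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition-matrix rows must sum to 1")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = _check_stochastic(P)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class CohortSpec:
    """Parameters of one synthetic two-group resting-state study.

    ``snr`` is the ratio of per-voxel template amplitude to the noise standard
    deviation; templates are rendered at per-voxel RMS 1, so noise SD = 1/snr.
    ``behaviour_link`` is the planted correlation between the latent subject
    score and the designated stress columns (patients only).
    ``dynamics_gain`` scales how strongly the latent score modulates patients'
    entry probabilities into states 1 (down) and 2 (up).
    """

    n_per_group: int = 30
    n_volumes: int = 300
    tr_seconds: float = 1.3
    n_voxels: int = 2000
    n_states: int = 3
    snr: float = 2.0
    seed_gain: float = 1.0
    motion_spike_rate: float = 0.02
    behaviour_link: float = 0.5
    dynamics_gain: float = 0.35
    n_seed_voxels: int = 30
    drift_amplitude: float = 0.3
    walk_sd_mm: float = 0.02
    walk_sd_rad: float = 2e-4
    transition_control: np.ndarray | None = None
    transition_patient: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 10:
            raise ValueError("n_volumes must be >= 10")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if not (0.0 <= self.motion_spike_rate <= 1.0):
            raise ValueError("motion_spike_rate must be a probability")
        if self.n_seed_voxels < 1 or self.n_seed_voxels > self.n_voxels:
            raise ValueError("n_seed_voxels must be in [1, n_voxels]")
        if self.transition_control is None:
            self.transition_control = default_transition_matrix("control", self.n_states)
        if self.transition_patient is None:
            self.transition_patient = default_transition_matrix("patient", self.n_states)
        for P in (self.transition_control, self.transition_patient):
            Q = _check_stochastic(P)
            if Q.shape[0] != self.n_states + 1:
                raise ValueError("transition matrices must be (K+1) x (K+1)")

    def transition_matrix(self, group: str) -> np.ndarray:
        if group == "control":
            return np.asarray(self.transition_control, dtype=float)
        if group == "patient":
            return np.asarray(self.transition_patient, dtype=float)
        raise ValueError(f"unknown group {group!r}")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for recovery tests."""

    templates: np.ndarray  # (K, n_voxels), unit-norm rows
    state_sequences: dict[str, np.ndarray]  # subject -> (n_volumes,) labels 0..K
    fd_true: dict[str, np.ndarray]  # subject -> planted FD (mm)
    spike_mask: dict[str, np.ndarray]  # subject -> planted spike indicator
    latent_scores: dict[str, float]  # subject -> latent scalar
    transition_matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        K = self.templates.shape[0]
        for i in range(K):
            for j in range(i + 1, K):
                r = np.corrcoef(self.templates[i], self.templates[j])[0, 1]
                if abs(r) >= 0.5:
                    raise ValueError("templates are not mutually distinguishable")


@dataclass
class BoldRun:
    """One subject's time x voxel signal with acquisition metadata."""

    signal: np.ndarray  # (n_volumes, n_voxels)
    tr_seconds: float
    seed_voxels: np.ndarray  # voxel indices forming the seed region
    mask: np.ndarray | None = None  # optional voxel coordinate bookkeeping

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[1]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    bold: BoldRun
    motion_params: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad
    behaviour_row: pd.Series


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectRecord]
    behaviour: pd.DataFrame
    ground_truth: GroundTruth


def simulate_state_sequence(
    transition_matrix: np.ndarray,
    n_volumes: int,
    rng: np.random.Generator,
    initial: int | None = None,
) -> np.ndarray:
    """Sample a first-order Markov label sequence over {0..K}.

    The first label is drawn from the stationary distribution unless
    ``initial`` forces a start state.
    """
    P = _check_stochastic(transition_matrix)
    cum = np.cumsum(P, axis=1)
    labels = np.empty(n_volumes, dtype=np.int64)
    if initial is None:
        pi = stationary_distribution(P)
        labels[0] = rng.choice(len(pi), p=pi)
    else:
        labels[0] = int(initial)
    u = rng.random(n_volumes)
    for t in range(1, n_volumes):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t])
    return labels


def _make_templates(n_states: int, n_voxels: int, rng: np.random.Generator) -> np.ndarray:
    T = rng.standard_normal((n_states, n_voxels))
    T -= T.mean(axis=1, keepdims=True)
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    return T


def render_bold_run(
    templates: np.ndarray,
    states: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> BoldRun:
    """Render one BOLD run from a planted state sequence.

    signal(t) = active template (per-voxel RMS 1) + seed_gain on seed voxels
    during active states + linear/quadratic voxel-wise drift + Gaussian noise
    with SD 1/snr.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape[1] != spec.n_voxels:
        raise ValueError("templates are not defined over spec.n_voxels voxels")
    T, V = spec.n_volumes, spec.n_voxels
    states = np.asarray(states)
    if states.shape[0] != T:
        raise ValueError("state sequence length must equal n_volumes")
    amp = np.sqrt(V)  # unit-norm template -> per-voxel RMS 1
    Y = np.zeros((T, V))
    active = states > 0
    if active.any():
        Y[active] = templates[states[active] - 1] * amp
    seed_voxels = np.arange(spec.n_seed_voxels)
    Y[:, seed_voxels] += spec.seed_gain * active[:, None]
    # slow scanner drifts, per-voxel random linear + quadratic coefficients
    t = np.linspace(-1.0, 1.0, T)
    basis = np.stack([t, t * t - np.mean(t * t)])
    coef = rng.normal(0.0, spec.drift_amplitude, size=(2, V))
    Y += basis.T @ coef
    Y += rng.standard_normal((T, V)) / spec.snr
    return BoldRun(signal=Y, tr_seconds=spec.tr_seconds, seed_voxels=seed_voxels)


def _fd_power(motion: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def simulate_motion(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth random-walk motion parameters with step-change spikes.

    Returns ``(motion, fd_true, spike_mask)``.  Spikes are sustained offsets of
    a random translation axis, sized so the framewise displacement at each
    spiked volume exceeds 0.5 mm.
    """
    T = spec.n_volumes
    if T < 2:
        raise ValueError("need at least 2 volumes")
    steps = np.concatenate(
        [
            rng.normal(0.0, spec.walk_sd_mm, size=(T, 3)),
            rng.normal(0.0, spec.walk_sd_rad, size=(T, 3)),
        ],
        axis=1,
    )
    steps[0] = 0.0
    spikes = np.zeros(T, dtype=bool)
    spikes[1:] = rng.random(T - 1) < spec.motion_spike_rate
    axes = rng.integers(0, 3, size=T)
    signs = rng.choice([-1.0, 1.0], size=T)
    for t in np.nonzero(spikes)[0]:
        steps[t, axes[t]] += signs[t] * 0.6
    motion = np.cumsum(steps, axis=0)
    fd = _fd_power(motion)
    # guarantee FD > 0.5 at spiked volumes even if the walk opposes the step
    for t in np.nonzero(spikes)[0]:
        while fd[t] <= 0.5:
            motion[t:, axes[t]] += signs[t] * 0.2
            fd = _fd_power(motion)
    return motion, fd, spikes


def _linked_column(
    latent: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized column correlating with ``latent`` at population r."""
    noise = rng.standard_normal(latent.shape[0])
    return r * latent + np.sqrt(max(0.0, 1.0 - r * r)) * noise


def simulate_behaviour_table(
    subject_ids: list[str],
    groups: list[str],
    latent_scores: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Behaviour/covariate table with a planted stress link in patients only.

    The designated stress columns (perceived stress, and the cortisol-bump
    amplitude behind CAR AUC_I) equal ``behaviour_link * latent + noise`` in the
    patient group and pure noise in controls.  Childhood trauma and
    alpha-amylase get group-specific means but no latent link, matching a
    stress battery in which only part of the measures track current HPA-axis
    load.  Covariates (age, sex, medication, mood) are independent draws.
    """
    n = len(subject_ids)
    latent = np.asarray(latent_scores, dtype=float)
    is_pat = np.array([g == "patient" for g in groups])
    r = spec.behaviour_link

    def scaled(name: str, z: np.ndarray) -> np.ndarray:
        (mu_p, sd_p), (mu_c, sd_c) = _BEHAVIOUR_SCALE[name]
        out = np.where(is_pat, mu_p + sd_p * z, mu_c + sd_c * z)
        return out

    z_pss = np.where(is_pat, _linked_column(latent, r, rng), rng.standard_normal(n))
    z_ctq = rng.standard_normal(n)
    z_amy = rng.standard_normal(n)
    z_mood = rng.standard_normal(n)
    z_cort = np.where(is_pat, _linked_column(latent, r, rng), rng.standard_normal(n))

    (a_mu_p, a_sd_p), (a_mu_c, a_sd_c) = _CAR_AUCI_SCALE
    auci_target = np.where(is_pat, a_mu_p + a_sd_p * z_cort, a_mu_c + a_sd_c * z_cort)
    bump_amp = auci_target / _CORTISOL_BUMP_AUC
    baseline = np.clip(rng.normal(9.0, 3.0, size=n), 0.5, None)
    cort = baseline[:, None] + bump_amp[:, None] * _CORTISOL_BUMP[None, :]
    cort = cort + rng.normal(0.0, 0.05, size=cort.shape)

    table = pd.DataFrame(
        {
            "subject": subject_ids,
            "group": groups,
            "age": np.clip(np.round(rng.normal(41.0, 12.5, size=n)), 18, 70).astype(int),
            "sex": rng.permuted(np.where(np.arange(n) % 5 == 0, "M", "F")),
            "psychotropic_medication": np.where(
                is_pat, rng.random(n) < 16 / 30, rng.random(n) < 1 / 30
            ).astype(int),
            "non_opioid_analgesics": np.where(
                is_pat, rng.random(n) < 6 / 30, 0.0
            ).astype(int),
            "contraceptive_use": (rng.random(n) < 0.25).astype(int),
            "smoking": np.where(is_pat, rng.random(n) < 9 / 30, rng.random(n) < 1 / 30).astype(int),
            "mood_score": scaled("mood_score", z_mood),
            "pss": scaled("pss", z_pss),
            "ctq_total": scaled("ctq_total", z_ctq),
            "alpha_amylase": np.clip(scaled("alpha_amylase", z_amy), 5.0, None),
            "wpi": scaled("wpi", rng.standard_normal(n)),
            "bpi_severity": scaled("bpi_severity", rng.standard_normal(n)),
            "bpi_interference": scaled("bpi_interference", rng.standard_normal(n)),
            "peg_algometry": np.clip(scaled("peg_algometry", rng.standard_normal(n)), 0, 10),
        }
    )
    for i, minutes in enumerate(CORTISOL_TIMES):
        table[f"cortisol_{int(minutes)}"] = cort[:, i]
    return table


def _subject_transition(
    spec: CohortSpec, group: str, latent: float
) -> np.ndarray:
    """Per-subject transition matrix; patients' entries are latent-modulated."""
    P = spec.transition_matrix(group).copy()
    if group != "patient" or spec.dynamics_gain == 0.0 or spec.n_states < 2:
        return P
    s = float(np.clip(latent, -2.0, 2.0))
    g = spec.dynamics_gain
    row = P[0].copy()
    row[1] = np.clip(P[0, 1] * (1.0 - g * s), 1e-4, 0.9)
    row[2] = np.clip(P[0, 2] * (1.0 + g * s), 1e-4, 0.9)
    row[0] = 1.0 - row[1:].sum()
    if row[0] <= 0:
        raise ValueError("dynamics_gain too large for the baseline row")
    P[0] = row
    return P


def _seed_streams(spec: CohortSpec) -> tuple[np.random.Generator, np.random.Generator, list]:
    ss = np.random.SeedSequence(spec.seed)
    kids = ss.spawn(3)
    cohort_rng = np.random.default_rng(kids[0])
    behav_rng = np.random.default_rng(kids[1])
    subj_seeds = kids[2].spawn(2 * spec.n_per_group)
    return cohort_rng, behav_rng, subj_seeds


def _roster(spec: CohortSpec) -> tuple[list[str], list[str]]:
    ids = [f"sub-{i + 1:03d}" for i in range(2 * spec.n_per_group)]
    groups = ["control"] * spec.n_per_group + ["patient"] * spec.n_per_group
    return ids, groups


def iter_subjects(spec: CohortSpec):
    """Yield ``(SubjectRecord, state_sequence)`` one subject at a time.

    Streaming counterpart of :func:`simulate_cohort`: the full cohort's BOLD
    runs are never held in memory together.  The behaviour table and ground
    truth are deterministic given the spec, so the two entry points generate
    identical cohorts for identical specs.
    """
    cohort_rng, behav_rng, subj_seeds = _seed_streams(spec)
    templates = _make_templates(spec.n_states, spec.n_voxels, cohort_rng)
    ids, groups = _roster(spec)
    latents = behav_rng.standard_normal(len(ids))
    behaviour = simulate_behaviour_table(ids, groups, latents, spec, behav_rng)
    for i, (sid, group) in enumerate(zip(ids, groups)):
        rng = np.random.default_rng(subj_seeds[i])
        P = _subject_transition(spec, group, latents[i])
        states = simulate_state_sequence(P, spec.n_volumes, rng)
        bold = render_bold_run(templates, states, spec, rng)
        motion, fd, spikes = simulate_motion(spec, rng)
        rec = SubjectRecord(
            subject_id=sid,
            group=group,
            bold=bold,
            motion_params=motion,
            behaviour_row=behaviour.iloc[i],
        )
        yield rec, {
            "states": states,
            "fd_true": fd,
            "spikes": spikes,
            "latent": float(latents[i]),
            "templates": templates,
            "behaviour": behaviour,
            "transition": P,
        }


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort (subjects, behaviour table, ground truth)."""
    subjects: list[SubjectRecord] = []
    state_sequences: dict[str, np.ndarray] = {}
    fd_true: dict[str, np.ndarray] = {}
    spike_mask: dict[str, np.ndarray] = {}
    latent_scores: dict[str, float] = {}
    transitions: dict[str, np.ndarray] = {}
    templates = None
    behaviour = None
    for rec, truth in iter_subjects(spec):
        subjects.append(rec)
        state_sequences[rec.subject_id] = truth["states"]
        fd_true[rec.subject_id] = truth["fd_true"]
        spike_mask[rec.subject_id] = truth["spikes"]
        latent_scores[rec.subject_id] = truth["latent"]
        transitions[rec.subject_id] = truth["transition"]
        templates = truth["templates"]
        behaviour = truth["behaviour"]
    gt = GroundTruth(
        templates=templates,
        state_sequences=state_sequences,
        fd_true=fd_true,
        spike_mask=spike_mask,
        latent_scores=latent_scores,
        transition_matrices=transitions,
    )
    gt.validate()
    return Cohort(spec=spec, subjects=subjects, behaviour=behaviour, ground_truth=gt)


def make_network_atlas(
    n_voxels: int, n_networks: int = 17, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Integer atlas assigning each voxel to one of ``n_networks`` labels 1..N.

    Contiguous blocks of roughly equal size, mimicking a parcel-level network
    parcellation used for CAP topography summaries.
    """
    edges = np.linspace(0, n_voxels, n_networks + 1).astype(int)
    atlas = np.zeros(n_voxels, dtype=int)
    for k in range(n_networks):
        atlas[edges[k] : edges[k + 1]] = k + 1
    return atlas


# ---------------------------------------------------------------------------
# file export


def _cube_shape(n_voxels: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    return (side, side, int(np.ceil(n_voxels / side**2)))


def write_nifti_run(path: str, bold: BoldRun) -> None:
    """Pack a voxel-vector run into a padded cubic 4D NIfTI volume."""
    import nibabel as nib

    shape = _cube_shape(bold.n_voxels)
    vol = np.zeros((*shape, bold.n_volumes), dtype=np.float32)
    flat = vol.reshape(-1, bold.n_volumes)
    flat[: bold.n_voxels] = bold.signal.T
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, bold.tr_seconds))
    nib.save(img, path)


def write_cohort(cohort: Cohort, out_dir: str, nifti: bool = False) -> None:
    """Write a cohort to disk: one BOLD file + motion table per subject, a
    behaviour CSV, and a ground-truth JSON bundle."""
    os.makedirs(out_dir, exist_ok=True)
    for rec in cohort.subjects:
        if nifti:
            write_nifti_run(os.path.join(out_dir, f"{rec.subject_id}_bold.nii.gz"), rec.bold)
        else:
            np.savez_compressed(
                os.path.join(out_dir, f"{rec.subject_id}_bold.npz"),
                signal=rec.bold.signal.astype(np.float32),
                tr_seconds=rec.bold.tr_seconds,
                seed_voxels=rec.bold.seed_voxels,
            )
        np.savetxt(
            os.path.join(out_dir, f"rp_{rec.subject_id}.txt"),
            rec.motion_params,
            fmt="%.8e",
        )
    cohort.behaviour.to_csv(os.path.join(out_dir, "behaviour.csv"), index=False)
    gt = cohort.ground_truth
    bundle = {
        "spec": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(cohort.spec).items()
        },
        "templates": gt.templates.tolist(),
        "state_sequences": {k: v.tolist() for k, v in gt.state_sequences.items()},
        "fd_true": {k: v.tolist() for k, v in gt.fd_true.items()},
        "spike_mask": {k: v.astype(int).tolist() for k, v in gt.spike_mask.items()},
        "latent_scores": gt.latent_scores,
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(bundle, fh)
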