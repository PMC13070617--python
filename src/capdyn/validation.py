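"""Recovery and calibration studies on synthetic cohorts.

Each function regenerates its own inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantity: threshold calibration,
cluster-number selection, CAP map recovery, frame-assignment accuracy,
occupancy recovery, group-contrast calibration and power, and PLSC
calibration and power.  These are the package's built-in checks that the
method recovers what the generator plants; problem sizes are scaled for a
desktop run and stated in the methods documentation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import caps as cap_ops
from . import metrics as metric_ops
from . import stats as stat_ops
from . import synthetic as synth
from .metrics import StateLabelSeries
from .pipeline import RunConfig, run_end_to_end
from .synthetic import CohortSpec

__all__ = [
    "retained_fraction_calibration",
    "consensus_k_selection_rate",
    "cohort_recovery",
    "occupancy_recovery_error",
    "null_contrast_rejection_rate",
    "contrast_sign_recovery_rate",
    "plsc_type_one_rate",
    "plsc_power",
    "plsc_end_to_end_power",
    "plsc_perfect_p",
    "determinism_check",
]


def retained_fraction_calibration(
    seed: int, n_subjects: int = 100, n_volumes: int = 300
) -> tuple[float, float, int]:
    """Retained-frame fraction for standard-normal seed series, no motion.

    Returns ``(fraction, analytic, n)`` where analytic = 1 - Phi(0.84).
    """
    rng = np.random.default_rng(seed)
    retained = 0
    total = n_subjects * n_volumes
    fd = np.zeros(n_volumes)
    for _ in range(n_subjects):
        z = rng.standard_normal(n_volumes)
        retained += cap_ops.select_active_frames(z, fd).n_retained
    return retained / total, float(1.0 - norm.cdf(0.84)), total


def _mini_cohort_frames(spec: CohortSpec, groups=("control",)) -> np.ndarray:
    """Pooled retained reference frames of a synthetic cohort."""
    from . import preprocess as prep

    frames = []
    for rec, _ in synth.iter_subjects(spec):
        if rec.group not in groups:
            continue
        clean = prep.clean_run(rec.bold, rec.motion_params)
        seed_z = cap_ops.extract_seed_timecourse(clean)
        sel = cap_ops.select_active_frames(seed_z, clean.fd)
        frames.append(clean.signal[sel.retained_indices])
    return np.concatenate(frames, axis=0)


def consensus_k_selection_rate(
    seed: int,
    n_repeats: int = 20,
    k_true: int = 3,
    k_range=(2, 3, 4, 5),
    n_subjects: int = 12,
    n_voxels: int = 400,
    n_resamples: int = 100,
) -> tuple[float, int]:
    """Fraction of seeded repeats in which PAC picks the planted K.

    Each repeat simulates a reference group with ``k_true`` planted templates,
    selects seed-active frames, reduces them by PCA, and runs consensus
    clustering over ``k_range``.  The seed region is sized at 2 % of the
    (reduced) voxel grid, matching the seed-to-brain proportion of the default
    cohort, so global-signal regression does not swallow the seed signal.
    """
    ss = np.random.SeedSequence(seed).spawn(n_repeats)
    hits = 0
    for rep in range(n_repeats):
        child = ss[rep].generate_state(1)[0] % (2**31 - 1)
        spec = CohortSpec(
            n_per_group=n_subjects,
            n_voxels=n_voxels,
            n_states=k_true,
            n_seed_voxels=max(4, round(0.02 * n_voxels)),
            seed=int(child),
        )
        frames = _mini_cohort_frames(spec)
        _, reduced = cap_ops.pca_reduce(frames)
        report = cap_ops.consensus_cluster(
            reduced, k_range, n_resamples=n_resamples, rng=np.random.default_rng(child)
        )
        hits += report.k_optimal == k_true
    return hits / n_repeats, n_repeats


def cohort_recovery(seed: int, config: RunConfig | None = None):
    """Run the full pipeline on the default 30+30 cohort and score recovery.

    Returns a dict with the minimum Hungarian-matched CAP-template spatial
    correlation, the patient frame-assignment accuracy against planted state
    labels (confusion-matrix accuracy over retained, truly state-active
    frames that the rule assigns; the unassigned fraction — the rule's
    designed rejection plus its out-of-sample shift — is reported
    separately), the maximum per-CAP error between mean relative occurrence
    and the planted seed-conditional occupancy, the reference re-matching
    self-consistency, and the study result itself.
    """
    if config is None:
        config = RunConfig(
            cohort=CohortSpec(seed=seed),
            k=3,
            n_permutations=200,
            n_boot=100,
            seed=seed,
        )
    result = run_end_to_end(config)
    gt = result.ground_truth
    template_idx, match_r = cap_ops.match_caps_to_templates(
        result.cap_set.maps, gt.templates
    )
    # cap label c (1..K) corresponds to planted state template_idx[c-1] + 1
    state_of_cap = {c + 1: int(template_idx[c]) + 1 for c in range(result.cap_set.k)}

    correct = 0
    assigned = 0
    total = 0
    for s in result.series:
        if s.group != "patient":
            continue
        true_states = gt.state_sequences[s.subject_id]
        retained = s.volume_labels != cap_ops.NOT_RETAINED
        active = retained & (true_states > 0)
        total += int(active.sum())
        pred = s.volume_labels[active]
        truth = true_states[active]
        decided = pred != cap_ops.UNASSIGNED
        assigned += int(decided.sum())
        mapped = np.array([state_of_cap.get(p, -9) for p in pred[decided]])
        correct += int(np.sum(mapped == truth[decided]))
    accuracy = correct / assigned if assigned else float("nan")
    unassigned_rate = 1.0 - assigned / total if total else float("nan")

    # occupancy recovery: mean relative occurrence per CAP vs planted
    # seed-conditional occupancy (fraction of retained frames truly in the
    # CAP's matched state), averaged over all subjects
    occ = result.metrics[result.metrics["metric"] == "occurrence"]
    errs = []
    for cap_label in range(1, result.cap_set.k + 1):
        measured = occ[occ["cap"] == cap_label]["value"].mean()
        planted = []
        for s in result.series:
            true_states = gt.state_sequences[s.subject_id]
            retained = s.volume_labels != cap_ops.NOT_RETAINED
            n_ret = int(retained.sum())
            planted.append(
                np.sum(true_states[retained] == state_of_cap[cap_label]) / n_ret
            )
        errs.append(abs(measured - float(np.mean(planted))))
    rematched = cap_ops.match_frames_to_caps(result.reference_frames, result.cap_set)
    self_consistency = float(np.mean(rematched == result.reference_labels))
    flips = float(
        np.mean((rematched != result.reference_labels) & (rematched != cap_ops.UNASSIGNED))
    )

    return {
        "min_template_r": float(np.min(np.abs(match_r))),
        "assignment_accuracy": float(accuracy),
        "assignment_unassigned_rate": float(unassigned_rate),
        "n_scored_frames": int(assigned),
        "max_occupancy_error": float(np.max(errs)),
        "reference_self_consistency": self_consistency,
        "reference_flip_rate": flips,
        "result": result,
    }


def occupancy_recovery_error(seed: int) -> tuple[float, int]:
    rec = cohort_recovery(seed)
    return rec["max_occupancy_error"], rec["n_scored_frames"]


# ---------------------------------------------------------------------------
# group-contrast calibration


def _metrics_from_sequences(
    spec: CohortSpec, rng: np.random.Generator, null: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric and design tables from planted label sequences directly.

    Bypasses the imaging stages: state-active volumes count as retained with
    their planted label, isolating the statistical model from the frame
    selection (which has its own calibration checks).  Under ``null`` both
    groups use the control transition matrix.
    """
    ids = [f"sub-{i:03d}" for i in range(2 * spec.n_per_group)]
    groups = ["control"] * spec.n_per_group + ["patient"] * spec.n_per_group
    latents = rng.standard_normal(len(ids))
    series = []
    for sid, grp, lat in zip(ids, groups, latents):
        if null:
            P = spec.transition_matrix("control")
        else:
            P = synth._subject_transition(spec, grp, lat)
        states = synth.simulate_state_sequence(P, spec.n_volumes, rng)
        labels = np.where(states > 0, states, metric_ops.NOT_RETAINED)
        if not (labels != metric_ops.NOT_RETAINED).any():
            labels[0] = 1  # degenerate guard: keep n_retained > 0
        series.append(
            StateLabelSeries(sid, labels, spec.tr_seconds, group=grp)
        )
    metrics = metric_ops.metrics_table(series, spec.n_states)
    behav = synth.simulate_behaviour_table(ids, groups, latents, spec, rng)
    behav["n_retained"] = behav["subject"].map(
        {s.subject_id: s.n_retained for s in series}
    )
    return metrics, behav


def null_contrast_rejection_rate(
    seed: int,
    n_sims: int = 500,
    n_per_group: int = 20,
    n_volumes: int = 300,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Type-I rate of the per-state group contrasts under null cohorts."""
    rng = np.random.default_rng(seed)
    spec = CohortSpec(n_per_group=n_per_group, n_volumes=n_volumes, seed=seed)
    rejections = 0
    total = 0
    for _ in range(n_sims):
        metrics, design = _metrics_from_sequences(spec, rng, null=True)
        table = stat_ops.fit_group_state_model(metrics, design, "entries")
        rejections += int(np.sum(table["p"] < alpha))
        total += len(table)
    return rejections / total, total


def contrast_sign_recovery_rate(
    seed: int, n_replicates: int = 20, n_per_group: int = 30
) -> tuple[float, int]:
    """Fraction of replicate cohorts recovering the planted entry-rate sign.

    Patients are planted to enter state 1 less often, so the control-minus-
    patient contrast at state 1 should be positive.
    """
    rng = np.random.default_rng(seed)
    spec = CohortSpec(n_per_group=n_per_group, seed=seed)
    hits = 0
    for _ in range(n_replicates):
        metrics, design = _metrics_from_sequences(spec, rng, null=False)
        table = stat_ops.fit_group_state_model(metrics, design, "entries")
        est = table.loc[table["cap"] == 1, "estimate"].iloc[0]
        hits += est > 0
    return hits / n_replicates, n_replicates


# ---------------------------------------------------------------------------
# PLSC calibration


def plsc_type_one_rate(
    seed: int,
    n_sims: int = 1000,
    n_permutations: int = 200,
    n_patients: int = 27,
    n_controls: int = 30,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Rejection rate of the first PLSC component under independence."""
    groups = np.array(["patient"] * n_patients + ["control"] * n_controls)
    rej = 0
    ss = np.random.SeedSequence(seed).spawn(n_sims)
    for child in ss:
        r = np.random.default_rng(child)
        X = r.standard_normal((groups.size, 4))
        Y = r.standard_normal((groups.size, 4))
        p = stat_ops.plsc_permutation_test(X, Y, groups, n_permutations, r)
        rej += p[0] < alpha
    return rej / n_sims, n_sims


def plsc_power(
    seed: int,
    n_replicates: int = 20,
    n_permutations: int = 200,
    n_patients: int = 27,
    n_controls: int = 30,
    r_link: float = 0.5,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Power to detect a planted patient-only behaviour-brain link.

    In patients, every behaviour and brain column loads on a shared latent
    factor with loading sqrt(r_link), so each cross-block pair correlates at
    ``r_link``; controls are independent noise.  Group sizes mirror the
    unbalanced study (27 patients with complete stress data, 30 controls).
    """
    lam = np.sqrt(r_link)
    groups = np.array(["patient"] * n_patients + ["control"] * n_controls)
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    hits = 0
    for child in ss:
        rng = np.random.default_rng(child)
        s = rng.standard_normal(n_patients)
        X = rng.standard_normal((groups.size, 4))
        Y = rng.standard_normal((groups.size, 4))
        X[:n_patients] = lam * s[:, None] + np.sqrt(1 - r_link) * X[:n_patients]
        Y[:n_patients] = lam * s[:, None] + np.sqrt(1 - r_link) * Y[:n_patients]
        p = stat_ops.plsc_permutation_test(X, Y, groups, n_permutations, rng)
        hits += p[0] < alpha
    return hits / n_replicates, n_replicates


def plsc_end_to_end_power(
    seed: int,
    n_replicates: int = 20,
    n_permutations: int = 200,
    n_patients: int = 27,
    n_controls: int = 30,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Power when the stress link is mediated by the planted dynamics.

    Brain features are entries/occurrence of states 1 and 2 computed from
    planted label sequences with latent-modulated patient dynamics; behaviour
    columns carry the r = 0.5 latent link in patients only.  The effective
    behaviour-brain correlation is the product of the behaviour link and the
    latent-to-metric correlation (~0.3 at the default dynamics gain), so this
    is a strictly harder detection problem than :func:`plsc_power`.
    """
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    hits = 0
    for child in ss:
        rng = np.random.default_rng(child)
        spec = CohortSpec(
            n_per_group=max(n_patients, n_controls),
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        metrics, behav = _metrics_from_sequences(spec, rng, null=False)
        wide = metrics.pivot_table(index="subject", columns=["metric", "cap"], values="value")
        feats = np.column_stack(
            [wide[("entries", 1)], wide[("entries", 2)],
             wide[("occurrence", 1)], wide[("occurrence", 2)]]
        )
        behav = behav.set_index("subject").loc[wide.index]
        # trim to the paper-sized unbalanced groups
        keep = np.concatenate(
            [np.nonzero(behav["group"].values == "control")[0][:n_controls],
             np.nonzero(behav["group"].values == "patient")[0][:n_patients]]
        )
        X = behav[["pss", "ctq_total", "alpha_amylase"]].copy()
        X["car_auci"] = [
            stat_ops.auc_increase(row[[f"cortisol_{int(m)}" for m in synth.CORTISOL_TIMES]].values)
            for _, row in behav.iterrows()
        ]
        p = stat_ops.plsc_permutation_test(
            X.values[keep], feats[keep], behav["group"].values[keep],
            n_permutations, rng,
        )
        hits += p[0] < alpha
    return hits / n_replicates, n_replicates


def plsc_perfect_p(seed: int, n_permutations: int = 200) -> tuple[float, int]:
    """Permutation p for a perfectly correlated behaviour/brain pair."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(40)
    p = stat_ops.plsc_permutation_test(z, z, ["g"] * 40, n_permutations, rng)
    return float(p[0]), n_permutations


def determinism_check(seed: int, tmp_dir: str) -> bool:
    """Two end-to-end runs with identical config/seed are byte-identical."""
    import filecmp
    import os

    from .pipeline import write_study_outputs

    config = RunConfig(
        cohort=CohortSpec(n_per_group=6, n_volumes=80, n_voxels=200, seed=seed),
        k=3,
        n_permutations=50,
        n_boot=20,
        n_consensus_resamples=20,
        seed=seed,
    )
    paths = []
    for run in ("a", "b"):
        out = os.path.join(tmp_dir, run)
        write_study_outputs(run_end_to_end(config), out)
        paths.append(out)
    same_metrics = filecmp.cmp(
        os.path.join(paths[0], "metrics.csv"), os.path.join(paths[1], "metrics.csv"),
        shallow=False,
    )
    same_contrasts = filecmp.cmp(
        os.path.join(paths[0], "contrasts.csv"), os.path.join(paths[1], "contrasts.csv"),
        shallow=False,
    )
    return bool(same_metrics and same_contrasts)
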