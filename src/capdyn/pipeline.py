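"""End-to-end study orchestration: simulate -> preprocess -> CAPs -> metrics
-> stats, with deterministic seeding and file-based stage outputs.

The master seed deterministically derives independent per-stage seeds, so
changing, say, the number of permutations never changes the CAP maps or the
metrics table, and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import caps as cap_ops
from . import metrics as metric_ops
from . import preprocess as prep
from . import stats as stat_ops
from . import synthetic as synth
from .caps import CapSet, ConsensusReport, FrameSelection
from .metrics import StateLabelSeries

__all__ = ["RunConfig", "StudyResult", "run_end_to_end", "write_study_outputs"]

log = logging.getLogger(__name__)

#: behaviour columns forming the stress block of the PLSC
STRESS_BLOCK = ("pss", "ctq_total", "alpha_amylase", "car_auci")
#: behaviour columns forming the pain block (patients only carry WPI/BPI)
PAIN_BLOCK = ("wpi", "bpi_severity", "bpi_interference", "peg_algometry")


@dataclass
class RunConfig:
    """All knobs of one end-to-end study run."""

    cohort: synth.CohortSpec = field(default_factory=synth.CohortSpec)
    z_threshold: float = 0.84
    fd_threshold: float = 0.5
    fd_max_fraction: float = 0.40
    highpass_hz: float = 0.01
    use_gsr: bool = True
    variance_target: float = 0.9
    k: int | str = "auto"  # int, or "auto" for consensus selection
    k_range: tuple = (2, 3, 4, 5, 6)
    n_consensus_resamples: int = 100
    consensus_subsample: float = 0.8
    n_kmeans_repeats: int = 50
    n_permutations: int = 2000
    n_boot: int = 500
    contiguity: str = "volumes"
    plsc_caps: tuple = (1, 2)
    n_networks: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.k, int) and self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 < self.variance_target <= 1):
            raise ValueError("variance_target must lie in (0, 1]")
        if not (0 < self.z_threshold < 10):
            raise ValueError("z_threshold outside the documented range")
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class StudyResult:
    config: RunConfig
    cap_set: CapSet
    consensus: ConsensusReport | None
    metrics: pd.DataFrame  # tidy metrics table
    contrasts: pd.DataFrame  # group-by-state contrast table with FDR and d
    plsc: stat_ops.PlscResult | None
    behaviour: pd.DataFrame
    series: list[StateLabelSeries]
    selections: dict[str, FrameSelection]
    overlap: dict[int, pd.DataFrame]
    ground_truth: synth.GroundTruth | None = None
    excluded_subjects: list[str] = field(default_factory=list)
    reference_frames: np.ndarray | None = None  # pooled HC retained frames
    reference_labels: np.ndarray | None = None  # their clustering memberships


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["consensus", "kmeans", "permutation", "bootstrap"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def run_end_to_end(config: RunConfig) -> StudyResult:
    """Run the whole study on a synthetic cohort and return all artifacts."""
    rngs = _stage_rngs(config.seed)
    spec = dataclasses.replace(config.cohort, seed=config.cohort.seed or config.seed)
    log.info("stage=simulate config_hash=%s spec_seed=%d", config.config_hash(), spec.seed)

    frames_by_subject: dict[str, np.ndarray] = {}
    selections: dict[str, FrameSelection] = {}
    groups: dict[str, str] = {}
    n_volumes = spec.n_volumes
    excluded: list[str] = []
    gt: synth.GroundTruth | None = None
    state_sequences: dict[str, np.ndarray] = {}
    fd_true: dict[str, np.ndarray] = {}
    spikes: dict[str, np.ndarray] = {}
    latents: dict[str, float] = {}
    behaviour = None
    templates = None
    seed_voxels = None

    for rec, truth in synth.iter_subjects(spec):
        behaviour = truth["behaviour"]
        templates = truth["templates"]
        state_sequences[rec.subject_id] = truth["states"]
        fd_true[rec.subject_id] = truth["fd_true"]
        spikes[rec.subject_id] = truth["spikes"]
        latents[rec.subject_id] = truth["latent"]
        clean = prep.clean_run(
            rec.bold,
            rec.motion_params,
            use_gsr=config.use_gsr,
            highpass_hz=config.highpass_hz,
            fd_threshold=config.fd_threshold,
        )
        if prep.flag_high_motion_subject(
            clean.fd, config.fd_threshold, config.fd_max_fraction
        ):
            excluded.append(rec.subject_id)
            log.info("stage=preprocess subject=%s excluded for motion", rec.subject_id)
            continue
        seed_z = cap_ops.extract_seed_timecourse(clean)
        sel = cap_ops.select_active_frames(
            seed_z, clean.fd, config.z_threshold, config.fd_threshold
        )
        selections[rec.subject_id] = sel
        frames_by_subject[rec.subject_id] = clean.signal[sel.retained_indices].astype(
            np.float32
        )
        groups[rec.subject_id] = rec.group
        seed_voxels = rec.bold.seed_voxels

    gt = synth.GroundTruth(
        templates=templates,
        state_sequences=state_sequences,
        fd_true=fd_true,
        spike_mask=spikes,
        latent_scores=latents,
    )

    hc_ids = [s for s, g in groups.items() if g == "control"]
    pat_ids = [s for s, g in groups.items() if g == "patient"]
    hc_frames = np.concatenate([frames_by_subject[s] for s in hc_ids], axis=0)
    hc_counts = [frames_by_subject[s].shape[0] for s in hc_ids]
    log.info("stage=caps reference_frames=%d subjects=%d", hc_frames.shape[0], len(hc_ids))

    pca, reduced = cap_ops.pca_reduce(hc_frames, config.variance_target)
    consensus = None
    if config.k == "auto":
        consensus = cap_ops.consensus_cluster(
            reduced,
            config.k_range,
            config.n_consensus_resamples,
            config.consensus_subsample,
            rngs["consensus"],
        )
        k = consensus.k_optimal
        log.info("stage=consensus k_optimal=%d pac=%s", k, consensus.pac)
    else:
        k = int(config.k)
    labels_hc = cap_ops.cluster_caps(reduced, k, config.n_kmeans_repeats, rngs["kmeans"])
    cap_set = cap_ops.build_cap_maps(hc_frames, labels_hc, pca, seed_voxels=seed_voxels)

    atlas = synth.make_network_atlas(spec.n_voxels, config.n_networks)
    overlap = {
        c + 1: cap_ops.network_overlap(
            cap_set.maps[c], atlas, 1.04, exclude=cap_set.seed_voxels
        )
        for c in range(k)
    }

    series: list[StateLabelSeries] = []
    offsets = np.concatenate([[0], np.cumsum(hc_counts)])
    for i, sid in enumerate(hc_ids):
        frame_labels = labels_hc[offsets[i] : offsets[i + 1]]
        vol = cap_ops.labels_to_volume_series(n_volumes, selections[sid], frame_labels)
        series.append(StateLabelSeries(sid, vol, spec.tr_seconds, group="control"))
    for sid in pat_ids:
        frame_labels = cap_ops.match_frames_to_caps(frames_by_subject[sid], cap_set)
        vol = cap_ops.labels_to_volume_series(n_volumes, selections[sid], frame_labels)
        series.append(StateLabelSeries(sid, vol, spec.tr_seconds, group="patient"))

    metrics = metric_ops.metrics_table(series, k, config.contiguity)
    log.info("stage=metrics rows=%d", len(metrics))

    design = behaviour.copy()
    design["car_auci"] = [
        stat_ops.auc_increase(
            row[[f"cortisol_{int(m)}" for m in synth.CORTISOL_TIMES]].values
        )
        for _, row in design.iterrows()
    ]
    n_ret = {s.subject_id: s.n_retained for s in series}
    design["n_retained"] = design["subject"].map(n_ret)
    design = design.dropna(subset=["n_retained"])

    contrasts = stat_ops.group_state_contrasts(metrics, design)
    log.info("stage=stats contrasts=%d", len(contrasts))

    plsc = _run_plsc(metrics, design, config, rngs)
    return StudyResult(
        config=config,
        cap_set=cap_set,
        consensus=consensus,
        metrics=metrics,
        contrasts=contrasts,
        plsc=plsc,
        behaviour=design,
        series=series,
        selections=selections,
        overlap=overlap,
        ground_truth=gt,
        excluded_subjects=excluded,
        reference_frames=hc_frames,
        reference_labels=labels_hc,
    )


def brain_feature_table(
    metrics: pd.DataFrame, design: pd.DataFrame, caps=(1, 2)
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject wide table of entries/occurrence for the chosen CAPs,
    residualized against the standard covariate set."""
    wide = metrics.pivot_table(
        index="subject", columns=["metric", "cap"], values="value"
    )
    cols = [("entries", c) for c in caps] + [("occurrence", c) for c in caps]
    feats = wide[cols].copy()
    feats.columns = [f"cap{c}_{m}" for m, c in cols]
    feats = feats.merge(design.set_index("subject"), left_index=True, right_index=True)
    names = [f"cap{c}_{m}" for m, c in cols]
    covs = ["age", "sex", "psychotropic_medication", "mood_score", "n_retained"]
    C = pd.get_dummies(feats[covs], drop_first=True).astype(float).values
    for name in names:
        feats[name] = stat_ops.residualize(feats[name].values, C)
    return feats, names


def _run_plsc(metrics, design, config, rngs) -> stat_ops.PlscResult | None:
    feats, brain_names = brain_feature_table(metrics, design, config.plsc_caps)
    stress = [c for c in STRESS_BLOCK if c in feats.columns]
    # residualize the biomarker columns against their own covariate set
    bio_covs = ["age", "sex", "contraceptive_use", "smoking"]
    Cb = pd.get_dummies(feats[bio_covs], drop_first=True).astype(float).values
    table = feats.dropna(subset=stress + brain_names)
    if table.empty or table["group"].nunique() < 2:
        return None
    mask = feats.index.isin(table.index)
    X = table[stress].copy()
    for col in ("alpha_amylase", "car_auci"):
        if col in X.columns:
            X[col] = stat_ops.residualize(table[col].values, Cb[mask])
    Y = table[brain_names].values
    g = table["group"].values
    fit = stat_ops.plsc_fit(X.values, Y, g, behaviour_names=stress, brain_names=brain_names)
    fit.component_p = stat_ops.plsc_permutation_test(
        X.values, Y, g, config.n_permutations, rngs["permutation"]
    )
    fit.bootstrap_intervals, fit.stable_flags = stat_ops.plsc_bootstrap(
        X.values, Y, g, config.n_boot, rngs["bootstrap"]
    )
    return fit


# ---------------------------------------------------------------------------
# file outputs


def write_study_outputs(result: StudyResult, out_dir: str, figures: bool = False) -> None:
    """Write the study artifacts: metrics CSV, CAP maps and thresholds,
    contrast table, PLSC JSON summary, and a markdown report."""
    os.makedirs(out_dir, exist_ok=True)
    cfg_hash = result.config.config_hash()
    result.metrics.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    result.contrasts.to_csv(os.path.join(out_dir, "contrasts.csv"), index=False)
    np.savetxt(os.path.join(out_dir, "cap_maps.csv"), result.cap_set.maps, delimiter=",")
    np.savetxt(
        os.path.join(out_dir, "cap_match_thresholds.csv"),
        result.cap_set.match_thresholds,
        delimiter=",",
    )
    for c, table in result.overlap.items():
        table.to_csv(os.path.join(out_dir, f"overlap_cap{c}.csv"))
    if result.consensus is not None:
        pd.DataFrame(
            {"k": result.consensus.k_candidates,
             "pac": [result.consensus.pac[k] for k in result.consensus.k_candidates]}
        ).to_csv(os.path.join(out_dir, "consensus_pac.csv"), index=False)
    summary = {"config_hash": cfg_hash, "k": int(result.cap_set.k),
               "excluded_subjects": result.excluded_subjects}
    if result.plsc is not None:
        summary["plsc"] = {
            "singular_values": result.plsc.singular_values.tolist(),
            "component_p": result.plsc.component_p.tolist(),
            "behaviour_names": result.plsc.behaviour_names,
            "brain_names": result.plsc.brain_names,
            "behaviour_saliences": result.plsc.behaviour_saliences.tolist(),
            "brain_saliences": result.plsc.brain_saliences.tolist(),
            "stable_behaviour": result.plsc.stable_flags["behaviour"].tolist(),
            "stable_brain": result.plsc.stable_flags["brain"].tolist(),
        }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_report(result, os.path.join(out_dir, "report.md"))
    if figures:
        _write_figures(result, out_dir)


def _write_report(result: StudyResult, path: str) -> None:
    lines = ["# CAP study report", "",
             f"Config hash: `{result.config.config_hash()}`", "",
             f"K = {result.cap_set.k} CAPs; excluded subjects: "
             f"{result.excluded_subjects or 'none'}", ""]
    if result.consensus is not None:
        lines += ["## Consensus clustering (PAC per K)", ""]
        for k in result.consensus.k_candidates:
            mark = " <- selected" if k == result.consensus.k_optimal else ""
            lines.append(f"- K={k}: PAC={result.consensus.pac[k]:.3f}{mark}")
        lines.append("")
    lines += ["## Group-by-state contrasts (control - patient)", "",
              result.contrasts.to_markdown(index=False), ""]
    if result.plsc is not None:
        lines += ["## PLSC (stress block)", "",
                  f"Singular values: {np.round(result.plsc.singular_values, 3).tolist()}",
                  f"Permutation p: {np.round(result.plsc.component_p, 4).tolist()}", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _write_figures(result: StudyResult, out_dir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # metric violins per CAP and group
    for metric in ("duration", "entries", "occurrence"):
        df = result.metrics[result.metrics["metric"] == metric]
        fig, ax = plt.subplots(figsize=(6, 3.2))
        ks = sorted(df["cap"].unique())
        pos = 0
        ticks, ticklabels = [], []
        for capk in ks:
            for grp, color in (("control", "C0"), ("patient", "C3")):
                vals = df[(df["cap"] == capk) & (df["group"] == grp)]["value"].dropna()
                if len(vals):
                    parts = ax.violinplot([vals], positions=[pos], widths=0.8)
                    for pc in parts["bodies"]:
                        pc.set_facecolor(color)
                ticks.append(pos)
                ticklabels.append(f"CAP{capk}\n{grp[:3]}")
                pos += 1
            pos += 0.5
        ax.set_xticks(ticks, ticklabels, fontsize=7)
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"fig_{metric}.png"), dpi=120)
        plt.close(fig)
    if result.plsc is not None:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        u = result.plsc.behaviour_saliences[:, 0]
        v = result.plsc.brain_saliences[:, 0]
        axes[0].bar(range(len(u)), u)
        axes[0].set_title("behaviour saliences (comp 1)")
        axes[1].bar(range(len(v)), v, color="C3")
        axes[1].set_title("brain saliences (comp 1)")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "fig_plsc.png"), dpi=120)
        plt.close(fig)
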