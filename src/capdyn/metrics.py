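"""Per-subject, per-CAP temporal brain-state metrics.

Three metrics summarize a labelled volume series: average duration (mean run
length in seconds), relative entries (runs per retained frame), and relative
occurrence (retained-frame share).  Volume labels use the coding of
:mod:`capdyn.caps`: ``-1`` = not retained, ``0`` = retained but unassigned,
``1..K`` = CAP labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caps import NOT_RETAINED

__all__ = [
    "StateLabelSeries",
    "run_lengths",
    "average_duration",
    "relative_entries",
    "relative_occurrence",
    "metrics_table",
]


@dataclass
class StateLabelSeries:
    """One subject's per-volume CAP label sequence."""

    subject_id: str
    volume_labels: np.ndarray  # per original volume: -1, 0, or 1..K
    tr_seconds: float
    group: str = ""

    @property
    def n_retained(self) -> int:
        return int(np.sum(self.volume_labels != NOT_RETAINED))


def _compact(labels: np.ndarray, contiguity: str) -> np.ndarray:
    labels = np.asarray(labels)
    if contiguity == "volumes":
        return labels
    if contiguity == "retained":
        return labels[labels != NOT_RETAINED]
    raise ValueError("contiguity must be 'volumes' or 'retained'")


def run_lengths(volume_labels: np.ndarray, cap: int, contiguity: str = "volumes") -> np.ndarray:
    """Lengths (in volumes) of maximal consecutive runs of ``cap``.

    Under the default ``contiguity='volumes'`` any other label — including
    not-retained and unassigned volumes — breaks a run; ``'retained'`` first
    drops not-retained volumes so runs may bridge scrubbed gaps.
    """
    labels = _compact(volume_labels, contiguity)
    is_cap = np.concatenate([[False], labels == cap, [False]])
    d = np.diff(is_cap.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return ends - starts


def average_duration(
    series: StateLabelSeries, cap: int, contiguity: str = "volumes"
) -> float:
    """Mean run length of ``cap`` times the TR, in seconds; NaN if the CAP
    never occurs for this subject."""
    if series.tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    runs = run_lengths(series.volume_labels, cap, contiguity)
    if runs.size == 0:
        return float("nan")
    return float(runs.mean() * series.tr_seconds)


def relative_entries(
    series: StateLabelSeries, cap: int, contiguity: str = "volumes"
) -> float:
    """Number of transitions into ``cap`` divided by the retained-frame count.
    A run starting at the first retained volume counts as an entry."""
    n = series.n_retained
    if n == 0:
        raise ValueError(f"subject {series.subject_id} has no retained frames")
    return float(run_lengths(series.volume_labels, cap, contiguity).size) / n


def relative_occurrence(series: StateLabelSeries, cap: int) -> float:
    """Fraction of retained frames assigned to ``cap`` (unassigned frames stay
    in the denominator)."""
    n = series.n_retained
    if n == 0:
        raise ValueError(f"subject {series.subject_id} has no retained frames")
    return float(np.sum(series.volume_labels == cap)) / n


def metrics_table(
    series_list: list[StateLabelSeries], k: int, contiguity: str = "volumes"
) -> pd.DataFrame:
    """Tidy table of the three metrics: one row per (subject, cap, metric).

    Columns: subject, group, cap, metric, value, n_retained.  Metrics are
    ``duration`` (s), ``entries`` and ``occurrence`` (proportions).  Missing
    durations (CAP never visited) are NaN, not zero.
    """
    rows = []
    for s in series_list:
        for cap in range(1, k + 1):
            vals = {
                "duration": average_duration(s, cap, contiguity),
                "entries": relative_entries(s, cap, contiguity),
                "occurrence": relative_occurrence(s, cap),
            }
            for metric, value in vals.items():
                rows.append(
                    {
                        "subject": s.subject_id,
                        "group": s.group,
                        "cap": cap,
                        "metric": metric,
                        "value": value,
                        "n_retained": s.n_retained,
                    }
                )
    return pd.DataFrame(rows)
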