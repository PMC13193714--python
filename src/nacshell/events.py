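"""Event-locked analysis of dF/F0: trial alignment, PSTHs, epoch metrics.

Trials are aligned on a common relative time grid, baseline-corrected
against the pre-event window, averaged hierarchically (trials within
animal, then across animals), and quantified per epoch by trapezoidal AUC
and signal extrema. The standard epochs contrast a pre-event baseline
(-6 to -1 s) with the event epoch (0-5 s); reward consumption is read out
as a pause (epoch minimum), aversive stimuli as an excitation (maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photometry import EventSeries, EventWindow, PreprocessResult

__all__ = [
    "AlignedTrials",
    "EpochDefinition",
    "EpochMetrics",
    "PairedSample",
    "align",
    "align_cohort",
    "baseline_correct",
    "psth",
    "heatmap_matrix",
    "epoch_metrics",
    "epoch_contrast",
    "TASK_PRESETS",
]

# per-task presets named after the figures they reproduce:
# reward consumption -> pause (minimum), shock / tail lift -> excitation (maximum)
TASK_PRESETS = {
    "reward": {"statistic": "min", "heatmap_row": "animal",
               "baseline": (-6.0, -1.0), "event": (0.0, 5.0)},
    "shock": {"statistic": "max", "heatmap_row": "trial",
              "baseline": (-6.0, -1.0), "event": (0.0, 5.0)},
    "lift": {"statistic": "max", "heatmap_row": "trial",
             "baseline": (-4.0, 0.0), "event": (0.0, 4.0)},
}


@dataclass
class AlignedTrials:
    """Trials x samples matrix of dF/F0 (%) on a shared relative time grid."""

    rel_time_s: np.ndarray
    matrix: np.ndarray
    animal_ids: np.ndarray
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rel_time_s = np.asarray(self.rel_time_s, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.animal_ids = np.asarray(self.animal_ids)
        if self.matrix.shape[1] != self.rel_time_s.size:
            raise ValueError("AlignedTrials: matrix columns must match rel_time_s length")
        if self.animal_ids.size != self.matrix.shape[0]:
            raise ValueError("AlignedTrials: one animal id per trial row required")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def animals(self) -> np.ndarray:
        # stable order of first appearance
        _, idx = np.unique(self.animal_ids, return_index=True)
        return self.animal_ids[np.sort(idx)]

    def per_animal_means(self) -> pd.DataFrame:
        """Trial-averaged trace per animal (rows: animals, cols: rel time)."""
        rows = {a: self.matrix[self.animal_ids == a].mean(axis=0) for a in self.animals}
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.rel_time_s)


@dataclass
class EpochDefinition:
    """A baseline/event epoch pair with the statistic used to contrast them."""

    baseline: tuple = (-6.0, -1.0)
    event: tuple = (0.0, 5.0)
    statistic: str = "min"

    def __post_init__(self) -> None:
        for name, (a, b) in (("baseline", self.baseline), ("event", self.event)):
            if not b > a:
                raise ValueError(f"EpochDefinition: {name} epoch must have positive length")
        if self.baseline[1] > self.event[0]:
            raise ValueError("EpochDefinition: baseline epoch must precede event epoch")
        if self.statistic not in ("min", "max", "auc"):
            raise ValueError(f"EpochDefinition: unknown statistic {self.statistic!r}")


@dataclass
class EpochMetrics:
    """Per-animal AUC and extrema for the baseline and event epochs."""

    table: pd.DataFrame  # index: animal; columns: (epoch, metric)
    epochs: EpochDefinition


@dataclass
class PairedSample:
    """Matched per-unit (animal) values under two conditions, for a paired test."""

    units: np.ndarray
    condition_a: np.ndarray
    condition_b: np.ndarray

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units)
        self.condition_a = np.asarray(self.condition_a, dtype=float)
        self.condition_b = np.asarray(self.condition_b, dtype=float)
        if not (self.units.size == self.condition_a.size == self.condition_b.size):
            raise ValueError("PairedSample: units and both condition arrays must have equal length")
        if self.units.size < 2:
            raise ValueError("PairedSample: at least 2 matched units required")


def align(windows: list[EventWindow] | PreprocessResult, animal_id="animal") -> AlignedTrials:
    """Stack per-event windows from one animal into an AlignedTrials block."""
    dropped = []
    if isinstance(windows, PreprocessResult):
        dropped = list(windows.dropped)
        windows = windows.windows
    if not windows:
        raise ValueError("align: no event windows to align")
    rel = windows[0].rel_time_s
    for w in windows[1:]:
        if w.rel_time_s.size != rel.size or not np.allclose(w.rel_time_s, rel):
            raise ValueError("align: windows do not share a relative time grid")
    mat = np.vstack([w.dff_pct for w in windows])
    return AlignedTrials(rel_time_s=rel, matrix=mat,
                         animal_ids=np.array([animal_id] * len(windows), dtype=object),
                         dropped=dropped)


def align_cohort(per_animal: dict) -> AlignedTrials:
    """Concatenate per-animal windows (``{animal_id: windows-or-result}``)."""
    blocks = [align(w, animal_id=a) for a, w in per_animal.items()]
    if not blocks:
        raise ValueError("align_cohort: empty cohort")
    rel = blocks[0].rel_time_s
    return AlignedTrials(
        rel_time_s=rel,
        matrix=np.vstack([b.matrix for b in blocks]),
        animal_ids=np.concatenate([b.animal_ids for b in blocks]),
        dropped=sum((b.dropped for b in blocks), []),
    )


def _epoch_mask(rel_time: np.ndarray, window: tuple) -> np.ndarray:
    # epochs are closed on both ends
    return (rel_time >= window[0]) & (rel_time <= window[1])


def baseline_correct(trials: AlignedTrials, window: tuple = (-10.0, -1.0)) -> AlignedTrials:
    """Subtract each row's mean over the pre-event baseline window."""
    mask = _epoch_mask(trials.rel_time_s, window)
    if not np.any(mask):
        raise ValueError(f"baseline_correct: window {window} contains no samples")
    base = trials.matrix[:, mask].mean(axis=1, keepdims=True)
    return AlignedTrials(trials.rel_time_s, trials.matrix - base,
                         trials.animal_ids, trials.dropped)


def psth(trials: AlignedTrials, level: str = "animal") -> pd.DataFrame:
    """Mean +/- SEM trace at the requested averaging level.

    ``level='trial'`` averages over rows; ``level='animal'`` first averages
    trials within each animal, then across animals (SEM over animals), so
    animals with unequal trial counts weigh equally.
    """
    if level == "trial":
        units = trials.matrix
    elif level in ("animal", "group"):
        units = trials.per_animal_means().to_numpy()
    else:
        raise ValueError(f"psth: unknown level {level!r}")
    n = units.shape[0]
    mean = units.mean(axis=0)
    sem = units.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return pd.DataFrame({"rel_time_s": trials.rel_time_s, "mean": mean, "sem": sem, "n": n})


def heatmap_matrix(trials: AlignedTrials, row: str = "animal") -> pd.DataFrame:
    """Heatmap rows: one per animal (reward task) or one per trial (aversive)."""
    if row == "animal":
        return trials.per_animal_means()
    if row == "trial":
        return pd.DataFrame(trials.matrix, columns=trials.rel_time_s)
    raise ValueError(f"heatmap_matrix: unknown row mode {row!r}")


def epoch_metrics(trials: AlignedTrials, epochs: EpochDefinition,
                  per: str = "animal") -> EpochMetrics:
    """Trapezoidal AUC and extrema per epoch, on trial-averaged traces.

    By default metrics are computed on each animal's trial-averaged trace
    (one value per animal, matching per-animal statistics downstream);
    ``per='trial'`` computes them per trial row instead.
    """
    if per == "animal":
        traces = trials.per_animal_means()
    elif per == "trial":
        traces = pd.DataFrame(trials.matrix, columns=trials.rel_time_s)
    else:
        raise ValueError(f"epoch_metrics: unknown per {per!r}")
    rel = trials.rel_time_s
    out = {}
    for name, win in (("baseline", epochs.baseline), ("event", epochs.event)):
        mask = _epoch_mask(rel, win)
        if mask.sum() < 2:
            raise ValueError(f"epoch_metrics: epoch {name} {win} contains fewer than 2 samples")
        seg = traces.to_numpy()[:, mask]
        t = rel[mask]
        out[(name, "auc")] = np.trapezoid(seg, t, axis=1)
        out[(name, "peak_max")] = seg.max(axis=1)
        out[(name, "peak_min")] = seg.min(axis=1)
    table = pd.DataFrame(out, index=traces.index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["epoch", "metric"])
    return EpochMetrics(table=table, epochs=epochs)


def epoch_contrast(metrics: EpochMetrics, statistic: str | None = None) -> PairedSample:
    """(baseline, event) value pairs per animal for a paired t-test."""
    stat = statistic or metrics.epochs.statistic
    col = {"min": "peak_min", "max": "peak_max", "auc": "auc"}.get(stat)
    if col is None:
        raise ValueError(f"epoch_contrast: unknown statistic {stat!r}")
    t = metrics.table
    return PairedSample(
        units=t.index.to_numpy(),
        condition_a=t[("baseline", col)].to_numpy(),
        condition_b=t[("event", col)].to_numpy(),
    )
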