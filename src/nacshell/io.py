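"""Plain-text readers and writers for every pipeline artifact.

Sessions and logs are tab-separated values with a JSON sidecar for
metadata; count matrices are Matrix Market plus plain-text gene/cell name
lists (the GEO-style triplet).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .expression import GeneCellMatrix
from .photometry import EventSeries, PhotometrySession

__all__ = [
    "write_photometry_session",
    "read_photometry_session",
    "write_events",
    "read_events",
    "write_lick_log",
    "read_lick_log",
    "write_positions",
    "read_positions",
    "write_count_matrix",
    "read_count_matrix",
    "write_ground_truth",
    "read_ground_truth",
]


def write_photometry_session(session: PhotometrySession, path) -> Path:
    """Write traces as TSV (time_s, f465, f405) + events + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": session.time_s, "f465": session.f_signal,
                  "f405": session.f_iso}).to_csv(path, sep="\t", index=False)
    write_events(session.events, path.with_suffix(".events.tsv"))
    meta = {"fs_hz": session.fs_hz, "session_id": session.session_id}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_photometry_session(path) -> PhotometrySession:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    ev_path = path.with_suffix(".events.tsv")
    events = read_events(ev_path) if ev_path.exists() else EventSeries.empty()
    return PhotometrySession(
        time_s=df["time_s"].to_numpy(), f_signal=df["f465"].to_numpy(),
        f_iso=df["f405"].to_numpy(), fs_hz=float(meta["fs_hz"]),
        events=events, session_id=meta.get("session_id", ""),
    )


def write_events(events: EventSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "timestamp_s": events.times_s,
        "event_type": events.kinds,
        "trial_id": events.trial_ids,
        "excluded": events.excluded.astype(int),
    }).to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> EventSeries:
    df = pd.read_csv(path, sep="\t")
    return EventSeries(
        times_s=df["timestamp_s"].to_numpy(),
        kinds=df["event_type"].to_numpy(dtype=object),
        trial_ids=df["trial_id"].to_numpy(),
        excluded=df["excluded"].to_numpy(dtype=bool) if "excluded" in df else None,
    )


def write_lick_log(df: pd.DataFrame, path) -> Path:
    """Lick/event log columns: timestamp_s, event_type, trial_id, block_id, laser_on."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_lick_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_positions(positions: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    positions.to_csv(path, sep="\t", index=False)
    return path


def read_positions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_count_matrix(m: GeneCellMatrix, out_dir) -> Path:
    """Matrix Market + genes.txt + cells.txt under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / "matrix.mtx", m.counts)
    (out_dir / "genes.txt").write_text("\n".join(map(str, m.gene_names)) + "\n")
    (out_dir / "cells.txt").write_text("\n".join(map(str, m.cell_ids)) + "\n")
    return out_dir


def write_ground_truth(truth, path) -> Path:
    """Simulation ground truth as a TSV sidecar + JSON per-event amplitudes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "time_s": truth.time_s,
        "true_dff_pct": truth.true_dff_pct,
        "motion": truth.motion,
        "bleach_signal": truth.bleach_signal,
        "bleach_iso": truth.bleach_iso,
        "noise_signal": truth.noise_signal,
        "noise_iso": truth.noise_iso,
    }).to_csv(path, sep="\t", index=False)
    path.with_suffix(".amplitudes.json").write_text(
        json.dumps({"event_amplitudes_pct": list(map(float, truth.event_amplitudes_pct))}))
    return path


def read_ground_truth(path):
    from .synth import GroundTruth

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    amps = json.loads(path.with_suffix(".amplitudes.json").read_text())
    return GroundTruth(
        time_s=df["time_s"].to_numpy(),
        true_dff_pct=df["true_dff_pct"].to_numpy(),
        event_amplitudes_pct=np.asarray(amps["event_amplitudes_pct"]),
        motion=df["motion"].to_numpy(),
        bleach_signal=df["bleach_signal"].to_numpy(),
        bleach_iso=df["bleach_iso"].to_numpy(),
        noise_signal=df["noise_signal"].to_numpy(),
        noise_iso=df["noise_iso"].to_numpy(),
    )


def read_count_matrix(out_dir) -> GeneCellMatrix:
    out_dir = Path(out_dir)
    counts = sparse.csr_matrix(spio.mmread(out_dir / "matrix.mtx"))
    genes = np.array((out_dir / "genes.txt").read_text().split(), dtype=object)
    cells = np.array((out_dir / "cells.txt").read_text().split(), dtype=object)
    return GeneCellMatrix(counts=counts.astype(np.int64), gene_names=genes, cell_ids=cells)
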