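"""Two-channel fiber-photometry preprocessing.

Raw recordings carry a calcium-dependent signal channel (465 nm excitation)
and a calcium-independent isosbestic reference (405 nm). Both see the same
slow motion/bleaching artifacts, so a per-window linear fit of the signal
channel onto the reference yields a motion baseline F0, and the normalized
signal is dF/F0 (%) = (F - F0) / F0 * 100.

The full chain, in fixed order: block-mean downsampling, zero-phase low-pass
filtering, trimming of the initial fast-bleaching segment, per-event window
extraction, per-window isosbestic fit, dF/F0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal


__all__ = [
    "EventSeries",
    "PhotometrySession",
    "IsosbesticFit",
    "DffTrace",
    "EventWindow",
    "PreprocessParams",
    "PreprocessResult",
    "downsample",
    "lowpass",
    "trim_start",
    "fit_isosbestic",
    "compute_dff",
    "preprocess_around_events",
]

EVENT_KINDS = ("reward_first_lick", "shock_onset", "lift_onset")


@dataclass
class EventSeries:
    """Timestamped behavioral events on the recording's absolute clock.

    ``excluded`` marks events invalidated by preprocessing (e.g. falling in
    the trimmed initial segment); their timestamps are kept so the clock
    stays absolute.
    """

    times_s: np.ndarray
    kinds: np.ndarray
    trial_ids: np.ndarray
    excluded: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.excluded is None:
            self.excluded = np.zeros(self.times_s.size, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = self.times_s.size
        if not (self.kinds.size == n and self.trial_ids.size == n and self.excluded.size == n):
            raise ValueError("EventSeries: times_s, kinds, trial_ids, excluded must have equal length")
        for kind in np.unique(self.kinds):
            t = self.times_s[self.kinds == kind]
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"EventSeries: times_s must be strictly increasing within kind {kind!r}")

    def __len__(self) -> int:
        return int(self.times_s.size)

    @classmethod
    def empty(cls) -> "EventSeries":
        return cls(np.empty(0), np.empty(0, dtype=object), np.empty(0, dtype=int))


@dataclass
class PhotometrySession:
    """Co-recorded signal (465 nm) and isosbestic (405 nm) traces.

    ``time_s`` is uniform and strictly increasing; ``fs_hz`` must match its
    spacing to within 1e-6 relative.
    """

    time_s: np.ndarray
    f_signal: np.ndarray
    f_iso: np.ndarray
    fs_hz: float
    events: EventSeries = field(default_factory=EventSeries.empty)
    session_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_signal = np.asarray(self.f_signal, dtype=float)
        self.f_iso = np.asarray(self.f_iso, dtype=float)
        n = self.time_s.size
        if self.f_signal.size != n or self.f_iso.size != n:
            raise ValueError("PhotometrySession: channel lengths must equal time_s length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("PhotometrySession: time_s must be strictly increasing")
            fs_obs = 1.0 / np.mean(dt)
            if abs(fs_obs - self.fs_hz) > 1e-6 * self.fs_hz:
                raise ValueError(
                    f"PhotometrySession: fs_hz={self.fs_hz} inconsistent with time spacing ({fs_obs:.6f} Hz)"
                )

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass
class IsosbesticFit:
    """Least-squares line mapping the 405 nm reference onto the 465 nm signal."""

    slope: float
    intercept: float
    fit_window_s: tuple
    fitted_f0: np.ndarray

    def __post_init__(self) -> None:
        self.fitted_f0 = np.asarray(self.fitted_f0, dtype=float)


@dataclass
class DffTrace:
    """Normalized fluorescence, dF/F0 in percent, on its own time axis."""

    time_s: np.ndarray
    dff_pct: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff_pct = np.asarray(self.dff_pct, dtype=float)
        if self.time_s.size != self.dff_pct.size:
            raise ValueError("DffTrace: time_s and dff_pct must have equal length")
        if not np.all(np.isfinite(self.dff_pct)):
            raise ValueError("DffTrace: dff_pct must be finite everywhere")


@dataclass
class EventWindow:
    """dF/F0 window around a single event, on a relative time grid."""

    rel_time_s: np.ndarray
    dff_pct: np.ndarray
    event_time_s: float
    kind: str
    trial_id: int
    fit: IsosbesticFit | None = None


@dataclass
class PreprocessParams:
    """Parameters of the standard preprocessing chain.

    Defaults follow the acquisition protocol: 10x downsampling of the
    1017.3 Hz stream (nominally "100 Hz", exactly 101.73 Hz), a 1 Hz
    zero-phase low-pass, 180 s trimmed from the start, and event windows
    of -10 to +20 s with the isosbestic fit computed per window.
    """

    downsample_factor: int = 10
    lowpass_hz: float = 1.0
    trim_s: float = 180.0
    window_s: tuple = (-10.0, 20.0)
    filter_isosbestic: bool = True
    baseline_mode: str = "isosbestic"  # or "window_mean": F0 = mean of F over the window

    def as_dict(self) -> dict:
        return {
            "downsample_factor": self.downsample_factor,
            "lowpass_hz": self.lowpass_hz,
            "trim_s": self.trim_s,
            "window_s": tuple(self.window_s),
            "filter_isosbestic": self.filter_isosbestic,
            "baseline_mode": self.baseline_mode,
        }


@dataclass
class PreprocessResult:
    windows: list
    dropped: list
    params: PreprocessParams


def downsample(session: PhotometrySession, factor: int) -> PhotometrySession:
    """Downsample both channels by non-overlapping block means.

    Each output sample is the mean of ``factor`` consecutive input samples;
    a trailing partial block is dropped. Block averaging acts as a crude
    anti-alias stage ahead of the low-pass filter.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"downsample: factor must be a positive integer, got {factor!r}")
    if len(session) < factor:
        raise ValueError("downsample: session shorter than one block")
    n_blocks = len(session) // factor
    n = n_blocks * factor

    def _block_mean(x: np.ndarray) -> np.ndarray:
        return x[:n].reshape(n_blocks, factor).mean(axis=1)

    return PhotometrySession(
        time_s=_block_mean(session.time_s),
        f_signal=_block_mean(session.f_signal),
        f_iso=_block_mean(session.f_iso),
        fs_hz=session.fs_hz / factor,
        events=session.events,
        session_id=session.session_id,
    )


def lowpass(trace: np.ndarray, fs_hz: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    Contract: unit DC gain; strong attenuation well above the cutoff.
    """
    trace = np.asarray(trace, dtype=float)
    if cutoff_hz >= fs_hz / 2:
        raise ValueError(f"lowpass: cutoff_hz={cutoff_hz} must be below Nyquist ({fs_hz / 2} Hz)")
    if cutoff_hz <= 0:
        raise ValueError("lowpass: cutoff_hz must be positive")
    sos = _signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return _signal.sosfiltfilt(sos, trace)


def lowpass_session(session: PhotometrySession, cutoff_hz: float,
                    filter_isosbestic: bool = True) -> PhotometrySession:
    """Low-pass both channels (or signal only) of a session."""
    f_sig = lowpass(session.f_signal, session.fs_hz, cutoff_hz)
    f_iso = lowpass(session.f_iso, session.fs_hz, cutoff_hz) if filter_isosbestic else session.f_iso
    return replace(session, f_signal=f_sig, f_iso=f_iso)


def trim_start(session: PhotometrySession, trim_s: float = 180.0) -> PhotometrySession:
    """Remove the initial ``trim_s`` seconds of both channels.

    The absolute clock is preserved; events earlier than ``trim_s`` are
    flagged excluded rather than deleted.
    """
    if trim_s < 0:
        raise ValueError("trim_start: trim_s must be non-negative")
    t0 = session.time_s[0]
    keep = session.time_s >= t0 + trim_s
    if not np.any(keep):
        raise ValueError(f"trim_start: session shorter than trim_s={trim_s}")
    ev = session.events
    excluded = ev.excluded | (ev.times_s < t0 + trim_s)
    return PhotometrySession(
        time_s=session.time_s[keep],
        f_signal=session.f_signal[keep],
        f_iso=session.f_iso[keep],
        fs_hz=session.fs_hz,
        events=EventSeries(ev.times_s, ev.kinds, ev.trial_ids, excluded),
        session_id=session.session_id,
    )


def fit_isosbestic(f_signal: np.ndarray, f_iso: np.ndarray,
                   fit_window_s: tuple = (np.nan, np.nan)) -> IsosbesticFit:
    """Least-squares line F ~ a * F_iso + b over the given samples.

    Returns the (slope, intercept) minimizing sum((F - (a*F_iso + b))^2) and
    the fitted baseline F0 = a * F_iso + b.
    """
    f_signal = np.asarray(f_signal, dtype=float)
    f_iso = np.asarray(f_iso, dtype=float)
    if f_signal.size != f_iso.size:
        raise ValueError("fit_isosbestic: channel windows must have equal length")
    if f_signal.size < 3:
        raise ValueError("fit_isosbestic: window must contain at least 3 samples")
    if np.ptp(f_iso) == 0:
        if np.ptp(f_signal) == 0:
            # doubly-constant window: the exact (degenerate) solution is F0 = F
            return IsosbesticFit(slope=0.0, intercept=float(f_signal[0]),
                                 fit_window_s=tuple(fit_window_s),
                                 fitted_f0=np.full_like(f_signal, f_signal[0]))
        raise ValueError("fit_isosbestic: isosbestic channel is constant within window (degenerate fit)")
    slope, intercept = np.polyfit(f_iso, f_signal, 1)
    return IsosbesticFit(
        slope=float(slope),
        intercept=float(intercept),
        fit_window_s=tuple(fit_window_s),
        fitted_f0=slope * f_iso + intercept,
    )


def compute_dff(f: np.ndarray, f0: np.ndarray, time_s: np.ndarray | None = None,
                provenance: dict | None = None) -> DffTrace:
    """dF/F0 (%) = (F - F0) / F0 * 100, defined only where F0 > 0."""
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if f.size != f0.size:
        raise ValueError("compute_dff: f and f0 must have equal length")
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"compute_dff: f0 <= 0 at indices {bad[:10].tolist()}"
                         + ("..." if bad.size > 10 else ""))
    if time_s is None:
        time_s = np.arange(f.size, dtype=float)
    return DffTrace(time_s=time_s, dff_pct=(f - f0) / f0 * 100.0,
                    provenance=provenance or {})


def preprocess_around_events(session: PhotometrySession,
                             params: PreprocessParams | None = None) -> PreprocessResult:
    """Run the full chain and return per-event dF/F0 windows.

    Order is fixed: downsample -> low-pass -> trim -> window extraction ->
    per-window isosbestic fit -> dF/F0. Events excluded by the trim or whose
    window would leave the recording are dropped with a logged reason.
    """
    params = params or PreprocessParams()
    ses = downsample(session, params.downsample_factor)
    ses = lowpass_session(ses, params.lowpass_hz, params.filter_isosbestic)
    ses = trim_start(ses, params.trim_s)

    fs = ses.fs_hz
    lo, hi = params.window_s
    n_before = int(round(-lo * fs))
    n_after = int(round(hi * fs))
    rel_time = np.arange(-n_before, n_after + 1) / fs

    windows: list[EventWindow] = []
    dropped: list[dict] = []
    prov = params.as_dict() | {"session_id": session.session_id}
    for i in range(len(ses.events)):
        t_ev = float(ses.events.times_s[i])
        kind = str(ses.events.kinds[i])
        trial = ses.events.trial_ids[i]
        if ses.events.excluded[i]:
            dropped.append({"trial_id": trial, "time_s": t_ev, "reason": "excluded_by_trim"})
            continue
        # nearest sample to the event time
        idx = int(np.searchsorted(ses.time_s, t_ev))
        if idx >= len(ses):
            idx = len(ses) - 1
        elif idx > 0 and t_ev - ses.time_s[idx - 1] < ses.time_s[idx] - t_ev:
            idx -= 1
        start, stop = idx - n_before, idx + n_after + 1
        if start < 0 or stop > len(ses):
            dropped.append({"trial_id": trial, "time_s": t_ev, "reason": "window_out_of_bounds"})
            continue
        f_sig = ses.f_signal[start:stop]
        f_iso = ses.f_iso[start:stop]
        if params.baseline_mode == "isosbestic":
            fit = fit_isosbestic(f_sig, f_iso, fit_window_s=(lo, hi))
            f0 = fit.fitted_f0
        elif params.baseline_mode == "window_mean":
            fit = None
            f0 = np.full_like(f_sig, f_sig.mean())
        else:
            raise ValueError(f"preprocess_around_events: unknown baseline_mode {params.baseline_mode!r}")
        dff = compute_dff(f_sig, f0, time_s=rel_time, provenance=prov)
        windows.append(EventWindow(rel_time_s=rel_time, dff_pct=dff.dff_pct,
                                   event_time_s=t_ev, kind=kind, trial_id=trial, fit=fit))
    return PreprocessResult(windows=windows, dropped=dropped, params=params)
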