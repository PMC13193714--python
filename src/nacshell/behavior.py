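"""Behavioral session scoring.

Covers the unpredicted-reward lickometer task (trial success, training
criteria), optogenetic block designs (lick counts per block, opto vs
non-opto epoch means, inhibition classification), real-time place
preference/avoidance (occupancy fractions, distance per chamber), and
indirect-calorimetry formulas (Weir energy expenditure, respiratory
quotient).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RewardTaskSession",
    "TrialOutcome",
    "OptoLickSession",
    "RTPPASession",
    "MetabolicRecord",
    "score_trials",
    "success_percentage",
    "training_criterion",
    "licks_per_block",
    "epoch_type_means",
    "rtppa_metrics",
    "weir_ee",
    "rq",
]


@dataclass
class RewardTaskSession:
    """One unpredicted-reward session: 10 s reward windows at random ITIs."""

    trial_onsets_s: np.ndarray
    lick_times_s: np.ndarray
    reward_window_s: float = 10.0
    phase: str = "testing"  # unrestricted | training | testing
    timeout_s: float = 60.0
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.trial_onsets_s = np.asarray(self.trial_onsets_s, dtype=float)
        self.lick_times_s = np.sort(np.asarray(self.lick_times_s, dtype=float))
        if self.trial_onsets_s.size == 0:
            raise ValueError("RewardTaskSession: trial list is empty")
        onsets = np.sort(self.trial_onsets_s)
        if np.any(np.diff(onsets) < self.reward_window_s):
            raise ValueError("RewardTaskSession: reward windows overlap")
        self.trial_onsets_s = onsets

    @property
    def n_trials(self) -> int:
        return int(self.trial_onsets_s.size)


@dataclass
class TrialOutcome:
    trial_id: int
    success: bool
    first_lick_s: float | None

    def __post_init__(self) -> None:
        if self.success != (self.first_lick_s is not None):
            raise ValueError("TrialOutcome: success iff first_lick_s is present")


@dataclass
class OptoLickSession:
    """Free-access licking across contiguous laser on/off blocks."""

    blocks: list  # of (start_s, end_s, laser_on)
    lick_times_s: np.ndarray
    protocol: str = "five_block_5min"
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.lick_times_s = np.sort(np.asarray(self.lick_times_s, dtype=float))
        self.blocks = [(float(s), float(e), bool(on)) for s, e, on in self.blocks]
        for (s, e, _on) in self.blocks:
            if not e > s:
                raise ValueError("OptoLickSession: block end must exceed start")
        for (_, e0, _), (s1, _, _) in zip(self.blocks, self.blocks[1:]):
            if not math.isclose(e0, s1, abs_tol=1e-9):
                raise ValueError("OptoLickSession: blocks must be contiguous and non-overlapping")


@dataclass
class RTPPASession:
    """Positions in a two-chamber (A|B) box; laser paired to one side.

    Chambers are two 30 x 30 cm squares side by side: chamber A is
    x in [0, 30), chamber B is x in [30, 60].
    """

    positions: pd.DataFrame  # columns t_s, x_cm, y_cm
    stim_side: str = "A"
    day: int = 1
    box_size_cm: float = 30.0
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        req = {"t_s", "x_cm", "y_cm"}
        if not req.issubset(self.positions.columns):
            raise ValueError(f"RTPPASession: positions must have columns {sorted(req)}")
        if len(self.positions) < 2:
            raise ValueError("RTPPASession: at least 2 position samples required")
        if self.stim_side not in ("A", "B"):
            raise ValueError("RTPPASession: stim_side must be 'A' or 'B'")
        x = self.positions["x_cm"].to_numpy()
        if np.any(~np.isfinite(x)) or np.any(x < 0) or np.any(x > 2 * self.box_size_cm):
            bad = np.flatnonzero(~((x >= 0) & (x <= 2 * self.box_size_cm)))
            raise ValueError(f"RTPPASession: unassignable positions at samples {bad[:10].tolist()}")

    def chamber_of(self) -> np.ndarray:
        x = self.positions["x_cm"].to_numpy()
        return np.where(x < self.box_size_cm, "A", "B")


@dataclass
class MetabolicRecord:
    vo2: float  # L O2 consumed
    vco2: float  # L CO2 produced
    ee: float = field(init=False)  # kcal
    rq: float = field(init=False)

    def __post_init__(self) -> None:
        self.ee = weir_ee(self.vo2, self.vco2)
        self.rq = rq(self.vo2, self.vco2)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def success_percentage(successes: float, n_trials: int) -> int:
    """Success percentage rounded half-up to an integer.

    Accepts fractional success counts so cohort means can be summarized
    (e.g. a cohort averaging 16.2 successful of 30 trials scores 54%).
    """
    if n_trials <= 0:
        raise ValueError("success_percentage: n_trials must be positive")
    if successes < 0 or successes > n_trials:
        raise ValueError("success_percentage: successes must lie in [0, n_trials]")
    return _round_half_up(100.0 * successes / n_trials)


def score_trials(session: RewardTaskSession) -> tuple[list[TrialOutcome], dict]:
    """Score each trial: success iff at least one lick lands in its window.

    The window is closed at both ends, [onset, onset + reward_window_s].
    In the training phase, licks outside every window additionally emit
    timeout events.
    """
    outcomes: list[TrialOutcome] = []
    licks = session.lick_times_s
    in_any_window = np.zeros(licks.size, dtype=bool)
    for tid, onset in enumerate(session.trial_onsets_s):
        mask = (licks >= onset) & (licks <= onset + session.reward_window_s)
        in_any_window |= mask
        if np.any(mask):
            outcomes.append(TrialOutcome(tid, True, float(licks[mask][0])))
        else:
            outcomes.append(TrialOutcome(tid, False, None))
    n_succ = sum(o.success for o in outcomes)
    summary = {
        "n_trials": session.n_trials,
        "success_count": n_succ,
        "success_pct": success_percentage(n_succ, session.n_trials),
    }
    if session.phase == "training":
        summary["timeout_events_s"] = licks[~in_any_window].tolist()
    return outcomes, summary


def training_criterion(history: list[dict], phase: str) -> tuple[bool, str]:
    """Training advancement rules.

    ``phase='tethering'``: pass at >= 10 successful trials in the latest
    session; ``phase='testing'``: >= 12; ``phase='opto'``: pass when the
    relative difference in total lick counts across the last two sessions,
    |L1 - L2| / mean(L1, L2), is below 0.30.
    """
    if not history:
        raise ValueError("training_criterion: empty session history")
    if phase in ("tethering", "testing"):
        need = 10 if phase == "tethering" else 12
        got = history[-1]["success_count"]
        ok = got >= need
        return ok, f"latest session: {got} successful trials (threshold {need})"
    if phase == "opto":
        if len(history) < 2:
            raise ValueError("training_criterion: opto criterion needs two sessions")
        l1, l2 = (history[-2]["lick_count"], history[-1]["lick_count"])
        mean = (l1 + l2) / 2.0
        if mean == 0:
            return False, "no licks in either session"
        var = abs(l1 - l2) / mean
        return var < 0.30, f"lick-count variability {var:.3f} (threshold 0.30)"
    raise ValueError(f"training_criterion: unknown phase {phase!r}")


def licks_per_block(session: OptoLickSession) -> pd.DataFrame:
    """Lick count and rate per block; blocks are half-open [start, end).

    Licks falling outside every block are excluded (reported in the frame's
    ``attrs['excluded_licks']``).
    """
    rows = []
    assigned = np.zeros(session.lick_times_s.size, dtype=bool)
    for i, (s, e, on) in enumerate(session.blocks):
        mask = (session.lick_times_s >= s) & (session.lick_times_s < e)
        assigned |= mask
        count = int(mask.sum())
        minutes = (e - s) / 60.0
        rows.append({"block": i, "start_s": s, "end_s": e, "laser_on": on,
                     "licks": count, "licks_per_min": count / minutes})
    out = pd.DataFrame(rows)
    out.attrs["excluded_licks"] = session.lick_times_s[~assigned].tolist()
    return out


def epoch_type_means(table: pd.DataFrame) -> dict:
    """Mean lick rate per laser state and the inhibition readout.

    Per-block rates are averaged within each laser state;
    delta = mean(non-opto) - mean(opto), and the animal is classified as
    inhibited when delta is strictly positive.
    """
    for state in (True, False):
        if not (table["laser_on"] == state).any():
            raise ValueError(f"epoch_type_means: no blocks with laser_on={state}")
    mean_opto = float(table.loc[table["laser_on"], "licks_per_min"].mean())
    mean_nonopto = float(table.loc[~table["laser_on"], "licks_per_min"].mean())
    delta = mean_nonopto - mean_opto
    return {"mean_opto": mean_opto, "mean_nonopto": mean_nonopto,
            "delta": delta, "inhibition": bool(delta > 0)}


def rtppa_metrics(session: RTPPASession) -> dict:
    """Time fraction in the stimulated chamber and distance per chamber.

    Each inter-sample interval is attributed to the chamber of its starting
    sample; distance is the Euclidean step length, attributed likewise.
    """
    t = session.positions["t_s"].to_numpy(dtype=float)
    x = session.positions["x_cm"].to_numpy(dtype=float)
    y = session.positions["y_cm"].to_numpy(dtype=float)
    chamber = session.chamber_of()
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("rtppa_metrics: position timestamps must be strictly increasing")
    step = np.hypot(np.diff(x), np.diff(y))
    start_chamber = chamber[:-1]
    time_in = {c: float(dt[start_chamber == c].sum()) for c in ("A", "B")}
    dist_in = {c: float(step[start_chamber == c].sum()) for c in ("A", "B")}
    total = time_in["A"] + time_in["B"]
    pct_time = {c: 100.0 * time_in[c] / total for c in ("A", "B")}
    return {
        "pct_time_stim": pct_time[session.stim_side],
        "pct_time": pct_time,
        "time_s": time_in,
        "distance_cm": dist_in,
    }


def preferred_side_day1(session: RTPPASession) -> str:
    """Chamber preferred on the habituation day; laser is paired to it on
    days 2-3. An exact 50/50 tie is broken toward chamber A with a warning."""
    m = rtppa_metrics(session)
    pa, pb = m["pct_time"]["A"], m["pct_time"]["B"]
    if pa == pb:
        warnings.warn("rtppa: exact 50/50 day-1 preference; tie broken toward chamber A")
        return "A"
    return "A" if pa > pb else "B"


def weir_ee(vo2: float, vco2: float) -> float:
    """Weir energy expenditure (kcal): EE = 3.9 * VO2 + 1.1 * VCO2."""
    if vo2 < 0 or vco2 < 0:
        raise ValueError("weir_ee: gas volumes must be non-negative")
    return 3.9 * vo2 + 1.1 * vco2


def rq(vo2: float, vco2: float) -> float:
    """Respiratory quotient: VCO2 / VO2."""
    if vo2 <= 0:
        raise ValueError("rq: vo2 must be positive")
    if vco2 < 0:
        raise ValueError("rq: vco2 must be non-negative")
    return vco2 / vo2
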