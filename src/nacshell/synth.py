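"""Synthetic-data generators for every pipeline input.

Each simulator is a pure function of its config (including the seed) and
returns ground truth alongside the data, so downstream stages can be tested
as parameter-recovery problems:

* photometry: two co-recorded channels sharing a slow motion artifact
  (Ornstein-Uhlenbeck) and per-channel exponential bleaching; calcium
  transients enter only the signal channel as difference-of-exponential
  kernels (pauses are negative-going);
* behavior: reward-task lick trains (homogeneous Poisson within access
  windows), optogenetic block designs with multiplicative laser
  suppression, aversive event schedules, and two-chamber occupancy with
  exponential dwell times;
* expression: sparse count matrices whose marker positivity and pairwise
  co-positivity follow configured probabilities via a Gaussian copula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import sparse
from scipy import stats as sps

from .behavior import OptoLickSession, RewardTaskSession, RTPPASession
from .expression import GeneCellMatrix
from .photometry import EventSeries, PhotometrySession

__all__ = [
    "PhotoSimConfig",
    "GroundTruth",
    "BehaviorSimConfig",
    "AversiveSession",
    "CountSimConfig",
    "event_kernel",
    "simulate_photometry_session",
    "simulate_photometry_cohort",
    "simulate_behavior_session",
    "simulate_count_matrix",
]


# ---------------------------------------------------------------- photometry

@dataclass
class PhotoSimConfig:
    """Two-channel photometry simulation parameters.

    Amplitudes are in dF/F0 percent; the signal/isosbestic baselines and
    artifact scales are in the same arbitrary fluorescence units. The
    default sampling rate matches the acquisition hardware (1017.3 Hz).
    """

    duration_s: float = 600.0
    fs_hz: float = 1017.3
    level_signal: float = 100.0   # a.u. baseline of the 465 nm channel
    level_iso: float = 80.0       # a.u. baseline of the 405 nm channel
    # fast initial bleaching, essentially complete before the 3-min trim:
    # bleach(t) = level * ((1 - frac) + frac * exp(-t / tau))
    bleach_tau_s: tuple = (25.0, 35.0)  # (signal, isosbestic)
    bleach_frac: float = 0.3
    motion_sd: float = 1.0        # a.u., stationary SD of the shared artifact
    motion_tau_s: float = 30.0
    noise_sd: float = 1.0         # a.u., white per channel
    event_times_s: tuple = ()
    event_kind: str = "reward_first_lick"
    kernel_kind: str = "none"     # pause | excitation | none
    kernel_amplitude_pct: float = 0.0
    kernel_rise_s: float = 0.5
    kernel_decay_s: float = 2.0
    coupling_405: float = 1.0     # gain of the shared artifact into the reference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("PhotoSimConfig: duration_s must be positive")
        if self.fs_hz <= 0:
            raise ValueError("PhotoSimConfig: fs_hz must be positive")
        for t in self.event_times_s:
            if not (0 <= t < self.duration_s):
                raise ValueError(f"PhotoSimConfig: event_times_s entry {t} outside [0, duration_s)")
        if self.kernel_kind not in ("pause", "excitation", "none"):
            raise ValueError(f"PhotoSimConfig: unknown kernel_kind {self.kernel_kind!r}")
        if self.kernel_kind == "pause" and self.kernel_amplitude_pct > 0:
            raise ValueError("PhotoSimConfig: kernel_amplitude_pct must be <= 0 for a pause")
        if self.kernel_kind == "excitation" and self.kernel_amplitude_pct < 0:
            raise ValueError("PhotoSimConfig: kernel_amplitude_pct must be >= 0 for an excitation")
        if not (0 < self.kernel_rise_s < self.kernel_decay_s):
            raise ValueError("PhotoSimConfig: need 0 < kernel_rise_s < kernel_decay_s")
        if self.motion_sd < 0 or self.noise_sd < 0:
            raise ValueError("PhotoSimConfig: motion_sd and noise_sd must be non-negative")
        if self.motion_tau_s <= 0:
            raise ValueError("PhotoSimConfig: motion_tau_s must be positive")
        if not (0.0 <= self.bleach_frac < 1.0):
            raise ValueError("PhotoSimConfig: bleach_frac must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Everything injected into a simulated photometry session."""

    time_s: np.ndarray
    true_dff_pct: np.ndarray
    event_amplitudes_pct: np.ndarray
    motion: np.ndarray
    bleach_signal: np.ndarray
    bleach_iso: np.ndarray
    noise_signal: np.ndarray
    noise_iso: np.ndarray


def event_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak transient k(t) = (exp(-t/decay) - exp(-t/rise)) / peak, t >= 0.

    The analytic peak sits at t* = rise*decay/(decay-rise) * ln(decay/rise).
    """
    t = np.asarray(t, dtype=float)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / decay_s) - np.exp(-t[pos] / rise_s)) / peak
    return out


def _ou_process(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path via its exact AR(1) discretization."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    eps = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    x0 = rng.normal(0.0, sd)
    out, _ = _signal.lfilter([1.0], [1.0, -a], eps, zi=np.array([a * x0]))
    return out


def simulate_photometry_session(cfg: PhotoSimConfig) -> tuple[PhotometrySession, GroundTruth]:
    """Generate a two-channel session plus its ground truth.

    signal  = bleach_s * (1 + dff/100) + motion + noise
    reference = bleach_i + coupling * motion + noise'
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz

    frac = cfg.bleach_frac
    bleach_s = cfg.level_signal * ((1.0 - frac) + frac * np.exp(-t / cfg.bleach_tau_s[0]))
    bleach_i = cfg.level_iso * ((1.0 - frac) + frac * np.exp(-t / cfg.bleach_tau_s[1]))

    dff = np.zeros(n)
    amps = np.full(len(cfg.event_times_s), float(cfg.kernel_amplitude_pct))
    if cfg.kernel_kind == "none":
        amps[:] = 0.0
    else:
        # the kernel is negligible beyond ~15 decay constants; inject locally
        support = 15.0 * cfg.kernel_decay_s
        for t_ev in cfg.event_times_s:
            i0 = int(np.searchsorted(t, t_ev))
            i1 = min(n, int(np.searchsorted(t, t_ev + support)))
            dff[i0:i1] += cfg.kernel_amplitude_pct * event_kernel(
                t[i0:i1] - t_ev, cfg.kernel_rise_s, cfg.kernel_decay_s)

    motion = _ou_process(n, 1.0 / cfg.fs_hz, cfg.motion_sd, cfg.motion_tau_s, rng)
    noise_s = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd else np.zeros(n)
    noise_i = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd else np.zeros(n)

    f_signal = bleach_s * (1.0 + dff / 100.0) + motion + noise_s
    f_iso = bleach_i + cfg.coupling_405 * motion + noise_i

    events = EventSeries(
        times_s=np.asarray(cfg.event_times_s, dtype=float),
        kinds=np.array([cfg.event_kind] * len(cfg.event_times_s), dtype=object),
        trial_ids=np.arange(len(cfg.event_times_s)),
    )
    session = PhotometrySession(time_s=t, f_signal=f_signal, f_iso=f_iso,
                                fs_hz=cfg.fs_hz, events=events)
    truth = GroundTruth(time_s=t, true_dff_pct=dff, event_amplitudes_pct=amps,
                        motion=motion, bleach_signal=bleach_s, bleach_iso=bleach_i,
                        noise_signal=noise_s, noise_iso=noise_i)
    return session, truth


def simulate_photometry_cohort(n_animals: int, base_cfg: PhotoSimConfig, seed: int,
                               iti_range_s: tuple = (20.0, 40.0),
                               n_events: int | None = None,
                               first_event_s: float = 195.0) -> dict:
    """Per-animal sessions with randomized event schedules.

    Event times follow the task structure (first event after the trimmed
    baseline, then uniform ITIs); each animal gets an independent seed
    derived from ``seed``.
    """
    n_events = n_events if n_events is not None else len(base_cfg.event_times_s) or 10
    ss = np.random.SeedSequence(seed)
    out = {}
    for i, child in enumerate(ss.spawn(n_animals)):
        sub = np.random.default_rng(child)
        itis = sub.uniform(*iti_range_s, size=n_events)
        ev = first_event_s + np.concatenate([[0.0], np.cumsum(itis[:-1])])
        duration = float(ev[-1] + 30.0)
        cfg = _replace_cfg(base_cfg, duration_s=duration,
                           event_times_s=tuple(ev),
                           seed=int(child.generate_state(1)[0] % (2 ** 31)))
        out[f"animal_{i:02d}"] = simulate_photometry_session(cfg)
    return out


def _replace_cfg(cfg, **kw):
    from dataclasses import replace
    return replace(cfg, **kw)


# ------------------------------------------------------------------ behavior

@dataclass
class AversiveSession:
    """Event-only aversive session (shock or tail lift)."""

    kind: str
    event_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)


@dataclass
class BehaviorSimConfig:
    """Behavioral-session simulation parameters.

    Protocol constants follow the task designs: 30 reward trials with 10 s
    access at 20-40 s ITIs, 10 shocks at 40-80 s ITIs, 5 tail lifts 5 min
    apart, and 5 x 5 min opto blocks with the laser on in blocks 1, 3, 5.
    Lick statistics and engagement are free parameters of the generator.
    """

    task: str  # reward | shock | tail_lift | opto_licking | rtppa
    n_trials: int = 30
    reward_window_s: float = 10.0
    iti_range_s: tuple = (20.0, 40.0)
    lick_rate_hz: float = 5.0
    p_engage: float = 0.9
    block_plan: tuple | None = None  # of (duration_s, laser_on)
    suppression_factor: float = 1.0
    chamber_exit_rates: tuple = (1.0 / 60.0, 1.0 / 60.0)  # exits/s for (A, B)
    session_duration_s: float = 900.0
    baseline_s: float = 190.0
    position_fs_hz: float = 10.0
    stim_side: str = "A"
    day: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("reward", "shock", "tail_lift", "opto_licking", "rtppa"):
            raise ValueError(f"BehaviorSimConfig: unknown task {self.task!r}")
        if self.iti_range_s[0] > self.iti_range_s[1]:
            raise ValueError("BehaviorSimConfig: iti_range_s lo must be <= hi")
        if not (0.0 < self.suppression_factor <= 1.0):
            raise ValueError("BehaviorSimConfig: suppression_factor must lie in (0, 1]")
        if not (0.0 <= self.p_engage <= 1.0):
            raise ValueError("BehaviorSimConfig: p_engage must lie in [0, 1]")
        if self.iti_range_s[0] < self.reward_window_s and self.task == "reward":
            raise ValueError("BehaviorSimConfig: ITIs must be at least one reward window "
                             "(windows must not overlap)")
        if self.lick_rate_hz < 0:
            raise ValueError("BehaviorSimConfig: lick_rate_hz must be non-negative")
        if any(r <= 0 for r in self.chamber_exit_rates):
            raise ValueError("BehaviorSimConfig: chamber_exit_rates must be positive")


DEFAULT_BLOCK_PLANS = {
    "five_block_5min": tuple((300.0, on) for on in (True, False, True, False, True)),
    "three_block_8min": tuple((480.0, on) for on in (False, True, False)),
}


def _poisson_train(rng: np.random.Generator, start: float, end: float, rate_hz: float) -> np.ndarray:
    if rate_hz <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate_hz * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def simulate_behavior_session(cfg: BehaviorSimConfig):
    """Dispatch to the task-specific generator; pure in (config, seed)."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.task == "reward":
        itis = rng.uniform(*cfg.iti_range_s, size=cfg.n_trials)
        onsets = cfg.baseline_s + np.cumsum(itis)
        licks = []
        for onset in onsets:
            if rng.uniform() < cfg.p_engage:
                licks.append(_poisson_train(rng, onset, onset + cfg.reward_window_s,
                                            cfg.lick_rate_hz))
        lick_times = np.sort(np.concatenate(licks)) if licks else np.empty(0)
        return RewardTaskSession(trial_onsets_s=onsets, lick_times_s=lick_times,
                                 reward_window_s=cfg.reward_window_s)
    if cfg.task in ("shock", "tail_lift"):
        itis = rng.uniform(*cfg.iti_range_s, size=cfg.n_trials)
        onsets = cfg.baseline_s + np.cumsum(itis)
        kind = "shock_onset" if cfg.task == "shock" else "lift_onset"
        return AversiveSession(kind=kind, event_times_s=onsets)
    if cfg.task == "opto_licking":
        plan = cfg.block_plan or DEFAULT_BLOCK_PLANS["five_block_5min"]
        blocks, licks, t0 = [], [], 0.0
        for duration, laser_on in plan:
            rate = cfg.lick_rate_hz * (cfg.suppression_factor if laser_on else 1.0)
            licks.append(_poisson_train(rng, t0, t0 + duration, rate))
            blocks.append((t0, t0 + duration, laser_on))
            t0 += duration
        name = "five_block_5min" if len(plan) == 5 else "three_block_8min"
        return OptoLickSession(blocks=blocks, lick_times_s=np.concatenate(licks),
                               protocol=name)
    if cfg.task == "rtppa":
        return _simulate_rtppa(cfg, rng)
    raise AssertionError("unreachable")


def _simulate_rtppa(cfg: BehaviorSimConfig, rng: np.random.Generator) -> RTPPASession:
    """Two-state chamber sequence with exponential dwell times, positions
    sampled uniformly inside the current 30 x 30 cm chamber at 10 Hz."""
    box = 30.0
    rates = {"A": cfg.chamber_exit_rates[0], "B": cfg.chamber_exit_rates[1]}
    chamber = "A" if rng.uniform() < 0.5 else "B"
    switches, t = [], 0.0
    while t < cfg.session_duration_s:
        dwell = rng.exponential(1.0 / rates[chamber])
        switches.append((t, chamber))
        t += dwell
        chamber = "B" if chamber == "A" else "A"
    times = np.arange(0.0, cfg.session_duration_s, 1.0 / cfg.position_fs_hz)
    switch_t = np.array([s[0] for s in switches])
    switch_c = np.array([s[1] for s in switches])
    idx = np.searchsorted(switch_t, times, side="right") - 1
    cur = switch_c[idx]
    x = np.where(cur == "A", rng.uniform(0, box, times.size),
                 rng.uniform(box, 2 * box, times.size))
    y = rng.uniform(0, box, times.size)
    positions = pd.DataFrame({"t_s": times, "x_cm": x, "y_cm": y})
    return RTPPASession(positions=positions, stim_side=cfg.stim_side,
                        day=cfg.day, box_size_cm=box)


# -------------------------------------------------------------- count matrix

@dataclass
class CountSimConfig:
    """Sparse count matrix with controlled marker (co-)positivity.

    ``positivity_probs[marker]`` is P(count >= 1); ``joint_probs[(a, b)]``
    is P(both >= 1) for a marker pair. Non-marker genes carry lognormal
    expression rates scaled so cells detect on the order of ``mean_depth``
    transcripts, giving the filter step realistic work.
    """

    n_genes: int = 2000
    n_cells: int = 2000
    marker_names: tuple = ()
    positivity_probs: dict = field(default_factory=dict)
    joint_probs: dict = field(default_factory=dict)
    mean_depth: float = 5000.0
    depth_sd_log: float = 0.3   # per-cell depth factor, lognormal sigma
    gene_rate_sd_log: float = 1.0
    marker_extra_mean: float = 1.0  # extra copies above 1 in positive cells
    seed: int = 0

    def __post_init__(self) -> None:
        self.marker_names = tuple(self.marker_names)
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("CountSimConfig: duplicate marker names")
        if self.n_genes < len(self.marker_names):
            raise ValueError("CountSimConfig: n_genes smaller than number of markers")
        for mk in self.marker_names:
            p = self.positivity_probs.get(mk)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(f"CountSimConfig: positivity_probs[{mk!r}] must lie in [0, 1]")
        for (a, b), pj in self.joint_probs.items():
            if a not in self.marker_names or b not in self.marker_names:
                raise ValueError(f"CountSimConfig: joint_probs pair ({a!r}, {b!r}) not in marker_names")
            pa, pb = self.positivity_probs[a], self.positivity_probs[b]
            if not (0.0 <= pj <= 1.0):
                raise ValueError(f"CountSimConfig: joint_probs[({a!r}, {b!r})] must lie in [0, 1]")
            if pj > min(pa, pb) + 1e-12:
                raise ValueError(f"CountSimConfig: joint_probs[({a!r}, {b!r})]={pj} exceeds "
                                 f"min of marginals ({min(pa, pb)})")
            if pj < max(0.0, pa + pb - 1.0) - 1e-12:
                raise ValueError(f"CountSimConfig: joint_probs[({a!r}, {b!r})]={pj} below the "
                                 f"Frechet lower bound ({max(0.0, pa + pb - 1.0)})")


def _bvn_cdf(za: float, zb: float, rho: float) -> float:
    return float(sps.multivariate_normal(mean=[0.0, 0.0],
                                         cov=[[1.0, rho], [rho, 1.0]],
                                         allow_singular=True).cdf([za, zb]))


def _solve_pair_rho(pa: float, pb: float, pj: float) -> float:
    """Latent Gaussian correlation giving P(Z_a < za, Z_b < zb) = pj."""
    from scipy.optimize import brentq
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return 0.0  # joint is determined by the marginals
    if abs(pj - pa * pb) < 1e-12:
        return 0.0
    if abs(pj - min(pa, pb)) < 1e-12:
        return 1.0
    if abs(pj - max(0.0, pa + pb - 1.0)) < 1e-12:
        return -1.0
    za, zb = sps.norm.ppf(pa), sps.norm.ppf(pb)
    return float(brentq(lambda r: _bvn_cdf(za, zb, r) - pj, -0.999999, 0.999999,
                        xtol=1e-10))


def simulate_count_matrix(cfg: CountSimConfig, return_truth: bool = False):
    """Generate a GeneCellMatrix (genes x cells) with controlled marker structure.

    Empirical per-marker positivity and pairwise co-positivity converge to
    the configured probabilities as n_cells grows.
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.marker_names)

    # latent Gaussian copula for marker indicators
    corr = np.eye(k)
    order = {mk: i for i, mk in enumerate(cfg.marker_names)}
    for (a, b), pj in cfg.joint_probs.items():
        rho = _solve_pair_rho(cfg.positivity_probs[a], cfg.positivity_probs[b], pj)
        corr[order[a], order[b]] = corr[order[b], order[a]] = rho
    if k:
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-8:
            raise ValueError("CountSimConfig: joint_probs are jointly infeasible "
                             "(latent correlation matrix is not positive semidefinite)")
        z = rng.multivariate_normal(np.zeros(k), corr, size=cfg.n_cells, method="eigh")
        thresholds = sps.norm.ppf([cfg.positivity_probs[mk] for mk in cfg.marker_names])
        positive = z < thresholds[None, :]  # cells x markers
    else:
        positive = np.zeros((cfg.n_cells, 0), dtype=bool)

    marker_counts = np.zeros((k, cfg.n_cells), dtype=np.int32)
    for i in range(k):
        pos = positive[:, i]
        marker_counts[i, pos] = 1 + rng.poisson(cfg.marker_extra_mean, size=int(pos.sum()))

    # background genes: lognormal per-gene rates, lognormal per-cell depth
    n_bg = cfg.n_genes - k
    depth = np.exp(rng.normal(0.0, cfg.depth_sd_log, size=cfg.n_cells))
    depth /= depth.mean()
    rates = np.exp(rng.normal(0.0, cfg.gene_rate_sd_log, size=n_bg))
    rates *= cfg.mean_depth / max(rates.sum(), 1e-300)

    chunks = []
    chunk_cells = max(1, int(5e6 // max(n_bg, 1)))
    for start in range(0, cfg.n_cells, chunk_cells):
        d = depth[start:start + chunk_cells]
        lam = rates[:, None] * d[None, :]
        chunks.append(sparse.csr_matrix(rng.poisson(lam).astype(np.int32)))
    bg = sparse.hstack(chunks, format="csr") if chunks else sparse.csr_matrix((0, cfg.n_cells))

    counts = sparse.vstack([sparse.csr_matrix(marker_counts), bg], format="csr")
    gene_names = np.array(list(cfg.marker_names)
                          + [f"gene_{i:05d}" for i in range(n_bg)], dtype=object)
    cell_ids = np.array([f"cell_{i:06d}" for i in range(cfg.n_cells)], dtype=object)
    matrix = GeneCellMatrix(counts=counts, gene_names=gene_names, cell_ids=cell_ids)
    if return_truth:
        truth = {mk: positive[:, i].copy() for i, mk in enumerate(cfg.marker_names)}
        return matrix, truth
    return matrix
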