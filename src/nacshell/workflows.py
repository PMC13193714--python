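"""Cohort-level experiment drivers built from the library primitives.

These functions wire the simulators to the analysis chain at the study's
conditions (sampling rate, trim, windows, epochs, trial counts) and are
used by the analysis scripts, the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import behavior as bh
from . import events as ev
from . import expression as ex
from . import photometry as ph
from . import stats as st
from . import synth

__all__ = [
    "photometry_cohort_contrast",
    "null_calibration",
    "amplitude_recovery",
    "motion_correction_ratio",
    "opto_inhibition_rate",
    "gse_scale_count_config",
    "coexpression_recovery",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def photometry_cohort_contrast(n_animals: int = 8, n_events: int = 10,
                               amplitude_pct: float = -3.0, noise_sd: float = 1.0,
                               motion_sd: float = 1.0, seed: int = 0,
                               statistic: str = "min",
                               iti_range_s: tuple = (20.0, 40.0),
                               params: ph.PreprocessParams | None = None):
    """Simulate one cohort, run the full chain, contrast baseline vs event epoch.

    Returns (aligned trials, epoch metrics, paired sample, t-test result).
    """
    if amplitude_pct < 0:
        kind = "pause"
    elif amplitude_pct > 0:
        kind = "excitation"
    else:
        kind = "none"
    cfg = synth.PhotoSimConfig(kernel_kind=kind, kernel_amplitude_pct=amplitude_pct,
                               noise_sd=noise_sd, motion_sd=motion_sd)
    cohort = synth.simulate_photometry_cohort(n_animals, cfg, seed=seed,
                                              n_events=n_events, iti_range_s=iti_range_s)
    results = {a: ph.preprocess_around_events(s, params) for a, (s, _t) in cohort.items()}
    trials = ev.align_cohort(results)
    trials = ev.baseline_correct(trials, (-10.0, -1.0))
    metrics = ev.epoch_metrics(trials, ev.EpochDefinition((-6.0, -1.0), (0.0, 5.0), statistic))
    pair = ev.epoch_contrast(metrics)
    ttest = st.paired_t(pair, name=f"epoch {statistic} baseline vs event")
    return trials, metrics, pair, ttest


def null_calibration(n_cohorts: int = 500, n_animals: int = 8, n_events: int = 10,
                     seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I-error rate of the full chain on kernel-free cohorts.

    Each cohort runs preprocess -> align -> baseline-correct -> epoch minima
    contrast -> paired t; the fraction of cohorts rejecting at ``alpha``
    estimates the pipeline's false-positive rate.
    """
    rejections = 0
    for s in _child_seeds(seed, n_cohorts):
        *_, ttest = photometry_cohort_contrast(
            n_animals=n_animals, n_events=n_events, amplitude_pct=0.0, seed=int(s))
        rejections += ttest.p_raw < alpha
    return {"rejection_rate": rejections / n_cohorts, "n_cohorts": n_cohorts,
            "alpha": alpha}


def amplitude_recovery(n_cohorts: int = 50, n_animals: int = 8, n_events: int = 10,
                       amplitude_pct: float = -3.0, noise_sd: float = 1.0,
                       seed: int = 0, alpha: float = 0.05) -> dict:
    """Recovery of a known pause amplitude across seeded cohorts.

    Reports the median recovered event-epoch minimum (cohort median of
    per-cohort median animal minima) and the fraction of cohorts whose
    paired contrast is significant.
    """
    minima, significant = [], 0
    for s in _child_seeds(seed, n_cohorts):
        _, _, pair, ttest = photometry_cohort_contrast(
            n_animals=n_animals, n_events=n_events, amplitude_pct=amplitude_pct,
            noise_sd=noise_sd, seed=int(s))
        minima.append(float(np.median(pair.condition_b)))
        significant += ttest.p_raw < alpha
    return {
        "median_recovered_min_pct": float(np.median(minima)),
        "true_amplitude_pct": amplitude_pct,
        "detection_rate": significant / n_cohorts,
        "n_cohorts": n_cohorts,
    }


def motion_correction_ratio(seed: int = 0, n_animals: int = 4, n_events: int = 8,
                            motion_sd: float = 2.0, noise_sd: float = 0.05) -> float:
    """RMS of signal-free dF/F0 without vs with the isosbestic fit.

    Both runs share the same simulated cohort (shared motion artifact, no
    calcium signal); the reference run replaces F0 by the window mean.
    Values well above 1 mean the isosbestic regression removes artifact the
    naive baseline cannot.
    """
    cfg = synth.PhotoSimConfig(kernel_kind="none", motion_sd=motion_sd,
                               noise_sd=noise_sd, coupling_405=1.0)
    cohort = synth.simulate_photometry_cohort(n_animals, cfg, seed=seed,
                                              n_events=n_events)

    def _rms(mode: str) -> float:
        params = ph.PreprocessParams(baseline_mode=mode)
        res = {a: ph.preprocess_around_events(s, params) for a, (s, _t) in cohort.items()}
        trials = ev.align_cohort(res)
        return float(np.sqrt(np.mean(trials.matrix ** 2)))

    return _rms("window_mean") / _rms("isosbestic")


def opto_inhibition_rate(n_seeds: int = 100, suppression_factor: float = 0.5,
                         lick_rate_hz: float = 2.0, seed: int = 0) -> float:
    """Fraction of simulated animals classified as lick-inhibited.

    Each seed simulates one five-block session and applies the
    mean(non-opto) - mean(opto) > 0 classification.
    """
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        ses = synth.simulate_behavior_session(synth.BehaviorSimConfig(
            task="opto_licking", lick_rate_hz=lick_rate_hz,
            suppression_factor=suppression_factor, seed=int(s)))
        hits += bh.epoch_type_means(bh.licks_per_block(ses))["inhibition"]
    return hits / n_seeds


# ---- marker co-expression at single-cell-atlas scale ----------------------

# Ground-truth population parameters for the NAc-atlas-scale synthetic
# matrix: receptor marginals are plausible SPN fractions; the conditional
# probabilities of carrying Stard5/Peg10 given each receptor are the
# quantities the co-expression analysis recovers.
ATLAS_N_CELLS = 36670
ATLAS_MARGINALS = {"Drd1a": 0.35, "Drd2": 0.30, "Stard5": 0.22, "Peg10": 0.10}
ATLAS_CONDITIONALS = {
    ("Stard5", "Drd1a"): 0.2955,  # P(Stard5+ | Drd1a+)
    ("Stard5", "Drd2"): 0.3819,
    ("Peg10", "Drd1a"): 0.1672,
    ("Peg10", "Drd2"): 0.1609,
}
def gse_scale_count_config(seed: int = 0, n_cells: int = ATLAS_N_CELLS) -> synth.CountSimConfig:
    """Synthetic count-matrix config at single-cell-atlas scale.

    The receptor-receptor (Drd1a, Drd2) joint is left unspecified: the
    recovered probe-in-receptor proportions do not depend on it, and the
    latent-Gaussian dependence model cannot combine near-disjoint receptor
    classes with both probes positively coupled to both receptors.
    """
    joints = {pair: ATLAS_MARGINALS[pair[1]] * p for pair, p in ATLAS_CONDITIONALS.items()}
    return synth.CountSimConfig(
        n_genes=2000, n_cells=n_cells,
        marker_names=tuple(ATLAS_MARGINALS),
        positivity_probs=dict(ATLAS_MARGINALS),
        joint_probs=joints,
        mean_depth=5000.0, seed=seed,
    )


def coexpression_recovery(seed: int = 0, n_cells: int = ATLAS_N_CELLS) -> dict:
    """Filter an atlas-scale synthetic matrix and recover the configured
    co-expression percentages (single-copy positivity, post-filter)."""
    matrix = synth.simulate_count_matrix(gse_scale_count_config(seed, n_cells))
    filtered = ex.filter_matrix(matrix, min_cells=3, min_features=1250)
    out = {"n_cells_total": matrix.shape[1], "n_cells_after_filter": filtered.shape[1],
           "n_genes_after_filter": filtered.shape[0]}
    for (probe, receptor), p in ATLAS_CONDITIONALS.items():
        key = f"{probe.lower()}_in_{receptor.lower()}_pct"
        out[key] = ex.coexpression_fraction(filtered, probe, receptor, denominator="b")
        out[key + "_true"] = 100.0 * p
    return out
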