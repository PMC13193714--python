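"""Generator contracts: determinism, signal decomposition, kernel shape,
behavioral timing, and count-matrix (co-)positivity convergence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nacshell import behavior as bh
from nacshell import synth
from nacshell.synth import (
    BehaviorSimConfig,
    CountSimConfig,
    PhotoSimConfig,
    event_kernel,
    simulate_behavior_session,
    simulate_count_matrix,
    simulate_photometry_session,
)


def kernel_oracle(t, rise, decay):
    """Direct evaluation of the difference-of-exponentials transient."""
    import math
    tp = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)
    out = np.where(t >= 0, (np.exp(-t / decay) - np.exp(-t / rise)) / peak, 0.0)
    return out


class TestPhotometrySim:
    def test_no_signal_case_is_flat(self):
        cfg = PhotoSimConfig(duration_s=20.0, kernel_kind="none",
                             motion_sd=0.0, noise_sd=0.0)
        ses, truth = simulate_photometry_session(cfg)
        assert np.all(truth.true_dff_pct == 0.0)
        np.testing.assert_allclose(ses.f_signal / truth.bleach_signal, 1.0, rtol=1e-12)

    def test_pause_kernel_minimum_matches_grid_evaluation(self):
        cfg = PhotoSimConfig(duration_s=30.0, kernel_kind="pause",
                             kernel_amplitude_pct=-3.0, event_times_s=(10.0,),
                             motion_sd=0.0, noise_sd=0.0)
        ses, truth = simulate_photometry_session(cfg)
        t = np.arange(len(ses)) / cfg.fs_hz
        mask = (t >= 10.0) & (t <= 15.0)
        expected = -3.0 * kernel_oracle(t[mask] - 10.0, cfg.kernel_rise_s,
                                        cfg.kernel_decay_s).max()
        assert np.min(truth.true_dff_pct[mask]) == pytest.approx(expected, rel=1e-9)

    def test_same_seed_bit_identical(self):
        cfg = PhotoSimConfig(duration_s=15.0, kernel_kind="excitation",
                             kernel_amplitude_pct=2.0, event_times_s=(5.0,), seed=42)
        s1, t1 = simulate_photometry_session(cfg)
        s2, t2 = simulate_photometry_session(cfg)
        assert np.array_equal(s1.f_signal, s2.f_signal)
        assert np.array_equal(s1.f_iso, s2.f_iso)
        assert np.array_equal(t1.motion, t2.motion)

    def test_signal_decomposition_reconstructs_dff_term(self):
        cfg = PhotoSimConfig(duration_s=25.0, kernel_kind="pause",
                             kernel_amplitude_pct=-4.0, event_times_s=(8.0, 18.0),
                             seed=7)
        ses, tr = simulate_photometry_session(cfg)
        residual = ses.f_signal - tr.motion - tr.noise_signal - tr.bleach_signal
        np.testing.assert_allclose(residual, tr.bleach_signal * tr.true_dff_pct / 100.0,
                                   atol=1e-9)

    def test_kernel_unit_peak_and_causality(self):
        import math
        rise, decay = 0.5, 2.0
        t = np.linspace(-2.0, 20.0, 4001)
        k = event_kernel(t, rise, decay)
        assert np.all(k[t < 0] == 0.0)
        assert k.max() <= 1.0 + 1e-12
        assert k.max() == pytest.approx(1.0, abs=1e-4)
        t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
        assert event_kernel(np.array([t_peak]), rise, decay)[0] == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("field,kw", [
        ("duration_s", {"duration_s": 0.0}),
        ("fs_hz", {"fs_hz": -1.0}),
        ("event_times_s", {"event_times_s": (999.0,), "duration_s": 10.0}),
        ("kernel_amplitude_pct", {"kernel_kind": "pause", "kernel_amplitude_pct": 1.0}),
        ("kernel_amplitude_pct", {"kernel_kind": "excitation", "kernel_amplitude_pct": -1.0}),
        ("kernel_rise_s", {"kernel_rise_s": 3.0, "kernel_decay_s": 2.0}),
    ])
    def test_invalid_config_names_field(self, field, kw):
        with pytest.raises(ValueError, match=field):
            PhotoSimConfig(**kw)


class TestBehaviorSim:
    def test_reward_itis_within_bounds_and_windows_disjoint(self):
        cfg = BehaviorSimConfig(task="reward", n_trials=30, iti_range_s=(20, 40), seed=3)
        ses = simulate_behavior_session(cfg)
        gaps = np.diff(np.concatenate([[cfg.baseline_s], ses.trial_onsets_s]))
        assert np.all((gaps >= 20) & (gaps <= 40))
        assert np.all(np.diff(ses.trial_onsets_s) >= cfg.reward_window_s)

    def test_full_engagement_gives_all_successes(self):
        cfg = BehaviorSimConfig(task="reward", p_engage=1.0, lick_rate_hz=50.0, seed=1)
        ses = simulate_behavior_session(cfg)
        _, summary = bh.score_trials(ses)
        assert summary["success_pct"] == 100

    def test_no_suppression_equalizes_block_rates(self):
        # suppression 1.0: expected licks/min equal across laser states
        rates_on, rates_off = [], []
        for seed in range(30):
            ses = simulate_behavior_session(BehaviorSimConfig(
                task="opto_licking", lick_rate_hz=2.0, suppression_factor=1.0, seed=seed))
            tab = bh.licks_per_block(ses)
            rates_on.append(tab.loc[tab.laser_on, "licks_per_min"].mean())
            rates_off.append(tab.loc[~tab.laser_on, "licks_per_min"].mean())
        # Poisson error of the mean rate over 30 x 5-min blocks is ~1%
        assert np.mean(rates_on) == pytest.approx(np.mean(rates_off), rel=0.05)

    def test_suppression_factor_sets_rate_ratio(self):
        # Monte-Carlo ratio vs the analytic expectation of 0.5
        on, off = [], []
        for seed in range(200):
            ses = simulate_behavior_session(BehaviorSimConfig(
                task="opto_licking", lick_rate_hz=2.0, suppression_factor=0.5, seed=seed))
            tab = bh.licks_per_block(ses)
            on.append(tab.loc[tab.laser_on, "licks_per_min"].mean())
            off.append(tab.loc[~tab.laser_on, "licks_per_min"].mean())
        assert np.mean(on) / np.mean(off) == pytest.approx(0.5, abs=0.02)

    def test_aversive_sessions_are_event_only(self):
        ses = simulate_behavior_session(BehaviorSimConfig(
            task="shock", n_trials=10, iti_range_s=(40, 80), seed=2))
        assert ses.kind == "shock_onset"
        assert ses.event_times_s.size == 10

    def test_rtppa_positions_stay_inside_current_chamber(self):
        ses = simulate_behavior_session(BehaviorSimConfig(
            task="rtppa", session_duration_s=120.0, seed=4))
        x = ses.positions["x_cm"].to_numpy()
        y = ses.positions["y_cm"].to_numpy()
        assert np.all((x >= 0) & (x <= 60)) and np.all((y >= 0) & (y <= 30))
        assert set(ses.chamber_of()) <= {"A", "B"}

    def test_task_config_mismatch_rejected(self):
        with pytest.raises(ValueError, match="task"):
            BehaviorSimConfig(task="flying")
        with pytest.raises(ValueError, match="suppression_factor"):
            BehaviorSimConfig(task="opto_licking", suppression_factor=0.0)


class TestCountSim:
    def test_zero_positivity_marker_row_all_zero(self):
        cfg = CountSimConfig(n_genes=5, n_cells=500, marker_names=("A",),
                             positivity_probs={"A": 0.0}, seed=0)
        m = simulate_count_matrix(cfg)
        assert m.counts[m.gene_index("A")].nnz == 0

    def test_perfect_overlap_gives_identical_positive_sets(self):
        cfg = CountSimConfig(n_genes=4, n_cells=2000, marker_names=("A", "B"),
                             positivity_probs={"A": 0.3, "B": 0.3},
                             joint_probs={("A", "B"): 0.3}, mean_depth=5, seed=1)
        _, truth = simulate_count_matrix(cfg, return_truth=True)
        assert np.array_equal(truth["A"], truth["B"])

    def test_joint_positivity_converges(self):
        cfg = CountSimConfig(n_genes=10, n_cells=50_000, marker_names=("A", "B"),
                             positivity_probs={"A": 0.3, "B": 0.4},
                             joint_probs={("A", "B"): 0.12}, mean_depth=20, seed=2)
        _, truth = simulate_count_matrix(cfg, return_truth=True)
        assert truth["A"].mean() == pytest.approx(0.3, abs=0.01)
        assert truth["B"].mean() == pytest.approx(0.4, abs=0.01)
        assert (truth["A"] & truth["B"]).mean() == pytest.approx(0.12, abs=0.01)

    def test_infeasible_joint_rejected(self):
        with pytest.raises(ValueError, match="joint_probs"):
            CountSimConfig(n_genes=4, n_cells=10, marker_names=("A", "B"),
                           positivity_probs={"A": 0.1, "B": 0.2},
                           joint_probs={("A", "B"): 0.15})

    def test_seed_determinism(self):
        cfg = CountSimConfig(n_genes=20, n_cells=300, marker_names=("A",),
                             positivity_probs={"A": 0.5}, seed=9)
        m1 = simulate_count_matrix(cfg)
        m2 = simulate_count_matrix(cfg)
        assert (m1.counts != m2.counts).nnz == 0


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_photometry_simulator_pure_in_seed(seed):
    cfg = PhotoSimConfig(duration_s=2.0, seed=seed)
    s1, _ = simulate_photometry_session(cfg)
    s2, _ = simulate_photometry_session(cfg)
    assert np.array_equal(s1.f_signal, s2.f_signal)
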