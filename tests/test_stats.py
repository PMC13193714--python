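"""Paired t, mixed repeated-measures ANOVA and Sidak adjustment, checked
against closed forms, a brute-force sums-of-squares oracle and pingouin."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats as sps

from nacshell.events import PairedSample
from nacshell.stats import (
    StatResult,
    mixed_rm_anova,
    paired_t,
    sidak_adjust,
    sidak_posthoc,
)


def long_table(values_by_subject, groups):
    """values_by_subject: {subject: (v_level1, v_level2, ...)}; groups: {subject: g}."""
    rows = []
    for s, vals in values_by_subject.items():
        for i, v in enumerate(vals):
            rows.append({"unit": s, "group": groups[s], "within": f"L{i + 1}", "value": v})
    return pd.DataFrame(rows)


def anova_ss_oracle(df):
    """Brute-force split-plot sums of squares from cell/marginal means."""
    y = df["value"].to_numpy()
    gm = y.mean()
    b = df["within"].nunique()
    ss = {"total": ((y - gm) ** 2).sum()}
    subj = {s: g["value"].mean() for s, g in df.groupby("unit")}
    sgrp = {s: g["group"].iloc[0] for s, g in df.groupby("unit")}
    ss_bs = b * sum((m - gm) ** 2 for m in subj.values())
    ss["group"] = b * sum(len([s for s in sgrp if sgrp[s] == g]) *
                          (df[df.group == g]["value"].mean() - gm) ** 2
                          for g in df["group"].unique())
    ss["subjects_within_groups"] = ss_bs - ss["group"]
    ss["within"] = len(subj) * sum((df[df.within == w]["value"].mean() - gm) ** 2
                                   for w in df["within"].unique())
    ss_cells = sum(len([s for s in sgrp if sgrp[s] == g]) *
                   (df[(df.group == g) & (df.within == w)]["value"].mean() - gm) ** 2
                   for g in df["group"].unique() for w in df["within"].unique())
    ss["interaction"] = ss_cells - ss["group"] - ss["within"]
    ss["within_error"] = ss["total"] - ss_bs - ss["within"] - ss["interaction"]
    return ss


class TestPairedT:
    def test_identical_conditions_t_zero_p_one(self):
        s = PairedSample(units=list("abc"), condition_a=[1, 2, 3], condition_b=[1, 2, 3])
        r = paired_t(s)
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_closed_form_small_sample(self):
        # d = (1, 2, 3): mean 2, sd 1 -> t = 2 * sqrt(3), df = 2
        s = PairedSample(units=list("abc"), condition_a=[2, 4, 6], condition_b=[1, 2, 3])
        r = paired_t(s)
        assert r.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert r.df == 2

    def test_matches_scipy_reference(self, rng):
        a, b = rng.normal(size=(2, 12))
        r = paired_t(PairedSample(units=np.arange(12), condition_a=a, condition_b=b))
        ref = sps.ttest_rel(a, b)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_raw == pytest.approx(ref.pvalue, rel=1e-12)

    def test_equals_one_sample_t_of_differences(self, rng):
        a, b = rng.normal(size=(2, 9))
        r = paired_t(PairedSample(units=np.arange(9), condition_a=a, condition_b=b))
        ref = sps.ttest_1samp(a - b, 0.0)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_p_from_incomplete_beta_identity(self):
        # two-tailed p = I_{df/(df+t^2)}(df/2, 1/2), checked at a printed quantile
        s = PairedSample(units=np.arange(5),
                         condition_a=np.array([1.0, 2.0, 3.0, 4.0, 5.0]) * 1.3,
                         condition_b=np.zeros(5))
        r = paired_t(s)
        ref = special.betainc(r.df / 2, 0.5, r.df / (r.df + r.statistic ** 2))
        assert abs(r.p_raw - ref) < 1e-10

    def test_zero_variance_nonzero_mean_errors(self):
        s = PairedSample(units=list("ab"), condition_a=[2.0, 3.0], condition_b=[1.0, 2.0])
        with pytest.raises(ValueError, match="infinite"):
            paired_t(s)

    def test_type_one_error_calibration(self, rng):
        n_rep, n = 10_000, 5
        d = rng.normal(size=(n_rep, n))
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), n - 1)
        rate = (p < 0.05).mean()
        assert 0.041 <= rate <= 0.059


class TestMixedAnova:
    def clean_2x2(self):
        vals = {"s1": (3, 5), "s2": (4, 6), "s3": (5, 7),
                "s4": (7, 6), "s5": (8, 7), "s6": (9, 8)}
        grp = {s: ("g1" if s in ("s1", "s2", "s3") else "g2") for s in vals}
        return long_table(vals, grp)

    def test_hand_computed_2x2_decomposition(self):
        # additive dataset: all sums of squares computed by hand
        t = mixed_rm_anova(self.clean_2x2()).table
        assert t.loc["group", "SS"] == pytest.approx(18.75, abs=1e-10)
        assert t.loc["subjects_within_groups", "SS"] == pytest.approx(8.0, abs=1e-10)
        assert t.loc["within", "SS"] == pytest.approx(0.75, abs=1e-10)
        assert t.loc["interaction", "SS"] == pytest.approx(6.75, abs=1e-10)
        assert t.loc["within_error", "SS"] == pytest.approx(0.0, abs=1e-10)
        assert t.loc["group", "df"] == 1 and t.loc["within_error", "df"] == 4

    def test_matches_brute_force_oracle_random_design(self, rng):
        subjects = {f"s{i}": tuple(rng.normal(size=3)) for i in range(11)}
        groups = {s: ("a" if i < 4 else "b" if i < 8 else "c")
                  for i, s in enumerate(subjects)}
        df = long_table(subjects, groups)
        t = mixed_rm_anova(df).table
        oracle = anova_ss_oracle(df)
        for effect in ("group", "subjects_within_groups", "within",
                       "interaction", "within_error"):
            assert t.loc[effect, "SS"] == pytest.approx(oracle[effect], rel=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        subjects = {f"s{i}": tuple(rng.normal(size=2)) for i in range(12)}
        groups = {s: ("a" if i < 6 else "b") for i, s in enumerate(subjects)}
        df = long_table(subjects, groups)
        ours = mixed_rm_anova(df)
        ref = pg.mixed_anova(data=df, dv="value", within="within",
                             between="group", subject="unit")
        ref = ref.set_index("Source")
        assert ours.table.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert ours.table.loc["within", "F"] == pytest.approx(ref.loc["within", "F"], rel=1e-8)
        assert ours.table.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)
        assert ours.table.loc["group", "p"] == pytest.approx(
            ref.loc["group", "p_unc"], rel=1e-8)

    def test_all_equal_values_zero_ss(self):
        vals = {f"s{i}": (4.0, 4.0) for i in range(6)}
        grp = {s: ("a" if i < 3 else "b") for i, s in enumerate(vals)}
        t = mixed_rm_anova(long_table(vals, grp)).table
        assert t["SS"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(t.loc["interaction", "F"])  # zero error MS is flagged

    def test_interaction_f_tracks_effect_size(self, rng):
        def one(effect, seed):
            r = np.random.default_rng(seed)
            vals, grp = {}, {}
            for i in range(12):
                g = "a" if i < 6 else "b"
                # crossed shift: leaves subject and level means untouched
                s = effect / 2 if g == "a" else -effect / 2
                vals[f"s{i}"] = (r.normal() + s, r.normal() - s)
                grp[f"s{i}"] = g
            return mixed_rm_anova(long_table(vals, grp)).table
        f_null = np.mean([one(0.0, s).loc["interaction", "F"] for s in range(40)])
        f_big = np.mean([one(2.0, s).loc["interaction", "F"] for s in range(40)])
        g_big = np.mean([one(2.0, s).loc["group", "F"] for s in range(40)])
        assert f_big > 5 * f_null
        assert g_big < f_big / 2  # pure interaction leaves the group effect near null

    def test_incomplete_design_rejected(self):
        df = self.clean_2x2().iloc[:-1]
        with pytest.raises(ValueError, match="complete"):
            mixed_rm_anova(df)

    @given(st.integers(0, 10_000))
    def test_ss_conservation_property(self, seed):
        r = np.random.default_rng(seed)
        n_levels = int(r.integers(2, 4))
        vals = {f"s{i}": tuple(r.normal(size=n_levels)) for i in range(6)}
        grp = {s: ("a" if i < 3 else "b") for i, s in enumerate(vals)}
        res = mixed_rm_anova(long_table(vals, grp))
        assert res.table["SS"].sum() == pytest.approx(res.ss_total, rel=1e-8, abs=1e-10)


class TestSidak:
    def test_identity_and_limits(self):
        assert sidak_adjust(0.3, 1) == 0.3
        assert sidak_adjust(0.0, 7) == 0.0
        assert sidak_adjust(1.0, 7) == 1.0

    def test_spot_value(self):
        assert sidak_adjust(0.02, 3) == pytest.approx(0.058808, abs=1e-9)

    @given(st.floats(0.0, 1.0), st.integers(1, 20))
    def test_never_below_raw(self, p, m):
        assert sidak_adjust(p, m) >= p - 1e-15


class TestSidakPosthoc:
    def build(self, n_per_group=(10, 13, 11), seed=0, shift=0.0):
        r = np.random.default_rng(seed)
        vals, grp = {}, {}
        i = 0
        for g, n in zip(("ctrl", "rostral", "caudal"), n_per_group):
            for _ in range(n):
                s = shift if g == "rostral" else 0.0
                vals[f"s{i}"] = (r.normal(), r.normal() - s)
                grp[f"s{i}"] = g
                i += 1
        return long_table(vals, grp)

    def test_error_df_pattern(self):
        # 34 animals in 3 groups, 2 within levels -> shared error df 31
        df = self.build()
        res = mixed_rm_anova(df)
        out = sidak_posthoc(df, res, "L1", "L2")
        assert all(r.df == 31 for r in out)
        assert all(r.m == 3 for r in out)

    def test_t_closed_form_balanced(self, rng):
        vals = {f"s{i}": tuple(rng.normal(size=2)) for i in range(8)}
        grp = {s: ("a" if i < 4 else "b") for i, s in enumerate(vals)}
        df = long_table(vals, grp)
        res = mixed_rm_anova(df)
        out = sidak_posthoc(df, res, "L1", "L2")
        ms_e = res.table.loc["within_error", "MS"]
        for r, g in zip(out, ("a", "b")):
            sub = df[df.group == g]
            delta = (sub[sub.within == "L1"]["value"].mean()
                     - sub[sub.within == "L2"]["value"].mean())
            assert r.statistic == pytest.approx(delta / np.sqrt(2 * ms_e / 4), rel=1e-10)

    def test_adjusted_never_below_raw(self):
        df = self.build(seed=5, shift=1.0)
        out = sidak_posthoc(df, mixed_rm_anova(df), "L1", "L2")
        assert all(r.p_adjusted >= r.p_raw for r in out)

    def test_identical_level_means_give_t_zero(self):
        vals = {f"s{i}": (float(i), float(i)) for i in range(6)}
        grp = {s: ("a" if i < 3 else "b") for i, s in enumerate(vals)}
        df = long_table(vals, grp)
        with pytest.raises(ValueError, match="zero"):
            # zero within-error MS cannot support a contrast
            sidak_posthoc(df, mixed_rm_anova(df), "L1", "L2")


def test_statresult_validates_probability_ranges():
    with pytest.raises(ValueError):
        StatResult("x", 1.0, 3, p_raw=1.5)
    with pytest.raises(ValueError):
        StatResult("x", 1.0, 3, p_raw=0.5, p_adjusted=0.3)
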