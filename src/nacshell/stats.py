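"""Inferential statistics: paired t-tests, mixed repeated-measures ANOVA,
Sidak-adjusted post-hoc contrasts.

The mixed (split-plot) design has one between-subjects factor (group) and
one within-subjects factor (epoch/day), every subject observed at every
within level. The classical decomposition tests the group effect against
the subjects-within-groups mean square and the within/interaction effects
against the within-subjects error mean square; no sphericity correction is
applied (exact anyway for two within levels). Post-hoc contrasts of within
levels inside each group reuse the within-error mean square and its
degrees of freedom, so all groups share one error df, and their raw
p-values are Sidak-adjusted over the family of groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import PairedSample

__all__ = [
    "StatResult",
    "AnovaTable",
    "paired_t",
    "mixed_rm_anova",
    "sidak_adjust",
    "sidak_posthoc",
]


@dataclass
class StatResult:
    """A single test: statistic, df, raw and (optionally) adjusted p."""

    name: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None
    m: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("StatResult: p_raw must lie in [0, 1]")
        if self.p_adjusted is not None:
            if not (0.0 <= self.p_adjusted <= 1.0):
                raise ValueError("StatResult: p_adjusted must lie in [0, 1]")
            if self.p_adjusted < self.p_raw - 1e-12:
                raise ValueError("StatResult: p_adjusted cannot undercut p_raw")


@dataclass
class AnovaTable:
    """Mixed-design ANOVA decomposition with both error strata."""

    table: pd.DataFrame  # index: effect; columns: SS, df, MS, F, p
    ss_total: float
    grand_mean: float

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def paired_t(sample: PairedSample, name: str = "paired_t") -> StatResult:
    """Two-tailed paired Student's t-test.

    t = mean(d) / (sd(d) / sqrt(n)) with d = a - b and the n-1 sample
    standard deviation; df = n - 1.
    """
    d = sample.condition_a - sample.condition_b
    n = d.size
    if n < 2:
        raise ValueError("paired_t: need at least 2 pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return StatResult(name, 0.0, n - 1, 1.0)
        raise ValueError("paired_t: zero variance of differences with nonzero mean (infinite t)")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult(name, float(t), float(n - 1), float(min(p, 1.0)))


def _check_complete(data: pd.DataFrame, subject: str, within: str, between: str) -> None:
    counts = data.groupby([subject, within], observed=True).size()
    levels = data[within].nunique()
    per_subj = counts.groupby(level=0, observed=True).size()
    if (counts != 1).any() or (per_subj != levels).any():
        raise ValueError("mixed_rm_anova: design must be complete "
                         "(every subject observed exactly once at every within level)")
    groups_per_subject = data.groupby(subject, observed=True)[between].nunique()
    if (groups_per_subject != 1).any():
        raise ValueError("mixed_rm_anova: each subject must belong to exactly one group")


def mixed_rm_anova(data: pd.DataFrame, dv: str = "value", within: str = "within",
                   between: str = "group", subject: str = "unit") -> AnovaTable:
    """Classical mixed (split-plot) ANOVA from a long-format table.

    Between effect F = MS_between / MS_subjects-within-groups; within and
    interaction F = MS / MS_within-error. Balanced within-structure is
    required; group sizes may differ.
    """
    _check_complete(data, subject, within, between)
    y = data[dv].to_numpy(dtype=float)
    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    b = data[within].nunique()

    subj_means = data.groupby(subject, observed=True)[dv].mean()
    subj_group = data.groupby(subject, observed=True)[between].first()
    group_means = data.groupby(between, observed=True)[dv].mean()
    level_means = data.groupby(within, observed=True)[dv].mean()
    cell_means = data.groupby([between, within], observed=True)[dv].mean()
    n_per_group = subj_group.value_counts()
    n_subj = len(subj_means)

    ss_between_subj = float(b * ((subj_means - gm) ** 2).sum())
    ss_group = float(b * sum(n_per_group[g] * (group_means[g] - gm) ** 2
                             for g in group_means.index))
    ss_subj_within = ss_between_subj - ss_group
    ss_within_subj = ss_total - ss_between_subj
    ss_level = float(n_subj * ((level_means - gm) ** 2).sum())
    ss_cells = float(sum(n_per_group[g] * (cell_means[(g, w)] - gm) ** 2
                         for (g, w) in cell_means.index))
    ss_interaction = ss_cells - ss_group - ss_level
    ss_error = ss_within_subj - ss_level - ss_interaction

    a = len(group_means)
    df_group = a - 1
    df_subj = n_subj - a
    df_level = b - 1
    df_inter = (a - 1) * (b - 1)
    df_error = (n_subj - a) * (b - 1)

    rows = {}
    ms_subj = ss_subj_within / df_subj if df_subj > 0 else np.nan
    ms_error = ss_error / df_error if df_error > 0 else np.nan

    def _row(ss, df, ms_err, df_err):
        ms = ss / df if df > 0 else np.nan
        if df > 0 and np.isfinite(ms_err) and ms_err > 0:
            f = ms / ms_err
            p = float(sps.f.sf(f, df, df_err))
        else:
            f, p = np.nan, np.nan
        return {"SS": ss, "df": df, "MS": ms, "F": f, "p": p}

    rows["group"] = _row(ss_group, df_group, ms_subj, df_subj)
    rows["subjects_within_groups"] = {"SS": ss_subj_within, "df": df_subj,
                                      "MS": ms_subj, "F": np.nan, "p": np.nan}
    rows["within"] = _row(ss_level, df_level, ms_error, df_error)
    rows["interaction"] = _row(ss_interaction, df_inter, ms_error, df_error)
    rows["within_error"] = {"SS": ss_error, "df": df_error,
                            "MS": ms_error, "F": np.nan, "p": np.nan}
    table = pd.DataFrame(rows).T[["SS", "df", "MS", "F", "p"]]
    return AnovaTable(table=table, ss_total=ss_total, grand_mean=float(gm))


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak family adjustment: p_adj = 1 - (1 - p)^m, clipped to [0, 1]."""
    if m < 1:
        raise ValueError("sidak_adjust: m must be >= 1")
    if not (0.0 <= p_raw <= 1.0):
        raise ValueError("sidak_adjust: p_raw must lie in [0, 1]")
    if m == 1:
        return float(p_raw)
    return float(min(1.0, 1.0 - (1.0 - p_raw) ** m))


def sidak_posthoc(data: pd.DataFrame, anova: AnovaTable, level_a, level_b,
                  dv: str = "value", within: str = "within",
                  between: str = "group", subject: str = "unit") -> list[StatResult]:
    """Within-level contrast (level_a - level_b) per group, Sidak-adjusted.

    Each group's t uses the shared within-error mean square:
    t = (mean_a - mean_b) / sqrt(2 * MS_error / n_g), df = within-error df;
    the family size m is the number of groups.
    """
    ms_error = float(anova.table.loc["within_error", "MS"])
    df_error = float(anova.table.loc["within_error", "df"])
    if not np.isfinite(ms_error) or ms_error <= 0:
        raise ValueError("sidak_posthoc: within-error mean square unavailable or zero")
    groups = list(data[between].unique())
    m = len(groups)
    out = []
    for g in groups:
        sub = data[data[between] == g]
        mean_a = sub.loc[sub[within] == level_a, dv].mean()
        mean_b = sub.loc[sub[within] == level_b, dv].mean()
        n_g = sub[subject].nunique()
        t = (mean_a - mean_b) / np.sqrt(2.0 * ms_error / n_g)
        p = 2.0 * sps.t.sf(abs(t), df_error)
        p = float(min(p, 1.0))
        out.append(StatResult(name=f"{g}: {level_a} vs {level_b}",
                              statistic=float(t), df=df_error,
                              p_raw=p, p_adjusted=sidak_adjust(p, m), m=m))
    return out
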