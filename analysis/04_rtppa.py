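#!/usr/bin/env python
"""Real-time place preference/avoidance (RTPPA).

Simulates three groups over three 15-min days in a two-chamber box. On
day 1 (habituation) both chambers have equal exit rates; the laser is then
paired to each animal's preferred day-1 chamber. On days 2-3 the opsin
groups leave the stimulated chamber faster (aversion), controls are
unchanged. Computes % time in the stimulated chamber and distance per
chamber, then a mixed RM-ANOVA (group x day) with Sidak post-hoc day 2
vs 1 and day 3 vs 1 contrasts. Writes tables under results/rtppa/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nacshell import behavior as bh
from nacshell import synth
from nacshell.stats import mixed_rm_anova, sidak_posthoc

OUT = Path(__file__).resolve().parent.parent / "results" / "rtppa"
SEED = 404

BASE_EXIT = 1.0 / 60.0  # one crossing a minute at baseline
GROUPS = {
    "mCherry": {"n": 12, "stim_exit_mult": 1.0},
    "rostral": {"n": 15, "stim_exit_mult": 3.0},
    "caudal": {"n": 15, "stim_exit_mult": 3.0},
}


def simulate_animal(group_spec, child):
    seeds = child.generate_state(3) % (2 ** 31)
    # day 1: habituation, symmetric exit rates
    day1 = synth.simulate_behavior_session(synth.BehaviorSimConfig(
        task="rtppa", chamber_exit_rates=(BASE_EXIT, BASE_EXIT),
        session_duration_s=900.0, day=1, seed=int(seeds[0])))
    stim = bh.preferred_side_day1(day1)
    day1.stim_side = stim
    out = [day1]
    for day, s in ((2, seeds[1]), (3, seeds[2])):
        mult = group_spec["stim_exit_mult"]
        rates = (BASE_EXIT * mult, BASE_EXIT) if stim == "A" else (BASE_EXIT, BASE_EXIT * mult)
        out.append(synth.simulate_behavior_session(synth.BehaviorSimConfig(
            task="rtppa", chamber_exit_rates=rates, session_duration_s=900.0,
            stim_side=stim, day=day, seed=int(s))))
    return out


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(SEED)
    rows = []
    for (group, spec), child in zip(GROUPS.items(), ss.spawn(len(GROUPS))):
        for i, animal_seed in enumerate(child.spawn(spec["n"])):
            animal = f"{group}_{i:02d}"
            for ses in simulate_animal(spec, animal_seed):
                m = bh.rtppa_metrics(ses)
                rows.append({"group": group, "animal": animal, "day": ses.day,
                             "pct_time_stim": m["pct_time_stim"],
                             "distance_A_cm": m["distance_cm"]["A"],
                             "distance_B_cm": m["distance_cm"]["B"]})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "occupancy.tsv", sep="\t", index=False)

    long = table.rename(columns={"animal": "unit", "day": "within",
                                 "pct_time_stim": "value"})[
        ["unit", "group", "within", "value"]]
    anova = mixed_rm_anova(long)
    anova.table.to_csv(OUT / "rm_anova.tsv", sep="\t")

    report = {
        "mean_pct_time_stim": {
            g: {int(d): round(float(sub[sub.day == d]["pct_time_stim"].mean()), 2)
                for d in (1, 2, 3)}
            for g, sub in table.groupby("group")},
        "anova": {e: {"F": round(float(anova.table.loc[e, "F"]), 4),
                      "df": int(anova.table.loc[e, "df"]),
                      "p": round(float(anova.table.loc[e, "p"]), 6)}
                  for e in ("group", "within", "interaction")},
        "posthoc": [],
    }
    for day in (2, 3):
        for r in sidak_posthoc(long, anova, day, 1):
            report["posthoc"].append({"contrast": f"day {day} vs 1, {r.name.split(':')[0]}",
                                      "t": round(r.statistic, 4), "df": int(r.df),
                                      "p_adj": round(r.p_adjusted, 6)})
    (OUT / "stats.json").write_text(json.dumps(report, indent=2) + "\n")

    print("RTPPA % time in stimulated chamber (group means by day):")
    for g, days in report["mean_pct_time_stim"].items():
        print(f"  {g}: " + ", ".join(f"day {d}: {v}%" for d, v in days.items()))
    for e, v in report["anova"].items():
        print(f"  {e}: F = {v['F']}, p = {v['p']}")


if __name__ == "__main__":
    main()
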