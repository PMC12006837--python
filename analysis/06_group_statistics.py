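"""Group statistics on the audiogenic-seizure incidence counts.

Builds the 2x2 incidence tables from the published cohort counts (WT
saline 2/15, KO saline 9/11, KO Glyx-13 5/16), runs the exact two-sided
Fisher test on the two planned comparisons, and demonstrates the rest of
the statistics layer (outlier rule, mean +/- SEM, t-test, one-way ANOVA
with Bonferroni) on a simulated labeling dataset.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from spineburst import synth
from spineburst.metabolic import normalize_batch
from spineburst.stats import (
    ContingencyTable2x2,
    anova_oneway,
    fisher_exact,
    mean_sem,
    remove_outliers,
    t_test,
)

ROOT = Path(__file__).resolve().parents[1]

COHORTS = {"WT:saline": (2, 15), "KO:saline": (9, 11), "KO:glyx13": (5, 16)}
COMPARISONS = [("WT:saline", "KO:saline"), ("KO:saline", "KO:glyx13")]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out = {"fisher": {}}
    for g1, g2 in COMPARISONS:
        s1, n1 = COHORTS[g1]
        s2, n2 = COHORTS[g2]
        table = ContingencyTable2x2.from_incidence(s1, n1, s2, n2)
        r = fisher_exact(table)
        out["fisher"][f"{g1} vs {g2}"] = {
            "table": [[table.a, table.b], [table.c, table.d]],
            "incidence": [f"{s1}/{n1}", f"{s2}/{n2}"],
            "p_two_sided": r.p_two_sided,
        }
        print(f"{g1} ({s1}/{n1}) vs {g2} ({s2}/{n2}): Fisher exact p = {r.p_two_sided:.4f}")

    # the rest of the statistics layer on a synthetic labeling experiment
    p = synth.LabelingSimParams(
        group_effects={"WT": 1.0, "KO": 1.15, "CR": 1.0}, cv=0.1, seed=args.seed
    )
    table, _ = synth.gen_labeling_experiment(p)
    norm = normalize_batch(table)
    groups, labels = [], []
    for g, sub in norm.groupby("group"):
        vals, removed = remove_outliers(sub["normalized_percent"].to_numpy())
        groups.append(vals)
        labels.append(g)
        m, s, n = mean_sem(vals)
        print(f"{g}: {m:.1f} +/- {s:.1f}% (n={n}, {removed.size} outliers removed)")
    tt = t_test(groups[labels.index("WT")], groups[labels.index("KO")])
    an = anova_oneway(groups, labels)
    print(f"WT vs KO unpaired t: t = {tt.statistic:.3f}, p = {tt.p_two_sided:.4f}")
    print(f"one-way ANOVA: F = {an.statistic:.3f}, p = {an.p_two_sided:.4f}")
    out["labeling_demo"] = {
        "group_summaries": {lab: mean_sem(g) for lab, g in zip(labels, groups)},
        "wt_vs_ko_t": {"t": tt.statistic, "df": tt.df, "p": tt.p_two_sided},
        "anova": {"F": an.statistic, "p": an.p_two_sided,
                  "bonferroni": {f"{a} vs {b}": p for (a, b), p in an.pairwise.items()}},
    }

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "statistics.json").write_text(json.dumps(out, indent=1))
    print("-> results/statistics.json")


if __name__ == "__main__":
    main()
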