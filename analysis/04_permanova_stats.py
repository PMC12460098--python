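#!/usr/bin/env python
"""Permutational ANOVA of the avoidance-distance table.

Fits Timing (before/during/after, fixed) crossed with Pen (random) on the
Euclidean distance matrix, tests each term by permutation of reduced-model
residuals, pools terms that are clearly non-significant (p >= 0.25), and
follows up with pairwise Timing comparisons within each pen (consulting the
parametric tail probability where fewer than 100 unique permutations
exist).  Writes results/permanova.csv and results/pairwise_timing.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pensonar import Design, Factor, pairwise, permanova, pool_terms


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=9999)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    tab = pd.read_csv(args.results / "avoidance_measurements.csv")
    design = Design(
        factors=(Factor("phase", "fixed"), Factor("pen", "random")),
        terms=(("phase",), ("pen",), ("phase", "pen")),
        response="distance_m",
    )
    res = permanova(tab, design, n_perm=args.n_perm, seed=args.seed)
    pooled, pooled_design = pool_terms(res, tab, design, threshold=0.25,
                                       n_perm=args.n_perm, seed=args.seed)
    pooled.table.to_csv(args.results / "permanova.csv", index=False)
    print("omnibus (after pooling):")
    print(pooled.table[["term", "df", "F", "p_perm", "p_MC", "n_unique"]].round(4))
    if pooled.pooling_log:
        for entry in pooled.pooling_log:
            print(f"  pooled {entry['term']} (p={entry['p_perm']:.3f}, "
                  f"df={entry['df']}) into the residual")

    pw_rows = []
    for pen in sorted(tab["pen"].unique()):
        pw = pairwise(tab, "phase", n_perm=args.n_perm, seed=args.seed,
                      stratum={"pen": pen}, design=design)
        pw_rows.append(pw.table.assign(pen=pen))
    pw_all = pd.concat(pw_rows, ignore_index=True)
    pw_all["p_use"] = pw_all["p_MC"].where(pw_all["n_unique"] < 100, pw_all["p_perm"])
    pw_all.to_csv(args.results / "pairwise_timing.csv", index=False)
    print("pairwise Timing within pens (p_use = p_MC when <100 unique perms):")
    print(pw_all[["pen", "level_a", "level_b", "t", "p_use"]].round(4))

    sig = pw_all[(pw_all.level_a == "before") & (pw_all.level_b == "during")]
    for _, r in sig.iterrows():
        verdict = "During > Before" if r["p_use"] < 0.05 else "no Timing contrast"
        print(f"pen {r['pen']}: {verdict} (p={r['p_use']:.4f})")


if __name__ == "__main__":
    main()
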