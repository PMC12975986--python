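#!/usr/bin/env python
"""Augmented-design analysis: adjusted means, ANOVA, critical differences,
promising accessions.

Reads results/data/, writes adjusted means, the per-trait ANOVA, the four
Federer critical differences at 5%, and the accessions beating the best
check by more than CD(test-check) on each trait.
"""

import argparse
from pathlib import Path

import pandas as pd

import mungcore as mc

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    fb = mc.load_collection(args.data / "fieldbook.csv",
                            args.data / "descriptors.csv")
    adj = mc.adjust_means(fb)
    adj.means.to_csv(args.out / "adjusted_means.csv", index_label="accession")
    adj.block_effects.to_csv(args.out / "block_effects.csv",
                             index_label="block")
    print(f"adjusted means for {len(adj.means)} accessions "
          f"(error df = {adj.error_df})")

    anova_rows, cd_rows, promising = [], {}, {}
    design = (adj.n_blocks, adj.n_checks)
    for trait in fb.quantitative_traits:
        table = mc.abd_anova(fb, trait)
        tidy = table.table.reset_index()
        tidy.insert(0, "trait", trait)
        anova_rows.append(tidy)
        cd = mc.critical_differences(table, design, alpha=args.alpha)
        cd_rows[trait] = {"check_check": cd.check_check,
                          "test_test_same_block": cd.test_test_same_block,
                          "test_test_diff_block": cd.test_test_diff_block,
                          "test_check": cd.test_check}
        promising[trait] = mc.identify_promising(adj, cd, trait, "higher")

    pd.concat(anova_rows).to_csv(args.out / "anova.csv", index=False)
    pd.DataFrame(cd_rows).T.to_csv(args.out / "critical_differences.csv",
                                   index_label="trait")
    with open(args.out / "promising_accessions.csv", "w") as fh:
        fh.write("trait,accessions\n")
        for trait, ids in promising.items():
            fh.write(f"{trait},{'|'.join(ids)}\n")
    n_prom = sum(len(v) for v in promising.values())
    print(f"promising accessions across traits (higher than best check "
          f"by > CD at {args.alpha:.0%}): {n_prom}")
    print(f"tables -> {args.out}")


if __name__ == "__main__":
    main()
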