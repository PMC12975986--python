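#!/usr/bin/env python
"""Compare the five core sets against the entire collection and pick the best.

For each core: Hu indices (MD%, VD%, CR%, VR%), class coverage, phenotype
retention, nearest-entry distances, sign tests, Mantel test and the Shannon
diversity table. The verdict maximizes E-NE among cores satisfying the
quality gate MD% < 20 and CR% > 80.
"""

import argparse
from pathlib import Path

import pandas as pd

import mungcore as mc
from mungcore.sampling import METHODS

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--cores", type=Path, default=ROOT / "results" / "cores")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--permutations", type=int, default=499)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    fb = mc.load_collection(args.data / "fieldbook.csv",
                            args.data / "descriptors.csv")
    adj = mc.adjust_means(fb)
    ec = adj.test_means()
    qual = fb.qualitative_table().loc[list(adj.test_ids)]
    d = mc.gower_matrix(ec, fb.descriptors)

    reports = {}
    for method in METHODS:
        path = args.cores / f"{method}.csv"
        if not path.exists():
            print(f"(no core list for {method}; skipped)")
            continue
        core = mc.load_core_list(path)
        reports[method] = mc.evaluate_core(
            ec, core.ids, fb.descriptors, ec_qual=qual, distance=d,
            method=method, permutations=args.permutations, seed=args.seed,
            run_trait_tests=False)

    comparison = pd.DataFrame({m: r.summary_row() for m, r in reports.items()})
    comparison.to_csv(args.out / "comparison.csv", index_label="index")
    show = comparison.loc[["E-NE", "A-NE", "E-E", "MD%", "VD%", "CR%", "VR%",
                           "class_coverage%", "phenotype_ratio"]]
    print(show.astype(float).round(3).to_string())

    for m, r in reports.items():
        if len(r.shannon):
            r.shannon.to_csv(args.out / f"shannon_{m}.csv",
                             index_label="trait")

    passing = [m for m, r in reports.items() if r.passes_quality_gate()]
    pool = passing or list(reports)
    best = max(pool, key=lambda m: reports[m].objectives.e_ne)
    print(f"\ncores passing the quality gate (MD%<20, CR%>80): "
          f"{', '.join(passing) or 'none'}")
    print(f"best core by E-NE among them: {best}")
    (args.out / "best_core.txt").write_text(best + "\n")


if __name__ == "__main__":
    main()
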