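#!/usr/bin/env python
"""Build the five core sets (10% of the collection) on Gower distances.

PowerCore-style greedy class coverage, the PCSS principal-component score
strategy, and the three nearest-entry local-search cores (EN100, AN100,
EN50:AN50). Core membership lists go to results/cores/.
"""

import argparse
import time
from pathlib import Path

import mungcore as mc
from mungcore.sampling import METHOD_WEIGHTS, METHODS, ObjectiveNormalizer

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cores")
    ap.add_argument("--size", type=int, default=None,
                    help="core size (default 10%% of the collection)")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--budget", type=int, default=1500,
                    help="consecutive non-improving proposals before stop")
    ap.add_argument("--max-proposals", type=int, default=12_000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fb = mc.load_collection(args.data / "fieldbook.csv",
                            args.data / "descriptors.csv")
    adj = mc.adjust_means(fb)
    ec = adj.test_means()
    size = args.size or max(2, round(0.10 * len(ec)))
    d = mc.gower_matrix(ec, fb.descriptors)
    norm = ObjectiveNormalizer(d, size, seed=args.seed)
    print(f"collection {len(ec)}, core size {size} (10%)")

    for method in METHODS:
        t0 = time.time()
        if method in METHOD_WEIGHTS:
            w_en, w_an = METHOD_WEIGHTS[method]
            core = mc.optimize_core(d, size, w_en, w_an, seed=args.seed,
                                    budget=args.budget, restarts=1,
                                    max_proposals=args.max_proposals,
                                    normalizer=norm, method=method)
        elif method == "powercore":
            table = ec.join(fb.qualitative_table(), how="left")
            core, cov = mc.powercore_sample(table, fb.descriptors, size,
                                            seed=args.seed)
        else:
            core = mc.pcss_sample(ec, size)
        obj = mc.core_objective(d, core.ids)
        mc.save_core_list(core, args.out / f"{method}.csv")
        print(f"{method:9s} E-NE={obj.e_ne:.3f} A-NE={obj.a_ne:.3f} "
              f"E-E={obj.e_e:.3f}  ({time.time() - t0:.1f}s)")
    print(f"core lists -> {args.out}")


if __name__ == "__main__":
    main()
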