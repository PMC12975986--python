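#!/usr/bin/env python
"""Generate the synthetic germplasm collection the rest of the analysis runs on.

Writes the field book, trait descriptors, passport table and the generator's
truth record under results/data/. The default scale (1,000 test accessions)
keeps the downstream steps fast; --study-scale switches to the full trial
layout (3,903 accessions, 50 blocks).
"""

import argparse
from pathlib import Path

import mungcore as mc
from mungcore.pipeline import save_synthetic_inputs

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-test", type=int, default=1000)
    ap.add_argument("--study-scale", action="store_true",
                    help="use the full 3,903-accession trial layout")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = ap.parse_args()

    n_test = 3903 if args.study_scale else args.n_test
    cfg = mc.default_config(n_test=n_test, seed=args.seed)
    coll = mc.generate_collection(cfg)
    save_synthetic_inputs(coll, args.out)

    fb = coll.fieldbook
    print(f"collection: {len(fb.tests)} test accessions, "
          f"{len(fb.blocks)} blocks, {len(fb.checks)} checks x"
          f"{cfg.reps_per_check_per_block} reps/block")
    print(f"traits: {len(fb.quantitative_traits)} quantitative, "
          f"{len(fb.qualitative_traits)} qualitative "
          f"({sum(len(d.states) for d in fb.descriptors if d.is_qualitative)}"
          " descriptor states)")
    print(f"wrote field book + descriptors + truth + passport -> {args.out}")


if __name__ == "__main__":
    main()
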