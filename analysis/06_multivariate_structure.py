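#!/usr/bin/env python
"""Multivariate diversity structure of collection vs best core.

Correlation-matrix PCA of both populations (eigenvalues, variance shares,
loadings), hierarchical clustering of the core (Newick export), and Pearson
correlograms.
"""

import argparse
from pathlib import Path

import pandas as pd

import mungcore as mc

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--cores", type=Path, default=ROOT / "results" / "cores")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--clusters", type=int, default=2)
    args = ap.parse_args()

    fb = mc.load_collection(args.data / "fieldbook.csv",
                            args.data / "descriptors.csv")
    adj = mc.adjust_means(fb)
    ec = adj.test_means()
    best = "en100"
    best_file = args.out / "best_core.txt"
    if best_file.exists():
        best = best_file.read_text().strip()
    cc = ec.loc[list(mc.load_core_list(args.cores / f"{best}.csv").ids)]

    for label, table in (("ec", ec), ("cc", cc)):
        res = mc.pca(table)
        res.table().to_csv(args.out / f"pca_{label}.csv", index_label="row")
        print(f"PCA {label.upper()}: PC1 {res.variance_pct[0]:.2f}%, "
              f"first six cumulative {res.cumulative_pct[5]:.2f}%")
        r, p = mc.correlation_matrix(table)
        r.to_csv(args.out / f"correlogram_{label}.csv", index_label="trait")
    share_gap = abs(mc.pca(ec).variance_pct[0] - mc.pca(cc).variance_pct[0])
    print(f"|PC1 variance-share difference| EC vs CC: {share_gap:.2f} points")

    d = mc.euclidean_matrix(cc, fb.descriptors)
    dend = mc.hier_cluster(d, "ward")
    (args.out / f"dendrogram_{best}.nwk").write_text(dend.to_newick() + "\n")
    labels = dend.cut(args.clusters)
    labels.to_csv(args.out / f"clusters_{best}.csv", index_label="accession")
    sizes = labels.value_counts().sort_index().tolist()
    print(f"core dendrogram cut into {args.clusters} clusters "
          f"(sizes {sizes}) -> dendrogram_{best}.nwk")

    mantel = mc.mantel_test(mc.correlation_matrix(ec)[0],
                            mc.correlation_matrix(cc)[0],
                            permutations=499, seed=1)
    print(f"Mantel EC vs CC trait correlations: r={mantel.statistic:.3f}, "
          f"p={mantel.p:.4f}")


if __name__ == "__main__":
    main()
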