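#!/usr/bin/env python
"""Cluster strain fingerprints and map phenospace trajectories.

Builds per-strain fingerprints by concatenating the three recording periods,
Z-normalises feature-wise, clusters hierarchically (Euclidean, average
linkage) and writes the linkage table plus a Newick dendrogram.  A joint PCA
over all strain-by-period rows places each strain's prestim / bluelight /
poststim means in one shared phenospace; the printed trajectory lengths show
which strains respond to blue light.  Related planted phenotypes (mutB and
mutC share their affected feature set) should cluster together.

Usage: python analysis/04_fingerprint_phenospace.py
       [--panel results/panel] [--out results/phenospace]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from wormpheno import fingerprint as fpm
from wormpheno import io as wio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--out", type=Path, default=Path("results/phenospace"))
    ap.add_argument("--n-components", type=int, default=2)
    args = ap.parse_args()

    tables, meta = wio.read_experiment(args.panel)
    fp = fpm.build_fingerprint(tables, meta, level="strain")
    z = fpm.z_normalise(fp)
    clust = fpm.hierarchical_cluster(z)
    proj = fpm.pca_phenospace(tables, meta, n_components=args.n_components)

    args.out.mkdir(parents=True, exist_ok=True)
    z.values.to_csv(args.out / "fingerprints_z.csv")
    pd.DataFrame(clust.linkage,
                 columns=["left", "right", "distance", "size"]).to_csv(
        args.out / "linkage.csv", index=False)
    (args.out / "dendrogram.nwk").write_text(
        fpm.linkage_to_newick(clust) + "\n")
    proj.coords.to_csv(args.out / "phenospace.csv", index=False)

    print(f"fingerprints: {len(fp.entities)} strains x {fp.length} entries "
          f"({z.values.shape[1] // 3} features x 3 periods)")
    print("dendrogram leaf order:", " ".join(clust.leaf_order))
    cut = clust.cut(3)
    print("k=3 cluster assignment:",
          {g: c for g, c in sorted(cut.items())})
    evr = proj.explained_variance_ratio
    print(f"PCA: PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%} of variance")
    print("prestim->bluelight trajectory length per strain:")
    for g in sorted(set(proj.coords["group"])):
        tr = proj.trajectory(g)
        d = np.linalg.norm(
            tr.loc["bluelight", ["pc1", "pc2"]].to_numpy(float)
            - tr.loc["prestim", ["pc1", "pc2"]].to_numpy(float))
        print(f"  {g}: {d:.2f}")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
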