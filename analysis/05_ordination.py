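#!/usr/bin/env python
"""PCA of phage phyletic vectors with unit-variance scaling.

Deduplicates identical phyletic patterns, decomposes the scaled matrix,
reports the variance explained by the first five components, and writes
per-group convex hulls in PC1-PC2 space. Writes pca_scores.tsv and
pca_hulls.tsv under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from jumbophage import ordination as ordn
from jumbophage import profiles as prof


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--components", type=int, default=5)
    args = ap.parse_args()

    df = pd.read_csv(args.outdir / "phyletic_matrix.tsv", sep="\t", index_col=0)
    matrix = prof.PhyleticMatrix.from_frame(df)
    deduped, _ = prof.dedupe_patterns(matrix)
    res = ordn.pca(deduped, n_components=args.components)
    ncomp = min(args.components, res.explained_fraction.size)
    ve = ordn.variance_explained(res, ncomp)
    print(f"PCA on {len(deduped.phage_ids)} unique patterns x "
          f"{len(res.variable_ids)} variable families "
          f"({len(res.dropped_variables)} constant families dropped)")
    print(f"first {ncomp} components explain {ve:.1%} of the variance")

    scores = pd.DataFrame(
        res.scores, index=res.item_ids,
        columns=[f"PC{i+1}" for i in range(res.scores.shape[1])],
    )
    scores.to_csv(args.outdir / "pca_scores.tsv", sep="\t")

    with open(args.cohort / "truth.json") as fh:
        truth = json.load(fh)
    rows = []
    for group in sorted(set(truth["group"].values())):
        pts = scores.loc[
            [p for p in scores.index if truth["group"][p] == group], ["PC1", "PC2"]
        ].to_numpy()
        for x, y in ordn.convex_hull(pts):
            rows.append({"group": group, "PC1": x, "PC2": y})
    pd.DataFrame(rows).to_csv(args.outdir / "pca_hulls.tsv", sep="\t", index=False)
    print(f"wrote pca_scores.tsv and per-group hulls for "
          f"{len(set(truth['group'].values()))} groups")

    with open(args.outdir / "ordination.json", "w") as fh:
        json.dump(
            {
                "explained_fraction": [float(x) for x in res.explained_fraction[:ncomp]],
                "variance_explained_first_5": ve,
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
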