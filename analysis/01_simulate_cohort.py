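#!/usr/bin/env python
"""Generate the default synthetic phage cohort used by all later analyses.

Writes the gene table, the all-vs-all hit table and the ground-truth labels
under results/cohort/. Every later script regenerates nothing: it reads
these files (or re-derives them deterministically from the same seed).
"""

import argparse
import json
from pathlib import Path

from jumbophage import io as io_mod
from jumbophage import simulate as sim


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = sim.CohortConfig(seed=args.seed)
    genomes, truth = sim.generate_cohort(cfg)
    # plant three conserved cassettes spanning two host phyla each
    plants = [
        (("nadV", "pnuC"), ["cyanobacteria", "gammaproteobacteria"]),
        (("polB_neighbor_SH3", "polB_divergent_copy"), ["gammaproteobacteria", "firmicutes"]),
        (("rnlA_ligase", "pnkp", "hen1"), ["alphaproteobacteria", "bacteroidetes"]),
    ]
    for sig, taxa in plants:
        sim.plant_neighborhood(genomes, sig, taxa, gap_nt=10, strand="+",
                               truth=truth, seed=args.seed)
    hits = sim.generate_hits(genomes, truth, seed=args.seed)

    args.outdir.mkdir(parents=True, exist_ok=True)
    io_mod.write_gene_table(genomes, args.outdir / "genes.tsv")
    io_mod.write_hits(hits, args.outdir / "hits.tsv")
    with open(args.outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": args.seed,
                "subgroup": truth.subgroup,
                "group": truth.group,
                "size_category": truth.size_category,
                "planted_signatures": truth.planted_signatures,
            },
            fh,
            indent=2,
        )
    n_genes = sum(len(g.genes) for g in genomes)
    print(f"cohort: {len(genomes)} genomes, {n_genes} genes, {len(hits)} hits")
    print(f"planted {len(truth.planted_signatures)} cassette instances "
          f"({len(plants)} signatures)")
    print(f"wrote gene table, hit table and truth to {args.outdir}")


if __name__ == "__main__":
    main()
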