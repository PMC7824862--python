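#!/usr/bin/env python
"""Genome-scale statistics of the simulated collection.

Reproduces the descriptive analyses on synthetic data: coding density, the
trimodal genome-size distribution with its valley-based category cutoffs
(the objective jumbo-phage criterion), protein-length medians and skewness
by category, the rank tests between categories, and the genome-vs-proteome
regression. Writes results/genome_stats.json and the smoothed size density.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from jumbophage import io as io_mod
from jumbophage import simulate as sim
from jumbophage import stats as st


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genomes = io_mod.read_gene_table(args.cohort / "genes.tsv")
    dens = np.array([st.gene_density(g) for g in genomes])
    print(f"coding density: mean {dens.mean():.3f} / sd {dens.std(ddof=1):.3f} per kb")

    # the 200-genome cohort is too small for stable valley detection, so the
    # size model is fitted on a 10,000-draw sample from the same mixture
    rng = np.random.default_rng(args.seed + 7)
    sizes = sim.sample_genome_sizes(10_000, rng)
    model = st.detect_size_categories(sizes)
    print(f"size model: modes {[round(m,1) for m in model.mode_positions]} kb, "
          f"cutoffs {[round(c,1) for c in model.cutoffs]} kb "
          f"({model.n_categories} categories)")
    pd.DataFrame(
        {"size_kb": model.bin_edges, "density": model.smoothed_density}
    ).to_csv(args.outdir / "size_density.tsv", sep="\t", index=False)

    jumbo_cut = model.cutoffs[-1]
    lengths_by_cat = {"jumbo": [], "non-jumbo": []}
    for g in genomes:
        cat = "jumbo" if g.genome_length / 1000.0 > jumbo_cut else "non-jumbo"
        lengths_by_cat[cat].extend(gn.protein_length for gn in g.coding_genes)
    per_cat = {}
    for cat, lengths in lengths_by_cat.items():
        s = st.length_stats(lengths)
        fitted = st.fitted_lognormal_skewness(lengths)
        per_cat[cat] = {
            "n": s.n, "median": s.median, "mean": round(s.mean, 1),
            "sample_skewness": round(s.skewness, 2),
            "fitted_skewness": round(fitted, 2),
        }
        print(f"protein lengths [{cat}]: n={s.n} median={s.median:.0f} aa "
              f"raw skew={s.skewness:.2f} fitted skew={fitted:.2f}")

    rt = st.rank_test([lengths_by_cat["jumbo"], lengths_by_cat["non-jumbo"]])
    print(f"jumbo vs non-jumbo lengths: Kruskal-Wallis H={rt.statistic:.1f}, "
          f"p {st.format_pvalue(rt.pvalue)}")

    kb = [g.genome_length / 1000.0 for g in genomes]
    nprot = [len(g.coding_genes) for g in genomes]
    slope, intercept, r2 = st.size_regression(kb, nprot)
    print(f"proteome ~ genome size: slope {slope:.2f} proteins/kb, r2 = {r2:.3f}")

    out = {
        "density": {"mean": round(float(dens.mean()), 4),
                    "sd": round(float(dens.std(ddof=1)), 4)},
        "size_model": {"modes_kb": model.mode_positions,
                       "cutoffs_kb": model.cutoffs,
                       "n_categories": model.n_categories},
        "protein_lengths": per_cat,
        "rank_test": {"H": rt.statistic, "p": st.format_pvalue(rt.pvalue),
                      "U": rt.u_statistic},
        "regression": {"slope": slope, "intercept": intercept, "r2": r2},
    }
    with open(args.outdir / "genome_stats.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"wrote {args.outdir / 'genome_stats.json'}")


if __name__ == "__main__":
    main()
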