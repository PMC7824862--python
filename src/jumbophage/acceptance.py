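"""Reference computations behind the calibration and recovery checks.

Each function regenerates its inputs from the synthetic-cohort generator at
the study conditions (cohort sizes, noise levels, seeds derived from a base
seed) and measures the recovered quantity with the pipeline's own
operations. Shared by the acceptance script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np

from . import simulate as sim
from .families import filter_hits, single_linkage
from .io import protein_id
from .pipeline import compare_labels
from .profiles import build_matrix, cut_tree, pairwise_distances, ward_cluster
from .stats import detect_size_categories, fitted_lognormal_skewness, gene_density

__all__ = [
    "derive_seed",
    "density_recovery",
    "upper_cutoff",
    "protein_length_calibration",
    "group_recovery",
    "trna_recovery",
]


def derive_seed(base: int, stream: int) -> int:
    """Mix a base seed with a per-analysis stream id (stable, < 2^31)."""
    ss = np.random.SeedSequence(entropy=base, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2**31))


def _uniform_cohort(n_per_subgroup: int, seed: int) -> sim.CohortConfig:
    return sim.CohortConfig(
        n_phages={s: n_per_subgroup for s in ("1", "2.1", "2.2", "3.1", "3.2")},
        seed=seed,
    )


def density_recovery(n_genomes: int = 2000, seed: int = 1) -> tuple[float, float]:
    """Sample mean and SD of per-genome coding density over a default
    cohort of ``n_genomes`` genomes."""
    genomes, _ = sim.generate_cohort(_uniform_cohort(n_genomes // 5, seed))
    dens = np.array([gene_density(g) for g in genomes])
    return float(dens.mean()), float(dens.std(ddof=1))


def upper_cutoff(n_sizes: int = 10_000, seed: int = 7) -> float:
    """Upper category boundary (kb) from valley detection on sizes drawn
    from the default trimodal mixture."""
    rng = np.random.default_rng(seed)
    sizes = sim.sample_genome_sizes(n_sizes, rng)
    model = detect_size_categories(sizes)
    if model.n_categories != 3:
        raise RuntimeError(
            f"expected 3 size categories, detected {model.n_categories}"
        )
    return float(model.cutoffs[-1])


def protein_length_calibration(n: int = 50_000, seed: int = 0) -> dict:
    """Medians and fitted moment skewness of simulated jumbo and non-jumbo
    proteomes of ``n`` proteins each."""
    rng = np.random.default_rng(seed)
    jumbo = sim.sample_protein_lengths("jumbo", n, rng)
    nonjumbo = sim.sample_protein_lengths("non-jumbo", n, rng)
    return {
        "median_jumbo": float(np.median(jumbo)),
        "median_nonjumbo": float(np.median(nonjumbo)),
        "skewness_jumbo": fitted_lognormal_skewness(jumbo),
        "skewness_nonjumbo": fitted_lognormal_skewness(nonjumbo),
    }


def group_recovery(n_per_subgroup: int = 40, seed: int = 0) -> tuple[float, float]:
    """ARI of Canberra + Ward + cut-tree recovery of planted groups
    (k=3) and subgroups (k=5) on a default cohort."""
    genomes, truth = sim.generate_cohort(_uniform_cohort(n_per_subgroup, seed))
    hits = sim.generate_hits(genomes, truth, seed=seed)
    universe = {
        protein_id(g.phage_id, gn.gene_id) for g in genomes for gn in g.coding_genes
    }
    fams = single_linkage(filter_hits(hits), universe)
    matrix = build_matrix(fams, genomes, min_phages=5)
    tree = ward_cluster(pairwise_distances(matrix, axis="phages"))
    ari3 = compare_labels(cut_tree(tree, 3), truth.group)
    ari5 = compare_labels(cut_tree(tree, 5), truth.subgroup)
    return ari3, ari5


def trna_recovery(subgroup: str, n_genomes: int = 500, seed: int = 5) -> float:
    """Sample mean tRNA count per genome for one simulated subgroup."""
    cfg = sim.CohortConfig(n_phages={subgroup: n_genomes}, seed=seed)
    genomes, _ = sim.generate_cohort(cfg)
    return float(np.mean([len(g.trna_genes) for g in genomes]))
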