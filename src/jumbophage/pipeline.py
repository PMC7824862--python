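"""End-to-end orchestration: simulate-or-read, genome statistics, family
clustering, phyletic matrix, Ward classification, PCA and neighborhood
detection, with a machine-readable run report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import families as fam_mod
from . import io as io_mod
from . import neighborhoods as nb_mod
from . import ordination as ord_mod
from . import profiles as prof_mod
from . import simulate as sim_mod
from . import stats as stats_mod

__all__ = ["RunConfig", "run_pipeline", "compare_labels"]

log = logging.getLogger("jumbophage")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``gene_table`` (+ optional ``hits_table``) or ``simulate``
    must be given. ``simulate`` is a mapping of CohortConfig overrides.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    gene_table: str | None = None
    hits_table: str | None = None
    simulate: dict | None = None
    min_coverage: float = 0.6
    min_score_density: float = 1.0
    coverage_mode: str = "both"
    min_phages: int = 5
    k_top: int = 3
    k_sub: int = 5
    ward_variant: str = "ward_d2"
    n_components: int = 5
    anchor_families: list[str] = field(default_factory=list)
    window: int = 5
    max_gap_nt: int = 50
    min_taxa: int = 2

    def __post_init__(self):
        if (self.gene_table is None) == (self.simulate is None):
            raise ValueError("exactly one of gene_table / simulate must be configured")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls(**data)


def compare_labels(predicted: dict[str, int], truth: dict[str, str | int]) -> float:
    """Adjusted Rand Index between two labelings of the same item set."""
    from sklearn.metrics import adjusted_rand_score

    if set(predicted) != set(truth):
        raise ValueError("predicted and truth must label the same items")
    items = sorted(predicted)
    return float(
        adjusted_rand_score([str(truth[i]) for i in items], [predicted[i] for i in items])
    )


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.setdefault("stage_seconds", {})[name] = round(dt, 3)
            if exc_type is not None:
                report["failed_stage"] = name
                log.error("stage %s FAILED after %.2fs: %s", name, dt, exc)
            else:
                log.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order, writing artifacts under
    ``config.outdir``; returns (and writes) the run report."""
    from importlib.metadata import version

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}
    try:
        report["version"] = version("jumbophage")
    except Exception:
        report["version"] = "unknown"

    truth = None
    try:
        with _stage(report, "input"):
            if config.simulate is not None:
                overrides = dict(config.simulate)
                overrides.setdefault("seed", config.seed)
                cc = sim_mod.CohortConfig(**overrides)
                genomes, truth = sim_mod.generate_cohort(cc)
                hits = sim_mod.generate_hits(genomes, truth, seed=cc.seed)
                io_mod.write_gene_table(genomes, outdir / "genes.tsv")
                io_mod.write_hits(hits, outdir / "hits.tsv")
            else:
                genomes = io_mod.read_gene_table(config.gene_table)
                hits = io_mod.read_hits(config.hits_table) if config.hits_table else []
            report["n_phages"] = len(genomes)
            report["n_proteins"] = sum(len(g.coding_genes) for g in genomes)

        with _stage(report, "stats"):
            dens = [stats_mod.gene_density(g) for g in genomes]
            sizes = [g.genome_length / 1000.0 for g in genomes]
            st = {
                "density_mean": float(np.mean(dens)),
                "density_sd": float(np.std(dens, ddof=1)),
            }
            if len(sizes) >= 50:
                model = stats_mod.detect_size_categories(sizes)
                st["size_modes_kb"] = model.mode_positions
                st["size_cutoffs_kb"] = model.cutoffs
                st["n_size_categories"] = model.n_categories
            slope, intercept, r2 = stats_mod.size_regression(
                sizes, [len(g.coding_genes) for g in genomes]
            )
            st["regression"] = {"slope": slope, "intercept": intercept, "r2": r2}
            report["stats"] = st

        with _stage(report, "families"):
            if hits:
                params = fam_mod.ClusterParams(
                    config.min_coverage, config.min_score_density, config.coverage_mode
                )
                universe = {
                    io_mod.protein_id(g.phage_id, gn.gene_id)
                    for g in genomes
                    for gn in g.coding_genes
                }
                edges = fam_mod.filter_hits(hits, params)
                families = fam_mod.single_linkage(edges, universe)
            else:
                members: dict[str, set[str]] = {}
                for g in genomes:
                    for gn in g.coding_genes:
                        if gn.family_id:
                            members.setdefault(gn.family_id, set()).add(
                                io_mod.protein_id(g.phage_id, gn.gene_id)
                            )
                families = [
                    fam_mod.ProteinFamily(
                        f,
                        frozenset(ms),
                        len({io_mod.split_protein_id(m)[0] for m in ms}),
                    )
                    for f, ms in members.items()
                ]
            report["n_families"] = len(families)
            with open(outdir / "families.tsv", "w") as fh:
                fh.write("family_id\tprotein_id\tphage_id\n")
                for f in sorted(families, key=lambda x: x.family_id):
                    for m in sorted(f.members):
                        fh.write(f"{f.family_id}\t{m}\t{io_mod.split_protein_id(m)[0]}\n")

        with _stage(report, "matrix"):
            matrix = prof_mod.build_matrix(families, genomes, min_phages=config.min_phages)
            matrix.to_frame().to_csv(outdir / "phyletic_matrix.tsv", sep="\t")
            deduped, mapping = prof_mod.dedupe_patterns(matrix)
            report["matrix"] = {
                "n_families": len(matrix.family_ids),
                "n_phages": len(matrix.phage_ids),
                "n_unique_patterns": len(deduped.phage_ids),
            }

        with _stage(report, "cluster"):
            dm = prof_mod.pairwise_distances(matrix, axis="phages")
            tree = prof_mod.ward_cluster(dm, variant=config.ward_variant)
            (outdir / "phage_tree.nwk").write_text(prof_mod.to_newick(tree))
            labels_top = prof_mod.cut_tree(tree, config.k_top)
            labels_sub = prof_mod.cut_tree(tree, config.k_sub)
            cl = {"k_top": config.k_top, "k_sub": config.k_sub}
            if truth is not None:
                cl["ari_top"] = compare_labels(labels_top, truth.group)
                cl["ari_sub"] = compare_labels(labels_sub, truth.subgroup)
            fdm = prof_mod.pairwise_distances(matrix, axis="families")
            ftree = prof_mod.ward_cluster(fdm, variant=config.ward_variant)
            (outdir / "family_tree.nwk").write_text(prof_mod.to_newick(ftree))
            with open(outdir / "labels.tsv", "w") as fh:
                fh.write("phage_id\tlabel_top\tlabel_sub\n")
                for p in sorted(labels_top):
                    fh.write(f"{p}\t{labels_top[p]}\t{labels_sub[p]}\n")
            report["cluster"] = cl

        with _stage(report, "pca"):
            res = ord_mod.pca(deduped, n_components=config.n_components)
            report["pca"] = {
                "explained_fraction": [
                    float(x) for x in res.explained_fraction[: config.n_components]
                ],
                "variance_explained": ord_mod.variance_explained(
                    res, min(config.n_components, res.explained_fraction.size)
                ),
                "n_dropped_variables": len(res.dropped_variables),
            }
            import pandas as pd

            pd.DataFrame(
                res.scores,
                index=res.item_ids,
                columns=[f"PC{i+1}" for i in range(res.scores.shape[1])],
            ).to_csv(outdir / "pca_scores.tsv", sep="\t")

        with _stage(report, "neighborhoods"):
            reported = []
            for anchor in config.anchor_families:
                inst = nb_mod.extract_neighborhoods(genomes, anchor, window=config.window)
                reported.extend(
                    nb_mod.apply_filters(
                        inst, max_gap_nt=config.max_gap_nt, min_taxa=config.min_taxa
                    )
                )
            table = nb_mod.neighborhood_report(reported)
            table.to_csv(outdir / "neighborhoods.tsv", sep="\t", index=False)
            report["n_neighborhoods"] = len(table)
    except Exception:
        (outdir / "FAILED").write_text(report.get("failed_stage", "unknown"))
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
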