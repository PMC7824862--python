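"""Conserved gene-neighborhood detection.

For every occurrence of an anchor family, the flanking genes within a window
are extracted, trimmed to the maximal run around the anchor satisfying an
intergenic-gap constraint (and optionally shared directionality with the
anchor), and grouped by their ordered family signature. A signature counts as
conserved when it spans at least two genes and recurs in more than one taxon.

Gap convention: gap = start(next) - end(prev) - 1 under 1-based inclusive
coordinates, so immediately adjacent genes have gap 0 and overlapping genes
(common in operons) are treated as gap 0 as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GeneRecord, PhageGenome, UNKNOWN_TAXON

__all__ = [
    "NeighborhoodInstance",
    "ConservedNeighborhood",
    "extract_neighborhoods",
    "apply_filters",
    "neighborhood_report",
]


@dataclass
class NeighborhoodInstance:
    phage_id: str
    anchor_gene_id: str
    genes: list[GeneRecord]  # contiguous, genome order
    taxon: str

    def __post_init__(self):
        if all(g.gene_id != self.anchor_gene_id for g in self.genes):
            raise ValueError("anchor gene must be among the member genes")


@dataclass
class ConservedNeighborhood:
    family_signature: tuple[str, ...]
    instances: list[NeighborhoodInstance]
    n_taxa: int


def _gene_label(g: GeneRecord) -> str:
    return g.family_id or g.product or g.gene_id


def extract_neighborhoods(
    genomes: list[PhageGenome], anchor_family: str, window: int = 5
) -> list[NeighborhoodInstance]:
    """Up-to-(2*window+1)-gene windows centered on every gene of the anchor
    family, truncated at genome ends. An anchor family absent from the cohort
    yields an empty list."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out = []
    for gm in genomes:
        genes = gm.genes
        for i, g in enumerate(genes):
            if _gene_label(g) != anchor_family:
                continue
            lo = max(0, i - window)
            hi = min(len(genes), i + window + 1)
            out.append(
                NeighborhoodInstance(
                    phage_id=gm.phage_id,
                    anchor_gene_id=g.gene_id,
                    genes=list(genes[lo:hi]),
                    taxon=gm.taxon,
                )
            )
    return out


def _gap(prev: GeneRecord, nxt: GeneRecord) -> int:
    return max(nxt.start - prev.end - 1, 0)


def _trim_to_run(
    inst: NeighborhoodInstance, max_gap_nt: int, require_same_strand: bool
) -> list[GeneRecord]:
    """Maximal run of genes around the anchor with consecutive gaps
    <= max_gap_nt and (optionally) the anchor's strand."""
    genes = inst.genes
    ai = next(i for i, g in enumerate(genes) if g.gene_id == inst.anchor_gene_id)
    anchor = genes[ai]

    def ok(g: GeneRecord) -> bool:
        return (not require_same_strand) or g.strand == anchor.strand

    lo = ai
    while lo > 0 and ok(genes[lo - 1]) and _gap(genes[lo - 1], genes[lo]) <= max_gap_nt:
        lo -= 1
    hi = ai
    while hi + 1 < len(genes) and ok(genes[hi + 1]) and _gap(genes[hi], genes[hi + 1]) <= max_gap_nt:
        hi += 1
    return genes[lo : hi + 1]


def _signature(run: list[GeneRecord], anchor_strand: str) -> tuple[str, ...]:
    """Ordered family signature, strand-normalized so the anchor reads
    left-to-right (minus-strand anchors reverse the gene order)."""
    labels = [_gene_label(g) for g in run]
    return tuple(reversed(labels)) if anchor_strand == "-" else tuple(labels)


def apply_filters(
    instances: list[NeighborhoodInstance],
    max_gap_nt: int = 50,
    require_same_strand: bool = True,
    min_taxa: int = 2,
) -> list[ConservedNeighborhood]:
    """The three validity filters: intergenic distance, directionality, and
    presence in more than one taxon. The "unknown" taxon never counts toward
    the multi-taxon requirement."""
    if max_gap_nt < 0:
        raise ValueError("max_gap_nt must be >= 0")
    by_sig: dict[tuple[str, ...], list[NeighborhoodInstance]] = {}
    for inst in instances:
        run = _trim_to_run(inst, max_gap_nt, require_same_strand)
        if len(run) < 2:
            continue
        anchor = next(g for g in run if g.gene_id == inst.anchor_gene_id)
        sig = _signature(run, anchor.strand)
        trimmed = NeighborhoodInstance(
            phage_id=inst.phage_id,
            anchor_gene_id=inst.anchor_gene_id,
            genes=run,
            taxon=inst.taxon,
        )
        by_sig.setdefault(sig, []).append(trimmed)
    out = []
    for sig, insts in sorted(by_sig.items()):
        taxa = {i.taxon for i in insts} - {UNKNOWN_TAXON}
        if len(taxa) >= min_taxa:
            out.append(ConservedNeighborhood(sig, insts, len(taxa)))
    return out


def neighborhood_report(neighborhoods: list[ConservedNeighborhood]) -> pd.DataFrame:
    """One row per conserved neighborhood, sorted by (n_taxa desc,
    n_instances desc, signature) for a stable order."""
    rows = []
    for nb in neighborhoods:
        ex = nb.instances[0]
        locus = f"{ex.phage_id}:{ex.genes[0].start}-{ex.genes[-1].end}"
        rows.append(
            {
                "signature": ">".join(nb.family_signature),
                "n_genes": len(nb.family_signature),
                "n_instances": len(nb.instances),
                "n_taxa": nb.n_taxa,
                "example_locus": locus,
            }
        )
    df = pd.DataFrame(
        rows, columns=["signature", "n_genes", "n_instances", "n_taxa", "example_locus"]
    )
    if not df.empty:
        df = df.sort_values(
            ["n_taxa", "n_instances", "signature"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return df
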