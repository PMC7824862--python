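import pytest

from jumbophage.io import GeneRecord, PhageGenome
from jumbophage.neighborhoods import (
    apply_filters,
    extract_neighborhoods,
    neighborhood_report,
)


def _genome(phage_id, taxon, spec, length=50_000):
    """spec: list of (family, gap_before, strand); genes 300 bp each."""
    genes = []
    pos = 0
    for i, (fam, gap, strand) in enumerate(spec):
        start = pos + gap + 1
        end = start + 299
        genes.append(
            GeneRecord(
                f"g{i}", start, end, strand, product=fam, family_id=fam, protein_length=100
            )
        )
        pos = end
    return PhageGenome(phage_id=phage_id, genome_length=length, taxon=taxon, genes=genes)


def _cassette_genome(pid, taxon, gaps=(10, 10), strands=("+", "+", "+"), pre_fam="x"):
    spec = [
        (pre_fam + pid, 100, "+"),
        ("A", 500, strands[0]),
        ("B", gaps[0], strands[1]),
        ("C", gaps[1], strands[2]),
        ("post" + pid, 500, "-"),
    ]
    return _genome(pid, taxon, spec)


class TestExtract:
    def test_window_mid_genome(self):
        gm = _genome("P", "t", [(f"f{i}", 100, "+") for i in range(7)])
        gm.genes[3] = GeneRecord("anchor", gm.genes[3].start, gm.genes[3].end, "+",
                                 product="A", family_id="A", protein_length=100)
        inst = extract_neighborhoods([gm], "A", window=2)
        assert len(inst) == 1 and len(inst[0].genes) == 5

    def test_window_truncated_at_start(self):
        gm = _genome("P", "t", [("A", 100, "+"), ("f1", 50, "+"), ("f2", 50, "+"), ("f3", 50, "+")])
        inst = extract_neighborhoods([gm], "A", window=2)
        assert len(inst[0].genes) == 3  # anchor + 2 downstream only

    def test_two_anchors_two_instances(self):
        gm = _genome("P", "t", [("A", 100, "+"), ("f", 50, "+"), ("A", 50, "+")])
        assert len(extract_neighborhoods([gm], "A", window=1)) == 2

    def test_absent_anchor_empty(self):
        gm = _genome("P", "t", [("f", 100, "+")])
        assert extract_neighborhoods([gm], "nope") == []


class TestFilters:
    def test_planted_cassette_in_two_taxa_reported(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria"),
            _cassette_genome("P2", "firmicutes"),
        ]
        found = apply_filters(extract_neighborhoods(genomes, "A", window=3))
        assert len(found) == 1
        nb = found[0]
        assert nb.family_signature == ("A", "B", "C") and nb.n_taxa == 2

    def test_oversized_gap_trims_cassette(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria", gaps=(60, 60)),
            _cassette_genome("P2", "firmicutes", gaps=(60, 60)),
        ]
        found = apply_filters(extract_neighborhoods(genomes, "A", window=3), max_gap_nt=50)
        assert found == []

    def test_single_taxon_filtered(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria"),
            _cassette_genome("P2", "proteobacteria"),
            _cassette_genome("P3", "proteobacteria"),
        ]
        assert apply_filters(extract_neighborhoods(genomes, "A", window=3)) == []

    def test_unknown_taxon_never_counts(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria"),
            _cassette_genome("P2", "unknown"),
        ]
        assert apply_filters(extract_neighborhoods(genomes, "A", window=3)) == []

    def test_strand_inconsistency_breaks_run(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria", strands=("+", "-", "+")),
            _cassette_genome("P2", "firmicutes", strands=("+", "-", "+")),
        ]
        found = apply_filters(extract_neighborhoods(genomes, "A", window=3))
        assert all(nb.family_signature != ("A", "B", "C") for nb in found)

    def test_strand_requirement_can_be_disabled(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria", strands=("+", "-", "+")),
            _cassette_genome("P2", "firmicutes", strands=("+", "-", "+")),
        ]
        found = apply_filters(
            extract_neighborhoods(genomes, "A", window=3), require_same_strand=False
        )
        assert any(nb.family_signature == ("A", "B", "C") for nb in found)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            apply_filters([], max_gap_nt=-1)

    def test_gap_monotonicity(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria", gaps=(10, 45)),
            _cassette_genome("P2", "firmicutes", gaps=(10, 45)),
            _cassette_genome("P3", "bacteroidetes", gaps=(10, 10)),
        ]
        inst = extract_neighborhoods(genomes, "A", window=3)
        sigs_small = {nb.family_signature for nb in apply_filters(inst, max_gap_nt=45)}
        sigs_large = {nb.family_signature for nb in apply_filters(inst, max_gap_nt=80)}
        assert sigs_small <= sigs_large

    def test_genome_reversal_leaves_signatures_unchanged(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria"),
            _cassette_genome("P2", "firmicutes"),
        ]

        def reverse(gm):
            n = gm.genome_length
            rev = [
                GeneRecord(
                    g.gene_id,
                    n - g.end + 1,
                    n - g.start + 1,
                    "+" if g.strand == "-" else "-",
                    product=g.product,
                    family_id=g.family_id,
                    protein_length=g.protein_length,
                    is_trna=g.is_trna,
                )
                for g in gm.genes
            ]
            return PhageGenome(
                phage_id=gm.phage_id, genome_length=n, taxon=gm.taxon, genes=rev
            )

        fwd = apply_filters(extract_neighborhoods(genomes, "A", window=3))
        rev = apply_filters(
            extract_neighborhoods([reverse(g) for g in genomes], "A", window=3)
        )
        assert {nb.family_signature for nb in fwd} == {nb.family_signature for nb in rev}


class TestReport:
    def test_empty_input_has_header(self):
        df = neighborhood_report([])
        assert list(df.columns) == [
            "signature",
            "n_genes",
            "n_instances",
            "n_taxa",
            "example_locus",
        ]
        assert df.empty

    def test_instance_count(self):
        genomes = [
            _cassette_genome("P1", "proteobacteria"),
            _cassette_genome("P2", "firmicutes"),
            _cassette_genome("P3", "bacteroidetes"),
            _cassette_genome("P4", "cyanobacteria"),
        ]
        found = apply_filters(extract_neighborhoods(genomes, "A", window=3))
        df = neighborhood_report(found)
        assert df.loc[0, "n_instances"] == 4 and df.loc[0, "n_taxa"] == 4

    def test_sorted_by_taxa_then_instances(self):
        genomes = [
            _cassette_genome("P1", "t1"),
            _cassette_genome("P2", "t2"),
            _cassette_genome("P3", "t3"),
            _cassette_genome("Q1", "t1", gaps=(10, 60)),
            _cassette_genome("Q2", "t2", gaps=(10, 60)),
        ]
        # Q cassettes lose gene C to the 60 nt gap -> second signature (A,B)
        found = apply_filters(extract_neighborhoods(genomes, "A", window=3))
        df = neighborhood_report(found)
        assert list(df["signature"]) == ["A>B>C", "A>B"]
        assert list(df["n_taxa"]) == sorted(df["n_taxa"], reverse=True)
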