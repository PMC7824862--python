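"""Readers, writers and the canonical in-memory genome/hit representations.

Coordinates are 1-based and inclusive throughout (GenBank convention); all
downstream intergenic-gap arithmetic assumes this. Genes spanning the origin
of a circular genome are rejected rather than wrapped, because neighborhood
detection relies on a linear gene order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneRecord",
    "PhageGenome",
    "PairwiseHit",
    "GENE_TABLE_COLUMNS",
    "HIT_TABLE_COLUMNS",
    "FormatError",
    "RecordError",
    "protein_id",
    "split_protein_id",
    "read_gene_table",
    "write_gene_table",
    "read_genbank",
    "read_hits",
    "write_hits",
]

#: Exact column order of the gene-table TSV dialect.
GENE_TABLE_COLUMNS = [
    "phage_id",
    "genome_length",
    "taxon",
    "morphology",
    "gene_id",
    "start",
    "end",
    "strand",
    "product",
    "protein_length",
    "is_trna",
]

#: BLAST outfmt-6 columns plus appended qlen/slen (columns 13-14).
HIT_TABLE_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
    "slen",
]

#: Taxon label used when the host taxon is missing; never counted toward
#: the multi-taxon neighborhood filter.
UNKNOWN_TAXON = "unknown"


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class RecordError(ValueError):
    """A single record violates an invariant; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class GeneRecord:
    """One gene with 1-based inclusive coordinates.

    ``protein_length`` is the translated length in amino acids for
    protein-coding genes; tRNA genes are flagged with ``is_trna`` and are
    excluded from gene-density and proteome computations.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    family_id: str | None = None
    protein_length: int = 1
    is_trna: bool = False

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise RecordError(
                f"gene {self.gene_id}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise RecordError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.is_trna and self.protein_length <= 0:
            raise RecordError(f"gene {self.gene_id}: protein_length must be > 0")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class PhageGenome:
    """A phage genome: length, host-taxon label and an ordered gene list."""

    phage_id: str
    genome_length: int
    taxon: str = UNKNOWN_TAXON
    morphology: str | None = None
    genes: list[GeneRecord] = field(default_factory=list)
    #: gene ids occupied by deliberately placed cassettes (bookkeeping used
    #: by planting utilities to avoid overwriting one another); not part of
    #: the genome's identity
    planted_gene_ids: set[str] = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError(f"{self.phage_id}: genome_length must be > 0")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"{self.phage_id}: duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.end > self.genome_length:
                raise ValueError(
                    f"{self.phage_id}: gene {g.gene_id} ends at {g.end} beyond "
                    f"genome length {self.genome_length}"
                )

    @property
    def coding_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if not g.is_trna]

    @property
    def trna_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.is_trna]


@dataclass(frozen=True)
class PairwiseHit:
    """One pairwise protein alignment record (BLAST tabular semantics)."""

    query_id: str
    subject_id: str
    bit_score: float
    align_length: int
    query_length: int
    subject_length: int
    percent_identity: float = 100.0

    def __post_init__(self):
        if self.bit_score < 0 or self.bit_score != self.bit_score:
            raise ValueError(f"bit_score must be finite and >= 0, got {self.bit_score}")
        if self.align_length <= 0 or self.query_length <= 0 or self.subject_length <= 0:
            raise ValueError("alignment and sequence lengths must be > 0")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


def protein_id(phage_id: str, gene_id: str) -> str:
    """Globally unique protein identifier ``phage|gene``."""
    return f"{phage_id}|{gene_id}"


def split_protein_id(pid: str) -> tuple[str, str]:
    phage, _, gene = pid.partition("|")
    return phage, gene


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "t", "yes")


def read_gene_table(path) -> list[PhageGenome]:
    """Read the documented gene-table TSV into PhageGenome objects.

    One genome per distinct ``phage_id``; genes are re-sorted by start.
    Raises :class:`FormatError` for missing columns and :class:`RecordError`
    (with the 1-based file line) for invariant violations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    genomes: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        pid = row["phage_id"]
        try:
            gene = GeneRecord(
                gene_id=row["gene_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                product=row["product"],
                family_id=row["family_id"] if "family_id" in row and row.get("family_id") else None,
                protein_length=int(row["protein_length"]) if row["protein_length"] else 1,
                is_trna=_parse_bool(row["is_trna"]),
            )
        except (RecordError, ValueError) as exc:
            raise RecordError(str(exc), line=line) from exc
        entry = genomes.setdefault(
            pid,
            {
                "genome_length": int(row["genome_length"]),
                "taxon": row["taxon"] or UNKNOWN_TAXON,
                "morphology": row["morphology"] or None,
                "genes": [],
            },
        )
        entry["genes"].append(gene)
    return [
        PhageGenome(phage_id=pid, **entry) for pid, entry in genomes.items()
    ]


def write_gene_table(genomes: list[PhageGenome], path) -> None:
    rows = []
    for gm in genomes:
        for g in gm.genes:
            rows.append(
                {
                    "phage_id": gm.phage_id,
                    "genome_length": gm.genome_length,
                    "taxon": gm.taxon,
                    "morphology": gm.morphology or "",
                    "gene_id": g.gene_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "product": g.product,
                    "protein_length": g.protein_length,
                    "is_trna": g.is_trna,
                    "family_id": g.family_id or "",
                }
            )
    cols = GENE_TABLE_COLUMNS + ["family_id"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_genbank(path) -> list[PhageGenome]:
    """Read GenBank flat files: CDS features become GeneRecords, tRNA
    features are flagged, the source organism becomes the taxon label.

    Origin-spanning (compound wrap-around) locations are rejected; CDS
    features without a usable location are skipped with a warning.
    """
    from Bio import SeqIO

    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        length = len(rec.seq)
        if length == 0:
            raise FormatError(f"{path}: record {rec.id} has no sequence length")
        taxon = UNKNOWN_TAXON
        genes: list[GeneRecord] = []
        n = 0
        for feat in rec.features:
            if feat.type == "source":
                org = feat.qualifiers.get("organism", [None])[0]
                if org:
                    taxon = org
                continue
            if feat.type not in ("CDS", "tRNA"):
                continue
            if feat.location is None:
                warnings.warn(f"{rec.id}: {feat.type} without location skipped")
                continue
            start = int(feat.location.start) + 1  # 0-based -> 1-based
            end = int(feat.location.end)
            if start > end:
                raise FormatError(
                    f"{rec.id}: feature at {feat.location} spans the origin; "
                    "circular wrap-around is not supported"
                )
            strand = "-" if feat.location.strand == -1 else "+"
            n += 1
            gene_id = feat.qualifiers.get(
                "locus_tag", feat.qualifiers.get("protein_id", [f"{rec.id}_f{n}"])
            )[0]
            if feat.type == "tRNA":
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        start=start,
                        end=end,
                        strand=strand,
                        product=feat.qualifiers.get("product", ["tRNA"])[0],
                        is_trna=True,
                    )
                )
                continue
            translation = feat.qualifiers.get("translation", [None])[0]
            plen = len(translation) if translation else max((end - start + 1) // 3 - 1, 1)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=feat.qualifiers.get("product", [""])[0],
                    protein_length=plen,
                )
            )
        genomes.append(
            PhageGenome(phage_id=rec.id, genome_length=length, taxon=taxon, genes=genes)
        )
    if not genomes:
        raise FormatError(f"{path}: no GenBank records found")
    return genomes


def read_hits(path) -> list[PairwiseHit]:
    """Read the 14-column hit-table dialect (BLAST outfmt 6 + qlen + slen)."""
    hits: list[PairwiseHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(HIT_TABLE_COLUMNS):
                raise FormatError(
                    f"{path} line {lineno}: expected {len(HIT_TABLE_COLUMNS)} "
                    "tab-separated columns (BLAST outfmt 6 plus appended qlen and "
                    f"slen), got {len(parts)}"
                )
            try:
                hits.append(
                    PairwiseHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        align_length=int(parts[3]),
                        bit_score=float(parts[11]),
                        query_length=int(parts[12]),
                        subject_length=int(parts[13]),
                    )
                )
            except ValueError as exc:
                raise RecordError(str(exc), line=lineno) from exc
    return hits


def write_hits(hits: list[PairwiseHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            h.query_id,
                            h.subject_id,
                            f"{h.percent_identity:.1f}",
                            h.align_length,
                            0,
                            0,
                            1,
                            h.align_length,
                            1,
                            h.align_length,
                            "0.0",
                            f"{h.bit_score:.1f}",
                            h.query_length,
                            h.subject_length,
                        ],
                    )
                )
                + "\n"
            )
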