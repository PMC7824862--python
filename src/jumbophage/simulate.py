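"""Synthetic phage-cohort generator.

Emulates the statistical structure of a large tailed-phage collection so the
whole pipeline is testable without external data:

* genome sizes drawn from a trimodal Normal mixture (small / medium / jumbo,
  modes 50 / 130 / 230 kb) whose valley near 180 kb defines the jumbo
  category;
* protein-coding gene density Normal(1.5, 0.25) per kb;
* right-skewed lognormal protein lengths, median 151 aa in jumbo-category
  genomes and 127 aa otherwise, with the shape chosen so the population
  moment skewness is 6.5;
* three top-level phage groups split into five subgroups, each defined by a
  complement of marker protein families (multisubunit RNA polymerase,
  divergent PolB, T7-type or PolIII-type replicases, capsid types, ...) on
  top of universal families (terminase, SbcC/SbcD, lysozyme), with
  symmetric gain/loss flip noise;
* subgroup-specific Poisson tRNA counts;
* optionally planted conserved gene neighborhoods with exact intergenic gaps
  and strands.

Randomness is hierarchical: a single global seed spawns one independent
stream per phage (keyed by phage index), so enlarging the cohort never
perturbs earlier genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io import GeneRecord, PairwiseHit, PhageGenome, protein_id

__all__ = [
    "SizeComponent",
    "CohortConfig",
    "GroundTruth",
    "lognormal_sigma_for_skewness",
    "sample_genome_sizes",
    "sample_protein_lengths",
    "generate_cohort",
    "generate_hits",
    "plant_neighborhood",
]


@dataclass(frozen=True)
class SizeComponent:
    weight: float
    mode_kb: float
    sd_kb: float


#: Trimodal genome-size mixture. Small and jumbo modes (50, 230 kb) follow
#: the observed distribution; the medium mode (130 kb) and the weights are
#: free choices shaped to the observed relative abundances (small phages most
#: abundant, jumbo sparse).
DEFAULT_SIZE_MIXTURE = {
    "small": SizeComponent(0.55, 50.0, 12.0),
    "medium": SizeComponent(0.33, 130.0, 20.0),
    "jumbo": SizeComponent(0.12, 230.0, 28.0),
}

#: Marker-family complements per subgroup. Group-level markers are shared by
#: the group's subgroups; subgroup markers distinguish the splits.
GROUP_OF_SUBGROUP = {"1": "1", "2.1": "2", "2.2": "2", "3.1": "3", "3.2": "3"}

UNIVERSAL_FAMILIES = ("terminase", "sbcC", "sbcD", "lysozyme")

GROUP_MARKERS = {
    "1": (
        "msRNAP",
        "polB_divergent",
        "dnaB_divergent",
        "MCP_phiKZ",
        "tubulin",
        "hsp60",
        "NAD_ligase",
        "ruvC",
        "snf2_g1",
    ),
    "2": (
        "polB_classic",
        "SSB_OB",
        "uvsW",
        "sigma_factor",
        "MCP_gp23",
        "uvsX",
        "uvsY",
        "dnaG_primase",
    ),
    "3": ("ruvC", "xkdF_peptidase", "snf2_g3", "uvrD"),
}

SUBGROUP_MARKERS = {
    "1": (),
    "2.1": ("ligase_DBD", "flap_nuclease", "LPS_biosynthesis"),
    "2.2": ("polIII_split", "uvsW1", "ATP_ligase", "endoVII_HJR", "uri_endonuclease", "uvrD"),
    "3.1": ("polA_T7", "dnaB_standard", "AEP_primase", "RFC_loader"),
    "3.2": ("polIII_alpha_PHP",),
}

#: Morphology-linked family: the contractile tail sheath, present in
#: myoviruses of every group and absent from siphoviruses.
MORPHOLOGY_FAMILY = "tail_sheath"

#: Mean tRNA counts per genome by subgroup. The 3.2 value is a free choice
#: (not reported for that subgroup), kept between the neighboring means.
DEFAULT_TRNA_MEANS = {"1": 4.5, "2.1": 7.1, "2.2": 18.0, "3.1": 22.0, "3.2": 12.0}

#: Candidate host phyla per subgroup (taxon labels drawn uniformly).
DEFAULT_TAXA = {
    "1": ("gammaproteobacteria", "betaproteobacteria"),
    "2.1": ("cyanobacteria", "alphaproteobacteria"),
    "2.2": ("gammaproteobacteria", "alphaproteobacteria", "bacteroidetes"),
    "3.1": ("gammaproteobacteria", "actinobacteria"),
    "3.2": ("firmicutes", "gammaproteobacteria"),
}


def lognormal_sigma_for_skewness(target: float = 6.5) -> float:
    """Shape sigma of a lognormal whose moment skewness equals ``target``,
    from (e^{sigma^2} + 2) sqrt(e^{sigma^2} - 1) = target."""

    def f(s):
        w = math.exp(s * s)
        return (w + 2.0) * math.sqrt(w - 1.0) - target

    return brentq(f, 0.05, 3.0)


#: Solved once; moment skewness 6.5 sits centrally in the observed 6.4-6.8.
PROTEIN_LENGTH_SIGMA = lognormal_sigma_for_skewness(6.5)

PROTEIN_LENGTH_MEDIANS = {"jumbo": 151.0, "non-jumbo": 127.0}


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort. Defaults are the calibrated
    values; see the module docstring for their provenance."""

    n_phages: dict[str, int] = field(
        default_factory=lambda: {"1": 40, "2.1": 40, "2.2": 40, "3.1": 40, "3.2": 40}
    )
    size_mixture: dict[str, SizeComponent] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_MIXTURE)
    )
    gene_density_mean: float = 1.5
    gene_density_sd: float = 0.25
    protein_length_sigma: float = PROTEIN_LENGTH_SIGMA
    gain_loss_noise: float = 0.05
    n_background_families: int = 120
    background_presence: float = 0.15
    trna_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRNA_MEANS))
    intergenic_gap_mean: float = 100.0
    seed: int = 0

    def __post_init__(self):
        w = sum(c.weight for c in self.size_mixture.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"size-mixture weights must sum to 1, got {w}")
        if any(c.sd_kb <= 0 for c in self.size_mixture.values()):
            raise ValueError("size-mixture sds must be > 0")
        if not (0.0 <= self.gain_loss_noise < 0.5):
            raise ValueError("gain_loss_noise must be in [0, 0.5)")
        unknown = set(self.n_phages) - set(GROUP_OF_SUBGROUP)
        if unknown:
            raise ValueError(f"unknown subgroup(s): {sorted(unknown)}")


@dataclass
class GroundTruth:
    subgroup: dict[str, str] = field(default_factory=dict)  # phage -> subgroup
    group: dict[str, str] = field(default_factory=dict)  # phage -> top-level group
    size_category: dict[str, str] = field(default_factory=dict)
    family_of_protein: dict[str, str] = field(default_factory=dict)
    planted_signatures: list[dict] = field(default_factory=list)

    def members_by_family(self) -> dict[str, list[str]]:
        fam: dict[str, list[str]] = {}
        for pid, f in self.family_of_protein.items():
            fam.setdefault(f, []).append(pid)
        return {f: sorted(ms) for f, ms in fam.items()}


def _phage_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def sample_genome_sizes(n: int, rng: np.random.Generator, mixture=None) -> np.ndarray:
    """Draw n genome sizes (kb) from the trimodal mixture."""
    mixture = mixture or DEFAULT_SIZE_MIXTURE
    comps = list(mixture.values())
    idx = rng.choice(len(comps), size=n, p=[c.weight for c in comps])
    sizes = np.array([rng.normal(comps[i].mode_kb, comps[i].sd_kb) for i in idx])
    return np.maximum(sizes, 5.0)


def sample_protein_lengths(
    category: str, n: int, rng: np.random.Generator, sigma: float = PROTEIN_LENGTH_SIGMA
) -> np.ndarray:
    """Integer protein lengths (aa) for a size category ('jumbo' or
    'non-jumbo'): lognormal around the category median with common shape."""
    med = PROTEIN_LENGTH_MEDIANS[category]
    x = rng.lognormal(math.log(med), sigma, size=n)
    return np.maximum(np.rint(x), 1.0).astype(int)


def _layout(
    genome_length: int,
    footprints: np.ndarray,
    rng: np.random.Generator,
    gap_mean: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Place genes left-to-right with geometric intergenic gaps, rescaling
    footprints proportionally when the drawn genome is too short to hold the
    nominal 3 bp/aa extents. Returns (starts, ends), 1-based inclusive."""
    n = footprints.size
    gaps = rng.geometric(1.0 / gap_mean, size=n)  # gap before each gene, >= 1
    gaps[0] = 1
    total = int(footprints.sum() + gaps.sum())
    if total > genome_length:
        avail = genome_length - int(gaps.sum())
        scale = avail / float(footprints.sum())
        footprints = np.maximum(np.floor(footprints * scale), 30).astype(int)
        excess = int(footprints.sum() + gaps.sum()) - genome_length
        while excess > 0:  # shave the flooring remainder off the largest genes
            i = int(np.argmax(footprints))
            room = footprints[i] - 30
            if room <= 0:
                raise ValueError(
                    f"infeasible layout: {n} genes need >= "
                    f"{int(footprints.sum() + gaps.sum())} bp but genome is "
                    f"{genome_length} bp"
                )
            take = min(room, excess)
            footprints[i] -= take
            excess -= take
    starts = np.empty(n, dtype=int)
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        starts[i] = pos
        pos += int(footprints[i]) - 1
        pos += 1
    ends = starts + footprints.astype(int) - 1
    return starts, ends


def _marker_families(subgroup: str, morphology: str) -> set[str]:
    own = set(UNIVERSAL_FAMILIES)
    own.update(GROUP_MARKERS[GROUP_OF_SUBGROUP[subgroup]])
    own.update(SUBGROUP_MARKERS[subgroup])
    if morphology == "myo":
        own.add(MORPHOLOGY_FAMILY)
    return own


def _all_marker_families() -> list[str]:
    fams = list(UNIVERSAL_FAMILIES) + [MORPHOLOGY_FAMILY]
    for g in GROUP_MARKERS.values():
        fams.extend(g)
    for s in SUBGROUP_MARKERS.values():
        fams.extend(s)
    # families may belong to several complements; keep first occurrence
    return list(dict.fromkeys(fams))


def generate_cohort(config: CohortConfig | None = None) -> tuple[list[PhageGenome], GroundTruth]:
    """Generate the cohort. Fully reproducible from ``config.seed``."""
    config = config or CohortConfig()
    comps = list(config.size_mixture.items())
    weights = [c.weight for _, c in comps]
    all_markers = _all_marker_families()
    background = [f"bg{i:03d}" for i in range(config.n_background_families)]
    genomes: list[PhageGenome] = []
    truth = GroundTruth()

    index = 0
    for subgroup in sorted(config.n_phages):
        for _ in range(config.n_phages[subgroup]):
            rng = _phage_rng(config.seed, index)
            phage = f"phage{index:05d}"
            index += 1

            ci = rng.choice(len(comps), p=weights)
            cat_name, comp = comps[ci]
            size_kb = max(rng.normal(comp.mode_kb, comp.sd_kb), 5.0)
            genome_length = int(round(size_kb * 1000))
            density = max(rng.normal(config.gene_density_mean, config.gene_density_sd), 0.1)
            n_genes = max(int(round(density * size_kb)), 1)

            # family complement: universal + subgroup markers with flip
            # noise, plus background families at their presence probability
            morphology = "sipho" if subgroup == "3.2" else "myo"
            own = _marker_families(subgroup, morphology)
            present: list[str] = []
            for fam in all_markers:
                p = 1.0 - config.gain_loss_noise if fam in own else config.gain_loss_noise
                if rng.random() < p:
                    present.append(fam)
            for fam in background:
                if rng.random() < config.background_presence:
                    present.append(fam)
            if len(present) > n_genes:
                present = present[:n_genes]
            labels = present + [
                f"orphan_{phage}_{i}" for i in range(n_genes - len(present))
            ]
            order = rng.permutation(n_genes)
            labels = [labels[i] for i in order]

            lengths = sample_protein_lengths(
                "jumbo" if cat_name == "jumbo" else "non-jumbo",
                n_genes,
                rng,
                config.protein_length_sigma,
            )
            n_trna = int(rng.poisson(config.trna_means[subgroup]))

            footprints = np.concatenate([lengths * 3, np.full(n_trna, 75)])
            kinds = np.array([0] * n_genes + [1] * n_trna)
            shuffle = rng.permutation(footprints.size)
            footprints = footprints[shuffle]
            kinds = kinds[shuffle]
            starts, ends = _layout(
                genome_length, footprints.astype(float), rng, config.intergenic_gap_mean
            )
            strands = np.where(rng.random(footprints.size) < 0.5, "+", "-")

            genes: list[GeneRecord] = []
            ic = it = 0
            for j in range(footprints.size):
                if kinds[j] == 0:
                    fam = labels[ic]
                    gene_id = f"g{j + 1:04d}"
                    genes.append(
                        GeneRecord(
                            gene_id=gene_id,
                            start=int(starts[j]),
                            end=int(ends[j]),
                            strand=str(strands[j]),
                            product=fam,
                            family_id=fam,
                            protein_length=int(lengths[ic]),
                        )
                    )
                    truth.family_of_protein[protein_id(phage, gene_id)] = fam
                    ic += 1
                else:
                    genes.append(
                        GeneRecord(
                            gene_id=f"t{it + 1:03d}",
                            start=int(starts[j]),
                            end=int(ends[j]),
                            strand=str(strands[j]),
                            product="tRNA",
                            is_trna=True,
                        )
                    )
                    it += 1

            taxa = DEFAULT_TAXA[subgroup]
            taxon = taxa[int(rng.integers(len(taxa)))]
            genomes.append(
                PhageGenome(
                    phage_id=phage,
                    genome_length=genome_length,
                    taxon=taxon,
                    morphology=morphology,
                    genes=genes,
                )
            )
            truth.subgroup[phage] = subgroup
            truth.group[phage] = GROUP_OF_SUBGROUP[subgroup]
            truth.size_category[phage] = cat_name
    return genomes, truth


def generate_hits(
    genomes: list[PhageGenome],
    truth: GroundTruth,
    within_family_density: float = 1.5,
    decoy_density: float = 0.5,
    decoy_fraction: float = 0.02,
    seed: int = 0,
) -> list[PairwiseHit]:
    """Pairwise hit table consistent with the ground-truth families.

    Every within-family pair receives a hit at ``within_family_density``
    bits/position with full mutual coverage; a ``decoy_fraction`` of random
    cross-family pairs receive sub-threshold hits (low density, 30%
    coverage) that correct filtering must reject. Orphan (singleton)
    families yield no hits by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(987,)))
    plen: dict[str, int] = {}
    for gm in genomes:
        for g in gm.coding_genes:
            plen[protein_id(gm.phage_id, g.gene_id)] = g.protein_length
    hits: list[PairwiseHit] = []
    n_within = 0
    members = truth.members_by_family()
    for fam, ms in sorted(members.items()):
        if fam.startswith("orphan_") or len(ms) < 2:
            continue
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                q, s = ms[i], ms[j]
                if q not in plen or s not in plen:
                    continue
                align = max(plen[q], plen[s])
                hits.append(
                    PairwiseHit(
                        query_id=q,
                        subject_id=s,
                        bit_score=within_family_density * align,
                        align_length=align,
                        query_length=plen[q],
                        subject_length=plen[s],
                        percent_identity=float(rng.uniform(40, 95)),
                    )
                )
                n_within += 1
    proteins = sorted(plen)
    n_decoys = int(decoy_fraction * n_within)
    fam_of = truth.family_of_protein
    made = 0
    while made < n_decoys and len(proteins) >= 2:
        q, s = (proteins[i] for i in rng.choice(len(proteins), 2, replace=False))
        if fam_of.get(q) == fam_of.get(s):
            continue
        align = max(int(0.3 * min(plen[q], plen[s])), 1)
        hits.append(
            PairwiseHit(
                query_id=q,
                subject_id=s,
                bit_score=decoy_density * align,
                align_length=align,
                query_length=plen[q],
                subject_length=plen[s],
                percent_identity=float(rng.uniform(10, 25)),
            )
        )
        made += 1
    return hits


def plant_neighborhood(
    genomes: list[PhageGenome],
    signature: tuple[str, ...],
    taxa: list[str],
    gap_nt: int = 10,
    strand: str = "+",
    truth: GroundTruth | None = None,
    seed: int = 0,
    strands: list[str] | None = None,
) -> None:
    """Insert a conserved cassette in place into >= 1 genome per listed
    taxon: a run of len(signature) consecutive protein-coding genes is
    relabeled with the signature families and re-coordinated to exact
    ``gap_nt`` intergenic gaps on the given strand (or explicit per-gene
    ``strands``). Raises if a taxon has no genome with room."""
    if gap_nt < 0:
        raise ValueError("gap_nt must be >= 0")
    k = len(signature)
    if k < 2:
        raise ValueError("a cassette needs at least 2 genes")
    gene_strands = strands if strands is not None else [strand] * k
    if len(gene_strands) != k:
        raise ValueError("strands must match signature length")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(555,)))
    plen = 100  # planted genes get a fixed 300 bp footprint
    margin = 200  # gap isolating the cassette from flanking genes
    # on the minus strand the cassette is transcribed right-to-left, so its
    # genes are laid in reverse coordinate order
    uniform_minus = strands is None and strand == "-"
    coord_sig = tuple(reversed(signature)) if uniform_minus else tuple(signature)
    coord_strands = list(reversed(gene_strands)) if uniform_minus else list(gene_strands)
    for taxon in taxa:
        candidates = [g for g in genomes if g.taxon == taxon]
        if not candidates:
            raise ValueError(f"no genome with taxon {taxon}")
        planted = False
        for gm in sorted(candidates, key=lambda g: g.phage_id):
            coding_idx = [i for i, g in enumerate(gm.genes) if not g.is_trna]
            if len(coding_idx) < k + 2:
                continue
            # pick an interior run of k consecutive genes (any kind) whose
            # replacement cassette fits before the next untouched gene
            for start_at in rng.permutation(len(gm.genes) - k - 1)[:50]:
                i0 = int(start_at) + 1  # keep the first gene untouched
                block = gm.genes[i0 : i0 + k]
                # never disturb an earlier cassette or its flanks
                window_ids = {g.gene_id for g in gm.genes[i0 - 1 : i0 + k + 1]}
                if window_ids & gm.planted_gene_ids:
                    continue
                extent = k * (3 * plen) + (k - 1) * gap_nt
                left = gm.genes[i0 - 1].end + 1 + margin
                limit = (
                    gm.genes[i0 + k].start - 1 - margin
                    if i0 + k < len(gm.genes)
                    else gm.genome_length
                )
                if left + extent - 1 > limit:
                    continue
                new_genes = list(gm.genes)
                pos = left
                for j in range(k):
                    old = block[j]
                    new_genes[i0 + j] = GeneRecord(
                        gene_id=old.gene_id,
                        start=pos,
                        end=pos + 3 * plen - 1,
                        strand=coord_strands[j],
                        product=coord_sig[j],
                        family_id=coord_sig[j],
                        protein_length=plen,
                        is_trna=False,
                    )
                    if truth is not None:
                        truth.family_of_protein[
                            protein_id(gm.phage_id, old.gene_id)
                        ] = coord_sig[j]
                    pos += 3 * plen + gap_nt
                gm.genes = sorted(new_genes, key=lambda g: g.start)
                gm.planted_gene_ids.update(g.gene_id for g in block)
                planted = True
                if truth is not None:
                    truth.planted_signatures.append(
                        {
                            "signature": list(signature),
                            "phage_id": gm.phage_id,
                            "taxon": taxon,
                            "gap_nt": gap_nt,
                            "strands": list(gene_strands),
                        }
                    )
                break
            if planted:
                break
        if not planted:
            raise ValueError(f"no room to plant the cassette in taxon {taxon}")
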