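"""Protein-family construction by single-linkage clustering of pairwise
alignment hits, with coverage (L) and bit-score-density (S) thresholds.

An edge survives filtering when the alignment covers at least a fraction L of
the sequence length(s) and carries at least S bits per aligned position;
families are then the connected components of the surviving edge graph, so a
family is the transitive closure of above-threshold similarity. Proteins with
no surviving edge form singleton families.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io import PairwiseHit, split_protein_id

__all__ = ["ClusterParams", "ProteinFamily", "filter_hits", "single_linkage", "dereplicate"]


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for hit filtering.

    min_coverage (L): fraction of sequence length that must be aligned.
    min_score_density (S): bits per aligned position.
    coverage_mode: "both" requires the coverage test on query and subject,
    "either" on at least one of them.
    """

    min_coverage: float = 0.6
    min_score_density: float = 1.0
    coverage_mode: str = "both"

    def __post_init__(self):
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.min_score_density < 0:
            raise ValueError("min_score_density must be >= 0")
        if self.coverage_mode not in ("both", "either"):
            raise ValueError("coverage_mode must be 'both' or 'either'")


@dataclass(frozen=True)
class ProteinFamily:
    family_id: str
    members: frozenset[str]
    n_phages: int

    def __post_init__(self):
        if not self.members:
            raise ValueError("a family cannot be empty")


def _best_per_pair(hits: list[PairwiseHit]) -> dict[tuple[str, str], PairwiseHit]:
    """Keep the best hit (max bit-score density) per unordered pair."""
    best: dict[tuple[str, str], PairwiseHit] = {}
    for h in hits:
        if h.is_self:
            continue
        key = (h.query_id, h.subject_id) if h.query_id <= h.subject_id else (h.subject_id, h.query_id)
        cur = best.get(key)
        if cur is None or h.bit_score / h.align_length > cur.bit_score / cur.align_length:
            best[key] = h
    return best


def _passes(h: PairwiseHit, params: ClusterParams) -> bool:
    if h.bit_score / h.align_length < params.min_score_density:
        return False
    covq = h.align_length / h.query_length
    covs = h.align_length / h.subject_length
    if params.coverage_mode == "both":
        return covq >= params.min_coverage and covs >= params.min_coverage
    return covq >= params.min_coverage or covs >= params.min_coverage


def filter_hits(hits: list[PairwiseHit], params: ClusterParams | None = None) -> list[tuple[str, str]]:
    """Edges (q, s), q != s, passing the score-density and coverage tests.

    Multiple hits for a pair are reduced to the best-density one first, and
    the result is direction-symmetric.
    """
    params = params or ClusterParams()
    return [tuple(k) for k, h in sorted(_best_per_pair(hits).items()) if _passes(h, params)]


def single_linkage(edges, universe) -> list[ProteinFamily]:
    """Connected components of the edge graph over ``universe``.

    Every protein belongs to exactly one family (singletons included); the
    family_id is the lexicographically smallest member id.
    """
    universe = set(universe)
    g = nx.Graph()
    g.add_nodes_from(universe)
    for q, s in edges:
        if q not in universe or s not in universe:
            raise ValueError(f"edge endpoint outside universe: ({q}, {s})")
        g.add_edge(q, s)
    families = []
    for comp in nx.connected_components(g):
        members = frozenset(comp)
        fid = min(members)
        phages = {split_protein_id(m)[0] for m in members}
        families.append(ProteinFamily(family_id=fid, members=members, n_phages=len(phages)))
    families.sort(key=lambda f: f.family_id)
    return families


def dereplicate(
    hits: list[PairwiseHit],
    identity_threshold: float = 90.0,
    min_coverage: float = 0.9,
) -> dict[str, list[str]]:
    """Purge nearly identical sequences: single-linkage clusters at
    >= identity_threshold percent identity and >= min_coverage coverage of
    both sequences, keeping one representative per cluster (the longest
    member, ties broken by id).

    Returns {representative: sorted cluster members}.
    """
    lengths: dict[str, int] = {}
    for h in hits:
        lengths[h.query_id] = h.query_length
        lengths[h.subject_id] = h.subject_length
    edges = []
    for key, h in _best_per_pair(hits).items():
        if (
            h.percent_identity >= identity_threshold
            and h.align_length / h.query_length >= min_coverage
            and h.align_length / h.subject_length >= min_coverage
        ):
            edges.append(key)
    out: dict[str, list[str]] = {}
    for fam in single_linkage(edges, lengths.keys()):
        # longest member; among equal lengths the lexicographically first id
        rep = sorted(fam.members, key=lambda m: (-lengths[m], m))[0]
        out[rep] = sorted(fam.members)
    return out
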