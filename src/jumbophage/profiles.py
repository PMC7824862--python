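"""Phyletic-pattern analysis: the binary families x phages matrix, Canberra
distances, Ward and average-linkage dendrograms, tree cutting and Newick
export.

The phyletic pattern of a protein family is its presence/absence vector
across phages; the same matrix read column-wise gives the family complement
of each phage. Canberra distance on such binary vectors reduces to the count
of coordinates present in exactly one of the two (0/0 terms contribute
nothing, by the standard statistical-computing convention for the otherwise
indeterminate 0/0 ratio).

The agglomerative clustering is implemented directly via the Lance-Williams
recurrence so that the Ward variants (on squared vs raw distances) and the
tie-breaking rule (smallest index pair) are explicit and platform-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhyleticMatrix",
    "DistanceMatrix",
    "Dendrogram",
    "build_matrix",
    "dedupe_patterns",
    "canberra",
    "pairwise_distances",
    "ward_cluster",
    "upgma_cluster",
    "cut_tree",
    "to_newick",
    "zscore_tree",
]


@dataclass
class PhyleticMatrix:
    """Binary families (rows) x phages (columns) presence/absence matrix."""

    family_ids: list[str]
    phage_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.family_ids), len(self.phage_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        self.values = self.values.astype(np.int8)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.family_ids, columns=self.phage_ids)

    @classmethod
    def from_frame(cls, df) -> "PhyleticMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.isfinite(self.d).all():
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("diagonal must be zero")


@dataclass
class Dendrogram:
    """Merge tree from agglomerative clustering.

    Clusters are numbered scipy-style: leaves 0..n-1, the i-th merge creates
    cluster n+i. ``merges`` holds (cluster_a, cluster_b, height, new_size)
    with cluster_a < cluster_b.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.leaf_ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_scipy_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def build_matrix(families, genomes, selected=None, min_phages: int = 1) -> PhyleticMatrix:
    """Presence/absence matrix: entry (f, p) = 1 iff family f has a member
    protein from phage p.

    ``selected`` restricts to a family subset (error if unknown families are
    named); ``min_phages`` drops families represented in fewer phages, the
    "wide representation" filter used before classification.
    """
    from .io import split_protein_id

    phage_ids = [g.phage_id for g in genomes]
    phage_index = {p: i for i, p in enumerate(phage_ids)}
    fam_list = sorted(families, key=lambda f: f.family_id)
    if selected is not None:
        known = {f.family_id for f in fam_list}
        unknown = set(selected) - known
        if unknown:
            raise ValueError(f"selected families not found: {sorted(unknown)}")
        fam_list = [f for f in fam_list if f.family_id in set(selected)]
    rows, ids = [], []
    for fam in fam_list:
        row = np.zeros(len(phage_ids), dtype=np.int8)
        for m in fam.members:
            phage = split_protein_id(m)[0]
            if phage in phage_index:
                row[phage_index[phage]] = 1
        npres = int(row.sum())
        if npres == 0:
            warnings.warn(f"family {fam.family_id} absent from all phages; dropped")
            continue
        if npres < min_phages:
            continue
        rows.append(row)
        ids.append(fam.family_id)
    if not ids:
        raise ValueError("no families left after filtering")
    return PhyleticMatrix(ids, phage_ids, np.vstack(rows))


def dedupe_patterns(m: PhyleticMatrix) -> tuple[PhyleticMatrix, dict[str, list[str]]]:
    """Collapse phages with identical family complements to one
    representative column (the first in matrix order); returns the reduced
    matrix and {representative: all members}."""
    seen: dict[bytes, str] = {}
    mapping: dict[str, list[str]] = {}
    keep: list[int] = []
    for j, pid in enumerate(m.phage_ids):
        key = m.values[:, j].tobytes()
        if key in seen:
            mapping[seen[key]].append(pid)
        else:
            seen[key] = pid
            mapping[pid] = [pid]
            keep.append(j)
    reduced = PhyleticMatrix(
        list(m.family_ids), [m.phage_ids[j] for j in keep], m.values[:, keep]
    )
    return reduced, mapping


def canberra(p, q) -> float:
    """Canberra distance sum_i |p_i - q_i| / (|p_i| + |q_i|), with 0/0 terms
    contributing 0. On binary vectors this is the number of coordinates
    present in exactly one of the two vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    num = np.abs(p - q)
    den = np.abs(p) + np.abs(q)
    mask = den > 0
    return float((num[mask] / den[mask]).sum())


def pairwise_distances(m: PhyleticMatrix, axis: str = "phages") -> DistanceMatrix:
    """All-pairs Canberra distance over phages (columns) or families (rows)."""
    if axis == "phages":
        x = m.values.T.astype(float)
        ids = list(m.phage_ids)
    elif axis == "families":
        x = m.values.astype(float)
        ids = list(m.family_ids)
    else:
        raise ValueError("axis must be 'phages' or 'families'")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two items on the chosen axis")
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :])
        den = np.abs(x[i]) + np.abs(x[i + 1 :])
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        d[i, i + 1 :] = terms.sum(axis=1)
    d = d + d.T
    return DistanceMatrix(ids, d)


def _lance_williams(d0: np.ndarray, ids: list[str], update) -> Dendrogram:
    """Generic agglomerator. ``update(di_k, dj_k, d_ij, ni, nj, nk)`` returns
    the distance from the merged cluster (i u j) to cluster k. Ties on the
    minimum inter-cluster distance are broken by the smallest (a, b) cluster
    index pair, giving platform-stable dendrograms."""
    n = len(ids)
    d = d0.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))  # current cluster labels, scipy numbering
    sizes = {i: 1 for i in range(n)}
    pos = {i: i for i in range(n)}  # cluster label -> row in d
    row_label = list(range(n))  # row in d -> cluster label
    merges = []
    for step in range(n - 1):
        # global minimum; exact ties broken by smallest (a, b) label pair
        m = d.min()
        ii, jj = np.nonzero(np.triu(d == m, 1))
        cand = sorted(
            (min(row_label[i], row_label[j]), max(row_label[i], row_label[j]))
            for i, j in zip(ii, jj)
        )
        a, b = cand[0]
        dist = d[pos[a], pos[b]]
        new = n + step
        ni, nj = sizes[a], sizes[b]
        # update distances from the merged cluster to every other active one
        ia, ib = pos[a], pos[b]
        for c in active:
            if c in (a, b):
                continue
            ic = pos[c]
            d[ia, ic] = d[ic, ia] = update(d[ia, ic], d[ib, ic], dist, ni, nj, sizes[c])
        # merged cluster reuses row ia
        active.remove(b)
        active.remove(a)
        active.append(new)
        pos[new] = ia
        row_label[ia] = new
        sizes[new] = ni + nj
        d[ib, :] = np.inf
        d[:, ib] = np.inf
        d[ia, ia] = np.inf
        merges.append((a, b, float(dist), ni + nj))
    return Dendrogram(list(ids), merges)


def ward_cluster(dm: DistanceMatrix, variant: str = "ward_d2") -> Dendrogram:
    """Ward agglomeration via the Lance-Williams recurrence with coefficients
    alpha_i = (n_i + n_k) / (n_i + n_j + n_k), beta = -n_k / (n_i + n_j + n_k).

    ``ward_d2`` applies the recurrence to squared distances and reports merge
    heights on the original scale (square roots) — the textbook minimum
    increase in within-cluster sum of squares when the input is Euclidean.
    ``ward_d`` applies it to the raw distances, matching the alternative
    convention of some statistical environments.
    """
    if variant not in ("ward_d2", "ward_d"):
        raise ValueError("variant must be 'ward_d2' or 'ward_d'")

    def upd(dik, djk, dij, ni, nj, nk):
        t = ni + nj + nk
        return ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / t

    if variant == "ward_d2":
        dend = _lance_williams(dm.d**2, dm.ids, upd)
        dend.merges = [(a, b, float(np.sqrt(h)), s) for a, b, h, s in dend.merges]
        return dend
    return _lance_williams(dm.d, dm.ids, upd)


def upgma_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration."""

    def upd(dik, djk, dij, ni, nj, nk):
        return (ni * dik + nj * djk) / (ni + nj)

    return _lance_williams(dm.d, dm.ids, upd)


def zscore_tree(z: np.ndarray, ids: list[str]) -> Dendrogram:
    """Average-linkage tree from an all-vs-all structural-similarity Z-score
    matrix: similarity is converted to distance d(i,j) = max(z) - z(i,j)
    (zero diagonal), then clustered by UPGMA."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] != z.shape[1] or z.shape[0] != len(ids):
        raise ValueError("z must be square and match ids")
    if np.abs(z - z.T).max() > 1e-8:
        raise ValueError("z-score matrix is asymmetric beyond tolerance 1e-8")
    d = z.max() - z
    np.fill_diagonal(d, 0.0)
    return upgma_cluster(DistanceMatrix(list(ids), d))


def cut_tree(t: Dendrogram, k: int) -> dict[str, int]:
    """Labels of the k-cluster partition obtained by undoing the k-1 highest
    (last) merges. Label ids are assigned in order of first leaf appearance."""
    n = t.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + max(n - 1, 0)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _h, _s) in enumerate(t.merges[: n - k]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, leaf in enumerate(t.leaf_ids):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[leaf] = roots[r]
    return labels


def _escape_newick(name: str) -> str:
    if any(c in name for c in " ()[]:;,'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(t: Dendrogram) -> str:
    """Newick string with branch lengths equal to height differences between
    a cluster and its parent merge."""
    n = t.n_leaves
    if n == 1:
        return f"{_escape_newick(t.leaf_ids[0])}:0.0;"
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: _escape_newick(t.leaf_ids[i]) for i in range(n)}
    for step, (a, b, h, _s) in enumerate(t.merges):
        new = n + step
        sa = f"{node[a]}:{h - height[a]:g}"
        sb = f"{node[b]}:{h - height[b]:g}"
        node[new] = f"({sa},{sb})"
        height[new] = h
    return node[n + len(t.merges) - 1] + ";"
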