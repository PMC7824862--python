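"""Principal component analysis of phyletic vectors with unit-variance
scaling, plus convex hulls bounding groups in score space.

Items are phages, variables are protein families. Each variable is centered
and divided by its population standard deviation (ddof 0); constant
(ubiquitous or universally absent) families carry no signal and are dropped
rather than erroring. The eigenvector sign is fixed deterministically so
scores are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import PhyleticMatrix

__all__ = ["PCAResult", "pca", "variance_explained", "convex_hull"]


@dataclass
class PCAResult:
    item_ids: list[str]
    variable_ids: list[str]
    scores: np.ndarray  # items x components
    loadings: np.ndarray  # variables x components (orthonormal columns)
    explained_fraction: np.ndarray  # per component, sums to 1 over all
    dropped_variables: list[str] = field(default_factory=list)


def pca(m: PhyleticMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of phages (items) over family presence/absence (variables).

    Variables are scaled to unit variance, so the decomposition is of the
    correlation structure. ``explained_fraction`` is each eigenvalue over the
    total variance of the kept variables; summed over all components it is 1.
    """
    x = m.values.T.astype(float)  # phages x families
    n_items, _ = x.shape
    if n_items < 2:
        raise ValueError("need at least two items")
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [f for f, k in zip(m.family_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all variables are constant; nothing to decompose")
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    # SVD of the scaled data; eigenvalues of the correlation matrix = s^2 / n
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = s**2 / n_items
    total = eig.sum()
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    ncomp = vt.shape[0] if n_components is None else min(n_components, vt.shape[0])
    return PCAResult(
        item_ids=list(m.phage_ids),
        variable_ids=[f for f, k in zip(m.family_ids, keep) if k],
        scores=scores[:, :ncomp],
        loadings=vt.T[:, :ncomp],
        explained_fraction=eig / total,
        dropped_variables=dropped,
    )


def variance_explained(r: PCAResult, n: int) -> float:
    """Summed explained-variance fraction of the first n components."""
    if not (0 <= n <= r.explained_fraction.size):
        raise ValueError(f"n must be in [0, {r.explained_fraction.size}]")
    return float(r.explained_fraction[:n].sum())


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> np.ndarray:
    """Convex hull of 2-D points by the monotone chain, counter-clockwise,
    excluding collinear interior points.

    Degenerate inputs follow natural conventions: one point (or all
    identical) gives that point; collinear points give the two endpoints.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    uniq = sorted({(float(p[0]), float(p[1])) for p in pts})
    if len(uniq) == 1:
        return np.array(uniq)
    lower: list[tuple[float, float]] = []
    for p in uniq:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[tuple[float, float]] = []
    for p in reversed(uniq):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 2:  # all collinear: keep the two extreme points
        hull = [uniq[0], uniq[-1]]
    return np.array(hull)
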