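"""Isonymy matrices, log-distance transform, and the weighted Ward taxonomy.

The pairwise isonymy between areas i and j is the Lasker-style statistic

    eta_ij = sum_s n_si * n_sj / (2 * n_i * n_j)

where n_si is the number of bearers of surname s in area i and n_i the area's
total surname bearers.  eta is bounded by 0.5 (Cauchy–Schwarz on the count
vectors), attained exactly when both areas carry a single, identical surname.
Distances are the negative logarithm of eta; zero entries (no shared surname)
are floored before the log so distances stay finite.

The taxonomy is agglomerative Ward clustering on that distance matrix via the
Lance–Williams recurrence, with cluster sizes replaced by summed population
weights.  Two dialects are exposed: ``"D"`` applies the recurrence to the
distances as given; ``"D2"`` applies it to squared distances and reports square
roots (the convention scipy's unweighted Ward uses).  Merge ties break on the
smallest (i, j) index pair, so the tree is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .types import Partition, SurnameCounts, ValidationError

__all__ = [
    "IsonymyMatrix",
    "DistanceMatrix",
    "Taxonomy",
    "compute_isonymy",
    "isonymy_to_distance",
    "ward_taxonomy",
    "cut",
]


@dataclass
class IsonymyMatrix:
    """Symmetric matrix of pairwise isonymy eta_ij with area totals n_i."""

    values: np.ndarray
    ids: list[str]
    totals: np.ndarray  # n_i, same order as ids

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("isonymy matrix must be square")
        if not np.allclose(v, v.T):
            raise ValidationError("isonymy matrix must be symmetric")
        if (v < 0).any() or (v > 0.5 + 1e-12).any():
            raise ValidationError("isonymy entries must lie in [0, 0.5]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with an exactly-zero diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.isfinite(v).all():
            raise ValidationError("distance matrix must be finite")
        if (v < 0).any():
            raise ValidationError("distances must be non-negative")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v


def compute_isonymy(counts: SurnameCounts) -> IsonymyMatrix:
    """Pairwise isonymy over all areas present in ``counts``.

    Computed by sparse accumulation over shared surnames only: with C the
    (area x surname) count matrix, the numerator matrix is C @ C.T.
    """
    df = counts.df
    area_ids = sorted(df["area_id"].unique())
    surnames = {s: i for i, s in enumerate(df["surname"].unique())}
    aidx = {a: i for i, a in enumerate(area_ids)}
    C = sparse.coo_matrix(
        (
            df["count"].to_numpy(dtype=float),
            (df["area_id"].map(aidx).to_numpy(), df["surname"].map(surnames).to_numpy()),
        ),
        shape=(len(area_ids), len(surnames)),
    ).tocsr()
    totals = np.asarray(C.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = [a for a, t in zip(area_ids, totals) if t <= 0]
        raise ValidationError(f"area(s) with zero surname total: {bad[:5]}")
    num = (C @ C.T).toarray()
    eta = num / (2.0 * np.outer(totals, totals))
    return IsonymyMatrix(eta, area_ids, totals)


def isonymy_to_distance(m: IsonymyMatrix, zero_policy: str = "floor") -> DistanceMatrix:
    """d_ij = -log(eta_ij), with zeros replaced before the log.

    ``zero_policy="floor"`` (default) substitutes half the smallest positive
    off-diagonal eta for exact zeros, keeping distances finite while preserving
    the ordering of all positive entries.
    """
    eta = m.values.copy()
    off = ~np.eye(len(m.ids), dtype=bool)
    if zero_policy == "floor":
        pos = eta[off & (eta > 0)]
        if pos.size == 0:
            raise ValidationError("all off-diagonal isonymy values are zero; no floor available")
        eta[off & (eta == 0)] = pos.min() / 2.0
    elif zero_policy == "error":
        if (eta[off] == 0).any():
            raise ValidationError("zero isonymy encountered under zero_policy='error'")
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    with np.errstate(divide="ignore"):
        d = -np.log(eta)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(m.ids))


@dataclass
class Taxonomy:
    """A weighted agglomerative merge tree over N leaves.

    ``merges`` is an (N-1, 3)-like list of (left, right, height); node indices
    follow the scipy convention (leaves 0..N-1, the i-th merge creates node
    N+i).  ``leaf_ids`` and ``leaf_weights`` are in leaf-index order.
    """

    merges: list[tuple[int, int, float]]
    leaf_ids: list[str]
    leaf_weights: np.ndarray
    _cut_cache: dict[int, Partition] = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_linkage(self) -> np.ndarray:
        """4-column scipy-style linkage matrix (left, right, height, n_leaves)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            Z[i] = [a, b, h, sizes[n + i]]
        return Z

    def cut(self, k: int) -> Partition:
        return cut(self, k)

    def to_newick(self) -> str:
        n = self.n_leaves
        if n == 1:
            return f"{self.leaf_ids[0]};"
        node_h = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            la = max(h - node_h[a], 0.0)
            lb = max(h - node_h[b], 0.0)
            rep[n + i] = f"({rep[a]}:{la:g},{rep[b]}:{lb:g})"
            node_h[n + i] = h
        return rep[n + len(self.merges) - 1] + ";"

    def to_dict(self) -> dict:
        return {
            "merges": [[int(a), int(b), float(h)] for a, b, h in self.merges],
            "leaf_ids": list(self.leaf_ids),
            "leaf_weights": [float(w) for w in self.leaf_weights],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Taxonomy":
        return cls(
            [(int(a), int(b), float(h)) for a, b, h in d["merges"]],
            [str(i) for i in d["leaf_ids"]],
            np.asarray(d["leaf_weights"], dtype=float),
        )


def ward_taxonomy(
    d: DistanceMatrix,
    weights: np.ndarray | list[float] | None = None,
    dialect: str = "D",
) -> Taxonomy:
    """Weighted Ward agglomeration of a precomputed distance matrix.

    Lance–Williams update for Ward's criterion with cluster masses w:

        d(k, i+j)^p = ((w_i + w_k) d(ki)^p + (w_j + w_k) d(kj)^p
                       - w_k d(ij)^p) / (w_i + w_j + w_k)

    with p = 1 for dialect ``"D"`` (recurrence on the distances as given) and
    p = 2 for dialect ``"D2"`` (recurrence on squares, heights reported on the
    original scale).  Leaf masses are the population weights (all 1 when
    ``weights`` is None).
    """
    n = len(d.ids)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValidationError("weights length must match the distance matrix")
    if (w <= 0).any():
        raise ValidationError("population weights must be positive")
    if dialect not in {"D", "D2"}:
        raise ValueError(f"unknown ward dialect {dialect!r}")

    if n == 1:
        return Taxonomy([], list(d.ids), w)

    D = d.values.astype(float).copy()
    if dialect == "D2":
        D = D**2
    np.fill_diagonal(D, np.inf)

    active: dict[int, float] = {i: w[i] for i in range(n)}  # node -> mass
    pos = {i: i for i in range(n)}  # node -> row in D
    rows = list(range(n))  # row -> node
    merges: list[tuple[int, int, float]] = []
    next_node = n
    for _ in range(n - 1):
        # smallest distance among active pairs, ties by smallest (node_i, node_j)
        nodes = sorted(active)
        best = None
        for ii, a in enumerate(nodes):
            ra = pos[a]
            for b in nodes[ii + 1 :]:
                val = D[ra, pos[b]]
                if best is None or val < best[0] - 1e-15:
                    best = (val, a, b)
        dist, a, b = best
        height = float(np.sqrt(dist)) if dialect == "D2" else float(dist)
        merges.append((a, b, height))
        wa, wb = active[a], active[b]
        ra, rb = pos[a], pos[b]
        # Lance-Williams update into row ra, which becomes the new node's row
        for c in active:
            if c in (a, b):
                continue
            rc, wc = pos[c], active[c]
            new = ((wa + wc) * D[ra, rc] + (wb + wc) * D[rb, rc] - wc * dist) / (wa + wb + wc)
            D[ra, rc] = D[rc, ra] = new
        D[rb, :] = np.inf
        D[:, rb] = np.inf
        del active[a], active[b], pos[a], pos[b]
        active[next_node] = wa + wb
        pos[next_node] = ra
        next_node += 1
    return Taxonomy(merges, list(d.ids), w)


def cut(t: Taxonomy, k: int) -> Partition:
    """Cut the taxonomy into exactly ``k`` groups (labels "g1".."gk").

    Applying the first N-k merges in order yields the k-group partition; with
    monotone merge heights this equals cutting the dendrogram at height.  For
    k' > k the cut refines the k-group cut by construction.
    """
    n = t.n_leaves
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range [1, {n}]")
    if k in t._cut_cache:
        return t._cut_cache[k]
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _h) in enumerate(t.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, str] = {}
    labels = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = f"g{len(roots) + 1}"
        labels[t.leaf_ids[leaf]] = roots[r]
    p = Partition(labels)
    t._cut_cache[k] = p
    return p
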