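"""Global partition agreement: contingency tables, the Adjusted Rand Index,
the (l, k) correspondence grid, and peak detection.

The Adjusted Rand Index chance-corrects the raw pair-counting Rand agreement
between two partitions of the same units:

    R_adj = (R - E[R]) / (max(R) - E[R])

computed here in the Hubert–Arabie contingency-table form.  +1 means identical
partitions (up to relabelling), 0 the expectation under random partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import LinkedSample
from .types import Partition, SampleTable, ValidationError

__all__ = [
    "Contingency",
    "CorrespondenceGrid",
    "contingency",
    "adjusted_rand",
    "correspondence_grid",
    "find_peaks",
]


@dataclass
class Contingency:
    """Cross-tabulation n_kl of region (row) x cluster (column) with margins."""

    table: pd.DataFrame  # integer counts; index = region labels, columns = cluster labels

    def __post_init__(self) -> None:
        t = self.table
        arr = t.to_numpy()
        if (arr < 0).any():
            raise ValidationError("contingency entries must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("contingency entries must be integers")
        self.table = t.astype(int)

    @property
    def n(self) -> int:
        return int(self.table.to_numpy().sum())

    @property
    def row_margins(self) -> pd.Series:
        """n_k: observations per region."""
        return self.table.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        """n_l: observations per cluster."""
        return self.table.sum(axis=0)


def contingency(p1: Partition, p2: Partition) -> Contingency:
    """n_kl over the shared unit set; errors if the unit sets differ."""
    u1, u2 = set(p1.labels), set(p2.labels)
    if u1 != u2:
        raise ValidationError("partitions are over different unit sets")
    units = sorted(u1)
    df = pd.crosstab(
        pd.Series([p1.labels[u] for u in units], name="region"),
        pd.Series([p2.labels[u] for u in units], name="cluster"),
    )
    return Contingency(df)


def adjusted_rand(c: Contingency) -> float:
    """Hubert–Arabie Adjusted Rand Index from a contingency table."""
    n = c.n
    if n < 2:
        raise ValidationError("adjusted Rand requires at least 2 observations")
    m = c.table.to_numpy(dtype=np.int64)

    def comb2(x: np.ndarray) -> np.ndarray:
        return x * (x - 1) // 2

    sum_cells = int(comb2(m).sum())
    a = int(comb2(m.sum(axis=1)).sum())
    b = int(comb2(m.sum(axis=0)).sum())
    total = int(comb2(np.array([n]))[0])
    expected = a * b / total
    maximum = (a + b) / 2.0
    if maximum == expected:
        # degenerate (e.g. both partitions trivial): identical by construction
        return 1.0
    return float((sum_cells - expected) / (maximum - expected))


@dataclass
class CorrespondenceGrid:
    """R_adj for every (l genetic clusters, k isonymy groups) combination."""

    values: pd.DataFrame  # index = l, columns = k

    @property
    def l_range(self) -> list[int]:
        return [int(x) for x in self.values.index]

    @property
    def k_range(self) -> list[int]:
        return [int(x) for x in self.values.columns]

    def at(self, l: int, k: int) -> float:
        return float(self.values.loc[l, k])

    def best_l_profile(self) -> pd.DataFrame:
        """Per k: the best-agreeing l and its R_adj."""
        best_l = self.values.idxmax(axis=0)
        return pd.DataFrame(
            {"k": self.k_range, "l": [int(best_l[k]) for k in self.k_range],
             "r_adj": [float(self.values[k].max()) for k in self.k_range]}
        )


def correspondence_grid(
    linked: LinkedSample,
    sample: SampleTable,
    l_range: list[int],
    k_range: list[int],
) -> CorrespondenceGrid:
    """Adjusted Rand between cluster-at-l and isonymy-group-at-k partitions
    of the linked individuals, for every (l, k) combination."""
    for l in l_range:
        if l not in sample.cluster_at_level:
            raise ValidationError(f"sample has no cluster assignment at level {l}")
    for k in k_range:
        if k not in linked.group_at_k:
            raise ValidationError(f"linkage missing at k={k}")
    # restrict cluster labels to the linked individuals (some may be dropped)
    pos = {iid: i for i, iid in enumerate(sample.individual_id)}
    grid = np.zeros((len(l_range), len(k_range)))
    for i, l in enumerate(l_range):
        labels_l = sample.cluster_at_level[l]
        p_l = Partition({iid: labels_l[pos[iid]] for iid in linked.individual_id})
        for j, k in enumerate(k_range):
            p_k = linked.partition_at_k(k)
            grid[i, j] = adjusted_rand(contingency(p_k, p_l))
    return CorrespondenceGrid(pd.DataFrame(grid, index=l_range, columns=k_range))


def find_peaks(grid: CorrespondenceGrid, min_prominence: float = 0.0) -> list[tuple[int, int, float]]:
    """Local peaks of the per-k best-l agreement profile.

    For each k take the best l; a peak is a k (or the smallest k of a plateau
    run) whose profile value strictly exceeds both neighbouring runs (boundary
    ks compare against their single neighbour) by at least ``min_prominence``.
    Returned as (l, k, R_adj) sorted by descending R_adj.
    """
    prof = grid.best_l_profile()
    ks = prof["k"].tolist()
    vals = prof["r_adj"].tolist()
    # runs of equal value
    runs: list[tuple[int, int]] = []  # (start_idx, end_idx) inclusive
    s = 0
    for i in range(1, len(vals) + 1):
        if i == len(vals) or vals[i] != vals[s]:
            runs.append((s, i - 1))
            s = i
    peaks = []
    for r, (a, b) in enumerate(runs):
        v = vals[a]
        left_ok = r == 0 or v > vals[runs[r - 1][1]] + min_prominence
        right_ok = r == len(runs) - 1 or v > vals[runs[r + 1][0]] + min_prominence
        if left_ok and right_ok:
            k = ks[a]  # smallest k of the plateau
            l = int(prof.loc[prof["k"] == k, "l"].iloc[0])
            peaks.append((l, k, v))
    peaks.sort(key=lambda t: (-t[2], t[1]))
    return peaks
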