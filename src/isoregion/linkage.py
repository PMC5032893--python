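"""Linking sampled individuals to isonymy groups via grandparent locations.

Each individual carries up to four grandparent birth points.  A grandparent
point is mapped to the nearest area by Euclidean distance between planar
coordinates, and the individual takes the modal isonymy group among its
grandparents' areas at each cut level k; modal ties are resolved by a uniform
seeded draw among the tied groups and flagged.  The ancestral point of an
individual is the centroid of its available grandparent points.

`kde_bandwidth` provides the bandwidth statistic used to visualise the spatial
concentration of a group of points: an inflation factor (default 1.1) times the
95th percentile of nearest-neighbour distances within the group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .isonymy import Taxonomy, cut
from .types import AreaTable, Partition, SampleTable, ValidationError

__all__ = [
    "LinkedSample",
    "ancestral_centroid",
    "assign_isonymy_group",
    "link_sample",
    "tie_rate",
    "kde_bandwidth",
]


@dataclass
class LinkedSample:
    """Per-individual ancestral points and isonymy-group assignments by k."""

    individual_id: list[str]
    ancestral_points: np.ndarray  # (n, 2)
    grandparent_areas: list[list[str]]
    group_at_k: dict[int, list[str]] = field(default_factory=dict)
    tie_at_k: dict[int, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.individual_id)

    @property
    def ks(self) -> list[int]:
        return sorted(self.group_at_k)

    def partition_at_k(self, k: int) -> Partition:
        if k not in self.group_at_k:
            raise KeyError(f"no isonymy-group assignment at k={k}")
        return Partition(dict(zip(self.individual_id, self.group_at_k[k])))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "ancestral_x": self.ancestral_points[:, 0],
                "ancestral_y": self.ancestral_points[:, 1],
            }
        )
        for k in self.ks:
            df[f"group_k{k}"] = self.group_at_k[k]
            df[f"tie_k{k}"] = self.tie_at_k[k]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinkedSample":
        """Rebuild from :meth:`to_frame` output (grandparent areas are not
        serialized and come back empty)."""
        out = cls(
            df["individual_id"].astype(str).tolist(),
            df[["ancestral_x", "ancestral_y"]].to_numpy(dtype=float),
            [[] for _ in range(len(df))],
        )
        for col in df.columns:
            if col.startswith("group_k"):
                k = int(col[len("group_k"):])
                out.group_at_k[k] = df[col].astype(str).tolist()
                out.tie_at_k[k] = df[f"tie_k{k}"].to_numpy(dtype=bool)
        return out


def ancestral_centroid(points: list[tuple[float, float]]) -> tuple[float, float]:
    """Arithmetic mean of the available (1-4) grandparent points."""
    if len(points) == 0:
        raise ValidationError("individual has no located grandparents")
    arr = np.asarray(points, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def assign_isonymy_group(
    grandparent_areas: list[str],
    area_to_group: dict[str, str],
    rng: np.random.Generator,
) -> tuple[str, bool]:
    """Modal isonymy group among an individual's grandparent areas.

    Returns ``(label, tie_flag)``.  When several groups share the maximal
    count the label is drawn uniformly among them with the supplied generator
    and the tie flag is set.
    """
    if not grandparent_areas:
        raise ValidationError("individual has no located grandparents")
    try:
        groups = [area_to_group[a] for a in grandparent_areas]
    except KeyError as exc:
        raise ValidationError(f"grandparent area {exc.args[0]!r} has no isonymy group") from exc
    tally = Counter(groups)
    top = max(tally.values())
    modal = sorted(g for g, c in tally.items() if c == top)
    if len(modal) == 1:
        return modal[0], False
    return modal[int(rng.integers(len(modal)))], True


def link_sample(
    sample: SampleTable,
    areas: AreaTable,
    taxonomy: Taxonomy,
    ks: list[int],
    seed: int | np.random.Generator = 0,
    require_four: bool = False,
) -> LinkedSample:
    """Assign every individual an isonymy group at each cut level in ``ks``.

    Individuals with 1-3 located grandparents are retained by default, the
    modal rule applying to the available points; ``require_four=True`` drops
    them instead.  Identical seeds give bit-identical assignments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep_idx = []
    for i, pts in enumerate(sample.grandparent_points):
        if len(pts) == 0:
            continue
        if require_four and len(pts) < 4:
            continue
        keep_idx.append(i)
    if not keep_idx:
        raise ValidationError("no individuals with located grandparents")

    tree = cKDTree(areas.coords())
    area_ids = areas.area_ids
    ids, centroids, gp_areas = [], [], []
    for i in keep_idx:
        pts = sample.grandparent_points[i]
        ids.append(sample.individual_id[i])
        centroids.append(ancestral_centroid(pts))
        _, nearest = tree.query(np.asarray(pts, dtype=float))
        gp_areas.append([area_ids[j] for j in np.atleast_1d(nearest)])

    linked = LinkedSample(ids, np.asarray(centroids), gp_areas)
    for k in ks:
        mapping = cut(taxonomy, k).labels
        labels, ties = [], []
        for ga in gp_areas:
            lab, tie = assign_isonymy_group(ga, mapping, rng)
            labels.append(lab)
            ties.append(tie)
        linked.group_at_k[k] = labels
        linked.tie_at_k[k] = np.asarray(ties, dtype=bool)
    return linked


def tie_rate(linked: LinkedSample, k: int) -> float:
    """Fraction of individuals whose modal group at k was decided by a tie draw."""
    if k not in linked.tie_at_k:
        raise KeyError(f"no assignment at k={k}")
    return float(np.mean(linked.tie_at_k[k]))


def kde_bandwidth(points: np.ndarray, inflation_factor: float = 1.1) -> float:
    """Bandwidth for visualising one group's spatial concentration.

    ``inflation_factor`` times the 95th percentile of the distribution of
    nearest-neighbour distances among the group's points ("slightly wider" than
    the typical point-to-point spacing).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValidationError("kde_bandwidth requires at least 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    nn = d[:, 1]
    return float(inflation_factor * np.percentile(nn, 95))
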