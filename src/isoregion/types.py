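"""Core domain containers.

All tabular containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that downstream code can use ordinary pandas/numpy idioms while the wrapper
enforces the structural invariants (key uniqueness, non-negative populations,
finite planar coordinates, label-count bounds) once, at construction time.

Coordinates throughout the package are planar projected metres (British National
Grid style); all distances are Euclidean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AreaTable",
    "SurnameCounts",
    "SampleTable",
    "Partition",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container's structural invariants are violated."""


AREA_COLUMNS = ["area_id", "name", "x", "y", "population", "rural", "origin_class", "group_id"]


@dataclass
class AreaTable:
    """Areas (parishes or parish groups) with coordinates and register attributes.

    Parameters
    ----------
    df:
        One row per area with columns ``area_id`` (unique string key), ``name``,
        ``x``/``y`` (planar projected metres), ``population`` (non-negative int),
        ``rural`` (bool), ``origin_class`` (optional categorical, may be NA) and
        ``group_id`` (set after small-area grouping, else NA).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "area_id" not in df.columns:
            raise ValidationError("AreaTable requires an 'area_id' column")
        df["area_id"] = df["area_id"].astype(str)
        for col, default in (("name", ""), ("rural", True), ("origin_class", None), ("group_id", None)):
            if col not in df.columns:
                df[col] = default
        df["name"] = df["name"].fillna("").astype(str)
        for col in ("origin_class", "group_id"):
            df[col] = df[col].astype(object).where(pd.notna(df[col]), None)
        for col in ("x", "y"):
            if col not in df.columns:
                raise ValidationError(f"AreaTable requires a '{col}' coordinate column")
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            bad = df.loc[~np.isfinite(df[col]), "area_id"]
            if len(bad):
                raise ValidationError(f"non-finite coordinate '{col}' for area(s) {list(bad[:5])}")
        if "population" not in df.columns:
            raise ValidationError("AreaTable requires a 'population' column")
        df["population"] = pd.to_numeric(df["population"], errors="raise").astype(int)
        if (df["population"] < 0).any():
            raise ValidationError("population must be >= 0")
        if df["area_id"].duplicated().any():
            dupes = df.loc[df["area_id"].duplicated(), "area_id"].unique()
            raise ValidationError(f"duplicate area_id(s): {list(dupes[:5])}")
        df["rural"] = df["rural"].astype(bool)
        self.df = df[AREA_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def area_ids(self) -> list[str]:
        return self.df["area_id"].tolist()

    def coords(self) -> np.ndarray:
        """(N, 2) array of area coordinates, in area_id order of the table."""
        return self.df[["x", "y"]].to_numpy(dtype=float)


@dataclass
class SurnameCounts:
    """Long-format (area_id, surname, count) register table.

    Counts are positive integers and (area_id, surname) pairs are unique.  When
    an :class:`AreaTable` is supplied every ``area_id`` must exist in it.
    """

    df: pd.DataFrame
    areas: AreaTable | None = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"area_id", "surname", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"SurnameCounts missing column(s): {sorted(missing)}")
        df["area_id"] = df["area_id"].astype(str)
        df["surname"] = df["surname"].astype(str)
        df["count"] = pd.to_numeric(df["count"], errors="raise").astype(int)
        if (df["count"] < 1).any():
            bad = df.loc[df["count"] < 1].iloc[0]
            raise ValidationError(
                f"non-positive count {bad['count']} for ({bad['area_id']}, {bad['surname']})"
            )
        dup = df.duplicated(subset=["area_id", "surname"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValidationError(f"duplicate (area_id, surname) pair ({bad['area_id']}, {bad['surname']})")
        if self.areas is not None:
            known = set(self.areas.area_ids)
            unknown = set(df["area_id"]) - known
            if unknown:
                raise ValidationError(f"unknown area_id(s) in surname counts: {sorted(unknown)[:5]}")
        self.df = df[["area_id", "surname", "count"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def area_totals(self) -> pd.Series:
        """n_i: total surname bearers per area."""
        return self.df.groupby("area_id")["count"].sum()


@dataclass
class SampleTable:
    """Sampled individuals with grandparent birth locations and per-level cluster labels.

    ``grandparent_points`` holds 0–4 (x, y) tuples per individual;
    ``cluster_at_level`` maps a granularity level ``l`` (int >= 2, with level 1
    the degenerate single-cluster case) to a label per individual.  Cluster
    assignments at different levels are *not* assumed nested.
    """

    individual_id: list[str]
    grandparent_points: list[list[tuple[float, float]]]
    cluster_at_level: dict[int, list]

    def __post_init__(self) -> None:
        n = len(self.individual_id)
        self.individual_id = [str(i) for i in self.individual_id]
        if len(set(self.individual_id)) != n:
            raise ValidationError("duplicate individual_id")
        if len(self.grandparent_points) != n:
            raise ValidationError("grandparent_points length mismatch")
        for iid, pts in zip(self.individual_id, self.grandparent_points):
            if len(pts) > 4:
                raise ValidationError(f"individual {iid} has more than 4 grandparent points")
            for x, y in pts:
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise ValidationError(f"non-finite grandparent coordinate for {iid}")
        for level, labels in self.cluster_at_level.items():
            if len(labels) != n:
                raise ValidationError(f"cluster labels at level {level} have wrong length")
            k = len(set(labels))
            if k > max(int(level), 1):
                raise ValidationError(
                    f"level {level} has {k} distinct labels (> {level})"
                )

    def __len__(self) -> int:
        return len(self.individual_id)

    @property
    def levels(self) -> list[int]:
        return sorted(self.cluster_at_level)

    def partition_at_level(self, level: int) -> "Partition":
        if level not in self.cluster_at_level:
            raise KeyError(f"no cluster assignment at level {level}")
        return Partition(dict(zip(self.individual_id, self.cluster_at_level[level])))


@dataclass
class Partition:
    """A labelling of a fixed unit set; ``k`` is the number of distinct labels."""

    labels: dict[str, object]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("empty partition")
        self.labels = {str(u): lab for u, lab in self.labels.items()}

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    @property
    def units(self) -> list[str]:
        return list(self.labels)

    def labels_for(self, units: Iterable[str]) -> list:
        return [self.labels[str(u)] for u in units]

    def relabel(self, mapping: Mapping) -> "Partition":
        return Partition({u: mapping[lab] for u, lab in self.labels.items()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": list(self.labels), "label": list(self.labels.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Partition":
        return cls(dict(zip(df["unit_id"].astype(str), df["label"])))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.labels == other.labels
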