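"""Register preparation: attribute filters and minimum-population grouping.

The register emulates a historical census surname table.  Two filters restrict
it to the long-settled rural population: a rural flag (areas at least 2 km from
large towns, pre-encoded as an attribute — the geometric rule is not re-derived
here) and an optional whitelist of surname-origin classes.  Small areas are then
grouped so every unit carries at least ``min_pop`` people, merging the smallest
deficient unit with its nearest Euclidean neighbour until the threshold holds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AreaTable, SurnameCounts, ValidationError

__all__ = ["filter_register", "group_small_areas"]


def filter_register(
    areas: AreaTable,
    counts: SurnameCounts,
    rural_only: bool = True,
    origin_whitelist: set[str] | None = None,
) -> tuple[AreaTable, SurnameCounts]:
    """Restrict the register by the rural flag and/or surname-origin class.

    Raises
    ------
    ValidationError
        If the filters remove every area or every surname record.
    """
    adf = areas.df
    if rural_only:
        adf = adf[adf["rural"]]
    if origin_whitelist is not None:
        adf = adf[adf["origin_class"].isin(set(origin_whitelist))]
    if adf.empty:
        raise ValidationError("filters removed all records")
    kept = set(adf["area_id"])
    cdf = counts.df[counts.df["area_id"].isin(kept)]
    if cdf.empty:
        raise ValidationError("filters removed all records")
    out_areas = AreaTable(adf.reset_index(drop=True))
    return out_areas, SurnameCounts(cdf.reset_index(drop=True), areas=out_areas)


def group_small_areas(
    areas: AreaTable,
    counts: SurnameCounts,
    min_pop: int = 750,
) -> tuple[AreaTable, SurnameCounts]:
    """Merge areas until every group's population is at least ``min_pop``.

    Policy: repeatedly take the lowest-population group below the threshold and
    merge it with its nearest group by Euclidean distance between (population-
    weighted centroid) coordinates, ties broken by lexicographic area id.  Total
    population and total surname counts are conserved exactly.  If the global
    total is below the threshold a single group results.  Output areas carry a
    ``group_id`` and aggregated attributes; surname counts are summed within
    groups.
    """
    df = areas.df
    # state per current group
    groups: dict[str, dict] = {
        row["area_id"]: {
            "members": [row["area_id"]],
            "population": int(row["population"]),
            "x": float(row["x"]),
            "y": float(row["y"]),
        }
        for _, row in df.iterrows()
    }

    def weighted_centroid(a: dict, b: dict) -> tuple[float, float]:
        wa, wb = a["population"], b["population"]
        if wa + wb == 0:
            return (a["x"] + b["x"]) / 2, (a["y"] + b["y"]) / 2
        return (
            (a["x"] * wa + b["x"] * wb) / (wa + wb),
            (a["y"] * wa + b["y"] * wb) / (wa + wb),
        )

    while len(groups) > 1:
        deficient = [(g["population"], gid) for gid, g in groups.items() if g["population"] < min_pop]
        if not deficient:
            break
        _, gid = min(deficient)  # lowest population, ties by id
        g = groups[gid]
        best = None
        for oid, o in groups.items():
            if oid == gid:
                continue
            d = float(np.hypot(g["x"] - o["x"], g["y"] - o["y"]))
            key = (d, oid)
            if best is None or key < best[0]:
                best = (key, oid)
        oid = best[1]
        o = groups.pop(oid)
        x, y = weighted_centroid(g, o)
        g["members"] = sorted(g["members"] + o["members"])
        g["population"] += o["population"]
        g["x"], g["y"] = x, y
        # keep the lexicographically smallest member id as the group key
        new_id = g["members"][0]
        del groups[gid]
        groups[new_id] = g

    member_to_group = {m: gid for gid, g in groups.items() for m in g["members"]}
    rural = dict(zip(df["area_id"], df["rural"]))
    name = dict(zip(df["area_id"], df["name"]))
    origin = dict(zip(df["area_id"], df["origin_class"]))
    rows = []
    for gid in sorted(groups):
        g = groups[gid]
        rows.append(
            {
                "area_id": gid,
                "name": name[gid] if len(g["members"]) == 1 else "+".join(g["members"]),
                "x": g["x"],
                "y": g["y"],
                "population": g["population"],
                "rural": all(rural[m] for m in g["members"]),
                "origin_class": origin[gid],
                "group_id": gid,
            }
        )
    out_areas = AreaTable(pd.DataFrame(rows))
    cdf = counts.df.copy()
    cdf["area_id"] = cdf["area_id"].map(member_to_group)
    cdf = cdf.groupby(["area_id", "surname"], as_index=False)["count"].sum()
    return out_areas, SurnameCounts(cdf, areas=out_areas)
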