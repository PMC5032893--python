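"""Readers and writers for the package's tabular formats.

All delimited text is comma-separated UTF-8 with a header row.  Areas may also
be supplied as GeoJSON (Point or Polygon features; polygons contribute their
centroid).  Every writer is paired with a reader such that
``read(write(x)) == x`` for valid inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from shapely.geometry import shape

from .types import AreaTable, Partition, SampleTable, SurnameCounts, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_area_table",
    "write_area_table",
    "read_surname_counts",
    "write_surname_counts",
    "read_sample_table",
    "write_sample_table",
    "read_partition",
    "write_partition",
    "write_table",
    "write_run_metadata",
]


def read_area_table(path: str | Path, format: str | None = None) -> AreaTable:
    """Read an :class:`AreaTable` from CSV or GeoJSON.

    ``format`` is inferred from the suffix when not given (``.geojson``/``.json``
    vs delimited text).  Polygon features are reduced to their centroid.
    Missing ``rural``/``origin_class`` columns default to ``True``/missing with
    a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv"
    if format == "geojson":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj.get("features", []):
            props = dict(feat.get("properties") or {})
            geom = shape(feat["geometry"])
            c = geom.centroid
            props.setdefault("x", c.x)
            props.setdefault("y", c.y)
            rows.append(props)
        df = pd.DataFrame(rows)
    elif format == "csv":
        df = pd.read_csv(path, dtype={"area_id": str})
    else:
        raise ValueError(f"unknown area-table format {format!r}")
    for col, default in (("rural", True), ("origin_class", pd.NA)):
        if col not in df.columns:
            logger.warning("column %r missing from %s; defaulting to %r", col, path, default)
            df[col] = default
    try:
        return AreaTable(df)
    except (ValueError, TypeError) as exc:  # name the offending file
        raise ValidationError(f"{path}: {exc}") from exc


def write_area_table(areas: AreaTable, path: str | Path) -> None:
    areas.df.to_csv(path, index=False)


def read_surname_counts(path: str | Path, areas: AreaTable | None = None) -> SurnameCounts:
    path = Path(path)
    df = pd.read_csv(path, dtype={"area_id": str, "surname": str})
    try:
        return SurnameCounts(df, areas=areas)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_surname_counts(counts: SurnameCounts, path: str | Path) -> None:
    counts.df.to_csv(path, index=False)


def _sample_to_frame(sample: SampleTable) -> pd.DataFrame:
    rows: dict[str, list] = {"individual_id": sample.individual_id}
    for g in range(4):
        rows[f"gp{g + 1}_x"] = [pts[g][0] if len(pts) > g else None for pts in sample.grandparent_points]
        rows[f"gp{g + 1}_y"] = [pts[g][1] if len(pts) > g else None for pts in sample.grandparent_points]
    for level in sample.levels:
        rows[f"cluster_l{level}"] = sample.cluster_at_level[level]
    return pd.DataFrame(rows)


def write_sample_table(sample: SampleTable, path: str | Path) -> None:
    _sample_to_frame(sample).to_csv(path, index=False)


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, dtype={"individual_id": str})
    points = []
    for _, row in df.iterrows():
        pts = []
        for g in range(4):
            x, y = row.get(f"gp{g + 1}_x"), row.get(f"gp{g + 1}_y")
            if pd.notna(x) and pd.notna(y):
                pts.append((float(x), float(y)))
        points.append(pts)
    clusters = {}
    for col in df.columns:
        if col.startswith("cluster_l"):
            level = int(col[len("cluster_l"):])
            clusters[level] = df[col].tolist()
    return SampleTable(df["individual_id"].tolist(), points, clusters)


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, dtype={"unit_id": str})
    return Partition.from_frame(df)


def write_partition(p: Partition, path: str | Path) -> None:
    """Write a partition as a two-column CSV (labels quoted as needed)."""
    p.to_frame().to_csv(path, index=False)


def write_table(t, path: str | Path) -> None:
    """Write any of the package's table containers (or a bare DataFrame) to CSV."""
    if isinstance(t, AreaTable):
        write_area_table(t, path)
    elif isinstance(t, SurnameCounts):
        write_surname_counts(t, path)
    elif isinstance(t, SampleTable):
        write_sample_table(t, path)
    elif isinstance(t, Partition):
        write_partition(t, path)
    elif isinstance(t, pd.DataFrame):
        t.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot write object of type {type(t).__name__}")


def write_run_metadata(path: str | Path, *, seed: int | None, config: dict) -> None:
    """JSON sidecar recording the seed, resolved configuration and versions."""
    import hashlib
    import numpy
    import scipy

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "isoregion": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)
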