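"""End-to-end orchestration: simulate / load -> filter -> group -> isonymy ->
taxonomy -> link -> correspondence -> integrity -> regionalisation.

A :class:`RunConfig` captures every knob; `run_all` executes the stages into an
artifact directory with a JSON metadata sidecar, and identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as iomod
from .correspondence import correspondence_grid, find_peaks
from .isonymy import compute_isonymy, isonymy_to_distance, ward_taxonomy
from .linkage import link_sample
from .prepare import filter_register, group_small_areas
from .regionalise import optimal_regionalisation
from .synthetic import GeneratorParams, generate_world
from .types import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CONFIG_SCHEMA", "validate_config", "run_all"]

CONFIG_SCHEMA: dict = {
    "seed": "int >= 0",
    "min_pop": "int >= 0 (minimum grouped-area population; 750 emulates the register rule)",
    "rural_only": "bool",
    "origin_whitelist": "list[str] | null",
    "ward_dialect": "one of {'D', 'D2'}",
    "zero_policy": "one of {'floor', 'error'}",
    "l_range": "[lo, hi] with 2 <= lo <= hi",
    "k_range": "[lo, hi] with 2 <= lo <= hi",
    "ari_threshold": "float in [-1, 1]",
    "dom_expectation": "one of {'uniform', 'margins'} (only 'uniform' used by the pipeline)",
    "inflation_factor": "float > 0 (KDE bandwidth inflation)",
    "require_four": "bool (drop individuals with < 4 located grandparents)",
    "simulate": "dict of GeneratorParams overrides | null (when input paths are absent)",
    "areas_path": "str | null",
    "counts_path": "str | null",
    "sample_path": "str | null",
}


@dataclass
class RunConfig:
    seed: int = 0
    min_pop: int = 750
    rural_only: bool = True
    origin_whitelist: list[str] | None = None
    ward_dialect: str = "D"
    zero_policy: str = "floor"
    l_range: tuple[int, int] = (2, 5)
    k_range: tuple[int, int] = (2, 10)
    ari_threshold: float = 0.15
    dom_expectation: str = "uniform"
    inflation_factor: float = 1.1
    require_four: bool = False
    simulate: dict | None = field(default_factory=dict)
    areas_path: str | None = None
    counts_path: str | None = None
    sample_path: str | None = None

    def validate(self) -> list[str]:
        """Return a list of violations (empty = OK)."""
        v: list[str] = []
        if not isinstance(self.seed, int) or self.seed < 0:
            v.append("seed must be a non-negative integer")
        if not isinstance(self.min_pop, int) or self.min_pop < 0:
            v.append("min_pop must be a non-negative integer")
        if self.ward_dialect not in {"D", "D2"}:
            v.append(f"unknown ward_dialect {self.ward_dialect!r}")
        if self.zero_policy not in {"floor", "error"}:
            v.append(f"unknown zero_policy {self.zero_policy!r}")
        if self.dom_expectation not in {"uniform", "margins"}:
            v.append(f"unknown dom_expectation {self.dom_expectation!r}")
        for name in ("l_range", "k_range"):
            r = getattr(self, name)
            if len(r) != 2 or r[0] > r[1] or r[0] < 2:
                v.append(f"{name} must be [lo, hi] with 2 <= lo <= hi")
        if not (-1.0 <= self.ari_threshold <= 1.0):
            v.append("ari_threshold must lie in [-1, 1]")
        if self.inflation_factor <= 0:
            v.append("inflation_factor must be positive")
        have_files = self.areas_path and self.counts_path and self.sample_path
        if not have_files and self.simulate is None:
            v.append("either input paths or a 'simulate' block must be provided")
        return v

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.l_range = tuple(cfg.l_range)
        cfg.k_range = tuple(cfg.k_range)
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def validate_config(path: str | Path) -> list[str]:
    """Violation report for a JSON config file (empty list = OK)."""
    try:
        cfg = RunConfig.from_json(path)
    except (ValidationError, TypeError, json.JSONDecodeError) as exc:
        return [str(exc)]
    return cfg.validate()


def _stage(name: str, timings: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None:
                raise ValidationError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the directory."""
    violations = config.validate()
    if violations:
        raise ValidationError("invalid config: " + "; ".join(violations))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    with _stage("inputs", timings):
        if config.areas_path and config.counts_path and config.sample_path:
            areas = iomod.read_area_table(config.areas_path)
            counts = iomod.read_surname_counts(config.counts_path, areas=areas)
            sample = iomod.read_sample_table(config.sample_path)
            truth = None
        else:
            params = GeneratorParams(**(config.simulate or {}))
            areas, counts, sample, truth = generate_world(params, config.seed)
            iomod.write_area_table(areas, out / "areas.csv")
            iomod.write_surname_counts(counts, out / "counts.csv")
            iomod.write_sample_table(sample, out / "sample.csv")
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth.to_dict(), fh, indent=2, default=str)

    with _stage("filter", timings):
        areas, counts = filter_register(
            areas, counts, rural_only=config.rural_only,
            origin_whitelist=set(config.origin_whitelist) if config.origin_whitelist else None,
        )

    with _stage("group", timings):
        areas, counts = group_small_areas(areas, counts, min_pop=config.min_pop)
        iomod.write_area_table(areas, out / "grouped_areas.csv")

    with _stage("isonymy", timings):
        eta = compute_isonymy(counts)
        eta.to_frame().to_csv(out / "eta.csv")
        dist = isonymy_to_distance(eta, zero_policy=config.zero_policy)

    with _stage("cluster", timings):
        order = {a: i for i, a in enumerate(areas.area_ids)}
        weights = areas.df["population"].to_numpy(dtype=float)[
            [order[a] for a in dist.ids]
        ]
        taxonomy = ward_taxonomy(dist, weights, dialect=config.ward_dialect)
        with open(out / "taxonomy.json", "w", encoding="utf-8") as fh:
            json.dump(taxonomy.to_dict(), fh)

    k_lo, k_hi = config.k_range
    k_hi = min(k_hi, taxonomy.n_leaves)
    ks = list(range(k_lo, k_hi + 1))
    with _stage("link", timings):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
        linked = link_sample(sample, areas, taxonomy, ks, seed=rng,
                             require_four=config.require_four)
        linked.to_frame().to_csv(out / "linked.csv", index=False)

    l_lo, l_hi = config.l_range
    ls = [l for l in range(l_lo, l_hi + 1) if l in sample.cluster_at_level]
    with _stage("correspond", timings):
        grid = correspondence_grid(linked, sample, ls, ks)
        grid.values.to_csv(out / "grid.csv")
        peaks = find_peaks(grid)
        with open(out / "peaks.csv", "w", encoding="utf-8") as fh:
            fh.write("l,k,r_adj\n")
            for l, k, r in peaks:
                fh.write(f"{l},{k},{r}\n")

    with _stage("regionalise", timings):
        result = optimal_regionalisation(
            taxonomy, sample, linked, grid, peaks,
            ari_threshold=config.ari_threshold, seed=config.seed,
        )
        iomod.write_partition(result.final_partition, out / "final_partition.csv")
        result.final_integrity.to_csv(out / "integrity.csv", index_label="region")
        with open(out / "log.jsonl", "w", encoding="utf-8") as fh:
            for rec in result.iteration_log:
                fh.write(json.dumps(rec, default=str) + "\n")

    meta_config = config.to_dict()
    meta_config["stage_timings_s"] = timings
    iomod.write_run_metadata(out / "run_metadata.json", seed=config.seed, config=meta_config)
    return out
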