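"""Iterative hierarchy-constrained regionalisation maximising Regional Integrity.

Starting from the most disaggregate acceptable (l, k) combination, the
algorithm walks coarser partitions of the isonymy taxonomy (first the
agreement-grid peaks in decreasing-k order, then consecutive cuts) and at each
step proposes to merge the current regions that share a parent at the coarser
cut.  A proposed merger is accepted when the merged region's Regional Integrity
exceeds that of every one of its sub-regions; otherwise the best sub-region is
kept and the remaining sub-regions are merged (a no-op when only one remains).
Mergers never span different parent regions of the taxonomy, and the genetic
granularity l stays fixed at the starting combination throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correspondence import Contingency, CorrespondenceGrid, contingency
from .integrity import integrity_table
from .isonymy import Taxonomy, cut
from .linkage import LinkedSample
from .types import Partition, SampleTable, ValidationError

__all__ = [
    "RegionalisationResult",
    "select_start",
    "merge_candidates",
    "evaluate_merger",
    "optimal_regionalisation",
]


@dataclass
class RegionalisationResult:
    final_partition: Partition  # over areas
    final_integrity: pd.DataFrame
    iteration_log: list[dict] = field(default_factory=list)
    start_combination: tuple[int, int] = (0, 0)  # (l, k)
    ari_threshold: float = 0.0

    @property
    def n_regions(self) -> int:
        return self.final_partition.k


def select_start(
    peaks: list[tuple[int, int, float]],
    ari_threshold: float,
) -> tuple[int, int]:
    """The most disaggregate (largest-k) peak whose agreement meets the threshold."""
    if not peaks:
        raise ValidationError("no peaks found in the correspondence grid")
    ok = [(l, k, r) for (l, k, r) in peaks if r >= ari_threshold]
    if not ok:
        best = max(p[2] for p in peaks)
        raise ValidationError(
            f"no peak reaches ari_threshold={ari_threshold}; best peak agreement is "
            f"{best:.3f} — consider a lower threshold"
        )
    l, k, _ = max(ok, key=lambda p: p[1])
    return l, k


def merge_candidates(
    current: Partition,
    taxonomy: Taxonomy,
    next_k: int,
) -> list[list[str]]:
    """Groups of current regions sharing one parent at the coarser cut.

    Each proposal lists >= 2 current region labels whose areas fall under the
    same group of ``cut(taxonomy, next_k)``; regions under different parents
    are never proposed together.  A region already spanning several parents at
    this level (possible after an empty-region automerge) is left alone.
    """
    parent_labels = cut(taxonomy, next_k).labels
    region_parents: dict[str, set[str]] = {}
    for area, region in current.labels.items():
        region_parents.setdefault(region, set()).add(parent_labels[area])
    by_parent: dict[str, list[str]] = {}
    for region in sorted(region_parents):
        parents = region_parents[region]
        if len(parents) == 1:
            by_parent.setdefault(next(iter(parents)), []).append(region)
    return [regions for _, regions in sorted(by_parent.items()) if len(regions) >= 2]


def _individual_partition(
    current: Partition,
    linked: LinkedSample,
    start_k: int,
    start_groups: Partition,
) -> Partition:
    """Map linked individuals into current regions via their start-level group."""
    group_to_region: dict[str, str] = {}
    for area, group in start_groups.labels.items():
        group_to_region[group] = current.labels[area]
    return Partition(
        {
            iid: group_to_region[g]
            for iid, g in zip(linked.individual_id, linked.group_at_k[start_k])
        }
    )


def _integrity_of(
    current: Partition,
    linked: LinkedSample,
    sample: SampleTable,
    l: int,
    start_k: int,
    start_groups: Partition,
) -> pd.DataFrame:
    ind_regions = _individual_partition(current, linked, start_k, start_groups)
    pos = {iid: i for i, iid in enumerate(sample.individual_id)}
    clusters = sample.cluster_at_level[l]
    p_cluster = Partition({iid: clusters[pos[iid]] for iid in linked.individual_id})
    # regions with no linked individuals are absent from the table
    return integrity_table(contingency(ind_regions, p_cluster))


def _merged_label(regions: list[str]) -> str:
    return "+".join(sorted(regions))


def _apply_merge(current: Partition, regions: list[str]) -> Partition:
    new = _merged_label(regions)
    rset = set(regions)
    return Partition({a: (new if r in rset else r) for a, r in current.labels.items()})


def evaluate_merger(
    proposal: list[str],
    current: Partition,
    linked: LinkedSample,
    sample: SampleTable,
    l: int,
    start_k: int,
    start_groups: Partition,
    current_integrity: pd.DataFrame,
) -> dict:
    """Decide one merger proposal.

    Returns a record with ``action`` in {"accepted-full", "keep-best-merge-rest",
    "rejected"}, the tentative partition for accepted actions, and the RI values
    the decision was based on.  Sub-regions with no sample observations always
    merge (flagged), as does any merger when the sample carries a single
    genetic cluster at level l: homogeneity is then vacuous everywhere and the
    coarsest description is the only one not overfitted.
    """
    pos = {iid: i for i, iid in enumerate(sample.individual_id)}
    cluster_labels = {sample.cluster_at_level[l][pos[iid]] for iid in linked.individual_id}
    sub_ri = {}
    missing = []
    for r in proposal:
        if r in current_integrity.index:
            sub_ri[r] = float(current_integrity.loc[r, "RI"])
        else:
            missing.append(r)
    tentative = _apply_merge(current, proposal)
    merged = _merged_label(proposal)
    tent_int = _integrity_of(tentative, linked, sample, l, start_k, start_groups)
    merged_ri = float(tent_int.loc[merged, "RI"]) if merged in tent_int.index else float("nan")
    record = {
        "proposal": sorted(proposal),
        "merged_ri": merged_ri,
        "sub_ri": sub_ri,
        "empty_subs": missing,
    }
    if missing and len(sub_ri) <= 1:
        # only empty sub-regions to absorb: always merge
        record.update(action="accepted-full", partition=tentative)
        return record
    if len(cluster_labels) == 1:
        record.update(action="accepted-full", partition=tentative,
                      degenerate_single_cluster=True)
        return record
    if sub_ri and merged_ri > max(sub_ri.values()):
        record.update(action="accepted-full", partition=tentative)
        return record
    best = min((r for r in sub_ri if sub_ri[r] == max(sub_ri.values())))
    rest = [r for r in proposal if r != best]
    if len(rest) >= 2:
        record.update(action="keep-best-merge-rest", kept=best,
                      partition=_apply_merge(current, rest))
    else:
        record.update(action="rejected", kept=best)
    return record


def _build_schedule(peaks: list[tuple[int, int, float]], k_start: int) -> list[int]:
    """Descending sequence of coarser cut levels to visit.

    Every taxonomy cut below the start is visited in decreasing-k order, so the
    agreement-grid peak levels are reached in decreasing order as part of the
    descent; the intermediate dendrogram levels between peaks keep individual
    merge steps small (one parent at a time) instead of collapsing several
    hierarchy levels in a single proposal.
    """
    return list(range(k_start - 1, 0, -1))


def optimal_regionalisation(
    taxonomy: Taxonomy,
    sample: SampleTable,
    linked: LinkedSample,
    grid: CorrespondenceGrid | None,
    peaks: list[tuple[int, int, float]],
    ari_threshold: float = 0.15,
    seed: int | None = None,
    start: tuple[int, int] | None = None,
) -> RegionalisationResult:
    """Run the full iterative merging loop.

    ``start`` overrides the (l, k) chosen from the peak list.  The loop visits
    the remaining peak ks in decreasing order and then consecutive taxonomy
    cuts down to k=2, so it performs at most k_start - 1 outer iterations; it
    stops as soon as an iteration leaves the partition unchanged (no further
    improvements occur) or a single region remains.  Deterministic given its
    inputs (the ``seed`` argument is accepted for interface symmetry; no
    randomness is consumed here).
    """
    l, k_start = start if start is not None else select_start(peaks, ari_threshold)
    if k_start not in linked.group_at_k:
        raise ValidationError(f"linkage missing at starting k={k_start}")
    if l not in sample.cluster_at_level:
        raise ValidationError(f"sample has no cluster assignment at level {l}")
    start_groups = cut(taxonomy, k_start)
    current = Partition(dict(start_groups.labels))
    log: list[dict] = []

    # regions with no linked individuals auto-merge to their taxonomy-nearest sibling
    current = _absorb_empty_regions(current, taxonomy, linked, sample, l, k_start, start_groups, log)

    for step, next_k in enumerate(_build_schedule(peaks, k_start)):
        if current.k <= 1:
            break
        current_int = _integrity_of(current, linked, sample, l, k_start, start_groups)
        changed = False
        for proposal in merge_candidates(current, taxonomy, next_k):
            record = evaluate_merger(
                proposal, current, linked, sample, l, k_start, start_groups, current_int
            )
            record.update(step=step, next_k=next_k)
            if "partition" in record:
                current = record.pop("partition")
                current_int = _integrity_of(current, linked, sample, l, k_start, start_groups)
                changed = True
            log.append(record)
        if not changed:
            # no further improvements at this level: the aggregation has converged
            break

    final_int = _integrity_of(current, linked, sample, l, k_start, start_groups)
    return RegionalisationResult(
        final_partition=current,
        final_integrity=final_int,
        iteration_log=log,
        start_combination=(l, k_start),
        ari_threshold=ari_threshold,
    )


def _absorb_empty_regions(
    current: Partition,
    taxonomy: Taxonomy,
    linked: LinkedSample,
    sample: SampleTable,
    l: int,
    start_k: int,
    start_groups: Partition,
    log: list[dict],
) -> Partition:
    while True:
        it = _integrity_of(current, linked, sample, l, start_k, start_groups)
        observed = set(it.index)
        empty = sorted(set(current.labels.values()) - observed)
        if not empty or current.k <= 1:
            return current
        region = empty[0]
        # walk coarser cuts until this region gains a sibling under one parent
        for k in range(start_k - 1, 0, -1):
            parents = cut(taxonomy, k).labels
            areas = [a for a, r in current.labels.items() if r == region]
            parent = parents[areas[0]]
            siblings = sorted(
                {r for a, r in current.labels.items() if parents[a] == parent and r != region}
            )
            if siblings:
                # absorb into the sibling with most observations (ties by label)
                weights = {
                    s: int(it.loc[s, "n_k"]) if s in it.index else 0 for s in siblings
                }
                target = max(sorted(weights), key=lambda s: weights[s])
                current = _apply_merge(current, [region, target])
                log.append(
                    {
                        "action": "empty-region-automerge",
                        "proposal": [region, target],
                        "step": -1,
                        "next_k": k,
                    }
                )
                break
        else:
            return current
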