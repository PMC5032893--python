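"""Stage-3 iterative merging: start selection, proposals, decisions, recovery."""

import numpy as np
import pandas as pd
import pytest

import isoregion as ir
from isoregion.isonymy import Taxonomy
from isoregion.regionalise import _build_schedule, _integrity_of
from isoregion.types import ValidationError


class TestSelectStart:
    PEAKS = [(3, 3, 0.6), (15, 20, 0.16)]

    def test_most_disaggregate_above_threshold(self):
        assert ir.select_start(self.PEAKS, 0.15) == (15, 20)

    def test_higher_threshold_falls_back_to_coarse_peak(self):
        assert ir.select_start(self.PEAKS, 0.5) == (3, 3)

    def test_no_peak_meets_threshold_errors(self):
        with pytest.raises(ValidationError, match="lower threshold"):
            ir.select_start(self.PEAKS, 0.7)

    def test_empty_peaks_errors(self):
        with pytest.raises(ValidationError, match="no peaks"):
            ir.select_start([], 0.1)


def chain_taxonomy(n):
    """Leaves a0..a{n-1} merging left to right with increasing heights."""
    merges = []
    node = 0
    for i in range(1, n):
        merges.append((node, i, float(i)))
        node = n + i - 1
    return Taxonomy(merges, [f"a{i}" for i in range(n)], np.ones(n))


def balanced_taxonomy():
    """4 leaves: (a0,a1) and (a2,a3) then the two pairs."""
    return Taxonomy([(0, 1, 1.0), (2, 3, 1.0), (4, 5, 2.0)],
                    ["a0", "a1", "a2", "a3"], np.ones(4))


class TestMergeCandidates:
    def test_nested_cut_four_to_two(self):
        tax = balanced_taxonomy()
        current = tax.cut(4)
        props = ir.merge_candidates(current, tax, 2)
        merged_sets = sorted(sorted(current.labels[a] for a in ("a0", "a1")) for _ in [0])
        assert len(props) == 2
        flat = sorted(map(sorted, props))
        left = sorted({current.labels["a0"], current.labels["a1"]})
        right = sorted({current.labels["a2"], current.labels["a3"]})
        assert flat == sorted([left, right])

    def test_parent_with_single_region_not_proposed(self):
        tax = balanced_taxonomy()
        # merge a0,a1 by hand: at next_k=2 only the right pair remains mergeable
        current = ir.Partition({"a0": "left", "a1": "left", "a2": "r1", "a3": "r2"})
        props = ir.merge_candidates(current, tax, 2)
        assert props == [["r1", "r2"]]

    def test_three_siblings_one_proposal(self):
        """Three current regions under one parent yield a single 3-way proposal."""
        tax = chain_taxonomy(4)
        current = tax.cut(4)
        props = ir.merge_candidates(current, tax, 2)
        # chain cut(2): {a0,a1,a2} | {a3}
        sizes = sorted(len(p) for p in props)
        assert sizes == [3]


def two_region_setup(ri_by_group):
    """A hand-built world: areas a0..a3 as 4 starting groups, individuals whose
    cluster labels induce the given per-group integrity ordering."""
    tax = balanced_taxonomy()
    areas = ir.AreaTable(pd.DataFrame({
        "area_id": ["a0", "a1", "a2", "a3"],
        "x": [0.0, 1.0, 10.0, 11.0], "y": [0.0] * 4,
        "population": [100] * 4,
    }))
    return tax, areas


class TestEvaluateMerger:
    def _context(self, group_clusters, n_per_group=40):
        """Synthesize linked individuals: group g's individuals carry the
        cluster mix given by group_clusters[g] (list of labels, cycled)."""
        tax = balanced_taxonomy()
        start_k = 4
        start_groups = tax.cut(4)
        area_of_group = {g: a for a, g in start_groups.labels.items()}
        ids, gps, clusters, groups = [], [], [], []
        for g, mix in group_clusters.items():
            for i in range(n_per_group):
                ids.append(f"{g}_{i}")
                gps.append([(0.0, 0.0)])
                clusters.append(mix[i % len(mix)])
                groups.append(g)
        sample = ir.SampleTable(ids, gps, {4: clusters})
        linked = ir.LinkedSample(ids, np.zeros((len(ids), 2)),
                                 [[area_of_group[g]] for g in groups],
                                 group_at_k={4: groups},
                                 tie_at_k={4: np.zeros(len(ids), bool)})
        current = ir.Partition(dict(start_groups.labels))
        integ = _integrity_of(current, linked, sample, 4, 4, start_groups)
        return tax, sample, linked, current, start_groups, integ

    def test_improving_merger_accepted(self):
        # two halves of one homogeneous population merge: RI improves
        g = {f"g{i}": ["c1"] if i <= 2 else ["c2"] for i in range(1, 5)}
        tax, sample, linked, current, sg, integ = self._context(g)
        siblings = sorted({current.labels["a0"], current.labels["a1"]})
        rec = ir.evaluate_merger(siblings, current, linked, sample, 4, 4, sg, integ)
        assert rec["action"] == "accepted-full"
        assert rec["merged_ri"] > max(rec["sub_ri"].values())

    def test_two_sub_rejection_is_noop(self):
        # merging two internally pure but different populations hurts
        g = {"g1": ["c1"], "g2": ["c2"], "g3": ["c3"], "g4": ["c4"]}
        tax, sample, linked, current, sg, integ = self._context(g)
        siblings = sorted({current.labels["a0"], current.labels["a1"]})
        rec = ir.evaluate_merger(siblings, current, linked, sample, 4, 4, sg, integ)
        assert rec["action"] == "rejected"
        assert "partition" not in rec

    def test_keep_best_merge_rest_on_three_subs(self):
        tax = chain_taxonomy(3)
        start_groups = tax.cut(3)
        area_of_group = {g: a for a, g in start_groups.labels.items()}
        ids, gps, clusters, groups = [], [], [], []
        mixes = {  # one pure group, two noisy ones sharing clusters
            "b1": ["c1"] * 8,
            "b2": ["c2", "c3", "c1", "c2"],
            "b3": ["c3", "c2", "c2", "c1"],
        }
        group_names = dict(zip(sorted({g for g in start_groups.labels.values()}),
                               ["b1", "b2", "b3"]))
        inv = {v: k for k, v in group_names.items()}
        for b, mix in mixes.items():
            g = inv[b]
            for i in range(40):
                ids.append(f"{b}_{i}")
                gps.append([(0.0, 0.0)])
                clusters.append(mix[i % len(mix)])
                groups.append(g)
        sample = ir.SampleTable(ids, gps, {4: clusters})
        linked = ir.LinkedSample(ids, np.zeros((len(ids), 2)),
                                 [[area_of_group[g]] for g in groups],
                                 group_at_k={3: groups},
                                 tie_at_k={3: np.zeros(len(ids), bool)})
        current = ir.Partition(dict(start_groups.labels))
        integ = _integrity_of(current, linked, sample, 4, 3, start_groups)
        proposal = sorted(set(groups))
        rec = ir.evaluate_merger(proposal, current, linked, sample, 4, 3,
                                 start_groups, integ)
        assert rec["action"] == "keep-best-merge-rest"
        assert rec["kept"] == max(rec["sub_ri"], key=lambda r: rec["sub_ri"][r])
        merged_label = "+".join(sorted(r for r in proposal if r != rec["kept"]))
        assert merged_label in set(rec["partition"].labels.values())


class TestSchedule:
    def test_consecutive_descent(self):
        assert _build_schedule([(3, 3, 0.5), (5, 7, 0.2)], 10) == list(range(9, 0, -1))

    def test_bounded_by_start(self):
        assert len(_build_schedule([], 6)) <= 5


class TestOptimalRegionalisation:
    @pytest.fixture(scope="class")
    def recovered(self):
        params = ir.GeneratorParams(n_individuals=2000, cluster_noise=0.02)
        areas, counts, sample, truth = ir.generate_world(params, 1)
        eta = ir.compute_isonymy(counts)
        dist = ir.isonymy_to_distance(eta)
        w = areas.df.set_index("area_id")["population"]
        tax = ir.ward_taxonomy(dist, w[dist.ids].to_numpy(float))
        linked = ir.link_sample(sample, areas, tax, list(range(2, 11)), seed=1)
        grid = ir.correspondence_grid(linked, sample, [2, 3, 4, 5],
                                      list(range(2, 11)))
        peaks = ir.find_peaks(grid)
        res = ir.optimal_regionalisation(tax, sample, linked, grid, peaks,
                                         start=(5, 10))
        return res, truth, tax

    def test_recovers_planted_regions(self, recovered):
        """eps = 0.02, R = 5, start k = 10: the merge loop lands exactly on
        the planted regions."""
        res, truth, _ = recovered
        tp = ir.truth_partition(truth, 5)
        ari = ir.adjusted_rand(ir.contingency(res.final_partition, tp))
        assert ari == pytest.approx(1.0)

    def test_final_regions_are_unions_of_start_groups(self, recovered):
        res, _, tax = recovered
        start = ir.cut(tax, res.start_combination[1])
        group_to_region = {}
        for a, g in start.labels.items():
            r = res.final_partition.labels[a]
            assert group_to_region.setdefault(g, r) == r

    def test_log_replays_to_same_decisions(self, recovered):
        """Each accepted merger in the log strictly improved RI over every
        observed sub-region."""
        res, _, _ = recovered
        for rec in res.iteration_log:
            if rec["action"] == "accepted-full" and rec["sub_ri"] and not rec["empty_subs"]:
                assert rec["merged_ri"] > max(rec["sub_ri"].values())

    def test_termination_bound(self, recovered):
        res, _, _ = recovered
        steps = {rec["step"] for rec in res.iteration_log if rec["step"] >= 0}
        assert len(steps) <= res.start_combination[1] - 1

    def test_all_maximal_start_is_identity(self):
        """When every proposed merger lowers RI the starting partition
        survives unchanged."""
        tax = balanced_taxonomy()
        start_groups = tax.cut(4)
        area_of_group = {g: a for a, g in start_groups.labels.items()}
        ids, gps, clusters, groups = [], [], [], []
        for gi, g in enumerate(sorted(area_of_group)):
            for i in range(30):
                ids.append(f"{g}_{i}")
                gps.append([(0.0, 0.0)])
                clusters.append(f"c{gi}")  # each group its own pure cluster
                groups.append(g)
        sample = ir.SampleTable(ids, gps, {4: clusters})
        linked = ir.LinkedSample(ids, np.zeros((len(ids), 2)),
                                 [[area_of_group[g]] for g in groups],
                                 group_at_k={4: groups},
                                 tie_at_k={4: np.zeros(len(ids), bool)})
        res = ir.optimal_regionalisation(tax, sample, linked, None, [],
                                         start=(4, 4))
        assert res.final_partition.labels == start_groups.labels

    def test_single_cluster_sample_collapses(self):
        """A degenerate one-cluster sample merges all the way to one region."""
        tax = balanced_taxonomy()
        start_groups = tax.cut(4)
        area_of_group = {g: a for a, g in start_groups.labels.items()}
        ids, gps, clusters, groups = [], [], [], []
        for g in sorted(area_of_group):
            for i in range(30):
                ids.append(f"{g}_{i}")
                gps.append([(0.0, 0.0)])
                clusters.append("only")
                groups.append(g)
        sample = ir.SampleTable(ids, gps, {2: clusters})
        linked = ir.LinkedSample(ids, np.zeros((len(ids), 2)),
                                 [[area_of_group[g]] for g in groups],
                                 group_at_k={4: groups},
                                 tie_at_k={4: np.zeros(len(ids), bool)})
        res = ir.optimal_regionalisation(tax, sample, linked, None, [],
                                         start=(2, 4))
        assert res.final_partition.k == 1

    def test_empty_region_automerges_with_flag(self):
        tax = balanced_taxonomy()
        start_groups = tax.cut(4)
        area_of_group = {g: a for a, g in start_groups.labels.items()}
        groups_order = sorted(area_of_group)
        ids, gps, clusters, groups = [], [], [], []
        for g in groups_order[:3]:  # last group gets no individuals
            for i in range(30):
                ids.append(f"{g}_{i}")
                gps.append([(0.0, 0.0)])
                clusters.append(f"c_{g}")
                groups.append(g)
        sample = ir.SampleTable(ids, gps, {3: clusters})
        linked = ir.LinkedSample(ids, np.zeros((len(ids), 2)),
                                 [[area_of_group[g]] for g in groups],
                                 group_at_k={4: groups},
                                 tie_at_k={4: np.zeros(len(ids), bool)})
        res = ir.optimal_regionalisation(tax, sample, linked, None, [],
                                         start=(3, 4))
        automerges = [r for r in res.iteration_log
                      if r["action"] == "empty-region-automerge"]
        assert len(automerges) == 1
        assert groups_order[3] in automerges[0]["proposal"]
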