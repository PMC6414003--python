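"""Lineage tracking, stability, natural-cluster extraction, reporting."""

import numpy as np
import pytest

from ramanspc import (
    DegenerateSpectrumError,
    InputError,
    TreeConfig,
    extract_natural_clusters,
    first_split_index,
    membership_report,
    stability,
    track_clusters,
)
from ramanspc.engine import SweepPoint
from ramanspc.tree import Lineage, natural_leaf_labels, render_tree


def sweep_from_partitions(partitions, t0=0.01, dt=0.01):
    """Hand-built sweep points from explicit member-set partitions."""
    out = []
    for k, part in enumerate(partitions):
        out.append(
            SweepPoint(
                T=t0 + k * dt,
                g=np.empty(0),
                chi=0.0,
                partition=[np.array(sorted(c)) for c in part],
            )
        )
    return out


ABC = [{0, 1, 2}]
AB_C = [{0, 1}, {2}]
A_B_C = [{0}, {1}, {2}]


class TestTrackClusters:
    def test_static_partition_single_lineage_full_lifetime(self):
        sweep = sweep_from_partitions([ABC] * 5)
        lineages = track_clusters(sweep, TreeConfig())
        assert len(lineages) == 1
        assert lineages[0].lifetime == pytest.approx(0.04)

    def test_two_stage_split_lineages_and_parentage(self):
        # hand enumeration with Jaccard 0.8 matching:
        #   {ABC} -> {AB|C}: neither AB (2/3) nor C (1/3) continues ABC
        #   {AB|C} -> {A|B|C}: C continues, A and B are new children of AB
        sweep = sweep_from_partitions([ABC, AB_C, A_B_C])
        lineages = track_clusters(sweep, TreeConfig(gap_tolerance=0))
        by_members = {tuple(sorted(l.members)): l for l in lineages}
        assert len(lineages) == 5
        root = by_members[(0, 1, 2)]
        ab = by_members[(0, 1)]
        c = by_members[(2,)]
        a = by_members[(0,)]
        b = by_members[(1,)]
        assert root.parent is None
        assert ab.parent == root.lineage_id and c.parent == root.lineage_id
        assert a.parent == ab.lineage_id and b.parent == ab.lineage_id
        assert c.lifetime == pytest.approx(0.01)  # alive at steps 1 and 2

    def test_cluster_id_permutation_invariance(self):
        sweep1 = sweep_from_partitions([ABC, AB_C, A_B_C])
        sweep2 = sweep_from_partitions([ABC, AB_C[::-1], A_B_C[::-1]])
        l1 = track_clusters(sweep1, TreeConfig())
        l2 = track_clusters(sweep2, TreeConfig())
        key = lambda ls: sorted(
            (tuple(sorted(l.members)), l.birth_index, l.death_index) for l in ls
        )
        assert key(l1) == key(l2)

    def test_flicker_bridged_by_gap_tolerance(self):
        # split, re-merge for one step, split again: with the grace period
        # the two subcluster lineages persist through the flicker
        sweep = sweep_from_partitions([ABC, AB_C, ABC, AB_C, AB_C])
        lineages = track_clusters(sweep, TreeConfig(gap_tolerance=2))
        ab = [l for l in lineages if l.members == frozenset({0, 1})]
        assert len(ab) == 1
        assert ab[0].lifetime == pytest.approx(0.03)  # steps 1 through 4

    def test_empty_sweep_rejected(self):
        with pytest.raises(InputError):
            track_clusters([], TreeConfig())


class TestStability:
    def _lineage(self, life, lid=0):
        return Lineage(
            lineage_id=lid, members=frozenset({0}), birth_index=0, birth_T=0.0,
            death_index=1, death_T=life,
        )

    def test_root_relative_to_itself_is_one(self):
        root = self._lineage(0.5)
        assert stability(root, root) == 1.0

    def test_half_lifetime_gives_half(self):
        assert stability(self._lineage(0.25), self._lineage(0.5)) == pytest.approx(0.5)

    def test_toy_lifetimes_30_and_45(self):
        assert stability(self._lineage(30.0), self._lineage(45.0)) == pytest.approx(
            2 / 3
        )

    def test_zero_root_lifetime_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            stability(self._lineage(1.0), self._lineage(0.0))


class TestExtraction:
    def test_unsplit_root_is_single_natural_node(self):
        sweep = sweep_from_partitions([ABC] * 4)
        lineages = track_clusters(sweep, TreeConfig())
        tree = extract_natural_clusters(lineages, TreeConfig(), sweep=sweep)
        assert tree.children == []
        assert tree.is_natural
        assert tree.size == 3

    def test_persistent_split_yields_natural_children(self):
        # root splits immediately; both halves persist, then shatter
        half1, half2 = {0, 1, 2}, {3, 4, 5}
        parts = (
            [[half1 | half2]]
            + [[half1, half2]] * 10
            + [[{v} for v in range(6)]] * 3
        )
        sweep = sweep_from_partitions(parts)
        cfg = TreeConfig()
        lineages = track_clusters(sweep, cfg)
        tree = extract_natural_clusters(lineages, cfg, sweep=sweep)
        naturals = tree.natural_clusters()
        assert not tree.is_natural
        assert sorted(sorted(n.members) for n in naturals) == [[0, 1, 2], [3, 4, 5]]
        # hierarchical ids extend the parent's id
        for node in tree.children:
            assert node.hierarchical_id in ("1", "2")

    def test_ephemeral_substructure_is_absorbed(self):
        # the root set persists; a sub-split exists for one step only
        whole = {0, 1, 2, 3}
        parts = [[whole]] * 6 + [[{0, 1}, {2, 3}]] + [[whole]] * 6 + [
            [{v} for v in whole]
        ]
        sweep = sweep_from_partitions(parts)
        cfg = TreeConfig()
        lineages = track_clusters(sweep, cfg)
        tree = extract_natural_clusters(lineages, cfg, sweep=sweep)
        assert tree.is_natural
        assert tree.natural_clusters() == [tree]

    def test_planted_cluster_in_uniform_noise_recovered(self):
        """One tight planted cluster among dispersed noise points."""
        from ramanspc import (
            PottsConfig,
            build_neighbor_graph,
            compute_couplings,
            distance_matrix,
            temperature_sweep,
        )

        rng = np.random.default_rng(12)
        planted = rng.normal(0.0, 0.3, size=(10, 5))
        noise = rng.uniform(-4, 4, size=(8, 5))
        pts = np.vstack([planted, noise])
        dist = distance_matrix(pts.T)
        graph = compute_couplings(build_neighbor_graph(dist, K=4))
        sweep = temperature_sweep(
            graph,
            PottsConfig(t_min=0.001, t_step=0.001, n_sweeps=300, n_burnin=100, seed=3),
        )
        cfg = TreeConfig()
        tree = extract_natural_clusters(track_clusters(sweep, cfg), cfg, sweep=sweep)
        naturals = [n for n in tree.natural_clusters() if n.size >= 2]
        assert len(naturals) == 1
        overlap = len(naturals[0].members & set(range(10)))
        assert overlap >= 0.9 * 10

    def test_cosmic_spike_outliers_stay_out_of_natural_clusters(self):
        """Spectra carrying smoothing-resistant cosmic-ray residue become
        residual singletons rather than polluting the natural clusters."""
        from conftest import run_clustering

        run = run_clustering(seed=1, spikes=True)
        spiked = [
            i for i, s in enumerate(run["processed"]) if s.intensities.max() > 2.0
        ]
        assert spiked  # this cohort does contain spike outliers
        members_of_naturals = set()
        for node in run["tree"].natural_clusters():
            members_of_naturals |= node.members
        assert not (set(spiked) & members_of_naturals)

    def test_natural_clusters_are_disjoint(self, bench_run):
        naturals = bench_run["tree"].natural_clusters()
        seen = set()
        for n in naturals:
            assert not (n.members & seen)
            seen |= n.members

    def test_hierarchical_ids_follow_parentage(self, bench_run):
        def visit(node):
            for i, child in enumerate(node.children):
                if node.hierarchical_id == "0":
                    assert child.hierarchical_id == str(i + 1)
                else:
                    assert child.hierarchical_id.startswith(node.hierarchical_id + " ")
                visit(child)

        visit(bench_run["tree"])


class TestReporting:
    def test_membership_report_columns_and_sizes(self, bench_run):
        labels = [s.class_label for s in bench_run["cohort"]]
        report = membership_report(bench_run["tree"], labels)
        assert {"cluster", "size", "t_ferro", "s_t", "is_natural"} <= set(report.columns)
        root_row = report[report["cluster"] == "0"].iloc[0]
        assert root_row["size"] == 30
        assert root_row[["n_breast", "n_cervical", "n_leukemia"]].sum() == 30

    def test_composition_columns_omitted_without_labels(self, bench_run):
        report = membership_report(bench_run["tree"], None)
        assert not any(c.startswith("n_") for c in report.columns)

    def test_render_tree_marks_naturals(self, bench_run):
        text = render_tree(bench_run["tree"])
        assert "*natural*" in text
        assert "[0] size=30" in text

    def test_natural_leaf_labels_cover_all_points(self, bench_run):
        labels = natural_leaf_labels(bench_run["tree"], 30)
        assert labels.shape == (30,)
        # every point labeled; residuals get unique negative ids
        assert len(set(labels.tolist())) >= len(
            bench_run["tree"].natural_clusters()
        )


def test_first_split_index():
    sweep = sweep_from_partitions([ABC, ABC, AB_C, A_B_C])
    assert first_split_index(sweep) == 2
    assert first_split_index(sweep_from_partitions([ABC])) is None
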