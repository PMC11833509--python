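"""Tests for SWC handling, stem identification, staging, branches, and group stats."""

import numpy as np
import pytest

from synmatch.morpho import (
    BoxRegion,
    MidlinePlane,
    NeuriteTree,
    PointCloudRegion,
    RegionSet,
    SphereRegion,
    branch_statistics,
    classify_stage,
    compare_groups,
    extract_primary_branches,
    identify_stem_axon,
    locate_entry_and_end,
)


def tree_from(rows):
    """rows: (id, parent, x, y, z, r)"""
    arr = np.array(rows, dtype=float)
    return NeuriteTree(
        ids=arr[:, 0], parents=arr[:, 1], xyz=arr[:, 2:5], radius=arr[:, 5]
    )


def random_tree(rng, n_nodes):
    rows = [(1, -1, 0.0, 0.0, 0.0, rng.uniform(0.2, 1.5))]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        pos = rng.normal(size=3) * 5 + np.array(rows[parent - 1][2:5])
        rows.append((i, parent, *pos, rng.uniform(0.2, 1.5)))
    return tree_from(rows)


class TestSwcRoundTrip:
    def test_read_write_preserves_tree(self, tmp_path):
        t = random_tree(np.random.default_rng(0), 20)
        t.to_swc(tmp_path / "a.swc")
        t2 = NeuriteTree.from_swc(tmp_path / "a.swc")
        assert np.array_equal(t.ids, t2.ids)
        assert np.array_equal(t.parents, t2.parents)
        assert np.allclose(t.xyz, t2.xyz, atol=1e-4)

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            tree_from([(1, -1, 0, 0, 0, 1), (2, -1, 1, 0, 0, 1)])

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            tree_from([(1, -1, 0, 0, 0, 1), (2, 1, 1, 0, 0, 0.0)])


def _stem_oracle(tree):
    """Exhaustive enumeration of root-to-leaf paths by the same criterion,
    implemented independently (recursive DFS, explicit arithmetic)."""
    best = None

    def walk(idx, path):
        nonlocal best
        kids = tree.children(idx)
        if not kids:
            L = 0.0
            w = 0.0
            for a, b in zip(path[:-1], path[1:]):
                seg = np.sqrt(((tree.xyz[b] - tree.xyz[a]) ** 2).sum())
                L += seg
                w += seg * (tree.radius[a] + tree.radius[b]) / 2
            score = w / L if L > 0 else tree.radius[path].mean()
            key = (-score, -L, str(tree.ids[idx]))
            if best is None or key < best[0]:
                best = (key, list(path))
        for c in kids:
            walk(c, path + [c])

    walk(tree.root, [tree.root])
    return best[1]


class TestStemIdentification:
    def test_unbranched_path_is_the_stem(self):
        t = tree_from([(1, -1, 0, 0, 0, 1), (2, 1, 5, 0, 0, 1), (3, 2, 10, 0, 0, 1)])
        assert identify_stem_axon(t) == [0, 1, 2]

    def test_thick_limb_beats_thin_limb(self):
        t = tree_from(
            [
                (1, -1, 0, 0, 0, 1.0),
                (2, 1, 10, 0, 0, 1.0),
                (3, 2, 20, 0, 0, 1.0),   # thick limb
                (4, 2, 10, 10, 0, 0.3),  # thin limb, equal length
            ]
        )
        stem = identify_stem_axon(t)
        assert stem[-1] == t.index_of(3)

    def test_single_node_tree_raises(self):
        t = tree_from([(1, -1, 0, 0, 0, 1)])
        with pytest.raises(ValueError):
            identify_stem_axon(t)

    def test_matches_exhaustive_enumeration_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            t = random_tree(rng, int(rng.integers(2, 51)))
            assert identify_stem_axon(t) == _stem_oracle(t)


class TestEntryEnd:
    def straight_stem(self, n=7, spacing=10.0):
        rows = [(1, -1, 0, 0, 0, 1)]
        for i in range(2, n + 1):
            rows.append((i, i - 1, (i - 1) * spacing, 0, 0, 1))
        return tree_from(rows)

    def test_stem_inside_region_entry_at_root_side(self):
        t = self.straight_stem()
        stem = identify_stem_axon(t)
        regions = RegionSet(
            antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
            pn_region=SphereRegion(np.zeros(3), 1.0),
        )
        ann = locate_entry_and_end(t, stem, regions)
        assert ann.entry_node == stem[0]
        assert ann.end_node == stem[-1]
        assert ann.stem_length == pytest.approx(60.0)

    def test_partial_overlap_arc_length_by_hand(self):
        # nodes at 0,10,...,60; region covers x >= 20: entry at node 3,
        # 4 spacings to the tip -> 40 um
        t = self.straight_stem()
        stem = identify_stem_axon(t)
        regions = RegionSet(
            antennal_lobe=BoxRegion([20 - 1e-9, -1, -1], [1e6, 1, 1]),
            pn_region=SphereRegion(np.zeros(3), 1.0),
        )
        ann = locate_entry_and_end(t, stem, regions)
        assert ann.stem_length == pytest.approx(40.0)

    def test_touch_only_at_tip_gives_zero_length(self):
        t = self.straight_stem()
        stem = identify_stem_axon(t)
        regions = RegionSet(
            antennal_lobe=BoxRegion([60 - 1e-9, -1, -1], [1e6, 1, 1]),
            pn_region=SphereRegion(np.zeros(3), 1.0),
        )
        ann = locate_entry_and_end(t, stem, regions)
        assert ann.entry_node == ann.end_node
        assert ann.stem_length == 0.0

    def test_no_overlap_raises(self):
        t = self.straight_stem()
        stem = identify_stem_axon(t)
        regions = RegionSet(
            antennal_lobe=BoxRegion([100, -1, -1], [200, 1, 1]),
            pn_region=SphereRegion(np.zeros(3), 1.0),
        )
        with pytest.raises(ValueError):
            locate_entry_and_end(t, stem, regions)


class TestStage:
    @pytest.mark.parametrize(
        "length,stage",
        [(0, 1), (99.9, 1), (100.0, 2), (135, 2), (170.0, 2), (170.1, 3), (500, 3)],
    )
    def test_boundaries(self, length, stage):
        assert classify_stage(length) == stage

    def test_sweep_matches_piecewise_oracle(self):
        rng = np.random.default_rng(0)
        for L in rng.uniform(0, 300, 200):
            expect = 1 if L < 100 else (2 if L <= 170 else 3)
            assert classify_stage(L) == expect


def _build_branched_axon():
    """Stem along x at 10 um spacing with two collaterals and one secondary."""
    rows = [
        (1, -1, 0, 0, 0, 1.0),
        (2, 1, 10, 0, 0, 1.0),
        (3, 2, 20, 0, 0, 1.0),
        (4, 3, 30, 0, 0, 1.0),
        (5, 4, 40, 0, 0, 1.0),
        # collateral at node 3 (x=20, mid of entry(0)->end(40))
        (6, 3, 20, 8, 0, 0.3),
        (7, 6, 20, 16, 0, 0.3),
        # second collateral at node 4, multifurcated
        (8, 4, 30, -8, 0, 0.3),
        (9, 8, 30, -16, 0, 0.3),
        (10, 8, 36, -10, 0, 0.2),
    ]
    return tree_from(rows)


class TestBranches:
    def regions(self, pn_points=((20.0, 16.0, 0.0),), eps=2.0):
        return RegionSet(
            antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
            pn_region=PointCloudRegion(np.array(pn_points), eps=eps),
        )

    def annotate(self, t, regions):
        stem = identify_stem_axon(t)
        return locate_entry_and_end(t, stem, regions)

    def test_no_collaterals_empty(self):
        t = tree_from([(1, -1, 0, 0, 0, 1), (2, 1, 10, 0, 0, 1)])
        ann = self.annotate(t, self.regions())
        assert extract_primary_branches(t, ann, self.regions()) == []

    def test_midpoint_branch_position_half(self):
        t = _build_branched_axon()
        regions = self.regions()
        ann = self.annotate(t, regions)
        recs = extract_primary_branches(t, ann, regions)
        assert len(recs) == 2
        assert recs[0].normalized_position == pytest.approx(0.5)
        assert recs[1].normalized_position == pytest.approx(0.75)

    def test_contact_and_multifurcation_flags(self):
        t = _build_branched_axon()
        regions = self.regions()
        ann = self.annotate(t, regions)
        recs = extract_primary_branches(t, ann, regions)
        assert recs[0].contacts_pn is True        # node 7 within eps of cloud
        assert recs[0].multifurcated is False
        assert recs[1].contacts_pn is False
        assert recs[1].multifurcated is True      # node 8 splits into 9 and 10
        assert recs[1].n_secondary == 1

    def test_flags_match_exhaustive_subtree_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            t = random_tree(rng, 30)
            cloud = rng.normal(scale=10, size=(5, 3))
            regions = RegionSet(
                antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
                pn_region=PointCloudRegion(cloud, eps=2.0),
            )
            stem = identify_stem_axon(t)
            ann = locate_entry_and_end(t, stem, regions)
            recs = extract_primary_branches(t, ann, regions)
            stem_set = set(stem)
            for rec in recs:
                sub = t.subtree_indices(rec.branch_root_node)
                # brute-force contact: explicit per-node distance scan
                contact = False
                for k in sub:
                    for c in cloud:
                        if np.sqrt(((t.xyz[k] - c) ** 2).sum()) <= 2.0:
                            contact = True
                assert rec.contacts_pn == contact
                # brute-force multifurcation: any subtree node with >= 2
                # children inside the subtree
                subset = set(sub)
                multi = any(
                    len([c for c in t.children(k) if c in subset]) >= 2 for k in sub
                )
                assert rec.multifurcated == multi

    def test_contact_invariant_under_rigid_transform(self):
        rng = np.random.default_rng(3)
        t = random_tree(rng, 25)
        cloud = rng.normal(scale=8, size=(4, 3))
        regions = RegionSet(
            antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
            pn_region=PointCloudRegion(cloud, eps=3.0),
        )
        stem = identify_stem_axon(t)
        ann = locate_entry_and_end(t, stem, regions)
        recs = extract_primary_branches(t, ann, regions)

        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([5.0, -3.0, 2.0])
        t2 = NeuriteTree(t.ids, t.parents, t.xyz @ R.T + shift, t.radius)
        regions2 = RegionSet(
            antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
            pn_region=PointCloudRegion(cloud @ R.T + shift, eps=3.0),
        )
        ann2 = locate_entry_and_end(t2, identify_stem_axon(t2), regions2)
        recs2 = extract_primary_branches(t2, ann2, regions2)
        assert [r.contacts_pn for r in recs] == [r.contacts_pn for r in recs2]

    def test_midline_side_assignment(self):
        t = _build_branched_axon()
        regions = RegionSet(
            antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
            pn_region=PointCloudRegion(np.array([[20.0, 16, 0]]), eps=2.0),
            midline=MidlinePlane(point=np.array([25.0, 0, 0]), normal=np.array([1.0, 0, 0])),
        )
        ann = self.annotate(t, regions)
        recs = extract_primary_branches(t, ann, regions)
        # entry at x=0 (negative side); branch at x=20 same side, x=30 across
        assert recs[0].side == "ipsilateral"
        assert recs[1].side == "contralateral"


class TestBranchStatistics:
    def test_density_arithmetic(self):
        t = _build_branched_axon()
        regions = RegionSet(
            antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
            pn_region=PointCloudRegion(np.array([[20.0, 16, 0]]), eps=2.0),
        )
        stem = identify_stem_axon(t)
        ann = locate_entry_and_end(t, stem, regions)
        recs = extract_primary_branches(t, ann, regions)
        s = branch_statistics(recs, ann)
        assert s["branch_density"] == pytest.approx(2 / 40.0)
        assert s["total_branches"] == 2
        assert s["contacting_fraction"] == pytest.approx(0.5)
        assert s["position_histogram"].sum() == 2

    def test_zero_branches_fractions_nan(self):
        t = tree_from([(1, -1, 0, 0, 0, 1), (2, 1, 10, 0, 0, 1)])
        regions = RegionSet(
            antennal_lobe=BoxRegion([-1e6] * 3, [1e6] * 3),
            pn_region=SphereRegion(np.zeros(3), 1.0),
        )
        ann = locate_entry_and_end(t, identify_stem_axon(t), regions)
        s = branch_statistics([], ann)
        assert s["branch_density"] == 0.0
        assert np.isnan(s["contacting_fraction"])

    def test_histogram_matches_brute_force_binning(self):
        rng = np.random.default_rng(6)
        positions = rng.uniform(0, 1, 40)
        from synmatch.morpho import BranchRecord, StemAnnotation

        recs = [
            BranchRecord(branch_point_node=0, branch_root_node=0, normalized_position=u)
            for u in positions
        ]
        ann = StemAnnotation(stem_path=[0, 1], entry_node=0, end_node=1, stem_length=100.0)
        s = branch_statistics(recs, ann, bins=10)
        oracle = [0] * 10
        for u in positions:
            oracle[min(9, int(u * 10))] += 1
        assert list(s["position_histogram"]) == oracle


class TestGroupComparisons:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        rep = compare_groups({"a": base, "b": base.copy()}, test="anova_tukey")
        assert rep["pairwise"][("a", "b")]["p_corrected"] > 0.99

    def test_chi2_matches_textbook_2x2_formula(self):
        rep = compare_groups(
            {"g1": (50, 100), "g2": (90, 100)}, test="chi2_bonferroni"
        )
        # hand-evaluated 2x2 chi-squared without continuity correction:
        # chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 50, 50, 90, 10
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert rep["pairwise"][("g1", "g2")]["chi2"] == pytest.approx(expect)

    def test_planted_shift_detected_with_tukey(self):
        rng = np.random.default_rng(1)
        groups = {
            "ctrl": rng.normal(0, 1, 25),
            "same": rng.normal(0, 1, 25),
            "shift": rng.normal(3, 1, 25),
        }
        rep = compare_groups(groups, test="anova_tukey")
        assert rep["pairwise"][("ctrl", "shift")]["p_corrected"] < 0.05
        assert rep["pairwise"][("ctrl", "same")]["p_corrected"] > 0.05
        assert "brown_forsythe_p" in rep and "shapiro" in rep

    def test_kruskal_bonferroni_corrected(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0, 1, 20),
            "c": rng.normal(4, 1, 20),
        }
        rep = compare_groups(groups, test="kruskal_bonferroni")
        assert rep["pairwise"][("a", "c")]["p_corrected"] < 0.05
        pair = rep["pairwise"][("a", "b")]
        assert pair["p_corrected"] == pytest.approx(min(1.0, pair["p"] * 3))

    def test_anova_group_too_small_raises(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]}, test="anova_tukey")
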