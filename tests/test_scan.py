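"""Pair enumeration, patch clustering, adaptive threshold and scan statistics."""

import numpy as np
import pytest

from lrldscan.ld_core import PDTailTable, contingency_table, p_D
from lrldscan.scan import (
    PairScore,
    ScanConfig,
    build_patches,
    choose_threshold,
    eligible_pairs,
    patch_count_trajectory,
    patch_target,
    scan_chromosome,
    score_pairs,
    statistic_pd_max,
)
from lrldscan.synthetic import (
    PlantedAssociation,
    SimConfig,
    feasible_planted_pair,
    plant_association,
    simulate,
)
from conftest import make_panel


def random_pairs(rng, n_pairs, span_cm=50.0):
    """Random PairScore list over synthetic coordinates (index = position)."""
    cm = np.sort(rng.uniform(0, span_cm, size=2 * n_pairs))
    pairs, seen = [], set()
    for _ in range(n_pairs):
        i, j = sorted(rng.choice(len(cm), size=2, replace=False))
        if cm[j] - cm[i] <= 0.25 or (i, j) in seen:
            continue
        seen.add((i, j))
        pairs.append(PairScore(int(i), int(j), float(rng.uniform(0, 1e-3))))
    return cm, pairs


def components_oracle(pairs, r_min, cm):
    """Explicit adjacency graph + networkx connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(pairs)))
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if (
                abs(cm[pairs[a].left] - cm[pairs[b].left]) < r_min
                and abs(cm[pairs[a].right] - cm[pairs[b].right]) < r_min
            ):
                g.add_edge(a, b)
    return sorted(
        sorted(tuple(sorted((pairs[k].left, pairs[k].right))) for k in comp)
        for comp in nx.connected_components(g)
    )


class TestEligiblePairs:
    def test_strict_distance_filter(self):
        cm = [0.0, 0.1, 0.5]
        assert list(eligible_pairs(cm, 0.25)) == [(0, 2), (1, 2)]
        assert list(eligible_pairs([0.0, 0.1, 0.2], 0.25)) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        cm = np.sort(rng.uniform(0, 30, size=200))
        got = set(eligible_pairs(cm, 0.25))
        want = {
            (i, j)
            for i in range(200)
            for j in range(i + 1, 200)
            if cm[j] - cm[i] > 0.25
        }
        assert got == want

    def test_negative_r_min_rejected(self):
        with pytest.raises(ValueError):
            list(eligible_pairs([0.0, 1.0], -0.1))


class TestScorePairs:
    def test_cap_one_returns_all_eligible(self, mosaic_panel):
        pairs = score_pairs(mosaic_panel, r_min=5.0, p_cap=1.0)
        n_elig = sum(1 for _ in eligible_pairs(mosaic_panel.cm, 5.0))
        assert len(pairs) == n_elig

    def test_retained_set_matches_scalar_rescoring(self):
        hm = simulate(SimConfig(n_hap=40, n_snp=30, map_length_cm=20, seed=2))
        pairs = score_pairs(hm, r_min=0.25, p_cap=0.05)
        got = {(p.left, p.right): p.p for p in pairs}
        cm = hm.cm
        want = {}
        for i in range(hm.n_site):
            for j in range(i + 1, hm.n_site):
                if cm[j] - cm[i] > 0.25:
                    pv = p_D(contingency_table(hm, i, j))
                    if pv <= 0.05:
                        want[(i, j)] = pv
        assert set(got) == set(want)
        for k in got:
            assert got[k] == pytest.approx(want[k], rel=1e-9)


class TestBuildPatches:
    def test_single_pair_single_patch(self):
        cm = np.array([10.0, 50.0])
        patches = build_patches([PairScore(0, 1, 1e-6)], 1e-5, 0.25, cm=cm)
        assert len(patches) == 1 and len(patches[0]) == 1

    def test_two_close_pairs_merge(self):
        cm = np.array([10.0, 10.1, 50.0, 50.1])
        pairs = [PairScore(0, 2, 1e-6), PairScore(1, 3, 1e-7)]
        patches = build_patches(pairs, 1e-5, 0.25, cm=cm)
        assert len(patches) == 1 and len(patches[0]) == 2
        assert patches[0].min_p == 1e-7
        assert patches[0].extreme_pair == pairs[1]

    def test_transitive_chain_forms_one_patch(self):
        cm = np.array([10.0, 10.2, 10.4, 50.0, 50.2, 50.4])
        pairs = [PairScore(0, 3, 1e-6), PairScore(1, 4, 1e-6), PairScore(2, 5, 1e-6)]
        # 0~1 and 1~2 mergeable (0.2 < 0.25) but 0~2 not (0.4 >= 0.25)
        patches = build_patches(pairs, 1e-5, 0.25, cm=cm)
        assert len(patches) == 1 and len(patches[0]) == 3

    def test_matches_graph_components_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cm, pairs = random_pairs(rng, 100)
            patches = build_patches(pairs, 1e-3, 0.25, cm=cm)
            got = sorted(
                sorted((m.left, m.right) for m in p.members) for p in patches
            )
            assert got == components_oracle(pairs, 0.25, cm)

    def test_partition_property(self):
        rng = np.random.default_rng(13)
        cm, pairs = random_pairs(rng, 200)
        patches = build_patches(pairs, 1e-3, 0.25, cm=cm)
        seen = [tuple((m.left, m.right)) for p in patches for m in p.members]
        assert len(seen) == len(set(seen)) == len(pairs)

    def test_span_ordering(self):
        rng = np.random.default_rng(17)
        cm, pairs = random_pairs(rng, 150)
        for p in build_patches(pairs, 1e-3, 0.25, cm=cm):
            assert p.left_span_cm[0] <= p.left_span_cm[1]
            assert p.right_span_cm[0] <= p.right_span_cm[1]
            if not p.self_overlapping:
                assert p.left_span_cm[1] < p.right_span_cm[0]


class TestTrajectoryAndThreshold:
    def test_two_pair_trajectories(self):
        cm = np.array([10.0, 30.0, 50.0, 70.0])
        apart = [PairScore(0, 2, 1e-6), PairScore(1, 3, 1e-5)]
        assert [c for _p, c in patch_count_trajectory(apart, 0.25, cm)] == [1, 2]
        cm2 = np.array([10.0, 10.1, 50.0, 50.1])
        close = [PairScore(0, 2, 1e-6), PairScore(1, 3, 1e-5)]
        assert [c for _p, c in patch_count_trajectory(close, 0.25, cm2)] == [1, 1]

    def test_trajectory_pointwise_equals_rebuilds(self):
        rng = np.random.default_rng(21)
        cm, pairs = random_pairs(rng, 300)
        traj = patch_count_trajectory(pairs, 0.25, cm)
        for p, count in traj:
            assert count == len(build_patches(pairs, p, 0.25, cm=cm))

    def test_chosen_threshold_is_optimal_among_candidates(self):
        rng = np.random.default_rng(23)
        for n_target in (2, 5, 9):
            cm, pairs = random_pairs(rng, 120)
            t = choose_threshold(pairs, 0.25, n_target, cm)
            best = abs(len(build_patches(pairs, t, 0.25, cm=cm)) - n_target)
            for cand in {p.p for p in pairs}:
                gap = abs(len(build_patches(pairs, cand, 0.25, cm=cm)) - n_target)
                assert best <= gap

    def test_tie_broken_toward_smaller_threshold(self):
        # counts trajectory (1, 3): both candidates one patch away from
        # target 2, so the smaller (more conservative) threshold must win
        cm = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 99.0])
        pairs = [
            PairScore(0, 3, 1e-8),
            PairScore(1, 4, 1e-6),
            PairScore(2, 5, 1e-6),
        ]
        assert [c for _p, c in patch_count_trajectory(pairs, 0.25, cm)] == [1, 3]
        assert choose_threshold(pairs, 0.25, 2, cm) == 1e-8

    def test_no_pairs_is_actionable_error(self):
        with pytest.raises(ValueError, match="p_cap"):
            choose_threshold([], 0.25, 5, np.array([0.0, 1.0]))


class TestPatchTarget:
    @pytest.mark.parametrize(
        "n_snps,ref,n1,want",
        [(1000, 1000, 250, 250), (500, 1000, 250, 63), (10, 1000, 250, 1)],
    )
    def test_density_scaling(self, n_snps, ref, n1, want):
        assert patch_target(n_snps, ref, n1) == want

    def test_positive_arguments_required(self):
        with pytest.raises(ValueError):
            patch_target(0, 10, 10)


class TestStatistic:
    def test_means(self):
        cm = np.array([0.0, 10.0, 20.0, 30.0])
        mk = lambda p, i, j: build_patches([PairScore(i, j, p)], 1, 0.25, cm=cm)[0]
        patches = [mk(1e-4, 0, 2), mk(1e-8, 1, 3)]
        assert statistic_pd_max(patches) == pytest.approx((1e-4 + 1e-8) / 2)
        assert statistic_pd_max(patches, "geometric") == pytest.approx(1e-6)
        assert statistic_pd_max(patches[:1]) == pytest.approx(
            statistic_pd_max(patches[:1], "geometric"), rel=1e-12
        )
        with pytest.raises(ValueError):
            statistic_pd_max([])


class TestScanChromosome:
    def test_deterministic(self, mosaic_panel):
        cfg = ScanConfig(p_cap=5e-3, n_1=10)
        a = scan_chromosome(mosaic_panel, cfg)
        b = scan_chromosome(mosaic_panel, cfg)
        assert a.threshold == b.threshold and a.pd_max == b.pd_max
        assert [p.min_p for p in a.patches] == [p.min_p for p in b.patches]

    def test_threshold_adaptivity_on_null_panel(self, mosaic_panel):
        res = scan_chromosome(mosaic_panel, ScanConfig(p_cap=5e-3, n_1=5))
        assert abs(res.n_p - 5) <= 2

    def test_planted_association_recovered_in_patch_spans(self, mosaic_panel):
        i, j = feasible_planted_pair(mosaic_panel, 20.0, 0.9)
        hm = plant_association(
            mosaic_panel, PlantedAssociation(i, j, 0.9), 0.4, np.random.default_rng(1)
        )
        res = scan_chromosome(hm, ScanConfig(p_cap=5e-3, n_1=10))
        a_bp, b_bp = hm.sites[i].bp, hm.sites[j].bp
        assert res.n_p >= 1
        assert any(
            p.left_span_bp[0] <= a_bp <= p.left_span_bp[1]
            and p.right_span_bp[0] <= b_bp <= p.right_span_bp[1]
            for p in res.patches
        )

    def test_cap_transparency(self, mosaic_panel):
        lo = scan_chromosome(mosaic_panel, ScanConfig(p_cap=5e-3, n_1=10))
        hi = scan_chromosome(mosaic_panel, ScanConfig(p_cap=5e-2, n_1=10))
        assert lo.threshold < 5e-3  # cap did not bind
        assert hi.threshold == lo.threshold
        assert hi.n_p == lo.n_p and hi.pd_max == lo.pd_max
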