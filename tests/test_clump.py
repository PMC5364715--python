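"""Pairwise r² and the greedy clumping rule."""

from __future__ import annotations

import numpy as np
import pytest

import popscore as ps
from _oracles import greedy_clump_oracle, masked_r2
from conftest import make_region, make_weights
from popscore.clump import ALL_SAMPLES, clumps_from_frame, clumps_to_frame


def random_instance(rng, max_variants=30, max_samples=50):
    """A random clumping instance with LD blocks and occasional missing calls."""
    m = int(rng.integers(3, max_variants + 1))
    n = int(rng.integers(4, max_samples + 1))
    base = rng.binomial(2, rng.uniform(0.1, 0.9, size=m), size=(n, m)).astype(float)
    # copy some columns (with flips) to create strong LD
    for _ in range(m // 3):
        src, dst = rng.integers(0, m, size=2)
        flip = rng.random() < 0.3
        base[:, dst] = 2 - base[:, src] if flip else base[:, src]
    if rng.random() < 0.5:
        miss = rng.random(size=base.shape) < 0.05
        base[miss] = np.nan
    positions = np.sort(rng.choice(np.arange(1, 60_000), size=m, replace=False))
    region = make_region(base, positions=positions)
    pvals = rng.uniform(0, 0.2, size=m)
    weights = make_weights(region.variant_ids, ["T1"], [np.ones(m)], [pvals], region=region)
    params = ps.ClumpParams(
        p_threshold=0.1,
        r2_threshold=float(rng.choice([0.2, 0.5, 0.8])),
        window_kb=float(rng.choice([5.0, 10.0, 20.0])),
    )
    return region, weights, pvals, params


class TestPairwiseR2:
    def test_identical_vectors_give_one(self):
        region = make_region(np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=float))
        assert ps.pairwise_r2(region, region.sample_ids, 0, 1) == pytest.approx(1.0)

    def test_monomorphic_is_undefined(self):
        region = make_region(np.array([[0, 0], [0, 1], [0, 2], [0, 1]], dtype=float))
        assert np.isnan(ps.pairwise_r2(region, region.sample_ids, 0, 1))

    def test_matches_definition(self):
        x = np.array([0, 1, 2, 2, 0], dtype=float)
        y = np.array([1, 1, 2, 0, 0], dtype=float)
        region = make_region(np.column_stack([x, y]))
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert ps.pairwise_r2(region, region.sample_ids, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_missing_calls_use_complete_pairs_only(self):
        x = np.array([0, 1, 2, np.nan, 0])
        y = np.array([1, 1, 2, 0, np.nan])
        region = make_region(np.column_stack([x, y]))
        got = ps.pairwise_r2(region, region.sample_ids, 0, 1)
        assert got == pytest.approx(masked_r2(x, y), abs=1e-12)

    def test_unknown_sample_raises(self):
        region = make_region(np.zeros((3, 2)))
        with pytest.raises(KeyError):
            ps.pairwise_r2(region, ["nope"], 0, 1)

    def test_r2_matrix_agrees_with_pairwise(self, rng):
        d = rng.binomial(2, 0.4, size=(20, 6)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        region = make_region(d)
        mat = ps.r2_matrix(region, region.sample_ids)
        for i in range(6):
            for j in range(6):
                expected = ps.pairwise_r2(region, region.sample_ids, i, j)
                if np.isnan(expected):
                    assert np.isnan(mat[i, j]) or i == j
                else:
                    assert mat[i, j] == pytest.approx(expected, abs=1e-12)


class TestClumpGreedy:
    def test_three_variant_worked_instance(self):
        """A(p=.001) absorbs B (5 kb away, r²=1 by construction); C is 50 kb
        away and must index itself."""
        col_a = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=float)
        col_b = col_a.copy()  # r² = 1 >= 0.5
        col_c = np.array([2, 0, 1, 0, 2, 1, 0, 1], dtype=float)
        region = make_region(
            np.column_stack([col_a, col_b, col_c]),
            positions=[100, 5000, 50_000],
            ids=["A", "B", "C"],
        )
        weights = make_weights(
            ["A", "B", "C"], ["T1"], [[1, 1, 1]], [[0.001, 0.01, 0.05]], region=region
        )
        res = ps.clump(region, weights, "T1", region.sample_ids, ps.ClumpParams())
        assert res.index_variants == ["A", "C"]
        assert res.members == {"A": ["B"], "C": []}

    def test_mutually_uncorrelated_candidates_all_index(self, rng):
        d = rng.binomial(2, 0.5, size=(200, 5)).astype(float)
        region = make_region(d)
        weights = make_weights(
            region.variant_ids, ["T1"], [np.ones(5)], [[0.01] * 5], region=region
        )
        res = ps.clump(region, weights, "T1", region.sample_ids,
                       ps.ClumpParams(r2_threshold=0.9))
        assert len(res.index_variants) == 5

    def test_single_candidate_is_sole_index(self):
        region = make_region(np.array([[0.0], [1.0], [2.0]]))
        weights = make_weights(["v0"], ["T1"], [[0.5]], [[0.05]], region=region)
        res = ps.clump(region, weights, "T1", region.sample_ids)
        assert res.index_variants == ["v0"]

    def test_empty_candidate_set_is_not_an_error(self):
        region = make_region(np.array([[0.0], [1.0], [2.0]]))
        weights = make_weights(["v0"], ["T1"], [[0.5]], [[0.9]], region=region)
        res = ps.clump(region, weights, "T1", region.sample_ids)
        assert res.index_variants == [] and res.members == {}

    def test_absent_tissue_raises(self):
        region = make_region(np.array([[0.0], [1.0], [2.0]]))
        weights = make_weights(["v0"], ["T1"], [[0.5]], [[0.05]], region=region)
        with pytest.raises(KeyError):
            ps.clump(region, weights, "nope", region.sample_ids)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            region, weights, pvals, params = random_instance(rng)
            res = ps.clump(region, weights, "T1", region.sample_ids, params)
            idx, members = greedy_clump_oracle(
                region.variant_ids,
                [v.pos for v in region.variants],
                list(pvals),
                region.dosages,
                params.p_threshold,
                params.r2_threshold,
                params.window_kb * 1000,
            )
            assert res.index_variants == idx
            assert res.members == members

    def test_raising_r2_threshold_never_loses_indices(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            region, weights, pvals, _ = random_instance(rng)
            counts = []
            for r2_thr in (0.2, 0.5, 0.8, 1.0):
                res = ps.clump(
                    region, weights, "T1", region.sample_ids,
                    ps.ClumpParams(r2_threshold=r2_thr),
                )
                counts.append(len(res.index_variants))
            assert counts == sorted(counts)

    def test_no_index_in_previous_index_window_with_high_r2(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            region, weights, pvals, params = random_instance(rng)
            res = ps.clump(region, weights, "T1", region.sample_ids, params)
            pos = {v.id: v.pos for v in region.variants}
            col = {v.id: k for k, v in enumerate(region.variants)}
            for earlier_i, a in enumerate(res.index_variants):
                for b in res.index_variants[earlier_i + 1:]:
                    if abs(pos[a] - pos[b]) <= params.window_kb * 1000:
                        r2 = masked_r2(
                            region.dosages[:, col[a]], region.dosages[:, col[b]]
                        )
                        assert np.isnan(r2) or r2 < params.r2_threshold


class TestClumpAll:
    def test_among_yields_one_result_per_tissue(self, small_sim):
        results = ps.clump_all(
            small_sim.region, small_sim.weights, small_sim.panel, perspective="among"
        )
        assert len(results) == 3
        assert {r.ld_subset for r in results} == {ALL_SAMPLES}

    def test_within_yields_tissues_times_groups(self, small_sim):
        results = ps.clump_all(
            small_sim.region, small_sim.weights, small_sim.panel, perspective="within"
        )
        assert len(results) == 3 * 2
        assert {r.ld_subset for r in results} == {"G1", "G2"}

    def test_within_single_group_equals_among_on_that_subset(self, small_sim):
        panel_df = small_sim.panel.df
        g1 = panel_df[panel_df["group"] == "G1"]
        from popscore.io import SamplePanel

        sub_panel = SamplePanel(df=g1.copy())
        within = ps.clump_all(
            small_sim.region, small_sim.weights, sub_panel, perspective="within"
        )
        for res in within:
            direct = ps.clump(
                small_sim.region,
                small_sim.weights,
                res.tissue,
                sub_panel.samples,
                ps.ClumpParams(),
            )
            assert res.index_variants == direct.index_variants
            assert res.members == direct.members

    def test_serialization_round_trip(self, small_sim):
        results = ps.clump_all(
            small_sim.region, small_sim.weights, small_sim.panel, perspective="within"
        )
        back = clumps_from_frame(clumps_to_frame(results))
        by_key = {(r.tissue, r.ld_subset): r for r in back}
        for res in results:
            got = by_key[(res.tissue, res.ld_subset)]
            assert got.index_variants == res.index_variants
            assert got.members == res.members
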