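"""Design construction: candidates, D-optimal exchange, augmentation, blocks, df."""

import itertools

import numpy as np
import pytest

import mixamount as mx
from mixamount.design import CandidateSet, build_study_design, select_d_optimal

from conftest import make_small_design


def random_instance(rng):
    """A feasible random small instance for the exhaustive D-optimality oracle."""
    q = int(rng.integers(2, 4))
    morder = 2 if (q == 2 and rng.random() < 0.5) else 1
    terms = mx.enumerate_terms(q, morder, 1)
    t = len(terms)
    m = int(rng.integers(max(t + 2, 8), 13))
    P = rng.dirichlet(np.ones(q), size=m)
    c = rng.choice([-1.0, 0.0, 1.0], size=m)
    cands = CandidateSet(P, c, ["interior"] * m)
    n = int(rng.integers(t, min(m, t + 3) + 1))
    return cands, terms, n


def exhaustive_logdet(cands, terms, n):
    F = cands.model_matrix(terms)
    best = -np.inf
    for sub in itertools.combinations(range(cands.m), n):
        sign, ld = np.linalg.slogdet(F[list(sub)].T @ F[list(sub)])
        if sign > 0 and ld > best:
            best = ld
    return best


class TestCandidates:
    @pytest.mark.parametrize(
        "q,levels,kinds,expected",
        [
            (3, (-1, 1), ("vertex", "edge", "centroid"), 14),
            (2, (0,), ("vertex",), 2),
            (5, (-1, 0, 1), ("vertex", "edge", "centroid", "axial"), 63),
        ],
    )
    def test_counts(self, q, levels, kinds, expected):
        space = mx.ComponentSpace(tuple(f"c{i}" for i in range(q)))
        cs = mx.generate_candidates(space, levels, kinds)
        assert cs.m == expected

    def test_candidates_valid_and_distinct(self):
        space = mx.ComponentSpace(("A", "B", "C", "D"))
        cs = mx.generate_candidates(space, (-1, 0, 1))
        np.testing.assert_allclose(cs.proportions.sum(axis=1), 1.0, atol=1e-9)
        coords = cs.coords()
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1e-9

    def test_empty_levels_rejected(self, space3):
        with pytest.raises(ValueError):
            mx.generate_candidates(space3, ())


class TestDOptimal:
    def test_two_point_linear_picks_vertices(self):
        cands = CandidateSet(
            np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]]),
            np.zeros(3),
            ["vertex", "vertex", "edge-midpoint"],
        )
        terms = mx.enumerate_terms(2, 1, 0)
        d = select_d_optimal(cands, terms, 2, mx.AmountFactor("a", 0, 1), seed=0)
        P = d.proportions
        assert {tuple(r) for r in P} == {(1.0, 0.0), (0.0, 1.0)}

    def test_three_vertices_beat_centroid(self):
        P = np.vstack([np.eye(3), np.full((1, 3), 1 / 3)])
        cands = CandidateSet(P, np.zeros(4), ["vertex"] * 3 + ["centroid"])
        terms = mx.enumerate_terms(3, 1, 0)
        d = select_d_optimal(cands, terms, 3, mx.AmountFactor("a", 0, 1), seed=0)
        np.testing.assert_allclose(np.sort(d.proportions, axis=0), np.sort(np.eye(3), axis=0))

    def test_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            cands, terms, n = random_instance(rng)
            best = exhaustive_logdet(cands, terms, n)
            d = select_d_optimal(cands, terms, n, mx.AmountFactor("a", 0, 1), seed=3)
            _, ld = np.linalg.slogdet(d.model_matrix(terms).T @ d.model_matrix(terms))
            assert ld == pytest.approx(best, abs=1e-8)

    def test_beats_random_subsets(self):
        rng = np.random.default_rng(7)
        cands, terms, n = random_instance(rng)
        F = cands.model_matrix(terms)
        d = select_d_optimal(cands, terms, n, mx.AmountFactor("a", 0, 1), seed=1)
        _, ld = np.linalg.slogdet(d.model_matrix(terms).T @ d.model_matrix(terms))
        for _ in range(500):
            sub = rng.choice(cands.m, n, replace=False)
            sign, ld_r = np.linalg.slogdet(F[sub].T @ F[sub])
            assert (sign <= 0) or (ld_r <= ld + 1e-8)

    def test_infeasible_reported(self):
        # all candidates on one vertex: singular for a 2-term model
        P = np.tile([[1.0, 0.0]], (4, 1))
        cands = CandidateSet(P, np.zeros(4), ["vertex"] * 4)
        with pytest.raises(mx.InestimableError):
            select_d_optimal(cands, mx.enumerate_terms(2, 1, 0), 2, mx.AmountFactor("a", 0, 1))


class TestAugmentation:
    def test_lack_of_fit_maximin(self, space3, factor):
        # design holds two vertices; farthest candidate must be picked first
        from mixamount.design import Design, DesignPoint

        pts = [
            DesignPoint((1.0, 0.0, 0.0), 150.0),
            DesignPoint((0.0, 1.0, 0.0), 150.0),
        ]
        d = Design(pts, space3, factor)
        cands = mx.generate_candidates(space3, (0.0,))
        d2 = mx.augment_lack_of_fit(d, cands, 1, seed=0)
        assert d2.points[-1].role == "lack_of_fit"
        np.testing.assert_allclose(d2.points[-1].proportions, (0.0, 0.0, 1.0))

    def test_lof_zero_is_identity(self, paper_design):
        assert mx.augment_lack_of_fit(paper_design, None, 0) is paper_design

    def test_replicates_do_not_change_distinct_count(self, space3, factor):
        d = make_small_design(seed=3, n_dup=0, q=3)
        terms = mx.enumerate_terms(3, 1, 1)
        before = d.n_distinct
        d2 = mx.augment_replicates(d, 5, terms, seed=0)
        assert d2.n == d.n + 5
        assert d2.n_distinct == before
        assert all(p.role == "replicate" for p in d2.points[-5:])

    def test_duplicate_all_pure_error(self):
        d = make_small_design(seed=5, n_unique=5, n_dup=0, n_blocks=1, q=3)
        terms = mx.enumerate_terms(3, 1, 0)
        d2 = mx.augment_replicates(d, 5, terms, seed=0)
        part = mx.df_partition(d2, terms)
        # sum(n_i - 1) = 5 with one block
        assert part.pure_error == 5
        assert part.block == 0

    def test_center_points(self, space3, factor):
        d = make_small_design(seed=1, q=3)
        before = d.n_distinct
        d2 = mx.add_center_points(d, 5)
        assert d2.n == d.n + 5
        assert d2.n_distinct == before + 1
        last = d2.points[-1]
        np.testing.assert_allclose(last.proportions, (1 / 3, 1 / 3, 1 / 3))
        assert last.amount == pytest.approx(20.0)
        assert mx.add_center_points(d, 0).n == d.n


class TestBlocks:
    @pytest.mark.parametrize("n,b,sizes", [(100, 5, {20}), (7, 3, {2, 3})])
    def test_balanced_sizes(self, n, b, sizes):
        d = make_small_design(seed=2, n_unique=n - 2, n_dup=2, n_blocks=1)
        d2 = mx.assign_blocks(d, b, seed=0)
        counts = np.bincount(d2.blocks, minlength=b)
        assert set(counts.tolist()) <= sizes
        assert counts.sum() == n

    def test_replicates_spread_across_blocks(self):
        d = make_small_design(seed=4, n_unique=10, n_dup=4, n_blocks=1)
        d2 = mx.assign_blocks(d, 4, seed=0)
        _, group = d2.distinct()
        for g in set(group):
            runs = np.flatnonzero(group == g)
            if len(runs) > 1:
                assert len(set(d2.blocks[runs])) == len(runs)

    def test_too_many_blocks_rejected(self, small_design):
        with pytest.raises(ValueError):
            mx.assign_blocks(small_design, small_design.n + 1)


class TestDfPartition:
    def test_paper_structure(self, paper_design):
        part = mx.df_partition(paper_design, mx.enumerate_terms(5, 2, 2))
        assert (part.block, part.model, part.lack_of_fit, part.pure_error) == (4, 44, 6, 45)
        assert part.total == 99

    def test_saturated_unreplicated(self):
        d = make_small_design(seed=6, n_unique=6, n_dup=0, n_blocks=1, q=3)
        terms = mx.enumerate_terms(3, 1, 1)  # 6 terms on 6 distinct points
        part = mx.df_partition(d, terms)
        assert (part.block, part.model, part.lack_of_fit, part.pure_error) == (0, 5, 0, 0)

    def test_partition_sums_to_n_minus_1_fuzz(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            d = make_small_design(
                seed=int(rng.integers(10**6)),
                n_unique=int(rng.integers(8, 15)),
                n_dup=int(rng.integers(0, 5)),
                n_blocks=int(rng.integers(1, 4)),
                q=3,
            )
            try:
                part = mx.df_partition(d, mx.enumerate_terms(3, 1, 1))
            except mx.InestimableError:
                continue  # too few replicate df for the blocks drawn
            assert part.block + part.model + part.lack_of_fit + part.pure_error == d.n - 1

    def test_too_few_distinct_points(self):
        d = make_small_design(seed=8, n_unique=4, n_dup=4, n_blocks=1, q=3)
        with pytest.raises(mx.InestimableError):
            mx.df_partition(d, mx.enumerate_terms(3, 2, 1))


class TestStudyBuilder:
    def test_full_study_shape(self, paper_design):
        d = paper_design
        assert d.n == 100
        assert d.n_distinct == 51
        roles = np.array(d.roles)
        assert (roles == "model").sum() == 45
        assert (roles == "lack_of_fit").sum() == 5
        assert (roles == "replicate").sum() == 45
        assert (roles == "center").sum() == 5
        counts = np.bincount(d.blocks, minlength=5)
        assert counts.tolist() == [20] * 5
        d.validate()

    def test_deterministic_given_seed(self, paper_config):
        d1 = paper_config.build_design(seed=9)
        d2 = paper_config.build_design(seed=9)
        assert d1.to_frame().equals(d2.to_frame())

    def test_replicates_duplicate_existing_points(self, paper_design):
        keys = {p.key() for p in paper_design.points if p.role in ("model", "lack_of_fit")}
        for p in paper_design.points:
            if p.role == "replicate":
                assert p.key() in keys
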