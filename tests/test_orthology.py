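"""Reciprocal-best-hit orthology and shared-X conservation tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from hemix.io_tables import HitRecord
from hemix.orthology import (
    OrthologyMap,
    extrapolate_via_reference,
    filter_hits_by_score,
    monte_carlo_shared_x,
    reciprocal_best_hits,
    shared_x_test,
)
from hemix.sexlink import AUTOSOME, X
from hemix.simulate import SimulationConfig, simulate_study


def hit(q, t, score, evalue=None):
    return HitRecord(q, t, score, evalue)


def brute_force_rbh(score_ab: np.ndarray, score_ba: np.ndarray):
    """Oracle: check the RBH condition directly for every (a, b) cell."""
    n_a, n_b = score_ab.shape
    pairs = []
    for i in range(n_a):
        for j in range(n_b):
            a_best = score_ab[i, j] > max(
                [score_ab[i, k] for k in range(n_b) if k != j], default=-np.inf
            )
            b_best = score_ba[j, i] > max(
                [score_ba[j, k] for k in range(n_a) if k != i], default=-np.inf
            )
            if a_best and b_best:
                pairs.append((f"a{i}", f"b{j}"))
    return sorted(pairs)


class TestScoreFilter:
    def test_boundary_inclusive_by_default(self):
        hits = [hit("q", "t", 50.0), hit("q", "t2", 49.9)]
        assert [h.target_id for h in filter_hits_by_score(hits)] == ["t"]

    def test_strict_option_drops_boundary(self):
        assert filter_hits_by_score([hit("q", "t", 50.0)], strict=True) == []

    def test_count_matches_scan_oracle(self, rng):
        hits = [hit(f"q{i}", "t", float(s)) for i, s in enumerate(rng.uniform(0, 100, 200))]
        expected = sum(1 for h in hits if h.score >= 50)
        assert len(filter_hits_by_score(hits)) == expected


class TestReciprocalBestHits:
    def test_unique_mutual_best_is_kept(self):
        pairs = reciprocal_best_hits([hit("a1", "b1", 80)], [hit("b1", "a1", 80)])
        assert pairs == [("a1", "b1")]

    def test_asymmetric_best_hits_drop_the_pair(self):
        ab = [hit("a1", "b1", 90), hit("a2", "b1", 70)]
        ba = [hit("b1", "a2", 95)]  # b1 prefers a2: a1's choice is unrequited
        pairs = reciprocal_best_hits(ab, ba)
        assert ("a1", "b1") not in pairs
        assert pairs == [("a2", "b1")]  # the mutual pair survives

    def test_repeated_hits_collapse_to_max_score(self):
        ab = [hit("a1", "b1", 60), hit("a1", "b1", 90), hit("a1", "b2", 70)]
        ba = [hit("b1", "a1", 85)]
        assert reciprocal_best_hits(ab, ba) == [("a1", "b1")]

    def test_tied_best_hits_are_dropped(self):
        ab = [hit("a1", "b1", 80), hit("a1", "b2", 80)]
        ba = [hit("b1", "a1", 80), hit("b2", "a1", 80)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_evalue_tie_break_option(self):
        ab = [hit("a1", "b1", 80, 1e-30), hit("a1", "b2", 80, 1e-10)]
        ba = [hit("b1", "a1", 80, 1e-28)]
        assert reciprocal_best_hits(ab, ba, tie_break="evalue") == [("a1", "b1")]

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            score_ab = rng.integers(51, 300, size=(5, 5)).astype(float)
            score_ba = rng.integers(51, 300, size=(5, 5)).astype(float)
            ab = [hit(f"a{i}", f"b{j}", score_ab[i, j]) for i in range(5) for j in range(5)]
            ba = [hit(f"b{j}", f"a{i}", score_ba[j, i]) for i in range(5) for j in range(5)]
            assert reciprocal_best_hits(ab, ba) == brute_force_rbh(score_ab, score_ba)

    def test_symmetry(self, rng):
        score_ab = rng.integers(51, 300, size=(6, 4)).astype(float)
        score_ba = rng.integers(51, 300, size=(4, 6)).astype(float)
        ab = [hit(f"a{i}", f"b{j}", score_ab[i, j]) for i in range(6) for j in range(4)]
        ba = [hit(f"b{j}", f"a{i}", score_ba[j, i]) for i in range(6) for j in range(4)]
        forward = reciprocal_best_hits(ab, ba)
        backward = reciprocal_best_hits(ba, ab)
        assert sorted((b, a) for a, b in forward) == backward


class TestExtrapolation:
    def make_map(self, pairs, species=("ref", "s")):
        return OrthologyMap(species, pairs, {}, {})

    def test_shared_reference_gene_pairs_species(self):
        m1 = self.make_map([("r1", "a1")], ("ref", "s1"))
        m2 = self.make_map([("r1", "b1")], ("ref", "s2"))
        assert extrapolate_via_reference(m1, m2).pairs == [("a1", "b1")]

    def test_unmatched_reference_gene_gives_no_pair(self):
        m1 = self.make_map([("r1", "a1"), ("r2", "a2")], ("ref", "s1"))
        m2 = self.make_map([("r2", "b2")], ("ref", "s2"))
        assert extrapolate_via_reference(m1, m2).pairs == [("a2", "b2")]

    def test_mismatched_references_rejected(self):
        m1 = self.make_map([], ("refA", "s1"))
        m2 = self.make_map([], ("refB", "s2"))
        with pytest.raises(ValueError, match="ref"):
            extrapolate_via_reference(m1, m2)

    def test_matches_join_oracle_on_random_maps(self, rng):
        refs = [f"r{i}" for i in range(40)]
        sel1 = [r for r in refs if rng.random() < 0.6]
        sel2 = [r for r in refs if rng.random() < 0.6]
        m1 = self.make_map([(r, f"a_{r}") for r in sel1], ("ref", "s1"))
        m2 = self.make_map([(r, f"b_{r}") for r in sel2], ("ref", "s2"))
        oracle = sorted((f"a_{r}", f"b_{r}") for r in set(sel1) & set(sel2))
        assert extrapolate_via_reference(m1, m2).pairs == oracle


def label_map(prefix, is_x):
    return {f"{prefix}{i}": (X if flag else AUTOSOME) for i, flag in enumerate(is_x)}


def make_map(is_x_1, is_x_2):
    n = len(is_x_1)
    return OrthologyMap(
        ("s1", "s2"),
        [(f"a{i}", f"b{i}") for i in range(n)],
        label_map("a", is_x_1),
        label_map("b", is_x_2),
    )


class TestSharedX:
    def test_perfect_conservation_ratio(self):
        # 10% X copied exactly: obs = 0.1 n, exp = 0.01 n -> ratio 10
        is_x = np.arange(1000) < 100
        result = shared_x_test(make_map(is_x, is_x))
        assert result.ratio == pytest.approx(10.0)
        assert result.obs_xx == 100 and result.exp_xx == pytest.approx(10.0)

    def test_all_x_margin_is_degenerate(self):
        is_x = np.ones(50, dtype=bool)
        with pytest.raises(ValueError, match="degenerate"):
            shared_x_test(make_map(is_x, is_x))

    def test_excluded_genes_removed_before_testing(self):
        omap = OrthologyMap(
            ("s1", "s2"),
            [("a0", "b0"), ("a1", "b1"), ("a2", "b2"), ("a3", "b3")],
            {"a0": X, "a1": AUTOSOME, "a2": "excluded", "a3": AUTOSOME},
            {"b0": X, "b1": AUTOSOME, "b2": X, "b3": X},
        )
        result = shared_x_test(omap)
        assert result.n == 3  # a2/b2 dropped

    def test_independent_linkage_gives_null_behaviour(self, rng):
        ok = 0
        for _ in range(50):
            result = shared_x_test(
                make_map(rng.random(5000) < 0.1, rng.random(5000) < 0.1)
            )
            ok += abs(result.ratio - 1.0) <= 0.35 and result.chi2_p > 0.05
        assert ok >= 45  # ratio near 1 and no significance in >= 90%


class TestMonteCarlo:
    def test_perfect_conservation_attains_minimum_p(self):
        is_x = np.arange(1000) < 100
        # no permutation can reach obs: hypergeometric P(X = 100) ~ 1e-103
        result = monte_carlo_shared_x(make_map(is_x, is_x), reps=1000, seed=1)
        assert result.p_two_sided == pytest.approx(2 / 1001)

    def test_tail_matches_hypergeometric(self, rng):
        # permutation null over n pairs is exactly hypergeometric
        n, x1, x2 = 30, 10, 12
        is_x_1 = np.concatenate([np.ones(x1, bool), np.zeros(n - x1, bool)])
        is_x_2 = np.concatenate([np.ones(x2, bool), np.zeros(n - x2, bool)])
        rng.shuffle(is_x_2)
        result = monte_carlo_shared_x(make_map(is_x_1, is_x_2), reps=20_000, seed=2)
        expected = sps.hypergeom.sf(result.observed - 1, n, x1, x2)
        se = np.sqrt(expected * (1 - expected) / result.reps)
        assert abs(result.p_greater - expected) <= 3 * se + 1 / result.reps

    def test_rep_counts_agree_within_monte_carlo_error(self):
        is_x_1 = np.arange(2000) < 220
        rng = np.random.default_rng(3)
        is_x_2 = (np.arange(2000) < 240)[rng.permutation(2000)]
        omap = make_map(is_x_1, is_x_2)
        small = monte_carlo_shared_x(omap, reps=100, seed=4).p_two_sided
        large = monte_carlo_shared_x(omap, reps=10_000, seed=5).p_two_sided
        tol = 2 * np.sqrt(max(large, 1e-3) * (1 - min(large, 0.999)) / 100) + 0.02
        assert abs(small - large) <= tol

    def test_seed_required(self):
        is_x = np.arange(200) < 20
        with pytest.raises(ValueError, match="seed"):
            monte_carlo_shared_x(make_map(is_x, is_x), reps=1000)


class TestConservationRecovery:
    def test_ratio_increases_with_conservation(self):
        means = []
        for rho in (0.0, 0.5, 1.0):
            ratios = []
            for seed in range(20):
                cfg = SimulationConfig(
                    n_scaffolds=200, seed=seed, n_species=2, conservation_rho=rho
                )
                study = simulate_study(cfg)
                result = shared_x_test(study.true_map("sp1", "sp2"))
                ratios.append(result.ratio)
            means.append(np.mean(ratios))
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(1.0, abs=0.15)

    def test_chi2_and_monte_carlo_agree_on_significance(self, rng):
        agree = total = 0
        for i in range(100):
            rho = float(rng.uniform(0, 1))
            cfg = SimulationConfig(
                n_scaffolds=200, seed=1000 + i, n_species=2, conservation_rho=rho
            )
            study = simulate_study(cfg)
            result = shared_x_test(study.true_map("sp1", "sp2"),
                                   mc_reps=2000, seed=2000 + i)
            agree += (result.chi2_p < 0.05) == (result.mc_p < 0.05)
            total += 1
        assert agree / total >= 0.95
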