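"""Minimal r-covering MILP against exhaustive subset search."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stpcover import (
    CoveringProblem,
    InfeasibleCoveringError,
    ValidationError,
    certify_core_union,
    compute_alpha_star,
    enumerate_optima,
    representative_covering,
    solve_min_covering,
)


def brute_force_optima(Z: pd.DataFrame, r: int, alpha: float, weights=None):
    """Oracle: scan all feature subsets; return (min objective, set of optimal J)."""
    n, m = Z.shape
    w = np.ones(m) if weights is None else np.asarray(weights, float)
    need = math.ceil(n * (1 - alpha) - 1e-9)
    arr = Z.to_numpy()
    best_obj, best_sets = np.inf, []
    for size in range(m + 1):
        for combo in combinations(range(m), size):
            covered = (arr[:, list(combo)].sum(axis=1) >= r).sum()
            if covered >= need:
                obj = w[list(combo)].sum()
                if obj < best_obj - 1e-9:
                    best_obj, best_sets = obj, [frozenset(combo)]
                elif abs(obj - best_obj) <= 1e-9:
                    best_sets.append(frozenset(combo))
    return best_obj, set(best_sets)


def random_problem(rng, n=15, m=8, r=1, density=0.3):
    Z = pd.DataFrame(
        (rng.random((n, m)) < density).astype(int), columns=[f"f{i}" for i in range(m)]
    )
    alpha = compute_alpha_star(Z, r)
    return CoveringProblem(Z, r=r, alpha=alpha)


class TestAlphaStar:
    def test_full_coverage_gives_zero(self):
        Z = pd.DataFrame(np.ones((5, 2), dtype=int))
        assert compute_alpha_star(Z, 1) == 0.0

    def test_direct_count(self):
        Z = pd.DataFrame(np.ones((10, 3), dtype=int))
        Z.iloc[0] = 0
        Z.iloc[5] = 0
        assert compute_alpha_star(Z, 1) == pytest.approx(0.2)

    def test_matches_rowsum_scan(self, rng):
        for _ in range(20):
            Z = pd.DataFrame(rng.integers(0, 2, (12, 6)))
            for r in (1, 2, 3):
                expected = 1 - (Z.sum(axis=1) >= r).mean()
                assert compute_alpha_star(Z, r) == pytest.approx(expected)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValidationError):
            compute_alpha_star(pd.DataFrame(), 1)


class TestSolveMinCovering:
    def test_single_universal_feature(self):
        Z = pd.DataFrame({"hit": [1] * 6, "miss": [0] * 6})
        sol = solve_min_covering(CoveringProblem(Z, r=1, alpha=0.0))
        assert sol.selected == ["hit"] and sol.objective == 1.0
        assert sol.covered_fraction == 1.0

    def test_alpha_one_allows_empty_selection(self):
        Z = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        sol = solve_min_covering(CoveringProblem(Z, r=1, alpha=1.0))
        assert sol.objective == 0.0 and sol.selected == []

    @pytest.mark.parametrize("r", [1, 3])
    def test_objective_matches_exhaustive_search(self, rng, r):
        """8-feature, 15-sample random instances: MILP optimum equals the 2^8 scan."""
        for _ in range(15):
            problem = random_problem(rng, r=r, density=0.4)
            sol = solve_min_covering(problem)
            oracle_obj, _ = brute_force_optima(problem.Z, r, problem.alpha)
            assert sol.objective == pytest.approx(oracle_obj)

    def test_solution_satisfies_constraints(self, rng):
        for _ in range(10):
            problem = random_problem(rng, r=2, density=0.5)
            sol = solve_min_covering(problem)
            rowsum = problem.Z[sol.selected].sum(axis=1)
            assert (rowsum >= problem.r).mean() >= 1 - problem.alpha - 1e-12

    def test_weighted_objective(self, rng):
        Z = pd.DataFrame({"cheap": [1, 1, 0, 0], "exp1": [1, 1, 1, 1], "exp2": [0, 0, 1, 1]})
        w = np.array([1.0, 5.0, 1.0])
        sol = solve_min_covering(CoveringProblem(Z, r=1, alpha=0.0, weights=w))
        assert set(sol.selected) == {"cheap", "exp2"} and sol.objective == 2.0

    def test_infeasible_alpha_raises_naming_alpha_star(self):
        Z = pd.DataFrame({"a": [1, 0, 0, 0]})
        with pytest.raises(InfeasibleCoveringError, match="0.75"):
            solve_min_covering(CoveringProblem(Z, r=1, alpha=0.1))


class TestEnumerateOptima:
    def test_unique_optimum_found_and_exhausted(self):
        Z = pd.DataFrame({"hit": [1] * 4, "half": [1, 1, 0, 0]})
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        sols, exhausted = enumerate_optima(problem, 1.0, max_solutions=10)
        assert len(sols) == 1 and exhausted
        assert sols[0].selected == ["hit"]

    def test_two_interchangeable_features_both_found(self):
        Z = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 1, 1, 1], "c": [1, 0, 0, 0]})
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        sols, exhausted = enumerate_optima(problem, 1.0, max_solutions=10)
        assert {frozenset(s.selected) for s in sols} == {frozenset(["a"]), frozenset(["b"])}
        assert exhausted

    def test_cap_respected(self, rng):
        Z = pd.DataFrame(np.ones((4, 8), dtype=int), columns=[f"f{i}" for i in range(8)])
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        sols, exhausted = enumerate_optima(problem, 1.0, max_solutions=5)
        assert len(sols) == 5 and not exhausted

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(8):
            problem = random_problem(rng, n=12, m=7, density=0.35)
            opt = solve_min_covering(problem).objective
            sols, exhausted = enumerate_optima(problem, opt, max_solutions=200)
            assert exhausted
            found = {frozenset(problem.Z.columns.get_loc(f) for f in s.selected) for s in sols}
            _, oracle_sets = brute_force_optima(problem.Z, problem.r, problem.alpha)
            assert found == oracle_sets


class TestCoreUnion:
    def test_unique_optimum_core_equals_union(self):
        Z = pd.DataFrame({"hit": [1] * 4, "half": [1, 1, 0, 0]})
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        core, union, und = certify_core_union(problem, 1.0)
        assert core == union == ["hit"] and not und

    def test_certificates_match_brute_force(self, rng):
        """Core/union from forcing tests equal intersection/union of all brute-force optima."""
        for _ in range(10):
            problem = random_problem(rng, n=12, m=7, density=0.35)
            opt = solve_min_covering(problem).objective
            core, union, und = certify_core_union(problem, opt)
            assert not und
            _, oracle_sets = brute_force_optima(problem.Z, problem.r, problem.alpha)
            names = problem.feature_ids
            oracle_union = sorted({names[j] for s in oracle_sets for j in s})
            oracle_core = sorted(set(names[j] for j in set.intersection(*map(set, oracle_sets))) if oracle_sets else [])
            assert sorted(union) == oracle_union
            assert sorted(core) == oracle_core
            assert set(core) <= set(union)

    def test_feature_outside_every_optimum_excluded_from_union(self):
        Z = pd.DataFrame({"a": [1, 1, 1, 1], "never": [1, 0, 0, 0]})
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        _, union, _ = certify_core_union(problem, 1.0)
        assert union == ["a"]


class TestRepresentative:
    def test_unique_optimum_unaffected_by_frequencies(self):
        Z = pd.DataFrame({"hit": [1] * 4, "half": [1, 1, 0, 0]})
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        freqs = pd.Series({"hit": 0.1, "half": 0.9})
        sol = representative_covering(problem, 1.0, freqs)
        assert sol.selected == ["hit"]

    def test_prefers_higher_frequency_sum(self):
        Z = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 1, 1, 1], "c": [1, 0, 0, 0]})
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        sol = representative_covering(problem, 1.0, pd.Series({"a": 0.3, "b": 0.8, "c": 0.5}))
        assert sol.selected == ["b"]

    def test_uniform_frequency_tie_breaks_to_smallest_indices(self):
        Z = pd.DataFrame({"a": [1] * 4, "b": [1] * 4, "c": [1] * 4})
        problem = CoveringProblem(Z, r=1, alpha=0.0)
        sol = representative_covering(problem, 1.0, pd.Series({"a": 0.5, "b": 0.5, "c": 0.5}))
        assert sol.selected == ["a"]

    def test_matches_enumerate_and_score_oracle(self, rng):
        for _ in range(6):
            problem = random_problem(rng, n=12, m=7, density=0.35)
            opt = solve_min_covering(problem).objective
            freqs = pd.Series(problem.Z.mean(axis=0))
            sol = representative_covering(problem, opt, freqs)
            _, oracle_sets = brute_force_optima(problem.Z, problem.r, problem.alpha)
            names = problem.feature_ids
            best = max(sum(freqs[names[j]] for j in s) for s in oracle_sets)
            assert sum(freqs[f] for f in sol.selected) == pytest.approx(best)
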