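"""Plug-in and bias-corrected configuration entropy, partitioning, and CIs."""

import itertools

import numpy as np
import pytest
from scipy.special import digamma

from stpcover import (
    ConfigDistribution,
    ValidationError,
    corrected_entropy,
    entropy_with_ci,
    greedy_partition,
    plugin_entropy,
)

LOG2E = np.log2(np.e)
EULER_GAMMA = 0.5772156649015329


def exact_entropy(probs) -> float:
    p = np.asarray(probs, float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestPluginEntropy:
    def test_uniform_and_point_mass(self):
        assert plugin_entropy(ConfigDistribution(np.array([5, 5, 5, 5]), 20)) == pytest.approx(2.0)
        assert plugin_entropy(ConfigDistribution(np.array([7]), 7)) == 0.0

    def test_three_one_split(self):
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert plugin_entropy(ConfigDistribution(np.array([3, 1]), 4)) == pytest.approx(expected)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_invalid_distributions_error(self):
        with pytest.raises(ValidationError):
            ConfigDistribution(np.array([]), 1)
        with pytest.raises(ValidationError):
            ConfigDistribution(np.array([2, 1]), 4)  # counts don't sum to n


class TestCorrectedEntropy:
    def test_single_config_observed_twice(self):
        """N=2 one config: log2(e) * (ln 2 - psi(2) - 1/6), with psi(2) = 1 - gamma."""
        val = corrected_entropy(ConfigDistribution(np.array([2]), 2))
        expected = LOG2E * (np.log(2) - (1 - EULER_GAMMA) - 1 / 6)
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.1496, abs=1e-3)

    def test_balanced_split_near_one_bit(self):
        """N=1000 split 500/500: digamma asymptotics put the estimate at ~1.0015 bits."""
        val = corrected_entropy(ConfigDistribution(np.array([500, 500]), 1000))
        oracle = LOG2E * 2 * 0.5 * (np.log(1000) - digamma(500) - 1 / (500 * 501))
        assert val == pytest.approx(oracle, abs=1e-12)
        assert val == pytest.approx(1.0015, abs=1e-3)

    def test_invariant_to_sample_order(self, rng):
        Z = rng.integers(0, 2, (40, 3))
        d1 = ConfigDistribution.from_matrix(Z)
        d2 = ConfigDistribution.from_matrix(Z[rng.permutation(40)])
        assert corrected_entropy(d1) == pytest.approx(corrected_entropy(d2))

    def test_correction_exceeds_plugin(self, rng):
        """The Grassberger estimate corrects the plug-in's downward bias."""
        for _ in range(10):
            Z = rng.integers(0, 2, (25, 3))
            d = ConfigDistribution.from_matrix(Z)
            assert corrected_entropy(d) > plugin_entropy(d)

    def test_gap_to_plugin_shrinks_with_n(self):
        """On a fixed distribution the correction vanishes as N grows."""
        rng = np.random.default_rng(3)
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        gaps = []
        for n in (100, 1000, 10000):
            counts = rng.multinomial(n, probs)
            d = ConfigDistribution(counts[counts > 0], n)
            gaps.append(corrected_entropy(d) - plugin_entropy(d))
        assert gaps[0] > gaps[1] > gaps[2] > 0

    def test_bias_dominance_over_repeated_sampling(self):
        """Mean |Hc - H| < mean |plugin - H| across 200 draws of size 50 (3 variables)."""
        rng = np.random.default_rng(11)
        probs = rng.dirichlet(np.ones(8))  # 3 binary variables -> 8 configs
        truth = exact_entropy(probs)
        err_c, err_p = [], []
        for _ in range(200):
            counts = rng.multinomial(50, probs)
            d = ConfigDistribution(counts[counts > 0], 50)
            err_c.append(abs(corrected_entropy(d) - truth))
            err_p.append(abs(plugin_entropy(d) - truth))
        assert np.mean(err_c) < np.mean(err_p)


def set_partitions(items):
    """All partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


class TestSubadditivity:
    def test_joint_entropy_below_every_partition_sum(self, rng):
        """Exact distributions on <= 5 binary variables: H(joint) <= sum of block entropies."""
        for n_vars in (3, 4, 5):
            probs = rng.dirichlet(np.ones(2**n_vars) * 0.5)
            configs = np.array(list(itertools.product([0, 1], repeat=n_vars)))
            joint = exact_entropy(probs)
            for part in set_partitions(list(range(n_vars))):
                total = 0.0
                for block in part:
                    marg = {}
                    for cfg, p in zip(map(tuple, configs[:, block]), probs):
                        marg[cfg] = marg.get(cfg, 0.0) + p
                    total += exact_entropy(list(marg.values()))
                assert joint <= total + 1e-9


def oracle_greedy(Z, L):
    """Step-by-step re-implementation of the aggregation procedure."""
    blocks = [(j,) for j in range(Z.shape[1])]

    def hc(block):
        return corrected_entropy(ConfigDistribution.from_matrix(Z[:, list(block)]))

    while True:
        candidates = []
        for h in range(len(blocks)):
            for hp in range(h + 1, len(blocks)):
                if len(blocks[h]) + len(blocks[hp]) <= L:
                    merged = tuple(sorted(blocks[h] + blocks[hp]))
                    saving = hc(blocks[h]) + hc(blocks[hp]) - hc(merged)
                    candidates.append((saving, h, hp, merged))
        if not candidates:
            return blocks
        best = max(candidates, key=lambda t: (t[0], -t[1], -t[2]))
        _, h, hp, merged = best
        blocks = [b for i, b in enumerate(blocks) if i not in (h, hp)] + [merged]


class TestGreedyPartition:
    def test_cap_one_keeps_singletons(self, rng):
        Z = rng.integers(0, 2, (20, 4))
        assert greedy_partition(Z, L=1) == [(0,), (1,), (2,), (3,)]

    def test_unbounded_cap_merges_everything(self, rng):
        Z = rng.integers(0, 2, (30, 4))
        blocks = greedy_partition(Z, L=10)
        assert blocks == [(0, 1, 2, 3)]
        est = entropy_with_ci(Z, L=10, M=5, seed=0)
        assert est.h_sum == pytest.approx(
            corrected_entropy(ConfigDistribution.from_matrix(Z))
        )

    def test_matches_step_by_step_oracle(self, rng):
        """5 variables, L=2, 30-sample fixtures: merges replay the pair-scan procedure."""
        for _ in range(10):
            Z = rng.integers(0, 2, (30, 5))
            got = sorted(greedy_partition(Z, L=2))
            expected = sorted(oracle_greedy(Z, 2))
            assert got == expected

    def test_blocks_partition_all_variables(self, rng):
        for L in (2, 3, 4):
            Z = rng.integers(0, 2, (25, 7))
            blocks = greedy_partition(Z, L=L)
            flat = sorted(j for b in blocks for j in b)
            assert flat == list(range(7))
            assert all(len(b) <= L for b in blocks)


class TestEntropyWithCI:
    def test_degenerate_all_zero_data(self):
        """A point-mass cohort keeps the small positive correction floor; CI shrinks with N."""
        widths = []
        for n in (20, 200):
            Z = np.zeros((n, 3), dtype=int)
            est = entropy_with_ci(Z, L=4, M=200, seed=1)
            single = ConfigDistribution(np.array([n]), n)
            per_var = corrected_entropy(single)
            # one block of 3 identical all-zero variables after merging
            assert est.h_sum > 0
            assert est.h_sum <= 3 * per_var + 1e-9
            widths.append(est.ci[1] - est.ci[0])
        assert widths[1] <= widths[0]

    def test_m_one_beta_half_collapses_ci(self, rng):
        Z = rng.integers(0, 2, (40, 3))
        with pytest.warns(UserWarning):
            est = entropy_with_ci(Z, L=4, M=1, beta=0.499, seed=2)
        point = est.h_sum + est.h_model - est.replicate_entropies[0]
        assert est.ci[0] == pytest.approx(point)
        assert est.ci[1] == pytest.approx(point)

    def test_seed_reproducibility(self, rng):
        Z = rng.integers(0, 2, (50, 4))
        a = entropy_with_ci(Z, L=2, M=50, seed=9)
        b = entropy_with_ci(Z, L=2, M=50, seed=9)
        assert a.ci == b.ci
        assert np.array_equal(a.replicate_entropies, b.replicate_entropies)

    def test_invalid_parameters(self, rng):
        Z = rng.integers(0, 2, (10, 2))
        with pytest.raises(ValidationError):
            entropy_with_ci(Z, M=0)
        with pytest.raises(ValidationError):
            entropy_with_ci(Z, beta=0.7)
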