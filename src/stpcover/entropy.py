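"""Cross-sample heterogeneity as bias-corrected entropy of aberration configurations.

With a covering J of m binary variables, each sample realizes one of 2^m
configurations; the Shannon entropy of the configuration distribution
measures population heterogeneity.  The plug-in estimator is badly biased
downward at the sample sizes typical of tumor cohorts, so a Grassberger-type
corrected estimator is used:

    H_c = log2(e) * sum_z (N_z / N) * [ln N - digamma(N_z) - (-1)^N_z / (N_z (N_z + 1))]

summing over observed configurations with counts N_z.  Even the corrected
estimator needs the number of jointly-estimated variables to stay small, so J
is split into blocks of at most L variables by a greedy merge that loses as
little entropy as possible; the block-entropy sum upper-bounds the joint
entropy (subadditivity).  Confidence intervals come from a parametric
bootstrap under the independent-blocks product model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .matrices import ValidationError

LOG2E = np.log2(np.e)

DEFAULT_L = 4
DEFAULT_M = 1000
DEFAULT_BETA = 0.025


@dataclass
class ConfigDistribution:
    """Empirical distribution over observed binary configurations."""

    counts: np.ndarray  # counts per distinct observed configuration
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n < 1:
            raise ValidationError("sample size must be >= 1")
        if self.counts.size == 0:
            raise ValidationError("empty distribution")
        if (self.counts <= 0).any():
            raise ValidationError("configuration counts must be positive")
        if int(self.counts.sum()) != self.n:
            raise ValidationError("counts must sum to the sample size")

    @classmethod
    def from_matrix(cls, Z: np.ndarray) -> "ConfigDistribution":
        """Count distinct rows of a samples x variables binary array."""
        Z = np.asarray(Z)
        if Z.ndim != 2 or Z.shape[0] == 0:
            raise ValidationError("need a non-empty 2-D samples x variables array")
        _, counts = np.unique(Z, axis=0, return_counts=True)
        return cls(counts, Z.shape[0])

    def probabilities(self) -> np.ndarray:
        return self.counts / self.n


def plugin_entropy(dist: ConfigDistribution) -> float:
    """Plug-in Shannon entropy in bits; 0 log 0 terms contribute 0."""
    p = dist.probabilities()
    return float(-(p * np.log2(p)).sum())


def corrected_entropy(dist: ConfigDistribution) -> float:
    """Grassberger bias-corrected entropy estimate in bits.

    The sum runs over observed configurations only; the alternating term
    (-1)^N_z / (N_z (N_z + 1)) sharpens the correction for small counts.
    """
    c = dist.counts.astype(float)
    n = float(dist.n)
    sign = np.where(dist.counts % 2 == 0, 1.0, -1.0)
    terms = (c / n) * (np.log(n) - digamma(c) - sign / (c * (c + 1.0)))
    return float(LOG2E * terms.sum())


def _block_corrected(Z: np.ndarray, block: tuple[int, ...]) -> float:
    return corrected_entropy(ConfigDistribution.from_matrix(Z[:, list(block)]))


def greedy_partition(Z: np.ndarray, L: int = DEFAULT_L) -> list[tuple[int, ...]]:
    """Partition the variables into blocks of at most L by greedy merging.

    Starting from singletons, repeatedly merge the admissible pair (A, B)
    with the largest entropy saving H_c(A) + H_c(B) - H_c(A u B); the merge
    proceeds even when the best saving is non-positive, stopping only when no
    pair fits under the size cap.  Ties pick the smallest block indices.
    Returns blocks as tuples of column indices, each internally sorted.
    """
    Z = np.asarray(Z)
    if L < 1:
        raise ValidationError(f"L must be >= 1, got {L}")
    blocks: list[tuple[int, ...]] = [(j,) for j in range(Z.shape[1])]
    ent = [_block_corrected(Z, b) for b in blocks]
    while True:
        best = None  # (saving, h, hp)
        for h in range(len(blocks)):
            for hp in range(h + 1, len(blocks)):
                if len(blocks[h]) + len(blocks[hp]) > L:
                    continue
                merged = tuple(sorted(blocks[h] + blocks[hp]))
                saving = ent[h] + ent[hp] - _block_corrected(Z, merged)
                if best is None or saving > best[0] + 1e-12:
                    best = (saving, h, hp)
        if best is None:
            return blocks
        _, h, hp = best
        merged = tuple(sorted(blocks[h] + blocks[hp]))
        new_ent = _block_corrected(Z, merged)
        for idx in (hp, h):
            del blocks[idx]
            del ent[idx]
        blocks.append(merged)
        ent.append(new_ent)


@dataclass
class EntropyEstimate:
    """Partitioned entropy estimate with product-model confidence interval."""

    blocks: list[tuple[str, ...]]
    block_entropies: list[float]
    h_sum: float  # sum of corrected block entropies (upper bound on joint H)
    h_model: float  # exact entropy of the independent-blocks product model
    ci: tuple[float, float]
    replicate_entropies: np.ndarray
    L: int
    M: int
    beta: float
    n: int


def entropy_with_ci(
    Z: np.ndarray,
    feature_ids: list[str] | None = None,
    L: int = DEFAULT_L,
    M: int = DEFAULT_M,
    beta: float = DEFAULT_BETA,
    seed: int | np.random.Generator = 0,
    repartition_replicates: bool = False,
) -> EntropyEstimate:
    """Estimate the configuration entropy of Z with a bootstrap CI.

    The variables are partitioned greedily into blocks of at most ``L``; the
    estimate ``h_sum`` is the sum of corrected block entropies.  Under the
    product model (independent blocks, empirical within-block distributions)
    ``M`` synthetic cohorts of the same size are drawn and the corrected sum
    recomputed on the fixed partition (or re-partitioned from scratch when
    ``repartition_replicates``); the CI at level 1 - 2 beta follows from the
    bootstrap quantiles of these replicates.
    """
    Z = np.asarray(Z)
    if M < 1:
        raise ValidationError(f"M must be >= 1, got {M}")
    if not 0 < beta < 0.5:
        raise ValidationError(f"beta must be in (0, 0.5), got {beta}")
    if feature_ids is None:
        feature_ids = [str(j) for j in range(Z.shape[1])]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = Z.shape[0]
    if beta * M < 1:
        import warnings

        warnings.warn("beta * M < 1: bootstrap quantiles are unstable", stacklevel=2)

    blocks = greedy_partition(Z, L=L)
    block_cols = [list(b) for b in blocks]
    block_dists = [ConfigDistribution.from_matrix(Z[:, cols]) for cols in block_cols]
    block_ent = [corrected_entropy(d) for d in block_dists]
    h_sum = float(sum(block_ent))
    h_model = float(sum(plugin_entropy(d) for d in block_dists))

    # Distinct configurations per block, for replicate sampling.
    block_configs = [np.unique(Z[:, cols], axis=0) for cols in block_cols]
    replicates = np.empty(M)
    for i in range(M):
        if repartition_replicates:
            sim = np.empty((n, Z.shape[1]), dtype=Z.dtype)
            for cols, cfgs, d in zip(block_cols, block_configs, block_dists):
                picks = rng.choice(len(cfgs), size=n, p=d.probabilities())
                sim[:, cols] = cfgs[picks]
            rep_blocks = greedy_partition(sim, L=L)
            replicates[i] = sum(_block_corrected(sim, b) for b in rep_blocks)
        else:
            total = 0.0
            for d in block_dists:
                cnt = rng.multinomial(n, d.probabilities())
                cnt = cnt[cnt > 0]
                total += corrected_entropy(ConfigDistribution(cnt, n))
            replicates[i] = total

    q_lo, q_hi = np.quantile(replicates, [beta, 1.0 - beta])
    ci = (h_sum + h_model - float(q_hi), h_sum + h_model - float(q_lo))
    named_blocks = [tuple(feature_ids[j] for j in b) for b in blocks]
    return EntropyEstimate(
        blocks=named_blocks,
        block_entropies=block_ent,
        h_sum=h_sum,
        h_model=h_model,
        ci=ci,
        replicate_entropies=replicates,
        L=L,
        M=M,
        beta=beta,
        n=n,
    )


def entropy_by_phenotype(
    matrix_values: pd.DataFrame,
    labels: dict[str, str],
    L: int = DEFAULT_L,
    M: int = DEFAULT_M,
    beta: float = DEFAULT_BETA,
    seed: int = 0,
) -> dict[str, EntropyEstimate]:
    """Entropy estimate per phenotype group (and for the pooled cohort under key "All")."""
    out: dict[str, EntropyEstimate] = {}
    feats = list(matrix_values.columns)
    out["All"] = entropy_with_ci(matrix_values.to_numpy(), feats, L=L, M=M, beta=beta, seed=seed)
    groups: dict[str, list[str]] = {}
    for s in matrix_values.index:
        if s in labels:
            groups.setdefault(labels[s], []).append(s)
    for k, (name, members) in enumerate(sorted(groups.items())):
        sub = matrix_values.loc[members]
        out[name] = entropy_with_ci(sub.to_numpy(), feats, L=L, M=M, beta=beta, seed=seed + 1 + k)
    return out
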