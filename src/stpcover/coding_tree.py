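"""Balanced binary coding trees over aberration events.

A coding tree of depth d partitions the cohort into at most 2^d terminal
bins.  Splits are unsupervised: at each node the candidate event (a single
feature, or a two-feature disjunction/conjunction) that best balances the
subtype-weighted mass of the two children is chosen, where each sample is
weighted inversely to the size of its subtype so that small subtypes count as
much as large ones.  Samples for which the event holds go to the LEFT child.
Phenotype-conditional histograms over the terminal bins can then be compared
with a label-permutation test, the tree held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .matrices import ValidationError

logger = logging.getLogger(__name__)

#: Above this many features, pair events are restricted to the most frequent ones.
PAIR_EVENT_CAP = 80


@dataclass(frozen=True)
class SplitEvent:
    """A binary splitting event: single feature, OR of two, or AND of two."""

    kind: str  # "single" | "or" | "and"
    features: tuple[str, ...]

    def evaluate(self, values: pd.DataFrame) -> np.ndarray:
        cols = [values[f].to_numpy().astype(bool) for f in self.features]
        if self.kind == "single":
            return cols[0]
        if self.kind == "or":
            return cols[0] | cols[1]
        if self.kind == "and":
            return cols[0] & cols[1]
        raise ValidationError(f"unknown event kind {self.kind!r}")

    @property
    def arity(self) -> int:
        return len(self.features)

    def __str__(self) -> str:
        op = {"single": "", "or": " OR ", "and": " AND "}[self.kind]
        return op.join(self.features) if op else self.features[0]


@dataclass
class TreeNode:
    samples: list[str]
    depth: int
    event: SplitEvent | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    bin_index: int | None = None

    @property
    def is_terminal(self) -> bool:
        return self.event is None


@dataclass
class CodingTree:
    root: TreeNode
    depth: int
    feature_ids: list[str]
    terminals: list[TreeNode] = field(default_factory=list)
    sample_bins: dict[str, int] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def assign_bin(self, row: pd.Series) -> int:
        """Terminal bin of a configuration: a deterministic function of the row."""
        node = self.root
        frame = row.to_frame().T
        while not node.is_terminal:
            node = node.left if bool(node.event.evaluate(frame)[0]) else node.right
        assert node.bin_index is not None
        return node.bin_index


def _candidate_events(feature_ids: list[str], family: str, frequencies: pd.Series) -> list[SplitEvent]:
    feats = sorted(feature_ids)
    events = [SplitEvent("single", (f,)) for f in feats]
    if family == "single":
        return events
    if family not in ("pairs_or", "pairs_and"):
        raise ValidationError(f"unknown event family {family!r}")
    pair_feats = feats
    if len(feats) > PAIR_EVENT_CAP:
        top = frequencies.loc[feats].sort_values(ascending=False).index[:PAIR_EVENT_CAP]
        pair_feats = sorted(top)
        logger.info("coding tree: pair events limited to top %d features by frequency", PAIR_EVENT_CAP)
    kind = "or" if family == "pairs_or" else "and"
    events += [SplitEvent(kind, pair) for pair in combinations(pair_feats, 2)]
    return events


def _best_event(
    values: pd.DataFrame, samples: list[str], events: list[SplitEvent], weights: dict[str, float]
) -> tuple[SplitEvent | None, np.ndarray | None]:
    """The candidate minimizing |weight(left) - weight(right)|, or None if all are degenerate.

    Candidates are scanned in (arity, feature names) order and a strict
    improvement is required to displace the incumbent, which implements the
    documented tie-break.
    """
    sub = values.loc[samples]
    w = np.array([weights[s] for s in samples])
    best: tuple[float, SplitEvent, np.ndarray] | None = None
    for ev in sorted(events, key=lambda e: (e.arity, e.features)):
        mask = ev.evaluate(sub)
        if mask.all() or not mask.any():
            continue  # degenerate split
        imbalance = abs(w[mask].sum() - w[~mask].sum())
        if best is None or imbalance < best[0] - 1e-12:
            best = (imbalance, ev, mask)
    if best is None:
        return None, None
    return best[1], best[2]


def build_coding_tree(
    values: pd.DataFrame,
    labels: dict[str, str],
    d: int = 5,
    event_family: str = "single",
    on_unlabeled: str = "error",
) -> CodingTree:
    """Grow a depth-d balanced coding tree on a samples x features binary table.

    Sample weights are inversely proportional to global subtype size.  A node
    stops splitting when all its samples share one configuration, no candidate
    event separates them, or depth ``d`` is reached.
    """
    if d < 1:
        raise ValidationError(f"depth must be >= 1, got {d}")
    unlabeled = [s for s in values.index if s not in labels]
    if unlabeled:
        if on_unlabeled == "error":
            raise ValidationError(f"unlabeled samples: {unlabeled[:10]}")
        if on_unlabeled != "drop":
            raise ValidationError("on_unlabeled must be 'error' or 'drop'")
        logger.warning("dropping %d unlabeled samples", len(unlabeled))
        values = values.drop(index=unlabeled)
    present = {labels[s] for s in values.index}
    if len(present) < 2:
        raise ValidationError("need at least 2 phenotype labels among the samples")
    sizes: dict[str, int] = {}
    for s in values.index:
        sizes[labels[s]] = sizes.get(labels[s], 0) + 1
    weights = {s: 1.0 / sizes[labels[s]] for s in values.index}
    events = _candidate_events(list(values.columns), event_family, values.mean(axis=0))

    root = TreeNode(samples=list(values.index), depth=0)
    stack = [root]
    while stack:
        node = stack.pop()
        sub = values.loc[node.samples]
        if node.depth >= d or len(node.samples) < 2 or (sub.nunique(axis=0) <= 1).all():
            continue
        ev, mask = _best_event(values, node.samples, events, weights)
        if ev is None:
            continue
        node.event = ev
        left_samples = [s for s, m in zip(node.samples, mask) if m]
        right_samples = [s for s, m in zip(node.samples, mask) if not m]
        node.left = TreeNode(samples=left_samples, depth=node.depth + 1)
        node.right = TreeNode(samples=right_samples, depth=node.depth + 1)
        stack.append(node.right)
        stack.append(node.left)

    tree = CodingTree(root=root, depth=d, feature_ids=list(values.columns), weights=weights)
    # Index terminals left-to-right and record each sample's bin.
    def _collect(node: TreeNode) -> None:
        if node.is_terminal:
            node.bin_index = len(tree.terminals)
            tree.terminals.append(node)
            for s in node.samples:
                tree.sample_bins[s] = node.bin_index
        else:
            _collect(node.left)
            _collect(node.right)

    _collect(root)
    return tree


def subtype_histograms(tree: CodingTree, labels: dict[str, str]) -> pd.DataFrame:
    """Unweighted per-phenotype sample counts over the terminal bins."""
    phenos = sorted({labels[s] for s in tree.sample_bins})
    n_bins = len(tree.terminals)
    hist = pd.DataFrame(0, index=phenos, columns=range(n_bins))
    for s, b in tree.sample_bins.items():
        hist.loc[labels[s], b] += 1
    return hist


def _chi2_distance(hist: pd.DataFrame) -> float:
    """Chi-square statistic between phenotype-conditional bin distributions (pooled expected)."""
    obs = hist.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    return float(cells.sum())


def _tv_distance(hist: pd.DataFrame) -> float:
    """Total-variation distance between two phenotype-conditional bin distributions."""
    if hist.shape[0] != 2:
        raise ValidationError("total-variation statistic requires exactly 2 phenotypes")
    p = hist.to_numpy(dtype=float)
    p = p / p.sum(axis=1, keepdims=True)
    return float(0.5 * np.abs(p[0] - p[1]).sum())


def histogram_permutation_test(
    tree: CodingTree,
    labels: dict[str, str],
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    statistic: str = "chi2",
) -> tuple[float, float]:
    """Permutation p-value for a phenotype difference in terminal-bin distributions.

    The tree (hence each sample's bin) stays fixed; phenotype labels are
    permuted across samples.  Returns (observed statistic, p) with the
    add-one estimate p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100: p-value resolution is coarse", stacklevel=2)
    stat_fn = {"chi2": _chi2_distance, "tv": _tv_distance}.get(statistic)
    if stat_fn is None:
        raise ValidationError(f"unknown statistic {statistic!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = sorted(tree.sample_bins)
    bins = np.array([tree.sample_bins[s] for s in samples])
    labs = np.array([labels[s] for s in samples])
    phenos = sorted(set(labs))
    n_bins = len(tree.terminals)

    def hist_of(lab_arr: np.ndarray) -> pd.DataFrame:
        h = pd.DataFrame(0, index=phenos, columns=range(n_bins))
        for ph in phenos:
            idx, cnt = np.unique(bins[lab_arr == ph], return_counts=True)
            h.loc[ph, idx] = cnt
        return h

    observed = stat_fn(hist_of(labs))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labs)
        if stat_fn(hist_of(perm)) >= observed - 1e-12:
            exceed += 1
    return observed, (1 + exceed) / (1 + n_perm)
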