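"""Source-target pair (STP) catalog over a directed regulatory network.

An STP (g_s => g_t) exists when some directed chain of at most ``k_max`` links
leads from g_s to g_t, where intermediate links may either control a state
change or control expression, but the *final* link must control the target's
expression.  The catalog is a network property, independent of any cohort.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

from .matrices import PAIR_SEP, ValidationError

logger = logging.getLogger(__name__)

STATE = "state_change"
EXPR = "expression_control"
KINDS = (STATE, EXPR)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    kind: str


@dataclass
class InteractionNetwork:
    """Directed gene-gene interactions of two kinds.

    Edges are a set of (regulator, target, kind) triples with kind in
    {``state_change``, ``expression_control``}; parallel edges of the two
    kinds between the same gene pair are allowed and act as alternative links.
    """

    edges: set[Edge] = field(default_factory=set)

    def add(self, source: str, target: str, kind: str) -> None:
        if kind not in KINDS:
            raise ValidationError(f"unknown interaction kind {kind!r}")
        if not source or not target:
            raise ValidationError("gene ids must be non-empty strings")
        self.edges.add(Edge(source, target, kind))

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.source)
            out.add(e.target)
        return out

    def successors(self) -> dict[str, list[str]]:
        """Sorted any-kind adjacency (duplicate kinds collapsed)."""
        adj: dict[str, set[str]] = {}
        for e in self.edges:
            adj.setdefault(e.source, set()).add(e.target)
        return {u: sorted(vs) for u, vs in adj.items()}

    def expr_parents(self) -> dict[str, list[str]]:
        """For each gene, the sorted regulators linked to it by an expression-control edge."""
        par: dict[str, set[str]] = {}
        for e in self.edges:
            if e.kind == EXPR:
                par.setdefault(e.target, set()).add(e.source)
        return {t: sorted(us) for t, us in par.items()}


@dataclass(frozen=True)
class STP:
    """One source-target pair with its minimal chain length and a witness path."""

    source: str
    target: str
    length: int
    witness_path: tuple[str, ...]

    @property
    def pair_id(self) -> str:
        return f"{self.source}{PAIR_SEP}{self.target}"


@dataclass
class STPCatalog:
    """The set of STPs of length <= k_max, with source/target indexes."""

    pairs: dict[tuple[str, str], STP]
    k_max: int

    @property
    def sources(self) -> set[str]:
        return {s for s, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}

    def targets_of(self, g: str) -> set[str]:
        return {t for s, t in self.pairs if s == g}

    def sources_of(self, g: str) -> set[str]:
        return {s for s, t in self.pairs if t == g}

    def pair_ids(self) -> list[str]:
        return [self.pairs[k].pair_id for k in sorted(self.pairs)]

    def subset(self, keep: set[tuple[str, str]]) -> "STPCatalog":
        return STPCatalog({k: v for k, v in self.pairs.items() if k in keep}, self.k_max)

    def __len__(self) -> int:
        return len(self.pairs)


def _bfs_lex(adj: dict[str, list[str]], start: str, depth_cap: int) -> dict[str, tuple[int, tuple[str, ...]]]:
    """Bounded BFS returning, per reachable node, (distance, lex-smallest shortest path).

    The queue is expanded in lexicographic path order with sorted adjacency,
    so the first discovery of a node is along the lexicographically smallest
    among its shortest paths.  ``start`` itself is included at distance 0.
    """
    found: dict[str, tuple[int, tuple[str, ...]]] = {start: (0, (start,))}
    queue: deque[str] = deque([start])
    while queue:
        u = queue.popleft()
        d, path = found[u]
        if d >= depth_cap:
            continue
        for v in adj.get(u, ()):
            if v not in found:
                found[v] = (d + 1, path + (v,))
                queue.append(v)
    return found


def build_stp_catalog(network: InteractionNetwork, k_max: int = 3) -> STPCatalog:
    """Enumerate all STPs of length at most ``k_max``.

    For each candidate source, a breadth-first search bounded at ``k_max - 1``
    links finds the shortest any-kind chain to each reachable gene; appending
    an expression-control edge to a downstream gene closes an STP.  The
    recorded length is the minimal total number of links; ties pick the
    lexicographically smallest witness path.  Self-pairs arising from cycles
    are kept: the formal definition admits them.
    """
    if k_max < 1:
        raise ValidationError(f"k_max must be >= 1, got {k_max}")
    adj = network.successors()
    expr_par = network.expr_parents()
    pairs: dict[tuple[str, str], STP] = {}
    for src in sorted(network.nodes):
        reach = _bfs_lex(adj, src, k_max - 1)
        # Close each chain with an expression-control edge into the target.
        best: dict[str, tuple[int, tuple[str, ...]]] = {}
        for tgt, parents in expr_par.items():
            for u in parents:
                if u in reach:
                    d, path = reach[u]
                    cand = (d + 1, path + (tgt,))
                    if tgt not in best or cand < best[tgt]:
                        best[tgt] = cand
        for tgt, (length, path) in best.items():
            pairs[(src, tgt)] = STP(src, tgt, length, path)
    return STPCatalog(pairs, k_max)


def catalog_stats(catalog: STPCatalog) -> tuple[int, int, int]:
    """(number of pairs, number of distinct sources, number of distinct targets)."""
    return len(catalog), len(catalog.sources), len(catalog.targets)
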