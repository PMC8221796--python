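"""Pair-level aberration variables and the association/frequency filters.

A pair variable Z for the STP (g_s => g_t) is the product of the source's DNA
call and the target's RNA call, so Z = 1 exactly when both ends are aberrant
in the same sample.  The tissue-specific catalog keeps only pairs whose
DNA/RNA events are dependent (Pearson chi-square at a configurable level, no
multiple-testing correction), and rare features are removed at each level by
a minimum-frequency filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .catalog import STPCatalog
from .matrices import PAIR_SEP, BinaryAberrationMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CHI2_LEVEL = 0.05
DEFAULT_MIN_FREQ = 0.02


@dataclass
class FilterReport:
    """Per-pair contingency counts, test results and the thresholds applied."""

    table: pd.DataFrame  # columns: source, target, n11, n10, n01, n00, chi2, p, kept
    level: float

    def kept_pairs(self) -> set[tuple[str, str]]:
        k = self.table[self.table["kept"]]
        return set(zip(k["source"], k["target"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _aligned(dna: BinaryAberrationMatrix, rna: BinaryAberrationMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    if list(dna.values.index) != list(rna.values.index):
        raise ValidationError("DNA and RNA matrices must share the sample axis")
    return dna.values, rna.values


def compute_pair_matrix(
    dna: BinaryAberrationMatrix, rna: BinaryAberrationMatrix, catalog: STPCatalog
) -> BinaryAberrationMatrix:
    """Z(pair, sample) = X_dna(source) * X_rna(target), samples x pairs.

    Pairs whose source is absent from the DNA matrix or whose target is absent
    from the RNA matrix are dropped with a logged count.
    """
    dv, rv = _aligned(dna, rna)
    cols: dict[str, np.ndarray] = {}
    dropped = 0
    for (s, t) in sorted(catalog.pairs):
        if s not in dv.columns or t not in rv.columns:
            dropped += 1
            continue
        cols[f"{s}{PAIR_SEP}{t}"] = dv[s].to_numpy() * rv[t].to_numpy()
    if dropped:
        logger.warning("compute_pair_matrix: dropped %d pairs with genes missing from matrices", dropped)
    values = pd.DataFrame(cols, index=dv.index, dtype=np.int8)
    return BinaryAberrationMatrix(values, "stp_pair")


def pearson_chi2_2x2(n11: int, n10: int, n01: int, n00: int, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (1 df) for a 2x2 table.

    Uses the closed form N(ad - bc)^2 / (r1 r2 c1 c2); with ``correction``
    the Yates continuity adjustment |ad - bc| - N/2 (floored at 0) is applied.
    Degenerate tables (a zero margin) return (nan, 1.0).
    """
    n = n11 + n10 + n01 + n00
    r1, r2 = n11 + n10, n01 + n00
    c1, c2 = n11 + n01, n10 + n00
    if min(r1, r2, c1, c2) == 0:
        return float("nan"), 1.0
    det = n11 * n00 - n10 * n01
    if correction:
        det = max(abs(det) - n / 2.0, 0.0)
    stat = n * float(det) ** 2 / (float(r1) * r2 * c1 * c2)
    p = float(chi2_dist.sf(stat, 1))
    return stat, p


def chi2_independence_filter(
    dna: BinaryAberrationMatrix,
    rna: BinaryAberrationMatrix,
    catalog: STPCatalog,
    level: float = DEFAULT_CHI2_LEVEL,
    correction: bool = False,
    positive_only: bool = False,
) -> tuple[STPCatalog, FilterReport]:
    """Keep STPs whose source-DNA / target-RNA events are dependent.

    For each pair the 2x2 table of (source DNA-aberrant, target RNA-aberrant)
    is built over the tumor samples; the pair is kept iff the Pearson
    chi-square test rejects independence at ``level``.  Tables with any zero
    margin carry no signal and are dropped.  With ``positive_only`` pairs kept
    must additionally be positively associated (observed joint above expected).
    """
    if not 0 < level < 1:
        raise ValidationError(f"significance level must be in (0,1), got {level}")
    dv, rv = _aligned(dna, rna)
    n = len(dv.index)
    if n < 2:
        raise ValidationError("need at least 2 samples for the chi-square filter")
    rows = []
    for (s, t) in sorted(catalog.pairs):
        if s not in dv.columns or t not in rv.columns:
            continue
        x = dv[s].to_numpy().astype(bool)
        y = rv[t].to_numpy().astype(bool)
        n11 = int((x & y).sum())
        n10 = int((x & ~y).sum())
        n01 = int((~x & y).sum())
        n00 = n - n11 - n10 - n01
        stat, p = pearson_chi2_2x2(n11, n10, n01, n00, correction=correction)
        kept = bool(np.isfinite(stat) and p < level)
        if kept and positive_only:
            expected = (n11 + n10) * (n11 + n01) / n
            kept = n11 > expected
        rows.append((s, t, n11, n10, n01, n00, stat, p, kept))
    table = pd.DataFrame(
        rows, columns=["source", "target", "n11", "n10", "n01", "n00", "chi2", "p", "kept"]
    )
    report = FilterReport(table, level)
    return catalog.subset(report.kept_pairs()), report


def frequency_filter(matrix: BinaryAberrationMatrix, min_freq: float = DEFAULT_MIN_FREQ) -> BinaryAberrationMatrix:
    """Drop features aberrant in fewer than ``min_freq`` of the samples.

    The boundary is inclusive: a feature at exactly the threshold is kept.
    Column order is preserved.
    """
    if not 0 <= min_freq <= 1:
        raise ValidationError(f"min_freq must be in [0,1], got {min_freq}")
    freqs = matrix.frequencies()
    keep = [f for f in matrix.feature_ids if freqs[f] >= min_freq]
    return matrix.subset_features(keep)


def collapse_level(pairs: BinaryAberrationMatrix, catalog: STPCatalog, level: str) -> BinaryAberrationMatrix:
    """Collapse pair variables to source- or target-level events.

    ``level="source"``: feature g is the OR over all pairs with source g — the
    event "g is DNA-aberrant with at least one RNA-aberrant target".
    ``level="target"``: the OR over pairs with target g — "g is RNA-aberrant
    with at least one DNA-aberrant upstream source".
    """
    if pairs.level != "stp_pair":
        raise ValidationError("collapse_level expects a pair-level matrix")
    if level not in ("source", "target"):
        raise ValidationError(f"level must be 'source' or 'target', got {level!r}")
    idx = 0 if level == "source" else 1
    groups: dict[str, list[str]] = {}
    for fid in pairs.feature_ids:
        s, t = fid.split(PAIR_SEP)
        groups.setdefault((s, t)[idx], []).append(fid)
    cols = {g: pairs.values[members].max(axis=1) for g, members in sorted(groups.items())}
    values = pd.DataFrame(cols, index=pairs.values.index, dtype=np.int8)
    tag = "source_with_target" if level == "source" else "target_with_source"
    return BinaryAberrationMatrix(values, tag)
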