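"""Binarization of DNA and RNA data into per-gene aberration calls.

DNA side: a gene is aberrant in a sample when it carries a non-synonymous
somatic mutation or an extreme copy-number state (homozygous deletion, -2, or
a two-copy gain, +2).  Heterozygous deletions and single-copy gains are
deliberately excluded: their functional impact is ambiguous.

RNA side: a gene is aberrant ("divergent") when its within-sample expression
rank falls outside the normal range of that rank estimated from baseline
(normal tissue) samples.  The call for a tumor sample depends only on that
sample's profile and the fitted baseline model, never on other tumor samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrices import BinaryAberrationMatrix, OmicsBundle, ValidationError

#: Default tail mass on each side of the normal rank interval.
DEFAULT_Q = 0.025

#: MAF variant classifications treated as non-synonymous by default.
DEFAULT_KEPT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


def fractional_ranks(expression: pd.DataFrame) -> pd.DataFrame:
    """Within-sample fractional ranks of each gene, in [0, 1].

    For each column (sample) the genes are ranked by expression with average
    ties, and the rank is normalized to ``(rank - 1) / (G - 1)`` so the lowest
    expressed gene sits at 0 and the highest at 1.
    """
    if expression.isna().any().any():
        raise ValidationError("expression contains NaN values")
    g = expression.shape[0]
    if g < 2:
        raise ValidationError("need at least 2 genes to rank")
    ranks = rankdata(expression.to_numpy(), axis=0, method="average")
    return pd.DataFrame((ranks - 1.0) / (g - 1.0), index=expression.index, columns=expression.columns)


@dataclass
class RnaBaselineModel:
    """Per-gene normal interval on the within-sample rank scale.

    ``lower`` and ``upper`` are the q and 1-q quantiles, across baseline
    samples, of each gene's fractional rank.  A rank exactly equal to an
    endpoint is considered inside the normal range (closed interval), so with
    q=0 a baseline sample is never called aberrant.
    """

    lower: pd.Series
    upper: pd.Series
    q: float

    def __post_init__(self) -> None:
        if not self.lower.index.equals(self.upper.index):
            raise ValidationError("lower/upper bounds must share the gene axis")
        if (self.lower > self.upper).any():
            raise ValidationError("lower bound exceeds upper bound for some gene")
        for s in (self.lower, self.upper):
            if ((s < 0) | (s > 1)).any():
                raise ValidationError("rank bounds must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.lower.index)


def call_dna_aberrations(mutation: pd.DataFrame, copy_number: pd.DataFrame) -> BinaryAberrationMatrix:
    """Binary DNA aberration calls: mutation OR extreme copy number.

    ``X_dna(g, w) = 1`` iff the gene is mutated or its copy-number code is -2
    (homozygous deletion) or +2 (two-copy gain).  Codes -1 and +1 contribute 0.
    Returns a samples x genes matrix (level ``dna_gene``).
    """
    if not mutation.index.equals(copy_number.index) or not mutation.columns.equals(copy_number.columns):
        raise ValidationError("mutation and copy_number must share gene and sample axes")
    cn = copy_number.to_numpy()
    if cn.size and not np.isin(cn, (-2, -1, 0, 1, 2)).all():
        raise ValidationError("copy-number codes must be in {-2,-1,0,+1,+2}")
    calls = (mutation.to_numpy().astype(bool) | (np.abs(cn) == 2)).astype(np.int8)
    values = pd.DataFrame(calls.T, index=mutation.columns, columns=mutation.index)
    return BinaryAberrationMatrix(values, "dna_gene")


def fit_rna_baseline(baseline_expression: pd.DataFrame, q: float = DEFAULT_Q) -> RnaBaselineModel:
    """Estimate the per-gene normal rank interval from baseline samples.

    Each gene's fractional ranks across the baseline samples are summarized by
    their q and 1-q quantiles (linear interpolation).  ``q=0`` yields the full
    observed range [min, max].
    """
    if not 0 <= q < 0.5:
        raise ValidationError(f"q must be in [0, 0.5), got {q}")
    if baseline_expression.shape[1] < 2:
        raise ValidationError("at least 2 baseline samples are required")
    ranks = fractional_ranks(baseline_expression)
    arr = ranks.to_numpy()
    lower = np.quantile(arr, q, axis=1)
    upper = np.quantile(arr, 1.0 - q, axis=1)
    genes = baseline_expression.index
    return RnaBaselineModel(pd.Series(lower, index=genes), pd.Series(upper, index=genes), q)


def call_rna_aberrations(tumor_expression: pd.DataFrame, model: RnaBaselineModel) -> BinaryAberrationMatrix:
    """Binary RNA divergence calls against a fitted baseline model.

    A gene is aberrant in a sample iff its within-sample fractional rank is
    strictly below the model's lower bound or strictly above the upper bound.
    Ranks are computed over the genes present in ``tumor_expression``, which
    must all be covered by the model.
    """
    missing = [g for g in tumor_expression.index if g not in model.lower.index]
    if missing:
        raise ValidationError(f"genes missing from baseline model: {missing[:10]}")
    ranks = fractional_ranks(tumor_expression)
    lo = model.lower.loc[tumor_expression.index].to_numpy()[:, None]
    hi = model.upper.loc[tumor_expression.index].to_numpy()[:, None]
    arr = ranks.to_numpy()
    calls = ((arr < lo) | (arr > hi)).astype(np.int8)
    values = pd.DataFrame(calls.T, index=tumor_expression.columns, columns=tumor_expression.index)
    return BinaryAberrationMatrix(values, "rna_gene")


def collapse_maf(
    maf: pd.DataFrame,
    genes: list[str],
    samples: list[str],
    kept_classes: frozenset[str] = DEFAULT_KEPT_CLASSES,
) -> pd.DataFrame:
    """Collapse a minimal MAF-like table to a gene x sample mutation indicator.

    Requires columns ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
    ``Variant_Classification``; rows whose classification is not in
    ``kept_classes`` are dropped.  Genes/samples absent from the MAF get 0.
    """
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    if not required.issubset(maf.columns):
        raise ValidationError(f"MAF table missing columns: {sorted(required - set(maf.columns))}")
    kept = maf[maf["Variant_Classification"].isin(kept_classes)]
    out = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=samples, dtype=np.int8)
    for g, s in zip(kept["Hugo_Symbol"], kept["Tumor_Sample_Barcode"]):
        if g in out.index and s in out.columns:
            out.loc[g, s] = 1
    return out


def call_aberrations(bundle: OmicsBundle, q: float = DEFAULT_Q) -> tuple[BinaryAberrationMatrix, BinaryAberrationMatrix]:
    """Run both callers on a matched bundle; returns (dna, rna) matrices."""
    dna = call_dna_aberrations(bundle.mutation, bundle.copy_number)
    model = fit_rna_baseline(bundle.baseline_expression, q=q)
    rna = call_rna_aberrations(bundle.tumor_expression, model)
    return dna, rna
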