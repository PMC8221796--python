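"""Core data containers for binary aberration analysis.

The central object is :class:`BinaryAberrationMatrix`, a samples x features
0/1 table tagged with the level of the features it holds: per-gene DNA or RNA
calls, per-pair source-target aberrations, or the collapsed source/target
level events.  :class:`OmicsBundle` groups the matched raw inputs (mutations,
copy number, expression) that the callers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Feature levels a BinaryAberrationMatrix can carry.
LEVELS = ("dna_gene", "rna_gene", "stp_pair", "source_with_target", "target_with_source")

#: Separator used in pair feature identifiers, e.g. ``"TP53=>MYBL2"``.
PAIR_SEP = "=>"

#: Admissible GISTIC-style copy-number codes.
CN_CODES = (-2, -1, 0, 1, 2)


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated {what}: {dups[:5]}")


@dataclass
class BinaryAberrationMatrix:
    """A samples x features binary matrix at one aberration level.

    Parameters
    ----------
    values
        DataFrame with samples as rows and features as columns; entries in {0, 1}.
    level
        One of :data:`LEVELS`; pair-level feature ids must contain exactly one
        ``"=>"``, gene-level ids must contain none.
    """

    values: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "feature ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = np.unique(arr[~np.isin(arr, (0, 1))])
            raise ValidationError(f"non-binary entries: {bad[:5]}")
        pairish = self.level in ("stp_pair",)
        for fid in self.values.columns:
            n_sep = str(fid).count(PAIR_SEP)
            if pairish and n_sep != 1:
                raise ValidationError(f"pair feature id {fid!r} must contain exactly one '=>'")
            if not pairish and n_sep != 0:
                raise ValidationError(f"gene-level feature id {fid!r} must not contain '=>'")
        self.values = self.values.astype(np.int8)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def frequencies(self) -> pd.Series:
        """Per-feature aberration frequency (column mean)."""
        return self.values.mean(axis=0)

    def subset_features(self, keep: list[str]) -> "BinaryAberrationMatrix":
        return BinaryAberrationMatrix(self.values.loc[:, keep], self.level)

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.values.shape
        return f"BinaryAberrationMatrix(level={self.level!r}, samples={n}, features={m})"


@dataclass
class OmicsBundle:
    """Matched mutation, copy-number, and expression data for one cohort.

    All gene x sample tables share the gene axis; the tumor-side tables share
    the sample axis.  ``baseline_expression`` holds the normal-tissue samples
    used to fit the RNA divergence model and has its own sample axis.
    """

    mutation: pd.DataFrame
    copy_number: pd.DataFrame
    tumor_expression: pd.DataFrame
    baseline_expression: pd.DataFrame
    phenotype_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = self.mutation.index
        for name, df in (
            ("copy_number", self.copy_number),
            ("tumor_expression", self.tumor_expression),
            ("baseline_expression", self.baseline_expression),
        ):
            _check_unique(df.index, f"{name} gene ids")
            if not df.index.equals(genes):
                raise ValidationError(f"{name} gene axis differs from mutation gene axis")
        _check_unique(self.mutation.columns, "tumor sample ids")
        for name, df in (("copy_number", self.copy_number), ("tumor_expression", self.tumor_expression)):
            if not df.columns.equals(self.mutation.columns):
                raise ValidationError(f"{name} sample axis differs from mutation sample axis")
        cn = self.copy_number.to_numpy()
        if cn.size and not np.isin(cn, CN_CODES).all():
            bad = np.unique(cn[~np.isin(cn, CN_CODES)])
            raise ValidationError(f"copy-number codes outside {CN_CODES}: {bad[:5]}")
        mut = self.mutation.to_numpy()
        if mut.size and not np.isin(mut, (0, 1)).all():
            raise ValidationError("mutation table must be binary")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mutation.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mutation.columns)
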