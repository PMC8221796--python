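"""Sample-based aberration probabilities and the identities linking them.

For an STP (g => g') over a cohort the quantities of interest are the joint
probability P(DNA & RNA) that the source is DNA-aberrant and the target
RNA-aberrant in the same sample, the two marginals P(DNA), P(RNA), and the
two conditionals; they satisfy P(DNA & RNA) = P(DNA) * P(RNA | DNA)
= P(RNA) * P(DNA | RNA).  The same identities hold at source level with the
event "some downstream target RNA-aberrant" and at target level with "some
upstream source DNA-aberrant".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import BinaryAberrationMatrix, ValidationError


def reconstruct_joint(p_marginal: float, p_conditional: float, decimals: int = 3) -> float:
    """Joint probability from a marginal and the matching conditional.

    ``P(A & B) = P(A) * P(B | A)``, rounded to ``decimals`` places (the
    precision at which such probabilities are conventionally reported).
    """
    for name, p in (("p_marginal", p_marginal), ("p_conditional", p_conditional)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {p}")
    return round(p_marginal * p_conditional, decimals)


def pair_probability_table(dna: BinaryAberrationMatrix, rna: BinaryAberrationMatrix, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Empirical P(DNA&RNA), marginals and conditionals for the given pairs.

    Conditionals are NaN when the conditioning event never occurs.
    """
    if list(dna.values.index) != list(rna.values.index):
        raise ValidationError("DNA and RNA matrices must share the sample axis")
    rows = []
    for s, t in pairs:
        x = dna.values[s].to_numpy().astype(bool)
        y = rna.values[t].to_numpy().astype(bool)
        p_dna = float(x.mean())
        p_rna = float(y.mean())
        p_joint = float((x & y).mean())
        rows.append(
            {
                "source": s,
                "target": t,
                "p_dna_and_rna": p_joint,
                "p_dna": p_dna,
                "p_rna": p_rna,
                "p_rna_given_dna": p_joint / p_dna if p_dna > 0 else np.nan,
                "p_dna_given_rna": p_joint / p_rna if p_rna > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def marginal_conditional_table(collapsed: BinaryAberrationMatrix, marginal: BinaryAberrationMatrix) -> pd.DataFrame:
    """Source- or target-level joint/marginal/conditional summary.

    ``collapsed`` holds the with-partner events (e.g. DNA-aberrant source with
    some RNA-aberrant target); ``marginal`` holds the plain per-gene calls the
    conditioning is on (DNA calls at source level, RNA calls at target level).
    """
    rows = []
    for g in collapsed.feature_ids:
        z = collapsed.values[g].to_numpy().astype(bool)
        x = marginal.values[g].to_numpy().astype(bool)
        p_joint = float(z.mean())
        p_marg = float(x.mean())
        rows.append(
            {
                "gene": g,
                "p_joint": p_joint,
                "p_marginal": p_marg,
                "p_conditional": p_joint / p_marg if p_marg > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
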