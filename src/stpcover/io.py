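"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as TSV with genes (or features) as rows and samples as
columns, first column holding the row id; ``.gz`` paths are handled
transparently.  Networks use the extended SIF dialect: three tab-separated
columns PARTICIPANT_A, INTERACTION_TYPE, PARTICIPANT_B, with the types
``controls-state-change-of`` and ``controls-expression-of`` recognized and
all other rows skipped (counted in the log).
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import EXPR, STATE, InteractionNetwork
from .matrices import BinaryAberrationMatrix, ValidationError

logger = logging.getLogger(__name__)

SIF_TYPES = {"controls-state-change-of": STATE, "controls-expression-of": EXPR}


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix; validates header and id uniqueness."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.size == 0:
        raise ValidationError(f"{path}: no sample columns found (malformed header?)")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated row ids {dup[:5]}")
    if df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicated sample columns")
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_binary_matrix(path, level: str) -> BinaryAberrationMatrix:
    """Read a features x samples binary TSV into a samples x features matrix."""
    df = read_matrix_tsv(path)
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(f"{path}: non-binary cell at row {df.index[r]!r} (line {r + 2})")
    return BinaryAberrationMatrix(df.T, level)


def write_binary_matrix(matrix: BinaryAberrationMatrix, path) -> None:
    """Write features x samples (transposed back to the gene-rows convention)."""
    write_matrix_tsv(matrix.values.T, path)


def read_labels_tsv(path) -> dict[str, str]:
    """Two-column sample -> phenotype TSV (header required)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (sample, phenotype)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_labels_tsv(labels: dict[str, str], path) -> None:
    pd.DataFrame({"sample": list(labels), "phenotype": list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_sif(path) -> InteractionNetwork:
    """Parse an extended SIF file into an interaction network."""
    net = InteractionNetwork()
    opener = gzip.open if str(path).endswith(".gz") else open
    skipped = 0
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 tab-separated columns")
            a, kind, b = parts[0], parts[1], parts[2]
            if kind == "INTERACTION_TYPE":  # header row
                continue
            if kind not in SIF_TYPES:
                skipped += 1
                continue
            net.add(a, b, SIF_TYPES[kind])
    if skipped:
        logger.info("read_sif: skipped %d rows with unrecognized interaction types", skipped)
    return net


def write_sif(net: InteractionNetwork, path) -> None:
    inv = {v: k for k, v in SIF_TYPES.items()}
    with open(path, "w") as fh:
        fh.write("PARTICIPANT_A\tINTERACTION_TYPE\tPARTICIPANT_B\n")
        for e in sorted(net.edges, key=lambda e: (e.source, e.target, e.kind)):
            fh.write(f"{e.source}\t{inv[e.kind]}\t{e.target}\n")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults."""

    k_max: int = 3
    q: float = 0.025
    chi2_level: float = 0.05
    min_freq: float = 0.02
    r_pair: int = 1
    r_source: int = 1
    r_target: int = 3
    alpha_policy: str = "alpha_star"  # or "fixed"
    alpha_fixed: float = 0.0
    L: int = 4
    M: int = 1000
    beta: float = 0.025
    d: int = 5
    max_solutions: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_policy not in ("alpha_star", "fixed"):
            raise ValidationError(f"alpha_policy must be 'alpha_star' or 'fixed', got {self.alpha_policy!r}")

    def r_for(self, level: str) -> int:
        return {"pair": self.r_pair, "source": self.r_source, "target": self.r_target}[level]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_covering_report(path, level: str, problem, best, ensemble) -> None:
    """JSON covering report: settings, optimum, solutions, core/union membership."""
    payload = {
        "level": level,
        "r": problem.r,
        "alpha": problem.alpha,
        "n_samples": problem.n_samples,
        "n_features": len(problem.feature_ids),
        "optimum": best.objective,
        "covered_fraction": best.covered_fraction,
        "selected": best.selected,
        "core": ensemble.J_core,
        "union": ensemble.J_all,
        "n_solutions_enumerated": len(ensemble.solutions),
        "enumeration_exhausted": ensemble.exhausted,
        "representative": ensemble.representative.selected if ensemble.representative else None,
        "undetermined": ensemble.undetermined,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_signature_tsv(path, level: str, ensemble, frequencies: pd.Series) -> None:
    """Gene/pair list per level, features sorted by (frequency desc, name asc)."""
    feats = sorted(ensemble.J_all, key=lambda f: (-float(frequencies.get(f, 0.0)), f))
    rows = [
        {
            "feature": f,
            "level": level,
            "frequency": float(frequencies.get(f, np.nan)),
            "in_core": f in set(ensemble.J_core),
        }
        for f in feats
    ]
    pd.DataFrame(rows, columns=["feature", "level", "frequency", "in_core"]).to_csv(
        path, sep="\t", index=False
    )
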