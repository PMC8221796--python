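"""Synthetic matched cohorts and networks with planted source-target structure.

The generator plants a set of source-target pairs with known marginal DNA
aberration probability p_dna and conditional RNA aberration probability
p_rna_given_dna, embeds them (with optional intermediate chains) in a random
directed interaction network, and emits a matched bundle of mutation,
copy-number, tumor-expression and baseline-expression tables whose
rank-divergence calls recover the planted binary states.

Expression design.  Gene values live in disjoint zones.  Most genes sit at
fixed, well-separated levels with tiny jitter, so their within-sample ranks
are stable.  Target genes of planted/decoy pairs are drawn uniformly across a
"crowd" zone densely filled with filler genes; their baseline rank interval is
therefore wide.  In tumor samples a non-aberrant target is drawn from the
central 60% of the zone — safely inside the baseline interval even after the
small rank displacement caused by other targets going aberrant — while an
aberrant target is placed in a "sky" zone above every other gene, far outside
any baseline interval.  This makes the rank-based caller reproduce the
intended binary RNA states with high fidelity, by construction.

With ``guarantee_coverage`` each sample is assigned one planted pair that is
forced aberrant (so the planted set covers every sample), and the first few
samples of each assignment block are kept "private": no other feature is
aberrant there, making every planted pair necessary in any covering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import EXPR, STATE, InteractionNetwork
from .matrices import PAIR_SEP, OmicsBundle, ValidationError

# Expression zone layout (arbitrary units; only ranks matter downstream).
_LOW_BASE = 1_000.0
_LOW_STEP = 10.0
_CROWD_BASE = 50_000.0
_CROWD_STEP = 10.0
_CEIL_BASE = 200_000.0
_SKY_BASE = 1e6
#: Fraction of the crowd zone used for tumor draws of non-aberrant targets.
_TUMOR_SHRINK = 0.6


def binary_entropy(p: float) -> float:
    """Entropy of a Bernoulli(p) variable, in bits."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


@dataclass(frozen=True)
class PlantedPair:
    """One planted source-target pair and its aberration rates."""

    source: str
    target: str
    p_dna: float
    p_rna_given_dna: float
    chain_length: int = 1

    def __post_init__(self) -> None:
        for name, p in (("p_dna", self.p_dna), ("p_rna_given_dna", self.p_rna_given_dna)):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {p}")
        if self.chain_length < 1:
            raise ValidationError(f"chain_length must be >= 1, got {self.chain_length}")

    @property
    def pair_id(self) -> str:
        return f"{self.source}{PAIR_SEP}{self.target}"

    def p_joint(self, rate_multiplier: float = 1.0) -> float:
        """Marginal probability that the pair variable is aberrant.

        Background RNA aberrations never co-occur with a non-aberrant source
        in the pair variable (the product needs both ends), so the joint rate
        is p_dna * p_rna_given_dna regardless of the background rate.
        """
        return min(self.p_dna * rate_multiplier, 1.0) * self.p_rna_given_dna


@dataclass
class PlantedModel:
    """Full specification of one synthetic cohort."""

    n_samples: int
    planted: list[PlantedPair]
    decoys: list[PlantedPair] = field(default_factory=list)
    p_rna_background: float = 0.0
    subtype_rates: dict[str, float] = field(default_factory=lambda: {"A": 1.0})
    guarantee_coverage: bool = False
    n_private_per_pair: int = 0
    n_crowd: int = 300
    n_low_filler: int = 50
    n_baseline: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0.0 <= self.p_rna_background <= 1.0:
            raise ValidationError("p_rna_background must be in [0,1]")
        names = [p.target for p in self.planted + self.decoys]
        if len(set(names)) != len(names):
            raise ValidationError("planted/decoy targets must be distinct genes")
        if self.guarantee_coverage and self.n_private_per_pair * len(self.planted) > self.n_samples:
            raise ValidationError("not enough samples for the requested private blocks")

    @property
    def all_pairs(self) -> list[PlantedPair]:
        return list(self.planted) + list(self.decoys)

    def subtype_of(self, i: int) -> str:
        names = sorted(self.subtype_rates)
        return names[i % len(names)]

    def pair_marginal(self, pair: PlantedPair, subtype: str) -> float:
        """P(Z=1) for one pair within one subtype (no coverage forcing)."""
        return pair.p_joint(rate_multiplier=self.subtype_rates[subtype])

    def true_entropy(self, subtype: str | None = None) -> float | None:
        """Closed-form entropy (bits) of the planted pair configuration vector.

        Valid when pairs are independent Bernoulli variables, i.e. without
        coverage forcing; with a subtype given, the per-subtype rates apply,
        otherwise a single-subtype model is required.  Returns None when the
        closed form does not apply.
        """
        if self.guarantee_coverage:
            return None
        if subtype is None:
            if len(self.subtype_rates) != 1:
                return None
            subtype = next(iter(self.subtype_rates))
        return sum(binary_entropy(self.pair_marginal(p, subtype)) for p in self.planted)

    @classmethod
    def toy_study(
        cls,
        n_samples: int = 500,
        n_planted: int = 5,
        n_decoys: int = 30,
        p_dna: float = 0.45,
        p_rna_given_dna: float = 0.9,
        decoy_p_dna: float = 0.3,
        decoy_p_rna_given_dna: float = 0.8,
        seed: int = 0,
        **kwargs,
    ) -> "PlantedModel":
        """The default toy study: planted pairs jointly cover every sample,
        each has a private block making it necessary, and decoy pairs are
        dependent enough to survive filtering but each cover well under 40%
        of the samples."""
        planted = [
            PlantedPair(f"SRC{i:02d}", f"TGT{i:02d}", p_dna, p_rna_given_dna) for i in range(n_planted)
        ]
        decoys = [
            PlantedPair(f"DSRC{i:02d}", f"DTGT{i:02d}", decoy_p_dna, decoy_p_rna_given_dna)
            for i in range(n_decoys)
        ]
        kwargs.setdefault("guarantee_coverage", True)
        kwargs.setdefault("n_private_per_pair", 8)
        kwargs.setdefault("subtype_rates", {"A": 1.0, "B": 0.8})
        return cls(n_samples=n_samples, planted=planted, decoys=decoys, seed=seed, **kwargs)


def generate_network(
    planted_pairs: list[PlantedPair],
    n_extra_genes: int = 20,
    n_state_edges: int = 30,
    n_expr_edges: int = 10,
    seed: int = 0,
) -> InteractionNetwork:
    """Random directed network containing a valid chain for every planted pair.

    A pair with chain_length 1 gets a direct expression-control edge; longer
    chains pass through fresh intermediate genes via state-change links, the
    final link controlling expression.  Decoy edges of both kinds are added
    among ``n_extra_genes`` extra genes.
    """
    rng = np.random.default_rng(seed)
    net = InteractionNetwork()
    n_inter = 0
    for pair in planted_pairs:
        prev = pair.source
        for _ in range(pair.chain_length - 1):
            inter = f"INT{n_inter:03d}"
            n_inter += 1
            net.add(prev, inter, STATE)
            prev = inter
        net.add(prev, pair.target, EXPR)
    extras = [f"NET{i:03d}" for i in range(n_extra_genes)]
    if extras and len(extras) >= 2:
        for kind, count in ((STATE, n_state_edges), (EXPR, n_expr_edges)):
            for _ in range(count):
                u, v = rng.choice(len(extras), size=2, replace=False)
                net.add(extras[u], extras[v], kind)
    return net


@dataclass
class GroundTruth:
    """Intended binary states and derived quantities for a generated cohort."""

    dna: pd.DataFrame  # samples x source genes (intended DNA aberration)
    rna: pd.DataFrame  # samples x target genes (intended RNA aberration)
    pairs: pd.DataFrame  # samples x pair ids (intended pair aberration)
    labels: dict[str, str]
    planted_pair_ids: list[str]
    decoy_pair_ids: list[str]
    true_entropy_bits: float | None

    def to_json(self, path) -> None:
        payload = {
            "planted_pair_ids": self.planted_pair_ids,
            "decoy_pair_ids": self.decoy_pair_ids,
            "true_entropy_bits": self.true_entropy_bits,
            "labels": self.labels,
            "pair_frequencies": self.pairs.mean(axis=0).round(6).to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def generate_cohort(model: PlantedModel, network: InteractionNetwork) -> tuple[OmicsBundle, GroundTruth]:
    """Draw one matched cohort realizing the planted model on the network.

    Returns the omics bundle (mutation, copy number, tumor and baseline
    expression, phenotype labels) plus the ground truth: the intended binary
    DNA/RNA/pair states the aberration callers should recover.
    """
    for pair in model.all_pairs:
        if pair.source not in network.nodes or pair.target not in network.nodes:
            raise ValidationError(f"planted pair {pair.pair_id} absent from the network")
    rng = np.random.default_rng(model.seed)
    pairs = model.all_pairs
    sources = [p.source for p in pairs]
    targets = [p.target for p in pairs]
    other_net = sorted(network.nodes - set(sources) - set(targets))
    low_fill = [f"FIL{i:03d}" for i in range(model.n_low_filler)]
    crowd = [f"CRW{i:03d}" for i in range(model.n_crowd)]
    # Ceiling genes sit between the crowd zone and the sky, so a target's
    # baseline rank never reaches the top of the scale and a sky value always
    # exceeds the baseline interval even when every target is aberrant at once.
    ceiling = [f"CEI{i:03d}" for i in range(len(pairs) + 5)]
    genes = sources + other_net + low_fill + crowd + ceiling + targets
    samples = [f"TUMOR{i:04d}" for i in range(model.n_samples)]
    normals = [f"NORMAL{i:04d}" for i in range(model.n_baseline)]
    labels = {s: model.subtype_of(i) for i, s in enumerate(samples)}

    # --- intended binary states -------------------------------------------
    n, k = model.n_samples, len(pairs)
    dna = np.zeros((n, k), dtype=np.int8)
    rna = np.zeros((n, k), dtype=np.int8)
    for j, pair in enumerate(pairs):
        for i in range(n):
            p_dna = min(pair.p_dna * model.subtype_rates[labels[samples[i]]], 1.0)
            d = rng.random() < p_dna
            r = rng.random() < (pair.p_rna_given_dna if d else model.p_rna_background)
            dna[i, j] = d
            rna[i, j] = r
    n_planted = len(model.planted)
    if model.guarantee_coverage and n_planted:
        for i in range(n):
            a = i % n_planted
            dna[i, a] = 1
            rna[i, a] = 1
            if (i // n_planted) < model.n_private_per_pair:
                for j in range(k):
                    if j != a:
                        dna[i, j] = 0
                        rna[i, j] = 0
    Z = dna * rna

    # --- DNA tables --------------------------------------------------------
    mutation = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=samples, dtype=np.int8)
    copy_number = pd.DataFrame(0, index=mutation.index, columns=samples, dtype=np.int8)
    for j, pair in enumerate(pairs):
        for i in range(n):
            if dna[i, j]:
                u = rng.random()
                if u < 0.5:
                    mutation.loc[pair.source, samples[i]] = 1
                elif u < 0.75:
                    copy_number.loc[pair.source, samples[i]] = -2
                else:
                    copy_number.loc[pair.source, samples[i]] = 2

    # --- expression tables -------------------------------------------------
    zone_w = model.n_crowd * _CROWD_STEP
    lo_t = _CROWD_BASE + (1.0 - _TUMOR_SHRINK) / 2.0 * zone_w
    hi_t = _CROWD_BASE + (1.0 + _TUMOR_SHRINK) / 2.0 * zone_w
    fixed_levels: dict[str, float] = {}
    level = 0
    for g in sources + other_net + low_fill:
        fixed_levels[g] = _LOW_BASE + level * _LOW_STEP
        level += 1
    for idx, g in enumerate(crowd):
        fixed_levels[g] = _CROWD_BASE + idx * _CROWD_STEP
    for idx, g in enumerate(ceiling):
        fixed_levels[g] = _CEIL_BASE + idx * _CROWD_STEP

    def _fixed_block(cols: list[str]) -> pd.DataFrame:
        vals = np.array([fixed_levels[g] for g in genes if g in fixed_levels])
        jitter = rng.uniform(-1, 1, size=(len(vals), len(cols)))
        return pd.DataFrame(vals[:, None] + jitter, index=[g for g in genes if g in fixed_levels], columns=cols)

    baseline = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=normals, dtype=float)
    baseline.loc[list(fixed_levels)] = _fixed_block(normals)
    for t in targets:
        baseline.loc[t] = rng.uniform(_CROWD_BASE, _CROWD_BASE + zone_w, size=model.n_baseline)

    tumor = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=samples, dtype=float)
    tumor.loc[list(fixed_levels)] = _fixed_block(samples)
    for j, pair in enumerate(pairs):
        vals = rng.uniform(lo_t, hi_t, size=n)
        sky = _SKY_BASE + j * 10.0 + rng.uniform(0, 1, size=n)
        tumor.loc[pair.target] = np.where(rna[:, j] == 1, sky, vals)

    bundle = OmicsBundle(
        mutation=mutation,
        copy_number=copy_number,
        tumor_expression=tumor,
        baseline_expression=baseline,
        phenotype_labels=labels,
    )
    pair_ids = [p.pair_id for p in pairs]
    truth = GroundTruth(
        dna=pd.DataFrame(dna, index=samples, columns=sources),
        rna=pd.DataFrame(rna, index=samples, columns=targets),
        pairs=pd.DataFrame(Z, index=samples, columns=pair_ids),
        labels=labels,
        planted_pair_ids=[p.pair_id for p in model.planted],
        decoy_pair_ids=[p.pair_id for p in model.decoys],
        true_entropy_bits=model.true_entropy(),
    )
    return bundle, truth
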