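"""End-to-end workflow: call aberrations, build and filter pairs, cover, measure.

The order is fixed: per-gene DNA/RNA calls, STP catalog over the network,
pair variables, chi-square dependence filter, then the minimum-frequency
filter applied independently at the pair, source and target levels, then a
minimal covering per level (r=1 at pair and source level, r=3 at target
level by default, each at the smallest feasible alpha), and finally entropy
estimates on the representative covering's variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aberrations import call_aberrations
from .catalog import STPCatalog, build_stp_catalog
from .covering import CoveringEnsemble, CoveringProblem, CoveringSolution, covering_analysis
from .entropy import EntropyEstimate, entropy_by_phenotype
from .filtering import FilterReport, chi2_independence_filter, collapse_level, compute_pair_matrix, frequency_filter
from .io import PipelineConfig
from .matrices import BinaryAberrationMatrix, OmicsBundle

LEVEL_NAMES = ("pair", "source", "target")


@dataclass
class LevelResult:
    matrix: BinaryAberrationMatrix
    problem: CoveringProblem
    best: CoveringSolution
    ensemble: CoveringEnsemble
    entropy: dict[str, EntropyEstimate] = field(default_factory=dict)


@dataclass
class PipelineResult:
    dna: BinaryAberrationMatrix
    rna: BinaryAberrationMatrix
    catalog_full: STPCatalog
    catalog: STPCatalog
    filter_report: FilterReport
    levels: dict[str, LevelResult]


def run_pipeline(bundle: OmicsBundle, network, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full workflow on a matched cohort and a directed network."""
    cfg = config or PipelineConfig()
    dna, rna = call_aberrations(bundle, q=cfg.q)
    catalog_full = build_stp_catalog(network, k_max=cfg.k_max)
    catalog, report = chi2_independence_filter(dna, rna, catalog_full, level=cfg.chi2_level)
    pair_matrix = compute_pair_matrix(dna, rna, catalog)

    matrices = {
        "pair": frequency_filter(pair_matrix, cfg.min_freq),
        "source": frequency_filter(collapse_level(pair_matrix, catalog, "source"), cfg.min_freq),
        "target": frequency_filter(collapse_level(pair_matrix, catalog, "target"), cfg.min_freq),
    }
    levels: dict[str, LevelResult] = {}
    for name, matrix in matrices.items():
        alpha = None if cfg.alpha_policy == "alpha_star" else cfg.alpha_fixed
        problem, best, ensemble = covering_analysis(
            matrix, r=cfg.r_for(name), alpha=alpha, max_solutions=cfg.max_solutions
        )
        rep = ensemble.representative
        chosen = rep.selected if rep is not None else best.selected
        entropy = {}
        if chosen:
            entropy = entropy_by_phenotype(
                matrix.values[chosen],
                dict(bundle.phenotype_labels),
                L=cfg.L,
                M=cfg.M,
                beta=cfg.beta,
                seed=cfg.seed,
            )
        levels[name] = LevelResult(matrix, problem, best, ensemble, entropy)
    return PipelineResult(dna, rna, catalog_full, catalog, report, levels)
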