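"""Minimal r-coverings of a cohort by integer programming.

Given a samples x features binary matrix Z, an r-covering at level alpha is a
feature subset J such that at least a fraction 1 - alpha of the samples have
r or more aberrant features in J.  A minimal covering minimizes the weighted
size sum_{j in J} w_j.  The problem is solved exactly as a mixed-integer
program with binary selection variables psi_j and per-sample coverage
indicators Y(w):

    minimize    sum_j w_j psi_j
    subject to  sum_j psi_j Z(w, j) >= r Y(w)   for every sample w
                sum_w Y(w) >= N (1 - alpha)

Optima are typically non-unique; the module also computes the union J_all and
core J_core of all optimal coverings via exact forcing certificates, an
explicit enumeration of optima through no-good cuts, and a representative
covering maximizing the total aberration frequency among its members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .matrices import BinaryAberrationMatrix, ValidationError

#: Integrality tolerance for interpreting MILP variable values.
INT_TOL = 1e-6


class InfeasibleCoveringError(ValueError):
    """Raised when no covering exists at the requested (r, alpha)."""


@dataclass
class CoveringProblem:
    """One covering instance: binary matrix, weights, r and alpha."""

    Z: pd.DataFrame  # samples x features, binary
    r: int = 1
    alpha: float = 0.0
    weights: np.ndarray | None = None  # per-feature, default all ones

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValidationError(f"r must be >= 1, got {self.r}")
        if not 0 <= self.alpha <= 1:
            raise ValidationError(f"alpha must be in [0,1], got {self.alpha}")
        if self.Z.shape[0] == 0 or self.Z.shape[1] == 0:
            raise ValidationError("covering problem needs at least one sample and one feature")
        if self.weights is None:
            self.weights = np.ones(self.Z.shape[1])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.Z.shape[1],):
            raise ValidationError("weights length must match the number of features")
        if not np.isfinite(self.weights).all() or (self.weights < 0).any():
            raise ValidationError("weights must be finite and non-negative")

    @classmethod
    def from_matrix(
        cls, matrix: BinaryAberrationMatrix, r: int = 1, alpha: float | None = None, weights=None
    ) -> "CoveringProblem":
        """Build a problem from an aberration matrix; alpha=None uses the smallest feasible alpha."""
        if alpha is None:
            alpha = compute_alpha_star(matrix.values, r)
        return cls(matrix.values, r=r, alpha=alpha, weights=weights)

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.Z.columns)

    def min_covered(self) -> int:
        """Smallest integer number of covered samples satisfying the alpha constraint."""
        return int(math.ceil(self.n_samples * (1.0 - self.alpha) - 1e-9))


@dataclass
class CoveringSolution:
    """One optimal covering with its per-sample coverage indicators."""

    selected: list[str]
    psi: np.ndarray
    Y: np.ndarray
    objective: float
    covered_fraction: float
    status: str

    def as_set(self) -> frozenset[str]:
        return frozenset(self.selected)


@dataclass
class CoveringEnsemble:
    """Enumerated optima plus exact union/core membership."""

    solutions: list[CoveringSolution]
    J_all: list[str]
    J_core: list[str]
    representative: CoveringSolution | None = None
    exhausted: bool = False
    undetermined: list[str] = field(default_factory=list)


def compute_alpha_star(Z: pd.DataFrame, r: int) -> float:
    """Smallest feasible alpha: 1 - (fraction of samples with >= r aberrant features)."""
    if Z.shape[0] == 0:
        raise ValidationError("empty matrix")
    rowsum = Z.to_numpy().sum(axis=1)
    return 1.0 - float((rowsum >= r).mean())


def _base_milp(problem: CoveringProblem):
    """Objective, constraints, and bound vectors for the covering MILP.

    Variable layout: [psi_0..psi_{m-1}, Y_0..Y_{n-1}], all binary.
    """
    Z = problem.Z.to_numpy().astype(float)
    n, m = Z.shape
    c = np.concatenate([problem.weights, np.zeros(n)])
    # Row coverage: Z psi - r Y >= 0.
    A_cov = sparse.hstack([sparse.csr_matrix(Z), -problem.r * sparse.eye(n, format="csr")])
    cov = LinearConstraint(A_cov, lb=np.zeros(n), ub=np.full(n, np.inf))
    # Population coverage: sum Y >= ceil(N (1 - alpha)).
    A_pop = sparse.csr_matrix(np.concatenate([np.zeros(m), np.ones(n)])[None, :])
    pop = LinearConstraint(A_pop, lb=[problem.min_covered()], ub=[np.inf])
    lb = np.zeros(m + n)
    ub = np.ones(m + n)
    return c, [cov, pop], lb, ub


def _run(c, constraints, lb, ub):
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones_like(c),
        bounds=Bounds(lb, ub),
    )
    return res


def _extract(problem: CoveringProblem, res) -> CoveringSolution:
    m = problem.Z.shape[1]
    x = res.x
    psi = (x[:m] > 0.5).astype(int)
    Y = (x[m:] > 0.5).astype(int)
    selected = [f for f, v in zip(problem.feature_ids, psi) if v]
    # Report the realized coverage, not just the indicator sum: a sample may
    # be covered even when the solver left its Y at 0.
    rowsum = problem.Z.to_numpy()[:, psi.astype(bool)].sum(axis=1)
    covered = float((rowsum >= problem.r).mean())
    return CoveringSolution(
        selected=selected,
        psi=psi,
        Y=Y,
        objective=float(problem.weights[psi.astype(bool)].sum()),
        covered_fraction=covered,
        status="optimal",
    )


def solve_min_covering(problem: CoveringProblem) -> CoveringSolution:
    """Solve the minimal r-covering MILP to proven optimality.

    Raises :class:`InfeasibleCoveringError` (naming the smallest feasible
    alpha) when the requested alpha is below alpha*.
    """
    a_star = compute_alpha_star(problem.Z, problem.r)
    if problem.min_covered() > int(round((1.0 - a_star) * problem.n_samples)):
        raise InfeasibleCoveringError(
            f"alpha={problem.alpha} infeasible for r={problem.r}; smallest feasible alpha is {a_star:.6g}"
        )
    c, constraints, lb, ub = _base_milp(problem)
    res = _run(c, constraints, lb, ub)
    if res.status != 0:
        raise InfeasibleCoveringError(f"solver returned status {res.status}: {res.message}")
    return _extract(problem, res)


def _objective_equality(problem: CoveringProblem, optimum: float) -> LinearConstraint:
    m, n = problem.Z.shape[1], problem.n_samples
    row = sparse.csr_matrix(np.concatenate([problem.weights, np.zeros(n)])[None, :])
    return LinearConstraint(row, lb=[optimum - INT_TOL], ub=[optimum + INT_TOL])


def enumerate_optima(problem: CoveringProblem, optimum: float, max_solutions: int = 1000) -> tuple[list[CoveringSolution], bool]:
    """Collect distinct optimal coverings via no-good cuts.

    After each optimum J found, the cut sum_{j in J} psi_j <= |J| - 1 excludes
    it and the model is re-solved with the objective pinned at the optimum,
    until the pool is exhausted or ``max_solutions`` is reached.  Returns the
    solutions and an exhaustion flag.
    """
    if max_solutions < 1:
        raise ValidationError(f"max_solutions must be >= 1, got {max_solutions}")
    c, constraints, lb, ub = _base_milp(problem)
    constraints = constraints + [_objective_equality(problem, optimum)]
    m, n = problem.Z.shape[1], problem.n_samples
    solutions: list[CoveringSolution] = []
    exhausted = False
    while len(solutions) < max_solutions:
        res = _run(c, constraints, lb, ub)
        if res.status != 0:
            exhausted = True
            break
        sol = _extract(problem, res)
        solutions.append(sol)
        cut_row = np.zeros(m + n)
        cut_row[: m][sol.psi.astype(bool)] = 1.0
        constraints = constraints + [
            LinearConstraint(sparse.csr_matrix(cut_row[None, :]), lb=[-np.inf], ub=[len(sol.selected) - 1])
        ]
    return solutions, exhausted


def certify_core_union(problem: CoveringProblem, optimum: float) -> tuple[list[str], list[str], list[str]]:
    """Exact core and union of all optimal coverings by forcing certificates.

    A feature is in the core iff forcing psi_j = 0 makes the problem worse
    than ``optimum`` (or infeasible); it is in the union iff forcing
    psi_j = 1 still attains ``optimum``.  Independent of any enumeration.
    Returns (J_core, J_all, undetermined); a feature lands in the last list
    only if the solver fails on its certificate.
    """
    c, constraints, lb, ub = _base_milp(problem)
    core: list[str] = []
    union: list[str] = []
    undetermined: list[str] = []
    for j, fid in enumerate(problem.feature_ids):
        # Union test: force inclusion.
        lb_in = lb.copy()
        lb_in[j] = 1.0
        res_in = _run(c, constraints, lb_in, ub)
        if res_in.status == 0 and res_in.fun <= optimum + INT_TOL:
            union.append(fid)
            # Core test: force exclusion; only union members can be core.
            ub_out = ub.copy()
            ub_out[j] = 0.0
            res_out = _run(c, constraints, lb, ub_out)
            if res_out.status == 2 or (res_out.status == 0 and res_out.fun > optimum + INT_TOL):
                core.append(fid)
            elif res_out.status not in (0, 2):
                undetermined.append(fid)
        elif res_in.status not in (0, 2):
            undetermined.append(fid)
    return core, union, undetermined


def representative_covering(
    problem: CoveringProblem, optimum: float, frequencies: pd.Series, lexicographic: bool = True
) -> CoveringSolution:
    """Among minimal coverings, the one maximizing the total aberration frequency.

    A second MILP maximizes sum_{j in J} freq_j subject to the covering
    constraints and the objective pinned at ``optimum``.  With
    ``lexicographic`` remaining ties are broken deterministically by greedily
    preferring the earliest feature indices.
    """
    freq = np.asarray([frequencies[f] for f in problem.feature_ids], dtype=float)
    m, n = problem.Z.shape[1], problem.n_samples
    c, constraints, lb, ub = _base_milp(problem)
    constraints = constraints + [_objective_equality(problem, optimum)]
    c2 = np.concatenate([-freq, np.zeros(n)])  # maximize freq sum
    res = _run(c2, constraints, lb, ub)
    if res.status != 0:
        raise InfeasibleCoveringError(f"representative solve failed: {res.message}")
    best_freq = -res.fun
    if lexicographic:
        freq_row = sparse.csr_matrix(np.concatenate([freq, np.zeros(n)])[None, :])
        constraints = constraints + [
            LinearConstraint(freq_row, lb=[best_freq - 1e-7], ub=[np.inf])
        ]
        lb = lb.copy()
        ub = ub.copy()
        for j in range(m):
            lb_try = lb.copy()
            lb_try[j] = 1.0
            res_j = _run(c2, constraints, lb_try, ub)
            if res_j.status == 0:
                lb = lb_try
            else:
                ub[j] = 0.0
        res = _run(c2, constraints, lb, ub)
    return _extract(problem, res)


def covering_analysis(
    matrix: BinaryAberrationMatrix,
    r: int = 1,
    alpha: float | None = None,
    weights=None,
    max_solutions: int = 1000,
    frequencies: pd.Series | None = None,
) -> tuple[CoveringProblem, CoveringSolution, CoveringEnsemble]:
    """Full covering workflow for one level: solve, certify, enumerate, represent."""
    problem = CoveringProblem.from_matrix(matrix, r=r, alpha=alpha, weights=weights)
    best = solve_min_covering(problem)
    core, union, undetermined = certify_core_union(problem, best.objective)
    solutions, exhausted = enumerate_optima(problem, best.objective, max_solutions=max_solutions)
    if frequencies is None:
        frequencies = matrix.frequencies()
    rep = representative_covering(problem, best.objective, frequencies)
    ensemble = CoveringEnsemble(
        solutions=solutions,
        J_all=union,
        J_core=core,
        representative=rep,
        exhausted=exhausted,
        undetermined=undetermined,
    )
    return problem, best, ensemble
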