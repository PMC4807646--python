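"""Linear-Gaussian oracle and data-level partition queries.

A regression graph without interaction terms induces a linear structural
system: each variable is a linear function of its parents plus a Gaussian
error; errors are correlated only within boxes (dashed edges), and context
boxes carry a concentration-graph structure (full lines = nonzero entries of
the error precision).  The implied joint covariance lets every separation
statement be checked numerically: m-separation of x and y given C must force
the partial correlation of x and y given C to vanish.

Data-level partition queries implement the same idea on a cohort table:
regress one variable of interest on another after partitioning out a chosen
conditioning set, which need not contain the directly explanatory variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, complete_cases
from .errors import ValidityError
from .graph_model import CONTEXT, RegressionGraph, m_separated
from .seqreg_fit import fit_ols


@dataclass
class GaussianSystem:
    """Linear structural system read off a regression graph.

    ``order`` lists variables background-first (descending box index), so the
    coefficient matrix is strictly lower triangular: ``coef[i, j]`` is the
    structural coefficient of order[j] in the equation for order[i].
    ``error_cov`` is positive definite and block-diagonal by box.
    """

    order: list[str]
    coef: np.ndarray
    error_cov: np.ndarray
    boxes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.order)
        self.coef = np.asarray(self.coef, dtype=float)
        self.error_cov = np.asarray(self.error_cov, dtype=float)
        if self.coef.shape != (k, k) or self.error_cov.shape != (k, k):
            raise ValidityError("dimension mismatch")
        if np.any(np.triu(self.coef) != 0):
            raise ValidityError("coef must be strictly lower triangular "
                                "(background-first order)")
        if not np.allclose(self.error_cov, self.error_cov.T):
            raise ValidityError("error covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.error_cov)) <= 0:
            raise ValidityError("error covariance must be positive definite")
        if self.boxes:
            for i, a in enumerate(self.order):
                for j, b in enumerate(self.order):
                    if i != j and self.boxes[a] != self.boxes[b] \
                            and self.error_cov[i, j] != 0:
                        raise ValidityError(
                            f"error covariance links {a} and {b} across boxes")

    def index(self, name: str) -> int:
        return self.order.index(name)


def implied_covariance(sys: GaussianSystem) -> pd.DataFrame:
    """Joint covariance of the linear system: (I-B)^-1 Omega (I-B)^-T."""
    k = len(sys.order)
    A = np.eye(k) - sys.coef
    Ainv = np.linalg.solve(A, np.eye(k))
    cov = Ainv @ sys.error_cov @ Ainv.T
    cov = (cov + cov.T) / 2.0
    return pd.DataFrame(cov, index=sys.order, columns=sys.order)


def _cov_matrix(cov, names):
    if isinstance(cov, pd.DataFrame):
        order = list(cov.index)
        return cov.to_numpy(dtype=float), {n: order.index(n) for n in names}
    cov = np.asarray(cov, dtype=float)
    return cov, {n: n for n in names}  # integer indices


def partial_correlation(cov, x, y, given=()) -> float:
    """Partial correlation of x and y given a set, from a covariance matrix.

    Computed from the inverse of the submatrix over {x, y} | given.
    """
    given = sorted(given) if not isinstance(given, (list, tuple)) else list(given)
    names = [x, y] + list(given)
    mat, idx = _cov_matrix(cov, names)
    sel = [idx[n] for n in names]
    sub = mat[np.ix_(sel, sel)]
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def system_from_graph(g: RegressionGraph, rng=None,
                      coef_range=(0.5, 1.5),
                      corr_range=(0.2, 0.4)) -> GaussianSystem:
    """Generic random parameters whose structure mirrors the graph exactly.

    Arrow coefficients are uniform in +-coef_range; dashed edges become
    within-box error correlations; full lines become off-diagonal entries of
    the context-box error *precision* (so a missing full line is a zero
    concentration, the concentration-graph reading of context boxes).
    """
    rng = np.random.default_rng(rng)
    order = sorted(g.nodes, key=lambda n: (-g.nodes[n], n))
    idx = {n: i for i, n in enumerate(order)}
    k = len(order)
    B = np.zeros((k, k))
    for tail, head in g.arrows:
        B[idx[head], idx[tail]] = rng.uniform(*coef_range) * rng.choice([-1, 1])
    omega = np.zeros((k, k))
    by_box: dict[int, list[str]] = {}
    for n, b in g.nodes.items():
        by_box.setdefault(b, []).append(n)
    for b, members in by_box.items():
        members = sorted(members)
        m = len(members)
        local = np.eye(m)
        pairs = g.full if g.box_kinds[members[0]] == CONTEXT else g.dashed
        for a_, b_ in pairs:
            if a_ in members and b_ in members:
                i, j = members.index(a_), members.index(b_)
                rho = rng.uniform(*corr_range) * rng.choice([-1, 1])
                local[i, j] = local[j, i] = rho
        while np.min(np.linalg.eigvalsh(local)) <= 1e-8:
            off = local - np.diag(np.diag(local))
            local = np.eye(m) + 0.8 * off
        if g.box_kinds[members[0]] == CONTEXT:
            local = np.linalg.inv(local)  # pattern lives in the precision
        sel = [idx[n] for n in members]
        omega[np.ix_(sel, sel)] = local
    return GaussianSystem(order=order, coef=B, error_cov=omega,
                          boxes=dict(g.nodes))


@dataclass
class ConsistencyReport:
    """Result of checking m-separation against the Gaussian oracle."""

    n_queries: int
    violations: list[tuple]  # (x, y, given, partial correlation)
    faithfulness_flags: list[tuple]  # non-separated pairs with tiny |r| (logged)

    @property
    def ok(self) -> bool:
        return not self.violations


def check_markov_consistency(g: RegressionGraph, sys: GaussianSystem,
                             max_cond: int, tol: float = 1e-10,
                             faith_tol: float = 1e-8) -> ConsistencyReport:
    """Every m-separation must be a vanishing partial correlation.

    Violations of the converse (a non-separated pair with numerically zero
    partial correlation) can occur on a measure-zero parameter set, so they
    are flagged, not counted as failures.
    """
    _check_structure_match(g, sys)
    cov = implied_covariance(sys)
    names = sorted(g.nodes)
    violations, flags = [], []
    n_q = 0
    for x, y in itertools.combinations(names, 2):
        rest = [n for n in names if n not in (x, y)]
        for k in range(min(max_cond, len(rest)) + 1):
            for cond in itertools.combinations(rest, k):
                n_q += 1
                r = partial_correlation(cov, x, y, list(cond))
                if m_separated(g, x, y, cond):
                    if abs(r) >= tol:
                        violations.append((x, y, cond, r))
                elif abs(r) < faith_tol:
                    flags.append((x, y, cond, r))
    return ConsistencyReport(n_queries=n_q, violations=violations,
                             faithfulness_flags=flags)


def _check_structure_match(g: RegressionGraph, sys: GaussianSystem) -> None:
    idx = {n: i for i, n in enumerate(sys.order)}
    arrows = {(t, h) for t, h in g.arrows}
    nonzero = {(sys.order[j], sys.order[i])
               for i, j in zip(*np.nonzero(sys.coef))}
    if arrows != nonzero:
        raise ValidityError(
            f"coefficient pattern does not match arrows: {arrows ^ nonzero}")
    for a, b in itertools.combinations(sorted(g.nodes), 2):
        if g.nodes[a] != g.nodes[b]:
            continue
        if g.box_kinds[a] == CONTEXT:
            continue  # context pattern lives in the precision, checked below
        linked = tuple(sorted((a, b))) in g.dashed
        val = sys.error_cov[idx[a], idx[b]]
        if linked != (val != 0):
            raise ValidityError(f"error covariance mismatch for ({a}, {b})")
    by_box: dict[int, list[str]] = {}
    for n, b in g.nodes.items():
        if g.box_kinds[n] == CONTEXT:
            by_box.setdefault(b, []).append(n)
    for b, members in by_box.items():
        members = sorted(members)
        if len(members) < 2:
            continue
        sel = [idx[n] for n in members]
        prec = np.linalg.inv(sys.error_cov[np.ix_(sel, sel)])
        for i, j in itertools.combinations(range(len(members)), 2):
            linked = tuple(sorted((members[i], members[j]))) in g.full
            if linked != (abs(prec[i, j]) > 1e-9):
                raise ValidityError(
                    f"context precision mismatch for ({members[i]}, {members[j]})")


def coefficients_from_covariance(cov, y, xs, given=()) -> dict[str, float]:
    """Population regression slopes of y on xs | given by covariance algebra."""
    preds = list(xs) + list(given)
    mat, idx = _cov_matrix(cov, [y] + preds)
    p = [idx[n] for n in preds]
    Sxx = mat[np.ix_(p, p)]
    Sxy = mat[np.ix_(p, [idx[y]])].ravel()
    beta = np.linalg.solve(Sxx, Sxy)
    return {n: float(beta[i]) for i, n in enumerate(preds) if n in set(xs)}


def partition_query(t: CohortTable, y: str, xs, given=()):
    """Inference for y on xs after partitioning out a conditioning set.

    Fits y ~ xs + given by least squares on the log-transformed table
    (complete cases over all named variables) and returns the coefficient,
    95% CI and p-value for each x only.
    """
    xs, given = list(xs), sorted(set(given))
    if not t.log_applied:
        raise ValidityError("partition queries expect a log-transformed table")
    tt = complete_cases(t, [y] + xs + given)
    model = fit_ols(tt.data[y], tt.data[xs + given], response=y)
    out = {}
    for x in xs:
        rec = model[x]
        rec["n"] = model.n_used
        out[x] = rec
    return out
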