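"""Sequence-of-regressions engine.

Each response in a response box is regressed, by least squares on the natural
-log scale, on the variables in strictly later boxes.  Model selection is
backward elimination at a fixed significance level, followed by greedy
screening of two-way products and squares (hierarchical: a retained product
or square keeps its main effects in the model).  Within-box residual
associations are tested by partial correlation given the union of the two
responses' selected regressors.  The retained terms and significant
within-box tests assemble into a regression graph.

On the log-log scale a partial regression coefficient is an elasticity: a 1%
difference in the explanatory variable corresponds to a beta% difference in
the response, holding the remaining regressors fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, complete_cases, log_transform
from .errors import (
    CollinearityError,
    DegenerateDataError,
    DomainError,
    SeqregError,
)
from .graph_model import CONTEXT, RESPONSE, BlockOrdering, RegressionGraph


@dataclass(frozen=True)
class TermSpec:
    """One regression term: a main effect, a two-way product, or a square."""

    kind: str  # 'main' | 'interaction' | 'quadratic'
    variables: tuple[str, ...]

    def __post_init__(self):
        if self.kind == "main" and len(self.variables) != 1:
            raise ValueError("main term takes exactly one variable")
        if self.kind == "quadratic" and len(self.variables) != 1:
            raise ValueError("quadratic term takes exactly one variable")
        if self.kind == "interaction":
            if len(self.variables) != 2 or self.variables[0] == self.variables[1]:
                raise ValueError("interaction takes two distinct variables")
            object.__setattr__(self, "variables", tuple(sorted(self.variables)))
        if self.kind not in ("main", "interaction", "quadratic"):
            raise ValueError(f"unknown term kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "main":
            return self.variables[0]
        if self.kind == "interaction":
            return f"{self.variables[0]}:{self.variables[1]}"
        return f"{self.variables[0]}^2"

    @classmethod
    def main(cls, name):
        return cls("main", (name,))

    @classmethod
    def interaction(cls, a, b):
        return cls("interaction", (a, b))

    @classmethod
    def quadratic(cls, name):
        return cls("quadratic", (name,))


@dataclass
class FitConfig:
    """Tuning knobs for model selection."""

    alpha: float = 0.05
    screen_interactions: bool = True
    screen_quadratics: bool = True
    center_before_products: bool = True
    interaction_scope: str = "all"  # 'all' candidates or 'retained' mains only
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.interaction_scope not in ("all", "retained"):
            raise ValueError("interaction_scope must be 'all' or 'retained'")


@dataclass
class NodeModel:
    """One fitted response: retained terms with coefficients, CIs, p, R^2."""

    response: str
    terms: list[TermSpec]
    beta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    r_squared: float
    n_used: int
    sigma: float
    intercept: float = 0.0

    def __getitem__(self, label: str) -> dict:
        for i, t in enumerate(self.terms):
            if t.label == label:
                return {
                    "beta": float(self.beta[i]),
                    "ci_low": float(self.ci_low[i]),
                    "ci_high": float(self.ci_high[i]),
                    "p": float(self.p[i]),
                }
        raise KeyError(label)

    def term_labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "n_used": self.n_used,
            "r_squared": self.r_squared,
            "sigma": self.sigma,
            "intercept": self.intercept,
            "terms": [
                {
                    "label": t.label,
                    "kind": t.kind,
                    "beta": float(self.beta[i]),
                    "ci_low": float(self.ci_low[i]),
                    "ci_high": float(self.ci_high[i]),
                    "p": float(self.p[i]),
                }
                for i, t in enumerate(self.terms)
            ],
        }


# -- least squares core -------------------------------------------------------


def _ols_arrays(y: np.ndarray, X: np.ndarray, names: list[str]):
    """QR least squares with residual-t inference.

    X excludes the intercept; one is prepended here.  Returns coefficient
    vector (without intercept), CIs, p-values, R^2, residual SD, intercept.
    """
    n, k = X.shape
    if n < k + 2:
        raise DegenerateDataError(
            f"n = {n} too small for {k} terms plus intercept"
        )
    Xd = np.column_stack([np.ones(n), X])
    Q, R = np.linalg.qr(Xd)
    diag = np.abs(np.diag(R))
    tol = max(n, k + 1) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        bad = [(["intercept"] + names)[i] for i in np.where(diag < tol)[0]]
        raise CollinearityError(
            f"rank-deficient design; dependent column(s) {bad}", columns=bad
        )
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - Xd @ coef
    df = n - k - 1
    rss = float(resid @ resid)
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(k + 1))
    se = np.sqrt(sigma2 * np.sum(Rinv * Rinv, axis=1))
    tcrit = stats.t.ppf(0.975, df)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p = 2 * stats.t.sf(np.abs(tval), df)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return {
        "intercept": float(coef[0]),
        "beta": coef[1:],
        "se": se[1:],
        "ci_low": coef[1:] - tcrit * se[1:],
        "ci_high": coef[1:] + tcrit * se[1:],
        "p": p[1:],
        "r_squared": r2,
        "sigma": float(np.sqrt(sigma2)),
        "n": n,
        "df": df,
    }


def fit_ols(y, design: pd.DataFrame, response: str = "y") -> NodeModel:
    """Least-squares fit of y on a labelled design matrix (intercept added).

    Two-sided t p-values and 95% CIs use the residual t distribution with
    n - k - 1 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    names = list(design.columns)
    res = _ols_arrays(y, design.to_numpy(dtype=float), names)
    terms = [TermSpec.main(c) for c in names]
    return NodeModel(
        response=response,
        terms=terms,
        beta=res["beta"],
        ci_low=res["ci_low"],
        ci_high=res["ci_high"],
        p=res["p"],
        r_squared=res["r_squared"],
        n_used=res["n"],
        sigma=res["sigma"],
        intercept=res["intercept"],
    )


class _DesignCache:
    """Lazily built, centered term columns over a fixed analysis sample."""

    def __init__(self, data: pd.DataFrame, center: bool):
        self.raw = {c: data[c].to_numpy(dtype=float) for c in data.columns}
        self.center = center
        self.means = {c: float(np.mean(v)) for c, v in self.raw.items()}
        self._cols: dict[str, np.ndarray] = {}

    def column(self, term: TermSpec) -> np.ndarray:
        key = term.label
        if key not in self._cols:
            if term.kind == "main":
                self._cols[key] = self.raw[term.variables[0]]
            else:
                vals = []
                for v in term.variables:
                    x = self.raw[v]
                    vals.append(x - self.means[v] if self.center else x)
                if term.kind == "interaction":
                    self._cols[key] = vals[0] * vals[1]
                else:
                    self._cols[key] = vals[0] * vals[0]
        return self._cols[key]

    def matrix(self, terms: list[TermSpec]) -> np.ndarray:
        if not terms:
            return np.empty((len(next(iter(self.raw.values()))), 0))
        return np.column_stack([self.column(t) for t in terms])


def candidate_terms(response: str, ordering: BlockOrdering) -> list[TermSpec]:
    """Main-effect candidates: every variable in a strictly later box.

    Deterministic order: box order, then declaration order within box.
    """
    spec = ordering[response]
    if spec.box_kind == CONTEXT:
        raise ValueError(f"{response!r} is a context variable, not a response")
    out = []
    for box in ordering.boxes[spec.box_index + 1:]:
        for v in box:
            out.append(TermSpec.main(v.name))
    return out


def _node_model(response, terms, res) -> NodeModel:
    return NodeModel(
        response=response,
        terms=list(terms),
        beta=res["beta"],
        ci_low=res["ci_low"],
        ci_high=res["ci_high"],
        p=res["p"],
        r_squared=res["r_squared"],
        n_used=res["n"],
        sigma=res["sigma"],
        intercept=res["intercept"],
    )


def select_model(
    t: CohortTable,
    response: str,
    candidates: list[TermSpec],
    cfg: FitConfig,
    selection_log: list | None = None,
) -> NodeModel:
    """Backward elimination, then greedy product/square augmentation.

    Starting from all main-effect candidates, the largest-p term is dropped
    until every retained p < alpha.  If screening is enabled, all two-way
    products and squares over the screening pool are tried one at a time;
    the smallest-p significant augmentation is added (with its main effects,
    hierarchically) and the model re-pruned, until nothing more enters.
    Main effects locked by a retained product or square are never dropped.
    Exact p ties break by candidate order.
    """
    log = selection_log if selection_log is not None else []
    involved = [response] + sorted({v for c in candidates for v in c.variables})
    tt = complete_cases(t, involved)
    y = tt.data[response].to_numpy(dtype=float)
    n = len(y)
    cache = _DesignCache(tt.data[[c for c in involved if c != response]]
                         if len(involved) > 1 else tt.data[[]],
                         center=cfg.center_before_products)

    terms = list(candidates)
    if n < len(terms) + 2:
        keep = max(n - 2, 0)
        log.append({
            "step": "start", "action": "truncate-candidates",
            "detail": f"n={n} supports {keep} of {len(terms)} candidates",
        })
        terms = terms[:keep]
    if not terms:
        resid = y - y.mean()
        sigma = float(np.sqrt(resid @ resid / max(n - 1, 1)))
        return NodeModel(response, [], np.array([]), np.array([]), np.array([]),
                         np.array([]), 0.0, n, sigma, intercept=float(y.mean()))

    def fit(term_list):
        return _ols_arrays(y, cache.matrix(term_list), [t_.label for t_ in term_list])

    def locked(term_list):
        lock = set()
        for t_ in term_list:
            if t_.kind != "main":
                lock.update(t_.variables)
        return lock

    def prune(term_list, res):
        while term_list:
            lock = locked(term_list)
            drop_i, drop_p = None, -1.0
            for i, t_ in enumerate(term_list):
                if t_.kind == "main" and t_.variables[0] in lock:
                    continue
                if res["p"][i] >= cfg.alpha and res["p"][i] > drop_p:
                    drop_i, drop_p = i, res["p"][i]
            if drop_i is None:
                return term_list, res
            dropped = term_list[drop_i]
            term_list = term_list[:drop_i] + term_list[drop_i + 1:]
            log.append({"step": "prune", "action": "drop",
                        "term": dropped.label, "p": float(drop_p)})
            if not term_list:
                return term_list, None
            res = fit(term_list)
        return term_list, res

    res = fit(terms)
    terms, res = prune(terms, res)

    if cfg.screen_interactions or cfg.screen_quadratics:
        cand_vars = [c.variables[0] for c in candidates]
        for _round in range(25):
            if cfg.interaction_scope == "all":
                pool = cand_vars
            else:
                pool = [v for v in cand_vars
                        if any(t_.kind == "main" and t_.variables[0] == v
                               for t_ in terms)]
            augs = []
            if cfg.screen_interactions:
                augs += [TermSpec.interaction(a, b)
                         for a, b in itertools.combinations(pool, 2)]
            if cfg.screen_quadratics:
                augs += [TermSpec.quadratic(v) for v in pool]
            have = {t_.label for t_ in terms}
            best = None
            for aug in augs:
                if aug.label in have:
                    continue
                trial = list(terms)
                for v in aug.variables:
                    if v not in {x.variables[0] for x in trial if x.kind == "main"}:
                        trial.append(TermSpec.main(v))
                trial.append(aug)
                if n < len(trial) + 2:
                    continue
                try:
                    trial_res = fit(trial)
                except (CollinearityError, DegenerateDataError):
                    continue
                p_aug = float(trial_res["p"][-1])
                if p_aug < cfg.alpha and (best is None or p_aug < best[0]):
                    best = (p_aug, aug, trial, trial_res)
            if best is None:
                break
            p_aug, aug, terms, res = best
            log.append({"step": "screen", "action": "add",
                        "term": aug.label, "p": p_aug})
            terms, res = prune(terms, res)
            if res is None:
                res = fit(terms) if terms else None
                if res is None:
                    break

    if not terms or res is None:
        resid = y - y.mean()
        sigma = float(np.sqrt(resid @ resid / max(n - 1, 1)))
        return NodeModel(response, [], np.array([]), np.array([]), np.array([]),
                         np.array([]), 0.0, n, sigma, intercept=float(y.mean()))
    return _node_model(response, terms, res)


def fit_full_model(t: CohortTable, response: str, terms: list[TermSpec],
                   cfg: FitConfig) -> NodeModel:
    """Fit a fixed term set with no selection (used for coverage studies)."""
    involved = [response] + sorted({v for c in terms for v in c.variables})
    tt = complete_cases(t, involved)
    y = tt.data[response].to_numpy(dtype=float)
    cache = _DesignCache(tt.data[[c for c in involved if c != response]],
                         center=cfg.center_before_products)
    res = _ols_arrays(y, cache.matrix(list(terms)), [x.label for x in terms])
    return _node_model(response, list(terms), res)


def within_box_test(t: CohortTable, a: str, b: str, combined_explanatory):
    """Partial correlation of two same-box responses given a regressor union.

    Computed from the residuals of the two least-squares fits; the p-value
    uses the t transform with n - |set| - 2 degrees of freedom.
    """
    if a == b:
        raise ValueError("the two responses must differ")
    if a in t.meta and b in t.meta and t.meta[a].box_index != t.meta[b].box_index:
        raise ValueError(f"{a!r} and {b!r} are not in the same box")
    given = sorted(set(combined_explanatory) - {a, b})
    tt = complete_cases(t, [a, b] + given)
    n = tt.n_rows
    X = np.column_stack([np.ones(n)] +
                        [tt.data[g].to_numpy(dtype=float) for g in given])
    def residualize(name):
        v = tt.data[name].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ coef
    ra, rb = residualize(a), residualize(b)
    va, vb = float(ra @ ra), float(rb @ rb)
    if va <= 0 or vb <= 0:
        raise DegenerateDataError("zero residual variance in within-box test")
    r = float((ra @ rb) / np.sqrt(va * vb))
    df = n - len(given) - 2
    if df <= 0:
        raise DegenerateDataError("no residual degrees of freedom")
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    tval = r * np.sqrt(df / (1 - r * r))
    p = float(2 * stats.t.sf(abs(tval), df))
    return r, p


@dataclass
class SequenceFit:
    """Full output of a sequence-of-regressions run."""

    models: dict[str, NodeModel]
    dashed_tests: list[dict]
    graph: RegressionGraph
    config: FitConfig
    ordering: BlockOrdering
    selection_logs: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": {
                "alpha": self.config.alpha,
                "screen_interactions": self.config.screen_interactions,
                "screen_quadratics": self.config.screen_quadratics,
                "center_before_products": self.config.center_before_products,
                "interaction_scope": self.config.interaction_scope,
                "multiple_testing_adjustment": "none",
            },
            "models": {r: m.to_dict() for r, m in sorted(self.models.items())},
            "dashed_tests": self.dashed_tests,
            "graph": {
                "arrows": sorted(self.graph.arrows),
                "dashed": sorted(self.graph.dashed),
                "full": sorted(self.graph.full),
            },
            "selection_logs": self.selection_logs,
        }


def fit_sequence(t: CohortTable, ordering: BlockOrdering,
                 cfg: FitConfig | None = None) -> SequenceFit:
    """Fit every response in block order and assemble the regression graph.

    The raw table is log-transformed; each response uses complete cases over
    itself and its candidate regressors; within-box pairs are tested given
    the union of the two responses' selected explanatory variables.  Arrows
    come from the variables appearing in retained terms; dashed edges from
    significant within-box tests; context variables in a shared box are
    joined by full lines.
    """
    cfg = cfg or FitConfig()
    logged = log_transform(t) if not t.log_applied else t
    models: dict[str, NodeModel] = {}
    logs: dict[str, list] = {}
    for box in ordering.boxes:
        if box[0].box_kind != RESPONSE:
            continue
        for v in box:
            cands = candidate_terms(v.name, ordering)
            log: list = []
            try:
                models[v.name] = select_model(logged, v.name, cands, cfg, log)
            except DegenerateDataError as exc:
                log.append({"step": "fit", "action": "not-estimable",
                            "detail": str(exc)})
                raise SeqregError(f"model for {v.name} not estimable: {exc}")
            logs[v.name] = log

    dashed_tests = []
    dashed_edges = set()
    for box in ordering.boxes:
        if box[0].box_kind != RESPONSE:
            continue
        for va, vb in itertools.combinations([v.name for v in box], 2):
            union = set()
            for r in (va, vb):
                for term in models[r].terms:
                    union.update(term.variables)
            r_ab, p_ab = within_box_test(logged, va, vb, union)
            rec = {"pair": tuple(sorted((va, vb))),
                   "partial_correlation": r_ab, "p": p_ab,
                   "given": sorted(union)}
            dashed_tests.append(rec)
            if p_ab < cfg.alpha:
                dashed_edges.add(tuple(sorted((va, vb))))

    arrows = set()
    for r, m in models.items():
        for term in m.terms:
            for vname in term.variables:
                arrows.add((vname, r))
    full = set()
    for box in ordering.boxes:
        if box[0].box_kind == CONTEXT:
            for a, b in itertools.combinations([v.name for v in box], 2):
                full.add(tuple(sorted((a, b))))
    graph = RegressionGraph.from_ordering(ordering, arrows=arrows,
                                          dashed=dashed_edges, full=full)
    return SequenceFit(models=models, dashed_tests=dashed_tests, graph=graph,
                       config=cfg, ordering=ordering, selection_logs=logs)


# -- interpretation helpers ---------------------------------------------------


@dataclass(frozen=True)
class Elasticity:
    """Percent change in the outcome for a pct% change in the regressor."""

    linear: float  # pct * beta, the usual log-log reading
    exact: float  # 100 * ((1 + pct/100)^beta - 1)


def interpret_coefficient(beta: float, pct: float) -> Elasticity:
    """Translate a log-log coefficient into a percent-change statement."""
    exact = 100.0 * ((1.0 + pct / 100.0) ** beta - 1.0)
    return Elasticity(linear=pct * beta, exact=exact)


@dataclass(frozen=True)
class TurningPoint:
    """Vertex of a quadratic-in-log response profile."""

    log_location: float
    original_scale: float
    kind: str  # 'minimum' (U shape) or 'maximum'


def quadratic_turning_point(beta1: float, beta2: float) -> TurningPoint:
    """Vertex -beta1/(2 beta2) of beta1*x + beta2*x^2 on the log scale."""
    if beta2 == 0:
        raise DomainError("no vertex: quadratic coefficient is zero")
    loc = -beta1 / (2.0 * beta2)
    return TurningPoint(
        log_location=loc,
        original_scale=float(np.exp(loc)),
        kind="minimum" if beta2 > 0 else "maximum",
    )


def format_coefficient(beta: float, lo: float, hi: float) -> str:
    """'beta (lo, hi)' with each number at 2 significant figures."""
    return f"{beta:.2g} ({lo:.2g}, {hi:.2g})"


def export_models_tsv(fit: SequenceFit, path=None) -> pd.DataFrame:
    """Summary table: one row per term, one column per response."""
    labels: list[str] = []
    for m in fit.models.values():
        for t_ in m.terms:
            if t_.label not in labels:
                labels.append(t_.label)
    responses = [v.name for box in fit.ordering.boxes
                 if box[0].box_kind == RESPONSE for v in box]
    tab = pd.DataFrame(index=labels + ["R^2", "n"], columns=responses, dtype=object)
    for r in responses:
        m = fit.models[r]
        for i, t_ in enumerate(m.terms):
            tab.loc[t_.label, r] = format_coefficient(
                m.beta[i], m.ci_low[i], m.ci_high[i])
        tab.loc["R^2", r] = f"{m.r_squared:.2g}"
        tab.loc["n", r] = str(m.n_used)
    if path is not None:
        tab.to_csv(path, sep="\t")
    return tab
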