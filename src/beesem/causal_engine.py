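"""Piecewise structural equation modelling by d-separation.

A candidate causal model is a DAG over the site-level variables.  The
model is tested locally: every pair of non-adjacent variables must be
conditionally independent given the union of both variables' parents
(the basis set).  Each independence claim is tested with the p-value of
a Pearson partial correlation; the claim p-values aggregate into
Fisher's C = -2 * sum(ln p_i), which follows a chi-square distribution
with 2k degrees of freedom when the model is correct (k = number of
claims).  Competing models are ranked by an AIC built on C, and each
retained edge receives a standardized path coefficient: the partial
correlation of cause and effect controlling for the effect's other
parents.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateInputError, DomainError, InsufficientDataError,
                     ModelError)

Edge = tuple[str, str]

AIC_FORMULAS = ("shipley", "shipley_corrected", "as_printed")

#: dAIC support thresholds: < 3 substantial, <= 10 considerably less, > 10 none
SUPPORT_THRESHOLDS = (3.0, 10.0)


@dataclass(frozen=True)
class CausalModel:
    """A named DAG over labelled variables.

    ``keep_edges`` marks edges protected from pruning regardless of
    significance (e.g. effects retained for suggestive trends).
    ``claim_overrides`` optionally replaces the derived conditioning set
    for specific non-adjacent pairs, keyed by the sorted pair.
    """

    name: str
    variables: tuple[str, ...]
    edges: tuple[Edge, ...]
    keep_edges: frozenset[Edge] = frozenset()
    response: str | None = None
    claim_overrides: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        vset = set(self.variables)
        if len(vset) != len(self.variables):
            raise ModelError(f"{self.name}: duplicate variable labels")
        for u, v in self.edges:
            if u == v:
                raise ModelError(f"{self.name}: self-loop at {u!r}")
            if u not in vset or v not in vset:
                raise ModelError(f"{self.name}: edge ({u!r}, {v!r}) has endpoint "
                                 "outside the variable list")
        if len(set(self.edges)) != len(self.edges):
            raise ModelError(f"{self.name}: duplicate edges")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ModelError(f"{self.name}: graph is cyclic")
        bad_keep = set(self.keep_edges) - set(self.edges)
        if bad_keep:
            raise ModelError(f"{self.name}: keep-list edges {sorted(bad_keep)} "
                             "not in the model")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, w in self.edges if w == v))

    def n_free_parameters(self, rule: str = "edges") -> int:
        """K for the AIC penalty.

        ``edges`` (default) counts one parameter per path coefficient;
        ``edges_plus_variances`` adds one residual variance per
        variable.  The default keeps the small-sample AIC well defined
        at the study scale (14 sites), where the richer counting rule
        pushes K past n - 1 for the complete model.
        """
        if rule == "edges_plus_variances":
            return len(self.edges) + len(self.variables)
        if rule == "edges":
            return len(self.edges)
        raise DomainError(f"unknown parameter-counting rule {rule!r}")


@dataclass(frozen=True)
class IndependenceClaim:
    """One basis-set claim: X independent of Y given Z, with its test result."""

    x: str
    y: str
    z: tuple[str, ...]
    partial_r: float | None = None
    p_value: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class DSepResult:
    """Fisher's C over the basis set of one model on one dataset."""

    model: str
    C: float
    k: int
    df: int
    p_value: float
    claims: tuple[IndependenceClaim, ...]
    saturated: bool = False


@dataclass(frozen=True)
class ModelScore:
    model: str
    C: float
    K: int
    n: int
    AIC: float
    formula: str
    delta_AIC: float = math.nan
    support_class: str = ""


@dataclass(frozen=True)
class PathEstimate:
    edge: Edge
    coefficient: float
    p_value: float
    n: int


def partial_correlation(x, y, z=()) -> tuple[float, float, int]:
    """Pearson partial correlation of x and y given the vectors in z.

    Residualizes x and y on Z (with intercept) and correlates the
    residuals; with empty Z this is the plain Pearson correlation.  The
    two-sided p-value uses the t distribution with n - 2 - |Z| df.

    Returns ``(r, p, n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zmat = [np.asarray(v, dtype=float) for v in z]
    n = x.size
    if y.size != n or any(v.size != n for v in zmat):
        raise DomainError("x, y and conditioning vectors must share a length")
    if np.isnan(x).any() or np.isnan(y).any() or any(np.isnan(v).any() for v in zmat):
        raise DomainError("missing values must be removed before the test")
    k = len(zmat)
    if n < k + 3:
        raise InsufficientDataError(f"need at least |Z| + 3 = {k + 3} rows, got {n}")
    if k:
        design = np.column_stack([np.ones(n), *zmat])
        coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
        rx = x - design @ coef_x
        ry = y - design @ coef_y
    else:
        rx = x - x.mean()
        ry = y - y.mean()
    sx = float(np.sqrt(rx @ rx))
    sy = float(np.sqrt(ry @ ry))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance after residualization")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        raise InsufficientDataError("non-positive degrees of freedom")
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p), n


def basis_set(model: CausalModel) -> list[IndependenceClaim]:
    """Independence claims testing the model: one per non-adjacent pair.

    For each unordered pair (X, Y) with no edge in either direction, the
    conditioning set is the union of the parents of X and the parents of
    Y; the list is ordered lexicographically by the sorted pair.  Any
    entry in ``model.claim_overrides`` replaces the derived set.
    """
    adjacent = {frozenset(e) for e in model.edges}
    claims = []
    ordered = sorted(model.variables)
    for i, xvar in enumerate(ordered):
        for yvar in ordered[i + 1:]:
            if frozenset((xvar, yvar)) in adjacent:
                continue
            if (xvar, yvar) in model.claim_overrides:
                zset = tuple(sorted(model.claim_overrides[(xvar, yvar)]))
            else:
                zset = tuple(sorted((set(model.parents(xvar))
                                     | set(model.parents(yvar)))
                                    - {xvar, yvar}))
            claims.append(IndependenceClaim(x=xvar, y=yvar, z=zset))
    return claims


def fisher_c(p_values) -> float:
    """Fisher's C = -2 * sum(ln p_i) over independence p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 0.0
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("an independence p-value is exactly 0: the model is "
                      "decisively rejected (C = inf)", stacklevel=2)
        return math.inf
    return float(-2.0 * np.log(p).sum())


def dsep_test(model: CausalModel, data: pd.DataFrame) -> DSepResult:
    """Run every basis-set claim on ``data`` and aggregate into Fisher's C.

    Rows with a missing value in any model variable are dropped
    (complete-case).  An empty basis set (saturated model) returns
    C = 0, df = 0, p = 1 by convention.
    """
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise DomainError(f"data lacks model variable(s) {missing}")
    frame = data[list(model.variables)].dropna()
    claims = basis_set(model)
    if not claims:
        return DSepResult(model=model.name, C=0.0, k=0, df=0, p_value=1.0,
                          claims=(), saturated=True)
    tested = []
    for c in claims:
        r, p, n = partial_correlation(frame[c.x], frame[c.y],
                                      [frame[v] for v in c.z])
        tested.append(replace(c, partial_r=r, p_value=p, n=n))
    C = fisher_c([c.p_value for c in tested])
    df = 2 * len(tested)
    p_val = float(stats.chi2.sf(C, df)) if math.isfinite(C) else 0.0
    return DSepResult(model=model.name, C=C, k=len(tested), df=df,
                      p_value=p_val, claims=tuple(tested))


def model_aic(result: DSepResult, K: int, n: int,
              formula: str = "shipley_corrected") -> ModelScore:
    """AIC of a model from its Fisher's C.

    ``shipley``: AIC = C + 2K.  ``shipley_corrected`` (default, the
    small-sample form): AIC = C + 2K * n / (n - K - 1).  ``as_printed``
    (audit option): AIC = 2 ln C + 2K, which is undefined for C <= 0 —
    one reason it is not the default.
    """
    if K < 1:
        raise DomainError("K must be >= 1")
    if formula == "shipley":
        aic = result.C + 2.0 * K
    elif formula == "shipley_corrected":
        if n <= K + 1:
            raise DomainError(f"corrected AIC needs n > K + 1 (n={n}, K={K})")
        aic = result.C + 2.0 * K * n / (n - K - 1.0)
    elif formula == "as_printed":
        if result.C <= 0:
            raise DomainError("AIC = 2 ln C + 2K is undefined for C <= 0")
        aic = 2.0 * math.log(result.C) + 2.0 * K
    else:
        raise DomainError(f"unknown AIC formula {formula!r}; "
                          f"choose one of {AIC_FORMULAS}")
    return ModelScore(model=result.model, C=result.C, K=K, n=n,
                      AIC=float(aic), formula=formula)


def support_class(delta: float) -> str:
    """Qualitative support from dAIC: substantial / less / none."""
    lo, hi = SUPPORT_THRESHOLDS
    if delta < lo:
        return "substantial"
    if delta <= hi:
        return "less"
    return "none"


def rank_models(scores: list[ModelScore]) -> list[ModelScore]:
    """Attach dAIC and support class; sort by AIC then model name."""
    if not scores:
        return []
    best = min(s.AIC for s in scores)
    ranked = [replace(s, delta_AIC=s.AIC - best, support_class=support_class(s.AIC - best))
              for s in scores]
    return sorted(ranked, key=lambda s: (s.AIC, s.model))


def path_coefficients(model: CausalModel, data: pd.DataFrame) -> list[PathEstimate]:
    """Standardized path coefficient for every edge of the model.

    For edge X -> Y the coefficient is the partial correlation of X and
    Y conditioning on Y's other parents; a sole-parent edge reduces to
    the plain Pearson correlation.  Edge order follows the model.
    """
    frame = data[list(model.variables)].dropna()
    estimates = []
    for (u, v) in model.edges:
        others = [p for p in model.parents(v) if p != u]
        r, p, n = partial_correlation(frame[u], frame[v],
                                      [frame[w] for w in others])
        estimates.append(PathEstimate(edge=(u, v), coefficient=r, p_value=p, n=n))
    return estimates


def prune_model(model: CausalModel, estimates: list[PathEstimate],
                alpha: float = 0.05, min_abs_r: float = 0.0,
                name: str | None = None) -> CausalModel:
    """Nested model with weak, non-significant edges removed.

    An edge is dropped when its p-value exceeds ``alpha`` and |r| falls
    below ``min_abs_r`` (with the default ``min_abs_r = 0`` the p-value
    rule alone decides).  Edges on the model's keep-list survive
    regardless.  Variables left without any edge are removed.
    """
    by_edge = {e.edge: e for e in estimates}
    missing = set(model.edges) - set(by_edge)
    if missing:
        raise DomainError(f"no estimate for edge(s) {sorted(missing)}")
    kept = []
    for edge in model.edges:
        est = by_edge[edge]
        # weak = non-significant and, when an |r| floor is set, also small
        weak = est.p_value > alpha if min_abs_r == 0.0 else (
            est.p_value > alpha and abs(est.coefficient) < min_abs_r)
        if edge in model.keep_edges or not weak:
            kept.append(edge)
    if not kept:
        warnings.warn(f"{model.name}: pruning removed every edge", stacklevel=2)
    used = {v for e in kept for v in e}
    variables = tuple(v for v in model.variables if v in used) or model.variables
    return CausalModel(
        name=name or f"{model.name}-pruned",
        variables=variables,
        edges=tuple(kept),
        keep_edges=frozenset(e for e in model.keep_edges if e in kept),
        response=model.response if (model.response in used or not kept) else None,
    )


def implied_covariance(model: CausalModel, coefficients: dict[Edge, float],
                       noise_variances: dict[str, float]) -> pd.DataFrame:
    """Model-implied covariance of a linear Gaussian system.

    With x = B^T x + e (B[i, j] the coefficient of edge i -> j) and
    independent noises e with the given variances, the covariance is
    (I - B^T)^-1 Omega (I - B^T)^-T.  Used for calibrating synthetic
    data and for closed-form checks of estimated partial correlations.
    """
    order = list(model.variables)
    idx = {v: i for i, v in enumerate(order)}
    m = len(order)
    B = np.zeros((m, m))
    for (u, v), b in coefficients.items():
        if (u, v) not in model.edges:
            raise DomainError(f"coefficient for non-edge ({u!r}, {v!r})")
        B[idx[u], idx[v]] = b
    omega = np.diag([noise_variances[v] for v in order])
    inv = np.linalg.inv(np.eye(m) - B.T)
    sigma = inv @ omega @ inv.T
    return pd.DataFrame(sigma, index=order, columns=order)


def partial_correlation_from_cov(sigma: pd.DataFrame, x: str, y: str,
                                 z: tuple[str, ...] = ()) -> float:
    """Population partial correlation implied by a covariance matrix."""
    labels = [x, y, *z]
    sub = sigma.loc[labels, labels].to_numpy()
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))
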