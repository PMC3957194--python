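"""Per-voxel path-model regressions and conditional indirect effects.

The causal model relates age group A (young=0, old=1), brain activity B
(a first-level task contrast value) and task performance C (seconds of
switch cost) through two linear equations:

    mediator:            B = b0 + a*A + e
    outcome (moderated): C = b0 + b*B + c'*A + v*A*B + e
    outcome (simple):    C = b0 + b*B + c'*A + e

The moderated outcome equation can be rewritten as
C = b0 + c'*A + (b + v*A)*B + e, so the brain->performance slope is
conditional on group, and the indirect (mediated) effect of group on
performance is a*(b + v*A): a*b for the young group, a*b + a*v for the
old group.

A "reversed" outcome formulation, B = b0 + g*A + h*C + j*A*C + e, is the
way standard neuroimaging packages would set up the same three variables
(brain as the dependent measure).  It is provided for comparison only:
it does not encode the causal ordering and in general yields different
interaction statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    InsufficientGroupsError,
    SingularDesignError,
)

YOUNG = 0
OLD = 1

ModelKind = Literal["moderated", "simple", "reversed"]


@dataclass(frozen=True)
class CoefficientEstimate:
    """A single regression coefficient with its t-based inference."""

    estimate: float
    standard_error: float
    t_value: float
    p_value: float


@dataclass(frozen=True)
class PathVariables:
    """Per-subject triples (group A, brain B, performance C) at one voxel."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    @staticmethod
    def from_arrays(A, B, C) -> "PathVariables":
        A = np.asarray(A, dtype=float).ravel()
        B = np.asarray(B, dtype=float).ravel()
        C = np.asarray(C, dtype=float).ravel()
        if not (A.shape == B.shape == C.shape):
            raise InsufficientDataError("A, B and C must have equal length")
        if A.size < 4:
            raise InsufficientDataError("need at least 4 subjects")
        if not np.isin(A, (YOUNG, OLD)).all():
            raise InsufficientGroupsError(
                "group codes must be 0 (young) or 1 (old)")
        if not ((A == YOUNG).any() and (A == OLD).any()):
            raise InsufficientGroupsError("both groups must be represented")
        if not (np.isfinite(B).all() and np.isfinite(C).all()):
            raise InsufficientDataError("B and C must be finite")
        return PathVariables(A=A, B=B, C=C)

    @property
    def n(self) -> int:
        return self.A.size


@dataclass(frozen=True)
class OLSFit:
    """Least-squares fit summary for an arbitrary design matrix."""

    coefficients: tuple[CoefficientEstimate, ...]
    r_squared: float
    dof: int
    residual_variance: float
    degenerate: bool = False


@dataclass(frozen=True)
class MediatorFit:
    """Fit of B = b0 + a*A + e."""

    intercept: CoefficientEstimate
    a: CoefficientEstimate
    r_squared: float
    dof: int
    residual_variance: float
    degenerate: bool = False


@dataclass(frozen=True)
class OutcomeFit:
    """Fit of the outcome equation (moderated, simple, or reversed)."""

    kind: ModelKind
    intercept: CoefficientEstimate
    r_squared: float
    dof: int
    residual_variance: float
    b: CoefficientEstimate | None = None
    c_prime: CoefficientEstimate | None = None
    v: CoefficientEstimate | None = None
    g: CoefficientEstimate | None = None
    h: CoefficientEstimate | None = None
    j: CoefficientEstimate | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class ConditionalIndirect:
    """Indirect effect of group on performance, conditional on group."""

    group: int
    value: float


def _coefficient(beta: float, se: float, dof: int) -> CoefficientEstimate:
    if se > 0:
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), dof)
    elif beta == 0.0:
        # zero-variance convention: a slope that cannot be anything else
        # carries no evidence
        t, p = 0.0, 1.0
    else:
        t, p = math.copysign(math.inf, beta), 0.0
    return CoefficientEstimate(float(beta), float(se), float(t), float(p))


def ols_solve(design, response, column_names: Sequence[str] | None = None) -> OLSFit:
    """Ordinary least squares with classical t inference per column.

    ``design`` must carry a leading intercept column.  Raises
    :class:`SingularDesignError` naming the first linearly dependent
    column, and :class:`InsufficientDataError` when n <= p.  A constant
    response is handled by convention (slopes 0, p = 1, degenerate flag)
    rather than by raising, so voxel sweeps can skip flat voxels.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if column_names is None:
        column_names = ["intercept"] + [f"x{i}" for i in range(1, p)]
    if n <= p:
        raise InsufficientDataError(
            f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        prev = 1  # the intercept column alone always has rank 1
        for j in range(1, p):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == prev:
                raise SingularDesignError(column_names[j])
            prev = r
        raise SingularDesignError(column_names[0])
    dof = n - p

    if np.ptp(y) == 0.0:
        coefs = [CoefficientEstimate(float(y[0]), 0.0, 0.0, 1.0)]
        coefs += [_coefficient(0.0, 0.0, dof) for _ in range(p - 1)]
        return OLSFit(tuple(coefs), 0.0, dof, 0.0, degenerate=True)

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    # exact fits produce tiny negative/zero residual noise; treat as exact
    if rss <= 1e-12 * max(tss, 1.0):
        rss, sigma2 = 0.0, 0.0
        se = np.zeros(p)
    coefs = tuple(_coefficient(b, s, dof) for b, s in zip(beta, se))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OLSFit(coefs, float(r2), dof, float(sigma2))


def fit_mediator(vars: PathVariables) -> MediatorFit:
    """Fit B = b0 + a*A + e.

    With binary A the slope equals the old-minus-young difference of
    group means and the intercept equals the young-group mean.
    """
    X = np.column_stack([np.ones(vars.n), vars.A])
    fit = ols_solve(X, vars.B, ["intercept", "A"])
    return MediatorFit(
        intercept=fit.coefficients[0],
        a=fit.coefficients[1],
        r_squared=fit.r_squared,
        dof=fit.dof,
        residual_variance=fit.residual_variance,
        degenerate=fit.degenerate,
    )


def fit_outcome(vars: PathVariables, kind: ModelKind = "moderated") -> OutcomeFit:
    """Fit the outcome equation of the requested kind.

    moderated: C ~ 1 + B + A + A*B   (coefficients b, c', v)
    simple:    C ~ 1 + B + A         (coefficients b, c')
    reversed:  B ~ 1 + A + C + A*C   (coefficients g, h, j)

    Raises :class:`SingularDesignError` when a predictor column (for
    example the interaction term when B is constant within groups) is
    collinear with the others.
    """
    n = vars.n
    ones = np.ones(n)
    if kind == "moderated":
        X = np.column_stack([ones, vars.B, vars.A, vars.A * vars.B])
        fit = ols_solve(X, vars.C, ["intercept", "B", "A", "A*B"])
        return OutcomeFit(
            kind=kind, intercept=fit.coefficients[0],
            b=fit.coefficients[1], c_prime=fit.coefficients[2],
            v=fit.coefficients[3], r_squared=fit.r_squared, dof=fit.dof,
            residual_variance=fit.residual_variance, degenerate=fit.degenerate)
    if kind == "simple":
        X = np.column_stack([ones, vars.B, vars.A])
        fit = ols_solve(X, vars.C, ["intercept", "B", "A"])
        return OutcomeFit(
            kind=kind, intercept=fit.coefficients[0],
            b=fit.coefficients[1], c_prime=fit.coefficients[2],
            r_squared=fit.r_squared, dof=fit.dof,
            residual_variance=fit.residual_variance, degenerate=fit.degenerate)
    if kind == "reversed":
        X = np.column_stack([ones, vars.A, vars.C, vars.A * vars.C])
        fit = ols_solve(X, vars.B, ["intercept", "A", "C", "A*C"])
        return OutcomeFit(
            kind=kind, intercept=fit.coefficients[0],
            g=fit.coefficients[1], h=fit.coefficients[2],
            j=fit.coefficients[3], r_squared=fit.r_squared, dof=fit.dof,
            residual_variance=fit.residual_variance, degenerate=fit.degenerate)
    raise ValueError(f"unknown model kind: {kind!r}")


def conditional_indirect(a: float, b: float, v: float, group: int) -> ConditionalIndirect:
    """Conditional indirect effect a*(b + v*A) of group on performance.

    For the young group (A=0) this is a*b; for the old group (A=1) it is
    a*b + a*v.  For a simple mediation model pass v=0, which makes the
    indirect effect identical for both groups.
    """
    if group not in (YOUNG, OLD):
        raise InsufficientGroupsError("group must be 0 (young) or 1 (old)")
    return ConditionalIndirect(group=group, value=float(a * (b + v * group)))


def variance_explained(C, predictor_sets: Sequence[tuple[str, np.ndarray]]) -> dict[str, float]:
    """R-squared of nested models built by accumulating predictor blocks.

    ``predictor_sets`` is an ordered sequence of (name, n-by-k matrix)
    blocks; block i's reported R-squared uses an intercept plus all
    blocks up to and including i, so values are non-decreasing.
    """
    y = np.asarray(C, dtype=float).ravel()
    X = np.ones((y.size, 1))
    names = ["intercept"]
    out: dict[str, float] = {}
    for name, block in predictor_sets:
        block = np.asarray(block, dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        X = np.hstack([X, block])
        names += [f"{name}[{i}]" for i in range(block.shape[1])]
        out[name] = ols_solve(X, y, names).r_squared
    return out


def total_effect(vars: PathVariables) -> CoefficientEstimate:
    """Slope of C ~ 1 + A: the total effect of group on performance.

    In a simple mediation model with no further covariates this equals
    c' + a*b exactly (the classical effect decomposition).
    """
    X = np.column_stack([np.ones(vars.n), vars.A])
    return ols_solve(X, vars.C, ["intercept", "A"]).coefficients[1]
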