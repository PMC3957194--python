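"""Stratified bootstrap inference for conditional indirect effects.

Resampling is stratified by age group: every resample draws, with
replacement, exactly n_young subjects from the young stratum and n_old
from the old stratum, so the unequal group sizes of the design are
preserved in every draw.  Confidence intervals are bias-corrected (BC)
percentile intervals by default; bias-corrected accelerated (BCa) and
plain percentile intervals are also available.

The per-resample refits are vectorised: because stratified resampling
fixes which columns of the index matrix hold young vs old subjects, the
group column of the design matrix is constant across resamples, and the
normal equations of the small outcome regressions can be assembled from
row sums and solved as a batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, InsufficientGroupsError
from .paths import (
    OLD,
    YOUNG,
    CoefficientEstimate,
    PathVariables,
    conditional_indirect,
    fit_mediator,
    fit_outcome,
)

CI_METHODS = ("bias_corrected", "bca", "percentile")


@dataclass(frozen=True)
class BootstrapSettings:
    """How many resamples, which interval, at what level, which seed."""

    n_resamples: int = 5000
    alpha: float = 0.05
    ci_method: str = "bias_corrected"
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be at least 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha * self.n_resamples < 2:
            raise ValueError("alpha * n_resamples must be at least 2")
        if self.ci_method not in CI_METHODS:
            raise ValueError(f"ci_method must be one of {CI_METHODS}")


@dataclass(frozen=True)
class ResamplePlan:
    """Pre-drawn stratified resample indices, shared across voxels.

    ``indices`` is an (R, n) integer matrix of subject row indices.  The
    first n_young columns always index young subjects and the remaining
    n_old columns old subjects, which is what makes batched refitting
    possible.
    """

    indices: np.ndarray
    n_young: int
    n_old: int

    @property
    def n_resamples(self) -> int:
        return self.indices.shape[0]

    @property
    def young_columns(self) -> slice:
        return slice(0, self.n_young)

    @property
    def old_columns(self) -> slice:
        return slice(self.n_young, self.n_young + self.n_old)


@dataclass(frozen=True)
class IndirectCI:
    """Bootstrap confidence interval for one group's indirect effect."""

    group: int
    point: float
    lower: float
    upper: float
    z0: float
    significant: bool
    accel: float = 0.0
    degenerate: bool = False


@dataclass(frozen=True)
class BootstrapResult:
    """Per-voxel bootstrap outcome: one CI per group plus bookkeeping."""

    young: IndirectCI
    old: IndirectCI
    n_dropped: int = 0
    degenerate: bool = False


def make_resample_plan(group_labels, settings: BootstrapSettings) -> ResamplePlan:
    """Draw the stratified resample index matrix, deterministic in seed."""
    A = np.asarray(group_labels)
    young_idx = np.flatnonzero(A == YOUNG)
    old_idx = np.flatnonzero(A == OLD)
    if young_idx.size == 0 or old_idx.size == 0:
        raise InsufficientGroupsError("both strata must be non-empty")
    rng = np.random.default_rng(settings.seed)
    R = settings.n_resamples
    young_draw = young_idx[rng.integers(0, young_idx.size, size=(R, young_idx.size))]
    old_draw = old_idx[rng.integers(0, old_idx.size, size=(R, old_idx.size))]
    return ResamplePlan(
        indices=np.hstack([young_draw, old_draw]),
        n_young=young_idx.size,
        n_old=old_idx.size,
    )


def _order_statistic(sorted_draws: np.ndarray, prob: float) -> float:
    """Nearest-rank empirical quantile: the ceil(p*R)-th order statistic."""
    R = sorted_draws.size
    k = min(max(int(math.ceil(prob * R)), 1), R)
    return float(sorted_draws[k - 1])


def percentile_interval(draws, alpha: float) -> tuple[float, float]:
    s = np.sort(np.asarray(draws, dtype=float))
    return (_order_statistic(s, alpha / 2.0),
            _order_statistic(s, 1.0 - alpha / 2.0))


def bc_interval(draws, point: float, alpha: float) -> tuple[float, float, float]:
    """Bias-corrected percentile interval.

    z0 is the normal quantile of the proportion of bootstrap draws
    strictly below the point estimate (ties count to the upper side),
    clamped to [1/(2R), 1 - 1/(2R)] when the proportion is degenerate.
    Endpoints are nearest-rank empirical quantiles at the shifted
    probabilities Phi(2*z0 + z_{alpha/2}) and Phi(2*z0 + z_{1-alpha/2}).
    Returns (lower, upper, z0).
    """
    d = np.asarray(draws, dtype=float).ravel()
    R = d.size
    if R < 100:
        raise InsufficientDataError("need at least 100 bootstrap draws")
    if not np.isfinite(d).all():
        raise InsufficientDataError("bootstrap draws must be finite")
    if np.ptp(d) == 0.0:
        return float(d[0]), float(d[0]), 0.0
    prop = np.count_nonzero(d < point) / R
    prop = min(max(prop, 1.0 / (2 * R)), 1.0 - 1.0 / (2 * R))
    z0 = float(stats.norm.ppf(prop))
    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)
    p_lo = stats.norm.cdf(2.0 * z0 + z_lo)
    p_hi = stats.norm.cdf(2.0 * z0 + z_hi)
    s = np.sort(d)
    return _order_statistic(s, p_lo), _order_statistic(s, p_hi), z0


def bca_interval(draws, point: float, alpha: float,
                 jackknife_estimates) -> tuple[float, float, float, float]:
    """Bias-corrected accelerated interval.

    The acceleration constant comes from the jackknife skewness formula
    a = sum((m - t_i)^3) / (6 * sum((m - t_i)^2)^{3/2}) with m the mean
    of the leave-one-out estimates t_i.  With a = 0 this reduces exactly
    to :func:`bc_interval`.  Returns (lower, upper, z0, accel).
    """
    jack = np.asarray(jackknife_estimates, dtype=float).ravel()
    if jack.size < 3:
        raise InsufficientDataError("need at least 3 jackknife estimates")
    d = np.asarray(draws, dtype=float).ravel()
    if np.ptp(d) == 0.0:
        return float(d[0]), float(d[0]), 0.0, 0.0
    centred = jack.mean() - jack
    denom = 6.0 * float(np.sum(centred**2)) ** 1.5
    if denom == 0.0:
        lo, hi, z0 = bc_interval(d, point, alpha)
        return lo, hi, z0, 0.0
    accel = float(np.sum(centred**3)) / denom

    R = d.size
    prop = np.count_nonzero(d < point) / R
    prop = min(max(prop, 1.0 / (2 * R)), 1.0 - 1.0 / (2 * R))
    z0 = float(stats.norm.ppf(prop))
    s = np.sort(d)
    out = []
    for z in (stats.norm.ppf(alpha / 2.0), stats.norm.ppf(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        out.append(_order_statistic(s, float(stats.norm.cdf(adj))))
    return out[0], out[1], z0, accel


def sobel_test(a_fit: CoefficientEstimate, b_fit: CoefficientEstimate) -> tuple[float, float]:
    """Normal-theory z test of the product a*b (delta-method SE).

    A cheap cross-check on the bootstrap: z = a*b / sqrt(a^2 se_b^2 +
    b^2 se_a^2), two-sided normal p.
    """
    a, sa = a_fit.estimate, a_fit.standard_error
    b, sb = b_fit.estimate, b_fit.standard_error
    if sa <= 0 or sb <= 0:
        raise InsufficientDataError("Sobel test needs positive standard errors")
    denom = math.sqrt(a * a * sb * sb + b * b * sa * sa)
    if denom == 0.0:
        return 0.0, 1.0
    z = a * b / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# vectorised per-resample refitting


def _batched_solve(XtX: np.ndarray, Xty: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve a stack of small normal-equation systems, flagging singular ones.

    Returns (beta, good) where bad rows hold NaN.  Singularity is judged
    by the determinant relative to the Hadamard bound of the diagonal.
    """
    diag = np.einsum("rii->ri", XtX)
    scale = np.prod(np.maximum(np.abs(diag), 1e-300), axis=1)
    det = np.linalg.det(XtX)
    good = np.abs(det) > 1e-12 * scale
    beta = np.full(Xty.shape, np.nan)
    if good.any():
        beta[good] = np.linalg.solve(XtX[good], Xty[good][..., None])[..., 0]
    good &= np.isfinite(beta).all(axis=1)
    return beta, good


def indirect_draws(B: np.ndarray, C: np.ndarray, plan: ResamplePlan,
                   model_kind: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-resample conditional indirect effects for both groups.

    Refits the mediator and outcome equations on every resample of the
    plan and returns (ind_young, ind_old, good) arrays of length R, with
    NaN where the resampled design was singular.
    """
    idx = plan.indices
    yc, oc = plan.young_columns, plan.old_columns
    n = plan.n_young + plan.n_old
    n_o = plan.n_old
    Bb = B[idx]
    Cb = C[idx]

    a = Bb[:, oc].mean(axis=1) - Bb[:, yc].mean(axis=1)

    Sb = Bb.sum(axis=1)
    Sbb = np.einsum("rj,rj->r", Bb, Bb)
    Sab = Bb[:, oc].sum(axis=1)
    Sabb = np.einsum("rj,rj->r", Bb[:, oc], Bb[:, oc])
    Sc = Cb.sum(axis=1)
    Sac = Cb[:, oc].sum(axis=1)
    Sbc = np.einsum("rj,rj->r", Bb, Cb)
    Sabc = np.einsum("rj,rj->r", Bb[:, oc], Cb[:, oc])

    R = idx.shape[0]
    if model_kind == "moderated":
        # columns: [1, B, A, A*B]
        XtX = np.empty((R, 4, 4))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = Sb
        XtX[:, 0, 2] = XtX[:, 2, 0] = n_o
        XtX[:, 0, 3] = XtX[:, 3, 0] = Sab
        XtX[:, 1, 1] = Sbb
        XtX[:, 1, 2] = XtX[:, 2, 1] = Sab
        XtX[:, 1, 3] = XtX[:, 3, 1] = Sabb
        XtX[:, 2, 2] = n_o
        XtX[:, 2, 3] = XtX[:, 3, 2] = Sab
        XtX[:, 3, 3] = Sabb
        Xty = np.stack([Sc, Sbc, Sac, Sabc], axis=1)
        beta, good = _batched_solve(XtX, Xty)
        b, v = beta[:, 1], beta[:, 3]
        ind_young = a * b
        ind_old = a * (b + v)
    elif model_kind == "simple":
        # columns: [1, B, A]
        XtX = np.empty((R, 3, 3))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = Sb
        XtX[:, 0, 2] = XtX[:, 2, 0] = n_o
        XtX[:, 1, 1] = Sbb
        XtX[:, 1, 2] = XtX[:, 2, 1] = Sab
        XtX[:, 2, 2] = n_o
        Xty = np.stack([Sc, Sbc, Sac], axis=1)
        beta, good = _batched_solve(XtX, Xty)
        b = beta[:, 1]
        ind_young = a * b
        ind_old = a * b
    else:
        raise ValueError(f"cannot bootstrap model kind {model_kind!r}")
    ind_young = np.where(good, ind_young, np.nan)
    ind_old = np.where(good, ind_old, np.nan)
    return ind_young, ind_old, good


def _jackknife_indirect(vars: PathVariables, model_kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out conditional indirect effects (for BCa)."""
    n = vars.n
    ind_y = np.empty(n)
    ind_o = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        sub = PathVariables(vars.A[keep], vars.B[keep], vars.C[keep])
        med = fit_mediator(sub)
        out = fit_outcome(sub, model_kind)
        v = out.v.estimate if model_kind == "moderated" else 0.0
        ind_y[i] = conditional_indirect(med.a.estimate, out.b.estimate, v, YOUNG).value
        ind_o[i] = conditional_indirect(med.a.estimate, out.b.estimate, v, OLD).value
        keep[i] = True
    return ind_y, ind_o


def _interval(draws: np.ndarray, point: float, settings: BootstrapSettings,
              jackknife: np.ndarray | None) -> tuple[float, float, float, float]:
    if settings.ci_method == "percentile":
        lo, hi = percentile_interval(draws, settings.alpha)
        return lo, hi, 0.0, 0.0
    if settings.ci_method == "bca":
        return bca_interval(draws, point, settings.alpha, jackknife)
    lo, hi, z0 = bc_interval(draws, point, settings.alpha)
    return lo, hi, z0, 0.0


def bootstrap_indirect(vars: PathVariables, model_kind: str,
                       plan: ResamplePlan, settings: BootstrapSettings) -> BootstrapResult:
    """Bootstrap CIs for both groups' conditional indirect effects.

    The point estimates come from the original (unresampled) fit; each
    resample refits the mediator and the selected outcome model.
    Resamples with singular designs are dropped when they are at most 1%
    of the plan; more than that marks the voxel degenerate.
    """
    med = fit_mediator(vars)
    out = fit_outcome(vars, model_kind)
    v = out.v.estimate if model_kind == "moderated" else 0.0
    point_y = conditional_indirect(med.a.estimate, out.b.estimate, v, YOUNG).value
    point_o = conditional_indirect(med.a.estimate, out.b.estimate, v, OLD).value

    draws_y, draws_o, good = indirect_draws(vars.B, vars.C, plan, model_kind)
    n_bad = int(np.count_nonzero(~good))
    R = plan.n_resamples
    if n_bad > 0.01 * R:
        nan_ci = IndirectCI(YOUNG, point_y, math.nan, math.nan, 0.0, False,
                            degenerate=True)
        return BootstrapResult(
            young=nan_ci,
            old=replace(nan_ci, group=OLD, point=point_o),
            n_dropped=n_bad, degenerate=True)

    jack_y = jack_o = None
    if settings.ci_method == "bca":
        jack_y, jack_o = _jackknife_indirect(vars, model_kind)

    cis = []
    for group, draws, point, jack in ((YOUNG, draws_y, point_y, jack_y),
                                      (OLD, draws_o, point_o, jack_o)):
        d = draws[good]
        lo, hi, z0, accel = _interval(d, point, settings, jack)
        cis.append(IndirectCI(
            group=group, point=point, lower=lo, upper=hi, z0=z0,
            significant=bool(not (lo <= 0.0 <= hi)), accel=accel,
            degenerate=bool(np.ptp(d) == 0.0)))
    return BootstrapResult(young=cis[0], old=cis[1], n_dropped=n_bad)
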