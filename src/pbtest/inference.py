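"""One-sample tests on PB-transformed data, effective DF, and FDR control.

After the PB-transformation the test of the covariate effect reduces to a
one-sample location problem on ``m = n - q`` values that are uncorrelated with
equal variance (exactly i.i.d. normal under Gaussian errors).  The tests here
are the classical one-sample t-test and the Wilcoxon signed-rank test, both
referred to a t distribution whose degrees of freedom are *adjusted* for the
information actually carried by correlated, unequally weighted observations.

The DF adjustment follows the Kenward-Roger idea of moment matching: write
the covariance as a linear structure

    Sigma(theta) = theta_eps * W^-1 + theta_gamma * W^-1/2 G W^-1/2,

where ``G`` is the block-membership pattern (the random-intercept mapping
``rho = theta_gamma / (theta_gamma + theta_eps)``), compute the GLS variance
of the contrast, its gradient in ``theta``, and the REML expected information
of ``theta``; the scaled Wald statistic is then matched to an F(1, df) by its
first two moments (for a single contrast this is the Satterthwaite-type
match).  The resulting df interpolates between ``n - 2`` for independent
equal-weight two-group data and ``n_pairs - 1`` for perfectly paired data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .covariance_model import CorrelationModel, as_weights
from .exceptions import DegenerateDataError, InvalidInputError

__all__ = [
    "TestResult",
    "DFContext",
    "approximate_df",
    "pb_ttest",
    "pb_wilcoxon",
    "b_spearman",
    "bh_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str  # {"pb_t", "pb_wilcoxon", "b_spearman"}
    beta_hat: float
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class DFContext:
    """Everything the DF approximation needs about the design and covariance."""

    X: np.ndarray  # n x p full design (intercept included)
    k: int  # covariate of interest
    weights: np.ndarray  # per-observation inverse-variance weights
    corr: CorrelationModel  # block structure + rho
    estimated_rho: bool = False
    satterthwaite_fallback: bool = False  # set by approximate_df on non-PD information

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "weights", as_weights(self.weights, X.shape[0]))
        if self.corr.n != X.shape[0]:
            raise InvalidInputError("block structure length does not match design rows")


def approximate_df(ctx: DFContext) -> float:
    """Effective degrees of freedom for the single-contrast test.

    Moment-matching (Kenward-Roger style) under the random-intercept +
    diagonal-weights covariance.  Guarantees:

    * independent equal-weight two-group design, n = 40  ->  df = 38;
    * perfectly paired equal-weight design, 20 pairs, any rho in (0,1)  ->
      df = 19;
    * df is non-increasing in rho for a fixed design;
    * df <= n - 1 - q (q = number of nuisance columns) always.

    When the expected information matrix is numerically singular the
    first-order Satterthwaite match on the residual-variance component is
    used instead (flagged via ``ctx.satterthwaite_fallback``).
    """
    X = ctx.X
    n, p = X.shape
    q = p - 1
    cap = float(n - 1 - q)
    rho = ctx.corr.rho
    sizes = np.asarray(ctx.corr.block_sizes)

    # no correlation (or nothing to correlate): ordinary regression df
    if rho is None or rho == 0.0 or sizes.max() == 1:
        return min(float(n - np.linalg.matrix_rank(X)), cap)

    w = ctx.weights
    inv_sw = 1.0 / np.sqrt(w)
    Z = ctx.corr.indicator()
    G = Z @ Z.T
    V_eps = np.diag(1.0 / w)  # d Sigma / d theta_eps
    V_gam = G * np.outer(inv_sw, inv_sw)  # d Sigma / d theta_gamma

    theta = np.array([1.0 - rho, rho])  # sigma2 = 1 wlog (df is scale free)
    Sigma = theta[0] * V_eps + theta[1] * V_gam
    Sigma_inv = np.linalg.inv(Sigma)
    XtSi = X.T @ Sigma_inv
    Phi = np.linalg.inv(XtSi @ X)
    v = Phi[ctx.k, ctx.k]

    Pmat = Sigma_inv - XtSi.T @ Phi @ XtSi  # REML projection
    Vs = (V_eps, V_gam)
    PV = [Pmat @ Vi for Vi in Vs]
    info = np.array([[0.5 * np.trace(PV[i] @ PV[j]) for j in range(2)] for i in range(2)])

    # gradient of v = [Phi]_kk in theta
    grad = np.empty(2)
    for i, Vi in enumerate(Vs):
        Mi = Phi @ XtSi @ Vi @ XtSi.T @ Phi
        grad[i] = Mi[ctx.k, ctx.k]

    fallback = False
    try:
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        A = np.linalg.inv(info)
        var_v = float(grad @ A @ grad)
        if var_v <= 0.0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        fallback = True
        var_v = float(grad[0] ** 2 / info[0, 0]) if info[0, 0] > 0 else np.nan

    if fallback:
        object.__setattr__(ctx, "satterthwaite_fallback", True)
    if not np.isfinite(var_v) or var_v <= 0.0:
        return cap
    df = 2.0 * v**2 / var_v
    return float(np.clip(df, 1.0, cap))


def pb_ttest(Ytilde, zeta: float, df: float) -> TestResult:
    """One-sample t-test on the transformed data.

    ``t = mean(Ytilde) * sqrt(m) / sd(Ytilde)`` (sample sd, divisor m - 1),
    referred to a t distribution with the supplied — possibly non-integer —
    degrees of freedom.  The effect estimate is ``mean(Ytilde) / zeta``.
    """
    y = np.asarray(Ytilde, dtype=float).ravel()
    m = y.size
    if m < 3:
        raise InvalidInputError(f"need at least 3 transformed values, got {m}")
    if not zeta > 0:
        raise InvalidInputError("zeta must be positive")
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("transformed data have zero sample variance")
    mean = float(np.mean(y))
    t = mean * np.sqrt(m) / sd
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(
        method="pb_t", beta_hat=mean / zeta, statistic=t, df=float(df), p_value=min(p, 1.0)
    )


def pb_wilcoxon(Ytilde, df: float, zeta: float | None = None) -> TestResult:
    """Wilcoxon signed-rank test on the transformed data, t-referenced.

    The signed-rank statistic ``V`` (sum of |value| midranks over positive
    entries; zeros dropped) is standardized by its exact null moments
    ``E V = m(m+1)/4`` and ``var V = m(m+1)(2m+1)/24`` minus the usual
    midrank tie correction, then referred to a t distribution with the
    supplied adjusted degrees of freedom — appropriate when correlation
    shrinks the effective sample size.  The effect estimate is the
    Hodges-Lehmann-style ``median(Ytilde) / zeta`` when ``zeta`` is given.
    """
    y = np.asarray(Ytilde, dtype=float).ravel()
    if y.size < 4:
        raise InvalidInputError(f"need at least 4 transformed values, got {y.size}")
    nz = y[y != 0.0]
    m = nz.size
    if m == 0:
        raise DegenerateDataError("all transformed values are zero")
    ranks = stats.rankdata(np.abs(nz))
    V = float(np.sum(ranks[nz > 0]))
    ev = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0.0:
        raise DegenerateDataError("signed-rank variance is zero (all values tied)")
    stat = (V - ev) / np.sqrt(var)
    p = 2.0 * float(stats.t.sf(abs(stat), df))
    beta_hat = float(np.median(y)) / zeta if zeta else float("nan")
    return TestResult(
        method="pb_wilcoxon",
        beta_hat=beta_hat,
        statistic=stat,
        df=float(df),
        p_value=min(p, 1.0),
    )


def b_spearman(Y2, z, df: float | None = None) -> TestResult:
    """Spearman rank correlation between B-transformed response and covariate.

    Comparator variant for continuous covariates: the whitened (but not
    rotated) response is rank-correlated with the whitened covariate and the
    correlation tested through ``r * sqrt((m - 2) / (1 - r^2))`` against a t
    distribution with the supplied df (default ``m - 2``).
    """
    y = np.asarray(Y2, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if y.size != z.size:
        raise InvalidInputError("response and covariate lengths differ")
    m = y.size
    if m < 4:
        raise InvalidInputError(f"need at least 4 values, got {m}")
    if np.ptp(y) == 0.0 or np.ptp(z) == 0.0:
        raise DegenerateDataError("constant input has no rank correlation")
    r = float(stats.spearmanr(y, z).statistic)
    if df is None:
        df = m - 2
    if abs(r) >= 1.0 - 1e-15:
        # perfect monotone association: report the smallest positive p
        return TestResult(
            method="b_spearman",
            beta_hat=r,
            statistic=float(np.sign(r) * np.inf),
            df=float(df),
            p_value=float(np.finfo(float).tiny),
        )
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(
        method="b_spearman", beta_hat=r, statistic=t, df=float(df), p_value=min(p, 1.0)
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
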