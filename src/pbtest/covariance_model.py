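"""Variance-covariance construction, standardization, and correlation estimation.

The covariance model used throughout the package is

    Sigma = W^{-1/2} Cor W^{-1/2},

where ``W`` is a diagonal matrix of per-observation inverse-variance weights
(for RNA-seq, sequencing depth in million reads) and ``Cor`` is a
block-exchangeable (compound-symmetry) correlation matrix: observations from
the same subject/block share a common correlation ``rho``, observations from
different blocks are independent.

Every covariance is split as ``Sigma = sigma2 * S`` with the standardized
structure matrix ``S`` normalized so that ``1' S^{-1} 1 = 1``; this
normalization is what makes the downstream centering and whitening operators
take their simple closed forms.

When ``rho`` is unknown it is estimated from weighted least-squares residuals
by a moment estimator built from two residual sums of squares (within-block
identity and all-pairs forms), optionally bias-corrected by Olkin and Pratt's
multiplier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import (
    DecompositionError,
    EstimationError,
    InvalidInputError,
)

__all__ = [
    "CorrelationModel",
    "CovarianceSpec",
    "RhoEstimate",
    "as_weights",
    "build_covariance",
    "standardize",
    "estimate_rho",
]

#: relative eigenvalue tolerance below which a matrix is treated as singular
PD_RTOL = 1e-10


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def _check_pd(sigma: np.ndarray, name: str = "Sigma") -> np.ndarray:
    """Validate symmetric positive definiteness; return the symmetrized matrix."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise DecompositionError(f"{name} must be a square matrix, got {sigma.shape}")
    if not np.allclose(sigma, sigma.T, rtol=1e-8, atol=1e-8):
        raise DecompositionError(f"{name} is not symmetric")
    sigma = _symmetrize(sigma)
    evals = np.linalg.eigvalsh(sigma)
    if evals[0] <= PD_RTOL * max(evals[-1], 0.0) or evals[-1] <= 0.0:
        raise DecompositionError(
            f"{name} is not positive definite (eigenvalue range "
            f"[{evals[0]:.3e}, {evals[-1]:.3e}])"
        )
    return sigma


def as_weights(w: Sequence[float] | np.ndarray, n: int | None = None) -> np.ndarray:
    """Validate a per-observation weight vector (all entries strictly positive)."""
    w = np.asarray(w, dtype=float).ravel()
    if n is not None and w.size != n:
        raise InvalidInputError(f"weight vector has length {w.size}, expected {n}")
    if w.size == 0 or not np.all(np.isfinite(w)) or np.any(w <= 0.0):
        raise InvalidInputError("weights must be finite and strictly positive")
    return w


@dataclass(frozen=True)
class CorrelationModel:
    """Block-exchangeable correlation structure.

    Each block (subject) of size ``n_l`` has within-block correlation matrix
    ``Cor_l(rho) = (1 - rho) I + rho J``; blocks are mutually independent.
    ``Cor_l`` is positive definite iff ``rho`` lies in
    ``(-1/(n_l - 1), 1)``, so the admissible interval for a shared ``rho`` is
    governed by the largest block.

    Parameters
    ----------
    subject_labels
        Per-observation block identifier, length ``n``, in observation order.
    rho
        Common within-block correlation.  ``None`` for a structure-only model
        (e.g. prior to estimation).
    """

    subject_labels: tuple
    rho: float | None = None
    block_sizes: tuple[int, ...] = field(init=False)
    L: int = field(init=False)

    def __post_init__(self):
        labels = tuple(self.subject_labels)
        if len(labels) == 0:
            raise InvalidInputError("subject_labels must be non-empty")
        object.__setattr__(self, "subject_labels", labels)
        _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
        object.__setattr__(self, "block_sizes", tuple(int(c) for c in counts))
        object.__setattr__(self, "L", len(counts))
        if self.rho is not None:
            lo, hi = self.admissible_interval()
            if not (lo < self.rho < hi):
                raise InvalidInputError(
                    f"rho={self.rho} outside the positive-definite interval "
                    f"({lo:.6g}, {hi:.6g}) for the largest block"
                )

    @property
    def n(self) -> int:
        return len(self.subject_labels)

    def admissible_interval(self) -> tuple[float, float]:
        """Open interval of ``rho`` values keeping every block PD."""
        nmax = max(self.block_sizes)
        lo = -1.0 / (nmax - 1) if nmax > 1 else -1.0
        return lo, 1.0

    def with_rho(self, rho: float) -> "CorrelationModel":
        return CorrelationModel(self.subject_labels, rho)

    def indicator(self) -> np.ndarray:
        """n x L block-membership indicator matrix Z (Z Z' has block-J pattern)."""
        labels = np.asarray(self.subject_labels, dtype=object)
        uniq, inv = np.unique(labels, return_inverse=True)
        Z = np.zeros((labels.size, uniq.size))
        Z[np.arange(labels.size), inv] = 1.0
        return Z

    def correlation_matrix(self) -> np.ndarray:
        """Full n x n correlation matrix in the original observation order."""
        if self.rho is None:
            raise InvalidInputError("rho is not set on this CorrelationModel")
        Z = self.indicator()
        same_block = Z @ Z.T
        n = self.n
        return (1.0 - self.rho) * np.eye(n) + self.rho * same_block


@dataclass(frozen=True)
class CovarianceSpec:
    """A covariance split into magnitude and standardized shape.

    ``Sigma = sigma2 * S`` with ``1' S^{-1} 1 = 1``.  ``source`` records
    whether the matrix was supplied directly or built from weights + rho.
    """

    Sigma: np.ndarray
    sigma2: float
    S: np.ndarray
    source: str = "supplied"  # {"supplied", "built"}

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_sigma(cls, Sigma: np.ndarray, source: str = "supplied") -> "CovarianceSpec":
        sigma2, S = standardize(Sigma)
        return cls(Sigma=np.asarray(Sigma, dtype=float), sigma2=sigma2, S=S, source=source)


@dataclass(frozen=True)
class RhoEstimate:
    """Moment-based correlation estimate with its building blocks.

    ``rho_moment`` is the raw ratio estimator; ``rho`` additionally carries the
    Olkin-Pratt small-sample correction (when applicable) and the clamp into
    the positive-definite admissible interval.
    """

    ss1: float
    ss2: float
    rho_moment: float
    rho: float
    L_used: int
    corrected: bool
    clamped: bool = False


def standardize(Sigma: np.ndarray) -> tuple[float, np.ndarray]:
    """Split a PD covariance into ``(sigma2, S)`` with ``1' S^{-1} 1 = 1``.

    ``sigma2 = 1 / sum_ij (Sigma^{-1})_ij`` and ``S = Sigma / sigma2``.  The
    scalar absorbs the overall magnitude; the shape matrix ``S`` is what the
    transform operators consume.
    """
    Sigma = _check_pd(Sigma, "Sigma")
    n = Sigma.shape[0]
    ones = np.ones(n)
    sol = np.linalg.solve(Sigma, ones)
    total = float(ones @ sol)
    if total <= 0.0:
        raise DecompositionError("sum of inverse-covariance entries is non-positive")
    sigma2 = 1.0 / total
    S = Sigma / sigma2
    return sigma2, S


def build_covariance(weights, corr: CorrelationModel) -> CovarianceSpec:
    """Assemble ``Sigma = W^{-1/2} Cor W^{-1/2}`` and standardize it.

    The correlation matrix is materialized directly in the original
    observation order (block-diagonal after any permutation that makes blocks
    contiguous), so no user-facing reordering occurs.
    """
    w = as_weights(weights, corr.n)
    if corr.rho is None:
        raise InvalidInputError("CorrelationModel must carry rho to build a covariance")
    cor = corr.correlation_matrix()
    inv_sqrt_w = 1.0 / np.sqrt(w)
    Sigma = cor * np.outer(inv_sqrt_w, inv_sqrt_w)
    sigma2, S = standardize(Sigma)
    return CovarianceSpec(Sigma=Sigma, sigma2=sigma2, S=S, source="built")


def _wls_residuals(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """sqrt(w)-scaled residuals of the diagonal-weight least-squares fit.

    With ``cov(y) = sigma^2 W^{-1/2} Cor W^{-1/2}`` the scaled residuals have
    covariance proportional to the block-diagonal correlation alone, which is
    exactly the structure the moment estimator assumes.
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return yw - Xw @ beta


def estimate_rho(
    y,
    X,
    weights,
    corr_blocks: CorrelationModel,
    correct: bool = True,
) -> RhoEstimate:
    """Moment estimator of the within-block correlation.

    Writing ``eps_l`` for the weighted residual vector of block ``l``,

        SS1 = sum_l eps_l' eps_l,      SS2 = sum_l (sum_i eps_li)^2,

    the estimator is ``(SS2 - SS1) / ((1/n) sum_l n_l (n_l - 1) * SS1)``.  On
    balanced designs it coincides with the Gaussian maximum-likelihood
    estimator ``(SS2 - SS1) / ((n_1 - 1) SS1)``.  With ``correct=True`` and
    more than three informative blocks the Olkin-Pratt multiplier
    ``1 + (1 - r^2) / (2 (L - 3))`` is applied.  The result is clamped into
    the positive-definite admissible interval.

    Parameters
    ----------
    y, X
        Response and full design matrix (including intercept and any
        nuisance columns) of the model whose residuals carry the correlation.
    weights
        Per-observation inverse-variance weights.
    corr_blocks
        Block structure (``rho`` ignored if set).
    correct
        Apply the Olkin-Pratt bias correction when enough blocks exist.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise InvalidInputError("y and X row counts differ")
    w = as_weights(weights, y.size)
    if y.size != corr_blocks.n:
        raise InvalidInputError("block structure length does not match y")

    sizes = np.asarray(corr_blocks.block_sizes)
    L_used = int(np.sum(sizes >= 2))
    if L_used == 0:
        raise EstimationError(
            "all blocks are singletons: within-block correlation is not estimable"
        )

    eps = _wls_residuals(y, X, w)
    labels = np.asarray(corr_blocks.subject_labels, dtype=object)
    uniq, inv = np.unique(labels, return_inverse=True)
    ss1 = float(eps @ eps)
    block_sums = np.bincount(inv, weights=eps)
    ss2 = float(block_sums @ block_sums)
    if ss1 <= 0.0:
        raise DegenerateResiduals("residuals are identically zero; rho is undefined")

    n = y.size
    denom = (np.sum(sizes * (sizes - 1)) / n) * ss1
    rho_m = (ss2 - ss1) / denom

    corrected = False
    rho = rho_m
    if correct:
        if L_used > 3:
            rho = rho_m * (1.0 + (1.0 - rho_m**2) / (2.0 * (L_used - 3)))
            corrected = True
        else:
            warnings.warn(
                "Olkin-Pratt correction skipped: needs more than 3 blocks of size >= 2",
                stacklevel=2,
            )

    lo, hi = corr_blocks.admissible_interval()
    lo_c, hi_c = lo + 1e-6, hi - 1e-6
    clamped = not (lo_c <= rho <= hi_c)
    rho = float(np.clip(rho, lo_c, hi_c))
    return RhoEstimate(
        ss1=ss1,
        ss2=ss2,
        rho_moment=float(rho_m),
        rho=rho,
        L_used=L_used,
        corrected=corrected,
        clamped=clamped,
    )


class DegenerateResiduals(EstimationError):
    """Residuals are identically zero, so SS1 = 0 and rho is undefined."""
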