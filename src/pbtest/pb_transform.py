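"""The PB linear operators: nuisance projection, whitening B-map, rotation P-map.

Given a regression problem ``y = X beta + eps`` with ``cov(eps) = sigma2 * S``
and a single covariate of interest (column ``k`` of ``X``), the transform
reduces the test of ``beta_k = 0`` to a one-sample location test:

1. **Projection** ``C = I - X_mk (X_mk' S^-1 X_mk)^-1 X_mk' S^-1`` removes the
   nuisance columns ``X_mk`` by generalized-least-squares residualization
   (for an intercept-only nuisance this is weighted centering,
   ``C = I - J S^-1``).
2. **Whitening** ``B`` is built from the eigen-decomposition of the projected
   structure ``M = C S C' = T Lambda T'`` as ``B = Lambda^{-1/2} T' C``, an
   ``(n - q) x n`` map with ``B S B' = I`` and ``B X_mk = 0``.
3. **Rotation** ``P`` (from a QR construction) is the unique orthogonal map of
   the reduced space sending the transformed covariate ``z = B x_k`` to
   ``zeta * 1`` while acting as the identity on the orthogonal complement of
   ``span(1, z)``.

Under the null the transformed data ``PB y`` are mean-zero with scalar
covariance ``sigma2 * I``; under the alternative they share the common mean
``zeta * beta_k``.  The composite map is computed once per (design,
covariance) pair and applied to any number of response vectors by a single
matrix product — this is what makes feature-by-feature testing cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .covariance_model import CovarianceSpec
from .exceptions import DecompositionError, InvalidDesignError, InvalidInputError

__all__ = [
    "RegressionProblem",
    "TransformOperators",
    "compute_center",
    "compute_B",
    "compute_P",
    "make_plan",
    "apply_plan",
]

_STD_TOL = 1e-8  # tolerance for the 1' S^-1 1 = 1 contract
_RANK_RTOL = 1e-10  # eigenvalue cut relative to the largest eigenvalue


@dataclass(frozen=True)
class RegressionProblem:
    """A response (or feature matrix) with its design and covariate of interest."""

    y: np.ndarray  # length n, or features x n
    X: np.ndarray  # n x p, including the intercept column
    k: int  # index of the covariate under test

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        n, p = X.shape
        if not (0 <= self.k < p):
            raise InvalidDesignError(f"covariate index k={self.k} outside 0..{p - 1}")
        if (y.ndim == 1 and y.size != n) or (y.ndim == 2 and y.shape[1] != n):
            raise InvalidDesignError("response dimension does not match design rows")
        if np.linalg.matrix_rank(X) < p:
            raise InvalidDesignError("design matrix is rank deficient")


@dataclass(frozen=True)
class TransformOperators:
    """The cached operators of one PB plan.

    Attributes
    ----------
    C, B, P
        Projection (n x n), whitening ((n-q) x n) and rotation ((n-q) x (n-q)).
    PB
        The precomputed composite ``P @ B``.
    z
        Transformed covariate ``B x_k`` (length ``n - q``).
    xi
        Cosine of the angle between ``z`` and the constant vector.
    zeta
        ``||z|| / sqrt(n - q)`` — the factor by which the effect appears in
        the one-sample mean.
    eigvals, eigvecs
        Retained spectrum of the projected structure matrix (audit trail).
    df
        Effective degrees of freedom, attached by the inference layer.
    """

    C: np.ndarray
    B: np.ndarray
    P: np.ndarray
    PB: np.ndarray
    z: np.ndarray
    xi: float
    zeta: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    df: float | None = None

    @property
    def m(self) -> int:
        """Dimension of the transformed space (n minus nuisance rank)."""
        return self.B.shape[0]

    def with_df(self, df: float) -> "TransformOperators":
        return replace(self, df=df)


def _check_standardized(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    ones = np.ones(n)
    val = float(ones @ np.linalg.solve(S, ones))
    if abs(val - 1.0) > _STD_TOL * max(1.0, n):
        raise InvalidInputError(
            f"structure matrix is not standardized: 1'S^-1 1 = {val:.6g}, expected 1"
        )
    return S


def compute_center(Y, S) -> tuple[float, np.ndarray]:
    """Weighted centering ``Y - 1 mu_hat`` with ``mu_hat = 1' S^-1 Y``.

    Because ``1' S^-1 1 = 1``, the GLS intercept estimate is the S-weighted
    mean and the centered vector satisfies ``1' S^-1 (Y - 1 mu_hat) = 0``.
    """
    S = _check_standardized(S)
    Y = np.asarray(Y, dtype=float)
    ones = np.ones(S.shape[0])
    weights = np.linalg.solve(S, ones)  # S^-1 1
    mu_hat = float(weights @ Y)
    return mu_hat, Y - mu_hat


def compute_B(S, nuisance) -> tuple[np.ndarray, np.ndarray]:
    """Build the projection ``C`` and whitening ``B`` for a nuisance design.

    ``M = C S C'`` has rank ``n - q``; its eigen-decomposition (descending
    eigenvalues, sign fixed so each eigenvector's largest-magnitude entry is
    positive) yields ``B = Lambda^{-1/2} T' C`` with ``B S B' = I`` and
    ``B X_nuisance = 0``.  For an intercept-only nuisance ``M = S - J``
    exactly.
    """
    S = _check_standardized(S)
    n = S.shape[0]
    Xn = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if Xn.shape[0] != n:
        raise InvalidDesignError("nuisance design rows do not match S")
    q = Xn.shape[1]
    if np.linalg.matrix_rank(Xn) < q:
        raise InvalidDesignError("nuisance design is rank deficient")
    if n - q < 1:
        raise InvalidDesignError("nuisance design leaves no residual dimensions")

    Sinv_Xn = np.linalg.solve(S, Xn)
    gram = Xn.T @ Sinv_Xn
    C = np.eye(n) - Xn @ np.linalg.solve(gram, Sinv_Xn.T)
    M = C @ S @ C.T
    M = (M + M.T) / 2.0

    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > _RANK_RTOL * evals[0]
    if int(np.sum(~keep)) != q:
        raise DecompositionError(
            f"projected structure matrix has null space of dimension "
            f"{int(np.sum(~keep))}, expected {q}: ill-conditioned covariance"
        )
    evals, evecs = evals[keep], evecs[:, keep]
    # deterministic eigenvector signs: largest-|entry| coordinate positive
    idx = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[idx, np.arange(evecs.shape[1])])
    evecs = evecs * signs

    B = (evecs / np.sqrt(evals)).T @ C
    return C, B


def compute_P(z) -> tuple[np.ndarray, float, float]:
    """Orthogonal rotation aligning ``z`` with the constant vector.

    Returns ``(P, xi, zeta)`` where ``P z = zeta * 1`` with
    ``zeta = ||z|| / sqrt(m)``, ``P`` is the identity on the orthogonal
    complement of ``span(1, z)``, and ``xi`` is the cosine of the angle
    between ``z`` and ``1``.  Built from the QR decomposition of
    ``A = (1 | z)`` with the positive-diagonal convention, which pins the
    rotation uniquely; when ``z`` is (numerically) collinear with ``1`` the
    map degenerates to the identity (``z`` a positive multiple) or to the
    reflection sending ``z/||z||`` to ``1/sqrt(m)``.
    """
    z = np.asarray(z, dtype=float).ravel()
    m = z.size
    norm_z = float(np.linalg.norm(z))
    if norm_z <= 0.0:
        raise InvalidDesignError(
            "transformed covariate is zero: the covariate of interest lies in "
            "the span of the nuisance design"
        )
    ones = np.ones(m)
    xi = float(z @ ones) / (np.sqrt(m) * norm_z)
    xi = float(np.clip(xi, -1.0, 1.0))
    zeta = norm_z / np.sqrt(m)

    if 1.0 - abs(xi) < 1e-12:
        if xi > 0:
            return np.eye(m), xi, zeta
        # antiparallel: Householder reflection of z/||z|| onto 1/sqrt(m)
        v = z / norm_z - ones / np.sqrt(m)
        P = np.eye(m) - 2.0 * np.outer(v, v) / (v @ v)
        return P, xi, zeta

    A = np.column_stack([ones, z])
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    s = np.sqrt(1.0 - xi * xi)
    rot = np.array([[xi, s], [-s, xi]])
    P = np.eye(m) - Q @ (np.eye(2) - rot) @ Q.T
    return P, xi, zeta


def make_plan(X, k: int, cov: CovarianceSpec) -> TransformOperators:
    """Bundle the full PB plan for design ``X``, covariate ``k``, covariance ``cov``.

    The returned operators are reusable across any number of response vectors
    sharing the same (design, covariance) pair; :func:`apply_plan` is a single
    matrix product.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if cov.n != n:
        raise InvalidDesignError("covariance dimension does not match design rows")
    if not (0 <= k < p):
        raise InvalidDesignError(f"covariate index k={k} outside 0..{p - 1}")
    nuisance = np.delete(X, k, axis=1)
    if nuisance.shape[1] == 0:
        raise InvalidDesignError("design must contain at least an intercept nuisance column")
    if n - nuisance.shape[1] < 3:
        raise InvalidDesignError(
            f"only {n - nuisance.shape[1]} residual dimensions (< 3): sample too small"
        )

    C, B = compute_B(cov.S, nuisance)
    z = B @ X[:, k]
    P, xi, zeta = compute_P(z)

    # recover spectrum for the audit fields (rows of B are Lambda^{-1/2} T' C)
    M = C @ cov.S @ C.T
    evals = np.sort(np.linalg.eigvalsh((M + M.T) / 2.0))[::-1][: B.shape[0]]
    return TransformOperators(
        C=C,
        B=B,
        P=P,
        PB=P @ B,
        z=z,
        xi=xi,
        zeta=zeta,
        eigvals=evals,
        eigvecs=np.array([]),  # retained implicitly in B; kept light
        df=None,
    )


def apply_plan(plan: TransformOperators, Y) -> np.ndarray:
    """Transform responses: ``Ytilde = (P B) Y`` per response vector.

    ``Y`` may be a single length-``n`` vector or a ``features x n`` matrix;
    the result has the matching shape with ``n`` replaced by ``n - q``.
    """
    Y = np.asarray(Y, dtype=float)
    n = plan.PB.shape[1]
    if Y.ndim == 1:
        if Y.size != n:
            raise InvalidInputError(f"response length {Y.size}, expected {n}")
        return plan.PB @ Y
    if Y.ndim == 2:
        if Y.shape[1] != n:
            raise InvalidInputError(f"response columns {Y.shape[1]}, expected {n}")
        return Y @ plan.PB.T
    raise InvalidInputError("Y must be a vector or a features x samples matrix")
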