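"""File I/O and the vectorized many-features runner (RNA-seq use case).

An :class:`ExpressionStudy` bundles a features x samples matrix (assumed
variance-stabilized / log-scale), a per-sample design table, inverse-variance
weights (for RNA-seq: sequencing depth in million reads), and an optional
known within-subject correlation.  :func:`run_pbtest` builds a single PB plan
for the shared design/covariance and transforms *all* features with one
matrix product, so per-feature cost beyond the shared transform is O(n) —
the mechanism that makes feature selection on tens of thousands of features
run in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance_model import (
    CorrelationModel,
    as_weights,
    build_covariance,
    estimate_rho,
)
from .exceptions import AlignmentError, InvalidInputError
from .inference import DFContext, approximate_df, bh_adjust, pb_ttest, pb_wilcoxon
from .pb_transform import apply_plan, make_plan

__all__ = [
    "ExpressionStudy",
    "RESULT_COLUMNS",
    "read_study",
    "run_pbtest",
    "write_results",
]

logger = logging.getLogger("pbtest")

RESULT_COLUMNS = ["feature_id", "beta_hat", "statistic", "df", "p_value", "fdr", "method"]

#: conversion from raw sequencing depth (reads) to the weight scale (million reads)
DEPTH_TO_WEIGHT = 1e-6


@dataclass
class ExpressionStudy:
    """Aligned expression matrix + design + weights for high-throughput testing."""

    matrix: pd.DataFrame  # features x samples
    design: pd.DataFrame  # one row per sample, indexed by sample id
    covariate: str
    nuisance: tuple[str, ...] = ()
    block: str | None = None
    weights: np.ndarray | None = None
    rho: float | None = None

    def __post_init__(self):
        mat_ids = list(self.matrix.columns)
        des_ids = list(self.design.index)
        if mat_ids != des_ids:
            missing = sorted(set(mat_ids) ^ set(des_ids))
            raise AlignmentError(
                f"matrix columns and design rows disagree; offending ids: {missing[:10]}"
            )
        for col in (self.covariate, *self.nuisance):
            if col not in self.design.columns:
                raise InvalidInputError(f"design table has no column {col!r}")
            if self.design[col].isna().any():
                raise InvalidInputError(f"design column {col!r} contains missing values")
        if self.block is not None and self.block not in self.design.columns:
            raise InvalidInputError(f"design table has no block column {self.block!r}")
        if self.weights is None:
            self.weights = np.ones(len(des_ids))
        self.weights = as_weights(self.weights, len(des_ids))

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    def design_matrix(self) -> tuple[np.ndarray, int]:
        """Numeric design (intercept | nuisance | covariate); returns (X, k)."""
        cols = [np.ones(self.n_samples)]
        for name in self.nuisance:
            cols.append(_numeric_column(self.design, name))
        cols.append(_numeric_column(self.design, self.covariate))
        X = np.column_stack(cols)
        return X, X.shape[1] - 1

    def correlation_model(self, rho: float | None = None) -> CorrelationModel:
        if self.block is None:
            labels = tuple(str(i) for i in range(self.n_samples))  # all singletons
        else:
            labels = tuple(self.design[self.block].astype(str))
        return CorrelationModel(labels, rho)


def _numeric_column(design: pd.DataFrame, name: str) -> np.ndarray:
    col = design[name]
    if col.dtype == object or str(col.dtype) == "category":
        levels = sorted(col.astype(str).unique())
        if len(levels) != 2:
            raise InvalidInputError(
                f"non-numeric design column {name!r} must have exactly 2 levels, "
                f"found {len(levels)}"
            )
        return (col.astype(str) == levels[1]).to_numpy(dtype=float)
    out = pd.to_numeric(col, errors="coerce")
    if out.isna().any():
        bad = list(col.index[out.isna()])[:5]
        raise InvalidInputError(f"non-numeric cells in design column {name!r} at {bad}")
    return out.to_numpy(dtype=float)


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except ValueError as exc:  # surfaced parse location from pandas
        raise InvalidInputError(f"failed to parse {path}: {exc}") from exc


def read_study(
    matrix_path,
    design_path,
    weights_path=None,
    *,
    covariate: str,
    nuisance: tuple[str, ...] = (),
    block: str | None = None,
    depth_col: str | None = None,
    rho: float | None = None,
) -> ExpressionStudy:
    """Load and align a features x samples matrix with its design table.

    The matrix and weight tables are delimited text (TSV, or CSV by ``.csv``
    extension) with feature/sample ids in the first column.  If ``depth_col``
    names a sequencing-depth column of the design (raw read counts), weights
    are computed as depth x 1e-6 (million reads); a ``weights_path`` file
    (one column of weights per sample id) is passed through unchanged.
    """
    matrix = _read_table(matrix_path)
    bad = matrix.columns[matrix.dtypes == object]
    if len(bad):
        raise InvalidInputError(f"non-numeric cells in matrix columns {list(bad)[:5]}")
    design = _read_table(design_path)
    design = design.reindex(matrix.columns)
    if design.isna().all(axis=1).any():
        missing = list(design.index[design.isna().all(axis=1)])
        raise AlignmentError(f"design rows missing for samples: {missing[:10]}")

    weights = None
    if weights_path is not None and depth_col is not None:
        raise InvalidInputError("give either a weights file or a depth column, not both")
    if weights_path is not None:
        wtab = _read_table(weights_path)
        wtab = wtab.reindex(matrix.columns)
        if wtab.iloc[:, 0].isna().any():
            missing = list(wtab.index[wtab.iloc[:, 0].isna()])
            raise AlignmentError(f"weights missing for samples: {missing[:10]}")
        weights = wtab.iloc[:, 0].to_numpy(dtype=float)
    elif depth_col is not None:
        if depth_col not in design.columns:
            raise InvalidInputError(f"design table has no depth column {depth_col!r}")
        weights = pd.to_numeric(design[depth_col]).to_numpy(dtype=float) * DEPTH_TO_WEIGHT

    study = ExpressionStudy(
        matrix=matrix,
        design=design,
        covariate=covariate,
        nuisance=tuple(nuisance),
        block=block,
        weights=weights,
        rho=rho,
    )
    sizes = study.correlation_model().block_sizes if block else ()
    logger.info(
        "loaded study: %d features, %d samples, blocks: %s",
        study.n_features,
        study.n_samples,
        dict(zip(*np.unique(sizes, return_counts=True))) if block else "none",
    )
    return study


def pool_rho(study: ExpressionStudy, max_features: int | None = None) -> float:
    """Shared correlation: median of per-feature moment estimates.

    The per-feature Olkin-Pratt-corrected estimates are pooled by their
    median (robust to the handful of features where the moment estimator
    lands on a boundary); the IQR is logged as a dispersion diagnostic.
    """
    X, _ = study.design_matrix()
    corr_blocks = study.correlation_model()
    Y = study.matrix.to_numpy(dtype=float)
    if max_features is not None and Y.shape[0] > max_features:
        Y = Y[:max_features]
    rhos = []
    for row in Y:
        if np.ptp(row) == 0.0:
            continue
        rhos.append(estimate_rho(row, X, study.weights, corr_blocks).rho)
    if not rhos:
        raise InvalidInputError("no feature with nonzero variance to estimate rho from")
    rhos = np.asarray(rhos)
    med = float(np.median(rhos))
    q1, q3 = np.percentile(rhos, [25, 75])
    logger.info("pooled rho = %.4f (median of %d features, IQR %.4f)", med, len(rhos), q3 - q1)
    return med


def run_pbtest(
    study: ExpressionStudy,
    method: str = "t",
    estimate_rho_if_missing: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test every feature for association with the covariate of interest.

    Builds one covariance and one PB plan for the shared design, transforms
    the whole matrix with a single product, applies the chosen one-sample
    test (``"t"`` or ``"wilcoxon"``) per feature, and appends BH-FDR.
    Zero-variance features are skipped and logged.  ``seed`` is accepted for
    interface symmetry; the runner itself is deterministic.
    """
    if method not in ("t", "wilcoxon"):
        raise InvalidInputError("method must be 't' or 'wilcoxon'")
    if study.n_samples < 6:
        raise InvalidInputError("need at least 6 samples")

    keep = study.matrix.std(axis=1, ddof=1) > 0.0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("skipping %d zero-variance features", dropped)
    matrix = study.matrix.loc[keep]

    rho = study.rho
    corr_blocks = study.correlation_model()
    has_blocks = max(corr_blocks.block_sizes) > 1
    if rho is None:
        if estimate_rho_if_missing and has_blocks:
            rho = pool_rho(study)
        else:
            rho = 0.0
    corr = corr_blocks.with_rho(rho)

    X, k = study.design_matrix()
    cov = build_covariance(study.weights, corr)
    plan = make_plan(X, k, cov)
    df = approximate_df(
        DFContext(X, k, study.weights, corr, estimated_rho=study.rho is None)
    )
    plan = plan.with_df(df)
    logger.info("plan built: m = %d, zeta = %.4f, df = %.2f", plan.m, plan.zeta, df)

    Yt = apply_plan(plan, matrix.to_numpy(dtype=float))
    rows = []
    for fid, yt in zip(matrix.index, Yt):
        if method == "t":
            res = pb_ttest(yt, plan.zeta, df)
        else:
            res = pb_wilcoxon(yt, df, zeta=plan.zeta)
        rows.append((fid, res.beta_hat, res.statistic, res.df, res.p_value))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS[:5])
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["method"] = "pb_t" if method == "t" else "pb_wilcoxon"
    return table[RESULT_COLUMNS]


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV (round-trips at 12 significant digits)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
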