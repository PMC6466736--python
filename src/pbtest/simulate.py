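"""Semiparametric data generator and the simulation/evaluation harness.

The generator produces response vectors with *exact* first and second moments
``E Y = 1 mu + x beta`` and ``cov(Y) = sigma2 * S`` from any symmetric base
density: it draws ``n - 1`` i.i.d. variables plus one independent grand-mean
variable, shifts them by the transformed effect, and pushes them through the
linear map ``D = S (PB)'`` which satisfies ``D D' = S - J`` and ``(PB) D = I``.
With a normal base density the output is exactly multivariate normal; with
double-exponential or logistic bases it is a non-normal distribution with the
same mean and covariance.  Because ``(PB) D = I``, applying the PB plan to a
noise-free draw returns exactly ``zeta * beta * 1`` — the generator and the
transform are mutual inverses on the signal component, which makes the
generator the package's core oracle.

The harness runs two study designs:

* ``group_comparison`` — complete subject pairs, one observation per group in
  each pair (paired two-group comparison);
* ``continuous_covariate`` — a regression-type test with a standard-normal
  covariate on subject blocks of size 2.

For each scenario it evaluates the PB-transformed tests (oracle and
estimated correlation) against a panel of classical comparators, reporting
type-I error and power at a chosen level (mean and SD across replicate sets)
and pooled ROC curves with trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .covariance_model import (
    CorrelationModel,
    CovarianceSpec,
    build_covariance,
    estimate_rho,
)
from .exceptions import InvalidInputError
from .inference import DFContext, approximate_df, b_spearman, pb_ttest, pb_wilcoxon
from .pb_transform import TransformOperators, apply_plan, make_plan

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "generate_semiparametric",
    "classical_tests",
    "run_study",
    "PB_METHODS",
    "CLASSICAL_METHODS",
]

_SYMMETRIC_DISTS = ("normal", "double_exponential", "logistic")

PB_METHODS = (
    "pb_t_oracle",
    "pb_t_estimated",
    "pb_wilcoxon_oracle",
    "pb_wilcoxon_estimated",
    "b_spearman",
)
CLASSICAL_METHODS = (
    "two_sample_t",
    "paired_t",
    "welch_t",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "regression_t",
    "spearman",
)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated study condition.

    Defaults encode the study conditions used throughout the package's own
    evaluation: n = 40 observations in 20 subject blocks of size 2, unit noise
    scale, per-sample weights drawn once per replicate from Uniform(0.5, 2)
    and treated as known, and an effect size giving mid-range power at the
    5% level.
    """

    n: int = 40
    design_kind: str = "group_comparison"  # or "continuous_covariate"
    n_blocks: int = 20
    rho: float = 0.2
    weights_scheme: str = "uniform"  # {"uniform": U(0.5, 2), "equal": all 1}
    beta: float = 0.6
    mu: float = 0.0
    sigma2: float = 1.0
    dist: str = "normal"
    seed: int = 0

    def __post_init__(self):
        if self.dist not in _SYMMETRIC_DISTS:
            raise InvalidInputError(
                f"dist must be one of {_SYMMETRIC_DISTS} (a symmetric density); "
                f"got {self.dist!r}"
            )
        if self.design_kind not in ("group_comparison", "continuous_covariate"):
            raise InvalidInputError(f"unknown design_kind {self.design_kind!r}")
        if self.n != 2 * self.n_blocks:
            raise InvalidInputError("n must equal 2 * n_blocks (blocks of size 2)")

    def block_labels(self) -> tuple:
        return tuple(f"s{i // 2}" for i in range(self.n))

    def draw_weights(self, rng: np.random.Generator) -> np.ndarray:
        if self.weights_scheme == "uniform":
            return rng.uniform(0.5, 2.0, size=self.n)
        if self.weights_scheme == "equal":
            return np.ones(self.n)
        raise InvalidInputError(f"unknown weights_scheme {self.weights_scheme!r}")

    def draw_covariate(self, rng: np.random.Generator) -> np.ndarray:
        if self.design_kind == "group_comparison":
            return np.tile([0.0, 1.0], self.n_blocks)
        return rng.standard_normal(self.n)


@dataclass(frozen=True)
class SimulationResult:
    """Evaluation summary of one study condition across all methods."""

    spec: SimulationSpec
    n_reps: int
    n_sets: int
    alpha: float
    type1: Mapping[str, float]
    type1_sd: Mapping[str, float]
    power: Mapping[str, float]
    power_sd: Mapping[str, float]
    auc: Mapping[str, float]
    roc: Mapping[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default=None)

    def to_rows(self) -> list[dict]:
        """Tidy per-method rows (method, scenario, rho, dist, rates, auc)."""
        rows = []
        for method in self.type1:
            rows.append(
                {
                    "method": method,
                    "scenario": self.spec.design_kind,
                    "rho": self.spec.rho,
                    "dist": self.spec.dist,
                    "type1": self.type1[method],
                    "type1_sd": self.type1_sd[method],
                    "power": self.power[method],
                    "power_sd": self.power_sd[method],
                    "auc": self.auc[method],
                }
            )
        return rows


def _draw_iid(dist: str, sigma: float, size, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. draws from the symmetric base density scaled to sd ``sigma``."""
    if dist == "normal":
        return sigma * rng.standard_normal(size)
    if dist == "double_exponential":
        return rng.laplace(scale=sigma / np.sqrt(2.0), size=size)
    if dist == "logistic":
        return rng.logistic(scale=sigma * np.sqrt(3.0) / np.pi, size=size)
    raise InvalidInputError(f"unknown dist {dist!r}")


def generate_semiparametric(
    spec: SimulationSpec,
    x: np.ndarray,
    cov: CovarianceSpec,
    rng: np.random.Generator | None = None,
    n_draws: int | None = None,
    plan: TransformOperators | None = None,
) -> np.ndarray:
    """Draw response vectors with mean ``1 mu + x beta`` and covariance ``sigma2 S``.

    Parameters
    ----------
    spec
        Carries ``mu``, ``beta``, ``sigma2``, ``dist`` and the fallback seed.
    x
        Covariate vector (must not lie in span(1)).
    cov
        Standardized covariance of the target distribution.
    rng
        Source of randomness; defaults to ``default_rng(spec.seed)``.
    n_draws
        If given, return an ``(n_draws, n)`` matrix of independent vectors.
    plan
        Optional precomputed PB plan for ``X = (1 | x)`` (saves the
        eigen-decomposition when generating many replicates).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    x = np.asarray(x, dtype=float).ravel()
    n = cov.n
    if x.size != n:
        raise InvalidInputError("covariate length does not match covariance")
    if np.ptp(x) == 0.0:
        raise InvalidInputError("covariate lies in span(1); effect is unidentifiable")

    if plan is None:
        X = np.column_stack([np.ones(n), x])
        plan = make_plan(X, 1, cov)
    S = cov.S
    D = S @ plan.PB.T  # D D' = S - J and (PB) D = I
    u = plan.zeta * spec.beta
    v = spec.mu + spec.beta * float(np.ones(n) @ np.linalg.solve(S, x))
    sigma = float(np.sqrt(spec.sigma2))

    squeeze = n_draws is None
    m = 1 if squeeze else int(n_draws)
    Ycheck = _draw_iid(spec.dist, sigma, (m, n - 1), rng)
    Ystar = _draw_iid(spec.dist, sigma, m, rng)
    Y = (Ycheck + u) @ D.T + (Ystar + v)[:, None]
    return Y[0] if squeeze else Y


def classical_tests(y: np.ndarray, design: Mapping) -> dict[str, float]:
    """Two-sided p-values for the classical comparator panel.

    ``design`` carries the covariate ``x``, the block labels, and the
    ``design_kind``; pair-based tests are only produced for paired two-group
    designs, rank/correlation tests for continuous covariates.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(design["x"], dtype=float).ravel()
    kind = design.get("design_kind", "group_comparison")
    out: dict[str, float] = {}
    if kind == "group_comparison":
        g0, g1 = y[x == 0.0], y[x == 1.0]
        out["two_sample_t"] = float(stats.ttest_ind(g1, g0).pvalue)
        out["welch_t"] = float(stats.ttest_ind(g1, g0, equal_var=False).pvalue)
        out["wilcoxon_rank_sum"] = float(stats.ranksums(g1, g0).pvalue)
        labels = np.asarray(design["labels"], dtype=object)
        # pair up observations by block label for the paired tests
        order = np.lexsort((x, labels))
        ys = y[order].reshape(-1, 2)  # column 0: group 0, column 1: group 1
        out["paired_t"] = float(stats.ttest_rel(ys[:, 1], ys[:, 0]).pvalue)
        out["wilcoxon_signed_rank"] = float(stats.wilcoxon(ys[:, 1] - ys[:, 0]).pvalue)
    else:
        res = stats.linregress(x, y)
        out["regression_t"] = float(res.pvalue)
        out["spearman"] = float(stats.spearmanr(x, y).pvalue)
    return out


def _pb_pvalues(
    y: np.ndarray,
    x: np.ndarray,
    weights: np.ndarray,
    corr: CorrelationModel,
    oracle_cov: CovarianceSpec,
    oracle_plan: TransformOperators,
    oracle_df: float,
    methods: Sequence[str],
) -> dict[str, float]:
    """p-values of the PB-transformed tests for one dataset."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    out: dict[str, float] = {}

    need_est = any(m.endswith("estimated") or m == "b_spearman" for m in methods)
    est_plan = est_df = est_B = None
    if need_est:
        est = estimate_rho(y, X, weights, corr, correct=True)
        est_corr = corr.with_rho(est.rho)
        est_cov = build_covariance(weights, est_corr)
        est_plan = make_plan(X, 1, est_cov)
        est_df = approximate_df(DFContext(X, 1, weights, est_corr, estimated_rho=True))

    for method in methods:
        if method == "pb_t_oracle":
            yt = apply_plan(oracle_plan, y)
            out[method] = pb_ttest(yt, oracle_plan.zeta, oracle_df).p_value
        elif method == "pb_t_estimated":
            yt = apply_plan(est_plan, y)
            out[method] = pb_ttest(yt, est_plan.zeta, est_df).p_value
        elif method == "pb_wilcoxon_oracle":
            yt = apply_plan(oracle_plan, y)
            out[method] = pb_wilcoxon(yt, oracle_df).p_value
        elif method == "pb_wilcoxon_estimated":
            yt = apply_plan(est_plan, y)
            out[method] = pb_wilcoxon(yt, est_df).p_value
        elif method == "b_spearman":
            y2 = est_plan.B @ y
            out[method] = b_spearman(y2, est_plan.z).p_value
        else:
            raise InvalidInputError(f"unknown PB method {method!r}")
    return out


def run_study(
    specs: SimulationSpec | Sequence[SimulationSpec],
    methods: Sequence[str] | None = None,
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    n_sets: int = 20,
) -> list[SimulationResult]:
    """Monte-Carlo evaluation of type-I error, power, and ROC/AUC.

    For each spec in the grid, ``n_reps`` replicate pairs are generated (one
    null dataset with ``beta = 0`` and one alternative with ``beta =
    spec.beta``, sharing weights and covariate).  Rejection rates at ``alpha``
    are reported as mean and SD over ``n_sets`` equal replicate sets; ROC
    curves pool the null and alternative p-values over all replicates.  Fully
    reproducible from ``seed``.
    """
    if isinstance(specs, SimulationSpec):
        specs = [specs]
    results = []
    for spec in specs:
        if methods is None:
            if spec.design_kind == "group_comparison":
                use = list(PB_METHODS[:4]) + [
                    "two_sample_t",
                    "paired_t",
                    "welch_t",
                    "wilcoxon_rank_sum",
                    "wilcoxon_signed_rank",
                ]
            else:
                use = list(PB_METHODS) + ["regression_t", "spearman"]
        else:
            use = list(methods)
        results.append(_run_one(spec, use, n_reps, alpha, seed, n_sets))
    return results


def _run_one(spec, methods, n_reps, alpha, seed, n_sets) -> SimulationResult:
    unknown = set(methods) - set(PB_METHODS) - set(CLASSICAL_METHODS)
    if unknown:
        raise InvalidInputError(f"unknown method labels: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pb_methods = [m for m in methods if m in PB_METHODS]
    cls_methods = [m for m in methods if m not in PB_METHODS]
    labels = spec.block_labels()
    corr_blocks = CorrelationModel(labels)
    corr = corr_blocks.with_rho(spec.rho)
    null_spec = replace(spec, beta=0.0)

    p_null = {m: np.empty(n_reps) for m in methods}
    p_alt = {m: np.empty(n_reps) for m in methods}
    for r in range(n_reps):
        w = spec.draw_weights(rng)
        x = spec.draw_covariate(rng)
        X = np.column_stack([np.ones(spec.n), x])
        cov = build_covariance(w, corr)
        plan = make_plan(X, 1, cov)
        df = approximate_df(DFContext(X, 1, w, corr))
        design = {"x": x, "labels": labels, "design_kind": spec.design_kind}

        for sim, sink in ((null_spec, p_null), (spec, p_alt)):
            # spec.sigma2 scales the *natural* covariance W^-1/2 Cor W^-1/2,
            # so unit weights give unit observation variance
            gen_spec = replace(sim, sigma2=sim.sigma2 * cov.sigma2)
            y = generate_semiparametric(gen_spec, x, cov, rng=rng, plan=plan)
            if pb_methods:
                pv = _pb_pvalues(y, x, w, corr_blocks, cov, plan, df, pb_methods)
                for m in pb_methods:
                    sink[m][r] = pv[m]
            if cls_methods:
                pv = classical_tests(y, design)
                for m in cls_methods:
                    sink[m][r] = pv[m]

    n_sets = max(1, min(n_sets, n_reps))
    sets = np.array_split(np.arange(n_reps), n_sets)
    type1, type1_sd, power, power_sd, auc, roc = {}, {}, {}, {}, {}, {}
    for m in methods:
        r_null = np.array([np.mean(p_null[m][ix] <= alpha) for ix in sets])
        r_alt = np.array([np.mean(p_alt[m][ix] <= alpha) for ix in sets])
        type1[m] = float(np.mean(r_null))
        type1_sd[m] = float(np.std(r_null, ddof=1)) if n_sets > 1 else 0.0
        power[m] = float(np.mean(r_alt))
        power_sd[m] = float(np.std(r_alt, ddof=1)) if n_sets > 1 else 0.0
        fpr, tpr = _roc_points(p_null[m], p_alt[m])
        roc[m] = (fpr, tpr)
        auc[m] = float(np.trapezoid(tpr, fpr))
    return SimulationResult(
        spec=spec,
        n_reps=n_reps,
        n_sets=n_sets,
        alpha=alpha,
        type1=type1,
        type1_sd=type1_sd,
        power=power,
        power_sd=power_sd,
        auc=auc,
        roc=roc,
    )


def _roc_points(p_null: np.ndarray, p_alt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC by sweeping the rejection threshold over the pooled p-values."""
    thresholds = np.unique(np.concatenate([p_null, p_alt]))
    thresholds = np.concatenate([[0.0], thresholds, [1.0]])
    fpr = np.array([np.mean(p_null <= t) for t in thresholds])
    tpr = np.array([np.mean(p_alt <= t) for t in thresholds])
    order = np.argsort(fpr, kind="stable")
    return fpr[order], tpr[order]
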