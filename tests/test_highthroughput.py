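import time

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pbtest.covariance_model import CorrelationModel, build_covariance, estimate_rho
from pbtest.exceptions import AlignmentError, InvalidInputError
from pbtest.highthroughput_io import (
    DEPTH_TO_WEIGHT,
    ExpressionStudy,
    read_study,
    run_pbtest,
    write_results,
)
from pbtest.simulate import SimulationSpec, generate_semiparametric


def _paired_study(n_features=50, L=10, rho=0.5, seed=0, weights=None, beta=0.0):
    """Synthetic paired expression study on 2L samples."""
    rng = np.random.default_rng(seed)
    n = 2 * L
    labels = [f"subj{i // 2}" for i in range(n)]
    x = np.tile([0, 1], L)
    w = np.ones(n) if weights is None else weights
    cov = build_covariance(w, CorrelationModel(tuple(labels), rho))
    spec = SimulationSpec(
        n=n, n_blocks=L, rho=rho, beta=beta, sigma2=cov.sigma2, weights_scheme="equal"
    )
    Y = generate_semiparametric(spec, x.astype(float), cov, rng=rng, n_draws=n_features)
    samples = [f"s{i}" for i in range(n)]
    matrix = pd.DataFrame(Y, index=[f"g{j}" for j in range(n_features)], columns=samples)
    design = pd.DataFrame({"group": x, "subject": labels}, index=samples)
    return matrix, design, w


class TestReadStudy:
    def _write(self, tmp_path, matrix, design, depth=None):
        mpath = tmp_path / "matrix.tsv"
        dpath = tmp_path / "design.tsv"
        if depth is not None:
            design = design.assign(depth=depth)
        matrix.to_csv(mpath, sep="\t")
        design.to_csv(dpath, sep="\t")
        return mpath, dpath

    def test_depth_column_converts_to_million_reads(self, tmp_path):
        matrix, design, _ = _paired_study(n_features=5, L=4)
        depth = np.linspace(23_800_000, 76_080_000, 8)
        mpath, dpath = self._write(tmp_path, matrix, design, depth=depth)
        study = read_study(
            mpath, dpath, covariate="group", block="subject", depth_col="depth"
        )
        assert study.weights[0] == pytest.approx(23.80)
        assert study.weights[-1] == pytest.approx(76.08)
        assert DEPTH_TO_WEIGHT == 1e-6

    def test_weights_file_passes_through(self, tmp_path):
        matrix, design, _ = _paired_study(n_features=5, L=4)
        mpath, dpath = self._write(tmp_path, matrix, design)
        w = pd.DataFrame({"w": np.arange(1.0, 9.0)}, index=matrix.columns)
        wpath = tmp_path / "weights.tsv"
        w.to_csv(wpath, sep="\t")
        study = read_study(mpath, dpath, wpath, covariate="group", block="subject")
        np.testing.assert_allclose(study.weights, np.arange(1.0, 9.0))

    def test_misaligned_ids_raise_with_offenders(self, tmp_path):
        matrix, design, _ = _paired_study(n_features=5, L=4)
        design = design.rename(index={"s3": "intruder"})
        mpath, dpath = self._write(tmp_path, matrix, design)
        with pytest.raises(AlignmentError, match="s3"):
            read_study(mpath, dpath, covariate="group", block="subject")

    def test_missing_covariate_values_rejected(self, tmp_path):
        matrix, design, _ = _paired_study(n_features=5, L=4)
        design.loc["s2", "group"] = np.nan
        mpath, dpath = self._write(tmp_path, matrix, design)
        with pytest.raises(InvalidInputError, match="missing"):
            read_study(mpath, dpath, covariate="group", block="subject")


class TestRunPBTest:
    def test_null_features_calibrated(self):
        matrix, design, w = _paired_study(n_features=1000, L=10, rho=0.5, seed=4)
        study = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w, rho=0.5,
        )
        table = run_pbtest(study, method="t")
        frac = float((table["p_value"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert frac <= 0.05 + 3 * se

    def test_duplicate_features_get_identical_results(self):
        matrix, design, w = _paired_study(n_features=6, L=8, seed=2)
        matrix.iloc[3] = matrix.iloc[0].to_numpy()
        study = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w, rho=0.3,
        )
        table = run_pbtest(study, method="t").set_index("feature_id")
        for col in ("beta_hat", "statistic", "p_value"):
            assert table.loc["g3", col] == table.loc["g0", col]

    def test_zero_variance_features_skipped(self):
        matrix, design, w = _paired_study(n_features=8, L=8, seed=3)
        matrix.iloc[5] = 1.0
        study = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w, rho=0.3,
        )
        table = run_pbtest(study, method="t")
        assert len(table) == 7
        assert "g5" not in set(table["feature_id"])

    def test_paired_equal_weight_equals_paired_t(self):
        """With the plug-in moment estimate of rho the per-feature results
        reproduce the classical paired t-test exactly."""
        matrix, design, w = _paired_study(n_features=1, L=10, rho=0.6, seed=9, beta=0.4)
        y = matrix.iloc[0].to_numpy()
        x = design["group"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(20), x])
        est = estimate_rho(
            y, X, w, CorrelationModel(tuple(design["subject"])), correct=False
        )
        study = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w, rho=est.rho,
        )
        table = run_pbtest(study, method="t")
        expected = stats.ttest_rel(y[x == 1], y[x == 0])
        assert table["statistic"].iloc[0] == pytest.approx(expected.statistic, abs=1e-8)
        assert table["df"].iloc[0] == pytest.approx(9.0, abs=1e-6)
        assert table["p_value"].iloc[0] == pytest.approx(expected.pvalue, abs=1e-8)

    def test_wilcoxon_method_runs(self):
        matrix, design, w = _paired_study(n_features=20, L=10, seed=6)
        study = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w,
        )
        table = run_pbtest(study, method="wilcoxon")
        assert (table["method"] == "pb_wilcoxon").all()
        assert table["p_value"].between(0, 1).all()

    def test_per_feature_cost_is_flat(self):
        """Per-feature runtime grows sublinearly: the plan is shared."""
        matrix, design, w = _paired_study(n_features=10_000, L=10, seed=8)
        study_small = ExpressionStudy(
            matrix=matrix.iloc[:1000], design=design, covariate="group",
            block="subject", weights=w, rho=0.4,
        )
        study_large = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w, rho=0.4,
        )
        run_pbtest(study_small, method="t")  # warm up
        t0 = time.perf_counter()
        run_pbtest(study_small, method="t")
        per_small = (time.perf_counter() - t0) / 1000
        t0 = time.perf_counter()
        run_pbtest(study_large, method="t")
        per_large = (time.perf_counter() - t0) / 10_000
        assert per_large < 3.0 * per_small


class TestWriteResults:
    def test_round_trip_preserves_pvalues(self, tmp_path):
        matrix, design, w = _paired_study(n_features=30, L=8, seed=5)
        study = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w, rho=0.2,
        )
        table = run_pbtest(study, method="t")
        path = tmp_path / "results.tsv"
        write_results(table, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == list(table.columns)
        np.testing.assert_allclose(back["p_value"], table["p_value"], atol=1e-12)

    def test_empty_table_writes_header_only(self, tmp_path):
        from pbtest.highthroughput_io import RESULT_COLUMNS

        path = tmp_path / "empty.tsv"
        write_results(pd.DataFrame(columns=RESULT_COLUMNS), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == RESULT_COLUMNS

    def test_fdr_monotone_with_p(self, tmp_path):
        matrix, design, w = _paired_study(n_features=40, L=8, seed=7)
        study = ExpressionStudy(
            matrix=matrix, design=design, covariate="group",
            block="subject", weights=w, rho=0.2,
        )
        table = run_pbtest(study, method="t").sort_values("p_value")
        assert np.all(np.diff(table["fdr"].to_numpy()) >= -1e-12)
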