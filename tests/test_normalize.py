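"""Quantile normalization, median polish and replicate averaging, checked
against hand-iterated oracles and R reference implementations."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from polyte.normalize import (
    ExpressionMatrix,
    median_polish,
    median_polish_summarize,
    quantile_normalize,
    scale_arrays,
    summarize_tech_reps,
)


def _em(arr, scale="linear", columns=None, gene_map=None):
    arr = np.asarray(arr, dtype=float)
    cols = columns or [f"a{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=cols)
    gm = None
    if gene_map is not None:
        gm = pd.Series(gene_map, index=df.index, name="gene_id")
    return ExpressionMatrix(df, scale=scale, gene_map=gm)


class TestExpressionMatrix:
    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            _em([[1.0, -2.0]])  # non-positive linear intensity
        with pytest.raises(ValueError):
            _em([[1.0, np.nan]])
        with pytest.raises(ValueError):
            _em([[1.0, 2.0]], columns=["a", "a"])

    def test_scale_round_trip(self):
        m = _em([[2.0, 8.0]])
        np.testing.assert_allclose(m.to_log2().data.to_numpy(), [[1.0, 3.0]])
        np.testing.assert_allclose(m.to_log2().to_linear().data.to_numpy(), [[2.0, 8.0]])


class TestQuantileNormalize:
    def test_hand_oracle(self):
        """Sort/average/reassign by hand: [1,2,3],[4,2,6] -> [1.5,3,4.5],[3,1.5,4.5]."""
        out = quantile_normalize(_em(np.array([[1, 4], [2, 2], [3, 6]])))
        np.testing.assert_allclose(out.data.to_numpy(), [[1.5, 3.0], [3.0, 1.5], [4.5, 4.5]])

    def test_single_column_identity(self):
        m = _em([[5.0], [1.0], [3.0]])
        pd.testing.assert_frame_equal(quantile_normalize(m).data, m.data)

    def test_identical_columns_fixed_point(self):
        m = _em(np.tile([[3.0], [1.0], [7.0]], (1, 4)))
        pd.testing.assert_frame_equal(quantile_normalize(m).data, m.data)

    def test_ties_get_mean_of_tied_reference_values(self):
        # column 2 is constant: every value has rank 2 of 3, so each gets
        # the midpoint of the reference distribution
        out = quantile_normalize(_em(np.array([[1, 5], [2, 5], [3, 5]])))
        ref = np.mean(np.sort(np.array([[1, 2, 3], [5, 5, 5]]), axis=1), axis=0)
        assert np.unique(out.data.iloc[:, 1]).size == 1
        assert out.data.iloc[0, 1] == pytest.approx(ref[1])

    def test_columns_share_distribution_and_ranks_are_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(3, 1, size=(40, 5))
        out = quantile_normalize(_em(x)).data.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 5):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)
            assert (np.argsort(out[:, j]) == np.argsort(x[:, j])).all()

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against limma::normalizeBetweenArrays (method='quantile')."""
        rng = np.random.default_rng(1)
        x = rng.lognormal(2, 0.7, size=(15, 4))
        ours = quantile_normalize(_em(x)).data.to_numpy()
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\\t"))
            y <- normalizeBetweenArrays(x, method="quantile")
            write.table(y, commandArgs(TRUE)[2], sep="\\t", row.names=FALSE, col.names=FALSE)
            """
        )
        (tmp_path / "qn.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "qn.R"), str(tmp_path / "x.tsv"), str(tmp_path / "y.tsv")],
            check=True,
            capture_output=True,
        )
        theirs = np.loadtxt(tmp_path / "y.tsv", delimiter="\t")
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


class TestScaleArrays:
    def test_identity_when_means_already_equal(self):
        equal = _em(np.array([[1.0, 3.0], [4.0, 2.0]]), scale="log2")  # both col means 2.5
        pd.testing.assert_frame_equal(scale_arrays(equal).data, equal.data)

    def test_removes_per_array_log_offsets(self):
        base = np.array([[1.0], [3.0], [5.0]])
        x = np.hstack([base, base + 0.7, base - 0.4])
        out = scale_arrays(_em(x, scale="log2")).data.to_numpy()
        np.testing.assert_allclose(out[:, 0], out[:, 1], atol=1e-12)
        np.testing.assert_allclose(out[:, 0], out[:, 2], atol=1e-12)
        assert out.mean() == pytest.approx(x.mean())

    def test_linear_scale_round_trip(self):
        x = np.array([[2.0, 8.0], [4.0, 16.0]])
        out = scale_arrays(_em(x))
        assert out.scale == "linear"
        col_means = np.log2(out.data.to_numpy()).mean(axis=0)
        np.testing.assert_allclose(col_means, col_means[0], atol=1e-12)


class TestMedianPolish:
    def test_constant_matrix(self):
        overall, row, col, resid = median_polish(np.full((3, 4), 2.5))
        assert overall == pytest.approx(2.5)
        np.testing.assert_allclose(row, 0.0, atol=1e-12)
        np.testing.assert_allclose(col, 0.0, atol=1e-12)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_hand_iterated_2x3_oracle(self):
        """[[1,2,3],[3,4,5]]: row medians (2,4) -> residuals +-(1,0,1);
        column medians (-1,0,1) -> zero residuals; overall 3, array
        summaries (2,3,4)."""
        overall, row, col, resid = median_polish(np.array([[1.0, 2, 3], [3, 4, 5]]))
        np.testing.assert_allclose(overall + col, [2.0, 3.0, 4.0], atol=1e-12)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_residual_medians_vanish_at_convergence(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 8))
        _, _, _, resid = median_polish(x, tol=1e-9, max_iter=100)
        np.testing.assert_allclose(np.median(resid, axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(np.median(resid, axis=1), 0.0, atol=1e-6)

    def test_matches_r_medpolish(self, tmp_path):
        # odd dimensions: medians are unique order statistics, so the sweep
        # converges to a unique fixed point (even sizes can oscillate and
        # implementations may stop at different phases)
        rng = np.random.default_rng(3)
        x = rng.normal(5, 1, size=(5, 7))
        overall, row, col, _ = median_polish(x, tol=1e-9, max_iter=200)
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        script = textwrap.dedent(
            """
            x <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\\t"))
            fit <- medpolish(x, eps=1e-9, maxiter=200, trace.iter=FALSE)
            cat(fit$overall, fit$col, sep="\\n")
            """
        )
        (tmp_path / "mp.R").write_text(script)
        res = subprocess.run(
            ["Rscript", str(tmp_path / "mp.R"), str(tmp_path / "x.tsv")],
            check=True,
            capture_output=True,
            text=True,
        )
        vals = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(overall + col, vals[0] + vals[1:], atol=1e-5)


class TestMedianPolishSummarize:
    def test_requires_log2_scale(self):
        m = _em([[1.0, 2.0]], gene_map=["g1"])
        with pytest.raises(ValueError):
            median_polish_summarize(m)

    def test_single_probe_genes_pass_through(self):
        m = _em(np.array([[1.0, 2, 3], [9, 8, 7]]), scale="log2", gene_map=["g1", "g2"])
        out = median_polish_summarize(m)
        np.testing.assert_allclose(out.data.loc["g1"], [1, 2, 3], atol=1e-12)
        np.testing.assert_allclose(out.data.loc["g2"], [9, 8, 7], atol=1e-12)

    def test_blocked_equals_per_gene_sweep(self):
        """The vectorized uniform-probe-count path agrees with gene-by-gene
        polish (forced by making block sizes unequal)."""
        rng = np.random.default_rng(4)
        x = rng.normal(8, 1, size=(9, 5))
        uniform = median_polish_summarize(
            _em(x, scale="log2", gene_map=["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3)
        )
        # same genes plus a 1-probe extra gene -> ragged path
        x2 = np.vstack([x, rng.normal(8, 1, size=(1, 5))])
        ragged = median_polish_summarize(
            _em(x2, scale="log2", gene_map=["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3 + ["g4"])
        )
        np.testing.assert_allclose(
            uniform.data.to_numpy(), ragged.data.loc[["g1", "g2", "g3"]].to_numpy(), atol=1e-9
        )

    def test_probe_affinities_cancel_in_summaries(self):
        # probes differ by constant offsets; summaries recover array levels
        levels = np.array([3.0, 4.0, 5.0, 6.0])
        offsets = np.array([-1.0, 0.5, 2.0])
        x = levels[None, :] + offsets[:, None]
        out = median_polish_summarize(_em(x, scale="log2", gene_map=["g"] * 3))
        diff = out.data.loc["g"].to_numpy() - levels
        np.testing.assert_allclose(diff - diff[0], 0.0, atol=1e-12)


class TestSummarizeTechReps:
    def _sheet(self, arrays, reps):
        return pd.DataFrame(
            {
                "array_id": arrays,
                "strain": "WT",
                "fraction": "T",
                "project": "I",
                "tech_rep": reps,
            }
        )

    def test_arithmetic_mean_on_linear_scale(self):
        m = _em(np.array([[2.0, 4.0, 6.0]]))
        out = summarize_tech_reps(m, self._sheet(["a0", "a1", "a2"], [1, 2, 3]))
        assert out.data.iloc[0, 0] == pytest.approx(4.0)

    def test_single_replicate_passthrough(self):
        m = _em(np.array([[3.5]]))
        out = summarize_tech_reps(m, self._sheet(["a0"], [1]))
        assert out.data.iloc[0, 0] == pytest.approx(3.5)

    def test_log2_input_averaged_on_linear_scale(self):
        """mean(2^x) != 2^mean(x): for x = (1, 3) the linear mean is 5."""
        m = _em(np.array([[1.0, 3.0]]), scale="log2")
        out = summarize_tech_reps(m, self._sheet(["a0", "a1"], [1, 2]))
        assert out.scale == "log2"
        assert out.data.iloc[0, 0] == pytest.approx(np.log2(5.0))

    def test_sheet_matrix_mismatch_rejected(self):
        m = _em(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="missing array"):
            summarize_tech_reps(m, self._sheet(["a0", "a1", "aX"], [1, 2, 3]))
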