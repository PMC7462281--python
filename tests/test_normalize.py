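"""Expression normalization: TMM, CPM, filtering, quantile norm, batch adjustment."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from eqtlkit import (
    batch_adjust,
    cpm,
    expression_filter,
    log_quantile_normalize,
    sample_pca_outliers,
    tmm_factors,
)
from eqtlkit.containers import ExpressionMatrix, PipelineStateError


def make_expr(values, state="counts", dataset=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(g)],
            "chrom": "1",
            "start": np.arange(g) * 1000 + 1,
            "end": np.arange(g) * 1000 + 500,
            "strand": "+",
            "biotype": "other",
        }
    )
    return ExpressionMatrix(
        values=values, genes=genes, samples=[f"s{i}" for i in range(n)],
        state=state, dataset=dataset,
    )


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        x = np.tile(np.arange(1, 101)[:, None], (1, 4)).astype(float)
        np.testing.assert_allclose(tmm_factors(make_expr(x)), 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=200).astype(float) + 1
        x = np.column_stack([a, 2 * a, a])
        np.testing.assert_allclose(tmm_factors(make_expr(x)), 1.0, atol=1e-9)

    def test_upshifted_sample_composition_corrected_matches_plain_oracle(self):
        # independent trimmed weighted-mean computation with plain loops;
        # a sample whose library is inflated by a minority of upshifted
        # genes gets a factor BELOW 1 (its effective library shrinks so
        # the majority genes are not artificially deflated)
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, size=(20, 2)).astype(float) + 1
        counts[:5, 1] *= 8  # 25% of genes upshifted 8-fold in sample 2
        em = make_expr(counts)
        f = tmm_factors(em)
        assert f[1] < 1.0

        # mirror the reference-selection rule: UQ of proportions closest
        # to the mean UQ
        lib = counts.sum(0)
        uq = np.array([np.quantile(counts[:, k] / lib[k], 0.75) for k in range(2)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        other = 1 - ref
        ordered = counts[:, [ref, other]]
        n0, n1 = ordered.sum(0)
        m, a, w = [], [], []
        for y0, y1 in ordered:
            m.append(np.log2((y1 / n1) / (y0 / n0)))
            a.append(0.5 * np.log2((y1 / n1) * (y0 / n0)))
            w.append((n1 - y1) / (n1 * y1) + (n0 - y0) / (n0 * y0))
        from scipy.stats import rankdata

        m, a, w = map(np.array, (m, a, w))
        km = rankdata(m)  # 1-based average ranks
        ka = rankdata(a)
        ng = len(m)
        lo_m, lo_a = int(ng * 0.30) + 1, int(ng * 0.05) + 1
        keep = (
            (km >= lo_m) & (km <= ng + 1 - lo_m)
            & (ka >= lo_a) & (ka <= ng + 1 - lo_a)
        )
        expect = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        # both factors normalized to zero log-mean
        pair = np.empty(2)
        pair[ref], pair[other] = 1.0, expect
        pair /= np.exp(np.mean(np.log(pair)))
        np.testing.assert_allclose(f, pair, rtol=1e-10)

    def test_matches_edger_reference(self, tmp_path):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(5, 0.01, size=(300, 5)).astype(float)
        counts[:15, 3] *= 6
        em = make_expr(counts)
        ours = tmm_factors(em)
        cfile = tmp_path / "counts.tsv"
        np.savetxt(cfile, counts, delimiter="\t", fmt="%d")
        r = subprocess.run(
            [
                "Rscript", "-e",
                f'suppressMessages(library(edgeR));'
                f'x <- as.matrix(read.table("{cfile}"));'
                f'cat(calcNormFactors(x, method="TMM"), sep="\\n")',
            ],
            capture_output=True, text=True, timeout=300,
        )
        assert r.returncode == 0, r.stderr
        theirs = np.array([float(v) for v in r.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=1e-5)

    def test_zero_library_errors(self):
        x = np.zeros((10, 2))
        x[:, 1] = 5
        with pytest.raises(ValueError):
            tmm_factors(make_expr(x))


class TestCpm:
    def test_simple_value_and_invariances(self):
        x = np.full((1000, 2), 500.0)
        em = make_expr(x)
        out = cpm(em, np.ones(2))
        assert out.state == "cpm"
        np.testing.assert_allclose(out.values, 500 / 500000 * 1e6)
        # doubling all counts of a sample leaves CPM unchanged
        x2 = x.copy()
        x2[:, 1] *= 2
        out2 = cpm(make_expr(x2), np.ones(2))
        np.testing.assert_allclose(out2.values[:, 1], out.values[:, 1])
        # factor 2 halves CPM
        out3 = cpm(em, np.array([1.0, 2.0]))
        np.testing.assert_allclose(out3.values[:, 1], out.values[:, 1] / 2)

    def test_state_machine_rejects_wrong_order(self):
        em = cpm(make_expr(np.ones((10, 3)) * 100))
        with pytest.raises(PipelineStateError):
            cpm(em)


class TestExpressionFilter:
    def test_ten_percent_threshold_uses_ceiling(self):
        # 10 of 94 samples (10.6%) > threshold of ceil(9.4) = 10 -> expressed
        x = np.zeros((1, 94))
        x[0, :10] = 1.5
        em = make_expr(x, state="cpm")
        shared, _ = expression_filter({"d": em}, cpm_min=1.0, sample_frac=0.10)
        assert shared == ["g0"]
        # 9 samples -> not expressed
        x9 = np.zeros((1, 94))
        x9[0, :9] = 1.5
        shared, _ = expression_filter({"d": make_expr(x9, state="cpm")})
        assert shared == []

    def test_gene_missing_in_one_dataset_excluded(self):
        a = make_expr(np.full((2, 20), 5.0), state="cpm")
        bvals = np.full((2, 20), 5.0)
        bvals[1] = 0.0  # g1 silent in dataset b
        b = make_expr(bvals, state="cpm")
        shared, summary = expression_filter({"a": a, "b": b})
        assert shared == ["g0"]
        assert summary.attrs["n_failing_intersection"] == 1

    def test_identical_datasets_intersection_equals_each(self):
        a = make_expr(np.full((3, 10), 2.0), state="cpm")
        b = make_expr(np.full((3, 10), 2.0), state="cpm")
        shared, _ = expression_filter({"a": a, "b": b})
        assert shared == ["g0", "g1", "g2"]


class TestQuantileNormalize:
    def test_identical_sorted_vectors_and_idempotence(self):
        rng = np.random.default_rng(3)
        em = make_expr(rng.gamma(2, 50, size=(50, 8)), state="cpm")
        out = log_quantile_normalize(em)
        cols = [np.sort(out.values[:, k]) for k in range(8)]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0], atol=1e-12)
        again = log_quantile_normalize(out.with_values(out.values, "cpm"))
        # applying the rank-map twice = once (idempotent up to the log recoding)
        np.testing.assert_allclose(
            np.sort(again.values, axis=0), np.sort(np.log2(out.values + 1), axis=0),
            atol=1e-12,
        )

    def test_hand_computed_toy_with_tie(self):
        # 4 genes x 3 samples; sample 3 has a tie in rows 0 and 1
        x = np.array(
            [
                [2.0, 4.0, 3.0],
                [5.0, 1.0, 3.0],
                [3.0, 6.0, 8.0],
                [4.0, 8.0, 9.0],
            ]
        )
        em = make_expr(x, state="log2cpm")
        out = log_quantile_normalize(em)
        # target distribution = mean of sorted columns of x
        target = np.mean(np.sort(x, axis=0), axis=1)
        # sample 3 ranks: values (3,3,8,9); tied pair takes mean(target[0:2])
        tie_val = target[:2].mean()
        expect = np.array(
            [
                [target[0], target[1], tie_val],
                [target[3], target[0], tie_val],
                [target[1], target[2], target[2]],
                [target[2], target[3], target[3]],
            ]
        )
        np.testing.assert_allclose(out.values, expect, atol=1e-12)


class TestBatchAdjust:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(4)
        em = make_expr(rng.normal(size=(20, 10)), state="quantile", dataset=["a"] * 10)
        out = batch_adjust(em)
        np.testing.assert_array_equal(out.values, em.values)
        assert out.state == "batch_adjusted"

    def test_planted_constant_shift_removed(self):
        # noise sd small relative to the 0.05 tolerance so the check
        # measures shift removal, not batch-mean estimation noise
        rng = np.random.default_rng(5)
        g = 200
        x = rng.normal(5, 0.1, size=(g, 100))
        x[:, 50:] += 2.0  # batch B shifted +2
        em = make_expr(x, state="quantile", dataset=["A"] * 50 + ["B"] * 50)
        out = batch_adjust(em)
        diff = out.values[:, :50].mean(axis=1) - out.values[:, 50:].mean(axis=1)
        assert (np.abs(diff) < 0.05).mean() >= 0.95

    def test_batch_f_statistic_on_pc1_drops(self):
        rng = np.random.default_rng(6)
        g = 100
        x = rng.normal(0, 1, size=(g, 60))
        x[:, 30:] += rng.normal(1.0, 0.2, size=(g, 1))
        em = make_expr(x, state="quantile", dataset=["A"] * 30 + ["B"] * 30)
        out = batch_adjust(em)

        def f_stat(vals):
            u, s, _ = np.linalg.svd(vals.T - vals.T.mean(0), full_matrices=False)
            pc1 = u[:, 0] * s[0]
            a, b = pc1[:30], pc1[30:]
            ssb = 30 * ((a.mean() - pc1.mean()) ** 2 + (b.mean() - pc1.mean()) ** 2)
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return (ssb / 1) / (ssw / 58)

        assert f_stat(out.values) < f_stat(em.values) / 10

    def test_small_batch_errors(self):
        em = make_expr(np.ones((5, 3)), state="quantile", dataset=["A", "A", "B"])
        with pytest.raises(ValueError):
            batch_adjust(em)

    def test_matches_sva_combat_reference(self, tmp_path):
        rng = np.random.default_rng(7)
        g, n = 80, 24
        x = rng.normal(5, 1, size=(g, n))
        batch = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        x[:, 8:16] += 1.2
        em = make_expr(x, state="quantile", dataset=batch)
        ours = batch_adjust(em).values
        xf = tmp_path / "x.tsv"
        bf = tmp_path / "b.txt"
        np.savetxt(xf, x, delimiter="\t")
        bf.write_text("\n".join(batch))
        r = subprocess.run(
            [
                "Rscript", "-e",
                f'suppressMessages(library(sva));'
                f'x <- as.matrix(read.table("{xf}"));'
                f'b <- readLines("{bf}");'
                f'out <- ComBat(dat=x, batch=b, par.prior=TRUE);'
                f'write.table(out, "{tmp_path}/r.tsv", sep="\\t",'
                f'row.names=FALSE, col.names=FALSE)',
            ],
            capture_output=True, text=True, timeout=300,
        )
        assert r.returncode == 0, r.stderr
        theirs = np.loadtxt(tmp_path / "r.tsv")
        np.testing.assert_allclose(ours, theirs, atol=1e-4)


class TestPcaOutliers:
    def test_shifted_sample_flagged(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(100, 30))
        x[:, 7] += 10.0
        em = make_expr(x, state="quantile")
        assert sample_pca_outliers(em, sd_threshold=3.0) == ["s7"]

    def test_homogeneous_data_unflagged_and_inf_threshold(self):
        rng = np.random.default_rng(9)
        flags = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=(50, 25))
            em = make_expr(x, state="quantile")
            flags += len(sample_pca_outliers(em, sd_threshold=6.0))
        assert flags == 0
        em = make_expr(rng.normal(size=(50, 25)), state="quantile")
        assert sample_pca_outliers(em, sd_threshold=np.inf) == []
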