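"""Cis mapping: regression oracle, permutation/beta machinery, q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlkit import (
    Covariates,
    QvalueParams,
    nominal_scan,
    permutation_pass,
    qvalues,
    residualize,
)
from eqtlkit.mapping import CollinearityError, fit_beta, gene_thresholds
from eqtlkit.containers import GeneEqtlSummary


def make_cov(n, k=0, seed=0):
    rng = np.random.default_rng(seed)
    return Covariates(
        values=rng.normal(size=(n, k)),
        names=[f"c{i}" for i in range(k)],
        samples=[f"s{i}" for i in range(n)],
    )


def meta_for(m):
    return pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "G",
            "maf": 0.3,
        }
    )


def ols_oracle(y, g, cov_values):
    """Full design-matrix least squares: slope, se, two-sided p for g."""
    n = y.size
    x = np.column_stack([np.ones(n), cov_values, g])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - x.shape[1]
    sigma2 = resid @ resid / df
    cov_beta = sigma2 * np.linalg.inv(x.T @ x)
    slope = beta[-1]
    se = np.sqrt(cov_beta[-1, -1])
    t = slope / se
    p = 2 * stats.t.sf(abs(t), df)
    return slope, se, p


class TestResidualize:
    def test_intercept_only_centers(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=30)
        out = residualize(row, make_cov(30, 0))
        np.testing.assert_allclose(out[0], row - row.mean(), atol=1e-12)

    def test_row_in_span_goes_to_zero_and_orthogonality(self):
        cov = make_cov(40, 3, seed=1)
        span_row = cov.values @ np.array([1.0, -2.0, 0.5]) + 3.0
        out = residualize(span_row, cov)
        np.testing.assert_allclose(out[0], 0, atol=1e-10)
        rng = np.random.default_rng(2)
        res = residualize(rng.normal(size=(5, 40)), cov)
        assert np.abs(res @ cov.design()).max() < 1e-8

    def test_rank_deficient_names_columns(self):
        cov = make_cov(20, 2, seed=3)
        cov = cov.with_columns(cov.values[:, 0] * 2, ["dup_of_c0"])
        with pytest.raises(CollinearityError, match="dup_of_c0"):
            residualize(np.ones(20), cov)


class TestNominalScan:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, size=50).astype(float)
        y = 2.0 * g
        recs = nominal_scan("g", g[:, None], meta_for(1), y, make_cov(50, 0))
        assert recs[0].slope == pytest.approx(2.0, abs=1e-10)
        assert recs[0].nominal_p < 1e-60

    def test_matches_full_design_matrix_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(40, 120))
            k = int(rng.integers(0, 6))
            cov = make_cov(n, k, seed=trial)
            g = rng.binomial(2, rng.uniform(0.1, 0.5), size=n).astype(float)
            y = rng.normal(size=n) + rng.uniform(-1, 1) * g
            recs = nominal_scan("g", g[:, None], meta_for(1), y, cov)
            slope, se, p = ols_oracle(y, g, cov.values)
            assert recs[0].slope == pytest.approx(slope, abs=1e-8)
            assert recs[0].slope_se == pytest.approx(se, abs=1e-8)
            assert recs[0].nominal_p == pytest.approx(p, abs=1e-8, rel=1e-6)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        n = 60
        g = rng.binomial(2, 0.3, size=n).astype(float)
        cov = make_cov(n, 2, seed=7)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            y = rng.normal(size=n)
            recs = nominal_scan("g", g[:, None], meta_for(1), y, cov)
            hits += recs[0].nominal_p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_zero_variance_dosage_skipped(self):
        rng = np.random.default_rng(8)
        g = np.column_stack([np.full(30, 1.0), rng.binomial(2, 0.4, 30)])
        recs = nominal_scan("g", g, meta_for(2), rng.normal(size=30), make_cov(30, 0))
        assert [r.variant_id for r in recs] == ["v1"]

    def test_tss_distance_sign_follows_strand(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.4, size=(40, 1)).astype(float)
        y = rng.normal(size=40)
        meta = meta_for(1)  # variant at pos 100
        plus = nominal_scan("g", g, meta, y, make_cov(40, 0), tss=300, strand="+")
        minus = nominal_scan("g", g, meta, y, make_cov(40, 0), tss=300, strand="-")
        assert plus[0].tss_distance == -200  # upstream on +
        assert minus[0].tss_distance == 200  # downstream on -


class TestPermutationPass:
    def test_null_window_beta_shape1_near_one(self):
        # minimum of M independent uniforms ~ Beta(1, M)
        rng = np.random.default_rng(10)
        n, m = 120, 50
        g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        # independent variants: no LD columns
        y = rng.normal(size=n)
        s = permutation_pass(
            "g", g, meta_for(m), y, make_cov(n, 0), perm_min=1000,
            perm_max=1000, seed=1, adaptive=False,
        )
        assert 0.8 <= s.beta_shape1 <= 1.2
        assert s.beta_shape2 == pytest.approx(m, rel=0.5)

    def test_planted_effect_tiny_empirical_p(self):
        rng = np.random.default_rng(11)
        n, m = 300, 30
        g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        beta = np.sqrt(0.3 / 0.7) / g[:, 4].std()
        y = beta * g[:, 4] + rng.normal(size=n)
        s = permutation_pass("g", g, meta_for(m), y, make_cov(n, 0), seed=2)
        assert s.perm_p_beta < 1e-4
        assert s.best.variant_id == "v4"

    def test_direct_and_beta_p_agree_within_twofold(self):
        rng = np.random.default_rng(12)
        n, m = 80, 20
        agree = 0
        n_genes = 100
        for i in range(n_genes):
            g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            y = rng.normal(size=n) + 0.15 * g[:, 0] * (i % 2)
            s = permutation_pass(
                "g", g, meta_for(m), y, make_cov(n, 0), perm_min=1000,
                perm_max=1000, seed=i, adaptive=False,
            )
            lo, hi = sorted((s.perm_p_beta, s.perm_p_direct))
            if hi <= 2 * lo:
                agree += 1
        assert agree >= 95

    def test_adaptive_stops_early_under_null(self):
        rng = np.random.default_rng(13)
        n, m = 60, 10
        g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        s = permutation_pass("g", g, meta_for(m), y, make_cov(n, 0),
                             perm_min=200, perm_max=10000, seed=3)
        assert s.n_permutations < 10000

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(14)
        n, m = 50, 8
        g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        a = permutation_pass("g", g, meta_for(m), y, make_cov(n, 0), seed=9,
                             perm_min=200, perm_max=200, adaptive=False)
        b = permutation_pass("g", g, meta_for(m), y, make_cov(n, 0), seed=9,
                             perm_min=200, perm_max=200, adaptive=False)
        assert a.perm_p_beta == b.perm_p_beta
        assert a.beta_shape1 == b.beta_shape1


class TestBetaFit:
    def test_recovers_known_beta_parameters(self):
        rng = np.random.default_rng(15)
        x = rng.beta(1.0, 40.0, size=2000)
        a, b, ok = fit_beta(x)
        assert ok
        assert a == pytest.approx(1.0, rel=0.15)
        assert b == pytest.approx(40.0, rel=0.15)


class TestQvalues:
    def test_all_ones(self):
        q, pi0 = qvalues(np.ones(50))
        assert pi0 == 1.0
        np.testing.assert_allclose(q, 1.0)

    def test_small_block_significant(self):
        rng = np.random.default_rng(16)
        p = np.concatenate([np.full(10, 0.001), rng.uniform(0.01, 1, 90)])
        q, pi0 = qvalues(p)
        assert (q[:10] < 0.05).all()

    def test_direct_formula_on_tiny_vector(self):
        p = np.array([0.01, 0.2, 0.5, 0.9, 1.0])
        lam = 0.85
        q, pi0 = qvalues(p, QvalueParams(lambda_=lam))
        m = 5
        pi0_expect = min(1.0, (p > lam).sum() / (m * (1 - lam)))
        assert pi0 == pytest.approx(pi0_expect)
        order = np.argsort(p)
        raw = pi0_expect * m * p[order] / np.arange(1, m + 1)
        expect = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(q[order], np.minimum(expect, 1.0))

    def test_monotone_in_p(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=200)
        q, _ = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            qvalues(np.array([]))
        with pytest.raises(ValueError):
            qvalues(np.array([0.0, 0.5]))


class TestGeneThresholds:
    @staticmethod
    def _summary(gene, perm_p, a, b):
        from eqtlkit.containers import AssocRecord

        return GeneEqtlSummary(
            gene_id=gene, n_cis_variants=10,
            best=AssocRecord(gene, "v0", 1, 0.1, 10, perm_p / 10, 0),
            beta_shape1=a, beta_shape2=b, perm_p_beta=perm_p, perm_p_direct=perm_p,
        )

    def test_beta_1_m_closed_form_inverse(self):
        # Beta(1, M): CDF(x) = 1 - (1-x)^M, so p_g = 1 - (1-p_t)^(1/M)
        m_var = 25.0
        s1 = self._summary("a", 0.01, 1.0, m_var)
        s2 = self._summary("b", 0.9, 1.0, m_var)
        q = np.array([0.01, 0.9])
        p_t = gene_thresholds([s1, s2], q, fdr=0.05)
        assert p_t == pytest.approx((0.01 + 0.9) / 2)
        expect = 1 - (1 - p_t) ** (1 / m_var)
        assert s1.nominal_threshold == pytest.approx(expect, rel=1e-9)

    def test_all_significant_uses_max_only(self):
        s = [self._summary(f"g{i}", 0.001 * (i + 1), 1.0, 30.0) for i in range(4)]
        p_t = gene_thresholds(s, np.full(4, 0.01), fdr=0.05)
        assert p_t == pytest.approx(0.004)

    def test_none_significant_warns_and_nan(self):
        s = [self._summary("g", 0.9, 1.0, 30.0)]
        with pytest.warns(UserWarning):
            p_t = gene_thresholds(s, np.array([0.9]), fdr=0.05)
        assert np.isnan(p_t)
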