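import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicsbn.genetics import (
    AssocResult,
    FilterParams,
    GenotypeMatrix,
    allele_score,
    association_scan,
    bonferroni_retain,
    clump,
    inverse_normal_transform,
)
from omicsbn.synthetic_data import simulate_genotypes


def _geno(dosages, chrom=None, pos=None, snp_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=snp_ids or [f"snp{j}" for j in range(m)],
        chromosome=np.asarray(chrom) if chrom is not None else np.ones(m, int),
        position=np.asarray(pos) if pos is not None else np.arange(m) * 1000,
        dosages=dosages,
    )


class TestAssociationScan:
    def test_noiseless_fit_recovers_slope(self, rng):
        g = rng.integers(0, 3, size=(50, 1)).astype(float)
        y = 2.0 * g[:, 0]
        res = association_scan(y, _geno(g))
        assert res[0].beta == pytest.approx(2.0, abs=1e-10)
        assert res[0].pvalue < 1e-100

    def test_null_pvalues_are_uniform(self, rng):
        n, m = 400, 500
        g = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        res = association_scan(y, _geno(g))
        pvals = np.array([r.pvalue for r in res])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_normal_equations_oracle(self, rng):
        # single SNP with two covariates against an explicit lstsq solve
        n = 10
        g = rng.integers(0, 3, size=(n, 1)).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.7 * g[:, 0] + cov @ [0.5, -0.3] + rng.normal(size=n)
        res = association_scan(y, _geno(g), covariates=cov)[0]
        X = np.column_stack([np.ones(n), cov, g[:, 0]])
        beta_full = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_full
        sigma2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
        assert res.beta == pytest.approx(beta_full[-1], rel=1e-8)
        assert res.se == pytest.approx(se, rel=1e-8)

    def test_monomorphic_snp_p_one(self):
        g = np.ones((20, 1))
        y = np.arange(20.0)
        res = association_scan(y, _geno(g))[0]
        assert np.isnan(res.beta)
        assert res.pvalue == 1.0

    def test_missing_dosages_mean_imputed(self, rng):
        g = rng.integers(0, 3, size=(30, 1)).astype(float)
        y = 1.5 * g[:, 0] + rng.normal(scale=0.1, size=30)
        g_missing = g.copy()
        g_missing[:3, 0] = np.nan
        res = association_scan(y, _geno(g_missing))[0]
        assert res.pvalue < 1e-10  # signal survives mean imputation


class TestBonferroniRetain:
    def _pvals(self, n_sig, n_snps=100, n_vars=3, threshold=None):
        params = FilterParams()
        thr = params.alpha / (n_vars * n_snps)
        p = pd.DataFrame(
            np.full((n_vars, n_snps), 0.5),
            index=[f"v{i}" for i in range(n_vars)],
            columns=[f"snp{j}" for j in range(n_snps)],
        )
        p.iloc[0, :n_sig] = thr / 10
        return p

    def test_boundary_at_min_snps(self):
        retained_25 = bonferroni_retain(self._pvals(25))
        assert "v0" in retained_25 and len(retained_25["v0"]) == 25
        retained_20 = bonferroni_retain(self._pvals(20))
        assert "v0" in retained_20
        retained_19 = bonferroni_retain(self._pvals(19))
        assert retained_19 == {}

    def test_expression_rule_needs_more_than_one(self):
        assert "v0" in bonferroni_retain(self._pvals(2), rule="expression")
        assert bonferroni_retain(self._pvals(1), rule="expression") == {}

    def test_threshold_uses_total_test_count(self):
        # a p-value below alpha/n_snps but above alpha/(n_vars*n_snps) fails
        params = FilterParams(min_snps=1)
        p = self._pvals(0)
        p.iloc[0, 0] = params.alpha / p.shape[1] * 0.5  # per-variable level only
        assert bonferroni_retain(p, params) == {}


class TestClump:
    def test_duplicate_columns_keep_lower_p(self, rng):
        col = rng.integers(0, 3, size=(50, 1)).astype(float)
        g = _geno(np.hstack([col, col]), pos=[0, 100])
        assoc = [AssocResult("snp0", 1.0, 0.1, 1e-8), AssocResult("snp1", 1.0, 0.1, 1e-6)]
        assert clump(assoc, g, r2_max=0.1) == ["snp0"]

    def test_uncorrelated_snps_all_kept(self, rng):
        g = _geno(rng.integers(0, 3, size=(2000, 4)).astype(float))
        assoc = [AssocResult(f"snp{j}", 1.0, 0.1, 10 ** -(8 - j)) for j in range(4)]
        kept = clump(assoc, g, r2_max=0.1)
        assert sorted(kept) == [f"snp{j}" for j in range(4)]
        assert kept[0] == "snp0"  # p-ascending order

    def test_matches_greedy_oracle_on_ld_blocks(self, rng):
        g = simulate_genotypes(
            800, np.full(20, 0.3), seed=rng, ld_block_size=5, ld_r2=0.8
        )
        assoc = [
            AssocResult(s, 1.0, 0.1, float(p))
            for s, p in zip(g.snp_ids, rng.uniform(1e-10, 1e-2, 20))
        ]
        r2_max, window = 0.1, 250_000

        def oracle():
            d = g.dosage_filled()
            remaining = sorted(range(20), key=lambda i: (assoc[i].pvalue, assoc[i].snp_id))
            out, removed = [], set()
            for i in remaining:
                if i in removed:
                    continue
                out.append(assoc[i].snp_id)
                removed.add(i)
                for j in remaining:
                    if j in removed or g.chromosome[j] != g.chromosome[i]:
                        continue
                    if abs(int(g.position[j]) - int(g.position[i])) > window:
                        continue
                    r = np.corrcoef(d[:, i], d[:, j])[0, 1]
                    if r**2 > r2_max:
                        removed.add(j)
            return out

        assert clump(assoc, g, r2_max=r2_max, window_bp=window) == oracle()

    def test_clump_output_is_an_antichain(self, rng):
        g = simulate_genotypes(500, np.full(12, 0.25), seed=rng, ld_block_size=4, ld_r2=0.7)
        assoc = [
            AssocResult(s, 1.0, 0.1, float(p))
            for s, p in zip(g.snp_ids, rng.uniform(0, 1e-4, 12))
        ]
        kept = clump(assoc, g, r2_max=0.2, window_bp=100_000)
        d = g.dosage_filled()
        idx = [g.snp_index(s) for s in kept]
        for a in idx:
            for b in idx:
                if a >= b or g.chromosome[a] != g.chromosome[b]:
                    continue
                if abs(int(g.position[a]) - int(g.position[b])) > 100_000:
                    continue
                r = np.corrcoef(d[:, a], d[:, b])[0, 1]
                assert r**2 <= 0.2 + 1e-12


class TestAlleleScore:
    def test_direct_weighted_sum(self):
        g = _geno(np.array([[0.0, 1.0, 2.0]]).reshape(1, 3))
        score = allele_score(g, ["snp0", "snp1", "snp2"], [0.5, 1.0, -0.2])
        assert score[0] == pytest.approx(0.6)

    def test_zero_weights_zero_scores(self, rng):
        g = _geno(rng.integers(0, 3, size=(10, 3)).astype(float))
        assert np.all(allele_score(g, g.snp_ids, [0.0, 0.0, 0.0]) == 0.0)

    def test_missing_dosage_contributes_snp_mean(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        g = _geno(d)
        score = allele_score(g, ["snp0"], [0.5])
        assert score[2] == pytest.approx(0.5 * 1.0)

    def test_linearity_in_weights(self, rng):
        g = _geno(rng.integers(0, 3, size=(30, 4)).astype(float))
        w1 = rng.normal(size=4)
        w2 = rng.normal(size=4)
        s = allele_score(g, g.snp_ids, list(2 * w1 + 3 * w2))
        expected = 2 * allele_score(g, g.snp_ids, list(w1)) + 3 * allele_score(
            g, g.snp_ids, list(w2)
        )
        assert np.allclose(s, expected)

    def test_unknown_snp_raises(self):
        g = _geno(np.zeros((2, 1)) )
        with pytest.raises(KeyError):
            allele_score(g, ["nope"], [1.0])


class TestInverseNormalTransform:
    def test_rankit_closed_form(self):
        out = inverse_normal_transform(np.array([10.0, 20.0, 30.0]))
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        assert np.allclose(out, expected)

    def test_monotone_rescaling_invariance(self, rng):
        x = rng.normal(size=40)
        assert np.allclose(
            inverse_normal_transform(x), inverse_normal_transform(np.exp(3 * x))
        )

    def test_ties_share_value_and_missing_stay_missing(self):
        x = np.array([1.0, 1.0, 2.0, np.nan])
        out = inverse_normal_transform(x)
        assert out[0] == out[1]
        assert np.isnan(out[3])

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.array([3.0, 3.0, 3.0]))

    def test_large_sample_standardisation(self, rng):
        out = inverse_normal_transform(rng.exponential(size=5000))
        assert abs(out.mean()) < 0.05
        assert abs(out.std() - 1.0) < 0.05

    def test_blom_offset_supported(self):
        out = inverse_normal_transform(np.array([1.0, 2.0, 3.0]), offset=0.375)
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / (3 + 0.25))
        assert np.allclose(out, expected)
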