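"""Kinship, EMMAX mixed-model scan, BH-FDR, stratification audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from bogdiv.genotype_io import MISSING
from bogdiv.gwas import (
    GwasError,
    bh_fdr,
    mlm_scan,
    stratification_audit,
    vanraden_kinship,
)
from bogdiv.synthetic_data import simulate_structured_population, simulate_trait
from conftest import toy_matrix, toy_metadata
from oracles import bh_oracle


class TestVanRadenKinship:
    def test_duplicated_individuals(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, 30).astype(np.int8)
        other = rng.integers(0, 3, 30).astype(np.int8)
        G = toy_matrix(np.stack([row, row, other]))
        A = vanraden_kinship(G).matrix
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-12)
        assert A[0, 1] == pytest.approx(A[1, 1], abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(4, 6)).astype(np.int8)
        A = vanraden_kinship(toy_matrix(dos)).matrix
        # element-by-element reference computation
        M = dos.astype(float)
        p = M.mean(axis=0) / 2
        W = M - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        ref = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                ref[i, j] = np.sum(W[i] * W[j]) / denom
        np.testing.assert_allclose(A, ref, atol=1e-12)

    def test_unrelated_mean_offdiagonal_near_zero(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 2000), size=(40, 2000)).astype(np.int8)
        A = vanraden_kinship(toy_matrix(dos)).matrix
        off = A[~np.eye(40, dtype=bool)]
        # in-sample centering forces row sums to zero exactly, so the mean
        # off-diagonal sits at -diag_mean/(n-1); near zero at this n
        assert off.mean() == pytest.approx(-A.diagonal().mean() / 39, abs=1e-10)
        assert abs(off.mean()) < 0.05
        assert np.abs(off).max() < 0.25

    def test_all_monomorphic_rejected(self):
        with pytest.raises(GwasError):
            vanraden_kinship(toy_matrix(np.zeros((3, 4), dtype=np.int8)))


class TestMlmScan:
    def _panel(self, seed=0, n=(60, 60), L=300, fst=0.05):
        G, meta, _ = simulate_structured_population(n, L, fst, seed=seed)
        return G, meta

    def test_identity_kinship_equals_ols(self):
        import statsmodels.api as sm

        G, _ = self._panel(3, n=(40, 40), L=80, fst=0.0)
        y, _ = simulate_trait(G, h2_poly=0.2, seed=4)
        res = mlm_scan(G, y, K=None)
        X = G.dosages_float()
        p = np.nanmean(X, axis=0) / 2
        ix = np.where(np.isnan(X))
        X[ix] = (2 * p)[ix[1]]
        for l in [0, 17, 55]:
            if res.table["flag"].iloc[l] != "ok":
                continue
            ols = sm.OLS(y.to_numpy(), sm.add_constant(X[:, l])).fit()
            assert res.table["p"].iloc[l] == pytest.approx(ols.pvalues[1], abs=1e-8)
            assert res.table["beta"].iloc[l] == pytest.approx(ols.params[1], abs=1e-8)

    def test_null_pvalues_uniform(self):
        G, _ = self._panel(21, n=(150, 150), L=500)
        y, _ = simulate_trait(G, h2_poly=0.3, seed=22)
        res = mlm_scan(G, y, K=vanraden_kinship(G))
        p = res.table["p"].dropna()
        frac = (p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_qtl_detected(self):
        G, _ = self._panel(31, n=(150, 150), L=400)
        y, _ = simulate_trait(G, h2_poly=0.2, qtl_index=200, qtl_var=0.2, seed=32)
        res = mlm_scan(G, y, K=vanraden_kinship(G), fdr_alpha=0.1)
        assert res.table["q"].iloc[200] <= 0.1

    def test_marker_collinear_with_covariate_flagged(self):
        G, _ = self._panel(5, n=(40, 40), L=60, fst=0.0)
        y, _ = simulate_trait(G, h2_poly=0.2, seed=6)
        X = G.dosages_float()
        p = np.nanmean(X, axis=0) / 2
        ix = np.where(np.isnan(X))
        X[ix] = (2 * p)[ix[1]]
        covs = pd.DataFrame({"PC1": X[:, 10]}, index=G.accession_ids)
        res = mlm_scan(G, y, covariates=covs, K=None)
        assert res.table["flag"].iloc[10] == "collinear"
        assert np.isnan(res.table["p"].iloc[10])

    def test_scan_invariant_to_marker_order(self):
        G, _ = self._panel(7, n=(40, 40), L=50)
        y, _ = simulate_trait(G, h2_poly=0.3, seed=8)
        K = vanraden_kinship(G)
        r1 = mlm_scan(G, y, K=K)
        perm = np.random.default_rng(0).permutation(50)
        G2 = toy_matrix(G.dosages[:, perm], ids=G.accession_ids)
        K2 = vanraden_kinship(G2)  # same markers, same matrix
        np.testing.assert_allclose(K.matrix, K2.matrix, atol=1e-12)
        r2 = mlm_scan(G2, y, K=K2)
        np.testing.assert_allclose(
            r1.table["p"].to_numpy()[perm], r2.table["p"].to_numpy(),
            atol=1e-10, equal_nan=True,
        )

    def test_small_subset_rejected(self):
        G, meta = self._panel(9, n=(20, 20), L=60)
        y, _ = simulate_trait(G, h2_poly=0.3, seed=10)
        with pytest.raises(GwasError, match=">= 30"):
            mlm_scan(G, y, subset=list(G.accession_ids[:10]))

    def test_per_subgroup_scan_skips_low_maf(self):
        G, meta = self._panel(11, n=(40, 40), L=200, fst=0.2)
        y, _ = simulate_trait(G, h2_poly=0.3, seed=12)
        sub = [a for a in G.accession_ids if a.startswith("WLD")]
        res = mlm_scan(G, y, subset=sub, subset_label="WLD")
        flags = set(res.table["flag"])
        assert "low_maf" in flags or "monomorphic" in flags
        low = res.table[res.table["flag"] == "low_maf"]
        assert low["p"].isna().all()


class TestBhFdr:
    bh_oracle = staticmethod(bh_oracle)

    def test_matches_exhaustive_oracle(self):
        p = np.array([0.001, 0.02, 0.03, 0.5, 0.9])
        q, reject = bh_fdr(p, alpha=0.1)
        np.testing.assert_array_equal(reject, self.bh_oracle(p, 0.1))
        assert reject.tolist() == [True, True, True, False, False]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_oracle_equivalence_random(self, p_list):
        p = np.array(p_list)
        q, reject = bh_fdr(p, alpha=0.1)
        np.testing.assert_array_equal(reject, self.bh_oracle(p, 0.1))
        # q-values monotone in p
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_all_ones_no_discoveries(self):
        q, reject = bh_fdr(np.ones(10))
        assert not reject.any()

    def test_single_tiny_p_discovered(self):
        p = np.concatenate([[1e-9], np.random.default_rng(0).uniform(0.2, 1, 999)])
        _, reject = bh_fdr(p, alpha=0.1)
        assert reject[0] and reject.sum() == 1

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(GwasError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(GwasError):
            bh_fdr(np.array([]))


class TestStratificationAudit:
    def _confounded_panel(self):
        # marker fixed-different between subgroups; trait differs only
        # between subgroups -> association is pure stratification
        rng = np.random.default_rng(13)
        n = 40
        dose = np.array([0] * 20 + [2] * 20, dtype=np.int8)
        other = rng.integers(0, 3, (n, 4)).astype(np.int8)
        dos = np.column_stack([dose, other])
        ids = [f"A{i}" for i in range(n)]
        G = toy_matrix(dos, ids=ids)
        meta = toy_metadata(ids, ["WLD"] * 20 + ["CLT2"] * 20)
        y = pd.Series(
            np.concatenate([rng.normal(0, 1, 20), rng.normal(4, 1, 20)]), index=ids
        )
        return G, meta, y

    def test_between_subgroup_confounder_flagged(self):
        G, meta, y = self._confounded_panel()
        audit = stratification_audit(G, 0, y, meta)
        assert audit["confounded"] is True

    def test_consistent_within_subgroup_effect_not_flagged(self):
        rng = np.random.default_rng(14)
        n = 80
        dose = rng.integers(0, 3, n).astype(np.int8)
        dos = np.column_stack([dose, rng.integers(0, 3, (n, 3)).astype(np.int8)])
        ids = [f"A{i}" for i in range(n)]
        G = toy_matrix(dos, ids=ids)
        meta = toy_metadata(ids, ["WLD"] * 40 + ["CLT2"] * 40)
        y = pd.Series(2.0 * dose + rng.normal(0, 0.5, n), index=ids)
        audit = stratification_audit(G, 0, y, meta)
        assert audit["confounded"] is False
        eff = audit["within_subgroup_effects"]
        assert np.all(eff["slope"] > 1.0)
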