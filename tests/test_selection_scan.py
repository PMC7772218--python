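"""Weir-Cockerham F_ST, permutation thresholds, and ROD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from bogdiv.genotype_io import MISSING
from bogdiv.selection_scan import (
    ROD_STEPS,
    ScanError,
    fst_permutation_threshold,
    fst_scan,
    rod_locus,
    rod_scan,
    wc_fst_locus,
)
from conftest import toy_matrix, toy_metadata
from oracles import wc84_oracle


class TestWcFstLocus:
    def test_complete_fixation_is_one(self):
        assert wc_fst_locus((10, 0, 0), (0, 0, 10)) == pytest.approx(1.0)

    def test_identical_counts_nonpositive(self):
        th = wc_fst_locus((3, 4, 3), (3, 4, 3))
        assert th <= 0.0

    def test_matches_brute_force_oracle(self):
        th = wc_fst_locus((8, 2, 0), (2, 4, 4))
        assert th == pytest.approx(wc84_oracle((8, 2, 0), (2, 4, 4)), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        hst.tuples(*[hst.integers(0, 12)] * 3),
        hst.tuples(*[hst.integers(0, 12)] * 3),
    )
    def test_oracle_equivalence_random_counts(self, ca, cb):
        if sum(ca) < 2 or sum(cb) < 2:
            th = wc_fst_locus(ca, cb)
            assert np.isnan(th)
            return
        th = wc_fst_locus(ca, cb)
        ref = wc84_oracle(ca, cb)
        if np.isnan(ref):
            assert np.isnan(th)
        else:
            assert th == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_global_allele_swap(self):
        for ca, cb in [((5, 3, 2), (1, 6, 3)), ((9, 1, 0), (0, 2, 8))]:
            assert wc_fst_locus(ca, cb) == pytest.approx(
                wc_fst_locus(ca[::-1], cb[::-1]), abs=1e-12
            )

    def test_undersized_group_undefined(self):
        assert np.isnan(wc_fst_locus((1, 0, 0), (5, 5, 0)))


class TestFstScan:
    def _random_split_panel(self, seed=0, n=40, L=60):
        rng = np.random.default_rng(seed)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, L), size=(n, L)).astype(np.int8)
        ids = [f"A{i}" for i in range(n)]
        sgs = np.array(["WLD"] * (n // 2) + ["NS"] * (n // 2))
        rng.shuffle(sgs)
        return toy_matrix(dos, ids=ids), toy_metadata(ids, sgs)

    def test_scan_matches_locus_estimator(self):
        G, meta = self._random_split_panel(3)
        scan = fst_scan(G, meta, ("WLD", "NS"))
        ia = meta.members("WLD", G.accession_ids)
        ib = meta.members("NS", G.accession_ids)
        for l in [0, 7, 33]:
            def counts(rows):
                d = G.dosages[rows, l]
                d = d[d != MISSING]
                return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
            expect = wc_fst_locus(counts(ia), counts(ib))
            got = scan.theta[l]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_random_split_mean_near_zero(self):
        G, meta = self._random_split_panel(1, n=60, L=400)
        scan = fst_scan(G, meta, ("WLD", "NS"))
        assert abs(scan.mean_fst) < 0.01

    def test_identical_membership_rejected(self):
        G, meta = self._random_split_panel(0)
        one = toy_metadata(G.accession_ids, ["WLD"] * G.n_accessions)
        with pytest.raises(ScanError):
            fst_scan(G, one, ("WLD", "WLD"))

    def test_balding_nichols_calibration(self):
        from bogdiv.synthetic_data import simulate_structured_population

        G, meta, _ = simulate_structured_population((100, 100), 2000, 0.05, seed=6)
        scan = fst_scan(G, meta, ("WLD", "NS"))
        ok = np.isfinite(scan.theta)
        se = scan.theta[ok].std() / np.sqrt(ok.sum())
        assert scan.mean_fst_ratio_of_sums == pytest.approx(0.05, abs=3 * se)


class TestPermutationThreshold:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(11)
        dos = rng.integers(0, 3, size=(8, 50)).astype(np.int8)
        ids = [f"A{i}" for i in range(8)]
        G = toy_matrix(dos, ids=ids)
        meta = toy_metadata(ids, ["WLD"] * 4 + ["NS"] * 4)
        s1 = fst_permutation_threshold(G, meta, ("WLD", "NS"), R=100, seed=13)
        s2 = fst_permutation_threshold(G, meta, ("WLD", "NS"), R=100, seed=13)
        assert s1.perm_threshold_p95 == s2.perm_threshold_p95
        assert s1.n_significant == s2.n_significant

    def test_bad_quantile_rejected(self):
        G, meta, _ = _tiny_pair_panel()
        with pytest.raises(ScanError):
            fst_permutation_threshold(G, meta, ("WLD", "NS"), R=5, q=1.5)

    def test_mean_permuted_theta_near_zero(self):
        from bogdiv.synthetic_data import simulate_structured_population

        G, meta, _ = simulate_structured_population((30, 30), 2000, 0.0, seed=2)
        ia = meta.members("WLD", G.accession_ids)
        ib = meta.members("NS", G.accession_ids)
        pool = np.concatenate([ia, ib])
        rng = np.random.default_rng(0)
        from bogdiv.selection_scan import _theta_vector

        perm = rng.permutation(pool)
        th = _theta_vector(G.dosages[perm[: len(ia)]], G.dosages[perm[len(ia):]])
        assert abs(np.nanmean(th)) < 0.005


def _tiny_pair_panel():
    rng = np.random.default_rng(9)
    dos = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
    ids = [f"A{i}" for i in range(10)]
    return toy_matrix(dos, ids=ids), toy_metadata(ids, ["WLD"] * 5 + ["NS"] * 5), None


class TestRod:
    @pytest.mark.parametrize(
        "he_a,he_d,expect",
        [(0.5, 0.0, 1.0), (0.3, 0.3, 0.0), (0.5, 0.18, 0.64)],
    )
    def test_arithmetic(self, he_a, he_d, expect):
        assert rod_locus(he_a, he_d) == pytest.approx(expect)

    def test_zero_ancestral_diversity_undefined(self):
        assert np.isnan(rod_locus(0.0, 0.2))

    def test_negative_rod_not_clamped(self):
        assert rod_locus(0.18, 0.5) == pytest.approx(1 - 0.5 / 0.18)

    def test_unknown_step_rejected(self):
        G, meta, _ = _tiny_pair_panel()
        with pytest.raises(ScanError, match="unknown step"):
            rod_scan(G, meta, "step9")

    def test_single_clone_bottleneck_rod_one_everywhere(self):
        rng = np.random.default_rng(4)
        n_anc = 20
        anc = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(n_anc, 50))
        clone = np.tile(rng.integers(0, 3, 50), (3, 1))  # derived: one genotype
        dos = np.vstack([anc, clone]).astype(np.int8)
        ids = [f"A{i}" for i in range(len(dos))]
        G = toy_matrix(dos, ids=ids)
        meta = toy_metadata(ids, ["WLD"] * n_anc + ["NS"] * 3)
        scan = rod_scan(G, meta, "step1")
        poly_anc = scan.he_ancestral > 0
        het_clone = clone[0] == 1  # a heterozygous clone keeps He > 0
        expect_one = poly_anc & ~het_clone
        np.testing.assert_allclose(scan.rod[expect_one], 1.0)
        assert scan.bin_counts["rod_eq_1"] == int(expect_one.sum())

    def test_bins_partition_all_loci(self, fixture_panel):
        for step in ROD_STEPS:
            scan = rod_scan(fixture_panel.genotypes, fixture_panel.metadata, step)
            assert sum(scan.bin_counts.values()) + scan.n_undefined == len(scan.rod)
            # headline bins are disjoint by construction; ROD <= 1 always
            assert np.nanmax(scan.rod) <= 1.0 + 1e-12

    def test_rod1_iff_derived_fixed_where_ancestor_polymorphic(self, fixture_panel):
        scan = rod_scan(fixture_panel.genotypes, fixture_panel.metadata, "step2")
        ok = np.isfinite(scan.rod)
        lhs = ok & (scan.rod == 1.0)
        rhs = ok & (scan.he_ancestral > 0) & (scan.he_derived == 0.0)
        np.testing.assert_array_equal(lhs, rhs)

    def test_founder_bottleneck_beats_random_subset(self):
        # 7-founder breeding step fixes more loci than an equally sized
        # random subset of the ancestral stage, across seeds
        from bogdiv.diversity import subgroup_freqs, expected_het
        from bogdiv.synthetic_data import ScenarioConfig, simulate_panel

        wins = 0
        for seed in range(5):
            cfg = ScenarioConfig(
                n_wld=10, n_ns=40, n_clt1=20, n_clt2=10, n_markers=300,
                missing_rate=0.0, years=(2006,), seed=seed,
            )
            panel = simulate_panel(cfg)
            scan = rod_scan(panel.genotypes, panel.metadata, "step2")
            n_bottleneck = scan.bin_counts["rod_eq_1"]

            rng = np.random.default_rng(100 + seed)
            ns_rows = panel.metadata.members("NS", panel.genotypes.accession_ids)
            sub = rng.choice(ns_rows, size=20, replace=False)
            dos = panel.genotypes.dosages
            he_ns = scan.he_ancestral
            p_sub = dos[sub].mean(axis=0) / 2.0
            he_sub = 2 * p_sub * (1 - p_sub)
            n_random = int(np.sum((he_ns > 0) & (he_sub == 0)))
            wins += n_bottleneck > n_random
        assert wins >= 4
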