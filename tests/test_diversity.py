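"""Subgroup allele-frequency summaries, joint MAF, heterozygosity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from bogdiv.diversity import (
    DiversityError,
    expected_het,
    joint_maf,
    maf_bin_edges,
    polymorphic_fraction,
    subgroup_freqs,
)
from bogdiv.genotype_io import MISSING
from conftest import toy_matrix, toy_metadata


@pytest.fixture()
def two_group_panel():
    # 4 WLD + 4 NS accessions, 5 markers
    dos = np.array(
        [
            # m0   m1   m2   m3   m4
            [0, 0, 0, 1, 2],
            [1, 0, 2, 1, 2],
            [1, 0, 1, 0, 2],
            [2, 0, 1, 2, 2],  # WLD ends; m1 fixed ref, m4 fixed alt in WLD
            [0, 1, MISSING, 1, 0],
            [0, 1, MISSING, 1, 1],
            [0, 2, MISSING, 0, 2],
            [0, 0, MISSING, 2, 1],  # NS: m0 fixed ref, m2 all-missing
        ],
        dtype=np.int8,
    )
    ids = [f"A{i}" for i in range(8)]
    meta = toy_metadata(ids, ["WLD"] * 4 + ["NS"] * 4)
    return toy_matrix(dos, ids=ids), meta


class TestSubgroupFreqs:
    def test_hand_frequencies(self, two_group_panel):
        G, meta = two_group_panel
        F = subgroup_freqs(G, meta)
        wld = F.per_subgroup("WLD")
        assert wld["p"].tolist() == [0.5, 0.0, 0.5, 0.5, 1.0]
        ns = F.per_subgroup("NS")
        np.testing.assert_allclose(ns["p"].tolist()[0], 0.0)
        # heterozygote/dosage mix: {0/0,0/1,1/1} -> p = 0.5
        assert ns["p"].tolist()[1] == 0.5

    def test_all_missing_marker_is_undefined(self, two_group_panel):
        G, meta = two_group_panel
        F = subgroup_freqs(G, meta)
        ns = F.per_subgroup("NS")
        assert np.isnan(ns["p"].iloc[2]) and ns["n_obs"].iloc[2] == 0

    def test_empty_subgroup_errors(self, two_group_panel):
        G, _ = two_group_panel
        meta = toy_metadata([f"B{i}" for i in range(8)], ["WLD"] * 8)
        with pytest.raises(DiversityError):
            subgroup_freqs(G, meta)

    def test_estimates_match_generating_frequencies(self):
        # binomial sampling oracle: p_hat within 3 SE of the truth
        rng = np.random.default_rng(42)
        p_true = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        n = 200
        dos = rng.binomial(2, p_true, size=(n, 5)).astype(np.int8)
        ids = [f"A{i}" for i in range(n)]
        G = toy_matrix(dos, ids=ids)
        F = subgroup_freqs(G, toy_metadata(ids, ["WLD"] * n))
        p_hat = F.per_subgroup("WLD")["p"].to_numpy()
        se = np.sqrt(p_true * (1 - p_true) / (2 * n))
        assert np.all(np.abs(p_hat - p_true) <= 3 * se)


class TestPolymorphicFraction:
    def test_hand_count_and_denominators(self, two_group_panel):
        G, meta = two_group_panel
        F = subgroup_freqs(G, meta)
        wld = polymorphic_fraction(F, "WLD")
        # m1 fixed ref, m4 fixed alt -> 3 of 5 polymorphic
        assert (wld.n_polymorphic, wld.n_defined, wld.n_total) == (3, 5, 5)
        ns = polymorphic_fraction(F, "NS")
        # m0 fixed, m2 undefined -> 3 polymorphic of 4 defined
        assert (ns.n_polymorphic, ns.n_defined) == (3, 4)
        assert ns.fraction_defined == pytest.approx(0.75)
        assert ns.fraction_total == pytest.approx(0.6)

    def test_all_fixed_gives_zero(self):
        ids = ["A0", "A1", "A2"]
        G = toy_matrix(np.array([[0, 2], [0, 2], [0, 2]], dtype=np.int8), ids=ids)
        F = subgroup_freqs(G, toy_metadata(ids, ["WLD"] * 3))
        assert polymorphic_fraction(F, "WLD").n_polymorphic == 0

    def test_subsampling_decreases_fraction_in_expectation(self):
        rng = np.random.default_rng(7)
        n, L = 60, 300
        dos = rng.binomial(2, rng.uniform(0.02, 0.5, L), size=(n, L)).astype(np.int8)
        ids = [f"A{i}" for i in range(n)]
        G = toy_matrix(dos, ids=ids)
        meta_full = toy_metadata(ids, ["WLD"] * n)
        full = polymorphic_fraction(subgroup_freqs(G, meta_full), "WLD").fraction_total
        subs = []
        for seed in range(6):
            keep = np.random.default_rng(seed).choice(n, size=10, replace=False)
            Gs = G.take_accessions(np.sort(keep))
            m = toy_metadata(Gs.accession_ids, ["WLD"] * 10)
            subs.append(polymorphic_fraction(subgroup_freqs(Gs, m), "WLD").fraction_total)
        assert np.mean(subs) <= full + 1e-12


class TestJointMaf:
    def test_self_comparison_is_diagonal(self, two_group_panel):
        G, meta = two_group_panel
        F = subgroup_freqs(G, meta)
        jm = joint_maf(F, "WLD", "WLD")
        assert jm.diagonal_mass == 1.0
        assert jm.counts.sum() == 5

    def test_hand_binned_counts(self):
        # WLD MAFs: .5,.125 | NS MAFs: .5,.375  (4 accessions each)
        dos = np.array(
            [
                [1, 0], [1, 0], [1, 0], [1, 1],
                [2, 0], [0, 1], [1, 1], [1, 1],
            ],
            dtype=np.int8,
        )
        ids = [f"A{i}" for i in range(8)]
        G = toy_matrix(dos, ids=ids)
        F = subgroup_freqs(G, toy_metadata(ids, ["WLD"] * 4 + ["NS"] * 4))
        jm = joint_maf(F, "WLD", "NS", bin_width=0.25)
        # bins: [0,.25), [.25,.5]; m0: (.5,.5)->(1,1); m1: (.125,.375)->(0,1)
        np.testing.assert_array_equal(jm.counts, [[0, 1], [0, 1]])
        assert jm.diagonal_mass == 0.5

    def test_marginals_equal_subgroup_histograms(self, two_group_panel):
        G, meta = two_group_panel
        F = subgroup_freqs(G, meta)
        jm = joint_maf(F, "WLD", "NS")
        common = (
            F.per_subgroup("WLD")["maf"].notna()
            & F.per_subgroup("NS")["maf"].notna()
        ).to_numpy()
        for sg, marg in (("WLD", jm.counts.sum(axis=1)), ("NS", jm.counts.sum(axis=0))):
            maf = F.per_subgroup(sg)["maf"].to_numpy()[common]
            hist, _ = np.histogram(maf, bins=jm.bin_edges)
            # final bin closed at 0.5, matching numpy's closed last edge
            np.testing.assert_array_equal(marg, hist)

    def test_bad_bin_width_rejected(self, two_group_panel):
        G, meta = two_group_panel
        F = subgroup_freqs(G, meta)
        with pytest.raises(DiversityError, match="divide"):
            joint_maf(F, "WLD", "NS", bin_width=0.07)

    def test_bottleneck_lowers_diagonal_mass(self):
        # same generating freqs vs a strong bottleneck: fixed-seed simulation
        from bogdiv.synthetic_data import simulate_structured_population

        G0, meta0, _ = simulate_structured_population((60, 60), 400, 0.0, seed=3)
        F0 = subgroup_freqs(G0, meta0)
        same = joint_maf(F0, "WLD", "NS").diagonal_mass
        G1, meta1, _ = simulate_structured_population((60, 60), 400, 0.25, seed=3)
        F1 = subgroup_freqs(G1, meta1)
        apart = joint_maf(F1, "WLD", "NS").diagonal_mass
        assert same > apart


class TestExpectedHet:
    @pytest.mark.parametrize(
        "p,he", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.1, 0.18)]
    )
    def test_arithmetic(self, p, he):
        n = 10
        dos = np.full((n, 1), 0, dtype=np.int8)
        k = int(round(p * 2 * n))
        flat = np.zeros(2 * n, dtype=np.int8)
        flat[:k] = 1
        dos[:, 0] = flat.reshape(n, 2).sum(axis=1)
        ids = [f"A{i}" for i in range(n)]
        F = subgroup_freqs(toy_matrix(dos, ids=ids), toy_metadata(ids, ["WLD"] * n))
        assert expected_het(F)["he"].iloc[0] == pytest.approx(he)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_invariant_to_allele_label_swap(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
        ids = [f"A{i}" for i in range(8)]
        meta = toy_metadata(ids, ["WLD"] * 8)
        he = expected_het(subgroup_freqs(toy_matrix(dos, ids=ids), meta))["he"]
        he_swap = expected_het(
            subgroup_freqs(toy_matrix(2 - dos, ids=ids), meta)
        )["he"]
        np.testing.assert_allclose(he, he_swap)


def test_bin_edges_cover_half():
    edges = maf_bin_edges(0.05)
    assert len(edges) == 11 and edges[0] == 0.0 and edges[-1] == 0.5
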