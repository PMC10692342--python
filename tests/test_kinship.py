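"""Relationship matrices: pedigree A and its inverse, SNP QC, G, Gw, H."""

import numpy as np
import pandas as pd
import pytest

from heatnorm import kinship
from conftest import random_pedigree


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


def recursive_a(ped: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Independent oracle: memoised recursion a(i,j) = ½[a(s_i,j) + a(d_i,j)]."""
    ped = kinship.sort_pedigree(ped)
    ids = ped["id"].tolist()
    parents = {r["id"]: (r["sire"], r["dam"]) for _, r in ped.iterrows()}
    order = {v: i for i, v in enumerate(ids)}
    cache = {}

    def a(i, j):
        if i in (0, "0", None) or j in (0, "0", None):
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        s, d = parents[i]
        if i == j:
            val = 1.0 + 0.5 * a(s, d)
        else:
            val = 0.5 * (a(s, j) + a(d, j))
        cache[(i, j)] = val
        return val

    return np.array([[a(i, j) for j in ids] for i in ids]), ids


class TestBuildA:
    def test_parent_offspring(self):
        A, ids = kinship.build_A(_ped([("p1", 0, 0), ("p2", 0, 0), ("o", "p1", "p2")]))
        i = {v: k for k, v in enumerate(ids)}
        assert A[i["o"], i["p1"]] == pytest.approx(0.5)
        assert A[i["o"], i["o"]] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        ped = _ped([("p1", 0, 0), ("p2", 0, 0),
                    ("s1", "p1", "p2"), ("s2", "p1", "p2"),
                    ("x", "s1", "s2")])
        A, ids = kinship.build_A(ped)
        i = {v: k for k, v in enumerate(ids)}
        assert A[i["s1"], i["s2"]] == pytest.approx(0.5)
        assert A[i["x"], i["x"]] == pytest.approx(1.25)  # F = 0.25

    def test_matches_recursive_oracle(self, rng):
        for _ in range(5):
            ped = random_pedigree(rng, n_founders=3, n_total=12)
            A, ids = kinship.build_A(ped)
            expect, oids = recursive_a(ped)
            assert ids == oids
            np.testing.assert_allclose(A, expect, atol=1e-12)

    def test_psd_and_diag(self, rng):
        ped = random_pedigree(rng, n_founders=5, n_total=40)
        A, _ = kinship.build_A(ped)
        assert np.linalg.eigvalsh(A).min() >= -1e-9
        assert np.all(np.diag(A) >= 1.0 - 1e-12)

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            kinship.sort_pedigree(_ped([("a", "b", 0), ("b", "a", 0)]))


def test_a_inverse_matches_dense_inverse(rng):
    ped = random_pedigree(rng, n_founders=4, n_total=20)
    A, _ = kinship.build_A(ped)
    Ainv, _ = kinship.a_inverse(ped)
    np.testing.assert_allclose(Ainv.toarray(), np.linalg.inv(A), atol=1e-9)


class TestSnpQc:
    def test_monomorphic_and_missing(self):
        g = np.zeros((40, 3))
        g[:, 1] = np.tile([0, 1, 2, 1], 10)   # polymorphic, HWE-ish
        g[:4, 2] = np.nan                      # 10% missing → call rate 0.90
        g[:, 2][4:] = np.tile([0, 1, 2, 1], 9)
        keep, rep = kinship.snp_qc(g, ["1", "2", "3"])
        assert not keep[0] and rep["fail_maf"] >= 1      # monomorphic = MAF 0
        assert not keep[2] and rep["fail_call_rate"] == 1
        assert keep[1]

    def test_hwe_chi_square_hand_value(self):
        # counts (AA, Aa, aa) = (50, 0, 50): expected (25, 50, 25), chi² = 100
        g = np.concatenate([np.zeros(50), np.full(50, 2.0)])[:, None]
        g = np.hstack([g, np.tile([0, 1, 2, 1], 25)[:, None]])  # second SNP passes
        keep, rep = kinship.snp_qc(g, ["1", "1"], hwe_alpha=1e-6)
        assert not keep[0] and rep["fail_hwe"] == 1
        assert keep[1]

    def test_non_autosomal_removed(self):
        g = np.tile([0.0, 1.0, 2.0, 1.0], 25)[:, None]
        keep, rep = kinship.snp_qc(np.hstack([g, g]), ["X", "12"])
        assert not keep[0] and keep[1]

    def test_all_removed_raises(self):
        g = np.zeros((20, 1))
        with pytest.raises(ValueError, match="all SNPs removed"):
            kinship.snp_qc(g, ["1"])


class TestBuildG:
    def test_single_snp_hand_value(self):
        # genotypes (2, 0), p = 0.5: Z = (1, −1), denom = 0.5 → [[2,−2],[−2,2]]
        G = kinship.build_G(np.array([[2.0], [0.0]]))
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_identical_genotypes(self, rng):
        g1 = rng.binomial(2, rng.uniform(0.2, 0.5, 50), size=(1, 50)).astype(float)
        G = kinship.build_G(np.vstack([g1, g1, rng.binomial(2, 0.3, 50)]))
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-12)
        assert G[0, 1] == pytest.approx(G[1, 1], abs=1e-12)

    def test_mean_diagonal_near_one(self, rng):
        # HWE population, n=500, m=2000: E[diag] = 1
        p = rng.uniform(0.05, 0.5, 2000)
        g = rng.binomial(2, p, size=(500, 2000)).astype(float)
        G = kinship.build_G(g)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_allele_coding_swap_invariance(self, rng):
        p = rng.uniform(0.1, 0.5, 60)
        g = rng.binomial(2, p, size=(25, 60)).astype(float)
        G1 = kinship.build_G(g)
        g2 = g.copy()
        g2[:, ::2] = 2.0 - g2[:, ::2]  # swap coding of half the SNPs
        np.testing.assert_allclose(G1, kinship.build_G(g2), atol=1e-10)

    def test_monomorphic_denominator(self):
        with pytest.raises(ValueError, match="monomorphic"):
            kinship.build_G(np.full((4, 3), 2.0))


def _g_with_pairs(n, pairs, rel=0.99):
    G = np.eye(n)
    for i, j in pairs:
        G[i, j] = G[j, i] = rel
    return G


class TestPrune:
    def test_duplicates_one_retained(self):
        G = _g_with_pairs(5, [(1, 4)])  # individual e duplicates b
        kept = kinship.prune_high_relationship(G, ["a", "b", "c", "d", "e"])
        assert len(kept) == 4 and ("b" in kept) != ("e" in kept)

    def test_no_violations_identity(self):
        G = _g_with_pairs(6, [(0, 1)], rel=0.90)  # below the 0.95 threshold
        ids = list("abcdef")
        assert kinship.prune_high_relationship(G, ids) == ids

    def test_two_duplicate_pairs_minimal_removal(self):
        G = _g_with_pairs(6, [(0, 4), (2, 5)])
        kept = kinship.prune_high_relationship(G, list("abcdef"))
        # exhaustive minimal removal: drop exactly one from each pair
        assert len(kept) == 4
        assert ("a" in kept) != ("e" in kept)
        assert ("c" in kept) != ("f" in kept)

    def test_tie_breaks_drop_larger_id(self):
        G = _g_with_pairs(3, [(0, 2)])
        assert kinship.prune_high_relationship(G, ["x", "y", "z"]) == ["x", "y"]


class TestSingleStep:
    def _toy(self, rng, n_geno=3):
        ped = _ped([("s1", 0, 0), ("s2", 0, 0), ("d1", 0, 0), ("d2", 0, 0),
                    ("a", "s1", "d1"), ("b", "s1", "d2"), ("c", "s2", "d1"),
                    ("x", "a", "d2")])
        A, ids = kinship.build_A(ped)
        gidx = [ids.index("s1"), ids.index("s2"), ids.index("a")][:n_geno]
        G = A[np.ix_(gidx, gidx)] + np.diag(rng.uniform(0.01, 0.1, len(gidx)))
        return ped, A, ids, gidx, G

    def test_no_genotyped_is_pedigree_only(self, rng):
        ped, A, ids, _, _ = self._toy(rng)
        _, H_inv = kinship.blend_and_H_inverse(None, A, [])
        np.testing.assert_allclose(H_inv, np.linalg.inv(A), atol=1e-10)

    def test_blend_zero_is_pedigree_only(self, rng):
        ped, A, ids, gidx, G = self._toy(rng)
        Gw, H_inv = kinship.blend_and_H_inverse(G, A, gidx, blend_w=0.0)
        np.testing.assert_allclose(Gw, A[np.ix_(gidx, gidx)], atol=1e-12)
        np.testing.assert_allclose(H_inv, np.linalg.inv(A), atol=1e-9)

    def test_h_inverse_matches_direct_formula(self, rng):
        ped, A, ids, gidx, G = self._toy(rng)
        Gw, H_inv = kinship.blend_and_H_inverse(G, A, gidx, blend_w=0.95)
        H_direct = kinship.build_H(A, Gw, gidx)
        np.testing.assert_allclose(np.linalg.inv(H_inv), H_direct, atol=1e-8)

    def test_ungenotyped_block_unchanged_without_genotyped_descendants(self, rng):
        # animals unrelated to any genotyped animal keep their pedigree block
        ped = _ped([("s1", 0, 0), ("u1", 0, 0), ("u2", 0, 0),
                    ("g1", "s1", 0), ("v", "u1", "u2")])
        A, ids = kinship.build_A(ped)
        gidx = [ids.index("g1")]
        G = np.array([[1.05]])
        Gw, H_inv = kinship.blend_and_H_inverse(G, A, gidx)
        H = np.linalg.inv(H_inv)
        for a in ("u1", "u2", "v"):
            for b in ("u1", "u2", "v"):
                assert H[ids.index(a), ids.index(b)] == pytest.approx(
                    A[ids.index(a), ids.index(b)], abs=1e-9)

    def test_singular_gw_raises(self):
        A = np.eye(3)
        G = np.ones((2, 2))  # singular
        with pytest.raises(np.linalg.LinAlgError, match="blend_w"):
            kinship.blend_and_H_inverse(G, A, [0, 1], blend_w=1.0)
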