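"""Relationship matrices: M, A, G, H and the population partition."""

import numpy as np
import pytest

from erosim import (
    PedigreeRecord,
    PopulationPartition,
    RelationshipMatrix,
    build_A,
    build_G,
    build_H,
    center_scale,
    partition,
)
from conftest import toy_genotypes
from _oracles import single_step_H, tabular_A_full


class TestCenterScale:
    def test_single_variant_half_freq(self):
        geno = toy_genotypes(np.array([[0], [1], [2]]))
        M = center_scale(geno, freqs=np.array([0.5]))
        np.testing.assert_allclose(
            M.values[:, 0], np.array([-1.0, 0.0, 1.0]) * 0.5**-0.5
        )

    def test_own_frequencies_center_columns(self, founders_small):
        geno, _ = founders_small
        M = center_scale(geno)
        assert np.abs(M.values.mean(axis=0)).max() < 1e-12

    def test_scale_factor_hand_computation(self):
        # sum 2p(1-p) over p = (0.2, 0.5, 0.7) is 0.32 + 0.5 + 0.42 = 1.24
        geno = toy_genotypes(np.array([[0, 1, 2], [1, 1, 1]]))
        M = center_scale(geno, freqs=np.array([0.2, 0.5, 0.7]))
        assert M.scale_factor == pytest.approx(1.24**-0.5, rel=1e-12)

    def test_monomorphic_frequency_rejected(self):
        geno = toy_genotypes(np.array([[0, 2], [0, 0]]))
        with pytest.raises(ValueError, match="v0"):
            center_scale(geno, freqs=np.array([0.0, 0.5]))


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        recs = [PedigreeRecord(f"f{i}") for i in range(4)]
        A = build_A(recs)
        np.testing.assert_allclose(A.values, np.eye(4))

    def test_textbook_relationships(self, trio_records):
        recs = trio_records + [PedigreeRecord("kid2", "sire1", "dam1", "M", 1)]
        A = build_A(recs)
        i = {s: k for k, s in enumerate(A.ids)}
        assert A.values[i["sire1"], i["kid1"]] == pytest.approx(0.5)
        assert A.values[i["kid1"], i["kid2"]] == pytest.approx(0.5)  # full sibs
        assert A.values[i["kid1"], i["kid1"]] == pytest.approx(1.0)

    def test_half_sib_mating_inbreeding(self):
        recs = [
            PedigreeRecord("S"), PedigreeRecord("d1"), PedigreeRecord("d2"),
            PedigreeRecord("h1", "S", "d1", "M", 1),
            PedigreeRecord("h2", "S", "d2", "F", 1),
            PedigreeRecord("c", "h1", "h2", "F", 2),
        ]
        A = build_A(recs)
        i = A.ids.index("c")
        assert A.values[i, i] == pytest.approx(1.125)

    def test_matches_scalar_tabular_oracle(self):
        rng = np.random.default_rng(0)
        recs = [PedigreeRecord(f"f{i}") for i in range(6)]
        parents = {r.id: (None, None) for r in recs}
        for g, size in ((1, 6), (2, 6)):
            prev = [r.id for r in recs if r.generation == g - 1]
            for k in range(size):
                s, d = rng.choice(prev, size=2, replace=False)
                rid = f"g{g}_{k}"
                recs.append(PedigreeRecord(rid, s, d, None, g))
                parents[rid] = (s, d)
        A = build_A(recs, max_depth=None)
        expected = tabular_A_full([r.id for r in recs], parents)
        np.testing.assert_allclose(A.align([r.id for r in recs]), expected,
                                   atol=1e-12)

    def test_depth_truncation_turns_ancestors_into_founders(self):
        chain = [PedigreeRecord("a0")]
        for k in range(1, 6):
            chain.append(PedigreeRecord(f"a{k}", sire=f"a{k-1}", generation=k))
        full = build_A(chain, ids=["a5", "a0"], max_depth=None)
        trunc = build_A(chain, ids=["a5", "a0"], max_depth=3)
        assert full.values[0, 1] == pytest.approx(0.5**5)
        assert trunc.values[0, 1] == pytest.approx(0.0)

    def test_own_ancestor_rejected(self):
        recs = [PedigreeRecord("x", sire="x")]
        with pytest.raises(ValueError):
            build_A(recs)

    def test_missing_id_rejected(self, trio_records):
        with pytest.raises(KeyError):
            build_A(trio_records, ids=["ghost"])


class TestGenomicG:
    def test_two_individual_hand_computation(self):
        geno = toy_genotypes(np.array([[0], [2]]))
        G = build_G(center_scale(geno, freqs=np.array([0.5])))
        np.testing.assert_allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_constant_heterozygote_zero_matrix(self):
        geno = toy_genotypes(np.ones((3, 4), dtype=int))
        G = build_G(center_scale(geno, freqs=np.full(4, 0.5)))
        np.testing.assert_allclose(G.values, 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        geno = toy_genotypes(rng.integers(0, 3, size=(5, 50)))
        M = center_scale(geno)
        G = build_G(M)
        brute = np.zeros((5, 5))
        for i in range(5):
            for k in range(5):
                brute[i, k] = sum(M.values[i, j] * M.values[k, j] for j in range(50))
        np.testing.assert_allclose(G.values, brute, atol=1e-12)

    def test_psd_and_mean_diagonal(self, founders_small):
        geno, _ = founders_small
        G = build_G(center_scale(geno))
        ev = np.linalg.eigvalsh(G.values)
        assert ev.min() > -1e-8
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.15)


class TestSingleStepH:
    @staticmethod
    def _toy():
        recs = [
            PedigreeRecord("f1"), PedigreeRecord("f2"),
            PedigreeRecord("k1", "f1", "f2", None, 1),
            PedigreeRecord("k2", "f1", "f2", None, 1),
        ]
        A = build_A(recs)
        rng = np.random.default_rng(2)
        geno = toy_genotypes(rng.integers(0, 3, size=(2, 30)), ids=["k1", "k2"])
        G = build_G(center_scale(geno, freqs=np.full(30, 0.5)))
        return A, G

    def test_reduces_to_G_when_all_genotyped(self, founders_small):
        geno, records = founders_small
        sub = geno.subset_samples(geno.sample_ids[:20])
        p = sub.allele_freqs()
        sub = sub.subset_variants((p > 0) & (p < 1))
        A = build_A(records[:20])
        G = build_G(center_scale(sub))
        H = build_H(A, G, list(sub.sample_ids), blend_beta=1.0)
        np.testing.assert_allclose(H.values, G.align(A.ids), atol=1e-10)

    def test_reduces_to_A_when_none_genotyped(self):
        A, G = self._toy()
        H = build_H(A, G, [])
        np.testing.assert_allclose(H.values, A.values)

    def test_matches_block_formula_oracle(self):
        A, G = self._toy()
        H = build_H(A, G, ["k1", "k2"], blend_beta=0.95)
        g_idx = [A.ids.index(s) for s in ("k1", "k2")]
        u_idx = [i for i in range(4) if i not in g_idx]
        expected = single_step_H(
            A.values, G.align(["k1", "k2"]), g_idx, u_idx, 0.95
        )
        np.testing.assert_allclose(H.values, expected, atol=1e-10)


class TestPartition:
    @staticmethod
    def _W(n=5):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((n, n + 2))
        return RelationshipMatrix("G", [f"s{i}" for i in range(n)], X @ X.T)

    def test_block_shapes_and_symmetry(self):
        W = self._W()
        split = PopulationPartition(["s0", "s1", "s2"], ["s3", "s4"])
        W11, W12, W21, W22 = partition(W, split)
        assert W11.shape == (3, 3) and W12.shape == (3, 2)
        assert W21.shape == (2, 3) and W22.shape == (2, 2)
        np.testing.assert_array_equal(W21, W12.T)

    def test_blocks_reassemble(self):
        W = self._W()
        split = PopulationPartition(["s0", "s1", "s2"], ["s3", "s4"])
        W11, W12, W21, W22 = partition(W, split)
        re = np.block([[W11, W12], [W21, W22]])
        np.testing.assert_array_equal(re, W.values)

    def test_scrambled_order_same_blocks(self):
        W = self._W()
        split = PopulationPartition(["s2", "s0"], ["s4", "s1"])
        W11, _, W21, _ = partition(W, split)
        idx = {s: i for i, s in enumerate(W.ids)}
        for a, sa in enumerate(["s2", "s0"]):
            for b, sb in enumerate(["s2", "s0"]):
                assert W11[a, b] == W.values[idx[sa], idx[sb]]
            for t, st in enumerate(["s4", "s1"]):
                assert W21[t, a] == W.values[idx[st], idx[sa]]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PopulationPartition(["s0", "s1"], ["s1", "s2"])
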