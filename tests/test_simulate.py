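"""Simulator: LD structure, mating/recombination, trait generation."""

import numpy as np
import pytest

from erosim import (
    GenotypeMatrix,
    LDGenotypeModel,
    TraitSimConfig,
    advance_generation,
    simulate_founders,
    simulate_trait,
    simulate_trait_from_W,
)
from conftest import toy_genotypes


class TestFounders:
    def test_model_validation(self):
        with pytest.raises(ValueError):
            LDGenotypeModel(n_snps=5, n_chromosomes=10)
        with pytest.raises(ValueError):
            LDGenotypeModel(ld_decay=0.0)
        with pytest.raises(ValueError):
            LDGenotypeModel(freq_range=(0.0, 0.5))

    def test_too_few_snps_per_chromosome(self):
        model = LDGenotypeModel(n_snps=10, n_chromosomes=10)
        with pytest.raises(ValueError, match="fewer than 2 SNPs"):
            simulate_founders(model, 10)

    def test_independence_limit(self):
        """With a vanishing decay length adjacent loci are uncorrelated."""
        model = LDGenotypeModel(n_snps=200, n_chromosomes=1, ld_decay=1e-6,
                                freq_range=(0.4, 0.6), seed=3)
        geno, _ = simulate_founders(model, 400)
        H = geno.haplotypes.reshape(-1, geno.m).astype(float)
        cors = [np.corrcoef(H[:, j], H[:, j + 1])[0, 1] for j in range(0, 199, 7)]
        assert abs(np.mean(cors)) < 0.05

    def test_comonotone_limit(self):
        """With an enormous decay length and p=0.5 adjacent loci nearly match."""
        model = LDGenotypeModel(n_snps=100, n_chromosomes=1, ld_decay=1e6,
                                freq_range=(0.5, 0.5), seed=4)
        geno, _ = simulate_founders(model, 200)
        H = geno.haplotypes.reshape(-1, geno.m)
        agree = (H[:, :-1] == H[:, 1:]).mean()
        assert agree > 0.99

    def test_r2_decays_with_map_distance(self):
        """Pairs ~1 cM apart carry more LD than pairs ~20 cM apart."""
        model = LDGenotypeModel(n_snps=200, n_chromosomes=1, ld_decay=5.0, seed=5)
        geno, _ = simulate_founders(model, 500)
        H = geno.haplotypes.reshape(-1, geno.m).astype(float)
        C2 = np.corrcoef(H.T) ** 2
        near, far = [], []
        for i in range(geno.m):
            for j in range(i + 1, geno.m):
                d = geno.pos_cM[j] - geno.pos_cM[i]
                if d < 1.5:
                    near.append(C2[i, j])
                elif 18.0 < d < 25.0:
                    far.append(C2[i, j])
        assert np.mean(near) > 2.0 * np.mean(far)

    def test_sex_balance_and_reproducibility(self):
        model = LDGenotypeModel(n_snps=60, n_chromosomes=2, seed=8)
        g1, r1 = simulate_founders(model, 100)
        g2, r2 = simulate_founders(model, 100)
        assert np.array_equal(g1.dosages, g2.dosages)
        assert [r.sex for r in r1] == [r.sex for r in r2]
        assert sum(r.sex == "M" for r in r1) == 50


class TestMating:
    def test_requires_haplotypes(self, founders_small):
        geno, records = founders_small
        bare = GenotypeMatrix(
            sample_ids=list(geno.sample_ids), variant_ids=list(geno.variant_ids),
            chrom=geno.chrom, pos_cM=geno.pos_cM, dosages=geno.dosages,
        )
        with pytest.raises(ValueError, match="haplotypes"):
            advance_generation(bare, records, 10, seed=0)

    def test_zero_map_length_gives_intact_haplotypes(self, founders_small):
        geno, records = founders_small
        off, _ = advance_generation(
            geno, records, 30, seed=1, map_length_per_chrom=0.0
        )
        # chromosomes still assort independently, so compare per chromosome
        for c in np.unique(geno.chrom):
            sel = geno.chrom == c
            parental = {
                h[sel].tobytes() for ind in geno.haplotypes for h in ind
            }
            for ind in off.haplotypes:
                for h in ind:
                    assert h[sel].tobytes() in parental

    def test_mid_parent_transmission(self):
        """Offspring mean dosage matches the parental average per locus."""
        model = LDGenotypeModel(n_snps=100, n_chromosomes=2, seed=9)
        geno, records = simulate_founders(model, 2)
        off, _ = advance_generation(geno, records, 1000, seed=2,
                                    map_length_per_chrom=100.0)
        mid = geno.dosages.mean(axis=0)
        diff = off.dosages.mean(axis=0) - mid
        # transmission is binomial: SE per locus <= sqrt(0.5)/sqrt(n)
        assert np.max(np.abs(diff)) < 5 * np.sqrt(0.5 / 1000)

    def test_dosage_haplotype_consistency_and_pedigree(self, two_generations):
        geno, records, off, off_rec = two_generations
        assert np.array_equal(off.haplotypes.sum(axis=1), off.dosages)
        assert set(np.unique(off.dosages)) <= {0, 1, 2}
        parent_ids = set(geno.sample_ids)
        for r in off_rec:
            assert r.sire in parent_ids and r.dam in parent_ids
            assert r.generation == 1

    def test_neutral_drift_is_unbiased(self, founders_small):
        """Mean allele-frequency change over replicate matings is ~0."""
        geno, records = founders_small
        p0 = geno.allele_freqs()
        deltas = []
        for seed in range(6):
            off, _ = advance_generation(geno, records, 150, seed=seed,
                                        map_length_per_chrom=100.0)
            deltas.append(off.allele_freqs() - p0)
        assert abs(np.mean(deltas)) < 0.01


class TestTrait:
    def test_h2_domain(self):
        with pytest.raises(ValueError):
            TraitSimConfig(h2=0.0)
        with pytest.raises(ValueError):
            TraitSimConfig(h2=1.0)

    def test_identity_y_eq_g_plus_e(self, founders_small):
        geno, _ = founders_small
        trait = simulate_trait(geno, TraitSimConfig(h2=0.5, n_qtl=50, seed=1))
        np.testing.assert_allclose(trait.y, trait.g_true + trait.epsilon)

    def test_all_monomorphic_qtl_error(self):
        geno = toy_genotypes(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError, match="monomorphic"):
            simulate_trait(geno, TraitSimConfig(h2=0.3, n_qtl=4, seed=0))

    def test_monomorphic_qtl_warns_but_runs(self):
        d = np.array([[0, 0, 2], [0, 1, 0], [0, 2, 1], [0, 1, 1]])
        geno = toy_genotypes(d)
        with pytest.warns(UserWarning, match="monomorphic"):
            trait = simulate_trait(
                geno, TraitSimConfig(h2=0.3, qtl_ids=("v0", "v1"), seed=0)
            )
        assert np.isfinite(trait.y).all()

    def test_heritability_calibration(self):
        """Across replicates the realized var(g)/var(y) is centred on h2."""
        model = LDGenotypeModel(n_snps=800, n_chromosomes=8, seed=10)
        geno, _ = simulate_founders(model, 400)
        ratios = []
        for seed in range(300):
            t = simulate_trait(geno, TraitSimConfig(h2=0.4, n_qtl=100, seed=seed))
            ratios.append(np.var(t.g_true) / np.var(t.y))
        mean, se = np.mean(ratios), np.std(ratios) / np.sqrt(len(ratios))
        assert abs(mean - 0.4) < 3 * se + 0.01


class TestTraitFromW:
    def test_identity_covariance(self):
        t = simulate_trait_from_W(np.eye(2000), h2=0.5, sigma2_y=100.0, seed=3)
        assert abs(np.var(t.g_true) - 50.0) < 5.0
        assert abs(np.var(t.y) - 100.0) < 10.0

    def test_parent_offspring_covariance_recovery(self):
        W = np.array([[1.0, 0.5], [0.5, 1.0]])
        gp, go = [], []
        for seed in range(4000):
            t = simulate_trait_from_W(W, h2=0.8, sigma2_y=1.0, seed=seed)
            gp.append(t.g_true[0])
            go.append(t.g_true[1])
        assert abs(np.corrcoef(gp, go)[0, 1] - 0.5) < 0.05

    def test_determinism(self):
        W = np.eye(50)
        a = simulate_trait_from_W(W, 0.3, 100.0, seed=11)
        b = simulate_trait_from_W(W, 0.3, 100.0, seed=11)
        assert a.y.tobytes() == b.y.tobytes()

    def test_asymmetric_rejected(self):
        W = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            simulate_trait_from_W(W, 0.5, 1.0, seed=0)
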