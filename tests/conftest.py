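import numpy as np
import pytest

from erosim import (
    GenotypeMatrix,
    LDGenotypeModel,
    PedigreeRecord,
    advance_generation,
    simulate_founders,
)


@pytest.fixture(scope="session")
def founders_small():
    """200 founders x 400 SNPs with moderate LD (session-wide, read-only)."""
    model = LDGenotypeModel(n_snps=400, n_chromosomes=4, ld_decay=10.0, seed=42)
    return simulate_founders(model, 200)


@pytest.fixture(scope="session")
def two_generations(founders_small):
    """Founders plus one offspring generation of 100."""
    geno, records = founders_small
    off, off_rec = advance_generation(
        geno, records, 100, seed=7, map_length_per_chrom=100.0
    )
    return geno, records, off, off_rec


@pytest.fixture()
def trio_records():
    return [
        PedigreeRecord("sire1", None, None, "M", 0),
        PedigreeRecord("dam1", None, None, "F", 0),
        PedigreeRecord("kid1", "sire1", "dam1", "F", 1),
    ]


def toy_genotypes(dosages, pos=None, chrom=None, ids=None):
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        variant_ids=[f"v{j}" for j in range(m)],
        chrom=np.ones(m, dtype=int) if chrom is None else chrom,
        pos_cM=np.arange(1.0, m + 1.0) if pos is None else pos,
        dosages=dosages,
    )
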