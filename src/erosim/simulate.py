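"""Forward-in-time SNP genotype and additive trait simulator.

Generates founder haplotypes with tunable linkage disequilibrium through a
latent-Gaussian autoregressive copula, advances a population by random mating
with Poisson recombination (no selection, mutation or migration), and
simulates additive phenotypes either from genotypes (explicit SNP effects)
or directly from a relationship matrix.  The defaults mimic a livestock
genomic-prediction design: a phenotyped reference population followed by
non-phenotyped descendant generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "LDGenotypeModel",
    "GenotypeMatrix",
    "PedigreeRecord",
    "TraitSimConfig",
    "SimulatedTrait",
    "simulate_founders",
    "advance_generation",
    "simulate_trait",
    "simulate_trait_from_W",
]


@dataclass(frozen=True)
class LDGenotypeModel:
    """Generative model for founder SNP haplotypes.

    Each chromosome carries a latent stationary Gaussian process along the
    genetic map; the latent correlation between adjacent loci decays as
    ``exp(-d_cM / ld_decay)``, and alleles are obtained by thresholding the
    latent value at the normal quantile of the locus allele frequency.  This
    is a simple, seedable stand-in for a cattle-like LD structure; ``ld_decay``
    tunes how fast pairwise r^2 decays with map distance.

    Parameters
    ----------
    n_snps : total number of SNPs across all chromosomes.
    n_chromosomes : number of chromosomes; SNPs are spread evenly.
    map_length : genetic length of each chromosome in centimorgans.
    ld_decay : correlation-decay length in centimorgans (> 0).
    freq_range : closed interval in (0, 1) for founder allele frequencies.
    seed : default random seed for founder simulation.
    """

    n_snps: int = 1000
    n_chromosomes: int = 10
    map_length: float = 100.0
    ld_decay: float = 15.0
    freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("n_snps must be >= n_chromosomes")
        if not self.map_length > 0:
            raise ValueError("map_length must be > 0")
        if not self.ld_decay > 0:
            raise ValueError("ld_decay must be > 0")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must be inside (0, 1)")


@dataclass
class GenotypeMatrix:
    """SNP data for a set of individuals.

    ``dosages`` counts ALT alleles (0/1/2).  ``haplotypes`` (n, 2, m), when
    present, carries the two phased allele vectors per individual and must be
    consistent with ``dosages``; it is required for mating.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    chrom: np.ndarray
    pos_cM: np.ndarray
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.variant_ids) != m:
            raise ValueError("id lengths inconsistent with dosage shape")
        if self.chrom.shape != (m,) or self.pos_cM.shape != (m,):
            raise ValueError("per-variant metadata length mismatch")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        for c in np.unique(self.chrom):
            p = self.pos_cM[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"pos_cM not strictly increasing on chromosome {c}")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes)
            if self.haplotypes.shape != (n, 2, m):
                raise ValueError("haplotypes must have shape (n, 2, m)")
            if not np.array_equal(self.haplotypes.sum(axis=1), self.dosages):
                raise ValueError("dosages inconsistent with haplotypes")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Observed ALT allele frequencies per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=[v for v, k in zip(self.variant_ids, mask) if k],
            chrom=self.chrom[mask],
            pos_cM=self.pos_cM[mask],
            dosages=self.dosages[:, mask],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, mask],
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            variant_ids=list(self.variant_ids),
            chrom=self.chrom,
            pos_cM=self.pos_cM,
            dosages=self.dosages[rows],
            haplotypes=None if self.haplotypes is None else self.haplotypes[rows],
        )

    @staticmethod
    def concat(parts: list["GenotypeMatrix"]) -> "GenotypeMatrix":
        first = parts[0]
        for p in parts[1:]:
            if p.variant_ids != first.variant_ids:
                raise ValueError("cannot concatenate: variant sets differ")
        haps = None
        if all(p.haplotypes is not None for p in parts):
            haps = np.concatenate([p.haplotypes for p in parts], axis=0)
        return GenotypeMatrix(
            sample_ids=[s for p in parts for s in p.sample_ids],
            variant_ids=list(first.variant_ids),
            chrom=first.chrom,
            pos_cM=first.pos_cM,
            dosages=np.concatenate([p.dosages for p in parts], axis=0),
            haplotypes=haps,
        )


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree entry; ``sire``/``dam`` are None when unknown."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str | None = None  # "M" | "F" | None
    generation: int = 0


@dataclass(frozen=True)
class TraitSimConfig:
    """Configuration for the additive trait simulator.

    ``sigma2_y`` is the phenotypic variance (default 100), ``h2`` the
    heritability, ``n_qtl`` the number of causal variants drawn uniformly
    without replacement unless ``qtl_ids`` pins them explicitly.
    """

    sigma2_y: float = 100.0
    h2: float = 0.4
    n_qtl: int = 100
    qtl_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")
        if not self.sigma2_y > 0:
            raise ValueError("sigma2_y must be > 0")
        if self.n_qtl < 1 and self.qtl_ids is None:
            raise ValueError("n_qtl must be >= 1")


@dataclass
class SimulatedTrait:
    """Simulated phenotypes with their generative components.

    Satisfies ``y = g_true + epsilon`` elementwise; across replicates the
    realized var(g_true)/var(y) converges to the configured heritability.
    """

    y: np.ndarray
    g_true: np.ndarray
    epsilon: np.ndarray
    alpha: np.ndarray | None = None
    qtl_ids: list[str] | None = None


def _chrom_layout(model: LDGenotypeModel, rng: np.random.Generator):
    """Assign SNP counts and strictly increasing map positions per chromosome."""
    base = model.n_snps // model.n_chromosomes
    counts = np.full(model.n_chromosomes, base, dtype=int)
    counts[: model.n_snps - base * model.n_chromosomes] += 1
    if (counts < 2).any():
        raise ValueError(
            "fewer than 2 SNPs on a chromosome; increase n_snps or reduce n_chromosomes"
        )
    chrom = np.repeat(np.arange(1, model.n_chromosomes + 1), counts)
    pos = np.empty(model.n_snps)
    start = 0
    for k in counts:
        p = np.sort(rng.uniform(0.0, model.map_length, size=k))
        # enforce strict increase against ties from finite precision
        p = p + np.arange(k) * 1e-9
        pos[start : start + k] = p
        start += k
    return chrom, pos, counts


def simulate_founders(
    model: LDGenotypeModel, n: int, seed: int | None = None, id_prefix: str = "G0"
) -> tuple[GenotypeMatrix, list[PedigreeRecord]]:
    """Simulate ``n`` founder individuals (2n haplotypes) under ``model``.

    Returns the genotype matrix (with haplotypes) and generation-0 pedigree
    records with an exact 50/50 sex split (randomly assigned).
    """
    if n < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    chrom, pos, counts = _chrom_layout(model, rng)
    freqs = rng.uniform(model.freq_range[0], model.freq_range[1], size=model.n_snps)
    thresholds = norm.ppf(freqs)

    haps2d = np.empty((2 * n, model.n_snps), dtype=np.int8)
    start = 0
    for k in counts:
        sl = slice(start, start + k)
        p = pos[sl]
        z = np.empty((2 * n, k))
        z[:, 0] = rng.standard_normal(2 * n)
        rho = np.exp(-np.diff(p) / model.ld_decay)
        innov = rng.standard_normal((2 * n, k - 1))
        for j in range(1, k):
            r = rho[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * innov[:, j - 1]
        haps2d[:, sl] = (z < thresholds[sl]).astype(np.int8)
        start += k

    haplotypes = haps2d.reshape(n, 2, model.n_snps)
    width = max(4, len(str(n)))
    sample_ids = [f"{id_prefix}_{i:0{width}d}" for i in range(1, n + 1)]
    variant_ids = [f"snp{j + 1}" for j in range(model.n_snps)]
    sexes = np.array(["M", "F"] * (n // 2) + (["M"] if n % 2 else []))
    rng.shuffle(sexes)
    records = [
        PedigreeRecord(id=s, sire=None, dam=None, sex=sx, generation=0)
        for s, sx in zip(sample_ids, sexes)
    ]
    geno = GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        chrom=chrom,
        pos_cM=pos,
        dosages=haplotypes.sum(axis=1),
        haplotypes=haplotypes,
    )
    return geno, records


def _gamete(
    hap: np.ndarray, chrom_slices, positions, lengths, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from a (2, m) parental haplotype pair.

    Crossover counts per chromosome are Poisson(map length in Morgans) with
    positions uniform on the map and no interference.
    """
    out = np.empty(hap.shape[1], dtype=np.int8)
    for sl, p, length in zip(chrom_slices, positions, lengths):
        start = rng.integers(2)
        n_x = rng.poisson(length / 100.0)
        if n_x == 0:
            out[sl] = hap[start, sl]
        else:
            cuts = np.sort(rng.uniform(0.0, length, size=n_x))
            pick = (start + np.searchsorted(cuts, p)) % 2
            seg = hap[:, sl]
            out[sl] = seg[pick, np.arange(len(p))]
    return out


def advance_generation(
    geno: GenotypeMatrix,
    records: list[PedigreeRecord],
    n_offspring: int,
    seed: int,
    id_prefix: str | None = None,
    map_length_per_chrom: float | None = None,
) -> tuple[GenotypeMatrix, list[PedigreeRecord]]:
    """Produce one generation of offspring by random mating, no selection.

    Each offspring receives one gamete from a uniformly drawn sire and one
    from a uniformly drawn dam (sampling with replacement); sexes are
    assigned with an exact 50/50 split.  ``map_length_per_chrom`` overrides
    the genetic length used for the Poisson crossover count (defaults to the
    observed map span rounded up per chromosome).
    """
    if geno.haplotypes is None:
        raise ValueError(
            "parental haplotypes are required for mating; simulate founders or "
            "phase the genotypes first"
        )
    by_id = {r.id: r for r in records}
    males = [i for i, s in enumerate(geno.sample_ids) if by_id[s].sex == "M"]
    females = [i for i, s in enumerate(geno.sample_ids) if by_id[s].sex == "F"]
    if not males or not females:
        raise ValueError("need at least one male and one female parent")
    rng = np.random.default_rng(seed)

    gen = max(by_id[s].generation for s in geno.sample_ids) + 1
    prefix = id_prefix if id_prefix is not None else f"G{gen}"
    uniq = np.unique(geno.chrom)
    chrom_slices, positions, lengths = [], [], []
    for c in uniq:
        idx = np.where(geno.chrom == c)[0]
        sl = slice(idx[0], idx[-1] + 1)
        chrom_slices.append(sl)
        positions.append(geno.pos_cM[sl])
        if map_length_per_chrom is not None:
            lengths.append(map_length_per_chrom)
        else:
            lengths.append(float(np.ceil(geno.pos_cM[sl].max())))

    haps = np.empty((n_offspring, 2, geno.m), dtype=np.int8)
    width = max(4, len(str(n_offspring)))
    new_ids, new_records = [], []
    sexes = np.array(["M", "F"] * (n_offspring // 2) + (["M"] if n_offspring % 2 else []))
    rng.shuffle(sexes)
    for i in range(n_offspring):
        si = males[rng.integers(len(males))]
        di = females[rng.integers(len(females))]
        haps[i, 0] = _gamete(geno.haplotypes[si], chrom_slices, positions, lengths, rng)
        haps[i, 1] = _gamete(geno.haplotypes[di], chrom_slices, positions, lengths, rng)
        child = f"{prefix}_{i + 1:0{width}d}"
        new_ids.append(child)
        new_records.append(
            PedigreeRecord(
                id=child,
                sire=geno.sample_ids[si],
                dam=geno.sample_ids[di],
                sex=sexes[i],
                generation=gen,
            )
        )
    offspring = GenotypeMatrix(
        sample_ids=new_ids,
        variant_ids=list(geno.variant_ids),
        chrom=geno.chrom,
        pos_cM=geno.pos_cM,
        dosages=haps.sum(axis=1),
        haplotypes=haps,
    )
    return offspring, new_records


def simulate_trait(geno: GenotypeMatrix, cfg: TraitSimConfig) -> SimulatedTrait:
    """Simulate an additive phenotype from genotypes.

    SNP effects are drawn ``alpha ~ N(0, h2 * sigma2_y / sum 2p(1-p))`` over
    the QTL set, genetic values are ``g = M alpha`` with M centred (not
    scaled) at the observed allele frequencies, and residuals are
    ``N(0, (1-h2) * sigma2_y)``.  Monomorphic QTL are excluded from the
    variance denominator with a warning (their centred column is zero).
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.qtl_ids is not None:
        index = {v: j for j, v in enumerate(geno.variant_ids)}
        missing = [v for v in cfg.qtl_ids if v not in index]
        if missing:
            raise KeyError(f"qtl_ids not in genotype matrix: {missing[:5]}")
        qtl = np.array([index[v] for v in cfg.qtl_ids])
    else:
        if cfg.n_qtl > geno.m:
            raise ValueError("n_qtl exceeds the number of variants")
        qtl = np.sort(rng.choice(geno.m, size=cfg.n_qtl, replace=False))

    X = geno.dosages[:, qtl].astype(float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all QTL are monomorphic; no genetic variance possible")
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic QTL excluded from the variance "
            "denominator",
            stacklevel=2,
        )
    denom = float((2.0 * p * (1.0 - p))[poly].sum())
    alpha = rng.normal(0.0, np.sqrt(cfg.h2 * cfg.sigma2_y / denom), size=len(qtl))
    alpha[~poly] = 0.0
    g = (X - 2.0 * p) @ alpha
    eps = rng.normal(0.0, np.sqrt((1.0 - cfg.h2) * cfg.sigma2_y), size=geno.n)
    return SimulatedTrait(
        y=g + eps,
        g_true=g,
        epsilon=eps,
        alpha=alpha,
        qtl_ids=[geno.variant_ids[j] for j in qtl],
    )


def cholesky_with_jitter(
    W: np.ndarray, max_retries: int = 3
) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of ``W + delta*I`` with escalating jitter.

    ``delta`` starts at 1e-8 times the mean diagonal and grows tenfold per
    retry (at most ``max_retries`` retries) before failing with condition
    diagnostics.
    """
    W = np.asarray(W, dtype=float)
    try:
        return np.linalg.cholesky(W), 0.0
    except np.linalg.LinAlgError:
        pass
    delta = 1e-8 * float(np.mean(np.diag(W)))
    for _ in range(max_retries):
        try:
            return np.linalg.cholesky(W + delta * np.eye(W.shape[0])), delta
        except np.linalg.LinAlgError:
            delta *= 10.0
    ev = np.linalg.eigvalsh(W)
    raise np.linalg.LinAlgError(
        "covariance factorization failed after maximum jitter "
        f"(eigenvalue range [{ev.min():.3e}, {ev.max():.3e}])"
    )


def simulate_trait_from_W(
    W: np.ndarray, h2: float, sigma2_y: float, seed: int
) -> SimulatedTrait:
    """Simulate ``g ~ N(0, W h2 sigma2_y)`` plus iid residuals.

    Usable when genotypes are unavailable (pedigree-only A, or H).  ``W``
    must be symmetric; near-singular matrices are handled by the documented
    jitter policy.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("W must be symmetric")
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    L, _ = cholesky_with_jitter(W)
    n = W.shape[0]
    g = np.sqrt(h2 * sigma2_y) * (L @ rng.standard_normal(n))
    eps = rng.normal(0.0, np.sqrt((1.0 - h2) * sigma2_y), size=n)
    return SimulatedTrait(y=g + eps, g_true=g, epsilon=eps)
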