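"""Relationship matrices for genetic evaluation: pedigree A, genomic G,
single-step H, plus the centred/scaled genotype matrix M and the
reference/target partition of any of them."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import GenotypeMatrix, PedigreeRecord

__all__ = [
    "CenteredScaledGenotypes",
    "RelationshipMatrix",
    "PopulationPartition",
    "center_scale",
    "build_A",
    "build_G",
    "build_H",
    "partition",
]


@dataclass
class CenteredScaledGenotypes:
    """Centred and scaled SNP matrix M.

    ``values`` is n x m with column j equal to ``(dosage_j - 2 p_j) * s``
    where the common scale factor is ``s = (sum_j 2 p_j (1 - p_j))^(-1/2)``,
    so that ``M M'`` is a VanRaden genomic relationship matrix.
    """

    values: np.ndarray
    freqs: np.ndarray
    scale_factor: float
    sample_ids: list[str]
    variant_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix with ordered sample ids."""

    kind: str  # "A" | "G" | "H"
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: list[str]) -> np.ndarray:
        """Submatrix for ``ids`` in the requested order."""
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids not in relationship matrix: {missing[:5]}")
        rows = np.array([index[s] for s in ids])
        return self.values[np.ix_(rows, rows)]


@dataclass
class PopulationPartition:
    """Reference (phenotyped) vs target (non-phenotyped) sample ids."""

    reference_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        if not self.reference_ids or not self.target_ids:
            raise ValueError("both partitions must be nonempty")
        overlap = set(self.reference_ids) & set(self.target_ids)
        if overlap:
            raise ValueError(
                f"reference and target populations overlap: {sorted(overlap)[:5]}"
            )

    @property
    def n1(self) -> int:
        return len(self.reference_ids)

    @property
    def n2(self) -> int:
        return len(self.target_ids)

    def indices(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        index = {s: i for i, s in enumerate(ids)}
        missing = [
            s for s in self.reference_ids + self.target_ids if s not in index
        ]
        if missing:
            raise KeyError(f"partition ids missing from matrix: {missing[:5]}")
        i1 = np.array([index[s] for s in self.reference_ids])
        i2 = np.array([index[s] for s in self.target_ids])
        return i1, i2


def center_scale(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> CenteredScaledGenotypes:
    """Centre and scale dosages into the matrix M.

    ``freqs`` defaults to the observed allele frequencies of ``geno`` itself
    ("own" frequencies).  Frequencies of exactly 0 or 1 are rejected since a
    monomorphic column carries no scalable information; drop such variants
    beforehand.
    """
    p = geno.allele_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (geno.m,):
        raise ValueError("freqs length must match the number of variants")
    bad = np.where((p <= 0.0) | (p >= 1.0))[0]
    if bad.size:
        names = [geno.variant_ids[j] for j in bad[:5]]
        raise ValueError(f"allele frequency 0 or 1 for variants {names}")
    scale = float(np.sum(2.0 * p * (1.0 - p))) ** -0.5
    M = (geno.dosages - 2.0 * p) * scale
    return CenteredScaledGenotypes(
        values=M,
        freqs=p,
        scale_factor=scale,
        sample_ids=list(geno.sample_ids),
        variant_ids=list(geno.variant_ids),
    )


def _ancestor_closure(
    ped: dict[str, tuple[str | None, str | None]],
    ids: list[str],
    max_depth: int | None,
) -> dict[str, int]:
    """Minimal generation-depth of each ancestor kept within ``max_depth``."""
    depth: dict[str, int] = {}
    frontier = list(ids)
    for s in frontier:
        if s not in ped:
            raise KeyError(f"id {s!r} absent from pedigree")
        depth[s] = 0
    while frontier:
        nxt = []
        for s in frontier:
            d = depth[s]
            if max_depth is not None and d >= max_depth:
                continue
            for parent in ped.get(s, (None, None)):
                if parent is None or parent not in ped:
                    continue
                if parent not in depth or depth[parent] > d + 1:
                    depth[parent] = d + 1
                    nxt.append(parent)
        frontier = nxt
    return depth


def build_A(
    pedigree: list[PedigreeRecord],
    ids: list[str] | None = None,
    max_depth: int | None = 3,
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Ancestors more than ``max_depth`` generations above every requested
    individual are treated as unknown founders (their relationship
    contribution is truncated); ``max_depth=None`` uses the full pedigree.
    """
    ped = {r.id: (r.sire, r.dam) for r in pedigree}
    if len(ped) != len(pedigree):
        raise ValueError("duplicate ids in pedigree")
    want = [r.id for r in pedigree] if ids is None else list(ids)
    depth = _ancestor_closure(ped, want, max_depth)

    kept = set(depth)

    def parents_of(s: str) -> tuple[str | None, str | None]:
        sire, dam = ped[s]
        if max_depth is not None and depth[s] >= max_depth:
            return None, None
        return (sire if sire in kept else None, dam if dam in kept else None)

    rank: dict[str, int] = {}

    def get_rank(s: str) -> int:
        if s in rank:
            return rank[s]
        stack = [s]
        while stack:
            top = stack[-1]
            ps = [p for p in parents_of(top) if p is not None]
            pending = [p for p in ps if p not in rank]
            if pending:
                if top in pending:
                    raise ValueError(f"individual {top!r} is its own ancestor")
                stack.extend(pending)
                if len(stack) > 2 * len(kept) + 4:
                    raise ValueError("pedigree contains a cycle")
                continue
            rank[top] = 1 + max((rank[p] for p in ps), default=-1)
            stack.pop()
        return rank[s]

    order = sorted(kept, key=lambda s: (get_rank(s), s))
    pos = {s: i for i, s in enumerate(order)}
    nA = len(order)
    A = np.zeros((nA, nA))
    for i, s in enumerate(order):
        sire, dam = parents_of(s)
        si = pos[sire] if sire is not None else None
        di = pos[dam] if dam is not None else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        inbreeding = 0.5 * A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + inbreeding
    rows = np.array([pos[s] for s in want])
    return RelationshipMatrix(kind="A", ids=want, values=A[np.ix_(rows, rows)])


def build_G(M: CenteredScaledGenotypes) -> RelationshipMatrix:
    """Genomic relationship matrix ``G = M M'`` (VanRaden's first method)."""
    if M.n < 2:
        raise ValueError("need at least 2 individuals")
    G = M.values @ M.values.T
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(kind="G", ids=list(M.sample_ids), values=G)


def build_H(
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    genotyped_ids: list[str],
    blend_beta: float = 0.95,
) -> RelationshipMatrix:
    """Single-step relationship matrix combining pedigree and genomic data.

    With g = genotyped and u = ungenotyped and the blended
    ``G* = beta G + (1 - beta) A_gg``::

        H_gg = G*
        H_ug = A_ug A_gg^-1 G*
        H_uu = A_uu + A_ug A_gg^-1 (G* - A_gg) A_gg^-1 A_gu

    Reduces to G when everyone is genotyped and ``beta = 1``, and to A when
    nobody is.
    """
    if not 0.0 <= blend_beta <= 1.0:
        raise ValueError("blend_beta must be in [0, 1]")
    a_index = {s: i for i, s in enumerate(A.ids)}
    missing = [s for s in genotyped_ids if s not in a_index]
    if missing:
        raise KeyError(f"genotyped ids absent from A: {missing[:5]}")
    if set(genotyped_ids) - set(G.ids):
        raise KeyError("G does not cover all genotyped ids")
    gset = set(genotyped_ids)
    g_idx = np.array([i for i, s in enumerate(A.ids) if s in gset], dtype=int)
    u_idx = np.array([i for i, s in enumerate(A.ids) if s not in gset], dtype=int)
    H = np.array(A.values, copy=True)
    if g_idx.size == 0:
        return RelationshipMatrix(kind="H", ids=list(A.ids), values=H)

    g_ids_in_a_order = [A.ids[i] for i in g_idx]
    Agg = A.values[np.ix_(g_idx, g_idx)]
    Gmat = G.align(g_ids_in_a_order)
    Gstar = blend_beta * Gmat + (1.0 - blend_beta) * Agg
    H[np.ix_(g_idx, g_idx)] = Gstar
    if u_idx.size:
        Agu = A.values[np.ix_(g_idx, u_idx)]
        Auu = A.values[np.ix_(u_idx, u_idx)]
        try:
            X = np.linalg.solve(Agg, Agu)  # A_gg^-1 A_gu
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "A_gg is singular; condition number "
                f"{np.linalg.cond(Agg):.3e}"
            ) from exc
        Hug = X.T @ Gstar  # A_ug A_gg^-1 G*
        Huu = Auu + X.T @ (Gstar - Agg) @ X
        H[np.ix_(u_idx, g_idx)] = Hug
        H[np.ix_(g_idx, u_idx)] = Hug.T
        H[np.ix_(u_idx, u_idx)] = 0.5 * (Huu + Huu.T)
    return RelationshipMatrix(kind="H", ids=list(A.ids), values=H)


def partition(
    W: RelationshipMatrix, split: PopulationPartition
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (W11, W12, W21, W22) blocks for a reference/target split."""
    i1, i2 = split.indices(W.ids)
    W11 = W.values[np.ix_(i1, i1)]
    W12 = W.values[np.ix_(i1, i2)]
    W21 = W.values[np.ix_(i2, i1)]
    W22 = W.values[np.ix_(i2, i2)]
    return W11, W12, W21, W22
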