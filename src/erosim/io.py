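"""Readers and writers for the formats the toolkit touches.

Supported: VCF (v4.x, GT field) via cyvcf2, plain dosage TSV, pedigree CSV
(``id,sire,dam[,sex,generation]`` with ``0`` for an unknown parent),
phenotype CSV (``id,value``), partition CSV (``id,role``), relationship
matrix TSV, and a variant map TSV carrying genetic positions in cM.

All readers validate and reject rather than impute: the downstream
equations assume complete relationship matrices and phenotypes, and silent
imputation would change G.  Every writer/reader pair round-trips
losslessly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .relmat import PopulationPartition, RelationshipMatrix
from .simulate import GenotypeMatrix, PedigreeRecord

__all__ = [
    "DatasetBundle",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_partition",
    "write_partition",
    "read_relmat",
    "write_relmat",
]

_UNKNOWN = {"", "0", "NA", "na", ".", "none", "None"}


@dataclass
class DatasetBundle:
    """A validated analysis-ready dataset."""

    phenotypes: dict[str, float]
    split: PopulationPartition
    genotypes: GenotypeMatrix | None = None
    pedigree: list[PedigreeRecord] | None = None

    def __post_init__(self) -> None:
        if self.genotypes is None and self.pedigree is None:
            raise ValueError("need genotypes and/or a pedigree")
        known: set[str] = set()
        if self.genotypes is not None:
            known |= set(self.genotypes.sample_ids)
        if self.pedigree is not None:
            known |= {r.id for r in self.pedigree}
        missing = [s for s in self.split.target_ids if s not in known]
        if missing:
            raise ValueError(f"target ids without data: {missing[:5]}")
        ref = set(self.split.reference_ids)
        stray = [s for s in self.phenotypes if s not in ref]
        if stray:
            raise ValueError(
                f"phenotyped ids outside the reference population: {stray[:5]}"
            )


# ---------------------------------------------------------------- genotypes

def _read_map(map_path) -> dict[str, float]:
    df = pd.read_csv(map_path, sep="\t", dtype={"variant_id": str})
    if not {"variant_id", "pos_cM"} <= set(df.columns):
        raise ValueError("map file needs columns variant_id and pos_cM")
    return dict(zip(df["variant_id"], df["pos_cM"].astype(float)))


def read_genotypes(
    path, format: str = "vcf", map_path=None
) -> GenotypeMatrix:
    """Read genotypes from VCF or dosage TSV into a :class:`GenotypeMatrix`.

    Dosages count ALT alleles.  Multiallelic records and missing calls are
    rejected (the method requires complete data).  Map positions in cM come
    from ``map_path`` when given; otherwise VCF bp positions are converted
    at 1 cM per Mb and dosage TSVs get a uniform 1 cM spacing.
    """
    if format == "vcf":
        return _read_vcf(path, map_path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path, map_path=None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids, chroms, pos_bp, rows, hap_rows = [], [], [], [], []
    chrom_index: dict[str, int] = {}
    phased_all = True
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS} "
                f"({v.ID or 'unnamed'}); only biallelic variants are supported"
            )
        gts = v.genotypes  # [allele0, allele1, phased] per sample
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=int)
        if (alleles < 0).any():
            raise ValueError(
                f"missing genotype call at {v.CHROM}:{v.POS}; the method "
                "requires complete data"
            )
        phased_all = phased_all and all(bool(g[2]) for g in gts)
        variant_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chrom_index.setdefault(v.CHROM, len(chrom_index) + 1)
        chroms.append(chrom_index[v.CHROM])
        pos_bp.append(v.POS)
        rows.append(alleles.sum(axis=1))
        hap_rows.append(alleles)
    if not variant_ids:
        raise ValueError(f"no variants found in {path}")
    dosages = np.array(rows).T
    haplotypes = None
    if phased_all:
        haplotypes = np.transpose(np.array(hap_rows), (1, 2, 0)).astype(np.int8)
    if map_path is not None:
        cm = _read_map(map_path)
        pos_cM = np.array([cm[v] for v in variant_ids])
    else:
        pos_cM = np.asarray(pos_bp, dtype=float) / 1e6
    return GenotypeMatrix(
        sample_ids=samples,
        variant_ids=variant_ids,
        chrom=np.asarray(chroms),
        pos_cM=pos_cM,
        dosages=dosages,
        haplotypes=haplotypes,
    )


def _read_dosage_tsv(path, map_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValueError("dosage TSV must start with a sample_id column")
    if df.isna().any().any():
        raise ValueError("missing dosage values; the method requires complete data")
    variant_ids = list(df.columns[1:])
    dosages = df[variant_ids].to_numpy(dtype=int)
    if map_path is not None:
        cm = _read_map(map_path)
        pos_cM = np.array([cm[v] for v in variant_ids])
        chrom = np.ones(len(variant_ids), dtype=int)
    else:
        pos_cM = np.arange(1.0, len(variant_ids) + 1.0)
        chrom = np.ones(len(variant_ids), dtype=int)
    return GenotypeMatrix(
        sample_ids=list(df["sample_id"]),
        variant_ids=variant_ids,
        chrom=chrom,
        pos_cM=pos_cM,
        dosages=dosages,
    )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, columns=geno.variant_ids)
    df.insert(0, "sample_id", geno.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_map(geno: GenotypeMatrix, path) -> None:
    pd.DataFrame(
        {"variant_id": geno.variant_ids, "chrom": geno.chrom, "pos_cM": geno.pos_cM}
    ).to_csv(path, sep="\t", index=False)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only; phased bars when haplotypes exist).

    Genetic positions are encoded as bp at 1 cM per Mb, bumped minimally to
    stay strictly increasing within a chromosome.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=erosim\n")
        for c in np.unique(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        last = {}
        for j, vid in enumerate(geno.variant_ids):
            c = int(geno.chrom[j])
            bp = int(round(geno.pos_cM[j] * 1e6)) + 1
            if bp <= last.get(c, 0):
                bp = last[c] + 1
            last[c] = bp
            if geno.haplotypes is not None:
                calls = [
                    f"{geno.haplotypes[i, 0, j]}|{geno.haplotypes[i, 1, j]}"
                    for i in range(geno.n)
                ]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1"}
                calls = [code[int(d)] for d in geno.dosages[:, j]]
            fh.write(
                f"{c}\t{bp}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ----------------------------------------------------------------- pedigree

def read_pedigree(path) -> list[PedigreeRecord]:
    """Read a pedigree CSV into topologically ordered records.

    Unknown parents are normalized to None; cycles raise an error listing
    the offending ids.  Missing sex/generation columns are inferred where
    possible (parental role for sex, ancestral depth for generation).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    need = {"id", "sire", "dam"}
    if not need <= set(df.columns):
        raise ValueError("pedigree CSV needs columns id,sire,dam")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate pedigree ids: {dup[:5]}")

    def norm(v: str) -> str | None:
        return None if v.strip() in _UNKNOWN else v.strip()

    ids = list(df["id"])
    sires = [norm(v) for v in df["sire"]]
    dams = [norm(v) for v in df["dam"]]
    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    known = set(ids)
    for child, s, d in zip(ids, sires, dams):
        for parent in (s, d):
            if parent is not None and parent in known:
                graph.add_edge(parent, child)
    try:
        # lexicographic tie-break makes the ordering deterministic
        order = list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        cycle = [e[0] for e in nx.find_cycle(graph)]
        raise ValueError(f"pedigree contains a cycle: {cycle}") from None

    row = {i: k for k, i in enumerate(ids)}
    sex_col = "sex" in df.columns
    gen_col = "generation" in df.columns
    as_sire = set(s for s in sires if s is not None)
    as_dam = set(d for d in dams if d is not None)
    depth: dict[str, int] = {}
    for s in order:
        ps = [p for p, _ in graph.in_edges(s)]
        depth[s] = 1 + max((depth[p] for p in ps), default=-1)
    records = []
    for s in order:
        k = row[s]
        if sex_col and df.at[k, "sex"].strip():
            sex = df.at[k, "sex"].strip().upper()[0]
        elif s in as_sire:
            sex = "M"
        elif s in as_dam:
            sex = "F"
        else:
            sex = None
        gen = int(df.at[k, "generation"]) if gen_col and df.at[k, "generation"].strip() else depth[s]
        records.append(
            PedigreeRecord(id=s, sire=sires[k], dam=dams[k], sex=sex, generation=gen)
        )
    return records


def write_pedigree(records: list[PedigreeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sire", "dam", "sex", "generation"])
        for r in records:
            w.writerow(
                [r.id, r.sire or "0", r.dam or "0", r.sex or "0", r.generation]
            )


# --------------------------------------------------------------- phenotypes

def read_phenotypes(path) -> dict[str, float]:
    """Read an ``id,value`` CSV; duplicates and non-numeric values are errors."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("phenotype CSV needs columns id,value")
    id_col, val_col = df.columns[0], df.columns[1]
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate phenotype ids: {dup[:5]}")
    values = pd.to_numeric(df[val_col], errors="coerce")
    bad = df.index[values.isna()]
    if len(bad):
        k = int(bad[0])
        raise ValueError(
            f"non-numeric phenotype for id {df.at[k, id_col]!r} (row {k + 2})"
        )
    return dict(zip(df[id_col], values.astype(float)))


def write_phenotypes(values: dict[str, float], path) -> None:
    pd.DataFrame({"id": list(values), "value": list(values.values())}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------- partition

def read_partition(path) -> PopulationPartition:
    df = pd.read_csv(path, dtype=str)
    if not {"id", "role"} <= set(df.columns):
        raise ValueError("partition CSV needs columns id,role")
    roles = set(df["role"])
    if not roles <= {"reference", "target"}:
        raise ValueError(f"unknown roles {sorted(roles - {'reference', 'target'})}")
    return PopulationPartition(
        reference_ids=list(df.loc[df["role"] == "reference", "id"]),
        target_ids=list(df.loc[df["role"] == "target", "id"]),
    )


def write_partition(split: PopulationPartition, path) -> None:
    rows = [(s, "reference") for s in split.reference_ids] + [
        (s, "target") for s in split.target_ids
    ]
    pd.DataFrame(rows, columns=["id", "role"]).to_csv(path, index=False)


# ---------------------------------------------------- relationship matrices

def write_relmat(W: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(W.values, index=W.ids, columns=W.ids)
    df.index.name = W.kind
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_relmat(path, kind: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("relationship TSV must have matching id row/column")
    k = kind or (df.index.name if df.index.name in ("A", "G", "H") else "G")
    return RelationshipMatrix(kind=k, ids=[str(s) for s in df.index],
                              values=df.to_numpy(dtype=float))
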