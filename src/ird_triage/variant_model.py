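"""Domain types and I/O for variants, pedigrees, target designs and fixture tables.

Coordinates are 1-based inclusive throughout the package (VCF convention);
BED input is 0-based half-open and converted on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree


class Karyotype(str, Enum):
    XX = "XX"
    XY = "XY"
    XXY = "XXY"

    @property
    def x_copies(self) -> int:
        return {"XX": 2, "XY": 1, "XXY": 2}[self.value]


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEM_ALT = "hem_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEM_ALT)


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    SPLICE_CANONICAL = "splice_canonical"
    INTRONIC = "intronic"
    UTR = "UTR"
    OTHER = "other"


#: consequence categories that count as coding/splicing for the cascade
CODING_CONSEQUENCES = {
    Consequence.MISSENSE,
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.INFRAME_INDEL,
    Consequence.SPLICE_CANONICAL,
    Consequence.SYNONYMOUS,
}


class PedigreeError(ValueError):
    """Structural or referential problem in a pedigree."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


class AmbiguousJoinError(ValueError):
    """More than one annotation row shares a variant join key."""


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex_karyotype: Karyotype = Karyotype.XX
    affected: Affection = Affection.UNKNOWN


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError(f"duplicate individual ids in family {self.family_id}")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise PedigreeError(f"{m.id}: unknown parent id {pid!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {m.id: [p for p in (m.father_id, m.mother_id) if p] for m in self.members}
        state: dict[str, int] = {}

        def visit(i: str) -> None:
            if state.get(i) == 1:
                raise PedigreeError(f"ancestry cycle involving {i!r}")
            if state.get(i) == 2:
                return
            state[i] = 1
            for p in parent[i]:
                visit(p)
            state[i] = 2

        for m in self.members:
            visit(m.id)

    def __getitem__(self, ind_id: str) -> Individual:
        for m in self.members:
            if m.id == ind_id:
                return m
        raise KeyError(ind_id)

    def __contains__(self, ind_id: str) -> bool:
        return any(m.id == ind_id for m in self.members)

    @property
    def affected_members(self) -> list[Individual]:
        return [m for m in self.members if m.affected is Affection.AFFECTED]

    @property
    def index(self) -> Individual:
        """First affected member, by file order — the index patient."""
        aff = self.affected_members
        if not aff:
            raise PedigreeError(f"family {self.family_id} has no affected member")
        return aff[0]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.OTHER
    splice_distance_bp: int = 0
    exon_boundary_offset: int | None = None
    maf_by_db: dict[str, float] = field(default_factory=dict)
    gnomad_het: int = 0
    gnomad_hem: int = 0
    gnomad_hom: int = 0
    acmg_codes: frozenset[str] = frozenset()
    acmg_class: int | None = None
    reported_pathogenic: bool = False
    depth: int = 0
    fs_phred: float = 0.0
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for db, maf in self.maf_by_db.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF for {db} out of [0,1]: {maf}")
        if self.depth < 0:
            raise ValueError("negative depth")
        for c in (self.gnomad_het, self.gnomad_hem, self.gnomad_hom):
            if c < 0:
                raise ValueError("negative GnomAD genotype count")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def effective_maf(self) -> float:
        """Max MAF across population databases; absent everywhere means 0."""
        return max(self.maf_by_db.values(), default=0.0)

    @property
    def is_x(self) -> bool:
        return self.chrom.removeprefix("chr") == "X"

    def genotype_of(self, ind_id: str) -> Genotype:
        return self.genotypes.get(ind_id, Genotype.MISSING)


@dataclass
class TargetDesign:
    name: str
    primary_regions: list[GenomicInterval] = field(default_factory=list)
    captured_regions: list[GenomicInterval] = field(default_factory=list)
    gene_set: frozenset[str] = frozenset()
    covered_gene_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.covered_gene_set <= self.gene_set:
            raise ValueError("covered_gene_set must be a subset of gene_set")


@dataclass(frozen=True)
class FixtureRecord:
    family_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    status: str  # Het / Hom / Hem
    acmg_class: int | None
    segregation: str  # e.g. "Yes(2/5)" or "No"
    solved: bool
    reference: str


# ---------------------------------------------------------------------------
# PED I/O


_SEX_TO_KARYO = {"1": Karyotype.XY, "2": Karyotype.XX}
_PHENO = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK six-column PED file (optional 7th karyotype column).

    The karyotype column accepts XX / XY / XXY; when absent, sex code 1
    maps to XY and 2 to XX.
    """
    members: list[Individual] = []
    family_id: str | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 6:
            raise PedigreeError(f"PED line has {len(f)} columns, need >= 6: {line!r}")
        fam, iid, fid, mid, sex, pheno = f[:6]
        if iid in (fid, mid):
            raise PedigreeError(f"{iid} listed as its own parent")
        karyo = Karyotype(f[6]) if len(f) > 6 else _SEX_TO_KARYO.get(sex, Karyotype.XX)
        members.append(
            Individual(
                id=iid,
                family_id=fam,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex_karyotype=karyo,
                affected=_PHENO.get(pheno, Affection.UNKNOWN),
            )
        )
        family_id = family_id or fam
    if family_id is None:
        raise PedigreeError(f"empty PED file: {path}")
    return Pedigree(family_id=family_id, members=members)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    rows = []
    for m in ped.members:
        sex = "1" if m.sex_karyotype in (Karyotype.XY, Karyotype.XXY) else "2"
        pheno = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2"}.get(m.affected, "0")
        rows.append(
            "\t".join(
                [m.family_id, m.id, m.father_id or "0", m.mother_id or "0", sex, pheno,
                 m.sex_karyotype.value]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(GenomicInterval(f[0], int(f[1]) + 1, int(f[2])))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    lines = [f"{iv.chrom}\t{iv.start - 1}\t{iv.end}" for iv in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Variant table I/O

_ANNOT_COLUMNS = {"chrom", "pos", "ref", "alt", "gene"}

_MAF_DBS = ("GnomAD", "EVS", "1000GP", "CSVS")


def _parse_annotation_row(row: Mapping) -> dict:
    maf = {}
    for db in _MAF_DBS:
        col = f"maf_{db}"
        v = row.get(col)
        if v is not None and v == v and str(v) != "":
            maf[db] = float(v)
    codes_raw = row.get("acmg_codes", "")
    codes = "" if codes_raw is None or codes_raw != codes_raw else str(codes_raw)
    ebo = row.get("exon_boundary_offset")
    ebo = None if ebo is None or ebo != ebo or str(ebo) == "" else int(ebo)
    return dict(
        gene=str(row.get("gene", "")),
        transcript=str(row.get("transcript", "") or ""),
        hgvs_c=str(row.get("hgvs_c", "") or ""),
        hgvs_p=str(row.get("hgvs_p", "") or ""),
        consequence=Consequence(str(row.get("consequence", "other"))),
        splice_distance_bp=int(row.get("splice_distance_bp", 0) or 0),
        exon_boundary_offset=ebo,
        maf_by_db=maf,
        gnomad_het=int(row.get("gnomad_het", 0) or 0),
        gnomad_hem=int(row.get("gnomad_hem", 0) or 0),
        gnomad_hom=int(row.get("gnomad_hom", 0) or 0),
        acmg_codes=frozenset(c for c in codes.split(",") if c),
        acmg_class=None
        if row.get("acmg_class") in (None, "") or row.get("acmg_class") != row.get("acmg_class")
        else int(row["acmg_class"]),
        reported_pathogenic=str(row.get("reported_pathogenic", "0")).lower()
        in ("1", "true", "yes"),
        depth=int(row.get("depth", 0) or 0),
        fs_phred=float(row.get("fs_phred", 0.0) or 0.0),
    )


def read_variant_table(
    vcf_path: str | Path, annotation_path: str | Path
) -> tuple[list[AnnotatedVariant], list[tuple[str, int, str, str]]]:
    """Join a VCF with its sidecar annotation TSV into AnnotatedVariants.

    Returns (variants, unmatched_keys). Genotypes are taken from the VCF
    sample columns; haploid calls become hem_alt. A duplicated annotation
    join key raises :class:`AmbiguousJoinError`.
    """
    import pysam

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    ann["pos"] = ann["pos"].astype(int)
    keys = list(zip(ann["chrom"], ann["pos"], ann["ref"], ann["alt"]))
    if len(set(keys)) != len(keys):
        dup = pd.Series(keys).value_counts()
        raise AmbiguousJoinError(f"duplicate annotation keys: {dup[dup > 1].index.tolist()}")
    by_key = {k: _parse_annotation_row(row) for k, (_, row) in zip(keys, ann.iterrows())}

    variants: list[AnnotatedVariant] = []
    unmatched: list[tuple[str, int, str, str]] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for alt in rec.alts or ():
                key = (rec.chrom, rec.pos, rec.ref, alt)
                fields = by_key.get(key)
                if fields is None:
                    unmatched.append(key)
                    continue
                gts: dict[str, Genotype] = {}
                for s in samples:
                    alleles = rec.samples[s]["GT"]
                    if alleles is None or all(a is None for a in alleles):
                        gts[s] = Genotype.MISSING
                        continue
                    calls = [a for a in alleles if a is not None]
                    n_alt = sum(1 for a in calls if a >= 1)
                    if len(calls) == 1:
                        gts[s] = Genotype.HEM_ALT if n_alt else Genotype.HOM_REF
                    elif n_alt == 0:
                        gts[s] = Genotype.HOM_REF
                    elif n_alt == len(calls):
                        gts[s] = Genotype.HOM_ALT
                    else:
                        gts[s] = Genotype.HET
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        genotypes=gts, **fields,
                    )
                )
    return variants, unmatched


# ---------------------------------------------------------------------------
# Design intersection


def build_interval_tree(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, iv)
    return trees


def intersect_with_design(
    variants: Iterable[AnnotatedVariant],
    design: TargetDesign,
    use: str = "primary",
) -> list[AnnotatedVariant]:
    """Keep variants whose position falls inside the selected region set.

    ``use='primary'`` retains variants in regions intended by the design
    even when no capture probe exists there; ``use='captured'`` restricts
    to probe-covered regions.
    """
    if use not in ("primary", "captured"):
        raise ValueError(f"use must be 'primary' or 'captured', got {use!r}")
    regions = design.primary_regions if use == "primary" else design.captured_regions
    trees = build_interval_tree(regions)
    kept = []
    for v in variants:
        t = trees.get(v.chrom)
        if t is not None and t.overlaps_point(v.pos):
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# Packaged fixtures (hand-transcribed published cohort tables)


def _data_path(name: str):
    return resources.files("ird_triage.data").joinpath(name)


def _verify_checksum(name: str, raw: bytes) -> None:
    sums = json.loads(_data_path("checksums.json").read_text())
    digest = hashlib.sha256(raw).hexdigest()
    if sums.get(name) != digest:
        raise FixtureIntegrityError(f"fixture {name} checksum mismatch: {digest}")


def load_fixtures(which: str) -> list[FixtureRecord]:
    """Load a packaged cohort fixture table: 'table1', 'table2' or 'table3'."""
    if which not in ("table1", "table2", "table3"):
        raise ValueError(f"unknown fixture table {which!r}")
    name = f"{which}.tsv"
    raw = _data_path(name).read_bytes()
    _verify_checksum(name, raw)
    df = pd.read_csv(_data_path(name), sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            FixtureRecord(
                family_id=r["family_id"],
                gene=r["gene"],
                hgvs_c=r["hgvs_c"],
                hgvs_p=r["hgvs_p"],
                status=r["status"],
                acmg_class=int(r["acmg_class"]) if r["acmg_class"].isdigit() else None,
                segregation=r["segregation"],
                solved=r["solved"] == "Yes",
                reference=r["reference"],
            )
        )
    return out


def load_cohort_counts() -> dict[str, int]:
    """Study-design counts of the published cohort (families, patients, relatives)."""
    raw = _data_path("cohort.tsv").read_bytes()
    _verify_checksum("cohort.tsv", raw)
    df = pd.read_csv(_data_path("cohort.tsv"), sep="\t")
    return {str(k): int(v) for k, v in zip(df["key"], df["value"])}


def load_retnet_genes() -> frozenset[str]:
    """Packaged snapshot of retinal-disease-associated gene symbols."""
    text = _data_path("retnet_snapshot.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
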