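"""Seeded generators for every input the pipeline consumes.

Families are simulated with a planted causal genotype under a chosen
inheritance mode plus a background of annotated variants whose statistical
structure emulates germline short-variant callsets: a point mass of
never-observed (database-absent) alleles mixed with Beta-distributed
population frequencies, categorical consequence classes, negative-binomial
depths, exponential strand-bias scores and Poisson control-population
genotype counts scaled by frequency. Background genotypes are assigned by
Mendelian gene-dropping from founder alleles, so transmission is always
legal. The planted genotype segregates perfectly by construction and its
annotations are drawn from the passing region of the filter space.

A single integer seed drives named RNG streams per output kind, so adding a
generator does not perturb existing outputs; identical seeds reproduce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .variant_model import (
    Affection,
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenomicInterval,
    Individual,
    Karyotype,
    Pedigree,
    write_pedigree,
)
from .qc_cnv import CoverageProfile, CoverageTarget
from .str_linkage import StrGenotypeTable, StrMarker, load_marker_map

SCENARIOS = ("AR_hom", "AR_comphet", "AD", "XLR", "XLR_with_XXY")

# background-variant model defaults
BG_NOVEL_WEIGHT = 0.6  # point mass of database-absent alleles
BG_MAF_BETA = (0.5, 30.0)
BG_DEPTH_NB = (10.0, 100.0)  # (dispersion n, mean)
BG_FS_MEAN = 5.0
BG_IRD_GENE_FRACTION = 0.015  # ~250 retinal genes over an ~18,000-gene exome
GNOMAD_ALLELES = 250_000  # diploid control alleles behind the count model

_CONSEQ_WEIGHTS = {
    Consequence.MISSENSE: 0.45,
    Consequence.SYNONYMOUS: 0.15,
    Consequence.INTRONIC: 0.15,
    Consequence.UTR: 0.08,
    Consequence.OTHER: 0.05,
    Consequence.INFRAME_INDEL: 0.03,
    Consequence.NONSENSE: 0.02,
    Consequence.FRAMESHIFT: 0.02,
    Consequence.SPLICE_CANONICAL: 0.05,
}

_ACMG_CODE_SETS = [
    (frozenset(), 0.35),
    (frozenset({"BP4"}), 0.25),
    (frozenset({"BP4", "BP7"}), 0.15),
    (frozenset({"BS1", "BP4"}), 0.10),
    (frozenset({"PM2"}), 0.10),
    (frozenset({"PP3"}), 0.05),
]

_AUTOSOMAL_IRD = [
    "ABCA4", "USH2A", "EYS", "PDE6B", "PDE6A", "CRB1", "CEP290", "PROM1",
    "BBS10", "MFRP", "FAM161A", "RP1L1", "RP1", "RHO", "RPE65", "GUCY2D",
    "PRPH2", "WHRN",
]
_X_IRD = ["RPGR", "RP2", "CHM", "CACNA1F", "NYX", "NDP", "PGK1", "TIMM8A", "PRPS1"]


@dataclass
class SimulationManifest:
    seed: int
    scenario: str
    family_id: str
    planted_gene: str
    planted_keys: list[list]  # variant join keys
    n_background: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class FamilySim:
    pedigree: Pedigree
    variants: list[AnnotatedVariant]
    manifest: SimulationManifest

    @property
    def planted(self) -> list[AnnotatedVariant]:
        keys = {tuple(k) for k in self.manifest.planted_keys}
        return [v for v in self.variants if v.key in keys]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# Pedigree structures


def _family_structure(scenario: str, fam: str) -> Pedigree:
    F, M = f"{fam}_F", f"{fam}_M"
    XY, XX, XXY = Karyotype.XY, Karyotype.XX, Karyotype.XXY
    AFF, UN = Affection.AFFECTED, Affection.UNAFFECTED

    def child(cid, karyo, aff):
        return Individual(cid, fam, F, M, karyo, aff)

    if scenario in ("AR_hom", "AR_comphet"):
        members = [
            Individual(F, fam, None, None, XY, UN),
            Individual(M, fam, None, None, XX, UN),
            child(f"{fam}_C1", XY, AFF),
            child(f"{fam}_C2", XX, AFF),
            child(f"{fam}_C3", XY, UN),
            child(f"{fam}_C4", XX, UN),
        ]
    elif scenario == "AD":
        members = [
            Individual(F, fam, None, None, XY, UN),
            Individual(M, fam, None, None, XX, AFF),
            child(f"{fam}_C1", XY, AFF),
            child(f"{fam}_C2", XX, AFF),
            child(f"{fam}_C3", XY, UN),
            child(f"{fam}_C4", XX, UN),
        ]
    elif scenario == "XLR":
        members = [
            Individual(F, fam, None, None, XY, UN),
            Individual(M, fam, None, None, XX, UN),
            child(f"{fam}_S1", XY, AFF),
            child(f"{fam}_S2", XY, AFF),
            child(f"{fam}_D1", XX, UN),
            child(f"{fam}_S3", XY, UN),
        ]
    elif scenario == "XLR_with_XXY":
        members = [
            Individual(F, fam, None, None, XY, UN),
            Individual(M, fam, None, None, XX, UN),
            child(f"{fam}_S1", XY, AFF),
            child(f"{fam}_S2", XXY, AFF),
            child(f"{fam}_D1", XX, UN),
        ]
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    # children first so the index patient (first affected) is a sequenced child
    members.sort(key=lambda m: m.father_id is None)
    return Pedigree(family_id=fam, members=members)


# ---------------------------------------------------------------------------
# Gene dropping


def _drop_autosomal(rng, ped: Pedigree, founder_alleles: dict[str, tuple[int, int]]
                    ) -> dict[str, tuple[int, int]]:
    out = dict(founder_alleles)
    for m in ped.members:
        if m.id in out:
            continue
        pa = out[m.father_id][rng.integers(0, 2)]
        ma = out[m.mother_id][rng.integers(0, 2)]
        out[m.id] = (pa, ma)
    return out


def _drop_x(rng, ped: Pedigree, father_allele: int, mother_alleles: tuple[int, int]
            ) -> dict[str, tuple[int, ...]]:
    out: dict[str, tuple[int, ...]] = {}
    for m in ped.members:
        if m.father_id is None:
            out[m.id] = (
                (father_allele,) if m.sex_karyotype is Karyotype.XY else mother_alleles
            )
    for m in ped.members:
        if m.father_id is None:
            continue
        ma = mother_alleles[rng.integers(0, 2)]
        if m.sex_karyotype is Karyotype.XY:
            out[m.id] = (ma,)
        elif m.sex_karyotype is Karyotype.XX:
            out[m.id] = (father_allele, ma)
        else:  # XXY via maternal heterodisomy: both maternal alleles
            out[m.id] = mother_alleles
    return out


def _alleles_to_genotype(alleles: tuple[int, ...]) -> Genotype:
    n_alt = sum(alleles)
    if len(alleles) == 1:
        return Genotype.HEM_ALT if n_alt else Genotype.HOM_REF
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


# ---------------------------------------------------------------------------
# Background variants


def _draw_background(
    rng: np.random.Generator, ped: Pedigree, n: int, fam: str
) -> list[AnnotatedVariant]:
    conseqs = list(_CONSEQ_WEIGHTS)
    cw = np.array(list(_CONSEQ_WEIGHTS.values()))
    cw = cw / cw.sum()
    acmg_sets = [s for s, _ in _ACMG_CODE_SETS]
    aw = np.array([w for _, w in _ACMG_CODE_SETS])
    aw = aw / aw.sum()

    variants: list[AnnotatedVariant] = []
    used_pos: set[tuple[str, int]] = set()
    bases = np.array(list("ACGT"))
    for i in range(n):
        on_x = rng.random() < 0.06
        chrom = "X" if on_x else str(rng.integers(1, 23))
        while True:
            pos = int(rng.integers(1_000_000, 150_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                break
        if rng.random() < BG_IRD_GENE_FRACTION:
            gene = rng.choice(_X_IRD) if on_x else rng.choice(_AUTOSOMAL_IRD)
        else:
            gene = f"GENE{rng.integers(0, 4000):04d}"
        maf = 0.0 if rng.random() < BG_NOVEL_WEIGHT else float(
            rng.beta(*BG_MAF_BETA)
        )
        maf_by_db = {}
        if maf > 0:
            maf_by_db["GnomAD"] = maf
            for db in ("EVS", "1000GP", "CSVS"):
                if rng.random() < 0.5:
                    maf_by_db[db] = float(min(1.0, maf * rng.uniform(0.7, 1.0)))
        cons = conseqs[int(rng.choice(len(conseqs), p=cw))]
        splice_dist = 0
        ebo = None
        if cons in (Consequence.INTRONIC, Consequence.UTR, Consequence.OTHER):
            splice_dist = int(np.ceil(rng.lognormal(4.0, 1.5)))
        elif cons is Consequence.SYNONYMOUS and rng.random() < 0.05:
            ebo = int(rng.integers(1, 3))
        depth = int(rng.negative_binomial(BG_DEPTH_NB[0],
                                          BG_DEPTH_NB[0] / (BG_DEPTH_NB[0] + BG_DEPTH_NB[1])))
        fs = float(rng.exponential(BG_FS_MEAN))
        het = int(rng.poisson(GNOMAD_ALLELES * maf))
        hom = int(rng.poisson(GNOMAD_ALLELES / 2 * maf * maf))
        hem = int(rng.poisson(GNOMAD_ALLELES / 3 * maf)) if on_x else 0
        codes = acmg_sets[int(rng.choice(len(acmg_sets), p=aw))]

        # founder alleles: rejection-sample until someone carries the allele
        q = max(maf, 0.03)
        if on_x:
            while True:
                fa = int(rng.random() < q)
                ma = (int(rng.random() < q), int(rng.random() < q))
                if fa or any(ma):
                    break
            alleles = _drop_x(rng, ped, fa, ma)
        else:
            while True:
                f = (int(rng.random() < q), int(rng.random() < q))
                m = (int(rng.random() < q), int(rng.random() < q))
                if any(f) or any(m):
                    break
            founders = {
                p.id: (f if p.sex_karyotype is Karyotype.XY else m)
                for p in ped.members if p.father_id is None
            }
            alleles = _drop_autosomal(rng, ped, founders)
        gts = {ind: _alleles_to_genotype(a) for ind, a in alleles.items()}
        if not any(g.carries_alt for g in gts.values()):
            continue  # allele lost in transmission: not called in this family
        ref, alt = rng.choice(bases, size=2, replace=False)
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=str(ref), alt=str(alt), gene=str(gene),
                transcript=f"NM_{rng.integers(1, 10**6):06d}",
                hgvs_c=f"c.{rng.integers(1, 9000)}{ref}>{alt}",
                hgvs_p="p.?",
                consequence=cons, splice_distance_bp=splice_dist,
                exon_boundary_offset=ebo, maf_by_db=maf_by_db,
                gnomad_het=het, gnomad_hem=hem, gnomad_hom=hom,
                acmg_codes=codes, reported_pathogenic=False,
                depth=depth, fs_phred=round(fs, 2), genotypes=gts,
            )
        )
    return variants


# ---------------------------------------------------------------------------
# Planted causal genotypes


def _planted_variants(
    rng: np.random.Generator, scenario: str, ped: Pedigree
) -> tuple[str, list[AnnotatedVariant]]:
    fam = ped.family_id
    ids = {m.id: m for m in ped.members}
    F, M = f"{fam}_F", f"{fam}_M"

    def base_variant(chrom, pos, gene, gts, consequence=Consequence.FRAMESHIFT):
        return AnnotatedVariant(
            chrom=chrom, pos=pos, ref="G", alt="T", gene=gene,
            transcript="NM_000001", hgvs_c=f"c.{pos % 5000 + 1}G>T", hgvs_p="p.?",
            consequence=consequence, splice_distance_bp=0,
            maf_by_db={}, gnomad_het=0, gnomad_hem=0, gnomad_hom=0,
            acmg_codes=frozenset({"PVS1", "PS3"}), reported_pathogenic=bool(rng.random() < 0.5),
            depth=int(rng.integers(60, 180)), fs_phred=round(float(rng.exponential(2.0)), 2),
            genotypes=gts,
        )

    if scenario == "AR_hom":
        gene = str(rng.choice(_AUTOSOMAL_IRD))
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1_000_000, 150_000_000))
        gts = {F: Genotype.HET, M: Genotype.HET}
        for c in ids:
            if c in (F, M):
                continue
            aff = ids[c].affected is Affection.AFFECTED
            gts[c] = Genotype.HOM_ALT if aff else (
                Genotype.HET if rng.random() < 0.67 else Genotype.HOM_REF
            )
        return gene, [base_variant(chrom, pos, gene, gts)]

    if scenario == "AR_comphet":
        gene = str(rng.choice(_AUTOSOMAL_IRD))
        chrom = str(rng.integers(1, 23))
        p1 = int(rng.integers(1_000_000, 75_000_000))
        p2 = int(rng.integers(75_000_001, 150_000_000))
        gts1 = {F: Genotype.HET, M: Genotype.HOM_REF}
        gts2 = {F: Genotype.HOM_REF, M: Genotype.HET}
        for c in ids:
            if c in (F, M):
                continue
            if ids[c].affected is Affection.AFFECTED:
                gts1[c] = gts2[c] = Genotype.HET
            else:
                which = rng.integers(0, 3)  # one of the two, or neither
                gts1[c] = Genotype.HET if which == 0 else Genotype.HOM_REF
                gts2[c] = Genotype.HET if which == 1 else Genotype.HOM_REF
        v1 = base_variant(chrom, p1, gene, gts1, Consequence.NONSENSE)
        v2 = base_variant(chrom, p2, gene, gts2, Consequence.MISSENSE)
        return gene, [v1, v2]

    if scenario == "AD":
        gene = str(rng.choice(_AUTOSOMAL_IRD))
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1_000_000, 150_000_000))
        gts = {}
        for i, ind in ids.items():
            gts[i] = Genotype.HET if ind.affected is Affection.AFFECTED else Genotype.HOM_REF
        return gene, [base_variant(chrom, pos, gene, gts, Consequence.MISSENSE)]

    # X-linked recessive scenarios
    gene = str(rng.choice(_X_IRD))
    pos = int(rng.integers(1_000_000, 150_000_000))
    gts = {F: Genotype.HOM_REF, M: Genotype.HET}
    for c, ind in ids.items():
        if c in (F, M):
            continue
        if ind.affected is Affection.AFFECTED:
            gts[c] = (
                Genotype.HEM_ALT if ind.sex_karyotype is Karyotype.XY else Genotype.HOM_ALT
            )
        else:
            gts[c] = (
                Genotype.HET if ind.sex_karyotype in (Karyotype.XX, Karyotype.XXY)
                and rng.random() < 0.5
                else Genotype.HOM_REF
            )
    return gene, [base_variant("X", pos, gene, gts)]


def simulate_family(
    scenario: str,
    n_background: int = 150,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> FamilySim:
    """Simulate one family with a planted causal genotype.

    When ``out_dir`` is given, writes ``family.vcf``, ``annotations.tsv``,
    ``family.ped`` and ``manifest.json`` there.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    fam = f"SIM{seed % (2**31):d}"
    ped = _family_structure(scenario, fam)
    rng_bg = _rng(seed, 1)
    rng_pl = _rng(seed, 2)
    gene, planted = _planted_variants(rng_pl, scenario, ped)
    background = _draw_background(rng_bg, ped, n_background, fam)
    # planted positions must not collide with background
    bg_keys = {(v.chrom, v.pos) for v in background}
    for v in planted:
        while (v.chrom, v.pos) in bg_keys:
            v.pos += 1
    variants = sorted(planted + background, key=lambda v: (v.chrom, v.pos))
    manifest = SimulationManifest(
        seed=seed, scenario=scenario, family_id=fam, planted_gene=gene,
        planted_keys=[list(v.key) for v in planted], n_background=n_background,
        params={
            "novel_weight": BG_NOVEL_WEIGHT, "maf_beta": BG_MAF_BETA,
            "depth_negbin": BG_DEPTH_NB, "fs_mean": BG_FS_MEAN,
            "ird_gene_fraction": BG_IRD_GENE_FRACTION,
        },
    )
    sim = FamilySim(pedigree=ped, variants=variants, manifest=manifest)
    if out_dir is not None:
        write_family(sim, out_dir)
    return sim


# ---------------------------------------------------------------------------
# File output


_GT_TO_VCF = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
    Genotype.HEM_ALT: "1",
}


def write_family(sim: FamilySim, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = [m.id for m in sim.pedigree.members]
    chroms = sorted({v.chrom for v in sim.variants}, key=lambda c: (len(c), c))
    vcf_lines = ["##fileformat=VCFv4.2"]
    vcf_lines += [f"##contig=<ID={c},length=250000000>" for c in chroms]
    vcf_lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    vcf_lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ann_cols = [
        "chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c", "hgvs_p",
        "consequence", "splice_distance_bp", "exon_boundary_offset",
        "maf_GnomAD", "maf_EVS", "maf_1000GP", "maf_CSVS",
        "gnomad_het", "gnomad_hem", "gnomad_hom",
        "acmg_codes", "acmg_class", "reported_pathogenic", "depth", "fs_phred",
    ]
    ann_lines = ["\t".join(ann_cols)]
    for v in sim.variants:
        gts = "\t".join(_GT_TO_VCF[v.genotype_of(s)] for s in samples)
        vcf_lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t100\tPASS\t.\tGT\t{gts}"
        )
        row = [
            v.chrom, str(v.pos), v.ref, v.alt, v.gene, v.transcript, v.hgvs_c,
            v.hgvs_p, v.consequence.value, str(v.splice_distance_bp),
            "" if v.exon_boundary_offset is None else str(v.exon_boundary_offset),
            *(
                f"{v.maf_by_db[db]:.8g}" if db in v.maf_by_db else ""
                for db in ("GnomAD", "EVS", "1000GP", "CSVS")
            ),
            str(v.gnomad_het), str(v.gnomad_hem), str(v.gnomad_hom),
            ",".join(sorted(v.acmg_codes)), "",
            "1" if v.reported_pathogenic else "0", str(v.depth), f"{v.fs_phred:g}",
        ]
        ann_lines.append("\t".join(row))
    paths = {
        "vcf": out / "family.vcf",
        "annotations": out / "annotations.tsv",
        "ped": out / "family.ped",
        "manifest": out / "manifest.json",
    }
    paths["vcf"].write_text("\n".join(vcf_lines) + "\n")
    paths["annotations"].write_text("\n".join(ann_lines) + "\n")
    write_pedigree(sim.pedigree, paths["ped"])
    paths["manifest"].write_text(sim.manifest.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# STR haplotypes and coverage profiles


@dataclass
class StrSim:
    table: StrGenotypeTable
    truth: dict[str, list[str]]  # child -> maternal haplotype label per marker
    manifest: dict


def _maternal_gamete(
    markers: Sequence[StrMarker], start: str, breaks: Sequence[int]
) -> list[str]:
    labels = []
    hap = start
    bi = 0
    breaks = sorted(breaks)
    for mk in markers:
        while bi < len(breaks) and mk.position > breaks[bi]:
            hap = "M2" if hap == "M1" else "M1"
            bi += 1
        labels.append(hap)
    return labels


def simulate_str_genotypes(
    pedigree: Pedigree,
    crossovers: Mapping[str, Sequence[Mapping]],
    seed: int = 0,
    markers: Sequence[StrMarker] | None = None,
    het_fraction: float = 1.0,
) -> StrSim:
    """Drop maternal STR haplotypes through a family with planted crossovers.

    ``crossovers`` maps each child id to a list of gamete specs
    ``{"start": "M1", "breaks": [pos, ...]}`` — one spec for the maternal
    gamete of an XY/XX child, two for a 47,XXY child carrying both maternal
    X's. Crossover positions must lie within the marker map span.
    """
    markers = list(markers or load_marker_map())
    span = (markers[0].position, markers[-1].position)
    for specs in crossovers.values():
        for spec in specs:
            for b in spec.get("breaks", ()):
                if not span[0] <= b <= span[1]:
                    raise ValueError(f"crossover {b} outside marker map span {span}")
    rng = _rng(seed, 11)
    mother_id = next(m.id for m in pedigree.members
                     if any(c.mother_id == m.id for c in pedigree.members))
    father_id = next(m.id for m in pedigree.members
                     if any(c.father_id == m.id for c in pedigree.members))
    m1, m2, pat = {}, {}, {}
    for mk in markers:
        a = int(rng.integers(1, 9))
        if rng.random() < het_fraction:
            b = int(rng.integers(1, 9))
            while b == a:
                b = int(rng.integers(1, 9))
        else:
            b = a
        m1[mk.name], m2[mk.name] = a, b
        pat[mk.name] = int(rng.integers(1, 9))

    alleles: dict[str, dict[str, tuple[int, ...]]] = {
        mother_id: {mk.name: (m1[mk.name], m2[mk.name]) for mk in markers},
        father_id: {mk.name: (pat[mk.name],) for mk in markers},
    }
    truth: dict[str, list[str]] = {}
    hap_allele = {"M1": m1, "M2": m2}
    for child_id, specs in crossovers.items():
        ind = pedigree[child_id]
        gametes = [_maternal_gamete(markers, s.get("start", "M1"), s.get("breaks", ()))
                   for s in specs]
        if ind.sex_karyotype is Karyotype.XY:
            truth[child_id] = gametes[0]
            alleles[child_id] = {
                mk.name: (hap_allele[g][mk.name],)
                for mk, g in zip(markers, gametes[0])
            }
        elif ind.sex_karyotype is Karyotype.XX:
            truth[child_id] = gametes[0]
            alleles[child_id] = {
                mk.name: (pat[mk.name], hap_allele[g][mk.name])
                for mk, g in zip(markers, gametes[0])
            }
        else:  # XXY with two maternal gametes
            if len(gametes) != 2:
                raise ValueError(f"XXY child {child_id} needs two gamete specs")
            truth[child_id] = [f"{a}+{b}" for a, b in zip(*gametes)]
            alleles[child_id] = {
                mk.name: tuple(sorted((hap_allele[a][mk.name], hap_allele[b][mk.name])))
                for mk, a, b in zip(markers, *gametes)
            }
    table = StrGenotypeTable(markers=markers, alleles=alleles)
    manifest = {"seed": seed, "crossovers": {k: [dict(s) for s in v]
                                             for k, v in crossovers.items()}}
    return StrSim(table=table, truth=truth, manifest=manifest)


def simulate_coverage_profile(
    gene: str,
    n_exons: int,
    cnv_exons: tuple[int, int] | None,
    copy_factor: float,
    seed: int = 0,
    base_depth: float = 200.0,
    noise_sd: float = 0.05,
    chrom: str = "4",
) -> CoverageProfile:
    """Per-exon coverage with an optional planted CNV.

    Exons inside ``cnv_exons`` (inclusive 1-based range) have their sample
    depth scaled by ``copy_factor`` (0.5 het deletion, 0.0 hom deletion,
    1.5 duplication) with additive Gaussian noise of sd ``noise_sd`` on the
    ratio scale, truncated at zero.
    """
    rng = _rng(seed, 21)
    targets = []
    start = 1_000_000
    for e in range(1, n_exons + 1):
        iv = GenomicInterval(chrom, start, start + 149)
        start += 5_000
        factor = 1.0
        if cnv_exons is not None and cnv_exons[0] <= e <= cnv_exons[1]:
            factor = copy_factor
        ratio = max(0.0, factor + rng.normal(0.0, noise_sd))
        targets.append(
            CoverageTarget(
                interval=iv, gene=gene, exon=str(e),
                sample_depth=base_depth * ratio,
                reference_depth=base_depth,
            )
        )
    return CoverageProfile(targets)
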