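"""X-chromosome microsatellite haplotype reconstruction and shared regions.

Given STR genotypes for a nuclear family, each child's maternally inherited
allele is identified (the single allele of an XY son; the non-paternal
allele of an XX daughter; both alleles of a 47,XXY son who inherited both
maternal homologs). Maternal haplotypes are then labelled M1/M2 by a
minimum-recombination phasing of the mother, solved by dynamic programming
over marker order. Maximal intervals where all affected individuals carry
the same maternal haplotype — on both X copies for the XXY dosage
hypothesis — and every excluder lacks it are reported as shared regions,
with bounds extended outward to the flanking discordant markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_model import Genotype, GenomicInterval, Karyotype, Pedigree

M1, M2 = "M1", "M2"
UNINFORMATIVE = "?"


@dataclass(frozen=True)
class StrMarker:
    name: str
    chrom: str
    position: int


@dataclass
class StrGenotypeTable:
    """Alleles per individual per marker; tuple length matches X-copy number."""

    markers: list[StrMarker]
    alleles: dict[str, dict[str, tuple[int, ...]]]  # ind -> marker -> alleles

    def __post_init__(self) -> None:
        pos = [m.position for m in self.markers]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("marker positions must be strictly increasing")

    def of(self, ind: str, marker: str) -> tuple[int, ...]:
        return self.alleles[ind][marker]


@dataclass(frozen=True)
class SharedRegion:
    interval: GenomicInterval
    haplotype: str
    carriers: frozenset[str]
    excluded: frozenset[str]
    bounding_markers: tuple[str, str]
    ambiguous: bool = False


def load_marker_map() -> list[StrMarker]:
    """Packaged 26-marker X-chromosome map (synthetic stand-in positions)."""
    path = resources.files("ird_triage.data").joinpath("str_markers_synthetic.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    return [StrMarker(r.name, str(r.chrom), int(r.position))
            for r in df.itertuples(index=False)]


def load_x_gene_map() -> dict[str, GenomicInterval]:
    """Packaged X-gene intervals (synthetic stand-in coordinates)."""
    path = resources.files("ird_triage.data").joinpath("x_genes_synthetic.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        r.gene: GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Haplotype assignment


def _maternal_alleles(
    table: StrGenotypeTable, ped: Pedigree, child_id: str, marker: str
) -> tuple[tuple[int, ...], bool]:
    """The child's maternally inherited allele(s) at a marker.

    Returns (alleles, ok). XY sons contribute their single allele; daughters
    contribute the non-paternal allele; XXY sons with two maternal X's
    contribute both. ok=False marks a Mendelian inconsistency.
    """
    child = ped[child_id]
    alleles = table.of(child_id, marker)
    if child.sex_karyotype is Karyotype.XY:
        return (alleles[0],), True
    father = child.father_id
    pat = table.of(father, marker)[0] if father and father in table.alleles else None
    if child.sex_karyotype is Karyotype.XX:
        a, b = alleles
        if pat is None:
            return (a,) if a == b else (), True  # phase unknown unless homozygous
        if a == pat:
            return (b,), True
        if b == pat:
            return (a,), True
        return (), False
    # XXY: decide paternal involvement globally in assign_haplotypes; here both
    return alleles, True


def _xxy_has_paternal_x(table: StrGenotypeTable, ped: Pedigree, child_id: str) -> bool:
    """An XXY child carries a paternal X only if the father's allele fits
    his genotype at every marker where the father is typed."""
    child = ped[child_id]
    if not child.father_id or child.father_id not in table.alleles:
        return False
    for m in table.markers:
        pat = table.of(child.father_id, m.name)[0]
        if pat not in table.of(child_id, m.name):
            return False
    return True


def assign_haplotypes(
    table: StrGenotypeTable, pedigree: Pedigree, mother_id: str | None = None
) -> dict[str, dict[str, str]]:
    """Label each child's maternal haplotype(s) M1/M2 at each marker.

    The mother's phase is chosen to minimise the total number of
    recombination events across all children (dynamic programming over the
    ordered markers). Output labels per child per marker: "M1", "M2",
    "M1+M2" / "M1+M1" / "M2+M2" for two-maternal-X individuals, or "?"
    where the marker is uninformative or Mendelian-inconsistent.
    """
    if mother_id is None:
        mothers = {m.mother_id for m in pedigree.members if m.mother_id}
        if len(mothers) != 1:
            raise ValueError("cannot infer a unique mother; pass mother_id")
        mother_id = mothers.pop()
    children = [
        m.id for m in pedigree.members
        if m.mother_id == mother_id and m.id in table.alleles
    ]
    markers = table.markers

    # Child maternal allele observations.
    obs: dict[str, dict[str, tuple[tuple[int, ...], bool]]] = {
        c: {m.name: _maternal_alleles(table, pedigree, c, m.name) for m in markers}
        for c in children
    }
    xxy_two_maternal = {
        c: pedigree[c].sex_karyotype is Karyotype.XXY
        and not _xxy_has_paternal_x(table, pedigree, c)
        for c in children
    }
    # XXY child with one paternal X behaves like a daughter: strip paternal allele
    for c in children:
        if pedigree[c].sex_karyotype is Karyotype.XXY and not xxy_two_maternal[c]:
            father = pedigree[c].father_id
            for m in markers:
                alleles, ok = obs[c][m.name]
                pat = table.of(father, m.name)[0]
                rest = list(alleles)
                if pat in rest:
                    rest.remove(pat)
                    obs[c][m.name] = (tuple(rest), True)
                else:
                    obs[c][m.name] = ((), False)

    mother = {m.name: table.of(mother_id, m.name) for m in markers}

    def child_labels(c: str, mk: StrMarker, orient: int) -> str:
        """Label under a given mother orientation (0: as stored; 1: swapped)."""
        ma, mb = mother[mk.name]
        m1a, m2a = (ma, mb) if orient == 0 else (mb, ma)
        alleles, ok = obs[c][mk.name]
        if not ok:
            return UNINFORMATIVE
        if ma == mb:  # mother homozygous: uninformative for phase
            return UNINFORMATIVE
        if xxy_two_maternal.get(c) and len(alleles) == 2:
            labs = []
            rem = {M1: m1a, M2: m2a}
            pool = sorted(alleles)
            if sorted([m1a, m2a]) == pool:
                return "M1+M2"
            if pool == [m1a, m1a]:
                return "M1+M1"
            if pool == [m2a, m2a]:
                return "M2+M2"
            return UNINFORMATIVE
        if len(alleles) != 1:
            return UNINFORMATIVE
        a = alleles[0]
        if a == m1a:
            return M1
        if a == m2a:
            return M2
        return UNINFORMATIVE

    # DP over mother orientation per marker minimising label switches.
    n = len(markers)
    INF = float("inf")
    cost = [[0.0, 0.0] for _ in range(n)]
    back = [[0, 0] for _ in range(n)]
    labels_by_orient = [
        {o: {c: child_labels(c, mk, o) for c in children} for o in (0, 1)}
        for mk in markers
    ]

    def switch_cost(l1: Mapping[str, str], l2: Mapping[str, str]) -> float:
        s = 0
        for c in children:
            a, b = l1[c], l2[c]
            if UNINFORMATIVE in (a, b):
                continue
            if xxy_two_maternal.get(c):
                s += len(set(a.split("+")) ^ set(b.split("+"))) / 2
            elif a != b:
                s += 1
        return s

    prev_inform = None
    dp = [[0.0, 0.0]]
    choices: list[list[int]] = []
    informative_idx = [
        i for i in range(n)
        if any(labels_by_orient[i][0][c] != UNINFORMATIVE for c in children)
    ]
    for step, i in enumerate(informative_idx):
        if step == 0:
            dp = [[0.0, 0.0]]
            choices.append([0, 0])
            prev = i
            continue
        new = [INF, INF]
        ch = [0, 0]
        for o in (0, 1):
            for po in (0, 1):
                c_ = dp[-1][po] + switch_cost(
                    labels_by_orient[prev][po], labels_by_orient[i][o]
                )
                if c_ < new[o]:
                    new[o] = c_
                    ch[o] = po
        dp.append(new)
        choices.append(ch)
        prev = i

    orient = {}
    if informative_idx:
        o = 0 if dp[-1][0] <= dp[-1][1] else 1
        for step in range(len(informative_idx) - 1, -1, -1):
            orient[informative_idx[step]] = o
            o = choices[step][o]
    result: dict[str, dict[str, str]] = {c: {} for c in children}
    for i, mk in enumerate(markers):
        o = orient.get(i, 0)
        for c in children:
            result[c][mk.name] = labels_by_orient[i][o][c]
    return result


# ---------------------------------------------------------------------------
# Shared regions


def _carries(label: str, hap: str, both_copies: bool) -> bool | None:
    """Does a label carry haplotype ``hap``? None = uninformative."""
    if label == UNINFORMATIVE:
        return None
    parts = label.split("+")
    if both_copies and len(parts) == 2:
        return all(p == hap for p in parts)
    return hap in parts


def shared_regions(
    assignments: Mapping[str, Mapping[str, str]],
    markers: Sequence[StrMarker],
    affected: Iterable[str],
    unaffected_excluders: Iterable[str] = (),
    pedigree: Pedigree | None = None,
) -> list[SharedRegion]:
    """Maximal intervals where all affected share one maternal haplotype.

    For affected individuals with two X copies the dosage hypothesis
    requires the haplotype on both copies; excluders must lack it on every
    copy. Uninformative markers neither support nor break a run. Interval
    bounds extend outward to the flanking discordant markers (or chromosome
    ends), so breakpoint uncertainty is contained in the reported interval;
    a region whose inner markers are all uninformative on one side is
    flagged ambiguous.
    """
    affected = list(affected)
    excluders = list(unaffected_excluders)
    if not affected:
        return []

    def karyo(ind: str) -> Karyotype:
        return pedigree[ind].sex_karyotype if pedigree is not None else Karyotype.XY

    regions: list[SharedRegion] = []
    chrom = markers[0].chrom
    for hap in (M1, M2):
        status: list[bool | None] = []
        for mk in markers:
            ok: bool | None = True
            informative = False
            for a in affected:
                c = _carries(
                    assignments[a][mk.name], hap,
                    both_copies=karyo(a) in (Karyotype.XX, Karyotype.XXY),
                )
                if c is False:
                    ok = False
                elif c is True:
                    informative = True
            for e in excluders:
                if ok is False:
                    break
                c = _carries(assignments[e][mk.name], hap, both_copies=False)
                if c is True:
                    ok = False
                elif c is False:
                    informative = True
            if ok and not informative:
                ok = None
            status.append(ok)

        i, n = 0, len(markers)
        while i < n:
            if status[i] is not True:
                i += 1
                continue
            j = i
            while j + 1 < n and status[j + 1] is not False:
                j += 1
            while status[j] is not True:
                j -= 1
            # extend to flanking discordant markers (outer-bound convention)
            lo = i - 1
            while lo >= 0 and status[lo] is None:
                lo -= 1
            hi = j + 1
            while hi < n and status[hi] is None:
                hi += 1
            start = markers[lo].position if lo >= 0 else 1
            end = markers[hi].position if hi < n else markers[-1].position + 1
            regions.append(
                SharedRegion(
                    interval=GenomicInterval(chrom, start, end),
                    haplotype=hap,
                    carriers=frozenset(affected),
                    excluded=frozenset(excluders),
                    bounding_markers=(
                        markers[lo].name if lo >= 0 else "pter",
                        markers[hi].name if hi < n else "qter",
                    ),
                    ambiguous=(lo < i - 1) or (hi > j + 1),
                )
            )
            i = hi
    return regions


def genes_in_region(
    regions: Sequence[SharedRegion], gene_map: Mapping[str, GenomicInterval]
) -> dict[tuple[str, str], list[str]]:
    """Genes overlapping each shared region, in gene-map order."""
    out: dict[tuple[str, str], list[str]] = {}
    for r in regions:
        out[(r.haplotype, r.bounding_markers[0] + "-" + r.bounding_markers[1])] = [
            g for g, iv in gene_map.items() if iv.overlaps(r.interval)
        ]
    return out


# ---------------------------------------------------------------------------
# TSV I/O


def read_str_genotypes(path: str | Path, markers: Sequence[StrMarker]) -> StrGenotypeTable:
    """TSV columns: individual, marker, allele1[, allele2]."""
    alleles: dict[str, dict[str, tuple[int, ...]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "individual")):
            continue
        f = line.rstrip("\n").split("\t")
        ind, marker = f[0], f[1]
        vals = tuple(int(x) for x in f[2:] if x != "")
        alleles.setdefault(ind, {})[marker] = vals
    return StrGenotypeTable(markers=list(markers), alleles=alleles)


def write_str_genotypes(table: StrGenotypeTable, path: str | Path) -> None:
    lines = ["individual\tmarker\tallele1\tallele2"]
    for ind, per_marker in table.alleles.items():
        for mk in table.markers:
            vals = per_marker.get(mk.name)
            if vals is None:
                continue
            a2 = str(vals[1]) if len(vals) > 1 else ""
            lines.append(f"{ind}\t{mk.name}\t{vals[0]}\t{a2}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_regions_bed(regions: Sequence[SharedRegion], path: str | Path) -> None:
    lines = [
        f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}\t"
        f"{r.haplotype}:{r.bounding_markers[0]}-{r.bounding_markers[1]}"
        f"{':ambiguous' if r.ambiguous else ''}"
        for r in regions
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
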