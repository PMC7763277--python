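"""Pedigree-aware co-segregation checks for candidate calls.

A candidate is consistent when every genotyped relative's genotype matches
the inheritance hypothesis: affected relatives must carry the causal
genotype, unaffected relatives must not. Complete penetrance is assumed for
dominant hypotheses. X-linked logic accounts for karyotype: a 47,XXY male
carries two X copies, so X-chromosome "homozygosity" is legal for him and is
the causal state under the recessive hypothesis, exactly as for an XX female.

The (A/H) convention of clinical reports is reproduced: the index patient is
excluded from the affected/healthy counts of checked relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

from .variant_model import (
    Affection,
    AnnotatedVariant,
    Genotype,
    Karyotype,
    Pedigree,
)

if TYPE_CHECKING:  # pragma: no cover
    from .prioritization import CandidateCall


@dataclass
class SegregationResult:
    consistent: bool
    affected_checked: int
    healthy_checked: int
    violations: list[tuple[str, str, str]] = field(default_factory=list)
    phase_resolved: bool | None = None


def _gt(v: AnnotatedVariant, ind_id: str, overrides) -> Genotype:
    if overrides is not None:
        o = overrides.get(v.key, {})
        if ind_id in o:
            return o[ind_id]
    return v.genotype_of(ind_id)


def _causal_state_x(karyo: Karyotype, gt: Genotype) -> bool:
    """Does this X genotype constitute the disease state under XLR?"""
    if karyo is Karyotype.XY:
        return gt is Genotype.HEM_ALT
    return gt is Genotype.HOM_ALT  # XX and XXY: both X copies mutated


def _trans_confirmed(
    v1: AnnotatedVariant, v2: AnnotatedVariant, ind, pedigree: Pedigree, overrides
) -> bool | None:
    """Phase a double-het carrier via its parents.

    True when each genotyped parent carries exactly one (different) variant
    of the pair; None when parental genotypes cannot resolve phase.
    """
    if ind.father_id is None or ind.mother_id is None:
        return None
    f1 = _gt(v1, ind.father_id, overrides).carries_alt
    f2 = _gt(v2, ind.father_id, overrides).carries_alt
    m1 = _gt(v1, ind.mother_id, overrides).carries_alt
    m2 = _gt(v2, ind.mother_id, overrides).carries_alt
    if any(
        _gt(v, p, overrides) is Genotype.MISSING
        for v in (v1, v2)
        for p in (ind.father_id, ind.mother_id)
    ):
        return None
    if (f1 and not f2 and m2 and not m1) or (f2 and not f1 and m1 and not m2):
        return True
    if (f1 and f2 and not m1 and not m2) or (m1 and m2 and not f1 and not f2):
        return False  # both from one parent: cis
    return None


def check_segregation(
    call: "CandidateCall",
    pedigree: Pedigree,
    genotypes: Mapping[tuple, Mapping[str, Genotype]] | None = None,
) -> SegregationResult:
    """Check a candidate call against all genotyped non-index relatives.

    ``genotypes`` optionally overrides the genotype maps carried on the
    variants (e.g. confirmatory Sanger results keyed by variant).
    """
    from .prioritization import InheritanceMode  # local import, avoids cycle

    if genotypes is not None:
        for per_ind in genotypes.values():
            for ind_id in per_ind:
                if ind_id not in pedigree:
                    raise KeyError(f"genotype for unknown individual {ind_id!r}")

    index = pedigree.index
    mode = call.mode
    violations: list[tuple[str, str, str]] = []
    affected_checked = healthy_checked = 0
    phase_resolved: bool | None = None

    if call.is_compound_het:
        phase_resolved = _trans_confirmed(
            call.variants[0], call.variants[1], index, pedigree, genotypes
        )

    for member in pedigree.members:
        if member.id == index.id or member.affected is Affection.UNKNOWN:
            continue
        gts = [_gt(v, member.id, genotypes) for v in call.variants]
        if all(g is Genotype.MISSING for g in gts):
            continue

        ok = True
        expected = observed = ""
        if mode is InheritanceMode.AR:
            if call.is_compound_het:
                carries_both = all(g.carries_alt for g in gts)
                if member.affected is Affection.AFFECTED:
                    ok = carries_both
                    expected, observed = "both variants", "missing one or both"
                else:
                    trans = (
                        _trans_confirmed(
                            call.variants[0], call.variants[1], member, pedigree, genotypes
                        )
                        if carries_both
                        else None
                    )
                    ok = not (carries_both and trans is True)
                    expected, observed = "not both in trans", "both variants in trans"
            else:
                hom = gts[0] is Genotype.HOM_ALT
                if member.affected is Affection.AFFECTED:
                    ok = hom
                    expected, observed = "hom_alt", gts[0].value
                else:
                    ok = not hom
                    expected, observed = "not hom_alt", gts[0].value
        elif mode is InheritanceMode.AD:
            carrier = gts[0].carries_alt
            if member.affected is Affection.AFFECTED:
                ok = carrier
                expected, observed = "carrier", gts[0].value
            else:
                ok = not carrier
                expected, observed = "non-carrier", gts[0].value
        elif mode is InheritanceMode.XLR:
            causal = _causal_state_x(member.sex_karyotype, gts[0])
            if member.affected is Affection.AFFECTED:
                ok = causal
                expected = "hem_alt" if member.sex_karyotype is Karyotype.XY else "hom_alt"
                observed = gts[0].value
            else:
                # carrier females (and XXY het carriers) may be unaffected
                ok = not causal
                expected, observed = "not disease-state", gts[0].value
        else:  # XLD
            carrier = gts[0].carries_alt
            if member.affected is Affection.AFFECTED:
                ok = carrier
                expected, observed = "carrier", gts[0].value
            else:
                ok = not carrier
                expected, observed = "non-carrier", gts[0].value

        if member.affected is Affection.AFFECTED:
            affected_checked += 1
        else:
            healthy_checked += 1
        if not ok:
            violations.append((member.id, expected, observed))

    return SegregationResult(
        consistent=not violations,
        affected_checked=affected_checked,
        healthy_checked=healthy_checked,
        violations=violations,
        phase_resolved=phase_resolved,
    )


def count_segregants(result: SegregationResult) -> str:
    """Format a segregation result in the clinical-report (A/H) style.

    "Yes(A/H)" when at least one relative was checked and all are
    consistent; "No" when segregation was not performed or failed.
    """
    if result.affected_checked + result.healthy_checked == 0:
        return "No"
    if not result.consistent:
        return "No"
    return f"Yes({result.affected_checked}/{result.healthy_checked})"


def read_sanger_genotypes(path: str | Path) -> dict[tuple, dict[str, Genotype]]:
    """Read confirmatory genotypes from TSV: individual, variant key, genotype.

    The variant key column is ``chrom:pos:ref:alt``.
    """
    out: dict[tuple, dict[str, Genotype]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("individual"):
            continue
        ind, key, gt = line.split("\t")
        chrom, pos, ref, alt = key.split(":")
        out.setdefault((chrom, int(pos), ref, alt), {})[ind] = Genotype(gt)
    return out
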