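"""The multi-step variant prioritization cascade.

Every family is analysed under all four inheritance hypotheses — autosomal
recessive (AR), autosomal dominant (AD), X-linked recessive (XLR) and
X-linked dominant (XLD) — regardless of the apparent pedigree pattern. Each
mode applies, in order:

  quality control -> population frequency -> consequence/splice-distance ->
  zygosity & compound-het pairing -> control-population genotype counts ->
  ACMG pathogenicity class -> gene tiering -> familial segregation ->
  recovery (only when the mode produced nothing).

Candidates are tiered: variants in known retinal-disease genes first
(tier ``IRD_gene``), everything else second (tier ``novel_candidate``).
A ``lax`` run skips the control-genotype and ACMG steps; it is the fallback
used when strict filtering leaves a family unexplained (e.g. re-screening a
linked chromosomal interval).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .variant_model import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenomicInterval,
    Karyotype,
    Pedigree,
    load_retnet_genes,
)
from . import qc_cnv
from . import segregation as seg_mod


class InheritanceMode(str, Enum):
    AR = "AR"
    AD = "AD"
    XLR = "XLR"
    XLD = "XLD"

    @property
    def recessive(self) -> bool:
        return self in (InheritanceMode.AR, InheritanceMode.XLR)

    @property
    def x_linked(self) -> bool:
        return self in (InheritanceMode.XLR, InheritanceMode.XLD)


ALL_MODES = tuple(InheritanceMode)


@dataclass
class PrioritizationConfig:
    maf_recessive: float = 0.01
    maf_dominant: float = 0.0001
    splice_max_distance_bp: int = 10
    min_depth: int = 20
    max_fs: float = 60.0
    recovery_known_maf: float = 0.01
    ird_gene_list: frozenset[str] = field(default_factory=load_retnet_genes)
    acmg_discard_classes: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if self.maf_dominant > self.maf_recessive:
            raise ValueError("dominant MAF threshold must be <= recessive threshold")

    def maf_threshold(self, mode: InheritanceMode) -> float:
        return self.maf_recessive if mode.recessive else self.maf_dominant


TIER_IRD = "IRD_gene"
TIER_NOVEL = "novel_candidate"


@dataclass
class CandidateCall:
    mode: InheritanceMode
    variants: tuple[AnnotatedVariant, ...]  # length 1, or 2 for compound het
    gene: str
    tier: str
    audit: list[tuple[str, str]] = field(default_factory=list)
    recovered: bool = False
    modifier_flag: bool = False
    phase_resolved: bool | None = None
    segregation: "seg_mod.SegregationResult | None" = None

    @property
    def is_compound_het(self) -> bool:
        return len(self.variants) == 2

    @property
    def key(self) -> tuple:
        return (self.mode.value, self.gene, tuple(v.key for v in self.variants))


@dataclass
class PrioritizationResult:
    candidates: dict[InheritanceMode, list[CandidateCall]]
    removed: dict[InheritanceMode, list[tuple[AnnotatedVariant, list[str]]]]
    recovery_applied: dict[InheritanceMode, bool]
    lax_mode: bool = False

    def all_candidates(self) -> list[CandidateCall]:
        return [c for mode in ALL_MODES for c in self.candidates.get(mode, [])]


# ---------------------------------------------------------------------------
# Individual filter steps (each returns a subset of its input)


def frequency_filter(
    variants: Iterable[AnnotatedVariant],
    mode: InheritanceMode,
    config: PrioritizationConfig,
) -> list[AnnotatedVariant]:
    """Keep variants with effective MAF below the mode threshold.

    Effective MAF is the maximum frequency across the population databases;
    a variant absent everywhere scores 0 and is always kept.
    """
    thr = config.maf_threshold(mode)
    kept = []
    for v in variants:
        maf = v.effective_maf
        if not 0.0 <= maf <= 1.0:
            raise ValueError(f"MAF out of range for {v.key}: {maf}")
        if maf < thr:
            kept.append(v)
    return kept


def consequence_filter(
    variants: Iterable[AnnotatedVariant],
    config: PrioritizationConfig,
) -> list[AnnotatedVariant]:
    """Drop non-coding variants far from splice sites and off-boundary
    synonymous changes outside known retinal-disease genes.

    Intronic/UTR/other variants survive only within ``splice_max_distance_bp``
    of a canonical splice site. Synonymous variants always survive in known
    disease genes; elsewhere only when they sit in the first or last two
    bases of an exon.
    """
    kept = []
    for v in variants:
        if v.consequence in (Consequence.INTRONIC, Consequence.UTR, Consequence.OTHER):
            if v.splice_distance_bp <= config.splice_max_distance_bp:
                kept.append(v)
        elif v.consequence is Consequence.SYNONYMOUS:
            if v.gene in config.ird_gene_list or v.exon_boundary_offset in (1, 2):
                kept.append(v)
        else:
            kept.append(v)
    return kept


def _chromosome_matches(v: AnnotatedVariant, mode: InheritanceMode) -> bool:
    return v.is_x if mode.x_linked else not v.is_x


def zygosity_filter(
    variants: Sequence[AnnotatedVariant],
    mode: InheritanceMode,
    index_individual,
) -> list[AnnotatedVariant]:
    """Keep variants whose index genotype fits the inheritance hypothesis.

    AR keeps homozygotes and heterozygotes with at least one other surviving
    het partner in the same gene (compound-het compatibility). AD/XLD drop
    homozygotes and keep heterozygotes. XLR keeps hemizygous calls in XY
    males and homozygous calls in two-X individuals (XX and 47,XXY alike).
    Hemizygous males are handled under the recessive X branch, not XLD.
    """
    karyo = index_individual.sex_karyotype
    on_mode = [v for v in variants if _chromosome_matches(v, mode)]
    for v in on_mode:
        gt = v.genotype_of(index_individual.id)
        if gt is Genotype.HEM_ALT and not v.is_x:
            raise ValueError(f"hemizygous autosomal genotype for {v.key}")
        if gt is Genotype.HEM_ALT and v.is_x and karyo is not Karyotype.XY:
            raise ValueError(
                f"hemizygous X genotype recorded for {karyo.value} individual"
            )
    if mode is InheritanceMode.AR:
        homs = [v for v in on_mode if v.genotype_of(index_individual.id) is Genotype.HOM_ALT]
        hets = [v for v in on_mode if v.genotype_of(index_individual.id) is Genotype.HET]
        het_by_gene: dict[str, list[AnnotatedVariant]] = {}
        for v in hets:
            het_by_gene.setdefault(v.gene, []).append(v)
        paired = [v for vs in het_by_gene.values() if len(vs) >= 2 for v in vs]
        return sorted(homs + paired, key=lambda v: (v.chrom, v.pos))
    if mode in (InheritanceMode.AD, InheritanceMode.XLD):
        return [v for v in on_mode if v.genotype_of(index_individual.id) is Genotype.HET]
    # XLR
    kept = []
    for v in on_mode:
        gt = v.genotype_of(index_individual.id)
        if karyo is Karyotype.XY and gt is Genotype.HEM_ALT:
            kept.append(v)
        elif karyo in (Karyotype.XX, Karyotype.XXY) and gt is Genotype.HOM_ALT:
            kept.append(v)
    return kept


def control_genotype_filter(
    variants: Iterable[AnnotatedVariant], mode: InheritanceMode
) -> list[AnnotatedVariant]:
    """Screen against control-population genotype counts (GnomAD).

    Recessive modes require zero homozygotes and zero hemizygotes among
    controls; dominant modes additionally require zero heterozygotes.
    Variants already reported pathogenic bypass the screen.
    """
    kept = []
    for v in variants:
        if min(v.gnomad_het, v.gnomad_hem, v.gnomad_hom) < 0:
            raise ValueError(f"negative control genotype count for {v.key}")
        if v.reported_pathogenic:
            kept.append(v)
            continue
        ok = v.gnomad_hom == 0 and v.gnomad_hem == 0
        if not mode.recessive:
            ok = ok and v.gnomad_het == 0
        if ok:
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# ACMG evidence combining

_PATHOGENIC_STRENGTHS = {"PVS": 8, "PS": 4, "PM": 2, "PP": 1}

_VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)


def _evidence_counts(codes: frozenset[str]) -> dict[str, int]:
    counts = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for code in codes:
        if code not in _VALID_CODES:
            raise ValueError(f"unknown ACMG criterion code {code!r}")
        for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
            if code.startswith(prefix):
                counts[prefix] += 1
                break
    return counts


def acmg_combine(codes: Iterable[str]) -> int:
    """Combine ACMG evidence criteria into a five-tier class.

    Implements the standard combining rules: 1 benign, 2 likely benign,
    3 uncertain significance, 4 likely pathogenic, 5 pathogenic.
    Simultaneously satisfied pathogenic and benign rules yield 3.
    """
    c = _evidence_counts(frozenset(codes))
    pvs, ps, pm, pp = c["PVS"], c["PS"], c["PM"], c["PP"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = c["BA"] >= 1 or c["BS"] >= 2
    likely_benign = (c["BS"] == 1 and c["BP"] == 1) or c["BP"] >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return 3
    if pathogenic:
        return 5
    if likely_pathogenic:
        return 4
    if benign:
        return 1
    if likely_benign:
        return 2
    return 3


def variant_acmg_class(v: AnnotatedVariant) -> int:
    if v.acmg_class is not None:
        if not 1 <= v.acmg_class <= 5:
            raise ValueError(f"ACMG class out of range for {v.key}: {v.acmg_class}")
        return v.acmg_class
    return acmg_combine(v.acmg_codes)


def acmg_filter(
    variants: Iterable[AnnotatedVariant], config: PrioritizationConfig
) -> list[AnnotatedVariant]:
    """Discard variants with a benign or likely-benign verdict (classes 1-2)."""
    return [v for v in variants if variant_acmg_class(v) not in config.acmg_discard_classes]


# ---------------------------------------------------------------------------
# Recovery

RECOVERABLE_REASONS = {qc_cnv.LOW_COVERAGE, "maf"}


def recover_variants(
    removed_with_reason: Sequence[tuple[AnnotatedVariant, list[str]]],
    config: PrioritizationConfig,
) -> list[AnnotatedVariant]:
    """Re-admit variants removed solely for low depth, or reported-pathogenic
    variants removed solely for high population frequency.

    Only invoked when a mode produced no candidate for the family.
    """
    out = []
    for v, reasons in removed_with_reason:
        rs = set(reasons)
        if rs == {qc_cnv.LOW_COVERAGE}:
            out.append(v)
        elif rs == {"maf"} and v.reported_pathogenic:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Cascade


def _tier_of(gene: str, config: PrioritizationConfig) -> str:
    return TIER_IRD if gene in config.ird_gene_list else TIER_NOVEL


def _build_calls(
    survivors: Sequence[AnnotatedVariant],
    mode: InheritanceMode,
    index_id: str,
    config: PrioritizationConfig,
    audit: dict,
    recovered_keys: set,
) -> list[CandidateCall]:
    calls: list[CandidateCall] = []
    if mode.recessive:
        by_gene: dict[str, list[AnnotatedVariant]] = {}
        for v in survivors:
            by_gene.setdefault(v.gene, []).append(v)
        for gene, vs in by_gene.items():
            homs = [v for v in vs if v.genotype_of(index_id) in (Genotype.HOM_ALT, Genotype.HEM_ALT)]
            hets = [v for v in vs if v.genotype_of(index_id) is Genotype.HET]
            for v in homs:
                calls.append(
                    CandidateCall(
                        mode=mode, variants=(v,), gene=gene,
                        tier=_tier_of(gene, config), audit=list(audit.get(v.key, [])),
                        recovered=v.key in recovered_keys,
                    )
                )
            if len(hets) >= 2:
                for a, b in itertools.combinations(
                    sorted(hets, key=lambda v: (v.chrom, v.pos)), 2
                ):
                    calls.append(
                        CandidateCall(
                            mode=mode, variants=(a, b), gene=gene,
                            tier=_tier_of(gene, config),
                            audit=list(audit.get(a.key, [])) + list(audit.get(b.key, [])),
                            recovered=a.key in recovered_keys or b.key in recovered_keys,
                        )
                    )
    else:
        for v in survivors:
            calls.append(
                CandidateCall(
                    mode=mode, variants=(v,), gene=v.gene,
                    tier=_tier_of(v.gene, config), audit=list(audit.get(v.key, [])),
                    recovered=v.key in recovered_keys,
                )
            )
    return calls


def _sort_calls(calls: list[CandidateCall]) -> list[CandidateCall]:
    def rank(c: CandidateCall):
        cls = max(variant_acmg_class(v) for v in c.variants)
        maf = min(v.effective_maf for v in c.variants)
        pos = min((v.chrom, v.pos) for v in c.variants)
        return (0 if c.tier == TIER_IRD else 1, -cls, maf, pos)

    return sorted(calls, key=rank)


def _run_mode(
    variants: Sequence[AnnotatedVariant],
    pedigree: Pedigree,
    mode: InheritanceMode,
    config: PrioritizationConfig,
    lax: bool,
    skip_qc_keys: set = frozenset(),
    skip_maf_keys: set = frozenset(),
    recovered_keys: set = frozenset(),
) -> tuple[list[CandidateCall], list[tuple[AnnotatedVariant, list[str]]]]:
    index = pedigree.index
    audit: dict[tuple, list[tuple[str, str]]] = {v.key: [] for v in variants}
    removed: dict[tuple, list[str]] = {}

    def mark(vs_in, vs_kept, step):
        kept_keys = {v.key for v in vs_kept}
        for v in vs_in:
            verdict = "pass" if v.key in kept_keys else "fail"
            audit[v.key].append((step, verdict))
            if verdict == "fail":
                removed.setdefault(v.key, []).append(step)
        return vs_kept

    # QC
    qc_in = list(variants)
    exempt = [v for v in qc_in if v.key in skip_qc_keys]
    qc_kept, qc_removed = qc_cnv.apply_qc_filters(
        [v for v in qc_in if v.key not in skip_qc_keys],
        min_depth=config.min_depth, max_fs=config.max_fs,
    )
    for v, reasons in qc_removed:
        audit[v.key].append(("qc", "fail"))
        removed[v.key] = list(reasons)
    cur = qc_kept + exempt
    for v in cur:
        audit[v.key].append(("qc", "pass"))

    # frequency
    freq_exempt = [v for v in cur if v.key in skip_maf_keys]
    freq_kept = frequency_filter(
        [v for v in cur if v.key not in skip_maf_keys], mode, config
    )
    kept_keys = {v.key for v in freq_kept} | {v.key for v in freq_exempt}
    for v in cur:
        if v.key in kept_keys:
            audit[v.key].append(("maf", "pass"))
        else:
            audit[v.key].append(("maf", "fail"))
            removed.setdefault(v.key, []).append("maf")
    cur = [v for v in cur if v.key in kept_keys]

    cur = mark(cur, consequence_filter(cur, config), "consequence")
    cur = mark(cur, zygosity_filter(cur, mode, index), "zygosity")
    if not lax:
        cur = mark(cur, control_genotype_filter(cur, mode), "control_genotypes")
        cur = mark(cur, acmg_filter(cur, config), "acmg")

    calls = _build_calls(cur, mode, index.id, config, audit, set(recovered_keys))

    # familial segregation, when relatives are genotyped
    surviving: list[CandidateCall] = []
    for call in calls:
        res = seg_mod.check_segregation(call, pedigree)
        call.segregation = res
        call.phase_resolved = res.phase_resolved
        if res.consistent:
            surviving.append(call)
        else:
            for v in call.variants:
                removed.setdefault(v.key, []).append("segregation")

    removed_list = [
        (v, removed[v.key]) for v in variants if v.key in removed
    ]
    return _sort_calls(surviving), removed_list


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    pedigree: Pedigree,
    config: PrioritizationConfig | None = None,
    lax: bool = False,
    region: GenomicInterval | None = None,
) -> PrioritizationResult:
    """Run the full prioritization cascade under all four inheritance modes.

    ``region`` optionally restricts the analysis to one genomic interval
    (used when re-screening a linkage-defined region). When a mode yields no
    segregating candidate, the recovery rules re-admit variants removed
    solely for low coverage, or reported-pathogenic variants removed solely
    for frequency, and the mode is re-run with those exemptions.
    """
    config = config or PrioritizationConfig()
    pedigree.index  # raises if no affected member
    if region is not None:
        variants = [v for v in variants if region.contains(v.chrom, v.pos)]

    candidates: dict[InheritanceMode, list[CandidateCall]] = {}
    removed: dict[InheritanceMode, list[tuple[AnnotatedVariant, list[str]]]] = {}
    recovery_applied: dict[InheritanceMode, bool] = {}

    for mode in ALL_MODES:
        calls, rem = _run_mode(variants, pedigree, mode, config, lax)
        recovery_applied[mode] = False
        if not calls:
            recoverable = recover_variants(rem, config)
            if recoverable:
                keys = {v.key for v in recoverable}
                skip_qc = {
                    v.key for v, rs in rem if set(rs) == {qc_cnv.LOW_COVERAGE} and v.key in keys
                }
                skip_maf = keys - skip_qc
                calls, rem = _run_mode(
                    variants, pedigree, mode, config, lax,
                    skip_qc_keys=skip_qc, skip_maf_keys=skip_maf,
                    recovered_keys=keys,
                )
                recovery_applied[mode] = bool(calls)
        candidates[mode] = calls
        removed[mode] = rem

    return PrioritizationResult(
        candidates=candidates, removed=removed,
        recovery_applied=recovery_applied, lax_mode=lax,
    )


# ---------------------------------------------------------------------------
# Cross-strategy comparison


def cross_strategy_compare(
    result_a: PrioritizationResult,
    result_b: PrioritizationResult,
    common_regions: Sequence[GenomicInterval],
    same_phenotype: bool = True,
) -> tuple[PrioritizationResult, PrioritizationResult]:
    """Reconcile results from two affected relatives on different designs.

    A candidate seen in only one relative at a position covered by both
    designs is contradictory when the phenotypes match and is removed; with
    discordant phenotypes it is kept but flagged as a potential second-site
    modifier.
    """

    def var_keys(res: PrioritizationResult) -> set:
        return {v.key for c in res.all_candidates() for v in c.variants}

    def in_common(call: CandidateCall) -> bool:
        return all(
            any(r.contains(v.chrom, v.pos) for r in common_regions)
            for v in call.variants
        )

    keys_a, keys_b = var_keys(result_a), var_keys(result_b)

    def reconcile(res: PrioritizationResult, other_keys: set) -> PrioritizationResult:
        new: dict[InheritanceMode, list[CandidateCall]] = {}
        for mode, calls in res.candidates.items():
            out = []
            for c in calls:
                unshared = any(v.key not in other_keys for v in c.variants)
                if unshared and in_common(c):
                    if same_phenotype:
                        continue
                    c = replace(c, modifier_flag=True)
                out.append(c)
            new[mode] = out
        return PrioritizationResult(
            candidates=new, removed=res.removed,
            recovery_applied=res.recovery_applied, lax_mode=res.lax_mode,
        )

    return reconcile(result_a, keys_b), reconcile(result_b, keys_a)
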