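"""Sequencing-strategy comparison: output requirement, cost, diagnostic yield.

Per-sample sequencing output follows the standard coverage identity

    output = target_size * coverage / (on_target_fraction * (1 - duplicate_fraction))

i.e. enough raw bases that, after discarding duplicates and off-target
reads, the target is covered at the requested mean depth. Samples per run
and per-sample reagent cost follow from the instrument's run output.
First-line diagnostic yield asks, for each solved case in a cohort, whether
the causal gene is in a design's gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variant_model import FixtureRecord, TargetDesign, load_fixtures, load_retnet_genes

#: on-target read fractions achieved per strategy in the reference study
DEFAULT_ON_TARGET = {"PS": 0.966, "CES": 0.753, "WES": 0.74}
#: mean coverage targets per strategy (fold)
DEFAULT_COVERAGE = {"PS": 200.0, "CES": 100.0, "WES": 100.0}
#: enriched target sizes (bases); PS is design-specific
DEFAULT_TARGET_SIZE = {"CES": 12e6, "WES": 47e6}
DEFAULT_DUPLICATES = 0.10


@dataclass
class StrategyParams:
    name: str
    target_size: float  # bases
    mean_coverage_target: float
    on_target_fraction: float
    duplicate_fraction: float = DEFAULT_DUPLICATES
    run_output: float | None = None  # bases
    reagent_cost_per_run: float | None = None
    per_sample_library_cost: float = 0.0
    design: TargetDesign | None = None

    def __post_init__(self) -> None:
        if not 0 < self.on_target_fraction <= 1:
            raise ValueError("on_target_fraction must be in (0, 1]")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if self.mean_coverage_target <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class YieldEstimate:
    strategy: str
    diagnosable: int
    diagnosed_total: int

    @property
    def fraction(self) -> float:
        return self.diagnosable / self.diagnosed_total


def per_sample_output(params: StrategyParams) -> float:
    """Raw bases required per sample to reach the coverage target."""
    denom = params.on_target_fraction * (1.0 - params.duplicate_fraction)
    if denom <= 0:
        raise ValueError("on_target * (1 - duplicates) must be positive")
    return params.target_size * params.mean_coverage_target / denom


def samples_per_run_and_cost(params: StrategyParams) -> tuple[int, float | None]:
    """Maximum multiplexed samples per run and reagent cost per sample.

    Cost is None when reagent prices are not configured (the comparison is
    then relative, by output requirement only).
    """
    if params.run_output is None:
        raise ValueError("run_output not configured")
    need = per_sample_output(params)
    samples = int(params.run_output // need)
    if samples < 1:
        raise ValueError(
            f"run output {params.run_output:.3g} below per-sample requirement {need:.3g}"
        )
    if params.reagent_cost_per_run is None:
        return samples, None
    cost = (
        params.reagent_cost_per_run + params.per_sample_library_cost * samples
    ) / samples
    return samples, cost


def estimate_first_line_yield(
    solved_cases: Sequence[tuple[str, str]],
    designs: Iterable[TargetDesign],
) -> dict[str, YieldEstimate]:
    """Diagnostic rate had each design been used first-line.

    ``solved_cases`` is (family_id, causal gene symbol) per diagnosed case;
    a case is diagnosable by a design when its causal gene is in the
    design's gene set.
    """
    if not solved_cases:
        raise ValueError("empty solved-case list")
    out = {}
    for d in designs:
        diagnosable = sum(1 for _, gene in solved_cases if gene in d.gene_set)
        out[d.name] = YieldEstimate(d.name, diagnosable, len(solved_cases))
    return out


# ---------------------------------------------------------------------------
# Reconstructed designs for the packaged cohort fixtures


def solved_cases_from_fixtures(
    records: Iterable[FixtureRecord] | None = None,
) -> list[tuple[str, str]]:
    """(family, causal gene) for every solved family in the fixture tables."""
    if records is None:
        records = load_fixtures("table1") + load_fixtures("table2")
    seen: dict[str, str] = {}
    for r in records:
        if r.solved and r.family_id not in seen:
            seen[r.family_id] = r.gene
    return sorted(seen.items(), key=lambda kv: int(kv[0]))


def reconstructed_designs() -> dict[str, TargetDesign]:
    """Gene-set reconstructions of the three strategies.

    The panel (PS) design holds the genes in which panel-era diagnoses were
    made plus RPGR, whose mutational hotspot (ORF15) is in the design but
    effectively unsequenceable, so RPGR is absent from covered_gene_set.
    The clinical exome (CES) adds all disease-associated genes; the whole
    exome (WES) additionally reaches genes with no prior disease link.
    """
    t1 = load_fixtures("table1")
    t2 = load_fixtures("table2")
    t3 = load_fixtures("table3")
    retnet = load_retnet_genes()
    ps_genes = frozenset(r.gene for r in t1) | {"RPGR"}
    ces_genes = ps_genes | frozenset(r.gene for r in t2) | retnet | {"WDFY3"}
    wes_genes = ces_genes | frozenset(r.gene for r in t3)
    return {
        "PS": TargetDesign(
            name="PS", gene_set=ps_genes, covered_gene_set=ps_genes - {"RPGR"}
        ),
        "CES": TargetDesign(name="CES", gene_set=ces_genes, covered_gene_set=ces_genes),
        "WES": TargetDesign(name="WES", gene_set=wes_genes, covered_gene_set=wes_genes),
    }


def default_strategy_params(
    ps_target_size: float = 0.5e6,
    run_output: Mapping[str, float] | None = None,
    reagent_cost_per_run: Mapping[str, float] | None = None,
) -> dict[str, StrategyParams]:
    """Strategy parameter sets with the study's coverage/on-target values."""
    designs = reconstructed_designs()
    sizes = {"PS": ps_target_size, **DEFAULT_TARGET_SIZE}
    out = {}
    for name in ("PS", "CES", "WES"):
        out[name] = StrategyParams(
            name=name,
            target_size=sizes[name],
            mean_coverage_target=DEFAULT_COVERAGE[name],
            on_target_fraction=DEFAULT_ON_TARGET[name],
            run_output=(run_output or {}).get(name),
            reagent_cost_per_run=(reagent_cost_per_run or {}).get(name),
            design=designs[name],
        )
    return out
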