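# Methods

This note documents the models, parameter choices and numerical decisions
behind `ird_triage`, and what the synthetic-data experiments do and do not
demonstrate about real sequencing data.

## Prioritization cascade

The cascade is a deterministic filter composition run independently under
the four Mendelian hypotheses (AR, AD, XLR, XLD). Key parameters
(`PrioritizationConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| `maf_recessive` | 0.01 | allele fraction | recessive alleles may circulate at ~1% in carriers |
| `maf_dominant` | 0.0001 | allele fraction | a fully penetrant dominant allele cannot be common |
| `splice_max_distance_bp` | 10 | bp | beyond ±10 bp the splice impact of intronic changes is speculative without functional data |
| `min_depth` | 20 | reads | conventional germline short-variant floor |
| `max_fs` | 60.0 | Phred | standard Fisher strand-bias hard filter |
| `acmg_discard_classes` | {1, 2} | — | benign / likely benign verdicts |

Decisions taken where the procedure was genuinely open:

- **Effective MAF is the maximum over the four population databases**
  (GnomAD, EVS, 1000GP, CSVS). The maximum is the most conservative
  aggregation for rare-disease filtering: one credible observation of
  commonness is disqualifying. A database where the variant is absent
  contributes 0 (absence of evidence is not penalised).
- **"Control individuals" for the extra dominant screen are GnomAD
  genotype counts.** Recessive hypotheses tolerate heterozygous carriers
  but not homozygous/hemizygous ones; dominant hypotheses tolerate none.
- **Hemizygous males are routed through the recessive X branch.** X
  handling follows per-genotype legality rather than a separate dominant
  branch for males, for whom the het/hom distinction does not exist.
- **Compound-het pairing without parental genotypes keeps the pair** with
  phase marked unresolved; segregation resolves phase when parents are
  genotyped (trans confirmed when each parent carries exactly one of the
  pair).
- **Deterministic candidate ordering:** tier (known-disease gene first),
  then ACMG class descending, then effective MAF ascending, then genomic
  position.
- **Recovery runs per family per mode, after segregation**, and only
  re-admits variants whose *entire* removal reason set is recoverable
  (depth-only, or frequency-only for reported-pathogenic variants). A
  variant removed for, say, frequency *and* consequence stays removed.
- Class-3 VUS are retained for candidate tiering; clinical practice
  reports them as candidates pending functional work, and discarding them
  would hide every novel-gene signal.

ACMG combining implements the published 2015 rule table (pathogenic /
likely pathogenic / benign / likely benign combinations over PVS/PS/PM/PP
and BA/BS/BP evidence); simultaneously satisfied pathogenic-side and
benign-side rules yield class 3 (uncertain). The test suite checks the
implementation against an independently transcribed copy of the table on
every code combination up to size four.

## CNV calling

Coverage ratios use parameter-free double-median normalization:
`ratio_i = (s_i / median(s)) / (r_i / median(r))`. This removes
library-size differences and is invariant to rescaling either track. The
reference track may be a pooled batch median when no matched reference
exists. **Known limitation:** median normalization assumes the event
affects a minority of the profiled targets; an event spanning close to
half the profile shifts the median itself and attenuates the signal.
Profiles should therefore cover a panel's full target list, not a single
gene.

Calls are made by seed-and-extend: targets beyond the published cutoffs
(deletion < 0.6, duplication > 1.40) seed an event, which extends through
adjacent targets past the midpoint toward 1.0 (< 0.8 / > 1.2 at the
default cutoffs). A block is reported when it has ≥ `min_consecutive_targets`
targets (default 2; set 1 to call single-exon events), at least one seed,
and a block-mean ratio beyond the cutoff. Extension exists because a
heterozygous-deletion target (ratio centred at 0.5, sd ≈ 0.05) sits only
two standard deviations from the 0.6 cutoff: a strict per-target rule
would split or truncate a real multi-exon event a few percent of the
time, while normal-copy targets (centred at 1.0) essentially never reach
the extension bound. Deletion blocks with mean ratio < 0.25 are hinted
homozygous, otherwise heterozygous.

## Segregation

A candidate is consistent when every genotyped non-index relative matches
the hypothesis: affected relatives carry the causal genotype (hom for AR,
both variants for compound het, carrier for AD/XLD, hemizygous XY /
homozygous XX·XXY for XLR) and unaffected relatives do not. Complete
penetrance is assumed for dominant hypotheses; carrier females are legal
under XLR. An unaffected double-het relative only violates a compound-het
call when their own parents prove the trans configuration. The (A/H)
report counts genotyped non-index relatives, reproducing the clinical
`Yes(A/H)` convention; the index is never counted.

## STR linkage

The marker map is a packaged list of 26 X-chromosome microsatellites with
plausible ordered positions — synthetic stand-ins (files suffixed
`_synthetic`), since the logic, not the coordinates, is the testable
content. Maternal-origin alleles are extracted per child (single allele of
an XY son; non-paternal allele of a daughter; both alleles of a 47,XXY son
carrying two maternal X's, decided by whether the father's allele fits his
genotype at every marker). The mother's phase is the minimum-recombination
labelling, solved exactly by dynamic programming over marker order with a
two-state (orientation) chain; markers where the mother is homozygous are
uninformative. Shared regions are maximal runs where all affected carry
one maternal haplotype — on **both** X copies for the XXY dosage
hypothesis — and every excluder lacks it; bounds extend outward to the
flanking discordant markers ("maximum common region" convention), and a
run whose edge crosses uninformative markers is flagged ambiguous, which
represents breakpoint uncertainty as a widened interval.

## Strategy comparison

Per-sample output uses the standard coverage identity
`target_size × coverage / (on_target × (1 − duplicates))` with the
study-level parameters: 200× target coverage for the panel, 100× for
clinical/whole exome; on-target fractions 0.966 / 0.753 / 0.74; 10%
duplicates; target sizes 12 Mb (CES) and 47 Mb (WES). Reagent prices are
config inputs; without them the module compares strategies by output
requirement only. First-line yield counts, over the solved families of
the packaged cohort tables, whose causal gene each design's gene set
contains. The panel design is a gene-set reconstruction: the genes with
panel-era diagnoses plus RPGR, whose mutational hotspot (ORF15) is in the
design but effectively unsequenceable due to its repetitive structure —
so RPGR is in `gene_set` but not `covered_gene_set`, and the "included in
design" reading yields 21/24 = 87.5% for the panel.

## Synthetic data

`simulate_family` plants a causal genotype that segregates by construction
(annotations drawn from the filter-passing region: MAF 0, truncating or
missense consequence, strong pathogenic evidence codes, depth 60–180) in
one of five scenarios (AR hom, AR compound het, AD, XLR, XLR with a
47,XXY affected son). Background variants emulate an annotated germline
callset:

- MAF: mixture of a point mass at 0 (weight 0.6, never-observed alleles)
  and Beta(0.5, 30) otherwise; secondary databases observe a scaled copy.
- consequence: categorical mix dominated by missense (0.45), synonymous
  (0.15) and intronic (0.15); intronic splice distances log-normal.
- depth ~ NegBin(mean 100, dispersion 10); FS ~ Exponential(mean 5).
- GnomAD genotype counts ~ Poisson with intensity proportional to MAF
  (het), MAF² (hom), and a hemizygous term on X.
- gene symbols: 1.5% of background variants fall in known retinal-disease
  genes (≈ 250 such genes in an ~18,000-gene exome), drawn across the
  packaged snapshot; the rest use a 4,000-symbol synthetic pool.
- genotypes by Mendelian gene-dropping from founder alleles, conditioned
  on the allele being present in the family (otherwise it would not have
  been called).

A single integer seed drives named RNG streams per output kind, so
regeneration is byte-identical and adding generators does not perturb
existing outputs.

**What passing these tests shows — and does not.** The simulations verify
the *logic*: filter composition, pairing, segregation, recovery, CNV run
detection, haplotype phasing. They do not model linkage disequilibrium,
site-frequency spectra, annotation errors, pipeline-specific artifact
modes, or incomplete penetrance; real-data performance also depends on
annotation quality, which is consumed, not produced, here.

## Problem sizes

The default experiment sizes are 200 simulated families per inheritance
scenario (150 background variants each), 200 coverage profiles of 40–80
targets, and 200 STR families on the 26-marker map — large enough for
stable rate estimates while keeping a full run in tens of seconds on one
CPU core.

## Known limitations

- The dominant-model segregation check assumes complete penetrance;
  families like the mildly-affected carrier females in the X-linked
  worked example are handled by phenotype revision, not a penetrance
  parameter.
- The double-median CNV normalization is a documented stand-in for a
  matched-reference protocol and is replaceable.
- Marker and X-gene coordinates are synthetic; do not use the packaged
  maps for real positional inference.
- "Solved" verdicts in the fixture tables encode clinical judgement
  (e.g. a segregating VUS with unexplained intrafamilial variability
  remains unsolved) and are carried as data, not recomputed.
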