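"""Cascade filter steps, ACMG combining and cross-strategy reconciliation."""

import numpy as np
import pytest

from ird_triage.prioritization import (
    ALL_MODES,
    InheritanceMode,
    PrioritizationConfig,
    TIER_IRD,
    TIER_NOVEL,
    acmg_combine,
    acmg_filter,
    consequence_filter,
    control_genotype_filter,
    cross_strategy_compare,
    frequency_filter,
    recover_variants,
    run_cascade,
    zygosity_filter,
)
from ird_triage.variant_model import (
    Consequence,
    Genotype,
    GenomicInterval,
    load_fixtures,
)
from ird_triage.synthetic_data import simulate_family

from conftest import make_variant

AR, AD, XLR, XLD = InheritanceMode.AR, InheritanceMode.AD, InheritanceMode.XLR, InheritanceMode.XLD
CFG = PrioritizationConfig()


class TestFrequencyFilter:
    def test_between_thresholds_kept_only_recessive(self):
        v = make_variant(maf_by_db={"GnomAD": 0.005})
        for mode in (AR, XLR):
            assert frequency_filter([v], mode, CFG) == [v]
        for mode in (AD, XLD):
            assert frequency_filter([v], mode, CFG) == []

    def test_database_absent_kept_everywhere(self):
        v = make_variant(maf_by_db={})
        for mode in ALL_MODES:
            assert frequency_filter([v], mode, CFG) == [v]

    def test_effective_maf_is_max_across_databases(self):
        v = make_variant(maf_by_db={"GnomAD": 1e-6, "CSVS": 0.02})
        assert frequency_filter([v], AR, CFG) == []

    def test_matches_bruteforce_threshold_scan(self):
        rng = np.random.default_rng(12)
        vs = []
        for i, m in enumerate(rng.beta(0.3, 20, 1000)):
            vs.append(make_variant(pos=i + 1, maf_by_db={"GnomAD": float(m)}))
        for mode in ALL_MODES:
            thr = 0.01 if mode in (AR, XLR) else 0.0001
            got = {v.key for v in frequency_filter(vs, mode, CFG)}
            assert got == {v.key for v in vs if v.effective_maf < thr}


class TestConsequenceFilter:
    def test_near_splice_intronic_kept(self):
        """An intronic change 8 bp from the acceptor is a splice candidate."""
        v = make_variant(consequence=Consequence.INTRONIC, splice_distance_bp=8,
                         gene="WHRN", hgvs_c="c.1417-8G>A")
        assert consequence_filter([v], CFG) == [v]

    def test_intronic_11bp_removed(self):
        v = make_variant(consequence=Consequence.INTRONIC, splice_distance_bp=11)
        assert consequence_filter([v], CFG) == []

    def test_synonymous_exon_boundary_kept_in_novel_tier(self):
        v = make_variant(gene="GENE0001", consequence=Consequence.SYNONYMOUS,
                         exon_boundary_offset=2)
        assert consequence_filter([v], CFG) == [v]

    def test_synonymous_off_boundary_removed_outside_disease_genes(self):
        v = make_variant(gene="GENE0001", consequence=Consequence.SYNONYMOUS)
        assert consequence_filter([v], CFG) == []

    def test_synonymous_always_kept_in_disease_genes(self):
        """e.g. an exonic synonymous change in PDE6B stays in play."""
        v = make_variant(gene="PDE6B", consequence=Consequence.SYNONYMOUS,
                         hgvs_c="c.1593A>T")
        assert consequence_filter([v], CFG) == [v]


class TestZygosityFilter:
    def test_lone_het_removed_for_recessive(self, trio):
        v = make_variant(genotypes={"C1": Genotype.HET})
        assert zygosity_filter([v], AR, trio.index) == []

    def test_homozygous_removed_for_dominant(self, trio):
        v = make_variant(genotypes={"C1": Genotype.HOM_ALT})
        assert zygosity_filter([v], AD, trio.index) == []

    def test_compound_het_pair_kept(self, trio):
        """Two heterozygous hits in the same gene are mutually compatible."""
        v1 = make_variant(pos=100, hgvs_c="c.2276G>T",
                          genotypes={"C1": Genotype.HET})
        v2 = make_variant(pos=200, hgvs_c="c.6967C>T",
                          genotypes={"C1": Genotype.HET})
        assert zygosity_filter([v1, v2], AR, trio.index) == [v1, v2]

    def test_xlr_keeps_hemizygous_male(self, trio):
        v = make_variant(chrom="X", genotypes={"C1": Genotype.HEM_ALT})
        assert zygosity_filter([v], XLR, trio.index) == [v]
        assert zygosity_filter([v], AR, trio.index) == []  # wrong chromosome

    def test_autosomal_hemizygous_is_data_error(self, trio):
        v = make_variant(chrom="2", genotypes={"C1": Genotype.HEM_ALT})
        with pytest.raises(ValueError):
            zygosity_filter([v], AR, trio.index)


class TestControlGenotypeFilter:
    def test_hemizygous_controls_fail_recessive(self):
        """Two hemizygous control carriers rule the variant out under XLR."""
        v = make_variant(chrom="X", gene="CITED1", hgvs_c="c.182C>T",
                         gnomad_het=9, gnomad_hem=2, gnomad_hom=0)
        assert control_genotype_filter([v], XLR) == []

    def test_het_only_controls_pass_recessive(self):
        v = make_variant(gene="WDFY3", hgvs_c="c.10465C>T",
                         gnomad_het=2, gnomad_hem=0, gnomad_hom=0)
        assert control_genotype_filter([v], AR) == [v]
        assert control_genotype_filter([v], AD) == []  # het controls bar dominant

    def test_absent_from_controls_passes_all_modes(self):
        v = make_variant(gnomad_het=0, gnomad_hem=0, gnomad_hom=0)
        for mode in ALL_MODES:
            assert control_genotype_filter([v], mode) == [v]

    def test_reported_pathogenic_bypasses(self):
        v = make_variant(gnomad_het=50, gnomad_hem=0, gnomad_hom=1,
                         reported_pathogenic=True)
        assert control_genotype_filter([v], AR) == [v]


class TestAcmg:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            ({"PVS1", "PS1"}, 5),
            (set(), 3),
            ({"BA1"}, 1),
            ({"PS1", "PS2"}, 5),
            ({"PVS1", "PM2"}, 4),
            ({"PS1", "PM1", "PM2"}, 4),
            ({"PM1", "PM2", "PM3"}, 4),
            ({"BS1", "BP4"}, 2),
            ({"BP4", "BP7"}, 2),
            ({"BP4"}, 3),
            ({"PM2"}, 3),
            ({"PVS1", "PS1", "BA1"}, 3),  # contradictory evidence
        ],
    )
    def test_combining_rules(self, codes, expected):
        assert acmg_combine(frozenset(codes)) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            acmg_combine({"PX9"})

    def test_filter_keeps_vus_and_above(self):
        keep = make_variant(acmg_class=3, gene="CHM", hgvs_c="c.1797C>G")
        drop = make_variant(pos=2, acmg_class=2)
        assert acmg_filter([keep, drop], CFG) == [keep]

    def test_fixture_classes_survive_filter(self):
        """Published candidate tables contain no benign/likely-benign class."""
        classes = {r.acmg_class for r in load_fixtures("table1")}
        assert classes <= {3, 4, 5}


class TestRecovery:
    def test_low_coverage_only_is_recoverable(self):
        v = make_variant(depth=8)
        assert recover_variants([(v, ["low_coverage"])], CFG) == [v]

    def test_reported_pathogenic_high_maf_is_recoverable(self):
        v = make_variant(maf_by_db={"GnomAD": 0.03}, reported_pathogenic=True)
        assert recover_variants([(v, ["maf"])], CFG) == [v]
        v2 = make_variant(maf_by_db={"GnomAD": 0.03})
        assert recover_variants([(v2, ["maf"])], CFG) == []

    def test_multiple_reasons_not_recoverable(self):
        v = make_variant(maf_by_db={"GnomAD": 0.03},
                         consequence=Consequence.SYNONYMOUS)
        assert recover_variants([(v, ["maf", "consequence"])], CFG) == []


class TestCascade:
    def test_planted_compound_het_is_unique_disease_gene_candidate(self):
        sim = simulate_family("AR_comphet", n_background=300, seed=7)
        res = run_cascade(sim.variants, sim.pedigree)
        planted_keys = {tuple(k) for k in sim.manifest.planted_keys}
        ar = res.candidates[InheritanceMode.AR]
        tier1 = [c for c in ar if c.tier == TIER_IRD]
        assert len(tier1) == 1
        assert {v.key for v in tier1[0].variants} == planted_keys
        assert tier1[0].is_compound_het
        assert not res.recovery_applied[InheritanceMode.AR]

    def test_empty_variant_table_is_noop(self, trio):
        res = run_cascade([], trio)
        assert res.all_candidates() == []
        assert not any(res.recovery_applied.values())

    def test_filters_return_subsets_and_audit_reconstructs_removals(self):
        sim = simulate_family("AR_hom", n_background=200, seed=3)
        res = run_cascade(sim.variants, sim.pedigree)
        all_keys = {v.key for v in sim.variants}
        for mode in ALL_MODES:
            candidate_keys = {
                v.key for c in res.candidates[mode] for v in c.variants
            }
            removed_keys = {v.key for v, _ in res.removed[mode]}
            assert candidate_keys <= all_keys
            assert removed_keys <= all_keys
            # every removed variant carries at least one machine-readable reason
            assert all(reasons for _, reasons in res.removed[mode])

    def test_lax_mode_is_superset(self):
        sim = simulate_family("XLR", n_background=250, seed=5)
        strict = run_cascade(sim.variants, sim.pedigree, lax=False)
        lax = run_cascade(sim.variants, sim.pedigree, lax=True)
        for mode in ALL_MODES:
            strict_keys = {
                frozenset(v.key for v in c.variants)
                for c in strict.candidates[mode]
            }
            lax_keys = {
                frozenset(v.key for v in c.variants) for c in lax.candidates[mode]
            }
            assert strict_keys <= lax_keys

    def test_region_restriction(self, trio):
        inside = make_variant(chrom="X", pos=50, gene="CITED1",
                              genotypes={"C1": Genotype.HEM_ALT,
                                         "F": Genotype.HOM_REF,
                                         "M": Genotype.HET})
        outside = make_variant(chrom="X", pos=5000, gene="RP2",
                               genotypes={"C1": Genotype.HEM_ALT,
                                          "F": Genotype.HOM_REF,
                                          "M": Genotype.HET})
        res = run_cascade([inside, outside], trio,
                          region=GenomicInterval("X", 1, 100))
        keys = {v.key for c in res.candidates[XLR] for v in c.variants}
        assert keys == {inside.key}


class TestCrossStrategy:
    def _result_with(self, trio, *variants):
        return run_cascade(list(variants), trio)

    def make_pair(self, trio):
        shared = make_variant(chrom="1", pos=100, gene="USH2A", hgvs_c="s",
                              genotypes={"C1": Genotype.HOM_ALT,
                                         "F": Genotype.HET, "M": Genotype.HET})
        only_a = make_variant(chrom="1", pos=200, gene="EYS", hgvs_c="a",
                              genotypes={"C1": Genotype.HOM_ALT,
                                         "F": Genotype.HET, "M": Genotype.HET})
        return shared, only_a

    def test_unshared_in_common_region_removed_when_phenotype_matches(self, trio):
        shared, only_a = self.make_pair(trio)
        ra = self._result_with(trio, shared, only_a)
        rb = self._result_with(trio, shared)
        common = [GenomicInterval("1", 1, 1000)]
        fa, fb = cross_strategy_compare(ra, rb, common, same_phenotype=True)
        keys_a = {v.key for c in fa.all_candidates() for v in c.variants}
        assert only_a.key not in keys_a and shared.key in keys_a

    def test_unshared_flagged_as_modifier_when_phenotypes_differ(self, trio):
        shared, only_a = self.make_pair(trio)
        ra = self._result_with(trio, shared, only_a)
        rb = self._result_with(trio, shared)
        common = [GenomicInterval("1", 1, 1000)]
        fa, _ = cross_strategy_compare(ra, rb, common, same_phenotype=False)
        flags = {
            v.key: c.modifier_flag
            for c in fa.all_candidates() for v in c.variants
        }
        assert flags[only_a.key] is True
        assert flags[shared.key] is False

    def test_unshared_outside_common_regions_kept_unflagged(self, trio):
        shared, only_a = self.make_pair(trio)
        ra = self._result_with(trio, shared, only_a)
        rb = self._result_with(trio, shared)
        common = [GenomicInterval("1", 1, 150)]  # excludes pos 200
        fa, _ = cross_strategy_compare(ra, rb, common, same_phenotype=True)
        keys_a = {v.key for c in fa.all_candidates() for v in c.variants}
        assert only_a.key in keys_a
        assert all(not c.modifier_flag for c in fa.all_candidates())
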