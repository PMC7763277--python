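"""STR haplotype reconstruction, shared regions and gene lookup."""

import numpy as np
import pytest

from ird_triage.str_linkage import (
    M1,
    M2,
    UNINFORMATIVE,
    SharedRegion,
    StrGenotypeTable,
    StrMarker,
    assign_haplotypes,
    genes_in_region,
    load_marker_map,
    load_x_gene_map,
    read_str_genotypes,
    shared_regions,
    write_str_genotypes,
)
from ird_triage.variant_model import (
    Affection,
    GenomicInterval,
    Individual,
    Karyotype,
    Pedigree,
)
from ird_triage.synthetic_data import (
    _family_structure,
    simulate_str_genotypes,
)

MARKERS = load_marker_map()


def xlr_family(fam="S"):
    return _family_structure("XLR", fam)


def xxy_family(fam="S"):
    return _family_structure("XLR_with_XXY", fam)


class TestMarkerMap:
    def test_packaged_map_has_26_ordered_markers(self):
        assert len(MARKERS) == 26
        pos = [m.position for m in MARKERS]
        assert pos == sorted(pos) and len(set(pos)) == 26
        names = {m.name for m in MARKERS}
        assert {"DXS990", "DXS1106", "DXS1210"} <= names

    def test_unordered_markers_rejected(self):
        with pytest.raises(ValueError):
            StrGenotypeTable(markers=[StrMarker("a", "X", 200),
                                      StrMarker("b", "X", 100)], alleles={})


class TestHaplotypeAssignment:
    def test_no_recombination_gives_contiguous_labels(self):
        ped = xlr_family()
        xo = {f"S_{c}": [{"start": h, "breaks": []}]
              for c, h in (("S1", M2), ("S2", M2), ("D1", M1), ("S3", M1))}
        sim = simulate_str_genotypes(ped, xo, seed=1)
        asg = assign_haplotypes(sim.table, ped)
        for child, labels in sim.truth.items():
            inferred = [asg[child][m.name] for m in MARKERS]
            informative = [x for x in inferred if x != UNINFORMATIVE]
            assert len(set(informative)) == 1

    def test_planted_crossovers_recovered_within_one_interval(self):
        """Inferred breakpoints fall in the marker interval containing truth."""
        ped = xlr_family()
        breaks = {"S_S1": 60_000_000, "S_S2": 100_000_000, "S_S3": 25_000_000}
        xo = {c: [{"start": M1, "breaks": [b]}] for c, b in breaks.items()}
        xo["S_D1"] = [{"start": M2, "breaks": []}]
        sim = simulate_str_genotypes(ped, xo, seed=2)
        asg = assign_haplotypes(sim.table, ped)
        # labels may be globally swapped; compare switch positions
        for child, b in breaks.items():
            labels = [asg[child][m.name] for m in MARKERS]
            switches = [
                (MARKERS[i - 1].position, MARKERS[i].position)
                for i in range(1, len(labels))
                if UNINFORMATIVE not in (labels[i - 1], labels[i])
                and labels[i - 1] != labels[i]
            ]
            assert len(switches) == 1
            lo, hi = switches[0]
            assert lo <= b <= hi

    def test_min_recombination_never_exceeds_planted(self):
        rng = np.random.default_rng(8)
        ped = xlr_family()
        for trial in range(30):
            xo = {}
            planted = 0
            for c in ("S_S1", "S_S2", "S_S3"):
                k = int(rng.integers(0, 3))
                planted += k
                bps = sorted(rng.integers(MARKERS[0].position + 1,
                                          MARKERS[-1].position - 1, k).tolist())
                xo[c] = [{"start": M1 if rng.random() < 0.5 else M2, "breaks": bps}]
            xo["S_D1"] = [{"start": M1, "breaks": []}]
            sim = simulate_str_genotypes(ped, xo, seed=100 + trial)
            asg = assign_haplotypes(sim.table, ped)
            inferred = 0
            for c in xo:
                labels = [asg[c][m.name] for m in MARKERS
                          if asg[c][m.name] != UNINFORMATIVE]
                inferred += sum(1 for a, b in zip(labels, labels[1:]) if a != b)
            assert inferred <= planted

    def test_xxy_child_gets_pairwise_labels(self):
        ped = xxy_family()
        xo = {
            "S_S1": [{"start": M2, "breaks": []}],
            "S_S2": [{"start": M1, "breaks": [50_000_000]},
                     {"start": M2, "breaks": []}],
            "S_D1": [{"start": M1, "breaks": []}],
        }
        sim = simulate_str_genotypes(ped, xo, seed=3)
        asg = assign_haplotypes(sim.table, ped)
        labels = [asg["S_S2"][m.name] for m in MARKERS]
        assert any(l in ("M1+M2", "M2+M1") for l in labels)
        assert any(l in ("M1+M1", "M2+M2") for l in labels)


def brute_force_regions(asg, markers, affected, excluders, ped):
    """Exhaustive per-marker status scan and maximal-run search."""
    out = []
    for hap in (M1, M2):
        status = []
        for mk in markers:
            ok, informative = True, False
            for a in affected:
                lab = asg[a][mk.name]
                if lab == UNINFORMATIVE:
                    continue
                parts = lab.split("+")
                has = (
                    all(p == hap for p in parts)
                    if ped[a].sex_karyotype in (Karyotype.XX, Karyotype.XXY)
                    and len(parts) == 2
                    else hap in parts
                )
                informative |= has
                ok &= has
            for e in excluders:
                lab = asg[e][mk.name]
                if lab == UNINFORMATIVE:
                    continue
                if hap in lab.split("+"):
                    ok = False
                else:
                    informative = True
            status.append(None if (ok and not informative) else ok)
        n = len(markers)
        for i in range(n):
            for j in range(i, n):
                if status[i] is not True or status[j] is not True:
                    continue
                if any(status[k] is False for k in range(i, j + 1)):
                    continue
                # maximality of the informative run
                if any(status[k] is True for k in range(0, i)
                       if not any(status[t] is False for t in range(k, i))):
                    continue
                if any(status[k] is True for k in range(j + 1, n)
                       if not any(status[t] is False for t in range(j + 1, k + 1))):
                    continue
                lo = i - 1
                while lo >= 0 and status[lo] is None:
                    lo -= 1
                hi = j + 1
                while hi < n and status[hi] is None:
                    hi += 1
                out.append((
                    hap,
                    markers[lo].position if lo >= 0 else 1,
                    markers[hi].position if hi < n else markers[-1].position + 1,
                ))
    return sorted(set(out))


class TestSharedRegions:
    def test_single_affected_no_crossover_spans_chromosome(self):
        ped = xlr_family()
        xo = {"S_S1": [{"start": M2, "breaks": []}]}
        sim = simulate_str_genotypes(ped, xo, seed=4)
        asg = assign_haplotypes(sim.table, ped)
        regs = shared_regions(asg, MARKERS, affected=["S_S1"], pedigree=ped)
        assert len(regs) == 1
        r = regs[0]
        assert r.bounding_markers == ("pter", "qter")
        assert r.interval.start == 1

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(23)
        ped = xlr_family()
        children = ["S_S1", "S_S2", "S_D1", "S_S3"]
        for trial in range(60):
            xo = {}
            for c in children:
                k = int(rng.integers(0, 3))
                bps = sorted(rng.integers(MARKERS[0].position + 1,
                                          MARKERS[-1].position - 1, k).tolist())
                xo[c] = [{"start": M1 if rng.random() < 0.5 else M2, "breaks": bps}]
            sim = simulate_str_genotypes(ped, xo, seed=500 + trial,
                                         het_fraction=0.8)
            asg = assign_haplotypes(sim.table, ped)
            regs = shared_regions(
                asg, MARKERS, affected=["S_S1", "S_S2"],
                unaffected_excluders=["S_D1", "S_S3"], pedigree=ped,
            )
            got = sorted({(r.haplotype, r.interval.start, r.interval.end)
                          for r in regs})
            assert got == brute_force_regions(
                asg, MARKERS, ["S_S1", "S_S2"], ["S_D1", "S_S3"], ped
            ), trial

    def test_antitone_in_excluders(self):
        """Adding an excluder never enlarges any shared region."""
        ped = xlr_family()
        xo = {
            "S_S1": [{"start": M2, "breaks": [90_000_000]}],
            "S_S2": [{"start": M2, "breaks": [120_000_000]}],
            "S_D1": [{"start": M2, "breaks": [60_000_000]}],
            "S_S3": [{"start": M1, "breaks": []}],
        }
        sim = simulate_str_genotypes(ped, xo, seed=6)
        asg = assign_haplotypes(sim.table, ped)
        base = shared_regions(asg, MARKERS, ["S_S1", "S_S2"], [], pedigree=ped)
        more = shared_regions(asg, MARKERS, ["S_S1", "S_S2"], ["S_D1"], pedigree=ped)

        def covered(regs, hap):
            return [(r.interval.start, r.interval.end) for r in regs
                    if r.haplotype == hap]

        for hap in (M1, M2):
            for s, e in covered(more, hap):
                assert any(s2 <= s and e <= e2 for s2, e2 in covered(base, hap))

    def test_xxy_block_shared_homozygously(self):
        """The planted risk block is homozygous in the XXY brother,
        hemizygous in the XY brother and absent in the excluded sister."""
        ped = xxy_family("F35")
        xo = {
            "F35_S1": [{"start": M2, "breaks": [110_000_000]}],
            "F35_S2": [{"start": M1, "breaks": [40_000_000]},
                       {"start": M2, "breaks": []}],
            "F35_D1": [{"start": M1, "breaks": []}],
        }
        sim = simulate_str_genotypes(ped, xo, seed=9)
        asg = assign_haplotypes(sim.table, ped)
        regs = shared_regions(asg, MARKERS, ["F35_S1", "F35_S2"],
                              ["F35_D1"], pedigree=ped)
        assert len(regs) == 1
        r = regs[0]
        assert r.interval.start <= 42_500_000 and r.interval.end >= 107_800_000


class TestGenesInRegion:
    def test_mid_x_block_contains_disease_genes_and_candidate(self):
        gene_map = load_x_gene_map()
        region = SharedRegion(
            interval=GenomicInterval("X", 38_900_000, 113_200_000),
            haplotype=M2, carriers=frozenset(), excluded=frozenset(),
            bounding_markers=("DXS986", "DXS7132"),
        )
        genes = genes_in_region([region], gene_map)
        found = set(next(iter(genes.values())))
        assert {"NYX", "NDP", "RP2", "CACNA1F", "PGK1", "CHM", "TIMM8A",
                "PRPS1", "CITED1"} <= found
        assert "RPGR" not in found

    def test_empty_region_list(self):
        assert genes_in_region([], load_x_gene_map()) == {}

    def test_matches_bruteforce_overlap(self):
        rng = np.random.default_rng(31)
        gene_map = {
            f"G{i}": GenomicInterval("X", int(s), int(s) + int(rng.integers(1, 5_000_000)))
            for i, s in enumerate(rng.integers(1, 150_000_000, 40))
        }
        for _ in range(20):
            s = int(rng.integers(1, 140_000_000))
            region = SharedRegion(
                interval=GenomicInterval("X", s, s + int(rng.integers(1, 30_000_000))),
                haplotype=M1, carriers=frozenset(), excluded=frozenset(),
                bounding_markers=("a", "b"),
            )
            got = set(next(iter(genes_in_region([region], gene_map).values())))
            expect = {g for g, iv in gene_map.items() if iv.overlaps(region.interval)}
            assert got == expect


class TestStrIO:
    def test_tsv_roundtrip(self, tmp_path):
        ped = xxy_family()
        xo = {
            "S_S1": [{"start": M2, "breaks": []}],
            "S_S2": [{"start": M1, "breaks": []}, {"start": M2, "breaks": []}],
            "S_D1": [{"start": M1, "breaks": []}],
        }
        sim = simulate_str_genotypes(ped, xo, seed=13)
        path = tmp_path / "str.tsv"
        write_str_genotypes(sim.table, path)
        again = read_str_genotypes(path, MARKERS)
        assert again.alleles == sim.table.alleles
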