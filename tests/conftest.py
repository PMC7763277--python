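import pytest

from ird_triage.variant_model import (
    Affection,
    AnnotatedVariant,
    Consequence,
    Genotype,
    Individual,
    Karyotype,
    Pedigree,
)


def make_variant(**kw) -> AnnotatedVariant:
    """Variant factory with filter-passing defaults."""
    defaults = dict(
        chrom="1",
        pos=1_000_000,
        ref="G",
        alt="T",
        gene="USH2A",
        consequence=Consequence.MISSENSE,
        depth=100,
        fs_phred=3.0,
        genotypes={},
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        family_id="T1",
        members=[
            Individual("C1", "T1", "F", "M", Karyotype.XY, Affection.AFFECTED),
            Individual("F", "T1", None, None, Karyotype.XY, Affection.UNAFFECTED),
            Individual("M", "T1", None, None, Karyotype.XX, Affection.UNAFFECTED),
        ],
    )


@pytest.fixture
def quartet() -> Pedigree:
    """Parents + affected child (index) + unaffected sib."""
    return Pedigree(
        family_id="Q1",
        members=[
            Individual("C1", "Q1", "F", "M", Karyotype.XY, Affection.AFFECTED),
            Individual("C2", "Q1", "F", "M", Karyotype.XX, Affection.UNAFFECTED),
            Individual("F", "Q1", None, None, Karyotype.XY, Affection.UNAFFECTED),
            Individual("M", "Q1", None, None, Karyotype.XX, Affection.UNAFFECTED),
        ],
    )


GT = Genotype
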