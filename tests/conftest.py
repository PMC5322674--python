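"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import pytest

from famvar.io_formats import (
    AnnotationRecord,
    Genotype,
    Member,
    Pedigree,
    VariantSite,
)

G = {
    0: Genotype.HOM_REF,
    1: Genotype.HET,
    2: Genotype.HOM_ALT,
    -1: Genotype.MISSING,
}


def make_site(pos=100, chrom="chr1", gts=None, ref="A", alt="G", **ann):
    """Build a VariantSite from an {id: 0/1/2/-1} genotype dict."""
    gts = gts or {}
    return VariantSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={k: G[v] if isinstance(v, int) else v for k, v in gts.items()},
        ann=AnnotationRecord(**ann),
    )


@pytest.fixture
def trio_ped():
    return Pedigree(
        [
            Member("FA", sex="male"),
            Member("MO", sex="female"),
            Member("CH", father="FA", mother="MO", sex="male",
                   phenotypes=frozenset({"affected"})),
        ]
    )


@pytest.fixture
def quartet_ped():
    """Father, mother, affected child, unaffected sibling."""
    return Pedigree(
        [
            Member("FA", sex="male"),
            Member("MO", sex="female"),
            Member("CH", father="FA", mother="MO", sex="male",
                   phenotypes=frozenset({"affected"})),
            Member("SI", father="FA", mother="MO", sex="female"),
        ]
    )


@pytest.fixture
def small_kb():
    """Hand-checkable KB: 3 genes, 2 diseases, 3 terms, one gene-gene link."""
    from famvar.pheno_prioritize import (
        DiseaseTermLink,
        GeneDiseaseLink,
        GeneGeneLink,
        KnowledgeBase,
    )

    return KnowledgeBase(
        gene_disease=[
            GeneDiseaseLink("g1", "d1", 0.8),
            GeneDiseaseLink("g2", "d1", 0.4),
            GeneDiseaseLink("g2", "d2", 0.6),
            GeneDiseaseLink("g3", "d2", 1.0),
        ],
        disease_term=[
            DiseaseTermLink("d1", "t1", 0.9),
            DiseaseTermLink("d1", "t2", 0.5),
            DiseaseTermLink("d2", "t2", 0.7),
            DiseaseTermLink("d2", "t3", 1.0),
        ],
        gene_gene=[GeneGeneLink("g1", "g4", "biosystem", 0.5)],
    )


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive re-derivations, kept separate from
# the implementations they check)
# ---------------------------------------------------------------------------

# literal 27-entry truth table for informative-site classification under a
# paternal-allele deletion: (father, sibling, proband) -> (class, consistent)
# or None when not informative.  Derived by hand: informative requires the
# father homozygous and the sibling heterozygous; a proband hemizygous for
# the maternal allele shows hom-alt (class A consistent) where the father is
# hom-ref, hom-ref (class B consistent) where the father is hom-alt, and a
# het proband is impossible under hemizygosity (inconsistent in both).
INFORMATIVE_TRUTH_TABLE = {}
for fa in (0, 1, 2):
    for si in (0, 1, 2):
        for pr in (0, 1, 2):
            if si != 1 or fa == 1:
                INFORMATIVE_TRUTH_TABLE[(fa, si, pr)] = None
            elif fa == 0:
                INFORMATIVE_TRUTH_TABLE[(fa, si, pr)] = ("A", pr == 2)
            else:
                INFORMATIVE_TRUTH_TABLE[(fa, si, pr)] = ("B", pr == 0)


def mendel_possible_oracle(child: int, father: int, mother: int) -> bool:
    """Naive enumeration of transmissible allele pairs; -1 = missing."""
    sets = {0: [(0, 0)], 1: [(0, 1)], 2: [(1, 1)], -1: [(0, 0), (0, 1), (1, 1)]}
    for fa in sets[father]:
        for mo in sets[mother]:
            for a in set(fa):
                for b in set(mo):
                    if a + b == child:
                        return True
    return False


def pascal_comb(n: int, k: int) -> int:
    """Binomial coefficient by the Pascal recurrence (test oracle)."""
    row = [1]
    for _ in range(n):
        row = [1] + [row[i] + row[i + 1] for i in range(len(row) - 1)] + [1]
    return row[k]
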