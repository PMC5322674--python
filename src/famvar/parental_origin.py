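"""Parent-of-origin inference for hemizygous regions.

When one parent is unsequenced, the deleted parental allele of a
hemizygous child can still be inferred from Mendelian-inconsistency
informative sites: positions where the sequenced parent is homozygous and
an unaffected sibling is heterozygous.  Under a deletion of the sequenced
parent's allele the child shows only the other parent's allele, so

* class A (parent hom-ref, sibling het): consistency <=> child hom-alt —
  a genotype impossible under diploid transmission from a hom-ref parent;
* class B (parent hom-alt, sibling het): consistency <=> child hom-ref.

A child heterozygote inside the region is counted as inconsistent (not
dropped): hemizygosity admits no heterozygote, so it is evidence against
the call.  Sites with a missing genotype in any of the three individuals
are dropped from classification, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

from famvar.errors import ValidationError
from famvar.io_formats import Genotype, Pedigree, VariantSite


# ---------------------------------------------------------------------------
# informative sites
# ---------------------------------------------------------------------------


@dataclass
class InformativeSite:
    site: VariantSite
    klass: str  # "A" (parent hom_ref) | "B" (parent hom_alt)
    proband_gt: Genotype
    consistent: bool  # with deletion of the classified parent's allele


def classify_informative_sites(
    sites: list[VariantSite],
    region: tuple[str, int, int],
    parent_id: str,
    sibling_id: str,
    proband_id: str,
) -> list[InformativeSite]:
    """Informative sites within ``region = (chrom, start, end)``.

    Only sites where ``parent_id`` is homozygous, ``sibling_id`` is
    heterozygous and all three genotypes are non-missing are retained.
    ``consistent`` refers to deletion of the classified parent's allele
    in the proband.
    """
    chrom, start, end = region
    if start > end:
        raise ValidationError(f"invalid region {chrom}:{start}-{end}")
    out: list[InformativeSite] = []
    for s in sites:
        if s.chrom != chrom or not (start <= s.pos <= end):
            continue
        pg = s.gt(parent_id)
        sg = s.gt(sibling_id)
        cg = s.gt(proband_id)
        if pg.is_missing or sg.is_missing or cg.is_missing:
            continue
        if sg is not Genotype.HET:
            continue
        if pg is Genotype.HOM_REF:
            out.append(
                InformativeSite(
                    site=s, klass="A", proband_gt=cg,
                    consistent=cg is Genotype.HOM_ALT,
                )
            )
        elif pg is Genotype.HOM_ALT:
            out.append(
                InformativeSite(
                    site=s, klass="B", proband_gt=cg,
                    consistent=cg is Genotype.HOM_REF,
                )
            )
    return out


# ---------------------------------------------------------------------------
# origin call
# ---------------------------------------------------------------------------


@dataclass
class OriginCallResult:
    n_A: int
    n_A_consistent: int
    n_B: int
    n_B_consistent: int
    frac_A: float | None
    frac_B: float | None
    frac_combined: float | None
    call: str  # paternal_deleted | maternal_deleted | no_call
    min_sites_used: int
    threshold_used: float
    frac_maternal_test: float | None = None

    @property
    def n_total(self) -> int:
        return self.n_A + self.n_B


def _fractions(informative: list[InformativeSite]):
    n_a = sum(1 for i in informative if i.klass == "A")
    n_ac = sum(1 for i in informative if i.klass == "A" and i.consistent)
    n_b = sum(1 for i in informative if i.klass == "B")
    n_bc = sum(1 for i in informative if i.klass == "B" and i.consistent)
    frac_a = n_ac / n_a if n_a else None
    frac_b = n_bc / n_b if n_b else None
    frac = (n_ac + n_bc) / (n_a + n_b) if (n_a + n_b) else None
    return n_a, n_ac, n_b, n_bc, frac_a, frac_b, frac


def call_origin(
    informative: list[InformativeSite],
    maternal_informative: list[InformativeSite] | None = None,
    min_sites: int = 50,
    min_frac: float = 0.8,
) -> OriginCallResult:
    """Decide which parental allele is deleted.

    ``informative`` must come from classification against the father;
    ``maternal_informative`` (optional — requires mother genotypes) from
    the mirrored classification against the mother.  Insufficient data is
    a ``no_call``, never an exception.
    """
    n_a, n_ac, n_b, n_bc, frac_a, frac_b, frac = _fractions(informative)
    call = "no_call"
    frac_mat = None
    if frac is not None and frac >= min_frac and (n_a + n_b) >= min_sites:
        call = "paternal_deleted"
    elif maternal_informative is not None:
        m = _fractions(maternal_informative)
        frac_mat = m[6]
        if frac_mat is not None and frac_mat >= min_frac and (m[0] + m[2]) >= min_sites:
            call = "maternal_deleted"
    return OriginCallResult(
        n_A=n_a,
        n_A_consistent=n_ac,
        n_B=n_b,
        n_B_consistent=n_bc,
        frac_A=frac_a,
        frac_B=frac_b,
        frac_combined=frac,
        call=call,
        min_sites_used=min_sites,
        threshold_used=min_frac,
        frac_maternal_test=frac_mat,
    )


# ---------------------------------------------------------------------------
# Mendelian violation scan
# ---------------------------------------------------------------------------


def _possible(child: Genotype, father: Genotype, mother: Genotype) -> bool:
    """Is ``child`` possible under bi-allelic transmission?  MISSING parents
    are unconstrained."""

    def alleles(g: Genotype) -> set[int]:
        if g is Genotype.MISSING:
            return {0, 1}
        if g is Genotype.HOM_REF:
            return {0}
        if g is Genotype.HOM_ALT:
            return {1}
        return {0, 1}

    fa, mo = alleles(father), alleles(mother)
    targets = {
        Genotype.HOM_REF: [(0, 0)],
        Genotype.HET: [(0, 1), (1, 0)],
        Genotype.HOM_ALT: [(1, 1)],
    }[child]
    return any(a in fa and b in mo for a, b in targets)


@dataclass
class ViolationReport:
    child: str
    n_checked: int
    n_violations: int
    violation_sites: list[int]  # positions

    @property
    def rate(self) -> float:
        return self.n_violations / self.n_checked if self.n_checked else 0.0


def mendelian_violation_scan(
    sites: list[VariantSite], pedigree: Pedigree
) -> dict[str, ViolationReport]:
    """Per-child violation scan against whichever parents are genotyped.

    A violation is any child genotype impossible under bi-allelic
    transmission given the available (non-missing) parental genotypes;
    the rate denominator counts sites where the child and at least one
    parent are non-missing.
    """
    children = [
        m for m in pedigree if m.father is not None or m.mother is not None
    ]
    if not children:
        raise ValidationError("pedigree has no parent-child pairs")
    reports: dict[str, ViolationReport] = {}
    for child in children:
        n_checked = 0
        bad: list[int] = []
        for s in sites:
            cg = s.genotypes.get(child.id, Genotype.MISSING)
            if cg.is_missing:
                continue
            fg = (
                s.genotypes.get(child.father, Genotype.MISSING)
                if child.father
                else Genotype.MISSING
            )
            mg = (
                s.genotypes.get(child.mother, Genotype.MISSING)
                if child.mother
                else Genotype.MISSING
            )
            if fg.is_missing and mg.is_missing:
                continue
            n_checked += 1
            if not _possible(cg, fg, mg):
                bad.append(s.pos)
        reports[child.id] = ViolationReport(
            child=child.id, n_checked=n_checked, n_violations=len(bad),
            violation_sites=bad,
        )
    return reports
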