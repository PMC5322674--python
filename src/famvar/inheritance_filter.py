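"""Inheritance-model partitioning and the variant filtering cascade.

Variants are partitioned by disease inheritance model across the pedigree
(autosomal dominant, autosomal recessive, de novo, compound heterozygous,
X-linked dominant) and then pass an allele-frequency stage, an evidence
stage and — on a parallel track that never un-removes anything — a
clinical-significance report.

Boundary semantics are strict per the source wording: frequency "> 0.01"
is excluded (0.01 kept), CADD "greater than 15" keeps only > 15, adjusted
p "lower than 0.05" keeps only < 0.05.  A variant absent from both
frequency databases is treated as frequency 0 (novel), not removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from famvar.errors import ValidationError
from famvar.io_formats import Genotype, Pedigree, VariantSite, is_x_chrom

log = logging.getLogger(__name__)

MODELS = (
    "autosomal_dominant",
    "autosomal_recessive",
    "de_novo",
    "compound_het",
    "x_linked_dominant",
)

SiteKey = tuple[str, int, str, str]


# ---------------------------------------------------------------------------
# model partitioning
# ---------------------------------------------------------------------------


@dataclass
class CompoundHetPair:
    partner: SiteKey
    individual: str
    phased: bool  # True when transmission places the two variants in trans


@dataclass
class ModelAssignment:
    site: VariantSite
    models: set[str]
    detail: dict[str, dict] = field(default_factory=dict)
    compound_partners: list[CompoundHetPair] = field(default_factory=list)

    @property
    def key(self) -> SiteKey:
        return self.site.key


def _gt(site: VariantSite, mid: str) -> Genotype:
    return site.genotypes.get(mid, Genotype.MISSING)


def _is_dominant(
    site: VariantSite,
    pedigree: Pedigree,
    label: str,
    max_unaffected_carriers: int = 0,
) -> tuple[bool, dict]:
    """All affected carry >= 1 alt (genotyped, non-missing); at most
    ``max_unaffected_carriers`` genotyped unaffected carry."""
    affected = pedigree.affected(label)
    supporting, contradicting = [], []
    for m in affected:
        g = _gt(site, m.id)
        if g.is_missing or not g.carries_alt:
            contradicting.append(m.id)
        else:
            supporting.append(m.id)
    unaffected_carriers = [
        m.id
        for m in pedigree.unaffected(label)
        if not _gt(site, m.id).is_missing and _gt(site, m.id).carries_alt
    ]
    ok = (
        bool(affected)
        and not contradicting
        and len(unaffected_carriers) <= max_unaffected_carriers
    )
    return ok, {
        "supporting": supporting,
        "contradicting": contradicting,
        "unaffected_carriers": unaffected_carriers,
    }


def _transmission_origin(site: VariantSite, member) -> str:
    """Origin of a het variant in ``member`` by transmission, when parental
    genotypes permit: 'paternal', 'maternal' or 'ambiguous'."""
    fg = _gt(site, member.father) if member.father else Genotype.MISSING
    mg = _gt(site, member.mother) if member.mother else Genotype.MISSING
    if fg.is_missing or mg.is_missing:
        return "ambiguous"
    if fg.carries_alt and not mg.carries_alt:
        return "paternal"
    if mg.carries_alt and not fg.carries_alt:
        return "maternal"
    return "ambiguous"


def partition_by_model(
    sites: list[VariantSite],
    pedigree: Pedigree,
    phenotype_label: str,
    gene_map: dict[SiteKey, str] | None = None,
    max_unaffected_carriers: int = 0,
) -> list[ModelAssignment]:
    """Assign each variant the subset of inheritance models it satisfies.

    Model definitions (genotyped = non-missing):

    * ``de_novo`` — some affected member with both parents genotyped is
      het/hom-alt while both parents are hom-ref;
    * ``autosomal_dominant`` — every affected carries >= 1 alt and no
      genotyped unaffected carries (``max_unaffected_carriers`` relaxes
      this for reduced penetrance);
    * ``autosomal_recessive`` — every affected is hom-alt, no genotyped
      unaffected is hom-alt, and every genotyped parent of an affected
      carries >= 1 alt;
    * ``compound_het`` — two distinct het variants in the same gene in an
      affected member, flagged phased when transmission places them on
      opposite parental sides, ``unphased`` when parents do not resolve it
      (pairs proven cis are excluded);
    * ``x_linked_dominant`` — dominant logic restricted to X-labelled
      chromosomes; an affected male's het call counts as hemizygous alt.

    Models may overlap.  Returns one assignment per variant with at least
    one model.
    """
    affected = pedigree.affected(phenotype_label)
    if not any(m.is_affected(phenotype_label) for m in pedigree):
        raise ValidationError(f"no member affected for phenotype {phenotype_label!r}")
    gene_map = gene_map or {}

    assignments: dict[SiteKey, ModelAssignment] = {}

    def assign(site: VariantSite, model: str, detail: dict) -> ModelAssignment:
        a = assignments.setdefault(site.key, ModelAssignment(site=site, models=set()))
        a.models.add(model)
        a.detail[model] = detail
        return a

    for site in sites:
        on_x = is_x_chrom(site.chrom)

        # de novo
        for m in affected:
            if m.father is None or m.mother is None:
                continue
            g = _gt(site, m.id)
            fg, mg = _gt(site, m.father), _gt(site, m.mother)
            if (
                g in (Genotype.HET, Genotype.HOM_ALT)
                and fg is Genotype.HOM_REF
                and mg is Genotype.HOM_REF
            ):
                assign(site, "de_novo", {"child": m.id})
                break

        # dominant (autosomal and X-linked variants share the predicate; an
        # affected male het on X is hemizygous-equivalent, which carries_alt
        # already accepts)
        ok, detail = _is_dominant(site, pedigree, phenotype_label, max_unaffected_carriers)
        if ok:
            assign(site, "x_linked_dominant" if on_x else "autosomal_dominant", detail)

        # recessive
        if not on_x:
            rec_ok = bool(affected)
            supporting = []
            for m in affected:
                if _gt(site, m.id) is not Genotype.HOM_ALT:
                    rec_ok = False
                    break
                supporting.append(m.id)
            if rec_ok:
                for m in pedigree.unaffected(phenotype_label):
                    if _gt(site, m.id) is Genotype.HOM_ALT:
                        rec_ok = False
                        break
            if rec_ok:
                for m in affected:
                    for p in (m.father, m.mother):
                        if p is None:
                            continue
                        pg = _gt(site, p)
                        if not pg.is_missing and not pg.carries_alt:
                            rec_ok = False
            if rec_ok:
                assign(site, "autosomal_recessive", {"supporting": supporting})

    # compound het: per affected member, per gene, pairs of distinct hets
    by_gene: dict[tuple[str, str], list[VariantSite]] = {}
    for site in sites:
        gene = gene_map.get(site.key, site.ann.gene)
        if gene is None:
            continue
        for m in affected:
            if _gt(site, m.id) is Genotype.HET:
                by_gene.setdefault((m.id, gene), []).append(site)
    for (mid, gene), gsites in by_gene.items():
        if len(gsites) < 2:
            continue
        member = pedigree[mid]
        for i, s1 in enumerate(gsites):
            for s2 in gsites[i + 1 :]:
                o1 = _transmission_origin(s1, member)
                o2 = _transmission_origin(s2, member)
                if {o1, o2} == {"paternal", "maternal"}:
                    phased = True
                elif "ambiguous" in (o1, o2):
                    phased = False  # reported unphased, not dropped
                else:
                    continue  # proven cis
                for sa, sb in ((s1, s2), (s2, s1)):
                    a = assignments.setdefault(
                        sa.key, ModelAssignment(site=sa, models=set())
                    )
                    a.models.add("compound_het")
                    a.detail.setdefault("compound_het", {"gene": gene})
                    a.compound_partners.append(
                        CompoundHetPair(partner=sb.key, individual=mid, phased=phased)
                    )
    return list(assignments.values())


# ---------------------------------------------------------------------------
# filter trace
# ---------------------------------------------------------------------------


@dataclass
class TraceStage:
    label: str
    n_in: int
    kept: list  # assignment units (model, ModelAssignment) or VariantSite
    removed: list[tuple[object, list[str]]]

    def check_conservation(self) -> None:
        if len(self.kept) + len(self.removed) != self.n_in:
            raise ValidationError(
                f"stage {self.label}: kept {len(self.kept)} + removed "
                f"{len(self.removed)} != input {self.n_in}"
            )

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


@dataclass
class FilterTrace:
    stages: list[TraceStage] = field(default_factory=list)

    def add(self, stage: TraceStage) -> TraceStage:
        stage.check_conservation()
        self.stages.append(stage)
        return stage

    def summary(self) -> list[dict]:
        return [
            {
                "stage": s.label,
                "n_in": s.n_in,
                "kept": s.n_kept,
                "removed": s.n_removed,
            }
            for s in self.stages
        ]


ModelUnit = tuple[str, ModelAssignment]  # (model, assignment)

_AF_STRICT = 0.01  # dominant / de novo / X-linked
_AF_RELAXED = 0.05  # recessive / compound het


def af_filter(units: list[ModelUnit], trace: FilterTrace | None = None) -> TraceStage:
    """Population-frequency stage on (model, assignment) units.

    Keep iff both database frequencies are <= 0.01 for dominant, de novo
    and X-linked units, <= 0.05 for recessive and compound-het units.
    Missing frequency counts as 0 (absent from database).
    """
    kept, removed = [], []
    for model, a in units:
        cutoff = _AF_RELAXED if model in ("autosomal_recessive", "compound_het") else _AF_STRICT
        af1 = a.site.ann.af_db1 or 0.0
        af2 = a.site.ann.af_db2 or 0.0
        reasons = []
        if af1 > cutoff:
            reasons.append(f"af_db1>{cutoff}")
        if af2 > cutoff:
            reasons.append(f"af_db2>{cutoff}")
        if reasons:
            removed.append(((model, a), reasons))
        else:
            kept.append((model, a))
    stage = TraceStage(label="af_filter", n_in=len(units), kept=kept, removed=removed)
    if trace is not None:
        trace.add(stage)
    else:
        stage.check_conservation()
    return stage


def evidence_filter(units: list[ModelUnit], trace: FilterTrace | None = None) -> TraceStage:
    """Evidence stage: keep iff >= 2 supporting callers AND adjusted
    p < 0.05 AND (impact medium/high OR loss-of-function) AND CADD > 15.
    A missing numeric field fails its criterion (reported as a reason)."""
    kept, removed = [], []
    for model, a in units:
        ann = a.site.ann
        reasons = []
        if len(ann.callers) < 2:
            reasons.append("caller_concordance")
        if ann.p_adj is None or not ann.p_adj < 0.05:
            reasons.append("p_adj")
        if not ((ann.impact in ("medium", "high")) or ann.is_lof):
            reasons.append("impact")
        if ann.cadd is None or not ann.cadd > 15:
            reasons.append("cadd")
        if reasons:
            removed.append(((model, a), reasons))
        else:
            kept.append((model, a))
    stage = TraceStage(label="evidence_filter", n_in=len(units), kept=kept, removed=removed)
    if trace is not None:
        trace.add(stage)
    else:
        stage.check_conservation()
    return stage


RESCUE_LABELS = ("pathogenic", "probably_pathogenic", "mixed", "drug_response")


@dataclass
class RescueEntry:
    site: VariantSite
    label: str
    removed_at: list[str]  # stages that removed the variant earlier, if any


def clinvar_rescue(
    all_sites: list[VariantSite], trace: FilterTrace
) -> list[RescueEntry]:
    """Parallel clinical-significance report: variants labelled pathogenic,
    probably-pathogenic, mixed or drug-response are listed regardless of
    earlier removal.  This never re-inserts a variant into the model
    pipeline."""
    removed_at: dict[SiteKey, list[str]] = {}
    for stage in trace.stages:
        for unit, _reasons in stage.removed:
            if isinstance(unit, VariantSite):
                key = unit.key
            elif isinstance(unit, tuple):
                key = unit[1].key
            else:
                key = unit.key
            removed_at.setdefault(key, []).append(stage.label)
    out = []
    for s in all_sites:
        if s.ann.clinvar in RESCUE_LABELS:
            out.append(
                RescueEntry(
                    site=s, label=s.ann.clinvar, removed_at=removed_at.get(s.key, [])
                )
            )
    return out


def indel_qc_filter(
    sites: list[VariantSite],
    trace: FilterTrace | None = None,
    caller_label: str = "scalpel",
    conjunction: bool = True,
) -> TraceStage:
    """Assembly-caller INDEL QC: records carrying ``caller_label`` are
    removed iff alt coverage < 5 AND chi-square > 10.8 (as printed; set
    ``conjunction=False`` for the OR reading).  Other records untouched."""
    kept, removed = [], []
    for s in sites:
        if caller_label in s.ann.callers:
            low_cov = s.ann.alt_coverage is not None and s.ann.alt_coverage < 5
            high_chi = s.ann.chi2 is not None and s.ann.chi2 > 10.8
            bad = (low_cov and high_chi) if conjunction else (low_cov or high_chi)
            if bad:
                reasons = []
                if low_cov:
                    reasons.append("alt_coverage<5")
                if high_chi:
                    reasons.append("chi2>10.8")
                removed.append((s, reasons))
                continue
        kept.append(s)
    stage = TraceStage(label="indel_qc", n_in=len(sites), kept=kept, removed=removed)
    if trace is not None:
        trace.add(stage)
    else:
        stage.check_conservation()
    return stage


# ---------------------------------------------------------------------------
# cascade driver
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    per_model: dict[str, list[ModelAssignment]]
    rescue: list[RescueEntry]
    trace: FilterTrace


def run_filter_cascade(
    sites: list[VariantSite],
    pedigree: Pedigree,
    phenotype_label: str,
    gene_map: dict[SiteKey, str] | None = None,
    max_unaffected_carriers: int = 0,
    indel_conjunction: bool = True,
) -> CascadeResult:
    """Full cascade: INDEL QC -> model partition -> AF stage -> evidence
    stage, plus the parallel clinical-significance report."""
    trace = FilterTrace()
    qc = indel_qc_filter(sites, trace, conjunction=indel_conjunction)
    assignments = partition_by_model(
        [s for s in qc.kept],
        pedigree,
        phenotype_label,
        gene_map=gene_map,
        max_unaffected_carriers=max_unaffected_carriers,
    )
    units: list[ModelUnit] = [
        (model, a) for a in assignments for model in sorted(a.models)
    ]
    trace.add(
        TraceStage(
            label="partition_by_model",
            n_in=len(units),
            kept=units,
            removed=[],
        )
    )
    af_stage = af_filter(units, trace)
    ev_stage = evidence_filter(af_stage.kept, trace)
    per_model: dict[str, list[ModelAssignment]] = {m: [] for m in MODELS}
    for model, a in ev_stage.kept:
        per_model[model].append(a)
    rescue = clinvar_rescue(sites, trace)
    return CascadeResult(per_model=per_model, rescue=rescue, trace=trace)
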