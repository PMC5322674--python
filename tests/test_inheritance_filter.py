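"""Tests for model partitioning and the filtering cascade."""

import itertools

import numpy as np
import pytest

from famvar.errors import ValidationError
from famvar.io_formats import Genotype, Member, Pedigree
from famvar.inheritance_filter import (
    FilterTrace,
    af_filter,
    clinvar_rescue,
    evidence_filter,
    indel_qc_filter,
    partition_by_model,
    run_filter_cascade,
)
from famvar.synthetic_data import (
    SimulationSpec,
    annotate_variants,
    emitted_sites,
    generate_pedigree_genotypes,
    pedigree_preset,
)

from conftest import make_site


def models_of(assignments, site):
    for a in assignments:
        if a.site is site:
            return a.models
    return set()


# ---------------------------------------------------------------------------
# partitioning examples
# ---------------------------------------------------------------------------


class TestPartitionExamples:
    def test_trio_de_novo(self, trio_ped):
        site = make_site(gts={"FA": 0, "MO": 0, "CH": 1})
        (a,) = partition_by_model([site], trio_ped, "affected")
        assert "de_novo" in a.models

    def test_de_novo_requires_both_parents_genotyped(self, trio_ped):
        site = make_site(gts={"FA": 0, "MO": -1, "CH": 1})
        assignments = partition_by_model([site], trio_ped, "affected")
        assert all("de_novo" not in a.models for a in assignments)

    def test_recessive_family_fixture(self):
        # affected mother homozygous; relatives het or hom-ref
        ped = Pedigree(
            [
                Member("GF", sex="male"),
                Member("GM", sex="female"),
                Member("MO", father="GF", mother="GM", sex="female",
                       phenotypes=frozenset({"hh"})),
                Member("BR", father="GF", mother="GM", sex="male"),
            ]
        )
        site = make_site(gts={"GF": 1, "GM": 1, "MO": 2, "BR": 1})
        (a,) = partition_by_model([site], ped, "hh")
        assert "autosomal_recessive" in a.models

    def test_dominant_blocked_by_unaffected_carrier(self, quartet_ped):
        site = make_site(gts={"FA": 0, "MO": 0, "CH": 1, "SI": 1})
        assignments = partition_by_model([site], quartet_ped, "affected")
        assert all("autosomal_dominant" not in a.models for a in assignments)
        relaxed = partition_by_model(
            [site], quartet_ped, "affected", max_unaffected_carriers=1
        )
        assert any("autosomal_dominant" in a.models for a in relaxed)

    def test_x_linked_dominant_male_het_accepted(self, quartet_ped):
        site = make_site(chrom="chrX", gts={"FA": 0, "MO": 0, "CH": 1, "SI": 0})
        (a,) = partition_by_model([site], quartet_ped, "affected")
        assert "x_linked_dominant" in a.models
        assert "autosomal_dominant" not in a.models

    def test_unknown_phenotype_raises(self, quartet_ped):
        with pytest.raises(ValidationError):
            partition_by_model([], quartet_ped, "nonexistent")

    def test_compound_het_phased_by_transmission(self, trio_ped):
        s1 = make_site(pos=100, gts={"FA": 1, "MO": 0, "CH": 1})  # paternal
        s2 = make_site(pos=200, gts={"FA": 0, "MO": 1, "CH": 1})  # maternal
        gene_map = {s1.key: "GENE1", s2.key: "GENE1"}
        assignments = partition_by_model([s1, s2], trio_ped, "affected", gene_map)
        ch = [a for a in assignments if "compound_het" in a.models]
        assert len(ch) == 2
        assert all(p.phased for a in ch for p in a.compound_partners)

    def test_compound_het_cis_pair_excluded(self, trio_ped):
        s1 = make_site(pos=100, gts={"FA": 1, "MO": 0, "CH": 1})
        s2 = make_site(pos=200, gts={"FA": 1, "MO": 0, "CH": 1})  # both paternal
        gene_map = {s1.key: "G", s2.key: "G"}
        assignments = partition_by_model([s1, s2], trio_ped, "affected", gene_map)
        assert all("compound_het" not in a.models for a in assignments)

    def test_compound_het_unphased_flag(self, trio_ped):
        s1 = make_site(pos=100, gts={"FA": 1, "MO": 1, "CH": 1})  # ambiguous
        s2 = make_site(pos=200, gts={"FA": 0, "MO": 1, "CH": 1})
        gene_map = {s1.key: "G", s2.key: "G"}
        assignments = partition_by_model([s1, s2], trio_ped, "affected", gene_map)
        ch = [a for a in assignments if "compound_het" in a.models]
        assert len(ch) == 2
        assert all(not p.phased for a in ch for p in a.compound_partners)

    def test_different_genes_never_pair(self, trio_ped):
        s1 = make_site(pos=100, gts={"FA": 1, "MO": 0, "CH": 1})
        s2 = make_site(pos=200, gts={"FA": 0, "MO": 1, "CH": 1})
        gene_map = {s1.key: "G1", s2.key: "G2"}
        assignments = partition_by_model([s1, s2], trio_ped, "affected", gene_map)
        assert all("compound_het" not in a.models for a in assignments)


# ---------------------------------------------------------------------------
# exhaustive oracle on a 4-member pedigree
# ---------------------------------------------------------------------------


def oracle_models(g, label_affected, parents, chrom="chr1"):
    """Naive re-derivation of the single-site models for the quartet
    FA, MO, CH (affected), SI; ``g`` maps id -> -1/0/1/2."""
    affected = ["CH"]
    unaffected = ["FA", "MO", "SI"]
    carries = lambda x: g[x] in (1, 2)
    genotyped = lambda x: g[x] != -1

    out = set()
    # de novo: affected child het/hom-alt, both parents genotyped hom-ref
    if g["CH"] in (1, 2) and g["FA"] == 0 and g["MO"] == 0:
        out.add("de_novo")
    # dominant: all affected genotyped carriers, no genotyped unaffected carrier
    if all(genotyped(x) and carries(x) for x in affected) and not any(
        genotyped(x) and carries(x) for x in unaffected
    ):
        out.add("x_linked_dominant" if chrom == "chrX" else "autosomal_dominant")
    # recessive: all affected hom-alt, no genotyped unaffected hom-alt,
    # genotyped parents of affected carry
    if chrom != "chrX":
        if (
            all(g[x] == 2 for x in affected)
            and not any(genotyped(x) and g[x] == 2 for x in unaffected)
            and all(
                not genotyped(p) or carries(p)
                for p in parents
            )
        ):
            out.add("autosomal_recessive")
    return out


class TestExhaustiveOracle:
    @pytest.mark.parametrize("chrom", ["chr1", "chrX"])
    def test_all_genotype_assignments_match_oracle(self, quartet_ped, chrom):
        ids = ["FA", "MO", "CH", "SI"]
        for combo in itertools.product((-1, 0, 1, 2), repeat=4):
            g = dict(zip(ids, combo))
            site = make_site(chrom=chrom, gts=g)
            assignments = partition_by_model([site], quartet_ped, "affected")
            got = assignments[0].models if assignments else set()
            got = {m for m in got if m != "compound_het"}
            want = oracle_models(g, "affected", parents=["FA", "MO"], chrom=chrom)
            assert got == want, f"{chrom} {g}: got {got}, want {want}"


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------


def unit(model, gts=None, **ann):
    site = make_site(gts=gts or {"FA": 0, "MO": 0, "CH": 1}, **ann)
    from famvar.inheritance_filter import ModelAssignment

    return (model, ModelAssignment(site=site, models={model}))


STRONG = dict(impact="high", is_lof=True, cadd=20.0, p_adj=0.01,
              callers=frozenset({"a", "b"}))


class TestAfFilter:
    def test_de_novo_above_strict_cutoff_removed(self):
        stage = af_filter([unit("de_novo", af_db1=0.02, af_db2=0.001)])
        assert stage.n_removed == 1
        assert stage.removed[0][1] == ["af_db1>0.01"]

    def test_recessive_boundary_kept(self):
        stage = af_filter([unit("autosomal_recessive", af_db1=0.05, af_db2=0.05)])
        assert stage.n_kept == 1

    def test_dominant_boundary_kept_strictly_greater_excluded(self):
        assert af_filter([unit("autosomal_dominant", af_db1=0.01, af_db2=0.01)]).n_kept == 1
        assert af_filter([unit("autosomal_dominant", af_db1=0.0100001, af_db2=0.0)]).n_removed == 1

    def test_missing_af_treated_as_novel_kept(self):
        stage = af_filter([unit("de_novo")])
        assert stage.n_kept == 1

    def test_either_database_triggers(self):
        stage = af_filter([unit("compound_het", af_db1=0.001, af_db2=0.06)])
        assert stage.removed[0][1] == ["af_db2>0.05"]


class TestEvidenceFilter:
    def test_cadd_exactly_15_removed(self):
        stage = evidence_filter([unit("de_novo", **{**STRONG, "cadd": 15.0})])
        assert stage.n_removed == 1
        assert "cadd" in stage.removed[0][1]

    def test_lof_with_low_impact_passes_impact_criterion(self):
        stage = evidence_filter(
            [unit("de_novo", **{**STRONG, "impact": "low", "is_lof": True})]
        )
        assert stage.n_kept == 1

    def test_single_caller_removed_with_reason(self):
        stage = evidence_filter(
            [unit("de_novo", **{**STRONG, "callers": frozenset({"a"})})]
        )
        assert stage.removed[0][1] == ["caller_concordance"]

    def test_all_criteria_conjunctive(self):
        stage = evidence_filter([unit("de_novo", **STRONG)])
        assert stage.n_kept == 1

    def test_missing_padj_fails(self):
        stage = evidence_filter([unit("de_novo", **{**STRONG, "p_adj": None})])
        assert "p_adj" in stage.removed[0][1]


class TestClinvarRescue:
    def test_benign_not_rescued(self):
        site = make_site(clinvar="benign")
        assert clinvar_rescue([site], FilterTrace()) == []

    def test_drug_response_rescued_with_provenance(self):
        m, a = unit("de_novo", clinvar="drug_response", **{**STRONG, "cadd": 3.0})
        trace = FilterTrace()
        evidence_filter([(m, a)], trace)
        rescued = clinvar_rescue([a.site], trace)
        assert len(rescued) == 1
        assert rescued[0].label == "drug_response"
        assert rescued[0].removed_at == ["evidence_filter"]

    def test_rescue_set_subset_of_listed_labels(self):
        rng = np.random.default_rng(0)
        labels = ["pathogenic", "probably_pathogenic", "mixed", "drug_response",
                  "benign", "none"]
        sites = [
            make_site(pos=i + 1, clinvar=str(rng.choice(labels))) for i in range(500)
        ]
        rescued = clinvar_rescue(sites, FilterTrace())
        # oracle: direct recount
        want = [s for s in sites if s.ann.clinvar in labels[:4]]
        assert [r.site for r in rescued] == want


class TestIndelQc:
    def test_both_conditions_removed(self):
        site = make_site(callers=frozenset({"scalpel"}), alt_coverage=4, chi2=11.0)
        stage = indel_qc_filter([site])
        assert stage.n_removed == 1

    def test_conjunction_keeps_single_condition(self):
        site = make_site(callers=frozenset({"scalpel"}), alt_coverage=4, chi2=5.0)
        assert indel_qc_filter([site]).n_kept == 1

    def test_or_reading_switch(self):
        site = make_site(callers=frozenset({"scalpel"}), alt_coverage=4, chi2=5.0)
        assert indel_qc_filter([site], conjunction=False).n_removed == 1

    def test_non_scalpel_untouched(self):
        site = make_site(callers=frozenset({"gatk"}), alt_coverage=1, chi2=99.0)
        assert indel_qc_filter([site]).n_kept == 1


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


def random_units(n=300, seed=0):
    rng = np.random.default_rng(seed)
    models = ["de_novo", "autosomal_dominant", "autosomal_recessive", "compound_het"]
    units = []
    for i in range(n):
        units.append(
            unit(
                str(rng.choice(models)),
                af_db1=float(rng.choice([0.0, 0.005, 0.02, 0.06])),
                af_db2=float(rng.choice([0.0, 0.005, 0.02, 0.06])),
                impact=str(rng.choice(["low", "medium", "high"])),
                is_lof=bool(rng.random() < 0.2),
                cadd=float(rng.uniform(0, 40)),
                p_adj=float(rng.uniform(0, 0.2)),
                callers=frozenset(
                    ["a", "b", "c"][: 1 + int(rng.integers(3))]
                ),
            )
        )
    return units


class TestProperties:
    def test_af_and_evidence_commute(self):
        units = random_units()
        ab = evidence_filter(af_filter(units).kept).kept
        ba = af_filter(evidence_filter(units).kept).kept
        assert ab == ba

    def test_conservation_at_every_stage(self):
        units = random_units(seed=1)
        trace = FilterTrace()
        s1 = af_filter(units, trace)
        s2 = evidence_filter(s1.kept, trace)
        for s in trace.stages:
            assert s.n_kept + s.n_removed == s.n_in
        # trace reconstructs the input exactly (compare assignment identity;
        # removed units are re-wrapped tuples)
        reconstructed = {id(a) for _, a in s1.kept} | {id(u[1]) for u, _ in s1.removed}
        assert reconstructed == {id(a) for _, a in units}


# ---------------------------------------------------------------------------
# planted-variant recovery in a large synthetic run
# ---------------------------------------------------------------------------


def build_large_run(n_sites=10_000, seed=11):
    spec = SimulationSpec(seed=seed, n_sites=n_sites, chrom_length=2_000_000,
                          genotype_error_rate=0.005)
    ped, hidden = pedigree_preset("three_gen_9")
    ped, sites, truth = generate_pedigree_genotypes(spec, ped)
    annotate_variants(sites, spec, truth)
    # plant a pathogenic de novo SNV in the affected child 10133
    planted = sites[n_sites // 2]
    for mid in ped.ids:
        planted.genotypes[mid] = Genotype.HOM_REF
    planted.genotypes["10133"] = Genotype.HET
    planted.ann.af_db1 = 0.0
    planted.ann.af_db2 = 0.001
    planted.ann.impact = "high"
    planted.ann.is_lof = True
    planted.ann.cadd = 30.0
    planted.ann.p_adj = 0.001
    planted.ann.callers = frozenset({"gatk", "freebayes"})
    planted.ann.clinvar = "pathogenic"
    emitted = emitted_sites(sites, hidden)
    emitted_ped = ped.subset(set(ped.ids) - set(hidden))
    return emitted, emitted_ped, planted


def naive_de_novo_survivors(sites, ped, label="dysautonomia"):
    """Independent recount applying the cascade predicates literally."""
    affected = [m for m in ped if m.is_affected(label)]
    out = []
    for s in sites:
        if "scalpel" in s.ann.callers and (s.ann.alt_coverage or 0) < 5 and (
            s.ann.chi2 or 0
        ) > 10.8:
            continue
        dn = False
        for m in affected:
            if m.father is None or m.mother is None:
                continue
            if (
                s.genotypes.get(m.id) in (Genotype.HET, Genotype.HOM_ALT)
                and s.genotypes.get(m.father) is Genotype.HOM_REF
                and s.genotypes.get(m.mother) is Genotype.HOM_REF
            ):
                dn = True
        if not dn:
            continue
        if (s.ann.af_db1 or 0) > 0.01 or (s.ann.af_db2 or 0) > 0.01:
            continue
        if len(s.ann.callers) < 2:
            continue
        if s.ann.p_adj is None or s.ann.p_adj >= 0.05:
            continue
        if s.ann.impact not in ("medium", "high") and not s.ann.is_lof:
            continue
        if s.ann.cadd is None or s.ann.cadd <= 15:
            continue
        out.append(s.key)
    return out


class TestPlantedRecovery:
    def test_planted_de_novo_survives_and_matches_recount(self):
        emitted, ped, planted = build_large_run()
        result = run_filter_cascade(emitted, ped, "dysautonomia")
        keys = {a.key for a in result.per_model["de_novo"]}
        assert planted.key in keys
        assert keys == set(naive_de_novo_survivors(emitted, ped))
        # conservation across the full trace
        for s in result.trace.stages:
            assert s.n_kept + s.n_removed == s.n_in
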