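"""Seeded simulation of pedigree genotypes, deletions, depth and annotations.

The simulator emulates a 9-member, 3-generation family sequenced at ~40X:
founder haplotypes are drawn per-site from a Beta allele-frequency law,
children receive one whole haplotype per parent (recombination is off by
default so haplotype-scale signal survives; a per-site switch rate is
configurable for stress tests), genotype errors are symmetric swaps to a
uniformly chosen different genotype and are logged so tests can recount
them, and planted heterozygous deletions are emitted as ordinary diploid
genotypes — inside a deleted paternal segment the carrier's observed
genotype collapses to the maternal allele doubled, which is exactly what
makes parent-of-origin inference from Mendelian inconsistencies possible.

A fixed seed yields byte-identical outputs.  Separate random streams
(derived as ``default_rng([seed, stream])``) keep genotypes, depth and
annotations independently reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from famvar.errors import PedigreeError, ValidationError
from famvar.io_formats import (
    AnnotationRecord,
    DepthTrack,
    Genotype,
    Member,
    Pedigree,
    VariantSite,
)

CALLER_POOL = ("gatk", "freebayes", "scalpel", "repeatseq")

_STREAM_GENO = 0
_STREAM_DEPTH = 1
_STREAM_ANNOT = 2
_STREAM_KB = 3


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeletionPlan:
    """One planted deletion segment (1-based inclusive)."""

    start: int
    end: int
    carrier: str
    origin: str = "paternal"  # paternal | maternal
    de_novo: bool = True
    copies_lost: int = 1  # 1 = heterozygous, 2 = homozygous

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid deletion segment [{self.start}, {self.end}]")
        if self.origin not in ("paternal", "maternal"):
            raise ValidationError(f"unknown origin {self.origin!r}")
        if self.copies_lost not in (1, 2):
            raise ValidationError("copies_lost must be 1 or 2")


@dataclass
class SimulationSpec:
    """Everything needed to regenerate a synthetic dataset byte-identically."""

    seed: int = 0
    n_sites: int = 5000
    chrom: str = "chr15"
    chrom_length: int = 2_000_000
    pedigree_layout: str = "three_gen_9"
    af_beta: tuple[float, float] = (0.5, 0.5)
    mean_coverage: float = 40.0
    bin_size: int = 100
    genotype_error_rate: float = 0.005
    recombination_rate: float = 0.0
    deletion_plan: list[DeletionPlan] = field(default_factory=list)
    shared_maternal_pair: tuple[str, str] | None = None
    planted_pathogenic: list[int] = field(default_factory=list)  # site indices

    def __post_init__(self):
        if not (0.0 <= self.genotype_error_rate < 0.5):
            raise ValidationError("genotype_error_rate must be in [0, 0.5)")
        if self.n_sites < 1 or self.chrom_length < 1 or self.bin_size < 1:
            raise ValidationError("n_sites, chrom_length and bin_size must be >= 1")
        if self.n_sites > self.chrom_length:
            raise ValidationError("more sites than base pairs")
        segs = sorted((d.start, d.end) for d in self.deletion_plan)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValidationError("deletion segments overlap")
        for d in self.deletion_plan:
            if d.end > self.chrom_length:
                raise ValidationError("deletion segment beyond chrom_length")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        if "deletion_plan" in d:
            d["deletion_plan"] = [
                dp if isinstance(dp, DeletionPlan) else DeletionPlan(**dp)
                for dp in d["deletion_plan"]
            ]
        if d.get("af_beta") is not None:
            d["af_beta"] = tuple(d["af_beta"])
        if d.get("shared_maternal_pair") is not None:
            d["shared_maternal_pair"] = tuple(d["shared_maternal_pair"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["af_beta"] = list(self.af_beta)
        if self.shared_maternal_pair is not None:
            d["shared_maternal_pair"] = list(self.shared_maternal_pair)
        return d


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery oracles."""

    founder_afs: np.ndarray  # per-site truth allele frequency
    positions: np.ndarray  # 1-based site positions, sorted
    # transmitted allele pair per sample: id -> (2, n_sites) int8 array,
    # row 0 = paternal, row 1 = maternal (arbitrary hap order for founders)
    alleles: dict[str, np.ndarray]
    # hap choice per child and parent side: id -> {"father"|"mother": (n_sites,)}
    transmissions: dict[str, dict[str, np.ndarray]]
    errors: list[tuple[int, str, int, int]]  # (site_idx, sample, old, new)
    deletions: list[DeletionPlan] = field(default_factory=list)

    def error_free_genotype(self, sample: str, site_idx: int) -> Genotype:
        a = self.alleles[sample][:, site_idx]
        return Genotype(int(a[0] + a[1]))


# ---------------------------------------------------------------------------
# pedigree presets
# ---------------------------------------------------------------------------

HIDDEN_MOTHER = "10999"


def pedigree_preset(name: str) -> tuple[Pedigree, frozenset[str]]:
    """Named pedigree layouts.  Returns (pedigree, hidden ids).

    ``three_gen_9``: a 3-generation family with 9 sequenced members plus
    one hidden (unsequenced) founder — the mother of the two youngest
    brothers — so that maternal haplotypes exist in the simulation even
    though she is absent from every emitted file.
    """
    if name == "three_gen_9":
        members = [
            Member("10143", sex="male"),
            Member("10235", sex="female"),
            Member("10145", father="10143", mother="10235", sex="female",
                   phenotypes=frozenset({"hh", "dysautonomia"})),
            Member("10231", father="10143", mother="10235", sex="male"),
            Member("10144", sex="male"),
            Member("10133", father="10144", mother="10145", sex="female",
                   phenotypes=frozenset({"dysautonomia"})),
            Member("10138", father="10144", mother="10145", sex="male",
                   phenotypes=frozenset({"dysautonomia"})),
            Member(HIDDEN_MOTHER, sex="female"),
            Member("10232", father="10231", mother=HIDDEN_MOTHER, sex="male",
                   phenotypes=frozenset({"pws"})),
            Member("10233", father="10231", mother=HIDDEN_MOTHER, sex="male"),
        ]
        return Pedigree(members, family_id="K10031"), frozenset({HIDDEN_MOTHER})
    if name == "trio":
        members = [
            Member("FA", sex="male"),
            Member("MO", sex="female"),
            Member("CH", father="FA", mother="MO", sex="male",
                   phenotypes=frozenset({"affected"})),
        ]
        return Pedigree(members, family_id="TRIO1"), frozenset()
    raise ValidationError(f"unknown pedigree layout {name!r}")


def _validate_for_simulation(ped: Pedigree) -> None:
    for m in ped:
        if (m.father is None) != (m.mother is None):
            raise PedigreeError(
                f"member {m.id} has exactly one known parent; the simulator "
                "requires both or neither"
            )


# ---------------------------------------------------------------------------
# genotype generation
# ---------------------------------------------------------------------------


def _hap_choice(rng: np.random.Generator, n_sites: int, r: float) -> np.ndarray:
    """Which parental haplotype (0/1) is transmitted at each site; a Markov
    switch process with per-site rate ``r`` (r=0: one whole haplotype)."""
    start = int(rng.integers(2))
    if r <= 0:
        return np.full(n_sites, start, dtype=np.int8)
    switches = rng.random(n_sites - 1) < r
    return ((start + np.concatenate([[0], np.cumsum(switches)])) % 2).astype(np.int8)


def generate_pedigree_genotypes(
    spec: SimulationSpec, pedigree: Pedigree | None = None
) -> tuple[Pedigree, list[VariantSite], TruthRecord]:
    """Simulate genotypes for every pedigree member (hidden ones included;
    callers decide which samples to emit downstream).

    Post-conditions: founder haplotypes are Bernoulli(af) per site with
    af ~ Beta(*spec.af_beta*); each child receives one haplotype per parent;
    genotype errors occur independently at ``genotype_error_rate`` per
    genotype and are logged in the returned :class:`TruthRecord`.
    """
    if pedigree is None:
        pedigree, _hidden = pedigree_preset(spec.pedigree_layout)
    _validate_for_simulation(pedigree)
    rng = np.random.default_rng([spec.seed, _STREAM_GENO])
    n = spec.n_sites

    positions = np.sort(rng.choice(spec.chrom_length, size=n, replace=False)) + 1
    a, b = spec.af_beta
    afs = rng.beta(a, b, size=n)

    alleles: dict[str, np.ndarray] = {}
    transmissions: dict[str, dict[str, np.ndarray]] = {}
    shared = spec.shared_maternal_pair
    pending_shared: dict[str, np.ndarray] = {}

    for m in pedigree.topological_order():
        if m.father is None:
            haps = (rng.random((2, n)) < afs).astype(np.int8)
            alleles[m.id] = haps
        else:
            pat_choice = _hap_choice(rng, n, spec.recombination_rate)
            mat_choice = _hap_choice(rng, n, spec.recombination_rate)
            if shared and m.id in shared:
                other = shared[0] if m.id == shared[1] else shared[1]
                if pedigree[other].mother != m.mother:
                    raise ValidationError(
                        "shared_maternal_pair members must have the same mother"
                    )
                if other in pending_shared:
                    mat_choice = pending_shared.pop(other)
                else:
                    pending_shared[m.id] = mat_choice
            idx = np.arange(n)
            pat = alleles[m.father][pat_choice, idx]
            mat = alleles[m.mother][mat_choice, idx]
            alleles[m.id] = np.stack([pat, mat]).astype(np.int8)
            transmissions[m.id] = {"father": pat_choice, "mother": mat_choice}

    order = pedigree.ids
    geno = np.stack([alleles[mid].sum(axis=0) for mid in order]).astype(np.int8)

    errors: list[tuple[int, str, int, int]] = []
    if spec.genotype_error_rate > 0:
        mask = rng.random(geno.shape) < spec.genotype_error_rate
        hit = np.argwhere(mask)
        offsets = rng.integers(1, 3, size=len(hit))
        for (si, vi), off in zip(hit, offsets):
            old = int(geno[si, vi])
            new = (old + int(off)) % 3
            geno[si, vi] = new
            errors.append((int(vi), order[si], old, new))

    sites = []
    for j in range(n):
        sites.append(
            VariantSite(
                chrom=spec.chrom,
                pos=int(positions[j]),
                ref="A",
                alt="G",
                genotypes={mid: Genotype(int(geno[i, j])) for i, mid in enumerate(order)},
            )
        )
    truth = TruthRecord(
        founder_afs=afs,
        positions=positions,
        alleles=alleles,
        transmissions=transmissions,
        errors=errors,
    )
    return pedigree, sites, truth


# ---------------------------------------------------------------------------
# deletion planting
# ---------------------------------------------------------------------------


def plant_deletion(
    sites: list[VariantSite],
    pedigree: Pedigree,
    deletion_plan: list[DeletionPlan],
    truth: TruthRecord,
) -> tuple[list[VariantSite], TruthRecord]:
    """Overwrite the carrier's genotypes inside each planted segment with
    the hemizygous observation: the remaining parental allele doubled
    (both alleles deleted => homozygous reference, i.e. no call evidence).

    Parents' genotypes are untouched, so a ``de_novo`` deletion is absent
    from both parents by construction.  Mutates ``sites`` in place and
    returns them alongside the updated truth record.
    """
    for plan in deletion_plan:
        carrier = pedigree[plan.carrier]
        if carrier.father is None or carrier.mother is None:
            raise PedigreeError(
                f"deletion carrier {plan.carrier} is a founder with no simulated "
                f"parents; cannot honor origin={plan.origin!r}"
            )
        in_seg = np.flatnonzero(
            (truth.positions >= plan.start) & (truth.positions <= plan.end)
        )
        remaining_row = 1 if plan.origin == "paternal" else 0
        for j in in_seg:
            if plan.copies_lost == 2:
                obs = Genotype.HOM_REF
            else:
                allele = int(truth.alleles[plan.carrier][remaining_row, j])
                obs = Genotype.HOM_REF if allele == 0 else Genotype.HOM_ALT
            sites[j].genotypes[plan.carrier] = obs
        truth.deletions.append(plan)
    return sites, truth


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------


def simulate_depth(
    spec: SimulationSpec,
    deletions: list[DeletionPlan] | None = None,
    carrier: str | None = None,
) -> DepthTrack:
    """Per-bin depth ~ Poisson(mean_coverage x copy_number / 2) for one
    sample's genome.  Bins fully inside a deletion get the reduced copy
    number; partially overlapped edge bins keep copy number 2.
    """
    deletions = spec.deletion_plan if deletions is None else deletions
    rng = np.random.default_rng([spec.seed, _STREAM_DEPTH])
    n_bins = spec.chrom_length // spec.bin_size
    cn = np.full(n_bins, 2.0)
    for d in deletions:
        if carrier is not None and d.carrier != carrier:
            continue
        first = (d.start - 1 + spec.bin_size - 1) // spec.bin_size  # first full bin
        last = d.end // spec.bin_size  # one past last full bin
        cn[first:last] = 2 - d.copies_lost
    depths = rng.poisson(spec.mean_coverage * cn / 2.0).astype(float)
    return DepthTrack(chrom=spec.chrom, bin_size=spec.bin_size, depths=depths)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_IMPACT_PROBS = {"low": 0.75, "medium": 0.17, "high": 0.08}
_CADD_PARAMS = {"low": (5.0, 4.0), "medium": (12.0, 6.0), "high": (25.0, 6.0)}
_CLINVAR_RANDOM = ("pathogenic", "probably_pathogenic", "mixed", "drug_response", "benign")


def annotate_variants(
    sites: list[VariantSite], spec: SimulationSpec, truth: TruthRecord
) -> list[VariantSite]:
    """Populate every annotation field on every site.

    Population AFs are binomial-resampled from the truth AF (two database
    stand-ins with different sample sizes); impact, CADD-like score,
    ClinVar-like label, caller set and QC fields follow simple configured
    laws.  Sites listed in ``spec.planted_pathogenic`` are forced to a
    pathogenic label with a CADD-like score above 15.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_ANNOT])
    n = len(sites)
    afs = truth.founder_afs
    af1 = rng.binomial(2 * 2500, afs) / (2 * 2500)
    af2 = rng.binomial(2 * 30000, afs) / (2 * 30000)
    impacts = rng.choice(
        list(_IMPACT_PROBS), size=n, p=list(_IMPACT_PROBS.values())
    )
    clin_roll = rng.random(n)
    planted = set(spec.planted_pathogenic)
    for j, site in enumerate(sites):
        impact = str(impacts[j])
        mu, sd = _CADD_PARAMS[impact]
        cadd = max(0.0, float(rng.normal(mu, sd)))
        is_lof = impact == "high" and rng.random() < 0.5
        if clin_roll[j] < 0.02:
            clinvar = str(rng.choice(_CLINVAR_RANDOM))
        else:
            clinvar = "none"
        n_callers = 1 + int(rng.integers(3))
        callers = frozenset(
            rng.choice(CALLER_POOL, size=n_callers, replace=False).tolist()
        )
        if j in planted:
            clinvar = "pathogenic"
            cadd = max(cadd, 15.1 + float(rng.exponential(5.0)))
            impact = "high"
        site.ann = AnnotationRecord(
            af_db1=float(af1[j]),
            af_db2=float(af2[j]),
            impact=impact,
            is_lof=is_lof,
            cadd=cadd,
            clinvar=clinvar,
            callers=callers,
            alt_coverage=int(rng.poisson(spec.mean_coverage / 2.0)),
            chi2=float(rng.exponential(2.0)),
            p_adj=float(rng.uniform()),
            gene=site.ann.gene,
        )
    return sites


# ---------------------------------------------------------------------------
# knowledge base generation
# ---------------------------------------------------------------------------


@dataclass
class PlantedDiseaseSpec:
    """A contiguous gene cluster tied to one disease with a characteristic
    term profile (emulating an imprinted-region syndrome)."""

    disease: str = "PLANTED_SYNDROME"
    n_genes: int = 15
    n_terms: int = 9
    region: tuple[int, int] | None = None  # cluster placement on the chromosome
    gene_weight: float = 1.0
    term_weight: float = 1.0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("planted disease needs a nonempty gene set")


@dataclass
class KbTruth:
    planted_disease: str
    planted_genes: list[str]
    planted_terms: list[str]
    all_terms: list[str]


def generate_knowledge_base(
    n_genes: int,
    n_diseases: int,
    n_terms: int,
    planted: PlantedDiseaseSpec,
    seed: int,
    chrom: str = "chr15",
    chrom_length: int = 2_000_000,
):
    """Toy gene/disease/term knowledge base with a planted signal.

    Background link weights are capped well below the planted weights and
    background degrees are capped (<= 2 diseases per gene, <= 2 terms per
    disease, <= 2 gene-gene links per gene), so a single planted term in
    the input already dominates every background candidate — this is what
    makes the downsampling trend deterministic.  Planted terms link only
    to the planted disease.
    """
    from famvar.pheno_prioritize import (
        DiseaseTermLink,
        GeneDiseaseLink,
        GeneGeneLink,
        KnowledgeBase,
    )

    if planted.n_genes > n_genes:
        raise ValidationError("planted cluster larger than gene universe")
    if planted.n_terms > n_terms:
        raise ValidationError("more planted terms than terms")
    rng = np.random.default_rng([seed, _STREAM_KB])

    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    diseases = [planted.disease] + [f"DIS{i + 1:03d}" for i in range(n_diseases - 1)]
    terms = [f"HP:{9000001 + i:07d}" for i in range(n_terms)]
    planted_terms = terms[: planted.n_terms]
    background_terms = terms[planted.n_terms :]

    # gene coordinates: evenly tiled slots; the planted cluster occupies the
    # requested region (or the middle of the chromosome)
    region = planted.region or (chrom_length // 3, 2 * chrom_length // 3)
    n_bg_genes = n_genes - planted.n_genes
    coords: dict[str, tuple[str, int, int]] = {}
    planted_genes = genes[: planted.n_genes]
    span = region[1] - region[0] + 1
    slot = max(1, span // planted.n_genes)
    for i, g in enumerate(planted_genes):
        s = region[0] + i * slot
        coords[g] = (chrom, s, min(region[1], s + max(1, slot // 2)))
    bg_genes = genes[planted.n_genes :]
    outside = [(1, region[0] - 1), (region[1] + 1, chrom_length)]
    lengths = [max(0, e - s + 1) for s, e in outside]
    per_side = [
        int(round(n_bg_genes * l / sum(lengths))) if sum(lengths) else 0 for l in lengths
    ]
    per_side[0] = n_bg_genes - per_side[1]
    gi = 0
    for (s0, e0), count in zip(outside, per_side):
        if count <= 0:
            continue
        slot = max(1, (e0 - s0 + 1) // count)
        for i in range(count):
            g = bg_genes[gi]
            s = s0 + i * slot
            coords[g] = (chrom, s, min(e0, s + max(1, slot // 2)))
            gi += 1

    gene_disease = [
        GeneDiseaseLink(g, planted.disease, planted.gene_weight) for g in planted_genes
    ]
    disease_term = [
        DiseaseTermLink(planted.disease, t, planted.term_weight) for t in planted_terms
    ]
    gene_deg = {g: 0 for g in bg_genes}
    for dis in diseases[1:]:
        if bg_genes:
            k = 1 + int(rng.integers(2))
            pick = [
                str(g)
                for g in rng.choice(bg_genes, size=min(k, len(bg_genes)), replace=False)
                if gene_deg[str(g)] < 2
            ]
            for g in pick:
                gene_disease.append(GeneDiseaseLink(g, dis, float(rng.uniform(0.05, 0.2))))
                gene_deg[g] += 1
        if background_terms:
            kt = 1 + int(rng.integers(2))
            for t in rng.choice(background_terms, size=min(kt, len(background_terms)), replace=False):
                disease_term.append(
                    DiseaseTermLink(dis, str(t), float(rng.uniform(0.05, 0.2)))
                )

    gene_gene = []
    for g1, g2 in zip(planted_genes, planted_genes[1:]):
        gene_gene.append(GeneGeneLink(g1, g2, "biosystem", 0.5))
    gg_deg = {g: 0 for g in bg_genes}
    n_links = len(bg_genes) // 3
    for _ in range(n_links):
        g1, g2 = (str(x) for x in rng.choice(bg_genes, size=2, replace=False))
        if g1 == g2 or gg_deg[g1] >= 2 or gg_deg[g2] >= 2:
            continue
        rel = "family" if rng.random() < 0.5 else "biosystem"
        gene_gene.append(GeneGeneLink(str(g1), str(g2), rel, float(rng.uniform(0.1, 0.3))))
        gg_deg[g1] += 1
        gg_deg[g2] += 1

    kb = KnowledgeBase(
        gene_disease=gene_disease,
        disease_term=disease_term,
        gene_gene=gene_gene,
        gene_coords=coords,
    )
    kb_truth = KbTruth(
        planted_disease=planted.disease,
        planted_genes=planted_genes,
        planted_terms=planted_terms,
        all_terms=terms,
    )
    return kb, kb_truth


# ---------------------------------------------------------------------------
# truth serialization (plain text, for bundles)
# ---------------------------------------------------------------------------


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    """TSV dump of the truth record's testable parts (deletions, errors,
    per-site founder AFs)."""
    path = Path(path)
    lines = ["#section\tfields"]
    for d in truth.deletions:
        lines.append(
            f"deletion\t{d.start}\t{d.end}\t{d.carrier}\t{d.origin}\t"
            f"{int(d.de_novo)}\t{d.copies_lost}"
        )
    for site_idx, sample, old, new in truth.errors:
        lines.append(f"error\t{site_idx}\t{sample}\t{old}\t{new}")
    for j, (pos, af) in enumerate(zip(truth.positions, truth.founder_afs)):
        lines.append(f"site\t{j}\t{pos}\t{af:.8f}")
    path.write_text("\n".join(lines) + "\n")


def emitted_sites(
    sites: list[VariantSite], hidden_ids: frozenset[str]
) -> list[VariantSite]:
    """Copy of sites with hidden (unsequenced) samples removed."""
    out = []
    for s in sites:
        out.append(
            VariantSite(
                chrom=s.chrom,
                pos=s.pos,
                ref=s.ref,
                alt=s.alt,
                genotypes={k: v for k, v in s.genotypes.items() if k not in hidden_ids},
                ann=copy.copy(s.ann),
            )
        )
    return out
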