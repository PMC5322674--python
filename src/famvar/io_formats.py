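"""Core data model and file format readers/writers.

Internal coordinates are 1-based inclusive everywhere.  BED input
(0-based half-open on disk) is converted on read: a BED interval
``[s, e)`` becomes ``start = s + 1, end = e``; the conversion is
bijective and ``size = end - start + 1`` equals ``e - s``.

Parsers never silently coerce a missing value to a default: absent
annotation keys map to ``None`` (or an empty set for caller lists).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from famvar.errors import FormatError, PedigreeError, ValidationError

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


class Genotype(enum.IntEnum):
    """Unphased bi-allelic genotype of one sample at one site."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)

    @property
    def is_missing(self) -> bool:
        return self is Genotype.MISSING

    def flipped(self) -> "Genotype":
        """Genotype after swapping the ref/alt allele labels."""
        if self is Genotype.HOM_REF:
            return Genotype.HOM_ALT
        if self is Genotype.HOM_ALT:
            return Genotype.HOM_REF
        return self


_GT_TO_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}

# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


@dataclass(frozen=True)
class Member:
    """One pedigree member.  ``phenotypes`` is the set of labels for which
    the member is affected; parent ids are ``None`` when unknown."""

    id: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"
    phenotypes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.sex not in SEX_TO_CODE:
            raise PedigreeError(f"unknown sex {self.sex!r} for member {self.id}")

    def is_affected(self, label: str) -> bool:
        return label in self.phenotypes


class Pedigree:
    """A validated set of members with parent links.

    Invariants enforced at construction: unique ids, referenced parents
    exist, no member is its own ancestor.
    """

    def __init__(self, members: list[Member], family_id: str = "FAM1"):
        self.family_id = family_id
        self._members: dict[str, Member] = {}
        for m in members:
            if m.id in self._members:
                raise PedigreeError(f"duplicate member id {m.id}")
            self._members[m.id] = m
        dangling = [
            (m.id, p)
            for m in members
            for p in (m.father, m.mother)
            if p is not None and p not in self._members
        ]
        if dangling:
            raise PedigreeError(f"dangling parent ids: {dangling}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 1:
                raise PedigreeError(f"pedigree cycle through {mid}")
            if state.get(mid) == 2:
                return
            state[mid] = 1
            m = self._members[mid]
            for p in (m.father, m.mother):
                if p is not None:
                    visit(p)
            state[mid] = 2

        for mid in self._members:
            visit(mid)

    # -- accessors ---------------------------------------------------------
    def __contains__(self, mid: str) -> bool:
        return mid in self._members

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members.values())

    def __getitem__(self, mid: str) -> Member:
        try:
            return self._members[mid]
        except KeyError:
            raise PedigreeError(f"no member {mid!r} in pedigree") from None

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def members(self) -> list[Member]:
        return list(self._members.values())

    def founders(self) -> list[Member]:
        return [m for m in self if m.father is None and m.mother is None]

    def founder_couples(self) -> set[tuple[str, str]]:
        """Distinct (father, mother) founder pairs with at least one child."""
        couples = set()
        for m in self:
            if m.father and m.mother:
                f, mo = self[m.father], self[m.mother]
                if all(p.father is None and p.mother is None for p in (f, mo)):
                    couples.add((m.father, m.mother))
        return couples

    def children_of(self, parent_id: str) -> list[Member]:
        return [m for m in self if parent_id in (m.father, m.mother)]

    def affected(self, label: str) -> list[Member]:
        return [m for m in self if m.is_affected(label)]

    def unaffected(self, label: str) -> list[Member]:
        return [m for m in self if not m.is_affected(label)]

    def parent_child_pairs(self) -> list[tuple[str, str]]:
        """(parent_id, child_id) for every known parent link."""
        pairs = []
        for m in self:
            for p in (m.father, m.mother):
                if p is not None:
                    pairs.append((p, m.id))
        return pairs

    def topological_order(self) -> list[Member]:
        """Members ordered parents-before-children."""
        out: list[Member] = []
        seen: set[str] = set()

        def visit(mid: str) -> None:
            if mid in seen:
                return
            m = self._members[mid]
            for p in (m.father, m.mother):
                if p is not None:
                    visit(p)
            seen.add(mid)
            out.append(m)

        for mid in self._members:
            visit(mid)
        return out

    def subset(self, keep: set[str]) -> "Pedigree":
        """Pedigree restricted to ``keep``; parent links to dropped members
        become missing."""
        members = [
            replace(
                m,
                father=m.father if m.father in keep else None,
                mother=m.mother if m.mother in keep else None,
            )
            for m in self
            if m.id in keep
        ]
        return Pedigree(members, family_id=self.family_id)


# ---------------------------------------------------------------------------
# variant sites
# ---------------------------------------------------------------------------

CLINVAR_LABELS = (
    "pathogenic",
    "probably_pathogenic",
    "mixed",
    "drug_response",
    "benign",
    "none",
)

IMPACT_LEVELS = ("low", "medium", "high")


@dataclass
class AnnotationRecord:
    """Per-variant annotations consumed by the filtering cascade.

    ``None`` means the field is absent from the source, which is distinct
    from any numeric default (a variant with no database frequency is a
    novel variant, not one at frequency 0 — downstream rules decide how to
    treat absence).
    """

    af_db1: float | None = None  # 1000G-like population AF
    af_db2: float | None = None  # ExAC-like population AF
    impact: str | None = None  # low / medium / high
    is_lof: bool = False
    cadd: float | None = None
    clinvar: str = "none"
    callers: frozenset[str] = frozenset()
    alt_coverage: int | None = None
    chi2: float | None = None
    p_adj: float | None = None
    gene: str | None = None

    def __post_init__(self):
        for af in (self.af_db1, self.af_db2):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValidationError(f"allele frequency {af} outside [0, 1]")
        if self.impact is not None and self.impact not in IMPACT_LEVELS:
            raise ValidationError(f"unknown impact class {self.impact!r}")
        if self.clinvar not in CLINVAR_LABELS:
            raise ValidationError(f"unknown ClinVar-like label {self.clinvar!r}")
        if self.alt_coverage is not None and self.alt_coverage < 0:
            raise ValidationError("alt_coverage must be >= 0")
        self.callers = frozenset(self.callers)


@dataclass
class VariantSite:
    """One bi-allelic site with per-sample genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, Genotype]
    ann: AnnotationRecord = field(default_factory=AnnotationRecord)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position {self.pos} < 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def gt(self, sample: str) -> Genotype:
        try:
            return self.genotypes[sample]
        except KeyError:
            raise ValidationError(
                f"sample {sample!r} absent from genotype matrix at "
                f"{self.chrom}:{self.pos}"
            ) from None


def is_x_chrom(chrom: str) -> bool:
    """Recognize X-chromosome labels (no PAR handling; documented limitation)."""
    return chrom.removeprefix("chr").upper() == "X"


# ---------------------------------------------------------------------------
# CNV calls and depth tracks
# ---------------------------------------------------------------------------


@dataclass
class CnvCall:
    """An interval call, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    svtype: str = "DEL"  # DEL | DUP
    caller: str = "unknown"
    read_support: int | None = None
    confidence: float | None = None
    n_markers: int | None = None
    max_intermarker_gap: int | None = None
    segdup_overlap_frac: float | None = None
    truth_tag: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"CNV start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.svtype not in ("DEL", "DUP"):
            raise ValidationError(f"unknown svtype {self.svtype!r}")
        if self.segdup_overlap_frac is not None and not (
            0.0 <= self.segdup_overlap_frac <= 1.0
        ):
            raise ValidationError("segdup_overlap_frac outside [0, 1]")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class DepthTrack:
    """Binned mean depth over one chromosome; bins are contiguous,
    fixed-size, and start at ``origin`` (1-based)."""

    chrom: str
    bin_size: int
    depths: np.ndarray
    origin: int = 1

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if self.bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        if self.depths.ndim != 1:
            raise ValidationError("depth track must be one-dimensional")
        if np.any(self.depths < 0):
            raise ValidationError("negative depth in track")

    @property
    def n_bins(self) -> int:
        return int(self.depths.size)

    def bin_bounds(self, i: int) -> tuple[int, int]:
        """1-based inclusive coordinates covered by bin ``i``."""
        s = self.origin + i * self.bin_size
        return s, s + self.bin_size - 1

    def mean(self) -> float:
        return float(self.depths.mean()) if self.n_bins else float("nan")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_DEFS = [
    ("AF1", "1", "Float", "Population allele frequency, database 1"),
    ("AF2", "1", "Float", "Population allele frequency, database 2"),
    ("IMPACT", "1", "String", "Predicted impact class (low/medium/high)"),
    ("LOF", "0", "Flag", "Loss-of-function variant"),
    ("CADD", "1", "Float", "Deleteriousness score"),
    ("CLNSIG", "1", "String", "Clinical significance label"),
    ("CALLERS", ".", "String", "Supporting caller pipelines"),
    ("ALTC", "1", "Integer", "Alternate allele coverage"),
    ("CHI2", "1", "Float", "Allele balance chi-square score"),
    ("PADJ", "1", "Float", "Adjusted segregation p-value"),
    ("GENE", "1", "String", "Overlapping gene"),
]


def _fmt_float(x: float) -> str:
    return format(float(x), ".6g")


def write_vcf(sites: list[VariantSite], path: str | Path, samples: list[str] | None = None) -> None:
    """Write sites as minimal VCFv4.2 (GT only, scalar INFO keys)."""
    path = Path(path)
    if samples is None:
        samples = list(sites[0].genotypes) if sites else []
    contigs: dict[str, int] = {}
    for s in sites:
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos)
    lines = ["##fileformat=VCFv4.2", "##source=famvar"]
    for chrom, maxpos in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={maxpos + 1000}>")
    for key, num, typ, desc in _INFO_DEFS:
        lines.append(
            f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for s in sorted(sites, key=lambda v: (v.chrom, v.pos, v.alt)):
        a = s.ann
        info = []
        if a.af_db1 is not None:
            info.append(f"AF1={_fmt_float(a.af_db1)}")
        if a.af_db2 is not None:
            info.append(f"AF2={_fmt_float(a.af_db2)}")
        if a.impact is not None:
            info.append(f"IMPACT={a.impact}")
        if a.is_lof:
            info.append("LOF")
        if a.cadd is not None:
            info.append(f"CADD={_fmt_float(a.cadd)}")
        if a.clinvar != "none":
            info.append(f"CLNSIG={a.clinvar}")
        if a.callers:
            info.append("CALLERS=" + ",".join(sorted(a.callers)))
        if a.alt_coverage is not None:
            info.append(f"ALTC={a.alt_coverage}")
        if a.chi2 is not None:
            info.append(f"CHI2={_fmt_float(a.chi2)}")
        if a.p_adj is not None:
            info.append(f"PADJ={_fmt_float(a.p_adj)}")
        if a.gene is not None:
            info.append(f"GENE={a.gene}")
        gts = "\t".join(_GT_TO_STR[s.genotypes.get(smp, Genotype.MISSING)] for smp in samples)
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
            + (";".join(info) if info else ".")
            + "\tGT\t"
            + gts
        )
    path.write_text("\n".join(lines) + "\n")


def _info_scalar(value, idx: int, n_alt: int):
    """Pick the per-allele element of a possibly tuple-valued INFO field."""
    if isinstance(value, (tuple, list)):
        return value[idx] if len(value) == n_alt else value[0]
    return value


def read_vcf(path: str | Path) -> list[VariantSite]:
    """Read a VCF into :class:`VariantSite` records.

    Multi-allelic records are split into bi-allelic sites; genotype alleles
    belonging to other alternates are remapped to the reference allele and
    ``*`` (spanning-deletion) alleles are dropped with a logged warning.
    """
    from cyvcf2 import VCF  # heavy import kept local

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # htslib errors carry their own context
        raise FormatError(f"cannot open VCF: {exc}", path=path) from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    for var in vcf:
        alts = var.ALT
        n_alt = len(alts)
        gt_pairs = [(g[0], g[1]) for g in var.genotypes]
        for k, alt in enumerate(alts):
            if alt == "*":
                log.warning(
                    "dropping star allele at %s:%s", var.CHROM, var.POS
                )
                continue
            genotypes: dict[str, Genotype] = {}
            for smp, (a, b) in zip(samples, gt_pairs):
                if a < 0 or b < 0:
                    genotypes[smp] = Genotype.MISSING
                else:
                    dosage = int(a == k + 1) + int(b == k + 1)
                    genotypes[smp] = Genotype(dosage)

            def get(key, cast=None, idx=k, na=n_alt):
                v = var.INFO.get(key)
                if v is None:
                    return None
                v = _info_scalar(v, idx, na)
                return cast(v) if cast else v

            callers = var.INFO.get("CALLERS")
            ann = AnnotationRecord(
                af_db1=get("AF1", float),
                af_db2=get("AF2", float),
                impact=get("IMPACT", str),
                is_lof=var.INFO.get("LOF") is not None,
                cadd=get("CADD", float),
                clinvar=get("CLNSIG", str) or "none",
                callers=frozenset(str(callers).split(",")) if callers else frozenset(),
                alt_coverage=get("ALTC", int),
                chi2=get("CHI2", float),
                p_adj=get("PADJ", float),
                gene=get("GENE", str),
            )
            sites.append(
                VariantSite(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    genotypes=genotypes,
                    ann=ann,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------


def read_ped(path: str | Path, phenotype_label: str = "affected") -> Pedigree:
    """Read a whitespace-delimited 6-column PED file.

    Column 6 uses the PED convention: 2 = affected (for
    ``phenotype_label``), 1 = unaffected, 0/−9 = missing.
    """
    path = Path(path)
    members: list[Member] = []
    family_id = "FAM1"
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(
                f"expected 6 PED columns, got {len(fields)}", path=str(path), line=lineno
            )
        fam, mid, fid, moid, sex, pheno = fields[:6]
        family_id = fam
        if sex not in SEX_CODES:
            raise FormatError(
                f"unknown sex code {sex!r} for {mid}", path=str(path), line=lineno
            )
        members.append(
            Member(
                id=mid,
                father=None if fid == "0" else fid,
                mother=None if moid == "0" else moid,
                sex=SEX_CODES[sex],
                phenotypes=frozenset([phenotype_label]) if pheno == "2" else frozenset(),
            )
        )
    if not members:
        raise FormatError("empty PED file", path=str(path))
    return Pedigree(members, family_id=family_id)


def write_ped(pedigree: Pedigree, path: str | Path, phenotype_label: str = "affected") -> None:
    path = Path(path)
    lines = []
    for m in pedigree:
        pheno = "2" if m.is_affected(phenotype_label) else "1"
        lines.append(
            "\t".join(
                [
                    pedigree.family_id,
                    m.id,
                    m.father or "0",
                    m.mother or "0",
                    SEX_TO_CODE[m.sex],
                    pheno,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / CNV TSV
# ---------------------------------------------------------------------------


def read_bed_calls(path: str | Path, svtype: str = "DEL", caller: str = "unknown") -> list[CnvCall]:
    """Read BED3(+) interval calls, converting 0-based half-open to
    1-based inclusive: ``[s, e)`` on disk becomes ``(s + 1, e)``."""
    path = Path(path)
    calls: list[CnvCall] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError("expected >= 3 BED columns", path=str(path), line=lineno)
        try:
            s, e = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError("non-integer BED coordinates", path=str(path), line=lineno)
        if e <= s:
            raise FormatError(f"empty/negative BED interval [{s},{e})", path=str(path), line=lineno)
        calls.append(
            CnvCall(
                chrom=fields[0],
                start=s + 1,
                end=e,
                svtype=fields[3] if len(fields) > 3 else svtype,
                caller=fields[4] if len(fields) > 4 else caller,
            )
        )
    return calls


def write_bed_calls(calls: list[CnvCall], path: str | Path) -> None:
    """Inverse of :func:`read_bed_calls` (1-based inclusive -> BED)."""
    lines = [
        f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.svtype}\t{c.caller}" for c in calls
    ]
    Path(path).write_text("\n".join(lines) + "\n")


_CNV_TSV_COLS = [
    "chrom",
    "start",
    "end",
    "svtype",
    "caller",
    "read_support",
    "confidence",
    "n_markers",
    "max_intermarker_gap",
    "segdup_overlap_frac",
    "truth_tag",
]


def read_cnv_tsv(path: str | Path) -> list[CnvCall]:
    """Read the richer tab-separated call list (1-based inclusive on disk,
    header required, empty cells = missing)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = {"chrom", "start", "end"} - set(df.columns)
    if missing_cols:
        raise FormatError(f"CNV TSV missing columns {sorted(missing_cols)}", path=str(path))

    def opt(row, col, cast):
        v = row.get(col, "")
        return cast(v) if v not in ("", ".") else None

    calls = []
    for _, row in df.iterrows():
        calls.append(
            CnvCall(
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                svtype=row.get("svtype", "DEL") or "DEL",
                caller=row.get("caller", "unknown") or "unknown",
                read_support=opt(row, "read_support", int),
                confidence=opt(row, "confidence", float),
                n_markers=opt(row, "n_markers", int),
                max_intermarker_gap=opt(row, "max_intermarker_gap", int),
                segdup_overlap_frac=opt(row, "segdup_overlap_frac", float),
                truth_tag=opt(row, "truth_tag", str),
            )
        )
    return calls


def write_cnv_tsv(calls: list[CnvCall], path: str | Path, extra: dict[int, dict] | None = None) -> None:
    """Write calls as TSV; ``extra`` maps call index to additional columns
    (e.g. removal reasons)."""
    extra = extra or {}
    extra_cols: list[str] = sorted({k for d in extra.values() for k in d})
    header = _CNV_TSV_COLS + extra_cols
    lines = ["\t".join(header)]
    for i, c in enumerate(calls):
        vals = [
            c.chrom,
            str(c.start),
            str(c.end),
            c.svtype,
            c.caller,
            "" if c.read_support is None else str(c.read_support),
            "" if c.confidence is None else _fmt_float(c.confidence),
            "" if c.n_markers is None else str(c.n_markers),
            "" if c.max_intermarker_gap is None else str(c.max_intermarker_gap),
            "" if c.segdup_overlap_frac is None else _fmt_float(c.segdup_overlap_frac),
            c.truth_tag or "",
        ]
        vals += [str(extra.get(i, {}).get(k, "")) for k in extra_cols]
        lines.append("\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bedgraph depth track
# ---------------------------------------------------------------------------


def read_depth(path: str | Path) -> DepthTrack:
    """Read a 4-column bedgraph with contiguous fixed-size bins."""
    path = Path(path)
    chrom = None
    starts: list[int] = []
    ends: list[int] = []
    depths: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError("expected 4 bedgraph columns", path=str(path), line=lineno)
        c, s, e, d = fields
        if chrom is None:
            chrom = c
        elif c != chrom:
            raise FormatError("multi-chromosome bedgraph not supported", path=str(path), line=lineno)
        starts.append(int(s))
        ends.append(int(e))
        depths.append(float(d))
    if not depths:
        raise FormatError("empty bedgraph", path=str(path))
    sizes = {e - s for s, e in zip(starts, ends)}
    if len(sizes) != 1:
        raise FormatError("variable bin sizes in bedgraph", path=str(path))
    bin_size = sizes.pop()
    for i in range(1, len(starts)):
        if starts[i] != ends[i - 1]:
            raise FormatError("non-contiguous bins in bedgraph", path=str(path))
    return DepthTrack(
        chrom=chrom, bin_size=bin_size, depths=np.array(depths), origin=starts[0] + 1
    )


def write_depth(track: DepthTrack, path: str | Path) -> None:
    lines = []
    for i, d in enumerate(track.depths):
        s, e = track.bin_bounds(i)
        lines.append(f"{track.chrom}\t{s - 1}\t{e}\t{_fmt_float(d)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# knowledge base
# ---------------------------------------------------------------------------


def read_kb(kb_dir: str | Path):
    """Read the three knowledge-base link tables (and optional gene
    coordinates) from a directory.  Returns a
    :class:`famvar.pheno_prioritize.KnowledgeBase`."""
    import pandas as pd

    from famvar.pheno_prioritize import (
        DiseaseTermLink,
        GeneDiseaseLink,
        GeneGeneLink,
        KnowledgeBase,
    )

    kb_dir = Path(kb_dir)
    gd = pd.read_csv(kb_dir / "gene_disease.tsv", sep="\t")
    dt = pd.read_csv(kb_dir / "disease_term.tsv", sep="\t")
    gg = pd.read_csv(kb_dir / "gene_gene.tsv", sep="\t")
    gene_coords = {}
    coords_path = kb_dir / "genes.tsv"
    if coords_path.exists():
        gc = pd.read_csv(coords_path, sep="\t")
        gene_coords = {
            r.gene: (r.chrom, int(r.start), int(r.end)) for r in gc.itertuples()
        }
    return KnowledgeBase(
        gene_disease=[
            GeneDiseaseLink(r.gene, r.disease, float(r.weight)) for r in gd.itertuples()
        ],
        disease_term=[
            DiseaseTermLink(r.disease, r.term, float(r.weight)) for r in dt.itertuples()
        ],
        gene_gene=[
            GeneGeneLink(r.gene_a, r.gene_b, r.relation, float(r.weight))
            for r in gg.itertuples()
        ],
        gene_coords=gene_coords,
    )


def write_kb(kb, kb_dir: str | Path) -> None:
    """Inverse of :func:`read_kb`."""
    kb_dir = Path(kb_dir)
    kb_dir.mkdir(parents=True, exist_ok=True)
    with open(kb_dir / "gene_disease.tsv", "w") as fh:
        fh.write("gene\tdisease\tweight\n")
        for l in kb.gene_disease:
            fh.write(f"{l.gene}\t{l.disease}\t{_fmt_float(l.weight)}\n")
    with open(kb_dir / "disease_term.tsv", "w") as fh:
        fh.write("disease\tterm\tweight\n")
        for l in kb.disease_term:
            fh.write(f"{l.disease}\t{l.term}\t{_fmt_float(l.weight)}\n")
    with open(kb_dir / "gene_gene.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\trelation\tweight\n")
        for l in kb.gene_gene:
            fh.write(f"{l.gene_a}\t{l.gene_b}\t{l.relation}\t{_fmt_float(l.weight)}\n")
    if kb.gene_coords:
        with open(kb_dir / "genes.tsv", "w") as fh:
            fh.write("gene\tchrom\tstart\tend\n")
            for g, (chrom, s, e) in sorted(kb.gene_coords.items()):
                fh.write(f"{g}\t{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# HPO term lists
# ---------------------------------------------------------------------------


def read_terms(path: str | Path) -> dict[str, list[str]]:
    """Read a 2-column TSV (individual, hpo_id) into per-individual term lists."""
    path = Path(path)
    out: dict[str, list[str]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("individual\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError("expected 2 TSV columns", path=str(path), line=lineno)
        out.setdefault(fields[0], []).append(fields[1])
    return out


def write_terms(terms: dict[str, list[str]], path: str | Path) -> None:
    lines = ["individual\thpo_id"]
    for ind, tlist in terms.items():
        lines.extend(f"{ind}\t{t}" for t in tlist)
    Path(path).write_text("\n".join(lines) + "\n")
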