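"""Phenotype-driven candidate prioritization.

Candidate genes and CNV intervals are scored against a patient's HPO term
set through a weighted knowledge base of gene-disease, disease-term and
gene-gene (biosystem/family) links:

* direct gene score = sum over diseases of
  (gene-disease weight x sum of matched disease-term weights);
* one damped propagation round adds ``damping`` x weight x neighbor direct
  score over gene-gene links;
* an interval's score is the max (configurably the sum) over its genes;
* scores are normalized by the maximum raw score and banded into
  confidence tiers: high >= 0.5, medium in [0.1, 0.5), low < 0.1.

Because the raw score is linear in the term indicator vector, the
downsampling analysis uses a precomputed per-term score matrix; its
equivalence with :func:`score_entities` is covered by property tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from famvar.errors import ValidationError

TIERS = ("high", "medium", "low")


# ---------------------------------------------------------------------------
# knowledge base
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneDiseaseLink:
    gene: str
    disease: str
    weight: float


@dataclass(frozen=True)
class DiseaseTermLink:
    disease: str
    term: str
    weight: float


@dataclass(frozen=True)
class GeneGeneLink:
    gene_a: str
    gene_b: str
    relation: str  # biosystem | family
    weight: float


@dataclass
class KnowledgeBase:
    """Weighted link tables driving the prioritizer.

    Invariants: weights in (0, 1]; no gene-gene self links.
    """

    gene_disease: list[GeneDiseaseLink] = field(default_factory=list)
    disease_term: list[DiseaseTermLink] = field(default_factory=list)
    gene_gene: list[GeneGeneLink] = field(default_factory=list)
    gene_coords: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for l in itertools.chain(self.gene_disease, self.disease_term, self.gene_gene):
            if not (0.0 < l.weight <= 1.0):
                raise ValidationError(f"link weight {l.weight} outside (0, 1]: {l}")
        for l in self.gene_gene:
            if l.gene_a == l.gene_b:
                raise ValidationError(f"gene-gene self link: {l}")
            if l.relation not in ("biosystem", "family"):
                raise ValidationError(f"unknown gene-gene relation {l.relation!r}")

    @property
    def known_terms(self) -> set[str]:
        return {l.term for l in self.disease_term}

    def genes(self) -> set[str]:
        out = {l.gene for l in self.gene_disease}
        out |= {l.gene_a for l in self.gene_gene} | {l.gene_b for l in self.gene_gene}
        return out

    def genes_in(self, chrom: str, start: int, end: int) -> list[str]:
        """Genes whose recorded span overlaps [start, end] on chrom."""
        return sorted(
            g
            for g, (c, s, e) in self.gene_coords.items()
            if c == chrom and s <= end and e >= start
        )

    def term_contributions(self) -> dict[str, dict[str, float]]:
        """gene -> term -> summed (gene-disease x disease-term) weight."""
        profile: dict[str, list[tuple[str, float]]] = {}
        for l in self.disease_term:
            profile.setdefault(l.disease, []).append((l.term, l.weight))
        out: dict[str, dict[str, float]] = {}
        for l in self.gene_disease:
            row = out.setdefault(l.gene, {})
            for term, w in profile.get(l.disease, []):
                row[term] = row.get(term, 0.0) + l.weight * w
        return out


# ---------------------------------------------------------------------------
# candidates and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    """A prioritization candidate: a gene, or an interval with its gene
    content."""

    id: str
    kind: str  # gene | interval
    genes: tuple[str, ...]

    @classmethod
    def gene(cls, name: str) -> "Candidate":
        return cls(id=name, kind="gene", genes=(name,))

    @classmethod
    def interval(cls, name: str, genes: list[str]) -> "Candidate":
        return cls(id=name, kind="interval", genes=tuple(genes))


@dataclass
class EntityScore:
    raw: float
    normalized: float
    tier: str
    seed_gene: bool
    contributions: list[tuple[str, str, float]]  # (disease, term, value)


@dataclass
class PrioritizationResult:
    scores: dict[str, EntityScore]
    unknown_terms: list[str]
    normalization_skipped: bool

    def ranked(self) -> list[tuple[str, EntityScore]]:
        return sorted(self.scores.items(), key=lambda kv: (-kv[1].raw, kv[0]))


def assign_tier(normalized: float) -> str:
    """Confidence tier for a normalized score: high iff >= 0.5, medium iff
    in [0.1, 0.5), low iff < 0.1."""
    if not (0.0 <= normalized <= 1.0):
        raise ValidationError(f"normalized score {normalized} outside [0, 1]")
    if normalized >= 0.5:
        return "high"
    if normalized >= 0.1:
        return "medium"
    return "low"


def _gene_scores(
    terms: set[str], kb: KnowledgeBase, damping: float
) -> tuple[dict[str, float], dict[str, float], dict[str, list[tuple[str, str, float]]]]:
    """Direct and propagated scores per gene, with per-edge contributions."""
    profile: dict[str, list[tuple[str, float]]] = {}
    for l in kb.disease_term:
        if l.term in terms:
            profile.setdefault(l.disease, []).append((l.term, l.weight))
    direct: dict[str, float] = {}
    contribs: dict[str, list[tuple[str, str, float]]] = {}
    for l in kb.gene_disease:
        for term, w in profile.get(l.disease, []):
            val = l.weight * w
            direct[l.gene] = direct.get(l.gene, 0.0) + val
            contribs.setdefault(l.gene, []).append((l.disease, term, val))
    prop: dict[str, float] = {}
    if damping > 0:
        for l in kb.gene_gene:
            for g, nb in ((l.gene_a, l.gene_b), (l.gene_b, l.gene_a)):
                d = direct.get(nb, 0.0)
                if d > 0:
                    prop[g] = prop.get(g, 0.0) + damping * l.weight * d
    return direct, prop, contribs


def score_entities(
    terms: list[str] | set[str],
    candidates: list[Candidate],
    kb: KnowledgeBase,
    damping: float = 0.5,
    interval_mode: str = "max",
) -> PrioritizationResult:
    """Score each candidate against the term set (see module docstring).

    Unknown HPO ids are ignored with a warning and listed in the result.
    When every raw score is 0 normalization is skipped and all normalized
    scores are 0 (tier low).
    """
    if not candidates:
        raise ValidationError("no candidates to score")
    terms = set(terms)
    if not terms:
        raise ValidationError("empty term set")
    if interval_mode not in ("max", "sum"):
        raise ValidationError(f"unknown interval_mode {interval_mode!r}")
    known = kb.known_terms
    unknown = sorted(terms - known)
    if unknown:
        import logging

        logging.getLogger(__name__).warning("ignoring unknown HPO ids: %s", unknown)
    usable = terms & known
    direct, prop, contribs = _gene_scores(usable, kb, damping)
    raw: dict[str, float] = {}
    seeded: dict[str, bool] = {}
    for c in candidates:
        gvals = [direct.get(g, 0.0) + prop.get(g, 0.0) for g in c.genes]
        if not gvals:
            raw[c.id] = 0.0
        elif c.kind == "interval" and interval_mode == "sum":
            raw[c.id] = sum(gvals)
        else:
            raw[c.id] = max(gvals)
        seeded[c.id] = any(direct.get(g, 0.0) > 0 for g in c.genes)
    max_raw = max(raw.values())
    skipped = max_raw <= 0
    scores = {}
    for c in candidates:
        norm = 0.0 if skipped else raw[c.id] / max_raw
        scores[c.id] = EntityScore(
            raw=raw[c.id],
            normalized=norm,
            tier=assign_tier(norm),
            seed_gene=seeded[c.id],
            contributions=sorted(
                (t for g in c.genes for t in contribs.get(g, [])),
                key=lambda x: -x[2],
            ),
        )
    return PrioritizationResult(
        scores=scores, unknown_terms=unknown, normalization_skipped=skipped
    )


def term_importance(
    terms: list[str],
    target: str,
    candidates: list[Candidate],
    kb: KnowledgeBase,
    damping: float = 0.5,
) -> list[tuple[str, float]]:
    """Normalized score of ``target`` under each single-term run, sorted
    descending."""
    if target not in {c.id for c in candidates}:
        raise ValidationError(f"target {target!r} not among candidates")
    out = []
    for t in terms:
        res = score_entities([t], candidates, kb, damping=damping)
        out.append((t, res.scores[target].normalized))
    return sorted(out, key=lambda kv: (-kv[1], kv[0]))


def n_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k) in integer arithmetic."""
    if k < 0 or n < 0:
        raise ValidationError("n and k must be non-negative")
    if k > n:
        raise ValidationError(f"k={k} > n={n}")
    return math.comb(n, k)


# ---------------------------------------------------------------------------
# downsampling analysis
# ---------------------------------------------------------------------------


@dataclass
class KTally:
    n_combinations: int  # exact C(n, k)
    n_scored: int
    counts: dict[str, int]
    percentages: dict[str, float]
    mode: str  # exhaustive | sampled


@dataclass
class CombinationAnalysis:
    target: str
    per_k: dict[int, KTally]


def _score_matrix(
    terms: list[str], candidates: list[Candidate], kb: KnowledgeBase, damping: float
) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """(candidate x term) raw-score matrix for single-term inputs.

    Valid as a per-subset building block because the raw score is linear
    in the set of terms and interval max distributes per subset (the max
    is re-taken per subset over gene rows, not summed from single-term
    maxima)."""
    genes = sorted({g for c in candidates for g in c.genes})
    gidx = {g: i for i, g in enumerate(genes)}
    per_term = np.zeros((len(genes), len(terms)))
    tc = kb.term_contributions()
    tindex = {t: j for j, t in enumerate(terms)}
    direct = np.zeros_like(per_term)
    for g, row in tc.items():
        if g in gidx:
            for t, w in row.items():
                if t in tindex:
                    direct[gidx[g], tindex[t]] = w
    # propagation needs neighbor direct scores even for genes outside the
    # candidate set
    nb_direct: dict[str, np.ndarray] = {}
    prop = np.zeros_like(per_term)
    if damping > 0:
        for l in kb.gene_gene:
            for g, nb in ((l.gene_a, l.gene_b), (l.gene_b, l.gene_a)):
                if g not in gidx:
                    continue
                if nb not in nb_direct:
                    vec = np.zeros(len(terms))
                    for t, w in tc.get(nb, {}).items():
                        if t in tindex:
                            vec[tindex[t]] = w
                    nb_direct[nb] = vec
                prop[gidx[g]] += damping * l.weight * nb_direct[nb]
    gene_mat = direct + prop
    return gene_mat, genes, gidx


def downsample_analysis(
    terms: list[str],
    k_range: range | list[int],
    target: str,
    candidates: list[Candidate],
    kb: KnowledgeBase,
    cap: int = 60_000,
    seed: int = 0,
    damping: float = 0.5,
    interval_mode: str = "max",
) -> CombinationAnalysis:
    """Tier tallies for the designated ``target`` over term subsets.

    For each subset size ``k``: if C(n, k) <= ``cap`` every subset is
    enumerated exhaustively, otherwise ``cap`` distinct subsets are drawn
    without replacement using ``seed``.  Percentages are over the scored
    subsets and sum to 100 per k.
    """
    terms = list(dict.fromkeys(terms))
    n = len(terms)
    ids = {c.id for c in candidates}
    if target not in ids:
        raise ValidationError(f"target {target!r} not among candidates")
    for k in k_range:
        if not (1 <= k <= n):
            raise ValidationError(f"subset size {k} outside [1, {n}]")

    gene_mat, genes, gidx = _score_matrix(terms, candidates, kb, damping)
    cand_gene_rows = [
        np.array([gidx[g] for g in c.genes], dtype=int) for c in candidates
    ]
    target_idx = [c.id for c in candidates].index(target)
    rng = np.random.default_rng(seed)

    per_k: dict[int, KTally] = {}
    for k in k_range:
        total = math.comb(n, k)
        if total <= cap:
            mode = "exhaustive"
            combos = np.fromiter(
                itertools.chain.from_iterable(itertools.combinations(range(n), k)),
                dtype=np.int64,
            ).reshape(-1, k)
        else:
            mode = "sampled"
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < cap:
                pick = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
                chosen.add(pick)
            combos = np.array(sorted(chosen), dtype=np.int64)
        # gene raw scores per subset: sum selected term columns
        graw = np.zeros((len(genes), combos.shape[0]))
        for j in range(k):
            graw += gene_mat[:, combos[:, j]]
        cand_raw = np.empty((len(candidates), combos.shape[0]))
        for i, (c, rows) in enumerate(zip(candidates, cand_gene_rows)):
            if rows.size == 0:
                cand_raw[i] = 0.0
            elif c.kind == "interval" and interval_mode == "sum":
                cand_raw[i] = graw[rows].sum(axis=0)
            else:
                cand_raw[i] = graw[rows].max(axis=0)
        max_raw = cand_raw.max(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(max_raw > 0, cand_raw[target_idx] / max_raw, 0.0)
        counts = {
            "high": int(np.sum(norm >= 0.5)),
            "medium": int(np.sum((norm >= 0.1) & (norm < 0.5))),
            "low": int(np.sum(norm < 0.1)),
        }
        n_scored = combos.shape[0]
        per_k[k] = KTally(
            n_combinations=total,
            n_scored=n_scored,
            counts=counts,
            percentages={t: 100.0 * c / n_scored for t, c in counts.items()},
            mode=mode,
        )
    return CombinationAnalysis(target=target, per_k=per_k)
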