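"""Depth-based deletion detection, segment arithmetic and SV/CNV filters.

A heterozygous deletion halves the expected read depth, so maximal runs
of bins at <= ``ratio_threshold`` of the genome mean (default 0.65, which
separates copy-1 at an expected ratio of 0.5 from copy-2 under Poisson
noise at ~40X / 100-bp bins) are reported as DEL calls.

Filter boundary semantics follow the source wording literally:
">50 reads excluded" keeps <= 50; "less than four excluded" keeps >= 4;
"<10 Kb excluded" keeps >= 10,000 bp; segmental-duplication overlap
"by 50%" removes >= 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from famvar.errors import ValidationError
from famvar.io_formats import CnvCall, DepthTrack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# deletion calling
# ---------------------------------------------------------------------------


def call_deletions(
    track: DepthTrack,
    genome_mean: float,
    ratio_threshold: float = 0.65,
    min_bins: int = 5,
    max_merge_gap_bins: int = 0,
    edge_attach_gap_bins: int = 2,
    caller: str = "famvar-depth",
) -> list[CnvCall]:
    """Call DEL intervals from a binned depth track.

    Maximal runs of >= ``min_bins`` consecutive bins with
    depth / genome_mean <= ``ratio_threshold`` seed the calls; seed runs
    separated by <= ``max_merge_gap_bins`` bins are merged (bridging
    noise interruptions inside one event), and shorter low runs within
    ``edge_attach_gap_bins`` of a call boundary refine the breakpoint but
    never seed or bridge a call on their own.  Breakpoints are the outer
    low-bin edges, 1-based inclusive.  An empty track yields an empty
    result.
    """
    if genome_mean <= 0:
        raise ValidationError("genome_mean must be > 0")
    if track.n_bins == 0:
        return []
    low = track.depths / genome_mean <= ratio_threshold
    # raw runs of consecutive low bins
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, track.n_bins - 1))
    seeds = [r for r in runs if r[1] - r[0] + 1 >= min_bins]
    minor = [r for r in runs if r[1] - r[0] + 1 < min_bins]
    # merge seed runs separated by small gaps
    clusters: list[list[int]] = []
    for r0, r1 in seeds:
        if clusters and r0 - clusters[-1][1] - 1 <= max_merge_gap_bins:
            clusters[-1][1] = r1
        else:
            clusters.append([r0, r1])
    # attach short runs that refine a boundary (iterate until stable)
    changed = True
    while changed and clusters:
        changed = False
        remaining = []
        for r0, r1 in minor:
            attached = False
            for cl in clusters:
                if r1 < cl[0] and cl[0] - r1 - 1 <= edge_attach_gap_bins:
                    cl[0] = r0
                    attached = True
                    break
                if r0 > cl[1] and r0 - cl[1] - 1 <= edge_attach_gap_bins:
                    cl[1] = r1
                    attached = True
                    break
            if attached:
                changed = True
            else:
                remaining.append((r0, r1))
        minor = remaining
    calls = []
    for i0, i1 in clusters:
        s, _ = track.bin_bounds(i0)
        _, e = track.bin_bounds(i1)
        calls.append(
            CnvCall(chrom=track.chrom, start=s, end=e, svtype="DEL", caller=caller)
        )
    return calls


# ---------------------------------------------------------------------------
# segment arithmetic
# ---------------------------------------------------------------------------


@dataclass
class DeletionSegmentSet:
    """Ordered non-overlapping segments on one chromosome with their
    size/gap arithmetic.  ``gap_i = start_{i+1} - end_i`` (breakpoint to
    breakpoint) and ``size_i = end_i - start_i + 1``."""

    segments: list[CnvCall]
    sizes: list[int]
    gaps: list[int]
    total_size: int
    depth_ratios: list[float | None] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def segment_arithmetic(calls: list[CnvCall]) -> DeletionSegmentSet:
    """Sizes, gaps and total span of a sorted multi-segment event.

    Raises on overlapping segments or segments from several chromosomes.
    """
    if not calls:
        return DeletionSegmentSet(segments=[], sizes=[], gaps=[], total_size=0)
    chroms = {c.chrom for c in calls}
    if len(chroms) > 1:
        raise ValidationError(f"segments span several chromosomes: {sorted(chroms)}")
    ordered = sorted(calls, key=lambda c: c.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValidationError(
                f"overlapping segments {a.start}-{a.end} and {b.start}-{b.end}"
            )
    sizes = [c.size for c in ordered]
    gaps = [b.start - a.end for a, b in zip(ordered, ordered[1:])]
    return DeletionSegmentSet(
        segments=ordered, sizes=sizes, gaps=gaps, total_size=sum(sizes)
    )


# ---------------------------------------------------------------------------
# depth ratio
# ---------------------------------------------------------------------------


def depth_ratio(
    region: CnvCall, track: DepthTrack, genome_mean: float
) -> float | None:
    """Mean depth of bins fully inside ``region`` divided by
    ``genome_mean``.  Partial edge bins are excluded to avoid
    partial-overlap bias; a region covering zero full bins yields None.
    """
    if genome_mean <= 0:
        raise ValidationError("genome_mean must be > 0")
    first = (region.start - track.origin + track.bin_size - 1) // track.bin_size
    last = (region.end - track.origin + 1) // track.bin_size  # exclusive
    first = max(first, 0)
    last = min(last, track.n_bins)
    if last <= first:
        return None
    return float(track.depths[first:last].mean()) / genome_mean


# ---------------------------------------------------------------------------
# post-call filter rules
# ---------------------------------------------------------------------------


@dataclass
class FilterRuleset:
    """Thresholds for the per-caller post-call filters.

    ``caller_types`` maps a caller label to the rule family that applies:
    ``read_pair`` (read-support window), ``depth`` (confidence + size),
    ``array`` (marker count + inter-marker gap).  Unmapped callers face
    only the shared segmental-duplication rule.
    """

    support_min: int = 4
    support_max: int = 50
    depth_min_confidence: float = 300.0
    depth_min_dup_size: int = 200_000
    depth_min_del_size: int = 10_000
    array_min_markers: int = 10
    array_max_gap: int = 50_000
    segdup_max_frac: float = 0.5
    caller_types: dict[str, str] = field(
        default_factory=lambda: {
            "lumpy": "read_pair",
            "erds": "depth",
            "penncnv": "array",
        }
    )


@dataclass
class CnvFilterResult:
    kept: list[CnvCall]
    removed: list[tuple[CnvCall, list[str]]]
    unevaluable: list[tuple[CnvCall, list[str]]]  # kept, but rules lacked fields

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)


def filter_calls(calls: list[CnvCall], ruleset: FilterRuleset | None = None) -> CnvFilterResult:
    """Apply the post-call rules; every removal carries its rule ids.

    A call missing a field required by an applicable rule is flagged
    unevaluable for that rule, kept, and logged.
    """
    ruleset = ruleset or FilterRuleset()
    kept: list[CnvCall] = []
    removed: list[tuple[CnvCall, list[str]]] = []
    unevaluable: list[tuple[CnvCall, list[str]]] = []
    for call in calls:
        reasons: list[str] = []
        missing: list[str] = []
        ctype = ruleset.caller_types.get(call.caller.lower())
        if ctype == "read_pair":
            if call.read_support is None:
                missing.append("support_window")
            else:
                if call.read_support > ruleset.support_max:
                    reasons.append("support_above_max")
                if call.read_support < ruleset.support_min:
                    reasons.append("support_below_min")
        elif ctype == "depth":
            if call.confidence is None:
                missing.append("confidence")
            elif call.confidence <= ruleset.depth_min_confidence:
                reasons.append("low_confidence")
            if call.svtype == "DUP" and call.size < ruleset.depth_min_dup_size:
                reasons.append("dup_size")
            if call.svtype == "DEL" and call.size < ruleset.depth_min_del_size:
                reasons.append("del_size")
        elif ctype == "array":
            if call.n_markers is None:
                missing.append("n_markers")
            elif call.n_markers < ruleset.array_min_markers:
                reasons.append("few_markers")
            if call.max_intermarker_gap is None:
                missing.append("marker_gap")
            elif call.max_intermarker_gap > ruleset.array_max_gap:
                reasons.append("marker_gap")
        if call.segdup_overlap_frac is not None:
            if call.segdup_overlap_frac >= ruleset.segdup_max_frac:
                reasons.append("segdup_overlap")
        if reasons:
            removed.append((call, reasons))
        else:
            kept.append(call)
            if missing:
                log.warning(
                    "call %s:%s-%s (%s) unevaluable for rules %s; kept",
                    call.chrom, call.start, call.end, call.caller, missing,
                )
                unevaluable.append((call, missing))
    return CnvFilterResult(kept=kept, removed=removed, unevaluable=unevaluable)


def union_calls(calls_a: list[CnvCall], calls_b: list[CnvCall]) -> list[CnvCall]:
    """Union of two call sets with per-caller provenance preserved
    (duplicate intervals from the same caller collapse)."""
    seen = {}
    for c in list(calls_a) + list(calls_b):
        seen.setdefault((c.chrom, c.start, c.end, c.svtype, c.caller), c)
    return sorted(seen.values(), key=lambda c: (c.chrom, c.start, c.end, c.caller))


def intersect_calls(
    calls_a: list[CnvCall], calls_b: list[CnvCall], min_reciprocal_overlap: float = 0.5
) -> list[CnvCall]:
    """Calls from set A reciprocally overlapped (>= fraction) by some call
    of the same type in set B."""
    out = []
    for a in calls_a:
        for b in calls_b:
            if a.chrom != b.chrom or a.svtype != b.svtype:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov <= 0:
                continue
            if ov / a.size >= min_reciprocal_overlap and ov / b.size >= min_reciprocal_overlap:
                out.append(a)
                break
    return out
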