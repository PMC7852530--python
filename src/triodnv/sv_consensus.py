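"""Dual-caller consensus calling and filtering of de novo structural variants.

Neither of the two germline SV callers emits de novo calls directly, so
de novo SVs in a child are isolated by four successive filters, each of
which is recorded in an auditable trail:

1. **consensus** — the variant (> 10 bp) must be reported by both callers
   with >= 50% reciprocal overlap and matching type;
2. **parental** — any same-type record in either parent (confident call
   *or* low-confidence candidate) matching at the same reciprocal-overlap
   threshold removes the variant;
3. **annotation** — variants mostly covered by blacklist, low-mappability,
   segmental-duplication or repeat tracks are removed (covered fraction
   > phi, default 0.5);
4. **coverage** — the binned read-depth profile over the variant plus
   flanks must *not* follow a similar pattern between child and either
   parent (Pearson correlation >= rho, default 0.9, fails the variant);
   a true de novo deletion shows an interior depth drop unique to the
   child, which breaks the similarity.

The merged consensus interval is the caller-A (breakpoint-precise)
interval, giving one canonical coordinate set downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import AnnotationTrackSet
from .io_formats import GenomicInterval, SvCall

log = logging.getLogger(__name__)

RO_THRESHOLD = 0.5
EXCLUSION_COVER_THRESHOLD = 0.5
SIMILARITY_THRESHOLD = 0.9
MIN_SV_LENGTH = 10  # de novo analysis considers INDELs/SVs *larger* than 10 bp

FILTER_STAGES = ("consensus", "parental", "annotation", "coverage")


def reciprocal_overlap(x: SvCall | GenomicInterval, y: SvCall | GenomicInterval) -> tuple[float, float]:
    """Overlap of two same-chromosome intervals as a fraction of each span."""
    if x.chrom != y.chrom:
        raise ValueError("reciprocal overlap requires the same chromosome")
    if x.span == 0 or y.span == 0:
        raise ValueError("zero-length interval")
    overlap = max(0, min(x.end, y.end) - max(x.start, y.start))
    return overlap / x.span, overlap / y.span


def ro_match(x, y, threshold: float = RO_THRESHOLD) -> bool:
    if x.chrom != y.chrom:
        return False
    fx, fy = reciprocal_overlap(x, y)
    return fx >= threshold and fy >= threshold


@dataclass
class DeNovoSvCandidate:
    """A consensus SV candidate with its pass/fail trail per filter stage."""

    call_a: SvCall
    call_b: SvCall | None
    trail: dict = field(default_factory=dict)   # stage -> bool (absent = not evaluated)

    @property
    def interval(self) -> SvCall:
        """Canonical merged interval: the caller-A record."""
        return self.call_a

    @property
    def final(self) -> bool:
        return all(self.trail.get(stage, False) for stage in FILTER_STAGES)

    @property
    def first_failed(self) -> str | None:
        for stage in FILTER_STAGES:
            if self.trail.get(stage) is False:
                return stage
        return None


def intersect_callers(
    calls_a: Sequence[SvCall],
    calls_b: Sequence[SvCall],
    threshold: float = RO_THRESHOLD,
    min_length: int = MIN_SV_LENGTH,
) -> list[DeNovoSvCandidate]:
    """Pair caller-A and caller-B calls of the same type by reciprocal overlap.

    Greedy best-overlap pairing: candidate pairs are ranked by the smaller
    of their two overlap fractions (ties broken by caller-A start), and
    each call is used at most once.  Every caller-A call above the length
    cutoff yields a candidate; unpaired ones carry a failed consensus
    stage so that removals remain attributable.
    """
    calls_a = [c for c in calls_a if c.length > min_length]
    calls_b = [c for c in calls_b if c.length > min_length]
    pairs = []
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            if a.svtype != b.svtype or a.chrom != b.chrom:
                continue
            fa, fb = reciprocal_overlap(a, b)
            score = min(fa, fb)
            if score >= threshold:
                pairs.append((score, a.start, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1]))
    used_a, used_b = set(), set()
    matched: dict[int, int] = {}
    for score, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched[i] = j
    out = []
    for i, a in enumerate(calls_a):
        if i in matched:
            cand = DeNovoSvCandidate(a, calls_b[matched[i]])
            cand.trail["consensus"] = True
        else:
            cand = DeNovoSvCandidate(a, None)
            cand.trail["consensus"] = False
        out.append(cand)
    return out


def subtract_parental(
    candidates: Sequence[DeNovoSvCandidate],
    parental_calls: Sequence[SvCall],
    threshold: float = RO_THRESHOLD,
) -> Sequence[DeNovoSvCandidate]:
    """Fail candidates matched by any same-type parental record.

    ``parental_calls`` must include both the confident calls and the
    candidate-level (low-confidence) records from both parents and both
    callers; either kind removes a child candidate.
    """
    for cand in candidates:
        if cand.trail.get("consensus") is not True:
            continue
        a = cand.interval
        hit = any(
            p.svtype == a.svtype and ro_match(a, p, threshold)
            for p in parental_calls
        )
        cand.trail["parental"] = not hit
    return candidates


def exclusion_covered_fraction(interval, tracks: AnnotationTrackSet) -> float:
    """Largest fraction of the interval covered by any single exclusion track."""
    best = 0.0
    for name in ("blacklist", "mappability", "segdup", "repeats"):
        covered = 0
        for iv in getattr(tracks, name):
            if iv.chrom != interval.chrom:
                continue
            covered += max(0, min(iv.end, interval.end) - max(iv.start, interval.start))
        if interval.span:
            best = max(best, covered / interval.span)
    return best


def annotation_exclusion(
    candidates: Sequence[DeNovoSvCandidate],
    tracks: AnnotationTrackSet,
    cover_threshold: float = EXCLUSION_COVER_THRESHOLD,
) -> Sequence[DeNovoSvCandidate]:
    """Fail candidates whose interval is mostly inside an exclusion track."""
    for cand in candidates:
        if cand.first_failed is not None:
            continue
        frac = exclusion_covered_fraction(cand.interval, tracks)
        cand.trail["annotation"] = frac <= cover_threshold
    return candidates


# ---------------------------------------------------------------------------
# coverage similarity
# ---------------------------------------------------------------------------

class CoverageSet:
    """Genome-wide binned read depth for the three trio members.

    ``depth[sample][chrom]`` is a numpy array of per-bin mean depth;
    all samples share one bin grid (``bin_size`` bp, anchored at 0).
    """

    def __init__(self, depth: Mapping[str, Mapping[str, np.ndarray]], bin_size: int):
        self.depth = depth
        self.bin_size = bin_size

    def window(self, chrom: str, start: int, end: int) -> dict[str, np.ndarray]:
        lo = start // self.bin_size
        hi = -(-end // self.bin_size)
        out = {}
        for sample, chroms in self.depth.items():
            arr = chroms[chrom]
            out[sample] = arr[lo:min(hi, len(arr))]
        return out

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for sample, chroms in self.depth.items():
            for chrom, arr in chroms.items():
                for i, d in enumerate(arr):
                    rows.append((sample, chrom, i * self.bin_size,
                                 (i + 1) * self.bin_size, float(d)))
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "depth"])

    @classmethod
    def from_dataframe(cls, df) -> "CoverageSet":
        bin_size = int((df["end"] - df["start"]).iloc[0])
        depth: dict = {}
        for (sample, chrom), sub in df.groupby(["sample", "chrom"]):
            sub = sub.sort_values("start")
            depth.setdefault(sample, {})[chrom] = sub["depth"].to_numpy(dtype=float)
        return cls(depth, bin_size)


def profile_similarity(child: np.ndarray, parent: np.ndarray) -> float:
    """Pearson correlation of two binned depth profiles (NaN when constant)."""
    n = min(len(child), len(parent))
    child, parent = child[:n], parent[:n]
    if n < 2 or np.std(child) == 0 or np.std(parent) == 0:
        return float("nan")
    return float(np.corrcoef(child, parent)[0, 1])


def coverage_similarity_filter(
    candidate: DeNovoSvCandidate,
    coverage: CoverageSet,
    similarity_threshold: float = SIMILARITY_THRESHOLD,
    flank: int | None = None,
) -> bool:
    """True (pass) when the child's depth pattern matches neither parent.

    The comparison window is the SV interval plus flanks (default: half
    the span, at least 10 bins).  An undefined similarity (constant
    profile) keeps the candidate, with a warning.
    """
    iv = candidate.interval
    if flank is None:
        flank = max(iv.span // 2, 10 * coverage.bin_size)
    start = max(0, iv.start - flank)
    window = coverage.window(iv.chrom, start, iv.end + flank)
    child = window["child"]
    passed = True
    for parent in ("father", "mother"):
        sim = profile_similarity(child, window[parent])
        if np.isnan(sim):
            log.warning("similarity undefined for %s:%d-%d vs %s; keeping candidate",
                        iv.chrom, iv.start, iv.end, parent)
            continue
        if sim >= similarity_threshold:
            passed = False
    return passed


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_sv_pipeline(
    child_callsets: Mapping[str, Sequence[SvCall]],
    parental_calls: Sequence[SvCall],
    tracks: AnnotationTrackSet,
    coverage: CoverageSet | None = None,
    ro_threshold: float = RO_THRESHOLD,
    cover_threshold: float = EXCLUSION_COVER_THRESHOLD,
    similarity_threshold: float = SIMILARITY_THRESHOLD,
) -> list[DeNovoSvCandidate]:
    """Run consensus -> parental subtraction -> annotation -> coverage.

    ``child_callsets`` maps the two caller ids to their call lists for
    the child (the first mapping entry is treated as caller A, whose
    intervals are canonical).  Every candidate retains a full filter
    trail; the survivors are those with ``final`` set.
    """
    callers = list(child_callsets)
    if len(callers) != 2:
        raise ValueError(f"need exactly two child callsets, got {callers}")
    calls_a, calls_b = child_callsets[callers[0]], child_callsets[callers[1]]
    candidates = intersect_callers(calls_a, calls_b, ro_threshold)
    subtract_parental(candidates, parental_calls, ro_threshold)
    annotation_exclusion(candidates, tracks, cover_threshold)
    for cand in candidates:
        if cand.first_failed is not None:
            continue
        if coverage is None:
            cand.trail["coverage"] = True
        else:
            cand.trail["coverage"] = coverage_similarity_filter(
                cand, coverage, similarity_threshold)
    return candidates


def describe_exon_effect(sv: SvCall, tracks: AnnotationTrackSet) -> str | None:
    """Human-readable exon-level effect, e.g. ``"deletion of exons 3-7 of GENE"``.

    Exons are numbered along the transcription direction of the gene
    whose span overlaps the SV.  Returns ``None`` when no exon overlaps.
    """
    for gene in tracks.gene_spans:
        if gene.chrom != sv.chrom or gene.end <= sv.start or sv.end <= gene.start:
            continue
        exons = sorted(
            (iv for iv in tracks.gene_features
             if iv.label == "exon" and iv.chrom == sv.chrom
             and gene.start <= iv.start and iv.end <= gene.end),
            key=lambda iv: iv.start,
        )
        if gene.strand == "-":
            exons = list(reversed(exons))
        hit = [i + 1 for i, ex in enumerate(exons)
               if ex.start < sv.end and sv.start < ex.end]
        if not hit:
            continue
        verb = {"DEL": "deletion", "DUP": "duplication",
                "INV": "inversion", "INS": "insertion"}[sv.svtype]
        if len(hit) == 1:
            return f"{verb} of exon {hit[0]} of {gene.label}"
        return f"{verb} of exons {hit[0]}-{hit[-1]} of {gene.label}"
    return None


def candidates_to_dataframe(candidates: Sequence[DeNovoSvCandidate],
                            tracks: AnnotationTrackSet | None = None):
    import pandas as pd
    rows = []
    for c in candidates:
        iv = c.interval
        row = {
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "svtype": iv.svtype, "length": iv.length, "sample": iv.sample,
            "caller_a": iv.caller,
            "caller_b": c.call_b.caller if c.call_b else None,
            "final": c.final, "first_failed": c.first_failed,
        }
        for stage in FILTER_STAGES:
            row[f"pass_{stage}"] = c.trail.get(stage)
        if tracks is not None:
            row["exon_effect"] = describe_exon_effect(iv, tracks)
        rows.append(row)
    return pd.DataFrame(rows)
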