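"""Functional annotation of de novo variants against genomic interval tracks.

Each variant position receives:

* a gene-position class with annotator-style precedence
  exon > UTR5 > UTR3 > upstream > downstream > intron > intergenic,
  where "upstream" means within a window (default 1000 bp) 5' of a
  transcription start site, respecting strand;
* the chromatin-state label covering it (Promoter / Enhancer / Other);
* a DHS (open-chromatin) overlap flag;
* the number of TFBS cluster intervals overlapping the position;
* a GC-exclusion flag: true when the position lies in a 100 bp tile with
  >= 75% GC content or inside a "difficult promoter" interval (this
  filter is applied symmetrically to case and control sets upstream of
  any enrichment test);
* optionally, whether an SNV is non-synonymous, when a CDS-bearing gene
  model and reference sequence are available.

Interval lookups are vectorised with ``numpy.searchsorted`` over sorted
start/end arrays, which keeps cohort-scale annotation fast enough for
simulation studies with thousands of replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .dnv_calling import DnvCall
from .io_formats import GenomicInterval, fetch_sequence

log = logging.getLogger(__name__)

GC_WINDOW = 100           # bp, non-overlapping tiles anchored at coordinate 0
GC_THRESHOLD = 0.75       # inclusive ("at least 75%")
TFBS_RICH_CUTOFF = 10     # feature flag is tfbs_count >= 10

GENE_CLASS_PRECEDENCE = ("exon", "UTR5", "UTR3", "upstream", "downstream", "intron")


class IntervalArrayIndex:
    """Overlap counting over (possibly overlapping) intervals, per chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts, self._ends = {}, {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[chrom] = np.sort(arr[:, 0])
            self._ends[chrom] = np.sort(arr[:, 1])

    def count(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(positions.shape, dtype=np.int64)
        started = np.searchsorted(self._starts[chrom], positions, side="right")
        ended = np.searchsorted(self._ends[chrom], positions, side="right")
        return started - ended

    def member(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.count(chrom, positions) > 0


class LabelledIndex:
    """Label lookup over non-overlapping labelled intervals, per chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval], default: str = ""):
        self.default = default
        by_chrom: dict[str, list] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts, self._ends, self._labels = {}, {}, {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: x.start)
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._labels[chrom] = np.array([iv.label for iv in ivs], dtype=object)

    def label_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, self.default, dtype=object)
        if chrom not in self._starts:
            return out
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        valid = idx >= 0
        inside = np.zeros(positions.shape, dtype=bool)
        inside[valid] = positions[valid] < self._ends[chrom][idx[valid]]
        out[inside] = self._labels[chrom][idx[inside]]
        return out


# ---------------------------------------------------------------------------
# track set
# ---------------------------------------------------------------------------

@dataclass
class CdsModel:
    """Coding sequence of one gene: strand plus genomic exon intervals
    sorted in genomic order (the transcription order is derived from the
    strand).  Total length must be a multiple of 3."""

    gene: str
    chrom: str
    strand: str
    exons: list  # [(start, end), ...] 0-based half-open, genomic order


@dataclass
class AnnotationTrackSet:
    """Named interval collections consumed by the annotator and SV filters."""

    gene_features: list = field(default_factory=list)   # labels UTR5/UTR3/exon/intron
    tss: list = field(default_factory=list)             # 1 bp intervals, label=gene, stranded
    gene_spans: list = field(default_factory=list)      # label=gene, stranded
    chromatin: list = field(default_factory=list)       # Promoter/Enhancer (gaps = Other)
    dhs: list = field(default_factory=list)
    tfbs: list = field(default_factory=list)
    blacklist: list = field(default_factory=list)
    mappability: list = field(default_factory=list)
    segdup: list = field(default_factory=list)
    repeats: list = field(default_factory=list)
    difficult_promoters: list = field(default_factory=list)
    gc_windows: list = field(default_factory=list)      # precomputed high-GC tiles
    cds: dict = field(default_factory=dict)             # gene -> CdsModel
    reference: object = None                            # pyfaidx Fasta or dict[str, str]
    _cache: dict = field(default_factory=dict, repr=False)

    # -- cached indexes ------------------------------------------------
    def _index(self, name: str, builder):
        if name not in self._cache:
            self._cache[name] = builder()
        return self._cache[name]

    def feature_index(self, label: str) -> IntervalArrayIndex:
        return self._index(f"feat:{label}", lambda: IntervalArrayIndex(
            iv for iv in self.gene_features if iv.label == label))

    def chromatin_index(self) -> LabelledIndex:
        return self._index("chromatin", lambda: LabelledIndex(self.chromatin, "Other"))

    def dhs_index(self) -> IntervalArrayIndex:
        return self._index("dhs", lambda: IntervalArrayIndex(self.dhs))

    def tfbs_index(self) -> IntervalArrayIndex:
        return self._index("tfbs", lambda: IntervalArrayIndex(self.tfbs))

    def exclusion_indexes(self) -> dict:
        def build():
            return {
                name: IntervalArrayIndex(getattr(self, name))
                for name in ("blacklist", "mappability", "segdup", "repeats")
                if getattr(self, name)
            }
        return self._index("exclusion", build)

    def difficult_index(self) -> IntervalArrayIndex:
        return self._index("difficult", lambda: IntervalArrayIndex(self.difficult_promoters))

    def gc_window_index(self) -> IntervalArrayIndex:
        return self._index("gcwin", lambda: IntervalArrayIndex(self.gc_windows))

    def upstream_index(self, window: int) -> IntervalArrayIndex:
        def build():
            ivs = []
            for t in self.tss:
                if t.strand == "-":
                    ivs.append(GenomicInterval(t.chrom, t.end, t.end + window, t.label, "-"))
                else:
                    start = max(0, t.start - window)
                    if start < t.start:
                        ivs.append(GenomicInterval(t.chrom, start, t.start, t.label, "+"))
            return IntervalArrayIndex(ivs)
        return self._index(f"up:{window}", build)

    def downstream_index(self, window: int) -> IntervalArrayIndex:
        def build():
            ivs = []
            for g in self.gene_spans:
                if g.strand == "-":
                    start = max(0, g.start - window)
                    if start < g.start:
                        ivs.append(GenomicInterval(g.chrom, start, g.start, g.label, "-"))
                else:
                    ivs.append(GenomicInterval(g.chrom, g.end, g.end + window, g.label, "+"))
            return IntervalArrayIndex(ivs)
        return self._index(f"down:{window}", build)

    def chrom_length(self, chrom: str) -> int | None:
        if self.reference is None:
            return None
        return len(self.reference[chrom])

    # -- persistence ---------------------------------------------------
    def write(self, outdir) -> None:
        from pathlib import Path
        from .io_formats import write_bed, write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tracks = {
            "gene_features": self.gene_features, "tss": self.tss,
            "gene_spans": self.gene_spans, "chromatin": self.chromatin,
            "dhs": self.dhs, "tfbs": self.tfbs, "blacklist": self.blacklist,
            "mappability": self.mappability, "segdup": self.segdup,
            "repeats": self.repeats,
            "difficult_promoters": self.difficult_promoters,
            "gc_windows": self.gc_windows,
        }
        for name, ivs in tracks.items():
            write_bed(ivs, outdir / f"{name}.bed")
        if self.cds:
            rows = []
            for model in self.cds.values():
                for start, end in model.exons:
                    rows.append(GenomicInterval(model.chrom, start, end,
                                                model.gene, model.strand))
            write_bed(rows, outdir / "cds.bed")
        if self.reference is not None and isinstance(self.reference, dict):
            write_fasta(self.reference, outdir / "reference.fa")

    @classmethod
    def load(cls, indir) -> "AnnotationTrackSet":
        from pathlib import Path
        from .io_formats import load_reference, read_bed_track

        indir = Path(indir)
        kwargs = {}
        for name in ("gene_features", "tss", "gene_spans", "chromatin", "dhs",
                     "tfbs", "blacklist", "mappability", "segdup", "repeats",
                     "difficult_promoters", "gc_windows"):
            path = indir / f"{name}.bed"
            kwargs[name] = read_bed_track(path) if path.exists() else []
        tracks = cls(**kwargs)
        cds_path = indir / "cds.bed"
        if cds_path.exists():
            by_gene: dict[str, CdsModel] = {}
            for iv in read_bed_track(cds_path):
                model = by_gene.setdefault(
                    iv.label, CdsModel(iv.label, iv.chrom, iv.strand, []))
                model.exons.append((iv.start, iv.end))
            for model in by_gene.values():
                model.exons.sort()
            tracks.cds = by_gene
        fasta = indir / "reference.fa"
        if fasta.exists():
            tracks.reference = load_reference(fasta)
        return tracks


# ---------------------------------------------------------------------------
# scalar operations (thin wrappers over the vectorised core)
# ---------------------------------------------------------------------------

def classify_gene_position(
    chrom: str, pos: int, tracks: AnnotationTrackSet, upstream_window: int = 1000
) -> str:
    """Gene-position class of a single 0-based position."""
    return _gene_class_vector(tracks, chrom, np.array([pos]), upstream_window)[0]


def chromatin_state(chrom: str, pos: int, tracks: AnnotationTrackSet) -> str:
    return str(tracks.chromatin_index().label_at(chrom, np.array([pos]))[0])


def count_tfbs(chrom: str, pos: int, tracks: AnnotationTrackSet) -> int:
    return int(tracks.tfbs_index().count(chrom, np.array([pos]))[0])


def gc_filter(chrom: str, pos: int, tracks: AnnotationTrackSet) -> bool:
    """True when the position should be excluded before enrichment testing."""
    return bool(_gc_excluded_vector(tracks, chrom, np.array([pos]))[0])


# ---------------------------------------------------------------------------
# vectorised core
# ---------------------------------------------------------------------------

def _gene_class_vector(tracks, chrom, positions, upstream_window):
    masks = [
        tracks.feature_index("exon").member(chrom, positions),
        tracks.feature_index("UTR5").member(chrom, positions),
        tracks.feature_index("UTR3").member(chrom, positions),
        tracks.upstream_index(upstream_window).member(chrom, positions),
        tracks.downstream_index(upstream_window).member(chrom, positions),
        tracks.feature_index("intron").member(chrom, positions),
    ]
    return np.select(masks, GENE_CLASS_PRECEDENCE, default="intergenic")


def _gc_excluded_vector(tracks, chrom, positions):
    positions = np.asarray(positions, dtype=np.int64)
    excluded = tracks.difficult_index().member(chrom, positions)
    if tracks.reference is not None:
        length = tracks.chrom_length(chrom)
        if length is not None and positions.size and positions.max() >= length:
            raise ValueError(
                f"position {int(positions.max())} beyond end of {chrom} ({length} bp)")
        tiles = positions // GC_WINDOW
        gc_by_tile = {}
        for tile in np.unique(tiles[~excluded]):
            start = int(tile) * GC_WINDOW
            seq = fetch_sequence(tracks.reference, chrom, start,
                                 min(start + GC_WINDOW, length or start + GC_WINDOW))
            gc = (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0
            gc_by_tile[int(tile)] = gc >= GC_THRESHOLD
        high = np.array([gc_by_tile.get(int(t), False) for t in tiles])
        excluded = excluded | high
    elif tracks.gc_windows:
        excluded = excluded | tracks.gc_window_index().member(chrom, positions)
    return excluded


def _nearest_gene_vector(tracks, chrom, positions):
    spans = [g for g in tracks.gene_spans if g.chrom == chrom]
    out = np.full(len(positions), "", dtype=object)
    if not spans:
        return out
    spans.sort(key=lambda g: g.start)
    starts = np.array([g.start for g in spans])
    ends = np.array([g.end for g in spans])
    names = np.array([g.label for g in spans], dtype=object)
    idx = np.clip(np.searchsorted(starts, positions, side="right") - 1, 0, len(spans) - 1)
    nxt = np.clip(idx + 1, 0, len(spans) - 1)

    def dist(i, pos):
        return np.where(pos < starts[i], starts[i] - pos,
                        np.where(pos >= ends[i], pos - ends[i] + 1, 0))

    d0, d1 = dist(idx, positions), dist(nxt, positions)
    best = np.where(d1 < d0, nxt, idx)
    return names[best]


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G"}.get(base, "N")


def is_nonsynonymous(
    chrom: str, pos: int, ref: str, alt: str, tracks: AnnotationTrackSet
) -> bool | None:
    """Whether an SNV changes the encoded amino acid.

    Requires a CDS-bearing gene model and a reference sequence; returns
    ``None`` when the position is outside every CDS, the variant is not
    an SNV, or no model is available.
    """
    if tracks.reference is None or not tracks.cds:
        return None
    if len(ref) != 1 or len(alt) != 1:
        return None
    for model in tracks.cds.values():
        if model.chrom != chrom:
            continue
        offsets, total = [], 0
        exon_list = model.exons if model.strand == "+" else list(reversed(model.exons))
        hit = None
        for start, end in exon_list:
            if start <= pos < end:
                if model.strand == "+":
                    hit = total + (pos - start)
                else:
                    hit = total + (end - 1 - pos)
            total += end - start
        if hit is None:
            continue
        parts = [fetch_sequence(tracks.reference, chrom, s, e) for s, e in model.exons]
        cds_seq = "".join(parts)
        if model.strand == "-":
            cds_seq = str(Seq(cds_seq).reverse_complement())
            alt_base = _complement(alt)
        else:
            alt_base = alt
        codon_i = hit // 3
        codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
        if len(codon) < 3:
            return None
        mutated = list(codon)
        mutated[hit % 3] = alt_base
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq("".join(mutated)).translate())
        return aa_ref != aa_alt
    return None


def annotate_positions(
    tracks: AnnotationTrackSet,
    df: pd.DataFrame,
    upstream_window: int = 1000,
) -> pd.DataFrame:
    """Annotate a table of variants (columns chrom, pos [1-based], ref, alt).

    Returns a copy with gene_class, nearest_gene, chromatin, dhs,
    tfbs_count, gc_excluded and nssnv columns appended.
    """
    df = df.reset_index(drop=True).copy()
    n = len(df)
    gene_class = np.full(n, "intergenic", dtype=object)
    nearest = np.full(n, "", dtype=object)
    chromatin = np.full(n, "Other", dtype=object)
    dhs = np.zeros(n, dtype=bool)
    tfbs_count = np.zeros(n, dtype=np.int64)
    gc_excluded = np.zeros(n, dtype=bool)

    known_chroms = {iv.chrom for iv in tracks.gene_spans} | \
                   {iv.chrom for iv in tracks.chromatin}
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        if known_chroms and chrom not in known_chroms:
            log.warning("chromosome %s absent from annotation tracks", chrom)
        gene_class[idx] = _gene_class_vector(tracks, chrom, pos0, upstream_window)
        nearest[idx] = _nearest_gene_vector(tracks, chrom, pos0)
        chromatin[idx] = tracks.chromatin_index().label_at(chrom, pos0)
        dhs[idx] = tracks.dhs_index().member(chrom, pos0)
        tfbs_count[idx] = tracks.tfbs_index().count(chrom, pos0)
        gc_excluded[idx] = _gc_excluded_vector(tracks, chrom, pos0)

    nssnv: list = [None] * n
    if tracks.cds and tracks.reference is not None and "ref" in df.columns:
        exonic = gene_class == "exon"
        for i in np.nonzero(exonic)[0]:
            row = df.iloc[i]
            nssnv[i] = is_nonsynonymous(row["chrom"], int(row["pos"]) - 1,
                                        str(row["ref"]), str(row["alt"]), tracks)

    df["gene_class"] = gene_class
    df["nearest_gene"] = nearest
    df["chromatin"] = chromatin
    df["dhs"] = dhs
    df["tfbs_count"] = tfbs_count
    df["gc_excluded"] = gc_excluded
    df["nssnv"] = nssnv
    return df


# ---------------------------------------------------------------------------
# cohort-level wrapper
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedDnv:
    call: DnvCall
    gene_class: str
    nearest_gene: str
    chromatin: str
    dhs: bool
    tfbs_count: int
    gc_excluded: bool
    nssnv: bool | None = None

    @property
    def tfbs_rich(self) -> bool:
        return self.tfbs_count >= TFBS_RICH_CUTOFF


def annotate_cohort(
    calls: Sequence[DnvCall],
    tracks: AnnotationTrackSet,
    upstream_window: int = 1000,
) -> list[AnnotatedDnv]:
    """Annotate every call in a cohort; order of the input is preserved."""
    if not calls:
        return []
    df = pd.DataFrame([
        {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt}
        for c in calls
    ])
    ann = annotate_positions(tracks, df, upstream_window)
    return [
        AnnotatedDnv(
            call=c,
            gene_class=str(row.gene_class),
            nearest_gene=str(row.nearest_gene),
            chromatin=str(row.chromatin),
            dhs=bool(row.dhs),
            tfbs_count=int(row.tfbs_count),
            gc_excluded=bool(row.gc_excluded),
            nssnv=row.nssnv,
        )
        for c, row in zip(calls, ann.itertuples(index=False))
    ]


def annotated_to_dataframe(annotated: Sequence[AnnotatedDnv]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "child_id": a.call.child_id, "chrom": a.call.chrom, "pos": a.call.pos,
            "ref": a.call.ref, "alt": a.call.alt, "class": a.call.vclass,
            "gene_class": a.gene_class, "nearest_gene": a.nearest_gene,
            "chromatin": a.chromatin, "dhs": a.dhs,
            "tfbs_count": a.tfbs_count, "gc_excluded": a.gc_excluded,
            "nssnv": a.nssnv,
        }
        for a in annotated
    ])
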