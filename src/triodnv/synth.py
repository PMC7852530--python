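"""Synthetic trio cohorts with known ground truth.

Every pipeline stage is testable without external data: this module
generates annotation tracks and a reference sequence, trio genotype
cohorts with planted de novo SNVs, read-level phasing evidence, large
control DNV sets, and dual-caller SV call sets with coverage profiles —
all deterministic under a fixed seed, and all emitted in exactly the
formats ``io_formats`` reads.

The default configuration mirrors a 71-trio whole-genome study design:
~59 de novo SNVs per child on average, a paternal-age effect of 1.56
DNVs per year, an ~4:1 paternal:maternal origin ratio, ~30x depth, and a
97,942-variant control cohort.  The genome itself is a small synthetic
one (two chromosomes, 2 Mb total, 60 genes) so that cohort-scale
simulations run at desk scale.

De novo positions are drawn from a per-base weight grid: each feature
(promoter chromatin, DHS, TFBS-rich core, enhancer) multiplies the
weight of the bases it covers by a configurable factor.  Note that with
multiplier ``m`` on a feature occupying weight fraction ``f`` of the
genome, the implied case:control enrichment ratio is ``m / (1 + (m-1) f)``
(slightly below ``m``); :meth:`SyntheticTracks.expected_enrichment_ratio`
returns the exact value, which is what recovery tests should target.

Every planted event is recorded in a :class:`GroundTruthLedger` together
with its expected pipeline fate, derived from the emitted data (e.g. a
DNV whose sampled allele balance falls outside [0.30, 0.70] is expected
to fail the allele-balance filter).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotate as _annotate
from .annotate import AnnotationTrackSet, CdsModel
from .io_formats import (
    GenomicInterval,
    Pedigree,
    ReadEvidence,
    SvCall,
    TrioGenotypeRecord,
    write_evidence_tsv,
    write_pedigree,
    write_sv_vcf,
    write_trio_vcf,
)
from .sv_consensus import CoverageSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortConfig:
    """Study-design parameters for the synthetic cohort generator."""

    # cohort
    n_trios: int = 71
    base_rate: float = 6.7        # lambda0; mean DNVs/child = lambda0 + slope * father_age
    age_slope: float = 1.56       # DNVs per year of paternal age
    father_age_range: tuple = (22, 45)
    paternal_fraction: float = 0.8

    # genome & tracks
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_200_000,
                                                         "chr2": 800_000})
    n_genes: int = 60
    promoter_halfwidth: int = 500
    dhs_promoter_fraction: float = 0.5
    tfbs_rich_fraction: float = 0.35
    n_enhancers: int = 40
    n_intergenic_dhs: int = 20
    n_gc_rich_windows: int = 40
    n_difficult_promoters: int = 5

    # feature placement multipliers for case DNVs (1.0 = neutral)
    multipliers: dict = field(default_factory=lambda: {
        "promoter": 1.0, "dhs": 1.0, "tfbs": 1.0, "enhancer": 1.0})

    # genotype emission
    depth_mean: float = 30.0
    gq_range: tuple = (45, 99)
    low_gq_fraction: float = 0.0      # planted DNVs given a failing posterior
    background_sites: int = 150       # inherited (non-DNV) sites per trio
    hom_alt_decoys: int = 2           # child 1/1, parents 0/0 per trio

    # phasing evidence
    informative_fraction: float = 0.1
    supporting_reads: int = 3
    single_read_fraction: float = 0.05

    # control cohort
    control_size: int = 97_942

    # SV simulation (one trio)
    sv_n_true: int = 5
    sv_n_inherited: int = 8
    sv_n_artifact: int = 5
    sv_n_excluded: int = 4
    sv_n_consensus_fail: int = 3
    sv_len_range: tuple = (1000, 8000)
    sv_jitter_frac: float = 0.05
    coverage_bin: int = 100
    coverage_noise_sd: float = 1.0

    seed: int = 0


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class DnvTruth:
    family_id: str
    child_id: str
    chrom: str
    pos: int                   # 1-based
    ref: str
    alt: str
    origin: str                # paternal | maternal
    supporting_reads: int      # phasing reads emitted (0 = no evidence)
    expected_origin: str       # what assign_origin should return
    expected_fate: str         # accepted | filter_quality | filter_allele_balance
    features: dict             # promoter/dhs/tfbs_rich/enhancer/gc_excluded flags


@dataclass
class SvTruth:
    sv_id: str
    category: str              # true_de_novo | inherited | artifact | excluded | consensus_fail
    chrom: str
    start: int
    end: int
    svtype: str
    expected_stage: str | None  # first failing filter stage; None = survives


@dataclass
class GroundTruthLedger:
    dnvs: list = field(default_factory=list)
    hom_alt_decoys: list = field(default_factory=list)   # (family, chrom, pos)
    svs: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "dnvs": [asdict(d) for d in self.dnvs],
            "hom_alt_decoys": self.hom_alt_decoys,
            "svs": [asdict(s) for s in self.svs],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruthLedger":
        payload = json.loads(Path(path).read_text())
        return cls(
            dnvs=[DnvTruth(**d) for d in payload["dnvs"]],
            hom_alt_decoys=[tuple(x) for x in payload["hom_alt_decoys"]],
            svs=[SvTruth(**s) for s in payload["svs"]],
        )


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _mask_from_intervals(length: int, intervals, min_count: int = 1) -> np.ndarray:
    """Boolean occupancy mask built by difference-array accumulation."""
    diff = np.zeros(length + 1, dtype=np.int32)
    for start, end in intervals:
        diff[max(0, start)] += 1
        diff[min(length, end)] -= 1
    return np.cumsum(diff[:-1]) >= min_count


class SyntheticTracks:
    """Generated annotation tracks plus the machinery to sample positions."""

    def __init__(self, config: SyntheticCohortConfig, trackset: AnnotationTrackSet,
                 masks: dict):
        self.config = config
        self.trackset = trackset
        self.masks = masks            # feature -> {chrom: bool array}
        self.chroms = list(config.chrom_lengths)
        self._weight_cache: dict = {}

    # -- weights -------------------------------------------------------
    def _weights(self, multipliers: Mapping[str, float]):
        key = tuple(sorted((k, float(v)) for k, v in multipliers.items()))
        if key in self._weight_cache:
            return self._weight_cache[key]
        per_chrom = {}
        for chrom, length in self.config.chrom_lengths.items():
            w = np.ones(length)
            for feature, mult in multipliers.items():
                if mult != 1.0 and feature in self.masks:
                    w[self.masks[feature][chrom]] *= mult
            per_chrom[chrom] = w
        totals = np.array([per_chrom[c].sum() for c in self.chroms])
        cum = {c: np.cumsum(per_chrom[c]) for c in self.chroms}
        self._weight_cache[key] = (per_chrom, totals, cum)
        return self._weight_cache[key]

    def sample_positions(self, n: int, rng, multipliers=None):
        """Draw ``n`` distinct (chrom, pos0) pairs, feature-weighted."""
        multipliers = multipliers or {}
        _, totals, cum = self._weights(multipliers)
        out: list = []
        seen = set()
        while len(out) < n:
            need = n - len(out)
            counts = rng.multinomial(need, totals / totals.sum())
            for ci, k in enumerate(counts):
                if k == 0:
                    continue
                chrom = self.chroms[ci]
                u = rng.random(k) * totals[ci]
                pos = np.searchsorted(cum[chrom], u, side="right")
                np.minimum(pos, self.config.chrom_lengths[chrom] - 1, out=pos)
                for p in pos:
                    key = (chrom, int(p))
                    if key not in seen:
                        seen.add(key)
                        out.append(key)
        return out

    def expected_feature_probability(self, feature: str, multipliers=None,
                                     exclude_gc: bool = False) -> float:
        """Exact P(sampled position carries the feature) under the weights.

        With ``exclude_gc`` the probability is conditional on surviving
        the GC/difficult-promoter exclusion, matching what an enrichment
        table computes after symmetric filtering.
        """
        multipliers = multipliers or {}
        per_chrom, totals, _ = self._weights(multipliers)
        mass = denom = 0.0
        for c in self.chroms:
            keep = (~self.masks["gc_excluded"][c] if exclude_gc
                    else np.ones(len(per_chrom[c]), dtype=bool))
            mass += per_chrom[c][self.masks[feature][c] & keep].sum()
            denom += per_chrom[c][keep].sum()
        return mass / denom

    def expected_enrichment_ratio(self, feature: str, case_multipliers,
                                  control_multipliers=None,
                                  exclude_gc: bool = False) -> float:
        """The generator's implied case:control ratio of feature proportions."""
        p_case = self.expected_feature_probability(feature, case_multipliers,
                                                   exclude_gc)
        p_ctrl = self.expected_feature_probability(feature, control_multipliers,
                                                   exclude_gc)
        return p_case / p_ctrl

    def ref_base(self, chrom: str, pos0: int) -> str:
        return self.trackset.reference[chrom][pos0]

    def write(self, outdir) -> None:
        self.trackset.write(outdir)


def _place_free(rng, chrom_len: int, occupied: list, length: int,
                margin: int = 0, max_tries: int = 200) -> int | None:
    """Find a start for an interval of ``length`` avoiding occupied spans."""
    for _ in range(max_tries):
        start = int(rng.integers(margin, max(margin + 1, chrom_len - length - margin)))
        end = start + length
        if all(end + margin <= s or e + margin <= start for s, e in occupied):
            occupied.append((start, end))
            return start
    return None


def simulate_tracks(config: SyntheticCohortConfig) -> SyntheticTracks:
    """Generate gene models, chromatin states, DHS/TFBS tracks, exclusion
    tracks, GC-rich windows and a matching reference sequence."""
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())

    gene_features, tss_list, spans, chromatin = [], [], [], []
    dhs, tfbs, enhancers = [], [], []
    cds: dict = {}
    promoters: list[GenomicInterval] = []
    occupied = {c: [] for c in chroms}

    # genes proportional to chromosome length
    per_chrom = {c: max(1, round(config.n_genes * config.chrom_lengths[c] / total_len))
                 for c in chroms}
    gene_no = 0
    for chrom in chroms:
        chrom_len = config.chrom_lengths[chrom]
        cursor = 1500
        for _ in range(per_chrom[chrom]):
            cursor += int(rng.integers(3000, 9000))
            utr5, utr3, exon = 200, 300, 300
            introns = [int(rng.integers(600, 900)) for _ in range(2)]
            tx_len = utr5 + 3 * exon + sum(introns) + utr3
            if cursor + 1500 + tx_len + 1500 > chrom_len - 1500:
                raise ValueError(
                    f"genome too small: cannot place {config.n_genes} genes "
                    f"in {total_len} bp")
            strand = "+" if rng.random() < 0.5 else "-"
            gene = f"GENE{gene_no:03d}"
            gene_no += 1
            t = cursor + 1500
            # genomic block layout (left to right)
            if strand == "+":
                labels = ["UTR5", "exon", "intron", "exon", "intron", "exon", "UTR3"]
            else:
                labels = ["UTR3", "exon", "intron", "exon", "intron", "exon", "UTR5"]
            sizes = ([utr5, exon, introns[0], exon, introns[1], exon, utr3]
                     if strand == "+"
                     else [utr3, exon, introns[0], exon, introns[1], exon, utr5])
            pos = t
            exon_ivs = []
            for label, size in zip(labels, sizes):
                iv = GenomicInterval(chrom, pos, pos + size, label, strand)
                gene_features.append(iv)
                if label == "exon":
                    exon_ivs.append((pos, pos + size))
                pos += size
            tx_end = pos
            spans.append(GenomicInterval(chrom, t, tx_end, gene, strand))
            cds[gene] = CdsModel(gene, chrom, strand, exon_ivs)
            tss_pos = t if strand == "+" else tx_end - 1
            tss_list.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, gene, strand))
            hw = config.promoter_halfwidth
            prom = GenomicInterval(chrom, max(0, tss_pos - hw), tss_pos + hw,
                                   "Promoter", strand)
            chromatin.append(prom)
            promoters.append(prom)
            # DHS / TFBS inside the promoter
            if rng.random() < config.dhs_promoter_fraction:
                dhs.append(GenomicInterval(chrom, tss_pos - 150, tss_pos + 150, "DHS"))
            core_s, core_e = tss_pos - 50, tss_pos + 50
            n_sites = 12 if rng.random() < config.tfbs_rich_fraction else 3
            for j in range(n_sites):
                tfbs.append(GenomicInterval(chrom, core_s - 5 * j, core_e + 5 * j,
                                            f"TF{j}"))
            occupied[chrom].append((t - 1500, tx_end + 1500))
            cursor = tx_end
    # enhancers and intergenic DHS in free space
    for i in range(config.n_enhancers):
        chrom = chroms[i % len(chroms)]
        start = _place_free(rng, config.chrom_lengths[chrom], occupied[chrom],
                            500, margin=200)
        if start is not None:
            iv = GenomicInterval(chrom, start, start + 500, "Enhancer")
            chromatin.append(iv)
            enhancers.append(iv)
    for i in range(config.n_intergenic_dhs):
        chrom = chroms[i % len(chroms)]
        start = _place_free(rng, config.chrom_lengths[chrom], occupied[chrom],
                            200, margin=200)
        if start is not None:
            dhs.append(GenomicInterval(chrom, start, start + 200, "DHS"))
    # exclusion tracks (also give the SV simulator somewhere to hide decoys)
    blacklist, repeats, mappability, segdup = [], [], [], []
    for target, n, size in ((blacklist, 3, 6000), (repeats, 10, 2000),
                            (mappability, 3, 2500), (segdup, 2, 3000)):
        for i in range(n):
            chrom = chroms[i % len(chroms)]
            start = _place_free(rng, config.chrom_lengths[chrom], occupied[chrom],
                                size, margin=500)
            if start is not None:
                target.append(GenomicInterval(chrom, start, start + size, "exclude"))

    # difficult promoters
    n_diff = min(config.n_difficult_promoters, len(promoters))
    diff_idx = rng.choice(len(promoters), size=n_diff, replace=False)
    difficult = [GenomicInterval(p.chrom, p.start, p.end, "difficult")
                 for p in (promoters[i] for i in diff_idx)]

    # GC-rich 100 bp tiles: half inside promoters, half anywhere
    gc_tiles = set()
    n_gc = config.n_gc_rich_windows
    prom_pool = [p for p in promoters]
    for _ in range(n_gc // 2):
        p = prom_pool[int(rng.integers(len(prom_pool)))]
        tile = int(rng.integers(p.start, p.end)) // 100
        gc_tiles.add((p.chrom, tile))
    while len(gc_tiles) < n_gc:
        chrom = chroms[int(rng.integers(len(chroms)))]
        tile = int(rng.integers(config.chrom_lengths[chrom])) // 100
        gc_tiles.add((chrom, tile))
    gc_windows = [GenomicInterval(c, t * 100, (t + 1) * 100, "highGC")
                  for c, t in sorted(gc_tiles)]

    # reference sequence consistent with the GC tiles (~40% background GC)
    reference = {}
    byte_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    hi_gc_tile = np.frombuffer(b"GC" * 40 + b"AT" * 10, dtype=np.uint8).copy()
    for chrom, length in config.chrom_lengths.items():
        idx = rng.choice(4, size=length, p=[0.30, 0.20, 0.20, 0.30])
        arr = byte_map[idx]
        for c, t in gc_tiles:
            if c != chrom or (t + 1) * 100 > length:
                continue
            tile = hi_gc_tile.copy()
            rng.shuffle(tile)
            arr[t * 100:(t + 1) * 100] = tile
        reference[chrom] = arr.tobytes().decode("ascii")

    trackset = AnnotationTrackSet(
        gene_features=gene_features, tss=tss_list, gene_spans=spans,
        chromatin=sorted(chromatin, key=lambda iv: (iv.chrom, iv.start)),
        dhs=dhs, tfbs=tfbs, blacklist=blacklist, mappability=mappability,
        segdup=segdup, repeats=repeats, difficult_promoters=difficult,
        gc_windows=gc_windows, cds=cds, reference=reference,
    )

    # ground-truth masks (difference-array construction, independent of the
    # searchsorted annotation path)
    masks: dict = {}
    for feature, ivs in (("promoter", [p for p in promoters]),
                         ("enhancer", enhancers),
                         ("dhs", dhs)):
        masks[feature] = {
            c: _mask_from_intervals(config.chrom_lengths[c],
                                    [(iv.start, iv.end) for iv in ivs if iv.chrom == c])
            for c in chroms}
    masks["tfbs"] = {
        c: _mask_from_intervals(config.chrom_lengths[c],
                                [(iv.start, iv.end) for iv in tfbs if iv.chrom == c],
                                min_count=10)
        for c in chroms}
    gc_iv = [(iv.chrom, iv.start, iv.end) for iv in gc_windows] + \
            [(iv.chrom, iv.start, iv.end) for iv in difficult]
    masks["gc_excluded"] = {
        c: _mask_from_intervals(config.chrom_lengths[c],
                                [(s, e) for cc, s, e in gc_iv if cc == c])
        for c in chroms}
    return SyntheticTracks(config, trackset, masks)


# ---------------------------------------------------------------------------
# trio cohort
# ---------------------------------------------------------------------------

@dataclass
class TrioData:
    pedigree: Pedigree
    records: list          # TrioGenotypeRecord, sorted
    truths: list           # DnvTruth for this trio


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    trios: list
    evidence: list
    ledger: GroundTruthLedger

    @property
    def pedigrees(self) -> list:
        return [t.pedigree for t in self.trios]


def expected_acceptance_probability(config: SyntheticCohortConfig,
                                    ab_low: float = 0.30,
                                    ab_high: float = 0.70) -> float:
    """Exact probability that an emitted DNV passes the standard filters.

    Depth is ``max(10, Poisson(depth_mean))`` and the alt count is
    Binomial(depth, 1/2), so a computable tail of true DNVs falls outside
    the allele-balance window; genotype posteriors fail at the configured
    ``low_gq_fraction``.  The product gives the per-variant acceptance
    probability — the factor by which cohort-level rates (e.g. the
    paternal-age slope of *accepted* counts) are attenuated.
    """
    from scipy import stats as _stats

    mu = config.depth_mean
    depths = np.arange(0, int(mu + 10 * np.sqrt(mu)) + 1)
    p_depth = _stats.poisson.pmf(depths, mu)
    p_depth[10] += p_depth[:10].sum()    # depth clamped below at 10
    p_ab = 0.0
    for d, pd_ in zip(depths[10:], p_depth[10:]):
        lo = int(np.ceil(ab_low * d - 1e-9))
        hi = int(np.floor(ab_high * d + 1e-9))
        p_ab += pd_ * (_stats.binom.cdf(hi, d, 0.5) - _stats.binom.cdf(lo - 1, d, 0.5))
    return p_ab * (1.0 - config.low_gq_fraction)


def _alt_base(rng, ref: str) -> str:
    others = [b for b in "ACGT" if b != ref]
    return others[int(rng.integers(3))]


def _expected_fate(gq_trio, ab) -> str:
    if min(gq_trio) < 20:
        return "filter_quality"
    if ab is None or not (0.30 - 1e-12 <= ab <= 0.70 + 1e-12):
        return "filter_allele_balance"
    return "accepted"


def simulate_trio_cohort(
    config: SyntheticCohortConfig, tracks: SyntheticTracks, seed: int | None = None
) -> SyntheticCohort:
    """Emit genotype records, phasing reads and ground truth for every trio.

    Per child the DNV count is Poisson with mean ``base_rate +
    age_slope * father_age``; positions are drawn from the feature-
    weighted grid; depths are ~Poisson(30) with a Binomial(depth, 0.5)
    alt count, so a small tail of true DNVs naturally falls outside the
    30–70% allele-balance window (their expected fate records this).

    ``seed`` overrides ``config.seed`` for the cohort draw, so replicate
    studies can reuse one simulated track set.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    lo, hi = config.father_age_range
    trios, evidence = [], []
    ledger = GroundTruthLedger()
    for i in range(config.n_trios):
        fam = f"fam{i:04d}"
        ped = Pedigree(
            family_id=fam, child_id=f"{fam}c", father_id=f"{fam}f",
            mother_id=f"{fam}m",
            child_sex="F" if rng.random() < 0.85 else "M",
            father_age=float(rng.integers(lo, hi + 1)),
            mother_age=None,
        )
        # mother's age correlates with father's but keeps enough independent
        # spread for the conditional regression to be identifiable
        mother_age = float(np.clip(round(ped.father_age - 2 + rng.normal(0, 3.5)),
                                   18, hi))
        ped = Pedigree(ped.family_id, ped.child_id, ped.father_id, ped.mother_id,
                       ped.child_sex, ped.father_age, mother_age)
        records, truths = [], []
        used = set()

        n_dnv = rng.poisson(config.base_rate + config.age_slope * ped.father_age)
        positions = tracks.sample_positions(n_dnv, rng, config.multipliers)
        used.update(positions)
        for chrom, pos0 in positions:
            ref = tracks.ref_base(chrom, pos0)
            alt = _alt_base(rng, ref)
            depth = max(10, int(rng.poisson(config.depth_mean)))
            alt_depth = int(rng.binomial(depth, 0.5))
            gqs = [int(rng.integers(*config.gq_range)) for _ in range(3)]
            if config.low_gq_fraction and rng.random() < config.low_gq_fraction:
                gqs[0] = int(rng.integers(5, 20))
            origin = "paternal" if rng.random() < config.paternal_fraction else "maternal"
            ab = alt_depth / depth if depth else None
            pd_depth = max(10, int(rng.poisson(config.depth_mean)))
            md_depth = max(10, int(rng.poisson(config.depth_mean)))
            records.append(TrioGenotypeRecord(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                genotypes={"child": (0, 1), "father": (0, 0), "mother": (0, 0)},
                allele_depths={"child": (depth - alt_depth, alt_depth),
                               "father": (pd_depth, 0), "mother": (md_depth, 0)},
                qualities={"child": float(gqs[0]), "father": float(gqs[1]),
                           "mother": float(gqs[2])},
            ))
            # phasing evidence
            n_support = 0
            if rng.random() < config.informative_fraction:
                offset = int(rng.integers(80, 301)) * (1 if rng.random() < 0.5 else -1)
                inf_pos0 = pos0 + offset
                chrom_len = config.chrom_lengths[chrom]
                if 0 <= inf_pos0 < chrom_len and (chrom, inf_pos0) not in used:
                    used.add((chrom, inf_pos0))
                    inf_ref = tracks.ref_base(chrom, inf_pos0)
                    inf_alt = _alt_base(rng, inf_ref)
                    father_hom_alt = rng.random() < 0.5
                    pat_allele = 1 if father_hom_alt else 0
                    mat_allele = 1 - pat_allele
                    d = max(10, int(rng.poisson(config.depth_mean)))
                    records.append(TrioGenotypeRecord(
                        chrom=chrom, pos=inf_pos0 + 1, ref=inf_ref, alt=inf_alt,
                        genotypes={"child": (0, 1),
                                   "father": (1, 1) if father_hom_alt else (0, 0),
                                   "mother": (0, 0) if father_hom_alt else (1, 1)},
                        allele_depths={"child": (d // 2, d - d // 2),
                                       "father": (0, d) if father_hom_alt else (d, 0),
                                       "mother": (d, 0) if father_hom_alt else (0, d)},
                        qualities={m: float(rng.integers(*config.gq_range))
                                   for m in ("child", "father", "mother")},
                    ))
                    hap_allele = pat_allele if origin == "paternal" else mat_allele
                    hap_base = inf_alt if hap_allele == 1 else inf_ref
                    other_base = inf_ref if hap_allele == 1 else inf_alt
                    n_support = (1 if rng.random() < config.single_read_fraction
                                 else config.supporting_reads)
                    for k in range(n_support):
                        obs = sorted([(pos0 + 1, alt), (inf_pos0 + 1, hap_base)])
                        evidence.append(ReadEvidence(
                            f"{fam}_p{pos0}_r{k}", ped.child_id, obs))
                    for k in range(2):
                        obs = sorted([(pos0 + 1, ref), (inf_pos0 + 1, other_base)])
                        evidence.append(ReadEvidence(
                            f"{fam}_p{pos0}_o{k}", ped.child_id, obs))
            expected_origin = origin if n_support >= 2 else "unassigned"
            truth = DnvTruth(
                family_id=fam, child_id=ped.child_id, chrom=chrom, pos=pos0 + 1,
                ref=ref, alt=alt, origin=origin, supporting_reads=n_support,
                expected_origin=expected_origin,
                expected_fate=_expected_fate(gqs, ab),
                features={f: bool(tracks.masks[f][chrom][pos0])
                          for f in ("promoter", "dhs", "tfbs", "enhancer",
                                    "gc_excluded")},
            )
            truths.append(truth)
            ledger.dnvs.append(truth)

        # inherited background sites (never de novo)
        patterns = [((0, 1), (0, 1), (0, 0)), ((0, 1), (0, 0), (0, 1)),
                    ((0, 0), (0, 1), (0, 1)), ((1, 1), (0, 1), (0, 1)),
                    ((0, 1), (1, 1), (0, 0)), ((0, 1), (0, 1), (0, 1))]
        bg = 0
        while bg < config.background_sites:
            chrom = tracks.chroms[int(rng.integers(len(tracks.chroms)))]
            pos0 = int(rng.integers(config.chrom_lengths[chrom]))
            if (chrom, pos0) in used:
                continue
            used.add((chrom, pos0))
            bg += 1
            ref = tracks.ref_base(chrom, pos0)
            alt = _alt_base(rng, ref)
            gts = patterns[int(rng.integers(len(patterns)))]
            depths = {}
            for member, gt in zip(("child", "father", "mother"), gts):
                d = max(10, int(rng.poisson(config.depth_mean)))
                n_alt = sum(gt)
                if n_alt == 0:
                    depths[member] = (d, 0)
                elif n_alt == 2:
                    depths[member] = (0, d)
                else:
                    a = int(rng.binomial(d, 0.5))
                    depths[member] = (d - a, a)
            records.append(TrioGenotypeRecord(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                genotypes=dict(zip(("child", "father", "mother"), gts)),
                allele_depths=depths,
                qualities={m: float(rng.integers(*config.gq_range))
                           for m in ("child", "father", "mother")},
            ))
        # hom-alt Mendelian-violation decoys (genotyping-error pattern)
        for _ in range(config.hom_alt_decoys):
            chrom = tracks.chroms[int(rng.integers(len(tracks.chroms)))]
            pos0 = int(rng.integers(config.chrom_lengths[chrom]))
            if (chrom, pos0) in used:
                continue
            used.add((chrom, pos0))
            ref = tracks.ref_base(chrom, pos0)
            d = max(10, int(rng.poisson(config.depth_mean)))
            records.append(TrioGenotypeRecord(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=_alt_base(rng, ref),
                genotypes={"child": (1, 1), "father": (0, 0), "mother": (0, 0)},
                allele_depths={"child": (0, d), "father": (d, 0), "mother": (d, 0)},
                qualities={m: float(rng.integers(*config.gq_range))
                           for m in ("child", "father", "mother")},
            ))
            ledger.hom_alt_decoys.append((fam, chrom, pos0 + 1))

        records.sort(key=lambda r: (r.chrom, r.pos))
        trios.append(TrioData(ped, records, truths))
    return SyntheticCohort(config, trios, evidence, ledger)


def write_cohort(cohort: SyntheticCohort, tracks: SyntheticTracks, outdir) -> None:
    """Write the cohort in the on-disk formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(cohort.pedigrees, outdir / "pedigree.tsv")
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for trio in cohort.trios:
        write_trio_vcf(vcf_dir / f"{trio.pedigree.family_id}.vcf", trio.records,
                       trio.pedigree, contigs=cohort.config.chrom_lengths)
    write_evidence_tsv(cohort.evidence, outdir / "evidence.tsv")
    cohort.ledger.to_json(outdir / "ledger.json")
    tracks.write(outdir / "tracks")


# ---------------------------------------------------------------------------
# control set
# ---------------------------------------------------------------------------

def simulate_control_set(
    config: SyntheticCohortConfig,
    tracks: SyntheticTracks,
    size: int | None = None,
    multipliers: Mapping[str, float] | None = None,
    seed_offset: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """A large annotated DNV table emulating a population control cohort.

    Positions are drawn with neutral (or explicitly supplied) feature
    multipliers and annotated through the standard annotation path, so
    the table is directly usable as the control arm of
    :func:`triodnv.enrich.enrichment_table`.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + seed_offset)
    size = config.control_size if size is None else size
    positions = tracks.sample_positions(size, rng, multipliers or {})
    refs = [tracks.ref_base(c, p) for c, p in positions]
    alts = [_alt_base(rng, r) for r in refs]
    df = pd.DataFrame({
        "chrom": [c for c, _ in positions],
        "pos": [p + 1 for _, p in positions],
        "ref": refs,
        "alt": alts,
    })
    return _annotate.annotate_positions(tracks.trackset, df)


# ---------------------------------------------------------------------------
# SV call sets and coverage
# ---------------------------------------------------------------------------

@dataclass
class SvSimulation:
    child_callsets: dict       # caller -> [SvCall] (caller A first)
    parental_calls: list       # both parents, both callers, called + candidate
    coverage: CoverageSet
    truths: list               # SvTruth
    sample_ids: dict           # member -> sample id


def _jitter_call(rng, chrom, start, end, frac, caller, sample, status="called"):
    span = end - start
    j1 = int(rng.integers(0, max(1, int(frac * span))))
    j2 = int(rng.integers(0, max(1, int(frac * span))))
    s, e = start + j1, end + j2
    return SvCall(chrom, s, e, "DEL", (e - s) + 1, caller, sample, status)


def simulate_sv_data(
    config: SyntheticCohortConfig, tracks: SyntheticTracks, seed_offset: int = 3,
    seed: int | None = None,
) -> SvSimulation:
    """Dual-caller SV call sets for one trio, with planted ground truth.

    Categories and their expected first-failing pipeline stage:

    * ``true_de_novo`` — in both child callsets (breakpoints jittered
      below the reciprocal-overlap threshold), absent from parents,
      child-only interior depth drop: survives every filter;
    * ``consensus_fail`` — single-caller or heavily jittered: consensus;
    * ``inherited`` — also present in a parent (alternately as a
      confident call and a low-confidence candidate): parental;
    * ``excluded`` — planted inside a blacklist region: annotation;
    * ``artifact`` — trio-shared coverage dip: coverage.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + seed_offset)
    chroms = list(config.chrom_lengths)
    sample_ids = {"child": "sv_child", "father": "sv_father", "mother": "sv_mother"}
    occupied = {c: [(g.start - 2000, g.end + 2000) for g in tracks.trackset.gene_spans
                    if g.chrom == c] for c in chroms}
    for name in ("blacklist", "repeats", "mappability", "segdup"):
        for iv in getattr(tracks.trackset, name):
            occupied[iv.chrom].append((iv.start, iv.end))

    calls_a: list[SvCall] = []   # breakpoint-precise caller
    calls_b: list[SvCall] = []
    parental: list[SvCall] = []
    truths: list[SvTruth] = []
    dips: list = []              # (sample(s), chrom, start, end, factor)
    lo, hi = config.sv_len_range
    jit = config.sv_jitter_frac
    counter = 0

    def plant(category, n):
        nonlocal counter
        for k in range(n):
            length = int(rng.integers(lo, hi))
            if category == "excluded":
                pool = [iv for iv in tracks.trackset.blacklist if iv.span > 2000]
                if not pool:
                    raise ValueError("no blacklist interval large enough for decoys")
                iv = pool[int(rng.integers(len(pool)))]
                chrom, start = iv.chrom, iv.start + 500
                end = start + min(length, iv.span - 1000)
            else:
                chrom = chroms[counter % len(chroms)]
                # margin >= the coverage-filter flank keeps the similarity
                # windows of neighbouring plants disjoint
                start = _place_free(rng, config.chrom_lengths[chrom],
                                    occupied[chrom], length,
                                    margin=max(length, 2000), max_tries=500)
                if start is None:
                    raise ValueError("genome too small for requested SV fixtures")
                end = start + length
            counter += 1
            sv_id = f"sv{counter:03d}"
            expected = None
            if category in ("true_de_novo", "inherited", "excluded", "artifact"):
                calls_a.append(SvCall(chrom, start, end, "DEL", (end - start) + 1,
                                      "callerA", sample_ids["child"]))
                calls_b.append(_jitter_call(rng, chrom, start, end, jit,
                                            "callerB", sample_ids["child"]))
            if category == "true_de_novo":
                dips.append((("child",), chrom, start, end, 0.5))
            elif category == "inherited":
                status = "called" if k % 2 == 0 else "candidate"
                parental.append(_jitter_call(rng, chrom, start, end, jit,
                                             "callerA", sample_ids["father"], status))
                dips.append((("child", "father"), chrom, start, end, 0.5))
                expected = "parental"
            elif category == "excluded":
                dips.append((("child",), chrom, start, end, 0.5))
                expected = "annotation"
            elif category == "artifact":
                dips.append((("child", "father", "mother"), chrom, start, end, 0.6))
                expected = "coverage"
            elif category == "consensus_fail":
                calls_a.append(SvCall(chrom, start, end, "DEL", (end - start) + 1,
                                      "callerA", sample_ids["child"]))
                if k % 2 == 0:
                    # heavily jittered partner: reciprocal overlap < 0.5
                    shift = int(0.75 * length)
                    calls_b.append(SvCall(chrom, start + shift, end + shift, "DEL",
                                          (end - start) + 1, "callerB",
                                          sample_ids["child"]))
                dips.append((("child",), chrom, start, end, 0.5))
                expected = "consensus"
            truths.append(SvTruth(sv_id, category, chrom, start, end, "DEL", expected))

    plant("true_de_novo", config.sv_n_true)
    plant("inherited", config.sv_n_inherited)
    plant("artifact", config.sv_n_artifact)
    plant("excluded", config.sv_n_excluded)
    plant("consensus_fail", config.sv_n_consensus_fail)

    # binned coverage with the planted dosage changes
    bin_size = config.coverage_bin
    depth: dict = {m: {} for m in ("child", "father", "mother")}
    for chrom, length in config.chrom_lengths.items():
        nbins = -(-length // bin_size)
        for member in depth:
            depth[member][chrom] = 30.0 + rng.normal(
                0.0, config.coverage_noise_sd, nbins)
    for members, chrom, start, end, factor in dips:
        b0, b1 = start // bin_size, end // bin_size
        for member in members:
            depth[member][chrom][b0:b1] *= factor
    coverage = CoverageSet(depth, bin_size)

    return SvSimulation(
        child_callsets={"callerA": calls_a, "callerB": calls_b},
        parental_calls=parental,
        coverage=coverage,
        truths=truths,
        sample_ids=sample_ids,
    )


def write_sv_data(sim: SvSimulation, outdir, contigs=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for caller, calls in sim.child_callsets.items():
        write_sv_vcf(calls, outdir / f"child_{caller}.vcf", contigs)
    write_sv_vcf(sim.parental_calls, outdir / "parental_callerA.vcf", contigs)
    sim.coverage.to_dataframe().to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    Path(outdir / "sv_truths.json").write_text(
        json.dumps([asdict(t) for t in sim.truths], indent=1))
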