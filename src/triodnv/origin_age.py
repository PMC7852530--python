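"""Parent-of-origin assignment of de novo variants and paternal-age regression.

A de novo allele can be traced to the parental gamete it arose in when a
sequencing read (or read pair) carries both the de novo allele and a
nearby inherited heterozygous SNV whose alleles can be assigned
unambiguously to one parent (an "informative" site, e.g. father 1/1 and
mother 0/0).  Each such read votes for one parent; an origin is assigned
only when one parent collects at least two votes and the other none —
any opposing vote voids the assignment.

Because most de novo mutations arise in the continuously dividing male
germ line, the paternal:maternal ratio is expected near 4:1 and the
per-child DNV count rises roughly linearly with the father's age at
conception; ``age_regression`` fits that line by ordinary least squares,
marginally and conditioning on the mother's age.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .dnv_calling import DnvCall
from .io_formats import ReadEvidence, TrioGenotypeRecord

log = logging.getLogger(__name__)

MIN_SUPPORTING_READS = 2
DEFAULT_SEARCH_WINDOW = 500  # bp either side of the DNV


@dataclass(frozen=True)
class InformativeSite:
    """A child-het site whose two alleles map uniquely onto the parents."""

    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str
    paternal_allele: int   # 0 (ref) or 1 (alt) — the allele the father passed on
    maternal_allele: int

    def allele_base(self, index: int) -> str:
        return self.alt if index == 1 else self.ref


def _informative_from_record(rec: TrioGenotypeRecord) -> InformativeSite | None:
    child = rec.genotypes.get("child")
    father = rec.genotypes.get("father")
    mother = rec.genotypes.get("mother")
    if child != (0, 1) or father is None or mother is None:
        return None
    f_hom = father[0] == father[1]
    m_hom = mother[0] == mother[1]
    if f_hom and m_hom:
        if father[0] == mother[0]:
            return None  # both parents same homozygote: Mendelian violation at a het child
        pat, mat = father[0], mother[0]
    elif f_hom:
        pat = father[0]
        mat = 1 - pat
        if mat not in mother:
            return None  # inconsistent inheritance
    elif m_hom:
        mat = mother[0]
        pat = 1 - mat
        if pat not in father:
            return None
    else:
        return None  # both parents heterozygous: ambiguous
    return InformativeSite(rec.chrom, rec.pos, rec.ref, rec.alt, pat, mat)


def find_informative_snvs(
    dnv: DnvCall,
    records: Iterable[TrioGenotypeRecord],
    window: int = DEFAULT_SEARCH_WINDOW,
) -> list[InformativeSite]:
    """Informative heterozygous sites within ``window`` bp of the DNV."""
    sites = []
    for rec in records:
        if rec.chrom != dnv.chrom or rec.pos == dnv.pos:
            continue
        if abs(rec.pos - dnv.pos) > window:
            continue
        site = _informative_from_record(rec)
        if site is not None:
            sites.append(site)
    return sites


@dataclass
class PhasedDnv:
    """A de novo call with its read-backed parent-of-origin assignment."""

    call: DnvCall
    origin: str = "unassigned"            # paternal | maternal | unassigned
    paternal_votes: int = 0
    maternal_votes: int = 0
    informative_positions: list = field(default_factory=list)


def assign_origin(
    dnv: DnvCall,
    informative: Sequence[InformativeSite],
    evidence: Sequence[ReadEvidence],
) -> PhasedDnv:
    """Vote-count reads that carry the de novo allele across informative sites.

    A read carrying the DNV alt allele and covering an informative site
    votes for the parent whose transmitted allele it shows.  Origin is
    assigned only with >= 2 votes for one parent and zero for the other.
    """
    by_pos = {site.pos: site for site in informative}
    pat = mat = 0
    used_positions = set()
    for read in evidence:
        if read.allele_at(dnv.pos) != dnv.alt:
            continue  # read does not carry the de novo allele
        for pos, allele in read.observations:
            site = by_pos.get(pos)
            if site is None:
                continue
            if allele == site.allele_base(site.paternal_allele):
                pat += 1
                used_positions.add(pos)
            elif allele == site.allele_base(site.maternal_allele):
                mat += 1
                used_positions.add(pos)
    phased = PhasedDnv(dnv, paternal_votes=pat, maternal_votes=mat,
                       informative_positions=sorted(used_positions))
    if pat >= MIN_SUPPORTING_READS and mat == 0:
        phased.origin = "paternal"
    elif mat >= MIN_SUPPORTING_READS and pat == 0:
        phased.origin = "maternal"
    return phased


def phase_trio(
    dnvs: Sequence[DnvCall],
    records: Sequence[TrioGenotypeRecord],
    evidence: Sequence[ReadEvidence],
    sample_id: str,
    window: int = DEFAULT_SEARCH_WINDOW,
) -> list[PhasedDnv]:
    """Phase every DNV of one trio against its read evidence."""
    by_sample = [ev for ev in evidence if ev.sample_id == sample_id]
    reads_by_pos: dict[int, list] = defaultdict(list)
    for ev in by_sample:
        for pos, _ in ev.observations:
            reads_by_pos[pos].append(ev)
    # per-chromosome position-sorted records for windowed lookup
    by_chrom: dict[str, list] = defaultdict(list)
    for r in records:
        by_chrom[r.chrom].append(r)
    positions = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.pos)
        positions[chrom] = np.array([r.pos for r in recs])
    out = []
    for dnv in dnvs:
        recs = by_chrom.get(dnv.chrom, [])
        pos_arr = positions.get(dnv.chrom, np.empty(0))
        lo = np.searchsorted(pos_arr, dnv.pos - window, side="left")
        hi = np.searchsorted(pos_arr, dnv.pos + window, side="right")
        informative = [s for i in range(lo, hi)
                       if recs[i].pos != dnv.pos
                       and (s := _informative_from_record(recs[i])) is not None]
        out.append(assign_origin(dnv, informative, reads_by_pos.get(dnv.pos, [])))
    return out


@dataclass(frozen=True)
class OriginSummary:
    paternal: int
    maternal: int

    @property
    def ratio(self) -> float:
        if self.maternal == 0:
            return math.inf if self.paternal else float("nan")
        return self.paternal / self.maternal

    @property
    def paternal_fraction(self) -> float:
        assigned = self.paternal + self.maternal
        return self.paternal / assigned if assigned else float("nan")


def origin_summary(phased: Iterable[PhasedDnv]) -> OriginSummary:
    """Counts over assigned DNVs only, plus the paternal:maternal ratio."""
    pat = sum(1 for p in phased if p.origin == "paternal")
    mat = sum(1 for p in phased if p.origin == "maternal")
    return OriginSummary(pat, mat)


# ---------------------------------------------------------------------------
# paternal-age regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeRegressionResult:
    slope: float                 # DNVs per year of paternal age (marginal OLS)
    intercept: float
    r: float                     # Pearson correlation, count vs father age
    p: float                     # t-test p for the marginal slope
    conditional_slope: float     # father slope conditioning on mother age
    conditional_p: float
    slope_ci: tuple              # 95% CI for the marginal slope
    n: int


def age_regression(
    counts: Sequence[float],
    father_ages: Sequence[float],
    mother_ages: Sequence[float] | None = None,
) -> AgeRegressionResult:
    """OLS of per-child DNV count on parental age at conception.

    The marginal fit regresses count on father age alone; the
    conditional fit adds mother age and reports the father coefficient.
    """
    counts = np.asarray(counts, dtype=float)
    father = np.asarray(father_ages, dtype=float)
    if counts.shape != father.shape or counts.size < 3:
        raise ValueError("need >= 3 children with counts and father ages")
    if np.ptp(father) == 0:
        raise ValueError("degenerate design: father age is constant")
    marginal = sm.OLS(counts, sm.add_constant(father)).fit()
    slope = float(marginal.params[1])
    ci = tuple(float(x) for x in marginal.conf_int()[1])
    r = float(np.corrcoef(father, counts)[0, 1])
    if mother_ages is not None:
        mother = np.asarray(mother_ages, dtype=float)
        X = sm.add_constant(np.column_stack([father, mother]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            cond_slope, cond_p = float("nan"), float("nan")
        else:
            conditional = sm.OLS(counts, X).fit()
            cond_slope = float(conditional.params[1])
            cond_p = float(conditional.pvalues[1])
    else:
        cond_slope, cond_p = slope, float(marginal.pvalues[1])
    return AgeRegressionResult(
        slope=slope,
        intercept=float(marginal.params[0]),
        r=r,
        p=float(marginal.pvalues[1]),
        conditional_slope=cond_slope,
        conditional_p=cond_p,
        slope_ci=ci,
        n=counts.size,
    )
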