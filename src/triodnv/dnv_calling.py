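"""De novo SNV/INDEL candidate detection and filtering for sequenced trios.

A de novo variant (DNV) shows up as a Mendelian inconsistency: the child
carries an alternate allele seen in neither parental genotype.  At ~30x
short-read coverage the trustworthy pattern is child heterozygous with both
parents homozygous reference; other violation patterns (e.g. child hom-alt
with hom-ref parents) are almost always genotyping error and are flagged
but excluded by default.

Accepted calls must pass three filters, each stored as a named flag so the
order of application is irrelevant:

* ``quality`` — genotype-posterior quality >= Q20 in all three members;
* ``allele_balance`` — child alt-read fraction within [0.30, 0.70] (bounds
  inclusive);
* ``score`` — an externally supplied per-variant classifier score >= 0.5
  (an optional hook; calls without a score pass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import Pedigree, TrioGenotypeRecord

log = logging.getLogger(__name__)

FILTER_NAMES = ("quality", "allele_balance", "score")

_AB_EPS = 1e-12  # guards inclusive bounds against float representation


def variant_class(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


@dataclass
class DnvCall:
    """A candidate de novo variant with its filter trail."""

    chrom: str
    pos: int              # 1-based
    ref: str
    alt: str
    child_id: str
    allele_balance: float | None = None
    qualities: dict = field(default_factory=dict)
    score: float | None = None
    flags: dict = field(default_factory=dict)
    fail_reasons: dict = field(default_factory=dict)

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def accepted(self) -> bool:
        """True once every filter has run and passed."""
        return all(self.flags.get(name, False) for name in FILTER_NAMES)


class CandidateSet(list):
    """Candidate DNV calls plus detection tallies.

    Behaves as a plain list of :class:`DnvCall`; ``n_missing_parent``
    counts sites skipped for a missing parental genotype and
    ``n_other_violation`` counts Mendelian-violation patterns other than
    child-het / parents-hom-ref (excluded under default settings).
    """

    def __init__(self, calls=(), n_missing_parent=0, n_other_violation=0):
        super().__init__(calls)
        self.n_missing_parent = n_missing_parent
        self.n_other_violation = n_other_violation


def detect_candidates(
    records: Iterable[TrioGenotypeRecord],
    child_id: str,
    include_other_violations: bool = False,
) -> CandidateSet:
    """Find sites where the child carries an alt allele absent from both parents.

    Only the child-het / parents-hom-ref pattern is emitted by default;
    set ``include_other_violations`` to also emit e.g. child 1/1 with
    hom-ref parents.  Sites with a missing parental genotype are skipped
    and tallied.
    """
    calls, n_missing, n_other = [], 0, 0
    for rec in records:
        child = rec.genotypes.get("child")
        father = rec.genotypes.get("father")
        mother = rec.genotypes.get("mother")
        if child is None:
            continue
        if father is None or mother is None:
            if 1 in child:
                n_missing += 1
            continue
        if 1 not in child or 1 in father or 1 in mother:
            continue  # either no alt in child, or inherited
        canonical = child == (0, 1)
        if not canonical:
            n_other += 1
            if not include_other_violations:
                continue
        ad = rec.allele_depths.get("child")
        ab = None
        if ad is not None and sum(ad) > 0:
            ab = ad[1] / (ad[0] + ad[1])
        calls.append(DnvCall(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt,
            child_id=child_id, allele_balance=ab,
            qualities=dict(rec.qualities),
        ))
    return CandidateSet(calls, n_missing, n_other)


# ---------------------------------------------------------------------------
# filters (each sets one named flag; order of application is irrelevant)
# ---------------------------------------------------------------------------

def filter_quality(calls: Sequence[DnvCall], min_posterior: float = 20.0) -> Sequence[DnvCall]:
    """Pass iff the minimum genotype-posterior quality over the trio is >= Q20."""
    for call in calls:
        quals = [call.qualities.get(m) for m in ("child", "father", "mother")]
        if any(q is None for q in quals):
            call.flags["quality"] = False
            call.fail_reasons["quality"] = "missing_posterior"
        else:
            ok = min(quals) >= min_posterior
            call.flags["quality"] = ok
            if not ok:
                call.fail_reasons["quality"] = "below_threshold"
    return calls


def filter_allele_balance(
    calls: Sequence[DnvCall], low: float = 0.30, high: float = 0.70
) -> Sequence[DnvCall]:
    """Pass iff the child allele balance lies in [low, high], bounds inclusive."""
    for call in calls:
        if call.allele_balance is None:
            call.flags["allele_balance"] = False
            call.fail_reasons["allele_balance"] = "zero_depth"
        else:
            ok = (low - _AB_EPS) <= call.allele_balance <= (high + _AB_EPS)
            call.flags["allele_balance"] = ok
            if not ok:
                call.fail_reasons["allele_balance"] = "outside_bounds"
    return calls


def filter_score(
    calls: Sequence[DnvCall],
    scores: Mapping[tuple, float] | None = None,
    threshold: float = 0.5,
) -> Sequence[DnvCall]:
    """Pass iff the external DNV classifier score is >= threshold.

    ``scores`` maps (chrom, pos, ref, alt) to a score in [0, 1]; calls
    without a score pass (the score is an optional plug-in).
    """
    for call in calls:
        if scores is not None and call.key in scores:
            call.score = scores[call.key]
        if call.score is None:
            call.flags["score"] = True
            continue
        if not 0.0 <= call.score <= 1.0:
            raise ValueError(f"score {call.score} outside [0, 1] for {call.key}")
        ok = call.score >= threshold
        call.flags["score"] = ok
        if not ok:
            call.fail_reasons["score"] = "below_threshold"
    return calls


def apply_filters(
    calls: Sequence[DnvCall],
    min_posterior: float = 20.0,
    ab_low: float = 0.30,
    ab_high: float = 0.70,
    scores: Mapping[tuple, float] | None = None,
    score_threshold: float = 0.5,
) -> Sequence[DnvCall]:
    filter_quality(calls, min_posterior)
    filter_allele_balance(calls, ab_low, ab_high)
    filter_score(calls, scores, score_threshold)
    return calls


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientSummary:
    mean_exact: float
    mean_reported: int
    minimum: int
    maximum: int
    total: int
    per_child: dict

    @property
    def range(self) -> tuple:
        return (self.minimum, self.maximum)


def per_patient_summary(
    accepted: Iterable[DnvCall], cohort: Sequence[Pedigree]
) -> PatientSummary:
    """Per-patient DNV counts over a cohort (children without calls count 0)."""
    if not cohort:
        raise ValueError("empty cohort")
    counts = {p.child_id: 0 for p in cohort}
    for call in accepted:
        if call.child_id not in counts:
            raise ValueError(f"call for unknown child {call.child_id}")
        counts[call.child_id] += 1
    total = sum(counts.values())
    mean = total / len(counts)
    values = list(counts.values())
    return PatientSummary(
        mean_exact=mean,
        mean_reported=int(round(mean)),
        minimum=min(values),
        maximum=max(values),
        total=total,
        per_child=counts,
    )


@dataclass(frozen=True)
class ValidationTally:
    """Orthogonal-validation outcome: assays attempted and confirmed de novo."""

    tested: int
    confirmed: int

    def __post_init__(self):
        if self.tested < 0 or self.confirmed < 0 or self.confirmed > self.tested:
            raise ValueError(f"invalid validation tally {self}")


@dataclass(frozen=True)
class ValidationFdr:
    percent_exact: float
    percent_reported: int


def validation_fdr(tally: ValidationTally) -> ValidationFdr:
    """False-discovery rate from a validation tally, as a percentage."""
    if tally.tested == 0:
        raise ValueError("no successful validation assays")
    pct = 100.0 * (tally.tested - tally.confirmed) / tally.tested
    return ValidationFdr(percent_exact=pct, percent_reported=int(round(pct)))


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def calls_to_dataframe(calls: Iterable[DnvCall]):
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "child_id": c.child_id, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "class": c.vclass,
            "allele_balance": c.allele_balance, "score": c.score,
            "pass_quality": c.flags.get("quality"),
            "pass_allele_balance": c.flags.get("allele_balance"),
            "pass_score": c.flags.get("score"),
            "accepted": c.accepted,
        })
    return pd.DataFrame(rows)


def dataframe_to_calls(df) -> list[DnvCall]:
    calls = []
    for row in df.itertuples(index=False):
        call = DnvCall(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            child_id=row.child_id,
            allele_balance=None if row.allele_balance != row.allele_balance
            else float(row.allele_balance),
            score=None if row.score != row.score else float(row.score),
        )
        for name, col in (("quality", row.pass_quality),
                          ("allele_balance", row.pass_allele_balance),
                          ("score", row.pass_score)):
            if col == col and col is not None:  # NaN-safe
                call.flags[name] = bool(col)
        calls.append(call)
    return calls
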