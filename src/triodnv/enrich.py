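"""Case-versus-control enrichment statistics for annotated de novo SNVs.

For a genomic feature (promoter chromatin state, DHS overlap, ...) with
``a`` case DNVs of ``n1`` total and ``b`` control DNVs of ``n2`` total, the
enrichment ratio is the ratio of proportions

    R = (a / n1) / (b / n2).

This is the primary statistic (the published table's "odds ratio" column
reproduces from its printed counts under this formula); the cross-product
odds ratio ``(a / (n1 - a)) / (b / (n2 - b))`` is also emitted as a
secondary output.  Significance is a Pearson chi-squared test on the 2x2
table (optionally with Yates' continuity correction), Bonferroni-adjusted
for ``m`` tests (13 features by default).

Two derived quantities summarise what an enrichment means for a cohort of
``T`` patients:

* expected excess  E = a - a / R  — the number of case DNVs above the
  control-rate expectation;
* occupancy — distributing k excess variants uniformly at random over T
  patients, each patient carries >= 1 with probability 1 - (1 - 1/T)^k,
  and T times that is the expected number of carriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_TESTS = 13


@dataclass(frozen=True)
class ContingencyCounts:
    """Feature counts for a 2x2 case/control comparison."""

    a: int    # case DNVs with the feature
    n1: int   # total case DNVs
    b: int    # control DNVs with the feature
    n2: int   # total control DNVs

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("cohort totals must be positive")
        if not (0 <= self.a <= self.n1) or not (0 <= self.b <= self.n2):
            raise ValueError(f"counts outside totals: {self}")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.n1 - self.a],
                         [self.b, self.n2 - self.b]], dtype=float)


def enrichment_ratio(counts: ContingencyCounts, continuity: bool = False) -> float:
    """Ratio of proportions (a/n1)/(b/n2).

    With ``b == 0`` the ratio is undefined and NaN is returned unless
    ``continuity`` is set, in which case 0.5 is added to both feature
    counts (Haldane-Anscombe style).
    """
    a, b = counts.a, counts.b
    if b == 0:
        if not continuity:
            return float("nan")
        a, b = a + 0.5, b + 0.5
    elif continuity:
        a, b = a + 0.5, b + 0.5
    return (a / counts.n1) / (b / counts.n2)


def odds_ratio_cross_product(counts: ContingencyCounts) -> float:
    """Classical 2x2 cross-product odds ratio (secondary output)."""
    denom = counts.b * (counts.n1 - counts.a)
    if denom == 0:
        return float("nan")
    return (counts.a * (counts.n2 - counts.b)) / denom


def chi_squared(counts: ContingencyCounts, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test (1 df) on the 2x2 table; returns (statistic, p)."""
    table = counts.table
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: zero marginal in 2x2 table")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int = DEFAULT_N_TESTS) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return min(1.0, m * p)


def expected_excess(a: int, ratio: float) -> float:
    """Excess case DNVs above the control-rate expectation: E = a - a / R."""
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return a - a / ratio


@dataclass(frozen=True)
class Occupancy:
    probability: float          # per-patient P(>= 1 excess variant)
    expected_patients: float

    @property
    def expected_patients_reported(self) -> int:
        return int(round(self.expected_patients))


def occupancy_expectation(k: float, n_patients: int) -> Occupancy:
    """Uniform-allocation occupancy of k excess variants among T patients."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if n_patients < 1:
        raise ValueError("need at least one patient")
    prob = 1.0 - (1.0 - 1.0 / n_patients) ** k
    return Occupancy(probability=prob, expected_patients=n_patients * prob)


# ---------------------------------------------------------------------------
# the enrichment table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    """One row of the feature-enrichment report."""

    feature: str
    counts: ContingencyCounts
    ratio: float
    odds_ratio: float
    chi2: float
    p: float
    p_bonferroni: float
    significant: bool
    excess: float

    @property
    def case_percent(self) -> float:
        return 100.0 * self.counts.a / self.counts.n1

    @property
    def control_percent(self) -> float:
        return 100.0 * self.counts.b / self.counts.n2

    @property
    def excess_reported(self) -> int:
        return int(round(self.excess))


def _result_from_counts(label: str, counts: ContingencyCounts, m: int,
                        yates: bool, alpha: float) -> EnrichmentResult:
    ratio = enrichment_ratio(counts)
    orx = odds_ratio_cross_product(counts)
    if counts.a == 0 and counts.b == 0:
        chi2_stat, p = float("nan"), float("nan")
        p_adj, significant = float("nan"), False
    else:
        chi2_stat, p = chi_squared(counts, yates=yates)
        p_adj = bonferroni(p, m)
        significant = p_adj < alpha
    excess = expected_excess(counts.a, ratio) if ratio > 0 else float("nan")
    return EnrichmentResult(label, counts, ratio, orx, chi2_stat, p,
                            p_adj, significant, excess)


# Default feature set: the 13 tests behind the Bonferroni correction.
# Each entry maps a display label to a boolean predicate over an annotated
# DNV DataFrame (columns: gene_class, chromatin, dhs, tfbs_count, nssnv).
def _tfbs10(df):
    return df["tfbs_count"] >= 10


DEFAULT_FEATURES: list[tuple[str, Callable]] = [
    ("UTR5", lambda df: df["gene_class"] == "UTR5"),
    ("Upstream of gene", lambda df: df["gene_class"] == "upstream"),
    ("Exon", lambda df: df["gene_class"] == "exon"),
    ("Intron", lambda df: df["gene_class"] == "intron"),
    ("Intergenic region", lambda df: df["gene_class"] == "intergenic"),
    ("Promoter", lambda df: df["chromatin"] == "Promoter"),
    ("Enhancer", lambda df: df["chromatin"] == "Enhancer"),
    ("nsSNV", lambda df: df["nssnv"].eq(True)),
    ("No of TFBS >= 10", _tfbs10),
    ("Promoter + TFBS >= 10", lambda df: (df["chromatin"] == "Promoter") & _tfbs10(df)),
    ("DHS", lambda df: df["dhs"].astype(bool)),
    ("Promoter + DHS", lambda df: (df["chromatin"] == "Promoter") & df["dhs"].astype(bool)),
    ("Promoter + DHS + TFBS >= 10",
     lambda df: (df["chromatin"] == "Promoter") & df["dhs"].astype(bool) & _tfbs10(df)),
]


def enrichment_table(
    case: pd.DataFrame,
    control: pd.DataFrame,
    features: Sequence[tuple[str, Callable]] | None = None,
    m: int | None = None,
    yates: bool = False,
    alpha: float = 0.05,
    apply_gc_filter: bool = True,
) -> list[EnrichmentResult]:
    """Feature-enrichment rows from annotated case and control DNV tables.

    Both inputs must be annotated against the same track set.  The
    GC/difficult-promoter exclusion is applied symmetrically to both
    cohorts first (column ``gc_excluded``) unless disabled.
    """
    if features is None:
        features = DEFAULT_FEATURES
    if m is None:
        m = len(features)
    if apply_gc_filter and "gc_excluded" in case.columns:
        case = case[~case["gc_excluded"].astype(bool)]
    if apply_gc_filter and "gc_excluded" in control.columns:
        control = control[~control["gc_excluded"].astype(bool)]
    if len(case) == 0:
        raise ValueError("empty case cohort after GC filtering")
    if len(control) == 0:
        raise ValueError("empty control cohort after GC filtering")
    n1, n2 = len(case), len(control)
    results = []
    for label, predicate in features:
        a = int(predicate(case).sum())
        b = int(predicate(control).sum())
        counts = ContingencyCounts(a, n1, b, n2)
        results.append(_result_from_counts(label, counts, m, yates, alpha))
    return results


def enrichment_table_from_counts(
    rows: Sequence[tuple[str, int, int]],
    n1: int,
    n2: int,
    m: int | None = None,
    yates: bool = False,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrichment rows from precomputed per-feature counts (label, a, b)."""
    if m is None:
        m = len(rows)
    return [
        _result_from_counts(label, ContingencyCounts(a, n1, b, n2), m, yates, alpha)
        for label, a, b in rows
    ]


def results_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "feature": r.feature,
            "case_count": r.counts.a, "case_total": r.counts.n1,
            "case_percent": r.case_percent,
            "control_count": r.counts.b, "control_total": r.counts.n2,
            "control_percent": r.control_percent,
            "ratio": r.ratio, "odds_ratio": r.odds_ratio,
            "chi2": r.chi2, "p": r.p, "p_bonferroni": r.p_bonferroni,
            "significant": r.significant,
            "excess": r.excess,
            "excess_reported": r.excess_reported if not math.isnan(r.excess) else None,
        }
        for r in results
    ])
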