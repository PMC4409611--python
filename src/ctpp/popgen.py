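"""Population-genetic QC for genotyping runs.

Allele frequencies, Hardy-Weinberg equilibrium (HWE) testing, call-failure
rate, and concordance between two genotype call sets. These are the
standard sanity checks on a new genotyping assay: allele frequencies in a
population sample should match published values, genotype proportions
should follow HWE (p^2 : 2pq : q^2) under random mating, and calls should
agree with an independent platform.

The HWE test is the Pearson chi-square goodness-of-fit on the three
genotype classes with 1 degree of freedom (three classes, one estimated
allele frequency) and no continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .insilico import GenotypeCall


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts (n_xx, n_xy, n_yy) for a biallelic SNP."""

    n_xx: int
    n_xy: int
    n_yy: int

    def __post_init__(self) -> None:
        for name in ("n_xx", "n_xy", "n_yy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.n_xx + self.n_xy + self.n_yy

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "GenotypeCounts":
        tally = {"XX": 0, "XY": 0, "YY": 0}
        for lab in labels:
            if lab not in tally:
                raise ValueError(f"unknown genotype label {lab!r}")
            tally[lab] += 1
        return cls(tally["XX"], tally["XY"], tally["YY"])


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square HWE test result (df = 1)."""

    chi2: float
    p: float
    expected: tuple[float, float, float]  # (xx, xy, yy)
    df: int = 1
    monomorphic: bool = False


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """Allele frequencies (p_x, p_y) by allele counting.

    p_x = (2 n_xx + n_xy) / 2n; full precision is returned — round with
    :func:`round_frequency` for tabular reporting at 3 decimals.
    """
    if counts.n < 1:
        raise ValueError("allele frequencies need at least one genotype")
    p_x = (2 * counts.n_xx + counts.n_xy) / (2 * counts.n)
    return p_x, 1.0 - p_x


def round_frequency(freq: float) -> float:
    """Frequency rounded to 3 decimals, half-up."""
    return _round_half_up(freq, 3)


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    Expected counts are (n p^2, 2npq, n q^2) with p estimated from the
    sample; the statistic is referred to a chi-square distribution with
    one degree of freedom, upper tail, without Yates continuity
    correction. Monomorphic samples carry no information about HWE and
    return a degenerate result (chi2 = 0, p = 1) with a warning.
    """
    if counts.n < 1:
        raise ValueError("HWE test needs at least one genotype")
    p, q = allele_frequencies(counts)
    n = counts.n
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if p == 0.0 or q == 0.0:
        warnings.warn(
            "monomorphic genotype counts: HWE test is degenerate",
            stacklevel=2,
        )
        return HweResult(chi2=0.0, p=1.0, expected=expected, monomorphic=True)
    observed = (counts.n_xx, counts.n_xy, counts.n_yy)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p=pval, expected=expected)


def call_failure_rate(n_failed: int, n_total: int) -> float:
    """Failed-genotyping percentage, full precision.

    Round with :func:`round_percentage` for the conventional one-decimal
    presentation.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_failed <= n_total:
        raise ValueError("n_failed must lie in [0, n_total]")
    return 100.0 * n_failed / n_total


def round_percentage(pct: float) -> float:
    """Percentage rounded to 1 decimal, half-up."""
    return _round_half_up(pct, 1)


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between two genotype call sets on shared samples."""

    n_compared: int
    n_agreeing: int
    rate: float
    confusion: pd.DataFrame  # rows: calls_a, cols: calls_b

    def __eq__(self, other: object) -> bool:  # DataFrame breaks default eq
        if not isinstance(other, ConcordanceResult):
            return NotImplemented
        return (
            self.n_compared == other.n_compared
            and self.n_agreeing == other.n_agreeing
            and self.rate == other.rate
            and self.confusion.equals(other.confusion)
        )


def concordance(
    calls_a: Sequence[GenotypeCall], calls_b: Sequence[GenotypeCall]
) -> ConcordanceResult:
    """Inter-method concordance, pairing call sets by sample_id.

    Pairs in which either platform reports NO_CALL are excluded from the
    denominator. Raises when no comparable pair remains.
    """
    by_id_a = {c.sample_id: c for c in calls_a}
    by_id_b = {c.sample_id: c for c in calls_b}
    shared = [sid for sid in by_id_a if sid in by_id_b]
    genotypes = ("XX", "XY", "YY")
    confusion = pd.DataFrame(
        0, index=list(genotypes), columns=list(genotypes), dtype=int
    )
    n_compared = n_agreeing = 0
    for sid in shared:
        a, b = by_id_a[sid], by_id_b[sid]
        if not (a.is_call and b.is_call):
            continue
        n_compared += 1
        confusion.loc[a.call, b.call] += 1
        if a.call == b.call:
            n_agreeing += 1
    if n_compared == 0:
        raise ValueError("no comparable sample pairs (all unmatched or NO_CALL)")
    return ConcordanceResult(
        n_compared=n_compared,
        n_agreeing=n_agreeing,
        rate=n_agreeing / n_compared,
        confusion=confusion,
    )
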