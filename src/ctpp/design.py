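"""CTPP assay geometry: the four-primer layout, fragment sizes and design.

A confronting two-pair primer (CTPP) assay genotypes a biallelic SNP in a
single PCR without restriction digestion. Four primers are arranged on the
template::

    F1 ->        F2 ->
    =====--------=====X=====--------=====   plus strand
                  <- R1              <- R2

The inner, "confronting" pair anneals 3'-terminally on the SNP itself:
R1's 3' base is the complement of allele X, F2's 3' base is allele Y. A
3'-terminal mismatch blocks extension (the ARMS principle), so F1-R1
amplifies only X chromosomes and F2-R2 only Y chromosomes, while the outer
pair F1-R2 amplifies regardless of genotype. Three product sizes result:

    a  (F1-R1, allele X),  b  (F2-R2, allele Y),  c  (F1-R2, common)

related by the identity  c = a + b - (d - 1)  where  d = len(F2) + len(R1):
the X and Y products together tile the common product, overlapping on the
d - 1 template positions covered by F2 and R1 minus their single shared
base at the SNP. A genotype is read straight off the gel: XX -> {a, c},
XY -> {a, b, c}, YY -> {b, c}.

Coordinates are 0-based, half-open on the plus strand throughout. Reverse
primers are stored 5'->3' in their own (minus-strand) orientation with a
plus-strand footprint [start, start + len).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .seq import SequenceError, clean_sequence, complement_base, reverse_complement
from .thermo import DEFAULT_CONDITIONS, ThermoConditions, melting_temperature

Role = Literal["F1", "R1", "F2", "R2"]
Genotype = Literal["XX", "XY", "YY"]

GENOTYPES: tuple[Genotype, ...] = ("XX", "XY", "YY")


class AssayError(ValueError):
    """Raised when a CTPP assay violates its geometric invariants."""


@dataclass(frozen=True)
class SnpLocus:
    """A template strand plus a biallelic SNP — the design substrate.

    ``template`` is the plus strand 5'->3'; ``snp_offset`` indexes the SNP
    base; ``allele_x`` / ``allele_y`` are the two alleles. The template
    itself may carry either allele at the SNP position.
    """

    template: str
    snp_offset: int
    allele_x: str
    allele_y: str
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", clean_sequence(self.template))
        for name in ("allele_x", "allele_y"):
            base = getattr(self, name).upper()
            if base not in "ACGT" or len(base) != 1:
                raise SequenceError(f"{name} must be a single A/C/G/T base")
            object.__setattr__(self, name, base)
        if self.allele_x == self.allele_y:
            raise ValueError("allele_x and allele_y must differ")
        if not 0 <= self.snp_offset < len(self.template):
            raise ValueError("snp_offset outside template")
        if self.template[self.snp_offset] not in (self.allele_x, self.allele_y):
            raise ValueError(
                f"template base {self.template[self.snp_offset]!r} at SNP "
                f"offset is neither allele {self.allele_x!r} nor {self.allele_y!r}"
            )

    def haplotype(self, allele: str) -> str:
        """Template sequence carrying *allele* at the SNP position."""
        if allele not in (self.allele_x, self.allele_y):
            raise ValueError(f"{allele!r} is not an allele of this locus")
        t = self.template
        return t[: self.snp_offset] + allele + t[self.snp_offset + 1 :]

    def genotype_alleles(self, genotype: Genotype) -> str:
        """Base-pair spelling of an XX/XY/YY genotype, e.g. 'GA'."""
        mapping = {
            "XX": self.allele_x + self.allele_x,
            "XY": self.allele_x + self.allele_y,
            "YY": self.allele_y + self.allele_y,
        }
        try:
            return mapping[genotype]
        except KeyError:
            raise ValueError(f"unknown genotype {genotype!r}") from None


@dataclass(frozen=True)
class Primer:
    """One of the four CTPP primers with its template footprint.

    ``seq`` is 5'->3' in the primer's own orientation; ``start`` is the
    0-based plus-strand coordinate of the leftmost template base covered.
    Forward primers (F1, F2) equal the plus-strand substring of their
    footprint; reverse primers (R1, R2) equal its reverse complement.
    """

    seq: str
    role: Role
    start: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq))
        if self.role not in ("F1", "R1", "F2", "R2"):
            raise ValueError(f"unknown primer role {self.role!r}")
        if self.start < 0:
            raise ValueError("primer start must be non-negative")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def strand(self) -> Literal["+", "-"]:
        return "+" if self.role in ("F1", "F2") else "-"

    @property
    def end(self) -> int:
        """Exclusive plus-strand end of the footprint."""
        return self.start + len(self.seq)

    @property
    def allele_specificity(self) -> Literal["X", "Y", "none"]:
        return {"R1": "X", "F2": "Y"}.get(self.role, "none")

    @property
    def three_prime_plus_coord(self) -> int:
        """Plus-strand coordinate of the 3'-terminal base."""
        return self.end - 1 if self.strand == "+" else self.start

    def footprint_plus_seq(self) -> str:
        """Plus-strand sequence this primer must match (5'->3' plus strand)."""
        return self.seq if self.strand == "+" else reverse_complement(self.seq)


def common_fragment_size(a: int, b: int, d: int) -> int:
    """Size of the common F1-R2 product: c = a + b - (d - 1).

    The X product (a) and Y product (b) tile the common product, double
    counting the d - 1 positions where the F2 and R1 footprints overlap it
    (their combined length d minus the one SNP base they share).
    """
    return a + b - (d - 1)


@dataclass(frozen=True)
class FragmentPattern:
    """The three product sizes of a CTPP assay and the overlap constant d."""

    a: int  # F1-R1, allele X
    b: int  # F2-R2, allele Y
    c: int  # F1-R2, common
    d: int  # len(F2) + len(R1)

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"fragment size {name} must be positive")
        if self.a < self.d or self.b < self.d:
            raise ValueError("allele fragments cannot be shorter than d")
        if self.c != common_fragment_size(self.a, self.b, self.d):
            raise ValueError(
                f"fragment sizes violate c = a + b - (d - 1): "
                f"a={self.a}, b={self.b}, c={self.c}, d={self.d}"
            )

    def bands(self, genotype: Genotype) -> frozenset[int]:
        """Expected gel band sizes for a genotype."""
        if genotype == "XX":
            return frozenset((self.a, self.c))
        if genotype == "YY":
            return frozenset((self.b, self.c))
        if genotype == "XY":
            return frozenset((self.a, self.b, self.c))
        raise ValueError(f"unknown genotype {genotype!r}")


@dataclass(frozen=True)
class CtppAssay:
    """Four primers on a SNP locus plus the Tm conditions used to score them."""

    f1: Primer
    r1: Primer
    f2: Primer
    r2: Primer
    locus: SnpLocus
    conditions: ThermoConditions = DEFAULT_CONDITIONS
    label: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        violations = validate_assay(self)
        if violations:
            raise AssayError("; ".join(violations))

    @property
    def primers(self) -> tuple[Primer, Primer, Primer, Primer]:
        return (self.f1, self.r1, self.f2, self.r2)

    def tms(self) -> dict[Role, float]:
        """Unrounded Tm of each primer under the assay's conditions."""
        return {
            p.role: melting_temperature(p.seq, self.conditions)
            for p in self.primers
        }

    def tm_spread(self) -> float:
        """Max pairwise |dTm| among the four primers (the balance score)."""
        tms = list(self.tms().values())
        return max(tms) - min(tms)

    def genotype_for_alleles(self, alleles: str) -> Genotype:
        """Map a base-pair genotype spelling ('GA', 'AG', ...) to XX/XY/YY."""
        pair = frozenset(alleles.upper())
        x, y = self.locus.allele_x, self.locus.allele_y
        if pair == {x}:
            return "XX"
        if pair == {y}:
            return "YY"
        if pair == {x, y}:
            return "XY"
        raise ValueError(f"{alleles!r} does not match alleles {x}/{y}")


def validate_assay(assay: "CtppAssay | object") -> list[str]:
    """Check every CTPP invariant; return a list of violation descriptions.

    An empty list means the assay is well-formed. Each entry names the
    broken rule, so the list doubles as a design lint report.
    """
    v: list[str] = []
    locus: SnpLocus = assay.locus
    snp = locus.snp_offset
    f1, r1, f2, r2 = assay.f1, assay.r1, assay.f2, assay.r2
    tmpl_x = locus.haplotype(locus.allele_x)
    tmpl_y = locus.haplotype(locus.allele_y)

    for primer, role in ((f1, "F1"), (r1, "R1"), (f2, "F2"), (r2, "R2")):
        if primer.role != role:
            v.append(f"primer in {role} slot has role {primer.role}")
        if primer.end > len(locus.template):
            v.append(f"{role} footprint extends past the template")

    def matches(primer: Primer, template: str) -> bool:
        if primer.end > len(template):
            return False
        return template[primer.start : primer.end] == primer.footprint_plus_seq()

    # Confronting pair: 3' ends anchored on the SNP, allele-specific.
    if r1.start != snp:
        v.append("R1 3' end not anchored at SNP")
    elif not matches(r1, tmpl_x):
        v.append("R1 does not match the X-allele template at its footprint")
    if r1.seq and r1.seq[-1] != complement_base(locus.allele_x):
        v.append("R1 3' base is not the complement of allele X")

    if f2.end - 1 != snp:
        v.append("F2 3' end not anchored at SNP")
    elif not matches(f2, tmpl_y):
        v.append("F2 does not match the Y-allele template at its footprint")
    if f2.seq and f2.seq[-1] != locus.allele_y:
        v.append("F2 3' base is not allele Y")

    # Outer pair: flanking, allele-neutral (must not cover the SNP).
    if f1.end - 1 > snp - 1:
        v.append("F1 3' end must lie upstream of the SNP")
    elif not matches(f1, tmpl_x):
        v.append("F1 does not match the template at its footprint")
    if f1.start >= f2.start:
        v.append("F1 must start upstream of F2")

    if r2.start <= snp:
        v.append("R2 must lie strictly downstream of the SNP")
    elif not matches(r2, tmpl_x):
        v.append("R2 does not match the template at its footprint")
    if r2.end <= r1.end:
        v.append("R2 must end downstream of R1")

    return v


def fragment_pattern(assay: CtppAssay) -> FragmentPattern:
    """Compute the (a, b, c, d) fragment sizes of a valid assay.

    The identity c = a + b - (d - 1) holds by construction from the
    coordinates and is re-asserted by :class:`FragmentPattern`.
    """
    violations = validate_assay(assay)
    if violations:
        raise AssayError("; ".join(violations))
    snp = assay.locus.snp_offset
    a = (snp + len(assay.r1)) - assay.f1.start
    b = assay.r2.end - (snp - len(assay.f2) + 1)
    c = assay.r2.end - assay.f1.start
    d = len(assay.f2) + len(assay.r1)
    return FragmentPattern(a=a, b=b, c=c, d=d)


def expected_band_pattern(assay: CtppAssay, genotype: Genotype) -> frozenset[int]:
    """Gel band sizes a genotype produces: XX -> {a,c}, XY -> {a,b,c}, YY -> {b,c}."""
    return fragment_pattern(assay).bands(genotype)


@dataclass(frozen=True)
class DesignConstraints:
    """Search space and acceptance window for de-novo CTPP design.

    Defaults are informed by published CTPP assays: primer lengths 17-30 nt,
    Tm window 60-66 C with at most 3 C spread across the four primers, and
    product sizes resolvable on a standard agarose gel.
    """

    primer_len: tuple[int, int] = (17, 30)
    tm_window: tuple[float, float] = (60.0, 66.0)
    max_tm_spread: float = 3.0
    a_range: tuple[int, int] = (100, 260)
    b_range: tuple[int, int] = (100, 260)
    c_range: tuple[int, int] = (150, 520)
    min_flank: int = 100

    def __post_init__(self) -> None:
        for name in ("primer_len", "a_range", "b_range", "c_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if self.tm_window[0] > self.tm_window[1]:
            raise ValueError("tm_window is empty")
        if self.max_tm_spread < 0:
            raise ValueError("max_tm_spread must be >= 0")
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")


class InsufficientFlankError(ValueError):
    """The SNP sits too close to a template edge for the constraints."""


def _candidate_tm_ok(tm: float, constraints: DesignConstraints) -> bool:
    lo, hi = constraints.tm_window
    return lo <= tm <= hi


def design_assay(
    locus: SnpLocus,
    constraints: DesignConstraints = DesignConstraints(),
    cond: ThermoConditions = DEFAULT_CONDITIONS,
    limit: int | None = None,
) -> list[CtppAssay]:
    """Enumerate all feasible CTPP assays for *locus*, best first.

    The search is exhaustive over the constraint ranges: R1 and F2 are
    anchored on the SNP so only their lengths vary; F1 and R2 slide within
    the allele-product size ranges. Candidates failing the Tm window are
    dropped; quadruples failing the size ranges or the Tm-spread cap are
    dropped. Ranking is by ascending Tm spread, then smaller common
    product c, then primer start coordinates — fully deterministic.
    ``limit`` truncates the returned list after global ranking (the search
    itself is always exhaustive).

    Returns an empty list when no quadruple is feasible. Raises
    :class:`InsufficientFlankError` when the SNP has less than
    ``constraints.min_flank`` template on either side.
    """
    snp = locus.snp_offset
    flank_left = snp
    flank_right = len(locus.template) - snp - 1
    if flank_left < constraints.min_flank or flank_right < constraints.min_flank:
        raise InsufficientFlankError(
            f"SNP flanks ({flank_left}, {flank_right}) below "
            f"min_flank {constraints.min_flank}"
        )

    tmpl_x = locus.haplotype(locus.allele_x)
    tmpl_y = locus.haplotype(locus.allele_y)
    len_lo, len_hi = constraints.primer_len
    lengths = range(len_lo, len_hi + 1)

    def tm(seq: str) -> float:
        return melting_temperature(seq, cond)

    # Inner (confronting) primers: anchored, one candidate per length.
    r1_cands = []
    for L in lengths:
        if snp + L > len(tmpl_x):
            continue
        seq = reverse_complement(tmpl_x[snp : snp + L])
        t = tm(seq)
        if _candidate_tm_ok(t, constraints):
            r1_cands.append((Primer(seq=seq, role="R1", start=snp), t))
    f2_cands = []
    for L in lengths:
        if snp - L + 1 < 0:
            continue
        seq = tmpl_y[snp - L + 1 : snp + 1]
        t = tm(seq)
        if _candidate_tm_ok(t, constraints):
            f2_cands.append((Primer(seq=seq, role="F2", start=snp - L + 1), t))

    # Outer primers: slide within the product-size windows.
    f1_cands = []
    for L in lengths:
        for start in range(max(0, snp - constraints.a_range[1]), snp):
            if start + L - 1 > snp - 1:
                continue
            seq = tmpl_x[start : start + L]
            t = tm(seq)
            if _candidate_tm_ok(t, constraints):
                f1_cands.append((Primer(seq=seq, role="F1", start=start), t))
    r2_cands = []
    # b = r2.end - (snp - len(F2) + 1) <= b_hi bounds how far R2 can slide.
    r2_start_max = snp + constraints.b_range[1]
    for L in lengths:
        for start in range(snp + 1, min(len(tmpl_x) - L, r2_start_max) + 1):
            seq = reverse_complement(tmpl_x[start : start + L])
            t = tm(seq)
            if _candidate_tm_ok(t, constraints):
                r2_cands.append((Primer(seq=seq, role="R2", start=start), t))

    # Score lightweight primer tuples first; validated CtppAssay objects
    # are only materialised for the entries actually returned.
    scored: list[tuple[tuple, Primer, Primer, Primer, Primer]] = []
    a_lo, a_hi = constraints.a_range
    b_lo, b_hi = constraints.b_range
    c_lo, c_hi = constraints.c_range
    for (r1, t_r1), (f2, t_f2) in itertools.product(r1_cands, f2_cands):
        for f1, t_f1 in f1_cands:
            a = (snp + len(r1)) - f1.start
            if not a_lo <= a <= a_hi:
                continue
            if max(t_r1, t_f2, t_f1) - min(t_r1, t_f2, t_f1) > constraints.max_tm_spread:
                continue
            for r2, t_r2 in r2_cands:
                b = r2.end - (snp - len(f2) + 1)
                if not b_lo <= b <= b_hi:
                    continue
                c = r2.end - f1.start
                if not c_lo <= c <= c_hi:
                    continue
                tms = (t_f1, t_r1, t_f2, t_r2)
                spread = max(tms) - min(tms)
                if spread > constraints.max_tm_spread:
                    continue
                key = (
                    spread, c,
                    f1.start, f2.start, r1.start, r2.start,
                    len(f1), len(f2), len(r1), len(r2),
                )
                scored.append((key, f1, r1, f2, r2))
    scored.sort(key=lambda entry: entry[0])
    if limit is not None:
        scored = scored[:limit]
    return [
        CtppAssay(
            f1=f1, r1=r1, f2=f2, r2=r2, locus=locus,
            conditions=cond, label=locus.label or "designed",
        )
        for _, f1, r1, f2, r2 in scored
    ]
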