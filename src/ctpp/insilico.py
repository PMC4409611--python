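"""In-silico PCR for CTPP assays: amplification, genotype calling, text gels.

Annealing model: a primer anneals if and only if its full sequence matches
the haplotype exactly, 3'-terminal base included. This is deliberately
all-or-nothing — CTPP allele discrimination rests on a single 3' mismatch
blocking extension, and an exact-match rule reproduces that behaviour
without mismatch thermodynamics. Band intensity is not modelled; a band is
present or absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .design import CtppAssay, Genotype, GENOTYPES, fragment_pattern
from .seq import clean_sequence, reverse_complement

CallValue = Literal["XX", "XY", "YY", "NO_CALL"]

#: Default band-size matching tolerance (bp). Keeps the closest published
#: CTPP bands (119 vs 125 bp, 200 vs 208 bp) unambiguous.
DEFAULT_SIZE_TOLERANCE = 5

AMPLIFYING_PAIRS: tuple[tuple[str, str], ...] = (
    ("F1", "R1"),
    ("F2", "R2"),
    ("F1", "R2"),
)


@dataclass(frozen=True)
class DiploidTemplate:
    """Two haplotype strands of equal length differing at most at the SNP."""

    haplotype1: str
    haplotype2: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotype1", clean_sequence(self.haplotype1))
        object.__setattr__(self, "haplotype2", clean_sequence(self.haplotype2))
        if len(self.haplotype1) != len(self.haplotype2):
            raise ValueError("haplotypes must be equal length")
        diffs = [
            i
            for i, (p, q) in enumerate(zip(self.haplotype1, self.haplotype2))
            if p != q
        ]
        if len(diffs) > 1:
            raise ValueError(
                f"haplotypes differ at {len(diffs)} positions; at most the "
                "SNP position may differ"
            )

    @classmethod
    def from_genotype(cls, assay: CtppAssay, genotype: Genotype) -> "DiploidTemplate":
        """Build the diploid substrate carrying *genotype* at the assay's SNP."""
        locus = assay.locus
        alleles = locus.genotype_alleles(genotype)
        return cls(locus.haplotype(alleles[0]), locus.haplotype(alleles[1]))

    def genotype(self, assay: CtppAssay) -> Genotype:
        snp = assay.locus.snp_offset
        return assay.genotype_for_alleles(
            self.haplotype1[snp] + self.haplotype2[snp]
        )


@dataclass(frozen=True)
class Amplicon:
    """One PCR product from one haplotype."""

    size: int
    forward_primer_role: str
    reverse_primer_role: str
    source_haplotype: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("amplicon size must be positive")
        if (self.forward_primer_role, self.reverse_primer_role) not in AMPLIFYING_PAIRS:
            raise ValueError(
                f"({self.forward_primer_role}, {self.reverse_primer_role}) "
                "is not a CTPP amplifying pair"
            )
        if self.source_haplotype not in (1, 2):
            raise ValueError("source_haplotype must be 1 or 2")


@dataclass(frozen=True)
class BandObservation:
    """Observed fragment sizes for one gel lane / sample."""

    sample_id: str
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("band sizes must be positive")
        object.__setattr__(self, "sizes", sizes)


@dataclass(frozen=True)
class GenotypeCall:
    """Result of matching an observed band pattern against an assay."""

    sample_id: str
    call: CallValue
    matched_bands: tuple[tuple[int, int], ...] = ()  # (observed, expected)
    reason: str = ""

    @property
    def is_call(self) -> bool:
        return self.call != "NO_CALL"


def _anneal_sites(haplotype: str, pattern: str) -> list[int]:
    """All start offsets at which *pattern* matches *haplotype* exactly."""
    sites, i = [], haplotype.find(pattern)
    while i != -1:
        sites.append(i)
        i = haplotype.find(pattern, i + 1)
    return sites


def simulate(assay: CtppAssay, tmpl: DiploidTemplate) -> list[Amplicon]:
    """Amplify a CTPP assay on a diploid template.

    Per haplotype, each of the three primer pairs (F1-R1, F2-R2, F1-R2)
    yields a product wherever the forward primer matches the plus strand
    exactly and the reverse primer's reverse complement matches downstream.
    Allele-specific primers therefore amplify only their allele, because
    their 3'-terminal base sits on the SNP.
    """
    if len(tmpl.haplotype1) != len(assay.locus.template):
        raise ValueError("template length does not match the assay's locus")
    primers = {p.role: p for p in assay.primers}
    amplicons: list[Amplicon] = []
    for hap_idx, hap in ((1, tmpl.haplotype1), (2, tmpl.haplotype2)):
        fwd_sites = {
            role: _anneal_sites(hap, primers[role].seq) for role in ("F1", "F2")
        }
        rev_sites = {
            role: _anneal_sites(hap, reverse_complement(primers[role].seq))
            for role in ("R1", "R2")
        }
        for f_role, r_role in AMPLIFYING_PAIRS:
            for fs in fwd_sites[f_role]:
                for rs in rev_sites[r_role]:
                    size = rs + len(primers[r_role]) - fs
                    if rs >= fs and size > 0:
                        amplicons.append(
                            Amplicon(
                                size=size,
                                forward_primer_role=f_role,
                                reverse_primer_role=r_role,
                                source_haplotype=hap_idx,
                            )
                        )
    return amplicons


def band_sizes(amplicons: Iterable[Amplicon]) -> frozenset[int]:
    """Collapse amplicons from both haplotypes into the visible band set."""
    return frozenset(a.size for a in amplicons)


def simulate_bands(assay: CtppAssay, genotype: Genotype) -> frozenset[int]:
    """Band set produced by *genotype* under *assay* (simulation route)."""
    return band_sizes(simulate(assay, DiploidTemplate.from_genotype(assay, genotype)))


def _match_pattern(
    observed: Sequence[int], expected: frozenset[int], tol: int
) -> tuple[bool, list[tuple[int, int]]]:
    """Greedy one-pass match of observed sizes to an expected band set.

    Every expected band must attract at least one observed size within
    +/- tol, and every observed size must lie within tol of some expected
    band; duplicate observed sizes mapping to one band are allowed (a gel
    band has no multiplicity).
    """
    pairs: list[tuple[int, int]] = []
    covered: set[int] = set()
    for obs in observed:
        best = min(expected, key=lambda e: (abs(e - obs), e))
        if abs(best - obs) > tol:
            return False, []
        pairs.append((obs, best))
        covered.add(best)
    if covered != set(expected):
        return False, []
    return True, pairs


def call_genotype(
    obs: BandObservation,
    assay: CtppAssay,
    size_tolerance: int = DEFAULT_SIZE_TOLERANCE,
) -> GenotypeCall:
    """Call XX/XY/YY from observed band sizes, or NO_CALL with a reason.

    A genotype is called only when exactly one of the three expected
    patterns matches the observation: every expected band is observed
    within ``size_tolerance`` and no observed band is unexplained.
    Failure reasons mirror how a gel reader would describe the lane:
    no bands, common band without allele bands, an extra band, a missing
    band, or an ambiguous pattern.
    """
    if size_tolerance < 0:
        raise ValueError("size_tolerance must be >= 0")
    pattern = fragment_pattern(assay)
    if not obs.sizes:
        return GenotypeCall(obs.sample_id, "NO_CALL", reason="no bands observed")

    matches: list[tuple[Genotype, list[tuple[int, int]]]] = []
    for g in GENOTYPES:
        ok, pairs = _match_pattern(obs.sizes, pattern.bands(g), size_tolerance)
        if ok:
            matches.append((g, pairs))
    if len(matches) == 1:
        g, pairs = matches[0]
        return GenotypeCall(obs.sample_id, g, matched_bands=tuple(pairs))
    if len(matches) > 1:
        return GenotypeCall(
            obs.sample_id,
            "NO_CALL",
            reason="ambiguous: bands consistent with "
            + " and ".join(g for g, _ in matches),
        )

    # Diagnose why nothing matched.
    near_c = any(abs(s - pattern.c) <= size_tolerance for s in obs.sizes)
    near_allele = any(
        abs(s - e) <= size_tolerance
        for s in obs.sizes
        for e in (pattern.a, pattern.b)
    )
    if near_c and not near_allele:
        reason = "allele bands absent"
    elif near_allele and not near_c:
        reason = "missing common band"
    else:
        reason = "extra or unexplained bands"
    return GenotypeCall(obs.sample_id, "NO_CALL", reason=reason)


def render_gel(
    lanes: Sequence[BandObservation],
    ladder: Sequence[int] = (100, 200, 300, 400, 500),
) -> str:
    """Render lanes as a deterministic text gel.

    The first column is the ladder; larger fragments run higher. Every
    distinct size (ladder or band) gets one row, sorted descending, so the
    size-to-position mapping is monotone by construction.
    """
    if not lanes:
        raise ValueError("no lanes to render")
    sizes = sorted(
        {int(s) for s in ladder} | {s for lane in lanes for s in lane.sizes},
        reverse=True,
    )
    ladder_set = {int(s) for s in ladder}
    width = max(len(lane.sample_id) for lane in lanes)
    width = max(width, 3)
    header = "  bp | " + "M".center(5) + " | " + " | ".join(
        lane.sample_id.center(width) for lane in lanes
    )
    rule = "-" * len(header)
    rows = [header, rule]
    for s in sizes:
        cells = []
        cells.append(("=====" if s in ladder_set else "     "))
        for lane in lanes:
            cells.append(("#" * width) if s in lane.sizes else (" " * width))
        rows.append((f"{s:>4d} | " + " | ".join(cells)).rstrip())
    return "\n".join(row.rstrip() for row in rows) + "\n"
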