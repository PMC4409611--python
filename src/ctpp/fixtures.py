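"""Synthetic data generation: templates, cohorts and the bundled assays.

No genomic reference is required anywhere in this package. Given the four
primer sequences of a CTPP assay and its two allele-product sizes, the SNP
position and every primer footprint are fixed by the CTPP geometry, so a
template can be reconstructed exactly: primer footprints are written at
their implied coordinates and the gaps are filled with a deterministic
ACGT-repeat filler, repaired so the filler never creates a spurious
full-length primer match. Such templates are SYNTHETIC — they reproduce
the assay's amplification behaviour, not the flanking genomic sequence —
and are labelled as such.

Two published warfarin-pharmacogenetics assays are bundled: VKORC1
G-1639A (rs9923231) and CYP2C9 A1075C (CYP2C9*3, rs1057910).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .design import CtppAssay, Primer, SnpLocus
from .seq import clean_sequence, reverse_complement
from .thermo import DEFAULT_CONDITIONS, ThermoConditions

_FILLER = "ACGT"

#: Published primer sets: sequences, allele-product sizes and allele roles.
BUNDLED_ASSAY_TABLE: dict[str, dict] = {
    "vkorc1": {
        "label": "VKORC1 G-1639A (rs9923231)",
        "f1": "CACAGACGCCAGAGGAAGAGAG",
        "r1": "CGTGAGCCACCGCACCT",
        "f2": "GAAGACCTGAAAAACAACCATTGGCCG",
        "r2": "CTCAGCCTCCCAAGTAGTTTGG",
        "a": 119,
        "b": 208,
        "allele_x": "A",
        "allele_y": "G",
        "notes": (
            "SYNTHETIC template reconstructed from the published primers and "
            "fragment sizes; not genomic reference sequence."
        ),
    },
    "cyp2c9": {
        "label": "CYP2C9 A1075C (CYP2C9*3, rs1057910)",
        "f1": "CCAGGAAGAGATTGAACGTGTGATTG",
        "r1": "TGGTGGGGAGAAGGTCAAT",
        "f2": "GCACGAGGTCCAGAGATACC",
        "r2": "GAGTTATGCACTTCTCTCACCCG",
        "a": 125,
        "b": 200,
        "allele_x": "A",
        "allele_y": "C",
        "notes": (
            "SYNTHETIC template reconstructed from the published primers and "
            "fragment sizes; not genomic reference sequence. Some sources "
            "misprint the rsID as rs1570910; rs1057910 is correct."
        ),
    },
}


class ReconstructionError(ValueError):
    """Primer sequences and fragment sizes are geometrically inconsistent."""


def _write_footprints(
    length: int, placements: list[tuple[int, str]], snp_offset: int, allele_x: str
) -> list[str]:
    """Lay primer footprints onto a filler backbone, plus strand.

    Placements may overlap only where they agree, except at the SNP where
    the X- and Y-anchored footprints legitimately disagree; the canonical
    template carries allele X there.
    """
    template: list[str | None] = [None] * length
    for start, plus_seq in placements:
        for i, base in enumerate(plus_seq):
            pos = start + i
            prev = template[pos]
            if pos == snp_offset:
                continue  # resolved below
            if prev is not None and prev != base:
                raise ReconstructionError(
                    f"primer footprints disagree at template position {pos}: "
                    f"{prev} vs {base}; fragment sizes are inconsistent with "
                    "the primer sequences"
                )
            template[pos] = base
    template[snp_offset] = allele_x
    return [
        b if b is not None else _FILLER[i % len(_FILLER)]
        for i, b in enumerate(template)
    ]


def _spurious_hit(haplotype: str, patterns: list[tuple[str, int]]) -> tuple[int, int] | None:
    """First (position, length) of a primer match outside its own footprint."""
    for pattern, home in patterns:
        i = haplotype.find(pattern)
        while i != -1:
            if i != home:
                return i, len(pattern)
            i = haplotype.find(pattern, i + 1)
    return None


def template_from_assay(
    f1: str,
    r1: str,
    f2: str,
    r2: str,
    a: int,
    b: int,
    allele_x: str,
    allele_y: str,
    label: str = "",
    pad: int = 10,
) -> SnpLocus:
    """Reconstruct a synthetic locus on which the primers produce (a, b).

    The F1 footprint is placed ``pad`` bases from the left edge; the SNP
    offset, the confronting-primer footprints and the R2 footprint follow
    from the CTPP size equations. Filler bases repeat ACGT and are
    deterministically repaired so no primer has a spurious exact match on
    either haplotype.
    """
    f1, r1, f2, r2 = map(clean_sequence, (f1, r1, f2, r2))
    d = len(f2) + len(r1)
    if a < d or b < d:
        raise ReconstructionError(
            f"allele fragments a={a}, b={b} cannot be shorter than "
            f"d = len(F2) + len(R1) = {d}"
        )
    f1_start = pad
    snp = f1_start + a - len(r1)
    f2_start = snp - len(f2) + 1
    r2_end = b + snp - len(f2) + 1
    r2_start = r2_end - len(r2)
    if f2_start <= f1_start or f1_start + len(f1) > snp:
        raise ReconstructionError("F1 footprint collides with F2/SNP; a too small")
    if r2_start <= snp:
        raise ReconstructionError("R2 footprint reaches the SNP; b too small")
    length = r2_end + pad

    placements = [
        (f1_start, f1),
        (f2_start, f2),
        (snp, reverse_complement(r1)),
        (r2_start, reverse_complement(r2)),
    ]
    template = _write_footprints(length, placements, snp, clean_sequence(allele_x))

    # Repair filler-created spurious matches, deterministically.
    footprint_pos = {
        pos
        for start, plus_seq in placements
        for pos in range(start, start + len(plus_seq))
    }
    patterns = [
        (f1, f1_start),
        (f2, f2_start),
        (reverse_complement(r1), snp),
        (reverse_complement(r2), r2_start),
    ]
    for _ in range(4 * length):
        locus = SnpLocus(
            template="".join(template),
            snp_offset=snp,
            allele_x=allele_x,
            allele_y=allele_y,
            label=label,
        )
        hit = None
        for hap in (locus.haplotype(locus.allele_x), locus.haplotype(locus.allele_y)):
            hit = _spurious_hit(hap, patterns)
            if hit:
                break
        if hit is None:
            return locus
        pos0, plen = hit
        mutable = [p for p in range(pos0, pos0 + plen) if p not in footprint_pos]
        if not mutable:
            raise ReconstructionError(
                "spurious primer match inside footprints; primers are not "
                "unique on this template"
            )
        p = mutable[0]
        template[p] = _FILLER[(_FILLER.index(template[p]) + 1) % len(_FILLER)]
    raise ReconstructionError("could not eliminate spurious primer matches")


def assay_from_primers(
    name_or_row: str | dict,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    pad: int = 10,
) -> CtppAssay:
    """Build a full CtppAssay from a primer table row (or bundled name)."""
    row = (
        BUNDLED_ASSAY_TABLE[name_or_row]
        if isinstance(name_or_row, str)
        else name_or_row
    )
    locus = template_from_assay(
        row["f1"], row["r1"], row["f2"], row["r2"],
        row["a"], row["b"], row["allele_x"], row["allele_y"],
        label=row.get("label", ""), pad=pad,
    )
    snp = locus.snp_offset
    f1, r1, f2, r2 = map(clean_sequence, (row["f1"], row["r1"], row["f2"], row["r2"]))
    return CtppAssay(
        f1=Primer(seq=f1, role="F1", start=pad),
        r1=Primer(seq=r1, role="R1", start=snp),
        f2=Primer(seq=f2, role="F2", start=snp - len(f2) + 1),
        r2=Primer(seq=r2, role="R2", start=snp + row["b"] - len(f2) + 1 - len(r2)),
        locus=locus,
        conditions=conditions,
        label=row.get("label", ""),
        notes=row.get("notes", ""),
    )


def bundled_assay(name: str) -> CtppAssay:
    """Load a bundled assay ('vkorc1' or 'cyp2c9') from package data."""
    from .io import read_assay_json  # deferred: io imports design types

    key = name.lower()
    if key not in BUNDLED_ASSAY_TABLE:
        raise KeyError(
            f"unknown bundled assay {name!r}; available: "
            + ", ".join(sorted(BUNDLED_ASSAY_TABLE))
        )
    ref = resources.files("ctpp").joinpath(f"data/{key}.assay.json")
    with resources.as_file(ref) as path:
        return read_assay_json(path)


def list_bundled_assays() -> list[str]:
    return sorted(BUNDLED_ASSAY_TABLE)


def sample_genotypes(p_x: float, n: int, seed: int) -> list[str]:
    """Draw *n* genotype labels under Hardy-Weinberg equilibrium.

    Each individual draws two alleles independently, Bernoulli(p_x) for
    allele X; reproducible for a given seed.
    """
    if not 0.0 <= p_x <= 1.0:
        raise ValueError("p_x must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x_alleles = (rng.random((n, 2)) < p_x).sum(axis=1)
    labels = np.array(["YY", "XY", "XX"])
    return list(labels[x_alleles])


def random_locus(
    length: int,
    snp_offset: int,
    seed: int,
    label: str = "random locus",
) -> SnpLocus:
    """A uniformly random template with a biallelic SNP at *snp_offset*.

    The template base at the SNP becomes allele X; allele Y is drawn from
    the three remaining bases. Deterministic per seed.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if not 0 < snp_offset < length - 1:
        raise ValueError(
            f"snp_offset {snp_offset} leaves no flank within a template of "
            f"length {length}"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    template = "".join(rng.choice(bases, size=length))
    allele_x = template[snp_offset]
    allele_y = rng.choice([b for b in "ACGT" if b != allele_x])
    return SnpLocus(
        template=template,
        snp_offset=snp_offset,
        allele_x=allele_x,
        allele_y=str(allele_y),
        label=label,
    )
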