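"""Nucleotide sequence validation and strand arithmetic.

Sequences are plain uppercase strings over the unambiguous DNA alphabet
{A, C, G, T}, always written 5'->3'. Degenerate IUPAC codes are rejected
rather than coerced: allele-specific primer design depends on the identity
of single bases, so an N or R in the input is an error, not a wildcard.
"""

from __future__ import annotations

from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SequenceError(ValueError):
    """Raised for empty, non-DNA or degenerate-code input."""


def clean_sequence(bases: str) -> str:
    """Normalise *bases* to an uppercase A/C/G/T string or raise.

    Whitespace is stripped (primer sequences are conventionally printed in
    space-separated triplets); anything else outside {A, C, G, T} raises
    :class:`SequenceError`.
    """
    s = "".join(str(bases).split()).upper()
    if not s:
        raise SequenceError("empty sequence")
    bad = set(s) - VALID_BASES
    if bad:
        raise SequenceError(
            f"invalid characters {sorted(bad)} in sequence; "
            "only unambiguous A/C/G/T are accepted"
        )
    return s


def reverse_complement(bases: str) -> str:
    """Reverse complement of a validated A/C/G/T string."""
    return str(Seq(clean_sequence(bases)).reverse_complement())


def complement_base(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise SequenceError(f"invalid base {base!r}") from None
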