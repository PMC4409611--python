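"""Nearest-neighbor melting-temperature computation for CTPP primers.

The model is the classic dinucleotide nearest-neighbor thermodynamics of
Breslauer, Frank, Bloecker & Marky (1986) with the Schildkraut-Lifson
monovalent-salt correction:

    Tm(K) = dH_total / (dS_total + R * ln(CT / 4))
    Tm(C) = Tm(K) - 273.15 + 16.6 * log10([Na+])

where dH_total and dS_total are sums of per-dinucleotide helix-formation
enthalpies and entropies plus a helix-initiation entropy, R is the gas
constant (1.987 cal/mol/K), CT the total single-strand concentration and
[Na+] the monovalent cation molarity. The CT/4 term assumes the primer is
not self-complementary and is in excess of complement — the usual primer
approximation.

Defaults are the historical primer-design convention attached to this
parameter set: [Na+] = 50 mM, CT = 50 nM. No hairpin, dimer, mismatch or
divalent-cation corrections are applied; the value is a pure duplex Tm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .seq import clean_sequence

#: Gas constant, cal / (mol K).
GAS_CONSTANT_R = 1.987

#: Minimum primer length the nearest-neighbor model is applied to.
MIN_LENGTH = 8

# Breslauer et al. (1986) helix-formation parameters per 5'->3' dinucleotide,
# stored as magnitudes for duplex formation: dH in kcal/mol, dS in cal/mol/K
# (both are negative for formation; signs cancel in the Tm quotient and the
# tables are conventionally printed positive).
NN_DH: dict[str, float] = {
    "AA": 9.1, "TT": 9.1,
    "AT": 8.6,
    "TA": 6.0,
    "CA": 5.8, "TG": 5.8,
    "GT": 6.5, "AC": 6.5,
    "CT": 7.8, "AG": 7.8,
    "GA": 5.6, "TC": 5.6,
    "CG": 11.9,
    "GC": 11.1,
    "GG": 11.0, "CC": 11.0,
}

NN_DS: dict[str, float] = {
    "AA": 24.0, "TT": 24.0,
    "AT": 23.9,
    "TA": 16.9,
    "CA": 12.9, "TG": 12.9,
    "GT": 17.3, "AC": 17.3,
    "CT": 20.8, "AG": 20.8,
    "GA": 13.5, "TC": 13.5,
    "CG": 27.8,
    "GC": 26.7,
    "GG": 26.6, "CC": 26.6,
}

#: Helix-initiation entropy magnitude, cal/mol/K.
INITIATION_DS = 10.8


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for the Tm calculation.

    Parameters
    ----------
    monovalent_cation_conc:
        [Na+] in mol/L. Default 0.05 (50 mM).
    total_strand_conc:
        Total oligonucleotide strand concentration CT in mol/L.
        Default 5e-8 (50 nM).
    """

    monovalent_cation_conc: float = 0.05
    total_strand_conc: float = 5e-8

    def __post_init__(self) -> None:
        if self.monovalent_cation_conc <= 0:
            raise ValueError("monovalent cation concentration must be > 0")
        if self.total_strand_conc <= 0:
            raise ValueError("total strand concentration must be > 0")

    def to_dict(self) -> dict:
        return {
            "monovalent_cation_conc": self.monovalent_cation_conc,
            "total_strand_conc": self.total_strand_conc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThermoConditions":
        return cls(**d)


DEFAULT_CONDITIONS = ThermoConditions()


def duplex_enthalpy_entropy(seq: str) -> tuple[float, float]:
    """Summed nearest-neighbor (dH, dS) for *seq* as formation magnitudes.

    Returns dH in kcal/mol and dS in cal/mol/K, including the initiation
    entropy. Raises for sequences shorter than :data:`MIN_LENGTH`.
    """
    s = clean_sequence(seq)
    if len(s) < MIN_LENGTH:
        raise ValueError(
            f"sequence of length {len(s)} is too short for the "
            f"nearest-neighbor model (minimum {MIN_LENGTH})"
        )
    dh = 0.0
    ds = INITIATION_DS
    for i in range(len(s) - 1):
        nn = s[i : i + 2]
        dh += NN_DH[nn]
        ds += NN_DS[nn]
    return dh, ds


def melting_temperature(
    seq: str, cond: ThermoConditions = DEFAULT_CONDITIONS
) -> float:
    """Nearest-neighbor melting temperature of *seq* in degrees Celsius.

    Full double precision is returned; use :func:`round_tm` for the
    one-decimal presentation used in assay reports.
    """
    dh, ds = duplex_enthalpy_entropy(seq)
    # Formation signs: dH, dS negative; R ln(CT/4) negative for CT < 4 M.
    tm_kelvin = (-dh * 1000.0) / (
        -ds + GAS_CONSTANT_R * math.log(cond.total_strand_conc / 4.0)
    )
    return (
        tm_kelvin
        - 273.15
        + 16.6 * math.log10(cond.monovalent_cation_conc)
    )


def round_tm(tm_celsius: float) -> float:
    """Round a Tm to one decimal, half-up (65.05 -> 65.1)."""
    return float(
        Decimal(repr(tm_celsius)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
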