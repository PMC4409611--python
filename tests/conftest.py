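import numpy as np
import pytest

from ctpp.design import CtppAssay, Primer
from ctpp.fixtures import bundled_assay, random_locus
from ctpp.seq import reverse_complement


@pytest.fixture(scope="session")
def vkorc1():
    return bundled_assay("vkorc1")


@pytest.fixture(scope="session")
def cyp2c9():
    return bundled_assay("cyp2c9")


def make_random_assay(seed: int, length: int = 320) -> CtppAssay:
    """A geometrically valid CTPP assay on a random locus, no Tm screening.

    Product sizes are kept at least 4 bp apart so band patterns stay
    unambiguous at small calling tolerances.
    """
    rng = np.random.default_rng(seed)
    snp = int(rng.integers(length // 2 - 30, length // 2 + 30))
    locus = random_locus(length, snp, seed=int(rng.integers(0, 2**31 - 1)))
    snp = locus.snp_offset
    len_r1 = int(rng.integers(17, 26))
    len_f2 = int(rng.integers(17, 26))
    len_f1 = int(rng.integers(17, 26))
    len_r2 = int(rng.integers(17, 26))
    d = len_f2 + len_r1

    hap_x = locus.haplotype(locus.allele_x)
    hap_y = locus.haplotype(locus.allele_y)

    # a = snp + len_r1 - f1_start; keep F1 clear of the SNP and of F2.
    a_min = d + 3 + int(rng.integers(0, 20))
    f1_start = snp + len_r1 - a_min
    f1_start = max(0, min(f1_start, snp - len_f1))
    a = snp + len_r1 - f1_start
    # b = r2_end - (snp - len_f2 + 1); force |a - b| >= 4 and keep the R2
    # footprint strictly downstream of the SNP for any length pairing.
    b = a + 12 + int(rng.integers(0, 30))
    r2_end = b + snp - len_f2 + 1
    r2_end = min(r2_end, len(hap_x))
    b = r2_end - (snp - len_f2 + 1)
    assert abs(a - b) >= 4 and b >= d

    return CtppAssay(
        f1=Primer(seq=hap_x[f1_start : f1_start + len_f1], role="F1", start=f1_start),
        r1=Primer(seq=reverse_complement(hap_x[snp : snp + len_r1]), role="R1", start=snp),
        f2=Primer(seq=hap_y[snp - len_f2 + 1 : snp + 1], role="F2", start=snp - len_f2 + 1),
        r2=Primer(
            seq=reverse_complement(hap_x[r2_end - len_r2 : r2_end]),
            role="R2",
            start=r2_end - len_r2,
        ),
        locus=locus,
        label=f"random assay {seed}",
    )
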