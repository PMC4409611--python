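"""CTPP geometry: fragment sizes, band patterns, validation, design search."""

import itertools
from types import SimpleNamespace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctpp.design import (
    AssayError,
    CtppAssay,
    DesignConstraints,
    FragmentPattern,
    InsufficientFlankError,
    Primer,
    common_fragment_size,
    design_assay,
    expected_band_pattern,
    fragment_pattern,
    validate_assay,
)
from ctpp.fixtures import random_locus
from ctpp.seq import reverse_complement
from ctpp.thermo import melting_temperature
from conftest import make_random_assay


class TestFragmentPattern:
    def test_vkorc1_published_sizes(self, vkorc1):
        fp = fragment_pattern(vkorc1)
        assert (fp.a, fp.b, fp.c, fp.d) == (119, 208, 284, 44)

    def test_cyp2c9_published_sizes(self, cyp2c9):
        fp = fragment_pattern(cyp2c9)
        assert (fp.a, fp.b, fp.c, fp.d) == (125, 200, 287, 39)

    def test_degenerate_footprints_are_formula_fixed_point(self):
        # When the outer primers collapse onto the confronting footprints,
        # both allele products equal d - 1 and so does the common product.
        d = 40
        assert common_fragment_size(d - 1, d - 1, d) == d - 1

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.integers(40, 400),
        b=st.integers(40, 400),
        d=st.integers(34, 60),
    )
    def test_identity_enforced_and_consistent(self, a, b, d):
        if a < d or b < d:
            with pytest.raises(ValueError):
                FragmentPattern(a=a, b=b, c=common_fragment_size(a, b, d), d=d)
            return
        fp = FragmentPattern(a=a, b=b, c=common_fragment_size(a, b, d), d=d)
        assert fp.c == a + b - d + 1
        with pytest.raises(ValueError, match="c = a"):
            FragmentPattern(a=a, b=b, c=fp.c + 1, d=d)

    def test_identity_on_random_assays(self):
        for seed in range(100):
            fp = fragment_pattern(make_random_assay(seed))
            assert fp.c == common_fragment_size(fp.a, fp.b, fp.d)


class TestExpectedBandPattern:
    @pytest.mark.parametrize(
        "genotype,expected",
        [("XX", {119, 284}), ("XY", {119, 208, 284}), ("YY", {208, 284})],
    )
    def test_vkorc1_lanes(self, vkorc1, genotype, expected):
        assert expected_band_pattern(vkorc1, genotype) == expected

    @pytest.mark.parametrize(
        "genotype,expected",
        [("XX", {125, 287}), ("XY", {125, 200, 287}), ("YY", {200, 287})],
    )
    def test_cyp2c9_lanes(self, cyp2c9, genotype, expected):
        assert expected_band_pattern(cyp2c9, genotype) == expected

    def test_heterozygote_is_union_of_homozygotes(self):
        for seed in range(20):
            assay = make_random_assay(seed)
            assert expected_band_pattern(assay, "XY") == (
                expected_band_pattern(assay, "XX")
                | expected_band_pattern(assay, "YY")
            )

    def test_unknown_genotype_rejected(self, vkorc1):
        with pytest.raises(ValueError):
            expected_band_pattern(vkorc1, "ZZ")


class TestValidateAssay:
    def test_bundled_assays_are_clean(self, vkorc1, cyp2c9):
        assert validate_assay(vkorc1) == []
        assert validate_assay(cyp2c9) == []

    def _broken(self, assay, **overrides):
        fields = dict(
            f1=assay.f1, r1=assay.r1, f2=assay.f2, r2=assay.r2,
            locus=assay.locus,
        )
        fields.update(overrides)
        return SimpleNamespace(**fields)

    def test_r1_not_anchored_at_snp(self, vkorc1):
        shifted = Primer(seq=vkorc1.r1.seq, role="R1", start=vkorc1.r1.start + 1)
        violations = validate_assay(self._broken(vkorc1, r1=shifted))
        assert any("R1 3' end not anchored at SNP" in v for v in violations)

    def test_swapped_inner_primers(self, vkorc1):
        f2_as_r1 = Primer(seq=vkorc1.f2.seq, role="R1", start=vkorc1.locus.snp_offset)
        r1_as_f2 = Primer(seq=vkorc1.r1.seq, role="F2", start=vkorc1.f2.start)
        violations = validate_assay(self._broken(vkorc1, r1=f2_as_r1, f2=r1_as_f2))
        assert violations

    def test_wrong_allele_base_at_r1_three_prime(self, vkorc1):
        seq = vkorc1.r1.seq[:-1] + "G"  # should be complement of allele X (A->T)
        bad = Primer(seq=seq, role="R1", start=vkorc1.r1.start)
        violations = validate_assay(self._broken(vkorc1, r1=bad))
        assert any("complement of allele X" in v for v in violations)

    def test_constructor_rejects_invalid_assay(self, vkorc1):
        with pytest.raises(AssayError):
            CtppAssay(
                f1=vkorc1.f1,
                r1=Primer(seq=vkorc1.r1.seq, role="R1", start=vkorc1.r1.start + 3),
                f2=vkorc1.f2,
                r2=vkorc1.r2,
                locus=vkorc1.locus,
            )


def brute_force_best_spread(locus, cons):
    """Independent oracle: enumerate every primer quadruple in the
    constraint box with plain nested loops and return the minimal
    max-pairwise Tm difference among feasible CTPP assays."""
    snp = locus.snp_offset
    hap_x = locus.haplotype(locus.allele_x)
    hap_y = locus.haplotype(locus.allele_y)
    lo, hi = cons.primer_len
    tm_cache = {}

    def tm(seq):
        if seq not in tm_cache:
            tm_cache[seq] = melting_temperature(seq)
        return tm_cache[seq]

    best = None
    for len_r1 in range(lo, hi + 1):
        if snp + len_r1 > len(hap_x):
            continue
        r1_seq = reverse_complement(hap_x[snp : snp + len_r1])
        for len_f2 in range(lo, hi + 1):
            if snp - len_f2 + 1 < 0:
                continue
            f2_seq = hap_y[snp - len_f2 + 1 : snp + 1]
            for a in range(cons.a_range[0], cons.a_range[1] + 1):
                f1_start = snp + len_r1 - a
                if f1_start < 0:
                    continue
                for len_f1 in range(lo, hi + 1):
                    if f1_start + len_f1 - 1 > snp - 1:
                        continue
                    f1_seq = hap_x[f1_start : f1_start + len_f1]
                    for b in range(cons.b_range[0], cons.b_range[1] + 1):
                        r2_end = b + snp - len_f2 + 1
                        if r2_end > len(hap_x):
                            continue
                        c = r2_end - f1_start
                        if not cons.c_range[0] <= c <= cons.c_range[1]:
                            continue
                        for len_r2 in range(lo, hi + 1):
                            r2_start = r2_end - len_r2
                            if r2_start <= snp:
                                continue
                            r2_seq = reverse_complement(hap_x[r2_start:r2_end])
                            tms = [tm(s) for s in (f1_seq, r1_seq, f2_seq, r2_seq)]
                            if any(
                                not cons.tm_window[0] <= t <= cons.tm_window[1]
                                for t in tms
                            ):
                                continue
                            spread = max(tms) - min(tms)
                            if spread > cons.max_tm_spread:
                                continue
                            if best is None or spread < best:
                                best = spread
    return best


SMALL_CONSTRAINTS = DesignConstraints(
    primer_len=(18, 22),
    tm_window=(50.0, 80.0),
    max_tm_spread=10.0,
    a_range=(60, 90),
    b_range=(60, 90),
    c_range=(80, 200),
    min_flank=40,
)


class TestDesignAssay:
    def test_top_assay_matches_exhaustive_oracle(self):
        locus = random_locus(240, 120, seed=8)
        top = design_assay(locus, SMALL_CONSTRAINTS, limit=1)
        assert top, "expected a feasible design"
        oracle_best = brute_force_best_spread(locus, SMALL_CONSTRAINTS)
        assert top[0].tm_spread() == pytest.approx(oracle_best, abs=1e-9)

    def test_designs_satisfy_all_constraints_and_invariants(self):
        locus = random_locus(240, 120, seed=8)
        designs = design_assay(locus, SMALL_CONSTRAINTS, limit=50)
        assert designs
        for assay in designs:
            assert validate_assay(assay) == []
            fp = fragment_pattern(assay)
            assert fp.c == common_fragment_size(fp.a, fp.b, fp.d)
            assert SMALL_CONSTRAINTS.a_range[0] <= fp.a <= SMALL_CONSTRAINTS.a_range[1]
            assert SMALL_CONSTRAINTS.b_range[0] <= fp.b <= SMALL_CONSTRAINTS.b_range[1]
            assert assay.tm_spread() <= SMALL_CONSTRAINTS.max_tm_spread + 1e-12
            # allele-specific 3' anchoring
            assert assay.r1.seq[-1] == {"A": "T", "C": "G", "G": "C", "T": "A"}[
                assay.locus.allele_x
            ]
            assert assay.f2.seq[-1] == assay.locus.allele_y

    def test_ranking_is_deterministic(self):
        locus = random_locus(240, 120, seed=8)
        first = design_assay(locus, SMALL_CONSTRAINTS, limit=20)
        second = design_assay(locus, SMALL_CONSTRAINTS, limit=20)
        assert first == second

    def test_ranking_orders_by_spread_then_c(self):
        locus = random_locus(240, 120, seed=8)
        designs = design_assay(locus, SMALL_CONSTRAINTS, limit=200)
        keys = [
            (assay.tm_spread(), fragment_pattern(assay).c) for assay in designs
        ]
        assert keys == sorted(keys)

    def test_insufficient_flank_raises(self):
        locus = random_locus(200, 5, seed=1)
        with pytest.raises(InsufficientFlankError):
            design_assay(locus, DesignConstraints(min_flank=50))

    def test_infeasible_constraints_return_empty_list(self):
        locus = random_locus(240, 120, seed=8)
        impossible = DesignConstraints(
            primer_len=(18, 22), tm_window=(90.0, 95.0),
            a_range=(60, 90), b_range=(60, 90), c_range=(80, 200),
            min_flank=40,
        )
        assert design_assay(locus, impossible) == []


def test_constraint_ranges_validated():
    with pytest.raises(ValueError):
        DesignConstraints(primer_len=(30, 17))
    with pytest.raises(ValueError):
        DesignConstraints(max_tm_spread=-1.0)
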