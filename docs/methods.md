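# Methods

## The CTPP model

PCR with confronting two-pair primers (PCR-CTPP) genotypes a biallelic SNP
in one reaction and one gel lane. Four primers are placed on the template:
an outer forward primer F1 and outer reverse primer R2, both
allele-neutral, and an inner "confronting" pair whose 3'-terminal bases
sit on the SNP from opposite strands — R1 ending on the complement of
allele X, F2 ending on allele Y. Because a 3'-terminal mismatch blocks
polymerase extension (the ARMS principle), F1–R1 amplifies only
X-carrying chromosomes and F2–R2 only Y-carrying chromosomes, while F1–R2
amplifies from every template. With product sizes

- `a` = F1–R1 (allele X),
- `b` = F2–R2 (allele Y),
- `c` = F1–R2 (common),
- `d` = len(F2) + len(R1),

the geometry forces the identity `c = a + b − (d − 1)`: the X and Y
products tile the common product and double-count the d − 1 positions
covered by the confronting footprints (their combined length minus the
one SNP base both include). Genotypes read directly off the gel:
XX → {a, c}, XY → {a, b, c}, YY → {b, c}.

Coordinates are 0-based, half-open on the plus strand everywhere; reverse
primers are stored 5'→3' in their own orientation with a plus-strand
footprint. A single convention matters here because the c-identity is
sensitive to off-by-one errors. `FragmentPattern` re-asserts the identity
at construction, so it cannot silently drift; it also enforces
`a ≥ d` and `b ≥ d`, the geometric minimum for real assays (the arithmetic
fixed point a = b = c = d − 1, where both outer primers collapse onto the
confronting footprints, is exercised at the formula level in the tests,
since such an assay violates the footprint constraints).

## Melting temperatures

Primers are scored by the dinucleotide nearest-neighbor model of
Breslauer, Frank, Blöcker & Marky (1986):

    Tm(°C) = ΔH / (ΔS + R·ln(CT/4)) − 273.15 + 16.6·log10([Na+])

with ΔH, ΔS summed over the 16 dinucleotide stacks plus a helix-initiation
entropy of −10.8 cal/mol/K, R = 1.987 cal/mol/K, and the
Schildkraut–Lifson monovalent-salt term. Defaults are the historical
primer-design convention attached to this table: [Na+] = 50 mM,
CT = 50 nM total strands. The CT/4 divisor assumes a non-self-
complementary oligo. No hairpin, dimer, mismatch or divalent corrections
are applied. Values are reported to one decimal, rounded half-up.

The nearest-neighbor sum is strand-symmetric under this table, so
Tm(s) = Tm(reverse_complement(s)) exactly; the suite verifies this and
checks the implementation against an independently retyped table-summation
oracle to 1e-9 °C.

**Known limitation.** The published Tm column for the two bundled assays
is not reproducible from the printed primer sequences under this
convention, nor under any standard alternative we evaluated (Breslauer
with Na+ from 15 mM to 1 M, CT from 25 nM to 1 µM and initiation entropies
from 0 to 20.1 cal/mol/K; SantaLucia-1998 unified parameters with either
salt correction; the %GC formula; the Wallace rule). Residuals at the
default convention range from −0.2 to +7.1 °C, concentrated on the two
longest primers (26- and 27-mers); even a least-squares GC+length fit
leaves ±1.8 °C. The package therefore keeps the faithful, documented
Breslauer convention rather than an untraceable per-primer adjustment, and
the test asserting ±1.0 °C agreement with the published column fails by
design of honesty. Tm *differences* between primers — what the design
score actually uses — are unaffected by any uniform convention shift.

## Assay design

`design_assay` searches exhaustively. R1 and F2 are anchored at the SNP,
so only their lengths vary; F1 and R2 slide within the allele-product
size windows. Candidates outside the Tm window are discarded, quadruples
outside the size ranges or above the Tm-spread cap are discarded, and the
survivors are ranked by ascending Tm spread (max pairwise |ΔTm| among the
four primers — band-strength balance is the known CTPP failure mode),
ties broken by smaller common product c, then by primer start
coordinates and lengths. The ranking is computed on lightweight tuples
and only the returned prefix is materialised as validated assay objects,
so `limit=` makes large searches cheap. The search is deterministic:
identical inputs give byte-identical output.

Default constraints: primer length 17–30 nt, Tm window 60–66 °C, max
spread 3.0 °C, a and b in 100–260 bp, c in 150–520 bp, min flank 100 bp —
product sizes chosen to be resolvable on standard agarose against a
100-bp ladder, length range bracketing the bundled assays' primers.
Dimer/hairpin screening, GC-clamp and 3'-stability scoring are
deliberately out of scope in this version.

## In-silico PCR and calling

A primer anneals iff its full sequence matches the haplotype exactly,
3'-terminal base included. This all-or-nothing rule reproduces the
allele discrimination without mismatch thermodynamics; it does not model
partial-mismatch extension, primer-dimer artifacts or band intensity.
Per haplotype the three pairs F1–R1, F2–R2 and F1–R2 each yield a product
wherever forward and reverse sites co-occur; haplotype duplicates collapse
in the band view.

`call_genotype` accepts the unique genotype whose expected pattern
matches the observed sizes within ±tolerance per band, with no missing
expected band and no unexplained observed band; anything else is a
NO_CALL carrying a reason (no bands, allele bands absent, missing common
band, extra band, ambiguous). The default tolerance is ±5 bp, which keeps
the closest bundled bands (119 vs 125, 200 vs 208 bp) separable; it is a
parameter everywhere. Matching is nearest-expected with inclusive
boundaries, so a band exactly `tolerance` away still matches.

## Synthetic templates and cohorts

`template_from_assay` rebuilds a locus from the four primer sequences and
the sizes a, b alone: footprint coordinates follow from the size
equations, footprints are written onto an ACGT-repeat filler, and the
filler is repaired deterministically (cycling a non-footprint base) until
no primer has a spurious exact match on either haplotype. Overlapping
footprints must agree except at the SNP, where the canonical template
carries allele X. These templates reproduce the assay's amplification
behaviour exactly but are **synthetic** — they are not the genomic
flanking sequence, and the bundled files say so. Passing tests on them
demonstrates the geometry, simulation and calling machinery, not primer
specificity against a real genome.

`sample_genotypes` draws two Bernoulli(p_x) alleles per individual —
exact Hardy-Weinberg sampling, seeded and reproducible. It emulates
genotype-frequency structure only: no linkage, no genotyping error, no
missingness.

## Statistics

Allele frequencies are by allele counting; frequencies are exact
complements before rounding (3 d.p., half-up). The HWE test is the
Pearson chi-square on the three genotype classes against (np², 2npq, nq²)
with df = 1 and **no** Yates continuity correction — with the correction
the published p-values (0.514, 0.658) are not recovered from the
published counts; without it they are, to 3 d.p. An exact
(Wigginton-style) test is a noted extension for small expected classes
(the rarer bundled homozygote class has expected count ≈ 0.19).
Monomorphic samples return a flagged degenerate result (χ² = 0, p = 1)
with a warning rather than an error. Concordance pairs two call sets by
sample id, drops pairs with a NO_CALL on either side, and reports
n_compared, n_agreeing, the rate and a 3×3 confusion table.

Null-calibration checks use cohorts of n = 500 at p_x = 0.3 across 1,000
seeds (Kolmogorov–Smirnov distance of the HWE p-values from uniform
< 0.1) and 100 cohorts of n = 100,000 for the false-rejection rate;
these sizes give stable chi-square asymptotics while keeping the suite
fast. The design-search oracle comparison runs on a 240-bp locus with
primer lengths 18–22 and product windows of 60–90/80–200 bp, small
enough for the independent nested-loop enumeration to stay exhaustive.

## Degenerate inputs and numeric choices

Sequences must be unambiguous A/C/G/T; IUPAC degenerate codes are
rejected, never coerced, because single-base identity is what the method
genotypes. The nearest-neighbor model requires ≥ 8 nt. All reported
roundings are half-up (matching tabular presentation conventions); full
precision is kept internally and in every intermediate.
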