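# ctpp

Design, simulation and statistical validation of **PCR-CTPP** (PCR with
confronting two-pair primers) SNP genotyping assays — the single-tube,
gel-readout alternative to PCR-RFLP used in low-cost pharmacogenetic
typing, e.g. of the warfarin-dose loci *VKORC1* G-1639A (rs9923231) and
*CYP2C9* A1075C (*CYP2C9\*3*, rs1057910), whose published assays ship with
the package.

## The method

A CTPP assay places four primers around a biallelic SNP (alleles X and Y):

```
  F1 →            F2 →
  ──────────────────X──────────────────  plus strand
                  ← R1               ← R2
```

The inner, confronting primers end 3'-terminally **on** the SNP from
opposite strands (R1 matching allele X, F2 matching allele Y), so a
3'-terminal mismatch blocks extension and each allele yields a product of
its own size — `a` (F1–R1) for X, `b` (F2–R2) for Y — next to the common
outer product `c` (F1–R2). The sizes obey

```
c = a + b − (d − 1),      d = len(F2) + len(R1)
```

and the genotype is read straight off the gel: XX → {a, c},
XY → {a, b, c}, YY → {b, c}.

The package covers the full workflow:

- **thermo** — Breslauer nearest-neighbor melting temperatures with
  Schildkraut salt correction (defaults 50 mM Na⁺, 50 nM strands);
- **design** — exhaustive, deterministic assay search ranked by Tm
  balance (max pairwise ΔTm across the four primers);
- **insilico** — exact-match in-silico PCR, genotype calling from band
  sizes with explicit NO_CALL reasons, text-gel rendering;
- **popgen** — allele frequencies, Pearson χ² Hardy-Weinberg test
  (df = 1, no continuity correction), call-failure rate, inter-platform
  concordance;
- **fixtures** — synthetic template reconstruction from primers +
  fragment sizes, seeded Hardy-Weinberg cohort sampling, the two bundled
  assays;
- **io / cli** — FASTA, assay JSON and TSV formats plus the `ctpp`
  command-line tool.

## Worked example

```python
from ctpp import bundled_assay, fragment_pattern, expected_band_pattern
from ctpp.insilico import BandObservation, call_genotype
from ctpp.popgen import GenotypeCounts, allele_frequencies, hwe_test, round_frequency

assay = bundled_assay("vkorc1")
print("fragments:", fragment_pattern(assay))
print("GA bands:", sorted(expected_band_pattern(assay, "XY")))

call = call_genotype(BandObservation("patient_7", (121, 209, 285)), assay)
print("call:", call.call, dict(call.matched_bands))

counts = GenotypeCounts(2, 68, 356)   # GG, GA, AA
p_g, p_a = allele_frequencies(counts)
res = hwe_test(counts)
print(f"freq G={round_frequency(p_g)} A={round_frequency(p_a)} "
      f"chi2={res.chi2:.3f} p={res.p:.3f}")
```

prints

```
fragments: FragmentPattern(a=119, b=208, c=284, d=44)
GA bands: [119, 208, 284]
call: XY {121: 119, 209: 208, 285: 284}
freq G=0.085 A=0.915 chi2=0.426 p=0.514
```

The assay's heterozygote lane carries the 119-bp X-allele product, the
208-bp Y-allele product and the 284-bp common product; a lane observed at
121/209/285 bp still calls as a heterozygote within the ±5 bp default
tolerance; and the population sample is in Hardy-Weinberg equilibrium
(p = 0.514) with a minor-allele frequency of 0.085.

The same operations are available from the shell:

```sh
ctpp bands --assay vkorc1 --genotype GA      # 119,208,284
ctpp hwe --counts 2 68 356                   # frequencies, chi2, p
ctpp design --fasta locus.fa --snp-offset 300 --allele-x G --allele-y A
ctpp fixtures --outdir fixtures/             # write bundled assays to disk
```

## Caveats

Bundled templates are synthetic reconstructions from the published primer
sequences and fragment sizes, not genomic reference sequence. The Tm
engine is a pure duplex nearest-neighbor model: no hairpin, dimer,
mismatch or divalent-cation corrections. See `docs/methods.md` for the
model details, default parameters and known limitations.
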