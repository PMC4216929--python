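# strland

Short tandem repeats (STRs, microsatellites) are loci of tandemly repeated
2–6 bp motifs that mutate by gaining or losing repeat units. Cataloging them
and measuring their population variation from short-read sequencing is hard:
there is no consensus on when a repeat tract counts as an STR, PCR stutter
corrupts read lengths, and at low coverage one allele of a heterozygote
frequently drops out. `strland` is a toolkit for building STR catalogs with
statistically controlled false-positive rates and for computing the
population-genetic summary statistics that remain reliable despite those
error modes. It is aimed at researchers building or evaluating STR call sets
from population-scale sequencing.

## What it computes

**Catalog construction.** Candidate repeats are scored by wraparound
dynamic-programming alignment against an unbounded perfect repetition of
their motif (match +2, mismatch −7, indel −7). Because random DNA almost
never gives birth to a mature STR, null sequences drawn from a second-order
Markov chain fitted to the input genome (matching its composition and
transition frequencies) estimate the background detection rate. Per-period
score thresholds are then tuned so the expected fraction of false-positive
loci in the catalog is at most a target (1% by default):

    T_p = min { T : N_null,p(T) / N_real,p(T) ≤ α },

with null counts rescaled by sequence-length ratio.

**Call-set statistics.** Per-locus allele spectra, heterozygosity
H = 1 − Σᵢ pᵢ², dosage (Σ allele − reference, in bp), spectrum
normalization to repeat-unit offsets, common-polymorphism and
frameshift/LoF allele classification, saturation curves, and the diploid
dosage variance 2·Var(allele offset) under Hardy–Weinberg equilibrium.

**Quality control.** Trio Mendelian-inheritance rates versus coverage,
offset-calibrated concordance against capillary-style panels (the
1/0.5/0.25/0 per-sample scoring scheme), OLS dosage regression, and the
reference-deviation profile that localizes length-censoring bias.

**Population genetics and LD.** Slatkin's Rst in its pairwise-difference
form, Rst = (S̄ − S_W)/S̄; paired sign tests and Mann–Whitney comparisons
of heterozygosity; and STR–SNP linkage disequilibrium on phased hemizygous
haplotypes, as squared Pearson correlation of a SNP indicator with either
the STR bp-dosage or a per-population binary encoding, against a seed-SNP
SNP–SNP baseline.

**Synthetic data.** All of the above is exercised by a generator that
emulates low-coverage STR genotyping: stepwise (geometric) allele spectra,
HWE genotypes across differentiated populations, Poisson ~5× coverage with
a 76/100-bp read-length mixture, per-read stutter, length censoring by
`read length − 2 × flank`, trio transmission, and founder-based SNP–STR
haplotypes with distance-decaying LD.

## Worked example

```python
from strland import (SpectrumParams, SeqParams, simulate_population,
                     simulate_calls, spectrum_from_calls, heterozygosity,
                     dosage)

# a dinucleotide locus, major allele 30 bp, stepwise spectrum
spec = [("L0", SpectrumParams(major_allele_bp=30, period=2, decay=0.5))]
pop = simulate_population(spec, n_samples=200, seed=1)
calls = simulate_calls(pop, SeqParams(mean_coverage=5), seed=2)

s = spectrum_from_calls(calls.by_locus()["L0"])
print(f"n_calls={len(calls)}  het={heterozygosity(s):.3f}")
print(f"dosage of first call vs 30 bp ref: {dosage(calls.calls[0], 30)}")
```

prints

```
n_calls=198  het=0.811
dosage of first call vs 30 bp ref: 6
```

198 of 200 samples received at least one spanning read; the estimated
heterozygosity 0.811 sits close to the generating spectrum's 0.814 even
though individual genotypes suffer allelic dropout at 5× — dropout is
allele-symmetric here, so the frequency spectrum stays unbiased. The first
sample's genotype is 30/36 bp, three repeat units above the reference on
one chromosome, hence dosage +6.

A catalog build from the shell:

```sh
strland catalog build --fasta genome.fa --target-fp 0.01 \
    --null-length 10000000 --seed 1 --out catalog.bed \
    --calibration-out calibration.json
```

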