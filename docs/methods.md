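# Methods

## Repeat detection and scoring

A tandem repeat candidate is scored by aligning its sequence against an
unbounded perfect repetition of its motif with wraparound dynamic
programming. The alignment is global in the region (every region base is
matched, mismatched, or charged an indel) and free in the motif: any
starting phase, unbounded copies, free trailing bases. Weights are pinned
at match +2, mismatch −7, indel −7 so that scores are exactly reproducible;
a perfect tract of length L scores 2L. The DP state is the motif phase, with
phase-advancing gap moves relaxed around the cycle twice per column, and it
is verified in the test suite against an exhaustive linear-unrolled
Needleman–Wunsch oracle on all short inputs.

Detection seeds candidates wherever a motif occurs as an exact tandem pair
(a maximal run of positions with `seq[i] == seq[i+p]` of length ≥ p, for
each period p ≤ 6) and greedily merges same-motif seeds separated by at
most 8 bp when the merged wraparound score beats both parts; this recovers
interrupted repeats without heuristic consensus inference. Merging and
grouping use the strand-specific canonical rotation of the motif (scoring
"GT" against "AC" would be wrong), while reported loci carry the full
canonical motif (minimum over rotations and reverse complement of the
primitive unit) for cross-locus aggregation. Purity is the fraction of
positions in the locus whose next p bases are a cyclic rotation of the
motif. Overlap conflicts keep the highest score, ties breaking to the
leftmost then longest locus; periods above 6 are discarded first.

## Null calibration

Randomly shuffled DNA essentially never contains mature STRs, so repeats
detected in sequences drawn from an order-2 Markov chain fitted to the
input genome estimate the background rate of spurious detections. The fit
uses observed trinucleotide frequencies with add-one smoothing on all cells
— for well-sampled contexts the effect is negligible, and degenerate
training sequences cannot produce zero-probability lock-ups. Non-ACGT
characters reset the chain context so transitions never span assembly gaps.

Per motif period, the calibrated threshold is the minimal integer T at
which length-rescaled null detections with score ≥ T, divided by real
detections with score ≥ T, drop to the target false-positive fraction
(default 1%). Thresholds are per-period because the null score tail differs
by period. Homopolymers are detectable but excluded from the default
catalog (motifs of 2–6 bp). The default null length is 10 Mb: large enough
for stable tail estimates at the 1% target, small enough to run on a
desktop; null counts are rescaled by length ratio when real and null
lengths differ.

The end-to-end guarantee is checked by experiment
(`strland.experiments.calibration_fp_experiment`): simulate a 10 Mb genome
with embedded STR tracts at genome-like density (~230 loci/Mb of period
2–6, mean tract ~31 bp, 30% of tracts carrying 1–3 substitutions), fit the
null model, calibrate on one 10 Mb null draw, and measure leakage on an
independent second draw. Measured false-positive fractions sit at or below
the 1% target across seeds (binomial noise on a few dozen surviving null
detections makes single runs fluctuate by a few tenths of a percent).

## The synthetic sequencing pipeline

The generator emulates the statistical structure of low-coverage STR
genotyping, not the reads themselves:

- **Spectra**: p(k) ∝ decay^|k| over signed repeat-unit offsets k from the
  major allele (|k| ≤ max_steps, default 8). `decay` sets locus
  variability; an optional asymmetry skews the two tails. Defaults follow
  the prototypical STR: one prevalent major allele flanked by one-step
  minor alleles with geometrically falling tails.
- **Populations**: Hardy–Weinberg diploid draws; differentiated populations
  mix the base spectrum with a shifted copy, so the expected Rst is
  computable analytically from the construction (`rst_from_spectra`).
- **Reads**: Poisson coverage (default mean 5), each read sampling one true
  allele and a read length from a 50/50 mixture of 76 and 100 bp; a read
  observes the locus only if the allele fits in `read length − 2 × 8 bp`
  flanks. The mixture is what produces the non-monotone reference-deviation
  shape: alleles of 61–84 bp are visible only to 100-bp reads, above 84 bp
  to none.
- **Stutter**: with per-read probability 0.05, the reported length shifts
  by a geometric number of repeat units (parameter 0.7, so mostly ±1),
  direction fair. The published stutter-model parameters of the real
  genotyper are not public; these two values are free parameters of this
  package chosen to give visible but not dominant stutter at 5×, and both
  are exposed on `SeqParams`.
- **Calling**: a deliberately naive caller reports the one or two
  best-supported read lengths (ties to the shorter). Allelic dropout then
  emerges naturally at low coverage instead of being injected as an error
  rate. This is the main feature the generator is built to reproduce;
  what it does not model: alignment artifacts, read-level indel errors,
  GC-coverage bias, locus-specific stutter rates, population admixture.
  Passing tests therefore demonstrate correctness of the statistics under
  these idealized error modes, not calling accuracy on real reads.
- **Trios**: one allele transmitted uniformly from each parent, with
  optional ±1-unit stepwise mutation per transmission.
- **SNP–STR haplotypes**: a founder-copy model. Founder haplotypes carry
  Bernoulli SNP alleles and a spectrum-drawn STR allele; each output
  haplotype copies a random founder with distance-dependent switches
  (probability 1 − exp(−rate·gap)) and an optional stepwise STR mutation.
  LD with the STR decays with both distance and mutation rate, which is
  the mechanism behind the observed SNP–SNP > STR–SNP ordering.

All generators are reproducible from an integer seed.

## Statistics

- Heterozygosity H = 1 − Σ pᵢ² from aggregated spectra (two observations
  per diploid call, one per hemizygous call). Because random
  allele-symmetric dropout leaves the spectrum unbiased, H is
  dropout-robust; the suite verifies a regression slope of estimated on
  true H within [0.97, 1.03] across 220 simulated loci at 5×.
- Dosage: Σ(allele − reference) in bp; diploid dosage variance in repeat
  units is 2·Var(offset) under HWE, against the biallelic SNP ceiling of
  0.5.
- MAF of a multiallelic locus is 1 − major-allele frequency; major-allele
  ties break toward the shorter allele everywhere.
- Saturation curves use nested random subsets (sizes per the standard
  1–1000 ladder), median over 10 repetitions; with a MAF filter, frequency
  is assessed once on the full call set and membership per subset.
- Rst uses the pairwise-difference form: S_W pools within-population
  distinct pairs across populations (weight n_k(n_k−1)/2), S̄ averages all
  distinct pooled pairs, Rst = (S̄ − S_W)/S̄ (0 when S̄ = 0). This
  estimator is pinned by an all-pairs enumeration oracle. It carries a
  small negative finite-sample bias for undifferentiated populations
  (within-pairs exclude self-pairs; pooled cross-pairs do not), vanishing
  at realistic sample sizes.
- The sign test drops ties and uses a two-sided binomial p-value at p=0.5;
  the coding/noncoding comparison is a two-sided Mann–Whitney U.
- LD is the squared Pearson correlation between a SNP 0/1 indicator and
  either the STR bp-difference from the reference (dosage encoding) or a
  per-population major/other binary encoding. Pairs with missing entries
  drop pairwise; zero-variance vectors yield an undefined (missing) R².
  Profiles use 20 equal distance bins over the 200 kb window by default,
  filter SNPs at MAF ≥ 5% in every population and STRs at heterozygosity
  ≥ 9.5% with ≥ 20 genotypes per population, and average at the pair level.
  The SNP–SNP baseline anchors at the closest qualifying SNP within 1 kb
  of the STR start (the STR is omitted otherwise).

## Design choices and numerical notes

- Coordinates are BED-style 0-based half-open internally; 1-based only in
  VCF. VCF alleles are perfect-repeat expansions of the motif to the called
  length, so bp semantics survive third-party tools; records with no
  alternative allele write ALT ".".
- Writers are deterministic: stable ordering, floats at 6 significant
  digits.
- Offset calibration ties break to the smallest absolute offset, then the
  smaller offset. Dosage regression is ordinary least squares (alternative
  penalties change slopes negligibly on this kind of data); RMSE is of the
  raw paired differences.
- Mendelian assessment takes called genotypes at face value — no dropout
  modeling — so rates below 100% at low coverage are expected behavior,
  not a defect; rates rise monotonically with the trio-minimum coverage
  threshold.
- The binary-vs-dosage LD encoding agreement (within 10%) holds for
  major-allele-dominated spectra under moderate stepwise mutation, the
  regime typical of common STR polymorphisms; for highly multiallelic
  spectra under strong mutation the binary encoding genuinely loses graded
  length information and its mean R² falls further below the dosage
  encoding. The suite tests the agreement in the former regime and the
  SNP–SNP > STR–SNP ordering in the latter, pooling replicate simulations
  for per-bin stability.
- Degenerate inputs: empty regions, regions shorter than the motif,
  all-identical test vectors, and populations with fewer than two alleles
  raise `ValueError` rather than returning sentinel values; undefined R²
  is NaN and is excluded from profile means.

## Problem sizes

Validation experiments run at: 10 Mb genome + 2 × 10 Mb nulls
(calibration), 220 loci × 300 samples (heterozygosity recovery), 5000 loci
× 2 trios (Mendelian trends), 190 loci × 120 samples (reference
deviation), and 10⁴ haplotypes × 400 SNPs × 3 replicates (LD ordering).
These sizes keep every statistic's sampling noise well inside the asserted
tolerances while completing in minutes on a single CPU.
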