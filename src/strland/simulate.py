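"""Synthetic STR data with the statistical structure of low-coverage
population sequencing.

Emulates, per locus: a unimodal, roughly symmetric stepwise allele spectrum
with one prevalent major allele; diploid Hardy-Weinberg genotypes across
optionally differentiated populations; Poisson read coverage (~5x by
default); per-read PCR stutter (geometric step magnitude, +/- one direction
with equal probability, in repeat units); length censoring by read length
(a read observes the locus only when the allele plus flanks fits in the
read); and a naive caller that reports the one or two best-supported read
lengths, which produces natural allelic dropout at low coverage. Also
generates trios with optional germline stepwise mutation and hemizygous
SNP-STR haplotypes whose LD decays with distance and with the STR mutation
rate.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .callstats import AlleleSpectrum, CallSet, StrCall
from .catalog import MarkovModel, StrLocus, default_markov_model, generate_null
from .motif import canonical_motif, is_primitive


# ---------------------------------------------------------------------------
# parameters


@dataclass
class SpectrumParams:
    """Stepwise allele-spectrum shape at one locus.

    Frequencies follow p(k) proportional to decay^|k| for signed repeat-unit
    offsets k from the major allele, |k| <= max_steps, so ``decay`` sets the
    locus' variability (decay -> 0 is monomorphic). ``asymmetry`` skews the
    two tails: the downward tail decays by decay*(1-asymmetry), the upward
    by decay*(1+asymmetry).
    """

    major_allele_bp: int
    period: int
    decay: float = 0.4
    max_steps: int = 8
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay < 1.0:
            raise ValueError("decay must be in [0, 1)")
        if self.period < 1 or self.major_allele_bp < self.period:
            raise ValueError("invalid period / major allele length")


@dataclass
class SeqParams:
    """Sequencing and calling parameters of the emulated pipeline.

    Defaults mirror low-coverage whole-genome sequencing with a 50/50 mix of
    76-bp and 100-bp reads, ~5x mean coverage, and an 8-bp minimum flank on
    each side of the repeat for a read to span it.
    """

    mean_coverage: float = 5.0
    read_lengths: dict[int, float] = field(default_factory=lambda: {76: 0.5, 100: 0.5})
    flank_bp: int = 8
    stutter_prob: float = 0.05
    stutter_geom: float = 0.7  # P(step size = s) ~ geometric; 0.7 => mostly +/-1 unit
    min_support: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.stutter_prob <= 1.0:
            raise ValueError("stutter_prob must be in [0, 1]")
        if any(rl <= 0 for rl in self.read_lengths):
            raise ValueError("read lengths must be positive")
        total = sum(self.read_lengths.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("read-length mixture weights must sum to 1")

    def censoring_bound(self, read_length: int) -> int:
        """Longest allele (bp) a read of the given length can span."""
        return read_length - 2 * self.flank_bp


# ---------------------------------------------------------------------------
# allele spectra


def simulate_spectrum(params: SpectrumParams, seed: int | None = None) -> AlleleSpectrum:
    """Build the stepwise spectrum implied by ``params``.

    Deterministic given the parameters; the seed is accepted for interface
    symmetry and reserved for future stochastic spectrum shapes.
    """
    down = params.decay * (1.0 - params.asymmetry)
    up = params.decay * (1.0 + params.asymmetry)
    freqs: dict[int, float] = {params.major_allele_bp: 1.0}
    for k in range(1, params.max_steps + 1):
        lo = params.major_allele_bp - k * params.period
        hi = params.major_allele_bp + k * params.period
        if lo >= params.period and down > 0:
            freqs[lo] = down**k
        if up > 0:
            freqs[hi] = up**k
    total = sum(freqs.values())
    return AlleleSpectrum(freqs={a: f / total for a, f in freqs.items()})


def differentiate_populations(
    base: AlleleSpectrum,
    n_pops: int,
    shift_units: int,
    mix: float,
    period: int,
    seed: int | None = None,
) -> list[AlleleSpectrum]:
    """Construct ``n_pops`` spectra with known differentiation.

    Population i's spectrum is (1-mix)*base + mix*(base shifted by
    i*shift_units repeat units), so the expected between-population variance
    in allele size - hence Rst - is computable from the construction.
    Mass shifted below one repeat unit is clipped and renormalized.
    """
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must be in [0, 1]")
    out = []
    for i in range(n_pops):
        shifted: dict[int, float] = {}
        clipped = False
        for a, f in base.freqs.items():
            na = a + i * shift_units * period
            if na < period:
                clipped = True
                continue
            shifted[na] = shifted.get(na, 0.0) + f
        if clipped:
            import warnings

            warnings.warn("shift pushed mass below one repeat unit; renormalized")
        tot = sum(shifted.values())
        shifted = {a: f / tot for a, f in shifted.items()}
        mixed: dict[int, float] = {}
        for a, f in base.freqs.items():
            mixed[a] = mixed.get(a, 0.0) + (1.0 - mix) * f
        for a, f in shifted.items():
            mixed[a] = mixed.get(a, 0.0) + mix * f
        tot = sum(mixed.values())
        out.append(
            AlleleSpectrum(freqs={a: f / tot for a, f in mixed.items() if f > 0})
        )
    return out


# ---------------------------------------------------------------------------
# populations of true genotypes


@dataclass
class TruePopulation:
    """True (noise-free) diploid genotypes for a set of samples and loci."""

    samples: list[str]
    pop_of: dict[str, str]
    loci: list[str]
    period: dict[str, int]
    ref_len: dict[str, int]
    spectra: dict[tuple[str, str], AlleleSpectrum]  # (pop, locus) -> spectrum
    genotypes: dict[tuple[str, str], tuple[int, int]]  # (sample, locus)

    def populations(self) -> list[str]:
        return sorted(set(self.pop_of.values()))


def _sample_names(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def simulate_population(
    locus_specs: list[tuple[str, SpectrumParams]],
    n_samples: int = 100,
    populations: tuple[str, ...] = ("POP1",),
    shift_units: int = 0,
    mix: float = 0.0,
    seed: int = 0,
) -> TruePopulation:
    """Draw HWE diploid genotypes for every sample at every locus.

    With more than one population, per-population spectra come from
    :func:`differentiate_populations`; samples split evenly across
    populations.
    """
    rng = np.random.default_rng(seed)
    samples = _sample_names(n_samples)
    pop_of = {s: populations[i % len(populations)] for i, s in enumerate(samples)}
    loci = [lid for lid, _ in locus_specs]
    period = {lid: sp.period for lid, sp in locus_specs}
    ref_len = {lid: sp.major_allele_bp for lid, sp in locus_specs}
    spectra: dict[tuple[str, str], AlleleSpectrum] = {}
    genotypes: dict[tuple[str, str], tuple[int, int]] = {}
    for lid, sp in locus_specs:
        base = simulate_spectrum(sp)
        if len(populations) > 1:
            per_pop = differentiate_populations(
                base, len(populations), shift_units, mix, sp.period
            )
        else:
            per_pop = [base]
        for pop, spec in zip(populations, per_pop):
            spectra[(pop, lid)] = spec
        for s in samples:
            spec = spectra[(pop_of[s], lid)]
            a, b = spec.sample(rng, 2)
            genotypes[(s, lid)] = (int(min(a, b)), int(max(a, b)))
    return TruePopulation(
        samples=samples,
        pop_of=pop_of,
        loci=loci,
        period=period,
        ref_len=ref_len,
        spectra=spectra,
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# read-level simulation and the naive caller


def _stutter_shift(rng: np.random.Generator, period: int, geom_p: float) -> int:
    """Signed stutter offset in bp: geometric magnitude, +/- equally likely."""
    size = rng.geometric(geom_p)
    sign = 1 if rng.random() < 0.5 else -1
    return sign * size * period


def _call_reads(
    lengths: list[int], min_support: int
) -> tuple[tuple[int, ...], tuple[int, ...]] | None:
    """Naive caller: the one or two most-supported read lengths.

    Ties break toward the shorter length. A second allele is reported only
    with support >= min_support; otherwise the call is homozygous for the
    top length.
    """
    if not lengths:
        return None
    counts = Counter(lengths)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    a1, s1 = ranked[0]
    if len(ranked) > 1 and ranked[1][1] >= min_support:
        a2, s2 = ranked[1]
        (a1, s1), (a2, s2) = sorted([(a1, s1), (a2, s2)])
        return (a1, a2), (s1, s2)
    return (a1, a1), (s1, s1)


def simulate_calls(
    pop: TruePopulation,
    seq: SeqParams | None = None,
    seed: int = 0,
    hemizygous: bool = False,
) -> CallSet:
    """Push true genotypes through the emulated sequencing pipeline.

    Per sample-locus: the read count is Poisson(mean_coverage); each read
    draws one of the true alleles uniformly and a read length from the
    mixture; it observes the locus only if the allele fits within
    read_length - 2*flank_bp; with stutter_prob its reported length shifts
    by a geometric number of repeat units in a random direction. The naive
    caller then reports the top one or two supported lengths. Sample-loci
    with zero observing reads yield no call.
    """
    seq = seq or SeqParams()
    rng = np.random.default_rng(seed)
    rls = sorted(seq.read_lengths)
    rl_probs = np.array([seq.read_lengths[r] for r in rls])
    calls: list[StrCall] = []
    for lid in pop.loci:
        p = pop.period[lid]
        for s in pop.samples:
            g = pop.genotypes[(s, lid)]
            alleles = (g[0],) if hemizygous else g
            n_reads = rng.poisson(seq.mean_coverage)
            observed: list[int] = []
            for _ in range(n_reads):
                allele = alleles[int(rng.integers(len(alleles)))]
                rl = rls[int(rng.choice(len(rls), p=rl_probs))]
                if allele > seq.censoring_bound(rl):
                    continue
                length = allele
                if seq.stutter_prob > 0 and rng.random() < seq.stutter_prob:
                    length = max(p, length + _stutter_shift(rng, p, seq.stutter_geom))
                observed.append(length)
            called = _call_reads(observed, seq.min_support)
            if called is None:
                continue
            geno, supports = called
            if hemizygous:
                geno, supports = geno[:1], supports[:1]
            calls.append(
                StrCall(
                    sample=s,
                    locus=lid,
                    alleles=geno,
                    coverage=len(observed),
                    supports=supports,
                )
            )
    return CallSet(calls=calls)


# ---------------------------------------------------------------------------
# trios


def simulate_trio(
    mother: tuple[int, int],
    father: tuple[int, int],
    period: int,
    mutation_prob: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[int, int]:
    """Transmit one uniformly chosen allele from each parent to the child.

    With probability ``mutation_prob`` an inherited allele takes a stepwise
    mutation of +/- one repeat unit.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    m = mother[int(rng.integers(2))]
    f = father[int(rng.integers(2))]
    if mutation_prob > 0:
        if rng.random() < mutation_prob:
            m = max(period, m + period * (1 if rng.random() < 0.5 else -1))
        if rng.random() < mutation_prob:
            f = max(period, f + period * (1 if rng.random() < 0.5 else -1))
    return (min(m, f), max(m, f))


def simulate_trio_callset(
    locus_specs: list[tuple[str, SpectrumParams]],
    n_trios: int = 1,
    seq: SeqParams | None = None,
    mutation_prob: float = 0.0,
    seed: int = 0,
) -> tuple[CallSet, TruePopulation]:
    """Simulate trios end-to-end: parental HWE genotypes, transmission, and
    noisy calls for all three members.

    Sample ids are ``T{i}_child`` / ``T{i}_mother`` / ``T{i}_father``.
    Returns the callset and the underlying truth (children included).
    """
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    genotypes: dict[tuple[str, str], tuple[int, int]] = {}
    spectra: dict[tuple[str, str], AlleleSpectrum] = {}
    loci = [lid for lid, _ in locus_specs]
    for t in range(n_trios):
        for role in ("child", "mother", "father"):
            name = f"T{t}_{role}"
            samples.append(name)
            pop_of[name] = "POP1"
    for lid, sp in locus_specs:
        spec = simulate_spectrum(sp)
        spectra[("POP1", lid)] = spec
        for t in range(n_trios):
            mo = tuple(int(x) for x in spec.sample(rng, 2))
            fa = tuple(int(x) for x in spec.sample(rng, 2))
            ch = simulate_trio(mo, fa, sp.period, mutation_prob, rng=rng)
            genotypes[(f"T{t}_mother", lid)] = (min(mo), max(mo))
            genotypes[(f"T{t}_father", lid)] = (min(fa), max(fa))
            genotypes[(f"T{t}_child", lid)] = ch
    truth = TruePopulation(
        samples=samples,
        pop_of=pop_of,
        loci=loci,
        period={lid: sp.period for lid, sp in locus_specs},
        ref_len={lid: sp.major_allele_bp for lid, sp in locus_specs},
        spectra=spectra,
        genotypes=genotypes,
    )
    callset = simulate_calls(truth, seq=seq, seed=seed + 1)
    return callset, truth


# ---------------------------------------------------------------------------
# hemizygous SNP-STR haplotypes


@dataclass
class HaplotypeMatrix:
    """Phased hemizygous haplotypes: 0/1 SNP alleles plus STR bp lengths."""

    samples: list[str]
    snp_positions: np.ndarray  # (n_snp,) strictly increasing bp
    snp_alleles: np.ndarray  # (n_hap, n_snp) int8
    str_positions: np.ndarray  # (n_str,) bp
    str_bp: np.ndarray  # (n_hap, n_str) allele length in bp
    populations: list[str]  # per haplotype

    def __post_init__(self) -> None:
        if np.any(np.diff(self.snp_positions) <= 0):
            raise ValueError("SNP positions must be strictly increasing")


def simulate_snp_str_haplotypes(
    n_hap: int,
    str_spectrum: AlleleSpectrum,
    snp_positions: list[int],
    str_mut_prob: float = 0.0,
    recomb_decay: float = 0.0,
    seed: int = 0,
    n_founders: int = 20,
    period: int | None = None,
    str_position: int = 0,
    population: str = "POP1",
) -> HaplotypeMatrix:
    """Generate hemizygous haplotypes with distance-decaying SNP-STR LD.

    ``n_founders`` founder haplotypes get SNP alleles (Bernoulli with
    per-SNP frequency drawn uniform in [0.2, 0.8]) and an STR allele from
    ``str_spectrum``. Each output haplotype copies a random founder,
    switching to a fresh random founder between adjacent sites with
    probability 1 - exp(-recomb_decay * distance); the copied STR allele
    additionally takes a stepwise mutation (+/- one repeat unit, then
    geometric extras) with probability ``str_mut_prob``. LD with the STR
    therefore decays both with distance (recombination) and with the STR
    mutation rate - SNPs keep their founder associations while the STR
    drifts away from its.
    """
    if n_hap < 2:
        raise ValueError("need at least two haplotypes")
    rng = np.random.default_rng(seed)
    positions = np.asarray(sorted(snp_positions), dtype=np.int64)
    n_snp = positions.size
    if period is None:
        alleles = sorted(str_spectrum.freqs)
        period = int(np.gcd.reduce(np.diff(alleles))) if len(alleles) > 1 else 1
    snp_freqs = rng.uniform(0.2, 0.8, size=n_snp)
    founder_snps = (rng.random((n_founders, n_snp)) < snp_freqs).astype(np.int8)
    founder_strs = str_spectrum.sample(rng, n_founders).astype(np.int64)

    sites = np.concatenate([[str_position], positions])
    order = np.argsort(sites, kind="stable")
    gaps = np.diff(sites[order])
    p_switch = 1.0 - np.exp(-recomb_decay * gaps)

    snp_out = np.empty((n_hap, n_snp), dtype=np.int8)
    str_out = np.empty(n_hap, dtype=np.int64)
    for h in range(n_hap):
        f = int(rng.integers(n_founders))
        switch = rng.random(gaps.size) < p_switch
        site_vals = np.empty(sites.size, dtype=np.int64)
        for k in range(sites.size):
            if k > 0 and switch[k - 1]:
                f = int(rng.integers(n_founders))
            site_idx = order[k]
            if site_idx == 0:
                allele = int(founder_strs[f])
                if str_mut_prob > 0 and rng.random() < str_mut_prob:
                    allele = max(period, allele + _stutter_shift(rng, period, 0.7))
                site_vals[site_idx] = allele
            else:
                site_vals[site_idx] = founder_snps[f, site_idx - 1]
        str_out[h] = site_vals[0]
        snp_out[h] = site_vals[1:]
    return HaplotypeMatrix(
        samples=[f"H{i:05d}" for i in range(n_hap)],
        snp_positions=positions,
        snp_alleles=snp_out,
        str_positions=np.array([str_position], dtype=np.int64),
        str_bp=str_out.reshape(-1, 1),
        populations=[population] * n_hap,
    )


# ---------------------------------------------------------------------------
# synthetic genomes for catalog calibration


#: approximate share of catalog loci by motif period (di/tetra dominate).
PERIOD_WEIGHTS = {2: 0.40, 3: 0.14, 4: 0.33, 5: 0.08, 6: 0.05}


def _random_primitive_motif(rng: np.random.Generator, period: int) -> str:
    while True:
        m = "".join("ACGT"[int(c)] for c in rng.integers(0, 4, size=period))
        if is_primitive(m) and len(set(m)) > 1:
            return m


def simulate_genome(
    length: int = 10_000_000,
    str_per_mb: float = 230.0,
    seed: int = 0,
    model: MarkovModel | None = None,
    impure_fraction: float = 0.3,
    mean_tract_bp: float = 20.0,
    min_tract_bp: int = 14,
    max_tract_bp: int = 120,
) -> tuple[str, list[StrLocus]]:
    """A Markov-chain background with STR tracts embedded at known positions.

    Defaults give a genome-like STR density (~230 loci/Mb of period 2-6,
    matching ~700k loci per 3 Gb) with tract lengths of
    min + Exp(mean) bp capped at ``max_tract_bp`` (mean ~31 bp, the
    genome-wide average reference allele length). A fraction of tracts get
    1-3 random substitutions to emulate interrupted repeats. Returns the
    sequence and the embedded truth as loci (score 0; detection assigns
    real scores).
    """
    rng = np.random.default_rng(seed)
    model = model or default_markov_model()
    background = generate_null(model, length, seed=int(rng.integers(2**31)))
    n_str = int(str_per_mb * length / 1e6)
    periods = np.array(sorted(PERIOD_WEIGHTS))
    weights = np.array([PERIOD_WEIGHTS[p] for p in periods], dtype=float)
    weights /= weights.sum()
    # place tracts on a jittered grid to avoid overlap bookkeeping
    slot = length // n_str
    seq = list(background)
    truth: list[StrLocus] = []
    for i in range(n_str):
        p = int(rng.choice(periods, p=weights))
        motif = _random_primitive_motif(rng, p)
        tract = min(max_tract_bp, int(min_tract_bp + rng.exponential(mean_tract_bp)))
        tract = max(tract, 2 * p + p)  # at least ~3 copies
        copies = -(-tract // p)  # ceil
        repeat = (motif * copies)[:tract]
        if rng.random() < impure_fraction and tract > 2 * p + 2:
            n_subs = min(3, max(1, tract // 25))
            for _ in range(n_subs):
                pos = int(rng.integers(p, tract - p))
                repeat = repeat[:pos] + "ACGT"[int(rng.integers(4))] + repeat[pos + 1 :]
        start = i * slot + int(rng.integers(0, max(1, slot - tract - 50)))
        if start + tract > length:
            continue
        seq[start : start + tract] = repeat
        truth.append(
            StrLocus(
                chrom="synth",
                start=start,
                end=start + tract,
                motif=canonical_motif(motif),
                score=0,
                purity=1.0,
            )
        )
    return "".join(seq), truth
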