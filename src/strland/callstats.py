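"""Per-locus and per-callset summary statistics for STR genotype calls.

The unit of most statistics is the allele spectrum: the frequency
distribution of allele lengths (in bp) at one locus, aggregated over every
called allele observation (two per diploid call, one per hemizygous call).
Heterozygosity H = 1 - sum(p_i^2) is computed from the spectrum and is
robust to random allele-symmetric dropout, which is why it remains a
reliable summary at ~5x coverage where individual genotypes are not.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .catalog import StrLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrCall:
    """One sample's genotype at one locus.

    ``alleles`` holds 1 (hemizygous) or 2 (diploid) allele lengths in bp.
    ``coverage`` counts the reads spanning the locus; ``supports`` the reads
    backing each reported allele. Coverage may exceed the summed supports
    (the remainder being stutter or otherwise uncalled reads).
    """

    sample: str
    locus: str
    alleles: tuple[int, ...]
    coverage: int
    supports: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2):
            raise ValueError("a call carries 1 or 2 alleles")
        if any(a <= 0 for a in self.alleles):
            raise ValueError("allele lengths must be positive")

    @property
    def is_hemizygous(self) -> bool:
        return len(self.alleles) == 1

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and self.alleles[0] != self.alleles[1]


@dataclass
class AlleleSpectrum:
    """Allele-length frequency distribution at one locus."""

    freqs: dict[int, float]
    locus: str = ""
    n_obs: int = 0

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError("negative frequency")

    def major_allele(self) -> int:
        """Most frequent allele; ties break toward the shorter allele."""
        return min(self.freqs, key=lambda a: (-self.freqs[a], a))

    def maf(self) -> float:
        """Minor allele frequency of a multiallelic locus: 1 minus the
        major-allele frequency."""
        return 1.0 - self.freqs[self.major_allele()]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        alleles = np.array(sorted(self.freqs))
        probs = np.array([self.freqs[a] for a in alleles])
        probs = probs / probs.sum()
        return rng.choice(alleles, size=size, p=probs)


def spectrum_from_calls(calls: list[StrCall]) -> AlleleSpectrum:
    """Aggregate called allele observations at one locus into a spectrum."""
    if not calls:
        raise ValueError("no calls at locus")
    counts: Counter[int] = Counter()
    for c in calls:
        counts.update(c.alleles)
    n = sum(counts.values())
    return AlleleSpectrum(
        freqs={a: k / n for a, k in counts.items()},
        locus=calls[0].locus,
        n_obs=n,
    )


def heterozygosity(s: AlleleSpectrum) -> float:
    """H = 1 - sum(p_i^2): probability two random alleles differ."""
    return 1.0 - sum(p * p for p in s.freqs.values())


def dosage(call: StrCall, ref_len_bp: int) -> int:
    """Sum over the call's alleles of the bp difference from the reference.

    A 16 bp/18 bp genotype against a 14 bp reference has dosage 2 + 4 = 6;
    for a hemizygous call the dosage is the single difference.
    """
    return sum(a - ref_len_bp for a in call.alleles)


def normalize_spectrum(s: AlleleSpectrum, period: int) -> AlleleSpectrum:
    """Re-key a spectrum as repeat-unit offsets from the major allele.

    Keys become round((allele - major) / period); the major allele maps
    to offset 0 and mass is re-aggregated exactly. Rounding tolerates
    impure loci whose alleles are not exact multiples of the period apart.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    major = s.major_allele()
    out: dict[int, float] = {}
    for allele, f in s.freqs.items():
        k = round((allele - major) / period)
        out[k] = out.get(k, 0.0) + f
    return AlleleSpectrum(freqs=out, locus=s.locus, n_obs=s.n_obs)


def classify_common_polymorphism(s: AlleleSpectrum) -> tuple[bool, int]:
    """A locus is commonly polymorphic iff >= 2 alleles have frequency
    strictly above 5%. Returns (is_common, count of such alleles)."""
    n = sum(1 for f in s.freqs.values() if f > 0.05)
    return n >= 2, n


def dosage_variance(s: AlleleSpectrum, period: int) -> float:
    """Variance of the diploid dosage in repeat units under HWE.

    Equals 2 * Var of the per-allele repeat-unit offset from the major
    allele; the biallelic SNP analogue 2p(1-p) peaks at 0.5.
    """
    norm = normalize_spectrum(s, period)
    ks = np.array(sorted(norm.freqs))
    ps = np.array([norm.freqs[k] for k in ks])
    mean = float(ks @ ps)
    var = float(((ks - mean) ** 2) @ ps)
    return 2.0 * var


def snp_max_dosage_variance() -> float:
    """Theoretical maximum diploid dosage variance of a biallelic SNP under
    HWE, found by maximizing 2p(1-p) over allele frequency p."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda p: -2.0 * p * (1.0 - p), bounds=(0.0, 1.0), method="bounded")
    return float(-res.fun)


# ---------------------------------------------------------------------------
# callset container


@dataclass
class CallSet:
    """A collection of calls with sample/locus rosters."""

    calls: list[StrCall] = field(default_factory=list)

    def samples(self) -> list[str]:
        return sorted({c.sample for c in self.calls})

    def loci(self) -> list[str]:
        return sorted({c.locus for c in self.calls})

    def by_locus(self) -> dict[str, list[StrCall]]:
        out: dict[str, list[StrCall]] = {}
        for c in self.calls:
            out.setdefault(c.locus, []).append(c)
        return out

    def spectra(self) -> dict[str, AlleleSpectrum]:
        return {loc: spectrum_from_calls(cs) for loc, cs in self.by_locus().items()}

    def __len__(self) -> int:
        return len(self.calls)


DEFAULT_SUBSET_SIZES = (1, 5, 10, 25, 50, 100, 250, 500, 750, 1000)


def saturation_curve(
    callset: CallSet,
    subset_sizes: list[int] = list(DEFAULT_SUBSET_SIZES),
    reps: int = 10,
    maf_filter: float | None = None,
    seed: int = 0,
) -> dict[int, float]:
    """Median number of called loci in nested random sample subsets.

    Each repetition grows one nested chain of subsets (1 sample, then 4
    more, and so on), counting loci with >= 1 call in the subset. With
    ``maf_filter`` set, only loci whose MAF on the FULL callset exceeds the
    filter are counted (membership still checked per subset). Medians are
    taken across repetitions; nesting forces each rep's curve to be
    monotone non-decreasing.
    """
    rng = np.random.default_rng(seed)
    samples = callset.samples()
    sizes = []
    for s in subset_sizes:
        if s > len(samples):
            logger.warning("subset size %d exceeds %d samples; truncated", s, len(samples))
            s = len(samples)
        sizes.append(s)
    eligible: set[str] | None = None
    if maf_filter is not None:
        eligible = {
            loc for loc, spec in callset.spectra().items() if spec.maf() > maf_filter
        }
    loci_of_sample: dict[str, set[str]] = {s: set() for s in samples}
    for c in callset.calls:
        if eligible is None or c.locus in eligible:
            loci_of_sample[c.sample].add(c.locus)
    counts = np.zeros((reps, len(sizes)))
    for r in range(reps):
        order = rng.permutation(samples)
        seen: set[str] = set()
        taken = 0
        for j, s in enumerate(sizes):
            for samp in order[taken:s]:
                seen |= loci_of_sample[samp]
            taken = max(taken, s)
            counts[r, j] = len(seen)
    medians = np.median(counts, axis=0)
    return {s: float(m) for s, m in zip(subset_sizes, medians)}


def classify_lof_alleles(
    locus: StrLocus,
    calls: list[StrCall],
    min_reads: int = 2,
    min_fraction: float = 0.3,
    min_carriers: int = 10,
) -> list[tuple[int, int]]:
    """Frameshift (loss-of-function candidate) alleles at a coding locus.

    An allele qualifies iff its bp difference from the reference is not a
    multiple of 3, every counted carrier genotype supports it with at least
    ``min_reads`` reads making up at least ``min_fraction`` of that
    genotype's reads, and the qualifying carriers number >= ``min_carriers``.
    Returns (allele_bp, n_carriers) pairs.
    """
    if not locus.coding:
        raise ValueError("LoF classification applies to coding loci only")
    carriers: dict[int, int] = {}
    for c in calls:
        for allele, support in zip(c.alleles, c.supports or (0,) * len(c.alleles)):
            if (allele - locus.ref_len_bp) % 3 == 0:
                continue
            if support < min_reads:
                continue
            if c.coverage <= 0 or support / c.coverage < min_fraction:
                continue
            carriers[allele] = carriers.get(allele, 0) + 1
    return sorted((a, n) for a, n in carriers.items() if n >= min_carriers)


def per_locus_stats(callset: CallSet, catalog: dict[str, StrLocus] | None = None):
    """Per-locus summary table: n_samples, het, maf, n_common_alleles,
    dosage_variance (repeat units, when the period is known)."""
    import pandas as pd

    rows = []
    for loc, calls in callset.by_locus().items():
        spec = spectrum_from_calls(calls)
        is_common, n_common = classify_common_polymorphism(spec)
        period = None
        if catalog and loc in catalog:
            period = catalog[loc].period
        rows.append(
            {
                "locus": loc,
                "n_samples": len({c.sample for c in calls}),
                "het": heterozygosity(spec),
                "maf": spec.maf(),
                "n_common_alleles": n_common,
                "is_common": is_common,
                "dosage_variance": dosage_variance(spec, period) if period else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("locus").reset_index(drop=True)
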