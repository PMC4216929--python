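"""Population-genetic statistics for STR call sets.

Rst is the microsatellite analogue of Fst: it partitions variance in allele
size (repeat units) rather than allele identity, which is the appropriate
differentiation measure under stepwise mutation. The estimator here is the
pairwise-difference form: with S_W the mean squared size difference between
two distinct alleles drawn within the same population (pooled over
populations, each contributing its number of within-population pairs) and
S-bar the mean squared difference between two distinct alleles in the
pooled sample, Rst = (S-bar - S_W) / S-bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, mannwhitneyu

logger = logging.getLogger(__name__)


@dataclass
class PopulationAlleles:
    """All called allele observations (in repeat units) for one population."""

    label: str
    sizes: list[float]


def _ssd_and_pairs(x: np.ndarray) -> tuple[float, int]:
    """Sum of squared differences over distinct pairs, and the pair count.

    Uses sum_{i<j}(x_i-x_j)^2 = n*sum(x^2) - (sum x)^2.
    """
    n = x.size
    return float(n * np.sum(x**2) - np.sum(x) ** 2), n * (n - 1) // 2


def rst(pops: list[PopulationAlleles]) -> float:
    """Pairwise-difference Rst across two or more populations.

    Within-population pairs pool across populations (weight proportional to
    n_k(n_k-1)/2). Returns 0 when the pooled sample is monomorphic.
    """
    if len(pops) < 2:
        raise ValueError("Rst needs at least two populations")
    sw_num = 0.0
    sw_pairs = 0
    pooled: list[float] = []
    for p in pops:
        x = np.asarray(p.sizes, dtype=float)
        if x.size < 2:
            raise ValueError(f"population {p.label!r} has fewer than 2 alleles")
        ssd, pairs = _ssd_and_pairs(x)
        sw_num += ssd
        sw_pairs += pairs
        pooled.extend(p.sizes)
    s_w = sw_num / sw_pairs
    ssd_all, pairs_all = _ssd_and_pairs(np.asarray(pooled, dtype=float))
    s_bar = ssd_all / pairs_all
    if s_bar == 0.0:
        return 0.0
    return (s_bar - s_w) / s_bar


def rst_from_spectra(spectra: list[dict[float, float]]) -> float:
    """Analytic Rst for populations given as allele-size distributions
    (equal population weights, infinite sample limit).

    The expected squared difference between two independent draws from a
    distribution is 2*Var; between draws from two different populations it
    is Var_a + Var_b + (mean_a - mean_b)^2.
    """
    means = []
    variances = []
    for spec in spectra:
        sizes = np.array(sorted(spec))
        probs = np.array([spec[s] for s in sizes], dtype=float)
        probs = probs / probs.sum()
        m = float(sizes @ probs)
        means.append(m)
        variances.append(float(((sizes - m) ** 2) @ probs))
    k = len(spectra)
    s_w = float(np.mean([2 * v for v in variances]))
    cross = []
    for i in range(k):
        for j in range(k):
            cross.append(variances[i] + variances[j] + (means[i] - means[j]) ** 2)
    s_bar = float(np.mean(cross))
    if s_bar == 0:
        return 0.0
    return (s_bar - s_w) / s_bar


def heterozygosity_sign_test(
    het_a: list[float], het_b: list[float]
) -> tuple[int, int, float]:
    """Paired sign test for systematically higher heterozygosity in one
    population.

    Ties are dropped; the two-sided p-value is binomial with p = 0.5 on the
    remaining loci. Returns (n where A > B, n where B > A, p).
    """
    if len(het_a) != len(het_b):
        raise ValueError("paired lists must have equal length")
    n_a = sum(1 for a, b in zip(het_a, het_b) if a > b)
    n_b = sum(1 for a, b in zip(het_a, het_b) if b > a)
    n = n_a + n_b
    if n == 0:
        raise ValueError("all paired heterozygosities are tied")
    p = binomtest(n_a, n, 0.5, alternative="two-sided").pvalue
    return n_a, n_b, float(p)


def coding_noncoding_test(het_coding: list[float], het_noncoding: list[float]) -> float:
    """Two-sided Mann-Whitney U test for a coding vs noncoding
    heterozygosity difference."""
    if not het_coding or not het_noncoding:
        raise ValueError("both lists must be non-empty")
    if len(set(het_coding) | set(het_noncoding)) == 1:
        raise ValueError("degenerate input: all values identical")
    return float(mannwhitneyu(het_coding, het_noncoding, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# stratified variability trends


def purity_class(purity: float, pure_threshold: float = 1.0) -> str:
    """Coarse purity stratum: 'pure' at the threshold and above."""
    return "pure" if purity >= pure_threshold else "impure"


def variability_by_stratum(
    loci_stats: pd.DataFrame,
    min_samples: int = 100,
    strata: tuple[str, ...] = ("period", "major_len", "purity_class", "coding"),
) -> pd.DataFrame:
    """Heterozygosity summaries per stratum of motif length x major-allele
    length x purity class x coding flag.

    Expects columns ``het``, ``n_samples`` and the stratum columns; analysis
    restricts to loci with >= ``min_samples`` calls. Empty strata are
    omitted (pandas drops empty groups); rows partition the filtered loci.
    """
    needed = {"het", "n_samples", *strata}
    missing = needed - set(loci_stats.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = loci_stats[loci_stats["n_samples"] >= min_samples]
    if df.empty:
        logger.warning("no loci pass the min_samples filter")
    g = df.groupby(list(strata), observed=True)["het"]
    out = g.agg(
        mean="mean",
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
        n="count",
    ).reset_index()
    return out


def het_vs_length_profile(
    loci_stats: pd.DataFrame, window_bp: int = 2, min_samples: int = 100
) -> pd.DataFrame:
    """Smoothed heterozygosity-versus-major-allele-length profile.

    For each observed major-allele length, the value is the mean
    heterozygosity of loci whose major allele is within ``window_bp`` bp.
    """
    df = loci_stats[loci_stats["n_samples"] >= min_samples]
    lengths = np.sort(df["major_len"].unique())
    rows = []
    for L in lengths:
        sel = df[(df["major_len"] - L).abs() <= window_bp]
        rows.append({"major_len": int(L), "het": float(sel["het"].mean()), "n": len(sel)})
    return pd.DataFrame(rows)
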