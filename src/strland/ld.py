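"""STR-SNP linkage disequilibrium on phased hemizygous haplotypes.

LD is measured as the squared Pearson correlation between a SNP's 0/1
indicator and an STR encoding — either the bp difference from a reference
length (the multiallelic "dosage" encoding) or a per-population binary
encoding (major allele vs everything else). A SNP-SNP baseline anchored at
a seed SNP near each STR puts the STR profile in context: stepwise back
mutation erodes STR-SNP associations, so mean STR-SNP R^2 sits below
SNP-SNP R^2 at matched distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import HaplotypeMatrix


def str_snp_r2(snp: np.ndarray, str_dosage: np.ndarray) -> float:
    """Squared Pearson correlation between a 0/1 SNP vector and an STR
    dosage vector.

    Missing entries (NaN) are dropped pairwise; with fewer than 3 complete
    pairs or zero variance in either vector the value is undefined (NaN).
    Symmetric in its arguments and invariant to affine rescaling.
    """
    x = np.asarray(snp, dtype=float)
    y = np.asarray(str_dosage, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def binarize_str(alleles: np.ndarray, populations: list[str] | None = None) -> np.ndarray:
    """Map STR alleles to 0 (population's modal allele) / 1 (anything else).

    The mapping is applied within each population individually; modal-allele
    ties break toward the shorter allele.
    """
    alleles = np.asarray(alleles)
    if alleles.size == 0:
        raise ValueError("empty allele vector")
    pops = np.asarray(populations if populations is not None else ["_"] * alleles.size)
    out = np.zeros(alleles.size, dtype=np.int8)
    for pop in np.unique(pops):
        mask = pops == pop
        vals, counts = np.unique(alleles[mask], return_counts=True)
        mode = vals[counts == counts.max()].min()  # tie -> shorter allele
        out[mask] = (alleles[mask] != mode).astype(np.int8)
    return out


def _snp_maf(col: np.ndarray) -> float:
    f = float(np.mean(col))
    return min(f, 1.0 - f)


def _het(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - np.sum(p * p))


def ld_profile(
    h: HaplotypeMatrix,
    window_bp: int = 200_000,
    snp_maf_min: float = 0.05,
    str_het_min: float = 0.095,
    min_genotypes: int = 20,
    n_bins: int = 20,
    seed_snp_max_distance: int = 1_000,
    str_ref_len: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Distance-binned mean R^2 per population and encoding.

    For each qualifying STR (heterozygosity >= ``str_het_min`` and >=
    ``min_genotypes`` haplotypes in every population), R^2 is computed
    against every SNP within ``window_bp`` of the STR start whose MAF
    exceeds ``snp_maf_min`` in every population, under both the dosage and
    the binary STR encoding. The SNP-SNP baseline anchors at the closest
    qualifying SNP to the STR start; if none lies within
    ``seed_snp_max_distance`` the STR is omitted from the analysis.
    Distances pool into ``n_bins`` equal bins over [0, window_bp]; rows are
    (population, encoding, distance_bin, mean_r2, n_pairs) with encoding in
    {"dosage", "binary", "snp"}.
    """
    pops = np.asarray(h.populations)
    pop_names = sorted(np.unique(pops))
    bin_width = window_bp / n_bins
    records: list[tuple[str, str, int, float]] = []

    # per-population SNP MAF filter (must pass in every population)
    snp_ok = np.ones(h.snp_positions.size, dtype=bool)
    for pop in pop_names:
        mask = pops == pop
        if mask.sum() < min_genotypes:
            raise ValueError(f"population {pop} has fewer than {min_genotypes} haplotypes")
        mafs = np.array([_snp_maf(h.snp_alleles[mask, j]) for j in range(h.snp_positions.size)])
        snp_ok &= mafs >= snp_maf_min

    for k, str_pos in enumerate(np.asarray(h.str_positions)):
        alleles = h.str_bp[:, k]
        if any(_het(alleles[pops == pop]) < str_het_min for pop in pop_names):
            continue
        ref = (str_ref_len or {}).get(int(str_pos))
        if ref is None:
            vals, counts = np.unique(alleles, return_counts=True)
            ref = int(vals[counts == counts.max()].min())
        in_window = snp_ok & (np.abs(h.snp_positions - str_pos) <= window_bp)
        snp_idx = np.flatnonzero(in_window)
        if snp_idx.size == 0:
            continue
        dosage_enc = (alleles - ref).astype(float)
        binary_enc = binarize_str(alleles, list(pops)).astype(float)
        for pop in pop_names:
            mask = pops == pop
            for j in snp_idx:
                d = abs(int(h.snp_positions[j]) - int(str_pos))
                b = min(int(d // bin_width), n_bins - 1)
                snp_col = h.snp_alleles[mask, j].astype(float)
                records.append((pop, "dosage", b, str_snp_r2(snp_col, dosage_enc[mask])))
                records.append((pop, "binary", b, str_snp_r2(snp_col, binary_enc[mask])))
        # SNP-SNP baseline seeded at the closest qualifying SNP to the STR
        dist_to_str = np.abs(h.snp_positions - str_pos).astype(float)
        dist_to_str[~snp_ok] = np.inf
        seed = int(np.argmin(dist_to_str))
        if dist_to_str[seed] > seed_snp_max_distance:
            continue  # STR omitted from the baseline comparison
        seed_window = snp_ok & (np.abs(h.snp_positions - h.snp_positions[seed]) <= window_bp)
        for pop in pop_names:
            mask = pops == pop
            seed_col = h.snp_alleles[mask, seed].astype(float)
            for j in np.flatnonzero(seed_window):
                if j == seed:
                    continue
                d = abs(int(h.snp_positions[j]) - int(h.snp_positions[seed]))
                b = min(int(d // bin_width), n_bins - 1)
                snp_col = h.snp_alleles[mask, j].astype(float)
                records.append((pop, "snp", b, str_snp_r2(seed_col, snp_col)))

    df = pd.DataFrame(records, columns=["population", "encoding", "distance_bin", "r2"])
    df = df.dropna(subset=["r2"])
    if df.empty:
        return pd.DataFrame(
            columns=["population", "encoding", "distance_bin", "mean_r2", "n_pairs"]
        )
    out = (
        df.groupby(["population", "encoding", "distance_bin"], observed=True)["r2"]
        .agg(mean_r2="mean", n_pairs="count")
        .reset_index()
    )
    return out
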