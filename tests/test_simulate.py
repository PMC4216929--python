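import numpy as np
import pytest

from strland import (
    SeqParams,
    SpectrumParams,
    differentiate_populations,
    heterozygosity,
    rst_from_spectra,
    simulate_calls,
    simulate_genome,
    simulate_population,
    simulate_snp_str_haplotypes,
    simulate_spectrum,
    simulate_trio,
    spectrum_from_calls,
)
from strland.ld import str_snp_r2


# ---------------------------------------------------------------------------
# spectra


def test_spectrum_point_mass_at_zero_decay():
    s = simulate_spectrum(SpectrumParams(major_allele_bp=20, period=2, decay=0.0))
    assert s.freqs == {20: 1.0}
    assert heterozygosity(s) == 0.0


def test_spectrum_one_step():
    s = simulate_spectrum(SpectrumParams(major_allele_bp=20, period=2, decay=0.5, max_steps=1))
    assert s.freqs == pytest.approx({18: 0.25, 20: 0.5, 22: 0.25})


def test_spectrum_two_steps():
    s = simulate_spectrum(SpectrumParams(major_allele_bp=20, period=2, decay=0.5, max_steps=2))
    expected = {16: 1 / 10, 18: 2 / 10, 20: 4 / 10, 22: 2 / 10, 24: 1 / 10}
    assert s.freqs == pytest.approx(expected)


def test_spectrum_unimodal_and_normalized():
    s = simulate_spectrum(SpectrumParams(major_allele_bp=40, period=4, decay=0.6))
    assert sum(s.freqs.values()) == pytest.approx(1.0)
    assert s.major_allele() == 40
    alleles = sorted(s.freqs)
    freqs = [s.freqs[a] for a in alleles]
    peak = alleles.index(40)
    assert all(freqs[i] <= freqs[i + 1] for i in range(peak))
    assert all(freqs[i] >= freqs[i + 1] for i in range(peak, len(freqs) - 1))


def test_spectrum_rejects_bad_decay():
    with pytest.raises(ValueError):
        SpectrumParams(major_allele_bp=20, period=2, decay=1.0)


def test_differentiate_identical_when_mix_zero():
    base = simulate_spectrum(SpectrumParams(major_allele_bp=20, period=2, decay=0.5))
    specs = differentiate_populations(base, 3, shift_units=2, mix=0.0, period=2)
    for s in specs:
        assert s.freqs == pytest.approx(base.freqs)
    assert rst_from_spectra([s.freqs for s in specs]) == pytest.approx(0.0)


def test_differentiate_full_shift_near_fixation():
    base = simulate_spectrum(SpectrumParams(major_allele_bp=20, period=2, decay=0.3, max_steps=2))
    specs = differentiate_populations(base, 2, shift_units=20, mix=1.0, period=2)
    assert rst_from_spectra([s.freqs for s in specs]) > 0.98


# ---------------------------------------------------------------------------
# genotypes and calls


def test_spectrum_recovered_from_noise_free_draws():
    """1e5 diploid draws reproduce the generating spectrum within 1% TV."""
    spec = [("L0", SpectrumParams(major_allele_bp=30, period=2, decay=0.5, max_steps=4))]
    pop = simulate_population(spec, n_samples=50_000, seed=3)
    calls = simulate_calls(
        pop, SeqParams(mean_coverage=30, stutter_prob=0.0), seed=4
    )
    est = spectrum_from_calls(calls.by_locus()["L0"])
    truth = pop.spectra[("POP1", "L0")]
    tv = 0.5 * sum(
        abs(est.freqs.get(a, 0.0) - truth.freqs.get(a, 0.0))
        for a in set(est.freqs) | set(truth.freqs)
    )
    assert tv < 0.01


def test_noise_free_calls_match_truth():
    spec = [("L0", SpectrumParams(major_allele_bp=24, period=2, decay=0.5))]
    pop = simulate_population(spec, n_samples=200, seed=5)
    calls = simulate_calls(pop, SeqParams(mean_coverage=1000, stutter_prob=0.0), seed=6)
    assert len(calls) == 200
    for c in calls.calls:
        assert c.alleles == pop.genotypes[(c.sample, "L0")]


def test_long_allele_never_observed():
    """An allele longer than read_length - 2*flank is censored."""
    params = SeqParams(mean_coverage=100, stutter_prob=0.0)
    assert params.censoring_bound(100) == 84
    spec = [("L0", SpectrumParams(major_allele_bp=120, period=4, decay=0.0))]
    pop = simulate_population(spec, n_samples=50, seed=7)
    calls = simulate_calls(pop, params, seed=8)
    assert len(calls) == 0  # 120 bp > 100 - 16: no read spans the locus


def test_het_accuracy_increases_with_coverage_threshold():
    """Allelic dropout fades as more reads span the locus."""
    spec = [
        (f"L{i}", SpectrumParams(major_allele_bp=30, period=2, decay=0.6, max_steps=4))
        for i in range(40)
    ]
    pop = simulate_population(spec, n_samples=500, seed=9)
    calls = simulate_calls(pop, SeqParams(mean_coverage=5, stutter_prob=0.0), seed=10)
    truth_het = {
        (s, l): g for (s, l), g in pop.genotypes.items() if g[0] != g[1]
    }
    accs = []
    for cov in (1, 3, 5, 7):
        hits = tot = 0
        for c in calls.calls:
            g = truth_het.get((c.sample, c.locus))
            if g is None or c.coverage < cov:
                continue
            tot += 1
            hits += c.alleles == g
        accs.append(hits / tot)
    assert all(a < b for a, b in zip(accs, accs[1:])), accs


def test_dropout_is_allele_symmetric_below_censoring_bound():
    """Which allele of a heterozygote drops out is a fair coin for alleles
    the reads can span."""
    spec = [("L0", SpectrumParams(major_allele_bp=30, period=2, decay=0.9, max_steps=3))]
    pop = simulate_population(spec, n_samples=8000, seed=11)
    calls = simulate_calls(pop, SeqParams(mean_coverage=3, stutter_prob=0.0), seed=12)
    drop_short = drop_long = 0
    for c in calls.calls:
        g = pop.genotypes[(c.sample, c.locus)]
        if g[0] == g[1]:
            continue
        if c.alleles == (g[0], g[0]):
            drop_long += 1
        elif c.alleles == (g[1], g[1]):
            drop_short += 1
    total = drop_short + drop_long
    assert total > 200
    assert abs(drop_short / total - 0.5) < 0.05


# ---------------------------------------------------------------------------
# trios


def test_trio_no_mutation_is_consistent():
    rng = np.random.default_rng(0)
    for _ in range(200):
        mo = tuple(sorted(rng.integers(10, 20, size=2) * 2))
        fa = tuple(sorted(rng.integers(10, 20, size=2) * 2))
        child = simulate_trio(mo, fa, period=2, mutation_prob=0.0, rng=rng)
        assert (child[0] in mo and child[1] in fa) or (child[1] in mo and child[0] in fa)


def test_trio_forced_transmission():
    rng = np.random.default_rng(1)
    for _ in range(50):
        assert simulate_trio((10, 10), (12, 12), period=2, rng=rng) == (10, 12)


def test_trio_mutation_rate_matches_analytic():
    """Parents fixed two steps apart: the child is MI-consistent iff neither
    transmitted allele mutates, so P(consistent) = (1 - mu)^2."""
    mu = 0.5
    rng = np.random.default_rng(2)
    n = 10_000
    consistent = 0
    for _ in range(n):
        child = simulate_trio((20, 20), (28, 28), period=2, mutation_prob=mu, rng=rng)
        ok = (child[0] in (20,) and child[1] in (28,)) or (
            child[1] in (20,) and child[0] in (28,)
        )
        consistent += ok
    assert consistent / n == pytest.approx((1 - mu) ** 2, abs=0.02)


# ---------------------------------------------------------------------------
# SNP-STR haplotypes


def _spectrum():
    return simulate_spectrum(SpectrumParams(major_allele_bp=30, period=2, decay=0.5, max_steps=2))


def _wide_spectrum():
    return simulate_spectrum(SpectrumParams(major_allele_bp=30, period=2, decay=0.8, max_steps=6))


def test_haplotypes_two_founders_perfect_association():
    h = simulate_snp_str_haplotypes(
        n_hap=400,
        str_spectrum=_wide_spectrum(),
        snp_positions=list(range(1000, 50_000, 1000)),
        str_mut_prob=0.0,
        recomb_decay=0.0,
        seed=21,
        n_founders=2,
    )
    strs = h.str_bp[:, 0]
    assert len(np.unique(strs)) == 2  # seed chosen so founder STRs differ
    best = max(
        str_snp_r2(h.snp_alleles[:, j], strs.astype(float))
        for j in range(h.snp_positions.size)
        if len(np.unique(h.snp_alleles[:, j])) == 2
    )
    assert best == pytest.approx(1.0)


def test_haplotypes_mutation_decouples_str():
    common = dict(
        n_hap=2000,
        str_spectrum=_spectrum(),
        snp_positions=list(range(1000, 100_000, 1000)),
        recomb_decay=0.0,
        seed=22,
        n_founders=8,
    )
    quiet = simulate_snp_str_haplotypes(str_mut_prob=0.0, **common)
    noisy = simulate_snp_str_haplotypes(str_mut_prob=0.6, **common)

    def mean_r2(h):
        return np.nanmean(
            [
                str_snp_r2(h.snp_alleles[:, j], h.str_bp[:, 0].astype(float))
                for j in range(h.snp_positions.size)
            ]
        )

    assert mean_r2(noisy) < 0.65 * mean_r2(quiet)


def test_haplotypes_recombination_lowers_distal_r2():
    common = dict(
        n_hap=2000,
        str_spectrum=_spectrum(),
        snp_positions=list(range(90_000, 110_000, 500)),
        str_mut_prob=0.0,
        seed=23,
        n_founders=10,
    )
    slow = simulate_snp_str_haplotypes(recomb_decay=2e-5, **common)
    fast = simulate_snp_str_haplotypes(recomb_decay=4e-5, **common)

    def mean_r2(h):
        return np.nanmean(
            [
                str_snp_r2(h.snp_alleles[:, j], h.str_bp[:, 0].astype(float))
                for j in range(h.snp_positions.size)
            ]
        )

    assert mean_r2(fast) < mean_r2(slow)


def test_generators_reproducible():
    spec = [("L0", SpectrumParams(major_allele_bp=20, period=2, decay=0.4))]
    a = simulate_population(spec, n_samples=20, seed=1).genotypes
    b = simulate_population(spec, n_samples=20, seed=1).genotypes
    assert a == b
    pop = simulate_population(spec, n_samples=20, seed=1)
    ca = simulate_calls(pop, seed=2)
    cb = simulate_calls(pop, seed=2)
    assert ca.calls == cb.calls
    ha = simulate_snp_str_haplotypes(10, _spectrum(), [100, 200], seed=3)
    hb = simulate_snp_str_haplotypes(10, _spectrum(), [100, 200], seed=3)
    assert np.array_equal(ha.snp_alleles, hb.snp_alleles)
    assert np.array_equal(ha.str_bp, hb.str_bp)
    ga, _ = simulate_genome(50_000, seed=4)
    gb, _ = simulate_genome(50_000, seed=4)
    assert ga == gb


def test_simulate_genome_truth_is_embedded():
    seq, truth = simulate_genome(200_000, seed=6)
    assert len(seq) == 200_000
    assert truth
    for loc in truth[:20]:
        region = seq[loc.start : loc.end]
        # embedded tracts are repeats of the recorded motif, possibly impure
        from strland import purity

        assert purity(region, _strand_unit(region, loc)) >= 0.5


def _strand_unit(region, loc):
    return region[: loc.period]
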