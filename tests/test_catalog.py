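import itertools
import random

import numpy as np
import pytest

from oracles import exhaustive_repeat_score
from strland import (
    StrLocus,
    calibrate_thresholds,
    default_markov_model,
    detect_repeats,
    fit_markov,
    generate_null,
    purity,
    resolve_overlaps,
    wraparound_score,
)


# ---------------------------------------------------------------------------
# wraparound scoring


@pytest.mark.parametrize(
    "region,motif,expected",
    [
        ("ACACACACAC", "AC", 20),  # (AC)5: 10 matches
        ("A", "AC", 2),  # single match at free phase
        ("ACACATACAC", "AC", 11),  # one substitution: 9*2 - 7 (oracle-derived)
        ("ACGACGACG", "ACG", 18),
        ("AAAAA", "A", 10),
    ],
)
def test_wraparound_examples(region, motif, expected):
    assert wraparound_score(region, motif) == expected


def test_wraparound_empty_region_rejected():
    with pytest.raises(ValueError):
        wraparound_score("", "AC")


def test_wraparound_matches_exhaustive_alignment():
    """DP equals brute-force best alignment on an exhaustive short set and on
    random strings up to 12 bp."""
    for region in ("".join(t) for t in itertools.product("ACT", repeat=5)):
        for motif in ("AC", "ACT", "A"):
            assert wraparound_score(region, motif) == exhaustive_repeat_score(region, motif)
    rnd = random.Random(99)
    for _ in range(300):
        n = rnd.randint(1, 12)
        region = "".join(rnd.choice("ACGT") for _ in range(n))
        p = rnd.randint(1, 6)
        motif = "".join(rnd.choice("ACGT") for _ in range(p))
        assert wraparound_score(region, motif) == exhaustive_repeat_score(region, motif)


def test_wraparound_phase_invariance():
    """The free starting phase makes every rotation of the motif score the same."""
    rnd = random.Random(5)
    for _ in range(50):
        region = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(2, 12)))
        motif = "ACGT"[: rnd.randint(2, 4)]
        scores = {
            wraparound_score(region, motif[i:] + motif[:i]) for i in range(len(motif))
        }
        assert len(scores) == 1


# ---------------------------------------------------------------------------
# purity


@pytest.mark.parametrize(
    "region,motif,expected",
    [
        ("ACACACACAC", "AC", 1.0),
        ("ACACATACAC", "AC", 7 / 9),
        ("AC", "AC", 1.0),  # single window
        ("ACACATACAC", "CA", 7 / 9),  # rotation-invariant
    ],
)
def test_purity_examples(region, motif, expected):
    assert purity(region, motif) == pytest.approx(expected)


def test_purity_one_iff_every_window_matches():
    rnd = random.Random(3)
    for _ in range(100):
        motif = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 4)))
        n = rnd.randint(len(motif), 15)
        region = "".join(rnd.choice("ACGT") for _ in range(n))
        p = purity(region, motif)
        rots = {motif[i:] + motif[:i] for i in range(len(motif))}
        all_match = all(
            region[i : i + len(motif)] in rots for i in range(n - len(motif) + 1)
        )
        assert (p == 1.0) == all_match


def test_purity_region_too_short():
    with pytest.raises(ValueError):
        purity("A", "AC")


# ---------------------------------------------------------------------------
# detection


def _background(length, seed):
    return generate_null(default_markov_model(), length, seed=seed)


def test_detect_single_embedded_repeat():
    bg = _background(1000, seed=20)
    insert = "AT" * 12
    seq = bg[:500] + insert + bg[500:]
    loci = detect_repeats(seq, min_score=20)
    at_loci = [l for l in loci if l.motif == "AT"]
    assert len(at_loci) == 1
    (loc,) = at_loci
    assert loc.start <= 500 and loc.end >= 500 + len(insert)
    assert loc.score >= 2 * len(insert)


def test_detect_no_valid_windows():
    assert detect_repeats("N" * 500, min_score=10) == []


def test_detect_twin_repeats_identical():
    # background chosen so its bases adjacent to the inserts cannot extend
    # the repeat tracts, keeping the construction exactly symmetric
    bg = _background(1000, seed=35)
    insert = "AC" * 10
    seq = bg[:200] + insert + bg[200:500] + insert + bg[500:]
    loci = [l for l in loci_sorted(detect_repeats(seq, min_score=20)) if l.motif == "AC"]
    assert len(loci) == 2
    a, b = loci
    assert a.motif == b.motif == "AC"
    assert a.score == b.score
    assert (a.end - a.start) == (b.end - b.start)


def loci_sorted(loci):
    return sorted(loci, key=lambda l: l.start)


@pytest.mark.parametrize("period", [2, 3, 4, 5, 6])
def test_detect_recovers_embedded_span(period):
    """(motif)^k embedded in Markov background is recovered whenever the
    tract is at least 12 bp."""
    motifs = {2: "AG", 3: "AGC", 4: "AGGC", 5: "AAGCT", 6: "AAGGCT"}
    motif = motifs[period]
    for k in range(max(2, -(-12 // period)), 10):
        if k * period < 12:
            continue
        bg = _background(600, seed=100 + period * 10 + k)
        insert = motif * k
        seq = bg[:300] + insert + bg[300:]
        loci = detect_repeats(seq, min_score=2 * len(insert) - 2)
        hits = [
            l
            for l in loci
            if l.start <= 300 and l.end >= 300 + len(insert)
        ]
        assert hits, f"missed ({motif})x{k}"


def test_detect_deterministic():
    bg = _background(2000, seed=44)
    assert detect_repeats(bg, min_score=14) == detect_repeats(bg, min_score=14)


def test_detect_bad_args():
    with pytest.raises(ValueError):
        detect_repeats("", min_score=10)
    with pytest.raises(ValueError):
        detect_repeats("ACGT", min_period=0)
    with pytest.raises(ValueError):
        detect_repeats("ACGT", min_period=3, max_period=2)


# ---------------------------------------------------------------------------
# overlap resolution


def _locus(start, end, score, motif="AC", chrom="c1"):
    return StrLocus(chrom=chrom, start=start, end=end, motif=motif, score=score, purity=1.0)


def test_resolve_overlap_keeps_highest_score():
    a = _locus(0, 20, 40)
    b = _locus(17, 30, 25, motif="AT")
    assert resolve_overlaps([a, b]) == [a]


def test_resolve_nonoverlapping_unchanged():
    a = _locus(0, 20, 40)
    b = _locus(25, 40, 25)
    assert resolve_overlaps([b, a]) == [a, b]


def test_resolve_tiebreak_leftmost_then_longest():
    a = _locus(0, 30, 30)
    b = _locus(5, 40, 30, motif="AT")
    c = _locus(10, 35, 20, motif="AG")
    assert resolve_overlaps([c, b, a]) == [a]


def test_resolve_order_independent():
    rnd = random.Random(8)
    loci = [
        _locus(s, s + rnd.randint(5, 30), rnd.randint(10, 60), motif=m)
        for s, m in zip(range(0, 400, 13), itertools.cycle(["AC", "AT", "AG"]))
    ]
    expected = resolve_overlaps(loci)
    for _ in range(10):
        shuffled = loci[:]
        rnd.shuffle(shuffled)
        assert resolve_overlaps(shuffled) == expected


def test_resolve_drops_long_periods():
    ok = _locus(0, 20, 40)
    bad = StrLocus(chrom="c1", start=100, end=130, motif="ACGTACG", score=99, purity=1.0)
    assert resolve_overlaps([ok, bad]) == [ok]


# ---------------------------------------------------------------------------
# Markov model


def test_fit_markov_pure_a():
    model = fit_markov("A" * 1000)
    # P(A | AA) = 1 up to add-one smoothing mass
    assert model.trans[0, 0] > 0.99
    assert model.trans[0, 1:].sum() < 0.01


def test_fit_markov_uniform_iid():
    rng = np.random.default_rng(17)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1_000_000)])
    model = fit_markov(seq)
    assert np.allclose(model.trans, 0.25, atol=0.01)


def test_fit_generate_refit_roundtrip():
    model = default_markov_model()
    seq = generate_null(model, 1_000_000, seed=3)
    refit = fit_markov(seq)
    assert np.allclose(refit.trans, model.trans, atol=0.01)


def test_fit_markov_rejects_short():
    with pytest.raises(ValueError):
        fit_markov("AC")
    with pytest.raises(ValueError):
        fit_markov("NNNNNN")


def test_generate_null_deterministic_and_sized():
    model = default_markov_model()
    a = generate_null(model, 5000, seed=9)
    b = generate_null(model, 5000, seed=9)
    c = generate_null(model, 5000, seed=10)
    assert a == b and a != c and len(a) == 5000
    with pytest.raises(ValueError):
        generate_null(model, 0, seed=1)


def test_generate_null_composition_matches_stationary():
    model = default_markov_model()
    seq = generate_null(model, 1_000_000, seed=11)
    comp = np.array([seq.count(b) for b in "ACGT"]) / len(seq)
    assert np.allclose(comp, model.stationary_base_composition(), atol=0.01)


# ---------------------------------------------------------------------------
# calibration


def _fake(scores, period=2):
    motif = {2: "AC", 3: "ACG"}[period]
    return [
        StrLocus(chrom="x", start=100 * i, end=100 * i + 20, motif=motif, score=s, purity=1.0)
        for i, s in enumerate(scores)
    ]


def test_calibrate_empty_null_uses_min_real_score():
    cal = calibrate_thresholds(_fake([22, 30, 41]), [], 0.01, 1000, 1000)
    assert cal.thresholds == {2: 22}
    assert cal.achieved_fp[2] == 0.0


def test_calibrate_hand_enumerated_band():
    real = _fake([20] * 10 + [50])
    null = _fake([20])
    cal = calibrate_thresholds(real, null, 0.01, 1000, 1000)
    # at T=21 no null detection survives while the score-50 real locus does
    assert cal.thresholds[2] == 21
    assert cal.achieved_fp[2] == 0.0


def test_calibrate_vacuous_target():
    real = _fake([25, 31])
    null = _fake([18, 40])
    cal = calibrate_thresholds(real, null, 1.0, 1000, 1000)
    assert cal.thresholds[2] == 25  # minimal observed real score suffices


def test_calibrate_unachievable_target_goes_above_null_max():
    real = _fake([20, 20])
    null = _fake([60])
    cal = calibrate_thresholds(real, null, 0.01, 1000, 1000)
    assert cal.thresholds[2] == 61


def test_calibrate_omits_period_without_real_detections():
    real = _fake([30, 40], period=2)
    null = _fake([25], period=3)
    cal = calibrate_thresholds(real, null, 0.01, 1000, 1000)
    assert 3 not in cal.thresholds
    assert cal.skipped_periods == [3]


def test_calibrate_length_rescaling():
    # null twice as long as real: null counts halve
    real = _fake([30] * 100)
    null = _fake([30])
    cal_equal = calibrate_thresholds(real, null, 0.01, 1000, 1000)
    cal_long_null = calibrate_thresholds(real, null, 0.005, 1000, 2000)
    assert cal_long_null.thresholds[2] == cal_equal.thresholds[2]
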