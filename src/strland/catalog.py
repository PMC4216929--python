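"""STR catalog construction.

Detects candidate short tandem repeats (motifs of 1-6 bp) in a sequence,
scores each candidate by wraparound dynamic-programming alignment against an
unbounded perfect repetition of its motif, resolves overlap conflicts, and
calibrates per-period score thresholds against null sequences drawn from a
second-order Markov chain so that the expected fraction of false-positive
loci in the final catalog is held at a target (1% by default).

The rationale for the null calibration: randomly shuffled DNA essentially
never gives birth to a mature STR, so repeats detected in Markov-chain
sequences that match the real genome's composition and transition
frequencies estimate the background rate of spurious detections at any
score level.

Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .motif import canonical_motif, rotations, strand_canonical, is_primitive

logger = logging.getLogger(__name__)

#: Tandem Repeats Finder's default weight triple; pinned so scores are reproducible.
MATCH = 2
MISMATCH = -7
INDEL = -7

_NEG = -(10**9)

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StrLocus:
    """One catalog entry: an STR locus in a reference sequence."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    motif: str  # canonical motif
    score: int  # wraparound alignment score
    purity: float  # fraction of in-phase windows, in [0, 1]
    coding: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus end must exceed start: {self.start}..{self.end}")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity outside [0, 1]: {self.purity}")

    @property
    def ref_len_bp(self) -> int:
        return self.end - self.start

    @property
    def period(self) -> int:
        return len(self.motif)


@dataclass
class MarkovModel:
    """Order-2 nucleotide chain: P(next base | preceding 2-mer)."""

    trans: np.ndarray  # (16, 4) rows sum to 1
    init: np.ndarray  # (16,) distribution over starting 2-mers

    ORDER = 2

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        if self.trans.shape != (16, 4) or self.init.shape != (16,):
            raise ValueError("order-2 model needs a (16,4) transition matrix and (16,) init")
        if np.any(self.trans < 0) or np.any(self.init < 0):
            raise ValueError("negative probability in Markov model")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    def stationary_base_composition(self) -> np.ndarray:
        """Long-run A/C/G/T frequencies implied by the transition matrix.

        Computed from the stationary distribution of the chain on 2-mer
        states (state (a,b) -> (b,c) with probability trans[(a,b), c]).
        """
        big = np.zeros((16, 16))
        for s in range(16):
            b = s & 3
            for c in range(4):
                big[s, (b << 2) | c] = self.trans[s, c]
        vals, vecs = np.linalg.eig(big.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = pi / pi.sum()
        comp = np.zeros(4)
        for s in range(16):
            comp[s & 3] += pi[s]
        return comp


@dataclass
class CalibrationResult:
    """Per-period score thresholds tuned to a target false-positive fraction."""

    thresholds: dict[int, int]
    achieved_fp: dict[int, float]
    target_fp: float
    null_length: int
    real_length: int
    seed: int | None = None
    skipped_periods: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# scoring


def wraparound_score(region: str, motif: str) -> int:
    """Best alignment score of ``region`` against an unbounded perfect
    repetition of ``motif``.

    The alignment is global in the region (every region base is either
    aligned or charged an indel) and free in the motif: the starting phase is
    unconstrained, unbounded copies are available, and trailing motif bases
    cost nothing. Weights are match +2, mismatch -7, indel -7.

    Implemented as wraparound dynamic programming over motif phases: the
    state after consuming a region prefix is the next motif phase to align,
    and within each column phase-advancing gap moves are relaxed around the
    cycle.
    """
    if not region:
        raise ValueError("empty region")
    p = len(motif)
    dp = [0] * p  # free starting phase
    for ch in region:
        nxt = [_NEG] * p
        for j in range(p):
            s = dp[j] + (MATCH if motif[j] == ch else MISMATCH)
            jj = j + 1 if j + 1 < p else 0
            if s > nxt[jj]:
                nxt[jj] = s
            s = dp[j] + INDEL  # region base left unaligned
            if s > nxt[j]:
                nxt[j] = s
        # unaligned motif bases advance the phase at INDEL each; two sweeps
        # around the cycle reach every phase from its best source
        for _ in range(2):
            for j in range(p):
                jj = j + 1 if j + 1 < p else 0
                s = nxt[j] + INDEL
                if s > nxt[jj]:
                    nxt[jj] = s
        dp = nxt
    return max(dp)


def purity(region: str, motif: str) -> float:
    """Fraction of positions in ``region`` whose next ``period`` bases are a
    cyclic rotation of ``motif``.

    All ``len(region) - period + 1`` windows are scanned; a perfect repeat
    has purity 1.0 regardless of phase. Invariant to which rotation of the
    motif is supplied.
    """
    p = len(motif)
    if len(region) < p:
        raise ValueError("region shorter than motif period")
    rots = set(rotations(motif))
    n_win = len(region) - p + 1
    hits = sum(1 for i in range(n_win) if region[i : i + p] in rots)
    return hits / n_win


# ---------------------------------------------------------------------------
# detection


def _true_runs(mask: np.ndarray) -> np.ndarray:
    """(start, stop) pairs of maximal True runs in a boolean array."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    padded = np.empty(mask.size + 2, dtype=bool)
    padded[0] = padded[-1] = False
    padded[1:-1] = mask
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return np.stack([starts, stops], axis=1)


def detect_repeats(
    sequence: str,
    min_period: int = 2,
    max_period: int = 6,
    min_score: int = 20,
    chrom: str = "seq",
    merge_gap: int = 8,
) -> list[StrLocus]:
    """Find tandem repeats of period ``min_period``..``max_period`` scoring at
    least ``min_score``.

    Candidate regions are seeded wherever a motif occurs as an exact tandem
    pair (a maximal run of positions with ``seq[i] == seq[i+p]`` of length
    >= p). Nearby seeds carrying the same strand motif within ``merge_gap``
    bp are merged when the wraparound score of the union exceeds the best
    part, which recovers interrupted repeats. Each surviving region is
    reported once with its canonical motif, exact wraparound score and
    purity. Deterministic for fixed input.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not 1 <= min_period <= max_period <= 6:
        raise ValueError("periods must satisfy 1 <= min <= max <= 6")
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    candidates: list[tuple[int, int, str, int]] = []  # start, end, strand motif, score
    strand_cache: dict[str, str] = {}
    for p in range(min_period, max_period + 1):
        if arr.size <= p:
            continue
        eq = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        runs = _true_runs(eq)
        lengths = runs[:, 1] - runs[:, 0]
        runs = runs[lengths >= p]  # exact tandem pair present
        per_motif: list[tuple[int, int, str, int]] = []
        for a, b in runs:
            a = int(a)
            b = int(b)
            unit = seq[a : a + p]
            sc = strand_cache.get(unit)
            if sc is None:
                sc = strand_canonical(unit) if is_primitive(unit) else ""
                strand_cache[unit] = sc
            if len(sc) != p:
                continue  # degenerate unit; found at its primitive period
            # region [a, b + p) is a perfect repeat: score = 2 * length
            per_motif.append((a, b + p, sc, MATCH * (b + p - a)))
        per_motif.sort()
        candidates.extend(_merge_interrupted(seq, per_motif, merge_gap))

    # keep scoring candidates, canonicalize, dedupe identical spans
    best: dict[tuple[int, int, str], tuple[int, str]] = {}
    for a, b, unit, sc in candidates:
        if sc < min_score:
            continue
        canon = canonical_motif(unit)
        key = (a, b, canon)
        prev = best.get(key)
        if prev is None or sc > prev[0]:
            best[key] = (sc, unit)

    # one report per repeat: collapse same-motif overlapping candidates
    loci: list[StrLocus] = []
    per_canon: dict[str, list[tuple[int, int, int, str]]] = {}
    for (a, b, canon), (sc, unit) in best.items():
        per_canon.setdefault(canon, []).append((a, b, sc, unit))
    for canon, group in per_canon.items():
        group.sort(key=lambda t: (-t[2], t[0], -(t[1] - t[0])))
        taken: list[tuple[int, int]] = []
        for a, b, sc, unit in group:
            if any(a < tb and ta < b for ta, tb in taken):
                continue
            taken.append((a, b))
            loci.append(
                StrLocus(
                    chrom=chrom,
                    start=a,
                    end=b,
                    motif=canon,
                    score=sc,
                    purity=purity(seq[a:b], unit),
                )
            )
    loci.sort(key=lambda l: (l.start, l.end, l.motif))
    return loci


def _merge_interrupted(
    seq: str,
    cands: list[tuple[int, int, str, int]],
    merge_gap: int,
) -> list[tuple[int, int, str, int]]:
    """Greedy left-to-right merge of same-motif candidates separated by short
    interruptions, accepted only when the merged wraparound score improves on
    both parts."""
    out: list[tuple[int, int, str, int]] = []
    cur: tuple[int, int, str, int] | None = None
    for cand in cands:
        if cur is None:
            cur = cand
            continue
        a1, b1, m1, s1 = cur
        a2, b2, m2, s2 = cand
        if m1 == m2 and 0 <= a2 - b1 <= merge_gap:
            merged_score = wraparound_score(seq[a1:b2], m1)
            if merged_score > max(s1, s2):
                cur = (a1, b2, m1, merged_score)
                continue
        out.append(cur)
        cur = cand
    if cur is not None:
        out.append(cur)
    return out


def resolve_overlaps(loci: list[StrLocus]) -> list[StrLocus]:
    """Resolve overlap conflicts: the highest-scoring locus survives.

    Loci with period > 6 are removed before conflict resolution. Ties at
    equal score break to the leftmost start, then the longest span. The
    result is deterministic and independent of input order.
    """
    kept: list[StrLocus] = []
    by_chrom: dict[str, list[StrLocus]] = {}
    for loc in loci:
        if loc.period > 6:
            continue
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom in sorted(by_chrom):
        group = sorted(
            by_chrom[chrom],
            key=lambda l: (-l.score, l.start, -(l.end - l.start), l.motif),
        )
        taken: list[StrLocus] = []
        for loc in group:
            if any(loc.start < t.end and t.start < loc.end for t in taken):
                continue
            taken.append(loc)
        kept.extend(sorted(taken, key=lambda l: l.start))
    kept.sort(key=lambda l: (l.chrom, l.start))
    return kept


# ---------------------------------------------------------------------------
# Markov null model


def fit_markov(sequence: str) -> MarkovModel:
    """Fit an order-2 chain to observed trinucleotide frequencies.

    Non-ACGT characters are skipped and reset the context, so transitions
    are never counted across assembly gaps. Add-one smoothing keeps every
    transition available, which matters only for contexts that are rare or
    absent in the training sequence.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.size, 255, dtype=np.uint8)
    for base, c in _BASE_TO_CODE.items():
        code[arr == ord(base)] = c
    ok = code != 255
    if arr.size < 3:
        raise ValueError("sequence too short to contain a trinucleotide")
    tri_ok = ok[:-2] & ok[1:-1] & ok[2:]
    if not tri_ok.any():
        raise ValueError("no ACGT trinucleotide in sequence")
    c0 = code[:-2][tri_ok].astype(np.int64)
    c1 = code[1:-1][tri_ok].astype(np.int64)
    c2 = code[2:][tri_ok].astype(np.int64)
    counts = np.bincount((c0 << 4) | (c1 << 2) | c2, minlength=64).reshape(16, 4)
    counts = counts + 1  # add-one smoothing
    trans = counts / counts.sum(axis=1, keepdims=True)
    duo_ok = ok[:-1] & ok[1:]
    d0 = code[:-1][duo_ok].astype(np.int64)
    d1 = code[1:][duo_ok].astype(np.int64)
    init = np.bincount((d0 << 2) | d1, minlength=16).astype(float) + 1.0
    init /= init.sum()
    return MarkovModel(trans=trans, init=init)


def generate_null(model: MarkovModel, length: int, seed: int) -> str:
    """Sample a sequence of exactly ``length`` bases from the chain.

    Reproducible for a given seed; the first two bases are drawn from the
    model's initial 2-mer distribution.
    """
    if length < 3:
        raise ValueError("null sequence length must be >= 3")
    rng = np.random.default_rng(seed)
    state = int(rng.choice(16, p=model.init))
    out = bytearray(length)
    out[0] = ord(_CODE_TO_BASE[state >> 2])
    out[1] = ord(_CODE_TO_BASE[state & 3])
    # plain-python cumulative rows keep the per-base cost low
    cum = [tuple(np.cumsum(row)[:3]) for row in model.trans]
    codes = [ord(b) for b in _CODE_TO_BASE]
    u = rng.random(length - 2)
    for i in range(length - 2):
        a, b, c = cum[state]
        x = u[i]
        nxt = 0 if x < a else 1 if x < b else 2 if x < c else 3
        out[i + 2] = codes[nxt]
        state = ((state & 3) << 2) | nxt
    return out.decode("ascii")


def default_markov_model(gc: float = 0.41, cpg_depletion: float = 0.2) -> MarkovModel:
    """A human-like order-2 chain: ~41% GC and CpG dinucleotide depletion.

    Used by the synthetic genome generator as background; catalogs built on
    real FASTA input fit their own model instead.
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    trans = np.tile(base, (16, 1)).copy()
    for ctx in range(16):
        if (ctx & 3) == _BASE_TO_CODE["C"]:
            trans[ctx, _BASE_TO_CODE["G"]] *= cpg_depletion
    trans /= trans.sum(axis=1, keepdims=True)
    init = np.zeros(16)
    for a in range(4):
        for b in range(4):
            init[(a << 2) | b] = base[a] * base[b]
    init /= init.sum()
    return MarkovModel(trans=trans, init=init)


# ---------------------------------------------------------------------------
# threshold calibration


def calibrate_thresholds(
    real_loci: list[StrLocus],
    null_loci: list[StrLocus],
    target_fp_fraction: float,
    real_length: int,
    null_length: int,
    seed: int | None = None,
) -> CalibrationResult:
    """Tune per-period integer score thresholds to a target false-positive
    fraction.

    For each motif period, the threshold is the minimal integer T such that
    the length-rescaled count of null detections with score >= T, divided by
    the count of real detections with score >= T, is at most the target.
    If no threshold achieves the target, the threshold is one above the
    maximum observed null score. Periods with zero real detections are
    omitted and logged.
    """
    if not 0 < target_fp_fraction <= 1:
        raise ValueError("target_fp_fraction must be in (0, 1]")
    scale = real_length / null_length
    periods = sorted({l.period for l in real_loci} | {l.period for l in null_loci})
    thresholds: dict[int, int] = {}
    achieved: dict[int, float] = {}
    skipped: list[int] = []
    for p in periods:
        real = np.sort([l.score for l in real_loci if l.period == p])
        null = np.sort([l.score for l in null_loci if l.period == p])
        if real.size == 0:
            logger.warning("period %d: no real detections; omitted from calibration", p)
            skipped.append(p)
            continue
        if null.size == 0:
            thresholds[p] = int(real[0])
            achieved[p] = 0.0
            continue
        found = False
        for t in range(int(real[0]), int(null[-1]) + 1):
            n_real = real.size - np.searchsorted(real, t, side="left")
            if n_real == 0:
                break
            n_null = (null.size - np.searchsorted(null, t, side="left")) * scale
            frac = n_null / n_real
            if frac <= target_fp_fraction:
                thresholds[p] = t
                achieved[p] = float(frac)
                found = True
                break
        if not found:
            t = int(null[-1]) + 1
            thresholds[p] = t
            n_real = real.size - np.searchsorted(real, t, side="left")
            achieved[p] = 0.0 if n_real else float("nan")
    return CalibrationResult(
        thresholds=thresholds,
        achieved_fp=achieved,
        target_fp=target_fp_fraction,
        null_length=null_length,
        real_length=real_length,
        seed=seed,
        skipped_periods=skipped,
    )


def apply_thresholds(loci: list[StrLocus], cal: CalibrationResult) -> list[StrLocus]:
    """Filter detections by the calibrated per-period thresholds.

    Loci whose period has no calibrated threshold are dropped.
    """
    out = [
        l
        for l in loci
        if l.period in cal.thresholds and l.score >= cal.thresholds[l.period]
    ]
    return out


def false_positive_fraction(
    real_passing: list[StrLocus],
    null_loci: list[StrLocus],
    cal: CalibrationResult,
) -> float:
    """Measured FP fraction on a (typically independent) null replicate:
    length-rescaled null detections passing the thresholds over real
    detections passing them, pooled across periods."""
    scale = cal.real_length / cal.null_length
    n_null = len(apply_thresholds(null_loci, cal)) * scale
    n_real = len(real_passing)
    if n_real == 0:
        return float("nan")
    return n_null / n_real


# ---------------------------------------------------------------------------
# end-to-end catalog build


def build_catalog(
    sequences: dict[str, str],
    target_fp: float = 0.01,
    null_length: int = 10_000_000,
    seed: int = 0,
    min_period: int = 2,
    max_period: int = 6,
    detect_min_score: int = 14,
) -> tuple[list[StrLocus], CalibrationResult]:
    """Detect, calibrate and filter: the full catalog pipeline.

    Fits an order-2 Markov model to the input sequences, draws one null
    sequence of ``null_length`` bases, detects repeats in both with identical
    parameters, calibrates per-period thresholds to ``target_fp``, and
    returns the thresholded, overlap-resolved catalog. Homopolymers are
    excluded from the default catalog (``min_period=2``).
    """
    real: list[StrLocus] = []
    total_len = 0
    for chrom, seq in sequences.items():
        real.extend(
            detect_repeats(
                seq,
                min_period=min_period,
                max_period=max_period,
                min_score=detect_min_score,
                chrom=chrom,
            )
        )
        total_len += len(seq)
    model = fit_markov("N".join(sequences.values()))
    null_seq = generate_null(model, null_length, seed=seed)
    null = detect_repeats(
        null_seq,
        min_period=min_period,
        max_period=max_period,
        min_score=detect_min_score,
        chrom="null",
    )
    cal = calibrate_thresholds(
        real, null, target_fp, real_length=total_len, null_length=null_length, seed=seed
    )
    catalog = resolve_overlaps(apply_thresholds(real, cal))
    return catalog, cal
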