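"""Quality-control procedures for STR call sets.

Covers trio Mendelian-inheritance (MI) assessment as a function of read
coverage, concordance against an orthogonal genotyping technology (with the
product-length offset calibration that capillary panels require), dosage
regression metrics, and the reference-deviation profile that reveals length
censoring: when alleles are too long to be spanned by reads, calls skew
toward shorter alleles and the per-locus mean deviation from the reference
turns negative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .callstats import CallSet, StrCall, dosage
from .catalog import StrLocus

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Mendelian inheritance


@dataclass(frozen=True)
class TrioCalls:
    """Calls for child, mother and father at one locus.

    The trio's coverage is the minimum of the three members' coverages;
    loci lacking a call in any member are excluded upstream.
    """

    child: StrCall
    mother: StrCall
    father: StrCall

    @property
    def coverage(self) -> int:
        return min(self.child.coverage, self.mother.coverage, self.father.coverage)


def mendelian_consistent(t: TrioCalls) -> bool:
    """True iff one child allele can come from the mother's allele set and
    the other from the father's."""
    if any(c.is_hemizygous for c in (t.child, t.mother, t.father)):
        raise ValueError("trio MI is defined for diploid autosomal calls")
    c1, c2 = t.child.alleles
    mo, fa = set(t.mother.alleles), set(t.father.alleles)
    return (c1 in mo and c2 in fa) or (c2 in mo and c1 in fa)


def collect_trios(callset: CallSet, trio_names: list[tuple[str, str, str]]) -> list[TrioCalls]:
    """Pair up per-locus calls for (child, mother, father) sample triplets,
    keeping only loci where all three members have a call."""
    by = {(c.sample, c.locus): c for c in callset.calls}
    trios: list[TrioCalls] = []
    for child, mother, father in trio_names:
        for locus in callset.loci():
            try:
                trios.append(
                    TrioCalls(by[(child, locus)], by[(mother, locus)], by[(father, locus)])
                )
            except KeyError:
                continue
    return trios


def mi_rate_by_coverage(
    trios: list[TrioCalls], thresholds: list[int]
) -> dict[int, tuple[float, int]]:
    """MI-consistency rate among trios with coverage >= each threshold.

    Returns threshold -> (rate, n surviving trio-loci); the call count is
    non-increasing in the threshold by construction.
    """
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be ascending")
    consistent = np.array([mendelian_consistent(t) for t in trios], dtype=bool)
    coverage = np.array([t.coverage for t in trios])
    out: dict[int, tuple[float, int]] = {}
    for c in thresholds:
        mask = coverage >= c
        n = int(mask.sum())
        rate = float(consistent[mask].mean()) if n else float("nan")
        out[c] = (rate, n)
    return out


# ---------------------------------------------------------------------------
# offset calibration against capillary-style panels


def _score_sample(pipeline: tuple[int, ...], reference: tuple[int, ...], offset: int) -> float:
    """Per-sample concordance score under the 1 / 0.5 / 0.25 / 0 scheme:
    exact genotype match; homozygous call recovering one reference allele;
    heterozygous call recovering one reference allele; no match."""
    shifted = tuple(sorted(a + offset for a in pipeline))
    ref = tuple(sorted(reference))
    if shifted == ref:
        return 1.0
    hit = any(a in ref for a in shifted)
    if not hit:
        return 0.0
    is_hom = len(set(pipeline)) == 1
    return 0.5 if is_hom else 0.25


def calibrate_offset(
    pipeline_calls: dict[str, tuple[int, ...]],
    reference_calls: dict[str, tuple[int, ...]],
    min_calls: int = 20,
) -> tuple[int, float] | None:
    """Find the bp offset aligning pipeline calls to reference product
    lengths at one locus.

    Every observed pairwise difference between a pipeline and a reference
    allele is a candidate offset; the one maximizing the summed per-sample
    score wins, ties breaking to the smallest absolute offset (then the
    smaller offset). Returns (offset, mean per-sample score), or None when
    fewer than ``min_calls`` samples overlap (locus excluded, logged).
    """
    shared = sorted(set(pipeline_calls) & set(reference_calls))
    if len(shared) < min_calls:
        logger.info("offset calibration skipped: %d < %d overlapping calls", len(shared), min_calls)
        return None
    offsets = sorted(
        {
            r - p
            for s in shared
            for p, r in itertools.product(pipeline_calls[s], reference_calls[s])
        }
    )
    best: tuple[float, int] | None = None
    for off in offsets:
        total = sum(
            _score_sample(pipeline_calls[s], reference_calls[s], off) for s in shared
        )
        if best is None or total > best[0] or (
            total == best[0] and (abs(off), off) < (abs(best[1]), best[1])
        ):
            best = (total, off)
    assert best is not None
    return best[1], best[0] / len(shared)


# ---------------------------------------------------------------------------
# dosage concordance


@dataclass
class ConcordanceReport:
    slope: float
    r2: float
    rmse: float
    hom_exact: float | None = None
    het_one_allele: float | None = None
    het_both_alleles: float | None = None


def dosage_concordance(
    x: list[float],
    y: list[float],
    genotypes: list[tuple[tuple[int, ...], tuple[int, ...]]] | None = None,
) -> ConcordanceReport:
    """OLS regression of pipeline dosages (y) on reference dosages (x).

    RMSE is of the raw y-x differences. With genotype pairs supplied
    (reference, pipeline), also reports per-category accuracies: exact
    matches among reference-homozygous loci, and one-or-more / both-allele
    recovery among reference-heterozygous loci.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length paired lists with n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in reference dosages")
    fit = linregress(x, y)
    report = ConcordanceReport(
        slope=float(fit.slope),
        r2=float(fit.rvalue**2),
        rmse=float(np.sqrt(np.mean((y - x) ** 2))),
    )
    if genotypes:
        hom = [(r, p) for r, p in genotypes if len(set(r)) == 1]
        het = [(r, p) for r, p in genotypes if len(set(r)) > 1]
        if hom:
            report.hom_exact = float(
                np.mean([tuple(sorted(p)) == tuple(sorted(r)) for r, p in hom])
            )
        if het:
            report.het_one_allele = float(
                np.mean([len(set(r) & set(p)) >= 1 for r, p in het])
            )
            report.het_both_alleles = float(
                np.mean([set(r) <= set(p) and tuple(sorted(p)) == tuple(sorted(r)) for r, p in het])
            )
    return report


# ---------------------------------------------------------------------------
# reference-deviation profile


def reference_deviation_profile(
    callset: CallSet,
    catalog: dict[str, StrLocus],
    bin_bp: int = 5,
) -> dict[int, float]:
    """Median per-locus mean deviation from the reference allele, binned by
    reference allele length.

    Per locus: the mean over samples of the mean bp difference of the
    called alleles from the reference length. Loci pool into left-closed
    ``bin_bp``-wide bins of reference length ([0,5), [5,10), ... by
    default); the median within each bin is reported. Censoring of long
    alleles shows up as negative medians above the spanning bound.
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    per_locus: dict[str, float] = {}
    for locus, calls in callset.by_locus().items():
        if locus not in catalog:
            continue
        ref = catalog[locus].ref_len_bp
        devs = [np.mean([a - ref for a in c.alleles]) for c in calls]
        per_locus[locus] = float(np.mean(devs))
    bins: dict[int, list[float]] = {}
    for locus, dev in per_locus.items():
        b = (catalog[locus].ref_len_bp // bin_bp) * bin_bp
        bins.setdefault(b, []).append(dev)
    return {b: float(np.median(v)) for b, v in sorted(bins.items())}
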