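"""End-to-end validation experiments combining the simulator with the
analysis modules.

These are the package's own reproductions of its calibration and
quality-control claims: each function runs the full protocol from scratch on
synthetic data and returns the measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import catalog as cat
from .simulate import simulate_genome


@dataclass
class CalibrationExperiment:
    thresholds: dict[int, int]
    n_real_passing: int
    fp_fraction_train: float
    fp_fraction_independent: float


def calibration_fp_experiment(
    seed: int,
    genome_length: int = 10_000_000,
    null_length: int = 10_000_000,
    target_fp: float = 0.01,
    detect_min_score: int = 14,
) -> CalibrationExperiment:
    """Measure the realized false-positive fraction of a calibrated catalog.

    Protocol: simulate a genome with embedded STR tracts; fit an order-2
    Markov model to it; draw two independent null sequences; detect repeats
    in all three with identical parameters; calibrate per-period thresholds
    on the first null against the real detections at ``target_fp``; report
    the length-rescaled fraction of second-null detections passing the
    thresholds relative to real detections passing them.
    """
    rng = np.random.default_rng(seed)
    s_genome, s_null1, s_null2 = (int(rng.integers(2**31)) for _ in range(3))
    genome, _ = simulate_genome(genome_length, seed=s_genome)
    real = cat.detect_repeats(genome, min_score=detect_min_score, chrom="synth")
    model = cat.fit_markov(genome)
    null1 = cat.detect_repeats(
        cat.generate_null(model, null_length, seed=s_null1),
        min_score=detect_min_score,
        chrom="null1",
    )
    null2 = cat.detect_repeats(
        cat.generate_null(model, null_length, seed=s_null2),
        min_score=detect_min_score,
        chrom="null2",
    )
    cal = cat.calibrate_thresholds(
        real, null1, target_fp, real_length=genome_length, null_length=null_length, seed=seed
    )
    passing = cat.apply_thresholds(real, cal)
    fp_train = cat.false_positive_fraction(passing, null1, cal)
    fp_indep = cat.false_positive_fraction(passing, null2, cal)
    return CalibrationExperiment(
        thresholds=cal.thresholds,
        n_real_passing=len(passing),
        fp_fraction_train=fp_train,
        fp_fraction_independent=fp_indep,
    )
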