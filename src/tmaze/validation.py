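"""Monte-Carlo validation studies: calibration, recovery, asymmetry.

These are the package's own end-to-end checks, run over many simulated
datasets: the type-I error of the learning-score test under a null
generator, recovery of the intraclass correlation at known ground truth,
and the qualitative asymmetry between the two conditioning pairings in the
cross-assay comparison.  The same routines back the test suite and the
reproduction script.

All replicate seeds are drawn from a single base seed and kept below 2^31.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Optional

import numpy as np

from .assay_data import Assay
from .heritability import heritability_pipeline
from .pipeline import AnalysisConfig, run_cross_assay_comparison
from .scores import per_trial_scores
from .stat_tests import one_sample_location_test
from .synthetic import SimulationParams, expected_icc, line_sd_for_icc, simulate_dataset

__all__ = [
    "learning_null_rejection_rate",
    "icc_recovery",
    "IccRecoveryResult",
    "cross_assay_asymmetry_power",
]

_SEED_CAP = 2**31 - 1


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_CAP, size=n)


def learning_null_rejection_rate(
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    params: Optional[SimulationParams] = None,
) -> float:
    """Fraction of null datasets on which the learning-score test rejects.

    The null generator has no odor bias and no conditioning effect
    (p0 = 0.5, learning_effect = 0) in the mass-population design; each
    replicate runs the per-pair scores through the normality-gated
    one-sample test against 0 at level ``alpha``.  A calibrated test
    rejects at close to ``alpha``.
    """
    if params is None:
        params = SimulationParams.population_learning(p0=0.5, learning_effect=0.0)
    rejections = 0
    for rep_seed in _replicate_seeds(seed, n_reps):
        data = simulate_dataset(params.replace(seed=int(rep_seed)), Assay.LEARNING)
        values = [v for _, v in per_trial_scores(data)]
        result = one_sample_location_test(values, 0.0, method="auto")
        rejections += result.p_value < alpha
    return rejections / n_reps


@dataclass(frozen=True)
class IccRecoveryResult:
    target_icc: float
    expected: float
    mean_estimate: float
    estimates: tuple[float, ...]
    line_sd: float


def icc_recovery(
    target_icc: float,
    n_reps: int = 50,
    seed: int = 0,
    params: Optional[SimulationParams] = None,
) -> IccRecoveryResult:
    """Mean intraclass-correlation estimate over replicate line panels.

    ``line_sd`` is solved so the generator's implied ICC equals
    ``target_icc``; each replicate simulates a preference panel (default:
    10 lines x 2 exposure orders x 10 trials of 40 flies) and runs the full
    heritability pipeline on it.
    """
    if params is None:
        params = SimulationParams.inbred_panel()
    sd = line_sd_for_icc(target_icc, params, Assay.PREFERENCE)
    params = params.replace(line_sd=sd)
    estimates = []
    for rep_seed in _replicate_seeds(seed, n_reps):
        data = simulate_dataset(params.replace(seed=int(rep_seed)), Assay.PREFERENCE)
        _, est = heritability_pipeline(data, Assay.PREFERENCE)
        estimates.append(est.t)
    return IccRecoveryResult(
        target_icc=target_icc,
        expected=expected_icc(params, Assay.PREFERENCE),
        mean_estimate=fmean(estimates),
        estimates=tuple(estimates),
        line_sd=sd,
    )


def cross_assay_asymmetry_power(
    n_reps: int = 50,
    seed: int = 0,
    learning_effect: float = 0.15,
    asymmetry: float = 0.2,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rates of the stratified cross-assay test per pairing stratum.

    Simulates matched mass-population preference and conditioning
    experiments in which conditioning acts strongly in the apple-aversive
    pairing and only a fraction ``asymmetry`` as strongly (opposite
    direction) in the orange-aversive pairing, then counts how often each
    stratified comparison rejects.  With asymmetry < 1 and the effect
    sized near the detection threshold, the apple-aversive stratum should
    reject routinely and the orange-aversive stratum rarely.
    """
    config = AnalysisConfig(alpha=alpha)
    hits = {"A_stratum": 0, "O_stratum": 0}
    seeds = _replicate_seeds(seed, 2 * n_reps).reshape(n_reps, 2)
    for s_pref, s_learn in seeds:
        pref = simulate_dataset(
            SimulationParams.population_preference(order_effect=0.0, seed=int(s_pref)),
            Assay.PREFERENCE,
        )
        learn = simulate_dataset(
            SimulationParams.population_learning(
                learning_effect=learning_effect, asymmetry=asymmetry, seed=int(s_learn)
            ),
            Assay.LEARNING,
        )
        comparison = run_cross_assay_comparison(pref, learn, config)
        for stratum in hits:
            entry = comparison[stratum]
            if "p_value" in entry and entry["p_value"] < alpha:
                hits[stratum] += 1
    return {k: v / n_reps for k, v in hits.items()}
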