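"""Seeded generator of T-maze trial datasets with known ground truth.

Generative model (logit-additive, binomial trial noise): each trial of a
line with random effect ``b ~ Normal(0, line_sd^2)`` draws

    n_choosers ~ Binomial(flies_per_trial, responder_prob)
    n_orange   ~ Binomial(n_choosers, p_cell),
    logit(p_cell) = logit(p0) + design shift + b

where the design shift depends on the assay cell:

* preference, apple-then-orange exposure: ``+order_effect / 2``;
  orange-then-apple: ``-order_effect / 2`` (symmetric, so the baseline
  orange bias ``p0`` is the across-order mean);
* learning, apple-aversive pairing: ``+learning_effect`` (conditioning
  pushes toward orange, the palatable odor);
  orange-aversive pairing: ``-asymmetry * learning_effect`` (conditioning
  against the already-preferred orange odor is weaker; ``asymmetry`` is
  the retained fraction).

A line may be wholly non-responsive with probability
``nonresponder_line_prob``, in which case all its trials are emitted with
zero chamber counts — exercising the cohort-exclusion path the analysis
applies to such lines.

Defaults mirror the assay conditions the analysis is built for: trials of
40 flies per inbred line (250 in population mode), a baseline orange bias
of 0.56, conditioning shifts sized to the observed arm means (palatable-
orange trials near 0.70, palatable-apple near 0.48, learning score near
0.22), and a line effect spread giving moderate heritability.

Identical parameters + seed always reproduce the identical dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .assay_data import ARMS_BY_ASSAY, ArmDesign, Assay, TrialRecord, POPULATION_COHORT
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SimulationParams",
    "simulate_trial",
    "simulate_dataset",
    "expected_icc",
    "line_sd_for_icc",
]


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the choice simulator.

    Attributes
    ----------
    p0 : baseline orange-choice probability (unconditioned, order-averaged).
    order_effect : logit shift between the two exposure orders (A-then-O
        minus O-then-A); split symmetrically around ``p0``.
    learning_effect : logit shift toward orange under the apple-aversive
        pairing.
    asymmetry : fraction of ``learning_effect`` retained (with opposite
        sign) under the orange-aversive pairing, in [0, 1].
    line_sd : standard deviation of line-level random effects on the logit
        scale.
    n_lines, trials_per_cell, flies_per_trial : design sizes; each design
        cell is one (line, assay arm) combination.
    responder_prob : probability a released fly enters either chamber.
    nonresponder_line_prob : probability a line is wholly non-responsive.
    seed : base seed; full determinism contract.
    """

    p0: float = 0.56
    order_effect: float = 0.25
    learning_effect: float = 0.6
    asymmetry: float = 0.53
    line_sd: float = 0.4
    n_lines: int = 10
    trials_per_cell: int = 10
    flies_per_trial: int = 40
    responder_prob: float = 0.9
    nonresponder_line_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValidationError(f"p0 must lie in (0, 1), got {self.p0}")
        for name in ("responder_prob", "nonresponder_line_prob", "asymmetry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.line_sd < 0:
            raise ValidationError(f"line_sd must be >= 0, got {self.line_sd}")
        for name in ("n_lines", "trials_per_cell", "flies_per_trial"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")

    @classmethod
    def inbred_panel(cls, **overrides) -> "SimulationParams":
        """Ten-line panel, 40 flies per trial (line-replication design)."""
        return cls(**{**dict(n_lines=10, flies_per_trial=40, trials_per_cell=10), **overrides})

    @classmethod
    def population_preference(cls, **overrides) -> "SimulationParams":
        """Mass-population preference design: one cohort of 250-fly trials,
        14 trials per exposure order, no line structure."""
        base = dict(n_lines=1, line_sd=0.0, flies_per_trial=250, trials_per_cell=14)
        return cls(**{**base, **overrides})

    @classmethod
    def population_learning(cls, **overrides) -> "SimulationParams":
        """Mass-population conditioning design: one cohort of 250-fly trials,
        29 trials per pairing."""
        base = dict(n_lines=1, line_sd=0.0, flies_per_trial=250, trials_per_cell=29)
        return cls(**{**base, **overrides})

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)


def _cell_shifts(params: SimulationParams, assay: Assay) -> dict[ArmDesign, float]:
    if assay is Assay.PREFERENCE:
        return {
            ArmDesign.A_THEN_O: +params.order_effect / 2.0,
            ArmDesign.O_THEN_A: -params.order_effect / 2.0,
        }
    return {
        ArmDesign.A_AVERSIVE_O_PALATABLE: +params.learning_effect,
        ArmDesign.O_AVERSIVE_A_PALATABLE: -params.asymmetry * params.learning_effect,
    }


def simulate_trial(
    params: SimulationParams,
    line_effect: float,
    assay: Assay | str,
    arm: ArmDesign | str,
    rng: Optional[np.random.Generator] = None,
    trial_id: str = "sim-0",
    cohort: str = POPULATION_COHORT,
) -> TrialRecord:
    """Draw one trial record from the generative model.

    ``rng`` defaults to a fresh generator seeded with ``params.seed``, so
    repeated calls with the same arguments return the identical record.
    """
    assay = Assay(assay)
    arm = ArmDesign(arm)
    if arm not in ARMS_BY_ASSAY[assay]:
        raise ConfigurationError(f"arm {arm.value!r} does not belong to assay {assay.value!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_choosers = int(rng.binomial(params.flies_per_trial, params.responder_prob))
    p_cell = float(expit(logit(params.p0) + _cell_shifts(params, assay)[arm] + line_effect))
    n_orange = int(rng.binomial(n_choosers, p_cell)) if n_choosers else 0
    return TrialRecord(
        trial_id=trial_id,
        cohort=cohort,
        assay=assay,
        arm_design=arm,
        n_orange=n_orange,
        n_apple=n_choosers - n_orange,
        n_released=params.flies_per_trial,
    )


def simulate_dataset(params: SimulationParams, assay: Assay | str) -> list[TrialRecord]:
    """Full factorial dataset: lines x assay arms x trials_per_cell.

    Line effects are drawn once per line; wholly non-responsive lines (the
    ``nonresponder_line_prob`` draw) are emitted with zero-count trials so
    downstream exclusion logic has something to act on.
    """
    assay = Assay(assay)
    rng = np.random.default_rng(params.seed)
    line_effects = rng.normal(0.0, params.line_sd, size=params.n_lines)
    nonresponder = rng.random(params.n_lines) < params.nonresponder_line_prob
    records: list[TrialRecord] = []
    for i in range(params.n_lines):
        cohort = POPULATION_COHORT if params.n_lines == 1 else f"R{i + 1}"
        for arm in ARMS_BY_ASSAY[assay]:
            for k in range(params.trials_per_cell):
                trial_id = f"{cohort}-{arm.value}-{k:04d}"
                if nonresponder[i]:
                    records.append(
                        TrialRecord(
                            trial_id=trial_id, cohort=cohort, assay=assay, arm_design=arm,
                            n_orange=0, n_apple=0, n_released=params.flies_per_trial,
                        )
                    )
                else:
                    records.append(
                        simulate_trial(
                            params, float(line_effects[i]), assay, arm,
                            rng=rng, trial_id=trial_id, cohort=cohort,
                        )
                    )
    return records


def _cell_mean_functions(params: SimulationParams, assay: Assay):
    """Per-cell trait-mean functions of the line effect b.

    Preference trait is the orange proportion; learning trait is the
    palatable-paired proportion (1 - orange proportion in the
    orange-aversive cell).
    """
    eta0 = logit(params.p0)
    shifts = _cell_shifts(params, assay)
    fns = []
    for arm, s in shifts.items():
        if assay is Assay.LEARNING and arm is ArmDesign.O_AVERSIVE_A_PALATABLE:
            fns.append(lambda b, s=s: 1.0 - expit(eta0 + s + b))
        else:
            fns.append(lambda b, s=s: expit(eta0 + s + b))
    return fns


def expected_icc(params: SimulationParams, assay: Assay | str = Assay.PREFERENCE) -> float:
    """Intraclass correlation implied by the parameters for per-trial traits.

    Computed by Gauss-Hermite quadrature over the Normal line effect:
    the between-line variance is the variance of the line-level mean trait,
    and the within-line variance adds binomial sampling noise with the mean
    chooser count ``flies_per_trial * responder_prob`` as denominator plus
    the across-cell spread within a line.  The binomial term uses the mean
    denominator rather than its full distribution, so the result is
    approximate (and is validated against Monte-Carlo in the test suite).
    """
    assay = Assay(assay)
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    b = np.sqrt(2.0) * params.line_sd * nodes
    w = weights / np.sqrt(np.pi)
    fns = _cell_mean_functions(params, assay)
    mu = np.stack([f(b) for f in fns])          # (n_cells, n_nodes)
    lam = mu.mean(axis=0)                        # line-level mean trait
    e_lam = float(w @ lam)
    vb = float(w @ lam**2) - e_lam**2
    vb = max(vb, 0.0)
    m = params.flies_per_trial * params.responder_prob
    within_cells = (mu * (1.0 - mu) / m + (mu - lam) ** 2).mean(axis=0)
    vw = float(w @ within_cells)
    if vb + vw == 0:
        return 0.0
    return vb / (vb + vw)


def line_sd_for_icc(
    target_icc: float,
    params: SimulationParams,
    assay: Assay | str = Assay.PREFERENCE,
    bracket: tuple[float, float] = (1e-6, 5.0),
) -> float:
    """Line-effect SD whose :func:`expected_icc` equals ``target_icc``."""
    if not 0.0 < target_icc < 1.0:
        raise ConfigurationError(f"target ICC must lie in (0, 1), got {target_icc}")
    lo, hi = bracket
    f = lambda sd: expected_icc(params.replace(line_sd=sd), assay) - target_icc
    return float(brentq(f, lo, hi, xtol=1e-8))
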