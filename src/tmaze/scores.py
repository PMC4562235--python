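"""Choice proportions and the two trial-difference statistics.

Every trial yields the proportion of choosing flies that entered the
orange-odor chamber.  Two contrasts summarize a design:

* the **order-effect score** ``o`` — mean orange proportion of trials with
  apple-then-orange pre-exposure minus the mean of orange-then-apple
  trials.  A nonzero score means the exposure order shifts subsequent
  choice.
* the **learning score** ``l`` — mean orange proportion of trials
  conditioned apple-aversive/orange-palatable minus the mean of trials
  conditioned orange-aversive/apple-palatable.  Under this sign convention
  a positive score means conditioning shifted flies toward whichever odor
  was palatable-paired, i.e. successful aversive learning.

Sign convention: printed formulas for these scores circulate in both
orientations; here the positive direction always favours the
apple-first / apple-aversive arm, so that a positive learning score reads
as successful conditioning.  Pass ``flip_sign=True`` for the opposite
orientation.

Arms are summarized by *unweighted* means of per-trial proportions, not by
pooling counts across trials: the downstream tests operate on the trial as
the statistical unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from statistics import fmean
from typing import Sequence

from .assay_data import ARMS_BY_ASSAY, ArmDesign, Assay, TrialRecord
from .errors import DegenerateTrialError, InsufficientDesignError, ValidationError

__all__ = [
    "ChoiceProportion",
    "ScoreKind",
    "ScoreResult",
    "proportion_orange",
    "proportion_palatable",
    "order_effect_score",
    "learning_score",
    "per_trial_scores",
]


@dataclass(frozen=True)
class ChoiceProportion:
    """Orange-choice proportion of one trial, with its denominator."""

    value: float
    n_choosers: int


class ScoreKind(str, Enum):
    ORDER_EFFECT = "order_effect"
    LEARNING = "learning"


@dataclass(frozen=True)
class ScoreResult:
    """An arm-mean difference in [-1, 1] with the two arm summaries behind it.

    ``mean_arm1`` belongs to the positively-signed arm (A_then_O for the
    order-effect score, A_aversive_O_palatable for the learning score);
    ``score == mean_arm1 - mean_arm2`` up to an optional sign flip.
    """

    score: float
    mean_arm1: float
    mean_arm2: float
    n_trials_arm1: int
    n_trials_arm2: int
    score_kind: ScoreKind


def proportion_orange(record: TrialRecord) -> ChoiceProportion:
    """Proportion of choosing flies that entered the orange-odor chamber.

    Raises :class:`DegenerateTrialError` if no fly made a choice.
    """
    n = record.n_choosers
    if n == 0:
        raise DegenerateTrialError(f"trial {record.trial_id!r}: no flies entered a chamber")
    return ChoiceProportion(value=record.n_orange / n, n_choosers=n)


def proportion_palatable(record: TrialRecord) -> ChoiceProportion:
    """Proportion choosing the palatable-paired odor of a learning trial.

    For the A-aversive pairing orange was palatable, so this is the orange
    proportion; for the O-aversive pairing it is the apple proportion.
    """
    if record.assay is not Assay.LEARNING:
        raise ValidationError(f"trial {record.trial_id!r}: not a learning trial")
    p = proportion_orange(record)
    if record.arm_design is ArmDesign.A_AVERSIVE_O_PALATABLE:
        return p
    return ChoiceProportion(value=1.0 - p.value, n_choosers=p.n_choosers)


def _split_arms(
    trials: Sequence[TrialRecord], assay: Assay
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    arm1, arm2 = ARMS_BY_ASSAY[assay]
    bad = [t.trial_id for t in trials if t.assay is not assay]
    if bad:
        raise ValidationError(f"trials {bad} are not {assay.value} trials")
    group1 = [t for t in trials if t.arm_design is arm1]
    group2 = [t for t in trials if t.arm_design is arm2]
    if not group1 or not group2:
        raise InsufficientDesignError(
            f"{assay.value} score needs trials in both arms "
            f"({arm1.value}: {len(group1)}, {arm2.value}: {len(group2)})"
        )
    return group1, group2


def _arm_difference(
    trials: Sequence[TrialRecord], assay: Assay, kind: ScoreKind, flip_sign: bool
) -> ScoreResult:
    group1, group2 = _split_arms(trials, assay)
    m1 = fmean(proportion_orange(t).value for t in group1)
    m2 = fmean(proportion_orange(t).value for t in group2)
    if flip_sign:
        m1, m2 = m2, m1
        group1, group2 = group2, group1
    return ScoreResult(
        score=m1 - m2,
        mean_arm1=m1,
        mean_arm2=m2,
        n_trials_arm1=len(group1),
        n_trials_arm2=len(group2),
        score_kind=kind,
    )


def order_effect_score(
    preference_trials: Sequence[TrialRecord], flip_sign: bool = False
) -> ScoreResult:
    """Order-effect score ``o``: mean A-then-O minus mean O-then-A orange proportion."""
    return _arm_difference(preference_trials, Assay.PREFERENCE, ScoreKind.ORDER_EFFECT, flip_sign)


def learning_score(
    learning_trials: Sequence[TrialRecord], flip_sign: bool = False
) -> ScoreResult:
    """Learning score ``l``: mean A-aversive minus mean O-aversive orange proportion.

    Positive values mean conditioning shifted choice toward the
    palatable-paired odor in both arms.
    """
    return _arm_difference(learning_trials, Assay.LEARNING, ScoreKind.LEARNING, flip_sign)


def per_trial_scores(
    trials: Sequence[TrialRecord], flip_sign: bool = False
) -> list[tuple[str, float]]:
    """Per-pair signed score values feeding one-sample tests against zero.

    Trials are split by design arm and paired positionally in ``trial_id``
    order (trial ids encode the running pair when the experiment was run in
    matched blocks).  Each pair contributes ``p_arm1 - p_arm2``; a trailing
    unmatched trial is dropped with a warning.  Values lie in [-1, 1].
    """
    if not trials:
        return []
    assay = trials[0].assay
    group1, group2 = _split_arms(trials, assay)
    group1 = sorted(group1, key=lambda t: t.trial_id)
    group2 = sorted(group2, key=lambda t: t.trial_id)
    if flip_sign:
        group1, group2 = group2, group1
    n_pairs = min(len(group1), len(group2))
    if len(group1) != len(group2):
        warnings.warn(
            f"unbalanced arms ({len(group1)} vs {len(group2)}); "
            f"{abs(len(group1) - len(group2))} unmatched trial(s) dropped from paired scoring",
            stacklevel=2,
        )
    out = []
    for a, b in zip(group1[:n_pairs], group2[:n_pairs]):
        out.append((f"{a.trial_id}|{b.trial_id}", proportion_orange(a).value - proportion_orange(b).value))
    return out
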