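"""Intraclass-correlation heritability from replicated inbred-line assays.

Inbred lines are nearly uniform within and genetically variable between,
so the fraction of trait variance sitting between lines — the intraclass
correlation

    t = (Vb - Vw/n) / (Vb + (n - 1) Vw / n)
      = (n Vb - Vw) / (n Vb + (n - 1) Vw)

— serves as a proxy for broad-sense heritability.  ``Vb`` is the variance
between line summaries, ``Vw`` the pooled within-line variance of per-trial
trait values, and ``n`` a design size (by default the number of retained
lines, which is how the estimate is conventionally reported for this kind
of line panel; classical usage with ``n`` = measurements per line is
available through the same argument).

Two estimators for the components are provided:

``moments`` (default)
    Vb = sample variance of line means, Vw = pooled within-line sample
    variance.  Direct and transparent; note E[Vb] = sigma_b^2 + sigma_w^2/k
    for k trials per line, so Vb slightly overstates the between-line
    component at small k — exactly what the ``- Vw/n`` term in ``t``
    compensates when n is the replication count.
``anova``
    one-way ANOVA method-of-moments: Vb = (MSB - MSW)/n0 with n0 the
    effective per-group size for unbalanced data, Vw = MSW.  Offered as a
    sensitivity check; can yield Vb < 0 on noisy data (clipped to 0 with a
    warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .assay_data import Assay, TrialRecord, exclude_nonresponders
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientGroupsError,
)
from .scores import proportion_orange, proportion_palatable

__all__ = [
    "VarianceComponents",
    "HeritabilityEstimate",
    "variance_components",
    "intraclass_correlation",
    "heritability_pipeline",
    "bootstrap_icc_ci",
    "trait_values_by_line",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Between-line (Vb) and pooled within-line (Vw) variance with group sizes."""

    Vb: float
    Vw: float
    n_groups: int
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Intraclass correlation ``t`` with its admissible lower bound -1/(n-1)."""

    t: float
    n_used: int
    lower_bound: float
    trait: Optional[Assay] = None


def variance_components(
    per_line_values: Mapping[str, Sequence[float]], method: str = "moments"
) -> VarianceComponents:
    """Decompose per-trial trait values into between- and within-line variance.

    Parameters
    ----------
    per_line_values
        line id -> per-trial trait values.  At least two lines; lines with a
        single value contribute to Vb only (warned).
    method
        ``"moments"`` or ``"anova"`` (see module docstring).
    """
    if method not in ("moments", "anova"):
        raise ConfigurationError(f"unknown variance-component method {method!r}")
    groups = {k: np.asarray(v, dtype=float) for k, v in per_line_values.items() if len(v) > 0}
    if len(groups) < 2:
        raise InsufficientGroupsError(f"need >= 2 lines, got {len(groups)}")
    sizes = tuple(len(v) for v in groups.values())
    singletons = [k for k, v in groups.items() if len(v) == 1]
    if singletons:
        warnings.warn(
            f"lines with a single trial contribute to Vb only: {sorted(singletons)}",
            stacklevel=2,
        )
    if all(s == 1 for s in sizes):
        raise DegenerateDataError("all lines are singletons; within-line variance undefined")

    means = np.array([v.mean() for v in groups.values()])
    within_ss = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    within_df = sum(s - 1 for s in sizes)
    vw = within_ss / within_df

    if method == "moments":
        vb = float(np.var(means, ddof=1))
    else:
        k = len(groups)
        n_total = sum(sizes)
        grand = float(np.concatenate(list(groups.values())).mean())
        ssb = sum(s * (m - grand) ** 2 for s, m in zip(sizes, means))
        msb = ssb / (k - 1)
        n0 = (n_total - sum(s * s for s in sizes) / n_total) / (k - 1)
        vb = (msb - vw) / n0
        if vb < 0:
            warnings.warn("ANOVA between-line component negative; clipped to 0", stacklevel=2)
            vb = 0.0
    return VarianceComponents(Vb=vb, Vw=vw, n_groups=len(groups), group_sizes=sizes)


def intraclass_correlation(
    vc: VarianceComponents, n: int, trait: Optional[Assay] = None
) -> HeritabilityEstimate:
    """Intraclass correlation t = (n Vb - Vw) / (n Vb + (n - 1) Vw).

    ``n`` is the design size entering the formula (number of retained lines
    by default in :func:`heritability_pipeline`).  The estimate is bounded
    in [-1/(n-1), 1]; t = 1 only when Vw = 0 with Vb > 0.
    """
    if n < 2:
        raise ConfigurationError(f"n must be >= 2, got {n}")
    if vc.Vb < 0 or vc.Vw < 0:
        raise DegenerateDataError("variance components must be non-negative")
    denom = n * vc.Vb + (n - 1) * vc.Vw
    if denom == 0:
        raise DegenerateDataError("Vb = Vw = 0: intraclass correlation undefined")
    t = (n * vc.Vb - vc.Vw) / denom
    return HeritabilityEstimate(t=t, n_used=n, lower_bound=-1.0 / (n - 1), trait=trait)


def trait_values_by_line(
    records: Sequence[TrialRecord], assay: Assay
) -> dict[str, list[float]]:
    """Per-trial trait values grouped by line.

    Preference trait: orange-choice proportion.  Learning trait: proportion
    choosing the palatable-paired odor, which is well defined for every
    conditioning trial regardless of pairing arm.
    Trials with zero choosers are skipped.
    """
    out: dict[str, list[float]] = {}
    value_of = proportion_orange if assay is Assay.PREFERENCE else proportion_palatable
    for r in records:
        if r.assay is not assay or r.n_choosers == 0:
            continue
        out.setdefault(r.cohort, []).append(value_of(r).value)
    return out


def heritability_pipeline(
    records: Sequence[TrialRecord],
    assay: Assay,
    n: Optional[int] = None,
    min_choosers: int = 1,
    method: str = "moments",
) -> tuple[VarianceComponents, HeritabilityEstimate]:
    """Records -> exclusion -> per-trial trait values -> Vb/Vw -> t.

    ``n`` defaults to the number of lines retained after non-responder
    exclusion.
    """
    kept, _ = exclude_nonresponders(records, min_choosers=min_choosers)
    per_line = trait_values_by_line(kept, assay)
    vc = variance_components(per_line, method=method)
    n_used = vc.n_groups if n is None else n
    return vc, intraclass_correlation(vc, n_used, trait=assay)


def bootstrap_icc_ci(
    records: Sequence[TrialRecord],
    assay: Assay,
    n: Optional[int] = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    method: str = "moments",
) -> tuple[float, float]:
    """Percentile bootstrap CI for t, resampling trials within each line."""
    per_line = trait_values_by_line(records, assay)
    if len(per_line) < 2:
        raise InsufficientGroupsError("need >= 2 lines for a bootstrap CI")
    rng = np.random.default_rng(seed)
    arrays = {k: np.asarray(v) for k, v in per_line.items()}
    stats = []
    for _ in range(n_boot):
        resampled = {
            k: rng.choice(v, size=len(v), replace=True) for k, v in arrays.items() if len(v) > 0
        }
        try:
            vc = variance_components(resampled, method=method)
            n_used = vc.n_groups if n is None else n
            stats.append(intraclass_correlation(vc, n_used).t)
        except (DegenerateDataError, InsufficientGroupsError):
            continue
    if not stats:
        raise DegenerateDataError("no bootstrap replicate produced a defined estimate")
    lo = (1 - level) / 2
    return tuple(float(q) for q in np.quantile(stats, [lo, 1 - lo]))
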