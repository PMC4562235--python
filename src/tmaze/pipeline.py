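"""End-to-end analysis runners and report serialization.

Two runners mirror the two halves of a T-maze study — spontaneous
preference and conditioned (learning) choice — each producing a nested
report dict: per-arm summaries, the score with its test against zero,
one-sample tests against the chance proportion 0.5, and, for
line-structured data, Kruskal-Wallis across lines plus Holm-corrected
per-line post-hocs.  A third runner compares choice proportions across the
two assays, overall and stratified by matching exposure order/pairing
(apple-first preference trials vs apple-aversive conditioning trials, and
the orange counterparts).

Reports are plain dicts with deterministic key order, serialized to JSON
(full precision) and optionally to human-readable TSV (rounded: 2 decimals
for proportions and scores, 3 for statistics, scientific notation for
p < 0.001).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from statistics import fmean
from typing import Optional, Sequence

import yaml

from .assay_data import ARMS_BY_ASSAY, ArmDesign, Assay, TrialRecord, exclude_nonresponders
from .errors import TmazeError
from .heritability import heritability_pipeline
from .scores import (
    ScoreResult,
    learning_score,
    order_effect_score,
    per_trial_scores,
    proportion_orange,
)
from .stat_tests import (
    TestResult,
    holm_adjust,
    kruskal_wallis,
    one_sample_location_test,
    two_sample_test,
)

__all__ = [
    "AnalysisConfig",
    "run_preference_analysis",
    "run_learning_analysis",
    "run_cross_assay_comparison",
    "run_heritability",
    "write_report",
    "read_report",
]

logger = logging.getLogger("tmaze")

CHANCE = 0.5


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared by the analysis runners.

    ``method`` selects the test family: ``"auto"`` applies the Shapiro-Wilk
    gate per analysis vector (each experiment's vector gated on its own),
    ``"t"``/``"wilcoxon"`` force a branch.  ``icc_n`` overrides the design
    size in the intraclass-correlation formula (default: number of retained
    lines).  ``flip_score_signs`` flips the score orientation (see scores
    module).
    """

    min_choosers: int = 1
    alpha: float = 0.05
    gate_alpha: float = 0.05
    method: str = "auto"
    flip_score_signs: bool = False
    correction: str = "holm"
    equal_var: bool = True
    icc_n: Optional[int] = None
    vc_method: str = "moments"
    seed: Optional[int] = None

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise TmazeError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _tr(result: TestResult) -> dict:
    return dataclasses.asdict(result)


def _sr(result: ScoreResult) -> dict:
    d = dataclasses.asdict(result)
    d["score_kind"] = result.score_kind.value
    return d


def _safe(fn, *args, **kwargs):
    """Run a test, surfacing domain errors as report entries instead of crashes."""
    try:
        return _tr(fn(*args, **kwargs))
    except TmazeError as exc:
        return {"error": str(exc)}


def _one_sample_kwargs(config: AnalysisConfig) -> dict:
    return {"method": config.method if config.method != "auto" else "auto",
            "gate_alpha": config.gate_alpha}


def _props(records: Sequence[TrialRecord]) -> list[float]:
    return [proportion_orange(r).value for r in records if r.n_choosers > 0]


def _summary(records: Sequence[TrialRecord], assay: Assay) -> dict:
    arms = ARMS_BY_ASSAY[assay]
    by_arm = {arm.value: _props([r for r in records if r.arm_design is arm]) for arm in arms}
    overall = _props(records)
    return {
        "overall_mean": fmean(overall) if overall else None,
        "n_trials": len(overall),
        "arm_means": {a: (fmean(v) if v else None) for a, v in by_arm.items()},
        "n_by_arm": {a: len(v) for a, v in by_arm.items()},
    }


def _per_line_sections(records: Sequence[TrialRecord], assay: Assay, config: AnalysisConfig) -> dict:
    """Line-structured extras: Kruskal-Wallis across lines and Holm-corrected
    per-line-per-arm tests against chance."""
    cohorts = sorted({r.cohort for r in records})
    by_line = {c: _props([r for r in records if r.cohort == c]) for c in cohorts}
    section: dict = {"kruskal_wallis_lines": _safe(kruskal_wallis, by_line)}

    posthoc: dict = {}
    keys, pvals = [], []
    for c in cohorts:
        for arm in ARMS_BY_ASSAY[assay]:
            vals = _props([r for r in records if r.cohort == c and r.arm_design is arm])
            entry = _safe(one_sample_location_test, vals, CHANCE, **_one_sample_kwargs(config)) \
                if len(vals) >= 2 else {"error": f"fewer than 2 trials ({len(vals)})"}
            posthoc[f"{c}:{arm.value}"] = entry
            if "error" not in entry:
                keys.append(f"{c}:{arm.value}")
                pvals.append(entry["p_value"])
    if pvals:
        for key, adj in zip(keys, holm_adjust(pvals, method=config.correction)):
            posthoc[key]["p_adjusted"] = adj
    section["posthoc_vs_chance"] = posthoc
    return section


def _per_line_score_tests(
    records: Sequence[TrialRecord], assay: Assay, config: AnalysisConfig
) -> dict:
    """Per-line score tests against zero (paired per-trial values), Holm-corrected."""
    cohorts = sorted({r.cohort for r in records})
    out: dict = {}
    keys, pvals = [], []
    score_fn = order_effect_score if assay is Assay.PREFERENCE else learning_score
    for c in cohorts:
        line_recs = [r for r in records if r.cohort == c and r.n_choosers > 0]
        try:
            sc = score_fn(line_recs, flip_sign=config.flip_score_signs)
            values = [v for _, v in per_trial_scores(line_recs, flip_sign=config.flip_score_signs)]
            entry = {"score": _sr(sc)}
            test = _safe(one_sample_location_test, values, 0.0, **_one_sample_kwargs(config)) \
                if len(values) >= 2 else {"error": f"fewer than 2 score values ({len(values)})"}
            entry["test_vs_zero"] = test
            if "error" not in test:
                keys.append(c)
                pvals.append(test["p_value"])
        except TmazeError as exc:
            entry = {"error": str(exc)}
        out[c] = entry
    if pvals:
        for key, adj in zip(keys, holm_adjust(pvals, method=config.correction)):
            out[key]["test_vs_zero"]["p_adjusted"] = adj
    return out


def _base_analysis(
    records: Sequence[TrialRecord],
    assay: Assay,
    config: AnalysisConfig,
) -> tuple[list[TrialRecord], dict]:
    wanted = [r for r in records if r.assay is assay]
    kept, excluded = exclude_nonresponders(wanted, min_choosers=config.min_choosers)
    logger.info("%s analysis: %d trials in, %d kept, excluded cohorts: %s",
                assay.value, len(wanted), len(kept), excluded or "none")
    report = {
        "analysis": assay.value,
        "n_trials_in": len(wanted),
        "n_trials_kept": len(kept),
        "excluded_cohorts": excluded,
        "summary": _summary(kept, assay),
    }
    return kept, report


def run_preference_analysis(records: Sequence[TrialRecord], config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Spontaneous-preference analysis: choice vs chance, order-effect score.

    Tests: overall orange proportion against 0.5; each exposure-order arm
    against 0.5 (Holm-corrected pair); the order-effect score's per-pair
    values against 0; a two-sample comparison of the two orders.  With
    multiple lines, adds Kruskal-Wallis across lines and per-line post-hocs.
    """
    kept, report = _base_analysis(records, Assay.PREFERENCE, config)
    osk = _one_sample_kwargs(config)
    tests: dict = {"overall_vs_chance": _safe(one_sample_location_test, _props(kept), CHANCE, **osk)}

    arm_keys, arm_ps = [], []
    for arm in ARMS_BY_ASSAY[Assay.PREFERENCE]:
        vals = _props([r for r in kept if r.arm_design is arm])
        entry = _safe(one_sample_location_test, vals, CHANCE, **osk)
        tests[f"arm_{arm.value}_vs_chance"] = entry
        if "error" not in entry:
            arm_keys.append(f"arm_{arm.value}_vs_chance")
            arm_ps.append(entry["p_value"])
    for key, adj in zip(arm_keys, holm_adjust(arm_ps, method=config.correction)):
        tests[key]["p_adjusted"] = adj

    try:
        score = order_effect_score(kept, flip_sign=config.flip_score_signs)
        report["order_effect_score"] = _sr(score)
        pair_values = [v for _, v in per_trial_scores(kept, flip_sign=config.flip_score_signs)]
        tests["order_score_vs_zero"] = _safe(one_sample_location_test, pair_values, 0.0, **osk)
    except TmazeError as exc:
        report["order_effect_score"] = {"error": str(exc)}

    arm1, arm2 = ARMS_BY_ASSAY[Assay.PREFERENCE]
    tests["order_arms_comparison"] = _safe(
        two_sample_test,
        _props([r for r in kept if r.arm_design is arm1]),
        _props([r for r in kept if r.arm_design is arm2]),
        method=config.method, equal_var=config.equal_var, gate_alpha=config.gate_alpha,
    )
    report["tests"] = tests
    if len({r.cohort for r in kept}) > 1:
        report["per_line"] = _per_line_sections(kept, Assay.PREFERENCE, config)
        report["per_line_scores"] = _per_line_score_tests(kept, Assay.PREFERENCE, config)
    report["config"] = config.to_dict()
    return report


def run_learning_analysis(records: Sequence[TrialRecord], config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Conditioned-choice analysis: choice vs chance, pairing contrast,
    learning score, per-line post-hocs for line panels."""
    kept, report = _base_analysis(records, Assay.LEARNING, config)
    osk = _one_sample_kwargs(config)
    tests: dict = {"overall_vs_chance": _safe(one_sample_location_test, _props(kept), CHANCE, **osk)}

    arm1, arm2 = ARMS_BY_ASSAY[Assay.LEARNING]
    tests["pairing_arms_comparison"] = _safe(
        two_sample_test,
        _props([r for r in kept if r.arm_design is arm1]),
        _props([r for r in kept if r.arm_design is arm2]),
        method=config.method, equal_var=config.equal_var, gate_alpha=config.gate_alpha,
    )
    try:
        score = learning_score(kept, flip_sign=config.flip_score_signs)
        report["learning_score"] = _sr(score)
        pair_values = [v for _, v in per_trial_scores(kept, flip_sign=config.flip_score_signs)]
        tests["learning_score_vs_zero"] = _safe(one_sample_location_test, pair_values, 0.0, **osk)
    except TmazeError as exc:
        report["learning_score"] = {"error": str(exc)}

    report["tests"] = tests
    if len({r.cohort for r in kept}) > 1:
        report["per_line"] = _per_line_sections(kept, Assay.LEARNING, config)
        report["per_line_scores"] = _per_line_score_tests(kept, Assay.LEARNING, config)
    report["config"] = config.to_dict()
    return report


# exposure order -> matching conditioning pairing for stratified comparison
_STRATA = {
    "A_stratum": (ArmDesign.A_THEN_O, ArmDesign.A_AVERSIVE_O_PALATABLE),
    "O_stratum": (ArmDesign.O_THEN_A, ArmDesign.O_AVERSIVE_A_PALATABLE),
}


def run_cross_assay_comparison(
    pref_records: Sequence[TrialRecord],
    learn_records: Sequence[TrialRecord],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Did conditioning shift choice relative to spontaneous preference?

    Two-sample tests on per-trial orange proportions: all preference trials
    vs all conditioning trials, then stratified by matching first/aversive
    odor (apple-first vs apple-aversive; orange-first vs orange-aversive).
    An empty stratum is skipped with a warning.
    """
    pref, _ = exclude_nonresponders(
        [r for r in pref_records if r.assay is Assay.PREFERENCE], config.min_choosers)
    learn, _ = exclude_nonresponders(
        [r for r in learn_records if r.assay is Assay.LEARNING], config.min_choosers)
    kwargs = dict(method=config.method, equal_var=config.equal_var, gate_alpha=config.gate_alpha)
    out: dict = {"overall": _safe(two_sample_test, _props(learn), _props(pref), **kwargs)}
    for name, (pref_arm, learn_arm) in _STRATA.items():
        a = _props([r for r in learn if r.arm_design is learn_arm])
        b = _props([r for r in pref if r.arm_design is pref_arm])
        if not a or not b:
            warnings.warn(f"cross-assay stratum {name} empty; skipped", stacklevel=2)
            out[name] = {"skipped": "empty stratum"}
            continue
        out[name] = _safe(two_sample_test, a, b, **kwargs)
    return out


def run_heritability(records: Sequence[TrialRecord], config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Variance components and intraclass correlation per trait present."""
    out: dict = {}
    for assay in (Assay.PREFERENCE, Assay.LEARNING):
        subset = [r for r in records if r.assay is assay]
        if not subset:
            continue
        try:
            vc, est = heritability_pipeline(
                subset, assay, n=config.icc_n,
                min_choosers=config.min_choosers, method=config.vc_method,
            )
            out[assay.value] = {
                "Vb": vc.Vb,
                "Vw": vc.Vw,
                "n_lines": vc.n_groups,
                "group_sizes": list(vc.group_sizes),
                "t": est.t,
                "n_used": est.n_used,
                "lower_bound": est.lower_bound,
                "trait_note": "learning trait = per-trial palatable-paired choice proportion",
            }
        except TmazeError as exc:
            out[assay.value] = {"error": str(exc)}
    out["config"] = config.to_dict()
    return out


# ---------------------------------------------------------------- reporting

def _fmt(key: str, value) -> str:
    if not isinstance(value, float):
        return str(value)
    if "p_value" in key or "p_adjusted" in key:
        return f"{value:.3e}" if value < 0.001 else f"{value:.3f}"
    if any(tok in key for tok in ("mean", "score", "Vb", "Vw", "proportion", "t_", "_t")):
        return f"{value:.2f}"
    return f"{value:.3f}"


def _flatten(prefix: str, obj, rows: list[tuple[str, str, str]]) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, (list, tuple)):
        rows.append((prefix, "value", ";".join(str(x) for x in obj)))
    else:
        rows.append((prefix.rsplit(".", 1)[0] if "." in prefix else prefix,
                     prefix.rsplit(".", 1)[-1], _fmt(prefix, obj)))


def write_report(report: dict, path: str | Path, format: str = "json") -> list[Path]:
    """Serialize a report; ``format`` in {"json", "tsv", "both"}.

    JSON keeps full precision and field order; TSV is a flat three-column
    (section, field, value) table with display rounding.  Returns the paths
    written.
    """
    if format not in ("json", "tsv", "both"):
        raise TmazeError(f"unknown report format {format!r}")
    path = Path(path)
    written = []
    if format in ("json", "both"):
        p = path.with_suffix(".json")
        p.write_text(json.dumps(report, indent=2, allow_nan=False) + "\n", encoding="utf-8")
        written.append(p)
    if format in ("tsv", "both"):
        rows: list[tuple[str, str, str]] = []
        _flatten("", report, rows)
        p = path.with_suffix(".tsv")
        lines = ["section\tfield\tvalue"] + [f"{a}\t{b}\t{c}" for a, b, c in rows]
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(p)
    return written


def read_report(path: str | Path) -> dict:
    """Load a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
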