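"""Trial-level data model for two-choice T-maze assays and CSV I/O.

A *trial* releases a group of flies into a T-maze whose two arms carry
orange-odor and apple-odor food chambers; flies entering a chamber are
trapped and counted.  Two assay types share this readout:

``preference``
    spontaneous choice after sequential pre-exposure to both odors, in one
    of two orders (orange-then-apple ``O_then_A`` or apple-then-orange
    ``A_then_O``);
``learning``
    choice after aversive conditioning in which one odor's flavor was
    quinine-adulterated, in one of two pairings
    (``O_aversive_A_palatable`` or ``A_aversive_O_palatable``).

The canonical on-disk format is a long CSV, one row per trial.  Files with
other column names or enum spellings are adapted with a
:class:`ColumnMapping`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Assay",
    "ArmDesign",
    "Side",
    "TrialRecord",
    "ColumnMapping",
    "load_trials",
    "write_trials",
    "exclude_nonresponders",
    "POPULATION_COHORT",
]

#: Cohort token used for mass-population (non line-structured) experiments.
POPULATION_COHORT = "population"


class Assay(str, Enum):
    PREFERENCE = "preference"
    LEARNING = "learning"


class ArmDesign(str, Enum):
    # preference assay: exposure order
    O_THEN_A = "O_then_A"
    A_THEN_O = "A_then_O"
    # learning assay: conditioning pairing (which odor carried the aversive flavor)
    O_AVERSIVE_A_PALATABLE = "O_aversive_A_palatable"
    A_AVERSIVE_O_PALATABLE = "A_aversive_O_palatable"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


#: arm designs admissible for each assay type
ARMS_BY_ASSAY: dict[Assay, tuple[ArmDesign, ArmDesign]] = {
    Assay.PREFERENCE: (ArmDesign.A_THEN_O, ArmDesign.O_THEN_A),
    Assay.LEARNING: (ArmDesign.A_AVERSIVE_O_PALATABLE, ArmDesign.O_AVERSIVE_A_PALATABLE),
}

_REQUIRED_FIELDS = ("trial_id", "cohort", "assay", "arm_design", "n_orange", "n_apple")
_OPTIONAL_FIELDS = ("orange_side", "n_released")
CANONICAL_COLUMNS = _REQUIRED_FIELDS + _OPTIONAL_FIELDS


@dataclass(frozen=True)
class TrialRecord:
    """One T-maze trial: design factors plus per-arm choice counts.

    ``n_orange``/``n_apple`` count flies that entered each odor chamber;
    flies that never entered a chamber are non-responders and appear only
    in the optional ``n_released`` total.  ``orange_side`` records which
    physical side held the orange chamber at test (metadata; no side-bias
    correction is applied downstream).
    """

    trial_id: str
    cohort: str
    assay: Assay
    arm_design: ArmDesign
    n_orange: int
    n_apple: int
    orange_side: Optional[Side] = None
    n_released: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        object.__setattr__(self, "arm_design", ArmDesign(self.arm_design))
        if self.orange_side is not None:
            object.__setattr__(self, "orange_side", Side(self.orange_side))
        if self.n_orange < 0 or self.n_apple < 0:
            raise ValidationError(
                f"trial {self.trial_id!r}: counts must be non-negative "
                f"(n_orange={self.n_orange}, n_apple={self.n_apple})"
            )
        if self.n_released is not None and self.n_orange + self.n_apple > self.n_released:
            raise ValidationError(
                f"trial {self.trial_id!r}: choosers ({self.n_orange + self.n_apple}) "
                f"exceed flies released ({self.n_released})"
            )
        if self.arm_design not in ARMS_BY_ASSAY[self.assay]:
            raise ValidationError(
                f"trial {self.trial_id!r}: arm design {self.arm_design.value!r} "
                f"does not belong to assay {self.assay.value!r}"
            )

    @property
    def n_choosers(self) -> int:
        """Flies that made a choice; the denominator for choice proportions."""
        return self.n_orange + self.n_apple


@dataclass(frozen=True)
class ColumnMapping:
    """Adapter from a source CSV layout to the canonical trial schema.

    ``columns`` maps canonical field names to source column names and must
    cover every required field exactly once.  ``recode`` optionally maps,
    per canonical field, source cell tokens to canonical tokens (e.g.
    ``{"arm_design": {"O-/A": "O_aversive_A_palatable"}}``).
    """

    columns: Mapping[str, str]
    recode: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown canonical fields in mapping: {sorted(unknown)}")
        missing = [f for f in _REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise ConfigurationError(f"mapping is missing required fields: {missing}")
        sources = list(self.columns.values())
        if len(sources) != len(set(sources)):
            raise ConfigurationError("mapping assigns one source column to several fields")

    @classmethod
    def identity(cls) -> "ColumnMapping":
        """Mapping for files already in the canonical schema."""
        return cls(columns={name: name for name in CANONICAL_COLUMNS})

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMapping":
        """Read a mapping from YAML or JSON (``columns:`` and optional ``recode:``)."""
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict) or "columns" not in data:
            raise ConfigurationError(f"{path}: expected a mapping with a 'columns' key")
        return cls(columns=data["columns"], recode=data.get("recode", {}))


def _recode(mapping: ColumnMapping, field_name: str, value: object) -> object:
    table = mapping.recode.get(field_name)
    if table is None:
        return value
    return table.get(str(value), value)


def _parse_enum(enum_cls: type[Enum], token: object, field_name: str, row: int) -> Enum:
    try:
        return enum_cls(str(token))
    except ValueError:
        valid = [m.value for m in enum_cls]
        raise ValidationError(
            f"row {row}: unknown {field_name} token {token!r} (expected one of {valid})"
        ) from None


def load_trials(path: str | Path, mapping: Optional[ColumnMapping] = None) -> list[TrialRecord]:
    """Read a trial table from CSV, validating every row.

    Parameters
    ----------
    path
        CSV file with a header row.
    mapping
        Column adapter; ``None`` assumes the canonical schema.

    Raises
    ------
    ConfigurationError
        if a mapped source column is absent from the file.
    ValidationError
        if any row violates a record invariant; the message indexes the
        offending rows (0-based data-row index).
    """
    mapping = mapping or ColumnMapping.identity()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [src for src in (mapping.columns[f] for f in _REQUIRED_FIELDS) if src not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: mapped columns absent from file: {missing}")

    records: list[TrialRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            records.append(_row_to_record(rowd, mapping, i))
        except (ValidationError, ValueError) as exc:
            problems.append(str(exc) if str(exc).startswith("row") else f"row {i}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return records


def _row_to_record(rowd: Mapping[str, str], mapping: ColumnMapping, i: int) -> TrialRecord:
    def cell(fname: str) -> Optional[str]:
        src = mapping.columns.get(fname)
        if src is None or src not in rowd:
            return None
        raw = rowd[src]
        if raw == "":
            return None
        return str(_recode(mapping, fname, raw))

    def count(fname: str, required: bool) -> Optional[int]:
        raw = cell(fname)
        if raw is None:
            if required:
                raise ValidationError(f"row {i}: missing value for {fname}")
            return None
        try:
            value = int(float(raw))
        except ValueError:
            raise ValidationError(f"row {i}: non-integer {fname} value {raw!r}") from None
        return value

    assay = _parse_enum(Assay, cell("assay"), "assay", i)
    arm = _parse_enum(ArmDesign, cell("arm_design"), "arm_design", i)
    side_token = cell("orange_side")
    side = _parse_enum(Side, side_token, "orange_side", i) if side_token is not None else None
    try:
        return TrialRecord(
            trial_id=cell("trial_id") or f"row{i}",
            cohort=cell("cohort") or POPULATION_COHORT,
            assay=assay,
            arm_design=arm,
            n_orange=count("n_orange", required=True),
            n_apple=count("n_apple", required=True),
            orange_side=side,
            n_released=count("n_released", required=False),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {i}: {exc}") from None


def write_trials(records: Sequence[TrialRecord], path: str | Path) -> None:
    """Write records as canonical-schema CSV; ``load_trials`` round-trips exactly."""
    rows = []
    for r in records:
        rows.append(
            {
                "trial_id": r.trial_id,
                "cohort": r.cohort,
                "assay": r.assay.value,
                "arm_design": r.arm_design.value,
                "n_orange": r.n_orange,
                "n_apple": r.n_apple,
                "orange_side": "" if r.orange_side is None else r.orange_side.value,
                "n_released": "" if r.n_released is None else r.n_released,
            }
        )
    columns = ["trial_id", "cohort", "assay", "arm_design", "n_orange", "n_apple", "orange_side", "n_released"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def exclude_nonresponders(
    records: Iterable[TrialRecord], min_choosers: int = 1
) -> tuple[list[TrialRecord], list[str]]:
    """Drop cohorts whose *every* trial has fewer than ``min_choosers`` choosers.

    Lines of flies that consistently refuse to enter the food chambers carry
    no choice information; they are removed as whole cohorts (a cohort with
    even one adequately-responding trial is kept in full).

    Returns ``(kept_records, excluded_cohort_ids)`` with cohort ids sorted.
    """
    if min_choosers < 1:
        raise ConfigurationError(f"min_choosers must be >= 1, got {min_choosers}")
    records = list(records)
    cohorts: dict[str, bool] = {}
    for r in records:
        responded = r.n_choosers >= min_choosers
        cohorts[r.cohort] = cohorts.get(r.cohort, False) or responded
    excluded = sorted(c for c, any_ok in cohorts.items() if not any_ok)
    kept = [r for r in records if r.cohort not in set(excluded)]
    if excluded:
        warnings.warn(f"excluded non-responder cohorts: {excluded}", stacklevel=2)
    return kept, excluded


def swap_arms(record: TrialRecord) -> TrialRecord:
    """Relabel the trial's design arm with its counterpart (counts untouched)."""
    a, b = ARMS_BY_ASSAY[record.assay]
    return replace(record, arm_design=b if record.arm_design == a else a)
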