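"""Trial data model, CSV round-trips, column mapping, cohort exclusion."""

import numpy as np
import pytest

from tmaze.assay_data import (
    ArmDesign,
    Assay,
    ColumnMapping,
    TrialRecord,
    exclude_nonresponders,
    load_trials,
    write_trials,
)
from tmaze.errors import ConfigurationError, ValidationError

from conftest import make_trial, random_records


class TestTrialRecord:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            make_trial(-1, 5)

    def test_choosers_cannot_exceed_released(self):
        with pytest.raises(ValidationError, match="exceed"):
            make_trial(30, 20, n_released=40)

    @pytest.mark.parametrize(
        "assay,arm",
        [
            (Assay.PREFERENCE, ArmDesign.O_AVERSIVE_A_PALATABLE),
            (Assay.LEARNING, ArmDesign.A_THEN_O),
        ],
    )
    def test_arm_must_match_assay(self, assay, arm):
        with pytest.raises(ValidationError, match="does not belong"):
            make_trial(5, 5, assay=assay, arm=arm)

    def test_string_enums_coerced(self):
        r = TrialRecord("t", "R1", "learning", "O_aversive_A_palatable", 3, 4)
        assert r.assay is Assay.LEARNING
        assert r.n_choosers == 7


class TestCsvRoundTrip:
    def test_well_formed_rows_load(self, tmp_path):
        csv = tmp_path / "trials.csv"
        csv.write_text(
            "trial_id,cohort,assay,arm_design,n_orange,n_apple\n"
            "a,R1,preference,O_then_A,10,5\n"
            "b,R1,preference,A_then_O,7,8\n"
            "c,R2,learning,A_aversive_O_palatable,20,4\n"
        )
        records = load_trials(csv)
        assert len(records) == 3
        assert records[2].cohort == "R2"

    def test_negative_count_cites_row(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text(
            "trial_id,cohort,assay,arm_design,n_orange,n_apple\n"
            "a,R1,preference,O_then_A,-1,5\n"
        )
        with pytest.raises(ValidationError, match="row 0"):
            load_trials(csv)

    def test_unknown_enum_token_named(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text(
            "trial_id,cohort,assay,arm_design,n_orange,n_apple\n"
            "a,R1,preference,sideways,1,5\n"
        )
        with pytest.raises(ValidationError, match="sideways"):
            load_trials(csv)

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        csv = tmp_path / "trials.csv"
        csv.write_text("trial_id,cohort\n a,R1\n")
        with pytest.raises(ConfigurationError, match="absent"):
            load_trials(csv)

    def test_round_trip_is_identity(self, tmp_path, rng):
        records = random_records(rng, n=50)
        path = tmp_path / "out.csv"
        write_trials(records, path)
        assert load_trials(path) == records

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_trials([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("trial_id,")
        assert load_trials(path) == []


class TestColumnMapping:
    def test_mapping_with_recode(self, tmp_path):
        csv = tmp_path / "foreign.csv"
        csv.write_text(
            "Trial,Line,Exp,Pairing,Orange,Apple\n"
            "1,R3,learning,O-/A,12,20\n"
            "2,R3,learning,A-/O,25,6\n"
        )
        mapping = ColumnMapping(
            columns={
                "trial_id": "Trial",
                "cohort": "Line",
                "assay": "Exp",
                "arm_design": "Pairing",
                "n_orange": "Orange",
                "n_apple": "Apple",
            },
            recode={
                "arm_design": {
                    "O-/A": "O_aversive_A_palatable",
                    "A-/O": "A_aversive_O_palatable",
                }
            },
        )
        records = load_trials(csv, mapping)
        assert records[0].arm_design is ArmDesign.O_AVERSIVE_A_PALATABLE
        assert records[1].n_orange == 25

    def test_missing_required_field_rejected(self):
        with pytest.raises(ConfigurationError, match="missing required"):
            ColumnMapping(columns={"trial_id": "a"})

    def test_duplicate_source_column_rejected(self):
        cols = {f: "same" for f in ("trial_id", "cohort", "assay", "arm_design", "n_orange", "n_apple")}
        with pytest.raises(ConfigurationError, match="several"):
            ColumnMapping(columns=cols)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "map.yaml"
        path.write_text(
            "columns:\n"
            "  trial_id: Trial\n  cohort: Line\n  assay: Exp\n"
            "  arm_design: Arm\n  n_orange: O\n  n_apple: A\n"
            "recode:\n  assay: {pref: preference}\n"
        )
        m = ColumnMapping.from_file(path)
        assert m.columns["n_orange"] == "O"
        assert m.recode["assay"]["pref"] == "preference"


class TestExcludeNonresponders:
    def test_all_zero_cohort_excluded(self):
        dead = [make_trial(0, 0, cohort="R6", trial_id=f"d{i}") for i in range(3)]
        live = [make_trial(10, 5, cohort="R1", trial_id=f"l{i}") for i in range(3)]
        with pytest.warns(UserWarning, match="R6"):
            kept, excluded = exclude_nonresponders(dead + live)
        assert excluded == ["R6"]
        assert kept == live

    def test_identity_when_all_respond(self):
        records = [make_trial(5, 5, cohort=f"R{i}", trial_id=f"t{i}") for i in range(4)]
        kept, excluded = exclude_nonresponders(records)
        assert kept == records and excluded == []

    def test_one_responding_trial_saves_cohort(self):
        records = [
            make_trial(0, 0, cohort="R2", trial_id="a"),
            make_trial(1, 0, cohort="R2", trial_id="b"),
        ]
        kept, excluded = exclude_nonresponders(records, min_choosers=1)
        assert excluded == [] and len(kept) == 2

    def test_matches_brute_force_on_random_cohorts(self, rng):
        records = []
        for c in range(8):
            cohort = f"R{c}"
            responsive = rng.random() < 0.5
            for i in range(5):
                n = int(rng.integers(3, 10)) if (responsive and rng.random() < 0.7) else 0
                records.append(make_trial(n, 0, cohort=cohort, trial_id=f"{cohort}-{i}"))
        min_choosers = 3
        # oracle: explicit per-cohort loop
        expected_excluded = sorted(
            {r.cohort for r in records}
            - {r.cohort for r in records if r.n_choosers >= min_choosers}
        )
        _, excluded = exclude_nonresponders(records, min_choosers=min_choosers)
        assert excluded == expected_excluded

    def test_empty_input(self):
        assert exclude_nonresponders([]) == ([], [])
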