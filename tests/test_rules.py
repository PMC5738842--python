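"""Rule language: parsing, validation, bin semantics, coverage audits."""

import random
from fractions import Fraction

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from retroharm.dictionary import DataDictionary, VariableEntry
from retroharm.errors import SpecError
from retroharm.rules import (
    Bin,
    HarmonisationSpec,
    ThresholdBinRule,
    WaveExclusion,
    parse_spec_dict,
    serialize_spec,
    spec_to_dict,
    validate_coverage,
)


def var(study, vid, name, fmt="categorical", cats=("A", "B"), group="G", wave=1):
    return VariableEntry(
        study_id=study,
        variable_id=vid,
        name=name,
        label=name,
        format=fmt,
        categories=tuple(cats) if fmt == "categorical" else (),
        variable_group=group,
        wave=wave,
    )


TABLE5_BINS = [
    {"upper": 5, "label": "Less than or equal to 5 min"},
    {"lower": 5, "upper": 15, "label": "6–15 min"},
    {"lower": 15, "label": "More than 15 min"},
]


class TestParsing:
    def test_packaged_binary_mode_spec(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel2"]
        assert spec.target_categories == (
            "Active mode of travel",
            "Other mode of travel",
            "Missing",
        )
        assert {r.study_id for r in spec.rules} == {"SPEEDY", "KISS", "Ballabeina"}

    def test_overlapping_bins_rejected(self):
        bins = [
            {"upper": 5, "label": "low"},
            {"lower": 5, "upper": 15, "label": "mid"},
            {"lower": 15, "lower_inclusive": True, "label": "high"},
        ]
        data = {
            "name": "X",
            "target_categories": ["low", "mid", "high", "Missing"],
            "rules": [
                {"study_id": "S", "wave": 1, "kind": "threshold_bin",
                 "source_variable": "t", "bins": bins}
            ],
        }
        with pytest.raises(SpecError, match="overlap at 15"):
            parse_spec_dict(data)

    def test_gap_between_bins_rejected(self):
        with pytest.raises(SpecError, match="gap at 5"):
            ThresholdBinRule(
                source_variable="t",
                bins=(
                    Bin(None, 5.0, "low", upper_inclusive=False),
                    Bin(5.0, None, "high", lower_inclusive=False),
                ),
            )

    def test_unknown_mapping_key_names_value_and_candidates(self):
        d = DataDictionary(
            [var("KISS", 1, "mode", cats=("Walk", "Cycle/scooter", "Car", "Bus/train/tram"))]
        )
        data = {
            "name": "X",
            "target_categories": ["Active", "Missing"],
            "rules": [
                {"study_id": "KISS", "wave": 1, "kind": "category_map",
                 "source_variable": "mode", "mapping": {"Walkk": "Active"}}
            ],
        }
        with pytest.raises(SpecError) as exc:
            parse_spec_dict(data, d)
        assert "Walkk" in str(exc.value) and "Cycle/scooter" in str(exc.value)

    def test_unknown_source_variable_rejected(self):
        d = DataDictionary([var("S", 1, "mode")])
        data = {
            "name": "X",
            "target_categories": ["A", "Missing"],
            "rules": [
                {"study_id": "S", "wave": 1, "kind": "category_map",
                 "source_variable": "nope", "mapping": {"A": "A"}}
            ],
        }
        with pytest.raises(SpecError, match="nope"):
            parse_spec_dict(data, d)

    def test_exclusion_requires_reason(self):
        with pytest.raises(SpecError, match="reason"):
            WaveExclusion("S", 1, "  ")

    def test_mapping_to_undeclared_target_rejected(self):
        data = {
            "name": "X",
            "target_categories": ["A", "Missing"],
            "rules": [
                {"study_id": "S", "wave": 1, "kind": "category_map",
                 "source_variable": "v", "mapping": {"x": "B"}}
            ],
        }
        with pytest.raises(SpecError, match="'B'"):
            parse_spec_dict(data)

    def test_duplicate_study_wave_rule_rejected(self):
        rule = {"study_id": "S", "wave": 1, "kind": "category_map",
                "source_variable": "v", "mapping": {"x": "A"}}
        data = {"name": "X", "target_categories": ["A", "Missing"], "rules": [rule, rule]}
        with pytest.raises(SpecError, match="more than one"):
            parse_spec_dict(data)

    def test_missing_target_category_missing_rejected(self):
        with pytest.raises(SpecError, match="Missing"):
            HarmonisationSpec(name="X", description="", target_categories=("A", "B"))


class TestSerialisation:
    @pytest.mark.parametrize(
        "name", ["ICAD_SchoolTravel1", "ICAD_SchoolTravel2", "ICAD_SchoolTravel3"]
    )
    def test_parse_of_serialize_is_identity(self, bundle, name):
        spec = bundle.specs[name]
        again = parse_spec_dict(yaml.safe_load(serialize_spec(spec)), bundle.dictionary)
        assert again == spec

    def test_content_hash_tracks_content(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel2"]
        data = spec_to_dict(spec)
        data["description"] = "changed"
        assert parse_spec_dict(data).content_hash() != spec.content_hash()

    def test_spec_remains_valid_against_superset_dictionary(self, bundle):
        spec_data = spec_to_dict(bundle.specs["ICAD_SchoolTravel2"])
        superset = DataDictionary(
            list(bundle.dictionary.entries)
            + [var("NEW", 1, "extra", cats=("x",), group="Other_group")]
        )
        parse_spec_dict(spec_data, superset)  # must not raise


@settings(max_examples=300, derandomize=True)
@given(
    value=st.fractions(
        min_value=Fraction(0), max_value=Fraction(100)
    ).map(lambda f: round(float(f), 3)),
)
def test_bin_partition_totality(value):
    """Every non-negative value with <=3 decimals lands in exactly one bin."""
    rule = ThresholdBinRule(
        source_variable="t",
        bins=(
            Bin(None, 5.0, "low"),
            Bin(5.0, 15.0, "mid"),
            Bin(15.0, None, "high"),
        ),
    )
    accepting = [b.label for b in rule.bins if b.accepts(value)]
    assert len(accepting) == 1
    assert rule.assign(value) == accepting[0]


class TestCoverage:
    def test_complete_binary_spec_has_no_findings(self, bundle):
        assert validate_coverage(bundle.specs["ICAD_SchoolTravel2"], bundle.dictionary) == []

    def test_all_packaged_specs_cover_every_study_wave(self, bundle):
        for spec in bundle.specs.values():
            uncovered = [
                f
                for f in validate_coverage(spec, bundle.dictionary)
                if f.kind == "uncovered_study_wave"
            ]
            assert uncovered == []

    def test_omitting_an_exclusion_is_detected(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel3"]
        truncated = HarmonisationSpec(
            name=spec.name,
            description=spec.description,
            target_categories=spec.target_categories,
            rules=spec.rules,
            exclusions=(),  # drop the reasoned Ballabeina exclusion
            variable_group=spec.variable_group,
        )
        findings = validate_coverage(truncated, bundle.dictionary)
        assert [(f.kind, f.study_id, f.wave) for f in findings] == [
            ("uncovered_study_wave", "Ballabeina", 1)
        ]

    def test_rule_for_excluded_wave_is_a_finding(self):
        d = DataDictionary([var("S", 1, "v", cats=("a",))])
        spec = HarmonisationSpec(
            name="X",
            description="",
            target_categories=("A", "Missing"),
            rules=(
                parse_spec_dict(
                    {
                        "name": "X",
                        "target_categories": ["A", "Missing"],
                        "rules": [
                            {"study_id": "S", "wave": 1, "kind": "category_map",
                             "source_variable": "v", "mapping": {"a": "A"}}
                        ],
                    },
                    d,
                ).rules
            ),
            exclusions=(WaveExclusion("S", 1, "also excluded"),),
            variable_group="G",
        )
        kinds = {f.kind for f in validate_coverage(spec, d)}
        assert "rule_for_excluded_wave" in kinds

    def test_findings_match_brute_force_enumeration(self):
        """Random spec/dictionary pairs: type-(a) findings equal a cross-join check."""
        rng = random.Random(2024)
        for trial in range(20):
            entries, pairs = [], set()
            vid = 0
            for s in range(rng.randint(1, 4)):
                for w in range(1, rng.randint(1, 4) + 1):
                    vid += 1
                    entries.append(
                        var(f"S{s}", vid, f"W{w}_v{vid}", cats=("a", "b"), wave=w)
                    )
                    pairs.add((f"S{s}", w))
            d = DataDictionary(entries)
            covered = {p for p in pairs if rng.random() < 0.6}
            rules = [
                {
                    "study_id": s, "wave": w, "kind": "category_map",
                    "source_variable": next(
                        e.name for e in entries if (e.study_id, e.wave) == (s, w)
                    ),
                    "mapping": {"a": "A", "b": "A"},
                }
                for (s, w) in sorted(covered)
            ]
            spec = parse_spec_dict(
                {
                    "name": "X",
                    "variable_group": "G",
                    "target_categories": ["A", "Missing"],
                    "rules": rules,
                },
                d,
            )
            found = {
                (f.study_id, f.wave)
                for f in validate_coverage(spec, d)
                if f.kind == "uncovered_study_wave"
            }
            assert found == pairs - covered
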