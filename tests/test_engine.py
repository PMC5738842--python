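"""Engine transforms, pooling, tabulation and coverage summaries."""

import numpy as np
import pandas as pd
import pytest

from retroharm.dictionary import DataDictionary, VariableEntry
from retroharm.engine import (
    StudyWaveTable,
    apply_category_map,
    apply_inference,
    apply_threshold_bins,
    coverage_summary,
    harmonise_study_wave,
    harmonised_csv_bytes,
    pool,
    read_study_master,
    resolve_sources,
    tabulate,
)
from retroharm.errors import IntegrityError, SpecError, TransformError
from retroharm.fixtures import school_travel_inclusion_registry
from retroharm.rules import (
    Bin,
    CategoryMapRule,
    InferenceRule,
    SourcePreferenceRule,
    SourceSelector,
    ThresholdBinRule,
)

ST2_TARGETS = ("Active mode of travel", "Other mode of travel", "Missing")


def marginal_column(marginals):
    values = []
    for category, count in marginals.items():
        values.extend([pd.NA if category == "Missing" else category] * count)
    return pd.Series(values, dtype="object")


class TestCategoryMap:
    @pytest.mark.parametrize(
        "marginals,mapping,expected",
        [
            (  # published wave-1 marginals, first example study
                {"Car": 923, "Bus/train": 127, "Bicycle": 189, "On foot": 814, "Missing": 11},
                {"Bicycle": "Active mode of travel", "On foot": "Active mode of travel",
                 "Car": "Other mode of travel", "Bus/train": "Other mode of travel"},
                {"Active mode of travel": 1003, "Other mode of travel": 1050, "Missing": 11},
            ),
            (  # third example study: five source categories onto two
                {"Walk": 546, "Cycle/scooter": 1, "Bus/tram": 4, "Car": 32,
                 "Other": 24, "Missing": 62},
                {"Walk": "Active mode of travel", "Cycle/scooter": "Active mode of travel",
                 "Bus/tram": "Other mode of travel", "Car": "Other mode of travel",
                 "Other": "Other mode of travel"},
                {"Active mode of travel": 547, "Other mode of travel": 60, "Missing": 62},
            ),
        ],
    )
    def test_published_marginals_collapse_correctly(self, marginals, mapping, expected):
        column = marginal_column(marginals)
        rule = CategoryMapRule(source_variable="v", mapping=mapping)
        out = apply_category_map(column, rule, ST2_TARGETS)
        assert out.value_counts().to_dict() == expected

    def test_identity_map_preserves_counts(self):
        column = marginal_column({"A": 10, "B": 7, "Missing": 3})
        rule = CategoryMapRule("v", {"A": "A", "B": "B"})
        out = apply_category_map(column, rule, ("A", "B", "Missing"))
        assert out.value_counts().to_dict() == {"A": 10, "B": 7, "Missing": 3}

    def test_counts_match_linear_recount_oracle(self):
        rng = np.random.default_rng(99)
        cats = [f"c{i}" for i in range(5)]
        values = [
            pd.NA if rng.random() < 0.1 else cats[rng.integers(5)] for _ in range(300)
        ]
        mapping = {c: ("X" if i < 3 else "Y") for i, c in enumerate(cats)}
        out = apply_category_map(
            pd.Series(values, dtype="object"), CategoryMapRule("v", mapping), ("X", "Y", "Missing")
        )
        for i, v in enumerate(values):
            expected = "Missing" if pd.isna(v) else mapping[v]
            assert out.iloc[i] == expected

    def test_unmapped_value_raises_under_error_policy(self):
        column = pd.Series(["A", "Z"], dtype="object")
        with pytest.raises(TransformError, match="'Z'"):
            apply_category_map(
                column, CategoryMapRule("v", {"A": "X"}), ("X", "Missing")
            )

    def test_unmapped_value_becomes_missing_under_missing_policy(self):
        column = pd.Series(["A", "Z"], dtype="object")
        out = apply_category_map(
            column,
            CategoryMapRule("v", {"A": "X"}, unmapped_policy="missing"),
            ("X", "Missing"),
        )
        assert list(out) == ["X", "Missing"]

    def test_multi_select_resolved_by_priority(self):
        # a participant ticking both an active and a motorised mode
        column = pd.Series(["Walk;Car", "Car;Walk", "Car"], dtype="object")
        rule = CategoryMapRule(
            "v", {"Walk": "Active mode of travel", "Car": "Other mode of travel"}
        )
        out = apply_category_map(column, rule, ST2_TARGETS)
        assert list(out) == [
            "Active mode of travel", "Active mode of travel", "Other mode of travel",
        ]


class TestThresholdBins:
    RULE = ThresholdBinRule(
        source_variable="t",
        bins=(
            Bin(None, 5.0, "Less than or equal to 5 min"),
            Bin(5.0, 15.0, "6–15 min"),
            Bin(15.0, None, "More than 15 min"),
        ),
    )

    def test_published_cut_points(self):
        out = apply_threshold_bins(pd.Series([5, 6, 15, 16]), self.RULE)
        assert list(out) == [
            "Less than or equal to 5 min", "6–15 min", "6–15 min", "More than 15 min",
        ]

    def test_all_missing_column(self):
        out = apply_threshold_bins(pd.Series([pd.NA, pd.NA], dtype="object"), self.RULE)
        assert list(out) == ["Missing", "Missing"]

    def test_negative_values_are_an_error(self):
        with pytest.raises(TransformError, match="negative"):
            apply_threshold_bins(pd.Series([3.0, -1.0]), self.RULE)

    def test_uniform_values_match_if_chain_oracle(self):
        rng = np.random.default_rng(1234)
        values = rng.uniform(0, 60, size=1000)
        out = apply_threshold_bins(pd.Series(values), self.RULE)

        def oracle(v):
            if v <= 5:
                return "Less than or equal to 5 min"
            if v <= 15:
                return "6–15 min"
            return "More than 15 min"

        assert list(out) == [oracle(v) for v in values]


class TestSourceResolution:
    RULE = SourcePreferenceRule(
        selectors=(SourceSelector(variable="parent"), SourceSelector(variable="child")),
    )

    def test_parent_preferred_over_child(self):
        frame = pd.DataFrame({"parent": ["Walk"], "child": ["Car"]})
        resolved, conflicts = resolve_sources(frame, self.RULE)
        assert list(resolved) == ["Walk"]
        assert conflicts == 1

    def test_falls_back_when_preferred_missing(self):
        frame = pd.DataFrame({"parent": [pd.NA], "child": ["Car"]})
        resolved, conflicts = resolve_sources(frame, self.RULE)
        assert list(resolved) == ["Car"]
        assert conflicts == 0

    def test_missing_if_conflict_policy(self):
        rule = SourcePreferenceRule(
            selectors=self.RULE.selectors, conflict_policy="missing_if_conflict"
        )
        frame = pd.DataFrame({"parent": ["Walk", "Walk"], "child": ["Car", "Walk"]})
        resolved, conflicts = resolve_sources(frame, rule)
        assert resolved.isna().tolist() == [True, False]
        assert conflicts == 1

    def test_unknown_candidate_source_is_a_spec_error(self):
        frame = pd.DataFrame({"parent": ["Walk"], "teacher": ["Car"]})
        with pytest.raises(SpecError, match="teacher"):
            resolve_sources(frame, self.RULE, source_order=["parent"])

    def test_matches_per_row_oracle(self):
        rng = np.random.default_rng(77)
        cats = ["Walk", "Car", "Bus"]

        def draw():
            return pd.NA if rng.random() < 0.3 else cats[rng.integers(3)]

        frame = pd.DataFrame(
            {"parent": [draw() for _ in range(200)], "child": [draw() for _ in range(200)]},
            dtype="object",
        )
        resolved, conflicts = resolve_sources(frame, self.RULE)
        expected_conflicts = 0
        for i in range(200):
            p, c = frame.iloc[i]["parent"], frame.iloc[i]["child"]
            expected = c if pd.isna(p) else p
            if pd.isna(expected):
                assert pd.isna(resolved.iloc[i])
            else:
                assert resolved.iloc[i] == expected
            if not pd.isna(p) and not pd.isna(c) and p != c:
                expected_conflicts += 1
        assert conflicts == expected_conflicts


class TestInference:
    RULE = InferenceRule(
        variables=("walk", "cycle"),
        inferred_category="Other mode of travel",
        negative_values=("0", "No"),
    )

    def test_no_walking_no_cycling_implies_other_mode(self):
        frame = pd.DataFrame({"walk": ["0"], "cycle": ["No"]})
        base = pd.Series(["Missing"], dtype="string")
        out, n = apply_inference(frame, self.RULE, base)
        assert list(out) == ["Other mode of travel"]
        assert n == 1

    def test_assigned_rows_are_untouched(self):
        frame = pd.DataFrame({"walk": ["0"], "cycle": ["0"]})
        base = pd.Series(["Active mode of travel"], dtype="string")
        out, n = apply_inference(frame, self.RULE, base)
        assert list(out) == ["Active mode of travel"]
        assert n == 0

    def test_missing_indicator_blocks_inference(self):
        frame = pd.DataFrame({"walk": ["0"], "cycle": [pd.NA]})
        base = pd.Series(["Missing"], dtype="string")
        out, n = apply_inference(frame, self.RULE, base)
        assert list(out) == ["Missing"]
        assert n == 0

    def test_matches_predicate_filter_oracle(self):
        rng = np.random.default_rng(31)
        choices = ["0", "No", "Yes", pd.NA]
        frame = pd.DataFrame(
            {
                "walk": [choices[rng.integers(4)] for _ in range(500)],
                "cycle": [choices[rng.integers(4)] for _ in range(500)],
            },
            dtype="object",
        )
        base = pd.Series(
            [("Missing" if rng.random() < 0.5 else "Active mode of travel") for _ in range(500)],
            dtype="string",
        )
        out, n = apply_inference(frame, self.RULE, base)
        expected_reassigned = set()
        for i in range(500):
            w, c = frame.iloc[i]["walk"], frame.iloc[i]["cycle"]
            negative = (
                not pd.isna(w) and w in ("0", "No") and not pd.isna(c) and c in ("0", "No")
            )
            if base.iloc[i] == "Missing" and negative:
                expected_reassigned.add(i)
                assert out.iloc[i] == "Other mode of travel"
            else:
                assert out.iloc[i] == base.iloc[i]
        assert n == len(expected_reassigned)


class TestHarmoniseStudyWave:
    def test_second_example_study_counts(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel2"]
        fragment, recode = harmonise_study_wave(
            bundle.tables["KISS"], spec, bundle.dictionary
        )
        assert recode.output_marginals == {
            "Active mode of travel": 443, "Other mode of travel": 10, "Missing": 87,
        }
        assert recode.respondent == "parent"

    def test_incompatible_duration_scheme_is_excluded_with_reason(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel3"]
        fragment, recode = harmonise_study_wave(
            bundle.tables["Ballabeina"], spec, bundle.dictionary
        )
        assert len(fragment) == 0
        assert recode.excluded
        assert "boundaries incompatible" in recode.exclusion_reason.lower()

    def test_empty_table_gives_zero_marginals(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel2"]
        empty = StudyWaveTable(
            "KISS", 1, bundle.tables["KISS"].data.iloc[0:0].copy()
        )
        fragment, recode = harmonise_study_wave(empty, spec, bundle.dictionary)
        assert len(fragment) == 0
        assert recode.output_marginals == {c: 0 for c in spec.target_categories}

    def test_conservation_on_every_fixture_study_wave(self, harmonised, bundle):
        for name, (ds, recodes) in harmonised.items():
            for recode in recodes:
                if recode.excluded:
                    continue
                n_input = bundle.tables[recode.study_id].n
                assert sum(recode.output_marginals.values()) == n_input

    def test_row_order_invariance(self, bundle):
        """Shuffled input rows give byte-identical harmonised output."""
        spec = bundle.specs["ICAD_SchoolTravel2"]
        table = bundle.tables["KISS"]
        shuffled = StudyWaveTable(
            "KISS", 1,
            table.data.sample(frac=1.0, random_state=5).reset_index(drop=True),
        )
        a, _ = harmonise_study_wave(table, spec, bundle.dictionary)
        b, _ = harmonise_study_wave(shuffled, spec, bundle.dictionary)
        assert harmonised_csv_bytes(pool([a], spec)) == harmonised_csv_bytes(
            pool([b], spec)
        )


class TestPoolAndTabulate:
    def test_pooled_per_study_counts_match_published_summaries(self, tabulations):
        tab = tabulations["ICAD_SchoolTravel2"]
        assert tab.counts("SPEEDY", 1) == {
            "Active mode of travel": 1003, "Other mode of travel": 1050, "Missing": 11,
        }
        assert tab.counts("KISS", 1) == {
            "Active mode of travel": 443, "Other mode of travel": 10, "Missing": 87,
        }
        assert tab.counts("Ballabeina", 1) == {
            "Active mode of travel": 547, "Other mode of travel": 60, "Missing": 62,
        }

    def test_single_fragment_pool_is_identity(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel2"]
        fragment, _ = harmonise_study_wave(bundle.tables["KISS"], spec, bundle.dictionary)
        ds = pool([fragment], spec)
        assert len(ds.records) == len(fragment)

    def test_duplicate_records_are_an_integrity_error(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel2"]
        fragment, _ = harmonise_study_wave(bundle.tables["KISS"], spec, bundle.dictionary)
        with pytest.raises(IntegrityError, match="duplicate"):
            pool([fragment, fragment], spec)

    def test_pooled_n_is_sum_of_fragment_n(self, bundle):
        rng = np.random.default_rng(8)
        spec = bundle.specs["ICAD_SchoolTravel2"]
        fragments = []
        for s in range(4):
            n = int(rng.integers(1, 50))
            fragments.append(
                pd.DataFrame(
                    {
                        "study_id": f"R{s}",
                        "wave": 1,
                        "participant_id": [f"R{s}_{i}" for i in range(n)],
                        "variable": spec.name,
                        "category": "Missing",
                    }
                )
            )
        ds = pool(fragments, spec)
        assert len(ds.records) == sum(len(f) for f in fragments)

    def test_excluded_wave_is_absent_not_missing(self, tabulations):
        tab = tabulations["ICAD_SchoolTravel3"]
        assert ("Ballabeina", 1) not in tab.per_study_wave.index

    def test_empty_dataset_tabulates_to_zero(self, bundle):
        spec = bundle.specs["ICAD_SchoolTravel3"]
        ds = pool([], spec)
        tab = tabulate(ds)
        assert tab.n == 0 and all(v == 0 for v in tab.overall.values())

    def test_tabulation_matches_group_and_count_oracle(self, harmonised):
        ds, _ = harmonised["ICAD_SchoolTravel1"]
        tab = tabulate(ds)
        records = ds.records
        for (study_id, wave), row in tab.per_study_wave.iterrows():
            sub = records[(records.study_id == study_id) & (records.wave == wave)]
            for category in tab.categories:
                assert row[category] == (sub.category == category).sum()

    def test_multi_resolution_consistency(self, harmonised, tabulations):
        """Collapsing the five-category mode variable reproduces the binary one."""
        collapse = {
            "Walk": "Active mode of travel",
            "Cycle": "Active mode of travel",
            "Public transport": "Other mode of travel",
            "Car": "Other mode of travel",
            "Other": "Other mode of travel",
            "Missing": "Missing",
        }
        ds1, _ = harmonised["ICAD_SchoolTravel1"]
        collapsed = ds1.records.assign(category=ds1.records.category.map(collapse))
        tab2 = tabulations["ICAD_SchoolTravel2"]
        for (study_id, wave), row in tab2.per_study_wave.iterrows():
            sub = collapsed[(collapsed.study_id == study_id) & (collapsed.wave == wave)]
            assert {c: int((sub.category == c).sum()) for c in tab2.categories} == {
                c: int(row[c]) for c in tab2.categories
            }


class TestCoverageSummary:
    def test_published_inclusion_histograms(self):
        rows = {r.variable: r for r in coverage_summary(school_travel_inclusion_registry())}
        assert (rows["ICAD_SchoolTravel1"].n_studies,
                rows["ICAD_SchoolTravel1"].total_waves) == (11, 21)
        assert rows["ICAD_SchoolTravel1"].wave_histogram == {1: 4, 2: 4, 3: 3}
        assert (rows["ICAD_SchoolTravel2"].n_studies,
                rows["ICAD_SchoolTravel2"].total_waves) == (14, 25)
        assert (rows["ICAD_SchoolTravel3"].n_studies,
                rows["ICAD_SchoolTravel3"].total_waves) == (8, 13)

    def test_empty_registry(self):
        assert coverage_summary({}) == []


class TestMasterFiles:
    def test_wave_split_and_missing_code_translation(self, tmp_path):
        d = DataDictionary(
            [
                VariableEntry("S", 1, "W1_x", "x", format="categorical",
                              categories=("1", "2"), variable_group="G", wave=1),
                VariableEntry("S", 2, "W2_x", "x", format="categorical",
                              categories=("1", "2"), variable_group="G", wave=2),
                VariableEntry("S", 3, "sex", "sex", format="categorical",
                              categories=("M", "F"), variable_group="Demographics"),
            ]
        )
        path = tmp_path / "S.csv"
        path.write_text(
            "participant_id,W1_x,W2_x,sex\np1,1,2,M\np2,9,1,F\n", encoding="utf-8"
        )
        tables = read_study_master(path, "S", d, missing_codes={"W1_x": ["9"]})
        assert set(tables) == {1, 2}
        w1 = tables[1]
        assert w1.data["W1_x"].isna().tolist() == [False, True]
        assert w1.missing_code_translations == {"W1_x": 1}
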