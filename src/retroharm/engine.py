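"""Applying harmonisation specs to study tables and pooling the results.

The engine is deliberately dumb: every transform is a deterministic, row-wise
recode (category collapse, threshold binning, source resolution, negative
inference), and pooling is concatenation plus integrity checks. All
judgement lives in the specs; everything the engine does is transcribed into
recode tables so the provenance report can show exactly what happened to each
study-wave.

Data model
----------
Study data arrive as wide CSV master files (one row per participant, first
column ``participant_id``, wave-prefixed columns, empty field = missing).
:func:`read_study_master` splits a master file into per-wave
:class:`StudyWaveTable` objects using the dictionary (which knows each
column's wave, including unprefixed native names). Harmonised output is a
long table with columns ``study_id, wave, participant_id, variable,
category``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dictionary import DataDictionary, normalise_label
from .errors import IntegrityError, SpecError, TransformError
from .rules import (
    MISSING,
    CategoryMapRule,
    HarmonisationSpec,
    InferenceRule,
    SourcePreferenceRule,
    StudyWaveRule,
    ThresholdBinRule,
)

__all__ = [
    "StudyWaveTable",
    "HarmonisedDataset",
    "CategoryTabulation",
    "RecodeTable",
    "CoverageRow",
    "read_study_master",
    "apply_category_map",
    "apply_threshold_bins",
    "resolve_sources",
    "apply_inference",
    "harmonise_study_wave",
    "pool",
    "tabulate",
    "coverage_summary",
]

HARMONISED_COLUMNS = ("study_id", "wave", "participant_id", "variable", "category")


@dataclass
class StudyWaveTable:
    """One study's participant table restricted to one wave's columns.

    ``data`` holds ``participant_id`` plus data columns; missing values are
    ``pd.NA``. Columns must be declared in the dictionary when one is given.
    """

    study_id: str
    wave: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "participant_id" not in self.data.columns:
            raise IntegrityError(
                f"{self.study_id} wave {self.wave}: first column must be participant_id"
            )
        dup = self.data["participant_id"][self.data["participant_id"].duplicated()]
        if not dup.empty:
            raise IntegrityError(
                f"{self.study_id} wave {self.wave}: duplicate participant ids "
                f"{sorted(dup.unique().tolist())[:5]}"
            )

    @property
    def n(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise IntegrityError(
                f"{self.study_id} wave {self.wave}: no column {name!r}"
            )
        return self.data[name]


def _read_wide_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.replace("", pd.NA)


def read_study_master(
    path: str | Path,
    study_id: str,
    dictionary: DataDictionary,
    missing_codes: Mapping[str, Sequence[str]] | None = None,
) -> dict[int, StudyWaveTable]:
    """Split a study's wide master CSV into per-wave tables.

    Column-to-wave assignment comes from the dictionary (wave prefix or an
    explicit wave for unprefixed native names). ``missing_codes`` optionally
    maps a column name to the study's native missing codes (e.g. ``"9"``,
    ``"-99"``), which are translated to the canonical missing value on load;
    translations performed are recorded on each table for the report ledger.
    """
    df = _read_wide_csv(path)
    if df.columns[0] != "participant_id":
        raise IntegrityError(f"{path}: first column must be participant_id")
    translations: dict[str, int] = {}
    if missing_codes:
        for col, codes in missing_codes.items():
            if col in df.columns:
                mask = df[col].isin(list(codes))
                if mask.any():
                    translations[col] = int(mask.sum())
                    df.loc[mask, col] = pd.NA
    by_wave: dict[int, list[str]] = {}
    for col in df.columns[1:]:
        entry = dictionary.get(study_id, col)
        if entry is None:
            raise IntegrityError(
                f"{path}: column {col!r} is not in the dictionary for {study_id!r}"
            )
        if entry.wave is not None:
            by_wave.setdefault(entry.wave, []).append(col)
    tables = {}
    for wave, cols in sorted(by_wave.items()):
        table = StudyWaveTable(
            study_id=study_id,
            wave=wave,
            data=df[["participant_id", *cols]].copy(),
        )
        table.missing_code_translations = {  # type: ignore[attr-defined]
            c: n for c, n in translations.items() if c in cols
        }
        tables[wave] = table
    return tables


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------


def apply_category_map(
    column: pd.Series,
    rule: CategoryMapRule,
    targets: Sequence[str],
    multi_select_priority: Sequence[str] | None = None,
) -> pd.Series:
    """Map each source category to its target; missing becomes ``Missing``.

    Multi-select responses (several ticked modes in one cell, ``;``-separated)
    are mapped per ticked label and resolved by priority: the explicit
    ``multi_select_priority`` if given, otherwise the target-category order —
    which puts the more specific/active category first by construction of the
    packaged specs.
    """
    priority = list(multi_select_priority or targets)

    def one(value) -> str:
        if pd.isna(value):
            return MISSING
        label = normalise_label(str(value))
        if ";" in label:
            picks = [one(part) for part in label.split(";") if part.strip()]
            ranked = [p for p in priority if p in picks]
            return ranked[0] if ranked else MISSING
        if label in rule.mapping:
            return rule.mapping[label]
        if rule.unmapped_policy == "missing":
            return MISSING
        raise TransformError(
            f"source value {label!r} has no mapping and unmapped_policy is 'error'"
        )

    return column.map(one).astype("string")


def apply_threshold_bins(column: pd.Series, rule: ThresholdBinRule) -> pd.Series:
    """Assign each non-negative duration to its unique bin; missing → Missing.

    Raises :class:`TransformError` for negative values, identifying the rows.
    """
    values = pd.to_numeric(column, errors="coerce")
    bad = column.notna() & values.isna()
    if bad.any():
        raise TransformError(
            f"non-numeric duration values {column[bad].unique().tolist()[:5]}"
        )
    negative = values < 0
    if negative.any():
        raise TransformError(
            f"negative duration values at rows {values.index[negative].tolist()[:5]}"
        )
    return pd.Series(
        [MISSING if pd.isna(v) else rule.assign(v) for v in values],
        index=column.index,
        dtype="string",
    )


def resolve_sources(
    candidates: pd.DataFrame,
    rule: SourcePreferenceRule,
    source_order: Sequence[str] | None = None,
) -> tuple[pd.Series, int]:
    """Pick one value per participant from multiple candidate sources.

    ``candidates`` has one column per source, ordered by preference (or named
    by ``source_order``). The first non-missing value wins; rows where a
    less-preferred source is present *and disagrees* count as conflicts, and
    under ``missing_if_conflict`` become missing. Returns the resolved column
    and the conflict count (always surfaced in the provenance report).
    """
    order = list(source_order or candidates.columns)
    unknown = [c for c in order if c not in candidates.columns]
    if unknown:
        raise SpecError(f"candidate sources {unknown} not present in the data")
    if len(order) < len(candidates.columns):
        extra = [c for c in candidates.columns if c not in order]
        raise SpecError(f"candidate sources {extra} not in the selector list")
    resolved = pd.Series(pd.NA, index=candidates.index, dtype="string")
    conflicts = pd.Series(False, index=candidates.index)
    for col in order:
        col_vals = candidates[col].astype("string")
        newly = resolved.isna() & col_vals.notna()
        disagree = resolved.notna() & col_vals.notna() & (resolved != col_vals)
        conflicts |= disagree
        resolved[newly] = col_vals[newly]
    n_conflicts = int(conflicts.sum())
    if rule.conflict_policy == "missing_if_conflict":
        resolved[conflicts] = pd.NA
    return resolved, n_conflicts


def apply_inference(
    indicators: pd.DataFrame,
    rule: InferenceRule,
    base: pd.Series,
) -> tuple[pd.Series, int]:
    """Reassign Missing rows whose indicators all deny an active mode.

    Only rows with ``base == Missing`` are touched; a row is reassigned when
    every indicator is present and takes one of the rule's negative values.
    Returns the updated assignments and the number of reassigned rows.
    """
    negative = {normalise_label(v) for v in rule.negative_values}
    trigger = pd.Series(True, index=indicators.index)
    for col in rule.variables:
        vals = indicators[col].astype("string")
        trigger &= vals.notna() & vals.map(
            lambda v: normalise_label(str(v)) in negative
        ).fillna(False).astype(bool)
    reassign = trigger & (base == MISSING)
    out = base.copy()
    out[reassign] = rule.inferred_category
    return out, int(reassign.sum())


# ---------------------------------------------------------------------------
# Study-wave harmonisation
# ---------------------------------------------------------------------------


@dataclass
class RecodeTable:
    """Provenance record of one study-wave's harmonisation.

    Mirrors the documentation style of recode tables: which source variables
    (and respondent) fed the rule, the source marginals (or summary statistics
    for continuous sources), a transcription of the rule, and the output
    marginals. Excluded study-waves carry the reason instead.
    """

    study_id: str
    wave: int
    variable: str
    source_variables: list[str] = field(default_factory=list)
    respondent: str = "unknown"
    source_summary: dict = field(default_factory=dict)
    rule_text: str = ""
    output_marginals: dict = field(default_factory=dict)
    n: int = 0
    exclusion_reason: str | None = None
    conflict_count: int = 0
    inference_count: int = 0
    missing_code_translations: dict = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason is not None


def _continuous_summary(values: pd.Series) -> dict:
    """Mean, median, quartiles and range — the statistics recode tables print."""
    numeric = pd.to_numeric(values, errors="coerce").dropna()
    n_missing = len(values) - len(numeric)
    if numeric.empty:
        return {"n": 0, "missing": n_missing}
    return {
        "n": int(len(numeric)),
        "missing": n_missing,
        "mean": round(float(numeric.mean()), 1),
        "median": float(numeric.median()),
        "p25": float(numeric.quantile(0.25)),
        "p75": float(numeric.quantile(0.75)),
        "min": float(numeric.min()),
        "max": float(numeric.max()),
    }


def _categorical_marginals(values: pd.Series, categories: Sequence[str]) -> dict[str, int]:
    counts = values.value_counts(dropna=True)
    out = {c: int(counts.get(c, 0)) for c in categories}
    extra = sorted(set(counts.index) - set(categories))
    for c in extra:
        out[str(c)] = int(counts[c])
    out[MISSING] = int(values.isna().sum())
    return out


def _map_rule_text(rule: CategoryMapRule, source: str) -> str:
    by_target: dict[str, list[str]] = {}
    for src, tgt in rule.mapping.items():
        by_target.setdefault(tgt, []).append(src)
    lines = [
        f"If [{source}] = {' OR '.join(srcs)} -> {tgt}"
        for tgt, srcs in by_target.items()
    ]
    lines.append(f"If [{source}] = Missing -> {MISSING}")
    return "; ".join(lines)


def _bin_rule_text(rule: ThresholdBinRule, source: str) -> str:
    parts = []
    for b in rule.bins:
        if b.lower is None:
            cond = f"<= {b.upper:g}" if b.upper_inclusive else f"< {b.upper:g}"
        elif b.upper is None:
            cond = f"> {b.lower:g}" if not b.lower_inclusive else f">= {b.lower:g}"
        else:
            lo = f"{b.lower:g} <" + ("=" if b.lower_inclusive else "")
            hi = ("<= " if b.upper_inclusive else "< ") + f"{b.upper:g}"
            cond = f"{lo} value {hi}"
        parts.append(f"If [{source}] {cond} -> {b.label}")
    parts.append(f"If [{source}] = Missing -> {MISSING}")
    return "; ".join(parts)


def _gated_duration(table: StudyWaveTable, rule: ThresholdBinRule) -> pd.Series:
    """Materialise the duration column selected by a mode gate."""
    gate = rule.mode_gate
    assert gate is not None
    mode = table.column(gate.mode_variable).astype("string")
    out = pd.Series(np.nan, index=table.data.index, dtype="float64")
    for mode_label, src in gate.sources.items():
        mask = (mode == mode_label).fillna(False).astype(bool)
        if not mask.any():
            continue
        if src.variable is not None:
            vals = pd.to_numeric(table.column(src.variable), errors="coerce")
        else:
            hours = pd.to_numeric(table.column(src.hours), errors="coerce")
            minutes = pd.to_numeric(table.column(src.minutes), errors="coerce")
            vals = hours.fillna(0) * 60 + minutes.fillna(0)
            vals[hours.isna() & minutes.isna()] = np.nan
        out[mask] = vals[mask]
    return out


def harmonise_study_wave(
    table: StudyWaveTable,
    spec: HarmonisationSpec,
    dictionary: DataDictionary | None = None,
) -> tuple[pd.DataFrame, RecodeTable]:
    """Apply a spec to one study-wave.

    Returns a long-format fragment (one assigned category per participant;
    empty for an excluded wave) plus the recode table for the report. The
    conservation invariant — category counts, including Missing, sum to the
    participant count — is asserted before returning.
    """
    study_id, wave = table.study_id, table.wave
    exclusion = spec.exclusion_for(study_id, wave)
    rule = spec.rule_for(study_id, wave)
    if exclusion is not None and rule is not None:
        raise SpecError(
            f"{spec.name}: ({study_id}, wave {wave}) is both transformed and excluded"
        )
    recode = RecodeTable(
        study_id=study_id,
        wave=wave,
        variable=spec.name,
        missing_code_translations=getattr(table, "missing_code_translations", {}),
    )
    if exclusion is not None:
        recode.exclusion_reason = exclusion.reason
        recode.n = table.n
        empty = pd.DataFrame(columns=list(HARMONISED_COLUMNS))
        return empty, recode
    if rule is None:
        raise SpecError(
            f"{spec.name}: no rule or exclusion for ({study_id}, wave {wave})"
        )
    assigned = _apply_rule(table, rule, spec, dictionary, recode)

    fragment = pd.DataFrame(
        {
            "study_id": study_id,
            "wave": wave,
            "participant_id": table.data["participant_id"].astype("string"),
            "variable": spec.name,
            "category": assigned.to_numpy(dtype=object),
        }
    ).sort_values("participant_id", kind="mergesort", ignore_index=True)

    bad = sorted(set(fragment["category"]) - set(spec.target_categories))
    if bad:
        raise IntegrityError(
            f"{spec.name} ({study_id}, wave {wave}): assigned categories {bad} are "
            "not target categories"
        )
    recode.output_marginals = {
        c: int((fragment["category"] == c).sum()) for c in spec.target_categories
    }
    recode.n = table.n
    if sum(recode.output_marginals.values()) != table.n:
        raise IntegrityError(
            f"{spec.name} ({study_id}, wave {wave}): output marginals do not sum to n"
        )
    return fragment, recode


def _apply_rule(
    table: StudyWaveTable,
    rule: StudyWaveRule,
    spec: HarmonisationSpec,
    dictionary: DataDictionary | None,
    recode: RecodeTable,
) -> pd.Series:
    t = rule.transform

    def describe_source(name: str, values: pd.Series) -> None:
        recode.source_variables.append(name)
        entry = dictionary.get(table.study_id, name) if dictionary else None
        if entry is not None:
            recode.respondent = entry.respondent
        if entry is not None and entry.format == "categorical":
            recode.source_summary[name] = _categorical_marginals(values, entry.categories)
        else:
            recode.source_summary[name] = _continuous_summary(values)

    try:
        if isinstance(t, CategoryMapRule):
            if rule.source_preference is not None:
                order = _selector_columns(rule.source_preference, table, dictionary)
                for name in order:
                    describe_source(name, table.column(name))
                resolved, recode.conflict_count = resolve_sources(
                    table.data[order], rule.source_preference, order
                )
                source_name = " | ".join(order)
            else:
                resolved = table.column(t.source_variable).astype("string")
                describe_source(t.source_variable, resolved)
                source_name = t.source_variable
            recode.rule_text = _map_rule_text(t, source_name)
            assigned = apply_category_map(
                resolved, t, spec.target_categories, rule.multi_select_priority
            )
        else:
            if t.mode_gate is not None:
                for src in t.mode_gate.sources.values():
                    for col in src.columns:
                        describe_source(col, table.column(col))
                duration = _gated_duration(table, t)
                source_name = t.mode_gate.mode_variable + " -> duration"
                recode.rule_text = (
                    f"Duration taken from the mode-specific item selected by "
                    f"[{t.mode_gate.mode_variable}] "
                    f"({', '.join(t.mode_gate.sources)}); other modes -> {MISSING}. "
                ) + _bin_rule_text(t, "duration")
            else:
                duration = pd.to_numeric(table.column(t.source_variable), errors="coerce")
                raw = table.column(t.source_variable)
                nonnum = raw.notna() & duration.isna()
                if nonnum.any():
                    raise TransformError(
                        f"non-numeric duration values "
                        f"{raw[nonnum].unique().tolist()[:5]}"
                    )
                describe_source(t.source_variable, raw)
                recode.rule_text = _bin_rule_text(t, t.source_variable)
            assigned = apply_threshold_bins(duration, t)
        if rule.inference is not None:
            assigned, recode.inference_count = apply_inference(
                table.data[list(rule.inference.variables)], rule.inference, assigned
            )
    except TransformError as exc:
        raise TransformError(
            f"{spec.name} ({table.study_id}, wave {table.wave}): {exc}"
        ) from None
    return assigned


def _selector_columns(
    pref: SourcePreferenceRule,
    table: StudyWaveTable,
    dictionary: DataDictionary | None,
) -> list[str]:
    """Resolve selectors (by name and/or respondent) to concrete columns."""
    cols: list[str] = []
    for sel in pref.selectors:
        if sel.variable is not None:
            if sel.variable not in cols:
                cols.append(sel.variable)
            continue
        if dictionary is None:
            raise SpecError("respondent-only selectors need a dictionary")
        matches = [
            e.name
            for e in dictionary.entries
            if e.study_id == table.study_id
            and e.respondent == sel.respondent
            and e.name in table.data.columns
        ]
        if not matches:
            raise SpecError(
                f"no {sel.respondent}-reported column for {table.study_id!r} "
                f"wave {table.wave}"
            )
        for m in matches:
            if m not in cols:
                cols.append(m)
    return cols


# ---------------------------------------------------------------------------
# Pooling and tabulation
# ---------------------------------------------------------------------------


@dataclass
class HarmonisedDataset:
    """Pooled long table of harmonised assignments, with spec provenance."""

    records: pd.DataFrame
    spec_name: str
    target_categories: tuple[str, ...]
    spec_hash: str = ""

    @property
    def n(self) -> int:
        return len(self.records)


def pool(
    fragments: Iterable[pd.DataFrame],
    spec: HarmonisationSpec,
) -> HarmonisedDataset:
    """Append study-wave fragments into one harmonised dataset.

    Excluded waves contribute nothing (they are absent, not present-as-
    missing). Duplicate ``(study_id, wave, participant_id, variable)`` keys
    are an integrity error. Output is canonically sorted, so pooling is
    invariant to input row and fragment order.
    """
    frames = [f for f in fragments if len(f)]
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=list(HARMONISED_COLUMNS))
    records = records[list(HARMONISED_COLUMNS)]
    key = ["study_id", "wave", "participant_id", "variable"]
    dup = records.duplicated(subset=key)
    if dup.any():
        offenders = records.loc[dup, key].head(5).to_dict("records")
        raise IntegrityError(f"duplicate harmonised records: {offenders}")
    bad_var = set(records["variable"].unique()) - {spec.name}
    if bad_var:
        raise IntegrityError(
            f"fragments for {sorted(bad_var)} pooled into {spec.name!r}"
        )
    records = records.sort_values(key, kind="mergesort", ignore_index=True)
    return HarmonisedDataset(
        records=records,
        spec_name=spec.name,
        target_categories=spec.target_categories,
        spec_hash=spec.content_hash(),
    )


@dataclass
class CategoryTabulation:
    """Counts per target category, per study-wave and overall."""

    variable: str
    categories: tuple[str, ...]
    per_study_wave: pd.DataFrame  # index (study_id, wave), one column per category + n
    overall: dict[str, int]
    n: int

    def counts(self, study_id: str, wave: int) -> dict[str, int]:
        row = self.per_study_wave.loc[(study_id, wave)]
        return {c: int(row[c]) for c in self.categories}


def tabulate(ds: HarmonisedDataset, variable: str | None = None) -> CategoryTabulation:
    """Tabulate a harmonised dataset per study-wave and overall.

    Category columns follow the spec's target-category order, so reports are
    stable and diffable. Conservation (per-cell counts summing to the
    study-wave's n) holds by construction and is re-asserted here.
    """
    variable = variable or ds.spec_name
    if variable != ds.spec_name:
        raise IntegrityError(f"dataset holds {ds.spec_name!r}, not {variable!r}")
    cats = list(ds.target_categories)
    records = ds.records
    if records.empty:
        idx = pd.MultiIndex.from_arrays([[], []], names=["study_id", "wave"])
        empty = pd.DataFrame(columns=cats + ["n"], index=idx)
        return CategoryTabulation(variable, tuple(cats), empty, {c: 0 for c in cats}, 0)
    grouped = (
        records.groupby(["study_id", "wave"])["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=cats, fill_value=0)
    )
    grouped["n"] = grouped[cats].sum(axis=1)
    sizes = records.groupby(["study_id", "wave"]).size()
    if not (grouped["n"] == sizes).all():
        raise IntegrityError(f"{variable}: category counts do not sum to n")
    overall = {c: int(grouped[c].sum()) for c in cats}
    return CategoryTabulation(
        variable=variable,
        categories=tuple(cats),
        per_study_wave=grouped,
        overall=overall,
        n=int(sizes.sum()),
    )


# ---------------------------------------------------------------------------
# Coverage summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageRow:
    """Per harmonised variable: how many studies and waves contribute.

    ``wave_histogram`` maps k → number of studies contributing exactly k
    waves; ``total_waves`` is Σ k·n_k.
    """

    variable: str
    n_studies: int
    wave_histogram: dict[int, int]
    total_waves: int


def coverage_summary(
    registry: Mapping[str, Iterable[tuple[str, int]]],
) -> list[CoverageRow]:
    """Summarise study/wave coverage for each harmonised variable.

    ``registry`` maps each variable name to its included ``(study_id, wave)``
    pairs (e.g. ``spec.included_study_waves()``).
    """
    rows = []
    for variable, pairs in registry.items():
        per_study: dict[str, set[int]] = {}
        for study_id, wave in pairs:
            per_study.setdefault(study_id, set()).add(wave)
        hist: dict[int, int] = {}
        for waves in per_study.values():
            hist[len(waves)] = hist.get(len(waves), 0) + 1
        rows.append(
            CoverageRow(
                variable=variable,
                n_studies=len(per_study),
                wave_histogram=dict(sorted(hist.items())),
                total_waves=sum(k * n for k, n in hist.items()),
            )
        )
    return rows


def write_harmonised_csv(ds: HarmonisedDataset, path: str | Path) -> None:
    """Write the canonical long-format CSV (sorted, LF, UTF-8)."""
    Path(path).write_bytes(harmonised_csv_bytes(ds))


def harmonised_csv_bytes(ds: HarmonisedDataset) -> bytes:
    records = ds.records.sort_values(
        ["study_id", "wave", "participant_id", "variable"],
        kind="mergesort",
        ignore_index=True,
    )
    return records.to_csv(index=False, lineterminator="\n").encode("utf-8")


def wide_export(datasets: Iterable[HarmonisedDataset]) -> pd.DataFrame:
    """Optional wide export: one column per harmonised variable per wave."""
    frames = [ds.records for ds in datasets if len(ds.records)]
    if not frames:
        return pd.DataFrame(columns=["study_id", "participant_id"])
    long = pd.concat(frames, ignore_index=True)
    long["column"] = "W" + long["wave"].astype(int).astype(str) + "_" + long["variable"]
    wide = long.pivot_table(
        index=["study_id", "participant_id"],
        columns="column",
        values="category",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    return wide.sort_values(["study_id", "participant_id"], ignore_index=True)
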