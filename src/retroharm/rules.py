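"""The declarative harmonisation rule language.

A *harmonisation spec* is the full recipe for one harmonised variable: its
target categories (always including a reserved ``Missing``) and, for every
contributing study-wave, exactly one of

* a **category map** — collapse of the study's source categories onto the
  target categories (e.g. ``Bicycle``/``On foot`` → ``Active mode of travel``);
* a **threshold-bin rule** — cut points turning a continuous duration (in
  minutes) into ordered categories, covering ``[0, ∞)`` without gaps or
  overlaps;
* a reasoned **wave exclusion** — the study-wave's instrument could not be
  matched to the target categories (the reason is mandatory and is carried
  into the provenance report).

A rule may additionally carry

* a **source preference** — an ordered list of candidate sources (e.g. prefer
  the parent-reported item over the child-reported one, or the to-school item
  over the from-school item), resolved to one value per participant before
  the transform runs;
* an **inference rule** — walk/cycle-only questionnaires never ask about
  motorised modes, so a participant answering "no" to every active-mode
  indicator is inferred to use a non-active mode rather than left Missing;
* a **mode gate** (threshold bins only) — the duration source depends on the
  reported mode, e.g. take the walking-duration item for participants who
  walk and the cycling item for those who cycle, Missing otherwise.

Specs are written as YAML (JSON, being a YAML subset, is accepted) and are
validated structurally and against a loaded data dictionary: every source
variable must exist with a compatible format, and every mapped source label
must be among the variable's declared categories. The file layout is
documented in ``data/spec.schema.json``, which ships with the package; the
validator in this module enforces the same contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .dictionary import (
    DataDictionary,
    VariableEntry,
    normalise_label,
    study_waves_in_group,
)
from .errors import SpecError

__all__ = [
    "CategoryMapRule",
    "ThresholdBinRule",
    "Bin",
    "SourceSelector",
    "SourcePreferenceRule",
    "InferenceRule",
    "ModeGate",
    "DurationSource",
    "WaveExclusion",
    "StudyWaveRule",
    "HarmonisationSpec",
    "Finding",
    "parse_spec",
    "parse_spec_dict",
    "serialize_spec",
    "validate_coverage",
    "MISSING",
]

#: Reserved target category for missing responses.
MISSING = "Missing"

UNMAPPED_POLICIES = ("error", "missing")
CONFLICT_POLICIES = ("prefer_first", "missing_if_conflict")


# ---------------------------------------------------------------------------
# Rule types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryMapRule:
    """Collapse source categories onto target categories.

    ``unmapped_policy`` controls what happens when a non-missing source value
    has no mapping: ``"error"`` (default — silent missingness hides recode
    gaps) raises at transform time, ``"missing"`` assigns ``Missing``.
    """

    source_variable: str | None
    mapping: Mapping[str, str]
    unmapped_policy: str = "error"

    def __post_init__(self) -> None:
        if self.unmapped_policy not in UNMAPPED_POLICIES:
            raise SpecError(
                f"unmapped_policy {self.unmapped_policy!r} not in {UNMAPPED_POLICIES}"
            )


@dataclass(frozen=True)
class Bin:
    """One interval of a threshold-bin rule.

    ``lower is None`` means the bin starts at 0 (inclusive); ``upper is None``
    means it extends to +∞. The default convention is right-closed intervals,
    ``(lower, upper]``, matching cut points phrased as "<= 5", "6–15
    (inclusive)", "> 15" for integer minutes while staying total on the reals.
    """

    lower: float | None
    upper: float | None
    label: str
    lower_inclusive: bool = False
    upper_inclusive: bool = True

    def accepts(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (value == self.lower and not self.lower_inclusive):
                return False
        elif value < 0:
            return False
        if self.upper is not None:
            if value > self.upper or (value == self.upper and not self.upper_inclusive):
                return False
        return True


@dataclass(frozen=True)
class DurationSource:
    """Where a duration value comes from: one column, or an hours+minutes pair.

    With a pair, the value is ``60*hours + minutes``; a missing half counts as
    0 and the result is missing only when both halves are missing.
    """

    variable: str | None = None
    hours: str | None = None
    minutes: str | None = None

    def __post_init__(self) -> None:
        if self.variable is None and (self.hours is None or self.minutes is None):
            raise SpecError("duration source needs a variable or an hours+minutes pair")
        if self.variable is not None and (self.hours or self.minutes):
            raise SpecError("duration source is either one variable or a pair, not both")

    @property
    def columns(self) -> tuple[str, ...]:
        if self.variable is not None:
            return (self.variable,)
        return (self.hours, self.minutes)  # type: ignore[return-value]


@dataclass(frozen=True)
class ModeGate:
    """Select the duration source per participant from the reported mode.

    Modes not listed in ``sources`` (e.g. bus/car where the questionnaire only
    itemised walking and cycling durations) yield ``Missing``, as does a
    missing mode.
    """

    mode_variable: str
    sources: Mapping[str, DurationSource]


@dataclass(frozen=True)
class ThresholdBinRule:
    """Ordered bins that partition ``[0, +∞)``; values land in exactly one.

    Negative values are a validation error at transform time, not Missing —
    a negative duration indicates upstream corruption.
    """

    source_variable: str | None
    bins: tuple[Bin, ...]
    mode_gate: ModeGate | None = None

    def __post_init__(self) -> None:
        self.validate_partition()
        if self.source_variable is None and self.mode_gate is None:
            raise SpecError("threshold_bin rule needs a source_variable or a mode_gate")

    def validate_partition(self) -> None:
        bins = self.bins
        if not bins:
            raise SpecError("threshold_bin rule has no bins")
        if bins[0].lower is not None and (
            bins[0].lower > 0 or (bins[0].lower == 0 and not bins[0].lower_inclusive)
        ):
            raise SpecError("first bin must cover 0")
        if bins[-1].upper is not None:
            raise SpecError("last bin must be unbounded above (cover +inf)")
        bounds = []
        for i, b in enumerate(bins):
            if b.lower is not None and b.upper is not None and b.lower >= b.upper:
                raise SpecError(f"bin {b.label!r}: lower bound not below upper bound")
            if i < len(bins) - 1:
                if b.upper is None:
                    raise SpecError(f"bin {b.label!r}: only the last bin may be unbounded")
                bounds.append(b.upper)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise SpecError(f"bin bounds must be strictly increasing, got {bounds}")
        for left, right in zip(bins, bins[1:]):
            if right.lower is None or left.upper != right.lower:
                raise SpecError(
                    f"bins {left.label!r} and {right.label!r} are not adjacent"
                )
            if left.upper_inclusive and right.lower_inclusive:
                raise SpecError(
                    f"bins {left.label!r} and {right.label!r} overlap at {left.upper}"
                )
            if not left.upper_inclusive and not right.lower_inclusive:
                raise SpecError(
                    f"bins {left.label!r} and {right.label!r} leave a gap at {left.upper}"
                )

    def assign(self, value: float) -> str:
        for b in self.bins:
            if b.accepts(value):
                return b.label
        raise SpecError(f"value {value} not covered by any bin")  # pragma: no cover


@dataclass(frozen=True)
class SourceSelector:
    """One candidate source: a variable name, a respondent, or both."""

    variable: str | None = None
    respondent: str | None = None

    def __post_init__(self) -> None:
        if self.variable is None and self.respondent is None:
            raise SpecError("source selector needs a variable and/or a respondent")


@dataclass(frozen=True)
class SourcePreferenceRule:
    """Ordered source preference (e.g. parent report before child report).

    ``conflict_policy`` governs rows where two sources are simultaneously
    present and disagree: ``prefer_first`` (default) keeps the preferred
    source's value, ``missing_if_conflict`` sets the row to Missing. Conflicts
    are counted either way and surfaced in the provenance report.
    """

    selectors: tuple[SourceSelector, ...]
    conflict_policy: str = "prefer_first"

    def __post_init__(self) -> None:
        if not self.selectors:
            raise SpecError("source preference needs at least one selector")
        if len(set(self.selectors)) != len(self.selectors):
            raise SpecError("source preference selectors must be distinct")
        if self.conflict_policy not in CONFLICT_POLICIES:
            raise SpecError(
                f"conflict_policy {self.conflict_policy!r} not in {CONFLICT_POLICIES}"
            )


@dataclass(frozen=True)
class InferenceRule:
    """Reassign Missing rows whose indicator responses rule out active modes.

    A row still Missing after the main transform is reassigned to
    ``inferred_category`` when every listed indicator variable is present and
    takes one of ``negative_values``. Rows with any indicator missing stay
    Missing — absence of a response is not evidence of a non-active mode.
    """

    variables: tuple[str, ...]
    inferred_category: str
    negative_values: tuple[str, ...] = ("0", "No", "no", "Never")

    def __post_init__(self) -> None:
        if not self.variables:
            raise SpecError("inference rule needs at least one indicator variable")


@dataclass(frozen=True)
class WaveExclusion:
    """A study-wave left out of the harmonised variable, with justification."""

    study_id: str
    wave: int
    reason: str

    def __post_init__(self) -> None:
        if not self.reason or not self.reason.strip():
            raise SpecError(
                f"exclusion of ({self.study_id}, wave {self.wave}) needs a reason"
            )


@dataclass(frozen=True)
class StudyWaveRule:
    """The complete recipe for one included study-wave."""

    study_id: str
    wave: int
    transform: CategoryMapRule | ThresholdBinRule
    source_preference: SourcePreferenceRule | None = None
    inference: InferenceRule | None = None
    multi_select_priority: tuple[str, ...] | None = None


@dataclass(frozen=True)
class HarmonisationSpec:
    """One harmonised variable's full recipe across all study-waves."""

    name: str
    description: str
    target_categories: tuple[str, ...]
    rules: tuple[StudyWaveRule, ...] = ()
    exclusions: tuple[WaveExclusion, ...] = ()
    variable_group: str | None = None

    def __post_init__(self) -> None:
        if MISSING not in self.target_categories:
            raise SpecError(f"{self.name}: target_categories must include {MISSING!r}")
        if len(set(self.target_categories)) != len(self.target_categories):
            raise SpecError(f"{self.name}: target_categories must be distinct")
        # Duplicates within either list are construction errors; a study-wave
        # that is both transformed and excluded is reported as a coverage
        # finding instead, so audits can surface it rather than crash.
        for items, what in ((self.rules, "rule"), (self.exclusions, "exclusion")):
            seen: set[tuple[str, int]] = set()
            for item in items:
                key = (item.study_id, item.wave)
                if key in seen:
                    raise SpecError(
                        f"{self.name}: study-wave {key} has more than one {what}"
                    )
                seen.add(key)

    def rule_for(self, study_id: str, wave: int) -> StudyWaveRule | None:
        for r in self.rules:
            if (r.study_id, r.wave) == (study_id, wave):
                return r
        return None

    def exclusion_for(self, study_id: str, wave: int) -> WaveExclusion | None:
        for x in self.exclusions:
            if (x.study_id, x.wave) == (study_id, wave):
                return x
        return None

    def included_study_waves(self) -> list[tuple[str, int]]:
        return [(r.study_id, r.wave) for r in self.rules]

    def content_hash(self) -> str:
        """Stable hash of the canonical serialisation; versions the spec."""
        return hashlib.sha256(serialize_spec(self).encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _require(data: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in data:
        raise SpecError(f"{where}: missing required key {key!r}")
    return data[key]


def _norm_map(raw: Mapping[str, str], where: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for k, v in raw.items():
        nk = normalise_label(str(k))
        if nk in out:
            raise SpecError(f"{where}: duplicate mapping key {nk!r}")
        out[nk] = normalise_label(str(v))
    return out


def _parse_bins(raw: Any, where: str) -> tuple[Bin, ...]:
    if not isinstance(raw, list):
        raise SpecError(f"{where}: bins must be a list")
    bins = []
    for item in raw:
        if not isinstance(item, Mapping) or "label" not in item:
            raise SpecError(f"{where}: each bin needs at least a label")
        bins.append(
            Bin(
                lower=None if item.get("lower") is None else float(item["lower"]),
                upper=None if item.get("upper") is None else float(item["upper"]),
                label=normalise_label(str(item["label"])),
                lower_inclusive=bool(item.get("lower_inclusive", False)),
                upper_inclusive=bool(item.get("upper_inclusive", True)),
            )
        )
    return tuple(bins)


def _parse_duration_source(raw: Any, where: str) -> DurationSource:
    if isinstance(raw, str):
        return DurationSource(variable=raw)
    if isinstance(raw, Mapping):
        return DurationSource(
            variable=raw.get("variable"),
            hours=raw.get("hours"),
            minutes=raw.get("minutes"),
        )
    raise SpecError(f"{where}: duration source must be a name or an hours/minutes pair")


def _check_source_variable(
    dictionary: DataDictionary,
    study_id: str,
    name: str,
    expected_format: str,
    where: str,
) -> VariableEntry:
    entry = dictionary.get(study_id, name)
    if entry is None:
        known = sorted(e.name for e in dictionary.entries if e.study_id == study_id)
        raise SpecError(
            f"{where}: source variable {name!r} not in the dictionary for study "
            f"{study_id!r} (known: {known})"
        )
    if entry.format != expected_format:
        raise SpecError(
            f"{where}: source variable {name!r} has format {entry.format!r}, "
            f"expected {expected_format!r}"
        )
    return entry


def _parse_rule_item(
    item: Mapping[str, Any],
    targets: tuple[str, ...],
    dictionary: DataDictionary | None,
    where: str,
) -> StudyWaveRule | WaveExclusion:
    study_id = str(_require(item, "study_id", where))
    wave = int(_require(item, "wave", where))
    kind = str(_require(item, "kind", where))
    where = f"{where} ({study_id}, wave {wave})"

    if kind == "exclusion":
        return WaveExclusion(study_id=study_id, wave=wave, reason=str(item.get("reason", "")))

    # Optional attachments shared by the two transform kinds.
    source_pref = None
    if "source_preference" in item:
        sp = item["source_preference"]
        selectors = tuple(
            SourceSelector(variable=s.get("variable"), respondent=s.get("respondent"))
            for s in _require(sp, "selectors", where)
        )
        source_pref = SourcePreferenceRule(
            selectors=selectors,
            conflict_policy=str(sp.get("conflict_policy", "prefer_first")),
        )
    inference = None
    if "inference" in item:
        inf = item["inference"]
        inference = InferenceRule(
            variables=tuple(str(v) for v in _require(inf, "variables", where)),
            inferred_category=normalise_label(str(_require(inf, "inferred_category", where))),
            negative_values=tuple(
                str(v) for v in inf.get("negative_values", InferenceRule.negative_values)
            ),
        )

    if kind == "category_map":
        mapping = _norm_map(_require(item, "mapping", where), where)
        transform: CategoryMapRule | ThresholdBinRule = CategoryMapRule(
            source_variable=item.get("source_variable"),
            mapping=mapping,
            unmapped_policy=str(item.get("unmapped_policy", "error")),
        )
        if transform.source_variable is None and source_pref is None:
            raise SpecError(f"{where}: category_map needs a source_variable")
    elif kind == "threshold_bin":
        gate = None
        if "mode_gate" in item:
            mg = item["mode_gate"]
            gate = ModeGate(
                mode_variable=str(_require(mg, "mode_variable", where)),
                sources={
                    normalise_label(str(k)): _parse_duration_source(v, where)
                    for k, v in _require(mg, "sources", where).items()
                },
            )
        transform = ThresholdBinRule(
            source_variable=item.get("source_variable"),
            bins=_parse_bins(_require(item, "bins", where), where),
            mode_gate=gate,
        )
    else:
        raise SpecError(
            f"{where}: kind {kind!r} not one of ('category_map', 'threshold_bin', "
            "'exclusion')"
        )

    rule = StudyWaveRule(
        study_id=study_id,
        wave=wave,
        transform=transform,
        source_preference=source_pref,
        inference=inference,
        multi_select_priority=(
            tuple(normalise_label(str(c)) for c in item["multi_select_priority"])
            if "multi_select_priority" in item
            else None
        ),
    )
    _validate_rule_semantics(rule, targets, dictionary, where)
    return rule


def _validate_rule_semantics(
    rule: StudyWaveRule,
    targets: tuple[str, ...],
    dictionary: DataDictionary | None,
    where: str,
) -> None:
    t = rule.transform
    if isinstance(t, CategoryMapRule):
        bad_targets = sorted(set(t.mapping.values()) - set(targets))
        if bad_targets:
            raise SpecError(
                f"{where}: mapping values {bad_targets} are not declared target "
                f"categories {list(targets)}"
            )
    else:
        bad_labels = sorted({b.label for b in t.bins} - set(targets))
        if bad_labels:
            raise SpecError(
                f"{where}: bin labels {bad_labels} are not declared target categories"
            )
    if rule.inference is not None and rule.inference.inferred_category not in targets:
        raise SpecError(
            f"{where}: inferred category {rule.inference.inferred_category!r} is not a "
            "declared target category"
        )
    if rule.multi_select_priority is not None:
        bad = sorted(set(rule.multi_select_priority) - set(targets))
        if bad:
            raise SpecError(f"{where}: multi_select_priority entries {bad} not in targets")

    if dictionary is None:
        return

    def check_categorical(name: str) -> VariableEntry:
        return _check_source_variable(dictionary, rule.study_id, name, "categorical", where)

    def check_continuous(name: str) -> VariableEntry:
        return _check_source_variable(dictionary, rule.study_id, name, "continuous", where)

    if isinstance(t, CategoryMapRule):
        sources = []
        if t.source_variable is not None:
            sources.append(t.source_variable)
        if rule.source_preference is not None:
            sources.extend(
                s.variable for s in rule.source_preference.selectors if s.variable
            )
        declared: set[str] = set()
        for name in sources:
            declared.update(check_categorical(name).categories)
        unknown = sorted(set(t.mapping) - declared)
        if unknown:
            raise SpecError(
                f"{where}: mapping keys {unknown} are not declared categories of "
                f"{sources} (candidates: {sorted(declared)})"
            )
    else:
        if t.source_variable is not None:
            check_continuous(t.source_variable)
        if t.mode_gate is not None:
            mode_entry = check_categorical(t.mode_gate.mode_variable)
            unknown = sorted(set(t.mode_gate.sources) - set(mode_entry.categories))
            if unknown:
                raise SpecError(
                    f"{where}: mode_gate modes {unknown} are not declared categories "
                    f"of {t.mode_gate.mode_variable!r}"
                )
            for src in t.mode_gate.sources.values():
                for col in src.columns:
                    check_continuous(col)
    if rule.inference is not None:
        for name in rule.inference.variables:
            if dictionary.get(rule.study_id, name) is None:
                raise SpecError(
                    f"{where}: inference indicator {name!r} not in the dictionary "
                    f"for study {rule.study_id!r}"
                )


def parse_spec_dict(
    data: Mapping[str, Any],
    dictionary: DataDictionary | None = None,
    source: str = "<spec>",
) -> HarmonisationSpec:
    """Validate a parsed YAML/JSON document into a :class:`HarmonisationSpec`.

    With a ``dictionary``, semantic checks run too: source variables must
    exist with a compatible format and mapping keys must be declared
    categories. Without one, only structural validation applies.
    """
    if not isinstance(data, Mapping):
        raise SpecError(f"{source}: spec document must be a mapping")
    name = str(_require(data, "name", source))
    targets = tuple(
        normalise_label(str(c)) for c in _require(data, "target_categories", source)
    )
    raw_rules = _require(data, "rules", source)
    if not isinstance(raw_rules, list):
        raise SpecError(f"{source}: rules must be a list")
    rules: list[StudyWaveRule] = []
    exclusions: list[WaveExclusion] = []
    for i, item in enumerate(raw_rules):
        parsed = _parse_rule_item(item, targets, dictionary, f"{source}: rules[{i}]")
        if isinstance(parsed, WaveExclusion):
            exclusions.append(parsed)
        else:
            rules.append(parsed)
    return HarmonisationSpec(
        name=name,
        description=str(data.get("description", "")),
        target_categories=targets,
        rules=tuple(rules),
        exclusions=tuple(exclusions),
        variable_group=data.get("variable_group"),
    )


def parse_spec(path: str | Path, dictionary: DataDictionary | None = None) -> HarmonisationSpec:
    """Load a spec file (YAML or JSON) and validate it against a dictionary."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return parse_spec_dict(data, dictionary, source=str(path))


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _duration_source_to_obj(src: DurationSource) -> Any:
    if src.variable is not None:
        return src.variable
    return {"hours": src.hours, "minutes": src.minutes}


def spec_to_dict(spec: HarmonisationSpec) -> dict[str, Any]:
    """Canonical plain-data form of a spec (the inverse of parsing)."""
    items: list[dict[str, Any]] = []
    for r in spec.rules:
        item: dict[str, Any] = {"study_id": r.study_id, "wave": r.wave}
        t = r.transform
        if isinstance(t, CategoryMapRule):
            item["kind"] = "category_map"
            if t.source_variable is not None:
                item["source_variable"] = t.source_variable
            item["mapping"] = dict(t.mapping)
            if t.unmapped_policy != "error":
                item["unmapped_policy"] = t.unmapped_policy
        else:
            item["kind"] = "threshold_bin"
            if t.source_variable is not None:
                item["source_variable"] = t.source_variable
            item["bins"] = [
                {
                    k: v
                    for k, v in (
                        ("lower", b.lower),
                        ("upper", b.upper),
                        ("label", b.label),
                    )
                    if v is not None
                }
                for b in t.bins
            ]
            if t.mode_gate is not None:
                item["mode_gate"] = {
                    "mode_variable": t.mode_gate.mode_variable,
                    "sources": {
                        k: _duration_source_to_obj(v)
                        for k, v in t.mode_gate.sources.items()
                    },
                }
        if r.source_preference is not None:
            item["source_preference"] = {
                "selectors": [
                    {
                        k: v
                        for k, v in (("variable", s.variable), ("respondent", s.respondent))
                        if v is not None
                    }
                    for s in r.source_preference.selectors
                ],
                "conflict_policy": r.source_preference.conflict_policy,
            }
        if r.inference is not None:
            item["inference"] = {
                "variables": list(r.inference.variables),
                "inferred_category": r.inference.inferred_category,
                "negative_values": list(r.inference.negative_values),
            }
        if r.multi_select_priority is not None:
            item["multi_select_priority"] = list(r.multi_select_priority)
        items.append(item)
    for x in spec.exclusions:
        items.append(
            {"study_id": x.study_id, "wave": x.wave, "kind": "exclusion", "reason": x.reason}
        )
    out: dict[str, Any] = {
        "name": spec.name,
        "description": spec.description,
        "target_categories": list(spec.target_categories),
        "rules": items,
    }
    if spec.variable_group is not None:
        out["variable_group"] = spec.variable_group
    return out


def serialize_spec(spec: HarmonisationSpec) -> str:
    """Canonical YAML serialisation; ``parse(serialize(s))`` equals ``s``."""
    return yaml.safe_dump(spec_to_dict(spec), sort_keys=False, allow_unicode=True)


def specs_content_hash(specs: Iterable[HarmonisationSpec]) -> str:
    """Joint content hash of several specs, order-insensitive by spec name."""
    digest = hashlib.sha256()
    for spec in sorted(specs, key=lambda s: s.name):
        digest.update(serialize_spec(spec).encode("utf-8"))
    return digest.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Coverage validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    """One coverage problem reported by :func:`validate_coverage`."""

    kind: str  # uncovered_study_wave | unmapped_category | rule_for_excluded_wave
    study_id: str
    wave: int
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.study_id} wave {self.wave}: {self.detail}"


def validate_coverage(
    spec: HarmonisationSpec,
    dictionary: DataDictionary,
    variable_group: str | None = None,
) -> list[Finding]:
    """Audit a spec against a dictionary; returns findings, never raises.

    Findings enumerate (a) study-waves carrying the construct's variable group
    in the dictionary but given neither a rule nor an exclusion, (b) declared
    source categories a ``unmapped_policy="error"`` map would reject, and
    (c) rules that reference study-waves the same spec excludes.
    """
    group = variable_group or spec.variable_group
    findings: list[Finding] = []
    covered = {(r.study_id, r.wave) for r in spec.rules} | {
        (x.study_id, x.wave) for x in spec.exclusions
    }
    if group is not None:
        for study_id, wave in study_waves_in_group(dictionary, group):
            if (study_id, wave) not in covered:
                findings.append(
                    Finding(
                        "uncovered_study_wave",
                        study_id,
                        wave,
                        f"variable group {group!r} has data here but the spec "
                        f"{spec.name!r} gives neither a rule nor an exclusion",
                    )
                )
    for r in spec.rules:
        t = r.transform
        if isinstance(t, CategoryMapRule) and t.unmapped_policy == "error":
            sources = []
            if t.source_variable is not None:
                sources.append(t.source_variable)
            if r.source_preference is not None:
                sources.extend(s.variable for s in r.source_preference.selectors if s.variable)
            for name in sources:
                entry = dictionary.get(r.study_id, name)
                if entry is None:
                    continue
                unmapped = [c for c in entry.categories if c not in t.mapping]
                if unmapped:
                    findings.append(
                        Finding(
                            "unmapped_category",
                            r.study_id,
                            r.wave,
                            f"categories {unmapped} of {name!r} have no mapping and "
                            "unmapped_policy is 'error'",
                        )
                    )
        if spec.exclusion_for(r.study_id, r.wave) is not None:
            findings.append(
                Finding(
                    "rule_for_excluded_wave",
                    r.study_id,
                    r.wave,
                    f"spec {spec.name!r} both transforms and excludes this study-wave",
                )
            )
    return findings
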