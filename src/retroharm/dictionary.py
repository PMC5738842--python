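"""Per-study data dictionaries with uniform variable-group tagging.

Pooling questionnaire data across studies starts from a catalogue: every
column of every study's wide master file gets one dictionary entry recording
its name, label, description, unit, format and — crucially — a *variable
group*, a construct-level tag (e.g. ``School_travel``) applied with the same
vocabulary across all studies. Querying a group returns every variable, from
any study, that measures that construct; this is the starting point of each
harmonisation exercise.

Conventions
-----------
* Wide master files prefix column names with the wave of assessment:
  ``W1_X`` is variable ``X`` at wave 1, ``W2_X`` at wave 2, and so on.
  Unprefixed names are time-invariant unless the dictionary assigns a wave
  explicitly (some instruments keep their original native names).
* The dictionary itself is a CSV with the fixed header
  ``study_id,variable_id,name,label,description,unit,format,categories,variable_group,wave,respondent``.
  Empty fields mean "not applicable"/null. Category labels of categorical
  variables are stored as a ``;``-delimited ordered list (labels must not
  contain ``;``).
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, IntegrityError

__all__ = [
    "VariableEntry",
    "DataDictionary",
    "read_dictionary",
    "write_dictionary",
    "query_by_group",
    "catalogue_study",
    "parse_wave_prefix",
    "normalise_label",
    "DICTIONARY_COLUMNS",
    "FORMATS",
    "RESPONDENTS",
]

DICTIONARY_COLUMNS = (
    "study_id",
    "variable_id",
    "name",
    "label",
    "description",
    "unit",
    "format",
    "categories",
    "variable_group",
    "wave",
    "respondent",
)

FORMATS = frozenset({"continuous", "categorical", "free_text", "date"})
RESPONDENTS = frozenset({"child", "parent", "teacher", "objective", "unknown"})

#: Wave prefix convention: ``W<digits>_`` at the start of a column name.
WAVE_PREFIX_RE = re.compile(r"^W(\d+)_")


def normalise_label(label: str) -> str:
    """Canonical form used for all category-label comparisons.

    Unicode NFC normalisation plus whitespace trimming. Matching is otherwise
    exact and case-sensitive: translated instruments (German/French response
    options) are handled by mapping their verbatim labels, never by fuzzy
    matching, which risks silent miscoding.
    """
    return unicodedata.normalize("NFC", label).strip()


def parse_wave_prefix(name: str) -> int | None:
    """Return the wave encoded in a column name's ``W<k>_`` prefix, if any."""
    m = WAVE_PREFIX_RE.match(name)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class VariableEntry:
    """One dictionary row: the identity and metadata of a study variable.

    ``wave`` is ``None`` for time-invariant variables. ``respondent`` records
    who answered the instrument (child, parent, ...); source-preference rules
    depend on it. Categorical variables must declare their category labels in
    ``categories`` (ordered).
    """

    study_id: str
    variable_id: int
    name: str
    label: str
    description: str = ""
    unit: str = ""
    format: str = "free_text"
    categories: tuple[str, ...] = ()
    variable_group: str = ""
    wave: int | None = None
    respondent: str = "unknown"

    def __post_init__(self) -> None:
        if not self.study_id:
            raise IntegrityError("study_id must be non-empty")
        if not self.name:
            raise IntegrityError(f"{self.study_id}: variable name must be non-empty")
        if self.format not in FORMATS:
            raise FormatError(
                f"{self.study_id}/{self.name}: format {self.format!r} not one of "
                f"{sorted(FORMATS)}"
            )
        if self.respondent not in RESPONDENTS:
            raise FormatError(
                f"{self.study_id}/{self.name}: respondent {self.respondent!r} not one "
                f"of {sorted(RESPONDENTS)}"
            )
        if self.format == "categorical" and not self.categories:
            raise IntegrityError(
                f"{self.study_id}/{self.name}: categorical variable must declare its "
                "category labels"
            )
        if any(";" in c for c in self.categories):
            raise FormatError(
                f"{self.study_id}/{self.name}: category labels must not contain ';'"
            )
        if not self.variable_group or not self.variable_group.strip():
            raise IntegrityError(
                f"{self.study_id}/{self.name}: variable_group must be a non-empty token"
            )
        if self.wave is not None and self.wave < 1:
            raise IntegrityError(f"{self.study_id}/{self.name}: wave must be >= 1")
        prefix_wave = parse_wave_prefix(self.name)
        if self.wave is not None and prefix_wave is not None and prefix_wave != self.wave:
            raise IntegrityError(
                f"{self.study_id}/{self.name}: wave {self.wave} conflicts with the "
                f"name's W{prefix_wave}_ prefix"
            )


@dataclass
class DataDictionary:
    """An ordered collection of :class:`VariableEntry` spanning several studies.

    Uniqueness of ``(study_id, variable_id)`` and ``(study_id, name)`` is
    enforced on construction. Variable groups are a shared vocabulary:
    :meth:`query_by_group` returns matching entries from *any* study.
    """

    entries: list[VariableEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_unique("variable_id", lambda e: (e.study_id, e.variable_id))
        self._check_unique("name", lambda e: (e.study_id, e.name))

    def _check_unique(self, what, key) -> None:
        seen: dict = {}
        for e in self.entries:
            k = key(e)
            if k in seen:
                raise IntegrityError(
                    f"duplicate (study_id, {what}) {k!r}: variable_ids "
                    f"{seen[k].variable_id} and {e.variable_id}"
                )
            seen[k] = e

    @property
    def studies(self) -> set[str]:
        return {e.study_id for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, study_id: str, name: str) -> VariableEntry | None:
        for e in self.entries:
            if e.study_id == study_id and e.name == name:
                return e
        return None

    def require(self, study_id: str, name: str) -> VariableEntry:
        e = self.get(study_id, name)
        if e is None:
            raise IntegrityError(f"variable {name!r} not in dictionary for study {study_id!r}")
        return e

    def restrict_to_study(self, study_id: str) -> "DataDictionary":
        return DataDictionary([e for e in self.entries if e.study_id == study_id])

    def groups(self) -> list[str]:
        """Distinct variable groups, in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.variable_group, None)
        return list(seen)

    def lint_groups(self) -> list[str]:
        """Warnings for group tags that differ only by case.

        Case-only variants silently fragment a construct across studies, so
        the linter flags them; matching itself stays exact and case-sensitive.
        """
        by_fold: dict[str, set[str]] = {}
        for e in self.entries:
            by_fold.setdefault(e.variable_group.casefold(), set()).add(e.variable_group)
        return [
            f"variable groups differ only by case: {sorted(variants)}"
            for variants in by_fold.values()
            if len(variants) > 1
        ]


def query_by_group(dictionary: DataDictionary, group: str) -> list[VariableEntry]:
    """All entries tagged with ``group``, from any study.

    Matching is exact and case-sensitive. Results are ordered by
    ``(study_id, wave, variable_id)`` with time-invariant entries (null wave)
    first within a study. An unknown group returns an empty list.
    """
    hits = [e for e in dictionary.entries if e.variable_group == group]
    hits.sort(key=lambda e: (e.study_id, e.wave is not None, e.wave or 0, e.variable_id))
    return hits


def study_waves_in_group(dictionary: DataDictionary, group: str) -> list[tuple[str, int]]:
    """Distinct ``(study_id, wave)`` pairs covered by a variable group.

    Time-invariant entries carry no wave and do not contribute a pair.
    """
    pairs: dict[tuple[str, int], None] = {}
    for e in query_by_group(dictionary, group):
        if e.wave is not None:
            pairs.setdefault((e.study_id, e.wave), None)
    return list(pairs)


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------


def _entry_to_row(e: VariableEntry) -> list[str]:
    return [
        e.study_id,
        str(e.variable_id),
        e.name,
        e.label,
        e.description,
        e.unit,
        e.format,
        ";".join(e.categories),
        e.variable_group,
        "" if e.wave is None else str(e.wave),
        e.respondent,
    ]


def _row_to_entry(row: Mapping[str, str]) -> VariableEntry:
    try:
        variable_id = int(row["variable_id"])
    except ValueError as exc:
        raise FormatError(f"variable_id {row['variable_id']!r} is not an integer") from exc
    wave_raw = row["wave"].strip()
    if wave_raw:
        try:
            wave: int | None = int(wave_raw)
        except ValueError as exc:
            raise FormatError(f"wave {wave_raw!r} is not an integer") from exc
    else:
        wave = None
    categories = tuple(
        normalise_label(c) for c in row["categories"].split(";") if c.strip()
    )
    return VariableEntry(
        study_id=row["study_id"].strip(),
        variable_id=variable_id,
        name=row["name"].strip(),
        label=row["label"],
        description=row["description"],
        unit=row["unit"],
        format=row["format"].strip(),
        categories=categories,
        variable_group=row["variable_group"].strip(),
        wave=wave,
        respondent=row["respondent"].strip() or "unknown",
    )


def read_dictionary(path: str | Path) -> DataDictionary:
    """Load and validate a dictionary CSV.

    The header must be exactly the canonical column set (in order). Raises
    :class:`FormatError` for layout problems and :class:`IntegrityError` for
    duplicate ``(study_id, name)`` / ``(study_id, variable_id)`` pairs, naming
    the offending entries.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        if tuple(header) != DICTIONARY_COLUMNS:
            missing = set(DICTIONARY_COLUMNS) - set(header)
            extra = set(header) - set(DICTIONARY_COLUMNS)
            raise FormatError(
                f"{path}: header mismatch (missing: {sorted(missing)}, "
                f"unexpected: {sorted(extra)}, order must be canonical)"
            )
        entries = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or all(not cell.strip() for cell in raw):
                continue
            if len(raw) != len(DICTIONARY_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(DICTIONARY_COLUMNS)} fields")
            try:
                entries.append(_row_to_entry(dict(zip(DICTIONARY_COLUMNS, raw))))
            except (FormatError, IntegrityError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from None
    return DataDictionary(entries)


def dictionary_to_csv_bytes(dictionary: DataDictionary) -> bytes:
    """Canonical CSV serialisation (fixed column order, minimal quoting, LF)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(DICTIONARY_COLUMNS)
    for e in dictionary.entries:
        writer.writerow(_entry_to_row(e))
    return buf.getvalue().encode("utf-8")


def write_dictionary(dictionary: DataDictionary, path: str | Path) -> None:
    Path(path).write_bytes(dictionary_to_csv_bytes(dictionary))


# ---------------------------------------------------------------------------
# Cataloguing a study's master file
# ---------------------------------------------------------------------------


def catalogue_study(
    study_id: str,
    columns: Sequence[str],
    metadata: Mapping[str, Mapping[str, object]],
    start_variable_id: int = 1,
) -> DataDictionary:
    """Build dictionary entries for a study's columns from per-column annotations.

    ``metadata`` maps each column name to its annotations (``label``,
    ``description``, ``unit``, ``format``, ``categories``, ``variable_group``,
    ``respondent`` and optionally ``wave``). The wave is parsed from the
    column's ``W<k>_`` prefix when present; an explicit ``wave`` annotation may
    supply it for unprefixed native names, but must not conflict with a
    prefix. Variable ids are assigned sequentially in column order.
    """
    missing = [c for c in columns if c not in metadata]
    if missing:
        raise IntegrityError(f"{study_id}: no metadata for columns {missing}")
    entries = []
    for offset, name in enumerate(columns):
        meta = dict(metadata[name])
        prefix_wave = parse_wave_prefix(name)
        wave = meta.pop("wave", None)
        if wave is not None:
            wave = int(wave)  # type: ignore[arg-type]
        if prefix_wave is not None and wave is not None and wave != prefix_wave:
            raise IntegrityError(
                f"{study_id}/{name}: annotated wave {wave} conflicts with "
                f"W{prefix_wave}_ prefix"
            )
        categories = tuple(normalise_label(c) for c in meta.pop("categories", ()) or ())
        entries.append(
            VariableEntry(
                study_id=study_id,
                variable_id=start_variable_id + offset,
                name=name,
                label=str(meta.get("label", name)),
                description=str(meta.get("description", "")),
                unit=str(meta.get("unit", "")),
                format=str(meta.get("format", "free_text")),
                categories=categories,
                variable_group=str(meta.get("variable_group", "")),
                wave=wave if wave is not None else prefix_wave,
                respondent=str(meta.get("respondent", "unknown")),
            )
        )
    return DataDictionary(entries)


def merge_dictionaries(parts: Iterable[DataDictionary]) -> DataDictionary:
    """Concatenate per-study dictionaries into one pooled dictionary."""
    entries: list[VariableEntry] = []
    for part in parts:
        entries.extend(part.entries)
    return DataDictionary(entries)
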