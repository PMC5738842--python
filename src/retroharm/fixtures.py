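"""Synthetic multi-study data: a generic generator and the worked example.

Two things live here.

:func:`generate` turns declarative :class:`StudyBlueprint` descriptions into
study tables plus a matching data dictionary. Blueprints express the kinds of
heterogeneity real pooling projects meet — different instruments and category
schemes (possibly translated), different respondents, different wave counts,
per-variable missingness — and support *exact marginal* allocation: when a
blueprint pins category counts, the generated column reproduces them exactly
(deterministic allocation, seeded shuffle of row order), not approximately.

:func:`school_travel_fixture` is the packaged worked example: wave-1
school-travel data for three studies (SPEEDY, KISS, Ballabeina),
reconstructed from their published marginal counts, together with the
dictionary and three harmonisation specs (mode at two resolutions plus
journey duration). Where only summary statistics were published (the SPEEDY
and KISS duration items), value multisets are constructed to reproduce the
categorical marginals and threshold-bin counts exactly and the printed
quartiles to within a minute; individual values are synthetic. The fixture is
a pure function of its fixed internal seed, so regeneration is byte-identical
— frozen sha256 hashes of the canonical CSVs ship in
``data/fixture_hashes.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dictionary import (
    DataDictionary,
    catalogue_study,
    dictionary_to_csv_bytes,
    merge_dictionaries,
)
from .engine import StudyWaveTable
from .errors import SpecError
from .rules import HarmonisationSpec, parse_spec_dict

__all__ = [
    "VariableBlueprint",
    "StudyBlueprint",
    "GeneratorConfig",
    "generate",
    "load_generator_config",
    "school_travel_fixture",
    "school_travel_inclusion_registry",
    "write_fixture",
    "table_csv_bytes",
    "FixtureBundle",
]

#: Seed defining the packaged worked-example fixture (part of its identity).
FIXTURE_SEED = 20_171_220


# ---------------------------------------------------------------------------
# Generic blueprint-driven generator
# ---------------------------------------------------------------------------


@dataclass
class VariableBlueprint:
    """How to synthesise one variable of a study instrument."""

    name: str
    format: str = "categorical"
    label: str = ""
    description: str = ""
    unit: str = ""
    variable_group: str = ""
    categories: tuple[str, ...] = ()
    #: category → count, optionally including "Missing"; reproduced exactly.
    exact_marginals: dict[str, int] | None = None
    missing_rate: float = 0.0
    #: for continuous variables: target quantiles {0.25: q25, 0.5: median, ...}
    quantiles: dict[float, float] | None = None
    minimum: float = 0.0
    maximum: float = 60.0
    integer: bool = True

    def validate(self, n: int) -> None:
        if self.format == "categorical" and not self.categories:
            raise SpecError(f"{self.name}: categorical blueprint needs categories")
        if self.exact_marginals is not None:
            unknown = set(self.exact_marginals) - set(self.categories) - {"Missing"}
            if unknown:
                raise SpecError(
                    f"{self.name}: marginals for unknown categories {sorted(unknown)}"
                )
            total = sum(self.exact_marginals.values())
            if total != n:
                raise SpecError(
                    f"{self.name}: exact marginals (with missing) sum to {total}, "
                    f"but n = {n}"
                )


@dataclass
class StudyBlueprint:
    """One synthetic study: instrument, respondents, waves, sample size."""

    study_id: str
    n: int
    variables: list[VariableBlueprint]
    waves: int = 1
    #: respondent per wave (1-based); a single string applies to all waves.
    respondents: Mapping[int, str] | str = "unknown"
    #: prefix generated column names with W<wave>_ (False keeps native names
    #: and records the wave only in the dictionary, as some instruments do).
    prefix_names: bool = True

    def respondent_for(self, wave: int) -> str:
        if isinstance(self.respondents, str):
            return self.respondents
        return self.respondents.get(wave, "unknown")


@dataclass
class GeneratorConfig:
    blueprints: list[StudyBlueprint]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [b.study_id for b in self.blueprints]
        if len(set(ids)) != len(ids):
            raise SpecError(f"duplicate study ids in generator config: {ids}")


def _participant_ids(study_id: str, n: int) -> list[str]:
    return [f"{study_id}_{i:05d}" for i in range(1, n + 1)]


def _exact_column(marginals: Mapping[str, int], rng: np.random.Generator) -> np.ndarray:
    values: list[object] = []
    for category, count in marginals.items():
        values.extend([pd.NA if category == "Missing" else category] * count)
    arr = np.array(values, dtype=object)
    rng.shuffle(arr)
    return arr


def _quantile_column(bp: VariableBlueprint, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample through a piecewise-linear inverse CDF anchored at the targets."""
    qs = dict(sorted((bp.quantiles or {0.5: (bp.minimum + bp.maximum) / 2}).items()))
    probs = [0.0, *qs.keys(), 1.0]
    points = [bp.minimum, *qs.values(), bp.maximum]
    u = rng.random(n)
    vals = np.interp(u, probs, points)
    if bp.integer:
        vals = np.rint(vals)
    out = np.array(vals, dtype=object)
    if bp.missing_rate > 0:
        mask = rng.random(n) < bp.missing_rate
        out[mask] = pd.NA
    return out


def _random_categorical(bp: VariableBlueprint, n: int, rng: np.random.Generator) -> np.ndarray:
    out = rng.choice(np.array(bp.categories, dtype=object), size=n)
    if bp.missing_rate > 0:
        mask = rng.random(n) < bp.missing_rate
        out[mask] = pd.NA
    return out


def generate(config: GeneratorConfig) -> tuple[list[StudyWaveTable], DataDictionary]:
    """Synthesise study-wave tables and their dictionary from blueprints.

    Output is a pure function of the config (including its seed). Exact
    marginals are reproduced exactly; quantile-anchored continuous columns hit
    their targets approximately (to sampling error). Generated tables always
    validate against the generated dictionary.
    """
    tables: list[StudyWaveTable] = []
    dictionaries: list[DataDictionary] = []
    for study_index, bp in enumerate(config.blueprints):
        rng = np.random.default_rng([config.seed, study_index])
        columns: list[str] = []
        metadata: dict[str, dict] = {}
        wave_frames: dict[int, pd.DataFrame] = {}
        for wave in range(1, bp.waves + 1):
            data: dict[str, np.ndarray] = {}
            for vbp in bp.variables:
                vbp.validate(bp.n)
                name = f"W{wave}_{vbp.name}" if bp.prefix_names else vbp.name
                if not bp.prefix_names and wave > 1:
                    raise SpecError(
                        f"{bp.study_id}: unprefixed names cannot span multiple waves"
                    )
                if vbp.format == "categorical":
                    if vbp.exact_marginals is not None:
                        col = _exact_column(vbp.exact_marginals, rng)
                    else:
                        col = _random_categorical(vbp, bp.n, rng)
                else:
                    col = _quantile_column(vbp, bp.n, rng)
                data[name] = col
                columns.append(name)
                metadata[name] = {
                    "label": vbp.label or vbp.name,
                    "description": vbp.description,
                    "unit": vbp.unit,
                    "format": vbp.format,
                    "categories": vbp.categories,
                    "variable_group": vbp.variable_group or "Synthetic",
                    "respondent": bp.respondent_for(wave),
                    "wave": wave,
                }
            frame = pd.DataFrame(
                {"participant_id": _participant_ids(bp.study_id, bp.n), **data}
            )
            wave_frames[wave] = frame
        dictionaries.append(catalogue_study(bp.study_id, columns, metadata))
        for wave, frame in wave_frames.items():
            tables.append(StudyWaveTable(study_id=bp.study_id, wave=wave, data=frame))
    return tables, merge_dictionaries(dictionaries)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a generator config from YAML."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    blueprints = []
    for sb in raw.get("studies", []):
        variables = [
            VariableBlueprint(
                name=v["name"],
                format=v.get("format", "categorical"),
                label=v.get("label", ""),
                description=v.get("description", ""),
                unit=v.get("unit", ""),
                variable_group=v.get("variable_group", ""),
                categories=tuple(v.get("categories", ())),
                exact_marginals=v.get("exact_marginals"),
                missing_rate=float(v.get("missing_rate", 0.0)),
                quantiles={float(k): float(x) for k, x in v["quantiles"].items()}
                if "quantiles" in v
                else None,
                minimum=float(v.get("minimum", 0.0)),
                maximum=float(v.get("maximum", 60.0)),
                integer=bool(v.get("integer", True)),
            )
            for v in sb.get("variables", [])
        ]
        blueprints.append(
            StudyBlueprint(
                study_id=sb["study_id"],
                n=int(sb["n"]),
                variables=variables,
                waves=int(sb.get("waves", 1)),
                respondents=sb.get("respondents", "unknown"),
                prefix_names=bool(sb.get("prefix_names", True)),
            )
        )
    return GeneratorConfig(blueprints=blueprints, seed=int(raw.get("seed", 0)))


# ---------------------------------------------------------------------------
# The packaged worked example: three studies' wave-1 school-travel data
# ---------------------------------------------------------------------------

# Published wave-1 marginals for the mode items.
SPEEDY_MODE_MARGINALS = {
    "Car": 923,
    "Bus/train": 127,
    "Bicycle": 189,
    "On foot": 814,
    "Missing": 11,
}
KISS_MODE_MARGINALS = {
    "Walk": 392,
    "Cycle/scooter": 51,
    "Car": 7,
    "Bus/train/tram": 3,
    "Missing": 87,
}
BALLABEINA_MODE_MARGINALS = {
    "Walk": 546,
    "Cycle/scooter": 1,
    "Bus/tram": 4,
    "Car": 32,
    "Other": 24,
    "Missing": 62,
}
BALLABEINA_DURATION_MARGINALS = {
    "<10 min": 514,
    "10–20 min": 82,
    ">20 min": 10,
    "Missing": 63,
}

# Duration value multisets ({minutes: count}), constructed so that the
# threshold-bin counts (<=5 / 6–15 / >15) and, for SPEEDY and KISS, the
# published quartiles (p25 5, median 10, p75 15, to within a minute) are
# reproduced exactly. Individual values are synthetic: summary statistics
# underdetermine them.
SPEEDY_WALK_DURATIONS = {
    0: 1, 2: 10, 3: 20, 4: 40, 5: 219,                        # <=5: 290
    6: 30, 7: 30, 8: 30, 9: 18, 10: 100,
    11: 20, 12: 20, 13: 20, 14: 25, 15: 59,                   # 6–15: 352
    16: 5, 20: 20, 25: 35, 30: 50, 45: 35, 60: 10,            # >15: 155
}
SPEEDY_WALK_MISSING = 17
SPEEDY_CYCLE_DURATIONS = {
    0: 1, 1: 1, 3: 6, 4: 10, 5: 48,                           # <=5: 66
    6: 8, 7: 8, 8: 6, 9: 3, 10: 30,
    11: 5, 12: 5, 13: 4, 14: 2, 15: 9,                        # 6–15: 80
    16: 8, 20: 10, 25: 10, 30: 6, 45: 3, 60: 1,               # >15: 38
}
SPEEDY_CYCLE_MISSING = 5
KISS_DURATIONS = {
    1: 5, 2: 15, 3: 20, 4: 20, 5: 93,                         # <=5: 153
    6: 15, 7: 15, 8: 15, 9: 15, 10: 80,
    11: 12, 12: 12, 13: 11, 14: 10, 15: 64,                   # 6–15: 249
    16: 15, 18: 10, 20: 12, 25: 8, 30: 5,                     # >15: 50
}
KISS_TIME_MISSING = 88  # the 87 mode-missing participants plus one walker

FREQ_CATEGORIES = ("Never", "Once", "2 to 3 times", "4 or more times")


def _multiset(counts: Mapping[int, int]) -> list[int]:
    out: list[int] = []
    for value, count in counts.items():
        out.extend([value] * count)
    return out


def _mode_sequence(marginals: Mapping[str, int]) -> list[object]:
    seq: list[object] = []
    for category, count in marginals.items():
        seq.extend([pd.NA if category == "Missing" else category] * count)
    return seq


def _speedy_table(rng: np.random.Generator) -> pd.DataFrame:
    n = sum(SPEEDY_MODE_MARGINALS.values())
    mode = _mode_sequence(SPEEDY_MODE_MARGINALS)

    walk_vals = _multiset(SPEEDY_WALK_DURATIONS)
    rng.shuffle(walk_vals)
    cycle_vals = _multiset(SPEEDY_CYCLE_DURATIONS)
    rng.shuffle(cycle_vals)

    def split_hours_minutes(total: object) -> tuple[object, object]:
        if pd.isna(total):
            return pd.NA, pd.NA
        return str(int(total) // 60), str(int(total) % 60)

    walk_h: list[object] = []
    walk_m: list[object] = []
    cycle_h: list[object] = []
    cycle_m: list[object] = []
    freq_walk: list[object] = []
    freq_cycle: list[object] = []
    freq_motor: list[object] = []
    walk_iter = iter([pd.NA] * SPEEDY_WALK_MISSING + list(walk_vals))
    cycle_iter = iter([pd.NA] * SPEEDY_CYCLE_MISSING + list(cycle_vals))
    for m in mode:
        w: object = pd.NA
        c: object = pd.NA
        if pd.isna(m):
            freq_walk.append(pd.NA)
            freq_cycle.append(pd.NA)
            freq_motor.append(pd.NA)
        elif m == "On foot":
            w = next(walk_iter)
            freq_walk.append(rng.choice(FREQ_CATEGORIES[2:]))
            freq_cycle.append("Never")
            freq_motor.append("Never")
        elif m == "Bicycle":
            c = next(cycle_iter)
            freq_walk.append("Never")
            freq_cycle.append(rng.choice(FREQ_CATEGORIES[2:]))
            freq_motor.append("Never")
        else:
            freq_walk.append("Never")
            freq_cycle.append("Never")
            freq_motor.append(rng.choice(FREQ_CATEGORIES[1:]))
        wh, wm = split_hours_minutes(w)
        ch, cm = split_hours_minutes(c)
        walk_h.append(wh)
        walk_m.append(wm)
        cycle_h.append(ch)
        cycle_m.append(cm)

    # Combined car/bus journey-duration item: reported by motorised travellers
    # only, never used by the harmonised variables (the instrument did not
    # separate bus and car journeys).
    motor_h: list[object] = []
    motor_m: list[object] = []
    for m in mode:
        if not pd.isna(m) and m in ("Car", "Bus/train") and rng.random() > 0.05:
            total = int(rng.integers(5, 46))
            motor_h.append(str(total // 60))
            motor_m.append(str(total % 60))
        else:
            motor_h.append(pd.NA)
            motor_m.append(pd.NA)

    frame = pd.DataFrame(
        {
            "participant_id": _participant_ids("SPEEDY", n),
            "W1_school_travel": mode,
            "W1_a2acthrs_clean": walk_h,
            "W1_a2actmins_clean": walk_m,
            "W1_a3acthrs_clean": cycle_h,
            "W1_a3actmins_clean": cycle_m,
            "W1_a4acthrs_clean": motor_h,
            "W1_a4actmins_clean": motor_m,
            "W1_a2actfreq_clean": freq_walk,
            "W1_a3actfreq_clean": freq_cycle,
            "W1_a4actfreq_clean": freq_motor,
        }
    )
    return frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def _kiss_table(rng: np.random.Generator) -> pd.DataFrame:
    n = sum(KISS_MODE_MARGINALS.values())
    mode = _mode_sequence(KISS_MODE_MARGINALS)
    times = _multiset(KISS_DURATIONS)
    rng.shuffle(times)
    time_col: list[object] = []
    time_iter = iter(times)
    extra_missing = 1  # one mode-reporting participant skipped the time item
    for m in mode:
        if pd.isna(m):
            time_col.append(pd.NA)
        elif extra_missing and m == "Walk":
            time_col.append(pd.NA)
            extra_missing -= 1
        else:
            time_col.append(str(next(time_iter)))
    frame = pd.DataFrame(
        {
            "participant_id": _participant_ids("KISS", n),
            "a_schulweg_hin_sommer": mode,
            "a_schulweg_hin_sommer_time": time_col,
        }
    )
    return frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def _ballabeina_table(rng: np.random.Generator) -> pd.DataFrame:
    n = sum(BALLABEINA_MODE_MARGINALS.values())
    mode = _mode_sequence(BALLABEINA_MODE_MARGINALS)
    # The 62 mode-missing participants also lack a duration; one further
    # participant answered the mode item but skipped the duration item.
    observed = [
        v for v in _mode_sequence(BALLABEINA_DURATION_MARGINALS) if not pd.isna(v)
    ]
    rng.shuffle(observed)
    dur_col: list[object] = []
    obs_iter = iter(observed)
    extra_missing = 1
    for m in mode:
        if pd.isna(m):
            dur_col.append(pd.NA)
        elif extra_missing and m == "Walk":
            dur_col.append(pd.NA)
            extra_missing -= 1
        else:
            dur_col.append(next(obs_iter))
    frame = pd.DataFrame(
        {
            "participant_id": _participant_ids("Ballabeina", n),
            "W1_a_schulweg": mode,
            "W1_a_langeweg": dur_col,
        }
    )
    return frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def _fixture_dictionary() -> DataDictionary:
    group = "School_travel"
    speedy_cols = [
        "W1_school_travel",
        "W1_a2acthrs_clean",
        "W1_a2actmins_clean",
        "W1_a3acthrs_clean",
        "W1_a3actmins_clean",
        "W1_a4acthrs_clean",
        "W1_a4actmins_clean",
        "W1_a2actfreq_clean",
        "W1_a3actfreq_clean",
        "W1_a4actfreq_clean",
    ]
    dur = "Journey duration item, asked separately per mode prompt; 'clean' denotes range-checked values."
    freq = "Journey frequency over the previous 7 days, asked per mode prompt."
    speedy_meta = {
        "W1_school_travel": {
            "label": "Mode of travel to school",
            "description": "How do you usually travel to school?",
            "format": "categorical",
            "categories": ("Car", "Bus/train", "Bicycle", "On foot"),
        },
        "W1_a2acthrs_clean": {
            "label": "Walking to school: duration (hours part)",
            "description": dur, "unit": "hours", "format": "continuous",
        },
        "W1_a2actmins_clean": {
            "label": "Walking to school: duration (minutes part)",
            "description": dur, "unit": "minutes", "format": "continuous",
        },
        "W1_a3acthrs_clean": {
            "label": "Cycling to school: duration (hours part)",
            "description": dur, "unit": "hours", "format": "continuous",
        },
        "W1_a3actmins_clean": {
            "label": "Cycling to school: duration (minutes part)",
            "description": dur, "unit": "minutes", "format": "continuous",
        },
        "W1_a4acthrs_clean": {
            "label": "Travel to school by car or bus: duration (hours part)",
            "description": dur + " Bus and car journeys were estimated jointly.",
            "unit": "hours", "format": "continuous",
        },
        "W1_a4actmins_clean": {
            "label": "Travel to school by car or bus: duration (minutes part)",
            "description": dur + " Bus and car journeys were estimated jointly.",
            "unit": "minutes", "format": "continuous",
        },
        "W1_a2actfreq_clean": {
            "label": "Walking to school: frequency",
            "description": freq, "format": "categorical", "categories": FREQ_CATEGORIES,
        },
        "W1_a3actfreq_clean": {
            "label": "Cycling to school: frequency",
            "description": freq, "format": "categorical", "categories": FREQ_CATEGORIES,
        },
        "W1_a4actfreq_clean": {
            "label": "Travel to school by car or bus: frequency",
            "description": freq, "format": "categorical", "categories": FREQ_CATEGORIES,
        },
    }
    for meta in speedy_meta.values():
        meta.update({"variable_group": group, "respondent": "child"})
    speedy = catalogue_study("SPEEDY", speedy_cols, speedy_meta)

    kiss_meta = {
        "a_schulweg_hin_sommer": {
            "label": "Mode of travel to school during summer",
            "description": (
                "How does your child usually travel to school? Single most "
                "common mode. Translated from German."
            ),
            "format": "categorical",
            "categories": ("Walk", "Cycle/scooter", "Car", "Bus/train/tram"),
            "variable_group": group, "respondent": "parent", "wave": 1,
        },
        "a_schulweg_hin_sommer_time": {
            "label": "Duration of journey to school",
            "description": "Journey time by the most direct route, free text in minutes. Translated from German.",
            "unit": "minutes", "format": "continuous",
            "variable_group": group, "respondent": "parent", "wave": 1,
        },
    }
    kiss = catalogue_study(
        "KISS", ["a_schulweg_hin_sommer", "a_schulweg_hin_sommer_time"], kiss_meta
    )

    ballabeina_meta = {
        "W1_a_schulweg": {
            "label": "Mode of travel to school",
            "description": "How does your child make it to school? Translated from French/German.",
            "format": "categorical",
            "categories": ("Walk", "Cycle/scooter", "Bus/tram", "Car", "Other"),
            "variable_group": group, "respondent": "parent",
        },
        "W1_a_langeweg": {
            "label": "Duration of journey to school",
            "description": "One-way trip duration, coarse bands. Translated from French/German.",
            "format": "categorical",
            "categories": ("<10 min", "10–20 min", ">20 min"),
            "variable_group": group, "respondent": "parent",
        },
    }
    ballabeina = catalogue_study(
        "Ballabeina", ["W1_a_schulweg", "W1_a_langeweg"], ballabeina_meta
    )
    return merge_dictionaries([speedy, kiss, ballabeina])


@dataclass
class FixtureBundle:
    """Everything the worked example needs, generated in memory."""

    tables: dict[str, StudyWaveTable]
    dictionary: DataDictionary
    specs: dict[str, HarmonisationSpec] = field(default_factory=dict)

    def table(self, study_id: str) -> StudyWaveTable:
        return self.tables[study_id]


def _packaged(name: str) -> str:
    return resources.files("retroharm").joinpath("data", name).read_text(encoding="utf-8")


def packaged_spec_names() -> list[str]:
    return ["ICAD_SchoolTravel1", "ICAD_SchoolTravel2", "ICAD_SchoolTravel3"]


def load_packaged_specs(dictionary: DataDictionary | None = None) -> dict[str, HarmonisationSpec]:
    """Parse the three packaged school-travel specs (validated if a dictionary is given)."""
    specs = {}
    for stem in ("schooltravel1", "schooltravel2", "schooltravel3"):
        data = yaml.safe_load(_packaged(f"specs/icad_{stem}.yaml"))
        spec = parse_spec_dict(data, dictionary, source=f"icad_{stem}.yaml")
        specs[spec.name] = spec
    return specs


def school_travel_fixture() -> FixtureBundle:
    """Regenerate the packaged three-study wave-1 school-travel dataset.

    Deterministic: repeated calls produce byte-identical tables (see
    ``data/fixture_hashes.json`` for the frozen canonical hashes).
    """
    rng = np.random.default_rng(FIXTURE_SEED)
    dictionary = _fixture_dictionary()
    tables = {
        "SPEEDY": StudyWaveTable("SPEEDY", 1, _speedy_table(rng)),
        "KISS": StudyWaveTable("KISS", 1, _kiss_table(rng)),
        "Ballabeina": StudyWaveTable("Ballabeina", 1, _ballabeina_table(rng)),
    }
    specs = load_packaged_specs(dictionary)
    return FixtureBundle(tables=tables, dictionary=dictionary, specs=specs)


def table_csv_bytes(table: StudyWaveTable) -> bytes:
    """Canonical CSV bytes of a study-wave table (empty field = missing)."""
    df = table.data.fillna("")
    return df.to_csv(index=False, lineterminator="\n").encode("utf-8")


def fixture_hashes(bundle: FixtureBundle) -> dict[str, str]:
    import hashlib

    out = {
        f"{study_id}.csv": hashlib.sha256(table_csv_bytes(t)).hexdigest()
        for study_id, t in bundle.tables.items()
    }
    out["dictionary.csv"] = hashlib.sha256(
        dictionary_to_csv_bytes(bundle.dictionary)
    ).hexdigest()
    return out


def packaged_fixture_hashes() -> dict[str, str]:
    """The frozen canonical hashes the packaged fixture must reproduce."""
    return json.loads(_packaged("fixture_hashes.json"))


def write_fixture(out_dir: str | Path) -> list[Path]:
    """Write the worked-example dataset, dictionary and specs to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = school_travel_fixture()
    written = []
    for study_id, table in bundle.tables.items():
        path = out_dir / f"{study_id}.csv"
        path.write_bytes(table_csv_bytes(table))
        written.append(path)
    dict_path = out_dir / "dictionary.csv"
    dict_path.write_bytes(dictionary_to_csv_bytes(bundle.dictionary))
    written.append(dict_path)
    for stem in ("schooltravel1", "schooltravel2", "schooltravel3"):
        path = out_dir / f"icad_{stem}.yaml"
        path.write_text(_packaged(f"specs/icad_{stem}.yaml"), encoding="utf-8")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Published coverage of the three school-travel variables
# ---------------------------------------------------------------------------

# The published coverage summary reports, per harmonised variable, the number
# of contributing studies and a histogram of studies by contributed wave
# count (ICAD_SchoolTravel1: 11 studies {1:4, 2:4, 3:3}; ICAD_SchoolTravel2:
# 14 studies {1:7, 2:3, 3:4}; ICAD_SchoolTravel3: 8 studies {1:4, 2:3, 3:1}).
# The per-study assignments behind those totals are not public, so this
# registry encodes one consistent assignment: the three example studies keep
# their documented roles (SPEEDY contributes waves 1 and 3 of its duration
# data; Ballabeina's duration is excluded; four study-waves used walk/cycle-
# only questionnaires and enter only the binary mode variable), and the
# remaining studies carry synthetic ids STUDY04..STUDY14.

_ST2_WAVES: dict[str, list[int]] = {
    "SPEEDY": [1, 2, 3],
    "KISS": [1],
    "Ballabeina": [1, 2],
    "STUDY04": [1],  # walk/cycle-only questionnaire (inference rule)
    "STUDY05": [1],  # walk/cycle-only questionnaire (inference rule)
    "STUDY06": [1],  # walk/cycle-only questionnaire (inference rule)
    "STUDY07": [1, 2, 3],  # wave 3 used a walk/cycle-only questionnaire
    "STUDY08": [1, 2, 3],
    "STUDY09": [1, 2, 3],
    "STUDY10": [1, 2],
    "STUDY11": [1, 2],
    "STUDY12": [1],
    "STUDY13": [1],
    "STUDY14": [1],
}

_ST1_EXCLUDED: set[tuple[str, int]] = {
    ("STUDY04", 1),
    ("STUDY05", 1),
    ("STUDY06", 1),
    ("STUDY07", 3),
}

_ST3_WAVES: dict[str, list[int]] = {
    "SPEEDY": [1, 3],
    "KISS": [1],
    "STUDY08": [1, 2, 3],
    "STUDY09": [1],
    "STUDY10": [1, 2],
    "STUDY11": [1, 2],
    "STUDY12": [1],
    "STUDY13": [1],
}


def school_travel_inclusion_registry() -> dict[str, list[tuple[str, int]]]:
    """Included (study, wave) pairs per school-travel harmonised variable."""
    st2 = [(s, w) for s, waves in _ST2_WAVES.items() for w in waves]
    st1 = [pair for pair in st2 if pair not in _ST1_EXCLUDED]
    st3 = [(s, w) for s, waves in _ST3_WAVES.items() for w in waves]
    return {
        "ICAD_SchoolTravel1": st1,
        "ICAD_SchoolTravel2": st2,
        "ICAD_SchoolTravel3": st3,
    }
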