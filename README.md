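# retroharm

Retrospective harmonisation of questionnaire and covariate data pooled from
multiple epidemiological studies.

When individual-participant data are pooled across cohorts that were never
designed to be compatible, each study measures the same construct with a
different instrument: different response options (often translated),
different respondents (child vs parent), different resolutions (exact
minutes vs coarse bands), different numbers of assessment waves. Before any
co-analysis, study-specific variables must be recoded onto a common format —
and every recode, preference and exclusion must be documented, because the
validity of pooled estimates rests on those judgements. `retroharm` is a
toolkit for exactly that workflow, aimed at data managers and
epidemiologists running pooling consortia:

1. **Dictionary** (`retroharm.dictionary`) — per-study data dictionaries
   (name, label, description, unit, format, declared categories, wave,
   respondent), with a construct-level *variable group* tag applied
   uniformly across studies, so one query returns every variable measuring
   a construct (e.g. `School_travel`) from any study.
2. **Rules** (`retroharm.rules`) — a declarative YAML rule language for
   deriving a harmonised variable: per study-wave, a *category map*
   (collapse of source categories), a *threshold-bin rule* (cut points on a
   continuous duration, partitioning [0, ∞)), or a reasoned *exclusion*;
   optionally a *source preference* (e.g. parent report over child report),
   a *negative-response inference* (no walking and no cycling reported ⇒ a
   non-active mode, for instruments that never asked about motorised
   travel), and a *mode gate* (duration taken from the item matching the
   reported mode).
3. **Engine** (`retroharm.engine`) — applies the rules deterministically,
   pools the per-study fragments (appending; excluded waves stay absent,
   not present-as-missing), tabulates counts per study-wave, and
   summarises coverage (studies n, histogram of studies by wave count).
4. **Provenance** (`retroharm.provenance`) — builds and renders the audit
   document: coverage table, per-study-wave recode tables (source
   marginals, rule transcription, output marginals), exclusion reasons,
   study-specific notes, and a machine-readable decision ledger (source
   conflicts, inference reassignments, missing-code translations).
5. **Fixtures** (`retroharm.fixtures`) — a blueprint-driven synthetic
   multi-study data generator (exact marginal allocation, seeded), and the
   packaged worked example below.

The harmonisation strategy follows the *coverage vs resolution* trade-off:
one construct is issued at several resolutions, so a high-resolution
variant keeps detail where instruments support it while a low-resolution
variant admits the largest number of studies.

## Worked example: school travel in three studies

The packaged fixture reconstructs wave-1 school-travel data for three
cohorts — SPEEDY (UK, child-reported), KISS (Switzerland, parent-reported,
German instrument) and Ballabeina (Switzerland, parent-reported,
French/German instrument) — from their published marginal counts, together
with three harmonisation specs:

| variable | resolution | categories |
| --- | --- | --- |
| `ICAD_SchoolTravel1` | mode, 5 categories | Walk, Cycle, Public transport, Car, Other, Missing |
| `ICAD_SchoolTravel2` | mode, binary | Active mode of travel, Other mode of travel, Missing |
| `ICAD_SchoolTravel3` | duration, binned | ≤5 min, 6–15 min, >15 min, Missing |

```python
from retroharm import school_travel_fixture
from retroharm.engine import harmonise_study_wave, pool, tabulate

bundle = school_travel_fixture()
spec = bundle.specs["ICAD_SchoolTravel2"]
fragments = [
    harmonise_study_wave(table, spec, bundle.dictionary)[0]
    for table in bundle.tables.values()
]
print(tabulate(pool(fragments, spec)).per_study_wave)
```

```
category         Active mode of travel  Other mode of travel  Missing     n
study_id   wave
Ballabeina 1                       547                    60       62   669
KISS       1                       443                    10       87   540
SPEEDY     1                      1003                  1050       11  2064
```

Each row is one study-wave after collapsing its native mode categories
(e.g. SPEEDY's `Bicycle`/`On foot` → Active mode of travel): 1003 of the
2064 SPEEDY children used an active mode, 1050 a motorised one, and 11 gave
no answer. For the duration variable, KISS's free-text minutes bin to
153 / 249 / 50 (88 missing), SPEEDY's duration is taken from the walking or
cycling item selected by the reported mode (motorised travellers are
Missing, since their journey time was not itemised), and Ballabeina
contributes zero records with the documented reason that its coarse bands
(<10 / 10–20 / >20 min) cannot be collapsed to the harmonised boundaries.

The same workflow is scriptable from the shell:

```sh
retroharm simulate --example school-travel --out example/
retroharm harmonise --dictionary example/dictionary.csv --studies example/ \
    --specs example/icad_schooltravel1.yaml \
    --specs example/icad_schooltravel2.yaml \
    --specs example/icad_schooltravel3.yaml \
    --out harmonised/
```

which writes the pooled long-format CSVs, `report.md` and the CSV audit
bundle. `retroharm catalogue`, `validate`, `report` and blueprint-driven
`simulate` cover the rest of the workflow; all validation failures exit
with code 2.

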