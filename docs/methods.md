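# Methods

## The harmonisation model

`retroharm` implements *algorithmic* retrospective harmonisation:
deterministic recoding of study-specific variables onto common target
categories. No statistical calibration (regression- or latent-variable
based harmonisation) is attempted; where two instruments cannot be mapped
deterministically, the correct output is a reasoned exclusion, not an
estimate. The unit of harmonisation is the *study-wave*: one study's data
from one measurement occasion. A harmonised variable is defined by a spec
that gives every relevant study-wave exactly one of a category map, a
threshold-bin rule, or an exclusion with a mandatory justification.

Assumptions baked into the engine:

- **Wide master files.** Each study arrives as one row per participant,
  columns prefixed `W<k>_` for wave k (unprefixed columns are
  time-invariant unless the dictionary assigns a wave explicitly, which
  accommodates instruments that keep native names such as
  `a_schulweg_hin_sommer`). Participant identity across waves is
  `(study_id, participant_id)`; no linkage inference is performed.
- **Missing data.** The canonical missing value is the empty CSV field.
  Studies' native missing codes (9, −99, …) are translated at load time via
  an explicit per-variable declaration passed to `read_study_master`;
  the number of translated cells is carried into the report ledger. Codes
  are never guessed. (The dictionary CSV layout is fixed and has no
  missing-codes column, so the declaration travels with the load call
  rather than the dictionary file.)
- **Label matching.** Category labels are compared exactly after Unicode
  NFC normalisation and whitespace trimming — never fuzzily. Translated
  instruments are handled by mapping their verbatim labels.

## Rule semantics and numerical choices

**Category maps.** Total functions from declared source categories to
target categories. The default `unmapped_policy="error"` makes a source
value without a mapping a hard failure: silent missingness hides recode
gaps. Multi-select responses (several modes ticked, `;`-separated — `;` is
safe because declared category labels may not contain it) are mapped per
ticked option and resolved by a priority order, by default the spec's
target-category order, so in the packaged specs an active mode dominates.

**Threshold bins.** Bins partition [0, ∞) with right-closed intervals:
cut points 5 and 15 give (−∞, 5], (5, 15], (15, ∞), which reproduces rules
phrased for integer minutes ("≤ 5", "6–15 inclusive", "> 15") while staying
total on the reals (a reported 5.5 min falls in the middle bin). Explicit
inclusivity flags are supported; validation rejects gaps, overlaps,
non-increasing bounds, a first bin not covering 0 and a last bin not
reaching +∞. Negative durations raise an error rather than becoming
Missing — they indicate upstream corruption, and coercing them would
launder it.

**Source preference.** An ordered selector list (by variable and/or
respondent); per participant the first non-missing candidate wins. When a
lower-preference source is present *and disagrees*, the row counts as a
conflict; policy `prefer_first` (default) keeps the preferred value,
`missing_if_conflict` blanks the row. Conflict counts always surface in the
report ledger, so the choice is auditable either way.

**Negative-response inference.** Instruments that only ask about walking
and cycling cannot distinguish "travels by car" from "did not answer". The
inference rule reassigns a row from Missing to the inferred category
(e.g. "Other mode of travel") only when *every* indicator is present and
takes a declared negative value; a missing indicator blocks the inference,
because absence of an answer is not evidence of a non-active mode.

**Mode-gated duration.** Where journey duration was itemised per mode, the
duration source is selected by the reported mode; modes without an itemised
duration (or a missing mode) yield Missing. Hours+minutes column pairs are
combined as 60·h + m, a missing half counting as 0 and the result missing
only when both halves are missing.

**Pooling and tabulation.** Pooling is concatenation with a uniqueness
check on (study, wave, participant, variable); excluded waves are entirely
absent from the pooled set, which keeps "not included" distinct from
"included but Missing". Output is canonically sorted, so harmonised CSV
bytes are invariant to input row order. Tabulations order categories by the
spec's target list (stable, diffable reports) and re-assert conservation:
per study-wave, category counts including Missing sum to the participant
count.

## The provenance report

Reports are assembled only from engine outputs — the renderer copies
numbers, never recomputes them (a property the tests enforce by injecting
sentinel values) — and are deterministic: re-rendering an unchanged report
is byte-identical, and each report carries a content hash of the spec files
it documents, so a report provably corresponds to one set of recipes.
Continuous sources are summarised by mean, median, quartiles and range, the
statistics conventional for this documentation style. The machine-readable
ledger records source-conflict counts, inference reassignment counts and
missing-code translations per study-wave.

## The synthetic generator and the packaged worked example

The blueprint generator emulates the heterogeneity that makes pooling hard:
per-study instruments with their own category schemes and labels,
respondents per wave, wave counts, per-variable missingness, and either
exact categorical marginals (reproduced exactly: deterministic allocation,
seeded shuffle of row order) or continuous values drawn through a
piecewise-linear inverse CDF anchored at target quantiles. Output is a pure
function of the config including its seed. It does *not* emulate
within-participant response coherence (columns are sampled independently
unless a fixture couples them), attrition structure across waves, or
measurement error — so passing tests demonstrate the correctness of the
harmonisation machinery, not robustness to messy real-world response
behaviour.

The packaged worked example reconstructs wave-1 school-travel data for
SPEEDY (n = 2064), KISS (n = 540) and Ballabeina (n = 669) from their
published marginal counts. Design choices where the published record
underdetermines the data:

- **Mode columns** reproduce the published category marginals exactly.
- **KISS durations** are integer minutes on 1–30 constructed to reproduce
  the published bin counts (153 / 249 / 50, 88 missing) exactly, with the
  published quartiles (5 / 10 / 15) hit exactly and the mean within 0.15
  of the published 9.9 — bin counts, not moments, are the reproduction
  surface, since moments alone underdetermine the data.
- **SPEEDY durations** are split across walking and cycling hours+minutes
  column pairs; within each mode the multiset is constructed so that the
  pooled bin counts (356 / 432 / 193, 1083 missing) are exact and each
  column's published quartiles (5 / 10 / 15) and range (0–60) are matched,
  with means within 0.1 of the published 12.7 and 11.2. Motorised
  travellers carry a combined car/bus duration item that is catalogued but
  unused, mirroring the instrument's structure.
- **Missingness overlap** between mode and duration items (not published)
  is set to the most plausible nesting: participants missing the mode item
  are also missing the duration item, plus one extra duration-only
  missing participant where the published counts differ by one.
- **Ballabeina durations** are delivered only as the published coarse bands
  (<10 / 10–20 / >20 min), so the incompatible-category exclusion path is
  genuinely exercised.
- The fixture is a pure function of a fixed internal seed; regeneration is
  byte-identical, and sha256 hashes of the canonical CSVs are frozen in
  package data instead of shipping the (large) CSVs themselves.

The coverage registry encodes the published per-variable coverage — 11
studies (21 waves), 14 (25) and 8 (13) with their wave-count histograms —
as one concrete per-study assignment consistent with all published totals;
the eleven studies beyond the three examples carry synthetic ids
(`STUDY04`–`STUDY14`), since the true assignment is not public. The
histograms and totals, not the assignment, are the reproduction surface.

## Problem sizes and limitations

The test suite and the acceptance script run the full worked example
(3 studies, 3273 participants, three harmonised variables), property
sweeps of order 10³ rows per transform, and a conservation sweep over 100
synthetic study-waves; the whole suite completes in a few seconds on one
CPU. Known limitations: no statistical calibration of continuous
instruments; no multi-group tagging of a variable (a variable belongs to
exactly one group); no modelling of the human review workflow (the report
documents decisions, it does not adjudicate them); the wide export assumes
one value per participant per variable per wave.
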