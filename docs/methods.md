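# Methods

## What the package measures

A policy document is appraised against a framework of 21 core concepts of
human rights and 12 vulnerable groups.  The analytic object is the score
matrix: concepts as rows, the 12 base groups plus any country-specific
extras plus the Universal column as columns, each cell holding the best
quality score (1–4) among the rater-confirmed references that fall in it.
The three summary indices and the overall High/Moderate/Low ranking are
pure functions of that matrix.

The quality scale encodes rater judgment: 1 mention, 2 explanation, 3
specific action, 4 monitoring intention.  The package never infers levels
2–4 from text — automated detection only *proposes* mention candidates, and
anything it could defensibly auto-assign is level 1.  This boundary is kept
deliberately: explanation/action/monitoring distinctions are human calls.

## Framework as data

The concept and group rosters, definitions, key questions and key phrases
live in a YAML config (`concepts`, `vulnerable_groups`,
`universal_phrases`).  The shipped default has exactly 21 concepts and 12
base groups; entries beyond the canonically named ones carry study-default
key language and are flagged editable in the config header.  Loading
enforces unique ids and refuses any phrase assigned both to a group and to
the universal category (group-coverage denominators must be unambiguous);
a phrase shared by two *concepts* is permitted but reported as an ambiguity
for the rater.  Non-default cardinalities warn, or fail under `strict`.
Key phrases are stored lowercase and matched case-insensitively.

## Sentence segmentation

No statistical sentence tokenizer is available in the supported
environment, so segmentation is a small deterministic rule set: a boundary
after every run of `. ! ?` followed by whitespace, unless the immediately
preceding token is on a fixed abbreviation list (e.g., i.e., etc., vs.,
titles); every line break is also a boundary; decimals (`8.3`) never split.
Spans are 0-based half-open character coordinates; the invariant, property-
tested, is losslessness — spans are ordered, non-overlapping, in bounds,
and the inter-span gaps are whitespace only.  The rule set is simple by
design: the unit of analysis only has to be stable and auditable, not
linguistically perfect, because raters adjudicate all content decisions.

## Detection and pairing

Matching is exact-phrase, case-insensitive, on word boundaries (so "youth"
never fires inside "youthful"); internal whitespace in a phrase matches any
whitespace run.  No stemming by default; a normalizer hook exists for
studies that want one.  The pairing window is the sentence (configurable to
±N sentences): each concept mention pairs with every distinct group
mentioned in range; with only a universal phrase in range it pairs to
Universal; with neither, it pairs to Universal under the
`universal_default` option (on by default, matching the convention that a
population-wide concept statement scores as Universal) or is reported
unpaired.  Universal references are additionally counted per occurrence,
not per sentence, since their sheer frequency is itself informative.

## Scoring and indices

`build_matrix` applies the max rule per cell; it is idempotent,
order-independent, and monotone (adding an annotation never lowers a cell,
a row best score, or any index — property-tested).  N/A is concept-level;
a concept both scored and marked N/A in one annotation set is an error,
because that is a rater disagreement belonging to the reliability workflow,
not something to resolve silently.

Percentages are kept at full precision internally.  Display rounding is
decimal **half-up** (8.33 → 8.3, 91.67 → 92), chosen because it reproduces
every printed value in the published four-country benchmark tables, whose
prose description of rounding is looser than its numbers.  The ≥50%
ranking thresholds are inclusive and always applied to full-precision
values, so a policy at exactly 50% on an index has achieved it and a
49.96% displayed as "50" has not.

Denominators default to the full rosters (21 and 12).  Two documented
options deviate: `exclude_na` removes N/A concepts from the concept
denominators (the published tables keep 21; the N/A provision is never
reconciled with the fixed denominator there, so both conventions are
explicit and the summary records which was used), and country-specific
extra groups are reported separately but never alter the base-12 group
denominator.

## Reliability

Two raters per document.  Comparison is over the union of cells either
rater touched, on outcomes {absent, 1, 2, 3, 4, NA}; the union universe is
the conservative default because a full-grid comparison (21 × 14 cells)
inflates agreement through shared absences — a `full_grid` option enables
it anyway.  A concept-level N/A enters the universe as a pseudo-cell
(concept, `__NA__`), so "A said not applicable, B scored the row" surfaces
as discrepancies on both cells rather than vanishing.  Raw cell agreement
(matches / compared cells) mirrors the original dual-rater practice;
Cohen's kappa over the same outcome sequences adds chance correction.
Kappa is defined as 1.0 when observed agreement is 1.0 (the chance-model
denominator degenerates when both raters use a single identical category).
Consensus building requires an explicit resolution — take A, take B, an
explicit score, NA, or drop — for every discrepancy; there is no silent
auto-merge, and the merged set must itself validate as a single-rater set.

## Synthetic corpus

The generator emulates the structure the scoring pipeline consumes, not
policy prose style.  A plan states the planted (concept, column, quality,
n_mentions) cells, a count of stand-alone universal-population sentences,
and a count of distractor sentences; one sentence is rendered per planted
mention from a per-quality template (mention-only / explained / action /
monitoring clause), sentences are shuffled by the plan's seeded RNG, and
the same seed yields a byte-identical document.  Ground-truth annotations
carry the planted quality.  Template filler and the distractor vocabulary
are verified at generation time to contain no lexicon key phrase, so on
synthetic text detection recall and precision are exact and every document
is its own oracle: the expected indices are computed analytically from the
plan.

A green end-to-end test therefore establishes that detection, pairing, the
max rule, the indices and the ranking compose correctly — it does **not**
establish recall on real policy prose, where paraphrase, anaphora and
cross-sentence references defeat exact phrase matching.  That is why the
tool's outputs are rater worksheets, not final scores.

## Known limitations

- Input is plain text; PDF/Word extraction and OCR are out of scope.
- Exact-phrase matching under-detects paraphrased concepts; the lexicon is
  the recall ceiling and is deliberately editable.
- The default key phrases beyond the canonically named rosters are package
  defaults, not the framework manual's canonical key language.
- At most two raters per document; no automatic adjudication heuristics.
- The published reference dataset contains only the per-policy index rows,
  so document-level re-scoring of those 51 policies is not reproducible;
  fidelity checks rest on the ranking rule, the index arithmetic and the
  country tallies.
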