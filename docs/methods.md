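# Methods

## Problem

Clinical notes cannot be shared for research while they contain protected
health information (PHI).  For Korean tertiary-hospital radiology reports —
written in a mix of Korean and English — the PHI that actually occurs is
dominated by dates, followed by names of medical staff and patients,
hospital names, regions, internal phone/extension numbers, and occasional
demographics (age, sex, nationality).  `deidkit` implements a two-stage
de-identification method for such text:

1. a **rule engine** of 51 regular expressions across six categories
   (DAT, PER, ORG, LOC, NUM, ETC), built around *identifier words* —
   non-PHI anchors such as 환자이름 (patient name), 판독의 (reading
   radiologist), or `Tel.` that reliably precede PHI; and
2. a **weak-supervision pipeline** that uses those rules as pseudo-labelers
   over a large note pool, producing token-level BIO corpora on which a
   sequence tagger is trained.  The learned tagger generalizes past the
   rules' literal patterns and closes part of their recall gap.

Because real clinical notes are not shareable, the package carries a
seeded synthetic-note generator with gold annotations; every claim the
test suite makes is a claim about that benchmark, not about any hospital's
data (see "What the synthetic benchmark does and does not show").

## Coordinate and text conventions

All offsets are 0-based, half-open, counted in Unicode code points of the
NFC-normalized text.  NFC normalization at ingestion is load-bearing:
decomposed Hangul (as produced by some editors and macOS filenames) would
otherwise never match `[가-힣]` character classes.  Tokenization splits at
whitespace, then at boundaries between three script classes — Hangul,
Latin-or-digit, and punctuation — so `2019-02-04` becomes five tokens and
`환자이름:` becomes two.  Token-level evaluation and BIO projection both
use this tokenizer; anyone comparing token counts against other tools
should treat it as a convention, not ground truth.

## The rule set

Each rule is a regular expression with a named capture group `phi`; the
rule may match identifier context, but only the `phi` group is annotated
and masked, so identifiers survive masking (`판독의: [PER]`).  The shipped
set has 51 rules: 18 DAT, 8 PER-staff, 3 PER-patient, 13 ORG, 1 LOC,
4 NUM, 4 ETC.  The set is a versioned YAML config (patterns, categories,
priorities, vocabularies) so other institutions can extend it; the three
vocabularies (hospital aliases, region names, extension numbers) are
compiled into alternations at load time, longest alternative first.  The
extension vocabulary defaults to empty — extension lists are
institution-private — and an empty vocabulary compiles to a
never-matching pattern, so the NUM family still works through its
identifier-anchored rules.

Design constraints baked into the patterns:

* **Dates require a plausible year.**  Dash/dot/slash numeric dates must
  start with a 4-digit year (19xx/20xx); consequently short numeric ranges
  like `1.2-1.7` (a measurement, or possibly a date span — genuinely
  ambiguous in radiology text) are never matched, a deliberate
  precision-over-recall trade.
* **Bare 4-digit numbers never fire.**  A four-digit extension number is
  indistinguishable from a year without context, so NUM requires either an
  identifier anchor (`Tel.`, 전화번호, 환자번호) or a vocabulary hit.
* **Known over-triggers are kept, not patched.**  The 확인함/by rule pair
  tags 상기 in 상기확인함; the Korea-University alias family tags 고려
  ("considering"); the Chung-Ang family tags 중앙 inside 중앙값
  ("median"); `CMC` is tagged ORG whether it means a hospital or a
  carpometacarpal joint.  These are documented failure modes of this class
  of rule system.  The pipeline's answer to them is corpus-level
  correction (below), which mirrors how such systems are actually
  maintained, rather than silently improving the rules beyond what a
  regex can know.

**Overlap resolution.**  Raw firings from 51 rules overlap constantly
(alias families vs. suffix rules, year-month vs. full dates).  Conflicts
resolve by a total order: longer span wins; at equal length
ORG > LOC > DAT > PER > NUM > ETC (a city fused to a hospital name is the
organization, not the region); then leftmost; then the rule's priority
number; then rule id.  A total order makes `apply_rules` deterministic and
lets tests compare it against a run-every-rule-then-resolve oracle.

## Pseudo-labeling

Rule matches project onto tokens as BIO2 tags: a token inherits a
category if *any* of its characters overlaps a match (a partially covered
token must still be masked — leaking half a name is leaking), the first
token of each match gets `B-`, the rest `I-`, and staff/patient both
collapse to PER.  The 13-tag inventory is `O` plus B/I for six categories.

Training corpora are built by running the rules over a note pool, keeping
only notes with at least one match, and sampling a tier uniformly without
replacement under a fixed seed.  Tier sizes default to 800 / 1,600 / 3,200
notes (small / medium / large1) — a 1:2:4 ladder scaled one order of
magnitude below the source study's 8k/16k/32k so the full experiment grid
runs on one desk CPU in minutes; ratios, not absolutes, are the object of
study.

**Corrections (large2).**  A `CorrectionList` holds false-positive spans
to revert to O and gold-annotated notes (typically from other
departments) to append.  `corrections_from_gold` emulates the manual
correction pass: any pseudo-label entity whose token hull overlaps no
gold annotation of its note is flagged for removal.  A note that loses
its last annotation is dropped from the corpus.

## The reference tagger

The trainable model is an averaged perceptron over windowed token
features with greedy left-to-right decoding and a previous-tag feature,
followed by BIO repair (any orphan `I-X` is rewritten `B-X`).  Features
per token: surface, shape (digits→9, Hangul→H, Latin→a), script class,
surfaces at offsets −2..+2, shapes at ±1, surface and shape bigrams with
both neighbors, identifier-word flags in the window, and boundary flags.
Averaging uses the standard lazy-update formulation with time advancing
every token, so the weights the model settles into dominate the average.

**Cost-sensitive updates for weak supervision.**  Pseudo-labels inherit
the rules' error profile: where they mark an entity they are almost
always right (rule precision ≈ 1 on covered patterns), but an O label may
be a silent miss (rule recall < 1).  A symmetric learner trained to
convergence therefore learns the rules' blind spots as hard negative
evidence and *loses* recall on exactly the out-of-scope patterns the
semi-supervised step is meant to recover — measurably so on the synthetic
benchmark, where symmetric training made out-of-scope recall fall as the
corpus grew.  Updates on O-labeled tokens are therefore down-weighted by
`neg_cost = 0.5` (entity labels trusted twice as much as O labels); 1.0
recovers the symmetric perceptron.  This is the one place the package
departs from a textbook perceptron, and it is a weak-supervision design
choice, not a tuning knob: the default was fixed from the label-noise
argument above.

Training is deterministic given `(epochs, seed)`: the seed drives only
the note shuffle, ties in `argmax` break toward the lower tag index, and
all arithmetic is plain float64.  Defaults: 5 epochs for general use; the
experiment grid uses 3 (the model converges in 2–3 passes at these corpus
sizes).  The tagger follows the scikit-learn estimator protocol
(`fit` / `predict` / `get_params` / `set_params`, fitted attributes with a
trailing underscore).  External pretrained transformer taggers can
substitute through the `SequenceTagger` protocol — same corpus in, same
labeled tokens out; their fine-tuning hyperparameters are their own
business.

## Evaluation

Scoring is per token with B/I collapsed to the category, matching how
such systems are annotated and audited in practice (and deliberately
*not* span-exact entity scoring, which would double-penalize boundary
slips that are irrelevant to masking).  TP: gold and prediction agree on
a non-O category.  A non-O prediction disagreeing with gold is an FP for
the predicted category; a non-O gold token missed or mis-categorized is
an FN for the gold category — so a cross-category confusion counts once
on each side, keeping per-category marginals self-consistent.  `0/0` is
defined as 0.  Reported tables round half-up to two decimals; internal
values keep full precision.  Micro totals sum counts over categories.

## The synthetic benchmark

The generator assembles notes from filler sentences (radiology or
functional-test flavor, mixed Korean/English) and PHI context templates,
writing gold spans down at assembly time — gold is never derived from the
rules, which are the system under test.  Defaults emulate the source
distribution the rules target: 10% of notes carry PHI; category weights
proportional to DAT 1045 : PER-staff 56 : PER-patient 50 : ORG 47 :
LOC 7 : NUM 3 : ETC 5; 9% of PHI notes carry a second instance (≈1.09
instances per PHI note).  Names, hospitals and numbers are fictitious.

Distributional choices that matter:

* **Notation variety is long-tailed.**  A few date formats dominate while
  quote-years, English month names, compact dates and timestamped forms
  sit in the tail; hospital aliases likewise (a handful of common aliases
  plus dozens of rare referral hospitals and clinics).  Small training
  tiers genuinely undersample these tails — which is what makes training
  size matter, as it does on real text.
* **Filler is numerals-rich.**  Accession numbers, protocol versions,
  dose values, lab panels and sizes are generated with varying values.
  None of it is rule-matchable (no year-shaped prefix with a date
  separator, no identifier words), but its token shapes collide with date
  notations — the date-vs-measurement ambiguity that makes clinical
  de-identification hard, and a genuine discrimination problem for the
  learned tagger.
* **`out_of_scope_fraction`** is the fraction of PHI-bearing notes whose
  author writes in notation families the rules do not cover (월초/말경
  partial dates, 선생님-style name contexts, unlisted clinics,
  내선-anchored numbers, English month words in lowercase).  Scope is a
  property of the note, not of the individual instance — notation style
  belongs to the writer, and a writer who dates reports "3월초" does so
  throughout — so an out-of-scope note contains only out-of-scope PHI.
  This matters for the pipeline's semantics: such notes have no rule
  matches and therefore never enter the pseudo-labeled training corpus,
  exactly as uncovered-style notes drop out of a rule-filtered corpus in
  practice.  (Were scope drawn per instance instead, mixed notes would
  plant systematically repeated unmarked PHI in the training data as O
  tokens, and any converging discriminative learner would progressively
  unlearn those patterns as the corpus grows — an artifact of the mixing
  assumption, not of the method.)  With the fraction at 0, the rule
  engine scores exactly 1.00/1.00 against gold — an invariant the tests
  enforce.  Above 0, rule recall drops below 1 while gold stays
  complete: the gap the tagger must close.
* **`homonym_trap_rate`** appends known false-positive lines (고려해 볼
  때, 중앙값, CMC-as-joint, 상기확인함) that are gold-O; they exercise
  precision accounting and feed the correction workflow.

**What passing tests do and do not show.**  The benchmark reproduces the
*mechanisms* — identifier-anchored matching, homonym false positives,
notation-tail recall loss, pseudo-label noise propagation, correction
benefit — with surface realism only.  It does not contain typos, OCR
noise, real layout (section headers, tables), real name/hospital
frequency distributions, or adversarial formats, so absolute scores on it
say nothing about absolute scores on hospital data; only the directional
and structural claims transfer.

## Experiments (`deidkit.experiments`)

Problem sizes, fixed as the package's desk-scale conditions: training
pool of 4,500 PHI-bearing notes (generated at `phi_note_fraction = 1`,
since corpus construction discards matchless notes anyway), 400-note
held-out set, 5 seeds per condition, 3 epochs, out-of-scope fraction
0.15.  Each seed is a full replication — its own pool, held-out set,
tier sampling and shuffle order — so reported means average over
benchmark draws as well as training stochasticity; within a replication
all tiers share the pool and held-out set, keeping tier comparisons
paired.

* **Tier trend**: train on 800/1,600/3,200 pseudo-labeled notes, evaluate
  each on the same held-out gold; the 5-seed mean micro-F1 is
  non-decreasing in tier size, and the largest tier's recall exceeds the
  rule engine's recall on the same notes.
* **Correction benefit**: with `homonym_trap_rate = 0.2` (train and
  held-out alike — at the source study's ~1% trap incidence the effect
  exists but is too small to measure reliably at these sizes), train on
  the uncorrected large tier and on the same tier with
  generator-flagged false positives removed; corrected training yields
  strictly higher held-out precision, 5-seed mean.

Seeds derived inside experiments stay below 2^31.

## Numerical and degenerate-input choices

* Zero-length `phi` captures are discarded; a rule that can only match
  empty strings never produces annotations.
* `resolve_overlaps` is a greedy selection under the total order above;
  with a total order, greedy = unique fixed point.
* Masking with overlapping spans is a contract violation (raises), not a
  silent merge.
* `evaluate` refuses misaligned token sequences and mismatched note sets,
  naming the first offender — silent realignment would invalidate scores.
* Empty corpora: training raises; evaluation of an empty category yields
  0 by the 0/0 convention.

## Known limitations

* The rule set is faithful to its genre: vulnerable to typos, novel
  notations and homonyms by construction.  Fuzzy matching is out of
  scope.
* The reference tagger is linear and windowed; it cannot use long-range
  context and will not approach the scores of a fine-tuned pretrained
  transformer on real data.  It exists to demonstrate the pipeline's
  mechanics end to end and to give the adapter contract a working
  reference.
* The generator's non-radiology flavor is a thin template family, not a
  reconstruction of real functional-test reports.
* Token-level scoring is the only mode; span-exact scoring is a non-goal
  in this version.
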