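# deidkit

Rule-based and weakly supervised de-identification of bilingual
(Korean/English) clinical notes.

Clinical notes can't be shared for research while they contain protected
health information (PHI).  In Korean tertiary-hospital radiology reports
the PHI that actually occurs is dominated by dates, then names of medical
staff and patients, hospital names, regions, internal phone/extension
numbers, and occasional demographics.  `deidkit` is for NLP engineers and
clinical-data teams who need that PHI found and masked, and who want the
two-stage recipe that works with very little annotated data:

1. **A six-category rule engine** — 51 regular expressions over the
   categories DAT, PER (staff/patient), ORG, LOC, NUM, ETC.  Rules are
   anchored on *identifier words* (non-PHI context such as 환자이름,
   판독의, `Tel.`) and mask only the PHI capture group, so
   `판독의: 홍길동` becomes `판독의: [PER]`.
2. **Pseudo-labeling + a learned tagger** — the rules auto-annotate a
   large note pool into token-level BIO corpora (tiers of 800/1,600/3,200
   notes), on which an averaged-perceptron sequence tagger is trained
   with cost-sensitive updates (entity labels from high-precision rules
   are trusted more than O labels).  The learned model generalizes past
   the rules' literal patterns and recovers part of their recall gap; a
   correction pass that strips rule false positives from the training
   corpus further improves its precision.

Evaluation is token-level per category (B/I collapsed): precision,
recall, F1 and micro totals.  Since real notes are not shareable, a
seeded synthetic-note generator with gold annotations stands in for
them; it reproduces the genre's mechanics — identifier-anchored PHI,
homonym traps (고려 "considering" vs. 고려대병원, 중앙값 "median",
CMC-as-joint), long-tailed notation variety, measurement numerals that
look like dates — so every pipeline stage is testable offline.
See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from deidkit import ClinicalNote, apply_rules, compile_ruleset, mask_text

rules = compile_ruleset()          # the shipped 51-rule set
note = ClinicalNote(
    note_id="r1",
    department="radiology",
    text="2019-02-04 촬영한 영상과 비교함.\n판독의: 홍길동\n1.2-1.7 cm sized nodule.",
)
matches = apply_rules(note, rules)
for m in matches:
    print(m.span.slice(note.text), m.category.value, m.rule_id)
print(mask_text(note, matches))
```

prints

```
2019-02-04 DAT dat_ymd_dash
홍길동 PER per_pandok
[DAT] 촬영한 영상과 비교함.
판독의: [PER]
1.2-1.7 cm sized nodule.
```

The date and the radiologist's name are masked with category
placeholders; the identifier word 판독의 survives (it is context, not
PHI); and the measurement range `1.2-1.7` is left alone — numeric dates
require a plausible 4-digit year, a deliberate precision-over-recall
trade for the genre's classic date-vs-measurement ambiguity.

The same stages are available from the shell:

```bash
deidkit synth --seed 1 --n 1000 --out notes.jsonl        # synthetic notes + gold
deidkit mask  --in notes.jsonl --out masked.jsonl        # rule masking
deidkit label --in notes.jsonl --n 800 --seed 1 --out train.conll
deidkit train --corpus train.conll --epochs 3 --seed 1 --out model.json
deidkit predict --model model.json --in notes.jsonl --out pred.conll
deidkit eval  --gold gold.conll --pred pred.conll --out report.json
deidkit run   --seed 1 --n-train 800                     # whole pipeline, both reports
```

`deidkit run` ends by printing two token-level tables on the same
held-out notes — one for the rule engine, one for the trained tagger —
which is the comparison the whole package exists to make.

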