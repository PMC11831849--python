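"""Desk-scale study designs: the training-size trend, the rule-vs-tagger
recall gap, and the corpus-correction precision benefit.

The absolute scores of a transformer fine-tuned on institutional data are
not reproducible without that data; what is reproducible — and what these
experiments measure on the synthetic benchmark — are the directional
claims: held-out accuracy grows with the amount of pseudo-labeled training
data, a learned tagger recalls pattern variants the rules miss, and
removing rule false positives from the training corpus improves the
model's precision.

Problem sizes are scaled to a desk: training tiers of 800 / 1,600 / 3,200
pseudo-labeled notes (a 1:2:4 ladder mirroring the source study's
8k/16k/32k), a 400-note held-out set, and 5 random seeds per condition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .core import AnnotatedNote
from .evaluation import EvalReport, evaluate
from .pseudo_label import (
    TaggedCorpus,
    TaggedNote,
    Tier,
    apply_corrections,
    corrections_from_gold,
    label_note,
    label_note_gold,
    sample_corpus,
)
from .rules import RuleSet, compile_ruleset
from .synth import SynthConfig, generate_corpus
from .tagger import PerceptronTagger

TIER_SIZES: Dict[Tier, int] = {Tier.SMALL: 800, Tier.MEDIUM: 1600, Tier.LARGE1: 3200}
N_POOL = 4500  # PHI-note training pool; comfortably exceeds the largest tier
N_HELDOUT = 400
N_SEEDS = 5
EPOCHS = 3
OOS_FRACTION = 0.15
TRAP_RATE_CORRECTION = 0.20


def _seed(base: int, k: int) -> int:
    return (base * 100003 + k) % (2**31)


def make_training_pool(seed: int, oos: float = OOS_FRACTION, traps: float = 0.0) -> List[AnnotatedNote]:
    """PHI-note pool for tier sampling (non-PHI notes would be discarded by
    corpus construction anyway, so the pool generates PHI notes only)."""
    cfg = SynthConfig(
        seed=seed,
        n_notes=N_POOL,
        phi_note_fraction=1.0,
        out_of_scope_fraction=oos,
        homonym_trap_rate=traps,
    )
    return generate_corpus(cfg)


def make_heldout(seed: int, oos: float = OOS_FRACTION, traps: float = 0.0) -> List[AnnotatedNote]:
    cfg = SynthConfig(
        seed=seed,
        n_notes=N_HELDOUT,
        phi_note_fraction=1.0,
        out_of_scope_fraction=oos,
        homonym_trap_rate=traps,
    )
    return generate_corpus(cfg)


def rule_report(heldout: Sequence[AnnotatedNote], ruleset: RuleSet) -> EvalReport:
    gold = [label_note_gold(an) for an in heldout]
    pred = [label_note(an.note, ruleset) for an in heldout]
    return evaluate(gold, pred)


def tagger_report(
    tagger: PerceptronTagger, heldout: Sequence[AnnotatedNote]
) -> EvalReport:
    gold = [label_note_gold(an) for an in heldout]
    pred = tagger.predict_corpus(gold)
    return evaluate(gold, pred)


@dataclass
class TrendResult:
    """Mean held-out micro scores per training tier, plus the rule-engine
    baseline on the same held-out set."""

    tier_f1: Dict[str, float]
    tier_recall: Dict[str, float]
    tier_precision: Dict[str, float]
    rule_recall: float
    rule_precision: float
    rule_f1: float
    n_seeds: int
    seeds: List[int] = field(default_factory=list)


def tier_trend_experiment(base_seed: int, n_seeds: int = N_SEEDS) -> TrendResult:
    """Scaled training-size trend.

    Each seed is a full replication — its own training pool, held-out set,
    tier sampling and shuffle order; within a replication all three tiers
    share the pool and the held-out set, so tier comparisons are paired.
    Reported numbers are means over replications.
    """
    ruleset = compile_ruleset()
    sums_f1 = {t.value: 0.0 for t in TIER_SIZES}
    sums_r = {t.value: 0.0 for t in TIER_SIZES}
    sums_p = {t.value: 0.0 for t in TIER_SIZES}
    sum_rule_r = sum_rule_p = sum_rule_f = 0.0
    seeds = [_seed(base_seed, 10 + k) for k in range(n_seeds)]
    for k, s in enumerate(seeds):
        pool = make_training_pool(_seed(base_seed, 100 + k))
        heldout = make_heldout(_seed(base_seed, 200 + k))
        base = rule_report(heldout, ruleset).micro
        sum_rule_r += base.recall
        sum_rule_p += base.precision
        sum_rule_f += base.f1
        labeled = [label_note(an.note, ruleset) for an in pool]
        for tier, size in TIER_SIZES.items():
            corpus = sample_corpus(labeled, tier, size, seed=s)
            tagger = PerceptronTagger(epochs=EPOCHS, seed=s).fit(corpus)
            rep = tagger_report(tagger, heldout).micro
            sums_f1[tier.value] += rep.f1
            sums_r[tier.value] += rep.recall
            sums_p[tier.value] += rep.precision
    n = float(n_seeds)
    return TrendResult(
        tier_f1={k: v / n for k, v in sums_f1.items()},
        tier_recall={k: v / n for k, v in sums_r.items()},
        tier_precision={k: v / n for k, v in sums_p.items()},
        rule_recall=sum_rule_r / n,
        rule_precision=sum_rule_p / n,
        rule_f1=sum_rule_f / n,
        n_seeds=n_seeds,
        seeds=seeds,
    )


@dataclass
class CorrectionResult:
    uncorrected_precision: float
    corrected_precision: float
    uncorrected_recall: float
    corrected_recall: float
    n_removals_mean: float
    n_seeds: int


def correction_experiment(base_seed: int, n_seeds: int = N_SEEDS) -> CorrectionResult:
    """Scaled corpus-correction workflow: pseudo-label a trap-laden pool,
    flag rule entities with no gold overlap as false positives, train on
    both the uncorrected and the corrected corpus, compare held-out
    precision (mean over seeds)."""
    ruleset = compile_ruleset()
    sum_pu = sum_pc = sum_ru = sum_rc = 0.0
    sum_removals = 0.0
    for k in range(n_seeds):
        s = _seed(base_seed, 20 + k)
        pool = make_training_pool(_seed(base_seed, 300 + k), traps=TRAP_RATE_CORRECTION)
        heldout = make_heldout(_seed(base_seed, 400 + k), traps=TRAP_RATE_CORRECTION)
        gold_by_id = {an.note.note_id: an.annotations for an in pool}
        labeled = [label_note(an.note, ruleset) for an in pool]
        corpus = sample_corpus(labeled, Tier.LARGE1, TIER_SIZES[Tier.LARGE1], seed=s)
        corrections = corrections_from_gold(corpus, gold_by_id)
        corrected = apply_corrections(corpus, corrections)
        sum_removals += len(corrections.removals)

        rep_u = tagger_report(PerceptronTagger(epochs=EPOCHS, seed=s).fit(corpus), heldout).micro
        rep_c = tagger_report(PerceptronTagger(epochs=EPOCHS, seed=s).fit(corrected), heldout).micro
        sum_pu += rep_u.precision
        sum_pc += rep_c.precision
        sum_ru += rep_u.recall
        sum_rc += rep_c.recall
    n = float(n_seeds)
    return CorrectionResult(
        uncorrected_precision=sum_pu / n,
        corrected_precision=sum_pc / n,
        uncorrected_recall=sum_ru / n,
        corrected_recall=sum_rc / n,
        n_removals_mean=sum_removals / n,
        n_seeds=n_seeds,
    )
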