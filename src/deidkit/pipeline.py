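"""End-to-end pipeline: synthesize → rule-label → pseudo-label →
(optionally correct) → train → predict → evaluate.

Emits both a rule-engine report and a tagger report on the same held-out
gold, enabling the central rule-vs-learned comparison.  Every stage logs
per-stage counters to stderr, and every artifact embeds the seeds and a
config hash.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass
from typing import Optional, Tuple

from .evaluation import EvalReport, evaluate
from .experiments import rule_report, tagger_report
from .io import config_hash
from .pseudo_label import (
    Tier,
    apply_corrections,
    build_corpus,
    corrections_from_gold,
)
from .rules import compile_ruleset
from .synth import SynthConfig, generate_corpus
from .tagger import PerceptronTagger

logger = logging.getLogger("deidkit")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_train_pool: int = 2000
    n_heldout: int = 400
    n_train_notes: int = 800
    tier: Tier = Tier.CUSTOM
    epochs: int = 3
    out_of_scope_fraction: float = 0.15
    homonym_trap_rate: float = 0.0
    department_mix: float = 0.0
    apply_correction: bool = False
    rules_config: Optional[str] = None  # YAML path; packaged default if None

    def hash(self) -> str:
        d = asdict(self)
        d["tier"] = self.tier.value
        return config_hash(d)


def _log(stage: str, **counters) -> None:
    msg = " ".join(f"{k}={v}" for k, v in counters.items())
    logger.info("[%s] %s", stage, msg)


def run_pipeline(config: PipelineConfig) -> Tuple[EvalReport, EvalReport]:
    """Run the full desk-scale pipeline; returns (rule_report, tagger_report)
    computed on the same held-out gold."""
    if not logger.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    _log("config", hash=config.hash(), seed=config.seed)

    ruleset = compile_ruleset(config.rules_config)
    _log("rules", n_rules=len(ruleset))

    pool_cfg = SynthConfig(
        seed=config.seed * 100003 % (2**31),
        n_notes=config.n_train_pool,
        phi_note_fraction=1.0,
        out_of_scope_fraction=config.out_of_scope_fraction,
        homonym_trap_rate=config.homonym_trap_rate,
        department_mix=config.department_mix,
    )
    pool = generate_corpus(pool_cfg)
    heldout_cfg = SynthConfig(
        seed=(config.seed * 100003 + 1) % (2**31),
        n_notes=config.n_heldout,
        phi_note_fraction=1.0,
        out_of_scope_fraction=config.out_of_scope_fraction,
        homonym_trap_rate=config.homonym_trap_rate,
        department_mix=config.department_mix,
    )
    heldout = generate_corpus(heldout_cfg)
    _log("synth", pool=len(pool), heldout=len(heldout))

    corpus = build_corpus(
        [an.note for an in pool], ruleset, config.tier, config.n_train_notes, seed=config.seed
    )
    _log(
        "pseudo-label",
        notes=len(corpus),
        tokens=sum(len(tn.tokens) for tn in corpus.notes),
        phi_words=sum(corpus.phi_word_counts.values()),
    )

    if config.apply_correction:
        gold_by_id = {an.note.note_id: an.annotations for an in pool}
        corrections = corrections_from_gold(corpus, gold_by_id)
        corpus = apply_corrections(corpus, corrections)
        _log("correct", removals=len(corrections.removals), notes=len(corpus))

    tagger = PerceptronTagger(epochs=config.epochs, seed=config.seed).fit(corpus)
    _log("train", features=len(tagger.weights_), epochs=config.epochs)

    rules_rep = rule_report(heldout, ruleset)
    tag_rep = tagger_report(tagger, heldout)
    _log(
        "evaluate",
        rule_f1=f"{rules_rep.micro.f1:.4f}",
        tagger_f1=f"{tag_rep.micro.f1:.4f}",
    )
    return rules_rep, tag_rep
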