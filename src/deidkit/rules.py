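"""Six-category PHI rule engine: 51 regular-expression rules, overlap
resolution, and masking.

Each rule matches identifier context plus a PHI portion; only the named
``phi`` capture group is annotated, so identifier words (환자이름, 판독의,
Tel., ...) survive masking.  The default rule set deliberately reproduces
the known over-triggers of this style of rule family (고려/중앙/CMC
homonyms, the 상기확인함 split); those false positives are removed
downstream at the corpus level, not patched here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import yaml

from .core import ClinicalNote, PHICategory, PersonRole, Span
from .errors import DeidError, RuleConfigError

#: Expected rule counts for the shipped default configuration.
DEFAULT_EXPECTED_COUNTS = {
    "DAT": 18,
    "PER.staff": 8,
    "PER.patient": 3,
    "ORG": 13,
    "LOC": 1,
    "NUM": 4,
    "ETC": 4,
}

# Tie-break order for equal-length overlapping spans: a city name adjoined
# to a known hospital resolves to ORG over LOC, then dates over names over
# numbers over demographics.
CATEGORY_PRECEDENCE = {
    PHICategory.ORG: 0,
    PHICategory.LOC: 1,
    PHICategory.DAT: 2,
    PHICategory.PER: 3,
    PHICategory.NUM: 4,
    PHICategory.ETC: 5,
}

_NEVER_MATCH = "(?!x)x"


@dataclass(frozen=True)
class Rule:
    rule_id: str
    category: PHICategory
    pattern: str
    phi_group: str = "phi"
    priority: int = 0
    subcategory: Optional[PersonRole] = None
    description: str = ""
    regex: re.Pattern = field(compare=False, repr=False, default=None)

    @staticmethod
    def compile(
        rule_id: str,
        category: PHICategory,
        pattern: str,
        phi_group: str = "phi",
        priority: int = 0,
        subcategory: Optional[PersonRole] = None,
        description: str = "",
    ) -> "Rule":
        try:
            regex = re.compile(pattern)
        except re.error as exc:
            raise RuleConfigError(f"rule {rule_id!r}: pattern does not compile: {exc}") from exc
        if phi_group not in regex.groupindex:
            raise RuleConfigError(f"rule {rule_id!r}: missing capture group {phi_group!r}")
        if category is PHICategory.PER and subcategory is None:
            raise RuleConfigError(f"rule {rule_id!r}: PER rule needs a staff/patient subcategory")
        return Rule(rule_id, category, pattern, phi_group, priority, subcategory, description, regex)


@dataclass(frozen=True)
class RuleMatch:
    """The PHI portion matched by one rule firing."""

    rule_id: str
    span: Span
    category: PHICategory
    subcategory: Optional[PersonRole] = None
    priority: int = 0


@dataclass
class RuleSet:
    rules: List[Rule]
    hospital_vocab: List[str] = field(default_factory=list)
    region_vocab: List[str] = field(default_factory=list)
    extension_vocab: List[str] = field(default_factory=list)
    category_counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def by_category(self, category: PHICategory) -> List[Rule]:
        return [r for r in self.rules if r.category is category]


def _count_key(category: PHICategory, subcategory: Optional[PersonRole]) -> str:
    if category is PHICategory.PER:
        return f"PER.{subcategory.value}"
    return category.value


def _vocab_alternation(words: Sequence[str]) -> str:
    words = [w for w in words if w]
    if not words:
        return _NEVER_MATCH
    return "|".join(re.escape(w) for w in sorted(words, key=len, reverse=True))


def load_rule_config(source: Union[str, dict, None] = None) -> dict:
    """Load a rule configuration: a YAML path, a pre-parsed dict, or the
    packaged default when ``source`` is None."""
    if source is None:
        text = resources.files("deidkit.data").joinpath("default_rules.yaml").read_text("utf-8")
        return yaml.safe_load(text)
    if isinstance(source, dict):
        return source
    with open(source, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def compile_ruleset(config: Union[str, dict, None] = None) -> RuleSet:
    """Compile a rule configuration into a validated RuleSet.

    Validates that every pattern compiles, that the ``phi`` group exists,
    that rule ids are unique, and that per-category rule counts match the
    configuration's ``expected_counts`` (the default set totals 51).
    """
    cfg = load_rule_config(config)
    vocab = cfg.get("vocab") or {}
    hospital = list(vocab.get("hospital") or [])
    region = list(vocab.get("region") or [])
    extension = [str(x) for x in (vocab.get("extension") or [])]
    substitutions = {
        "{HOSPITAL_VOCAB}": _vocab_alternation(hospital),
        "{REGION_VOCAB}": _vocab_alternation(region),
        "{EXTENSION_VOCAB}": _vocab_alternation(extension),
    }

    rules: List[Rule] = []
    seen = set()
    for rec in cfg.get("rules") or []:
        rule_id = rec.get("id")
        if not rule_id:
            raise RuleConfigError("rule record without an id")
        if rule_id in seen:
            raise RuleConfigError(f"duplicate rule id {rule_id!r}")
        seen.add(rule_id)
        try:
            category = PHICategory(rec["category"])
        except (KeyError, ValueError) as exc:
            raise RuleConfigError(f"rule {rule_id!r}: bad category: {exc}") from exc
        subcategory = PersonRole(rec["subcategory"]) if rec.get("subcategory") else None
        pattern = rec["pattern"]
        for placeholder, repl in substitutions.items():
            pattern = pattern.replace(placeholder, repl)
        rules.append(
            Rule.compile(
                rule_id,
                category,
                pattern,
                phi_group=rec.get("phi_group", "phi"),
                priority=int(rec.get("priority", 0)),
                subcategory=subcategory,
                description=rec.get("description", ""),
            )
        )

    counts: Dict[str, int] = {}
    for rule in rules:
        key = _count_key(rule.category, rule.subcategory)
        counts[key] = counts.get(key, 0) + 1
    expected = cfg.get("expected_counts")
    if expected:
        expected = {str(k): int(v) for k, v in expected.items()}
        if counts != expected:
            raise RuleConfigError(
                f"rule count mismatch: expected {expected}, compiled {counts}"
            )
    return RuleSet(
        rules=rules,
        hospital_vocab=hospital,
        region_vocab=region,
        extension_vocab=extension,
        category_counts=counts,
    )


def run_rule(rule: Rule, text: str) -> List[RuleMatch]:
    """All firings of one rule over a text, as PHI-portion matches."""
    out: List[RuleMatch] = []
    for m in rule.regex.finditer(text):
        start, end = m.span(rule.phi_group)
        if start == end or start < 0:
            continue
        out.append(RuleMatch(rule.rule_id, Span(start, end), rule.category, rule.subcategory, rule.priority))
    return out


def _match_categories(note: ClinicalNote, ruleset: RuleSet, categories: Iterable[PHICategory]) -> List[RuleMatch]:
    wanted = set(categories)
    raw: List[RuleMatch] = []
    for rule in ruleset.rules:
        if rule.category in wanted:
            raw.extend(run_rule(rule, note.text))
    return resolve_overlaps(raw)


def match_dates(note: ClinicalNote, ruleset: RuleSet) -> List[RuleMatch]:
    return _match_categories(note, ruleset, [PHICategory.DAT])


def match_person(note: ClinicalNote, ruleset: RuleSet) -> List[RuleMatch]:
    return _match_categories(note, ruleset, [PHICategory.PER])


def match_org_loc(note: ClinicalNote, ruleset: RuleSet) -> List[RuleMatch]:
    return _match_categories(note, ruleset, [PHICategory.ORG, PHICategory.LOC])


def match_num_etc(note: ClinicalNote, ruleset: RuleSet) -> List[RuleMatch]:
    return _match_categories(note, ruleset, [PHICategory.NUM, PHICategory.ETC])


def apply_rules(note: ClinicalNote, ruleset: RuleSet) -> List[RuleMatch]:
    """Run every rule over the note and resolve overlaps.

    Deterministic: identical text yields identical matches, sorted by span
    start.
    """
    raw: List[RuleMatch] = []
    for rule in ruleset.rules:
        raw.extend(run_rule(rule, note.text))
    return resolve_overlaps(raw)


def resolve_overlaps(matches: Sequence[RuleMatch]) -> List[RuleMatch]:
    """Reduce raw rule firings to pairwise non-overlapping matches.

    Conflict policy (a total order, so the result is unique): longer span
    wins; on equal length ORG > LOC > DAT > PER > NUM > ETC; then leftmost;
    then the lower rule priority number; then rule id.
    """
    ranked = sorted(
        matches,
        key=lambda m: (
            -len(m.span),
            CATEGORY_PRECEDENCE[m.category],
            m.span.start,
            m.priority,
            m.rule_id,
        ),
    )
    kept: List[RuleMatch] = []
    for cand in ranked:
        if not any(cand.span.overlaps(k.span) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda m: m.span.start)
    return kept


def mask_text(note: ClinicalNote, matches: Sequence[RuleMatch]) -> str:
    """Replace each match span with its category placeholder, e.g. [DAT].

    Matches must be pairwise non-overlapping and within bounds; text outside
    the spans is unchanged.
    """
    ordered = sorted(matches, key=lambda m: m.span.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.span.overlaps(b.span):
            raise DeidError(f"overlapping mask spans {a.span} and {b.span}")
    text = note.text
    if ordered and ordered[-1].span.end > len(text):
        raise DeidError("mask span exceeds note bounds")
    pieces: List[str] = []
    pos = 0
    for m in ordered:
        pieces.append(text[pos : m.span.start])
        pieces.append(f"[{m.category.value}]")
        pos = m.span.end
    pieces.append(text[pos:])
    return "".join(pieces)
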