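"""Reference sequence tagger: an averaged perceptron over windowed
token features with greedy left-to-right decoding.

This is the trainable stand-in that demonstrates what pseudo-label-driven
learning adds on top of the rules — contextual and lexical generalization
beyond the exact patterns — at desk scale, with no pretrained weights.
External pretrained transformer taggers can plug in through the
``SequenceTagger`` protocol, consuming and producing the same corpus and
token types.
"""

from __future__ import annotations

import json
import random
from typing import Dict, Iterable, List, Optional, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np

from .core import Span
from .errors import DeidError, NotFittedError, TrainingError
from .pseudo_label import BIO_TAGS, LabeledToken, TaggedCorpus, TaggedNote, repair_bio
from .tokenize import HANGUL, WORD, script_class

#: Non-PHI identifier words that anchor PHI in clinical notes; their
#: presence in the context window is a strong cue for the neighboring tag.
IDENTIFIER_WORDS = frozenset(
    {
        "환자이름", "환자명", "판독의", "의료진", "전화번호", "환자번호",
        "Tel", "TEL", "T", "by", "from", "confirmed", "교수", "확인함",
    }
)

_TAG_INDEX = {t: i for i, t in enumerate(BIO_TAGS)}


def token_shape(surface: str, max_len: int = 8) -> str:
    """Digits to 9, Hangul to H, Latin to a; other characters verbatim."""
    out = []
    for ch in surface[:max_len]:
        if ch.isdigit():
            out.append("9")
        elif script_class(ch) == HANGUL:
            out.append("H")
        elif ch.isascii() and ch.isalpha():
            out.append("a")
        else:
            out.append(ch)
    return "".join(out)


def extract_features(tokens: Sequence, position: int) -> List[str]:
    """Deterministic, position-local features for the token at ``position``.

    Window is ±2 tokens; editing anything outside the window leaves the
    features unchanged.  Accepts (surface, span) pairs or LabeledTokens.
    """
    n = len(tokens)
    if not (0 <= position < n):
        raise DeidError(f"position {position} out of range for {n} tokens")

    def surf(i: int) -> Optional[str]:
        if i < 0 or i >= n:
            return None
        tok = tokens[i]
        return tok[0] if isinstance(tok, tuple) else tok.surface

    w = surf(position)
    shape = token_shape(w)
    feats = [f"W={w}", f"S={shape}", f"C={script_class(w[0])}"]
    for off in (-2, -1, 1, 2):
        s = surf(position + off)
        if s is None:
            feats.append(f"BND{off:+d}")
        else:
            feats.append(f"W{off:+d}={s}")
            if off in (-1, 1):
                feats.append(f"S{off:+d}={token_shape(s)}")
    # Neighbor conjunctions, the usual discriminative-NER feature templates.
    prev_s = surf(position - 1)
    next_s = surf(position + 1)
    feats.append(f"W-1|W={prev_s}|{w}")
    feats.append(f"W|W+1={w}|{next_s}")
    feats.append(f"S-1|S={token_shape(prev_s) if prev_s else None}|{shape}")
    feats.append(f"S|S+1={shape}|{token_shape(next_s) if next_s else None}")
    for off in (-2, -1, 0, 1, 2):
        s = surf(position + off)
        if s is not None and s in IDENTIFIER_WORDS:
            feats.append(f"ID{off:+d}={s}")
    return feats


def enforce_bio_validity(tags: Sequence[str]) -> List[str]:
    """Rewrite any orphan I-X to B-X.  Idempotent."""
    out: List[str] = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-") and prev not in (f"B-{tag[2:]}", tag):
            tag = "B-" + tag[2:]
        out.append(tag)
        prev = tag
    return out


@runtime_checkable
class SequenceTagger(Protocol):
    """Adapter contract for external taggers (e.g. fine-tuned transformer
    NER models): train on a TaggedCorpus, emit BIO-valid LabeledTokens."""

    def fit(self, corpus: TaggedCorpus) -> "SequenceTagger": ...

    def predict(self, tokens: Sequence[Tuple[str, Span]]) -> List[LabeledToken]: ...


class PerceptronTagger:
    """Averaged-perceptron BIO tagger with a previous-tag decoding feature.

    Training is cost-sensitive for weak supervision: pseudo-labels produced
    by high-precision rules are trustworthy where they mark an entity but
    unreliable where they say O (rule recall < 1 means some O tokens are
    unmarked PHI), so updates on O-labeled tokens are down-weighted by
    ``neg_cost``.

    Parameters
    ----------
    epochs : int
        Passes over the (seeded-shuffled) training notes.
    seed : int
        Controls the shuffle order; training is fully deterministic.
    neg_cost : float
        Update magnitude for errors on O-labeled tokens, in (0, 1].  1.0
        recovers the symmetric perceptron; the default trusts entity labels
        twice as much as O labels.
    """

    def __init__(self, epochs: int = 5, seed: int = 0, neg_cost: float = 0.5):
        self.epochs = epochs
        self.seed = seed
        self.neg_cost = neg_cost

    # -- sklearn-style parameter plumbing --------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"epochs": self.epochs, "seed": self.seed, "neg_cost": self.neg_cost}

    def set_params(self, **params) -> "PerceptronTagger":
        for key, value in params.items():
            if key not in ("epochs", "seed", "neg_cost"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- training ----------------------------------------------------------
    def fit(self, corpus: TaggedCorpus | Sequence[TaggedNote]) -> "PerceptronTagger":
        notes = list(corpus.notes) if isinstance(corpus, TaggedCorpus) else list(corpus)
        if not notes:
            raise TrainingError("cannot train on an empty corpus")
        n_tags = len(BIO_TAGS)
        weights: Dict[str, np.ndarray] = {}
        totals: Dict[str, np.ndarray] = {}
        stamps: Dict[str, int] = {}
        t = 1

        static = [
            [extract_features(tn.tokens, i) for i in range(len(tn.tokens))] for tn in notes
        ]
        gold = [[_TAG_INDEX[tok.tag] for tok in tn.tokens] for tn in notes]

        def score(feats: List[str]) -> np.ndarray:
            s = np.zeros(n_tags)
            for f in feats:
                w = weights.get(f)
                if w is not None:
                    s += w
            return s

        def bump(f: str, idx: int, delta: float) -> None:
            w = weights.get(f)
            if w is None:
                w = np.zeros(n_tags)
                weights[f] = w
                totals[f] = np.zeros(n_tags)
                stamps[f] = t
            else:
                totals[f] += (t - stamps[f]) * w
                stamps[f] = t
            w[idx] += delta

        rng = random.Random(self.seed)
        order = list(range(len(notes)))
        for _ in range(self.epochs):
            rng.shuffle(order)
            for ni in order:
                prev = "O"
                for i, feats in enumerate(static[ni]):
                    full = feats + [f"PT={prev}"]
                    pred = int(np.argmax(score(full)))
                    g = gold[ni][i]
                    if pred != g:
                        delta = self.neg_cost if g == 0 else 1.0  # index 0 is O
                        for f in full:
                            bump(f, g, delta)
                            bump(f, pred, -delta)
                    t += 1  # time advances every token, so stable late weights dominate the average
                    prev = BIO_TAGS[pred]

        # Classic averaging: mean of the weight vector over all update steps.
        averaged: Dict[str, List[float]] = {}
        for f, w in weights.items():
            total = totals[f] + (t - stamps[f]) * w
            vec = total / t
            if np.any(vec):
                averaged[f] = [float(x) for x in vec]
        self.weights_ = averaged
        self.classes_ = list(BIO_TAGS)
        self.meta_ = {
            "epochs": self.epochs,
            "seed": self.seed,
            "n_notes": len(notes),
            "tier": corpus.tier.value if isinstance(corpus, TaggedCorpus) else "custom",
        }
        return self

    # -- inference ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise NotFittedError("PerceptronTagger.predict called before fit")

    def predict_tags(self, tokens: Sequence[Tuple[str, Span]]) -> List[str]:
        self._check_fitted()
        if getattr(self, "_warr", None) is None or len(self._warr) != len(self.weights_):
            self._warr = {f: np.asarray(v, dtype=float) for f, v in self.weights_.items()}
        n_tags = len(BIO_TAGS)
        tags: List[str] = []
        prev = "O"
        for i in range(len(tokens)):
            feats = extract_features(tokens, i) + [f"PT={prev}"]
            s = np.zeros(n_tags)
            for f in feats:
                w = self._warr.get(f)
                if w is not None:
                    s += w
            pred = BIO_TAGS[int(np.argmax(s))]
            tags.append(pred)
            prev = pred
        return enforce_bio_validity(tags)

    def predict(self, tokens: Sequence[Tuple[str, Span]]) -> List[LabeledToken]:
        tags = self.predict_tags(tokens)
        return [
            LabeledToken(surface, span, tag)
            for (surface, span), tag in zip(tokens, tags)
        ]

    def predict_note(self, tn: TaggedNote) -> TaggedNote:
        """Re-tag a note's tokens (existing tags ignored)."""
        pairs = [(t.surface, t.span) for t in tn.tokens]
        return TaggedNote(tn.note, self.predict(pairs))

    def predict_corpus(self, notes: Iterable[TaggedNote]) -> List[TaggedNote]:
        return [self.predict_note(tn) for tn in notes]

    # -- serialization ----------------------------------------------------
    def save(self, path: str) -> None:
        self._check_fitted()
        payload = {"tags": self.classes_, "meta": self.meta_, "weights": self.weights_}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "PerceptronTagger":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        model = cls(
            epochs=payload["meta"].get("epochs", 5), seed=payload["meta"].get("seed", 0)
        )
        model.weights_ = {f: [float(x) for x in v] for f, v in payload["weights"].items()}
        model.classes_ = payload["tags"]
        model.meta_ = payload["meta"]
        return model


def train(corpus: TaggedCorpus, epochs: int, seed: int) -> PerceptronTagger:
    """Functional wrapper over PerceptronTagger.fit."""
    return PerceptronTagger(epochs=epochs, seed=seed).fit(corpus)
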