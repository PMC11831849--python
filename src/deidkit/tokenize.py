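"""Mixed-script tokenizer for Korean/English clinical text.

Whitespace splits first (the eojeol level), then each chunk is split at
boundaries between three script classes: Hangul, Latin-or-digit, and
everything else (punctuation; consecutive punctuation of the same class
stays one token).  ``"2019-02-04 촬영"`` therefore tokenizes to
``2019 / - / 02 / - / 04 / 촬영``.  Concatenating the tokens with the
original inter-token text reconstructs the note exactly.
"""

from __future__ import annotations

from typing import List, Tuple

from .core import Span

HANGUL = "H"
WORD = "A"  # Latin letters and digits share one class
PUNCT = "P"


def script_class(ch: str) -> str:
    o = ord(ch)
    if 0xAC00 <= o <= 0xD7A3 or 0x1100 <= o <= 0x11FF or 0x3130 <= o <= 0x318F:
        return HANGUL
    if ch.isascii() and ch.isalnum():
        return WORD
    return PUNCT


def tokenize(text: str) -> List[Tuple[str, Span]]:
    """Return (surface, span) pairs covering every non-space character."""
    tokens: List[Tuple[str, Span]] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        cls = script_class(text[i])
        j = i + 1
        while j < n and not text[j].isspace() and script_class(text[j]) == cls:
            j += 1
        tokens.append((text[i:j], Span(i, j)))
        i = j
    return tokens
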