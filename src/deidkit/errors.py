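"""Exception hierarchy for deidkit."""


class DeidError(Exception):
    """Base class for all deidkit errors."""


class NoteFormatError(DeidError):
    """A note record is malformed (undecodable text, missing keys, bad span)."""


class RuleConfigError(DeidError):
    """The rule-set configuration is invalid (bad pattern, count mismatch)."""


class CorpusError(DeidError):
    """Corpus construction failed (e.g. not enough PHI-bearing notes)."""


class CorrectionError(DeidError):
    """A correction references an annotation that does not exist."""


class AlignmentError(DeidError):
    """Gold and predicted token sequences do not align."""


class TrainingError(DeidError):
    """Tagger training was asked to do something impossible."""


class NotFittedError(DeidError):
    """Predict was called on an unfitted tagger."""
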