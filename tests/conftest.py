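import pytest

from deidkit.core import ClinicalNote, Department
from deidkit.rules import compile_ruleset
from deidkit.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def ruleset():
    return compile_ruleset()


@pytest.fixture(scope="session")
def small_corpus():
    """200 in-scope-only annotated notes (all PHI-bearing)."""
    return generate_corpus(SynthConfig(seed=42, n_notes=200, phi_note_fraction=1.0))


@pytest.fixture(scope="session")
def mixed_corpus():
    """Notes with out-of-scope variants and homonym traps."""
    return generate_corpus(
        SynthConfig(
            seed=43,
            n_notes=200,
            phi_note_fraction=1.0,
            out_of_scope_fraction=0.2,
            homonym_trap_rate=0.3,
        )
    )


def note(text: str, note_id: str = "n1", department: str = "radiology") -> ClinicalNote:
    return ClinicalNote(note_id=note_id, department=Department(department), text=text)


@pytest.fixture
def make_note():
    return note
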