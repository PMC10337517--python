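import pytest

from famhist.lexicon import Lexicon, LexiconEntry, SemanticType


def entry(variant, cui, stype="T047", snomed="", pref=""):
    return LexiconEntry(variant, cui, snomed, pref or variant.capitalize(),
                        SemanticType(stype))


@pytest.fixture
def tiny_lexicon():
    """Hand-built mini-lexicon exercising multiword variants, typo variants
    and an ambiguous variant shared by two concepts."""
    return Lexicon([
        entry("diabetes", "C0011854", "T047", "73211009"),
        entry("diabetes mellitus", "C0011854", "T047", "73211009"),
        entry("typediabetes", "C0011854"),
        entry("colon cancer", "C0007102", "T191"),
        entry("cancer", "C0006826", "T191"),
        entry("asthma", "C0004096", "T047"),
        entry("allergic asthma", "C0155877", "T047"),
        entry("hypertension", "C0020538", "T047"),
        entry("mi", "C0027051", "T047", "", "Myocardial infarction"),
        # ambiguous variant: maps to two CUIs
        entry("growth", "C0018270", "T033"),
        entry("growth", "C0220844", "T191"),
    ])
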