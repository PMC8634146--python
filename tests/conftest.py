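import pytest

from discrimlex import GeneratorSpec, Lexicon, ParadigmEntry, generate_toy_lexicon


def aal_paradigm() -> Lexicon:
    """The seven-cell eel paradigm: three surface forms, heavy homophony."""
    rows = [
        ("al", "nominative", "singular", 29),
        ("al", "dative", "singular", 29),
        ("al", "accusative", "singular", 29),
        ("al@", "nominative", "plural", 34),
        ("al@", "genitive", "plural", 34),
        ("al@n", "dative", "plural", 17),
        ("al@n", "accusative", "plural", 17),
    ]
    return Lexicon(
        [
            ParadigmEntry(form=f, lemma="al", case=c, number=n, gender="m", frequency=q)
            for f, c, n, q in rows
        ]
    )


@pytest.fixture
def aal():
    return aal_paradigm()


@pytest.fixture(scope="session")
def toy_lexicon():
    """Mid-sized synthetic lexicon with ground truth, shared across tests."""
    return generate_toy_lexicon(GeneratorSpec(n_lemmas=60, seed=7))


@pytest.fixture(scope="session")
def small_lexicon():
    return generate_toy_lexicon(GeneratorSpec(n_lemmas=12, seed=3))
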