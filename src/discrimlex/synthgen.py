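"""Seeded generator of German-like noun paradigm lexicons and wug nonces.

The generator emulates the structural properties of the German noun system
that the modeling machinery is sensitive to, without claiming phonotactic
fidelity: five declension classes with plural suffixes and optional stem-vowel
fronting at realistic type frequencies, a fixed within-paradigm homophony
template (nominative/dative/accusative singular identical; nominative/
genitive/accusative plural identical; dative plural adds -n), Zipf-distributed
token frequencies, three genders, and CV-maximal-onset syllabification so the
syllable cue mode is exercisable. Ground truth (class per lemma, homophone
groups, frequencies) is returned alongside the lexicon for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lexicon import CASES, Lexicon, ParadigmEntry

#: vowel fronting used for umlauting classes; keys are the generator's vowels
UMLAUT = {"a": "ä", "o": "ö", "u": "ü"}


@dataclass(frozen=True)
class DeclensionClass:
    name: str
    plural_suffix: str
    umlaut: bool
    probability: float


#: Class inventory mirroring the relative type frequencies of the five German
#: plural classes: -(e)n 56.5, (uml+)-e 23.9, (uml+)-er 2.3, (uml+)-zero 13.3,
#: -s 2.6 (percent; renormalized).
DEFAULT_CLASSES = (
    DeclensionClass("en", "@n", False, 0.565),
    DeclensionClass("e", "@", True, 0.239),
    DeclensionClass("er", "@r", True, 0.023),
    DeclensionClass("zero", "", True, 0.133),
    DeclensionClass("s", "s", False, 0.026),
)


@dataclass
class GeneratorSpec:
    n_lemmas: int = 100
    consonants: str = "bdfgklmnprstvz"
    vowels: str = "aeiou"
    stem_lengths: tuple[int, ...] = (3, 4, 5)
    classes: tuple[DeclensionClass, ...] = DEFAULT_CLASSES
    gender_probs: tuple[float, float, float] = (0.35, 0.45, 0.20)  # m, f, n
    zipf_exponent: float = 2.0
    seed: int = 0

    def __post_init__(self):
        total = sum(c.probability for c in self.classes)
        if total <= 0:
            raise ValueError("class probabilities must be positive")
        # renormalize once so published rounded percentages are usable as-is
        if abs(total - 1.0) > 1e-9:
            self.classes = tuple(
                DeclensionClass(c.name, c.plural_suffix, c.umlaut, c.probability / total)
                for c in self.classes
            )


@dataclass
class GroundTruth:
    class_per_lemma: dict[str, str]
    homophone_groups: dict[str, list[tuple[str, str, str]]]  # form -> (lemma, case, number)
    form_frequencies: dict[tuple[str, str], int]  # (lemma, form) -> freq


def syllabify(form: str, vowels: str) -> tuple[str, ...]:
    """CV-maximal-onset syllabification over the generator's own alphabet.

    Intervocalic consonant clusters attach entirely to the following
    syllable's onset; word-final consonants close the last syllable. '@' is
    treated as a vowel (schwa).
    """
    vset = set(vowels) | {"@"} | set(UMLAUT.values())
    nuclei = [i for i, ch in enumerate(form) if ch in vset]
    if not nuclei:
        return (form,)
    bounds = [0]
    for prev, nxt in zip(nuclei, nuclei[1:]):
        bounds.append(prev + 1)  # maximal onset: all consonants go right
    bounds.append(len(form))
    sylls = [form[a:b] for a, b in zip(bounds, bounds[1:])]
    return tuple(s for s in sylls if s)


def _apply_umlaut(stem: str) -> str:
    # front the last backable vowel, as German umlauting plurals do
    for i in range(len(stem) - 1, -1, -1):
        if stem[i] in UMLAUT:
            return stem[: i] + UMLAUT[stem[i]] + stem[i + 1 :]
    return stem


def paradigm_forms(stem: str, gender: str, cls: DeclensionClass) -> dict[tuple[str, str], str]:
    """Surface form per (case, number) cell, following the homophony template.

    Singular: nominative/dative/accusative share the bare stem; the genitive
    adds -s for masculine/neuter and stays bare for feminine (so feminine
    singulars are four-way homophones). Plural: nominative/genitive/accusative
    share the plural base (stem, optionally umlauted, plus the class suffix);
    the dative plural adds -n unless the base already ends in -n or the class
    is -s.
    """
    plural_base = (_apply_umlaut(stem) if cls.umlaut else stem) + cls.plural_suffix
    if plural_base.endswith("n") or cls.name == "s":
        dat_pl = plural_base
    else:
        dat_pl = plural_base + "n"
    gen_sg = stem if gender == "f" else stem + "s"
    return {
        ("nominative", "singular"): stem,
        ("genitive", "singular"): gen_sg,
        ("dative", "singular"): stem,
        ("accusative", "singular"): stem,
        ("nominative", "plural"): plural_base,
        ("genitive", "plural"): plural_base,
        ("dative", "plural"): dat_pl,
        ("accusative", "plural"): plural_base,
    }


def generate_toy_lexicon(spec: GeneratorSpec) -> tuple[Lexicon, GroundTruth]:
    """Deterministically generate a full-paradigm lexicon plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    max_stems = sum(
        (len(spec.consonants) ** 2) * len(spec.vowels) ** max(1, (l - 2) // 2)
        for l in spec.stem_lengths
    )
    if spec.n_lemmas > max_stems:
        raise ValueError("alphabet too small for the requested number of distinct stems")

    stems: list[str] = []
    seen: set[str] = set()
    guard = 0
    while len(stems) < spec.n_lemmas:
        guard += 1
        if guard > 1000 * max(1, spec.n_lemmas):
            raise ValueError("alphabet too small for the requested number of distinct stems")
        length = int(rng.choice(spec.stem_lengths))
        chars = []
        for i in range(length):
            pool = spec.vowels if i % 2 == 1 else spec.consonants
            chars.append(pool[int(rng.integers(len(pool)))])
        stem = "".join(chars)
        if stem not in seen:
            seen.add(stem)
            stems.append(stem)

    class_probs = [c.probability for c in spec.classes]
    class_idx = rng.choice(len(spec.classes), size=spec.n_lemmas, p=class_probs)
    genders = rng.choice(["m", "f", "n"], size=spec.n_lemmas, p=spec.gender_probs)

    entries: list[ParadigmEntry] = []
    gt = GroundTruth({}, {}, {})
    for li, stem in enumerate(stems):
        cls = spec.classes[class_idx[li]]
        gender = str(genders[li])
        gt.class_per_lemma[stem] = cls.name
        forms = paradigm_forms(stem, gender, cls)
        # one Zipf token frequency per distinct surface form of the lemma
        distinct = []
        for (case, number), form in forms.items():
            if form not in [f for f, _ in distinct]:
                distinct.append((form, int(rng.zipf(spec.zipf_exponent))))
        freq_of = dict(distinct)
        for (case, number) in [(c, n) for n in ("singular", "plural") for c in CASES]:
            form = forms[(case, number)]
            gt.homophone_groups.setdefault(form, []).append((stem, case, number))
            gt.form_frequencies[(stem, form)] = freq_of[form]
            entries.append(
                ParadigmEntry(
                    form=form,
                    lemma=stem,
                    case=case,
                    number=number,
                    gender=gender,
                    frequency=freq_of[form],
                    syllables=syllabify(form, spec.vowels),
                )
            )
    return Lexicon(entries, source=f"synthetic(seed={spec.seed})"), gt


def generate_wug_nonces(
    spec: GeneratorSpec,
    n: int,
    rhyme_with: Lexicon,
    rhyme_length: int = 2,
    seed: Optional[int] = None,
) -> list[str]:
    """Nonce forms rhyming with the lexicon but absent from it.

    Each nonce shares its final ``rhyme_length`` symbols with at least one
    existing form (nonces without existing rhymes would carry mostly untrained
    cues), and is guaranteed not to be a surface form of the lexicon.
    """
    if len(rhyme_with) == 0:
        raise ValueError("rhyme lexicon must be non-empty")
    if n == 0:
        return []
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    existing = set(rhyme_with.forms())
    bases = sorted({f for f in existing if len(f) > rhyme_length})
    if not bases:
        raise ValueError("cannot satisfy the rhyme constraint")
    nonces: list[str] = []
    guard = 0
    while len(nonces) < n:
        guard += 1
        if guard > 10_000 * n:
            raise ValueError("cannot satisfy the rhyme constraint")
        # swap the initial consonant of an existing form: maximal rhyme,
        # and the onset-vowel junction stays a familiar cue shape
        base = bases[int(rng.integers(len(bases)))]
        onset = spec.consonants[int(rng.integers(len(spec.consonants)))]
        cand = onset + base[1:]
        if onset != base[0] and cand not in existing and cand not in nonces:
            nonces.append(cand)
    return nonces
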