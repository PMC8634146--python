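"""Sublexical cue extraction and the binary cue matrix C.

Word forms are decomposed into overlapping n-grams over phones, letters, or
syllables, padded with a boundary symbol ``#``. A form is then a binary vector
over the cue inventory (1 = cue present), and the lexicon's stacked vectors
form the cue matrix C. Identical surface forms receive identical rows, which
is what makes paradigm-cell homophony visible to the linear mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lexicon import Lexicon, ParadigmEntry

BOUNDARY = "#"
SYLLABLE_SEP = "-"

UNITS = ("phone_ngram", "syllable_ngram", "letter_ngram")


def extract_ngram_cues(form: str, n: int) -> list[str]:
    """All length-n substrings of ``#form#``, in order.

    For *Aale* (al@): biphones #a, al, l@, @# and triphones #al, al@, l@#.
    A form shorter than n-2 symbols collapses to the single padded cue.
    """
    if not form:
        raise ValueError("form must be non-empty")
    if n < 2:
        raise ValueError("n must be at least 2")
    padded = BOUNDARY + form + BOUNDARY
    if len(padded) < n:
        return [padded]
    return [padded[i : i + n] for i in range(len(padded) - n + 1)]


def extract_syllable_cues(syllables: Sequence[str], n: int) -> list[str]:
    """All length-n windows over [#, syl1, ..., sylm, #], joined by '-'.

    For *Aale* syllabified as a-l@, the bi-syllable cues are #-a, a-l@, l@-#.
    """
    if not syllables:
        raise ValueError("syllable list must be non-empty")
    if n < 2:
        raise ValueError("n must be at least 2")
    elems = [BOUNDARY, *syllables, BOUNDARY]
    if len(elems) < n:
        return [SYLLABLE_SEP.join(elems)]
    return [SYLLABLE_SEP.join(elems[i : i + n]) for i in range(len(elems) - n + 1)]


def entry_cues(entry: ParadigmEntry, unit: str, n: int) -> list[str]:
    """Cues for one lexicon entry under the given unit."""
    if unit in ("phone_ngram", "letter_ngram"):
        return extract_ngram_cues(entry.form, n)
    if unit == "syllable_ngram":
        if entry.syllables is None:
            raise ValueError(f"entry {entry.form!r} has no syllabification")
        return extract_syllable_cues(entry.syllables, n)
    raise ValueError(f"unknown cue unit {unit!r}")


@dataclass
class CueInventory:
    """Ordered vocabulary of cues with a cue -> column index.

    Order is first occurrence over the lexicon the inventory was built from,
    which makes rebuilding deterministic without any sorting assumption.
    """

    unit: str
    n: int
    cues: list[str]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {c: j for j, c in enumerate(self.cues)}
        if len(self.index) != len(self.cues):
            raise ValueError("cues must be distinct")

    def __len__(self) -> int:
        return len(self.cues)

    def __contains__(self, cue: str) -> bool:
        return cue in self.index

    def split_cue(self, cue: str) -> list[str]:
        """Cue as a list of unit symbols (phones/letters, or syllables)."""
        if self.unit == "syllable_ngram":
            return cue.split(SYLLABLE_SEP)
        return list(cue)


@dataclass
class CueMatrix:
    """Binary form matrix: rows = lexicon entries, columns = inventory cues."""

    values: np.ndarray
    inventory: CueInventory
    row_keys: list[int]

    def __post_init__(self):
        if self.values.shape[1] != len(self.inventory):
            raise ValueError("column count does not match inventory size")


def vectorize_form(
    form_or_syllables, inventory: CueInventory, n: Optional[int] = None
) -> tuple[np.ndarray, list[str]]:
    """Binary cue vector of a form against a frozen inventory.

    Returns the vector and the novel cues (absent from the inventory), in
    order of occurrence. A zero vector is allowed; callers decide whether that
    is fatal.
    """
    n = n or inventory.n
    if isinstance(form_or_syllables, str):
        cues = extract_ngram_cues(form_or_syllables, n)
    else:
        cues = extract_syllable_cues(form_or_syllables, n)
    vec = np.zeros(len(inventory))
    novel = []
    for c in cues:
        j = inventory.index.get(c)
        if j is None:
            if c not in novel:
                novel.append(c)
        else:
            vec[j] = 1.0
    return vec, novel


def build_cue_matrix(
    lex: Lexicon,
    unit: str = "phone_ngram",
    n: int = 3,
    inventory: Optional[CueInventory] = None,
) -> tuple[CueMatrix, CueInventory, dict[int, list[str]]]:
    """Build (or apply) a cue inventory and fill the binary matrix C.

    Without an inventory, cues are collected in first-occurrence order over
    the lexicon. With a frozen inventory (validation vectorization), cues
    absent from it are dropped and reported per entry; an entry losing all
    its cues yields an all-zero row, flagged with key ``"__all_novel__"``
    prepended to its report list.
    """
    frozen = inventory is not None
    if not frozen:
        cues_in_order: list[str] = []
        seen: set[str] = set()
        for e in lex:
            for c in entry_cues(e, unit, n):
                if c not in seen:
                    seen.add(c)
                    cues_in_order.append(c)
        inventory = CueInventory(unit=unit, n=n, cues=cues_in_order)

    values = np.zeros((len(lex), len(inventory)))
    novel_report: dict[int, list[str]] = {}
    for i, e in enumerate(lex):
        novel = []
        for c in entry_cues(e, inventory.unit, inventory.n):
            j = inventory.index.get(c)
            if j is None:
                if c not in novel:
                    novel.append(c)
            else:
                values[i, j] = 1.0
        if novel:
            if not values[i].any():
                novel = ["__all_novel__"] + novel
            novel_report[i] = novel
    return CueMatrix(values, inventory, list(range(len(lex)))), inventory, novel_report


def write_cue_matrix(cm: CueMatrix, mtx_path, cues_path) -> None:
    """Serialize as Matrix Market sparse plus a sidecar cue-list text file."""
    from scipy import io as sio
    from scipy import sparse

    sio.mmwrite(str(mtx_path), sparse.coo_matrix(cm.values))
    with open(cues_path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit={cm.inventory.unit} n={cm.inventory.n}\n")
        for c in cm.inventory.cues:
            fh.write(c + "\n")
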