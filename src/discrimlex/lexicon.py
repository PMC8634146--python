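"""Paradigm lexicons: data model, I/O, articles, homophony, splits, semantic roles.

A lexicon holds one row per paradigm cell (word form x case x number, optionally
x semantic role x definiteness), each with a token frequency. Word forms are
phone strings in a one-character-per-phone convention (DISC-style), so any
single character counts as a phone; no phone table is bundled.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("discrimlex")

CASES = ("nominative", "genitive", "dative", "accusative")
NUMBERS = ("singular", "plural")
GENDERS = ("m", "f", "n")

#: Semantic-role distribution per case in the German noun system:
#: the most prominent roles and their usage probabilities.
DEFAULT_ROLE_TABLE: "RoleTable"  # defined after the class below


@dataclass(frozen=True)
class ParadigmEntry:
    """One inflected word in one paradigm cell.

    ``form`` is the phone string actually evaluated (article included once
    articles are attached); ``frequency`` is a corpus token count.
    """

    form: str
    lemma: str
    case: str
    number: str
    gender: Optional[str] = None
    frequency: int = 0
    role: Optional[str] = None
    definiteness: Optional[str] = None
    article: Optional[str] = None
    syllables: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if not self.form:
            raise ValueError("entry form must be non-empty")
        if self.frequency < 0:
            raise ValueError("frequency must be non-negative")
        if self.case not in CASES:
            raise ValueError(f"unknown case: {self.case!r}")
        if self.number not in NUMBERS:
            raise ValueError(f"unknown number: {self.number!r}")
        if self.syllables is not None and "".join(self.syllables) != self.form:
            raise ValueError(
                f"syllables {self.syllables!r} do not concatenate to form {self.form!r}"
            )

    @property
    def cell_key(self) -> tuple:
        return (self.lemma, self.case, self.number, self.role, self.definiteness)


@dataclass
class Lexicon:
    """Ordered collection of paradigm entries plus provenance metadata."""

    entries: list[ParadigmEntry]
    source: str = ""

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            k = e.cell_key
            if k in seen:
                raise ValueError(f"duplicate paradigm cell: {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> ParadigmEntry:
        return self.entries[i]

    @property
    def alphabet(self) -> frozenset[str]:
        """Phone alphabet derived from the forms (every character is a phone)."""
        return frozenset(ch for e in self.entries for ch in e.form)

    def forms(self) -> list[str]:
        return [e.form for e in self.entries]

    def subset(self, indices: Iterable[int], source: str = "") -> "Lexicon":
        idx = list(indices)
        return Lexicon([self.entries[i] for i in idx], source or self.source)


@dataclass
class SplitResult:
    """Train/validation split with the validation entries classified.

    ``val_homophones`` are validation entries whose surface form also occurs in
    the training data; ``val_newforms`` have unseen forms but a known lemma;
    ``excluded_novel_lemmas`` have unseen forms of unseen lemmas (excluded from
    the new-form evaluation, but still counted in overall validation accuracy).
    The three index sets partition the validation lexicon.
    """

    train: Lexicon
    validation: Lexicon
    val_homophones: frozenset[int]
    val_newforms: frozenset[int]
    excluded_novel_lemmas: frozenset[int]

    def __post_init__(self):
        all_idx = set(range(len(self.validation)))
        parts = [self.val_homophones, self.val_newforms, self.excluded_novel_lemmas]
        union = set().union(*parts)
        if union != all_idx or sum(len(p) for p in parts) != len(all_idx):
            raise ValueError("validation categories do not partition the validation set")


@dataclass
class RoleTable:
    """Map from case to the semantic roles it can realize, with probabilities."""

    roles: Mapping[str, Sequence[tuple[str, float]]]

    def __post_init__(self):
        for case, pairs in self.roles.items():
            total = sum(p for _, p in pairs)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"role probabilities for {case} sum to {total}, not 1")

    def k(self, case: str) -> int:
        return len(self.roles[case])

    def __getitem__(self, case: str) -> Sequence[tuple[str, float]]:
        return self.roles[case]

    def __contains__(self, case: str) -> bool:
        return case in self.roles


DEFAULT_ROLE_TABLE = RoleTable(
    {
        "nominative": [("agent", 0.5), ("theme", 0.4), ("patient", 0.1)],
        "genitive": [("possessive", 0.9), ("partitive", 0.1)],
        "dative": [("beneficiary", 0.5), ("location", 0.5)],
        "accusative": [("patient", 0.4), ("motion", 0.3), ("experiencer", 0.3)],
    }
)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("form", "lemma", "case", "number", "frequency")
_OPTIONAL_COLUMNS = ("gender", "role", "definiteness", "article", "syllables")


def read_lexicon(path, dialect: Optional[Mapping[str, str]] = None) -> Lexicon:
    """Read a delimited-text paradigm lexicon (tab or comma, header row).

    ``dialect`` optionally maps canonical column names (form, lemma, case,
    number, frequency, ...) to the file's actual column names. Syllables are
    '.'-separated in the file.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"lexicon file is missing required column {col!r}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            freq = int(rec["frequency"])
        except ValueError as exc:
            raise ValueError(
                f"row {i + 2}: frequency {rec['frequency']!r} is not an integer"
            ) from exc
        kwargs = dict(
            form=rec["form"],
            lemma=rec["lemma"],
            case=rec["case"].lower(),
            number=rec["number"].lower(),
            frequency=freq,
        )
        for col in _OPTIONAL_COLUMNS:
            val = rec.get(col, "")
            if val:
                if col == "syllables":
                    kwargs[col] = tuple(val.split("."))
                else:
                    kwargs[col] = val
        entries.append(ParadigmEntry(**kwargs))
    return Lexicon(entries, source=str(path))


def write_lexicon(lex: Lexicon, path) -> None:
    """Write a lexicon in the same tab-delimited dialect ``read_lexicon`` accepts."""
    rows = []
    for e in lex:
        rows.append(
            {
                "form": e.form,
                "lemma": e.lemma,
                "case": e.case,
                "number": e.number,
                "gender": e.gender or "",
                "frequency": e.frequency,
                "role": e.role or "",
                "definiteness": e.definiteness or "",
                "article": e.article or "",
                "syllables": ".".join(e.syllables) if e.syllables else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Articles
# ---------------------------------------------------------------------------

def attach_articles(
    lex: Lexicon,
    article_map: Mapping[tuple, str],
    mode: str = "definite_only",
) -> Lexicon:
    """Prefix each form with its article, with no separator (auditory convention).

    ``article_map`` maps (gender, case, number, definiteness) to a phone-string
    article. Under ``definite_and_indefinite`` every input entry yields a
    definite and an indefinite variant, doubling the dataset; indefinite
    plurals are bare (German indefinite articles exist only in the singular),
    and get an empty article.
    """
    if mode not in ("definite_only", "definite_and_indefinite"):
        raise ValueError(f"unknown article mode {mode!r}")
    missing = sorted({e.lemma for e in lex if e.gender is None})
    if missing:
        raise ValueError(f"entries without gender for lemmas: {', '.join(missing)}")

    def make(e: ParadigmEntry, definiteness: str) -> ParadigmEntry:
        if definiteness == "indefinite" and e.number == "plural":
            art = ""
        else:
            art = article_map.get((e.gender, e.case, e.number, definiteness), "")
        sylls = None
        if e.syllables is not None:
            sylls = ((art,) if art else ()) + e.syllables
        return replace(
            e,
            form=art + e.form,
            article=art or None,
            definiteness=definiteness,
            syllables=sylls,
        )

    out = []
    for e in lex:
        out.append(make(e, "definite"))
        if mode == "definite_and_indefinite":
            out.append(make(e, "indefinite"))
    return Lexicon(out, source=lex.source)


# ---------------------------------------------------------------------------
# Homophones
# ---------------------------------------------------------------------------

def find_homophones(lex: Lexicon) -> "OrderedDict[str, list[int]]":
    """Group entry indices by exact surface form (post-article if attached)."""
    groups: OrderedDict[str, list[int]] = OrderedDict()
    for i, e in enumerate(lex):
        groups.setdefault(e.form, []).append(i)
    return groups


# ---------------------------------------------------------------------------
# Train/validation splitting
# ---------------------------------------------------------------------------

def _classify_validation(train: Lexicon, validation: Lexicon) -> tuple:
    train_forms = set(train.forms())
    train_lemmas = {e.lemma for e in train}
    homo, new, excl = set(), set(), set()
    for i, e in enumerate(validation):
        if e.form in train_forms:
            homo.add(i)
        elif e.lemma in train_lemmas:
            new.add(i)
        else:
            excl.add(i)
    return frozenset(homo), frozenset(new), frozenset(excl)


def split_train_validation(
    lex: Lexicon,
    train_fraction: float = 0.8,
    mode: str = "random",
    cue_extractor: Optional[Callable[[ParadigmEntry], Sequence[str]]] = None,
    seed: int = 0,
) -> SplitResult:
    """Deterministic train/validation split of the paradigm lexicon.

    Under ``no_novel_cues`` every cue of every validation form must already
    occur in some training form; entries whose removal from train would orphan
    a cue are forced into train (logged). ``cue_extractor`` maps an entry to
    its cue list and is required in that mode.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(lex)
    n_val = n - int(round(n * train_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    if mode == "random":
        val_idx = sorted(order[:n_val].tolist())
    elif mode == "no_novel_cues":
        if cue_extractor is None:
            raise ValueError("no_novel_cues mode requires a cue_extractor")
        cues = [tuple(cue_extractor(e)) for e in lex]
        counts: dict[str, int] = {}
        for cs in cues:
            for c in set(cs):
                counts[c] = counts.get(c, 0) + 1
        # Candidates are visited in descending cue-rarity order (rarest cues
        # first) so that forms forced into train are decided early and the
        # number of forced moves stays minimal.
        rarity = {i: min(counts[c] for c in set(cues[i])) for i in range(n)}
        candidates = sorted(order.tolist(), key=lambda i: (rarity[i], 0))
        val_idx = []
        for i in candidates:
            if len(val_idx) == n_val:
                break
            own = set(cues[i])
            if any(counts[c] - 1 == 0 for c in own):
                logger.warning(
                    "form %r forced into train: it is the sole carrier of a cue",
                    lex[i].form,
                )
                continue
            for c in own:
                counts[c] -= 1
            val_idx.append(i)
        val_idx = sorted(val_idx)
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    val_set = set(val_idx)
    train_idx = [i for i in range(n) if i not in val_set]
    train = lex.subset(train_idx)
    validation = lex.subset(val_idx)
    homo, new, excl = _classify_validation(train, validation)
    return SplitResult(train, validation, homo, new, excl)


# ---------------------------------------------------------------------------
# Semantic roles
# ---------------------------------------------------------------------------

def expand_roles(lex: Lexicon, roles: RoleTable = DEFAULT_ROLE_TABLE) -> Lexicon:
    """Replace each entry by one entry per semantic role its case can realize.

    Deterministic full cross-product; frequency simulation is a separate step.
    """
    out = []
    for e in lex:
        if e.case not in roles:
            raise ValueError(f"case {e.case!r} missing from role table")
        for role, _p in roles[e.case]:
            out.append(replace(e, role=role))
    return Lexicon(out, source=lex.source)


def allocate_cell_frequencies(
    freq_p: float,
    role_probs: Sequence[tuple[str, float]],
    dropped: Sequence[bool],
) -> dict[str, int]:
    """Distribute a paradigm cell's share of the form frequency over its roles.

    Dropped roles get 0; the cell's share ``freq_p`` is allocated over the
    surviving roles proportionally to their renormalized probabilities, rounded
    up to the nearest integer (the ceiling uniquely reproduces the published
    worked example: 35 = ceil(34.25), 20 = ceil(19.03), 16 = ceil(15.22),
    18 = ceil(17.125)).
    """
    surviving = [(r, p) for (r, p), d in zip(role_probs, dropped) if not d]
    total_p = sum(p for _, p in surviving)
    out = {r: 0 for r, _ in role_probs}
    if total_p > 0 and freq_p > 0:
        for r, p in surviving:
            out[r] = math.ceil(freq_p * p / total_p)
    return out


def simulate_role_frequencies(
    lex: Lexicon,
    roles: RoleTable = DEFAULT_ROLE_TABLE,
    seed: int = 0,
) -> Lexicon:
    """Simulate role-level token frequencies for a role-expanded lexicon.

    Each word form's frequency is shared equally (freq_p) among the case/number
    cells realizing that form. Within each cell, each role is independently
    dropped with probability 1/K (K = number of roles for the case), so on
    average one role is omitted per cell; the survivors split freq_p by their
    renormalized probabilities, rounded up. A cell can lose all its roles
    (all frequencies 0; logged).
    """
    rng = np.random.default_rng(seed)
    # cells realizing a surface form, derived from the homophone structure
    cells_per_form: dict[str, set] = {}
    for e in lex:
        cells_per_form.setdefault(e.form, set()).add((e.lemma, e.case, e.number))

    # group role-expanded entries by cell, preserving entry order
    by_cell: OrderedDict[tuple, list[int]] = OrderedDict()
    for i, e in enumerate(lex):
        by_cell.setdefault((e.lemma, e.case, e.number, e.form, e.definiteness), []).append(i)

    new_freq: dict[int, int] = {}
    for (lemma, case, number, form, _d), idxs in by_cell.items():
        entry0 = lex[idxs[0]]
        n_cells = len(cells_per_form[form])
        freq_p = entry0.frequency / n_cells
        pairs = list(roles[case])
        k = len(pairs)
        dropped = rng.binomial(1, 1.0 / k, size=k).astype(bool)
        if dropped.all():
            logger.info("all roles dropped for cell (%s, %s, %s)", lemma, case, number)
        alloc = allocate_cell_frequencies(freq_p, pairs, dropped)
        for i in idxs:
            new_freq[i] = alloc[lex[i].role]

    return Lexicon(
        [replace(e, frequency=new_freq[i]) for i, e in enumerate(lex)],
        source=lex.source,
    )
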