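"""Lexicon data model, I/O, articles, homophones, splits, and role frequencies."""

import math

import numpy as np
import pytest

from discrimlex import (
    DEFAULT_ROLE_TABLE,
    GeneratorSpec,
    Lexicon,
    ParadigmEntry,
    allocate_cell_frequencies,
    attach_articles,
    expand_roles,
    find_homophones,
    generate_toy_lexicon,
    read_lexicon,
    simulate_role_frequencies,
    split_train_validation,
    write_lexicon,
)
from discrimlex.forms import entry_cues


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def test_entry_invariants_rejected():
    with pytest.raises(ValueError):
        ParadigmEntry(form="", lemma="x", case="nominative", number="singular")
    with pytest.raises(ValueError):
        ParadigmEntry(form="ab", lemma="x", case="nominative", number="singular",
                      frequency=-1)
    with pytest.raises(ValueError):
        ParadigmEntry(form="ab", lemma="x", case="nominative", number="singular",
                      syllables=("a", "c"))


def test_duplicate_cells_rejected():
    e = ParadigmEntry(form="ab", lemma="x", case="nominative", number="singular")
    with pytest.raises(ValueError):
        Lexicon([e, e])


def test_alphabet_derived(aal):
    assert aal.alphabet == frozenset("al@n")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_aal_paradigm(tmp_path):
    path = tmp_path / "aal.tsv"
    path.write_text(
        "form\tlemma\tcase\tnumber\tgender\tfrequency\n"
        "al\tal\tnominative\tsingular\tm\t29\n"
        "al\tal\tdative\tsingular\tm\t29\n"
        "al\tal\taccusative\tsingular\tm\t29\n"
        "al@\tal\tnominative\tplural\tm\t34\n"
        "al@\tal\tgenitive\tplural\tm\t34\n"
        "al@n\tal\tdative\tplural\tm\t17\n"
        "al@n\tal\taccusative\tplural\tm\t17\n"
    )
    lex = read_lexicon(path)
    assert len(lex) == 7
    assert len(set(lex.forms())) == 3
    assert lex[0].frequency == 29 and lex[0].gender == "m"


def test_read_empty_file(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("form\tlemma\tcase\tnumber\tfrequency\n")
    assert len(read_lexicon(path)) == 0


def test_missing_column_named(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("form\tlemma\tcase\tnumber\nal\tal\tnominative\tsingular\n")
    with pytest.raises(ValueError, match="frequency"):
        read_lexicon(path)


def test_non_integer_frequency_reports_row(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "form\tlemma\tcase\tnumber\tfrequency\nal\tal\tnominative\tsingular\tmany\n"
    )
    with pytest.raises(ValueError, match="row 2"):
        read_lexicon(path)


def test_roundtrip_identity(tmp_path, toy_lexicon):
    lex, _ = toy_lexicon
    path = tmp_path / "lex.tsv"
    write_lexicon(lex, path)
    back = read_lexicon(path)
    assert len(back) == len(lex)
    for a, b in zip(lex, back):
        assert a == b


# ---------------------------------------------------------------------------
# articles
# ---------------------------------------------------------------------------

ARTICLES = {
    ("m", "nominative", "singular", "definite"): "der",
    ("m", "dative", "singular", "definite"): "dem",
    ("m", "accusative", "singular", "definite"): "den",
    ("m", "nominative", "plural", "definite"): "di",
    ("m", "genitive", "plural", "definite"): "der",
    ("m", "dative", "plural", "definite"): "den",
    ("m", "accusative", "plural", "definite"): "di",
    ("m", "nominative", "singular", "indefinite"): "ain",
    ("m", "dative", "singular", "indefinite"): "ainem",
    ("m", "accusative", "singular", "indefinite"): "ainen",
}


def test_definite_article_prefixed(aal):
    out = attach_articles(aal, ARTICLES, mode="definite_only")
    assert out[0].form == "deral"
    assert out[0].article == "der"
    assert out[0].definiteness == "definite"


def test_empty_article_map_is_identity_on_forms(aal):
    out = attach_articles(aal, {}, mode="definite_only")
    assert out.forms() == aal.forms()


def test_definite_and_indefinite_doubles_and_bare_plurals(aal):
    out = attach_articles(aal, ARTICLES, mode="definite_and_indefinite")
    assert len(out) == 2 * len(aal)
    indef_plural = [e for e in out
                    if e.definiteness == "indefinite" and e.number == "plural"]
    assert indef_plural and all(e.article is None for e in indef_plural)
    bare = {e.form for e in indef_plural}
    assert bare == {e.form for e in aal if e.number == "plural"}


def test_missing_gender_lists_lemmas():
    lex = Lexicon([ParadigmEntry(form="ab", lemma="abc", case="nominative",
                                 number="singular")])
    with pytest.raises(ValueError, match="abc"):
        attach_articles(lex, ARTICLES)


# ---------------------------------------------------------------------------
# homophones
# ---------------------------------------------------------------------------

def test_aal_homophone_groups(aal):
    groups = find_homophones(aal)
    assert sorted(len(g) for g in groups.values()) == [2, 2, 3]
    assert groups["al"] == [0, 1, 2]


def test_all_distinct_forms_singleton_groups():
    lex = Lexicon([
        ParadigmEntry(form=f, lemma=f, case="nominative", number="singular")
        for f in ("ab", "cd", "ef")
    ])
    assert all(len(g) == 1 for g in find_homophones(lex).values())


def test_generator_homophony_matches_ground_truth(toy_lexicon):
    lex, gt = toy_lexicon
    groups = find_homophones(lex)
    expected = {form: len(cells) for form, cells in gt.homophone_groups.items()}
    got = {form: len(idx) for form, idx in groups.items()}
    assert got == expected


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_random_split_deterministic_and_sized(toy_lexicon):
    lex, _ = toy_lexicon
    a = split_train_validation(lex, 0.8, "random", seed=11)
    b = split_train_validation(lex, 0.8, "random", seed=11)
    assert [e.form for e in a.validation] == [e.form for e in b.validation]
    assert len(a.train) == int(round(0.8 * len(lex)))


def test_split_categories_partition_and_match_membership(toy_lexicon):
    lex, _ = toy_lexicon
    res = split_train_validation(lex, 0.8, "random", seed=5)
    train_forms = set(res.train.forms())
    train_lemmas = {e.lemma for e in res.train}
    for i, e in enumerate(res.validation):
        in_homo = i in res.val_homophones
        in_new = i in res.val_newforms
        in_excl = i in res.excluded_novel_lemmas
        assert sum([in_homo, in_new, in_excl]) == 1
        if in_homo:
            assert e.form in train_forms
        elif in_new:
            assert e.form not in train_forms and e.lemma in train_lemmas
        else:
            assert e.lemma not in train_lemmas


@pytest.mark.parametrize("seed", range(20))
def test_no_novel_cues_coverage(toy_lexicon, seed):
    lex, _ = toy_lexicon
    extractor = lambda e: entry_cues(e, "phone_ngram", 3)
    res = split_train_validation(lex, 0.8, "no_novel_cues", extractor, seed=seed)
    train_cues = {c for e in res.train for c in extractor(e)}
    for e in res.validation:
        assert set(extractor(e)) <= train_cues


def test_unique_cue_form_forced_into_train():
    # 'xq' only ever occurs inside "axqa": that form can never be validation
    forms = ["axqa"] + [f"b{v}d" for v in "aeiou"] + [f"t{v}k" for v in "aeiou"]
    lex = Lexicon([
        ParadigmEntry(form=f, lemma=f, case="nominative", number="singular")
        for f in forms
    ])
    extractor = lambda e: entry_cues(e, "phone_ngram", 2)
    for seed in range(10):
        res = split_train_validation(lex, 0.6, "no_novel_cues", extractor, seed=seed)
        assert "axqa" in set(res.train.forms())


# ---------------------------------------------------------------------------
# semantic roles
# ---------------------------------------------------------------------------

def test_expand_roles_cross_product(aal):
    out = expand_roles(aal, DEFAULT_ROLE_TABLE)
    k = {"nominative": 3, "genitive": 2, "dative": 2, "accusative": 3}
    assert len(out) == sum(k[e.case] for e in aal)
    nom_sg = [e for e in out if e.case == "nominative" and e.number == "singular"]
    assert [e.role for e in nom_sg] == ["agent", "theme", "patient"]
    gen_pl = [e for e in out if e.case == "genitive"]
    assert [e.role for e in gen_pl] == ["possessive", "partitive"]


def test_single_role_table_preserves_size(aal):
    from discrimlex import RoleTable

    rt = RoleTable({c: [("only", 1.0)] for c in
                    ("nominative", "genitive", "dative", "accusative")})
    assert len(expand_roles(aal, rt)) == len(aal)


TABLE10 = [
    # (case, dropped flags aligned with the role table, expected frequencies)
    ("nominative", [False, False, True], {"agent": 20, "theme": 16, "patient": 0}),
    ("genitive", [True, False], {"possessive": 0, "partitive": 35}),
    ("dative", [False, False], {"beneficiary": 18, "location": 18}),
    ("accusative", [True, True, False], {"patient": 0, "motion": 0, "experiencer": 35}),
]


@pytest.mark.parametrize("case,dropped,expected", TABLE10)
def test_role_frequency_allocation_worked_example(case, dropped, expected):
    """Form frequency 137 shared over 4 singular cells reproduces the published
    role-frequency table cell-for-cell, given the drop pattern its zeros show."""
    alloc = allocate_cell_frequencies(137 / 4, DEFAULT_ROLE_TABLE[case], dropped)
    assert alloc == expected


def test_zero_frequency_yields_all_zero():
    alloc = allocate_cell_frequencies(0.0, DEFAULT_ROLE_TABLE["nominative"],
                                      [False, False, False])
    assert set(alloc.values()) == {0}


def test_simulated_role_frequencies_deterministic_and_zero_for_dropped(aal):
    expanded = expand_roles(aal, DEFAULT_ROLE_TABLE)
    a = simulate_role_frequencies(expanded, DEFAULT_ROLE_TABLE, seed=42)
    b = simulate_role_frequencies(expanded, DEFAULT_ROLE_TABLE, seed=42)
    assert [e.frequency for e in a] == [e.frequency for e in b]
    assert len(a) == len(expanded)


def test_average_one_role_dropped_per_cell():
    """Across many simulated cells, on average ~1 role is omitted per cell."""
    rng_cells = 4000
    lemmas = [f"l{i}m" for i in range(rng_cells // 4)]
    entries = []
    for lm in lemmas:
        for case in ("nominative", "genitive", "dative", "accusative"):
            entries.append(ParadigmEntry(form=lm, lemma=lm, case=case,
                                         number="singular", frequency=100))
    lex = expand_roles(Lexicon(entries), DEFAULT_ROLE_TABLE)
    sim = simulate_role_frequencies(lex, DEFAULT_ROLE_TABLE, seed=1)
    dropped = sum(1 for e in sim if e.frequency == 0)
    n_cells = rng_cells
    # each role ~ Bernoulli(1/K); mean drops per cell = 1, var per cell = sum p(1-p)
    per_cell = dropped / n_cells
    se = math.sqrt(0.75 / n_cells)  # conservative variance bound per cell
    assert abs(per_cell - 1.0) < 3 * math.sqrt(1.0) / math.sqrt(n_cells) + 3 * se
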