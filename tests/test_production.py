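"""Cue graph, path enumeration, learn_paths, and production evaluation."""

import numpy as np
import pytest

from discrimlex import (
    GeneratorSpec,
    Lexicon,
    ParadigmEntry,
    ProductionConfig,
    build_cue_graph,
    build_cue_matrix,
    build_semantic_matrix,
    enumerate_paths_bruteforce,
    estimate_endstate,
    evaluate_production,
    fit_positional_supports,
    generate_toy_lexicon,
    learn_paths,
    predict_form_supports,
    simulate_semantic_space,
)
from discrimlex.forms import CueInventory, entry_cues, extract_ngram_cues
from discrimlex.lexicon import _classify_validation
from discrimlex.mapping import LinearMapping
from discrimlex.production import (
    calibrate_theta,
    check_path,
    default_max_path_length,
    path_surface,
)
from discrimlex.semantics import default_feature_labels
from discrimlex import SplitResult


def inv_of(cues, unit="phone_ngram", n=3):
    return CueInventory(unit=unit, n=n, cues=list(cues))


def test_predict_form_supports_product():
    rng = np.random.default_rng(0)
    G = LinearMapping(rng.normal(size=(4, 6)), direction="production")
    assert np.allclose(predict_form_supports(np.eye(4), G), G.weights)
    assert (predict_form_supports(np.zeros((1, 4)), G) == 0).all()
    S = rng.normal(size=(3, 4))
    assert np.allclose(predict_form_supports(S, G), S @ G.weights)


def test_graph_edges_overlap_only():
    inv = inv_of(["ab", "bc", "cd"], n=2)
    g = build_cue_graph(inv, ["ab", "bc"])
    assert list(g.edges) == [("ab", "bc")]
    g2 = build_cue_graph(inv, ["ab", "cd"])
    assert list(g2.edges) == []
    inv3 = inv_of(["#al", "al@", "l@#"])
    g3 = build_cue_graph(inv3, inv3.cues)
    assert set(g3.edges) == {("#al", "al@"), ("al@", "l@#")}


def test_graph_mixed_n_rejected():
    inv = inv_of(["ab", "abc"], n=2)
    with pytest.raises(ValueError):
        build_cue_graph(inv, ["ab", "abc"])


def test_bruteforce_single_padded_cue():
    inv = inv_of(["#a#"])
    g = build_cue_graph(inv, inv.cues)
    paths = enumerate_paths_bruteforce(g, inv, max_path_length=4)
    assert paths == [(("#a#",), "a")]


def test_bruteforce_chain():
    inv = inv_of(["#ab", "aba", "ba#"])
    g = build_cue_graph(inv, inv.cues)
    paths = enumerate_paths_bruteforce(g, inv, max_path_length=5)
    assert (("#ab", "aba", "ba#"), "aba") in paths
    for p, surf in paths:
        check_path(p, "phone_ngram")
        assert path_surface(p, "phone_ngram") == surf


def test_bruteforce_cyclic_matches_hand_enumeration():
    """aba<->bab cycle: completed paths alternate; bounded length keeps the
    set finite and exactly enumerable by hand."""
    cues = ["#ab", "aba", "bab", "ba#"]
    inv = inv_of(cues)
    g = build_cue_graph(inv, cues)
    paths = {p for p, _ in enumerate_paths_bruteforce(g, inv, max_path_length=6)}
    expected = {
        ("#ab", "aba", "ba#"),
        ("#ab", "aba", "bab", "aba", "ba#"),
    }
    assert paths == expected
    surfaces = {path_surface(p, "phone_ngram") for p in paths}
    assert surfaces == {"aba", "ababa"}


def toy_production_setup(n_lemmas=8, seed=17, unit="phone_ngram", n=3):
    lex, _ = generate_toy_lexicon(GeneratorSpec(n_lemmas=n_lemmas, seed=seed))
    seen, keep = set(), []
    for i, e in enumerate(lex):
        if e.form not in seen:
            seen.add(e.form)
            keep.append(i)
    sub = lex.subset(keep)
    cm, inv, _ = build_cue_matrix(sub, unit, n)
    space = simulate_semantic_space(sorted({e.lemma for e in sub}),
                                    default_feature_labels(), d=len(inv), seed=seed)
    S = build_semantic_matrix(sub, space, seed=seed)
    F = estimate_endstate(cm.values, S.values)
    G = estimate_endstate(S.values, cm.values, "production")
    return sub, cm, inv, S, F, G


def test_learn_paths_unconstrained_equals_bruteforce():
    """With theta = -inf the graph-mode candidate set is exactly the
    brute-force boundary-to-boundary path set."""
    sub, cm, inv, S, F, G = toy_production_setup(4)
    config = ProductionConfig(theta=-np.inf, max_candidates=10_000,
                              path_budget=500_000)
    max_len = default_max_path_length(sub, inv)
    graph = build_cue_graph(inv, inv.cues)
    brute = {p for p, _ in enumerate_paths_bruteforce(graph, inv, max_len)}
    results = learn_paths(S.values[:3], G, F, inv, config, mode="graph",
                          max_path_length=max_len)
    for cands in results:
        assert {c.cue_path for c in cands} == brute


@pytest.mark.parametrize("fixture_seed", range(12))
def test_learn_paths_oracle_random_inventories(fixture_seed):
    """Random small inventories: unconstrained learn_paths set equals the
    exhaustive enumeration, path for path."""
    rng = np.random.default_rng(fixture_seed)
    alphabet = "abc"
    n_cues = int(rng.integers(4, 13))
    cues = set()
    while len(cues) < n_cues:
        kind = rng.integers(3)
        inner = "".join(rng.choice(list(alphabet), size=3))
        if kind == 0:
            cues.add("#" + inner[:2])
        elif kind == 1:
            cues.add(inner[:2] + "#")
        else:
            cues.add(inner)
    cues = sorted(cues)
    inv = inv_of(cues)
    graph = build_cue_graph(inv, cues)
    max_len = 6
    brute = {p for p, _ in enumerate_paths_bruteforce(graph, inv, max_len)}
    F = LinearMapping(rng.normal(size=(len(cues), 4)))
    G = LinearMapping(rng.normal(size=(4, len(cues))), direction="production")
    config = ProductionConfig(theta=-np.inf, max_candidates=10**6,
                              path_budget=10**6)
    results = learn_paths(rng.normal(size=(1, 4)), G, F, inv, config,
                          mode="graph", max_path_length=max_len)
    assert {c.cue_path for c in results[0]} == brute


def test_trained_form_is_top_candidate():
    """On a separable toy lexicon the gold meaning synthesizes its own form."""
    sub, cm, inv, S, F, G = toy_production_setup(8)
    # end-state interpolation: own cues get support ~1, others ~0
    config = ProductionConfig(theta=0.5, max_candidates=5)
    max_len = default_max_path_length(sub, inv)
    results = learn_paths(S.values, G, F, inv, config, mode="graph",
                          max_path_length=max_len)
    top = [cands[0].surface if cands else None for cands in results]
    correct = sum(t == e.form for t, e in zip(top, sub))
    assert correct / len(sub) == 1.0


def test_theta_monotonicity_and_tolerance_monotonicity():
    sub, cm, inv, S, F, G = toy_production_setup(4)
    max_len = default_max_path_length(sub, inv)
    target = S.values[:1]

    def cand_set(theta, tol):
        config = ProductionConfig(theta=theta, tolerance=tol,
                                  max_candidates=10**6, path_budget=10**6)
        res = learn_paths(target, G, F, inv, config, mode="graph",
                          max_path_length=max_len)
        return {c.cue_path for c in res[0]}

    supports = predict_form_supports(target, G)[0]
    lo, mid, hi = np.quantile(supports, [0.2, 0.5, 0.8])
    assert cand_set(hi, 0) <= cand_set(mid, 0) <= cand_set(lo, 0)
    assert cand_set(mid, 0) <= cand_set(mid, 1) <= cand_set(mid, 2)


def test_tolerance_rescues_unsupported_cue():
    """A validation form with one never-supported cue is only producible once
    sub-threshold cues are tolerated."""
    sub, cm, inv, S, F, G = toy_production_setup(6)
    max_len = default_max_path_length(sub, inv) + 2
    target = S.values[:1]
    supports = predict_form_supports(target, G)[0].copy()
    own_path = tuple(entry_cues(sub[0], "phone_ngram", 3))
    # force one of the form's own cues below any attainable threshold
    kill = inv.index[own_path[1]]
    G2 = LinearMapping(G.weights.copy(), direction="production")
    G2.weights[:, kill] = 0.0
    theta = 1e-6  # the killed cue now has support ~0 < theta

    def produced(tol):
        config = ProductionConfig(theta=theta, tolerance=tol,
                                  max_candidates=10**6, path_budget=10**6)
        res = learn_paths(target, G2, F, inv, config, mode="graph",
                          max_path_length=max_len)
        return any(c.surface == sub[0].form for c in res[0])

    assert not produced(0)
    assert produced(1) and produced(2)


def test_positional_mode_produces_trained_forms():
    sub, cm, inv, S, F, G = toy_production_setup(8)
    paths = [entry_cues(e, "phone_ngram", 3) for e in sub]
    positional = fit_positional_supports(S.values, paths, inv)
    config = ProductionConfig(top_k=4, max_candidates=5)
    max_len = default_max_path_length(sub, inv)
    results = learn_paths(S.values, G, F, inv, config, mode="positional",
                          positional=positional, max_path_length=max_len)
    top = [cands[0].surface if cands else None for cands in results]
    correct = sum(t == e.form for t, e in zip(top, sub))
    assert correct / len(sub) >= 0.9


def test_candidates_well_formed_and_ranked(aal):
    cm, inv, _ = build_cue_matrix(aal, "phone_ngram", 3)
    space = simulate_semantic_space(["al"], default_feature_labels(), d=len(inv),
                                    seed=1)
    S = build_semantic_matrix(aal, space, seed=1)
    F = estimate_endstate(cm.values, S.values)
    G = estimate_endstate(S.values, cm.values, "production")
    config = ProductionConfig(theta=-np.inf, max_candidates=50)
    results = learn_paths(S.values, G, F, inv, config, mode="graph",
                          max_path_length=8)
    for cands in results:
        assert cands
        rs = [c.synthesis_r for c in cands]
        assert rs == sorted(rs, reverse=True)
        for c in cands:
            check_path(c.cue_path, "phone_ngram")
            assert path_surface(c.cue_path, "phone_ngram") == c.surface


def test_evaluate_production_exact_match_and_categories():
    train = Lexicon([
        ParadigmEntry(form="ta", lemma="ta", case="nominative", number="singular"),
        ParadigmEntry(form="tb", lemma="tb", case="nominative", number="singular"),
    ])
    val = Lexicon([
        ParadigmEntry(form="ta", lemma="ta", case="dative", number="singular"),
        ParadigmEntry(form="tc", lemma="ta", case="accusative", number="singular"),
    ])
    homo, new, excl = _classify_validation(train, val)
    split = SplitResult(train, val, homo, new, excl)
    lex_all = Lexicon(list(train) + list(val))
    from discrimlex.production import CandidateForm

    def cand(surface):
        return CandidateForm(cue_path=("#x#",), surface=surface)

    candidates = [[cand("ta")], [cand("tb")], [cand("ta")], []]
    rep = evaluate_production(candidates, lex_all, [0, 1], [2, 3], split)
    assert rep["train"] == 1.0
    assert rep["val_lenient"] == 1.0  # the homophone row produced "ta"
    assert rep["val_newform"] == 0.0  # empty candidate list counts as wrong
    assert rep["val_all"] == 0.5
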