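"""Production: meaning-to-form synthesis over the cue-overlap graph.

A predicted cue vector c-hat = s G says how much support each n-gram cue
receives from a meaning, but not how to order cues into a word. Order is
implicit in n-gram overlap: cue ``ab`` can precede ``bc`` but not ``cd``, so
the admissible cues span a directed graph in which every boundary-to-boundary
path spells a word form. Candidate forms are assembled from well-supported
cues (support >= theta, with up to t tolerated sub-threshold cues per path)
and ranked by synthesis-by-analysis: each candidate's cue vector is projected
back through the comprehension mapping F and correlated with the target
meaning; the best-correlating path is articulated. A form counts as produced
correctly only if the top candidate string-matches the target exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .forms import BOUNDARY, SYLLABLE_SEP, CueInventory
from .lexicon import Lexicon, SplitResult
from .mapping import LinearMapping, estimate_endstate
from .comprehension import EvaluationReport, _accuracy, _row_correlations

logger = logging.getLogger("discrimlex")


@dataclass
class ProductionConfig:
    """Knobs of the path-synthesis algorithm.

    theta: minimum predicted support for a cue to be freely usable.
    tolerance: sub-threshold cues allowed per path (0 by default; small
        values let unseen forms through when one of their cues never
        received training support).
    top_k: cues retained per word position in positional mode.
    max_path_length: cap on path length in cues; None = longest training
        path + 2.
    max_candidates: ranked candidates returned per target.
    path_budget: hard cap on paths explored before a truncation error.
    """

    theta: float = 0.0
    tolerance: int = 0
    top_k: int = 5
    max_path_length: Optional[int] = None
    max_candidates: int = 5
    path_budget: int = 200_000


@dataclass
class CandidateForm:
    """A boundary-to-boundary cue path with its synthesis-by-analysis score."""

    cue_path: tuple[str, ...]
    surface: str
    synthesis_r: float = float("nan")
    tolerated_cues: int = 0
    supports: tuple[float, ...] = ()


class PathBudgetExceeded(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Cue graph and path machinery
# ---------------------------------------------------------------------------

def _symbols(cue: str, unit: str) -> tuple[str, ...]:
    if unit == "syllable_ngram":
        return tuple(cue.split(SYLLABLE_SEP))
    return tuple(cue)


def _join(symbols: Sequence[str], unit: str) -> str:
    if unit == "syllable_ngram":
        return SYLLABLE_SEP.join(symbols)
    return "".join(symbols)


def is_initial(cue: str, unit: str) -> bool:
    return _symbols(cue, unit)[0] == BOUNDARY


def is_final(cue: str, unit: str) -> bool:
    return _symbols(cue, unit)[-1] == BOUNDARY


def cues_overlap(u: str, v: str, unit: str) -> bool:
    """True iff the length-(n-1) suffix of u equals the length-(n-1) prefix of v."""
    su, sv = _symbols(u, unit), _symbols(v, unit)
    return su[1:] == sv[: len(su) - 1]


def build_cue_graph(inventory: CueInventory, admissible: Sequence[str]) -> nx.DiGraph:
    """Directed graph over admissible cues; edge u->v iff they properly overlap."""
    lengths = {len(_symbols(c, inventory.unit)) for c in admissible}
    if len(lengths) > 1:
        raise ValueError(f"mixed cue sizes in admissible set: {sorted(lengths)}")
    g = nx.DiGraph()
    g.add_nodes_from(admissible)
    adm = list(admissible)
    # index by (n-1)-prefix for linear-ish edge construction
    by_prefix: dict[tuple, list[str]] = {}
    for v in adm:
        sv = _symbols(v, inventory.unit)
        by_prefix.setdefault(sv[:-1], []).append(v)
    for u in adm:
        su = _symbols(u, inventory.unit)
        for v in by_prefix.get(su[1:], ()):
            g.add_edge(u, v)
    return g


def path_surface(path: Sequence[str], unit: str) -> str:
    """Concatenate an overlapping cue path and strip the boundary symbols."""
    syms = list(_symbols(path[0], unit))
    for cue in path[1:]:
        syms.append(_symbols(cue, unit)[-1])
    assert syms[0] == BOUNDARY and syms[-1] == BOUNDARY
    inner = [s for s in syms[1:-1] if s != BOUNDARY]
    return _join(inner, unit)


def check_path(path: Sequence[str], unit: str) -> None:
    """Assert boundary and overlap invariants of a candidate path."""
    if not is_initial(path[0], unit):
        raise AssertionError(f"path does not start at a boundary cue: {path}")
    if not is_final(path[-1], unit):
        raise AssertionError(f"path does not end at a boundary cue: {path}")
    for u, v in zip(path, path[1:]):
        if not cues_overlap(u, v, unit):
            raise AssertionError(f"cues {u!r} and {v!r} do not overlap")


def enumerate_paths_bruteforce(
    graph: nx.DiGraph,
    inventory: CueInventory,
    max_path_length: int,
) -> list[tuple[tuple[str, ...], str]]:
    """Exhaustive DFS over all boundary-to-boundary paths (the test oracle).

    Exponential in the worst case; intended for small inventories. Paths are
    returned deduplicated (cue sequence identity); surfaces can repeat when
    distinct paths spell the same string.
    """
    unit = inventory.unit
    starts = [c for c in graph.nodes if is_initial(c, unit)]
    out: list[tuple[tuple[str, ...], str]] = []
    budget = [10_000_000]

    def dfs(path: list[str]):
        budget[0] -= 1
        if budget[0] <= 0:
            raise PathBudgetExceeded("brute-force path budget exceeded")
        cue = path[-1]
        if is_final(cue, unit):
            out.append((tuple(path), path_surface(path, unit)))
        if len(path) >= max_path_length:
            return
        for nxt in graph.successors(cue):
            path.append(nxt)
            dfs(path)
            path.pop()

    for s in starts:
        dfs([s])
    return out


# ---------------------------------------------------------------------------
# Support prediction and path search
# ---------------------------------------------------------------------------

def predict_form_supports(S_rows: np.ndarray, G: LinearMapping) -> np.ndarray:
    """C-hat = S G: predicted support per cue, rows aligned with meanings."""
    S_rows = np.atleast_2d(np.asarray(S_rows, dtype=float))
    if S_rows.shape[1] != G.weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: meanings have {S_rows.shape[1]} columns, "
            f"mapping expects {G.weights.shape[0]}"
        )
    return S_rows @ G.weights


@dataclass
class PositionalSupport:
    """Position-specific support predictors for positional path search.

    One end-state mapping per word position p maps a meaning to an indicator
    of 'cue x occurs at position p', fitted on the training data. At
    synthesis time the top_k best-supported cues at each position restrict
    the path search.
    """

    mappings: list[LinearMapping]
    inventory: CueInventory

    @property
    def max_positions(self) -> int:
        return len(self.mappings)


def fit_positional_supports(
    S_train: np.ndarray,
    cue_paths_train: Sequence[Sequence[str]],
    inventory: CueInventory,
    max_positions: Optional[int] = None,
) -> PositionalSupport:
    """Fit one meaning-to-cue-indicator regression per word position."""
    if max_positions is None:
        max_positions = max(len(p) for p in cue_paths_train)
    maps = []
    for p in range(max_positions):
        Y = np.zeros((len(cue_paths_train), len(inventory)))
        for i, path in enumerate(cue_paths_train):
            if p < len(path) and path[p] in inventory:
                Y[i, inventory.index[path[p]]] = 1.0
        maps.append(estimate_endstate(S_train, Y, direction="production"))
    return PositionalSupport(maps, inventory)


def default_max_path_length(lex_train: Lexicon, inventory: CueInventory) -> int:
    """Longest training cue path plus two cues."""
    from .forms import entry_cues

    longest = max(len(entry_cues(e, inventory.unit, inventory.n)) for e in lex_train)
    return longest + 2


def _rank_candidates(
    raw: list[tuple[tuple[str, ...], int]],
    supports: np.ndarray,
    target: np.ndarray,
    F: LinearMapping,
    inventory: CueInventory,
    max_candidates: int,
) -> list[CandidateForm]:
    """Synthesis by analysis: project each path through F, rank by Pearson r.

    Ties break toward shorter paths, then lexicographic surface, for
    determinism.
    """
    if not raw:
        return []
    unit = inventory.unit
    vecs = np.zeros((len(raw), len(inventory)))
    for i, (path, _tol) in enumerate(raw):
        for c in path:
            vecs[i, inventory.index[c]] = 1.0
    S_hat = vecs @ F.weights
    cands = []
    for i, (path, tol) in enumerate(raw):
        check_path(path, unit)
        r = float(_row_correlations(target, S_hat[i : i + 1])[0])
        cands.append(
            CandidateForm(
                cue_path=path,
                surface=path_surface(path, unit),
                synthesis_r=r,
                tolerated_cues=tol,
                supports=tuple(float(supports[inventory.index[c]]) for c in path),
            )
        )
    cands.sort(key=lambda c: (-c.synthesis_r, len(c.cue_path), c.surface))
    return cands[:max_candidates]


def _graph_mode_paths(
    supports: np.ndarray,
    inventory: CueInventory,
    config: ProductionConfig,
    max_len: int,
) -> list[tuple[tuple[str, ...], int]]:
    """DFS over the full cue graph, counting sub-threshold cues per path."""
    unit = inventory.unit
    strong = {c for c in inventory.cues if supports[inventory.index[c]] >= config.theta}
    graph = build_cue_graph(inventory, inventory.cues)
    starts = [c for c in graph.nodes if is_initial(c, unit)]
    out: list[tuple[tuple[str, ...], int]] = []
    budget = [config.path_budget]

    def dfs(path: list[str], tol: int):
        budget[0] -= 1
        if budget[0] <= 0:
            raise PathBudgetExceeded(
                f"path budget {config.path_budget} exceeded; raise theta or lower tolerance"
            )
        cue = path[-1]
        if is_final(cue, unit):
            out.append((tuple(path), tol))
        if len(path) >= max_len:
            return
        for nxt in graph.successors(cue):
            t2 = tol + (0 if nxt in strong else 1)
            if t2 <= config.tolerance:
                path.append(nxt)
                dfs(path, t2)
                path.pop()

    for s in starts:
        t0 = 0 if s in strong else 1
        if t0 <= config.tolerance:
            dfs([s], t0)
    return out


def _positional_mode_paths(
    target: np.ndarray,
    positional: PositionalSupport,
    inventory: CueInventory,
    config: ProductionConfig,
    max_len: int,
) -> list[tuple[tuple[str, ...], int]]:
    """Position-by-position search restricted to top_k cues per position."""
    unit = inventory.unit
    max_len = min(max_len, positional.max_positions)
    per_pos: list[list[str]] = []
    for p in range(max_len):
        pred = (np.asarray(target, dtype=float) @ positional.mappings[p].weights).ravel()
        order = np.argsort(-pred, kind="stable")[: config.top_k]
        per_pos.append([inventory.cues[j] for j in order])

    out: list[tuple[tuple[str, ...], int]] = []
    budget = [config.path_budget]

    def dfs(path: list[str]):
        budget[0] -= 1
        if budget[0] <= 0:
            raise PathBudgetExceeded(f"path budget {config.path_budget} exceeded")
        cue = path[-1]
        if is_final(cue, unit):
            out.append((tuple(path), 0))
        p = len(path)
        if p >= max_len:
            return
        for nxt in per_pos[p]:
            if cues_overlap(cue, nxt, unit):
                path.append(nxt)
                dfs(path)
                path.pop()

    for s in per_pos[0] if per_pos else []:
        if is_initial(s, unit):
            dfs([s])
    return out


def learn_paths(
    targets: np.ndarray,
    G: LinearMapping,
    F: LinearMapping,
    inventory: CueInventory,
    config: ProductionConfig,
    mode: str = "graph",
    positional: Optional[PositionalSupport] = None,
    max_path_length: Optional[int] = None,
) -> list[list[CandidateForm]]:
    """Ranked candidate forms for each target meaning.

    graph mode: admissible cues are those with predicted support >= theta,
    plus up to ``tolerance`` sub-threshold cues per path; paths are assembled
    over the overlap graph. positional mode: a per-position support predictor
    (``positional``) restricts each step to the top_k cues for that position.
    Candidates are ranked by synthesis-by-analysis correlation with the
    target. An empty list (with a logged diagnostic) means no complete path
    survived.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    supports_all = predict_form_supports(targets, G)
    max_len = max_path_length or config.max_path_length
    if max_len is None:
        raise ValueError("max_path_length must be set (config or argument)")
    results: list[list[CandidateForm]] = []
    for i in range(targets.shape[0]):
        supports = supports_all[i]
        if mode == "graph":
            raw = _graph_mode_paths(supports, inventory, config, max_len)
        elif mode == "positional":
            if positional is None:
                raise ValueError("positional mode requires fitted positional supports")
            raw = _positional_mode_paths(targets[i], positional, inventory, config, max_len)
        else:
            raise ValueError(f"unknown learn_paths mode {mode!r}")
        if not raw:
            n_strong = int((supports >= config.theta).sum())
            logger.info(
                "no complete path for target %d (%d/%d cues above theta=%.3g)",
                i, n_strong, len(inventory), config.theta,
            )
        results.append(
            _rank_candidates(raw, supports, targets[i], F, inventory, config.max_candidates)
        )
    return results


def calibrate_theta(C_hat_train: np.ndarray, C_train: np.ndarray,
                    safety: float = 0.5) -> float:
    """Support threshold at which the median training form keeps all its cues.

    For each training form, take the minimum predicted support over its own
    active cues; theta is the median of those minima scaled by ``safety``.
    The back-off matters in the interpolation regime (more cues than training
    rows), where every own-cue support is ~1 and a threshold placed exactly
    at the median would cut trained and held-out forms on numerical noise;
    irrelevant cues cluster near zero support, so the scaled threshold still
    excludes them. Some fine-tuning per dataset is expected; this is a sane
    starting point.
    """
    mins = []
    for i in range(C_train.shape[0]):
        own = C_train[i] > 0
        if own.any():
            mins.append(C_hat_train[i][own].min())
    return safety * float(np.median(mins))


def evaluate_production(
    candidates: Sequence[Sequence[CandidateForm]],
    lex_all: Lexicon,
    train_rows: Sequence[int],
    val_rows: Sequence[int],
    split: SplitResult,
) -> EvaluationReport:
    """Exact-match production accuracy under the evaluation taxonomy.

    ``candidates[row]`` is the ranked list for the entry at that row of
    ``lex_all``. A row is correct iff its top candidate's surface equals the
    target form exactly; empty candidate lists count as incorrect (logged).
    """
    forms = lex_all.forms()

    def ok(row: int) -> bool:
        cands = candidates[row]
        if not cands:
            logger.info("no candidates produced for %r", forms[row])
            return False
        return cands[0].surface == forms[row]

    homo_rows = [val_rows[i] for i in sorted(split.val_homophones)]
    new_rows = [val_rows[i] for i in sorted(split.val_newforms)]
    return EvaluationReport(
        accuracies={
            "train": _accuracy([ok(r) for r in train_rows]),
            "val_all": _accuracy([ok(r) for r in val_rows]),
            "val_lenient": _accuracy([ok(r) for r in homo_rows]),
            "val_strict": _accuracy([ok(r) for r in homo_rows]),
            "val_newform": _accuracy([ok(r) for r in new_rows]),
        },
        counts={
            "train": len(train_rows),
            "val_all": len(val_rows),
            "val_homophones": len(homo_rows),
            "val_newforms": len(new_rows),
            "excluded_novel_lemmas": len(split.excluded_novel_lemmas),
        },
    )


def write_candidates(candidates, lex, path) -> None:
    """Delimited dump: entry, rank, surface, synthesis_r, tolerated_cues."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entry\ttarget\trank\tsurface\tsynthesis_r\ttolerated_cues\n")
        for i, cands in enumerate(candidates):
            for rank, c in enumerate(cands, start=1):
                fh.write(
                    f"{i}\t{lex[i].form}\t{rank}\t{c.surface}\t"
                    f"{c.synthesis_r:.6f}\t{c.tolerated_cues}\n"
                )
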