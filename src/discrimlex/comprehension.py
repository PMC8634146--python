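"""Comprehension: map cue vectors to meanings and score recognition.

A word is recognized as the gold-standard meaning whose vector correlates
most strongly (Pearson r) with the predicted vector s-hat = c F. Evaluation
distinguishes performance on training data (the model as a memory) from
held-out data (the model as a productive system), and, on held-out data,
homophones (forms seen in training under another cell) from genuinely new
forms. For homophones a strict criterion demands the exact target cell; a
lenient criterion accepts any meaning the surface form can carry — which is
all a listener could do with an isolated homophone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .lexicon import Lexicon, SplitResult
from .mapping import LinearMapping

logger = logging.getLogger("discrimlex")


@dataclass
class ComprehensionResult:
    """Per-entry nearest-neighbour outcome over the gold semantic matrix."""

    predicted: np.ndarray
    nearest_index: np.ndarray
    nearest_r: np.ndarray
    target_r: np.ndarray
    target_rank: np.ndarray


@dataclass
class EvaluationReport:
    """Accuracy grid: train, val_all, val_lenient, val_strict, val_newform.

    Accuracies are proportions in [0, 1], or None when the category is empty
    (undefined, not zero). ``counts`` holds the category sizes.
    """

    accuracies: dict[str, Optional[float]]
    counts: dict[str, int]

    def __getitem__(self, key: str) -> Optional[float]:
        return self.accuracies[key]


def predict_semantics(C_rows: np.ndarray, F: LinearMapping) -> np.ndarray:
    """S-hat = C F, rows aligned with the input rows."""
    C_rows = np.atleast_2d(np.asarray(C_rows, dtype=float))
    if C_rows.shape[1] != F.weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: cues have {C_rows.shape[1]} columns, "
            f"mapping expects {F.weights.shape[0]}"
        )
    return C_rows @ F.weights


def _row_correlations(v: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of a vector against every row of M; r = 0 for constant vectors."""
    vc = v - v.mean()
    nv = np.linalg.norm(vc)
    Mc = M - M.mean(axis=1, keepdims=True)
    nM = np.linalg.norm(Mc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ vc) / (nM * nv)
    r[~np.isfinite(r)] = 0.0
    if nv == 0:
        r[:] = 0.0
    return r


def nearest_meaning(s_hat: np.ndarray, S_gold: np.ndarray) -> tuple[int, float, np.ndarray]:
    """Index and r of the best-correlated gold row, plus the full ranking.

    Ties are broken toward the lowest row index (np.argmax convention), and
    logged. Pearson r makes the choice invariant to positive affine rescaling
    of the predicted vector.
    """
    S_gold = np.atleast_2d(S_gold)
    if S_gold.shape[0] < 1:
        raise ValueError("gold matrix must have at least one row")
    r = _row_correlations(np.asarray(s_hat, dtype=float).ravel(), S_gold)
    best = int(np.argmax(r))
    if np.sum(r == r[best]) > 1:
        logger.info("nearest_meaning tie at r=%.6f; lowest index %d chosen", r[best], best)
    ranking = np.argsort(-r, kind="stable")
    return best, float(r[best]), ranking


def nearest_meanings_batch(S_hat: np.ndarray, S_gold: np.ndarray) -> np.ndarray:
    """Vectorized argmax-correlation over the gold matrix for many rows.

    Equivalent to calling :func:`nearest_meaning` per row (same lowest-index
    tie-break), but a single matrix product.
    """
    A = S_hat - S_hat.mean(axis=1, keepdims=True)
    B = S_gold - S_gold.mean(axis=1, keepdims=True)
    nA = np.linalg.norm(A, axis=1, keepdims=True)
    nB = np.linalg.norm(B, axis=1, keepdims=True)
    nA[nA == 0] = np.inf
    nB[nB == 0] = np.inf
    R = (A / nA) @ (B / nB).T
    return np.argmax(R, axis=1)


def comprehend(C_rows: np.ndarray, F: LinearMapping, S_gold: np.ndarray,
               target_rows: Optional[Sequence[int]] = None) -> ComprehensionResult:
    """Predict and rank every row against the gold matrix."""
    S_hat = predict_semantics(C_rows, F)
    n = S_hat.shape[0]
    nearest = np.empty(n, dtype=int)
    nearest_r = np.empty(n)
    target_r = np.full(n, np.nan)
    target_rank = np.full(n, -1, dtype=int)
    for i in range(n):
        best, r_best, ranking = nearest_meaning(S_hat[i], S_gold)
        nearest[i] = best
        nearest_r[i] = r_best
        if target_rows is not None:
            t = target_rows[i]
            r_all = _row_correlations(S_hat[i], S_gold)
            target_r[i] = r_all[t]
            target_rank[i] = int(np.where(ranking == t)[0][0])
    return ComprehensionResult(S_hat, nearest, nearest_r, target_r, target_rank)


def _accuracy(flags: Sequence[bool]) -> Optional[float]:
    flags = list(flags)
    return float(np.mean(flags)) if flags else None


def evaluate_comprehension(
    F: LinearMapping,
    C_all: np.ndarray,
    S_gold_all: np.ndarray,
    lex_all: Lexicon,
    train_rows: Sequence[int],
    val_rows: Sequence[int],
    split: SplitResult,
) -> EvaluationReport:
    """Score comprehension under the full evaluation taxonomy.

    ``C_all``/``S_gold_all`` are row-aligned with ``lex_all`` (train entries
    followed by validation entries); ``train_rows``/``val_rows`` give the row
    indices of the two sets. The nearest-neighbour search runs over all gold
    rows. Strict = nearest row is the entry's own; lenient = nearest row's
    entry shares the surface form. The headline ``train`` accuracy counts
    homophones as understood (lenient) — an isolated homophone gives a
    listener no way to pick the cell — with ``train_strict`` reported
    alongside. val_strict/val_lenient are computed on the homophone subset,
    val_newform on new forms, and val_all applies the lenient criterion to
    every validation entry, novel-lemma entries included.
    """
    forms = lex_all.forms()
    S_hat = predict_semantics(C_all, F)
    nearest = nearest_meanings_batch(S_hat, S_gold_all)

    def lenient_ok(row: int) -> bool:
        return forms[nearest[row]] == forms[row]

    def strict_ok(row: int) -> bool:
        return nearest[row] == row

    homo_rows = [val_rows[i] for i in sorted(split.val_homophones)]
    new_rows = [val_rows[i] for i in sorted(split.val_newforms)]
    all_rows = list(val_rows)

    report = EvaluationReport(
        accuracies={
            "train": _accuracy([lenient_ok(r) for r in train_rows]),
            "train_strict": _accuracy([strict_ok(r) for r in train_rows]),
            "val_all": _accuracy([lenient_ok(r) for r in all_rows]),
            "val_lenient": _accuracy([lenient_ok(r) for r in homo_rows]),
            "val_strict": _accuracy([strict_ok(r) for r in homo_rows]),
            "val_newform": _accuracy([lenient_ok(r) for r in new_rows]),
        },
        counts={
            "train": len(train_rows),
            "val_all": len(all_rows),
            "val_homophones": len(homo_rows),
            "val_newforms": len(new_rows),
            "excluded_novel_lemmas": len(split.excluded_novel_lemmas),
        },
    )
    return report
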