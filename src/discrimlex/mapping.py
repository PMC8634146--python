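"""Linear form-meaning mappings: regression end-state and incremental learning.

Comprehension solves S = C F for F, production solves C = S G for G, both by
multivariate multiple linear regression without an intercept (the network
formulation has none). The end-state solution is the minimum-norm least
squares fit, which is what infinitely repeated incremental training converges
to. Incremental learning applies the Widrow-Hoff rule token by token,

    W(t+1) = W(t) + c^T (o - c W(t)) eta,

which is frequency- and order-sensitive: a single pass over a realistic token
stream learns frequent words better, while the end-state is frequency-blind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lexicon import Lexicon


@dataclass
class LinearMapping:
    """Weight matrix of one direction (comprehension F or production G)."""

    weights: np.ndarray
    direction: str = "comprehension"  # or "production"
    mode: str = "endstate"  # or "incremental"
    learning_rate: Optional[float] = None
    events_seen: int = 0
    epochs: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("mapping weights must be finite")

    @property
    def shape(self):
        return self.weights.shape


@dataclass
class TokenStream:
    """Ordered sequence of entry indices to present for learning."""

    indices: np.ndarray
    seed: int
    scheme: str

    def __len__(self) -> int:
        return len(self.indices)


def estimate_endstate(X: np.ndarray, Y: np.ndarray,
                      direction: str = "comprehension") -> LinearMapping:
    """Minimum-norm least-squares solution of Y = X W (the end-state of learning).

    With homophones X is rank-deficient; the pseudoinverse solution is the
    well-defined limit of error-driven learning started from zero weights.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"row-count mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}"
        )
    W, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return LinearMapping(W, direction=direction, mode="endstate")


def widrow_hoff_update(W: np.ndarray, c: np.ndarray, o: np.ndarray,
                       eta: float) -> np.ndarray:
    """One Widrow-Hoff step: W + c^T (o - c W) eta, for row vectors c, o.

    The input matrix is left unmodified.
    """
    c = np.asarray(c, dtype=float).ravel()
    o = np.asarray(o, dtype=float).ravel()
    if eta <= 0:
        raise ValueError("learning rate must be positive")
    if W.shape != (c.size, o.size):
        raise ValueError(
            f"dimension mismatch: W is {W.shape}, expected {(c.size, o.size)}"
        )
    err = o - c @ W
    return W + eta * np.outer(c, err)


def max_stable_eta(X: np.ndarray) -> float:
    """Largest learning rate for which per-token updates cannot diverge.

    A single update contracts iff eta * ||c||^2 < 2; the bound uses the
    largest squared row norm, i.e. the largest eigenvalue any single token's
    Gram contribution can have.
    """
    norms2 = (np.asarray(X, dtype=float) ** 2).sum(axis=1)
    mx = norms2.max()
    return float(2.0 / mx) if mx > 0 else np.inf


def sample_token_stream(
    lex: Lexicon,
    n_events: Optional[int] = None,
    scheme: str = "shuffled_census",
    seed: int = 0,
) -> TokenStream:
    """Token stream over lexicon entries.

    ``shuffled_census`` emits each entry exactly frequency-many times in a
    random order (one pass over the corpus, as in a single-epoch simulation);
    ``frequency_proportional`` draws ``n_events`` i.i.d. tokens with
    probability proportional to frequency.
    """
    freqs = np.array([e.frequency for e in lex], dtype=float)
    total = freqs.sum()
    if total <= 0:
        raise ValueError("total token frequency must be positive")
    rng = np.random.default_rng(seed)
    if scheme == "shuffled_census":
        census = np.repeat(np.arange(len(lex)), freqs.astype(int))
        rng.shuffle(census)
        return TokenStream(census, seed, scheme)
    if scheme == "frequency_proportional":
        if n_events is None:
            raise ValueError("frequency_proportional requires n_events")
        idx = rng.choice(len(lex), size=n_events, p=freqs / total)
        return TokenStream(idx, seed, scheme)
    raise ValueError(f"unknown sampling scheme {scheme!r}")


class DivergenceError(RuntimeError):
    pass


def train_incremental(
    C: np.ndarray,
    S: np.ndarray,
    stream: TokenStream,
    eta: float = 0.001,
    direction: str = "comprehension",
    checkpoints: Sequence[int] = (),
    epochs: int = 1,
) -> tuple[LinearMapping, list[LinearMapping]]:
    """Widrow-Hoff training from zero weights over a token stream.

    One update per event; snapshots are taken at the requested cumulative
    event counts. ``epochs`` > 1 replays the same stream (used to demonstrate
    convergence to the end-state; a single pass is the realistic regime).
    Divergence (exploding weight norm) raises with the offending eta.
    """
    C = np.asarray(C, dtype=float)
    S = np.asarray(S, dtype=float)
    if eta <= 0:
        raise ValueError("learning rate must be positive")
    if len(stream) and (stream.indices.min() < 0 or stream.indices.max() >= C.shape[0]):
        raise ValueError("stream contains out-of-range entry indices")
    W = np.zeros((C.shape[1], S.shape[1]))
    snaps: list[LinearMapping] = []
    wanted = sorted(set(int(x) for x in checkpoints))
    scale = max(1.0, float(np.abs(S).max()) * C.shape[1])
    limit = 1e9 * scale
    t = 0
    for _ in range(epochs):
        for i in stream.indices:
            c = C[i]
            err = S[i] - c @ W
            W += eta * np.outer(c, err)
            t += 1
            if wanted and t == wanted[0]:
                wanted.pop(0)
                snaps.append(
                    LinearMapping(W.copy(), direction, "incremental", eta, t, t / max(1, len(stream)))
                )
            if not np.all(np.isfinite(W)) or np.abs(W).max() > limit:
                raise DivergenceError(
                    f"incremental training diverged at event {t} with eta={eta}; "
                    f"try eta below {max_stable_eta(C):.3g}"
                )
    final = LinearMapping(W, direction, "incremental", eta, t, t / max(1, len(stream)))
    return final, snaps


def prune_weights(m: LinearMapping, theta: float) -> tuple[LinearMapping, float]:
    """Zero all weights with absolute value below theta; report the fraction.

    The original mapping is left unmodified. Many connection weights are near
    zero (low discriminative value), so substantial fractions can typically be
    pruned without hurting accuracy.
    """
    if theta < 0:
        raise ValueError("pruning threshold must be >= 0")
    mask = np.abs(m.weights) < theta
    W = m.weights.copy()
    W[mask] = 0.0
    frac = float(mask.mean()) if m.weights.size else 0.0
    pruned = LinearMapping(W, m.direction, m.mode, m.learning_rate,
                           m.events_seen, m.epochs)
    return pruned, frac


# ---------------------------------------------------------------------------
# Serialization: .npz weights + JSON text header
# ---------------------------------------------------------------------------

def save_mapping(m: LinearMapping, path) -> None:
    np.savez(
        path,
        weights=m.weights,
        header=json.dumps(
            {
                "direction": m.direction,
                "mode": m.mode,
                "learning_rate": m.learning_rate,
                "events_seen": m.events_seen,
                "epochs": m.epochs,
            }
        ),
    )


def load_mapping(path) -> LinearMapping:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["header"]))
    return LinearMapping(
        data["weights"],
        direction=meta["direction"],
        mode=meta["mode"],
        learning_rate=meta["learning_rate"],
        events_seen=meta["events_seen"],
        epochs=meta["epochs"],
    )
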