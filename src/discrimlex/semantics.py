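"""Semantic vectors: simulated spaces, compositional meanings, embeddings.

The meaning of an inflected word is the sum of its lexeme vector and the
vectors of its inflectional functions (number, case or semantic role,
optionally definiteness), plus a small amount of per-entry Gaussian noise
standing in for idiosyncratic usage. Lexeme and feature vectors are i.i.d.
Gaussian by default (SD 4 for both, noise SD 1), which leaves distinct
lexemes near-orthogonal: all semantic similarity then comes from shared
inflectional structure. A ``feature_scale`` below 1 (e.g. 1/110) shrinks the
inflectional vectors relative to the lexemes, which matters for nonce-word
production.

Alternatively, empirical embeddings (word2vec text format) can be loaded;
they carry no inflectional feature vectors of their own, but lexeme and
feature vectors can be reconstructed analytically by averaging.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .lexicon import Lexicon, ParadigmEntry

logger = logging.getLogger("discrimlex")

NUMBER_FEATURES = {"singular": "SINGULAR", "plural": "PLURAL"}
DEFINITENESS_FEATURES = {"definite": "DEFINITE", "indefinite": "INDEFINITE"}


@dataclass
class SemanticSpace:
    """Lexeme and inflectional-feature vectors of a common dimension."""

    d: int
    lexeme_vectors: dict[str, np.ndarray]
    feature_vectors: dict[str, np.ndarray]
    sd_lexeme: float = 4.0
    sd_feature: float = 4.0
    sd_noise: float = 1.0
    feature_scale: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        for name, v in {**self.lexeme_vectors, **self.feature_vectors}.items():
            if v.shape != (self.d,):
                raise ValueError(f"vector {name!r} has wrong dimension")

    def scaled(self, feature_scale: float) -> "SemanticSpace":
        """Copy with all feature vectors rescaled by feature_scale relative
        to their unscaled (scale-1) magnitude."""
        ratio = feature_scale / self.feature_scale
        return SemanticSpace(
            d=self.d,
            lexeme_vectors=dict(self.lexeme_vectors),
            feature_vectors={k: v * ratio for k, v in self.feature_vectors.items()},
            sd_lexeme=self.sd_lexeme,
            sd_feature=self.sd_feature,
            sd_noise=self.sd_noise,
            feature_scale=feature_scale,
            seed=self.seed,
        )


def simulate_semantic_space(
    lemmas: Sequence[str],
    features: Sequence[str],
    d: int,
    sd_lexeme: float = 4.0,
    sd_feature: float = 4.0,
    sd_noise: float = 1.0,
    feature_scale: float = 1.0,
    seed: int = 0,
) -> SemanticSpace:
    """Simulate i.i.d. Gaussian lexeme and feature vectors.

    Lexeme vectors ~ N(0, sd_lexeme^2) per dimension; feature vectors
    ~ N(0, (sd_feature * feature_scale)^2). Deterministic given the seed.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(seed)
    lex_vecs = {l: rng.normal(0.0, sd_lexeme, size=d) for l in lemmas}
    feat_vecs = {
        f: rng.normal(0.0, sd_feature, size=d) * feature_scale for f in features
    }
    return SemanticSpace(
        d, lex_vecs, feat_vecs, sd_lexeme, sd_feature, sd_noise, feature_scale, seed
    )


def features_for_entry(entry: ParadigmEntry, use_roles: bool = False) -> list[str]:
    """Inflectional feature labels composed into an entry's meaning.

    The semantic role replaces the case label when roles are in play (cases
    are distribution classes over roles, not meanings themselves). Gender
    carries no semantic vector.
    """
    feats = [NUMBER_FEATURES[entry.number]]
    if use_roles and entry.role is not None:
        feats.append(entry.role.upper())
    else:
        feats.append(entry.case.upper())
    if entry.definiteness is not None:
        feats.append(DEFINITENESS_FEATURES[entry.definiteness])
    return feats


def default_feature_labels(use_roles: bool = False, definiteness: bool = False):
    from .lexicon import CASES, DEFAULT_ROLE_TABLE

    labels = ["SINGULAR", "PLURAL"]
    if use_roles:
        seen = []
        for case in CASES:
            for role, _ in DEFAULT_ROLE_TABLE[case]:
                if role.upper() not in seen:
                    seen.append(role.upper())
        labels += seen
    else:
        labels += [c.upper() for c in CASES]
    if definiteness:
        labels += ["DEFINITE", "INDEFINITE"]
    return labels


def compose_meaning(
    entry: ParadigmEntry,
    space: SemanticSpace,
    number_coding: str = "equipollent",
    use_roles: bool = False,
    noise_seed: Optional[int] = None,
) -> np.ndarray:
    """Lexeme + number + case-or-role (+ definiteness) + Gaussian noise.

    Under privative number coding the singular is unmarked (no SINGULAR
    vector); equipollent coding, the default, marks both numbers. Noise is
    drawn once per entry with ``noise_seed`` so homophones in different
    paradigm cells still receive distinct vectors.
    """
    if number_coding not in ("equipollent", "privative"):
        raise ValueError(f"unknown number coding {number_coding!r}")
    if entry.lemma not in space.lexeme_vectors:
        raise KeyError(f"lexeme {entry.lemma!r} missing from semantic space")
    vec = space.lexeme_vectors[entry.lemma].copy()
    for feat in features_for_entry(entry, use_roles):
        if feat == "SINGULAR" and number_coding == "privative":
            continue
        if feat not in space.feature_vectors:
            raise KeyError(f"feature {feat!r} missing from semantic space")
        vec += space.feature_vectors[feat]
    if space.sd_noise > 0 and noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        vec += rng.normal(0.0, space.sd_noise, size=space.d)
    return vec


@dataclass
class SemanticMatrix:
    """Real-valued meaning matrix: rows aligned with lexicon entries."""

    values: np.ndarray
    row_keys: list[int]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("semantic matrix contains non-finite values")


def build_semantic_matrix(
    lex: Lexicon,
    space: SemanticSpace,
    number_coding: str = "equipollent",
    use_roles: bool = False,
    seed: int = 0,
) -> SemanticMatrix:
    """Stack composed meanings for every entry; noise independent across rows."""
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(lex))
    rows = [
        compose_meaning(e, space, number_coding, use_roles, noise_seed=int(seeds[i]))
        for i, e in enumerate(lex)
    ]
    return SemanticMatrix(np.array(rows), list(range(len(lex))))


# ---------------------------------------------------------------------------
# Empirical embeddings
# ---------------------------------------------------------------------------

def read_word2vec_text(path) -> dict[str, np.ndarray]:
    """Parse word2vec text format (optional count/dim header; optional gzip)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    vectors: dict[str, np.ndarray] = {}
    with opener(path, "rt", encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) == 2 and all(tok.isdigit() for tok in first):
            pass  # header line: "n_words dim"
        elif first:
            vectors[first[0]] = np.array([float(x) for x in first[1:]])
        for line in fh:
            parts = line.split()
            if parts:
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return vectors


def load_embeddings(path, lex: Lexicon) -> tuple[SemanticMatrix, list[int], list[str]]:
    """Look up each entry's surface form in an embedding file.

    Homophones necessarily share one vector (the embedding is keyed by the
    surface word). Entries whose form is absent are dropped with a warning;
    returns the matrix, the indices of the kept entries, and the missing forms.
    """
    vectors = read_word2vec_text(path)
    kept, rows, missing = [], [], []
    for i, e in enumerate(lex):
        v = vectors.get(e.form)
        if v is None:
            missing.append(e.form)
        else:
            kept.append(i)
            rows.append(v)
    if missing:
        logger.warning("%d entries dropped: forms missing from embeddings", len(missing))
    if not rows:
        raise ValueError("no lexicon form found in the embedding file")
    return SemanticMatrix(np.array(rows), kept), kept, missing


def derive_analytical_vectors(
    embeddings: SemanticMatrix,
    lex: Lexicon,
    use_roles: bool = False,
) -> tuple[SemanticSpace, np.ndarray]:
    """Reconstruct lexeme and inflectional vectors from entry embeddings.

    Lexeme vector = mean over the lemma's embedded variants. Feature vector =
    mean over the entries carrying the feature, minus the grand mean over all
    entries: the subtraction removes the paradigm-average component that a
    plain carrier mean would otherwise add twice when cell vectors are
    re-assembled as lexeme + number + case. Returns the analytical space and
    the per-entry Pearson r between reconstructed and original vectors.
    """
    X = embeddings.values
    keys = embeddings.row_keys
    d = X.shape[1]
    grand = X.mean(axis=0)

    by_lemma: dict[str, list[int]] = {}
    by_feat: dict[str, list[int]] = {}
    for pos, i in enumerate(keys):
        e = lex[i]
        by_lemma.setdefault(e.lemma, []).append(pos)
        for f in features_for_entry(e, use_roles):
            by_feat.setdefault(f, []).append(pos)

    lex_vecs = {l: X[pos].mean(axis=0) for l, pos in by_lemma.items()}
    feat_vecs = {}
    for f, pos in by_feat.items():
        feat_vecs[f] = X[pos].mean(axis=0) - grand
    for f in set().union(*(set(features_for_entry(lex[i], use_roles)) for i in keys)):
        if f not in feat_vecs:
            logger.warning("feature %s has no carriers; zero vector used", f)
            feat_vecs[f] = np.zeros(d)

    space = SemanticSpace(d, lex_vecs, feat_vecs, sd_noise=0.0)
    rs = np.empty(len(keys))
    for pos, i in enumerate(keys):
        recon = compose_meaning(lex[i], space, use_roles=use_roles)
        rs[pos] = _pearson(recon, X[pos])
    return space, rs


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def write_semantic_space(space: SemanticSpace, path) -> None:
    """Delimited container: one line per vector, label then d floats."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# d={space.d} sd_lexeme={space.sd_lexeme} "
                 f"sd_feature={space.sd_feature} sd_noise={space.sd_noise} "
                 f"feature_scale={space.feature_scale}\n")
        for kind, vecs in (("lexeme", space.lexeme_vectors),
                           ("feature", space.feature_vectors)):
            for name, v in vecs.items():
                fh.write("\t".join([kind, name, *(repr(float(x)) for x in v)]) + "\n")


def read_semantic_space(path) -> SemanticSpace:
    lex_vecs, feat_vecs = {}, {}
    params: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        for tok in header.lstrip("# ").split():
            k, v = tok.split("=")
            params[k] = float(v)
        for line in fh:
            kind, name, *vals = line.rstrip("\n").split("\t")
            vec = np.array([float(x) for x in vals])
            (lex_vecs if kind == "lexeme" else feat_vecs)[name] = vec
    return SemanticSpace(
        int(params["d"]), lex_vecs, feat_vecs,
        sd_lexeme=params.get("sd_lexeme", 4.0),
        sd_feature=params.get("sd_feature", 4.0),
        sd_noise=params.get("sd_noise", 1.0),
        feature_scale=params.get("feature_scale", 1.0),
    )
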