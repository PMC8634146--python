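"""Wug-task simulation: comprehend nonce singulars, synthesize their plurals.

In a wug experiment, speakers see a nonce noun in the nominative singular and
are asked to produce its plural. The model has no meaning for a nonce, so the
pipeline proceeds in five steps: (1) train a comprehension mapping on the
real lexicon; (2) map each nonce's cue vector into semantic space to obtain
an estimated singular meaning; (3) re-estimate the production mapping on the
real words plus the nonces (known only in their singular); (4) shift each
estimated meaning to the plural by adding the PLURAL vector and subtracting
the SINGULAR vector; (5) synthesize ranked candidate plural forms with the
path algorithm.

The default cue unit is letter bigrams, and inflectional feature vectors are
shrunk (feature_scale = 1/110 by default), both of which diversify the
candidate sets: without the shrinkage, meanings are numerically dominated by
the inflectional vectors rather than by the nonce's stem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .forms import CueInventory, build_cue_matrix, vectorize_form
from .lexicon import Lexicon
from .mapping import LinearMapping, estimate_endstate
from .production import CandidateForm, ProductionConfig, default_max_path_length, learn_paths
from .semantics import SemanticSpace, build_semantic_matrix
from .comprehension import predict_semantics

logger = logging.getLogger("discrimlex")

#: Wug-demonstration nonce items (nonce nouns with existing German rhymes).
DEFAULT_NONCES = (
    "Bral", "Kach", "Klot", "Mur", "Nuhl", "Pind",
    "Pisch", "Pund", "Raun", "Spand", "Spert", "Vag",
)

#: Default inflectional shrinkage for the wug regime.
WUG_FEATURE_SCALE = 1.0 / 110.0


@dataclass
class WugItem:
    """One nonce with its estimated meanings and ranked plural candidates."""

    nonce: str
    singular_meaning: np.ndarray
    plural_meaning: np.ndarray
    candidates: list[CandidateForm]


def estimate_nonce_meaning(
    nonce_forms: Sequence[str],
    F: LinearMapping,
    inventory: CueInventory,
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Map nonce cue vectors into semantic space: s-hat = c F.

    Novel cues are dropped (and reported); a nonce sharing no cue at all with
    the training data is rejected — nothing the mapping knows bears on it.
    """
    vecs = []
    novel_report: dict[str, list[str]] = {}
    for nf in nonce_forms:
        v, novel = vectorize_form(nf, inventory)
        if novel:
            novel_report[nf] = novel
        if not v.any():
            raise ValueError(
                f"nonce {nf!r} shares no cues with the training data; "
                "restrict nonces to items with existing rhymes"
            )
        vecs.append(v)
    return predict_semantics(np.array(vecs), F), novel_report


def wug_produce_plural(
    nonces: Sequence[str],
    lex: Lexicon,
    space: SemanticSpace,
    config: Optional[ProductionConfig] = None,
    feature_scale: float = WUG_FEATURE_SCALE,
    unit: str = "letter_ngram",
    n: int = 2,
    number_coding: str = "equipollent",
    use_roles: bool = False,
    seed: int = 0,
    top: int = 5,
) -> list[WugItem]:
    """Run the five-step wug pipeline; returns ranked plural candidates.

    The production mapping is re-estimated (end-state) on real words plus the
    nonce singulars with their estimated meanings; the comprehension mapping
    used for synthesis-by-analysis is the one trained on real words only.
    Articles are not attached in wug mode (participants produce bare plurals).
    """
    space = space.scaled(feature_scale)
    if "SINGULAR" not in space.feature_vectors or "PLURAL" not in space.feature_vectors:
        raise ValueError("semantic space must provide SINGULAR and PLURAL vectors")

    # step 1: comprehension trained on the full real-word lexicon
    cm, inventory, _ = build_cue_matrix(lex, unit=unit, n=n)
    S = build_semantic_matrix(lex, space, number_coding, use_roles, seed=seed)
    F = estimate_endstate(cm.values, S.values, direction="comprehension")

    # step 2: estimated singular meanings for the nonces
    s_sg, novel_report = estimate_nonce_meaning(nonces, F, inventory)
    if novel_report:
        logger.info("nonce cues unseen in training: %s", novel_report)

    # step 3: production mapping over real words plus nonce singulars
    nonce_C = np.array([vectorize_form(nf, inventory)[0] for nf in nonces])
    C_aug = np.vstack([cm.values, nonce_C])
    S_aug = np.vstack([S.values, s_sg])
    G = estimate_endstate(S_aug, C_aug, direction="production")

    # step 4: plural meanings = singular estimate + PLURAL - SINGULAR
    shift = space.feature_vectors["PLURAL"] - space.feature_vectors["SINGULAR"]
    s_pl = s_sg + shift

    # step 5: synthesize ranked candidates
    if config is None:
        # calibrate the support threshold on the real words, then relax it:
        # nonce plural targets give their cues weaker support than trained
        # forms give their own, so the trained-form threshold is too strict
        from .production import calibrate_theta, predict_form_supports

        theta = 0.5 * calibrate_theta(
            predict_form_supports(S.values, G), cm.values
        )
        config = ProductionConfig(theta=theta, tolerance=0, max_candidates=top)
    max_len = config.max_path_length or default_max_path_length(lex, inventory)
    candidates = learn_paths(
        s_pl, G, F, inventory, config, mode="graph", max_path_length=max_len
    )
    return [
        WugItem(nonce=nf, singular_meaning=s_sg[i], plural_meaning=s_pl[i],
                candidates=candidates[i][:top])
        for i, nf in enumerate(nonces)
    ]


def format_wug_table(items: Sequence[WugItem], top: int = 5) -> str:
    """Nonce-by-rank candidate table (tab-delimited, nonce headers)."""
    lines = ["\t".join(it.nonce for it in items)]
    for rank in range(top):
        row = []
        for it in items:
            row.append(it.candidates[rank].surface if rank < len(it.candidates) else "")
        lines.append("\t".join(row))
    return "\n".join(lines)
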