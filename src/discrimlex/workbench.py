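"""Experiment runner: one config in, one reproducible accuracy report out.

A run wires the full pipeline — cue extraction, semantic-matrix construction,
train/validation split, mapping estimation (end-state or a single incremental
pass), comprehension and production evaluation, and optional learning
trajectories and pruning sweeps — and is fully determined by the lexicon, the
config, and the master seed. Reports carry both strict and lenient accuracies
for every condition, the category counts, and a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import comprehension as compr
from . import production as prod
from .forms import build_cue_matrix, entry_cues
from .lexicon import (
    DEFAULT_ROLE_TABLE,
    Lexicon,
    expand_roles,
    simulate_role_frequencies,
    split_train_validation,
)
from .mapping import (
    estimate_endstate,
    prune_weights,
    sample_token_stream,
    train_incremental,
)
from .semantics import (
    SemanticSpace,
    build_semantic_matrix,
    default_feature_labels,
    simulate_semantic_space,
)

logger = logging.getLogger("discrimlex")


@dataclass
class ExperimentConfig:
    """Everything that determines a run, given the lexicon."""

    # cues
    unit: str = "phone_ngram"
    n: int = 3
    # semantics
    d: Optional[int] = None  # None: match the cue dimension
    sd_lexeme: float = 4.0
    sd_feature: float = 4.0
    sd_noise: float = 1.0
    feature_scale: float = 1.0
    number_coding: str = "equipollent"
    use_roles: bool = False
    simulate_frequencies: bool = False
    # split
    train_fraction: float = 0.8
    split_mode: str = "random"
    # training
    training: str = "endstate"  # or "incremental"
    eta: float = 0.001
    stream_scheme: str = "shuffled_census"
    n_events: Optional[int] = None
    checkpoints: tuple[int, ...] = ()
    # production
    theta: Optional[float] = None  # None: calibrate on the training data
    tolerance: int = 0
    top_k: int = 5
    max_candidates: int = 5
    run_production: bool = True
    # pruning sweep (fractions of weights to prune)
    pruning_fractions: tuple[float, ...] = ()
    # master seed
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        data = json.loads(text)
        for key in ("checkpoints", "pruning_fractions"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _prune_fraction_threshold(weights: np.ndarray, fraction: float) -> float:
    """Magnitude threshold that prunes approximately the given weight fraction."""
    if fraction <= 0:
        return 0.0
    return float(np.quantile(np.abs(weights), fraction))


def run_experiment(lex: Lexicon, config: ExperimentConfig) -> dict:
    """Execute the full pipeline; returns a JSON-serializable report."""
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=8)

    try:
        if config.use_roles:
            lex = expand_roles(lex, DEFAULT_ROLE_TABLE)
            if config.simulate_frequencies:
                lex = simulate_role_frequencies(lex, DEFAULT_ROLE_TABLE, seed=int(seeds[0]))
    except Exception as exc:
        raise RuntimeError(f"[roles] {exc}") from exc

    try:
        split = split_train_validation(
            lex,
            config.train_fraction,
            mode=config.split_mode,
            cue_extractor=lambda e: entry_cues(e, config.unit, config.n),
            seed=int(seeds[1]),
        )
    except Exception as exc:
        raise RuntimeError(f"[split] {exc}") from exc

    lex_all = Lexicon(list(split.train) + list(split.validation), source=lex.source)
    train_rows = list(range(len(split.train)))
    val_rows = list(range(len(split.train), len(lex_all)))

    try:
        cm_train, inventory, _ = build_cue_matrix(split.train, config.unit, config.n)
        cm_all, _, novel_report = build_cue_matrix(lex_all, inventory=inventory,
                                                   unit=config.unit, n=config.n)
    except Exception as exc:
        raise RuntimeError(f"[cues] {exc}") from exc

    try:
        d = config.d or len(inventory)
        labels = default_feature_labels(
            config.use_roles, any(e.definiteness for e in lex_all)
        )
        space = simulate_semantic_space(
            sorted({e.lemma for e in lex_all}), labels, d,
            config.sd_lexeme, config.sd_feature, config.sd_noise,
            config.feature_scale, seed=int(seeds[2]),
        )
        S_all = build_semantic_matrix(
            lex_all, space, config.number_coding, config.use_roles, seed=int(seeds[3])
        )
    except Exception as exc:
        raise RuntimeError(f"[semantics] {exc}") from exc

    C_train = cm_all.values[train_rows]
    S_train = S_all.values[train_rows]

    trajectory = []
    try:
        if config.training == "endstate":
            F = estimate_endstate(C_train, S_train, "comprehension")
        elif config.training == "incremental":
            stream = sample_token_stream(
                split.train, config.n_events, config.stream_scheme, seed=int(seeds[4])
            )
            F, snaps = train_incremental(
                C_train, S_train, stream, config.eta, "comprehension",
                checkpoints=config.checkpoints,
            )
            for ckpt, snap in zip(sorted(set(config.checkpoints)), snaps):
                rep = compr.evaluate_comprehension(
                    snap, cm_all.values, S_all.values, lex_all,
                    train_rows, val_rows, split,
                )
                trajectory.append({"events": int(ckpt), **rep.accuracies})
        else:
            raise ValueError(f"unknown training mode {config.training!r}")
    except Exception as exc:
        raise RuntimeError(f"[training] {exc}") from exc

    try:
        comp_report = compr.evaluate_comprehension(
            F, cm_all.values, S_all.values, lex_all, train_rows, val_rows, split
        )
    except Exception as exc:
        raise RuntimeError(f"[comprehension] {exc}") from exc

    report = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "n_entries": len(lex_all),
        "n_cues": len(inventory),
        "novel_cue_entries": len(novel_report),
        "comprehension": comp_report.accuracies,
        "counts": comp_report.counts,
        "trajectory": trajectory,
    }

    if config.run_production:
        try:
            G = estimate_endstate(S_train, C_train, "production")
            C_hat_train = prod.predict_form_supports(S_train, G)
            theta = (config.theta if config.theta is not None
                     else prod.calibrate_theta(C_hat_train, C_train))
            logger.info("production threshold theta=%.4g", theta)
            pconfig = prod.ProductionConfig(
                theta=theta, tolerance=config.tolerance, top_k=config.top_k,
                max_candidates=config.max_candidates,
            )
            max_len = prod.default_max_path_length(split.train, inventory)
            candidates = prod.learn_paths(
                S_all.values, G, F, inventory, pconfig, mode="graph",
                max_path_length=max_len,
            )
            prod_report = prod.evaluate_production(
                candidates, lex_all, train_rows, val_rows, split
            )
            report["production"] = prod_report.accuracies
            report["theta"] = theta
        except Exception as exc:
            raise RuntimeError(f"[production] {exc}") from exc

    if config.pruning_fractions:
        try:
            series = []
            for frac in config.pruning_fractions:
                thr = _prune_fraction_threshold(F.weights, frac)
                F_p, actual = prune_weights(F, thr)
                rep = compr.evaluate_comprehension(
                    F_p, cm_all.values, S_all.values, lex_all,
                    train_rows, val_rows, split,
                )
                series.append(
                    {"fraction": float(frac), "actual_fraction": actual,
                     "train": rep.accuracies["train"]}
                )
            report["pruning"] = series
        except Exception as exc:
            raise RuntimeError(f"[pruning] {exc}") from exc

    return report


def format_report(report: dict) -> str:
    """Human-readable accuracy table."""
    lines = [f"config {report['config_hash']}  "
             f"({report['n_entries']} entries, {report['n_cues']} cues)"]
    header = ["", "train", "val_all", "val_lenient", "val_strict", "val_newform"]
    lines.append("\t".join(header))
    for section in ("comprehension", "production"):
        if section not in report:
            continue
        acc = report[section]
        row = [section] + [
            f"{acc[k]:.3f}" if acc.get(k) is not None else "--"
            for k in header[1:]
        ]
        lines.append("\t".join(row))
    return "\n".join(lines)
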