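"""Imbalance-aware Random Forest ensemble.

Essential genes are heavily outnumbered (~8.5:1) by non-essential genes, so
training undersamples the negative class: negatives are shuffled and split
into ``n_folds`` disjoint, near-equal chunks, and one forest is fitted per
chunk on (all positives + that chunk).  Every negative therefore appears in
exactly one member model's training set, and the ensemble probability is
the arithmetic mean over members.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import LabelSet

logger = logging.getLogger("netgenes")

CANONICAL_WIDTH = 283


@dataclass
class ModelConfig:
    n_trees: int = 150
    criterion: str = "entropy"
    max_features: str = "sqrt"
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        if self.criterion not in ("gini", "entropy"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class TrainedEnsemble:
    models: list
    schema: list[str]
    config: ModelConfig
    organisms: list[str]
    version_tag: str = ""

    def _check_schema(self, features: pd.DataFrame) -> None:
        if list(features.columns) != self.schema:
            missing = [c for c in self.schema if c not in features.columns]
            extra = [c for c in features.columns if c not in self.schema]
            raise ValueError(
                f"feature schema mismatch: missing={missing[:5]}, extra={extra[:5]}"
            )

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        """Mean predicted essentiality probability across member models."""
        self._check_schema(features)
        x = features.to_numpy(dtype=float)
        probs = np.mean([m.predict_proba(x)[:, 1] for m in self.models], axis=0)
        return pd.Series(probs, index=features.index, name="probability")


def undersample_folds(
    positives: Sequence[str],
    negatives: Sequence[str],
    n_folds: int,
    seed: int,
    cap_chunks: bool = False,
) -> list[list[str]]:
    """Partition negatives into ``n_folds`` disjoint chunks and pair each with
    all positives.

    Chunk sizes differ by at most one and their union covers every negative,
    so each negative is seen by exactly one member model.  With
    ``cap_chunks`` each chunk is truncated to ``len(positives)`` (full
    balance at the cost of the coverage guarantee).
    """
    positives = list(positives)
    negatives = list(negatives)
    if not positives:
        raise ValueError("no positive examples")
    if n_folds > len(negatives):
        raise ValueError(
            f"n_folds={n_folds} exceeds number of negatives ({len(negatives)})"
        )
    rng = np.random.RandomState(seed)
    shuffled = list(negatives)
    rng.shuffle(shuffled)
    base, extra = divmod(len(shuffled), n_folds)
    sets = []
    start = 0
    for k in range(n_folds):
        size = base + (1 if k < extra else 0)
        chunk = shuffled[start : start + size]
        start += size
        if cap_chunks:
            chunk = chunk[: len(positives)]
        sets.append(positives + chunk)
    return sets


def train(
    features: pd.DataFrame,
    labels: LabelSet,
    cfg: ModelConfig | None = None,
    allow_nonstandard_schema: bool = False,
) -> TrainedEnsemble:
    """Fit one forest per undersampled fold.

    ``features`` must contain a row for every gene in ``labels.universe``;
    the canonical 283-column schema is enforced unless
    ``allow_nonstandard_schema`` is set (research use).
    """
    cfg = cfg or ModelConfig()
    if not labels.universe <= set(features.index):
        missing = sorted(labels.universe - set(features.index))
        raise ValueError(f"genes without features: {missing[:5]}")
    if features.shape[1] != CANONICAL_WIDTH and not allow_nonstandard_schema:
        raise ValueError(
            f"expected the canonical {CANONICAL_WIDTH}-column schema, "
            f"got {features.shape[1]} columns (set allow_nonstandard_schema to override)"
        )
    positives = sorted(labels.essential)
    negatives = sorted(labels.non_essential)
    if not positives or not negatives:
        raise ValueError("training requires at least one positive and one negative")
    folds = undersample_folds(positives, negatives, cfg.n_folds, cfg.seed)
    pos_set = set(positives)
    models = []
    for k, genes in enumerate(folds):
        x = features.loc[genes].to_numpy(dtype=float)
        y = np.array([1 if g in pos_set else 0 for g in genes])
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            criterion=cfg.criterion,
            max_features=cfg.max_features,
            random_state=cfg.seed + k,
            n_jobs=1,
        )
        forest.fit(x, y)
        models.append(forest)
    logger.info(
        "trained %d fold models on %d positives / %d negatives",
        len(models), len(positives), len(negatives),
    )
    return TrainedEnsemble(
        models=models,
        schema=list(features.columns),
        config=cfg,
        organisms=[labels.organism],
        version_tag=labels.version_tag,
    )


def predict_proba(ens: TrainedEnsemble, features: pd.DataFrame) -> pd.Series:
    """Module-level alias for :meth:`TrainedEnsemble.predict_proba`."""
    return ens.predict_proba(features)


def grid_search(
    features: pd.DataFrame,
    labels: LabelSet,
    grid: dict[str, list],
    n_folds: int = 10,
    seed: int = 0,
    allow_nonstandard_schema: bool = False,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by k-fold cross-validated AUROC.

    Returns the best configuration (ties broken by grid enumeration order)
    and the full score table, one row per grid point.
    """
    from itertools import product

    from .evaluate import auroc  # local import: evaluate imports model

    if not grid:
        raise ValueError("empty grid")
    keys = list(grid.keys())
    combos = list(product(*(grid[k] for k in keys)))

    genes = sorted(labels.universe)
    y = np.array([1 if g in labels.essential else 0 for g in genes])
    rng = np.random.RandomState(seed)
    order = rng.permutation(len(genes))
    fold_of = np.empty(len(genes), dtype=int)
    # stratified assignment: positives and negatives dealt round-robin
    for cls in (0, 1):
        idx = [i for i in order if y[i] == cls]
        for j, i in enumerate(idx):
            fold_of[i] = j % n_folds

    rows = []
    best_cfg, best_score = None, -np.inf
    for combo in combos:
        params = dict(zip(keys, combo))
        cfg = ModelConfig(seed=seed, **params)
        fold_scores = []
        for k in range(n_folds):
            test_mask = fold_of == k
            if y[test_mask].min() == y[test_mask].max():
                continue  # single-class test fold is unscorable
            train_genes = [g for g, m in zip(genes, test_mask) if not m]
            sub = LabelSet(
                organism=labels.organism,
                essential=labels.essential & set(train_genes),
                universe=set(train_genes),
                version_tag=labels.version_tag,
            )
            ens = train(
                features, sub, cfg, allow_nonstandard_schema=allow_nonstandard_schema
            )
            test_genes = [g for g, m in zip(genes, test_mask) if m]
            probs = ens.predict_proba(features.loc[test_genes])
            fold_scores.append(auroc(probs.to_numpy(), y[test_mask]))
        mean_score = float(np.mean(fold_scores))
        rows.append({**params, "mean_auroc": mean_score})
        if mean_score > best_score:
            best_cfg, best_score = cfg, mean_score
    return best_cfg, pd.DataFrame(rows)


def save_ensemble(ens: TrainedEnsemble, out_dir: str | Path) -> None:
    """Persist fold models (joblib) plus a JSON manifest with provenance."""
    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, m in enumerate(ens.models):
        joblib.dump(m, out / f"fold_{k:02d}.joblib")
    manifest = {
        "schema": ens.schema,
        "config": asdict(ens.config),
        "organisms": ens.organisms,
        "version_tag": ens.version_tag,
        "n_folds": len(ens.models),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(out_dir: str | Path) -> TrainedEnsemble:
    import joblib

    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    models = [
        joblib.load(out / f"fold_{k:02d}.joblib")
        for k in range(manifest["n_folds"])
    ]
    return TrainedEnsemble(
        models=models,
        schema=manifest["schema"],
        config=ModelConfig(**manifest["config"]),
        organisms=manifest["organisms"],
        version_tag=manifest["version_tag"],
    )
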