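"""Random-forest ranking of candidate 14-3-3 docking phosphosites.

Three ensembles are trained on nested feature subsets and each protein's
candidate Ser/Thr residues are ranked by the forest's positive-class
probability:

* ``total`` — all five inputs (ANN, SVM, PSSM, disorder, PTM score);
* ``ptm_disorder`` — PTM score and disorder only;
* ``sequence`` — the three consensus-sequence scores only.

A fourth output column, the adapted consensus, is the plain arithmetic
mean of the three sequence scores turned into a rank list; it involves no
learning and serves as the sequence-matching baseline.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core_data import DataError, Dataset, ProteinRecord
from .features import (
    FEATURE_COLUMNS,
    PSSMModel,
    assemble_features,
    build_pssm_from_labels,
)

FORMAT_VERSION = 1

#: Feature subsets per ensemble, in a fixed order.
ENSEMBLE_FEATURES: dict[str, list[str]] = {
    "total": ["ann", "svm", "pssm", "disorder", "ptm_score"],
    "ptm_disorder": ["ptm_score", "disorder"],
    "sequence": ["ann", "svm", "pssm"],
}

#: Ranked output columns, in reporting order.
OUTPUT_COLUMNS = ["total", "ptm_disorder", "sequence", "adapted"]


def derive_seed(*parts) -> int:
    """Stable sub-seed (< 2**31) from a base seed and context labels."""
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class ForestConfig:
    """Hyperparameters for the three forest ensembles.

    ``class_balance`` is either ``"weight"`` (balanced class weights, the
    default) or ``"downsample"`` (keep at most ``neg_ratio`` negatives per
    positive, sampled under the seed).  A seed is mandatory: every training
    run must be reproducible.
    """

    seed: int
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    min_leaf: int = 1
    class_balance: str = "weight"
    neg_ratio: float = 5.0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise DataError("n_trees must be >= 1")
        if self.class_balance not in ("weight", "downsample"):
            raise DataError(f"unknown class_balance {self.class_balance!r}")
        if self.seed is None:
            raise DataError("a seed is mandatory for training")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedRanker:
    """Three fitted ensembles plus training metadata.

    ``pssm`` is the built-in sequence model fitted alongside the forests;
    it is persisted with them so unlabeled proteins can be scored without
    external consensus-score tables.
    """

    forests: dict[str, RandomForestClassifier]
    config: ForestConfig
    feature_names: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in ENSEMBLE_FEATURES.items()}
    )
    dataset_digest: str = ""
    format_version: int = FORMAT_VERSION
    pssm: PSSMModel | None = None


def build_training_matrix(
    features: pd.DataFrame,
    dataset: Dataset,
    seed: int,
    class_balance: str = "weight",
    neg_ratio: float = 5.0,
    client_ids: list[str] | None = None,
    positive_keys: set[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble (X, y) from an assembled feature table.

    Positives are the validated docking sites; negatives are every other
    candidate S/T on the same client proteins (never random proteome
    background).  Rows are shuffled under the seed; optional seeded
    down-sampling keeps at most ``neg_ratio`` negatives per positive.
    """
    if positive_keys is None:
        positive_keys = {
            (s.protein_id, s.position) for s in dataset.positives()
        }
    if not positive_keys:
        raise DataError("no positive class: dataset has no validated docking sites")
    if client_ids is None:
        client_ids = sorted({pid for pid, _ in positive_keys})
    client_set = set(client_ids)

    rows = features[features["protein_id"].isin(client_set)].reset_index(drop=True)
    y = np.array(
        [
            1 if (pid, int(pos)) in positive_keys else 0
            for pid, pos in zip(rows["protein_id"], rows["position"])
        ],
        dtype=int,
    )
    if y.sum() == 0:
        raise DataError("no positive class after filtering to client proteins")
    per_protein = pd.DataFrame({"pid": rows["protein_id"], "y": y}).groupby("pid")["y"]
    all_positive = per_protein.agg(["sum", "count"])
    for pid in all_positive.index[all_positive["sum"] == all_positive["count"]]:
        warnings.warn(
            f"protein {pid} has a docking site but no negative candidates",
            stacklevel=2,
        )

    rng = np.random.default_rng(derive_seed(seed, "training-matrix"))
    if class_balance == "downsample":
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        keep = int(round(neg_ratio * len(pos_idx)))
        if len(neg_idx) > keep:
            neg_idx = rng.choice(neg_idx, size=keep, replace=False)
        idx = np.concatenate([pos_idx, neg_idx])
    else:
        idx = np.arange(len(y))
    idx = rng.permutation(idx)
    return rows.iloc[idx].reset_index(drop=True), y[idx]


def _fit_forest(
    X: np.ndarray, y: np.ndarray, config: ForestConfig, seed: int
) -> RandomForestClassifier:
    if len(np.unique(y)) < 2:
        raise DataError("degenerate single-class training data")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_leaf,
        class_weight="balanced" if config.class_balance == "weight" else None,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def train_from_features(
    features: pd.DataFrame,
    dataset: Dataset,
    config: ForestConfig,
    client_ids: list[str] | None = None,
    positive_keys: set[tuple[str, int]] | None = None,
    pssm: PSSMModel | None = None,
) -> TrainedRanker:
    """Fit the three ensembles from an already-assembled feature table."""
    X_df, y = build_training_matrix(
        features,
        dataset,
        seed=config.seed,
        class_balance=config.class_balance,
        neg_ratio=config.neg_ratio,
        client_ids=client_ids,
        positive_keys=positive_keys,
    )
    forests = {}
    for name, cols in ENSEMBLE_FEATURES.items():
        forests[name] = _fit_forest(
            X_df[cols].to_numpy(float), y, config, derive_seed(config.seed, name)
        )
    return TrainedRanker(forests, config, dataset_digest=dataset.digest(), pssm=pssm)


def train_ranker(dataset: Dataset, config: ForestConfig) -> TrainedRanker:
    """Assemble features (built-in scorers where needed) and fit the ranker."""
    dataset.validate()
    pssm = build_pssm_from_labels(dataset)
    features = assemble_features(dataset, pssm=pssm)
    return train_from_features(features, dataset, config, pssm=pssm)


def rank_scores(
    scores: np.ndarray, ptm: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Ranks 1..n, best score first; ties by higher PTM score then lower
    position, so rankings are deterministic."""
    order = np.lexsort((positions, -ptm, -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def adapted_consensus(features: pd.DataFrame) -> np.ndarray:
    """Arithmetic mean of the ANN, SVM and PSSM scores per site."""
    return features[["ann", "svm", "pssm"]].to_numpy(float).mean(axis=1)


def predict_table(
    ranker: TrainedRanker,
    features: pd.DataFrame,
    dataset_digest: str | None = None,
) -> pd.DataFrame:
    """Score and rank every candidate, per protein, for all four columns.

    Returns the feature table extended with ``<column>_score`` and
    ``<column>_rank`` for total, ptm_disorder (ptmdis), sequence (seq) and
    adapted.  Probabilities come from each forest's positive class.
    """
    if dataset_digest is not None and ranker.dataset_digest and (
        dataset_digest != ranker.dataset_digest
    ):
        warnings.warn(
            "dataset digest differs from the one the ranker was trained on",
            stacklevel=2,
        )
    df = features.copy()
    short = {"total": "total", "ptm_disorder": "ptmdis", "sequence": "seq"}
    for name, forest in ranker.forests.items():
        cols = ranker.feature_names[name]
        X = df[cols].to_numpy(float)
        pos_idx = int(np.flatnonzero(forest.classes_ == 1)[0])
        df[f"{short[name]}_score"] = (
            forest.predict_proba(X)[:, pos_idx] if len(df) else np.zeros(0)
        )
    df["adapted_score"] = adapted_consensus(df) if len(df) else np.zeros(0)

    for col in ["total", "ptmdis", "seq", "adapted"]:
        ranks = np.empty(len(df), dtype=int)
        for _, grp_idx in df.groupby("protein_id").indices.items():
            sub = df.iloc[grp_idx]
            ranks[grp_idx] = rank_scores(
                sub[f"{col}_score"].to_numpy(float),
                sub["ptm_score"].to_numpy(float),
                sub["position"].to_numpy(),
            )
        df[f"{col}_rank"] = ranks
    return df


def predict_ranks(
    ranker: TrainedRanker, protein: ProteinRecord, features: pd.DataFrame
) -> pd.DataFrame:
    """Ranked predictions for a single protein's candidates."""
    sub = features[features["protein_id"] == protein.protein_id]
    if len(sub) == 0:
        return predict_table(ranker, sub)
    return predict_table(ranker, sub.reset_index(drop=True))


def feature_importance(ranker: TrainedRanker) -> dict[str, dict[str, float]]:
    """Gini importance (mean decrease in impurity) per feature per ensemble."""
    report = {}
    for name, forest in ranker.forests.items():
        report[name] = {
            feat: float(v)
            for feat, v in zip(ranker.feature_names[name], forest.feature_importances_)
        }
    return report


def save_ranker(ranker: TrainedRanker, path) -> None:
    """Persist the ranker with an embedded metadata block."""
    payload = {
        "metadata": json.dumps(
            {
                "format_version": ranker.format_version,
                "seed": ranker.config.seed,
                "config": ranker.config.to_dict(),
                "feature_names": ranker.feature_names,
                "dataset_digest": ranker.dataset_digest,
            }
        ),
        "forests": ranker.forests,
        "pssm": ranker.pssm,
    }
    joblib.dump(payload, path)


def load_ranker(path) -> TrainedRanker:
    try:
        payload = joblib.load(path)
        meta = json.loads(payload["metadata"])
        forests = payload["forests"]
    except Exception as exc:  # corrupted or foreign file
        raise DataError(f"cannot load ranker from {path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise DataError(
            f"ranker format version {meta.get('format_version')} "
            f"not supported (expected {FORMAT_VERSION})"
        )
    config = ForestConfig(**meta["config"])
    return TrainedRanker(
        forests,
        config,
        feature_names=meta["feature_names"],
        dataset_digest=meta["dataset_digest"],
        format_version=meta["format_version"],
        pssm=payload.get("pssm"),
    )
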