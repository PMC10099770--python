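"""Validation machinery for the docking-site ranker.

Three held-out protocols, all of which retrain the forests (and the
built-in sequence model) strictly on the training side of each fold:

* leave-one-protein-out — retrain without one client protein, rank its
  candidates, record where the validated site lands;
* repeated holdout — repeatedly hold out a fraction of the client proteins
  (protein-level splits, so a protein's positive and negative sites never
  straddle the split), retrain, evaluate every held-out validated site;
* non-canonical leave-one-site-out — restrict to validated sites whose
  consensus-sequence score falls below a cutoff, remove one site at a time,
  retrain, and ask whether it re-surfaces within an absolute top-N.

Percentile protocols score a hit when the site's rank is within the top
k% of that protein's candidates (ceiling threshold); the non-canonical
protocol uses the absolute rank cutoff instead.  Plus the docking-vs-other
feature-enrichment statistics (Welch's unequal-variance t test and the
relative mean difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError, Dataset, LabeledSite
from .features import (
    FEATURE_COLUMNS,
    attach_sequence_scores,
    build_pssm_from_labels,
    candidate_table,
    consensus_rescale,
    encode_windows,
    extract_window,
)
from .model import (
    ForestConfig,
    OUTPUT_COLUMNS,
    derive_seed,
    predict_table,
    train_from_features,
)

RANK_COLUMNS = {"total": "total_rank", "ptm_disorder": "ptmdis_rank",
                "sequence": "seq_rank", "adapted": "adapted_rank"}


@dataclass
class EvalConfig:
    """Protocol parameters for the validation studies."""

    seed: int = 0
    k_fractions: tuple[float, ...] = (0.10, 0.25)
    holdout_fraction: float = 0.20
    holdout_reps: int = 200
    top_n_cutoff: int = 15
    consensus_cutoffs: tuple[float, ...] = (0.5, 0.8)

    def __post_init__(self) -> None:
        if not all(0 < k < 1 for k in self.k_fractions):
            raise DataError("k_fractions must lie in (0, 1)")
        if not 0 < self.holdout_fraction < 1:
            raise DataError("holdout_fraction must lie in (0, 1)")
        if self.holdout_reps < 1:
            raise DataError("holdout_reps must be >= 1")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "k_fractions": list(self.k_fractions),
            "holdout_fraction": self.holdout_fraction,
            "holdout_reps": self.holdout_reps,
            "top_n_cutoff": self.top_n_cutoff,
            "consensus_cutoffs": list(self.consensus_cutoffs),
        }


def topk_hit(rank: int, n_candidates: int, k_fraction: float) -> bool:
    """Is the site within the top k% of the protein's candidates?

    The threshold is ceiling(k * n): a rank-1 site on a 5-candidate protein
    is a top-10% hit.  A small tolerance guards the ceiling against float
    representation of k * n.
    """
    if not 1 <= rank <= n_candidates:
        raise DataError(f"rank {rank} outside 1..{n_candidates}")
    threshold = math.ceil(k_fraction * n_candidates - 1e-9)
    return rank <= threshold


@dataclass
class EvaluationReport:
    """Per-site rank records plus aggregated hit rates.

    Each record carries the protein, the validated site, the number of
    candidates, and the site's rank in each of the four output columns.
    Hit rates are exact fractions hits/denominator; the denominator counts
    evaluated validated sites (dual-site proteins contribute one record per
    site).  ``protein_hit_rate`` aggregates at the protein level instead: a
    protein is a hit when any of its validated sites is.
    """

    protocol: str
    config: dict
    records: list[dict] = field(default_factory=list)

    def _ranks(self, column: str) -> list[tuple[int, int]]:
        key = RANK_COLUMNS[column]
        return [(r[key], r["n_candidates"]) for r in self.records]

    def hit_rate(self, column: str, k_fraction: float) -> tuple[int, int, float]:
        """(hits, denominator, rate) for a top-k% criterion, per site."""
        pairs = self._ranks(column)
        hits = sum(topk_hit(rank, n, k_fraction) for rank, n in pairs)
        denom = len(pairs)
        return hits, denom, hits / denom if denom else float("nan")

    def hit_rate_topn(self, column: str, top_n: int) -> tuple[int, int, float]:
        """(hits, denominator, rate) for an absolute rank <= top_n criterion."""
        pairs = self._ranks(column)
        hits = sum(rank <= top_n for rank, _ in pairs)
        denom = len(pairs)
        return hits, denom, hits / denom if denom else float("nan")

    def protein_hit_rate(self, column: str, k_fraction: float) -> tuple[int, int, float]:
        key = RANK_COLUMNS[column]
        by_protein: dict[str, bool] = {}
        for r in self.records:
            hit = topk_hit(r[key], r["n_candidates"], k_fraction)
            by_protein[r["protein_id"]] = by_protein.get(r["protein_id"], False) or hit
        hits = sum(by_protein.values())
        denom = len(by_protein)
        return hits, denom, hits / denom if denom else float("nan")

    def stratified_topn(self, column: str, top_n: int) -> dict[str, dict]:
        """Top-N hit rates split by the missing-PTM-score flag."""
        out = {}
        for label, flag in (("with_ptm_score", False), ("missing_ptm_score", True)):
            sub = [r for r in self.records if bool(r.get("missing_ptm")) == flag]
            hits = sum(r[RANK_COLUMNS[column]] <= top_n for r in sub)
            out[label] = {
                "hits": hits,
                "denominator": len(sub),
                "rate": hits / len(sub) if sub else None,
            }
        return out

    def to_dict(self) -> dict:
        tables: dict[str, dict] = {}
        for column in OUTPUT_COLUMNS:
            tables[column] = {}
            for k in self.config.get("k_fractions", [0.10, 0.25]):
                h, d, rate = self.hit_rate(column, k)
                ph, pd_, prate = self.protein_hit_rate(column, k)
                tables[column][f"top_{int(round(k * 100))}pct"] = {
                    "hits": h, "denominator": d, "rate": rate,
                    "protein_hits": ph, "protein_denominator": pd_,
                    "protein_rate": prate,
                }
            if self.protocol == "noncanonical":
                n = self.config.get("top_n_cutoff", 15)
                h, d, rate = self.hit_rate_topn(column, n)
                tables[column][f"top_{n}_absolute"] = {
                    "hits": h, "denominator": d, "rate": rate,
                    "by_ptm_flag": self.stratified_topn(column, n),
                }
        return {
            "protocol": self.protocol,
            "config": self.config,
            "hit_tables": tables,
            "records": self.records,
        }


def _prepare(dataset: Dataset) -> tuple[pd.DataFrame, np.ndarray]:
    dataset.validate()
    base = candidate_table(dataset)
    codes = encode_windows(list(base["window"]))
    return base, codes


def _fold_features(
    dataset: Dataset,
    base: pd.DataFrame,
    codes: np.ndarray,
    train_positives: list[LabeledSite],
) -> pd.DataFrame:
    """Sequence scores recomputed with a PSSM fit on training positives only."""
    pssm = build_pssm_from_labels(dataset, train_positives)
    return attach_sequence_scores(base, pssm, dataset.seqscores, codes=codes)


def _record_site(
    predictions: pd.DataFrame, site: LabeledSite, extra: dict | None = None
) -> dict:
    sub = predictions[predictions["protein_id"] == site.protein_id]
    row = sub[sub["position"] == site.position]
    if len(row) != 1:
        raise DataError(
            f"validated site {site.protein_id}:{site.position} is not a "
            "candidate of its protein"
        )
    row = row.iloc[0]
    rec = {
        "protein_id": site.protein_id,
        "position": site.position,
        "n_candidates": int(len(sub)),
        "missing_ptm": bool(row["missing_ptm"]),
        "noncanonical": bool(site.noncanonical),
    }
    for column, key in RANK_COLUMNS.items():
        rec[key] = int(row[key])
    if extra:
        rec.update(extra)
    return rec


def _positives_by_protein(dataset: Dataset) -> dict[str, list[LabeledSite]]:
    out: dict[str, list[LabeledSite]] = {}
    for site in dataset.positives():
        out.setdefault(site.protein_id, []).append(site)
    return out


def evaluate_loo(
    dataset: Dataset, forest_config: ForestConfig, eval_config: EvalConfig
) -> EvaluationReport:
    """Leave-one-protein-out validation.

    For each client protein: retrain the ranker (forests and built-in PSSM)
    on all other client proteins, rank the held-out protein's candidates,
    and record the validated site's rank in all four columns.
    """
    base, codes = _prepare(dataset)
    by_protein = _positives_by_protein(dataset)
    clients = sorted(by_protein)
    if len(clients) < 2:
        raise DataError("leave-one-protein-out needs at least 2 client proteins")

    report = EvaluationReport("loo", eval_config.to_dict())
    for i, held_out in enumerate(clients):
        train_ids = [pid for pid in clients if pid != held_out]
        train_pos = [s for pid in train_ids for s in by_protein[pid]]
        feats = _fold_features(dataset, base, codes, train_pos)
        fc = replace(
            forest_config,
            seed=derive_seed(forest_config.seed, "loo", i),
        )
        ranker = train_from_features(
            feats, dataset, fc,
            client_ids=train_ids,
            positive_keys={(s.protein_id, s.position) for s in train_pos},
        )
        test = feats[feats["protein_id"] == held_out].reset_index(drop=True)
        pred = predict_table(ranker, test)
        for site in by_protein[held_out]:
            report.records.append(_record_site(pred, site))
    return report


def evaluate_holdout(
    dataset: Dataset, forest_config: ForestConfig, eval_config: EvalConfig
) -> EvaluationReport:
    """Repeated holdout: per repetition, hold out a fraction of the client
    proteins (protein-level split), retrain on the rest, evaluate every
    held-out validated site.  Splits are drawn from the evaluation seed."""
    base, codes = _prepare(dataset)
    by_protein = _positives_by_protein(dataset)
    clients = sorted(by_protein)
    n_test = max(1, int(round(eval_config.holdout_fraction * len(clients))))
    if n_test >= len(clients):
        raise DataError("holdout split leaves no training proteins")

    report = EvaluationReport("holdout", eval_config.to_dict())
    for rep in range(eval_config.holdout_reps):
        rng = np.random.default_rng(derive_seed(eval_config.seed, "holdout", rep))
        perm = rng.permutation(clients)
        test_ids = sorted(perm[:n_test])
        train_ids = sorted(perm[n_test:])
        train_pos = [s for pid in train_ids for s in by_protein[pid]]
        feats = _fold_features(dataset, base, codes, train_pos)
        fc = replace(
            forest_config,
            seed=derive_seed(forest_config.seed, "holdout", rep),
        )
        ranker = train_from_features(
            feats, dataset, fc,
            client_ids=train_ids,
            positive_keys={(s.protein_id, s.position) for s in train_pos},
        )
        test = feats[feats["protein_id"].isin(test_ids)].reset_index(drop=True)
        pred = predict_table(ranker, test)
        for pid in test_ids:
            for site in by_protein[pid]:
                report.records.append(_record_site(pred, site, {"rep": rep}))
    return report


def consensus_scores(dataset: Dataset) -> pd.DataFrame:
    """Consensus-sequence score per validated docking site.

    With ingested external scores the consensus is the adapted mean of the
    (ann, svm, pssm) triple, taken verbatim.  With the built-in fallback
    each site is scored by a PSSM fit on the *other* validated sites
    (leave-one-site-out, so a site's own window never inflates its own
    consensus) and the raw log-odds is squashed onto [0, 1] by a logistic
    so the same 0.5/0.8 cutoff scale applies (flagged ``builtin_seq``).
    """
    dataset.validate()
    positives = dataset.positives()
    rows = []
    for site in positives:
        external = (
            dataset.seqscores.get((site.protein_id, site.position))
            if dataset.seqscores
            else None
        )
        if external is not None:
            score = float(sum(external) / 3.0)
            builtin = False
        else:
            others = [
                s for s in positives
                if (s.protein_id, s.position) != (site.protein_id, site.position)
            ]
            if not others:
                raise DataError(
                    "cannot score consensus: only one validated site available"
                )
            pssm = build_pssm_from_labels(dataset, others)
            protein = dataset.proteins[site.protein_id]
            raw = pssm.score_window(
                extract_window(protein.sequence, site.position, pssm.offsets)
            )
            score = float(consensus_rescale(raw))
            builtin = True
        rows.append(
            {
                "protein_id": site.protein_id,
                "position": site.position,
                "consensus": score,
                "builtin_seq": builtin,
            }
        )
    return pd.DataFrame(rows)


def noncanonical_subset(
    dataset: Dataset,
    cutoff: float = 0.5,
) -> list[LabeledSite]:
    """Validated docking sites whose consensus score falls below the cutoff."""
    scores = consensus_scores(dataset)
    below = {
        (r.protein_id, int(r.position))
        for r in scores.itertuples(index=False)
        if r.consensus < cutoff
    }
    return [s for s in dataset.positives() if (s.protein_id, s.position) in below]


def evaluate_noncanonical(
    dataset: Dataset,
    subset: list[LabeledSite],
    forest_config: ForestConfig,
    eval_config: EvalConfig,
    train_on_subset_only: bool = False,
) -> EvaluationReport:
    """Leave-one-site-out over the non-canonical subset.

    Each subset site is removed from the training data (the site, not the
    protein: the protein's remaining candidates still serve as training
    rows when it retains another validated site), the ranker is retrained,
    and the site's de-novo rank is recorded; the headline criterion is an
    absolute rank <= top_n_cutoff.  ``train_on_subset_only`` retrains on
    the non-canonical subset alone, the reduced-training-set variant.
    """
    if not subset:
        raise DataError("non-canonical subset is empty")
    base, codes = _prepare(dataset)
    pool = subset if train_on_subset_only else dataset.positives()

    report = EvaluationReport("noncanonical", eval_config.to_dict())
    for i, site in enumerate(sorted(subset, key=lambda s: (s.protein_id, s.position))):
        train_pos = [
            s for s in pool
            if (s.protein_id, s.position) != (site.protein_id, site.position)
        ]
        if not train_pos:
            raise DataError("cannot retrain: no positives left after removal")
        feats = _fold_features(dataset, base, codes, train_pos)
        train_ids = sorted({s.protein_id for s in train_pos})
        # the evaluated site must not appear as a training negative
        train_feats = feats[
            ~(
                (feats["protein_id"] == site.protein_id)
                & (feats["position"] == site.position)
            )
        ].reset_index(drop=True)
        fc = replace(
            forest_config,
            seed=derive_seed(forest_config.seed, "noncanonical", i),
        )
        ranker = train_from_features(
            train_feats, dataset, fc,
            client_ids=train_ids,
            positive_keys={(s.protein_id, s.position) for s in train_pos},
        )
        test = feats[feats["protein_id"] == site.protein_id].reset_index(drop=True)
        pred = predict_table(ranker, test)
        report.records.append(_record_site(pred, site))
    return report


# --- feature enrichment -----------------------------------------------------


def relative_mean_difference(mean_a: float, mean_ref: float) -> float:
    """|(mean_a - mean_ref) / mean_ref| * 100, as a percentage."""
    if mean_ref == 0:
        raise DataError("reference mean is zero; relative difference undefined")
    return abs((mean_a - mean_ref) / mean_ref) * 100.0


def welch_enrichment(
    features: pd.DataFrame,
    dataset: Dataset,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Docking vs other candidate sites, per feature.

    Welch's unequal-variance two-sided t test plus the relative mean
    difference of the 'other' group against the docking group.  Zero
    variance in both groups is degenerate; the limit value is reported and
    flagged.
    """
    feature_names = feature_names or FEATURE_COLUMNS
    pos_keys = {(s.protein_id, s.position) for s in dataset.positives()}
    if len(pos_keys) < 2:
        raise DataError("need at least 2 docking sites for enrichment")
    is_pos = np.array(
        [
            (pid, int(p)) in pos_keys
            for pid, p in zip(features["protein_id"], features["position"])
        ]
    )
    if (~is_pos).sum() < 2:
        raise DataError("need at least 2 non-docking sites for enrichment")

    rows = []
    for feat in feature_names:
        a = features.loc[is_pos, feat].to_numpy(float)  # docking
        b = features.loc[~is_pos, feat].to_numpy(float)  # other
        # t is reported for (other - docking), so a docking-enriched feature
        # has a negative t
        degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
        if degenerate:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t = math.inf if b.mean() > a.mean() else -math.inf
                p = 0.0
        else:
            t, p = stats.ttest_ind(b, a, equal_var=False)
        mean_dock, mean_other = float(a.mean()), float(b.mean())
        rel = (
            relative_mean_difference(mean_other, mean_dock)
            if mean_dock != 0
            else float("nan")
        )
        rows.append(
            {
                "feature": feat,
                "mean_docking": mean_dock,
                "mean_other": mean_other,
                "t": float(t),
                "p": float(p),
                "rel_diff_pct": rel,
                "significant": bool(p < 0.001),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)
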