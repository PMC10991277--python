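"""Scoring: Pearson r and MAE, genome-level aggregation, per-fold
cross-validation reports, and the amino-acid-frequency-vs-thermophilicity
correlation analysis.

Correlations that are mathematically undefined (a constant vector) are
signalled explicitly — ``UndefinedCorrelationError`` from the scalar
routine, missing values in tabular reports — and never silently coerced
to zero, because sign analyses would otherwise be corrupted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ogtpred.corpus import STANDARD_AA, UNKNOWN_AA, Corpus, proteins_of
from ogtpred.orthology import SplitPlan

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedCorrelationError",
    "EvaluationReport",
    "pearson_r",
    "mae",
    "genome_average",
    "aa_frequency_correlation",
    "evaluate_cv",
    "leakage_audit",
]


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined (a vector is constant)."""


def pearson_r(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Product-moment correlation between predictions and observations.

    Raises ``ValueError`` on length mismatch or fewer than two pairs, and
    ``UndefinedCorrelationError`` if either vector is constant.
    """
    p = np.asarray(pred, dtype=np.float64)
    o = np.asarray(obs, dtype=np.float64)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 2:
        raise ValueError(f"need at least 2 pairs, got {p.size}")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(p, o).statistic)


def mae(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean absolute error in °C."""
    p = np.asarray(pred, dtype=np.float64)
    o = np.asarray(obs, dtype=np.float64)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 1:
        raise ValueError("need at least 1 pair")
    return float(np.mean(np.abs(p - o)))


def genome_average(
    predictions: Mapping[str, float], corpus: Corpus
) -> pd.DataFrame:
    """Average per-protein predictions within each genome.

    Returns one row per genome that received at least one prediction:
    ``genome_id, optTem_pre, optTem_exp, n_proteins``.  ``optTem_pre`` is
    the unweighted arithmetic mean of the member predictions and
    ``optTem_exp`` the genome's recorded OGT.  Genomes without
    predictions are omitted with a warning.
    """
    proteins_of(corpus, predictions.keys())  # validates resolution
    frame = pd.DataFrame(
        {
            "protein_id": list(predictions.keys()),
            "pred": list(predictions.values()),
        }
    )
    frame["genome_id"] = [
        corpus.proteins[pid].genome_id for pid in frame["protein_id"]
    ]
    grouped = (
        frame.groupby("genome_id")["pred"].agg(["mean", "size"]).reset_index()
    )
    grouped.columns = ["genome_id", "optTem_pre", "n_proteins"]
    grouped["optTem_exp"] = [
        corpus.genomes[g].ogt_celsius for g in grouped["genome_id"]
    ]
    skipped = set(corpus.genomes) - set(grouped["genome_id"])
    if skipped:
        logger.warning(
            "genome_average: %d genomes had no predictions and were omitted",
            len(skipped),
        )
    return grouped[["genome_id", "optTem_pre", "optTem_exp", "n_proteins"]].sort_values(
        "genome_id", ignore_index=True
    )


def _aa_frequencies(sequence: str) -> np.ndarray:
    """Per-residue frequencies over the 20 standard letters; unknown
    symbols are excluded from numerator and denominator."""
    counts = np.zeros(20, dtype=np.float64)
    n = 0
    for aa in sequence:
        if aa != UNKNOWN_AA:
            counts[STANDARD_AA.index(aa)] += 1
            n += 1
    return counts / n if n else counts


def aa_frequency_correlation(corpus: Corpus) -> pd.DataFrame:
    """Correlate each amino acid's per-protein frequency with the protein
    temperature label across all labelled proteins.

    Returns 20 rows: ``amino_acid, pearson_r, p_value, n``.  Undefined
    correlations (constant frequency, e.g. a residue absent everywhere)
    yield missing values; their count is stored in
    ``result.attrs["n_undefined"]``.
    """
    labelled = corpus.labelled_proteins()
    if len(labelled) < 2:
        raise ValueError("need at least 2 labelled proteins")
    labels = np.array([p.label_celsius for p in labelled], dtype=np.float64)
    if np.ptp(labels) == 0:
        raise UndefinedCorrelationError("all labels identical; correlation undefined")
    freqs = np.vstack([_aa_frequencies(p.sequence) for p in labelled])
    rows = []
    n_undefined = 0
    for i, aa in enumerate(STANDARD_AA):
        col = freqs[:, i]
        if np.ptp(col) == 0:
            rows.append({"amino_acid": aa, "pearson_r": np.nan, "p_value": np.nan, "n": len(col)})
            n_undefined += 1
            continue
        res = stats.pearsonr(col, labels)
        rows.append(
            {
                "amino_acid": aa,
                "pearson_r": float(res.statistic),
                "p_value": float(res.pvalue),
                "n": len(col),
            }
        )
    table = pd.DataFrame(rows, columns=["amino_acid", "pearson_r", "p_value", "n"])
    table.attrs["n_undefined"] = n_undefined
    return table


@dataclass
class EvaluationReport:
    """r and MAE for one split, with the per-fold breakdown when the split
    was scored fold-by-fold."""

    split_name: str
    n: int
    pearson_r: float      # NaN when undefined
    mae_celsius: float
    per_fold: pd.DataFrame
    mean_sd: tuple[tuple[float, float], tuple[float, float]]  # ((r mean, sd), (mae mean, sd))


def _score(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    try:
        r = pearson_r(pred, obs)
    except UndefinedCorrelationError:
        r = float("nan")
    return r, mae(pred, obs)


def _fold_report(name: str, rows: list[dict], n: int) -> EvaluationReport:
    per_fold = pd.DataFrame(rows, columns=["fold", "pearson_r", "mae_celsius", "n"])
    r_vals = per_fold["pearson_r"].to_numpy(dtype=float)
    m_vals = per_fold["mae_celsius"].to_numpy(dtype=float)
    defined = r_vals[~np.isnan(r_vals)]
    r_mean = float(np.mean(defined)) if defined.size else float("nan")
    r_sd = float(np.std(defined, ddof=1)) if defined.size > 1 else 0.0
    return EvaluationReport(
        split_name=name,
        n=n,
        pearson_r=r_mean,
        mae_celsius=float(np.mean(m_vals)),
        per_fold=per_fold,
        mean_sd=((r_mean, r_sd), (float(np.mean(m_vals)), float(np.std(m_vals, ddof=1)) if len(m_vals) > 1 else 0.0)),
    )


def evaluate_cv(
    fold_models: Mapping[int, object],
    split_plan: SplitPlan,
    corpus: Corpus,
    ensemble_test: bool = True,
) -> dict[str, EvaluationReport]:
    """Score every fold model on its training and validation proteins, and
    the held-out test pool.

    ``fold_models`` must provide one model per fold (any object with a
    ``predict(list[ProteinRecord]) -> array`` method).  Test-pool proteins
    are scored with the across-fold ensemble mean by default
    (``ensemble_test=False`` scores each fold model separately instead).
    """
    missing = [f for f in range(split_plan.k) if f not in fold_models]
    if missing:
        raise ValueError(f"missing fold models for folds {missing}")
    return evaluate_folds(fold_models, split_plan, corpus, ensemble_test)


def evaluate_folds(
    fold_models: Mapping[int, object],
    split_plan: SplitPlan,
    corpus: Corpus,
    ensemble_test: bool = True,
) -> dict[str, EvaluationReport]:
    """Like :func:`evaluate_cv` but accepts any subset of fold models
    (e.g. a single trained fold at desk scale); the test ensemble averages
    over the models provided."""
    train_rows, val_rows = [], []
    test_preds = []
    test_ids = sorted(split_plan.test_protein_ids)
    test_proteins = proteins_of(corpus, test_ids)
    test_obs = np.array([p.label_celsius for p in test_proteins], dtype=np.float64)

    n_train_total = 0
    n_val_total = 0
    test_rows = []
    for fold in sorted(fold_models):
        model = fold_models[fold]
        val_ids = sorted(split_plan.fold_protein_ids(fold))
        train_ids = sorted(split_plan.training_pool_ids(fold))
        for name, ids, rows in (("train", train_ids, train_rows), ("val", val_ids, val_rows)):
            prots = proteins_of(corpus, ids)
            obs = np.array([p.label_celsius for p in prots], dtype=np.float64)
            pred = np.asarray(model.predict(prots), dtype=np.float64)
            r, m = _score(pred, obs)
            rows.append({"fold": fold, "pearson_r": r, "mae_celsius": m, "n": len(ids)})
        n_train_total += len(train_ids)
        n_val_total += len(val_ids)
        if test_proteins:
            pred = np.asarray(model.predict(test_proteins), dtype=np.float64)
            test_preds.append(pred)
            if not ensemble_test:
                r, m = _score(pred, test_obs)
                test_rows.append(
                    {"fold": fold, "pearson_r": r, "mae_celsius": m, "n": len(test_proteins)}
                )

    reports = {
        "train": _fold_report("train", train_rows, n_train_total),
        "validation": _fold_report("validation", val_rows, n_val_total),
    }
    if test_proteins:
        if ensemble_test:
            ens = np.mean(np.vstack(test_preds), axis=0)
            r, m = _score(ens, test_obs)
            per_fold = pd.DataFrame(
                [{"fold": "ensemble", "pearson_r": r, "mae_celsius": m, "n": len(test_proteins)}]
            )
            reports["test"] = EvaluationReport(
                split_name="test",
                n=len(test_proteins),
                pearson_r=r,
                mae_celsius=m,
                per_fold=per_fold,
                mean_sd=((r, 0.0), (m, 0.0)),
            )
        else:
            reports["test"] = _fold_report("test", test_rows, len(test_proteins))
    return reports


def leakage_audit(
    corpus: Corpus,
    retained_clusters,
    k: int = 10,
    fold: int = 0,
    seed: int = 0,
    config=None,
    l_max: int | None = None,
):
    """Negative control for homology leakage: compare validation Pearson r
    under a cluster-level split and a deliberately protein-level split.

    Both models are trained with the same *leak-sensitive* configuration —
    no dropout and a long early-stopping patience — because a strongly
    regularised model can mask leakage by never fitting family-specific
    structure at all; the audit's purpose is to measure how much a
    protein-level split lets the model profit from homologs of its
    validation proteins.  An inflated protein-level r relative to the
    cluster-level r demonstrates that the cluster split is doing its job.

    Returns a dict with ``cluster_r``, ``protein_level_r``, ``gap`` and the
    two stopped epochs.
    """
    from ogtpred.corpus import proteins_of as _proteins_of
    from ogtpred.model import ModelConfig, train as _train
    from ogtpred.orthology import OrthologCluster, make_split

    if config is None:
        config = ModelConfig(
            n_neurons=32, dropout_rate=0.0, early_stop_patience=25, seed=seed
        )
    cluster_plan = make_split(retained_clusters, corpus, k=k, seed=seed)
    pool = sorted(cluster_plan.train_protein_ids)
    singletons = [
        OrthologCluster(f"LEAK{i:06d}", frozenset([pid])) for i, pid in enumerate(pool)
    ]
    protein_plan = make_split(singletons, corpus, k=k, seed=seed)
    if l_max is None:
        l_max = max(len(corpus.proteins[pid].sequence) for pid in pool)

    results = {}
    for name, plan in (("cluster", cluster_plan), ("protein_level", protein_plan)):
        train_prots = _proteins_of(corpus, sorted(plan.training_pool_ids(fold)))
        val_prots = _proteins_of(corpus, sorted(plan.fold_protein_ids(fold)))
        fitted = _train(train_prots, val_prots, config, l_max)
        preds = fitted.predict(val_prots)
        obs = np.array([p.label_celsius for p in val_prots], dtype=np.float64)
        results[name] = {
            "r": pearson_r(preds, obs),
            "stopped_epoch": fitted.stopped_epoch,
            "n_val": len(val_prots),
        }
    return {
        "cluster_r": results["cluster"]["r"],
        "protein_level_r": results["protein_level"]["r"],
        "gap": results["protein_level"]["r"] - results["cluster"]["r"],
        "cluster_stopped_epoch": results["cluster"]["stopped_epoch"],
        "protein_level_stopped_epoch": results["protein_level"]["stopped_epoch"],
    }
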