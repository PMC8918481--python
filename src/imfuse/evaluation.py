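"""Repeated stratified cross-validation and the subspace-count sweep.

The evaluation protocol is the standard one for imbalance benchmarks:
several independent runs of stratified K-fold cross-validation (defaults
5 runs x 5 folds), AUC per held-out fold, mean +/- standard deviation
over all run-folds.  The full pipeline is refitted from scratch on every
training partition — the test fold never touches the metric learning,
the oversampling, the members or the GA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .datasets import LabeledDataset, stratified_folds
from .ensemble import PipelineConfig, member_scores, train_ensemble, weighted_vote
from .metrics import auc_score
from .seeding import derive_seed

__all__ = ["CVResult", "auc_score", "repeated_cv_evaluate", "subspace_sweep"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVResult:
    """AUC table over runs x folds with summary statistics.

    ``std_auc`` is the population standard deviation over all run-fold
    AUCs; ``std_auc_runs`` aggregates at the run level (std of per-run
    means) since conventions differ between papers.  Folds skipped for a
    single-class test partition are NaN.
    """

    per_run_per_fold_auc: np.ndarray
    mean_auc: float
    std_auc: float
    mean_per_run: np.ndarray
    std_auc_runs: float
    config_echo: dict

    def to_frame(self) -> pd.DataFrame:
        runs, K = self.per_run_per_fold_auc.shape
        return pd.DataFrame(
            self.per_run_per_fold_auc,
            index=[f"run{r}" for r in range(runs)],
            columns=[f"fold{k}" for k in range(K)],
        )


def _config_echo(config: PipelineConfig, runs: int, K: int, seed: int) -> dict:
    echo = asdict(config)
    echo.update({"runs": runs, "folds": K, "master_seed": seed})
    return echo


def evaluate_fold(train: LabeledDataset, test: LabeledDataset,
                  config: PipelineConfig) -> float:
    """Fit the pipeline on ``train`` and return the test-fold AUC."""
    model = train_ensemble(train, config)
    fused = weighted_vote(member_scores(model, test), model.weights)
    return auc_score(fused, test.labels)


def repeated_cv_evaluate(dataset: LabeledDataset,
                         config: PipelineConfig = PipelineConfig(),
                         runs: int = 5, K: int = 5) -> CVResult:
    """Repeated stratified K-fold evaluation of the full pipeline.

    Fold seeds and per-fold pipeline seeds derive from ``config.seed``,
    so the whole experiment is reproducible from one integer.
    """
    master = config.seed
    table = np.full((runs, K), np.nan)
    for run in range(runs):
        folds = stratified_folds(dataset, K, derive_seed(master, "folds", run))
        for k in range(K):
            test = dataset.subset(folds.test_indices(k))
            if len(np.unique(test.labels)) < 2:
                warnings.warn(
                    f"run {run} fold {k}: single-class test partition, skipped",
                    stacklevel=2,
                )
                continue
            train = dataset.subset(folds.train_indices(k))
            fold_cfg = replace(config, seed=derive_seed(master, "fit", run, k))
            table[run, k] = evaluate_fold(train, test, fold_cfg)
            logger.info("run %d fold %d: AUC %.4f", run, k, table[run, k])
    flat = table[np.isfinite(table)]
    mean_per_run = np.array([
        np.nanmean(row) if np.isfinite(row).any() else np.nan for row in table
    ])
    run_means = mean_per_run[np.isfinite(mean_per_run)]
    return CVResult(
        per_run_per_fold_auc=table,
        mean_auc=float(flat.mean()),
        std_auc=float(flat.std()),
        mean_per_run=mean_per_run,
        std_auc_runs=float(run_means.std()),
        config_echo=_config_echo(config, runs, K, master),
    )


def subspace_sweep(dataset: LabeledDataset, config: PipelineConfig,
                   N_values: list[int], runs: int = 5, K: int = 5) -> pd.DataFrame:
    """Re-evaluate the pipeline for each subspace count, all else fixed.

    Returns a table with one row per N, in input order.
    """
    rows = []
    for N in N_values:
        result = repeated_cv_evaluate(dataset, replace(config, n_subspaces=N),
                                      runs=runs, K=K)
        rows.append({"n_subspaces": N, "mean_auc": result.mean_auc,
                     "std_auc": result.std_auc})
        logger.info("N=%d: AUC %.4f +/- %.4f", N, result.mean_auc, result.std_auc)
    return pd.DataFrame(rows)
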