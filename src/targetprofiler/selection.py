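"""Cross-validated cost sweep and replicate orchestration.

The only swept hyper-parameter is the SVM cost (inverse regularization
strength), evaluated by k-fold cross-validation: within each training
fold a full aggregated conformal predictor is trained and the held-out
fold predicted; predictions from all folds are pooled and scored by
observed fuzziness.  The cost with the lowest pooled OF wins, ties
resolving to the smaller (more regularized) cost.  CAOF and the M
criterion are reported alongside for information but never drive the
selection.

Assumed non-active records take part in every fold's proper training
set; they are never placed in test folds or calibration sets.

RNG discipline: one master seed, with child streams derived per
(replicate, fold, ICP index), so any unit of work is independently
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .conformal import SplitConfig, TrainConfig, train_acp
from .dataset import DatasetRecord, TargetDataset
from .metrics import EvaluatedPredictions, class_averaged_of, m_criterion, observed_fuzziness
from .signatures import SignatureConfig, featurize, parse_smiles, vectorize_many

logger = logging.getLogger(__name__)

__all__ = ["SweepConfig", "kfold_indices", "cost_sweep", "replicate_runs"]


@dataclass(frozen=True)
class SweepConfig:
    costs: tuple[float, ...] = (1.0, 10.0, 100.0)
    k_folds: int = 10
    n_icp: int = 10
    n_replicates: int = 3
    calibration_fraction: float = 0.2
    heights: SignatureConfig = field(default_factory=SignatureConfig)
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.costs or any(c <= 0 for c in self.costs):
            raise ValueError("costs must be positive and non-empty")


def kfold_indices(
    labels: np.ndarray | list[str], k: int, seed: int
) -> list[np.ndarray]:
    """Stratified k-fold partition of indices; per-class sizes differ by <= 1."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot make {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _fold_datasets(
    ds: TargetDataset, k: int, seed: int
) -> list[tuple[TargetDataset, list[DatasetRecord]]]:
    """(training dataset, held-out fold records) per fold.

    Assumed non-actives join every training side and no test fold.
    """
    real = [r for r in ds.records if not r.assumed_nonactive]
    assumed = [r for r in ds.records if r.assumed_nonactive]
    folds = kfold_indices([r.activity for r in real], k, seed)
    out = []
    for test_idx in folds:
        test_set = set(test_idx.tolist())
        train_records = [r for i, r in enumerate(real) if i not in test_set] + assumed
        test_records = [real[i] for i in test_idx]
        out.append((TargetDataset(ds.target, train_records), test_records))
    return out


def _pooled_cv_predictions(
    ds: TargetDataset,
    cost: float,
    sweep: SweepConfig,
    replicate: int,
    feature_cache: dict,
) -> EvaluatedPredictions:
    fold_seed = int(np.random.SeedSequence([sweep.seed, replicate]).generate_state(1)[0] % (2**31))
    ys, pas, pns = [], [], []
    for fold_i, (train_ds, test_records) in enumerate(
        _fold_datasets(ds, sweep.k_folds, fold_seed)
    ):
        icp_seed = int(
            np.random.SeedSequence([sweep.seed, replicate, fold_i]).generate_state(1)[0]
            % (2**31)
        )
        model = train_acp(
            train_ds,
            SplitConfig(
                calibration_fraction=sweep.calibration_fraction,
                n_icp=sweep.n_icp,
                seed=icp_seed,
            ),
            TrainConfig(cost=cost, heights=sweep.heights),
            feature_cache=feature_cache,
        )
        for r in test_records:
            if r.smiles not in feature_cache:
                feature_cache[r.smiles] = featurize(parse_smiles(r.smiles), sweep.heights)
        X = vectorize_many([feature_cache[r.smiles] for r in test_records], model.dictionary)
        p_a, p_n = model.predict_p_matrix(X)
        ys.extend(r.activity for r in test_records)
        pas.append(p_a)
        pns.append(p_n)
    return EvaluatedPredictions(
        np.array(ys), np.concatenate(pas), np.concatenate(pns)
    )


def cost_sweep(
    ds: TargetDataset, sweep: SweepConfig = SweepConfig(), replicate: int = 0
) -> tuple[float, pd.DataFrame]:
    """Pick the cost minimizing fold-pooled observed fuzziness.

    Returns ``(best_cost, report)`` where the report has one row per
    candidate cost with OF, CAOF and MC at confidence 0.8.
    """
    feature_cache: dict = {}
    rows = []
    for cost in sweep.costs:
        preds = _pooled_cv_predictions(ds, cost, sweep, replicate, feature_cache)
        rows.append(
            {
                "target": ds.target,
                "cost": cost,
                "OF": observed_fuzziness(preds),
                "CAOF": class_averaged_of(preds),
                "MC@conf0.8": m_criterion(preds, 0.2),
            }
        )
    report = pd.DataFrame(rows)
    best_idx = report.sort_values(["OF", "cost"], kind="stable").index[0]
    best_cost = float(report.loc[best_idx, "cost"])
    report["chosen"] = report["cost"] == best_cost
    logger.info("target %s: best cost %g (OF %.4f)", ds.target, best_cost, report.loc[best_idx, "OF"])
    return best_cost, report


def replicate_runs(
    ds: TargetDataset, sweep: SweepConfig = SweepConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the sweep ``n_replicates`` times on derived RNG streams.

    Returns the per-replicate report and the per-cost medians of each
    metric across replicates.
    """
    reports = []
    for rep in range(sweep.n_replicates):
        _, report = cost_sweep(ds, sweep, replicate=rep)
        report = report.assign(replicate=rep)
        reports.append(report)
    per_replicate = pd.concat(reports, ignore_index=True)
    medians = (
        per_replicate.groupby("cost")[["OF", "CAOF", "MC@conf0.8"]]
        .median()
        .reset_index()
    )
    return per_replicate, medians
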