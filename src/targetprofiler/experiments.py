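"""Canned evaluation experiments on synthetic data.

These reproduce, at desk scale, the two study designs the package is
validated with:

* :func:`validity_experiment` — train a Mondrian ACP on an exchangeable
  motif-labelled training set and predict a fresh test set drawn from
  the same process, returning the evaluated p-values.  Conformal theory
  says the fraction of prediction sets containing the true label at
  significance ``eps`` is at least ``1 - eps`` up to binomial noise,
  per class.

* :func:`augmentation_experiment` — compare observed fuzziness with and
  without assumed-non-active augmentation on a target that has many
  actives but few known non-actives, the regime where augmentation is
  expected to sharpen the predictor.
"""

from __future__ import annotations

import numpy as np

from .conformal import SplitConfig, TrainConfig, train_acp
from .dataset import ActivityRecord, DatasetRecord, PrepConfig, TargetDataset, add_assumed_nonactives
from .metrics import EvaluatedPredictions, observed_fuzziness
from .synthetic import SyntheticSpec, generate_molecules, generate_train_test

__all__ = ["validity_experiment", "augmentation_experiment"]


def validity_experiment(
    seed: int,
    n_train_per_class: int = 1000,
    n_test_per_class: int = 500,
    label_noise: float = 0.1,
    n_icp: int = 10,
    calibration_fraction: float = 0.2,
    cost: float = 1.0,
) -> EvaluatedPredictions:
    """Train on 2x``n_train_per_class`` molecules, predict a fresh exchangeable test set."""
    spec = SyntheticSpec(
        n_active=n_train_per_class,
        n_nonactive=n_train_per_class,
        label_noise=label_noise,
        seed=seed,
    )
    train, test = generate_train_test(
        spec, 0, n_test_active=n_test_per_class, n_test_nonactive=n_test_per_class
    )
    ds = TargetDataset(
        "T001",
        [DatasetRecord(s, obs, False, f"E{i:06d}") for i, (s, obs, _) in enumerate(train)],
    )
    model = train_acp(
        ds,
        SplitConfig(calibration_fraction=calibration_fraction, n_icp=n_icp, seed=seed),
        TrainConfig(cost=cost),
    )
    results = model.predict_many([s for s, _, _ in test])
    return EvaluatedPredictions(
        np.array([obs for _, obs, _ in test]),
        np.array([r.p_A for r in results]),
        np.array([r.p_N for r in results]),
    )


def augmentation_experiment(
    seed: int,
    n_active: int = 300,
    n_known_nonactive: int = 50,
    n_pool: int = 300,
    n_test_per_class: int = 150,
    label_noise: float = 0.1,
    n_icp: int = 10,
    n_replicates: int = 3,
) -> tuple[float, float]:
    """Median observed fuzziness with vs without assumed-non-active augmentation.

    The target has ``n_active`` actives and only ``n_known_nonactive``
    known non-actives; augmentation draws assumed non-actives from a
    pool built around a different target's motif until non-actives reach
    twice the actives.  Returns ``(median_OF_augmented,
    median_OF_unaugmented)`` over ``n_replicates`` train/evaluate runs
    on a shared exchangeable holdout.
    """
    spec = SyntheticSpec(
        n_active=n_active,
        n_nonactive=n_known_nonactive,
        label_noise=label_noise,
        seed=seed,
    )
    train, test = generate_train_test(
        spec, 0, n_test_active=n_test_per_class, n_test_nonactive=n_test_per_class
    )
    base_ds = TargetDataset(
        "T001",
        [DatasetRecord(s, obs, False, f"E{i:06d}") for i, (s, obs, _) in enumerate(train)],
    )
    pool_mols = generate_molecules(
        spec, 1,
        rng=np.random.default_rng([seed, 1, 314_159]),
        n_active=n_pool, n_nonactive=n_pool,
    )
    pool = [
        ActivityRecord("POOL", f"P{i:06d}", s, obs) for i, (s, obs, _) in enumerate(pool_mols)
    ]
    test_smiles = [s for s, _, _ in test]
    test_labels = np.array([obs for _, obs, _ in test])

    prep = PrepConfig(nonactive_ratio=2.0, seed=seed)
    cache: dict = {}
    of_aug, of_plain = [], []
    for rep in range(n_replicates):
        aug_ds = add_assumed_nonactives(
            base_ds, pool, prep, rng=np.random.default_rng([seed, 2, rep])
        )
        for ds, sink in ((aug_ds, of_aug), (base_ds, of_plain)):
            model = train_acp(
                ds,
                SplitConfig(calibration_fraction=0.2, n_icp=n_icp, seed=seed + 1000 * (rep + 1)),
                TrainConfig(cost=1.0),
                feature_cache=cache,
            )
            results = model.predict_many(test_smiles)
            preds = EvaluatedPredictions(
                test_labels,
                np.array([r.p_A for r in results]),
                np.array([r.p_N for r in results]),
            )
            sink.append(observed_fuzziness(preds))
    return float(np.median(of_aug)), float(np.median(of_plain))
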