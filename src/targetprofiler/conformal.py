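"""Mondrian inductive and aggregated conformal prediction for binary activity.

An inductive conformal predictor (ICP) splits the training data into a
*proper training set*, used to fit a linear SVM over signature-count
features, and a *calibration set*, used to turn the SVM margin into
per-class p-values.  The nonconformity score of an example with signed
decision value ``d`` (positive side = active) is ``-d`` under the
active hypothesis and ``+d`` under the non-active hypothesis: the
further an example sits on the wrong side of the decision surface, the
stranger it is.  Calibration is *Mondrian* — each class keeps its own
calibration score list — which gives class-conditional validity and
makes the predictor robust to class imbalance without resampling.

Because a single proper/calibration split adds variance, ``n_icp``
independent splits are drawn and their p-values combined (arithmetic
mean by default) into an aggregated conformal predictor (ACP).

Records flagged ``assumed_nonactive`` are placed in every proper
training set and never in a calibration set, so presumed negatives with
atypical chemistry can sharpen the decision surface without distorting
the calibration.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import sparse
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from . import __version__ as _pkg_version
from .dataset import DatasetRecord, TargetDataset
from .signatures import (
    SignatureConfig,
    SignatureDictionary,
    build_dictionary,
    featurize,
    parse_smiles,
    vectorize_many,
)

__all__ = [
    "SplitConfig",
    "TrainConfig",
    "ICPModel",
    "ACPModel",
    "PredictionResult",
    "split_proper_calibration",
    "fit_icp",
    "nonconformity",
    "pvalue",
    "train_acp",
    "predict_acp",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SplitConfig:
    """Proper/calibration split policy for the ICP ensemble."""

    calibration_fraction: float = 0.2
    n_icp: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.calibration_fraction < 1.0):
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.n_icp < 1:
            raise ValueError("n_icp must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Underlying-model and p-value options."""

    cost: float = 1.0
    heights: SignatureConfig = field(default_factory=SignatureConfig)
    aggregation: Literal["mean", "median"] = "mean"
    smoothed_pvalues: bool = False

    def __post_init__(self):
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")


@dataclass
class ICPModel:
    """One proper/calibration split: linear decision function + Mondrian calibration."""

    weights: np.ndarray
    intercept: float
    calib_scores_A: np.ndarray  # sorted ascending
    calib_scores_N: np.ndarray  # sorted ascending

    def decision_values(self, X: sparse.csr_matrix) -> np.ndarray:
        return np.asarray(X @ self.weights).ravel() + self.intercept

    def pvalues(
        self, X: sparse.csr_matrix,
        smoothed: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        d = self.decision_values(X)
        p_a = pvalue(-d, self.calib_scores_A, smoothed=smoothed, rng=rng)
        p_n = pvalue(+d, self.calib_scores_N, smoothed=smoothed, rng=rng)
        return p_a, p_n


@dataclass
class PredictionResult:
    """Two-class conformal prediction for one molecule."""

    p_A: float
    p_N: float

    def prediction_set(self, significance: float) -> frozenset[str]:
        return frozenset(
            c for c, p in (("A", self.p_A), ("N", self.p_N)) if p > significance
        )

    @property
    def confidence(self) -> float:
        return 1.0 - min(self.p_A, self.p_N)


@dataclass
class ACPModel:
    """Aggregated conformal predictor: an ensemble of ICPs over one dictionary."""

    icps: list[ICPModel]
    dictionary: SignatureDictionary
    train_config: TrainConfig
    split_config: SplitConfig
    metadata: dict = field(default_factory=dict)

    def _features(self, smiles_list: Sequence[str]) -> sparse.csr_matrix:
        heights = self.train_config.heights
        vectors = [featurize(parse_smiles(s), heights) for s in smiles_list]
        return vectorize_many(vectors, self.dictionary)

    def predict_p_matrix(self, X: sparse.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
        """Aggregated (p_A, p_N) arrays for pre-vectorized rows."""
        rng = (
            np.random.default_rng([self.split_config.seed, 777])
            if self.train_config.smoothed_pvalues
            else None
        )
        all_a = np.empty((len(self.icps), X.shape[0]))
        all_n = np.empty_like(all_a)
        for i, icp in enumerate(self.icps):
            all_a[i], all_n[i] = icp.pvalues(
                X, smoothed=self.train_config.smoothed_pvalues, rng=rng
            )
        agg = np.mean if self.train_config.aggregation == "mean" else np.median
        return agg(all_a, axis=0), agg(all_n, axis=0)

    def predict_many(self, smiles_list: Sequence[str]) -> list[PredictionResult]:
        p_a, p_n = self.predict_p_matrix(self._features(smiles_list))
        return [PredictionResult(a, n) for a, n in zip(p_a, p_n)]

    def predict(self, smiles: str) -> PredictionResult:
        return self.predict_many([smiles])[0]

    def mean_decision_values(self, X: sparse.csr_matrix) -> np.ndarray:
        return np.mean([icp.decision_values(X) for icp in self.icps], axis=0)

    @property
    def mean_weights(self) -> np.ndarray:
        return np.mean([icp.weights for icp in self.icps], axis=0)

    @property
    def mean_intercept(self) -> float:
        return float(np.mean([icp.intercept for icp in self.icps]))


def split_proper_calibration(
    ds: TargetDataset, config: SplitConfig, icp_index: int
) -> tuple[list[DatasetRecord], list[DatasetRecord]]:
    """Stratified proper/calibration split; assumed non-actives always go proper.

    Reproducible under ``(config.seed, icp_index)``; different
    ``icp_index`` values give different calibration membership of the
    same size.
    """
    rng = np.random.default_rng([config.seed, 101, icp_index])
    assumed = [r for r in ds.records if r.assumed_nonactive]
    proper: list[DatasetRecord] = list(assumed)
    calibration: list[DatasetRecord] = []
    for label in ("A", "N"):
        members = [r for r in ds.records if r.activity == label and not r.assumed_nonactive]
        if len(members) < 2:
            raise ValueError(
                f"target {ds.target}: class {label} has {len(members)} non-assumed "
                "examples; at least 2 are needed to calibrate"
            )
        n_cal = int(config.calibration_fraction * len(members))
        n_cal = min(max(n_cal, 1), len(members) - 1)
        order = rng.permutation(len(members))
        calibration.extend(members[i] for i in order[:n_cal])
        proper.extend(members[i] for i in order[n_cal:])
    return proper, calibration


def nonconformity(decision_value: float, label: str) -> float:
    """Signed-margin nonconformity: higher means stranger for the given label."""
    if label == "A":
        return -decision_value
    if label == "N":
        return +decision_value
    raise ValueError(f"unknown label {label!r}")


def pvalue(
    alpha: float | np.ndarray,
    calib_scores: np.ndarray,
    smoothed: bool = False,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """Conformal p-value of nonconformity ``alpha`` against sorted calibration scores.

    Unsmoothed: ``(#{j: alpha_j >= alpha} + 1) / (n + 1)``, which lies in
    ``[1/(n+1), 1]``.  The smoothed variant randomizes the tie mass with
    ``rng`` and is exactly valid rather than conservative.
    """
    calib = np.asarray(calib_scores)
    n = calib.size
    if n == 0:
        raise ValueError("calibration score list is empty")
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    n_ge = n - np.searchsorted(calib, a, side="left")
    if smoothed:
        if rng is None:
            rng = np.random.default_rng()
        n_gt = n - np.searchsorted(calib, a, side="right")
        ties = n_ge - n_gt
        tau = rng.random(a.shape)
        p = (n_gt + tau * (ties + 1)) / (n + 1)
    else:
        p = (n_ge + 1) / (n + 1)
    return p if np.ndim(alpha) else float(p[0])


def _fit_linear_svm(
    X: sparse.csr_matrix, y: np.ndarray, cost: float, seed: int
) -> tuple[np.ndarray, float]:
    if len(np.unique(y)) < 2:
        raise ValueError("proper training set is single-class; cannot fit SVM")
    clf = LinearSVC(
        C=cost,
        loss="hinge",
        tol=1e-4,
        max_iter=20_000,
        random_state=seed % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def fit_icp(
    proper: Sequence[DatasetRecord],
    calibration: Sequence[DatasetRecord],
    train_config: TrainConfig,
    dictionary: SignatureDictionary,
    feature_cache: dict | None = None,
    seed: int = 0,
) -> ICPModel:
    """Fit the linear SVM on the proper set and calibrate on the calibration set."""
    X_proper = _vectorize_records(proper, train_config.heights, dictionary, feature_cache)
    y_proper = np.array([1 if r.activity == "A" else 0 for r in proper])
    weights, intercept = _fit_linear_svm(X_proper, y_proper, train_config.cost, seed)

    X_cal = _vectorize_records(calibration, train_config.heights, dictionary, feature_cache)
    d = np.asarray(X_cal @ weights).ravel() + intercept
    labels = np.array([r.activity for r in calibration])
    calib_a = np.sort(-d[labels == "A"])
    calib_n = np.sort(+d[labels == "N"])
    if calib_a.size == 0 or calib_n.size == 0:
        raise ValueError("calibration set must contain both classes")
    return ICPModel(
        weights=weights,
        intercept=intercept,
        calib_scores_A=calib_a,
        calib_scores_N=calib_n,
    )


def _vectorize_records(
    records: Sequence[DatasetRecord],
    heights: SignatureConfig,
    dictionary: SignatureDictionary,
    feature_cache: dict | None,
) -> sparse.csr_matrix:
    vectors = []
    for r in records:
        if feature_cache is not None and r.smiles in feature_cache:
            vec = feature_cache[r.smiles]
        else:
            vec = featurize(parse_smiles(r.smiles), heights)
            if feature_cache is not None:
                feature_cache[r.smiles] = vec
        vectors.append(vec)
    return vectorize_many(vectors, dictionary)


def train_acp(
    ds: TargetDataset,
    split_config: SplitConfig = SplitConfig(),
    train_config: TrainConfig = TrainConfig(),
    feature_cache: dict | None = None,
) -> ACPModel:
    """Train an aggregated Mondrian conformal predictor for one target.

    The signature dictionary is built once from all training molecules
    (structure only, no labels involved) and shared by every ICP so the
    feature space is identical across the ensemble.
    """
    cache = {} if feature_cache is None else feature_cache
    for r in ds.records:
        if r.smiles not in cache:
            cache[r.smiles] = featurize(parse_smiles(r.smiles), train_config.heights)
    dictionary = build_dictionary([cache[r.smiles] for r in ds.records])
    icps = []
    for i in range(split_config.n_icp):
        proper, calibration = split_proper_calibration(ds, split_config, i)
        icps.append(
            fit_icp(
                proper, calibration, train_config, dictionary,
                feature_cache=cache, seed=split_config.seed * 1000 + i,
            )
        )
    return ACPModel(
        icps=icps,
        dictionary=dictionary,
        train_config=train_config,
        split_config=split_config,
        metadata={
            "target": ds.target,
            "n_records": len(ds.records),
            "n_assumed_nonactives": ds.n_assumed,
            "software_version": _pkg_version,
        },
    )


def predict_acp(model: ACPModel, smiles: str) -> PredictionResult:
    """Aggregated two-class p-values for a query molecule."""
    return model.predict(smiles)


def save_model(model: ACPModel, path) -> None:
    """Serialize an ACP to a single zip archive.

    The archive holds ``manifest.json``, the signature dictionary as TSV
    and per-ICP weight/calibration arrays; a load/predict round-trip is
    bit-identical to predicting before saving.
    """
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_icp": len(model.icps),
        "aggregation": model.train_config.aggregation,
        "smoothed_pvalues": model.train_config.smoothed_pvalues,
        "cost": model.train_config.cost,
        "heights": sorted(model.train_config.heights.heights),
        "calibration_fraction": model.split_config.calibration_fraction,
        "seed": model.split_config.seed,
        "metadata": model.metadata,
        "icp_files": [f"icp_{i:03d}.npz" for i in range(len(model.icps))],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        zf.writestr("dictionary.tsv", model.dictionary.to_tsv())
        for i, icp in enumerate(model.icps):
            buf = io.BytesIO()
            np.savez(
                buf,
                weights=icp.weights,
                intercept=np.array([icp.intercept]),
                calib_scores_A=icp.calib_scores_A,
                calib_scores_N=icp.calib_scores_N,
            )
            zf.writestr(manifest["icp_files"][i], buf.getvalue())


def load_model(path) -> ACPModel:
    """Load a model archive written by :func:`save_model`."""
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format_version") != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model archive {path} has format version "
                    f"{manifest.get('format_version')}; expected {MODEL_FORMAT_VERSION}"
                )
            dictionary = SignatureDictionary.from_tsv(zf.read("dictionary.tsv").decode())
            icps = []
            for name in manifest["icp_files"]:
                with np.load(io.BytesIO(zf.read(name))) as data:
                    icps.append(
                        ICPModel(
                            weights=data["weights"],
                            intercept=float(data["intercept"][0]),
                            calib_scores_A=data["calib_scores_A"],
                            calib_scores_N=data["calib_scores_N"],
                        )
                    )
    except zipfile.BadZipFile as exc:
        raise ValueError(f"corrupt or truncated model archive: {path}") from exc
    return ACPModel(
        icps=icps,
        dictionary=dictionary,
        train_config=TrainConfig(
            cost=manifest["cost"],
            heights=SignatureConfig(frozenset(manifest["heights"])),
            aggregation=manifest["aggregation"],
            smoothed_pvalues=manifest["smoothed_pvalues"],
        ),
        split_config=SplitConfig(
            calibration_fraction=manifest["calibration_fraction"],
            n_icp=manifest["n_icp"],
            seed=manifest["seed"],
        ),
        metadata=manifest["metadata"],
    )
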