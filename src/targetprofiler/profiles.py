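"""Multi-target profile prediction and atom-level contribution maps.

A *target profile* queries a panel of per-target conformal models with
one molecule and collects the two class p-values, the prediction set at
a chosen confidence, and the prediction confidence (1 minus the smaller
p-value) for each target.

Atom contributions explain a single linear model's vote: each signature
present in the molecule contributes its ensemble-averaged SVM weight,
accumulated onto the signature's root atom.  Summed over atoms this
reproduces the averaged decision value minus the averaged intercept
exactly (the model is linear in signature counts).  Scores are signed
so that positive means "toward the larger-p class".
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .conformal import ACPModel, PredictionResult
from .signatures import (
    MolecularGraph,
    atom_signature,
    parse_smiles,
    signature_with_height,
    vectorize_many,
    featurize,
)

logger = logging.getLogger(__name__)

__all__ = ["TargetProfile", "AtomContribution", "predict_profile", "atom_contributions"]


@dataclass
class TargetProfile:
    """Per-target conformal predictions for one query molecule."""

    smiles: str
    confidence_level: float
    entries: dict[str, PredictionResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def prediction_set(self, target: str) -> frozenset[str]:
        return self.entries[target].prediction_set(1.0 - self.confidence_level)

    def to_records(self) -> list[dict]:
        rows = []
        for target in sorted(self.entries):
            r = self.entries[target]
            pred_set = sorted(self.prediction_set(target))
            rows.append(
                {
                    "target": target,
                    "p_A": r.p_A,
                    "p_N": r.p_N,
                    "prediction_set": "".join(pred_set) or "Null",
                    "confidence": r.confidence,
                }
            )
        return rows

    def to_json(self) -> str:
        return json.dumps(
            {
                "smiles": self.smiles,
                "confidence_level": self.confidence_level,
                "predictions": self.to_records(),
                "failures": self.failures,
            },
            indent=2,
        )

    def write_csv(self, path) -> None:
        rows = self.to_records()
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(
                fh, fieldnames=["target", "p_A", "p_N", "prediction_set", "confidence"]
            )
            w.writeheader()
            w.writerows(rows)


@dataclass
class AtomContribution:
    """Signed per-heavy-atom scores; positive points toward the larger-p class."""

    smiles: str
    scores: np.ndarray
    larger_class: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "smiles": self.smiles,
                "larger_class": self.larger_class,
                "contributions": [
                    {"atom": i, "score": float(s)} for i, s in enumerate(self.scores)
                ],
            },
            indent=2,
        )


def predict_profile(
    models: Mapping[str, ACPModel], smiles: str, confidence: float = 0.8
) -> TargetProfile:
    """Query every model in the panel; one model failing does not kill the profile."""
    if not models:
        raise ValueError("no models loaded")
    parse_smiles(smiles)  # fail fast on an unparseable query
    profile = TargetProfile(smiles=smiles, confidence_level=confidence)
    for target, model in models.items():
        try:
            profile.entries[target] = model.predict(smiles)
        except Exception as exc:  # pragma: no cover - defensive per-target isolation
            logger.warning("model %s failed on %s: %s", target, smiles, exc)
            profile.failures[target] = str(exc)
    return profile


def atom_contributions(model: ACPModel, mol: MolecularGraph | str) -> AtomContribution:
    """Linear-weight decomposition of the ensemble decision onto root atoms.

    Atoms rooting only dictionary-unseen signatures score zero; the sum
    of scores equals the sign-adjusted averaged decision value minus the
    averaged intercept.
    """
    if isinstance(mol, str):
        smiles = mol
        mol = parse_smiles(mol)
    else:
        smiles = ""
    heights = model.train_config.heights
    w = model.mean_weights
    adj = mol.adjacency()
    raw = np.zeros(mol.n_atoms)
    for h in sorted(heights.heights):
        for root in range(mol.n_atoms):
            sig = signature_with_height(h, atom_signature(mol, root, h, _adj=adj))
            col = model.dictionary.index.get(sig)
            if col is not None:
                raw[root] += w[col]
    X = vectorize_many([featurize(mol, heights)], model.dictionary)
    p_a, p_n = model.predict_p_matrix(X)
    larger = "A" if p_a[0] >= p_n[0] else "N"
    sign = 1.0 if larger == "A" else -1.0  # decision is oriented toward A
    return AtomContribution(smiles=smiles, scores=sign * raw, larger_class=larger)
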