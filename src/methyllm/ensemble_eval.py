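"""Ensemble prediction and evaluation metrics.

The ensemble prediction for a sample is the unweighted arithmetic mean of
the positive-class probabilities returned by the member models (nominally
the five families fine-tuned for one methylation type).  Evaluation
reports AUC, accuracy, F1, recall and AUPR, plus the ROC curve points.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)

from .data_model import METHYL_TYPES, MethylSample
from .finetuning import FineTunedModel, predict_proba


@dataclass
class EnsembleModel:
    """Fine-tuned members of one methylation type plus the averaging rule."""

    members: Dict[str, FineTunedModel]
    methyl_type: str
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.methyl_type not in METHYL_TYPES:
            raise ValueError(f"unknown methylation type {self.methyl_type!r}")
        for fam, m in self.members.items():
            if m.methyl_type != self.methyl_type:
                raise ValueError(
                    f"member {fam!r} was fine-tuned for {m.methyl_type}, "
                    f"ensemble is for {self.methyl_type}"
                )
        if len(self.members) < 5:
            warnings.warn(
                f"ensemble for {self.methyl_type} has {len(self.members)} member(s); "
                "the full framework uses 5"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "ensemble.json"), "w") as fh:
            json.dump(
                {
                    "methyl_type": self.methyl_type,
                    "threshold": self.threshold,
                    "members": sorted(self.members),
                },
                fh,
                indent=2,
            )
        for fam, m in self.members.items():
            m.save(os.path.join(directory, fam))

    @classmethod
    def load(cls, directory: str) -> "EnsembleModel":
        with open(os.path.join(directory, "ensemble.json")) as fh:
            meta = json.load(fh)
        members = {
            fam: FineTunedModel.load(os.path.join(directory, fam))
            for fam in meta["members"]
        }
        return cls(members=members, methyl_type=meta["methyl_type"],
                   threshold=meta["threshold"])


def ensemble_predict(
    ensemble: EnsembleModel, samples: Sequence[MethylSample]
) -> np.ndarray:
    """Per-sample unweighted mean of member probabilities."""
    member_probs = []
    for fam, model in sorted(ensemble.members.items()):
        probs, errors = predict_proba(model, samples, return_errors=True)
        if errors:
            first = errors[0]
            raise RuntimeError(
                f"ensemble member {fam!r} failed on sample "
                f"{first.sample_id!r}: {first.message}"
            )
        member_probs.append(probs)
    return np.mean(member_probs, axis=0)


def classify(probabilities: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Binary labels: positive iff p >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    p = np.asarray(probabilities, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


@dataclass
class EvalReport:
    """Binary-classification metrics at a fixed threshold plus ROC points.

    ``auc`` and ``aupr`` are NaN when only one class is present.
    """

    auc: float
    accuracy: float
    f1: float
    recall: float
    aupr: float
    n_samples: int
    threshold: float = 0.5
    roc_fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> Dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "recall": self.recall,
            "aupr": self.aupr,
            "n_samples": self.n_samples,
            "threshold": self.threshold,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def roc_to_tsv(self, path) -> None:
        pd.DataFrame({"fpr": self.roc_fpr, "tpr": self.roc_tpr}).to_csv(
            path, sep="\t", index=False
        )


def evaluate(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> EvalReport:
    """Compute AUC, accuracy, F1, recall and AUPR.

    AUC is the probability that a random positive outscores a random
    negative (ties count half, the Mann-Whitney convention); AUPR is the
    area under the precision-recall curve (average-precision estimator).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} probabilities vs {y.shape} labels")
    if p.size == 0:
        raise ValueError("cannot evaluate empty inputs")

    pred = classify(p, threshold)
    both_classes = len(np.unique(y)) == 2
    if both_classes:
        auc = float(roc_auc_score(y, p))
        aupr = float(average_precision_score(y, p))
        fpr, tpr, _ = roc_curve(y, p)
        # roc_curve's first point may start above 0 only on degenerate input;
        # the standard output runs (0,0) -> (1,1)
    else:
        auc = float("nan")
        aupr = float("nan")
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])

    return EvalReport(
        auc=auc,
        accuracy=float(accuracy_score(y, pred)),
        f1=float(f1_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        aupr=aupr,
        n_samples=int(p.size),
        threshold=threshold,
        roc_fpr=fpr,
        roc_tpr=tpr,
    )


def write_predictions_tsv(samples: Sequence[MethylSample], probabilities, path,
                          threshold: float = 0.5) -> None:
    labels = classify(probabilities, threshold)
    pd.DataFrame(
        {
            "id": [s.id for s in samples],
            "probability": np.asarray(probabilities, dtype=float),
            "label": ["positive" if l else "negative" for l in labels],
        }
    ).to_csv(path, sep="\t", index=False)
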