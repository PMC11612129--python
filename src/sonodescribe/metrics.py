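"""Agreement and classification metrics: Cohen's kappa per descriptor, the
mean descriptor kappa, accuracy, confusion matrices, and the Boolean
malignancy suite (accuracy / recall / precision / F1 / specificity).

Kappa is unweighted: (p_o - p_e) / (1 - p_e), with the expected agreement
p_e from the product of marginals.  When both raters are constant and equal
(p_e = 1) the agreement is complete and kappa is reported as 1.0 by
convention.  Values above 0.8 are conventionally read as almost perfect
agreement, 0.6-0.8 as substantial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .vocab import ALL_DESCRIPTOR_NAMES


def confusion_matrix(y1, y2, labels=None) -> pd.DataFrame:
    y1, y2 = list(y1), list(y2)
    if labels is None:
        labels = sorted(set(y1) | set(y2), key=str)
    m = pd.DataFrame(0, index=labels, columns=labels)
    for a, b in zip(y1, y2):
        m.loc[a, b] += 1
    return m


def cohens_kappa(y1, y2) -> float:
    """Chance-corrected agreement between two label vectors."""
    y1, y2 = list(y1), list(y2)
    if len(y1) != len(y2) or len(y1) == 0:
        raise InputError("label vectors must have equal nonzero length")
    n = len(y1)
    m = confusion_matrix(y1, y2).to_numpy(dtype=float)
    p_o = np.trace(m) / n
    p_e = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        return 1.0  # both raters constant and identical: complete agreement
    return float((p_o - p_e) / (1.0 - p_e))


def accuracy(y1, y2) -> float:
    y1, y2 = list(y1), list(y2)
    return float(np.mean([a == b for a, b in zip(y1, y2)]))


def malignancy_metrics(pred, truth) -> dict[str, float]:
    """Standard 2x2 metrics with malignant as the positive class."""
    pred = [bool(p) for p in pred]
    truth = [bool(t) for t in truth]
    if len(pred) != len(truth) or not pred:
        raise InputError("prediction and truth must have equal nonzero length")
    tp = sum(p and t for p, t in zip(pred, truth))
    fp = sum(p and not t for p, t in zip(pred, truth))
    fn = sum(not p and t for p, t in zip(pred, truth))
    tn = sum(not p and not t for p, t in zip(pred, truth))
    if tp + fn == 0:
        warnings.warn("no positive cases in truth; recall reported as 0")
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return {
        "accuracy": (tp + tn) / len(pred),
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "specificity": specificity,
    }


@dataclass
class AgreementTable:
    """Per-descriptor agreement against a reference reading."""

    kappa: dict[str, float]
    accuracy: dict[str, float]
    confusion: dict[str, pd.DataFrame] = field(repr=False)
    mean_kappa: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = {name: {"kappa": self.kappa[name], "accuracy": self.accuracy[name]}
                for name in self.kappa}
        frame = pd.DataFrame(rows).T
        frame.loc["mean"] = [self.mean_kappa,
                             float(np.mean(list(self.accuracy.values())))]
        return frame

    def save_confusions(self, directory) -> None:
        """One CSV per descriptor's confusion matrix (model rows, reference
        columns)."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.confusion.items():
            frame.to_csv(directory / f"confusion_{name}.csv")


def agreement_report(model_descriptors, reference_descriptors) -> AgreementTable:
    """Kappa/accuracy/confusion per descriptor plus the unweighted mean kappa.

    Inputs are aligned sequences of descriptor mappings (or
    :class:`~sonodescribe.descriptors.DescriptorSet`).  The mean covers the
    seven descriptor outputs; the BI-RADS category, when compared, is
    reported separately by the caller.  Orientation "none" is a valid label,
    not a missing value.
    """
    model_rows = [_as_mapping(d) for d in model_descriptors]
    ref_rows = [_as_mapping(d) for d in reference_descriptors]
    if len(model_rows) != len(ref_rows) or not model_rows:
        raise InputError("aligned nonempty descriptor sequences required")
    kappas, accs, confusions = {}, {}, {}
    for name in ALL_DESCRIPTOR_NAMES:
        try:
            y_model = [row[name] for row in model_rows]
            y_ref = [row[name] for row in ref_rows]
        except KeyError:
            raise InputError(f"descriptor {name!r} missing from input") from None
        kappas[name] = cohens_kappa(y_model, y_ref)
        accs[name] = accuracy(y_model, y_ref)
        confusions[name] = confusion_matrix(y_model, y_ref)
    return AgreementTable(
        kappa=kappas, accuracy=accs, confusion=confusions,
        mean_kappa=float(np.mean([kappas[n] for n in ALL_DESCRIPTOR_NAMES])),
        n=len(model_rows),
    )


def _as_mapping(d) -> dict:
    if hasattr(d, "as_dict"):
        return d.as_dict()
    return dict(d)
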