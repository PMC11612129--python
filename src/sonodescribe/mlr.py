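"""Descriptor-driven BI-RADS classification by multinomial logistic regression.

The category model deliberately sees only the seven categorical descriptors —
never the image — so that every prediction decomposes exactly into per-feature
weight contributions: for each category k, the logit is the sum of the weights
of the active (feature = value) indicators plus the intercept.  Reading those
weights for the top candidate categories is the explanation shown to the
radiologist.

Fitting delegates to scikit-learn's L2-penalized multinomial solver, which
uses the symmetric (non-pivot) parameterization, so a full weight vector
exists for every category.  Only the categories a descriptor model can
produce (2, 3, 4A, 4B, 4C, 5) are modeled by default; the configurable
category list accepts others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .descriptors import DescriptorSet
from .errors import InputError, ModelStateError
from .vocab import ALL_DESCRIPTOR_NAMES, BIRADS_CATEGORIES, DEFAULT_VOCABULARIES, Vocabularies


@dataclass(frozen=True)
class BiradsResult:
    """Predicted category, per-category probabilities and the explanation.

    ``explanation`` lists, for the top-2 categories, each active feature's
    weight contribution; ``sum(active weights) + intercept`` equals the
    category logit exactly.
    """

    category: str
    probabilities: dict[str, float]
    explanation: dict[str, dict[str, float]]
    intercepts: dict[str, float]


@dataclass
class BiradsRegression:
    """One-hot multinomial logistic regression over descriptor indicators."""

    vocab: Vocabularies = DEFAULT_VOCABULARIES
    categories: tuple[str, ...] = BIRADS_CATEGORIES
    l2: float = 0.1
    weights: np.ndarray | None = field(default=None, repr=False)   # (K, P)
    intercepts: np.ndarray | None = field(default=None, repr=False)  # (K,)

    # -- encoding -----------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return [f"{name}={value}"
                for name in ALL_DESCRIPTOR_NAMES
                for value in self.vocab.descriptor_values(name)]

    def encode_features(self, d: DescriptorSet) -> np.ndarray:
        """Concatenated one-hot blocks, one per descriptor (7 ones total).

        Orientation "none" is its own indicator, so unoriented nodules are a
        modeled state, not missing data.
        """
        d.validate(self.vocab)
        blocks = []
        for name in ALL_DESCRIPTOR_NAMES:
            values = self.vocab.descriptor_values(name)
            one = np.zeros(len(values))
            one[values.index(getattr(d, name))] = 1.0
            blocks.append(one)
        return np.concatenate(blocks)

    def encode_table(self, descriptor_sets) -> np.ndarray:
        return np.stack([self.encode_features(d) for d in descriptor_sets])

    # -- fitting ------------------------------------------------------------

    def fit(self, features: np.ndarray, categories) -> "BiradsRegression":
        """Maximize the L2-penalized multinomial likelihood (deterministic)."""
        features = np.asarray(features, dtype=float)
        categories = list(categories)
        present = sorted(set(categories))
        unknown = [c for c in present if c not in self.categories]
        if unknown:
            raise InputError(f"categories outside configured scale: {unknown}")
        if len(present) < 2:
            raise InputError(
                "degenerate fit: need at least 2 distinct categories, "
                f"got {present}")
        y = np.array([self.categories.index(c) for c in categories])
        clf = LogisticRegression(
            C=1.0 / self.l2, solver="lbfgs", max_iter=5000, tol=1e-8)
        clf.fit(features, y)
        k_total, p = len(self.categories), features.shape[1]
        self.weights = np.zeros((k_total, p))
        self.intercepts = np.zeros(k_total)
        if len(clf.classes_) == 2:
            # sklearn collapses the two-class case to a single weight vector.
            lo, hi = clf.classes_
            self.weights[hi] = clf.coef_[0] / 2.0
            self.weights[lo] = -clf.coef_[0] / 2.0
            self.intercepts[hi] = clf.intercept_[0] / 2.0
            self.intercepts[lo] = -clf.intercept_[0] / 2.0
        else:
            for row, cls in enumerate(clf.classes_):
                self.weights[cls] = clf.coef_[row]
                self.intercepts[cls] = clf.intercept_[row]
        return self

    def fit_sets(self, descriptor_sets, categories) -> "BiradsRegression":
        return self.fit(self.encode_table(descriptor_sets), categories)

    # -- inference ----------------------------------------------------------

    def _require_fitted(self) -> None:
        if self.weights is None:
            raise ModelStateError("regression has not been fitted")

    def logits(self, x: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return x @ self.weights.T + self.intercepts

    def predict_explain(self, d: DescriptorSet) -> BiradsResult:
        """Category probabilities plus per-feature weight explanations.

        The explanation covers the two most probable categories, listing the
        weight each active (feature = value) indicator contributes to that
        category's logit.
        """
        self._require_fitted()
        x = self.encode_features(d)
        z = self.logits(x[None])[0]
        z_shift = z - z.max()
        p = np.exp(z_shift) / np.exp(z_shift).sum()
        order = np.argsort(-p)
        names = self.feature_names
        active = np.where(x > 0)[0]
        explanation = {}
        for k in order[:2]:
            explanation[self.categories[k]] = {
                names[j]: float(self.weights[k, j]) for j in active}
        return BiradsResult(
            category=self.categories[int(order[0])],
            probabilities={c: float(p[i]) for i, c in enumerate(self.categories)},
            explanation=explanation,
            intercepts={c: float(self.intercepts[i])
                        for i, c in enumerate(self.categories)},
        )

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        self._require_fitted()
        names = self.feature_names
        payload = {
            "categories": list(self.categories),
            "l2": self.l2,
            "intercepts": {c: self.intercepts[i]
                           for i, c in enumerate(self.categories)},
            "weights": {c: {names[j]: self.weights[i, j]
                            for j in range(len(names))}
                        for i, c in enumerate(self.categories)},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path, vocab: Vocabularies = DEFAULT_VOCABULARIES
             ) -> "BiradsRegression":
        payload = json.loads(Path(path).read_text())
        model = cls(vocab=vocab, categories=tuple(payload["categories"]),
                    l2=payload["l2"])
        names = model.feature_names
        k, p = len(model.categories), len(names)
        model.weights = np.zeros((k, p))
        model.intercepts = np.zeros(k)
        for i, c in enumerate(model.categories):
            model.intercepts[i] = payload["intercepts"][c]
            for j, name in enumerate(names):
                model.weights[i, j] = payload["weights"][c][name]
        return model


def explanation_table(result: BiradsResult):
    """Long-form table of the top-2 categories' weights (dot-plot input)."""
    import pandas as pd

    rows = []
    for category, weights in result.explanation.items():
        for feature, weight in weights.items():
            rows.append({"category": category, "feature": feature,
                         "weight": weight})
    return pd.DataFrame(rows)


def plot_explanation(result: BiradsResult, path=None):
    """Dot plot of per-feature weights for the top-2 categories."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = explanation_table(result)
    features = sorted(table["feature"].unique())
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(features) + 1.5))
    colors = {cat: color for cat, color in
              zip(result.explanation, ("tab:red", "tab:blue"))}
    for cat, sub in table.groupby("category"):
        ypos = [features.index(f) for f in sub["feature"]]
        ax.scatter(sub["weight"], ypos, label=f"BI-RADS {cat}",
                   color=colors.get(cat))
    ax.set_yticks(range(len(features)))
    ax.set_yticklabels(features)
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("weight contribution to logit")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
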