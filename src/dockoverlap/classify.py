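"""Propidium-displacement activity labels and the two-feature LDA classifier.

Displacement of propidium from the peripheral anionic site (PAS) of
acetylcholinesterase behaves as an all-or-nothing response: a compound's
raw displacement is expressed as a percentage of the donepezil value
(donepezil ≡ 100%) and the compound is called *active* when that normalized
displacement strictly exceeds 50%.  A Fisher linear discriminant on just
two docking-derived variables — percent volume overlap with the docked
propidium pose, and the docking binding energy Eb = −ΔG — predicts this
label; an exhaustive leave-one-out jackknife measures its accuracy.

The discriminant is implemented directly (pooled within-class covariance,
equal priors by default, threshold at the midpoint of the projected class
means) so that its algebra is fully specified; scikit-learn serves only as
an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "FeatureVector",
    "LDAModel",
    "normalize_displacement",
    "label_activity",
    "lda_fit",
    "lda_predict",
    "loo_accuracy",
    "accuracy",
    "study_cohort",
]

ACTIVE, INACTIVE = "active", "inactive"

#: Activity cut-off on donepezil-normalized displacement, percent (strict >).
ACTIVITY_THRESHOLD_PCT = 50.0


def normalize_displacement(raw_pct: float, donepezil_raw_pct: float) -> float:
    """Displacement as a percentage of the donepezil reference value."""
    if not donepezil_raw_pct > 0:
        raise ValueError(f"donepezil reference displacement must be positive, got {donepezil_raw_pct}")
    return 100.0 * raw_pct / donepezil_raw_pct


def label_activity(norm_pct: float) -> str:
    """'active' iff the normalized displacement strictly exceeds 50%.

    Exactly 50 is inactive: the boundary breaks toward the conservative
    call.
    """
    if norm_pct < 0:
        raise ValueError(f"normalized displacement cannot be negative, got {norm_pct}")
    return ACTIVE if norm_pct > ACTIVITY_THRESHOLD_PCT else INACTIVE


@dataclass(frozen=True)
class ActivityRecord:
    """A compound's displacement measurements with its binary label."""

    id: str
    raw_pct: float
    norm_pct: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in (ACTIVE, INACTIVE):
            raise ValueError(f"label must be 'active' or 'inactive', got {self.label!r}")
        if self.label != label_activity(self.norm_pct):
            raise ValueError(
                f"label {self.label!r} inconsistent with norm_pct {self.norm_pct} under the >50% rule"
            )

    @classmethod
    def from_raw(cls, id: str, raw_pct: float, donepezil_raw_pct: float) -> "ActivityRecord":
        norm = normalize_displacement(raw_pct, donepezil_raw_pct)
        return cls(id=id, raw_pct=raw_pct, norm_pct=norm, label=label_activity(norm))


@dataclass(frozen=True)
class FeatureVector:
    """The two docking-derived predictors of propidium displacement."""

    propidium_overlap_pct: float
    binding_energy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.propidium_overlap_pct <= 100.0):
            raise ValueError("propidium_overlap_pct must lie in [0, 100]")
        if not np.isfinite(self.binding_energy):
            raise ValueError("binding_energy must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.propidium_overlap_pct, self.binding_energy])


@dataclass
class LDAModel:
    """Fitted two-class Fisher discriminant.

    ``weights`` ∝ Σ_pooled⁻¹ (μ_active − μ_inactive); a case is predicted
    active when its projection wᵀx strictly exceeds ``threshold``.
    """

    weights: np.ndarray
    threshold: float
    class_means: dict[str, np.ndarray]
    pooled_covariance: np.ndarray
    priors: str = "equal"

    def project(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.weights

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "threshold": float(self.threshold),
            "class_means": {k: v.tolist() for k, v in self.class_means.items()},
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors,
        }


def _as_xy(features, labels) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray([f.as_array() if isinstance(f, FeatureVector) else f for f in features], dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must form an n × d matrix")
    if len(X) != len(y):
        raise ValueError(f"feature/label length mismatch: {len(X)} vs {len(y)}")
    return X, y


def lda_fit(features, labels, priors: str = "equal") -> LDAModel:
    """Fit the Fisher discriminant on features (n × 2) and binary labels.

    Pooled within-class covariance, weights w = Σ⁻¹Δμ, threshold at the
    midpoint of the projected class means; with ``priors="proportional"``
    the threshold is shifted by the log prior-odds term of the Gaussian
    equal-covariance classifier.  Deterministic.
    """
    if priors not in ("equal", "proportional"):
        raise ValueError("priors must be 'equal' or 'proportional'")
    X, y = _as_xy(features, labels)
    classes = set(y.tolist())
    if classes != {ACTIVE, INACTIVE}:
        raise ValueError(f"need both 'active' and 'inactive' cases, got classes {sorted(classes)}")
    Xa, Xi = X[y == ACTIVE], X[y == INACTIVE]
    if len(Xa) < 2 or len(Xi) < 2 or len(X) < 4:
        raise ValueError("need at least two cases per class (n >= 4) to estimate covariance")
    mu_a, mu_i = Xa.mean(axis=0), Xi.mean(axis=0)
    Sa = np.cov(Xa, rowvar=False, ddof=1)
    Si = np.cov(Xi, rowvar=False, ddof=1)
    pooled = ((len(Xa) - 1) * Sa + (len(Xi) - 1) * Si) / (len(X) - 2)
    pooled = np.atleast_2d(pooled)
    if np.linalg.cond(pooled) > 1e10:
        raise ValueError(
            "pooled within-class covariance is singular or near-singular; "
            "add jitter to the degenerate feature or drop it"
        )
    weights = np.linalg.solve(pooled, mu_a - mu_i)
    threshold = float(weights @ (mu_a + mu_i) / 2.0)
    if priors == "proportional":
        pa, pi = len(Xa) / len(X), len(Xi) / len(X)
        threshold -= np.log(pa / pi)
    return LDAModel(
        weights=weights,
        threshold=threshold,
        class_means={ACTIVE: mu_a, INACTIVE: mu_i},
        pooled_covariance=pooled,
        priors=priors,
    )


def lda_predict(model: LDAModel, x) -> tuple[str, float]:
    """Predicted label and discriminant score for one case.

    The score is wᵀx − threshold (positive ⇒ active); a case exactly on the
    decision boundary is called inactive.
    """
    vec = x.as_array() if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    score = float(vec @ model.weights - model.threshold)
    return (ACTIVE if score > 0 else INACTIVE), score


def accuracy(predictions: Sequence[str], truth: Sequence[str]) -> float:
    """Percent agreement, rounded to one decimal (e.g. 18/19 → 94.7)."""
    if len(predictions) != len(truth):
        raise ValueError(f"length mismatch: {len(predictions)} vs {len(truth)}")
    if len(truth) == 0:
        raise ValueError("cannot compute accuracy of zero cases")
    matches = sum(p == t for p, t in zip(predictions, truth))
    return round(100.0 * matches / len(truth), 1)


def loo_accuracy(features, labels, ids: Sequence[str] | None = None,
                 priors: str = "equal") -> tuple[float, pd.DataFrame]:
    """Exhaustive leave-one-out (jackknife) accuracy of the LDA classifier.

    Every case is held out in turn, the model refit on the remaining n−1,
    and the held-out case predicted.  Returns the percent accuracy (one
    decimal) and a per-case table identifying the misclassified ids.
    """
    X, y = _as_xy(features, labels)
    n = len(X)
    ids = list(ids) if ids is not None else [f"case_{i}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length mismatch")
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        if len(set(y[keep].tolist())) < 2:
            raise ValueError(f"leaving out case {ids[i]!r} removes an entire class")
        model = lda_fit(X[keep], y[keep], priors=priors)
        pred, score = lda_predict(model, X[i])
        rows.append({"id": ids[i], "truth": y[i], "prediction": pred,
                     "score": score, "correct": pred == y[i]})
    table = pd.DataFrame(rows)
    return accuracy(table["prediction"].tolist(), table["truth"].tolist()), table


# ---------------------------------------------------------------------------
# The published displacement cohort
# ---------------------------------------------------------------------------

def study_cohort() -> pd.DataFrame:
    """The 19-compound propidium-displacement cohort with its ground truth.

    Ten ferrocene (Fc) derivatives displaced propidium (donepezil-normalized
    values averaging 84.1%, all above the 50% cut, hence active); seven Fc
    compounds had zero displacement (inactive); donepezil defines 100%
    (active) and tacrine scored 26% (inactive).  Individual normalized
    values for the ten actives were reported only as a group mean and are
    left missing here; the labels are what the classifier is judged
    against.
    """
    actives = ["7a", "1b", "5b", "7b", "1c", "5c", "7c", "1d", "5d", "7d"]
    zeros = ["1a", "1e", "Fc", "5a", "5e", "8", "9"]
    rows = [{"id": c, "group": "Fc_derivative", "norm_pct": np.nan, "label": ACTIVE}
            for c in actives]
    rows += [{"id": c, "group": "Fc_derivative", "norm_pct": 0.0, "label": INACTIVE}
             for c in zeros]
    rows.append({"id": "donepezil", "group": "reference", "norm_pct": 100.0, "label": ACTIVE})
    rows.append({"id": "tacrine", "group": "reference", "norm_pct": 26.0, "label": INACTIVE})
    return pd.DataFrame(rows)
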