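"""SVM-based conformational affinity scoring in torsion space.

An RBF-kernel support vector classifier trained on the sine/cosine-encoded
torsion features of two variant ensembles defines a *characteristic axis*:
the signed decision value of a conformation measures its net affinity for
one variant over the other.  The decision surface is interrogated locally
by pairing support vectors across classes and examining their circular
angle differences, and globally by regressing affinity scores on the
encoded features and re-expressing each angle's (sine, cosine) coefficient
pair in modulus/argument ("orrery") form  b * sin(theta - y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .torsion import (ConformationSet, EncodedFeatures, circular_difference,
                      circular_mean, restrict_to_residues)

__all__ = [
    "AffinityModel",
    "SupportVectorPair",
    "OrreryCoefficients",
    "default_tuning_grid",
    "fit_affinity_model",
    "affinity_score",
    "pair_support_vectors",
    "sv_pair_angle_differences",
    "pca_of_differences",
    "linearize_scores",
    "restrict_to_residues",
]


def default_tuning_grid(n_features: int) -> dict:
    """Log-spaced default grid: gamma in 2^-9..2^1 times 1/n_features,
    cost in 2^-3..2^7."""
    return {
        "gamma": [2.0 ** e / n_features for e in range(-9, 2)],
        "cost": [2.0 ** e for e in range(-3, 8)],
    }


@dataclass
class AffinityModel:
    """Fitted RBF-SVM defining the affinity axis.

    Positive decision values point toward the designated positive class
    (class B); the feature column map ties encoded columns back to angles.
    """

    svc: SVC
    angle_labels: list[tuple[int, str]]
    class_a: str
    class_b: str
    gamma: float
    cost: float
    cv_accuracy: float
    tuning_record: pd.DataFrame
    chance_level: bool = False

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    def support_by_class(self):
        """(SVs of class A, SVs of class B) in encoded feature space."""
        n_a = self.svc.n_support_[0]
        sv = self.svc.support_vectors_
        return sv[:n_a], sv[n_a:]


def _as_matrix(features: EncodedFeatures) -> np.ndarray:
    return np.asarray(features.matrix, dtype=float)


def fit_affinity_model(class_a: EncodedFeatures, class_b: EncodedFeatures,
                       tuning_grid: dict | None = None, folds: int = 10,
                       seed: int = 0) -> AffinityModel:
    """Grid-searched RBF-SVM separating two encoded conformation sets.

    Mean cross-validation accuracy over `folds` stratified, seeded folds
    picks the (gamma, cost) pair; ties break toward smaller cost, then
    larger gamma.  The final model refits on all data at the chosen point.
    """
    if class_a.angle_labels != class_b.angle_labels:
        raise ValueError("class feature column maps differ")
    Xa, Xb = _as_matrix(class_a), _as_matrix(class_b)
    if min(len(Xa), len(Xb)) < folds:
        raise ValueError(f"each class needs at least folds={folds} members")
    X = np.vstack([Xa, Xb])
    y = np.concatenate([np.zeros(len(Xa)), np.ones(len(Xb))])
    if tuning_grid is None:
        tuning_grid = default_tuning_grid(X.shape[1])
    gammas = list(tuning_grid["gamma"])
    costs = list(tuning_grid["cost"])

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    records = []
    for gamma in gammas:
        for cost in costs:
            accs = []
            for tr, te in splits:
                clf = SVC(kernel="rbf", gamma=gamma, C=cost, tol=1e-6)
                clf.fit(X[tr], y[tr])
                accs.append(float((clf.predict(X[te]) == y[te]).mean()))
            records.append((gamma, cost, float(np.mean(accs))))
    record = pd.DataFrame(records, columns=["gamma", "cost", "cv_accuracy"])
    # ties: smaller cost first, then larger gamma
    order = record.sort_values(["cv_accuracy", "cost", "gamma"],
                               ascending=[False, True, False],
                               kind="stable")
    best = order.iloc[0]
    svc = SVC(kernel="rbf", gamma=float(best["gamma"]),
              C=float(best["cost"]), tol=1e-6)
    svc.fit(X, y)
    chance = best["cv_accuracy"] < 0.5 + 2.0 / np.sqrt(len(y))
    if chance:
        warnings.warn("cross-validated accuracy is at chance level; the two "
                      "classes may be indistinguishable")
    variant_a = str(class_a.variants[0]) if len(class_a.variants) else "A"
    variant_b = str(class_b.variants[0]) if len(class_b.variants) else "B"
    return AffinityModel(svc=svc, angle_labels=list(class_a.angle_labels),
                         class_a=variant_a, class_b=variant_b,
                         gamma=float(best["gamma"]), cost=float(best["cost"]),
                         cv_accuracy=float(best["cv_accuracy"]),
                         tuning_record=record, chance_level=bool(chance))


def affinity_score(model: AffinityModel,
                   features: EncodedFeatures) -> np.ndarray:
    """Signed decision value per conformation; positive leans toward class B."""
    if features.angle_labels != model.angle_labels:
        raise ValueError("feature columns do not match the model's map")
    return model.svc.decision_function(_as_matrix(features))


@dataclass
class SupportVectorPair:
    """A matched cross-class support-vector pair."""

    vec_a: np.ndarray  # encoded features, class A member
    vec_b: np.ndarray  # encoded features, class B member
    distance: float

    def angle_differences(self) -> np.ndarray:
        """Per-angle circular difference from the class-A member to the
        class-B member (decoded via atan2)."""
        ang_a = np.arctan2(self.vec_a[1::2], self.vec_a[0::2])
        ang_b = np.arctan2(self.vec_b[1::2], self.vec_b[0::2])
        return circular_difference(ang_a, ang_b)


def pair_support_vectors(model: AffinityModel) -> list[SupportVectorPair]:
    """Greedy without-replacement matching of cross-class support vectors.

    The globally closest pair (Euclidean distance in encoded input space) is
    matched first, then the next closest among the remainder, until one
    class's support vectors are exhausted.
    """
    sv_a, sv_b = model.support_by_class()
    if len(sv_a) == 0 or len(sv_b) == 0:
        raise ValueError("need at least one support vector per class")
    from scipy.spatial.distance import cdist

    D = cdist(sv_a, sv_b)
    pairs = []
    free_a = np.ones(len(sv_a), dtype=bool)
    free_b = np.ones(len(sv_b), dtype=bool)
    masked = D.copy()
    for _ in range(min(len(sv_a), len(sv_b))):
        flat = np.argmin(masked)
        i, j = np.unravel_index(flat, masked.shape)
        pairs.append(SupportVectorPair(sv_a[i].copy(), sv_b[j].copy(),
                                       float(D[i, j])))
        free_a[i] = free_b[j] = False
        masked[i, :] = np.inf
        masked[:, j] = np.inf
    return pairs


def sv_pair_angle_differences(pairs: list[SupportVectorPair],
                              angle_labels: list[tuple[int, str]],
                              level: float = 0.95,
                              bh_correct: bool = False) -> pd.DataFrame:
    """Per-angle circular mean difference across the decision boundary.

    For each angle, the circular mean of the pairwise (A -> B) differences
    with a 95% CI; flags +1 / -1 when the CI excludes zero.  An optional
    Benjamini-Hochberg layer (off by default, matching a per-angle
    presentation) recomputes flags from BH-adjusted two-sided p-values.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = np.array([p.angle_differences() for p in pairs])
    if diffs.shape[1] != len(angle_labels):
        raise ValueError("angle label count does not match feature width")
    rows = []
    pvals = []
    from scipy.stats import norm

    for col, (res, kind) in enumerate(angle_labels):
        cm = circular_mean(diffs[:, col], with_ci=True, level=level)
        covers_zero = cm.contains(0.0)
        flag = 0 if covers_zero else int(np.sign(cm.mean))
        half = 0.5 * (cm.ci_high - cm.ci_low)
        if half > 0:
            z = abs(cm.mean) / (half / norm.ppf(0.5 + level / 2.0))
            p = 2 * norm.sf(z)
        else:
            p = 0.0 if cm.mean != 0 else 1.0
        pvals.append(p)
        rows.append((res, kind, cm.mean, cm.ci_low, cm.ci_high, flag))
    df = pd.DataFrame(rows, columns=["residue", "angle_type", "mean",
                                     "lo", "hi", "flag"])
    df["p_value"] = pvals
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject, padj, *_ = multipletests(pvals, alpha=1 - level, method="fdr_bh")
        df["p_adjusted"] = padj
        df["flag"] = np.where(reject, np.sign(df["mean"]).astype(int), 0)
    return df


def pca_of_differences(pairs: list[SupportVectorPair]):
    """PCA of the pair-difference matrix (pairs x angles).

    Returns (loadings, scores, variance_fractions): loadings are orthonormal
    rows (components x angles), variance fractions non-increasing.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = np.array([p.angle_differences() for p in pairs])
    if diffs.shape[1] < 2:
        raise ValueError("need at least 2 angles")
    if np.allclose(diffs, diffs[0]):
        raise ValueError("pair-difference matrix has rank 0 after centering")
    from sklearn.decomposition import PCA

    pca = PCA()
    scores = pca.fit_transform(diffs)
    return pca.components_, scores, pca.explained_variance_ratio_


@dataclass
class OrreryCoefficients:
    """Per-angle modulus/argument form of the linearized affinity gradient.

    For angle theta_i the fitted sine coefficient beta and cosine
    coefficient beta' are re-expressed as b * sin(theta_i - y) with
    b = sqrt(beta^2 + beta'^2), beta = b cos y, beta' = -b sin y,
    i.e. y = atan2(-beta', beta).
    """

    angle_labels: list[tuple[int, str]]
    beta_sin: np.ndarray
    beta_cos: np.ndarray
    intercept: float

    @property
    def modulus(self) -> np.ndarray:
        return np.hypot(self.beta_sin, self.beta_cos)

    @property
    def reference_angle(self) -> np.ndarray:
        return np.arctan2(-self.beta_cos, self.beta_sin)

    def evaluate(self, col: int, theta) -> np.ndarray:
        """b_i sin(theta - y_i), identically beta sin(theta) + beta' cos(theta)."""
        return self.modulus[col] * np.sin(np.asarray(theta)
                                          - self.reference_angle[col])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": [r for r, _ in self.angle_labels],
            "angle_type": [t for _, t in self.angle_labels],
            "beta_sin": self.beta_sin,
            "beta_cos": self.beta_cos,
            "modulus": self.modulus,
            "reference_angle": self.reference_angle,
        })


def linearize_scores(scores: np.ndarray,
                     features: EncodedFeatures) -> OrreryCoefficients:
    """Least-squares regression of affinity scores on the encoded features.

    The coefficients estimate the mean gradient of the affinity score with
    respect to the sine/cosine components of each angle.  Minimum-norm least
    squares handles rank-deficient designs (small conformation sets), giving
    a deterministic, well-defined gradient estimate.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    X = _as_matrix(features)
    if scores.shape[0] != X.shape[0]:
        raise ValueError("score count must match conformation count")
    # Centering fits the intercept exactly and guarantees zero coefficients
    # for constant scores even on rank-deficient designs.
    x_mean = X.mean(axis=0)
    y_mean = scores.mean()
    coef, *_ = np.linalg.lstsq(X - x_mean, scores - y_mean, rcond=None)
    intercept = float(y_mean - x_mean @ coef)
    beta_cos = coef[0::2]  # cos columns sit at even feature positions
    beta_sin = coef[1::2]
    return OrreryCoefficients(list(features.angle_labels),
                              beta_sin=beta_sin, beta_cos=beta_cos,
                              intercept=intercept)
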