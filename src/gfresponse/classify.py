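"""Kinetic-class and dose-sensitivity classifiers.

Kinetic classes
    Trajectories of log10 fold-change at (10, 30, 90) min are pooled across
    cell lines, ligands, targets and doses and clustered with k-means
    (k = 4).  Each cluster centroid is then named by its shape: the
    lowest-amplitude centroid is "none"; among the rest an early peak that
    decays below half its maximum is "transient", a final-time peak starting
    below half its maximum is "late", and everything else is "sustained".
    By default each trajectory is divided by its own peak before clustering,
    with the divisor floored at the significance scale (m·control SD) so that
    sub-threshold trajectories stay near the origin: responses of any
    amplitude then map onto a common unit-peak shape while null trajectories
    keep populating the "none" cluster.  ``normalize=False`` clusters the raw
    pooled trajectories instead.
    Significance overrides geometry: a trajectory that fails the significance
    rule is labeled "none" regardless of its cluster.

Dose-sensitivity classes
    From the max fold-changes and significance calls at 1 and 100 ng/ml:
    "none" if neither dose is significant, "high_only" if only the high dose
    is, otherwise "equal" when the low-dose response magnitude is at least
    75% of the high-dose one and "high_greater" when it is less.  The ratio
    is taken on linear fold-change minus one (response above baseline) by
    default; ``mode="fold"`` uses the raw linear fold ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.cluster import KMeans

from .constants import HIGH_DOSE, LOW_DOSE
from .errors import ValidationError
from .metrics import RESPONSE_KEY, fold_columns

_FLOOR_EPS = 1e-12


def _features(X: np.ndarray, floor, normalize: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("trajectories must form a 2-D array")
    if not np.isfinite(X).all():
        raise ValidationError("trajectories must be finite")
    if not normalize:
        return X
    if floor is None:
        floor = 0.0
    floor = np.maximum(np.broadcast_to(np.asarray(floor, dtype=float), (len(X),)),
                       _FLOOR_EPS)
    peak = X.max(axis=1)
    denom = np.where(peak > floor, peak, floor)
    return X / denom[:, None]


def label_clusters(centroids: np.ndarray) -> np.ndarray:
    """Name k-means centroids by trajectory shape.

    The smallest-peak centroid (ties broken toward the flattest profile)
    becomes "none"; the rest are "transient", "late" or "sustained" by the
    half-peak rules.  "sustained" is the fallback for degenerate centroids.
    """
    C = np.asarray(centroids, dtype=float)
    amplitudes = C.max(axis=1)
    order = np.lexsort((C.var(axis=1), amplitudes))
    none_idx = order[0]
    labels = np.empty(len(C), dtype=object)
    for i, c in enumerate(C):
        if i == none_idx:
            labels[i] = "none"
            continue
        peak_idx = int(np.argmax(c))
        peak = c[peak_idx]
        if peak <= 0:
            labels[i] = "sustained"
        elif peak_idx < len(c) - 1 and c[-1] / peak < 0.5:
            labels[i] = "transient"
        elif peak_idx == len(c) - 1 and c[0] / peak < 0.5:
            labels[i] = "late"
        else:
            labels[i] = "sustained"
    return labels


class KineticClassifier(ClusterMixin, BaseEstimator):
    """k-means trajectory classifier with shape-named clusters.

    Parameters
    ----------
    n_clusters : int, default=4
    n_restarts : int, default=10
        Random initialisations; the best by within-cluster sum of squares wins.
    random_state : int, default=0
    normalize : bool, default=True
        Divide each trajectory by its peak (floored at its significance
        scale) before clustering.

    Attributes
    ----------
    cluster_centers_ : (k, t) array of centroids in feature space.
    labels_ : cluster index per training trajectory.
    cluster_names_ : shape name per cluster.
    kinetic_labels_ : shape name per training trajectory.
    inertia_ : within-cluster sum of squares of the best run.
    """

    def __init__(self, n_clusters: int = 4, n_restarts: int = 10,
                 random_state: int = 0, normalize: bool = True):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.normalize = normalize

    def fit(self, X, y=None, floor=None):
        F = _features(X, floor, self.normalize)
        if len(F) < self.n_clusters:
            raise ValidationError(
                f"need at least {self.n_clusters} trajectories, got {len(F)}")
        km = KMeans(n_clusters=self.n_clusters, n_init=self.n_restarts,
                    random_state=self.random_state, max_iter=300)
        km.fit(F)
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = float(km.inertia_)
        self.cluster_names_ = label_clusters(self.cluster_centers_)
        self.kinetic_labels_ = self.cluster_names_[self.labels_]
        return self

    def predict(self, X, floor=None):
        F = _features(X, floor, self.normalize)
        d = ((F[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def predict_labels(self, X, floor=None):
        return self.cluster_names_[self.predict(X, floor=floor)]


def cluster_kinetics(trajectories, k: int = 4, seed: int = 0, restarts: int = 10,
                     normalize: bool = True, floor=None):
    """Functional facade: returns (centroids, cluster index per trajectory)."""
    clf = KineticClassifier(n_clusters=k, n_restarts=restarts,
                            random_state=seed, normalize=normalize)
    clf.fit(trajectories, floor=floor)
    return clf.cluster_centers_, clf.labels_


def assign_kinetics(responses: pd.DataFrame, k: int = 4, seed: int = 0,
                    restarts: int = 10, normalize: bool = True,
                    sd_multiplier: float = 2.0) -> tuple[pd.DataFrame, KineticClassifier]:
    """Cluster all response trajectories and attach kinetic labels.

    The normalisation floor is the panel-pooled control SD (root mean square
    across control groups) times ``sd_multiplier``: per-group SDs estimated
    from duplicate controls are far too unstable to divide by, while the
    pooled value is a sturdy estimate of the measurement noise scale.

    Returns the per-condition assignment table (response key, trajectory,
    cluster index, label with the significance override applied) and the
    fitted classifier (whose centroids serve as the audit sidecar).
    """
    cols = fold_columns(responses)
    X = responses[cols].to_numpy(dtype=float)
    group_sd = (responses.groupby(["cell_line", "target"])["control_sd"].first()
                .to_numpy(dtype=float))
    floor = sd_multiplier * float(np.sqrt(np.mean(group_sd ** 2)))
    clf = KineticClassifier(n_clusters=k, n_restarts=restarts,
                            random_state=seed, normalize=normalize)
    clf.fit(X, floor=floor)
    out = responses[RESPONSE_KEY + cols + ["significant"]].copy()
    out["cluster_index"] = clf.labels_
    out["label"] = clf.kinetic_labels_
    out.loc[~out["significant"], "label"] = "none"
    return out, clf


# -- dose sensitivity -------------------------------------------------------

def _response_ratio(fc_low, fc_high, mode: str):
    fc_low = np.asarray(fc_low, dtype=float)
    fc_high = np.asarray(fc_high, dtype=float)
    if mode == "fold_minus_one":
        num = 10.0 ** fc_low - 1.0
        den = 10.0 ** fc_high - 1.0
    elif mode == "fold":
        num = 10.0 ** fc_low
        den = 10.0 ** fc_high
    else:
        raise ValidationError(f"unknown sensitivity mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                         np.where(num > 0, np.inf, 1.0))
    return ratio


def classify_sensitivity(fc_low, fc_high, sig_low, sig_high,
                         ratio_threshold: float = 0.75,
                         mode: str = "fold_minus_one"):
    """Dose-sensitivity label(s); vectorised and total.

    none        neither dose significant
    high_only   only the high dose significant
    equal       low-dose response magnitude >= ratio_threshold of high-dose
    high_greater otherwise
    """
    sig_low = np.asarray(sig_low, dtype=bool)
    sig_high = np.asarray(sig_high, dtype=bool)
    ratio = _response_ratio(fc_low, fc_high, mode)
    labels = np.where(
        ~sig_low & ~sig_high, "none",
        np.where(~sig_low & sig_high, "high_only",
                 np.where(ratio >= ratio_threshold, "equal", "high_greater")))
    if labels.ndim == 0:
        return str(labels)
    return labels.astype(object)


class SensitivityClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based dose-sensitivity classifier (stateless; ``fit`` is a no-op).

    ``predict`` takes an (n, 4) array-like of columns
    (fc_low, fc_high, sig_low, sig_high).
    """

    def __init__(self, ratio_threshold: float = 0.75, mode: str = "fold_minus_one"):
        self.ratio_threshold = ratio_threshold
        self.mode = mode

    def fit(self, X=None, y=None):
        self.classes_ = np.array(["equal", "high_greater", "high_only", "none"])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return classify_sensitivity(X[:, 0], X[:, 1], X[:, 2] != 0, X[:, 3] != 0,
                                    self.ratio_threshold, self.mode)


def assign_sensitivity(responses: pd.DataFrame, ratio_threshold: float = 0.75,
                       mode: str = "fold_minus_one") -> pd.DataFrame:
    """Per-(cell line, ligand, target) sensitivity labels from both doses."""
    low = responses[responses["dose"] == LOW_DOSE]
    high = responses[responses["dose"] == HIGH_DOSE]
    key = ["cell_line", "ligand", "target"]
    merged = low.set_index(key)[["max_fold_change", "significant"]].rename(
        columns={"max_fold_change": "fc_low", "significant": "sig_low"}).join(
        high.set_index(key)[["max_fold_change", "significant"]].rename(
            columns={"max_fold_change": "fc_high", "significant": "sig_high"}),
        how="inner").reset_index()
    merged["label"] = classify_sensitivity(
        merged["fc_low"], merged["fc_high"], merged["sig_low"], merged["sig_high"],
        ratio_threshold, mode)
    return merged
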