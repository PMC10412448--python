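"""Score calibration and evaluation.

The regional difference is calibrated to a probability-scale score via a
single-covariate logistic regression ("GEMINI score"); fragmentation
scores can be averaged in ("GEMINI–DELFI").  Evaluation uses the
Mann–Whitney AUC with DeLong variance/test, sensitivity at fixed
specificity, and — for tumor-type discrimination — principal coordinate
analysis with k-means clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .regional import FeatureBinSets, RegionalDifference, fixed_model_regional_difference


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class GeminiModel:
    """Frozen feature bin sets plus logistic calibration — a portable model."""

    mutation_type: str
    sets: FeatureBinSets
    intercept: float
    slope: float
    grid_checksum: str | None = None
    provenance: dict = field(default_factory=dict)

    def score_rd(self, rd_value: float) -> float:
        return float(_sigmoid(self.intercept + self.slope * rd_value))

    def apply(self, tally) -> tuple[float, RegionalDifference]:
        rd = fixed_model_regional_difference(
            tally, self.sets, self.mutation_type, self.grid_checksum
        )
        return self.score_rd(rd.value), rd

    def to_json(self, path: str) -> None:
        obj = {
            "mutation_type": self.mutation_type,
            "set_A": self.sets.set_A.tolist(),
            "set_B": self.sets.set_B.tolist(),
            "fold_id": self.sets.fold_id,
            "intercept": self.intercept,
            "slope": self.slope,
            "grid_checksum": self.grid_checksum,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GeminiModel":
        with open(path) as fh:
            obj = json.load(fh)
        for key in ("mutation_type", "set_A", "set_B", "intercept", "slope"):
            if key not in obj:
                raise ValueError(f"model file missing field {key!r}")
        return cls(
            obj["mutation_type"],
            FeatureBinSets(np.asarray(obj["set_A"]), np.asarray(obj["set_B"]),
                           obj.get("fold_id", "")),
            float(obj["intercept"]),
            float(obj["slope"]),
            obj.get("grid_checksum"),
            obj.get("provenance", {}),
        )


def fit_calibration(rd_values, labels) -> tuple[float, float]:
    """Maximum-likelihood logistic fit of cancer status on one covariate.

    Returns (intercept, slope).  A constant covariate gives slope 0 and
    scores equal to prevalence; perfect separation falls back to a
    ridge-stabilized fit (penalty 1e-6) with a warning.
    """
    import statsmodels.api as sm

    rd = np.asarray(rd_values, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both classes required to calibrate")
    if np.ptp(rd) == 0:
        prev = y.mean()
        return float(np.log(prev / (1 - prev))), 0.0
    X = sm.add_constant(rd)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(y, X).fit(disp=0)
            if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e8:
                return float(res.params[0]), float(res.params[1])
        except Exception:
            pass
    warnings.warn(
        "perfect separation in logistic calibration; using ridge-stabilized fit",
        stacklevel=2,
    )
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=100_000)
    clf.fit(rd.reshape(-1, 1), y.astype(int))
    return float(clf.intercept_[0]), float(clf.coef_[0, 0])


def combine_scores(gemini: float | np.ndarray, delfi: float | np.ndarray):
    """Arithmetic mean of the two scores; missing values propagate."""
    return (np.asarray(gemini, dtype=float) + np.asarray(delfi, dtype=float)) / 2.0


# --------------------------------------------------------------------------
# ROC / AUC with DeLong variance
# --------------------------------------------------------------------------

def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components (V10 per case, V01 per control)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes required for ROC analysis")
    allv = np.concatenate([pos, neg])
    tz = rankdata(allv)  # midranks handle ties
    tx = rankdata(pos)
    ty = rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


@dataclass(frozen=True)
class AucResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


def roc_auc(scores, labels, conf_level: float = 0.95) -> AucResult:
    """Mann–Whitney AUC (tie-corrected) with a DeLong confidence interval."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_structural(scores, labels)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(0.5 + conf_level / 2.0)
    half = z * np.sqrt(var)
    return AucResult(
        float(auc), float(var),
        float(max(0.0, auc - half)), float(min(1.0, auc + half)), m, n,
    )


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong paired two-sided test comparing two correlated AUCs.

    Returns (z statistic, p value) for AUC(a) − AUC(b) on the same samples.
    """
    labels = np.asarray(labels).astype(int)
    auc_a, v10_a, v01_a = _delong_structural(np.asarray(scores_a, float), labels)
    auc_b, v10_b, v01_b = _delong_structural(np.asarray(scores_b, float), labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(z), float(2 * norm.sf(abs(z)))


def roc_points(scores, labels) -> pd.DataFrame:
    """Full ROC curve as (threshold, sensitivity, specificity) rows."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.concatenate([[-np.inf], np.unique(scores)])
    rows = []
    pos, neg = scores[labels == 1], scores[labels == 0]
    for t in thresholds:
        rows.append(
            {"threshold": t,
             "sensitivity": float((pos > t).mean()),
             "specificity": float((neg <= t).mean())}
        )
    return pd.DataFrame(rows)


def threshold_at_specificity(scores, labels, spec: float) -> tuple[float, float]:
    """Smallest cutoff achieving at least the requested specificity.

    A sample scores positive when its score is strictly above the cutoff
    (ties at the cutoff count as negative).  Returns (cutoff, sensitivity).
    """
    if not 0.0 <= spec <= 1.0:
        raise ValueError("specificity must be in [0, 1]")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    for t in np.concatenate([[-np.inf], np.sort(np.unique(neg))]):
        if (neg <= t).mean() >= spec:
            return float(t), float((pos > t).mean())
    # unreachable: t = max(neg) always achieves specificity 1
    raise AssertionError


# --------------------------------------------------------------------------
# Tumor-type discrimination: PCoA + k-means
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    coordinates: pd.DataFrame  # samples × PCoA axes
    eigenvalues: np.ndarray
    cluster_labels: np.ndarray
    composition: pd.DataFrame | None


def pcoa_coordinates(distance_matrix: np.ndarray, n_axes: int | None = None):
    """Classical multidimensional scaling of a distance matrix.

    Double-centers the squared distances and eigendecomposes; axes with
    non-positive eigenvalues are dropped.  Returns (coordinates, eigvals).
    """
    D = np.asarray(distance_matrix, dtype=np.float64)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-9 * max(1.0, abs(evals[0]))
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return coords, evals[keep]


def cluster_types(
    features: pd.DataFrame,
    type_labels: list[str] | None = None,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterResult:
    """PCoA of Euclidean distances between feature vectors, plus k-means.

    K-means (k-means++ initialization, ``n_restarts`` restarts, best
    inertia kept) runs on the raw feature matrix; the PCoA embedding is
    for visualization and equals PCA up to rotation for Euclidean input.
    """
    from scipy.spatial.distance import pdist, squareform
    from sklearn.cluster import KMeans

    X = features.to_numpy(dtype=np.float64)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {X.shape[0]}")
    D = squareform(pdist(X, metric="euclidean"))
    coords, evals = pcoa_coordinates(D)
    coord_df = pd.DataFrame(
        coords, index=features.index,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    cl = km.fit_predict(X)
    comp = None
    if type_labels is not None:
        comp = (
            pd.crosstab(pd.Series(cl, name="cluster"),
                        pd.Series(list(type_labels), name="type"), normalize="index")
        )
    return ClusterResult(coord_df, evals, cl, comp)
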