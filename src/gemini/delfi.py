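"""DELFI-lite: genome-wide cfDNA fragmentation features and score.

Tumor-derived cfDNA fragments are shorter and more variable than those of
healthy plasma.  The fragmentation score summarizes, in 5 Mb bins passing
GC/mappability filters, the ratio of short (100–150 bp) to long
(151–220 bp) fragment counts — GC-corrected and library-size normalized —
together with 39 chromosome-arm coverage z-scores against a reference
panel of non-cancer samples.  Per training fold, bin profiles are reduced
by PCA to the fewest components explaining ≥90% of variance and combined
with the arm z-scores in an L1-penalized logistic regression.

This is a self-contained re-implementation of the fragmentation-profile
idea with its own reference panel: it does not reproduce any previously
published model's coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hg19 import autosome_arms
from .genome import GenomicBin

SHORT_RANGE = (100, 150)  # inclusive bounds, bp
LONG_RANGE = (151, 220)
MIN_FRAGMENT_MAPQ = 30
GC_MIN = 0.3
MAPPABILITY_MIN = 0.9


def filter_bins(
    bins: list[GenomicBin], gc: np.ndarray, mappability: np.ndarray
) -> np.ndarray:
    """Indices of bins passing the GC and mappability inclusion rules."""
    gc = np.asarray(gc, dtype=float)
    mp = np.asarray(mappability, dtype=float)
    keep = (gc >= GC_MIN) & (mp >= MAPPABILITY_MIN)
    return np.flatnonzero(keep)


@dataclass
class ReferencePanel:
    """Arm-level coverage reference: per-arm mean and SD of arm fractions."""

    arm_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def from_samples(cls, arm_fractions: pd.DataFrame) -> "ReferencePanel":
        """Build from a samples × arms table of arm coverage fractions."""
        sds = arm_fractions.std(axis=0, ddof=1).to_numpy()
        sds = np.where(sds > 0, sds, 1.0)  # degenerate panel: z collapses to 0
        return cls(list(arm_fractions.columns), arm_fractions.mean(axis=0).to_numpy(), sds)


def _loess_correct(counts: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Residualize counts on bin GC by locally weighted regression."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    counts = counts.astype(float)
    if np.ptp(gc) == 0:
        return counts
    fit = lowess(counts, gc, frac=0.75, return_sorted=False)
    return counts - fit + counts.mean()


def fragment_features(
    fragments: pd.DataFrame,
    bins: list[GenomicBin],
    gc: np.ndarray,
    mappability: np.ndarray,
    arms: list[tuple[str, str, int, int]] | None = None,
    gc_correction: str = "lowess",
) -> dict:
    """Per-bin short/long ratios and arm coverage fractions for one sample.

    ``fragments`` needs columns chrom/start/end (0-based half-open) and
    optionally mapq.  Fragments below MAPQ 30 or outside the 100–220 bp
    window are ignored.  Returns bin ratios (NaN where the long count is
    zero), the kept-bin index, and per-arm fragment fractions.
    """
    if gc_correction not in ("lowess", "none"):
        raise ValueError(f"unknown gc_correction {gc_correction!r}")
    frag = fragments.copy()
    if "mapq" in frag.columns:
        frag = frag[frag["mapq"] >= MIN_FRAGMENT_MAPQ]
    frag = frag.reset_index(drop=True)
    frag["length"] = frag["end"] - frag["start"]
    frag["mid"] = (frag["start"] + frag["end"]) // 2

    keep = filter_bins(bins, gc, mappability)
    if keep.size == 0:
        raise ValueError("no bins pass GC/mappability filters")
    n_short = np.zeros(len(bins), dtype=float)
    n_long = np.zeros(len(bins), dtype=float)
    by_chrom: dict[str, list[GenomicBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, sub in frag.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        cb = by_chrom[chrom]
        starts = np.array([b.start for b in cb])
        ends = np.array([b.end for b in cb])
        idx = np.array([b.index for b in cb])
        pos = sub["mid"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(cb) - 1)])
        tgt = idx[k[ok]]
        sub_short = sub["length"].between(*SHORT_RANGE).to_numpy()
        sub_long = sub["length"].between(*LONG_RANGE).to_numpy()
        np.add.at(n_short, tgt, sub_short[ok].astype(float))
        np.add.at(n_long, tgt, sub_long[ok].astype(float))

    s, l = n_short[keep], n_long[keep]
    total = s.sum() + l.sum()
    if total > 0:  # library-size normalization before GC correction
        scale = (len(keep) * 200.0) / total
        s, l = s * scale, l * scale
    if gc_correction == "lowess":
        s = _loess_correct(s, np.asarray(gc, float)[keep])
        l = _loess_correct(l, np.asarray(gc, float)[keep])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(l > 0, s / l, np.nan)

    arms = arms if arms is not None else autosome_arms()
    arm_names = [a[0] for a in arms]
    arm_counts = np.zeros(len(arms))
    for i, (_, chrom, start, end) in enumerate(arms):
        sel = (frag["chrom"] == chrom) & (frag["mid"] >= start) & (frag["mid"] < end)
        arm_counts[i] = sel.sum()
    tot = arm_counts.sum()
    arm_fractions = pd.Series(
        arm_counts / tot if tot else np.zeros(len(arms)), index=arm_names
    )
    return {"ratios": ratios, "kept_bins": keep, "arm_fractions": arm_fractions}


def arm_zscores(arm_fractions: pd.Series, panel: ReferencePanel) -> np.ndarray:
    obs = arm_fractions.reindex(panel.arm_names).to_numpy()
    return (obs - panel.means) / panel.sds


@dataclass
class DelfiLiteModel:
    """PCA basis + sparse logistic coefficients over [PCs, arm z-scores]."""

    pca_mean: np.ndarray
    pca_components: np.ndarray  # [n_components, n_bins]
    n_components: int
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    kept_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def transform(self, profiles: np.ndarray, zscores: np.ndarray) -> np.ndarray:
        pcs = (profiles - self.pca_mean) @ self.pca_components.T
        feats = np.column_stack([pcs, zscores])
        return (feats - self.feat_mean) / self.feat_scale

    def predict_proba(self, profiles: np.ndarray, zscores: np.ndarray) -> np.ndarray:
        z = self.transform(profiles, zscores) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def _n_components_for_variance(explained_ratio: np.ndarray, target: float = 0.9) -> int:
    cum = np.cumsum(explained_ratio)
    return int(np.searchsorted(cum, target - 1e-12) + 1)


def fit_delfi_lite(
    profiles: np.ndarray,
    zscores: np.ndarray,
    labels,
    seed: int = 0,
    inner_cv: int = 5,
) -> DelfiLiteModel:
    """Fit the fragmentation score on one training set.

    PCA retains the minimum number of components explaining ≥90% of the
    variance of the bin-ratio profiles; the components plus arm z-scores
    enter an L1-penalized logistic regression whose penalty is chosen by
    inner stratified cross-validation.
    """
    from sklearn.decomposition import PCA
    from sklearn.linear_model import LogisticRegressionCV

    X = np.asarray(profiles, dtype=float)
    y = np.asarray(labels).astype(int)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both classes required")
    X = np.nan_to_num(X, nan=np.nanmean(X))
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), random_state=seed)
    pcs_full = pca.fit_transform(X)
    ncomp = _n_components_for_variance(pca.explained_variance_ratio_)
    feats = np.column_stack([pcs_full[:, :ncomp], zscores])
    mean = feats.mean(axis=0)
    scale = feats.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    fs = (feats - mean) / scale
    cv = min(inner_cv, int((y == 1).sum()), int((y == 0).sum()))
    clf = LogisticRegressionCV(
        Cs=10, cv=max(2, cv), l1_ratios=[1.0], solver="liblinear",
        scoring="neg_log_loss", random_state=seed, max_iter=5000,
        use_legacy_attributes=False,
    )
    clf.fit(fs, y)
    return DelfiLiteModel(
        pca.mean_, pca.components_[:ncomp], ncomp, mean, scale,
        np.asarray(clf.coef_).ravel(), float(np.ravel(clf.intercept_)[0]),
    )


def apply_delfi_lite(model: DelfiLiteModel, profiles: np.ndarray, zscores: np.ndarray) -> np.ndarray:
    X = np.nan_to_num(np.asarray(profiles, dtype=float), nan=0.0)
    return model.predict_proba(np.atleast_2d(X), np.atleast_2d(zscores))


def delfi_lite_loocv(profiles, zscores, labels, seed: int = 0) -> np.ndarray:
    """Leave-one-out fragmentation scores (same folds as the mutation model)."""
    X = np.asarray(profiles, float)
    Z = np.asarray(zscores, float)
    y = np.asarray(labels).astype(int)
    n = len(y)
    out = np.empty(n)
    for h in range(n):
        keep = np.ones(n, dtype=bool)
        keep[h] = False
        model = fit_delfi_lite(X[keep], Z[keep], y[keep], seed=seed)
        out[h] = apply_delfi_lite(model, X[h], Z[h])[0]
    return out
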