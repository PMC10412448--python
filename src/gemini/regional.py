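"""Regional mutation-frequency statistics: the core of the method.

Somatic mutation rates vary systematically across the genome — late
replicating, heterochromatic regions mutate faster than early replicating
euchromatin — while background sequencing errors do not share that
regional structure.  The method exploits this: on a training cohort it
pools per-bin change counts into a per-bin difference statistic

    delta_i = sum_j y_ij(cancer) / sum_j x_ij(cancer)
            - sum_k y_ik(non-cancer) / sum_k x_ik(non-cancer)

(ratio of sums, never mean of ratios), ranks the 2.5 Mb bins by delta,
and takes the bottom decile (set A) and top decile (set B).  A held-out
sample's *regional difference* is its pooled frequency in B minus that in
A, per million evaluable bases — a per-sample scalar in which sample-wide
background error cancels.  Feature selection is repeated under
leave-one-out cross-validation so every sample is scored by bin sets
chosen without it.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genome import GenomicBin
from .scan import BinTallyMatrix, CLASSES


def grid_checksum(bins: list[GenomicBin]) -> str:
    h = hashlib.sha1()
    for b in bins:
        h.update(f"{b.chrom}:{b.start}-{b.end};".encode())
    return h.hexdigest()


def cohort_matrices(
    tallies: list[BinTallyMatrix], mutation_type: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-sample counts/denominators into [sample, bin] matrices."""
    Y = np.stack([t.counts_for(mutation_type) for t in tallies]).astype(np.float64)
    X = np.stack([t.denominators_for(mutation_type) for t in tallies]).astype(np.float64)
    return Y, X, [t.sample_id for t in tallies]


@dataclass
class DeltaVector:
    values: np.ndarray  # per-bin delta, NaN where unusable
    usable: np.ndarray  # bool per bin: both pooled denominators > 0
    mutation_type: str
    train_cancer_ids: list[str] = field(default_factory=list)
    train_noncancer_ids: list[str] = field(default_factory=list)


def pooled_delta_from_counts(
    Y1: np.ndarray, X1: np.ndarray, Y0: np.ndarray, X0: np.ndarray,
    mutation_type: str = "C>A",
) -> DeltaVector:
    """Per-bin pooled frequency difference from class count matrices.

    ``Y1/X1`` are [sample, bin] (or already-pooled [bin]) counts for the
    cancer class, ``Y0/X0`` for the non-cancer class.  Denominators are
    pooled before division.
    """
    def pool(a):
        a = np.asarray(a, dtype=np.float64)
        return a.sum(axis=0) if a.ndim == 2 else a

    y1, x1, y0, x0 = pool(Y1), pool(X1), pool(Y0), pool(X0)
    usable = (x1 > 0) & (x0 > 0)
    values = np.full(y1.shape, np.nan)
    values[usable] = y1[usable] / x1[usable] - y0[usable] / x0[usable]
    return DeltaVector(values, usable, mutation_type)


def pooled_delta(
    tallies: list[BinTallyMatrix],
    labels: list[int] | np.ndarray,
    mutation_type: str,
) -> DeltaVector:
    """Pooled delta over a labeled cohort (label 1 = cancer, 0 = non-cancer)."""
    labels = np.asarray(labels).astype(int)
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("both classes must be present to compute delta")
    Y, X, ids = cohort_matrices(tallies, mutation_type)
    dv = pooled_delta_from_counts(
        Y[labels == 1], X[labels == 1], Y[labels == 0], X[labels == 0], mutation_type
    )
    dv.train_cancer_ids = [i for i, l in zip(ids, labels) if l == 1]
    dv.train_noncancer_ids = [i for i, l in zip(ids, labels) if l == 0]
    return dv


@dataclass
class FeatureBinSets:
    """Bottom-decile (A) and top-decile (B) bin index sets from one fold."""

    set_A: np.ndarray
    set_B: np.ndarray
    fold_id: str = ""

    def __post_init__(self):
        self.set_A = np.sort(np.asarray(self.set_A, dtype=np.int64))
        self.set_B = np.sort(np.asarray(self.set_B, dtype=np.int64))
        if np.intersect1d(self.set_A, self.set_B).size:
            raise ValueError("decile bin sets overlap")

    def audit_hash(self) -> str:
        h = hashlib.sha1()
        h.update(self.set_A.tobytes())
        h.update(b"|")
        h.update(self.set_B.tobytes())
        h.update(self.fold_id.encode())
        return h.hexdigest()


def select_decile_bins(delta: DeltaVector, fold_id: str = "") -> FeatureBinSets:
    """Rank usable bins by delta and return the decile bin sets.

    With N usable bins, set A holds the floor(N/10) lowest-ranked bins and
    set B the bins from rank ceil(0.9 N) to N — an intentionally
    asymmetric convention (114 vs 115 bins at N = 1,144).  Ties are broken
    by ascending bin index, so selection is deterministic without a seed.
    """
    usable_idx = np.flatnonzero(delta.usable)
    N = usable_idx.size
    if N < 10:
        raise ValueError(f"need >= 10 usable bins to select deciles, have {N}")
    vals = delta.values[usable_idx]
    order = np.lexsort((usable_idx, vals))  # ascending delta, ties by bin index
    ranked = usable_idx[order]
    n_a = N // 10
    b_start_rank = math.ceil(0.9 * N)  # 1-based rank where set B begins
    return FeatureBinSets(ranked[:n_a], ranked[b_start_rank - 1:], fold_id)


@dataclass
class RegionalDifference:
    """Per-sample scalar: SMMF in set B minus SMMF in set A, per million."""

    sample_id: str
    mutation_type: str
    value: float
    y_B: float
    x_B: float
    y_A: float
    x_A: float

    @staticmethod
    def from_components(sample_id, mutation_type, y_B, x_B, y_A, x_A) -> "RegionalDifference":
        if x_B <= 0 or x_A <= 0:
            value = float("nan")
        else:
            value = 1e6 * (y_B / x_B - y_A / x_A)
        return RegionalDifference(sample_id, mutation_type, value, y_B, x_B, y_A, x_A)


def regional_difference(
    test_tally: BinTallyMatrix | tuple[np.ndarray, np.ndarray],
    sets: FeatureBinSets,
    mutation_type: str = "C>A",
    sample_id: str | None = None,
) -> RegionalDifference:
    """Regional difference of one sample under fixed bin sets.

    Accepts a tally matrix or raw per-bin ``(y, x)`` vectors.  A model bin
    beyond the grid contributes zero numerator and denominator.
    """
    if isinstance(test_tally, BinTallyMatrix):
        y = test_tally.counts_for(mutation_type).astype(np.float64)
        x = test_tally.denominators_for(mutation_type).astype(np.float64)
        sample_id = sample_id or test_tally.sample_id
    else:
        y, x = (np.asarray(a, dtype=np.float64) for a in test_tally)
    def safe_sum(v, idx):
        idx = idx[idx < v.size]
        return float(v[idx].sum())
    return RegionalDifference.from_components(
        sample_id or "sample", mutation_type,
        safe_sum(y, sets.set_B), safe_sum(x, sets.set_B),
        safe_sum(y, sets.set_A), safe_sum(x, sets.set_A),
    )


def loocv_regional_differences(
    tallies: list[BinTallyMatrix],
    labels: list[int] | np.ndarray,
    mutation_type: str = "C>A",
) -> tuple[list[RegionalDifference], list[FeatureBinSets]]:
    """Leave-one-out regional differences: each sample scored without itself.

    For every held-out sample the pooled delta and decile bin sets are
    recomputed on the remaining n−1 samples; the per-fold bin sets are
    returned for stability reporting.
    """
    labels = np.asarray(labels).astype(int)
    n = len(tallies)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    Y, X, ids = cohort_matrices(tallies, mutation_type)
    sum1_y, sum1_x = Y[labels == 1].sum(axis=0), X[labels == 1].sum(axis=0)
    sum0_y, sum0_x = Y[labels == 0].sum(axis=0), X[labels == 0].sum(axis=0)
    rds: list[RegionalDifference] = []
    folds: list[FeatureBinSets] = []
    for h in range(n):
        if labels[h] == 1:
            y1, x1, y0, x0 = sum1_y - Y[h], sum1_x - X[h], sum0_y, sum0_x
            if (labels == 1).sum() < 2:
                raise ValueError(f"fold {ids[h]}: no cancer samples left in training")
        else:
            y1, x1, y0, x0 = sum1_y, sum1_x, sum0_y - Y[h], sum0_x - X[h]
            if (labels == 0).sum() < 2:
                raise ValueError(f"fold {ids[h]}: no non-cancer samples left in training")
        dv = pooled_delta_from_counts(y1, x1, y0, x0, mutation_type)
        sets = select_decile_bins(dv, fold_id=f"loo:{ids[h]}")
        folds.append(sets)
        rds.append(regional_difference((Y[h], X[h]), sets, mutation_type, ids[h]))
    return rds, folds


def fixed_model_regional_difference(
    new_tally: BinTallyMatrix,
    sets: FeatureBinSets,
    mutation_type: str = "C>A",
    expected_grid_checksum: str | None = None,
) -> RegionalDifference:
    """Apply frozen full-cohort bin sets to an unseen sample (no refitting)."""
    if expected_grid_checksum is not None:
        got = grid_checksum(new_tally.bins)
        if got != expected_grid_checksum:
            raise ValueError(
                "bin grid mismatch between model and tally "
                f"(model {expected_grid_checksum[:12]}…, tally {got[:12]}…)"
            )
    return regional_difference(new_tally, sets, mutation_type)


def downsample_regional_difference(
    rd: RegionalDifference,
    r_A: int,
    r_B: int,
    seed: int | np.random.Generator = 0,
) -> RegionalDifference:
    """Thin a regional difference to reduced evaluable-base counts.

    Sampling ``r`` of the ``x`` evaluable-position indices without
    replacement and counting how many fall at or below ``y`` makes the
    thinned change count hypergeometric(x, y, r); the statistic is then
    recomputed from the thinned components.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for r, x, nm in ((r_A, rd.x_A, "A"), (r_B, rd.x_B, "B")):
        if r > x:
            raise ValueError(f"target evaluable count r_{nm}={r} exceeds x_{nm}={x}")
    y_A = int(rng.hypergeometric(rd.y_A, rd.x_A - rd.y_A, r_A)) if r_A < rd.x_A else rd.y_A
    y_B = int(rng.hypergeometric(rd.y_B, rd.x_B - rd.y_B, r_B)) if r_B < rd.x_B else rd.y_B
    return RegionalDifference.from_components(
        rd.sample_id, rd.mutation_type, y_B, r_B, y_A, r_A
    )


def fold_stability(folds: list[FeatureBinSets]) -> dict:
    """Mean pairwise Jaccard overlap of per-fold A and B sets."""
    def mean_jaccard(sets):
        if len(sets) < 2:
            return float("nan")
        vals = []
        for s, t in combinations(sets, 2):
            inter = np.intersect1d(s, t).size
            union = np.union1d(s, t).size
            vals.append(inter / union if union else 1.0)
        return float(np.mean(vals))

    return {
        "jaccard_A": mean_jaccard([f.set_A for f in folds]),
        "jaccard_B": mean_jaccard([f.set_B for f in folds]),
    }


def pairwise_feature_matrix(
    tallies: list[BinTallyMatrix],
    type_labels: list[str],
    mutation_types: tuple[str, ...] = CLASSES,
) -> pd.DataFrame:
    """Leave-one-out regional differences for every label pair × mutation type.

    For L tumor-type labels this yields C(L,2) × len(mutation_types)
    features per individual (18 for three types and six single-base
    classes); each individual is held out while the bin sets for every
    pairwise comparison are selected on all other individuals.
    """
    type_labels = list(type_labels)
    uniq = sorted(set(type_labels))
    for lab in uniq:
        if type_labels.count(lab) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 samples")
    n = len(tallies)
    mats = {mt: cohort_matrices(tallies, mt) for mt in mutation_types}
    ids = mats[mutation_types[0]][2]
    out = pd.DataFrame(index=ids)
    for la, lb in combinations(uniq, 2):
        in_a = np.array([l == la for l in type_labels])
        in_b = np.array([l == lb for l in type_labels])
        for mt in mutation_types:
            Y, X, _ = mats[mt]
            col = np.empty(n)
            for h in range(n):
                keep = np.ones(n, dtype=bool)
                keep[h] = False
                dv = pooled_delta_from_counts(
                    Y[keep & in_a], X[keep & in_a], Y[keep & in_b], X[keep & in_b], mt
                )
                sets = select_decile_bins(dv, fold_id=f"{la}|{lb}|{ids[h]}")
                col[h] = regional_difference((Y[h], X[h]), sets, mt, ids[h]).value
            out[f"{la}_vs_{lb}:{mt}"] = col
    return out
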