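"""Aggregation of genomic tracks onto the bin grid and chromatin associations.

Regional mutation frequencies track large-scale chromatin organization:
late-replicating, heterochromatic (B-compartment, H3K9me3-rich) regions
carry more somatic mutations.  This module reduces external tracks
(replication timing, compartment eigenvectors, histone-mark fold changes,
GC, mappability, copy-number segments, gene expression) to per-bin
covariates and runs the quintile-stratified association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicBin
from .scan import BinTallyMatrix


@dataclass
class BinCovariate:
    values: np.ndarray  # NaN where no track interval overlaps the bin
    source: str = ""
    aggregation: str = "weighted-average"

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def read_bedgraph(path: str) -> pd.DataFrame:
    """bedGraph / BED4: chrom, start, end, value (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        skip_blank_lines=True,
    )
    return df[~df["chrom"].isin(["track", "browser"])]


def _overlaps(bins: list[GenomicBin], intervals: pd.DataFrame):
    """Yield (bin_index, interval_row_index, overlap_bp) for all overlaps."""
    by_chrom = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, sub in intervals.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        rows = sub.index.to_numpy()
        for b in by_chrom[chrom]:
            lo = int(np.searchsorted(ends, b.start, side="right"))
            hi = int(np.searchsorted(starts, b.end, side="left"))
            for j in range(lo, hi):
                ov = min(b.end, ends[j]) - max(b.start, starts[j])
                if ov > 0:
                    yield b.index, rows[j], ov


def weighted_average_track(track: pd.DataFrame, bins: list[GenomicBin],
                           source: str = "") -> BinCovariate:
    """Coverage-weighted mean of a piecewise-constant track per bin.

    Track intervals must be non-overlapping after normalization; bins with
    no overlapping interval get NaN.
    """
    _assert_disjoint(track)
    num = np.zeros(len(bins))
    den = np.zeros(len(bins))
    vals = track["value"]
    for bi, row, ov in _overlaps(bins, track):
        num[bi] += vals.loc[row] * ov
        den[bi] += ov
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return BinCovariate(out, source, "weighted-average")


def _assert_disjoint(track: pd.DataFrame) -> None:
    for chrom, sub in track.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"track intervals overlap on {chrom}; normalize first")


def copy_number_bin(segments: pd.DataFrame, bins: list[GenomicBin]) -> BinCovariate:
    """Weighted-average copy number of segments overlapping each bin."""
    seg = segments.rename(columns={"CN": "value", "copy_number": "value"})
    return weighted_average_track(seg[["chrom", "start", "end", "value"]], bins,
                                  source="copy_number")


def expression_aggregate(genes: pd.DataFrame, bins: list[GenomicBin]) -> BinCovariate:
    """Transcript-length-weighted TPM sum per bin.

    ``genes`` columns: chrom, start, end, tpm.  Each gene contributes
    TPM × (overlap bp / transcript length) to every bin it overlaps;
    zero-length transcripts are skipped with a warning.
    """
    import warnings

    g = genes.copy()
    if (g["tpm"] < 0).any():
        raise ValueError("negative TPM values")
    lengths = (g["end"] - g["start"]).to_numpy()
    if (lengths <= 0).any():
        warnings.warn("skipping zero-length transcripts", stacklevel=2)
        g = g[lengths > 0]
    out = np.zeros(len(bins))
    touched = np.zeros(len(bins), dtype=bool)
    tpm = g["tpm"]
    tlen = g["end"] - g["start"]
    for bi, row, ov in _overlaps(bins, g):
        out[bi] += tpm.loc[row] * ov / tlen.loc[row]
        touched[bi] = True
    out[~touched] = np.nan
    return BinCovariate(out, "expression", "length-weighted-sum")


def quintile_strata(covariate: BinCovariate, n_strata: int = 5) -> list[np.ndarray]:
    """Split covariate-defined bins into rank strata of near-equal size.

    Bins are ranked ascending by covariate (ties by bin index); when the
    count is not divisible the larger strata sit at the low-covariate end.
    """
    idx = np.flatnonzero(covariate.defined())
    if idx.size < n_strata:
        raise ValueError(f"need >= {n_strata} bins with covariate values, have {idx.size}")
    order = np.lexsort((idx, covariate.values[idx]))
    ranked = idx[order]
    base, extra = divmod(idx.size, n_strata)
    sizes = [base + (1 if i < extra else 0) for i in range(n_strata)]
    strata, at = [], 0
    for s in sizes:
        strata.append(np.sort(ranked[at:at + s]))
        at += s
    return strata


def quintile_association(
    sample: BinTallyMatrix,
    covariate: BinCovariate,
    panel: list[BinTallyMatrix],
    mutation_type: str = "C>A",
    reference_profile: np.ndarray | None = None,
    n_strata: int = 5,
) -> dict:
    """Mutation frequency across covariate strata, panel-subtracted.

    Within each stratum the pooled SMMF is computed for the sample and
    for the pooled non-cancer panel; the panel value is subtracted and the
    per-sample profile shifted so its minimum is exactly zero.  When a
    tissue reference profile is supplied, its Pearson correlation with
    the shifted profile is returned.
    """
    if not panel:
        raise ValueError("non-cancer panel must be non-empty")
    strata = quintile_strata(covariate, n_strata)
    y = sample.counts_for(mutation_type).astype(float)
    x = sample.denominators_for(mutation_type).astype(float)
    py = np.sum([t.counts_for(mutation_type) for t in panel], axis=0).astype(float)
    px = np.sum([t.denominators_for(mutation_type) for t in panel], axis=0).astype(float)

    def pooled_smmf(yv, xv, idx):
        xs = xv[idx].sum()
        return 1e6 * yv[idx].sum() / xs if xs > 0 else np.nan

    samp = np.array([pooled_smmf(y, x, s) for s in strata])
    pan = np.array([pooled_smmf(py, px, s) for s in strata])
    diff = samp - pan
    shifted = diff - np.nanmin(diff)
    corr = float("nan")
    if reference_profile is not None:
        ref = np.asarray(reference_profile, float)
        ok = ~np.isnan(shifted) & ~np.isnan(ref)
        if ok.sum() >= 2 and np.ptp(shifted[ok]) > 0 and np.ptp(ref[ok]) > 0:
            corr = float(np.corrcoef(shifted[ok], ref[ok])[0, 1])
    return {
        "strata": strata,
        "sample_smmf": samp,
        "panel_smmf": pan,
        "shifted": shifted,
        "correlation": corr,
    }
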