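"""Germline/population filtering and oxidative-artifact handling.

Candidate single-molecule changes are filtered against a gnomAD-style
population VCF (a candidate is removed when the population site failed
quality filters, or segregates at allele frequency above 1 in 100,000),
and against the orientation signature of 8-oxo-dG damage: oxidized
guanine yields G>T miscalls on the strand that sequenced the guanine, so
artifactual C>A changes concentrate in the read-pair orientation where
read 1 observed the purine (``PYR_R2``).  Dropping that orientation —
numerator and denominator alike — leaves C>A frequencies unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import (
    BinTallyMatrix,
    CandidateVariant,
    CLASS_INDEX,
    ORIENT_INDEX,
    classify_change,
    smmf,
)

AF_REMOVAL_THRESHOLD = 1e-5  # remove iff population AF strictly exceeds 1/100,000


def _key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    return (chrom.removeprefix("chr"), pos, ref.upper(), alt.upper())


class PopulationSites:
    """Indexed population variants: (chrom, 0-based pos, ref, alt) → (AF, pass)."""

    def __init__(self, records: dict[tuple[str, int, str, str], tuple[float, bool]]):
        self._records = records

    def __len__(self) -> int:
        return len(self._records)

    def lookup(self, chrom, pos, ref, alt):
        return self._records.get(_key(chrom, pos, ref, alt))

    @classmethod
    def from_vcf(cls, path: str, af_field: str = "AF") -> "PopulationSites":
        """Load sites from a VCF; multiallelic records are decomposed.

        FILTER of PASS or '.' counts as passing.  The allele-frequency INFO
        field name is configurable (default ``AF``); a per-alt list is
        split across the decomposed records.
        """
        from cyvcf2 import VCF

        records: dict[tuple[str, int, str, str], tuple[float, bool]] = {}
        vcf = VCF(path)
        for v in vcf:
            passes = v.FILTER is None  # cyvcf2: None means PASS or '.'
            af = v.INFO.get(af_field)
            if af is None:
                afs = [0.0] * len(v.ALT)
            elif isinstance(af, (tuple, list)):
                afs = [float(a) for a in af]
            else:
                afs = [float(af)] * len(v.ALT)
            for alt, a in zip(v.ALT, afs):
                if len(v.REF) == 1 and len(alt) == 1:
                    records[_key(v.CHROM, v.POS - 1, v.REF, alt)] = (a, passes)
        vcf.close()
        return cls(records)


def population_filter(
    candidates: list[CandidateVariant],
    sites: PopulationSites,
    tally: BinTallyMatrix | None = None,
) -> tuple[list[CandidateVariant], BinTallyMatrix | None]:
    """Remove candidates present in the population at AF > 1e-5 or non-PASS.

    Only numerators are touched: for each removed candidate the matching
    change-count cell is decremented by its molecule support; evaluable
    denominators are left unchanged.  Candidates whose orientation has
    already been masked out of the tally are ignored (their counts are
    gone already), which makes this filter commute with the oxo-dG filter.
    """
    kept: list[CandidateVariant] = []
    out = None
    if tally is not None:
        out = BinTallyMatrix(
            tally.sample_id, tally.bins, tally.change_counts.copy(),
            tally.doublet_counts.copy(), tally.evaluable_CG.copy(),
            tally.evaluable_TA.copy(), tally.evaluable_CC.copy(),
            tally.orientation_mask.copy(), dict(tally.metadata),
        )
    removed = 0
    for c in candidates:
        hit = sites.lookup(c.chrom, c.pos, c.ref, c.alt)
        remove = hit is not None and ((not hit[1]) or hit[0] > AF_REMOVAL_THRESHOLD)
        if not remove:
            kept.append(c)
            continue
        removed += 1
        if out is not None and c.bin_index >= 0:
            cls, _ = classify_change(c.ref, c.alt, "pyrimidine")
            ci, oi = CLASS_INDEX[cls], ORIENT_INDEX[c.orientation]
            if out.orientation_mask[ci, oi]:
                out.change_counts[c.bin_index, ci, oi] = max(
                    0, out.change_counts[c.bin_index, ci, oi] - c.molecule_count
                )
    if out is not None:
        out.metadata.setdefault("filter_log", []).append(
            {"stage": "population_filter", "candidates_in": len(candidates),
             "candidates_removed": removed}
        )
    return kept, out


@dataclass(frozen=True)
class OxoGEstimate:
    """Orientation ratio of C>A frequencies used as an 8-oxo-dG proxy."""

    ratio: float
    numerator_freq: float  # C>A per Mb when G / G>T was on read 1 (PYR_R2)
    denominator_freq: float  # C>A per Mb when C / C>A was on read 1 (PYR_R1)


def estimate_oxog(tally: BinTallyMatrix) -> OxoGEstimate:
    """Genome-wide ratio of PYR_R2 to PYR_R1 single-molecule C>A frequency."""
    ci = CLASS_INDEX["C>A"]
    freqs = {}
    for o, oi in ORIENT_INDEX.items():
        y = int(tally.change_counts[:, ci, oi].sum())
        x = int(tally.evaluable_CG[:, oi].sum())
        freqs[o] = smmf(y, x)
    num, den = freqs["PYR_R2"], freqs["PYR_R1"]
    ratio = num / den if den and den > 0 else float("nan")
    return OxoGEstimate(ratio, num, den)


OXOG_POLICIES = ("none", "drop_pyr_r2", "drop_pyr_r1")


def filter_oxog(
    tally: BinTallyMatrix,
    candidates: list[CandidateVariant] | None = None,
    policy: str = "drop_pyr_r2",
) -> tuple[BinTallyMatrix, list[CandidateVariant] | None]:
    """Drop one read-pair orientation of C>A changes and its denominator.

    The default removes the canonical oxidative-damage orientation (G>T
    observed on read 1, i.e. ``PYR_R2``).  The surviving C>A frequency is
    then computed from the remaining orientation only; other change
    classes are untouched.
    """
    if policy not in OXOG_POLICIES:
        raise ValueError(f"unknown oxoG policy {policy!r}; choose from {OXOG_POLICIES}")
    if policy == "none":
        return tally, candidates
    drop = "PYR_R2" if policy == "drop_pyr_r2" else "PYR_R1"
    oi = ORIENT_INDEX[drop]
    ci = CLASS_INDEX["C>A"]
    out = BinTallyMatrix(
        tally.sample_id, tally.bins, tally.change_counts.copy(),
        tally.doublet_counts.copy(), tally.evaluable_CG.copy(),
        tally.evaluable_TA.copy(), tally.evaluable_CC.copy(),
        tally.orientation_mask.copy(), dict(tally.metadata),
    )
    removed = int(out.change_counts[:, ci, oi].sum())
    out.change_counts[:, ci, oi] = 0
    out.orientation_mask[ci, oi] = False
    out.metadata.setdefault("filter_log", []).append(
        {"stage": "filter_oxog", "policy": policy, "changes_removed": removed}
    )
    kept = None
    if candidates is not None:
        kept = [
            c for c in candidates
            if not (classify_change(c.ref, c.alt, "pyrimidine")[0] == "C>A"
                    and c.orientation == drop)
        ]
    return out, kept


class TruthSet:
    """A set of known variants (somatic or germline) for annotation."""

    def __init__(self, keys: set[tuple[str, int, str, str]]):
        self._keys = {_key(*k) for k in keys}

    def __contains__(self, item) -> bool:
        chrom, pos, ref, alt = item
        return _key(chrom, pos, ref, alt) in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    @classmethod
    def from_tsv(cls, path: str) -> "TruthSet":
        """4+ column TSV: chrom, pos (1-based), ref, alt."""
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = list(df.columns[:4])
        keys = {
            _key(str(c), int(p) - 1, str(r), str(a))
            for c, p, r, a in df[cols].itertuples(index=False)
        }
        return cls(keys)

    @classmethod
    def from_vcf(cls, path: str) -> "TruthSet":
        from cyvcf2 import VCF

        keys = set()
        vcf = VCF(path)
        for v in vcf:
            for alt in v.ALT:
                if len(v.REF) == 1 and len(alt) == 1:
                    keys.add(_key(v.CHROM, v.POS - 1, v.REF, alt))
        vcf.close()
        return cls(keys)


def annotate_truth(
    candidates: list[CandidateVariant],
    somatic_truth: TruthSet | None = None,
    germline_truth: TruthSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label candidates somatic/germline/unknown against truth sets.

    Returns the labeled table and a summary with the somatic fraction and
    molecule-weighted somatic fraction; germline takes precedence when a
    site appears in both truth sets.
    """
    labels = []
    for c in candidates:
        item = (c.chrom, c.pos, c.ref, c.alt)
        if germline_truth is not None and item in germline_truth:
            labels.append("germline")
        elif somatic_truth is not None and item in somatic_truth:
            labels.append("somatic")
        else:
            labels.append("unknown")
    df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in candidates],
            "pos": [c.pos for c in candidates],
            "ref": [c.ref for c in candidates],
            "alt": [c.alt for c in candidates],
            "orientation": [c.orientation for c in candidates],
            "molecules": [c.molecule_count for c in candidates],
            "label": labels,
        }
    )
    n = len(df)
    mol = df["molecules"].sum()
    summary = {
        "n_candidates": int(n),
        "fraction_somatic": float((df["label"] == "somatic").mean()) if n else float("nan"),
        "fraction_germline": float((df["label"] == "germline").mean()) if n else float("nan"),
        "molecule_fraction_somatic": (
            float(df.loc[df["label"] == "somatic", "molecules"].sum() / mol)
            if mol else float("nan")
        ),
    }
    return df, summary
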