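"""Synthetic data with known truth, plus downsampling/dilution experiments.

The cohort generator emulates the structure of low-coverage cfDNA
mutation data: a uniform per-base background change rate modulated by a
per-sample multiplicative "lane" factor (sequencing lane/run artifacts),
a cancer-only rate increase concentrated in a designated set of
late-replicating-like bins, oriented 8-oxo-dG-type C>A artifacts confined
to the read-pair orientation in which read 1 observed the purine,
residual germline contamination spread over all classes, and CC>AA
doublets.  Counts are binomial at fixed evaluable denominators so every
expectation is available in closed form for testing.

The read simulator builds tiny paired-end SAM/FASTA/VCF fixtures with
planted variants for the molecule scanner, and the dilution module
reproduces the tumor-fraction / coverage limit-of-detection experiment on
per-mutation allele-count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomicBin
from .scan import BinTallyMatrix, CLASSES, CLASS_INDEX


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    # independent substream per (seed, key...) so draw order is stable
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# --------------------------------------------------------------------------
# Cohort-level tally simulation
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Full parameterization of the simulated cohort world.

    Defaults are the study conditions used throughout the test suite:
    40 + 40 samples, a background change rate of 1e-6 per evaluable base,
    a cancer-only rate increase of 5e-6 concentrated in 100 enriched bins,
    2e6 evaluable bases per 2.5 Mb bin (≈1–2× genome coverage), lane
    factors lognormal with sigma 0.3, and an oriented oxo-dG artifact rate
    of 2e-6.
    """

    bins: list[GenomicBin]
    n_cancer: int = 40
    n_noncancer: int = 40
    base_rate: float = 1e-6
    n_enriched_bins: int = 100
    enriched_bins: np.ndarray | None = None  # chosen from seed when None
    effect_size: float = 5e-6
    effect_class: str = "C>A"
    lane_sigma: float = 0.3
    oxog_rate: float = 2e-6
    oxog_sample_sigma: float = 1.0  # lognormal spread of per-sample oxo-dG load
    germline_residual_rate: float = 1e-7
    doublet_rate: float = 1e-8
    doublet_cancer_fold: float = 2.0
    evaluable_per_bin: int = 2_000_000
    seed: int = 0

    def resolve_enriched(self) -> np.ndarray:
        if self.enriched_bins is not None:
            return np.asarray(self.enriched_bins, dtype=np.int64)
        rng = _rng_for(self.seed, 0xE)
        return np.sort(
            rng.choice(len(self.bins), size=self.n_enriched_bins, replace=False)
        )


def simulate_cohort_tallies(
    spec: SyntheticCohortSpec,
) -> tuple[list[BinTallyMatrix], np.ndarray, dict]:
    """Draw a labeled cohort of bin tally matrices.

    Returns (tallies, labels, truth); labels are 1 for cancer.  Per bin,
    class and orientation the change count is binomial with success rate
    ``lane * base_rate`` plus the cancer-only effect in enriched bins (for
    the effect class), the germline residual, and — for C>A in the
    PYR_R2 orientation only — the oxo-dG artifact rate.
    """
    n_bins = len(spec.bins)
    enriched = spec.resolve_enriched()
    if enriched.size and enriched.max() >= n_bins:
        raise ValueError("enriched bin index outside the grid")
    labels = np.concatenate(
        [np.ones(spec.n_cancer, dtype=int), np.zeros(spec.n_noncancer, dtype=int)]
    )
    # evaluable denominators: half C:G, half T:A, split evenly by orientation
    ev_orient = spec.evaluable_per_bin // 4
    ev_cc = spec.evaluable_per_bin // 20
    enr_mask = np.zeros(n_bins, dtype=bool)
    enr_mask[enriched] = True

    tallies: list[BinTallyMatrix] = []
    lane_factors = np.empty(len(labels))
    for s, lab in enumerate(labels):
        rng = _rng_for(spec.seed, 1, s)
        lane = float(rng.lognormal(mean=0.0, sigma=spec.lane_sigma)) if spec.lane_sigma > 0 else 1.0
        lane_factors[s] = lane
        oxog = spec.oxog_rate * (
            float(rng.lognormal(mean=0.0, sigma=spec.oxog_sample_sigma))
            if spec.oxog_sample_sigma > 0 else 1.0
        )
        t = BinTallyMatrix.zeros(f"{'ca' if lab else 'nc'}{s:03d}", spec.bins)
        t.evaluable_CG[:] = ev_orient
        t.evaluable_TA[:] = ev_orient
        t.evaluable_CC[:] = ev_cc
        for ci, cls in enumerate(CLASSES):
            for oi in (0, 1):
                rate = lane * spec.base_rate + spec.germline_residual_rate
                rate_vec = np.full(n_bins, rate)
                if lab and cls == spec.effect_class:
                    rate_vec[enr_mask] += spec.effect_size
                if cls == "C>A" and oi == 1:
                    rate_vec += oxog
                if (rate_vec > 1).any():
                    raise ValueError("change probability exceeds 1; lower the rates")
                t.change_counts[:, ci, oi] = rng.binomial(ev_orient, rate_vec)
        t.metadata["oxog_rate"] = oxog
        d_rate = np.full(n_bins, lane * spec.doublet_rate)
        if lab:
            d_rate[enr_mask] *= spec.doublet_cancer_fold
        t.doublet_counts[:] = rng.binomial(ev_cc, np.clip(d_rate, 0, 1))
        t.metadata["simulated"] = {"label": int(lab), "lane_factor": lane}
        tallies.append(t)
    truth = {
        "enriched_bins": enriched,
        "lane_factors": lane_factors,
        "labels": labels,
        "spec": spec,
    }
    return tallies, labels, truth


# --------------------------------------------------------------------------
# Read-level fixture simulation
# --------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def random_genome(lengths: dict[str, int], seed: int = 0, gc: float = 0.42) -> dict[str, str]:
    """Random toy genome sequences with the requested GC fraction."""
    rng = _rng_for(seed, 0xF)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        c: "".join(rng.choice(list("ACGT"), size=n, p=p)) for c, n in lengths.items()
    }


@dataclass
class PlannedVariant:
    """A variant planted into simulated molecules.

    ``fraction`` is the probability that a covering molecule carries the
    event.  ``kind`` is somatic | germline | oxog | doublet; oxog events
    (reference G) are applied only to molecules whose read 1 sequenced the
    purine-carrying strand, reproducing the orientation bias of oxidative
    damage.  Doublets substitute two adjacent bases.
    """

    chrom: str
    pos: int  # 0-based
    alt: str  # 1 base, or 2 bases for doublets
    fraction: float = 1.0
    kind: str = "somatic"
    phred: int | None = None  # base quality at the event, default read-wide


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_reads(
    genome: dict[str, str],
    plan: list[PlannedVariant],
    n_pairs: int,
    out_prefix: str,
    seed: int = 0,
    read_len: int = 50,
    frag_range: tuple[int, int] = (60, 90),
    base_q: int = 37,
    mapq: int = 60,
    error_rate: float = 0.0,
    sample_id: str = "sim",
) -> dict[str, str]:
    """Write a paired-end SAM + FASTA + truth VCF fixture.

    Fragments are uniform over each chromosome (proportional to length),
    mates overlap whenever the fragment is shorter than twice the read
    length, and per-read sequencing errors (rate ``error_rate``) are
    independent between mates so overlap consensus can remove them.
    Returns the paths written: keys fasta, sam, vcf.
    """
    import pysam

    rng = _rng_for(seed, 0xA)
    for v in plan:
        if v.chrom not in genome or v.pos + len(v.alt) > len(genome[v.chrom]):
            raise ValueError(f"planned variant outside genome: {v.chrom}:{v.pos}")
        if v.kind == "oxog" and genome[v.chrom][v.pos] != "G":
            raise ValueError("oxog events must sit on a reference G")

    chroms = list(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    by_chrom: dict[str, list[PlannedVariant]] = {}
    for v in plan:
        by_chrom.setdefault(v.chrom, []).append(v)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
            "RG": [{"ID": sample_id, "SM": sample_id}],
        }
    )
    reads = []
    for i in range(n_pairs):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        L = len(genome[chrom])
        flen = int(rng.integers(frag_range[0], frag_range[1] + 1))
        flen = min(flen, L)
        start = int(rng.integers(0, L - flen + 1))
        end = start + flen
        r1_forward = bool(rng.integers(0, 2))
        mol = list(genome[chrom][start:end])
        quals = {}  # offset -> phred override
        for v in by_chrom.get(chrom, []):
            if not (start <= v.pos and v.pos + len(v.alt) <= end):
                continue
            if v.kind == "oxog":
                # lesion strand carries the G (top strand here); only
                # molecules whose read 1 sequenced the top strand show it
                if not r1_forward:
                    continue
            if rng.random() >= v.fraction:
                continue
            for k, b in enumerate(v.alt):
                mol[v.pos - start + k] = b
                if v.phred is not None:
                    quals[v.pos - start + k] = v.phred

        rl = min(read_len, flen)
        for mate in (1, 2):
            forward = r1_forward if mate == 1 else not r1_forward
            if forward:
                seg_lo, seg_hi = 0, rl
            else:
                seg_lo, seg_hi = flen - rl, flen
            seq = list(mol[seg_lo:seg_hi])
            q = [quals.get(seg_lo + k, base_q) for k in range(len(seq))]
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(len(seq)) < error_rate)
                for e in errs:
                    seq[e] = rng.choice([b for b in "ACGT" if b != seq[e]])
            a = pysam.AlignedSegment(header)
            a.query_name = f"mol{i:06d}"
            a.query_sequence = "".join(seq)
            a.query_qualities = q
            a.reference_name = chrom
            a.reference_start = start + seg_lo
            a.mapping_quality = mapq
            a.cigarstring = f"{len(seq)}M"
            a.flag = (
                0x1 | 0x2
                | (0x40 if mate == 1 else 0x80)
                | (0x10 if not forward else 0)
                | (0x20 if forward else 0)
            )
            a.next_reference_name = chrom
            a.next_reference_start = start + (0 if (r1_forward) == (mate == 2) else flen - rl)
            a.template_length = flen if forward else -flen
            a.set_tag("RG", sample_id)
            reads.append(a)

    reads.sort(key=lambda r: (chroms.index(r.reference_name), r.reference_start))
    paths = {
        "fasta": f"{out_prefix}.fa",
        "sam": f"{out_prefix}.sam",
        "vcf": f"{out_prefix}.truth.vcf",
    }
    write_fasta(genome, paths["fasta"])
    pysam.FastaFile(paths["fasta"])  # force .fai creation
    with pysam.AlignmentFile(paths["sam"], "wh", header=header) as bam:
        for r in reads:
            bam.write(r)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=KIND,Number=1,Type=String,Description="planted kind">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={len(genome[c])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(plan, key=lambda v: (v.chrom, v.pos)):
            ref = genome[v.chrom][v.pos:v.pos + len(v.alt)]
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{ref}\t{v.alt}\t.\tPASS\tKIND={v.kind}\n"
            )
    return paths


# --------------------------------------------------------------------------
# Dilution / limit-of-detection experiment
# --------------------------------------------------------------------------

@dataclass
class DilutionSpec:
    mutations: pd.DataFrame  # columns: ref_count, alt_count (NaN = missing)
    purity: float = 1.0
    dilution_targets: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4)
    coverage_targets: tuple[float, ...] = (8.0, 4.0, 2.0, 1.0, 0.5)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


def exclude_missing_counts(mutations: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop mutations lacking a reference or mutant allele count."""
    n_in = len(mutations)
    out = mutations.dropna(subset=["ref_count", "alt_count"])
    return out, {"input": n_in, "missing_removed": n_in - len(out), "retained": len(out)}


def dilution_experiment(spec: DilutionSpec) -> pd.DataFrame:
    """Limit-of-detection table over the dilution × coverage grid.

    Per mutation the tumor-derived observation count is total × purity;
    reference-allele observations are spiked in (expected-value rounding)
    until the target tumor fraction is reached, then observations are
    subsampled without replacement so the mean coverage over mutated
    positions hits the target.  A mutation is detected when ≥1 mutant
    observation survives.
    """
    mut, accounting = exclude_missing_counts(spec.mutations)
    if len(mut) == 0:
        raise ValueError("mutation table is empty after exclusions")
    alt = mut["alt_count"].to_numpy(dtype=np.int64)
    ref = mut["ref_count"].to_numpy(dtype=np.int64)
    total = alt + ref
    rows = []
    for di, frac in enumerate(spec.dilution_targets):
        if frac > spec.purity:
            raise ValueError(
                f"target tumor fraction {frac} exceeds undiluted fraction {spec.purity}"
            )
        tumor_obs = total * spec.purity
        n_diluted = np.rint(tumor_obs / frac).astype(np.int64)
        n_diluted = np.maximum(n_diluted, total)
        mean_cov = n_diluted.mean()
        for ci, cov in enumerate(spec.coverage_targets):
            rng = _rng_for(spec.seed, 2, di, ci)
            p = min(1.0, cov / mean_cov)
            sample_n = np.minimum(np.rint(p * n_diluted).astype(np.int64), n_diluted)
            surviving_alt = rng.hypergeometric(alt, n_diluted - alt, np.maximum(sample_n, 0))
            surviving_alt = np.where(sample_n > 0, surviving_alt, 0)
            detected = surviving_alt >= 1
            rows.append(
                {
                    "tumor_fraction": frac,
                    "coverage": cov,
                    "n_mutations": len(mut),
                    "n_detected": int(detected.sum()),
                    "fraction_observed": float(detected.mean()),
                    "mean_mutant_observations": float(surviving_alt.mean()),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["accounting"] = accounting
    return out


def downsample_tally(tally: BinTallyMatrix, fraction: float, seed: int = 0) -> BinTallyMatrix:
    """Thin a whole tally matrix to a target coverage fraction."""
    if fraction > 1:
        raise ValueError("cannot downsample above current coverage")
    if fraction == 1.0:
        return tally
    if fraction == 0.0:
        warnings.warn("downsampling to zero coverage produces an empty tally",
                      stacklevel=2)
    rng = _rng_for(seed, 3)
    out = BinTallyMatrix.zeros(tally.sample_id, tally.bins)
    out.orientation_mask = tally.orientation_mask.copy()
    out.metadata = dict(tally.metadata)
    for oi in (0, 1):
        for denom_name, classes in (("evaluable_CG", ("C>A", "C>G", "C>T")),
                                    ("evaluable_TA", ("T>A", "T>C", "T>G"))):
            x = getattr(tally, denom_name)[:, oi]
            x_new = np.rint(fraction * x).astype(np.int64)
            getattr(out, denom_name)[:, oi] = x_new
            for cls in classes:
                ci = CLASS_INDEX[cls]
                y = tally.change_counts[:, ci, oi]
                out.change_counts[:, ci, oi] = rng.hypergeometric(
                    y, np.maximum(x - y, 0), np.maximum(x_new, 0)
                ) if x.size else y
    y, x = tally.doublet_counts, tally.evaluable_CC
    x_new = np.rint(fraction * x).astype(np.int64)
    out.evaluable_CC[:] = x_new
    out.doublet_counts[:] = rng.hypergeometric(y, np.maximum(x - y, 0),
                                               np.maximum(x_new, 0))
    return out


# --------------------------------------------------------------------------
# Cohort-manifest accounting (sample and mutation exclusion rules)
# --------------------------------------------------------------------------

def pcawg_like_manifest() -> pd.DataFrame:
    """Synthetic tumor manifest with the PCAWG cohort's published composition.

    A stand-in (no controlled-access data): 2,778 tumors of which 49 are
    flagged hypermutated, 129 sit in cancer types with fewer than 20
    samples, 89 belong to one adequately sized type averaging under 250
    mutations per sample, and the remaining 2,511 span 25 common types
    that survive every exclusion rule.  Per-sample mutation burdens are
    placeholders chosen only to trip or clear each threshold.
    """
    rows = []
    common_sizes = [101] * 11 + [100] * 14  # 25 types, 2,511 samples
    for t, size in enumerate(common_sizes):
        for s in range(size):
            rows.append((f"type{t:02d}", f"type{t:02d}_s{s:03d}", False, 5000))
    for h in range(49):  # hypermutated tumors spread over common types
        rows.append((f"type{h % 25:02d}", f"hyper_s{h:03d}", True, 1_000_000))
    rare_sizes = [19] * 6 + [15]  # 129 samples in under-sized types
    for t, size in enumerate(rare_sizes):
        for s in range(size):
            rows.append((f"rare{t}", f"rare{t}_s{s:02d}", False, 5000))
    for s in range(89):  # low-burden type (pilocytic-astrocytoma-like)
        rows.append(("low_burden", f"low_s{s:02d}", False, 150))
    return pd.DataFrame(rows, columns=["cancer_type", "sample_id",
                                       "hypermutated", "n_mutations"])


def pcawg_like_mutation_counts(seed: int = 0) -> pd.DataFrame:
    """Synthetic per-mutation allele-count table at the published scale.

    3,393,564 rows of which 5,857 lack a reference or mutant allele count,
    mirroring the accounting of the lung-cancer dilution input; counts
    themselves are placeholders.
    """
    n_total, n_missing = 3_393_564, 5_857
    rng = _rng_for(seed, 4)
    ref = np.full(n_total, 20.0)
    alt = np.full(n_total, 10.0)
    miss = rng.choice(n_total, size=n_missing, replace=False)
    half = n_missing // 2
    ref[miss[:half]] = np.nan
    alt[miss[half:]] = np.nan
    return pd.DataFrame({"ref_count": ref, "alt_count": alt})

def apply_cohort_exclusions(manifest: pd.DataFrame,
                            min_samples_per_type: int = 20,
                            min_mean_mutations: float = 250.0) -> tuple[pd.DataFrame, dict]:
    """Sequential tumor-manifest exclusions.

    1. hypermutated tumors (flag column ``hypermutated``);
    2. cancer types with fewer than ``min_samples_per_type`` samples;
    3. cancer types whose mean mutation burden is below
       ``min_mean_mutations``.

    Returns the retained manifest and a per-stage accounting dict.
    """
    acc = {"input": len(manifest)}
    m = manifest[~manifest["hypermutated"].astype(bool)]
    acc["hypermutated_removed"] = acc["input"] - len(m)
    sizes = m.groupby("cancer_type")["sample_id"].count()
    keep_types = sizes[sizes >= min_samples_per_type].index
    m2 = m[m["cancer_type"].isin(keep_types)]
    acc["rare_type_removed"] = len(m) - len(m2)
    means = m2.groupby("cancer_type")["n_mutations"].mean()
    keep_types = means[means >= min_mean_mutations].index
    m3 = m2[m2["cancer_type"].isin(keep_types)]
    acc["low_burden_type_removed"] = len(m2) - len(m3)
    acc["retained"] = len(m3)
    acc["retained_types"] = int(m3["cancer_type"].nunique())
    return m3, acc
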