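"""Single-molecule scanning of aligned read pairs.

Walks properly paired primary alignments, applies mapping/base-quality and
flanking-base rules, and tallies each single-base change class (pyrimidine
canonical form) and CC:GG>AA:TT doublets per genomic bin, together with the
evaluable-base denominators needed for single-molecule mutation frequencies
(SMMF).  Counts are kept separately by which mate of the pair observed the
pyrimidine of the reference base pair — the orientation axis on which the
oxidative-damage (8-oxo-dG) filter operates.

Two position-evaluability modes exist:

* ``tissue`` — a position is evaluable if at least one mate covers it with
  a passing base quality; positions covered by both mates count once per
  molecule, and a base-call disagreement between passing mates makes the
  position unevaluable.
* ``plasma`` — a position is evaluable only when both mates cover it with
  passing quality and the same base call (mate-overlap consensus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

from .genome import GenomicBin, MaskTrack, is_autosome

CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
ORIENTATIONS: tuple[str, str] = ("PYR_R1", "PYR_R2")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}
ORIENT_INDEX = {o: i for i, o in enumerate(ORIENTATIONS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = frozenset("CT")


def classify_change(ref: str, alt: str, read1_observes: str) -> tuple[str, str]:
    """Canonical (class, orientation) for a base-pair substitution.

    ``read1_observes`` says whether read 1 carried the purine or the
    pyrimidine of the reference base pair.  The class is reported with the
    pyrimidine as reference strand (G>T becomes C>A), and the orientation
    tag records which mate observed the pyrimidine.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if read1_observes not in ("purine", "pyrimidine"):
        raise ValueError(f"read1_observes must be purine|pyrimidine, got {read1_observes!r}")
    if ref in _PYRIMIDINES:
        cls = f"{ref}>{alt}"
    else:
        cls = f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    orientation = "PYR_R1" if read1_observes == "pyrimidine" else "PYR_R2"
    return cls, orientation


def smmf(y: float, x: float) -> float:
    """Sequence changes per million evaluable bases; NaN when x == 0."""
    if x == 0:
        return float("nan")
    return 1e6 * y / x


@dataclass
class QualityConfig:
    min_mapq: int = 40
    min_base_q: int = 30
    require_proper_pair: bool = True
    primary_only: bool = True
    adjacent_base_check: bool = True
    mode: str = "plasma"  # tissue|plasma
    # tissue-mode mate overlaps: count per molecule (True) or per read
    per_molecule_overlap: bool = True

    def __post_init__(self):
        if self.mode not in ("tissue", "plasma"):
            raise ValueError(f"mode must be tissue|plasma, got {self.mode!r}")
        if self.min_mapq < 0 or self.min_base_q < 0:
            raise ValueError("quality thresholds must be >= 0")


@dataclass(frozen=True)
class CandidateVariant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    orientation: str
    bin_index: int
    molecule_count: int = 1


@dataclass
class BinTallyMatrix:
    """Per-bin change counts and evaluable-base denominators for one sample.

    ``change_counts`` is [bin, class, orientation]; ``evaluable_CG`` and
    ``evaluable_TA`` are [bin, orientation]; doublets are orientation-blind
    vectors.  ``orientation_mask`` ([class, orientation] booleans) records
    which count/denominator combinations are still live after artifact
    filtering; masked combinations contribute to neither numerators nor
    denominators of frequencies.
    """

    sample_id: str
    bins: list[GenomicBin]
    change_counts: np.ndarray
    doublet_counts: np.ndarray
    evaluable_CG: np.ndarray
    evaluable_TA: np.ndarray
    evaluable_CC: np.ndarray
    orientation_mask: np.ndarray = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.bins)
        if self.orientation_mask is None:
            self.orientation_mask = np.ones((len(CLASSES), 2), dtype=bool)
        assert self.change_counts.shape == (n, len(CLASSES), 2)
        assert self.evaluable_CG.shape == (n, 2)
        if (self.change_counts < 0).any() or (self.evaluable_CG < 0).any():
            raise ValueError("negative tallies")

    @classmethod
    def zeros(cls, sample_id: str, bins: list[GenomicBin]) -> "BinTallyMatrix":
        n = len(bins)
        return cls(
            sample_id,
            bins,
            np.zeros((n, len(CLASSES), 2), dtype=np.int64),
            np.zeros(n, dtype=np.int64),
            np.zeros((n, 2), dtype=np.int64),
            np.zeros((n, 2), dtype=np.int64),
            np.zeros(n, dtype=np.int64),
        )

    # -- frequency access -------------------------------------------------
    def counts_for(self, mutation_type: str) -> np.ndarray:
        """Per-bin change counts summed over live orientations."""
        if mutation_type == "CC>AA":
            return self.doublet_counts.copy()
        ci = CLASS_INDEX[mutation_type]
        live = self.orientation_mask[ci]
        return self.change_counts[:, ci, :][:, live].sum(axis=1)

    def denominators_for(self, mutation_type: str) -> np.ndarray:
        """Per-bin evaluable bases for a class, over live orientations."""
        if mutation_type == "CC>AA":
            return self.evaluable_CC.copy()
        ci = CLASS_INDEX[mutation_type]
        live = self.orientation_mask[ci]
        denom = self.evaluable_CG if mutation_type.startswith("C") else self.evaluable_TA
        return denom[:, live].sum(axis=1)

    def genome_smmf(self, mutation_type: str) -> float:
        return smmf(
            self.counts_for(mutation_type).sum(),
            self.denominators_for(mutation_type).sum(),
        )

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "BinTallyMatrix") -> "BinTallyMatrix":
        if len(self.bins) != len(other.bins):
            raise ValueError("bin grids differ")
        if not np.array_equal(self.orientation_mask, other.orientation_mask):
            raise ValueError("orientation masks differ")
        return BinTallyMatrix(
            self.sample_id,
            self.bins,
            self.change_counts + other.change_counts,
            self.doublet_counts + other.doublet_counts,
            self.evaluable_CG + other.evaluable_CG,
            self.evaluable_TA + other.evaluable_TA,
            self.evaluable_CC + other.evaluable_CC,
            self.orientation_mask.copy(),
            dict(self.metadata),
        )

    def aggregate(self, coarse_bins: list[GenomicBin], index_map: np.ndarray) -> "BinTallyMatrix":
        """Sum tallies from fine bins into a coarse grid via a fine→coarse map."""
        if len(index_map) != len(self.bins):
            raise ValueError("index map length does not match fine bin count")
        keep = index_map >= 0
        tgt = index_map[keep]
        n = len(coarse_bins)

        def agg(a: np.ndarray) -> np.ndarray:
            out = np.zeros((n,) + a.shape[1:], dtype=a.dtype)
            np.add.at(out, tgt, a[keep])
            return out

        return BinTallyMatrix(
            self.sample_id,
            coarse_bins,
            agg(self.change_counts),
            agg(self.doublet_counts),
            agg(self.evaluable_CG),
            agg(self.evaluable_TA),
            agg(self.evaluable_CC),
            self.orientation_mask.copy(),
            dict(self.metadata),
        )

    # -- serialization ------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        cols = {
            "chrom": [b.chrom for b in self.bins],
            "start": [b.start for b in self.bins],
            "end": [b.end for b in self.bins],
        }
        for ci, c in enumerate(CLASSES):
            for oi, o in enumerate(ORIENTATIONS):
                cols[f"n[{c}|{o}]"] = self.change_counts[:, ci, oi]
        cols["n[CC>AA]"] = self.doublet_counts
        for oi, o in enumerate(ORIENTATIONS):
            cols[f"x[CG|{o}]"] = self.evaluable_CG[:, oi]
            cols[f"x[TA|{o}]"] = self.evaluable_TA[:, oi]
        cols["x[CC]"] = self.evaluable_CC
        meta = {
            "sample_id": self.sample_id,
            "orientation_mask": self.orientation_mask.tolist(),
            **self.metadata,
        }
        with open(path, "w") as fh:
            fh.write("#GEMINI_TALLY " + json.dumps(meta, default=str) + "\n")
            pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "BinTallyMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#GEMINI_TALLY "):
                raise ValueError(f"{path} is not a tally TSV")
            meta = json.loads(first[len("#GEMINI_TALLY "):])
            df = pd.read_csv(fh, sep="\t")
        bins = [
            GenomicBin(r.chrom, int(r.start), int(r.end), i)
            for i, r in enumerate(df.itertuples())
        ]
        n = len(bins)
        cc = np.zeros((n, len(CLASSES), 2), dtype=np.int64)
        for ci, c in enumerate(CLASSES):
            for oi, o in enumerate(ORIENTATIONS):
                cc[:, ci, oi] = df[f"n[{c}|{o}]"]
        ecg = np.stack([df[f"x[CG|{o}]"] for o in ORIENTATIONS], axis=1)
        eta = np.stack([df[f"x[TA|{o}]"] for o in ORIENTATIONS], axis=1)
        mask = np.asarray(meta.pop("orientation_mask"), dtype=bool)
        sample_id = meta.pop("sample_id")
        return cls(
            sample_id, bins, cc,
            df["n[CC>AA]"].to_numpy(np.int64),
            ecg.astype(np.int64), eta.astype(np.int64),
            df["x[CC]"].to_numpy(np.int64),
            mask, meta,
        )


class _BinLocator:
    """chrom,pos → bin index for a (per-chromosome contiguous) bin list."""

    def __init__(self, bins: list[GenomicBin]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int, int]]] = {}
        for b in bins:
            tmp.setdefault(b.chrom, []).append((b.start, b.end, b.index))
        for chrom, ivs in tmp.items():
            ivs.sort()
            s, e, i = (np.asarray(v) for v in zip(*ivs))
            self._by_chrom[chrom] = (s, e, i)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_chrom

    def locate(self, chrom: str, pos: int) -> int:
        if chrom not in self._by_chrom:
            return -1
        starts, ends, idx = self._by_chrom[chrom]
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k >= 0 and pos < ends[k]:
            return int(idx[k])
        return -1


def _mate_maps(read: pysam.AlignedSegment) -> dict[int, tuple[str, int]]:
    """Reference position → (base, qual) for aligned (non-indel) bases."""
    seq = read.query_sequence
    quals = read.query_qualities
    out = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        out[rpos] = (seq[qpos].upper(), quals[qpos])
    return out


def scan_alignments(
    alignments: str | pysam.AlignmentFile,
    reference: str,
    bins: list[GenomicBin],
    mask: MaskTrack | None = None,
    qc: QualityConfig | None = None,
    sample_id: str | None = None,
) -> tuple[BinTallyMatrix, list[CandidateVariant]]:
    """Tally single-base and doublet changes per bin from paired alignments.

    Returns the tally matrix and the list of candidate variants (one entry
    per distinct chrom/pos/ref/alt/orientation, with the number of
    supporting molecules).  Skip counters are recorded under
    ``metadata['scan_report']``.
    """
    qc = qc or QualityConfig()
    mask = mask or MaskTrack([])
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments
    fa = pysam.FastaFile(reference)
    locator = _BinLocator(bins)
    tally = BinTallyMatrix.zeros(sample_id or "sample", bins)
    candidates: dict[tuple[str, int, str, str, str], list[int]] = {}
    report = {
        "pairs_scanned": 0, "pairs_failed_filters": 0, "reads_seen": 0,
        "reads_off_grid": 0, "positions_masked": 0, "positions_non_acgt": 0,
    }

    pending: dict[str, pysam.AlignedSegment] = {}
    saw_on_grid_contig = False
    fa_refs = set(fa.references)
    for read in af:
        if read.is_unmapped or read.mate_is_unmapped:
            continue
        if qc.primary_only and (read.is_secondary or read.is_supplementary):
            continue
        report["reads_seen"] += 1
        chrom = read.reference_name
        if not is_autosome(chrom) or chrom not in locator:
            report["reads_off_grid"] += 1
            continue
        if chrom not in fa_refs:
            raise ValueError(
                f"contig {chrom!r} present in alignments but absent from reference FASTA"
            )
        saw_on_grid_contig = True
        key = read.query_name
        mate = pending.pop(key, None)
        if mate is None:
            pending[key] = read
            continue
        r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
        if qc.require_proper_pair and not (r1.is_proper_pair and r2.is_proper_pair):
            report["pairs_failed_filters"] += 1
            continue
        if r1.mapping_quality < qc.min_mapq or r2.mapping_quality < qc.min_mapq:
            report["pairs_failed_filters"] += 1
            continue
        if r1.reference_name != r2.reference_name:
            report["pairs_failed_filters"] += 1
            continue
        report["pairs_scanned"] += 1
        _scan_molecule(r1, r2, fa, locator, mask, qc, tally, candidates, report)

    if report["reads_seen"] and not saw_on_grid_contig:
        raise ValueError("no alignments overlap the bin grid (contig naming mismatch?)")
    tally.metadata["scan_report"] = report
    tally.metadata["mode"] = qc.mode
    tally.metadata["quality_config"] = asdict(qc)
    if own:
        af.close()
    fa.close()
    out = [
        CandidateVariant(c, p, r, a, o, locator.locate(c, p), n[0])
        for (c, p, r, a, o), n in sorted(candidates.items())
    ]
    return tally, out


def _scan_molecule(r1, r2, fa, locator, mask, qc, tally, candidates, report) -> None:
    chrom = r1.reference_name
    m1, m2 = _mate_maps(r1), _mate_maps(r2)
    positions = sorted(set(m1) | set(m2))
    if not positions:
        return
    lo, hi = positions[0], positions[-1] + 1
    try:
        refseq = fa.fetch(chrom, lo, hi).upper()
    except (KeyError, ValueError) as exc:
        raise ValueError(f"reference fetch failed for {chrom}:{lo}-{hi}") from exc

    def refbase(rpos: int) -> str:
        if rpos < lo or rpos >= hi:
            return "N"
        return refseq[rpos - lo]

    minq = qc.min_base_q

    def call(rpos: int) -> str | None:
        """Consensus base call at a position under the mode rule, or None."""
        b1 = m1.get(rpos)
        b2 = m2.get(rpos)
        p1 = b1 is not None and b1[1] >= minq
        p2 = b2 is not None and b2[1] >= minq
        if qc.mode == "plasma":
            if p1 and p2 and b1[0] == b2[0]:
                return b1[0]
            return None
        if p1 and p2:
            return b1[0] if b1[0] == b2[0] else None
        if p1:
            return b1[0]
        if p2:
            return b2[0]
        return None

    def orientation_index(ref: str) -> int:
        # which mate sequenced the pyrimidine of the reference base pair:
        # a forward-strand read observes the top (reference) strand base
        pyr_on_top = ref in _PYRIMIDINES
        pyr_on_read1 = pyr_on_top != r1.is_reverse
        return 0 if pyr_on_read1 else 1

    # first pass: per-position evaluability and calls
    evaluable: dict[int, tuple[str, str, int]] = {}  # rpos -> (ref, call, orient)
    for rpos in positions:
        ref = refbase(rpos)
        if ref not in _COMPLEMENT:
            report["positions_non_acgt"] += 1
            continue
        if mask.contains(chrom, rpos):
            report["positions_masked"] += 1
            continue
        b = locator.locate(chrom, rpos)
        if b < 0:
            continue
        c = call(rpos)
        if c is None or c not in _COMPLEMENT:
            continue
        evaluable[rpos] = (ref, c, orientation_index(ref))

    def flank_ok(rpos: int) -> bool:
        ref = refbase(rpos)
        if ref not in _COMPLEMENT:
            return False
        c = call(rpos)
        return c == ref

    # doublet pass: CC/GG dinucleotides, both positions evaluable
    doublet_members: set[int] = set()
    for rpos in positions:
        if rpos not in evaluable or (rpos + 1) not in evaluable:
            continue
        ref_l, call_l, _ = evaluable[rpos]
        ref_r, call_r, _ = evaluable[rpos + 1]
        dinuc = ref_l + ref_r
        if dinuc not in ("CC", "GG"):
            continue
        b = locator.locate(chrom, rpos)  # doublet assigned to its left base
        tally.evaluable_CC[b] += 1
        target = "AA" if dinuc == "CC" else "TT"
        if (
            call_l + call_r == target
            and (not qc.adjacent_base_check or (flank_ok(rpos - 1) and flank_ok(rpos + 2)))
        ):
            tally.doublet_counts[b] += 1
            doublet_members.update((rpos, rpos + 1))

    # single-base pass
    for rpos, (ref, c, oi) in evaluable.items():
        b = locator.locate(chrom, rpos)
        if ref in ("C", "G"):
            tally.evaluable_CG[b, oi] += 1
        else:
            tally.evaluable_TA[b, oi] += 1
        if c == ref or rpos in doublet_members:
            continue
        if qc.adjacent_base_check and not (flank_ok(rpos - 1) and flank_ok(rpos + 1)):
            continue
        read1_observes = "pyrimidine" if oi == 0 else "purine"
        cls, orient = classify_change(ref, c, read1_observes)
        tally.change_counts[b, CLASS_INDEX[cls], oi] += 1
        key = (chrom, rpos, ref, c, orient)
        if key in candidates:
            candidates[key][0] += 1
        else:
            candidates[key] = [1]


def tally_doublets(alignments, reference, bins, mask=None, qc=None) -> np.ndarray:
    """Per-bin CC:GG>AA:TT doublet counts (convenience wrapper over scan)."""
    tally, _ = scan_alignments(alignments, reference, bins, mask, qc)
    return tally.doublet_counts


def candidates_to_tsv(candidates: list[CandidateVariant], path: str) -> None:
    """Write candidates as a VCF-like TSV (1-based positions on export)."""
    df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in candidates],
            "pos": [c.pos + 1 for c in candidates],
            "ref": [c.ref for c in candidates],
            "alt": [c.alt for c in candidates],
            "orientation": [c.orientation for c in candidates],
            "bin_index": [c.bin_index for c in candidates],
            "molecules": [c.molecule_count for c in candidates],
        }
    )
    df.to_csv(path, sep="\t", index=False)
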