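"""Genome partitioning: builds, fixed-width bins, sliding windows, masks.

All coordinates are 0-based half-open internally.  BED interchange keeps
that convention; VCF interchange is 1-based and handled at the file
boundary only.  Partial trailing bins are dropped, never truncated, so a
bin's width is always exactly the requested width.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hg19 import HG19_AUTOSOME_LENGTHS

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")


def normalize_chrom(name: str, use_prefix: bool = True) -> str:
    """Normalize a chromosome name to the 'chr1'/'1' dialect requested.

    Accepts both prefixed and bare names; anything else is returned
    unchanged (sex/mito/alt contigs are never silently renamed away).
    """
    bare = name.removeprefix("chr")
    return f"chr{bare}" if use_prefix else bare


def is_autosome(name: str) -> bool:
    return _AUTOSOME_RE.match(name) is not None


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of (chromosome, length) pairs."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        for c, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {length}")

    @classmethod
    def hg19_autosomes(cls) -> "GenomeBuild":
        return cls("hg19", tuple(HG19_AUTOSOME_LENGTHS.items()))

    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def autosomes(self) -> "GenomeBuild":
        return GenomeBuild(
            self.name, tuple((c, l) for c, l in self.chromosomes if is_autosome(c))
        )

    def resolve(self, name: str) -> str:
        """Map an external chromosome name onto this build's dialect.

        Raises a ``KeyError`` listing the accepted dialects when the name
        matches no chromosome under either naming convention.
        """
        known = {c for c, _ in self.chromosomes}
        if name in known:
            return name
        for cand in (f"chr{name}", name.removeprefix("chr")):
            if cand in known:
                return cand
        raise KeyError(
            f"unknown chromosome {name!r}; accepted names are {sorted(known)} "
            "(the 'chr' prefix may be added or dropped)"
        )


@dataclass(frozen=True)
class GenomicBin:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    index: int  # genome-wide ordinal


def make_bins(build: GenomeBuild, width: int, scope: str = "autosomes") -> list[GenomicBin]:
    """Tile a build with non-overlapping fixed-width bins.

    Each chromosome contributes ``floor(length / width)`` bins of exactly
    ``width`` bp; the trailing remainder is discarded.  Genome-wide indices
    run in chromosome order.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if scope not in ("autosomes", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    chroms = build.autosomes().chromosomes if scope == "autosomes" else build.chromosomes
    bins: list[GenomicBin] = []
    idx = 0
    for chrom, length in chroms:
        for k in range(length // width):
            bins.append(GenomicBin(chrom, k * width, (k + 1) * width, idx))
            idx += 1
    return bins


def aggregate_bins(fine: list[GenomicBin], factor: int) -> tuple[list[GenomicBin], np.ndarray]:
    """Group consecutive same-chromosome fine bins into coarse bins.

    Returns the coarse bin list and a fine→coarse index map (``-1`` for
    fine bins in dropped incomplete trailing groups) used to aggregate
    tally matrices.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    widths = {b.end - b.start for b in fine}
    if len(widths) > 1:
        raise ValueError(f"fine bins are not uniform width: {sorted(widths)}")
    index_map = np.full(len(fine), -1, dtype=np.int64)
    coarse: list[GenomicBin] = []
    i = 0
    while i < len(fine):
        group = fine[i : i + factor]
        if len(group) == factor and all(
            g.chrom == group[0].chrom and g.start == group[0].start + j * (g.end - g.start)
            for j, g in enumerate(group)
        ):
            ci = len(coarse)
            coarse.append(GenomicBin(group[0].chrom, group[0].start, group[-1].end, ci))
            index_map[i : i + factor] = ci
            i += factor
        else:
            # chromosome break inside the group: restart at the break
            brk = next(
                (j for j in range(1, len(group)) if group[j].chrom != group[0].chrom),
                len(group),
            )
            i += brk
    return coarse, index_map


def sliding_windows(build: GenomeBuild, width: int, step: int, scope: str = "autosomes") -> list[GenomicBin]:
    """Overlapping windows starting at multiples of ``step``.

    Windows extending past the chromosome end are dropped.
    """
    if step > width:
        raise ValueError("step must not exceed width")
    if step <= 0:
        raise ValueError("step must be positive")
    chroms = build.autosomes().chromosomes if scope == "autosomes" else build.chromosomes
    out: list[GenomicBin] = []
    idx = 0
    for chrom, length in chroms:
        start = 0
        while start + width <= length:
            out.append(GenomicBin(chrom, start, start + width, idx))
            idx += 1
            start += step
    return out


@dataclass
class MaskTrack:
    """Sorted, merged half-open intervals to exclude from scanning."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = self._normalize(self.intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, start, end in self.intervals:
            self._by_chrom.setdefault(chrom, ([], []))  # type: ignore[arg-type]
        tmp: dict[str, list[list[int]]] = {}
        for chrom, start, end in self.intervals:
            tmp.setdefault(chrom, [[], []])
            tmp[chrom][0].append(start)
            tmp[chrom][1].append(end)
        self._by_chrom = {
            c: (np.asarray(s), np.asarray(e)) for c, (s, e) in tmp.items()
        }

    @staticmethod
    def _normalize(intervals):
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(intervals):
            if end <= start:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged.pop()
                merged.append((chrom, prev[1], max(prev[2], end)))
            else:
                merged.append((chrom, start, end))
        return merged

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._by_chrom:
            return 0
        starts, ends = self._by_chrom[chrom]
        lo = np.maximum(starts, start)
        hi = np.minimum(ends, end)
        return int(np.clip(hi - lo, 0, None).sum())

    @classmethod
    def from_bed(cls, path: str) -> "MaskTrack":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivs.append((chrom, int(start), int(end)))
        return cls(ivs)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def mask_coverage(bins: list[GenomicBin], mask: MaskTrack) -> np.ndarray:
    """bp of each bin covered by the mask (vector aligned to bin index)."""
    out = np.zeros(len(bins), dtype=np.int64)
    for b in bins:
        out[b.index] = mask.overlap_bp(b.chrom, b.start, b.end)
    return out


def bins_to_frame(bins: list[GenomicBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "index": [b.index for b in bins],
        }
    )


def bins_to_bed(bins: list[GenomicBin], path: str) -> None:
    bins_to_frame(bins)[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def bins_from_frame(df: pd.DataFrame) -> list[GenomicBin]:
    return [
        GenomicBin(r.chrom, int(r.start), int(r.end), int(r.index))
        for r in df.itertuples()
    ]
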