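"""Shared fixtures: toy builds, hand-written SAM helpers, random fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from gemini.genome import GenomeBuild, GenomicBin, MaskTrack, make_bins
from gemini.simulate import PlannedVariant, random_genome, simulate_reads, write_fasta


@pytest.fixture(scope="session")
def hg19():
    return GenomeBuild.hg19_autosomes()


@pytest.fixture(scope="session")
def hg19_bins_2p5mb(hg19):
    return make_bins(hg19, 2_500_000)


def toy_bins(n: int, width: int = 1000, chrom: str = "chr1") -> list[GenomicBin]:
    return [GenomicBin(chrom, i * width, (i + 1) * width, i) for i in range(n)]


# --------------------------------------------------------------------------
# Hand-written SAM fixtures for rule-level scanner tests
# --------------------------------------------------------------------------

FLAG_R1_FWD = 0x1 | 0x2 | 0x20 | 0x40  # 99
FLAG_R2_REV = 0x1 | 0x2 | 0x10 | 0x80  # 147
FLAG_R1_REV = 0x1 | 0x2 | 0x10 | 0x40  # 83
FLAG_R2_FWD = 0x1 | 0x2 | 0x20 | 0x80  # 163


def write_sam(path, lengths: dict[str, int], rows: list[dict]) -> str:
    """rows: qname, flag, chrom, pos (0-based), mapq, seq, qual (int list)."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for c, n in lengths.items():
        lines.append(f"@SQ\tSN:{c}\tLN:{n}")
    for r in sorted(rows, key=lambda r: (r["chrom"], r["pos"])):
        qual = "".join(chr(q + 33) for q in r["qual"])
        lines.append(
            "\t".join(
                [
                    r["qname"], str(r["flag"]), r["chrom"], str(r["pos"] + 1),
                    str(r["mapq"]), f"{len(r['seq'])}M", "=", "1", "0",
                    r["seq"], qual,
                ]
            )
        )
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def overlapping_pair(qname, chrom, pos, seq1, qual1, seq2=None, qual2=None,
                     mapq=60, r1_forward=True):
    """A fully overlapping FR read pair covering [pos, pos+len(seq1))."""
    seq2 = seq2 if seq2 is not None else seq1
    qual2 = qual2 if qual2 is not None else qual1
    f1 = FLAG_R1_FWD if r1_forward else FLAG_R1_REV
    f2 = FLAG_R2_REV if r1_forward else FLAG_R2_FWD
    return [
        {"qname": qname, "flag": f1, "chrom": chrom, "pos": pos, "mapq": mapq,
         "seq": seq1, "qual": list(qual1)},
        {"qname": qname, "flag": f2, "chrom": chrom, "pos": pos, "mapq": mapq,
         "seq": seq2, "qual": list(qual2)},
    ]


@pytest.fixture
def simple_reference(tmp_path):
    """A fixed 80 bp reference with known C, G and CC sites."""
    #          0         1         2         3         4         5         6         7
    #          0123456789012345678901234567890123456789012345678901234567890123456789
    seq = "ATGATCAGTAAGTGACGATATAGTGAACCGTTAGATAGGTACAGTCATGATTGATAGTCAGATAGCATGATAGCATGATA"
    path = tmp_path / "ref.fa"
    write_fasta({"chr1": seq}, str(path))
    return str(path), {"chr1": seq}


# --------------------------------------------------------------------------
# Randomized read-level fixtures for oracle-equivalence tests
# --------------------------------------------------------------------------

def make_random_fixture(tmp_path, seed: int):
    """A randomized small fixture exercising every scanner rule.

    Random genome (4–12 kb), random planted events of every kind with
    quality values straddling the Phred-30 threshold, per-read sequencing
    errors, occasional low-MAPQ files and random masks.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(4_000, 12_001))
    genome = random_genome({"chr1": length}, seed=seed)
    seq = genome["chr1"]
    plan = []
    alt_for = {"A": "G", "C": "A", "G": "T", "T": "C"}
    for k in range(int(rng.integers(3, 9))):
        pos = int(rng.integers(10, length - 10))
        ref = seq[pos]
        kind = str(rng.choice(["somatic", "germline", "oxog", "doublet"]))
        phred = int(rng.choice([20, 29, 30, 35, 40]))
        frac = float(rng.uniform(0.05, 1.0))
        if kind == "oxog":
            gpos = seq.find("G", pos)
            if gpos < 0 or gpos >= length - 5:
                continue
            plan.append(PlannedVariant("chr1", gpos, "T", frac, "oxog", phred))
        elif kind == "doublet":
            cpos = seq.find("CC", pos)
            if cpos < 0 or cpos >= length - 5:
                continue
            plan.append(PlannedVariant("chr1", cpos, "AA", frac, "doublet", phred))
        else:
            plan.append(PlannedVariant("chr1", pos, alt_for[ref], frac, kind, phred))
    mapq = int(rng.choice([39, 60], p=[0.15, 0.85]))
    base_q = int(rng.choice([29, 35, 40], p=[0.1, 0.6, 0.3]))
    paths = simulate_reads(
        genome, plan, n_pairs=int(rng.integers(80, 200)),
        out_prefix=str(tmp_path / f"rand{seed}"), seed=seed + 1,
        base_q=base_q, mapq=mapq,
        error_rate=float(rng.choice([0.0, 0.005, 0.02])),
    )
    mask_ivs = []
    if rng.random() < 0.5:
        s = int(rng.integers(0, length - 500))
        mask_ivs.append(("chr1", s, s + int(rng.integers(100, 500))))
    return paths, genome, mask_ivs


def assert_scan_matches_oracle(tally, oracle_result, bin_width):
    """Compare a BinTallyMatrix with the naive recount dictionaries."""
    from gemini.scan import CLASSES, ORIENTATIONS

    bykey = {}
    for b in tally.bins:
        bykey[(b.chrom, b.start // bin_width)] = b.index
    o = oracle_result
    for key, bi in bykey.items():
        for ci, cls in enumerate(CLASSES):
            for oi, pyr_r1 in ((0, True), (1, False)):
                assert tally.change_counts[bi, ci, oi] == o["changes"].get(
                    (key, cls, pyr_r1), 0
                ), (key, cls, pyr_r1)
        for oi, pyr_r1 in ((0, True), (1, False)):
            assert tally.evaluable_CG[bi, oi] == o["eval_cg"].get((key, pyr_r1), 0)
            assert tally.evaluable_TA[bi, oi] == o["eval_ta"].get((key, pyr_r1), 0)
        assert tally.doublet_counts[bi] == o["doublets"].get(key, 0)
        assert tally.evaluable_CC[bi] == o["eval_cc"].get(key, 0)
    # nothing outside the emitted bins
    for (key, cls, pyr), v in o["changes"].items():
        assert key in bykey or v == 0
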