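"""Independent naive oracles used to cross-check the implementation.

These are deliberately simple, position-by-position re-implementations
written directly from the stated counting rules, sharing no code with the
package's scanner or statistics: SAM records are parsed from text and
CIGAR strings walked by hand, AUC is counted over all case/control pairs,
and the DeLong variance is assembled from its structural components with
explicit loops.
"""

from __future__ import annotations

import itertools
import math


# --------------------------------------------------------------------------
# Naive pileup recount
# --------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def read_fasta_text(path):
    seqs, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name:
        seqs[name] = "".join(chunks)
    return seqs


def _parse_sam(path):
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            reads.append(
                {
                    "qname": f[0],
                    "flag": int(f[1]),
                    "chrom": f[2],
                    "pos": int(f[3]) - 1,
                    "mapq": int(f[4]),
                    "cigar": f[5],
                    "seq": f[9].upper(),
                    "qual": [ord(c) - 33 for c in f[10]],
                }
            )
    return reads


def _aligned_map(read):
    """reference pos -> (base, qual), walking the CIGAR by hand."""
    out = {}
    rpos, qpos = read["pos"], 0
    num = ""
    for ch in read["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "M=X":
            for k in range(n):
                out[rpos + k] = (read["seq"][qpos + k], read["qual"][qpos + k])
            rpos += n
            qpos += n
        elif ch in "IS":
            qpos += n
        elif ch in "DN":
            rpos += n
        elif ch in "HP":
            pass
        else:
            raise ValueError(f"oracle cannot handle CIGAR op {ch}")
    return out


def naive_recount(
    sam_path,
    fasta_path,
    bin_width,
    mode,
    mask_intervals=(),
    min_mapq=40,
    min_q=30,
):
    """Brute-force recount of per-bin tallies from first principles.

    Returns dicts keyed by (chrom, bin_ordinal): ``changes`` maps to
    {(class, pyr_on_read1): count}, plus ``eval_cg``/``eval_ta`` keyed by
    pyr_on_read1, ``doublets`` and ``eval_cc`` scalars.
    """
    genome = read_fasta_text(fasta_path)
    pairs = {}
    for r in _parse_sam(sam_path):
        if r["flag"] & (0x100 | 0x800 | 0x4 | 0x8):
            continue
        pairs.setdefault(r["qname"], []).append(r)

    changes, eval_cg, eval_ta, doublets, eval_cc = {}, {}, {}, {}, {}

    def bump(d, key, amt=1):
        d[key] = d.get(key, 0) + amt

    for qname, rs in pairs.items():
        if len(rs) != 2:
            continue
        r1 = next(r for r in rs if r["flag"] & 0x40)
        r2 = next(r for r in rs if r["flag"] & 0x80)
        if not (r1["flag"] & 0x2 and r2["flag"] & 0x2):
            continue
        if r1["mapq"] < min_mapq or r2["mapq"] < min_mapq:
            continue
        if r1["chrom"] != r2["chrom"] or r1["chrom"] not in genome:
            continue
        chrom = r1["chrom"]
        seq = genome[chrom]
        n_bins = len(seq) // bin_width
        m1, m2 = _aligned_map(r1), _aligned_map(r2)
        r1_reverse = bool(r1["flag"] & 0x10)

        def consensus(p):
            b1, b2 = m1.get(p), m2.get(p)
            ok1 = b1 is not None and b1[1] >= min_q
            ok2 = b2 is not None and b2[1] >= min_q
            if mode == "plasma":
                if ok1 and ok2 and b1[0] == b2[0]:
                    return b1[0]
                return None
            if ok1 and ok2:
                return b1[0] if b1[0] == b2[0] else None
            if ok1:
                return b1[0]
            if ok2:
                return b2[0]
            return None

        def masked(p):
            return any(s <= p < e for c, s, e in mask_intervals if c == chrom)

        def flank_ok(p):
            if p < 0 or p >= len(seq) or seq[p] not in _COMP:
                return False
            return consensus(p) == seq[p]

        usable = {}
        for p in sorted(set(m1) | set(m2)):
            if p >= n_bins * bin_width or seq[p] not in _COMP or masked(p):
                continue
            call = consensus(p)
            if call is None or call not in _COMP:
                continue
            usable[p] = call

        in_doublet = set()
        for p, call in usable.items():
            if p + 1 not in usable:
                continue
            dinuc = seq[p] + seq[p + 1]
            if dinuc not in ("CC", "GG"):
                continue
            key = (chrom, p // bin_width)
            bump(eval_cc, key)
            target = "AA" if dinuc == "CC" else "TT"
            if (call + usable[p + 1]) == target and flank_ok(p - 1) and flank_ok(p + 2):
                bump(doublets, key)
                in_doublet.update((p, p + 1))

        for p, call in usable.items():
            ref = seq[p]
            pyr_on_read1 = (ref in "CT") != r1_reverse
            key = (chrom, p // bin_width)
            if ref in "CG":
                bump(eval_cg, (key, pyr_on_read1))
            else:
                bump(eval_ta, (key, pyr_on_read1))
            if call == ref or p in in_doublet:
                continue
            if not (flank_ok(p - 1) and flank_ok(p + 1)):
                continue
            if ref in "CT":
                cls = f"{ref}>{call}"
            else:
                cls = f"{_COMP[ref]}>{_COMP[call]}"
            bump(changes, (key, cls, pyr_on_read1))

    return {
        "changes": changes,
        "eval_cg": eval_cg,
        "eval_ta": eval_ta,
        "doublets": doublets,
        "eval_cc": eval_cc,
    }


# --------------------------------------------------------------------------
# Brute-force AUC and DeLong components
# --------------------------------------------------------------------------

def pairwise_auc(scores, labels):
    """AUC by exhaustive case/control pair counting (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def delong_variance_reference(scores, labels):
    """DeLong AUC variance from explicitly looped structural components."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    m, n = len(pos), len(neg)

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    v10 = [sum(psi(p, q) for q in neg) / n for p in pos]
    v01 = [sum(psi(p, q) for p in pos) / m for q in neg]
    auc = sum(v10) / m

    def var(vs, mean):
        return sum((v - mean) ** 2 for v in vs) / (len(vs) - 1)

    return auc, var(v10, auc) / m + var(v01, auc) / n


def pcoa_reference(D):
    """Classical MDS via explicit double centering (independent route)."""
    import numpy as np

    D = np.asarray(D, float)
    n = len(D)
    B = np.empty((n, n))
    row = (D ** 2).mean(axis=1)
    grand = (D ** 2).mean()
    for i in range(n):
        for j in range(n):
            B[i, j] = -0.5 * (D[i, j] ** 2 - row[i] - row[j] + grand)
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1]
    w, v = w[idx], v[:, idx]
    keep = w > 1e-9 * max(1.0, abs(w[0]))
    return v[:, keep] * np.sqrt(w[keep]), w[keep]


def hypergeom_mean_var(ngood, nbad, nsample):
    N = ngood + nbad
    mean = nsample * ngood / N
    var = nsample * (ngood / N) * (nbad / N) * (N - nsample) / (N - 1)
    return mean, var
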