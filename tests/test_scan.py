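"""Molecule scanner: classification, quality rules, doublets, invariants."""

import numpy as np
import pytest

from conftest import (
    assert_scan_matches_oracle,
    make_random_fixture,
    overlapping_pair,
    write_sam,
)
from oracle import naive_recount

from gemini.genome import GenomeBuild, MaskTrack, make_bins
from gemini.scan import (
    BinTallyMatrix,
    CLASS_INDEX,
    QualityConfig,
    classify_change,
    scan_alignments,
    smmf,
    tally_doublets,
)


@pytest.mark.parametrize(
    "ref,alt,read1_observes,expected",
    [
        ("G", "T", "purine", ("C>A", "PYR_R2")),
        ("A", "G", "pyrimidine", ("T>C", "PYR_R1")),
        ("C", "A", "pyrimidine", ("C>A", "PYR_R1")),
        ("T", "G", "purine", ("T>G", "PYR_R2")),
        ("G", "C", "pyrimidine", ("C>G", "PYR_R1")),
    ],
)
def test_classify_change_canonical_form(ref, alt, read1_observes, expected):
    assert classify_change(ref, alt, read1_observes) == expected


def test_classify_change_rejects_bad_input():
    with pytest.raises(ValueError):
        classify_change("C", "C", "purine")
    with pytest.raises(ValueError):
        classify_change("N", "A", "purine")


@pytest.mark.parametrize("y,x,expected", [(5, 1_000_000, 5.0), (0, 7, 0.0), (13, 2_600_000, 5.0)])
def test_smmf_per_million(y, x, expected):
    assert smmf(y, x) == pytest.approx(expected, abs=0)


def test_smmf_zero_denominator_is_nan_not_zero():
    assert np.isnan(smmf(3, 0))


def _toy_bins(length=80, width=40):
    build = GenomeBuild("toy", (("chr1", length),))
    return make_bins(build, width, scope="all")


class TestScannerRules:
    """Hand-written read pairs exercising each stated counting rule."""

    def scan(self, tmp_path, ref_fa, rows, mode="plasma", mask=None, lengths=None):
        sam = write_sam(tmp_path / "t.sam", lengths or {"chr1": 80}, rows)
        return scan_alignments(
            sam, ref_fa, _toy_bins(), mask or MaskTrack([]), QualityConfig(mode=mode)
        )

    def test_concordant_overlap_tallies_one_change(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("G", 5)  # a G with non-G neighbors in this reference
        read = seq[2:42][: p - 2] + "T" + seq[2:42][p - 1 :]
        rows = overlapping_pair("m1", "chr1", 2, read, [35] * 40)
        tally, cands = self.scan(tmp_path, ref_fa, rows)
        assert tally.change_counts[:, CLASS_INDEX["C>A"], :].sum() == 1
        # ref G observed on forward read1 => read1 saw the purine => PYR_R2
        assert tally.change_counts[0, CLASS_INDEX["C>A"], 1] == 1
        assert len(cands) == 1 and cands[0].pos == p and cands[0].orientation == "PYR_R2"
        # the changed position itself still counts as evaluable C:G
        assert tally.evaluable_CG[:, 1].sum() >= 1

    def test_low_phred_on_one_mate_blocks_plasma_not_tissue(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("G", 5)
        read = seq[2:42][: p - 2] + "T" + seq[2:42][p - 1 :]
        q1 = [35] * 40
        q2 = [35] * 40
        q2[p - 2] = 29
        rows = overlapping_pair("m1", "chr1", 2, read, q1, read, q2)
        plasma, _ = self.scan(tmp_path, ref_fa, rows, mode="plasma")
        tissue, _ = self.scan(tmp_path, ref_fa, rows, mode="tissue")
        assert plasma.change_counts.sum() == 0
        assert tissue.change_counts[:, CLASS_INDEX["C>A"], :].sum() == 1

    def test_low_mapq_pair_skipped_entirely(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        rows = overlapping_pair("m1", "chr1", 2, seq[2:42], [35] * 40, mapq=39)
        tally, cands = self.scan(tmp_path, ref_fa, rows)
        assert tally.change_counts.sum() == 0
        assert tally.evaluable_CG.sum() == 0 and tally.evaluable_TA.sum() == 0

    def test_mate_disagreement_not_evaluable(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("G", 5)
        alt = seq[2:42][: p - 2] + "T" + seq[2:42][p - 1 :]
        rows = overlapping_pair("m1", "chr1", 2, alt, [35] * 40, seq[2:42], [35] * 40)
        for mode in ("plasma", "tissue"):
            tally, _ = self.scan(tmp_path, ref_fa, rows, mode=mode)
            assert tally.change_counts.sum() == 0
            # the disputed position is not evaluable in either mode
            covered = tally.evaluable_CG.sum() + tally.evaluable_TA.sum()
            assert covered == 39

    def test_flank_mismatch_suppresses_change(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("G", 5)
        # mutate the change and its left neighbor: neither counts as a SBS
        alt = list(seq[2:42])
        alt[p - 2] = "T"
        alt[p - 3] = "C" if seq[p - 1] != "C" else "A"
        rows = overlapping_pair("m1", "chr1", 2, "".join(alt), [35] * 40)
        tally, _ = self.scan(tmp_path, ref_fa, rows)
        assert tally.change_counts.sum() == 0

    def test_masked_position_never_tallied(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("G", 5)
        read = seq[2:42][: p - 2] + "T" + seq[2:42][p - 1 :]
        rows = overlapping_pair("m1", "chr1", 2, read, [35] * 40)
        mask = MaskTrack([("chr1", p, p + 1)])
        tally, cands = self.scan(tmp_path, ref_fa, rows, mask=mask)
        assert tally.change_counts.sum() == 0
        assert not cands

    def test_doublet_counted_once_not_as_two_sbs(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("CC")
        assert seq[p - 1] != "C" and seq[p + 2] != "C"
        alt = seq[2:42][: p - 2] + "AA" + seq[2:42][p :]
        rows = overlapping_pair("m1", "chr1", 2, alt, [35] * 40)
        tally, _ = self.scan(tmp_path, ref_fa, rows)
        assert tally.doublet_counts.sum() == 1
        assert tally.change_counts.sum() == 0
        assert tally.evaluable_CC.sum() >= 1

    def test_half_mutated_cc_is_no_doublet_but_valid_sbs(self, tmp_path, simple_reference):
        # only one C of a CC dinucleotide mutated: no doublet, and the
        # single change passes the flank rule because the untouched C
        # still matches the reference
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("CC")
        alt = seq[2:42][: p - 2] + "A" + seq[2:42][p - 1 :]
        rows = overlapping_pair("m1", "chr1", 2, alt, [35] * 40)
        tally, _ = self.scan(tmp_path, ref_fa, rows)
        assert tally.doublet_counts.sum() == 0
        assert tally.change_counts[:, CLASS_INDEX["C>A"], :].sum() == 1

    def test_tally_doublets_wrapper(self, tmp_path, simple_reference):
        ref_fa, genome = simple_reference
        seq = genome["chr1"]
        p = seq.index("CC")
        alt = seq[2:42][: p - 2] + "AA" + seq[2:42][p :]
        sam = write_sam(tmp_path / "d.sam", {"chr1": 80},
                        overlapping_pair("m1", "chr1", 2, alt, [35] * 40))
        d = tally_doublets(sam, ref_fa, _toy_bins())
        assert d.sum() == 1


class TestScannerInvariants:
    @pytest.mark.parametrize("seed", [11, 12])
    def test_oracle_equivalence_on_random_fixture(self, tmp_path, seed):
        paths, genome, mask_ivs = make_random_fixture(tmp_path, seed)
        build = GenomeBuild("toy", (("chr1", len(genome["chr1"])),))
        bins = make_bins(build, 1000, scope="all")
        for mode in ("plasma", "tissue"):
            tally, _ = scan_alignments(
                paths["sam"], paths["fasta"], bins, MaskTrack(list(mask_ivs)),
                QualityConfig(mode=mode),
            )
            oracle = naive_recount(paths["sam"], paths["fasta"], 1000, mode, mask_ivs)
            assert_scan_matches_oracle(tally, oracle, 1000)

    def test_additivity_over_disjoint_read_subsets(self, tmp_path):
        paths, genome, _ = make_random_fixture(tmp_path, 77)
        build = GenomeBuild("toy", (("chr1", len(genome["chr1"])),))
        bins = make_bins(build, 1000, scope="all")
        with open(paths["sam"]) as fh:
            lines = fh.readlines()
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        mols = sorted({l.split("\t")[0] for l in body})
        parts = []
        for r in (0, 1):
            keep = {m for i, m in enumerate(mols) if i % 2 == r}
            p = tmp_path / f"part{r}.sam"
            with open(p, "w") as fh:
                fh.writelines(header + [l for l in body if l.split("\t")[0] in keep])
            parts.append(str(p))
        whole, _ = scan_alignments(paths["sam"], paths["fasta"], bins)
        t0, _ = scan_alignments(parts[0], paths["fasta"], bins)
        t1, _ = scan_alignments(parts[1], paths["fasta"], bins)
        summed = t0 + t1
        assert np.array_equal(summed.change_counts, whole.change_counts)
        assert np.array_equal(summed.evaluable_CG, whole.evaluable_CG)
        assert np.array_equal(summed.doublet_counts, whole.doublet_counts)

    def test_plasma_evaluable_never_exceeds_tissue(self, tmp_path):
        paths, genome, _ = make_random_fixture(tmp_path, 42)
        build = GenomeBuild("toy", (("chr1", len(genome["chr1"])),))
        bins = make_bins(build, 1000, scope="all")
        pl, _ = scan_alignments(paths["sam"], paths["fasta"], bins,
                                qc=QualityConfig(mode="plasma"))
        ti, _ = scan_alignments(paths["sam"], paths["fasta"], bins,
                                qc=QualityConfig(mode="tissue"))
        assert (pl.evaluable_CG <= ti.evaluable_CG).all()
        assert (pl.evaluable_TA <= ti.evaluable_TA).all()

    def test_candidates_avoid_mask_and_match_counts(self, tmp_path):
        paths, genome, _ = make_random_fixture(tmp_path, 13)
        length = len(genome["chr1"])
        mask = MaskTrack([("chr1", 0, length // 3)])
        build = GenomeBuild("toy", (("chr1", length),))
        bins = make_bins(build, 1000, scope="all")
        tally, cands = scan_alignments(paths["sam"], paths["fasta"], bins, mask)
        for c in cands:
            assert not mask.contains(c.chrom, c.pos)
        assert sum(c.molecule_count for c in cands) == tally.change_counts.sum()

    def test_grid_mismatch_raises(self, tmp_path):
        paths, genome, _ = make_random_fixture(tmp_path, 5)
        build = GenomeBuild("toy", (("chr9", 5_000),))
        bins = make_bins(build, 1000, scope="all")
        with pytest.raises(ValueError, match="bin grid|overlap"):
            scan_alignments(paths["sam"], paths["fasta"], bins)


class TestTallySerialization:
    def test_tsv_round_trip(self, tmp_path):
        paths, genome, _ = make_random_fixture(tmp_path, 21)
        build = GenomeBuild("toy", (("chr1", len(genome["chr1"])),))
        bins = make_bins(build, 1000, scope="all")
        tally, _ = scan_alignments(paths["sam"], paths["fasta"], bins)
        p = tmp_path / "tally.tsv"
        tally.to_tsv(str(p))
        back = BinTallyMatrix.from_tsv(str(p))
        assert np.array_equal(back.change_counts, tally.change_counts)
        assert np.array_equal(back.evaluable_CG, tally.evaluable_CG)
        assert np.array_equal(back.evaluable_CC, tally.evaluable_CC)
        assert back.sample_id == tally.sample_id

    def test_aggregation_preserves_totals(self, tmp_path):
        paths, genome, _ = make_random_fixture(tmp_path, 22)
        build = GenomeBuild("toy", (("chr1", len(genome["chr1"])),))
        bins = make_bins(build, 1000, scope="all")
        tally, _ = scan_alignments(paths["sam"], paths["fasta"], bins)
        from gemini.genome import aggregate_bins

        coarse_bins, imap = aggregate_bins(bins, 2)
        coarse = tally.aggregate(coarse_bins, imap)
        kept = imap >= 0
        assert coarse.change_counts.sum() == tally.change_counts[kept].sum()
        assert coarse.evaluable_CG.sum() == tally.evaluable_CG[kept].sum()
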