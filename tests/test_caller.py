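import numpy as np
import pytest

from gbskaryo.caller import (
    DosageSegment,
    classify_chromosome,
    locus_dosage,
    read_segments,
    write_segments,
)
from gbskaryo.genome import Chromosome, Locus

# one 40 Mb chromosome, centromere at 18 Mb; 1 Mb grid -> arm boundary 19 Mb
CHROM = Chromosome("4B", "B", 40_000_000, 18_000_000)
WIDTH = 1_000_000
BOUNDARY = 19_000_000


def seg(start, end, cn, log2=None, sample="p1", chrom="4B"):
    mean = log2 if log2 is not None else float(np.log2(cn / 2)) if cn else -5.0
    return DosageSegment(sample, chrom, start, end, mean, cn,
                         (end - start) // WIDTH)


class TestClassifyChromosome:
    def test_disomic_emits_nothing(self):
        events, (cn_s, cn_l) = classify_chromosome(
            [seg(0, 40_000_000, 2, 0.0)], CHROM, WIDTH
        )
        assert events == []
        assert (cn_s, cn_l) == (2, 2)

    @pytest.mark.parametrize("cn,label", [(0, "nullisomic"), (1, "monosomic"),
                                          (3, "trisomic"), (4, "tetrasomic")])
    def test_whole_chromosome_states(self, cn, label):
        events, arms = classify_chromosome([seg(0, 40_000_000, cn)], CHROM, WIDTH)
        assert [e.label for e in events] == [label]
        assert arms == (cn, cn)

    def test_lost_long_arm_is_ditelosomic_short(self):
        """Retained S arm at CN2, L arm at CN0: a Dt-S karyotype."""
        events, arms = classify_chromosome(
            [seg(0, BOUNDARY, 2, 0.0), seg(BOUNDARY, 40_000_000, 0)], CHROM, WIDTH
        )
        assert [e.label for e in events] == ["ditelosomic:S"]
        assert arms == (2, 0)
        assert events[0].start == BOUNDARY  # the lost interval

    @pytest.mark.parametrize(
        "cn_s,cn_l,label",
        [(1, 0, "monotelosomic:S"), (0, 1, "monotelosomic:L"),
         (2, 1, "monotelosomic:S"), (1, 2, "monotelosomic:L"),
         (0, 2, "ditelosomic:L")],
    )
    def test_telosomic_vocabulary(self, cn_s, cn_l, label):
        events, arms = classify_chromosome(
            [seg(0, BOUNDARY, cn_s), seg(BOUNDARY, 40_000_000, cn_l)], CHROM, WIDTH
        )
        assert [e.label for e in events] == [label]
        assert arms == (cn_s, cn_l)

    def test_terminal_deletion_on_long_arm(self):
        """CN2 chromosome with a distal CN1 segment: terminal deletion on L."""
        events, arms = classify_chromosome(
            [seg(0, 34_000_000, 2, 0.0), seg(34_000_000, 40_000_000, 1)],
            CHROM, WIDTH,
        )
        assert [e.label for e in events] == ["terminal_deletion:L"]
        assert arms == (2, 2)

    def test_terminal_deletion_on_short_arm(self):
        events, _ = classify_chromosome(
            [seg(0, 4_000_000, 0), seg(4_000_000, 40_000_000, 2, 0.0)],
            CHROM, WIDTH,
        )
        assert [e.label for e in events] == ["terminal_deletion:S"]

    def test_pericentric_deletion_spans_centromere(self):
        events, _ = classify_chromosome(
            [seg(0, 15_000_000, 2, 0.0), seg(15_000_000, 22_000_000, 1),
             seg(22_000_000, 40_000_000, 2, 0.0)],
            CHROM, WIDTH,
        )
        assert [e.label for e in events] == ["pericentric_deletion"]

    def test_deletion_abutting_centromere_bin_is_pericentric(self):
        # centromere bin is [18, 19) Mb; a deletion ending at 18 Mb abuts it
        events, _ = classify_chromosome(
            [seg(0, 12_000_000, 2, 0.0), seg(12_000_000, 18_000_000, 1),
             seg(18_000_000, 40_000_000, 2, 0.0)],
            CHROM, WIDTH,
        )
        assert [e.label for e in events] == ["pericentric_deletion"]

    def test_interstitial_deletion(self):
        events, _ = classify_chromosome(
            [seg(0, 25_000_000, 2, 0.0), seg(25_000_000, 30_000_000, 0),
             seg(30_000_000, 40_000_000, 2, 0.0)],
            CHROM, WIDTH,
        )
        assert [e.label for e in events] == ["interstitial_deletion"]

    def test_deletion_within_lost_arm_not_double_counted(self):
        """Within a CN0 arm, CN0 segments are the arm state, not deletions."""
        events, _ = classify_chromosome(
            [seg(0, BOUNDARY, 2, 0.0), seg(BOUNDARY, 30_000_000, 0),
             seg(30_000_000, 40_000_000, 0)],
            CHROM, WIDTH,
        )
        assert [e.label for e in events] == ["ditelosomic:S"]


class TestLocusDosage:
    SEGMENTS = [seg(0, 30_000_000, 2, 0.0), seg(30_000_000, 40_000_000, 1)]

    def test_inside_disomic_segment(self):
        locus = Locus("Eml-A1", "4B", 10_000_000, 11_000_000, "S")
        assert locus_dosage(self.SEGMENTS, locus) == (2, True)

    def test_inside_deleted_terminal_segment(self):
        """A locus inside a CN0 terminal segment is reported absent."""
        segments = [seg(0, 32_000_000, 2, 0.0), seg(32_000_000, 40_000_000, 0)]
        locus = Locus("Eml-A1", "4B", 36_000_000, 37_000_000, "L")
        assert locus_dosage(segments, locus) == (0, False)

    def test_straddling_boundary_takes_minimum(self):
        locus = Locus("x", "4B", 29_500_000, 30_500_000, "L")
        assert locus_dosage(self.SEGMENTS, locus) == (1, True)

    def test_no_overlap_falls_back_to_arm_cn(self):
        locus = Locus("x", "4B", 1_000_000, 2_000_000, "S")
        cn, present = locus_dosage([], locus, {("4B", "S"): 1, ("4B", "L"): 2})
        assert (cn, present) == (1, True)


class TestSegmentIO:
    def test_bit_exact_round_trip(self, tmp_path):
        segments = [
            seg(0, 19_000_000, 2, 0.03818593659),
            seg(19_000_000, 40_000_000, 1, -1.0000000001192093),
        ]
        path = tmp_path / "segments.tsv"
        write_segments(segments, path)
        assert read_segments(path) == segments
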