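import numpy as np
import pandas as pd
import pytest

from cistrome_compare import formats
from cistrome_compare.formats import (
    FormatError,
    GenomicInterval,
    Peak,
    PWM,
    SignalTrack,
    ValidationError,
)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end", [("", 0, 10), ("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 10, 5)]
    )
    def test_invariant_violations_rejected(self, chrom, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval(chrom, start, end)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 100)
        assert a.overlaps(GenomicInterval("chr1", 99, 200))
        assert not a.overlaps(GenomicInterval("chr1", 100, 200))
        assert not a.overlaps(GenomicInterval("chr2", 50, 60))


class TestBedGraph:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("#total_reads=1000\nchr1\t0\t100\t5.0\n")
        track = formats.read_bedgraph(p)
        starts, ends, values = track.chrom_data["chr1"]
        assert list(starts) == [0] and list(ends) == [100] and list(values) == [5.0]
        assert track.total_reads == 1000

    def test_overlapping_records_rejected(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("#total_reads=10\nchr1\t0\t100\t1\nchr1\t50\t150\t2\n")
        with pytest.raises(ValidationError, match="overlap"):
            formats.read_bedgraph(p)

    def test_roundtrip_identity(self, tmp_path):
        track = SignalTrack(
            {
                "chr1": (np.array([0, 100]), np.array([100, 250]), np.array([5.0, 2.5])),
                "chr2": (np.array([10]), np.array([20]), np.array([1.0])),
            },
            total_reads=5000,
        )
        p = tmp_path / "rt.bedGraph"
        formats.write_bedgraph(track, p)
        back = formats.read_bedgraph(p)
        assert back.total_reads == track.total_reads
        for chrom in ("chr1", "chr2"):
            for a, b in zip(back.chrom_data[chrom], track.chrom_data[chrom]):
                np.testing.assert_array_equal(a, b)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bedGraph"
        p.write_text("#total_reads=10\nchr1\t0\t100\n")
        with pytest.raises(FormatError, match=":2"):
            formats.read_bedgraph(p)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "neg.bedGraph"
        p.write_text("#total_reads=10\nchr1\t0\t100\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            formats.read_bedgraph(p)

    def test_missing_total_reads_rejected(self, tmp_path):
        p = tmp_path / "no_tr.bedGraph"
        p.write_text("chr1\t0\t100\t1\n")
        with pytest.raises(ValidationError, match="total_reads"):
            formats.read_bedgraph(p)


class TestPeaks:
    def test_summit_offset_arithmetic(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t1000\t2000\tp1\t100\t.\t5.0\t-1\t-1\t500\n")
        peaks = formats.read_peaks(p)
        assert peaks[0].summit == 1500

    def test_summit_outside_peak_rejected(self, tmp_path):
        p = tmp_path / "bad.narrowPeak"
        p.write_text("chr1\t1000\t2000\tp1\t100\t.\t5.0\t-1\t-1\t1200\n")
        with pytest.raises(ValidationError, match="summit"):
            formats.read_peaks(p)

    def test_three_peak_fixture_sorted(self, tmp_path):
        rows = [
            "chr2\t10\t110\tb\t1\t.\t0\t-1\t-1\t50",
            "chr1\t500\t700\ta2\t1\t.\t0\t-1\t-1\t100",
            "chr1\t0\t100\ta1\t1\t.\t0\t-1\t-1\t10",
        ]
        p = tmp_path / "x.narrowPeak"
        p.write_text("\n".join(rows) + "\n")
        peaks = formats.read_peaks(p)
        assert [pk.name for pk in peaks] == ["a1", "a2", "b"]
        assert peaks[0].summit == 10

    def test_roundtrip(self, tmp_path):
        peaks = [Peak(GenomicInterval("chr1", 100, 400), 250, 7.0, "pk")]
        p = tmp_path / "rt.narrowPeak"
        formats.write_narrowpeak(peaks, p)
        assert formats.read_peaks(p) == peaks


class TestMeme:
    def test_uniform_motif(self, tmp_path):
        p = tmp_path / "m.meme"
        formats.write_meme([PWM("U", np.full((4, 4), 0.25))], p)
        pwms = formats.read_meme(p)
        assert len(pwms) == 1
        np.testing.assert_allclose(pwms[0].matrix, 0.25)

    def test_two_motifs_in_file_order(self, tmp_path):
        p = tmp_path / "m.meme"
        formats.write_meme(
            [PWM("A1", np.full((4, 4), 0.25)), PWM("B2", np.full((5, 4), 0.25))], p
        )
        assert [w.motif_id for w in formats.read_meme(p)] == ["A1", "B2"]

    def test_bad_row_sum_rejected(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(
            "MEME version 4\n\nMOTIF BAD\n"
            "letter-probability matrix: alength= 4 w= 4\n"
            + "0.5 0.5 0.1 0.0\n" * 4
        )
        with pytest.raises(ValidationError, match="sums to"):
            formats.read_meme(p)


class TestGmt:
    def test_duplicates_deduplicated(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("P1\tdesc\tg1\tg2\tg2\n")
        coll = formats.read_gmt(p)
        assert coll["P1"] == {"g1", "g2"}

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "e.gmt"
        p.write_text("")
        assert len(formats.read_gmt(p)) == 0

    def test_two_sets(self, tmp_path):
        p = tmp_path / "two.gmt"
        p.write_text("P1\td\tg1\tg2\nP2\td\tg3\n")
        coll = formats.read_gmt(p)
        assert set(coll) == {"P1", "P2"} and coll["P2"] == {"g3"}

    def test_empty_set_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("P1\tdesc\n")
        with pytest.raises(ValidationError, match="P1"):
            formats.read_gmt(p)


class TestCohort:
    def _write(self, tmp_path, samples_clin):
        expr = pd.DataFrame(
            np.arange(15, dtype=float).reshape(5, 3),
            index=[f"g{i}" for i in range(5)],
            columns=["s1", "s2", "s3"],
        )
        expr.to_csv(tmp_path / "expr.tsv", sep="\t")
        clin = pd.DataFrame(
            {
                "sample_id": samples_clin,
                "time": [10.0] * len(samples_clin),
                "event": [1] * len(samples_clin),
                "er_status": ["+"] * len(samples_clin),
            }
        )
        clin.to_csv(tmp_path / "clin.tsv", sep="\t", index=False)
        return tmp_path / "expr.tsv", tmp_path / "clin.tsv"

    def test_matching_tables(self, tmp_path):
        e, c = self._write(tmp_path, ["s1", "s2", "s3"])
        cohort = formats.read_cohort(e, c)
        assert cohort.n_samples == 3

    def test_extra_clinical_sample_dropped(self, tmp_path):
        e, c = self._write(tmp_path, ["s1", "s2", "s3", "s4"])
        cohort = formats.read_cohort(e, c)
        assert cohort.samples == ["s1", "s2", "s3"]

    def test_negative_time_rejected(self, tmp_path):
        e, c = self._write(tmp_path, ["s1", "s2", "s3"])
        clin = pd.read_csv(c, sep="\t")
        clin.loc[0, "time"] = -1
        clin.to_csv(c, sep="\t", index=False)
        with pytest.raises(ValidationError, match="negative survival"):
            formats.read_cohort(e, c)

    def test_no_overlap_rejected(self, tmp_path):
        e, c = self._write(tmp_path, ["x1", "x2"])
        with pytest.raises(ValidationError, match="overlap"):
            formats.read_cohort(e, c)
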