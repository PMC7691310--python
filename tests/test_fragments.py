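import numpy as np
import pytest

from polfoot.fragments import (FilterConfig, Fragment, FragmentSet,
                               SizeClassScheme, fractionate, read_fragments,
                               read_fragments_tsv, spikein_scale,
                               write_fragments_tsv)
from tests.conftest import make_fragment_set

SAM_HEADER = ("@HD\tVN:1.6\tSO:unsorted\n"
              "@SQ\tSN:chr1\tLN:100000\n"
              "@SQ\tSN:chrEBV\tLN:100000\n"
              "@SQ\tSN:sacCer3_chrI\tLN:100000\n")


def sam_record(name, flag, chrom, pos0, mapq, tlen, tags=""):
    """One SAM line; pos0 is 0-based, SAM text is 1-based."""
    rlen = 50
    line = (f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{rlen}M\t=\t"
            f"{pos0 + abs(tlen) - rlen + 1}\t{tlen}\t{'N' * rlen}\t{'I' * rlen}")
    if tags:
        line += f"\t{tags}"
    return line + "\n"


@pytest.fixture()
def sam_file(tmp_path):
    def write(records):
        p = tmp_path / "reads.sam"
        p.write_text(SAM_HEADER + "".join(records))
        return p
    return write


class TestReadAlignment:
    def test_proper_pair_yields_leftmost_fragment(self, sam_file):
        p = sam_file([sam_record("r1", 99, "chr1", 1000, 60, 180),
                      sam_record("r1", 147, "chr1", 1130, 60, -180)])
        target, spike, qc = read_fragments(p)
        assert len(target) == 1 and len(spike) == 0
        frag = next(iter(target))
        assert frag == Fragment("chr1", 1000, 1180)
        assert qc["rightmost_mate"] == 1

    def test_mapq_boundary_strictly_greater_than_20(self, sam_file):
        p = sam_file([sam_record("lo", 99, "chr1", 1000, 20, 180),
                      sam_record("hi", 99, "chr1", 2000, 21, 180)])
        target, _, qc = read_fragments(p)
        assert len(target) == 1
        assert next(iter(target)).start == 2000
        assert qc["low_mapq"] == 1

    @pytest.mark.parametrize("tag", ["XA:Z:chr2,+100,50M,0;", "SA:Z:chr2,100,+,50M,60,0;"])
    def test_multimapper_tags_excluded(self, sam_file, tag):
        p = sam_file([sam_record("r1", 99, "chr1", 1000, 60, 180, tags=tag)])
        target, _, qc = read_fragments(p)
        assert len(target) == 0 and qc["excluded_tag"] == 1

    def test_improper_pair_and_duplicates(self, sam_file):
        recs = [sam_record("solo", 0, "chr1", 1000, 60, 180),       # not flag 3
                sam_record("dup", 99 + 1024, "chr1", 2000, 60, 180)]
        p = sam_file(recs)
        target, _, qc = read_fragments(p)
        assert len(target) == 0
        assert qc["not_proper_pair"] == 1 and qc["duplicate"] == 1
        keep_dups = FilterConfig(drop_duplicates=False)
        target2, _, _ = read_fragments(p, keep_dups)
        assert len(target2) == 1  # duplicate honored only when asked

    def test_contig_routing_and_unknown_contig(self, sam_file):
        p = sam_file([sam_record("t", 99, "chr1", 1000, 60, 180),
                      sam_record("s", 99, "sacCer3_chrI", 1000, 60, 180),
                      sam_record("u", 99, "chrEBV", 1000, 60, 180)])
        target, spike, qc = read_fragments(p)
        assert len(target) == 1 and len(spike) == 1
        assert qc["unknown_contig"] == 1
        assert spike.genome == "spikein"

    def test_relaxing_mapq_never_reduces_count(self, sam_file):
        rng = np.random.default_rng(0)
        recs = [sam_record(f"r{i}", 99, "chr1", 1000 + 10 * i,
                           int(rng.integers(0, 61)), 180) for i in range(40)]
        p = sam_file(recs)
        counts = []
        for mapq in (60, 30, 21, 0):
            target, _, _ = read_fragments(p, FilterConfig(min_mapq=mapq))
            counts.append(len(target))
        assert counts == sorted(counts)


class TestFractionate:
    @pytest.mark.parametrize("length,label", [
        (80, "40-120"), (119, "40-120"), (120, "120-270"), (269, "120-270"),
        (270, "270-440"), (439, "270-440"), (440, "440+"), (1000, "440+"),
        (40, "40-120"),
    ])
    def test_boundary_convention(self, length, label):
        fs = make_fragment_set([(0, length)])
        classes, dropped = fractionate(fs)
        assert len(classes[label]) == 1 and dropped == 0

    def test_below_first_boundary_dropped(self):
        fs = make_fragment_set([(0, 30), (0, 39)])
        classes, dropped = fractionate(fs)
        assert dropped == 2
        assert all(len(c) == 0 for c in classes.values())

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(1, 600, 500)
        fs = make_fragment_set([(0, int(ln)) for ln in lengths])
        classes, dropped = fractionate(fs)
        assert sum(len(c) for c in classes.values()) + dropped == len(fs)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            SizeClassScheme((120, 40))
        with pytest.raises(ValueError):
            SizeClassScheme((40,))


class TestSpikeinScale:
    def test_reference_count_gives_unity(self):
        assert spikein_scale(10000) == 1.0

    def test_half_reference_doubles(self):
        fs = make_fragment_set([(i, i + 100) for i in range(0, 50000, 10)],
                               chrom="sacCer3_chrI", genome="spikein")
        assert spikein_scale(fs) == 10000 / 5000

    def test_zero_spikein_is_an_error(self):
        with pytest.raises(ValueError, match="spike-in"):
            spikein_scale(0)


def test_tsv_round_trip_exact(tmp_path):
    rng = np.random.default_rng(2)
    starts = rng.integers(0, 10000, 200)
    fs = FragmentSet.from_arrays(["chr1"] * 200, starts,
                                 starts + rng.integers(40, 500, 200))
    path = tmp_path / "frags.tsv"
    write_fragments_tsv(fs, path, header_comment="test")
    back = read_fragments_tsv(path)
    assert back.equals(fs.df)


def test_filterconfig_rejects_overlapping_genomes():
    with pytest.raises(ValueError):
        FilterConfig(allowed_contigs=("chr1",), spikein_contigs=("chr1",))
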