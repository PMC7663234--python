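"""Read loading, quality filtering and segmental classification."""

import numpy as np
import pandas as pd
import pytest

from conftest import classify_oracle
from spliceomir.annotation import (
    GenomicInterval,
    HairpinRecord,
    MatureRecord,
    build_segment_map,
)
from spliceomir.reads import (
    AlignedRead,
    SegmentIndex,
    assign_read,
    calls_to_frame,
    filter_reads,
    load_reads,
    segment_partition,
)
from spliceomir.simulate import simulate_reads, write_reads_bed


def _read(start, end, strand="+", chrom="chr1", rid="r1", mm=0, identity=None):
    length = end - start
    if identity is None:
        identity = (length - mm) / length
    return AlignedRead(rid, GenomicInterval(chrom, start, end, strand), length, mm, identity)


@pytest.fixture(scope="module")
def one_hairpin_maps():
    hp = HairpinRecord("hp1", GenomicInterval("chr1", 1000, 1080, "+"))
    m5 = MatureRecord(
        "hp1-5p", "hp1", GenomicInterval("chr1", 1005, 1027, "+"), "5p"
    )
    m3 = MatureRecord(
        "hp1-3p", "hp1", GenomicInterval("chr1", 1053, 1075, "+"), "3p"
    )
    return {"hp1": build_segment_map(hp, [m5, m3])}


class TestLoadReads:
    def test_bed_line_maps_directly(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t100\t122\tr1\t0\t+\n")
        (read,) = load_reads(bed, "bed")
        assert read.length == 22
        assert read.interval == GenomicInterval("chr1", 100, 122, "+")
        assert read.mismatches == 0 and read.identity_fraction == 1.0

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        with pytest.warns(UserWarning, match="no reads"):
            assert load_reads(bed, "bed") == []

    def test_unknown_format_is_an_error(self, tmp_path):
        path = tmp_path / "x"
        path.write_text("")
        with pytest.raises(ValueError, match="unknown read format"):
            load_reads(path, "fastq")

    def test_negative_coordinates_are_an_error(self, tmp_path):
        bed = tmp_path / "neg.bed"
        bed.write_text("chr1\t-5\t17\tr1\t0\t+\n")
        with pytest.raises(ValueError):
            load_reads(bed, "bed")

    def test_tsv_with_identity_column(self, tmp_path):
        tsv = tmp_path / "r.tsv"
        tsv.write_text(
            "read_id\tchrom\tstart\tend\tstrand\tlength\tmismatches\tidentity\n"
            "r1\tchr1\t10\t32\t-\t22\t2\t0.95\n"
        )
        (read,) = load_reads(tsv, "tsv")
        assert read.identity_fraction == 0.95 and read.mismatches == 2

    def test_sam_skips_unmapped_and_reads_nm_tag(self, tmp_path):
        sam = tmp_path / "r.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t101\t60\t22M\t*\t0\t0\t" + "A" * 22 + "\t*\tNM:i:1\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 22 + "\t*\n"
            "r3\t16\tchr1\t201\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0\n"
        )
        reads = load_reads(sam, "sam")
        assert [r.read_id for r in reads] == ["r1", "r3"]
        assert reads[0].interval.start == 100 and reads[0].mismatches == 1
        assert reads[1].interval.strand == "-"

    def test_bed_count_matches_generator_emission(self, fixture7, tmp_path):
        reads, truth = simulate_reads(fixture7, "MCF10A", 1)
        bed = tmp_path / "sample.bed"
        write_reads_bed(reads, bed)
        loaded = load_reads(bed, "bed")
        assert len(loaded) == len(reads) == len(truth)


class TestFilterReads:
    def test_length_boundary(self):
        short = _read(0, 16, rid="short")
        ok = _read(0, 17, rid="ok")
        assert filter_reads([short, ok]) == [ok]

    def test_mismatch_boundary(self):
        # identity kept high so only the mismatch rule can reject
        two = _read(0, 30, rid="two", mm=2)
        three = _read(0, 30, rid="three", mm=3, identity=0.95)
        assert filter_reads([two, three]) == [two]

    def test_identity_boundary(self):
        low = _read(0, 20, rid="low", mm=0, identity=0.89)
        high = _read(0, 20, rid="high", mm=0, identity=0.90)
        assert filter_reads([low, high]) == [high]

    def test_matches_bruteforce_predicate_on_random_reads(self):
        rng = np.random.default_rng(3)
        reads = [
            _read(
                0,
                int(rng.integers(10, 35)),
                rid=f"r{i}",
                mm=int(rng.integers(0, 5)),
                identity=float(rng.uniform(0.8, 1.0)),
            )
            for i in range(500)
        ]
        expected = [
            r
            for r in reads
            if r.length >= 17 and r.mismatches <= 2 and r.identity_fraction >= 0.9
        ]
        assert filter_reads(reads) == expected

    def test_raising_min_length_never_adds_reads(self):
        rng = np.random.default_rng(4)
        reads = [_read(0, int(rng.integers(10, 35)), rid=f"r{i}") for i in range(200)]
        counts = [len(filter_reads(reads, min_length=k)) for k in range(10, 36)]
        assert counts == sorted(counts, reverse=True)


class TestAssignRead:
    def test_contained_in_mature_is_mature(self, one_hairpin_maps):
        call = assign_read(_read(1008, 1025), one_hairpin_maps)
        assert (call.hairpin_id, call.category) == ("hp1", "mature_5p")

    def test_crossing_border_is_overlap(self, one_hairpin_maps):
        # spans the mature_5p / loop-extension border at 1027
        call = assign_read(_read(1020, 1040), one_hairpin_maps)
        assert call.category == "overlap"

    def test_one_nt_past_boundary_is_already_overlap(self, one_hairpin_maps):
        assert assign_read(_read(1005, 1028), one_hairpin_maps).category == "overlap"
        assert assign_read(_read(1005, 1027), one_hairpin_maps).category == "mature_5p"

    def test_antisense_read_unassigned_unless_both_mode(self, one_hairpin_maps):
        read = _read(1008, 1025, strand="-")
        assert assign_read(read, one_hairpin_maps).category == "unassigned"
        assert assign_read(read, one_hairpin_maps, strand_mode="both").category == "mature_5p"

    def test_read_leaving_window_is_unassigned(self, one_hairpin_maps):
        # window is [950, 1130); both ends must fall inside
        call = assign_read(_read(940, 960), one_hairpin_maps)
        assert call.category == "unassigned" and call.hairpin_id is None

    def test_multi_window_read_resolved_by_midpoint(self):
        # two overlapping windows; the read midpoint is nearer hpB's centre
        hps = [
            HairpinRecord("hpA", GenomicInterval("chr1", 1000, 1080, "+")),
            HairpinRecord("hpB", GenomicInterval("chr1", 1040, 1120, "+")),
        ]
        maps = {}
        for hp in hps:
            s = hp.interval.start
            m5 = MatureRecord(
                f"{hp.hairpin_id}-5p", hp.hairpin_id,
                GenomicInterval("chr1", s + 2, s + 24, "+"), "5p",
            )
            maps[hp.hairpin_id] = build_segment_map(hp, [m5])
        call = assign_read(_read(1090, 1110), maps)
        assert call.hairpin_id == "hpB"

    def test_classifier_equals_position_oracle_on_synthetic_reads(self, fixture7):
        reads, _ = simulate_reads(fixture7, "MCF10A", 2)
        kept = filter_reads(reads)
        index = SegmentIndex(fixture7.segment_maps)
        for read in kept:
            call = index.assign(read)
            hid, cat = classify_oracle(read, fixture7.segment_maps)
            assert (call.hairpin_id, call.category) == (hid, cat)

    def test_identical_inputs_give_identical_call_tables(self, fixture7):
        reads, _ = simulate_reads(fixture7, "MCF7", 1)
        kept = filter_reads(reads)
        index = SegmentIndex(fixture7.segment_maps)
        a = calls_to_frame([index.assign(r) for r in kept])
        b = calls_to_frame([index.assign(r) for r in kept])
        assert a.to_csv() == b.to_csv()


class TestSegmentPartition:
    def test_single_category_gives_fraction_one(self):
        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(10)],
                "hairpin_id": ["mirX"] * 10,
                "category": ["mature_5p"] * 10,
            }
        )
        table = segment_partition(calls, by="miRNA", normalized=True)
        assert table.loc["mirX", "mature_5p"] == 1.0

    def test_normalized_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        cats = ["mature_5p", "mature_3p", "extension", "overlap"]
        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(400)],
                "hairpin_id": rng.choice(["a", "b", "c"], 400),
                "category": rng.choice(cats, 400),
            }
        )
        table = segment_partition(calls, by="miRNA", normalized=True)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_opposite_compositions_each_sum_to_one(self):
        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(20)],
                "hairpin_id": ["a"] * 10 + ["b"] * 10,
                "category": ["mature_5p"] * 10 + ["extension"] * 10,
            }
        )
        table = segment_partition(calls, by="miRNA", normalized=True)
        assert np.allclose(table.sum(axis=1), 1.0)
        assert table.loc["a", "mature_5p"] == 1.0 and table.loc["b", "extension"] == 1.0

    def test_zero_assignable_reads_warns_and_returns_empty(self):
        calls = pd.DataFrame(
            {"read_id": ["r1"], "hairpin_id": [None], "category": ["unassigned"]}
        )
        with pytest.warns(UserWarning, match="no assignable"):
            table = segment_partition(calls)
        assert table.empty

    def test_sample_view_normalized_is_mean_of_per_mirna_fractions(self):
        # miRNA a: all mature; miRNA b: all extension -> sample mean 0.5/0.5,
        # although raw pooled counts are 3:1
        calls = pd.DataFrame(
            {
                "sample_id": ["s1"] * 8,
                "read_id": [f"r{i}" for i in range(8)],
                "hairpin_id": ["a"] * 6 + ["b"] * 2,
                "category": ["mature_5p"] * 6 + ["extension"] * 2,
            }
        )
        norm = segment_partition(calls, by="sample", normalized=True)
        assert norm.loc["s1", "mature_5p"] == pytest.approx(0.5)
        raw = segment_partition(calls, by="sample", normalized=False)
        assert raw.loc["s1", "mature_5p"] == 6

    def test_mixture_recovery_within_three_points(self):
        from spliceomir.simulate import SimulationSpec, make_annotation_fixture

        spec = SimulationSpec(n_mirnas=6, mean_reads_per_mirna=2000.0)
        with pytest.warns(UserWarning):
            fixture = make_annotation_fixture(spec, seed=13)
        reads, truth = simulate_reads(fixture, "MCF10A", 1)
        kept = filter_reads(reads)
        index = SegmentIndex(fixture.segment_maps)
        calls = calls_to_frame([index.assign(r) for r in kept])
        table = segment_partition(calls, by="miRNA", normalized=True)
        deep = truth[~truth["decoy"]].groupby("mirna").size()
        assert (deep >= 1000).all()  # ~2000 reads per miRNA, NB-dispersed
        for mirna in deep.index:
            expected = fixture.truth.mixtures[mirna]
            for category, frac in expected.items():
                got = table.loc[mirna].get(category, 0.0)
                assert abs(got - frac) <= 0.03, (mirna, category)
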