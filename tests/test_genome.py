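import numpy as np
import pytest

from nucorg.errors import ParseError, ValidationError
from nucorg.genome import (
    DEFAULT_RECLASS_RULES,
    Feature,
    FeatureSet,
    GenomeLayout,
    GenomicInterval,
    define_subtelomeres,
    pombe_layout,
    probes_overlapping,
    read_gff3,
    reclassify_features,
    write_gff3,
)

from conftest import brute_force_overlap, make_features, make_track, \
    random_overlap_instance


class TestLayoutAndIntervals:
    def test_duplicate_chromosome_names_rejected(self):
        with pytest.raises(ValidationError):
            GenomeLayout((("chr1", 100), ("chr1", 200)))

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            GenomeLayout((("chr1", 0),))

    def test_interval_bounds(self, toy_layout):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 50, 50)
        iv = GenomicInterval("chr1", 0, 20_000)
        with pytest.raises(ValidationError):
            iv.validate(toy_layout)

    def test_layout_tsv_roundtrip(self, toy_layout, tmp_path):
        path = tmp_path / "genome.tsv"
        toy_layout.to_tsv(path)
        assert GenomeLayout.from_tsv(path) == toy_layout


class TestGff3:
    def test_single_record_coordinate_conversion(self, toy_layout, tmp_path):
        # 1-based closed 101..180 becomes 0-based half-open 100..180
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\ttRNA\t101\t180\t.\t+\t.\tID=t1\n"
        )
        fs = read_gff3(gff, toy_layout)
        (f,) = fs.features
        assert (f.interval.chrom, f.interval.start, f.interval.end,
                f.interval.strand) == ("chr1", 100, 180, "+")
        assert f.feature_class == "tRNA"
        assert f.id == "t1"

    def test_empty_file_with_header(self, toy_layout, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("##gff-version 3\n")
        assert len(read_gff3(gff, toy_layout)) == 0

    def test_three_record_toy_file_hand_parsed(self, toy_layout, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\ttRNA\t1\t80\t.\t+\t.\tID=a\n"
            "chr1\tsrc\tLTR\t501\t850\t.\t-\t.\tID=b\n"
            "chr2\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=c;Name=x\n"
        )
        fs = read_gff3(gff, toy_layout)
        assert [f.feature_class for f in fs] == ["tRNA", "LTR", "gene"]
        assert [(f.interval.start, f.interval.end) for f in fs] == [
            (0, 80), (500, 850), (1000, 2000)
        ]

    def test_malformed_line_names_line_number(self, toy_layout, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("##gff-version 3\nchr1\tsrc\ttRNA\t1\n")
        with pytest.raises(ParseError, match=":2:"):
            read_gff3(gff, toy_layout)

    def test_out_of_range_record_named(self, toy_layout, tmp_path):
        gff = tmp_path / "oob.gff3"
        gff.write_text(
            "##gff-version 3\nchr1\tsrc\ttRNA\t1\t99999\t.\t+\t.\tID=far\n"
        )
        with pytest.raises(ValidationError, match="far"):
            read_gff3(gff, toy_layout)

    def test_roundtrip_coordinate_identical(self, toy_layout, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\ttRNA\t101\t180\t.\t+\t.\tID=t1;external_name=trna1\n"
            "chr2\tsrc\tLTR\t4000\t4349\t.\t-\t.\tID=l1\n"
        )
        fs = read_gff3(gff, toy_layout)
        out = tmp_path / "out.gff3"
        write_gff3(fs, out)
        fs2 = read_gff3(out, toy_layout)
        assert [(f.id, f.feature_class, f.interval) for f in fs] == \
               [(f.id, f.feature_class, f.interval) for f in fs2]


class TestReclassification:
    def _fs(self, records):
        layout = GenomeLayout((("chr1", 10_000),))
        feats = [
            Feature(GenomicInterval("chr1", 100 * i, 100 * i + 50), cls,
                    f"f{i}", attrs)
            for i, (cls, attrs) in enumerate(records)
        ]
        return FeatureSet(feats, layout)

    def test_quoted_rules(self):
        fs = self._fs([
            ("repeat", (("Name", "LTRTF2-1"),)),
            ("protein_coding_gene", (("Name", "Tf2-7"),)),
            ("origin_of_replication", ()),
            ("gene", (("external_name", "abc.intron.1"),)),
            ("tRNA", ()),
        ])
        out = reclassify_features(fs)
        assert [f.feature_class for f in out] == [
            "LTR", "Tf2", "origin", "intron", "tRNA"
        ]

    def test_tf2_rule_requires_protein_coding_class(self):
        fs = self._fs([("pseudogene", (("Name", "Tf2-like"),))])
        assert reclassify_features(fs).features[0].feature_class == "pseudogene"

    def test_idempotent(self):
        fs = self._fs([
            ("repeat", (("Name", "LTRTF2-1"),)),
            ("protein_coding_gene", (("Name", "Tf2-7"),)),
            ("tRNA", ()),
        ])
        once = reclassify_features(fs)
        twice = reclassify_features(once)
        assert [f.feature_class for f in once] == \
               [f.feature_class for f in twice]


class TestSubtelomeres:
    def test_default_pombe_regions(self):
        fs = define_subtelomeres(pombe_layout())
        assert len(fs) == 4
        assert fs.classes == {"subtelomere"}
        total = sum(len(f.interval) for f in fs)
        # spans of the 1-based closed regions: 98950 + 82834 + 96400 + 102505
        assert total == 380_689

    def test_empty_region_list(self, toy_layout):
        assert len(define_subtelomeres(toy_layout, [])) == 0

    def test_overlapping_regions_rejected(self, toy_layout):
        regions = [GenomicInterval("chr1", 0, 500),
                   GenomicInterval("chr1", 400, 900)]
        with pytest.raises(ValidationError, match="overlap"):
            define_subtelomeres(toy_layout, regions)

    def test_region_beyond_chromosome_rejected(self, toy_layout):
        with pytest.raises(ValidationError):
            define_subtelomeres(toy_layout,
                                [GenomicInterval("chr1", 0, 20_000)])


class TestProbeOverlap:
    def test_containment_is_membership(self, toy_layout):
        fs = make_features(toy_layout, [("chr1", 100, 180, "tRNA")])
        track = make_track(toy_layout, [("chr1", 150, 170, 1.0)])
        assert probes_overlapping(fs, track, {"tRNA"}).tolist() == [True]

    def test_half_open_abutment_is_not_overlap(self, toy_layout):
        fs = make_features(toy_layout, [("chr1", 100, 180, "tRNA")])
        track = make_track(toy_layout, [("chr1", 180, 200, 1.0)])
        assert probes_overlapping(fs, track, {"tRNA"}).tolist() == [False]

    def test_unknown_class_lists_available(self, toy_layout):
        fs = make_features(toy_layout, [("chr1", 0, 50, "tRNA")])
        track = make_track(toy_layout, [("chr1", 0, 60, 1.0)])
        with pytest.raises(ValidationError, match="tRNA"):
            probes_overlapping(fs, track, {"nonsense"})

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            _, track, fs = random_overlap_instance(rng)
            for classes in ({"tRNA"}, {"LTR"}, {"tRNA", "LTR"}):
                if not classes <= fs.classes:
                    continue
                fast = probes_overlapping(fs, track, classes)
                slow = brute_force_overlap(fs, track, classes)
                assert np.array_equal(fast, slow)

    def test_membership_monotone_in_class_set(self):
        rng = np.random.default_rng(7)
        _, track, fs = random_overlap_instance(rng)
        avail = fs.classes
        small = probes_overlapping(fs, track, {"tRNA"} & avail or avail)
        big = probes_overlapping(fs, track, avail)
        assert big.sum() >= small.sum()
        assert np.all(big[small])
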