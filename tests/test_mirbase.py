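import numpy as np
import pytest

from isomirarm.mirbase import (
    MatureAnnotation,
    PreMiRNA,
    arm_of_span,
    is_midpoint_tie,
    locate_matures,
    mirbase_major_arm,
    parse_location,
    read_annotation_tsv,
    read_hairpins,
    write_annotation_tsv,
)


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class TestReadHairpins:
    def test_single_record(self, tmp_path, rng):
        seq = _random_rna(rng, 75)
        path = tmp_path / "h.fa"
        _write_fasta(path, [("hsa-mir-101-1", seq)])
        hairpins = read_hairpins(path)
        assert list(hairpins) == ["hsa-mir-101-1"]
        assert hairpins["hsa-mir-101-1"].length == 75

    def test_case_fold_and_t_to_u(self, tmp_path):
        path = tmp_path / "h.fa"
        _write_fasta(path, [("x", "ucga" + "tACG" * 5)])
        assert read_hairpins(path)["x"].sequence == "UCGA" + "UACG" * 5

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "h.fa"
        _write_fasta(path, [("hsa-mir-511-1", "ACGU" * 10), ("hsa-mir-511-1", "UGCA" * 10)])
        with pytest.raises(ValueError, match="hsa-mir-511-1"):
            read_hairpins(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "h.fa"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_hairpins(path)

    def test_bad_character_reported_with_position(self, tmp_path):
        path = tmp_path / "h.fa"
        _write_fasta(path, [("bad", "ACGUACGUXCGU")])
        with pytest.raises(ValueError, match="'bad'.*position 9"):
            read_hairpins(path)


class TestArmAssignment:
    @pytest.mark.parametrize(
        "start,end,length,arm",
        [
            (80, 101, 101, "3p"),  # late span on a 101 nt hairpin
            (11, 32, 75, "5p"),  # early span on a 75 nt hairpin
            (17, 39, 94, "5p"),
            (53, 75, 94, "3p"),
        ],
    )
    def test_midpoint_rule(self, start, end, length, arm):
        assert arm_of_span(start, end, length) == arm

    def test_exact_center_is_tie_and_falls_to_3p(self):
        # span 30-51 on an 80 nt hairpin: midpoint 40.5 == (80+1)/2
        assert is_midpoint_tie(30, 51, 80)
        assert arm_of_span(30, 51, 80) == "3p"


class TestLocateMatures:
    def test_positions_and_arms(self, rng):
        hp_seq = _random_rna(rng, 101)
        hairpins = {"hsa-mir-1307": PreMiRNA("hsa-mir-1307", hp_seq)}
        mature = hp_seq[79:101]
        anns = locate_matures(hairpins, [("hsa-miR-1307-3p", mature)])
        (ann,) = anns
        assert (ann.start, ann.end, ann.arm) == (80, 101, "3p")
        assert hairpins["hsa-mir-1307"].subseq(ann.start, ann.end) == mature

    def test_prefix_matching_reaches_numbered_hairpins(self, rng):
        hp_seq = _random_rna(rng, 75)
        hairpins = {"hsa-mir-101-1": PreMiRNA("hsa-mir-101-1", hp_seq)}
        anns = locate_matures(hairpins, [("hsa-miR-101", hp_seq[46:67])])
        assert anns[0].premirna_id == "hsa-mir-101-1"
        assert (anns[0].start, anns[0].end) == (47, 67)

    def test_mature_not_found_names_both_ids(self, rng):
        hairpins = {"hsa-mir-1": PreMiRNA("hsa-mir-1", _random_rna(rng, 70))}
        with pytest.raises(ValueError, match="hsa-miR-1-5p.*hsa-mir-1"):
            locate_matures(hairpins, [("hsa-miR-1-5p", "ACGUACGUACGUACGUACGUA")])

    def test_multiple_occurrences_rejected(self):
        mature = "ACGUGGAUCCAUGGAUCGAUG"
        seq = "GG" + mature + "UUUUUUUU" + mature + "GG"
        hairpins = {"hsa-mir-9": PreMiRNA("hsa-mir-9", seq)}
        with pytest.raises(ValueError, match="2 times"):
            locate_matures(hairpins, [("hsa-miR-9-5p", mature)])

    def test_whole_hairpin_mature_rejected(self, rng):
        seq = _random_rna(rng, 60)
        hairpins = {"hsa-mir-2": PreMiRNA("hsa-mir-2", seq)}
        with pytest.raises(ValueError, match="whole hairpin"):
            locate_matures(hairpins, [("hsa-miR-2", seq)])


class TestAnnotationTsv:
    def test_round_trip(self, tmp_path, rng):
        anns = [
            MatureAnnotation(f"m-{i}", f"hp-{i}", 5 + i, 26 + i, "5p" if i % 2 else "3p",
                             source="detected" if i == 2 else "mirbase")
            for i in range(5)
        ]
        path = tmp_path / "ann.tsv"
        write_annotation_tsv(anns, path)
        back = read_annotation_tsv(path)
        assert [(a.mature_id, a.premirna_id, a.start, a.end, a.arm, a.source) for a in back] == [
            (a.mature_id, a.premirna_id, a.start, a.end, a.arm, a.source) for a in anns
        ]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("premirna_id\tmature_id\tstart\n")
        with pytest.raises(ValueError, match="missing column"):
            read_annotation_tsv(path)


class TestLocationStrings:
    @pytest.mark.parametrize(
        "premirna,location,major",
        [
            ("hsa-mir-17", "MA:14-36;mi:51-72", "5p"),
            ("hsa-mir-376a-1", "mi:7-28;MA:44-64", "3p"),
            ("hsa-mir-1307", "3p:80-101", "3p"),
            ("hsa-mir-511-1", "5p:16-36", "5p"),
            ("hsa-mir-423", "5p:17-39;3p:53-75", "both-undetermined"),
        ],
    )
    def test_major_arm_from_location(self, premirna, location, major):
        anns = parse_location(premirna, location)
        assert mirbase_major_arm(anns) == major

    def test_ma_mi_arms_follow_span_order(self):
        a5, a3 = parse_location("hsa-mir-664", "mi:11-34;MA:49-71")
        assert (a5.arm, a5.major) == ("5p", False)
        assert (a3.arm, a3.major) == ("3p", True)
        assert (a5.start, a5.end, a3.start, a3.end) == (11, 34, 49, 71)

    def test_unparseable_location_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_location("x", "5p:banana")
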