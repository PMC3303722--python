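import numpy as np
import pytest

from conftest import brute_force_map
from isomirarm.mapping import (
    assign_isomirs,
    detect_opposite_arm,
    expression_table,
    map_library,
    map_read,
)
from isomirarm.mirbase import MatureAnnotation, PreMiRNA
from isomirarm.preprocess import UniqueRead


@pytest.fixture()
def hairpin(rng):
    """A 75 nt hairpin with a 5p mature at 11-32 and a 3p mature at 47-67."""
    seq = "".join(rng.choice(list("ACGU"), size=75))
    hp = PreMiRNA("syn-mir-101-1", seq)
    anns = [
        MatureAnnotation("syn-miR-101-5p", hp.id, 11, 32, "5p"),
        MatureAnnotation("syn-miR-101-3p", hp.id, 47, 67, "3p"),
    ]
    return hp, anns


class TestMapRead:
    def test_exact_match_at_annotated_span(self, hairpin):
        hp, _ = hairpin
        read = UniqueRead(hp.subseq(47, 67), 5)
        (mr,) = map_read(read, {hp.id: hp})
        assert (mr.map_start, mr.map_end, mr.trimmed_fragment) == (47, 67, "")
        assert mr.count == 5

    def test_single_step_trim_records_fragment(self, hairpin):
        hp, _ = hairpin
        tail = "A" if hp.sequence[30] != "A" else "U"
        read = UniqueRead(hp.subseq(10, 30) + tail, 2)
        (mr,) = map_read(read, {hp.id: hp})
        assert (mr.map_start, mr.map_end, mr.trimmed_fragment) == (10, 30, tail)
        assert mr.mapped_sequence == hp.subseq(10, 30)

    def test_unmappable_read_returns_empty(self, hairpin):
        hp, _ = hairpin
        assert map_read(UniqueRead("A" * 20, 2), {hp.id: hp}) == []

    def test_multihit_full_count_vs_split(self, hairpin, rng):
        hp, _ = hairpin
        hp2 = PreMiRNA("syn-mir-101-2", "".join(rng.choice(list("ACGU"), 5)) + hp.sequence)
        hairpins = {hp.id: hp, hp2.id: hp2}
        read = UniqueRead(hp.subseq(47, 67), 10)
        full = map_read(read, hairpins)
        assert len(full) == 2 and all(mr.count == 10 for mr in full)
        split = map_read(read, hairpins, split_multihits=True)
        assert all(mr.count == 5 for mr in split)
        assert sum(mr.count for mr in split) == 10

    def test_mapped_sequence_reextracts_from_hairpin(self, sim_dataset, sim_result):
        hairpins = sim_dataset.hairpins
        for label in sim_dataset.config.library_names:
            for mr in sim_result.libs[label].mapped:
                assert (
                    hairpins[mr.premirna_id].subseq(mr.map_start, mr.map_end)
                    == mr.mapped_sequence
                )

    def test_agrees_with_brute_force_oracle(self, sim_dataset, rng):
        hairpins = sim_dataset.hairpins
        reads = [r.sequence for r in sim_dataset.libraries[0].reads[:150]]
        reads += ["".join(rng.choice(list("ACGU"), 22)) for _ in range(30)]
        for seq in reads:
            hits = map_read(UniqueRead(seq, 1), hairpins)
            length, oracle_hits = brute_force_map(seq, hairpins)
            got = sorted((mr.premirna_id, mr.map_start, mr.map_end) for mr in hits)
            assert got == sorted(oracle_hits)
            if hits:
                assert hits[0].mapped_length == length


class TestAssignIsomirs:
    def _mapped(self, hp, start, end, count=4):
        return map_read(UniqueRead(hp.subseq(start, end), count), {hp.id: hp})

    def test_reference_form_is_zero_zero(self, hairpin):
        hp, anns = hairpin
        isomirs, unassigned = assign_isomirs(self._mapped(hp, 47, 67), anns)
        assert unassigned == []
        assert [(i.mature_id, i.offsets) for i in isomirs] == [("syn-miR-101-3p", (0, 0))]

    def test_window_corners_accepted(self, hairpin):
        # a 25 nt mature so the (+2, -5) corner still leaves an 18 nt read
        hp, _ = hairpin
        anns = [MatureAnnotation("long-3p", hp.id, 43, 67, "3p")]
        isomirs, unassigned = assign_isomirs(self._mapped(hp, 45, 62), anns)
        assert unassigned == []
        assert isomirs[0].offsets == (2, -5)

    def test_start_offset_three_rejected(self, hairpin):
        hp, anns = hairpin
        isomirs, unassigned = assign_isomirs(self._mapped(hp, 50, 67), anns)
        assert isomirs == [] and len(unassigned) == 1

    def test_overlapping_annotations_take_smaller_start_offset(self, hairpin):
        hp, _ = hairpin
        anns = [
            MatureAnnotation("near", hp.id, 12, 33, "5p"),
            MatureAnnotation("far", hp.id, 9, 30, "5p"),
        ]
        isomirs, _ = assign_isomirs(self._mapped(hp, 11, 32), anns)
        assert [(i.mature_id, i.offsets) for i in isomirs] == [("near", (-1, -1))]

    def test_counts_accumulate_per_offset_pair(self, hairpin):
        hp, anns = hairpin
        mapped = self._mapped(hp, 47, 67, 3) + self._mapped(hp, 47, 67, 9)
        isomirs, _ = assign_isomirs(mapped, anns)
        assert len(isomirs) == 1 and isomirs[0].count == 12

    def test_no_emitted_isomir_violates_windows(self, sim_result):
        for label, lr in sim_result.libs.items():
            for iso in lr.isomirs:
                assert abs(iso.start_offset) <= 2 and abs(iso.end_offset) <= 5


class TestDetectOppositeArm:
    def test_planted_unannotated_arm_recovered(self, hairpin):
        hp, anns = hairpin
        only_3p = [a for a in anns if a.arm == "3p"]
        mapped = map_read(UniqueRead(hp.subseq(11, 32), 8), {hp.id: hp})
        mapped += map_read(UniqueRead(hp.subseq(12, 32), 3), {hp.id: hp})
        _, unassigned = assign_isomirs(mapped, only_3p)
        (det,) = detect_opposite_arm(unassigned, only_3p, {hp.id: hp})
        assert (det.annotation.start, det.annotation.end, det.annotation.arm) == (11, 32, "5p")
        assert det.annotation.source == "detected"
        assert det.defining_count == 8 and det.total_count == 11

    def test_fully_annotated_hairpin_yields_nothing(self, hairpin):
        hp, anns = hairpin
        mapped = map_read(UniqueRead(hp.subseq(2, 22), 9), {hp.id: hp})
        assert detect_opposite_arm(mapped, anns, {hp.id: hp}) == []

    def test_low_count_cluster_discarded(self, hairpin):
        hp, anns = hairpin
        only_3p = [a for a in anns if a.arm == "3p"]
        mapped = map_read(UniqueRead(hp.subseq(11, 32), 1), {hp.id: hp})
        assert detect_opposite_arm(mapped, only_3p, {hp.id: hp}, min_count=2) == []

    def test_simulated_hidden_arms_detected_at_planted_span(self, sim_dataset, sim_result):
        hidden = {
            (a.premirna_id, a.arm): a
            for a in sim_dataset.annotations_full
            if not any(
                p.premirna_id == a.premirna_id and p.arm == a.arm
                for p in sim_dataset.annotations_public
            )
        }
        assert hidden, "simulation fixture should hide at least one arm"
        detected = {(a.premirna_id, a.arm): a for a in sim_result.detected_merged}
        for key, truth in hidden.items():
            assert key in detected
            assert (detected[key].start, detected[key].end) == (truth.start, truth.end)


class TestExpressionTable:
    def test_sums_and_type_counts(self, hairpin):
        hp, anns = hairpin
        mapped = []
        for span, cnt in (((47, 67), 10), ((47, 66), 7), ((48, 67), 3)):
            mapped += map_read(UniqueRead(hp.subseq(*span), cnt), {hp.id: hp})
        isomirs, _ = assign_isomirs(mapped, anns)
        table = expression_table(isomirs)
        row = table.iloc[0]
        assert row["mature_id"] == "syn-miR-101-3p"
        assert row["expression"] == 20 and row["n_isomir_types"] == 3

    def test_empty_input(self):
        assert len(expression_table([])) == 0


class TestConservation:
    def test_isomir_plus_unassigned_plus_unmapped_equals_total(self, sim_result):
        for label in sim_result.labels:
            accounted, total = sim_result.conservation(label)
            assert accounted == pytest.approx(total)
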