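"""V(D)J annotation: alignments, identity, D assignment, CDR3 extraction."""
import numpy as np
import pytest

from cdr3shm._seqtools import encode
from cdr3shm.annotate import (
    align_j,
    align_v,
    annotate_batch,
    annotate_read,
    assign_d,
    compute_v_identity,
)
from cdr3shm.germline import GeneSegment
from cdr3shm.qc import merge_batch
from cdr3shm.simulate import InjectionSpec, inject_variant, simulate_repertoire

from conftest import random_seq


class TestAlignVJ:
    def test_archetype_self_alignment(self, db, arc1):
        aln = align_v(arc1.sequence, db.by_class("V"))
        assert aln.segment.name == "IGHV-CLAN1-SYN"
        assert aln.offset == 0 and aln.mismatches == 0

    def test_fr2_substitution_attributed_to_fr2(self, db, arc1):
        v = db["IGHV-CLAN1-SYN"]
        lo, hi = v.region_bounds["fr2"]
        pos = (lo + hi) // 2
        base = arc1.sequence[pos]
        alt = "ACGT"[("ACGT".index(base) + 1) % 4]
        mutated = arc1.sequence[:pos] + alt + arc1.sequence[pos + 1:]
        aln = align_v(mutated, db.by_class("V"))
        assert aln.segment.name == "IGHV-CLAN1-SYN"
        per_region = aln.region_mismatches(mutated)
        assert per_region["fr2"] == 1
        assert sum(per_region.values()) == 1

    def test_scrambled_sequence_unassigned(self, db, rng):
        assert align_v(random_seq(rng, 280), db.by_class("V")) is None

    def test_j_self_and_mismatch(self, db, arc1, rng):
        aln = align_j(arc1.sequence, db.by_class("J"), search_from=arc1.cdr3_start)
        assert aln.segment.name == "IGHJ4-SYN"
        assert aln.offset == len(arc1.sequence) - len(aln.segment.sequence)
        assert align_j(random_seq(rng, 120), db.by_class("J"), 0) is None


def brute_force_assign_d(junction, d_segments, min_match):
    """Oracle: enumerate all (junction, D) substring pairs."""
    best = None
    for seg in sorted(d_segments, key=lambda s: s.name):
        for i in range(len(junction)):
            for j in range(len(seg.sequence)):
                k = 0
                while (
                    i + k < len(junction)
                    and j + k < len(seg.sequence)
                    and junction[i + k] == seg.sequence[j + k]
                ):
                    k += 1
                if k >= min_match:
                    key = (-k, i, seg.name)
                    if best is None or key < best:
                        best = key
    return best


class TestAssignD:
    def test_subset1_frame1(self, db, arc1):
        junction = arc1.sequence[arc1.cdr3_start + 6: arc1.cdr3_end - 9]
        d = assign_d(junction, db.by_class("D"), codon_phase=(6 % 3))
        assert d.segment.name == "IGHD6-19-SYN"
        assert d.reading_frame == 1

    def test_subset6_frame2(self, db, arc6):
        v_end = arc6.cdr3_start + 6
        j_start = arc6.cdr3_end - 12
        junction = arc6.sequence[v_end:j_start]
        d = assign_d(junction, db.by_class("D"), codon_phase=(v_end - arc6.cdr3_start) % 3)
        assert d.segment.name == "IGHD3-16-SYN"
        assert d.reading_frame == 2

    def test_no_match_is_none(self, db):
        assert assign_d("ACACACACAC", db.by_class("D")) is None

    def test_tie_break_five_prime_most(self):
        seg = GeneSegment(name="D", segment_class="D", sequence="CAATGGTTA",
                          region_bounds={"reading_frames": [1, 2, 3]})
        junction = "CCCAATGTTTTTCAATGTTTT"  # two length-6 matches of CAATGT?
        d = assign_d(junction, [seg], min_match=5)
        oracle = brute_force_assign_d(junction, [seg], 5)
        assert d.junction_start == oracle[1]

    def test_matches_brute_force_on_random_junctions(self, db, rng):
        segs = db.by_class("D")
        for _ in range(150):
            junction = random_seq(rng, int(rng.integers(8, 61)))
            got = assign_d(junction, segs, min_match=4)
            oracle = brute_force_assign_d(junction, segs, 4)
            if oracle is None:
                assert got is None
            else:
                assert (-got.length, got.junction_start, got.segment.name) == oracle


class TestVIdentity:
    def test_perfect_match_is_100(self, db, arc1):
        aln = align_v(arc1.sequence, db.by_class("V"))
        assert compute_v_identity(arc1.sequence, aln) == 100.0

    def test_cdr3_mutation_does_not_reduce_identity(self, db, arc1):
        variant, _ = inject_variant(arc1, InjectionSpec(2, "A", "G", 0, 0.001))
        aln = align_v(variant, db.by_class("V"))
        assert compute_v_identity(variant, aln) == 100.0

    def test_single_fr1_mismatch_over_250(self):
        # constructed V with a 250-nt FR1-FR3 block
        seq = ("ACGT" * 63)[:250] + "TGT" + "GCGAGA"
        seg = GeneSegment(
            name="V250", segment_class="V", sequence=seq,
            region_bounds={"fr1": [0, 100], "cdr1": [100, 130], "fr2": [130, 180],
                           "cdr2": [180, 210], "fr3": [210, 253]},
        )
        read = "T" + seq[1:]
        from cdr3shm.annotate import SegmentAlignment

        aln = SegmentAlignment(seg, 0, 1, len(seq))
        ident = compute_v_identity(read, aln)
        assert ident == pytest.approx(100 * 252 / 253, abs=1e-9)

    def test_incomplete_alignment_flagged(self, db, arc1):
        truncated = arc1.sequence[: db["IGHV-CLAN1-SYN"].fr3_end - 10]
        from cdr3shm.annotate import SegmentAlignment

        aln = SegmentAlignment(db["IGHV-CLAN1-SYN"], 0, 0, len(truncated))
        assert compute_v_identity(truncated, aln) is None


class TestAnnotateRead:
    def test_round_trip_subset1(self, db, arc1):
        ann = annotate_read(arc1.sequence, db)
        assert (ann.v_call, ann.d_call, ann.j_call) == (
            "IGHV-CLAN1-SYN", "IGHD6-19-SYN", "IGHJ4-SYN"
        )
        assert ann.cdr3_aa == arc1.cdr3_aa
        assert ann.region_of_cdr3_codon == arc1.cdr3_region_map()
        assert ann.productive and ann.v_identity == 100.0
        assert ann.junction_nt == arc1.junction_nt

    def test_round_trip_subset6(self, db, arc6):
        ann = annotate_read(arc6.sequence, db)
        assert ann.d_call == "IGHD3-16-SYN"
        assert len(ann.cdr3_aa) == 21
        assert ann.region_of_cdr3_codon[9] == "D"
        assert ann.region_of_cdr3_codon[19] == "J"

    def test_germline_cdr3_ref_restores_germline(self, db, arc1):
        # V-encoded mutation: templated positions revert to germline in the
        # reference, N positions carry the read's own bases
        variant, _ = inject_variant(arc1, InjectionSpec(2, "A", "G", 0, 0.001))
        ann = annotate_read(variant, db)
        assert ann.germline_cdr3_ref == arc1.cdr3_nt

    def test_frame_shifted_junction_unproductive(self, db, arc1):
        # drop one nucleotide inside N2: J shifts, CDR3 length not divisible by 3
        cut = arc1.cdr3_start + 20
        shifted = arc1.sequence[:cut] + arc1.sequence[cut + 1:]
        ann = annotate_read(shifted, db)
        assert ann.productive is False

    def test_stop_codon_unproductive(self, db, arc1):
        pos = arc1.cdr3_start + 12  # TGG (W5) -> TGA stop
        assert arc1.sequence[pos: pos + 3] == "TGG"
        mutated = arc1.sequence[: pos + 2] + "A" + arc1.sequence[pos + 3:]
        ann = annotate_read(mutated, db)
        assert ann.productive is False


class TestAnnotateBatch:
    def test_matches_scalar_on_noisy_reads(self, db, arc1):
        s = simulate_repertoire(
            arc1, [InjectionSpec(2, "A", "G", 0, 0.05)], n_reads=200,
            error_rate=0.024, seed=21,
        )
        groups, _ = merge_batch(s.r1, s.q1, s.r2, s.q2)
        for g in groups:
            df = annotate_batch(g.seqs, db)
            for k in range(min(len(df), 80)):
                ann = annotate_read(df["sequence"].iloc[k], db)
                row = df.iloc[k]
                assert row["v_call"] == ann.v_call
                assert row["j_call"] == ann.j_call
                assert row["d_call"] == ann.d_call
                assert row["productive"] == ann.productive
                if ann.v_identity is not None:
                    assert row["v_identity"] == pytest.approx(ann.v_identity)
                assert row["cdr3_aa"] == ann.cdr3_aa
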