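import numpy as np

from conftest import random_dna
from ssrscape.flanks import extract_flanks, revcomp
from ssrscape.mining import SequenceRecord, mine_record
from ssrscape.polymorphism import (
    ABSENT,
    AMBIGUOUS,
    MONOMORPHIC,
    POLYMORPHIC,
    aggregate,
    call_genotype,
    call_locus,
    hypervariable_calls,
    index_genotype,
)


def build_reference(rng, unit="AG", count=7, pad=60):
    """One planted tract with junction-guarded random flanks."""
    left = random_dna(rng, pad)
    right = random_dna(rng, pad)
    while left[-1] == unit[-1]:
        left = left[:-1] + random_dna(rng, 1)
    while right[0] == unit[0]:
        right = random_dna(rng, 1) + right[1:]
    seq = left + unit * count + right
    record = SequenceRecord("ref1", seq)
    (locus,) = mine_record(record)
    sig = extract_flanks(locus, {"ref1": record})
    assert sig.valid
    return record, locus, sig


def contig_for(record, locus, new_count=None, pad=40, mutate_flank_at=None):
    """Copy the reference around the tract, optionally varying the count."""
    seq = record.seq
    unit, count = locus.motif, locus.repeat_count
    new_count = count if new_count is None else new_count
    left = seq[locus.start - 1 - pad : locus.start - 1]
    right = seq[locus.end : locus.end + pad]
    if mutate_flank_at is not None:
        # substitution inside the left signature flank
        pos = len(left) - mutate_flank_at
        old = left[pos]
        new = next(b for b in "ACGT" if b != old)
        left = left[:pos] + new + left[pos + 1 :]
    return SequenceRecord("c1", left + unit * new_count + right)


class TestCallLocus:
    def test_identical_contig_monomorphic(self):
        rng = np.random.default_rng(0)
        record, locus, sig = build_reference(rng)
        index = index_genotype([contig_for(record, locus)], genotype_id="g")
        call = call_locus(sig, index)
        assert call.status == MONOMORPHIC
        assert call.genotype_repeat_count == locus.repeat_count
        assert call.matched_strand == "+"

    def test_planted_variant_polymorphic(self):
        rng = np.random.default_rng(1)
        record, locus, sig = build_reference(rng, unit="AG", count=7)
        index = index_genotype([contig_for(record, locus, new_count=9)], genotype_id="g")
        call = call_locus(sig, index)
        assert call.status == POLYMORPHIC
        assert call.genotype_repeat_count == 9

    def test_flank_substitution_absent(self):
        rng = np.random.default_rng(2)
        record, locus, sig = build_reference(rng)
        contig = contig_for(record, locus, mutate_flank_at=10)
        index = index_genotype([contig], genotype_id="g")
        assert call_locus(sig, index).status == ABSENT

    def test_no_contigs_absent(self):
        rng = np.random.default_rng(3)
        _, _, sig = build_reference(rng)
        index = index_genotype([], genotype_id="g")
        assert call_locus(sig, index).status == ABSENT

    def test_invalid_signature_absent_with_reason(self):
        rng = np.random.default_rng(4)
        record, locus, _ = build_reference(rng)
        from ssrscape.flanks import FlankSignature

        bad = FlankSignature(
            locus_id="x", left_flank="ACGT", right_flank="ACGT",
            motif="AG", repeat_count=7, tract_length=14,
            valid=False, invalid_reason="truncated",
        )
        call = call_locus(bad, index_genotype([contig_for(record, locus)], genotype_id="g"))
        assert call.status == ABSENT
        assert "invalid_signature" in call.reason

    def test_conflicting_counts_ambiguous(self):
        rng = np.random.default_rng(5)
        record, locus, sig = build_reference(rng)
        c1 = contig_for(record, locus, new_count=8)
        c2 = SequenceRecord("c2", contig_for(record, locus, new_count=9).seq)
        index = index_genotype([c1, c2], genotype_id="g")
        assert call_locus(sig, index).status == AMBIGUOUS

    def test_consistent_double_hit_not_ambiguous(self):
        rng = np.random.default_rng(6)
        record, locus, sig = build_reference(rng)
        c1 = contig_for(record, locus)
        c2 = SequenceRecord("c2", c1.seq)
        index = index_genotype([c1, c2], genotype_id="g")
        assert call_locus(sig, index).status == MONOMORPHIC


class TestStrandInvariance:
    def test_reverse_complemented_contig_same_call(self):
        rng = np.random.default_rng(7)
        record, locus, sig = build_reference(rng, unit="ATC", count=6)
        contig = contig_for(record, locus, new_count=8)
        flipped = SequenceRecord(contig.id, revcomp(contig.seq))
        for c, strand in ((contig, "+"), (flipped, "-")):
            call = call_locus(sig, index_genotype([c], genotype_id="g"))
            assert call.status == POLYMORPHIC
            assert call.genotype_repeat_count == 8
            assert call.matched_strand == strand

    def test_strand_oracle_forward_path_on_revcomp(self):
        # indexing the reverse complement must equal re-running the forward
        # path on the reverse-complemented sequence
        rng = np.random.default_rng(8)
        record, locus, sig = build_reference(rng)
        contig = contig_for(record, locus)
        idx_fwd = index_genotype([contig], genotype_id="g")
        idx_rc = index_genotype(
            [SequenceRecord(contig.id, revcomp(contig.seq))], genotype_id="g"
        )
        assert set(idx_fwd.by_key) == set(idx_rc.by_key)


class TestSymmetry:
    def test_role_swap_preserves_status(self):
        rng = np.random.default_rng(9)
        record, locus, sig = build_reference(rng, unit="AG", count=7)
        variant = contig_for(record, locus, new_count=9)

        # forward direction: reference vs variant contig
        fwd = call_locus(sig, index_genotype([variant], genotype_id="g"))

        # swapped: variant acts as reference, original region as contig
        (v_locus,) = mine_record(variant)
        v_sig = extract_flanks(v_locus, {variant.id: variant})
        ref_fragment = SequenceRecord(
            "frag", record.seq[locus.start - 41 : locus.end + 40]
        )
        rev = call_locus(v_sig, index_genotype([ref_fragment], genotype_id="g"))
        assert fwd.status == rev.status == POLYMORPHIC

    def test_monomorphic_swap(self):
        rng = np.random.default_rng(10)
        record, locus, sig = build_reference(rng)
        same = contig_for(record, locus)
        (c_locus,) = mine_record(same)
        c_sig = extract_flanks(c_locus, {same.id: same})
        frag = SequenceRecord("frag", record.seq[locus.start - 41 : locus.end + 40])
        assert call_locus(sig, index_genotype([same], genotype_id="g")).status == MONOMORPHIC
        assert call_locus(c_sig, index_genotype([frag], genotype_id="g")).status == MONOMORPHIC


class TestMonotonicity:
    def test_adding_contigs_never_converts_polymorphic_to_absent(self):
        rng = np.random.default_rng(11)
        record, locus, sig = build_reference(rng)
        variant = contig_for(record, locus, new_count=9)
        extra = SequenceRecord("x", random_dna(np.random.default_rng(99), 150))
        small = call_locus(sig, index_genotype([variant], genotype_id="g"))
        big = call_locus(sig, index_genotype([variant, extra], genotype_id="g"))
        assert small.status == POLYMORPHIC
        assert big.status != ABSENT


class TestEdgeIndexing:
    def test_ssr_near_contig_end_not_indexed(self):
        # 5 bp of flank only: no valid 20-nt signature on either orientation
        contig = SequenceRecord("c", "ACGTC" + "AG" * 9 + "GTCAC")
        index = index_genotype([contig], genotype_id="g")
        assert index.by_key == {}

    def test_both_orientations_indexed(self):
        rng = np.random.default_rng(12)
        record, locus, sig = build_reference(rng)
        contig = contig_for(record, locus)
        index = index_genotype([contig], genotype_id="g")
        strands = {e.strand for hits in index.by_key.values() for e in hits}
        assert strands == {"+", "-"}


class TestCallGenotypeCollisions:
    def test_shared_genotype_locus_marks_all_ambiguous(self):
        rng = np.random.default_rng(13)
        record, locus, sig = build_reference(rng)
        contig = contig_for(record, locus)
        index = index_genotype([contig], genotype_id="g")
        # two "reference" signatures with identical keys hitting one tract
        calls = call_genotype([sig, sig], index)
        assert [c.status for c in calls] == [AMBIGUOUS, AMBIGUOUS]
        assert all(c.reason == "shared_genotype_locus" for c in calls)


class TestAggregate:
    def _call(self, locus_id, genotype, status, ref_len=14, geno_len=14):
        from ssrscape.polymorphism import PolymorphismCall

        return PolymorphismCall(
            ref_locus_id=locus_id,
            genotype_id=genotype,
            status=status,
            ref_tract_length=ref_len,
            genotype_tract_length=geno_len if status != ABSENT else None,
        )

    def test_polymorphic_in_two_genotypes_counts_once(self):
        calls = {
            "g1": [self._call("L1", "g1", POLYMORPHIC)],
            "g2": [self._call("L1", "g2", POLYMORPHIC)],
        }
        summary = aggregate(calls)
        assert summary.n_polymorphic == 1
        assert summary.n_common == 1

    def test_mixed_status_resolves_polymorphic(self):
        # monomorphic in one genotype, polymorphic in another -> polymorphic
        calls = {
            "g1": [self._call("L1", "g1", MONOMORPHIC)],
            "g2": [self._call("L1", "g2", POLYMORPHIC)],
        }
        summary = aggregate(calls)
        assert summary.n_polymorphic == 1
        assert summary.n_monomorphic == 0
        assert summary.polymorphic_union.isdisjoint(summary.monomorphic_union)

    def test_empty_panel_all_zero(self):
        summary = aggregate({})
        assert summary.n_common == 0
        assert summary.per_genotype == {}

    def test_partition_accounting(self):
        calls = {
            "g1": [
                self._call("L1", "g1", MONOMORPHIC),
                self._call("L2", "g1", POLYMORPHIC),
                self._call("L3", "g1", ABSENT),
            ],
            "g2": [
                self._call("L1", "g2", POLYMORPHIC),
                self._call("L2", "g2", MONOMORPHIC),
                self._call("L4", "g2", MONOMORPHIC),
            ],
        }
        summary = aggregate(calls)
        assert summary.n_polymorphic == 2  # L1, L2
        assert summary.n_monomorphic == 1  # L4
        assert summary.n_common == summary.n_polymorphic + summary.n_monomorphic

    def test_per_genotype_counts(self):
        calls = {
            "g1": [
                self._call("L1", "g1", MONOMORPHIC),
                self._call("L2", "g1", POLYMORPHIC),
                self._call("L3", "g1", ABSENT),
                self._call("L4", "g1", AMBIGUOUS),
            ]
        }
        row = aggregate(calls).per_genotype["g1"]
        assert row == {"monomorphic": 1, "polymorphic": 1, "absent": 1, "ambiguous": 1}


class TestHypervariableCalls:
    def _poly(self, ref_len, geno_len):
        from ssrscape.polymorphism import PolymorphismCall

        return PolymorphismCall(
            ref_locus_id="L",
            genotype_id="g",
            status=POLYMORPHIC,
            ref_tract_length=ref_len,
            genotype_tract_length=geno_len,
        )

    def test_genotype_side_qualifies(self):
        assert hypervariable_calls([self._poly(18, 22)])  # (TA)9 vs (TA)11

    def test_reference_side_qualifies(self):
        assert hypervariable_calls([self._poly(20, 16)])  # (TA)10 vs (TA)8

    def test_neither_side_dropped(self):
        assert hypervariable_calls([self._poly(16, 18)]) == []  # (TA)8 vs (TA)9

    def test_non_polymorphic_never_kept(self):
        from ssrscape.polymorphism import PolymorphismCall

        mono = PolymorphismCall(
            ref_locus_id="L", genotype_id="g", status=MONOMORPHIC,
            ref_tract_length=30, genotype_tract_length=30,
        )
        assert hypervariable_calls([mono]) == []


class TestCompoundCalling:
    def test_compound_length_change_polymorphic(self):
        rng = np.random.default_rng(14)
        left = random_dna(rng, 60)
        mid = random_dna(rng, 20)
        right = random_dna(rng, 60)
        # junction guards
        left = left[:-1] + "C"
        mid = "G" + mid[1:-1] + "C"
        right = "G" + right[1:]
        ref = SequenceRecord("r", left + "TA" * 6 + mid + "ATC" * 5 + right)
        (locus,) = mine_record(ref)
        assert locus.is_compound
        sig = extract_flanks(locus, {"r": ref})
        # genotype: second component expanded
        contig = SequenceRecord("c", left + "TA" * 6 + mid + "ATC" * 7 + right)
        call = call_locus(sig, index_genotype([contig], genotype_id="g"))
        assert call.status == POLYMORPHIC
        assert call.genotype_tract_length == locus.tract_length + 6

    def test_compound_identical_monomorphic(self):
        rng = np.random.default_rng(15)
        left = random_dna(rng, 60)[:-1] + "C"
        mid = "G" + random_dna(rng, 18) + "C"
        right = "G" + random_dna(rng, 59)
        ref = SequenceRecord("r", left + "TA" * 6 + mid + "ATC" * 5 + right)
        (locus,) = mine_record(ref)
        sig = extract_flanks(locus, {"r": ref})
        contig = SequenceRecord("c", ref.seq)
        assert call_locus(sig, index_genotype([contig], genotype_id="g")).status == MONOMORPHIC
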