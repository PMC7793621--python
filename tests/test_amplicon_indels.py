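"""Indel calling, read filtering and spectrum statistics on amplicon reads."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from f0screen import amplicon_indels as ai
from f0screen import synthetic_data as sd
from f0screen.amplicon_indels import (
    AlignedRead,
    AmpliconReference,
    IndelCall,
    ReadRecord,
    SampleEditProfile,
)

Q40 = 40


def _read(read_id, seq, quality=Q40):
    return ReadRecord(read_id, seq, tuple([quality] * len(seq)))


@pytest.fixture(scope="module")
def ref_plus():
    return sd.random_amplicon(np.random.default_rng(42), locus_id="plus", strand="+")


@pytest.fixture(scope="module")
def ref_minus():
    return sd.random_amplicon(np.random.default_rng(43), locus_id="minus", strand="-")


class TestAlignAndCall:
    def test_identical_read_yields_no_calls(self, ref_plus):
        assert ai.align_and_call(_read("wt", ref_plus.sequence), ref_plus) == []

    def test_three_base_deletion_at_cut_site(self, ref_plus):
        cut = ref_plus.predicted_cut
        seq = ref_plus.sequence[: cut - 2] + ref_plus.sequence[cut + 1 :]
        calls = ai.align_and_call(_read("d3", seq), ref_plus)
        assert len(calls) == 1
        (call,) = calls
        assert call.type == "deletion" and call.length == 3

    def test_single_base_insertion_five_prime_of_pam(self, ref_plus):
        pos = ref_plus.pam_position - 4
        base = "T" if ref_plus.sequence[pos - 1] != "T" else "C"
        seq = ref_plus.sequence[:pos] + base + ref_plus.sequence[pos:]
        calls = ai.align_and_call(_read("i1", seq), ref_plus)
        assert len(calls) == 1
        (call,) = calls
        assert call.type == "insertion"
        assert call.length == 1
        assert call.inserted_sequence == base

    def test_substitutions_create_no_calls(self, ref_plus):
        cut = ref_plus.predicted_cut
        orig = ref_plus.sequence[cut]
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
        seq = ref_plus.sequence[:cut] + sub + ref_plus.sequence[cut + 1 :]
        assert ai.align_and_call(_read("sub", seq), ref_plus) == []

    def test_gap_outside_reporting_window_not_called(self, ref_plus):
        seq = ref_plus.sequence[:5] + ref_plus.sequence[7:]  # deletion at position 5
        calls = ai.align_and_call(_read("far", seq), ref_plus, window=60)
        assert calls == []

    def test_random_junk_is_unalignable(self, ref_plus):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), len(ref_plus.sequence)))
        aligned = ai.align_read(_read("junk", junk), ref_plus)
        assert not aligned.alignable


class TestCoordinateRoundTrip:
    @pytest.mark.parametrize("strand", ["plus", "minus"])
    def test_pam_relative_round_trip_both_strands(self, strand, ref_plus, ref_minus):
        ref = ref_plus if strand == "plus" else ref_minus
        cut = ref.predicted_cut
        ops = [
            ("deletion", cut - 5, cut - 1, ""),
            ("deletion", cut, cut + 7, ""),
            ("insertion", cut - 2, cut - 2, "ACGT"),
        ]
        for op in ops:
            (call,) = ai.call_from_ops([op], ref)
            assert ai.call_to_amplicon_coords(call, ref) == op

    def test_deletion_positions_mirror_between_strands(self, ref_plus, ref_minus):
        # a deletion 4 bp 5' of the PAM lands at the same PAM-relative spot
        for ref in (ref_plus, ref_minus):
            pos = ref.from_pam_relative(-4)
            lo = min(pos, ref.from_pam_relative(-4))
            (call,) = ai.call_from_ops([("deletion", lo, lo + 1, "")], ref)
            assert (call.start, call.end) == (-4, -4)


class TestFilterReads:
    def _aligned(self, length, quality, clip):
        read = ReadRecord("r", "A" * length, tuple([quality] * length))
        return AlignedRead(read, 5.0 * length, [], clip)

    def test_length_139_discarded_despite_high_quality(self):
        kept, discarded = ai.filter_reads([self._aligned(139, 41, 0.0)])
        assert kept == [] and discarded[0][1] == "short"

    def test_all_boundaries_satisfied_is_kept(self):
        # length 140, mean Q exactly 40, no clipping: strict inequalities keep it
        kept, discarded = ai.filter_reads([self._aligned(140, 40, 0.0)])
        assert len(kept) == 1 and discarded == []

    def test_quarter_clipped_discarded(self):
        kept, discarded = ai.filter_reads([self._aligned(200, 41, 50 / 200)])
        assert kept == [] and discarded[0][1] == "soft-clipped"

    def test_mean_quality_below_40_discarded(self):
        kept, discarded = ai.filter_reads([self._aligned(160, 39, 0.0)])
        assert kept == [] and discarded[0][1] == "quality"

    def test_missing_qualities_fail_quality_rule(self):
        read = ReadRecord("r", "A" * 150, None)
        kept, discarded = ai.filter_reads([AlignedRead(read, 750.0, [], 0.0)])
        assert kept == [] and discarded[0][1] == "quality"

    def test_soft_clip_fraction_computed_from_alignment(self, ref_plus):
        # read = amplicon + 40% junk overhang: free end gaps leave it unaligned
        rng = np.random.default_rng(1)
        junk = "".join(rng.choice(list("ACGT"), int(0.4 * len(ref_plus.sequence))))
        aligned = ai.align_read(_read("ov", ref_plus.sequence + junk), ref_plus)
        assert aligned.clipped_fraction == pytest.approx(
            len(junk) / (len(ref_plus.sequence) + len(junk)), abs=0.02
        )


class TestClassifyFrameshift:
    @pytest.mark.parametrize(
        "signed_lengths,expected",
        [([2, 1], False), ([-1], True), ([-4, 1], False), ([], False), ([5], True)],
    )
    def test_examples(self, signed_lengths, expected):
        calls = [
            IndelCall("insertion", 0, 0, n, "A" * n)
            if n > 0
            else IndelCall("deletion", 0, -n - 1, -n)
            for n in signed_lengths
        ]
        assert ai.classify_frameshift(calls) is expected

    @given(st.lists(st.integers(-12, 12).filter(lambda n: n != 0), max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force_summation(self, lengths):
        calls = [
            IndelCall("insertion", 0, 0, n, "A" * n)
            if n > 0
            else IndelCall("deletion", 0, -n - 1, -n)
            for n in lengths
        ]
        assert ai.classify_frameshift(calls) == (sum(lengths) % 3 != 0)


class TestSummarizeSample:
    def test_indel_present_in_control_not_counted(self, ref_plus):
        cut = ref_plus.predicted_cut
        mut = ref_plus.sequence[: cut - 1] + ref_plus.sequence[cut:]
        reads = [_read(f"r{i}", mut) for i in range(80)]
        control = ai.summarize_sample(
            reads, ref_plus, animal_id="control", coverage_floor=0, is_control=True
        )
        sample = ai.summarize_sample(
            [_read(f"s{i}", mut) for i in range(80)],
            ref_plus,
            control_profile=control,
            animal_id="fish1",
        )
        assert sample.frac_mutated == 0.0
        assert sample.indels == []

    def test_low_coverage_sample_marked_excluded(self, ref_plus):
        reads = [_read(f"r{i}", ref_plus.sequence) for i in range(50)]
        with pytest.warns(UserWarning):
            profile = ai.summarize_sample(reads, ref_plus)  # 50 < 60x single-read
        assert profile.excluded

    def test_rare_indel_dropped_as_sequencing_error(self, ref_plus):
        cut = ref_plus.predicted_cut
        mut = ref_plus.sequence[: cut - 1] + ref_plus.sequence[cut:]
        reads = [_read(f"r{i}", ref_plus.sequence) for i in range(399)] + [_read("m", mut)]
        with pytest.warns(UserWarning):
            profile = ai.summarize_sample(reads, ref_plus)  # 1/400 < 0.005
        assert profile.frac_mutated == 0.0

    def test_recovers_seventy_percent_edited(self, ref_plus):
        cohort = sd.generate_amplicon_cohort(
            [ref_plus],
            sd.EditModel(p_mutation=0.7),
            n_animals=1,
            reads_per_sample=600,
            rng=7,
        )
        control = ai.summarize_sample(
            cohort.controls["plus"], ref_plus, animal_id="control", coverage_floor=0, is_control=True
        )
        profile = ai.summarize_sample(
            cohort.reads[("plus", "fish1")],
            ref_plus,
            control_profile=control,
            animal_id="fish1",
        )
        truth = cohort.truth.iloc[0]
        assert profile.frac_mutated == pytest.approx(truth.true_frac_mutated, abs=0.02)
        assert profile.frac_frameshift == pytest.approx(
            truth.true_frac_frameshift, abs=0.02
        )


def _profile_with(indel_specs, locus="L", animal="a"):
    calls = [
        IndelCall("deletion", start, end, end - start + 1, "", frequency=freq)
        for (start, end, freq) in indel_specs
    ]
    return SampleEditProfile(locus, animal, 100, 0, 0.5, 0.3, indels=calls)


class TestTop10Sharing:
    def _ten(self, offset=0):
        return [(-30 + 3 * i + offset, -29 + 3 * i + offset, 0.1 - 0.005 * i) for i in range(10)]

    def test_self_sharing_is_ten(self):
        p = _profile_with(self._ten())
        assert ai.top10_sharing(p, p) == 10

    def test_disjoint_sets_share_zero(self):
        a = _profile_with(self._ten())
        b = _profile_with(self._ten(offset=60), animal="b")
        assert ai.top10_sharing(a, b) == 0

    def test_constructed_three_indel_overlap(self):
        a_specs = self._ten()
        b_specs = a_specs[:3] + self._ten(offset=60)[3:]
        a, b = _profile_with(a_specs), _profile_with(b_specs, animal="b")
        assert ai.top10_sharing(a, b) == 3
        assert ai.top10_sharing(b, a) == 3  # symmetric

    def test_fewer_than_ten_indels_rejected(self):
        a = _profile_with(self._ten())
        small = _profile_with(self._ten()[:5], animal="small")
        with pytest.raises(ValueError):
            ai.top10_sharing(a, small)


class TestUniqueIndelSpectrum:
    def test_high_frequency_indel_counts_once_per_sample(self):
        p = _profile_with([(-5, -3, 0.4)])
        spectrum = ai.unique_indel_spectrum([p])
        assert spectrum.n_unique == 1
        assert spectrum.length_counts.to_dict() == {-3: 1}

    def test_deletion_positions_tallied_per_nucleotide(self):
        p = _profile_with([(-5, -3, 0.4)])
        spectrum = ai.unique_indel_spectrum([p])
        assert spectrum.deletion_positions.to_dict() == {-5: 1, -4: 1, -3: 1}

    def test_empty_cohort_empty_histogram(self):
        spectrum = ai.unique_indel_spectrum([])
        assert spectrum.n_unique == 0
        assert len(spectrum.length_counts) == 0

    def test_deletion_insertion_mix_recovered(self):
        rng = np.random.default_rng(21)
        refs = [
            sd.random_amplicon(rng, locus_id=f"L{i}") for i in range(3)
        ]
        cohort = sd.generate_amplicon_cohort(
            refs, sd.EditModel(repertoire_size=40), n_animals=2, reads_per_sample=200, rng=rng
        )
        counts = cohort.true_indels["type"].value_counts(normalize=True)
        spectrum_truth = counts.get("deletion", 0.0)
        # generator draws the repertoire from the 57:43 law
        assert spectrum_truth == pytest.approx(0.57, abs=0.12)


class TestMergePairs:
    def test_overlapping_mates_merged(self, ref_plus):
        seq = ref_plus.sequence
        r1 = _read("p/1", seq[:150])
        from Bio.Seq import reverse_complement

        r2 = ReadRecord("p/2", reverse_complement(seq[100:]), tuple([Q40] * (len(seq) - 100)))
        merged = ai.merge_pairs(r1, r2)
        assert merged.sequence == seq
        assert merged.mate == "merged"

    def test_non_overlapping_mates_fall_back_to_r1(self):
        r1 = _read("p/1", "ACGTACGTACGTACGTACGT")
        r2 = _read("p/2", "TTTTTTTTTTGGGGGGGGGG")
        merged = ai.merge_pairs(r1, r2)
        assert merged.sequence == r1.sequence
        assert merged.mate == "R1"


def test_reference_validation_rejects_misplaced_pam():
    with pytest.raises(ValueError):
        AmpliconReference("x", "ACGT" * 20, 10, 30, "+", 35)


def test_indel_call_validation():
    with pytest.raises(ValueError):
        IndelCall("deletion", 0, -2, 3)
    with pytest.raises(ValueError):
        IndelCall("insertion", 0, 0, 2, "A")
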