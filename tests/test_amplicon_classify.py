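"""Read QC, linker trimming, merging, alignment and outcome classification."""

import pytest

from proguide.amplicon_classify import (
    CS1,
    CS2,
    AlignmentCalls,
    ClassifierRules,
    align_read,
    classify,
    classify_reads,
    merge_pairs,
    profile,
    qc_reads,
    trim_linkers,
)
from proguide.seq_core import FastqRead, revcomp

RULES = ClassifierRules()


def _read(seq, name="r", qual=37):
    return FastqRead(name, seq, [qual] * len(seq))


class TestQc:
    def test_length_bounds_exclusive_of_limit(self):
        reads = [_read("A" * n, name=f"len{n}") for n in (40, 50, 100, 160, 161)]
        kept, counts = qc_reads(reads)
        assert [len(r) for r in kept] == [50, 100, 160]
        assert counts["too_short"] == 1 and counts["too_long"] == 1

    def test_trigger_reads_dropped_with_one_mismatch(self):
        trig = "GACGTCTAAGAAACCATTAT"
        near = "A" + trig[1:]
        far = "CC" + trig[2:]
        reads = [_read(trig + "C" * 40, "exact"), _read(near + "C" * 40, "near"),
                 _read(far + "C" * 40, "far")]
        kept, counts = qc_reads(reads, trigger_spacer=trig)
        assert [r.name for r in kept] == ["far"]
        assert counts["trigger"] == 2

    def test_empty_input(self):
        kept, counts = qc_reads([])
        assert kept == [] and counts["retained"] == 0


class TestTrimLinkers:
    def test_exact_cs1_removed(self):
        x = "ACGT" * 10
        assert trim_linkers(_read(CS1 + x)).bases == x

    def test_one_mismatch_tolerated_two_not(self):
        x = "ACGT" * 10
        one = "T" + CS1[1:]
        two = "TT" + CS1[2:]
        assert trim_linkers(_read(one + x)).bases == x
        assert trim_linkers(_read(two + x)).bases == two + x

    def test_cs2_and_mate_orientations(self):
        x = "ACGT" * 10
        assert trim_linkers(_read(x + CS2)).bases == x
        assert trim_linkers(_read(revcomp(CS2) + x)).bases == x
        assert trim_linkers(_read(x + revcomp(CS1))).bases == x

    def test_both_ends_trimmed(self):
        x = "ACGT" * 10
        assert trim_linkers(_read(CS1 + x + CS2)).bases == x


class TestMergePairs:
    def test_exact_overlap_arithmetic(self):
        left = "ACGGATTACCAGGATCACTTGG"
        right = "CACTTGGTTCAGACCATGAC"  # shares 7... use explicit overlap 12
        amplicon = "ACGGATTACCAGGATCACTTGGTTCAGACCATGACCAGTA"
        r1 = _read(amplicon[:25])
        r2 = _read(revcomp(amplicon[13:]))
        m = merge_pairs(r1, r2)
        assert m is not None
        assert m.bases == amplicon
        assert len(m.bases) == len(r1) + len(r2) - 12

    def test_overlap_below_minimum_fails(self):
        amplicon = "ACGGATTACCAGGATCACTTGGTTCAGACCATGACCAGTA"
        r1 = _read(amplicon[:24])
        r2 = _read(revcomp(amplicon[15:]))  # overlap 9
        assert merge_pairs(r1, r2) is None

    def test_mismatch_free_overlap_preferred(self):
        # r1 suffix AAAA could align at several offsets into a poly-A run
        # with mismatches; the mismatch-free candidate must win
        amplicon = "CGTACGTACGTAAAAAAAAAAACGTACGTACG"
        r1 = _read(amplicon[:20])
        r2 = _read(revcomp(amplicon[8:]))
        m = merge_pairs(r1, r2)
        assert m is not None and m.bases == amplicon

    def test_quality_resolves_disagreement(self):
        amplicon = "ACGGATTACCAGGATCACTTGGTTCAGACCATGA"
        r1 = _read(amplicon[:24])
        rc2 = amplicon[10:]
        bad = list(rc2)
        bad[2] = "A" if bad[2] != "A" else "C"  # error inside the overlap
        r2 = FastqRead("r", revcomp("".join(bad)), [40] * len(bad))
        m = merge_pairs(r1, r2)
        # r2's disagreeing base has higher quality and wins
        assert m.bases != amplicon
        assert m.bases[12] == bad[2]


class TestAlignRead:
    REF = "ACGGATTACCAGGATCACTTGGTTCAGACCATGACCAGTACCGGATAAGC"

    def test_identical_read_has_no_calls(self):
        assert align_read(self.REF, self.REF).is_empty

    def test_clean_deletion_recovered_exactly(self):
        read = self.REF[:20] + self.REF[35:]
        calls = align_read(read, self.REF)
        assert calls.deletions == [(20, 35)]
        assert not calls.substitutions and not calls.insertions

    def test_single_substitution(self):
        read = self.REF[:10] + ("A" if self.REF[10] != "A" else "C") + self.REF[11:]
        calls = align_read(read, self.REF)
        assert len(calls.substitutions) == 1
        assert calls.substitutions[0][0] == 10
        assert not calls.deletions

    def test_deletion_left_aligned_in_homopolymer(self):
        ref = "ACGTAAAAACGT"
        read = "ACGTAAAACGT"  # one A of the run deleted: left-aligned to (4,5)
        calls = align_read(read, ref)
        assert calls.deletions == [(4, 5)]

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            align_read("", self.REF)


def _calls(subs=0, dels=(), ins=()):
    return AlignmentCalls(
        substitutions=[(i, "A", "C") for i in range(subs)],
        deletions=list(dels), insertions=list(ins))


class TestClassify:
    CL, CR = 20, 40

    def clf(self, calls, **kw):
        return classify(calls, self.CL, self.CR, RULES, **kw)

    def test_perfect(self):
        assert self.clf(_calls(dels=[(20, 40)])) == "perfect"

    def test_perfect_with_substitution_is_adjacent(self):
        assert self.clf(_calls(subs=1, dels=[(20, 40)])) == "perfect_adjacent"

    def test_readthrough(self):
        assert self.clf(_calls()) == "readthrough"
        assert self.clf(_calls(subs=3)) == "readthrough"

    def test_adjacent_window(self):
        assert self.clf(_calls(subs=3, dels=[(18, 41)])) == "perfect_adjacent"
        assert self.clf(_calls(dels=[(16, 40)])) == "other_deletion"  # 4 bp off

    def test_substitution_cap_boundary(self):
        assert self.clf(_calls(subs=5, dels=[(19, 40)])) == "perfect_adjacent"
        assert self.clf(_calls(subs=6, dels=[(19, 40)])) == "other_deletion"

    def test_extra_deletion_rules(self):
        junction = (19, 41)
        ok = [(0, 4), (6, 10), (12, 14), (44, 46)]      # 4 extras, two > 2 bp
        assert self.clf(_calls(dels=[junction, *ok])) == "perfect_adjacent"
        too_many = ok + [(48, 49)]
        assert self.clf(_calls(dels=[junction, *too_many])) == "other_deletion"
        too_long = [(0, 5)]                             # 5 bp extra deletion
        assert self.clf(_calls(dels=[junction, *too_long])) == "other_deletion"
        three_over2 = [(0, 3), (5, 8), (10, 13)]
        assert self.clf(_calls(dels=[junction, *three_over2])) == "other_deletion"

    def test_inversion_exact_match(self):
        ref = "ACGGATTACCAGGATCACTTGGTTCAGACCATGACCAGTACCGGATAAGC"
        inv = ref[:20] + revcomp(ref[20:40]) + ref[40:]
        calls = align_read(inv, ref)
        assert classify(calls, 20, 40, RULES, read=inv, reference=ref,
                        inversion_template=inv) == "inversion"

    def test_insertion_tolerance_in_adjacent(self):
        assert self.clf(_calls(subs=1, dels=[(19, 40)],
                               ins=[(5, "A")])) == "perfect_adjacent"
        assert self.clf(_calls(subs=1, dels=[(19, 40)],
                               ins=[(5, "AC")])) == "other_deletion"


class TestProfile:
    REF = "ACGGATTACCAGGATCACTTGGTTCAGACCATGACCAGTACCGGATAAGC"

    def test_identical_perfect_reads_give_unit_frequency(self):
        read = self.REF[:20] + self.REF[40:]
        reads = [_read(read, name=f"r{i}") for i in range(100)]
        classified = classify_reads(reads, self.REF, 20, 40)
        prof = profile(classified, self.REF)
        assert prof.class_fractions == {"perfect": 1.0}
        assert (prof.per_base_deletion_freq[20:40] == 1.0).all()
        assert prof.per_base_deletion_freq[:20].sum() == 0
        assert prof.per_base_deletion_freq[40:].sum() == 0
        assert prof.deletion_sizes_by_class["perfect"][20] == 100

    def test_singletons_excluded(self):
        common = [_read(self.REF, name=f"a{i}") for i in range(5)]
        single = [_read(self.REF[:20] + self.REF[40:], name="s")]
        classified = classify_reads(common + single, self.REF, 20, 40)
        prof = profile(classified, self.REF)
        assert prof.n_reads == 5
        assert prof.excluded_low_support == 1
        assert prof.class_fractions == {"readthrough": 1.0}

    def test_mixture_fractions_count_reads(self):
        a = [_read(self.REF, name=f"a{i}") for i in range(60)]
        b = [_read(self.REF[:20] + self.REF[40:], name=f"b{i}") for i in range(40)]
        classified = classify_reads(a + b, self.REF, 20, 40)
        prof = profile(classified, self.REF)
        assert prof.class_fractions == {"readthrough": 0.6, "perfect": 0.4}
        assert abs(sum(prof.class_fractions.values()) - 1) < 1e-12

    def test_order_and_duplication_invariance(self):
        a = [_read(self.REF, name=f"a{i}") for i in range(4)]
        b = [_read(self.REF[:20] + self.REF[40:], name=f"b{i}") for i in range(2)]
        f1 = profile(classify_reads(a + b, self.REF, 20, 40), self.REF).class_fractions
        f2 = profile(classify_reads(b + a, self.REF, 20, 40), self.REF).class_fractions
        assert f1 == f2
        f3 = profile(classify_reads(a + b + b, self.REF, 20, 40),
                     self.REF).class_fractions
        assert f3 == {"readthrough": 0.5, "perfect": 0.5}

    def test_empty_profile_warns(self):
        single = [_read(self.REF, name="s")]
        classified = classify_reads(single, self.REF, 20, 40)
        with pytest.warns(UserWarning):
            prof = profile(classified, self.REF)
        assert prof.n_reads == 0
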