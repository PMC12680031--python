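"""CTS candidate generation and the composition/restriction/orthogonality filters."""

import math

import pytest

from proguide.cts_library import (
    CtsCandidate,
    FilterParams,
    LibraryConfig,
    build_library,
    composition_filter,
    generate_candidates,
    min_hamming_to_windows,
    orthogonality_filter,
    restriction_filter,
)
from proguide.fixtures import ToyGenomeSpec, make_toy_genome
from proguide.seq_core import GenomeIndex, NucSeq, revcomp

PARAMS = FilterParams()


class TestGeneration:
    def test_structure_and_determinism(self):
        a = generate_candidates(5, seed=1)
        assert len(a) == 5
        for c in a:
            assert len(c.site) == 23
            assert c.pam in ("AGG", "TGG", "CGG", "GGG")
        b = generate_candidates(5, seed=1)
        assert [c.site for c in a] == [c.site for c in b]
        assert [c.site for c in generate_candidates(5, seed=2)] != [c.site for c in a]

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            generate_candidates(0, seed=1)

    def test_gc_rule_alone_matches_binomial(self):
        # GC in [0.35, 0.75] over 20 uniform bases: P(7 <= K <= 15), K~Bin(20, 1/2)
        p_gc = sum(math.comb(20, k) for k in range(7, 16)) / 2**20
        assert round(p_gc, 4) == 0.9364
        n = 10_000
        cands = generate_candidates(n, seed=42)
        ok = sum(0.35 <= (c.protospacer.count("G") + c.protospacer.count("C")) / 20 <= 0.75
                 for c in cands)
        se = math.sqrt(p_gc * (1 - p_gc) / n)
        assert abs(ok / n - p_gc) <= 3 * se


class TestCompositionFilter:
    def test_distal_g_rule(self):
        # 5 G's in the 10 bases most distal to the PAM
        v = composition_filter(CtsCandidate("GGGGGAAAAAAAAAAAAAAA", "TGG"))
        assert not v and v.rule == "distal-G"
        # 4 distal G's pass the G rule (then GC = 4/20 fails downstream)
        v = composition_filter(CtsCandidate("GGGGAAAAAAAAAAAAAAAA", "TGG"))
        assert v.rule != "distal-G"

    def test_proximal_t_rule(self):
        # 3 T's in the 4 bases adjacent to the PAM
        v = composition_filter(CtsCandidate("ACGACGACGACGACGCTTTA", "TGG"))
        assert not v and v.rule == "proximal-T"
        # 2 proximal T's are tolerated
        assert composition_filter(CtsCandidate("ACGACGACGACGACGCGTTA", "TGG"))

    def test_gc_bounds_inclusive(self):
        assert composition_filter(CtsCandidate("ACGTACGTACGTACGTACGT", "TGG"))
        # GC = 7/20 = 35% exactly: inclusive bound
        assert composition_filter(CtsCandidate("GCGCGCGATAATAAATAAAA", "TGG"))
        v = composition_filter(CtsCandidate("GCGCGCATAATAAATAAAAA", "TGG"))  # 6/20
        assert not v and v.rule == "GC"

    def test_rule_order_first_violation_named(self):
        # violates both distal-G and GC; distal-G is reported
        v = composition_filter(CtsCandidate("GGGGGGGGGGGGGGGGGGGG", "TGG"))
        assert v.rule == "distal-G"


class TestRestrictionFilter:
    def test_candidate_containing_site_fails(self):
        v = restriction_filter(CtsCandidate("AAGAATTCAAACACACACAC", "TGG"))
        assert not v and v.rule == "restriction-site"

    def test_neutral_candidate_passes(self):
        assert restriction_filter(CtsCandidate("ACGTACGTACGTACGTACGT", "TGG"))

    def test_reverse_strand_site_detected(self):
        # GAGACG is the reverse complement of the BsmBI site CGTCTC
        v = restriction_filter(CtsCandidate("AAGAGACGAAACACACACAC", "TGG"))
        assert not v

    def test_junction_spanning_site(self):
        # candidate starting GTCTC after a flank ending in C completes the
        # BsmBI site CGTCTC across the junction
        cand = CtsCandidate("GTCTCAACAACAACAACAAC", "TGG")
        v = restriction_filter(cand, flank5="ACACAC", flank3="ACACAA")
        assert not v and v.rule == "restriction-site"
        # same candidate after a flank ending in A: no site forms
        assert restriction_filter(cand, flank5="ACACAA", flank3="ACACAA")

    def test_site_only_in_flanks_is_ignored(self):
        # pre-existing EcoRI site in the backbone does not penalise the candidate
        assert restriction_filter(
            CtsCandidate("ACGTACGTACGTACGTACGT", "TGG"),
            flank5="AAGAATTCAA", flank3="ACACAC")

    def test_short_nonempty_flank_rejected(self):
        with pytest.raises(ValueError):
            restriction_filter(CtsCandidate("ACGTACGTACGTACGTACGT", "TGG"),
                               flank5="ACg")


class TestOrthogonalityFilter:
    def test_planted_candidate_fails_with_zero_mismatches(self):
        cand = CtsCandidate("ACGGACTAACGGACTACCTA", "TGG")
        genome, _ = make_toy_genome(
            ToyGenomeSpec(2000, seed=5, plants=[(cand.protospacer, 0, "+")]))
        v = orthogonality_filter(cand, genome)
        assert not v
        assert v.stats["min_mismatches_found"] == 0

    def test_poly_a_genome_passes(self):
        cand = CtsCandidate("ACGTACGTACGTACGTACGT", "TGG")
        genome = GenomeIndex([NucSeq("A" * 10_000, "chrA")])
        v = orthogonality_filter(cand, genome)
        assert v
        assert v.stats["min_mismatches_found"] == 15  # 5 A's in the protospacer
        # the site's ...GTTGG junction shares "TT" with the bottom strand
        assert v.stats["max_stretch_found"] == 2

    def test_long_shared_stretch_fails_despite_mismatches(self):
        # a PAM-spanning 16-mer of the site embedded in a C background: every
        # genome window still mismatches the (C-free) protospacer at >= 7
        # positions, so only the stretch rule can reject it
        cand = CtsCandidate("ATGGATTAAGAGGATAAGTA", "TGG")
        genome = GenomeIndex(
            [NucSeq("C" * 500 + cand.site[7:23] + "C" * 500, "chr")])
        v = orthogonality_filter(cand, genome)
        assert not v and v.rule == "stretch"
        assert v.stats["max_stretch_found"] == 16
        assert v.stats["min_mismatches_found"] >= 7

    def test_reverse_strand_plant_detected(self):
        cand = CtsCandidate("ACGGACTAACGGACTACCTA", "TGG")
        genome = GenomeIndex(
            [NucSeq("C" * 300 + revcomp(cand.protospacer) + "C" * 300, "chr")])
        v = orthogonality_filter(cand, genome)
        assert not v
        assert v.stats["min_mismatches_found"] == 0

    def test_min_hamming_window_scan(self):
        # planted window at distance 3 against an A-background
        proto = "ACGGACTAACGGACTACCTA"
        m = list(proto)
        m[0], m[5], m[13] = "T", "G", "A"
        mutated = "".join(m)
        assert sum(a != b for a, b in zip(proto, mutated)) == 3
        assert min_hamming_to_windows(proto, "A" * 100 + mutated + "A" * 100) == 3


class TestBuildLibrary:
    def test_stage_counts_non_increasing_and_verdicts(self):
        cfg = LibraryConfig(n=400, seed=7)
        survivors, report = build_library(cfg)
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        assert report.stage_counts["final"] == len(survivors)
        # every survivor re-checks clean against the individual rules
        for c in survivors:
            assert composition_filter(c, cfg.params)
            assert restriction_filter(c, cfg.flank5, cfg.flank3, cfg.params)

    def test_planted_candidates_fail_orthogonality(self):
        cfg0 = LibraryConfig(n=60, seed=9)
        base, _ = build_library(cfg0)
        planted = [c.protospacer for c in base[:2]]
        genome, _ = make_toy_genome(
            ToyGenomeSpec(3000, seed=1, plants=[(p, 0, "+") for p in planted]))
        cfg = LibraryConfig(n=60, seed=9, genomes=(("toy", genome),))
        survivors, report = build_library(cfg)
        ids = {c.id for c in survivors}
        for c in base[:2]:
            assert c.id not in ids
            assert report.verdicts[c.id].startswith("mismatch")

    def test_zero_genomes_means_composition_and_restriction_only(self):
        a, _ = build_library(LibraryConfig(n=100, seed=3))
        expected = [c for c in generate_candidates(100, 3)
                    if composition_filter(c) and restriction_filter(c)]
        assert [c.site for c in a] == [c.site for c in expected]
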