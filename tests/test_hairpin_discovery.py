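"""Folding engine, structure decomposition and the 11-criterion screen."""

import numpy as np
import pytest

from circamir import hairpin_discovery as hp
from circamir.synthetic_data import build_hairpin

from oracles import enum_best_score


def make_candidate(built, energy=-60.0, arm="5p"):
    return hp.HairpinCandidate(built.sequence, built.mature,
                               built.mature_start, arm,
                               structure=built.structure, energy=energy)


class TestFold:
    def test_simple_hairpin(self):
        struct, energy = hp.fold("GGGAAACCC".ljust(10, "A"))
        assert struct.startswith("(((...)))")
        assert energy == -6.0  # three GC pairs, weight 2

    def test_no_complementarity_gives_open_chain(self):
        struct, energy = hp.fold("A" * 12)
        assert struct == "." * 12 and energy == 0.0

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            hp.fold("ACGTNNACGTAC")
        with pytest.raises(ValueError):
            hp.fold("ACGUA")  # too short

    def test_matches_exhaustive_enumeration(self):
        # optimality against a brute-force enumeration of every nested
        # pairing, across random sequences up to length 16
        rng = np.random.default_rng(42)
        for _ in range(220):
            n = int(rng.integers(10, 17))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            _, energy = hp.fold(seq)
            assert -energy == enum_best_score(seq), seq

    def test_structure_score_consistent_with_energy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGU"), size=40))
            struct, energy = hp.fold(seq)
            pt = hp.pair_table(struct)
            score = sum(hp.pair_score(seq[i], seq[j])
                        for i, j in enumerate(pt) if j > i)
            assert score == -energy
            # minimum loop size respected
            for i, j in enumerate(pt):
                if j > i:
                    assert j - i > hp.MIN_LOOP


class TestStructureParsing:
    def test_pair_table_balanced(self):
        assert hp.pair_table("((..))") == [5, 4, -1, -1, 1, 0]
        with pytest.raises(ValueError):
            hp.pair_table("((.)")
        with pytest.raises(ValueError):
            hp.pair_table(".))")

    def test_multibranch_rejected(self):
        assert hp.parse_hairpin("((...))((...))") is None
        assert hp.parse_hairpin("(((...)).((...)))") is None
        assert hp.parse_hairpin("......") is None

    def test_bulge_decomposition(self):
        #  ((..((...))))  : one bulge of 2 nt, 5' side only (biased)
        geom = hp.parse_hairpin("((..((...))))")
        assert geom is not None
        assert len(geom.pairs) == 4
        assert geom.loop_len == 3
        assert len(geom.bulges) == 1
        b = geom.bulges[0]
        assert b.size == 2 and b.biased and b.asymmetry == 2


class TestEvaluateCriteria:
    def test_perfect_stem_passes_everything(self):
        built = build_hairpin([("pair", 30)], loop_len=8,
                              mature_start=0, mature_len=22,
                              rng=np.random.default_rng(0))
        rep = hp.evaluate_criteria(make_candidate(built))
        assert rep.overall and all(rep.checks.values())
        assert rep.values["c2_stem_pairs"] == 30
        assert rep.values["c10_mature_pairs"] == 22
        assert rep.values["c11_mature_in_stem_pct"] == 100.0

    def test_truncated_stem_fails_pair_count(self):
        built = build_hairpin([("pair", 15)], loop_len=20,
                              mature_start=0, mature_len=18,
                              rng=np.random.default_rng(0))
        rep = hp.evaluate_criteria(make_candidate(built))
        assert not rep.checks["c2_stem_pairs"] and not rep.overall

    def test_wide_loop_fails_loop_criterion(self):
        built = build_hairpin([("pair", 20)], loop_len=21,
                              mature_start=0, mature_len=20,
                              rng=np.random.default_rng(0))
        rep = hp.evaluate_criteria(make_candidate(built))
        assert not rep.checks["c5_loop_len"]
        assert rep.values["c5_loop_len"] == 21

    def test_multibranch_not_a_hairpin(self):
        cand = hp.HairpinCandidate("GGGAAACCCGGGAAACCC", "GGGAAACCC", 0, "5p",
                                   structure="(((...)))(((...)))",
                                   energy=-12.0)
        rep = hp.evaluate_criteria(cand)
        assert not rep.overall and rep.reason == "not a hairpin"

    def test_mature_outside_precursor_errors(self):
        built = build_hairpin([("pair", 20)], loop_len=8,
                              mature_start=0, mature_len=22,
                              rng=np.random.default_rng(0))
        cand = hp.HairpinCandidate(built.sequence, "G" * 22,
                                   len(built.sequence) - 10, "5p",
                                   structure=built.structure, energy=-40.0)
        with pytest.raises(ValueError):
            hp.evaluate_criteria(cand)

    def test_purity(self):
        built = build_hairpin([("pair", 18), ("bulge", 2, 1), ("pair", 4)],
                              loop_len=8, mature_start=0, mature_len=18,
                              rng=np.random.default_rng(5))
        cand = make_candidate(built)
        r1 = hp.evaluate_criteria(cand)
        r2 = hp.evaluate_criteria(cand)
        assert r1.checks == r2.checks and r1.values == r2.values


class TestExtractCandidates:
    GENOME = "A" * 1000 + "GGCCGGCCGGCCGGCCGGCCGG" + "A" * 1000

    def test_plus_strand_windows(self):
        tag = "GGCCGGCCGGCCGGCCGGCCGG"
        cands = hp.extract_candidates((1000, 1022), "+", self.GENOME, tag,
                                      flank=100)
        a, b = cands
        assert a.arm == "5p" and a.precursor == self.GENOME[1000:1122]
        assert a.mature_start == 0
        assert b.arm == "3p" and b.precursor == self.GENOME[900:1022]
        assert b.mature_start == 100

    def test_minus_strand_windows_are_revcomp(self):
        tag = hp.revcomp("GGCCGGCCGGCCGGCCGGCCGG")
        cands = hp.extract_candidates((1000, 1022), "-", self.GENOME, tag,
                                      flank=50)
        a, b = cands
        assert a.precursor == hp.revcomp(self.GENOME[950:1022])
        assert a.precursor.startswith(tag) and a.mature_start == 0
        assert b.precursor == hp.revcomp(self.GENOME[1000:1072])
        assert b.precursor.endswith(tag)

    def test_truncation_at_genome_start(self):
        tag = "GGCCG"
        cands = hp.extract_candidates((5, 10), "+", self.GENOME[:200], tag,
                                      flank=100)
        b = cands[1]
        assert b.precursor == self.GENOME[:10] and b.mature_start == 5


class TestCallNovel:
    def _setup(self, counts):
        import numpy as np
        built = build_hairpin([("pair", 25)], loop_len=8, mature_start=0,
                              mature_len=22, rng=np.random.default_rng(11))
        genome = "A" * 150 + built.sequence + "A" * 150
        tag = built.mature
        loci = {tag: [((150, 172), "+")]}
        return {tag: counts}, loci, genome, tag

    def test_abundant_compliant_tag_called(self):
        tags, loci, genome, tag = self._setup({"BO": 15, "AO": 2})
        calls = hp.call_novel(tags, loci, genome)
        assert [c.tag for c in calls] == [tag]
        assert calls[0].candidate.arm == "5p"

    def test_abundance_boundary_is_inclusive_at_10(self):
        tags, loci, genome, tag = self._setup({"BO": 9, "AO": 9})
        assert hp.call_novel(tags, loci, genome) == []
        tags[tag]["AO"] = 10
        assert len(hp.call_novel(tags, loci, genome)) == 1

    def test_external_fold_results_used(self):
        tags, loci, genome, tag = self._setup({"BO": 50, "AO": 50})
        cand = hp.extract_candidates((150, 172), "+", genome, tag)[0]
        # external folder says the window is unstructured -> no call
        ext = {cand.precursor: ("." * len(cand.precursor), 0.0)}
        prec_b = hp.extract_candidates((150, 172), "+", genome, tag)[1]
        ext[prec_b.precursor] = ("." * len(prec_b.precursor), 0.0)
        assert hp.call_novel(tags, loci, genome, fold_results=ext) == []
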