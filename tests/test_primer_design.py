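import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from cladescout import primer_design as pdesign
from cladescout.io_formats import OperonAnnotation, OtuRecord, ValidationError
from conftest import mutate_dna, random_dna
from oracles import nn_melting_temperature, scan_decamer_hits


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", "GCAT"), ("RY", "RY"), ("ACGTN", "NACGT"), ("WSKM", "KMSW")],
    )
    def test_examples(self, seq, expected):
        assert pdesign.reverse_complement(seq) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=40))
    def test_involution(self, seq):
        assert pdesign.reverse_complement(pdesign.reverse_complement(seq)) == seq

    def test_rejects_non_iupac(self):
        with pytest.raises(ValidationError):
            pdesign.reverse_complement("ACX")


class TestGcFraction:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0)])
    def test_examples(self, seq, expected):
        assert pdesign.gc_fraction(seq) == expected

    def test_ambiguity_rejected(self):
        with pytest.raises(ValidationError, match="ambiguous"):
            pdesign.gc_fraction("ACGN")


class TestMeltingTemperature:
    @pytest.mark.parametrize("seq,expected", [("AAAA", 8.0), ("GGCC", 16.0), ("ATGC", 12.0)])
    def test_wallace_rule(self, seq, expected):
        assert pdesign.melting_temperature(seq, "wallace") == expected

    def test_nearest_neighbor_matches_independent_oracle(self, rng):
        """Tm_NN equals a from-scratch unified-parameter implementation to 0.1 degC."""
        fixed = "AGCTTGACCTGAAGCTGAAC"
        assert pdesign.melting_temperature(fixed) == pytest.approx(
            nn_melting_temperature(fixed), abs=0.1
        )
        for _ in range(25):
            seq = random_dna(rng, int(rng.integers(16, 22)))
            assert pdesign.melting_temperature(seq) == pytest.approx(
                nn_melting_temperature(seq), abs=0.1
            )

    def test_nn_duplex_symmetry(self, rng):
        """A duplex melts at one temperature: Tm(s) == Tm(revcomp(s))."""
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(16, 22)))
            assert pdesign.melting_temperature(seq) == pytest.approx(
                pdesign.melting_temperature(pdesign.reverse_complement(seq)), abs=1e-6
            )

    def test_too_short_for_nn(self):
        with pytest.raises(ValidationError):
            pdesign.melting_temperature("A", "nearest_neighbor")


def _toy_annotation(rng, its2_len=120, flanks=(150, 80, 40, 150)):
    lens = {"SSU18S": flanks[0], "ITS1": flanks[1], "r5_8S": flanks[2], "ITS2": its2_len, "LSU28S": flanks[3]}
    seq = random_dna(rng, sum(lens.values()))
    regions, pos = [], 0
    for name in ("SSU18S", "ITS1", "r5_8S", "ITS2", "LSU28S"):
        regions.append((name, pos, pos + lens[name]))
        pos += lens[name]
    return OperonAnnotation("t1", seq, regions)


def _candidate_at(annotation, offset, length, direction="forward"):
    var_start, _ = annotation.region("ITS2")
    start = var_start + offset
    slice_ = annotation.sequence[start : start + length]
    seq = slice_ if direction == "forward" else pdesign.reverse_complement(slice_)
    return pdesign.PrimerCandidate(
        target_id="t1",
        direction=direction,
        sequence=seq,
        template_start=start,
        template_end=start + length,
        tm=0.0,
        gc_pct=0.0,
        three_prime_hits=0,
        flank_distance=0,
    )


class TestThreePrimeSpecificity:
    def test_planted_decamer_counted_by_scan_oracle(self, rng):
        decamer = random_dna(rng, 10)
        hot = [OtuRecord(f"hit{i}", random_dna(rng, 60) + decamer + random_dna(rng, 40)) for i in range(5)]
        cold = [OtuRecord(f"miss{i}", random_dna(rng, 110)) for i in range(4)]
        otus = hot + cold
        candidate = "ACGTAC" + decamer  # 3' decamer is the planted one
        hits = pdesign.three_prime_specificity(candidate, otus)
        assert hits == scan_decamer_hits(decamer, [o.sequence for o in otus])
        assert hits >= 5

    def test_reverse_strand_counts(self, rng):
        decamer = random_dna(rng, 10)
        rc_host = OtuRecord("rc", random_dna(rng, 50) + pdesign.reverse_complement(decamer) + random_dna(rng, 50))
        assert pdesign.three_prime_specificity("AAAAAA" + decamer, [rc_host]) == 1

    def test_absent_decamer_zero(self, rng):
        otus = [OtuRecord("o", "A" * 200)]
        assert pdesign.three_prime_specificity("ACGTACGTACGTGCGC", otus) == 0

    def test_candidate_matches_own_target(self, rng):
        annotation = _toy_annotation(rng)
        otus = [OtuRecord("self", annotation.region_sequence("ITS2"))]
        candidate = _candidate_at(annotation, 30, 18)
        assert pdesign.three_prime_specificity(candidate, otus) >= 1


class TestEvaluateCriteria:
    def test_length_fail(self, rng):
        annotation = _toy_annotation(rng)
        candidate = _candidate_at(annotation, 40, 15)
        report = pdesign.evaluate_criteria(candidate, [], annotation)
        assert not report.length_ok and not report.overall

    def test_tm_window(self, rng):
        annotation = _toy_annotation(rng)
        candidate = _candidate_at(annotation, 40, 18)
        config = pdesign.PrimerConfig()
        tm = config.tm(candidate.sequence)
        report = pdesign.evaluate_criteria(candidate, [], annotation, config)
        assert report.tm_ok == (54.0 <= tm <= 58.0)
        hot = dataclasses.replace(config, tm_min=tm + 1, tm_max=tm + 2)
        assert not pdesign.evaluate_criteria(candidate, [], annotation, hot).tm_ok

    def test_flank_distance_fail_near_boundary(self, rng):
        annotation = _toy_annotation(rng)
        candidate = _candidate_at(annotation, 10, 18)  # 10 bases from the 5.8S side
        report = pdesign.evaluate_criteria(candidate, [], annotation)
        assert report.flank_distance == 10 and not report.flank_ok

    def test_specificity_fail_with_widespread_decamer(self, rng):
        annotation = _toy_annotation(rng)
        candidate = _candidate_at(annotation, 40, 18)
        decamer = candidate.sequence[-10:]
        otus = [
            OtuRecord(f"o{i}", random_dna(rng, 50) + decamer + random_dna(rng, 50))
            for i in range(20)
        ]
        report = pdesign.evaluate_criteria(candidate, otus, annotation)
        assert report.three_prime_hits >= 20 and not report.specificity_ok

    def test_candidate_outside_variable_region_rejected(self, rng):
        annotation = _toy_annotation(rng)
        candidate = _candidate_at(annotation, -30, 18)  # inside 5.8S
        with pytest.raises(ValidationError, match="variable region"):
            pdesign.evaluate_criteria(candidate, [], annotation)

    def test_gc_bounds(self, rng):
        annotation = _toy_annotation(rng)
        candidate = _candidate_at(annotation, 40, 18)
        gc = 100 * pdesign.gc_fraction(candidate.sequence)
        config = pdesign.PrimerConfig(gc_min=(gc + 5) / 100.0, gc_max=(gc + 10) / 100.0)
        assert not pdesign.evaluate_criteria(candidate, [], annotation, config).gc_ok


class TestDesignPrimers:
    def test_exhaustive_enumeration_finds_unique_compliant_candidate(self, rng):
        """Independent exhaustive oracle agrees on the compliant candidate set."""
        annotation = _toy_annotation(rng, its2_len=130)
        otus = [OtuRecord("self", annotation.region_sequence("ITS2"))]
        config = pdesign.PrimerConfig()
        forward, reverse = pdesign.design_primers("t1", annotation, otus, config)
        var_start, var_end = annotation.region("ITS2")
        window = annotation.sequence[var_start:var_end]
        expected = set()
        for length in range(16, 22):
            for offset in range(0, len(window) - length + 1):
                s = window[offset : offset + length]
                flank = min(offset, len(window) - (offset + length))
                for direction, oligo in (
                    ("forward", s),
                    ("reverse", pdesign.reverse_complement(s)),
                ):
                    tm = config.tm(oligo)
                    hits = scan_decamer_hits(oligo[-10:], [o.sequence for o in otus])
                    if (
                        54 <= tm <= 58
                        and 33 <= 100 * pdesign.gc_fraction(oligo) <= 62
                        and hits < 20
                        and flank > 20
                    ):
                        expected.add((direction, oligo))
        got = {(c.direction, c.sequence) for c in forward + reverse}
        assert got == expected

    def test_all_a_window_yields_nothing(self, rng):
        lens = [("SSU18S", 0, 150), ("ITS2", 150, 270), ("LSU28S", 270, 420)]
        seq = random_dna(rng, 150) + "A" * 120 + random_dna(rng, 150)
        annotation = OperonAnnotation("t", seq, lens)
        forward, reverse = pdesign.design_primers("t", annotation, [], pdesign.PrimerConfig())
        assert forward == [] and reverse == []

    def test_window_shorter_than_min_length_rejected(self, rng):
        lens = [("SSU18S", 0, 150), ("ITS2", 150, 160), ("LSU28S", 160, 310)]
        seq = random_dna(rng, 310)
        annotation = OperonAnnotation("t", seq, lens)
        with pytest.raises(ValidationError, match="shorter"):
            pdesign.design_primers("t", annotation, [], pdesign.PrimerConfig())

    def test_grouped_candidates_shared_across_members(self, rng):
        annotation = _toy_annotation(rng, its2_len=140)
        window = annotation.region_sequence("ITS2")
        member = mutate_dna(rng, window, 0.04)
        otus = [OtuRecord("rep", window), OtuRecord("m2", member)]
        forward, reverse = pdesign.design_primers(
            "g1", annotation, otus, group_member_windows=[window, member]
        )
        for candidate in forward:
            assert candidate.sequence in member
        for candidate in reverse:
            assert pdesign.reverse_complement(candidate.sequence) in member

    def test_output_invariant_to_otu_dataset_order(self, rng):
        annotation = _toy_annotation(rng)
        otus = [OtuRecord(f"o{i}", random_dna(rng, 120)) for i in range(6)]
        otus.append(OtuRecord("self", annotation.region_sequence("ITS2")))
        fwd_a, rev_a = pdesign.design_primers("t1", annotation, otus)
        fwd_b, rev_b = pdesign.design_primers("t1", annotation, list(reversed(otus)))
        assert [c.sequence for c in fwd_a] == [c.sequence for c in fwd_b]
        assert [c.sequence for c in rev_a] == [c.sequence for c in rev_b]

    def test_tightening_bounds_never_enlarges_passing_set(self, rng):
        annotation = _toy_annotation(rng, its2_len=160)
        otus = [OtuRecord("self", annotation.region_sequence("ITS2"))]
        loose = pdesign.PrimerConfig()
        tight = dataclasses.replace(
            loose,
            tm_min=54.5,
            tm_max=57.5,
            gc_min=0.40,
            gc_max=0.60,
            length_min=17,
            length_max=20,
            max_three_prime_hits=2,
            min_flank_distance=30,
        )
        loose_set = {
            (c.direction, c.sequence)
            for lists in pdesign.design_primers("t1", annotation, otus, loose)
            for c in lists
        }
        tight_set = {
            (c.direction, c.sequence)
            for lists in pdesign.design_primers("t1", annotation, otus, tight)
            for c in lists
        }
        assert tight_set <= loose_set


class TestPairing:
    def _candidate(self, rng, direction):
        annotation = _toy_annotation(rng)
        return _candidate_at(annotation, 40, 18, direction)

    def test_reverse_pairs_with_18s_universals(self, rng):
        pairs = pdesign.pair_with_universal(self._candidate(rng, "reverse"))
        assert [p.universal_name for p in pairs] == ["NS5a", "NS7a"]
        assert {p.amplified_gene for p in pairs} == {"SSU18S"}

    def test_forward_pairs_with_28s_universals(self, rng):
        pairs = pdesign.pair_with_universal(self._candidate(rng, "forward"))
        assert [p.universal_name for p in pairs] == ["TW13", "LR5"]
        assert {p.amplified_gene for p in pairs} == {"LSU28S"}

    def test_orientation_contract_refused(self, rng):
        universals = {
            "TW13": pdesign.UniversalPrimer("TW13", "GGTCCGTGTTTCAAGACG", "LSU28S", "reverse"),
            "LR5": pdesign.UniversalPrimer("LR5", "TCCTGAGGGAAACTTCG", "SSU18S", "reverse"),
        }
        with pytest.raises(ValidationError, match="pair only with"):
            pdesign.pair_with_universal(self._candidate(rng, "forward"), universals)

    def test_missing_universal_rejected(self, rng):
        with pytest.raises(ValidationError, match="missing"):
            pdesign.pair_with_universal(self._candidate(rng, "reverse"), {})


class TestInsilicoPcr:
    def test_own_operon_yields_single_spanning_amplicon(self, default_family):
        config, family = default_family
        annotation = family.operons["otu_00_00"]
        otus = family.otus
        forward, reverse = pdesign.design_primers("otu_00_00", annotation, otus)
        assert reverse, "default simulation must allow at least one reverse primer"
        pair = pdesign.pair_with_universal(reverse[0])[0]
        amplicons = pdesign.insilico_pcr(pair, {"otu_00_00": annotation.sequence})
        assert len(amplicons) == 1
        (amp,) = amplicons
        assert amp.end == pair.specific.template_end
        ns5a_site = annotation.sequence.find(pair.universal_seq)
        assert amp.start == ns5a_site

    def test_template_without_specific_site_gives_nothing(self, rng, default_family):
        _, family = default_family
        annotation = family.operons["otu_00_00"]
        forward, reverse = pdesign.design_primers("otu_00_00", annotation, family.otus)
        pair = pdesign.pair_with_universal(reverse[0])[0]
        assert pdesign.insilico_pcr(pair, {"random": random_dna(rng, 3000)}) == []

    def test_duplicated_site_reports_two_amplicons(self, rng):
        """Brute-force scan: a convergently duplicated specific site = unspecific."""
        universal = pdesign.DEFAULT_UNIVERSAL_PRIMERS["NS5a"]
        specific_site = random_dna(rng, 18)
        template = (
            random_dna(rng, 100)
            + universal.sequence
            + random_dna(rng, 200)
            + specific_site
            + random_dna(rng, 150)
            + specific_site
            + random_dna(rng, 100)
        )
        candidate = pdesign.PrimerCandidate(
            target_id="t",
            direction="reverse",
            sequence=pdesign.reverse_complement(specific_site),
            template_start=0,
            template_end=18,
            tm=55.0,
            gc_pct=50.0,
            three_prime_hits=1,
            flank_distance=30,
        )
        pair = pdesign.PrimerPair(candidate, "NS5a", universal.sequence, "SSU18S")
        amplicons = pdesign.insilico_pcr(pair, {"t": template})
        assert len(amplicons) == 2

    def test_mismatch_tolerance_excludes_three_prime_decamer(self, rng):
        universal = pdesign.DEFAULT_UNIVERSAL_PRIMERS["NS5a"]
        site = random_dna(rng, 18)
        template = random_dna(rng, 60) + universal.sequence + random_dna(rng, 100) + site + random_dna(rng, 60)
        # mutate one base in the 5' half of the reverse primer's binding site
        # (tolerated at max_mismatch=1) vs in its 3' decamer (never tolerated)
        candidate = pdesign.PrimerCandidate(
            "t", "reverse", pdesign.reverse_complement(site), 0, 18, 55.0, 50.0, 1, 30
        )
        pair = pdesign.PrimerPair(candidate, "NS5a", universal.sequence, "SSU18S")
        pos = template.find(site)
        five_prime_end = pos + 17  # last template base = primer 5' end
        mutated = list(template)
        mutated[five_prime_end] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[five_prime_end]]
        assert pdesign.insilico_pcr(pair, {"t": "".join(mutated)}, max_mismatch=0) == []
        assert len(pdesign.insilico_pcr(pair, {"t": "".join(mutated)}, max_mismatch=1)) == 1
        three_prime = list(template)
        three_prime[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[three_prime[pos]]
        assert pdesign.insilico_pcr(pair, {"t": "".join(three_prime)}, max_mismatch=1) == []
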