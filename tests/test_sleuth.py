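"""Reference-guided analysis: NG86 counting, codon threading, mutation
typing, frameshift impact, and the per-gene chain."""

import math
import random

import pytest

from oracles import (
    alignment_from_indels,
    ng86_path_counts,
    ng86_sites,
    nw_nt_score,
    out_of_frame_fraction,
)
from pseudoscan.config import Thresholds
from pseudoscan.fixtures import back_translate, diverge_cds
from pseudoscan.genome_io import GenomeRecord, reverse_complement
from pseudoscan.sleuth import (
    SENSE_CODONS,
    CodonAlignment,
    SleuthError,
    align_pair,
    align_semiglobal_nt,
    codon_align,
    compute_dnds,
    detect_mutations,
    frameshift_impact,
    jukes_cantor,
    map_reference_cds,
    pathway_differences,
    sleuth_gene,
    syn_nonsyn_sites,
)


def codon_aln_from(a: str, b: str) -> CodonAlignment:
    return CodonAlignment(
        [a[i : i + 3] for i in range(0, len(a), 3)],
        [b[i : i + 3] for i in range(0, len(b), 3)],
    )


class TestNG86Counting:
    def test_phenylalanine_codon_site_counts(self):
        s, n = syn_nonsyn_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            s, n = syn_nonsyn_sites(codon)
            es, en = ng86_sites(codon)
            assert s == pytest.approx(es), codon
            assert n == pytest.approx(en), codon
            assert s + n == pytest.approx(3.0)

    def test_pathway_counts_match_permutation_oracle_for_all_pairs(self):
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                sd, nd = pathway_differences(c1, c2)
                esd, end = ng86_path_counts(c1, c2)
                ndiff = sum(x != y for x, y in zip(c1, c2))
                assert sd == pytest.approx(esd), (c1, c2)
                assert nd == pytest.approx(end), (c1, c2)
                assert sd + nd == pytest.approx(ndiff)

    def test_identical_sequences_have_zero_divergence_and_are_gated(self):
        cds = back_translate("M" + "K" * 99, random.Random(0))
        r = compute_dnds(codon_aln_from(cds, cds))
        assert r.dN == 0.0 and r.dS == 0.0
        assert r.omega is None
        assert r.gated
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.n_codons)

    def test_no_comparable_codons_is_an_error(self):
        with pytest.raises(SleuthError):
            compute_dnds(CodonAlignment(["---"], ["ATG"]))

    def test_saturated_synonymous_divergence_is_marked_undefined(self):
        # every codon differs synonymously at its fourfold third position
        ref = "GGA" * 50
        query = "GGG" * 50
        r = compute_dnds(codon_aln_from(ref, query))
        assert r.dS is None and r.gated

    def test_jukes_cantor_saturation_boundary(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(1 - 0.4))


class TestCodonAlign:
    def test_threading_places_gap_codons(self):
        ca = codon_align(("MKV", "M-V"), "ATGAAAGTT", "ATGGTT")
        assert ca.ref_codons == ["ATG", "AAA", "GTT"]
        assert ca.query_codons == ["ATG", "---", "GTT"]

    def test_disagreeing_protein_row_names_the_residue(self):
        with pytest.raises(SleuthError, match="residue 2"):
            codon_align(("MKV", "MKV"), "ATGAAAGTT", "ATGAGAGTT")

    def test_dropping_gaps_recovers_the_cds(self):
        ca = codon_align(("MKV", "M-V"), "ATGAAAGTT", "ATGGTT")
        assert ca.ungapped("ref") == "ATGAAAGTT"
        assert ca.ungapped("query") == "ATGGTT"


class TestAlignPair:
    def test_identical_sequences_align_gaplessly(self):
        cds = back_translate("M" + "E" * 19, random.Random(4))
        (pr, pq), (nr, nq) = align_pair(cds, cds)
        assert "-" not in pr + pq + nr + nq

    def test_codon_deletion_appears_as_single_residue_gap(self):
        rng = random.Random(5)
        cds = back_translate("M" + "D" * 10 + "W" * 4 + "C" * 10, rng)
        query = cds[:30] + cds[33:]
        (pr, pq), _ = align_pair(cds, query)
        assert pq.count("-") == 1 and "-" not in pr

    def test_nucleotide_score_matches_dp_oracle_on_random_pairs(self):
        rng = random.Random(6)
        for _ in range(100):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 150)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 150)))
            _prot, (ra, rb) = align_pair(a, b)
            score = 0.0
            in_gap = False
            for x, y in zip(ra, rb):
                if x == "-" or y == "-":
                    score += -2.0 if in_gap else -7.0
                    in_gap = True
                else:
                    score += 2.0 if x == y else -3.0
                    in_gap = False
            assert score == nw_nt_score(a, b)

    def test_all_n_query_rejected(self):
        cds = back_translate("M" + "E" * 19, random.Random(7))
        with pytest.raises(SleuthError):
            align_pair(cds, "N" * 60)


def _ref(n_codons=32):
    return "ATG" + "GAA" * (n_codons - 2) + "TAA"


class TestDetectMutations:
    def test_internal_stop_typed_as_nonsense_at_its_codon(self):
        ref = _ref()
        query = ref[: 3 * 25] + "TAG" + ref[3 * 26 :]
        events = detect_mutations(None, (ref, query))
        assert [(e.kind, e.position) for e in events] == [("nonsense", 25)]

    def test_two_nt_gap_is_a_frameshifting_deletion(self):
        ref = _ref()
        query_row = ref[:30] + "--" + ref[32:]
        events = detect_mutations(None, (ref, query_row))
        dels = [e for e in events if e.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].length_nt == 2 and dels[0].frameshifting

    def test_three_nt_gap_is_in_frame(self):
        ref = _ref()
        query_row = ref[:30] + "---" + ref[33:]
        events = detect_mutations(None, (ref, query_row))
        dels = [e for e in events if e.kind == "deletion"]
        assert dels[0].length_nt == 3 and not dels[0].frameshifting
        assert not any(e.kind in ("nonsense", "stop_lost") for e in events)

    def test_start_codon_mutated_to_non_start(self):
        ref = _ref()
        query = "CTG" + ref[3:]
        events = detect_mutations(None, (ref, query))
        assert any(e.kind == "start_lost" and e.position == 0 for e in events)

    def test_terminal_stop_replaced_is_stop_lost(self):
        ref = _ref()
        query = ref[:-3] + "TAC"
        events = detect_mutations(None, (ref, query))
        assert any(e.kind == "stop_lost" for e in events)

    def test_late_frameshift_without_new_stop_is_stop_lost(self):
        # +1 insertion near the end: the reference stop is read out of
        # frame and no stop appears in the shifted reading
        ref = _ref()
        ref_row = ref[: 3 * 29] + "-" + ref[3 * 29 :]
        query_row = ref[: 3 * 29] + "G" + ref[3 * 29 :]
        events = detect_mutations(None, (ref_row, query_row))
        kinds = {e.kind for e in events}
        assert "insertion" in kinds and "stop_lost" in kinds


class TestFrameshiftImpact:
    def test_no_indels_means_zero_impact(self):
        ref = _ref(100)
        assert frameshift_impact(ref, ref, (ref, ref)) == 0.0

    def test_single_insertion_after_codon_90_of_100(self):
        ref = _ref(100)
        aln = alignment_from_indels(ref, [(270, +1)])
        assert frameshift_impact(ref, "", aln) == pytest.approx(0.10)

    def test_compensating_indels_impact_only_the_span_between(self):
        # +1 after codon 40, -1 at the end of codon 60: codons 41-60 are
        # read out of frame, everything downstream is back in frame
        ref = _ref(100)
        aln = alignment_from_indels(ref, [(120, +1), (179, -1)])
        assert frameshift_impact(ref, "", aln) == pytest.approx(0.20)
        assert out_of_frame_fraction(100, [(120, +1), (179, -1)]) == pytest.approx(0.20)

    def test_in_frame_indels_never_contribute(self):
        rng = random.Random(8)
        ref = _ref(80)
        for _ in range(50):
            pos = 3 * rng.randint(1, 70)
            ln = 3 * rng.randint(1, 3)
            sign = rng.choice((1, -1))
            aln = alignment_from_indels(ref, [(pos, sign * ln)])
            assert frameshift_impact(ref, "", aln) == 0.0

    def test_matches_direct_offset_oracle_on_random_plantings(self):
        rng = random.Random(9)
        for _ in range(200):
            n_codons = rng.randint(20, 90)
            ref = _ref(n_codons)
            k = rng.choice((1, 2))
            indels = []
            used = set()
            for _i in range(k):
                pos = 3 * rng.randint(1, n_codons - 2)
                if pos in used:
                    continue
                used.add(pos)
                indels.append((pos, rng.choice((1, 2, -1, -2))))
            aln = alignment_from_indels(ref, indels)
            assert frameshift_impact(ref, "", aln) == pytest.approx(
                out_of_frame_fraction(n_codons, indels)
            )


AAS = "ARNDCQEGHILKMFPSTWYV"


def _rand_prot(rng, n):
    return "M" + "".join(rng.choice(AAS) for _ in range(n - 1))


class TestMapReferenceCds:
    def _genome(self, inserts):
        rng = random.Random(10)
        parts = ["".join(rng.choice("ACGT") for _ in range(150))]
        spans = []
        pos = 150
        for cds in inserts:
            parts.append(cds)
            spans.append((pos, pos + len(cds)))
            pos += len(cds)
            parts.append("".join(rng.choice("ACGT") for _ in range(150)))
            pos += 150
        return GenomeRecord({"c1": "".join(parts)}, []), spans

    def test_verbatim_cds_maps_to_its_locus(self):
        cds = back_translate(_rand_prot(random.Random(11), 80), random.Random(11)) + "TAA"
        genome, spans = self._genome([cds])
        mapped, unmapped = map_reference_cds({"r1": cds}, genome)
        assert unmapped == []
        (rid, iv), = mapped
        assert iv.start <= spans[0][0] and iv.end >= spans[0][1]
        assert iv.start >= spans[0][0] - 60 and iv.end <= spans[0][1] + 60

    def test_absent_cds_reported_unmapped(self):
        cds = back_translate(_rand_prot(random.Random(12), 80), random.Random(12)) + "TAA"
        other = back_translate(_rand_prot(random.Random(13), 90), random.Random(13)) + "TAA"
        genome, _ = self._genome([cds])
        _mapped, unmapped = map_reference_cds({"r2": other}, genome)
        assert unmapped == ["r2"]

    def test_duplicated_locus_resolves_leftmost(self):
        cds = back_translate(_rand_prot(random.Random(14), 80), random.Random(14)) + "TAA"
        genome, spans = self._genome([cds, cds])
        mapped, _ = map_reference_cds({"r1": cds}, genome)
        (_rid, iv), = mapped
        assert iv.start < spans[1][0]

    def test_reverse_strand_locus_detected(self):
        cds = back_translate(_rand_prot(random.Random(15), 80), random.Random(15)) + "TAA"
        genome, spans = self._genome([reverse_complement(cds)])
        mapped, _ = map_reference_cds({"r1": cds}, genome)
        (_rid, iv), = mapped
        assert iv.strand == "-"


class TestSleuthGene:
    def _genome_with(self, cds):
        rng = random.Random(16)
        pre = "".join(rng.choice("ACGT") for _ in range(120))
        post = "".join(rng.choice("ACGT") for _ in range(120))
        return GenomeRecord({"c1": pre + cds + post}, [])

    def test_identical_query_raises_no_flags(self):
        cds = back_translate("M" + "L" * 60 + "K" * 39, random.Random(17)) + "TAA"
        genome = self._genome_with(cds)
        report = sleuth_gene("r1", cds, genome)
        assert not report.flagged_reasons()
        assert report.events == []

    def test_planted_premature_stop_flags_nonsense(self):
        cds = back_translate("M" + "L" * 60 + "K" * 39, random.Random(18)) + "TAA"
        ci = 30  # ~30% into the gene
        broken = cds[: 3 * ci] + "TGA" + cds[3 * ci + 3 :]
        genome = self._genome_with(broken)
        report = sleuth_gene("r1", cds, genome)
        assert report.flags["nonsense"]

    def test_elevated_omega_in_window_flags_high_dnds(self):
        cds = back_translate("M" + "L" * 150 + "K" * 149, random.Random(19)) + "TAA"
        diverged = diverge_cds(cds, 0.5, 0.8, seed=20)
        genome = self._genome_with(cds)
        report = sleuth_gene("r1", diverged, genome, Thresholds())
        assert report.dnds is not None and not report.dnds.gated
        assert report.dnds.omega > 0.3
        assert report.flags["high_dnds"]

    def test_gate_suppresses_flag_when_ds_leaves_window(self):
        cds = back_translate("M" + "L" * 150 + "K" * 149, random.Random(21)) + "TAA"
        diverged = diverge_cds(cds, 0.5, 0.8, seed=22)
        genome = self._genome_with(cds)
        tight = Thresholds(ds_min=0.0001, ds_max=0.01)
        report = sleuth_gene("r1", diverged, genome, tight)
        assert report.dnds.gated
        assert not report.flags["high_dnds"]
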