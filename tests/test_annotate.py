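"""Core pipeline: length classification, fragment chaining, intergenic
recovery, consolidation, caching and re-thresholding."""

import random

import networkx as nx
import pytest

from pseudoscan.annotate import (
    StaleCacheError,
    annotate,
    classify_length,
    consolidate,
    detect_fragments,
    reannotate,
    scan_intergenic,
)
from pseudoscan.annotate import PseudogeneCall
from pseudoscan.config import Thresholds
from pseudoscan.breaker import break_genome
from pseudoscan.fixtures import plant_remnant
from pseudoscan.genome_io import Feature, Interval
from pseudoscan.homology import HitSet, HomologyHit


def _hit(subject_id, subject_length, bits=100.0):
    return HomologyHit(
        "q", subject_id, 95.0, subject_length, 1e-20, bits,
        1, subject_length, 1, subject_length, subject_length,
    )


def _hitset(subject_lengths, ids=None):
    ids = ids or [f"s{i}" for i in range(len(subject_lengths))]
    return HitSet("q", [
        _hit(sid, ln, bits=200.0 - i)
        for i, (sid, ln) in enumerate(zip(ids, subject_lengths))
    ])


class TestClassifyLength:
    def test_gene_at_exactly_the_cutoff_is_not_flagged(self):
        # ratio 300/400 = 0.75 exactly: strict inequality spares it
        cat, _ = classify_length(300, _hitset([400, 400, 400]), Thresholds())
        assert cat == "intact"

    def test_gene_just_below_the_cutoff_is_short(self):
        cat, details = classify_length(299, _hitset([400, 400, 400]), Thresholds())
        assert cat == "short"
        assert float(details["ratio"]) < 0.75

    def test_full_length_gene_is_intact(self):
        cat, _ = classify_length(400, _hitset([400, 400, 400]), Thresholds())
        assert cat == "intact"

    def test_overlong_gene_is_run_on(self):
        cat, _ = classify_length(600, _hitset([400, 400, 400]), Thresholds())
        assert cat == "run_on"

    def test_too_few_homologs_leaves_gene_unevaluated(self):
        cat, details = classify_length(100, _hitset([400, 400]), Thresholds())
        assert cat == "unevaluated" and details["n_used"] == 2

    def test_sd_rule_requires_deviation_beyond_k_sd(self):
        t = Thresholds(use_sd_rule=True, sd_k=2.0)
        # ratio 0.7 < 0.75, but spread is huge: 280 is within 2 sd of 400
        spread = _hitset([250, 400, 550])
        assert classify_length(280, spread, t)[0] == "intact"
        tight = _hitset([398, 400, 402])
        assert classify_length(280, tight, t)[0] == "short"


def _gene(i, contig="c1", start=None):
    start = 100 * i if start is None else start
    return Feature("CDS", Interval(contig, start, start + 60, "+"), f"g{i}")


def _linked_hitsets(n, links, rng=None):
    """Hit sets realizing a consecutive-pair link plan exactly."""
    sets = {i: [f"own{i}a", f"own{i}b"] for i in range(n)}
    for (a, b) in links:
        sets[a].append(f"L{a}")
        sets[b].append(f"L{a}")
    return {
        i: HitSet(f"g{i}", [_hit(s, 100, bits=50.0) for s in sorted(sets[i])])
        for i in range(n)
    }


class TestDetectFragments:
    def test_identical_hit_sets_merge_adjacent_genes(self):
        hs = _hitset([100] * 5)
        genes = [(_gene(0), hs), (_gene(1), hs)]
        chains = detect_fragments(genes, Thresholds())
        assert [[f.locus_tag for f in c] for c in chains] == [["g0", "g1"]]

    def test_disjoint_hit_sets_do_not_merge(self):
        genes = [
            (_gene(0), _hitset([100] * 3, ids=["a1", "a2", "a3"])),
            (_gene(1), _hitset([100] * 3, ids=["b1", "b2", "b3"])),
        ]
        assert detect_fragments(genes, Thresholds()) == []

    def test_chain_closes_transitively(self):
        # (g0,g1) and (g1,g2) linked, (g0,g2) barely similar: one 3-chain
        ids0 = ["x1", "x2", "x3", "x4", "s0"]
        ids1 = ["x1", "x2", "x3", "x4", "s1"]
        ids2 = ["x2", "x3", "x4", "x5", "s2"]
        genes = [
            (_gene(0), _hitset([100] * 5, ids0)),
            (_gene(1), _hitset([100] * 5, ids1)),
            (_gene(2), _hitset([100] * 5, ids2)),
        ]
        chains = detect_fragments(genes, Thresholds())
        assert [[f.locus_tag for f in c] for c in chains] == [["g0", "g1", "g2"]]

    def test_chains_equal_connected_components_of_the_link_graph(self):
        rng = random.Random(77)
        t = Thresholds(shared_hit_fraction=0.2)
        for _trial in range(25):
            n = rng.randint(3, 12)
            links = [(i, i + 1) for i in range(n - 1) if rng.random() < 0.4]
            hitsets = _linked_hitsets(n, links)
            genes = [(_gene(i), hitsets[i]) for i in range(n)]
            chains = detect_fragments(genes, t)
            got = sorted(sorted(f.locus_tag for f in c) for c in chains)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(links)
            want = sorted(
                sorted(f"g{i}" for i in comp)
                for comp in nx.connected_components(g)
                if len(comp) >= 2
            )
            assert got == want


class TestScanIntergenic:
    def test_planted_remnant_recovered_with_interval_overlap(self, small_fx):
        genome, truth = plant_remnant(
            small_fx.genome, small_fx.db["fam003_a"], corruption=0.2, seed=9
        )
        from pseudoscan.genome_io import extract_intergenic_regions

        regions = extract_intergenic_regions(genome, 90)
        calls = scan_intergenic(regions, small_fx.db, Thresholds())
        assert len(calls) == 1
        iv = calls[0].interval
        overlap = max(0, min(iv.end, truth.end) - max(iv.start, truth.start))
        assert overlap / len(truth) >= 0.8

    def test_reverse_strand_remnant_called_minus(self, small_fx):
        genome, truth = plant_remnant(
            small_fx.genome, small_fx.db["fam003_a"], corruption=0.2, seed=9,
            strand="-",
        )
        from pseudoscan.genome_io import extract_intergenic_regions

        regions = extract_intergenic_regions(genome, 90)
        calls = scan_intergenic(regions, small_fx.db, Thresholds())
        assert calls and calls[0].interval.strand == "-"

    def test_random_intergenic_dna_yields_no_calls(self, small_fx):
        rng = random.Random(30)
        region = Interval("c1", 0, 600, "+")
        seq = "".join(rng.choice("ACGT") for _ in range(600))
        assert scan_intergenic([(region, seq)], small_fx.db, Thresholds()) == []


class TestConsolidate:
    def test_same_strand_overlaps_merge_with_union_of_reasons(self):
        a = PseudogeneCall(Interval("c1", 0, 100, "+"), ["g1"], {"short"})
        b = PseudogeneCall(Interval("c1", 50, 150, "+"), ["g2"], {"nonsense"})
        merged = consolidate([a, b])
        assert len(merged) == 1
        assert merged[0].reasons == {"short", "nonsense"}
        assert merged[0].interval == Interval("c1", 0, 150, "+")

    def test_opposite_strands_never_merge(self):
        a = PseudogeneCall(Interval("c1", 0, 100, "+"), ["g1"], {"short"})
        b = PseudogeneCall(Interval("c1", 50, 150, "-"), ["g2"], {"short"})
        assert len(consolidate([a, b])) == 2

    def test_merged_calls_are_disjoint_per_strand(self):
        rng = random.Random(5)
        calls = [
            PseudogeneCall(
                Interval("c1", s, s + rng.randint(20, 200), rng.choice("+-")),
                [], {"short"},
            )
            for s in (rng.randint(0, 2000) for _ in range(40))
        ]
        merged = consolidate(calls)
        by_strand = {}
        for c in merged:
            by_strand.setdefault(c.interval.strand, []).append(c.interval)
        for ivs in by_strand.values():
            ivs.sort(key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))


class TestPipeline:
    def test_intact_genome_produces_no_calls(self, small_fx):
        res = annotate(small_fx.genome, small_fx.db)
        assert res.calls == []
        assert sorted(res.intact) == sorted(
            f.locus_tag for f in small_fx.genome.cds_features()
        )

    def test_annotate_is_deterministic(self, small_fx, small_reference):
        mutated, _ = break_genome(small_fx.genome, 5, seed=3)
        r1 = annotate(mutated, small_fx.db, reference=small_reference)
        r2 = annotate(mutated, small_fx.db, reference=small_reference)
        assert r1.to_text() == r2.to_text()

    def test_every_locus_lands_in_exactly_one_bucket(self, small_fx, small_reference):
        mutated, _ = break_genome(small_fx.genome, 8, seed=4)
        res = annotate(mutated, small_fx.db, reference=small_reference)
        called = res.called_loci()
        all_loci = {f.locus_tag for f in mutated.cds_features()}
        assert called | set(res.intact) | set(res.unevaluated) == all_loci
        assert not called & set(res.intact)
        assert not called & set(res.unevaluated)
        assert not set(res.intact) & set(res.unevaluated)

    def test_empty_database_rejected(self, small_fx):
        with pytest.raises(Exception, match="empty"):
            annotate(small_fx.genome, {})


class TestReannotate:
    @pytest.fixture()
    def cached_run(self, tmp_path, small_fx, small_reference):
        mutated, entries = break_genome(small_fx.genome, 5, seed=3)
        cache = str(tmp_path / "cache")
        res = annotate(
            mutated, small_fx.db, reference=small_reference, cache_dir=cache
        )
        return mutated, cache, res

    def test_identical_thresholds_reproduce_the_run_exactly(self, cached_run):
        mutated, cache, res = cached_run
        assert reannotate(cache, mutated).to_text() == res.to_text()

    def test_raising_length_cutoff_grows_the_short_set(self, cached_run):
        mutated, cache, res = cached_run

        def short_loci(result):
            out = set()
            for c in result.calls:
                if "short" in c.reasons:
                    out.update(c.member_locus_tags)
            return out

        relaxed = reannotate(cache, mutated, Thresholds(length_ratio_min=0.9))
        assert short_loci(res) <= short_loci(relaxed)

    def test_cache_from_other_genome_is_stale(self, cached_run, small_fx):
        _mutated, cache, _res = cached_run
        with pytest.raises(StaleCacheError):
            reannotate(cache, small_fx.genome)
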