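"""Core pseudogene-calling pipeline.

The pipeline splits an annotated genome into coding and intergenic
regions, collects database homologs for every coding region, and
classifies genes by comparing their lengths to the mean length of their
top homologs (truncated below ``length_ratio_min`` of the mean, run-on
above ``length_ratio_max``; both strict inequalities, so a gene at exactly
the cutoff is not flagged). Adjacent genes recruiting the same homologs
are merged as fragments of one ancestral gene; intergenic regions are
searched in all six reading frames to recover degraded remnants invisible
to gene callers; and, when a close reference genome is supplied, the
reference-guided analysis contributes mutation-level and dN/dS evidence.
All evidence streams are consolidated into non-overlapping per-strand
calls.

Search results are cached so that re-classification under new thresholds
(``reannotate``) never repeats the expensive homology searches.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from .config import RunConfig, Thresholds, run_log
from .genome_io import (
    GenomeRecord,
    Interval,
    extract_coding_regions,
    extract_intergenic_regions,
    write_outputs,
)
from .homology import (
    BuiltinEngine,
    HitSet,
    hit_length_stats,
    parse_tabular_hits,
    search_proteins,
    search_translated,
    write_tabular_hits,
)
from . import sleuth as sleuth_mod

GENE_REASONS = ("short", "run_on")
SLEUTH_REASONS = ("high_dnds", "frameshift", "nonsense", "start_lost", "stop_lost")


class AnnotateError(RuntimeError):
    pass


class StaleCacheError(AnnotateError):
    """The cache was produced from a different genome."""


@dataclass
class PseudogeneCall:
    interval: Interval
    member_locus_tags: list
    reasons: set
    evidence: dict = field(default_factory=dict)

    def sort_key(self):
        iv = self.interval
        return (iv.contig_id, iv.start, iv.end, iv.strand)

    def to_line(self) -> str:
        iv = self.interval
        ev = ",".join(f"{k}={self.evidence[k]}" for k in sorted(self.evidence))
        return "\t".join(
            [
                iv.contig_id, str(iv.start), str(iv.end), iv.strand,
                ",".join(self.member_locus_tags) or ".",
                ",".join(sorted(self.reasons)),
                ev or ".",
            ]
        )


@dataclass
class AnnotationResult:
    calls: list
    intact: list
    unevaluated: list
    parameters: Thresholds
    cache_path: str | None = None

    def to_text(self) -> str:
        """Stable text serialization (used for fidelity comparisons)."""
        lines = ["#calls"]
        lines += [c.to_line() for c in sorted(self.calls, key=PseudogeneCall.sort_key)]
        lines.append("#intact\t" + ",".join(sorted(self.intact)))
        lines.append("#unevaluated\t" + ",".join(sorted(self.unevaluated)))
        lines.append(
            "#parameters\t"
            + json.dumps(self.parameters.to_dict(), sort_keys=True)
        )
        return "\n".join(lines) + "\n"

    def called_loci(self) -> set:
        out = set()
        for c in self.calls:
            out.update(c.member_locus_tags)
        return out


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


# ---------------------------------------------------------------------------
# classification primitives


def classify_length(protein_length: int, hitset: HitSet, t: Thresholds):
    """Classify one gene by homolog length statistics.

    Returns ``(category, details)`` with category one of ``intact``,
    ``short``, ``run_on`` or ``unevaluated``. Genes with fewer than
    ``min_hits_for_eval`` homologs are unevaluated; otherwise the ratio of
    the query protein length to the mean top-hit subject length decides,
    with strict inequalities at both cutoffs. With ``use_sd_rule`` the
    short call additionally requires the length to fall more than
    ``sd_k`` standard deviations below the homolog mean.
    """
    if protein_length <= 0:
        raise AnnotateError("protein length must be positive")
    mean, sd, n_used = hit_length_stats(hitset, t.max_hits)
    if n_used < t.min_hits_for_eval:
        return "unevaluated", {"n_used": n_used}
    ratio = protein_length / mean
    details = {
        "ratio": _fmt(ratio), "mean": _fmt(mean),
        "sd": _fmt(sd), "n_used": n_used,
    }
    if ratio < t.length_ratio_min:
        if t.use_sd_rule and not (protein_length < mean - t.sd_k * sd):
            return "intact", details
        return "short", details
    if ratio > t.length_ratio_max:
        return "run_on", details
    return "intact", details


def _set_overlap(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def detect_fragments(genes: list, t: Thresholds) -> list:
    """Chain adjacent genes that recruit the same database homologs.

    ``genes`` is a list of ``(Feature, HitSet)``. Adjacency means
    consecutive among hit-bearing genes on the same contig, regardless of
    strand. Pairs are linked when the min-normalized overlap of their
    top-hit subject-id sets reaches ``shared_hit_fraction``; transitive
    closure of links yields maximal chains, and every chain of two or more
    genes is one fragment group.
    """
    withhits = [
        (f, hs) for f, hs in genes if hs.hits
    ]
    withhits.sort(key=lambda p: (p[0].interval.contig_id, p[0].interval.start))
    chains = []
    current = []
    for i, (feat, hs) in enumerate(withhits):
        if not current:
            current = [(feat, hs)]
            continue
        prev_feat, prev_hs = current[-1]
        same_contig = feat.interval.contig_id == prev_feat.interval.contig_id
        linked = same_contig and _set_overlap(
            set(prev_hs.subject_ids(t.max_hits)),
            set(hs.subject_ids(t.max_hits)),
        ) >= t.shared_hit_fraction
        if linked:
            current.append((feat, hs))
        else:
            if len(current) >= 2:
                chains.append([f for f, _ in current])
            current = [(feat, hs)]
    if len(current) >= 2:
        chains.append([f for f, _ in current])
    return chains


def _chain_call(chain: list) -> PseudogeneCall:
    contig = chain[0].interval.contig_id
    start = min(f.interval.start for f in chain)
    end = max(f.interval.end for f in chain)
    strands = [f.interval.strand for f in chain]
    strand = "+" if strands.count("+") >= strands.count("-") else "-"
    return PseudogeneCall(
        Interval(contig, start, end, strand),
        [f.locus_tag for f in chain],
        {"fragmented"},
        {"fragmented": f"n_members:{len(chain)}"},
    )


def _remnant_call_from_hits(interval: Interval, hitset: HitSet,
                            t: Thresholds) -> PseudogeneCall | None:
    hits = [
        h for h in hitset.hits
        if h.evalue <= t.intergenic_evalue and h.percent_identity >= t.min_identity
    ]
    if not hits:
        return None
    lo = min(h.q_start for h in hits)
    hi = max(h.q_end for h in hits)
    plus = sum(1 for h in hits if h.reading_frame > 0)
    minus = len(hits) - plus
    strand = "+" if plus >= minus else "-"
    best = hits[0]
    call_iv = Interval(
        interval.contig_id, interval.start + lo - 1, interval.start + hi, strand
    )
    return PseudogeneCall(
        call_iv,
        [],
        {"intergenic_remnant"},
        {
            "intergenic_remnant": (
                f"n_hits:{len(hits)},best:{best.subject_id},"
                f"evalue:{_fmt(best.evalue)}"
            )
        },
    )


def scan_intergenic(regions: list, db: dict, t: Thresholds,
                    engine=None) -> list:
    """Six-frame translated search of intergenic regions for gene remnants."""
    engine = engine or BuiltinEngine()
    calls = []
    for interval, seq in regions:
        if len(seq) < t.intergenic_min_length:
            continue
        hitset = search_translated(
            seq, db, evalue_cutoff=t.intergenic_evalue, engine=engine,
            region_id=_region_id(interval),
        )
        call = _remnant_call_from_hits(interval, hitset, t)
        if call is not None:
            calls.append(call)
    return calls


def consolidate(calls: list) -> list:
    """Merge calls overlapping by >= 1 nt on the same contig and strand."""
    groups: dict = {}
    for c in calls:
        groups.setdefault((c.interval.contig_id, c.interval.strand), []).append(c)
    merged = []
    for (contig, strand), group in groups.items():
        group.sort(key=lambda c: (c.interval.start, c.interval.end))
        cluster = [group[0]]
        for c in group[1:]:
            if c.interval.start < max(x.interval.end for x in cluster):
                cluster.append(c)
            else:
                merged.append(_merge_cluster(cluster))
                cluster = [c]
        merged.append(_merge_cluster(cluster))
    merged.sort(key=PseudogeneCall.sort_key)
    return merged


def _merge_cluster(cluster: list) -> PseudogeneCall:
    if len(cluster) == 1:
        return cluster[0]
    iv0 = cluster[0].interval
    start = min(c.interval.start for c in cluster)
    end = max(c.interval.end for c in cluster)
    members: list = []
    for c in cluster:
        for m in c.member_locus_tags:
            if m not in members:
                members.append(m)
    reasons = set()
    evidence: dict = {}
    for c in cluster:
        reasons |= c.reasons
        for k, v in c.evidence.items():
            evidence[k] = v if k not in evidence else evidence[k] + ";" + v
    return PseudogeneCall(
        Interval(iv0.contig_id, start, end, iv0.strand), members, reasons, evidence
    )


# ---------------------------------------------------------------------------
# assembly from search results (shared by annotate and reannotate)


def _region_id(interval: Interval) -> str:
    return f"ig|{interval.contig_id}|{interval.start}|{interval.end}"


def _parse_region_id(rid: str) -> Interval:
    _, contig, start, end = rid.split("|")
    return Interval(contig, int(start), int(end), "+")


def _apply_identity_floor(hitset: HitSet, floor: float) -> HitSet:
    if floor <= 0:
        return hitset
    out = HitSet(hitset.query_id,
                 [h for h in hitset.hits if h.percent_identity >= floor])
    return out


def _assemble(genome: GenomeRecord, gene_hitsets: dict,
              intergenic_hitsets: dict, sleuth_metrics: list,
              t: Thresholds, cache_path: str | None) -> AnnotationResult:
    """Deterministically derive an AnnotationResult from search results.

    This single code path backs both ``annotate`` and ``reannotate``, so
    re-deriving with unchanged thresholds reproduces the original result
    exactly.
    """
    coding = extract_coding_regions(genome)
    per_gene_reasons: dict = {}
    per_gene_evidence: dict = {}
    unevaluated = []
    gene_entries = []
    for feat, _nt, prot in coding:
        hs = _apply_identity_floor(
            gene_hitsets.get(feat.locus_tag, HitSet(feat.locus_tag)), t.min_identity
        )
        gene_entries.append((feat, hs))
        category, details = classify_length(max(len(prot), 1), hs, t)
        if category == "unevaluated":
            unevaluated.append(feat.locus_tag)
        elif category in ("short", "run_on"):
            per_gene_reasons.setdefault(feat.locus_tag, set()).add(category)
            per_gene_evidence.setdefault(feat.locus_tag, {})[category] = (
                f"ratio:{details['ratio']},mean:{details['mean']},"
                f"n:{details['n_used']}"
            )

    # reference-guided evidence attaches to the overlapped gene
    features_by_contig: dict = {}
    for feat, _hs in gene_entries:
        features_by_contig.setdefault(feat.interval.contig_id, []).append(feat)
    orphan_sleuth_calls = []
    for m in sleuth_metrics:
        if m.get("absent"):
            continue
        iv = Interval(m["contig"], m["start"], m["end"], m["strand"])
        flags = _sleuth_flags(m, t)
        reasons = {k for k, v in flags.items() if v}
        if not reasons:
            continue
        evidence = {}
        if "high_dnds" in reasons:
            evidence["high_dnds"] = (
                f"omega:{_fmt(m.get('omega'))},dS:{_fmt(m.get('dS'))}"
            )
        if "frameshift" in reasons:
            evidence["frameshift"] = f"impact:{_fmt(m.get('impact'))}"
        for k in ("nonsense", "start_lost", "stop_lost"):
            if k in reasons:
                evidence[k] = f"ref:{m['reference_id']}"
        target = None
        for feat in features_by_contig.get(iv.contig_id, []):
            if feat.interval.overlaps(iv):
                if target is None or len(
                    _overlap_len(feat.interval, iv)
                ) > len(_overlap_len(target.interval, iv)):
                    target = feat
        if target is not None:
            per_gene_reasons.setdefault(target.locus_tag, set()).update(reasons)
            per_gene_evidence.setdefault(target.locus_tag, {}).update(evidence)
        else:
            orphan_sleuth_calls.append(PseudogeneCall(iv, [], reasons, evidence))

    calls = []
    loci_in_calls = set()
    for feat, _hs in gene_entries:
        reasons = per_gene_reasons.get(feat.locus_tag)
        if reasons:
            calls.append(
                PseudogeneCall(
                    feat.interval, [feat.locus_tag], set(reasons),
                    dict(per_gene_evidence.get(feat.locus_tag, {})),
                )
            )
            loci_in_calls.add(feat.locus_tag)

    for chain in detect_fragments(gene_entries, t):
        call = _chain_call(chain)
        calls.append(call)
        loci_in_calls.update(call.member_locus_tags)

    for rid in sorted(intergenic_hitsets):
        call = _remnant_call_from_hits(
            _parse_region_id(rid), intergenic_hitsets[rid], t
        )
        if call is not None:
            calls.append(call)
    calls.extend(orphan_sleuth_calls)

    consolidated = consolidate(calls) if calls else []
    loci_in_calls = set()
    for c in consolidated:
        loci_in_calls.update(c.member_locus_tags)
    unevaluated = [l for l in unevaluated if l not in loci_in_calls]
    intact = [
        feat.locus_tag
        for feat, _hs in gene_entries
        if feat.locus_tag not in loci_in_calls and feat.locus_tag not in unevaluated
    ]
    return AnnotationResult(consolidated, intact, unevaluated, t, cache_path)


def _overlap_len(a: Interval, b: Interval) -> range:
    return range(max(a.start, b.start), min(a.end, b.end))


def _sleuth_flags(m: dict, t: Thresholds) -> dict:
    dS = m.get("dS")
    omega = m.get("omega")
    gated = dS is None or not (t.ds_min < dS < t.ds_max)
    kinds = {e["kind"] for e in m.get("events", [])}
    return {
        "high_dnds": (not gated) and omega is not None and omega > t.dnds_max,
        "frameshift": m.get("impact", 0.0) > t.frameshift_impact_max,
        "nonsense": "nonsense" in kinds,
        "start_lost": "start_lost" in kinds,
        "stop_lost": "stop_lost" in kinds,
    }


def _report_to_metric(r) -> dict:
    if r.absent:
        return {"reference_id": r.reference_id, "absent": True}
    d = r.dnds
    return {
        "reference_id": r.reference_id,
        "absent": False,
        "contig": r.interval.contig_id,
        "start": r.interval.start,
        "end": r.interval.end,
        "strand": r.interval.strand,
        "events": [
            {
                "kind": e.kind, "position": e.position,
                "length_nt": e.length_nt, "frameshifting": e.frameshifting,
            }
            for e in r.events
        ],
        "impact": r.frameshift_impact,
        "dN": d.dN if d else None,
        "dS": d.dS if d else None,
        "omega": d.omega if d else None,
    }


# ---------------------------------------------------------------------------
# the pipeline


def annotate(genome: GenomeRecord, db: dict, t: Thresholds | None = None,
             engine=None, reference: dict | None = None,
             outdir: str | None = None,
             cache_dir: str | None = None) -> AnnotationResult:
    """Run the full pipeline: extract, search, classify, consolidate.

    ``db`` maps protein ids to sequences; ``reference`` (optional) maps
    reference CDS ids to nucleotide sequences and triggers the
    reference-guided branch. Search results are written to ``cache_dir``
    (default: ``<outdir>/cache`` when an outdir is given) for later
    re-thresholding.
    """
    if not db:
        raise AnnotateError("empty protein database")
    t = t or Thresholds()
    engine = engine or BuiltinEngine()
    genome.validate()
    coding = extract_coding_regions(genome)
    queries = {feat.locus_tag: prot for feat, _nt, prot in coding if prot}
    gene_hitsets = search_proteins(
        queries, db, evalue_cutoff=t.evalue, max_hits=t.max_hits, engine=engine
    )
    for feat, _nt, prot in coding:
        gene_hitsets.setdefault(feat.locus_tag, HitSet(feat.locus_tag))

    regions = extract_intergenic_regions(genome, t.intergenic_min_length)
    intergenic_hitsets = {}
    for interval, seq in regions:
        if len(seq) < 3 * 10:
            continue
        rid = _region_id(interval)
        intergenic_hitsets[rid] = search_translated(
            seq, db, evalue_cutoff=t.intergenic_evalue, engine=engine,
            region_id=rid,
        )

    sleuth_metrics = []
    if reference:
        reports = sleuth_mod.sleuth_genome(reference, genome, t, engine)
        sleuth_metrics = [_report_to_metric(r) for r in reports]

    cache_path = cache_dir or (os.path.join(outdir, "cache") if outdir else None)
    if cache_path:
        _write_cache(cache_path, genome, t, engine, gene_hitsets,
                     intergenic_hitsets, sleuth_metrics)

    result = _assemble(
        genome, gene_hitsets, intergenic_hitsets, sleuth_metrics, t, cache_path
    )
    if outdir:
        write_outputs(result.calls, genome, outdir)
        run_log(
            outdir,
            RunConfig(thresholds=t, engine=getattr(engine, "identifier", "custom")),
            getattr(engine, "identifier", "custom"),
            {"genome": genome.checksum()},
        )
    return result


def _write_cache(cache_path, genome, t, engine, gene_hitsets,
                 intergenic_hitsets, sleuth_metrics) -> None:
    os.makedirs(cache_path, exist_ok=True)
    meta = {
        "genome_checksum": genome.checksum(),
        "thresholds": t.to_dict(),
        "engine": getattr(engine, "identifier", "custom"),
    }
    with open(os.path.join(cache_path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    write_tabular_hits(gene_hitsets, os.path.join(cache_path, "gene_hits.tsv"))
    write_tabular_hits(
        intergenic_hitsets, os.path.join(cache_path, "intergenic_hits.tsv")
    )
    with open(os.path.join(cache_path, "sleuth.json"), "w") as fh:
        json.dump(sleuth_metrics, fh, indent=2, sort_keys=True)


def reannotate(cache_path: str, genome: GenomeRecord,
               t2: Thresholds | None = None) -> AnnotationResult:
    """Re-derive pseudogene calls from cached search results.

    With thresholds equal to the original run the output reproduces the
    original :class:`AnnotationResult` exactly; a cache recorded from a
    different genome raises :class:`StaleCacheError`. Searches are never
    repeated, so only thresholds at or tighter than the cached search
    cutoffs are meaningful.
    """
    t2 = t2 or Thresholds()
    meta_path = os.path.join(cache_path, "meta.json")
    if not os.path.exists(meta_path):
        raise AnnotateError(f"no cache at {cache_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("genome_checksum") != genome.checksum():
        raise StaleCacheError(
            "stale cache: genome checksum does not match the cached run"
        )
    gene_hitsets = parse_tabular_hits(os.path.join(cache_path, "gene_hits.tsv"))
    for feat in genome.cds_features():
        gene_hitsets.setdefault(feat.locus_tag, HitSet(feat.locus_tag))
    intergenic_hitsets = parse_tabular_hits(
        os.path.join(cache_path, "intergenic_hits.tsv")
    )
    with open(os.path.join(cache_path, "sleuth.json")) as fh:
        sleuth_metrics = json.load(fh)
    return _assemble(
        genome, gene_hitsets, intergenic_hitsets, sleuth_metrics, t2, cache_path
    )
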