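"""In-silico genome decay: simulate pseudogenization with known truth.

A user-set decay level (1–10) selects ``round(0.05 * level * n_genes)``
genes (at least one) uniformly at random; each selected gene receives
exactly one inactivating mutation drawn uniformly from five kinds:

* ``nonsense`` — an internal sense codon (middle 80% of the gene) is
  replaced by a random stop codon;
* ``frameshift_insertion`` — 1 or 2 random bases inserted internally;
* ``frameshift_deletion`` — 1 or 2 bases deleted internally;
* ``start_loss`` — the start codon's first base mutated so the codon is
  no longer a bacterial start (ATG/GTG/TTG);
* ``truncation`` — a contiguous internal block of 30–60% of the gene,
  length a multiple of 3, deleted (frame preserved so the truncation
  signal is isolated from frameshift signals).

All randomness flows from one seed; the emitted report carries enough
detail to invert every mutation, which is how the truth ledger is
validated. Coordinates of untouched features are shifted consistently
for indel-induced changes.
"""

from __future__ import annotations

import copy
import math
import os
import random
from dataclasses import dataclass

from .genome_io import (
    Feature,
    GenomeRecord,
    Interval,
    feature_nt,
    reverse_complement,
    write_fasta,
    write_gff,
)

MUTATION_KINDS = (
    "nonsense",
    "frameshift_insertion",
    "frameshift_deletion",
    "start_loss",
    "truncation",
)
STOPS = ("TAA", "TAG", "TGA")
STARTS = {"ATG", "GTG", "TTG"}
SENSE_GUARD = set(STOPS)

REPORT_HEADER = ["locus_tag", "kind", "contig", "position", "detail"]


class BreakError(ValueError):
    pass


@dataclass(frozen=True)
class ReportEntry:
    locus_tag: str
    kind: str
    contig: str
    position: int  # 1-based within the gene, coding strand
    detail: str


def validate_level(level: int) -> int:
    if not isinstance(level, int) or not (1 <= level <= 10):
        raise BreakError(f"decay level must be an integer in [1, 10], got {level!r}")
    return level


def select_targets(genes: list, level: int, rng_seed: int) -> list:
    """Pick ``round(0.05 * level * n)`` genes (min 1) without replacement."""
    validate_level(level)
    if not genes:
        raise BreakError("no genes to select from")
    rng = random.Random(rng_seed)
    n = max(1, round(0.05 * level * len(genes)))
    idx = sorted(rng.sample(range(len(genes)), min(n, len(genes))))
    return [genes[i] for i in idx]


def apply_mutation(gene_seq: str, kind: str, rng: random.Random,
                   locus_tag: str = "gene", contig: str = "contig"):
    """Apply one mutation kind to a coding-strand gene sequence.

    Returns ``(mutated_sequence, ReportEntry)``; a gene too short for
    truncation falls back to a nonsense substitution (recorded in the
    report detail).
    """
    if len(gene_seq) < 30:
        raise BreakError("gene shorter than 30 nt")
    fallback = ""
    ncod = len(gene_seq) // 3
    if kind == "truncation" and ncod < 12:
        kind = "nonsense"
        fallback = ",fallback_from:truncation"

    if kind == "nonsense":
        lo = max(1, round(0.1 * ncod))
        hi = min(ncod - 2, round(0.9 * ncod) - 1)
        candidates = [
            ci for ci in range(lo, hi + 1)
            if gene_seq[3 * ci : 3 * ci + 3] not in SENSE_GUARD
        ]
        if not candidates:
            raise BreakError("no internal sense codon available")
        ci = rng.choice(candidates)
        old = gene_seq[3 * ci : 3 * ci + 3]
        new = rng.choice(STOPS)
        mutated = gene_seq[: 3 * ci] + new + gene_seq[3 * ci + 3 :]
        return mutated, ReportEntry(
            locus_tag, "nonsense", contig, 3 * ci + 1,
            f"codon:{old}>{new}{fallback}",
        )

    if kind == "frameshift_insertion":
        n_ins = rng.choice((1, 2))
        pos = rng.randint(4, len(gene_seq) - 3)  # insert before this 1-based pos
        bases = "".join(rng.choice("ACGT") for _ in range(n_ins))
        mutated = gene_seq[: pos - 1] + bases + gene_seq[pos - 1 :]
        return mutated, ReportEntry(
            locus_tag, "frameshift_insertion", contig, pos, f"ins:{bases}"
        )

    if kind == "frameshift_deletion":
        n_del = rng.choice((1, 2))
        pos = rng.randint(4, len(gene_seq) - 3 - n_del)
        removed = gene_seq[pos - 1 : pos - 1 + n_del]
        mutated = gene_seq[: pos - 1] + gene_seq[pos - 1 + n_del :]
        return mutated, ReportEntry(
            locus_tag, "frameshift_deletion", contig, pos, f"del:{removed}"
        )

    if kind == "start_loss":
        start = gene_seq[:3]
        options = sorted(
            b for b in "ACGT"
            if b != start[0] and (b + start[1:]) not in STARTS
        )
        if not options:
            raise BreakError("cannot break start codon")
        new_base = rng.choice(options)
        mutated = new_base + gene_seq[1:]
        return mutated, ReportEntry(
            locus_tag, "start_loss", contig, 1,
            f"start:{start}>{new_base + start[1:]}",
        )

    if kind == "truncation":
        block = rng.randint(math.ceil(0.3 * ncod), math.floor(0.6 * ncod))
        block = max(1, min(block, ncod - 2))
        cs = rng.randint(1, ncod - block - 1)
        removed = gene_seq[3 * cs : 3 * (cs + block)]
        mutated = gene_seq[: 3 * cs] + gene_seq[3 * (cs + block) :]
        return mutated, ReportEntry(
            locus_tag, "truncation", contig, 3 * cs + 1, f"trunc:{removed}"
        )

    raise BreakError(f"unknown mutation kind {kind!r}")


def _splice(genome: GenomeRecord, edits: dict) -> GenomeRecord:
    """Replace gene slices and shift all feature coordinates consistently.

    ``edits`` maps locus_tag -> (old_interval, new_forward_slice).
    """
    new_contigs = dict(genome.contigs)
    deltas_by_contig: dict = {}
    for _locus, (iv, new_slice) in sorted(
        edits.items(), key=lambda kv: -kv[1][0].start
    ):
        seq = new_contigs[iv.contig_id]
        new_contigs[iv.contig_id] = seq[: iv.start] + new_slice + seq[iv.end :]
        deltas_by_contig.setdefault(iv.contig_id, []).append(
            (iv.end, len(new_slice) - len(iv))
        )
    new_features = []
    for f in genome.features:
        iv = f.interval
        d_start = sum(
            d for pos, d in deltas_by_contig.get(iv.contig_id, ()) if pos <= iv.start
        )
        d_end = sum(
            d for pos, d in deltas_by_contig.get(iv.contig_id, ()) if pos <= iv.end
        )
        nf = copy.deepcopy(f)
        nf.interval = Interval(iv.contig_id, iv.start + d_start, iv.end + d_end, iv.strand)
        new_features.append(nf)
    return GenomeRecord(new_contigs, new_features, genome.translation_table)


def break_genome(genome: GenomeRecord, level: int, seed: int,
                 outdir: str | None = None):
    """Simulate decay: returns ``(mutated_genome, report_entries)``.

    Selected genes each receive one mutation of a uniformly drawn kind;
    untouched genes are byte-identical in the output (their coordinates
    adjusted for upstream indels). When ``outdir`` is given, the mutated
    FASTA, adjusted GFF3 and the truth report TSV are written there.
    """
    validate_level(level)
    genome.validate()
    cds = sorted(
        genome.cds_features(), key=lambda f: (f.interval.contig_id, f.interval.start)
    )
    eligible = [f for f in cds if len(f.interval) >= 30]
    targets = select_targets(eligible, level, seed)
    rng = random.Random(seed + 1)
    edits = {}
    entries = []
    for feat in sorted(targets, key=lambda f: f.locus_tag):
        kind = rng.choice(MUTATION_KINDS)
        gene_seq = feature_nt(genome, feat)
        mutated, entry = apply_mutation(
            gene_seq, kind, rng, feat.locus_tag, feat.interval.contig_id
        )
        forward = (
            reverse_complement(mutated) if feat.interval.strand == "-" else mutated
        )
        edits[feat.locus_tag] = (feat.interval, forward)
        entries.append(entry)
    mutated_genome = _splice(genome, edits)
    entries.sort(key=lambda e: (e.contig, e.locus_tag))
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(mutated_genome.contigs.items(), os.path.join(outdir, "broken.fna"))
        write_gff(mutated_genome.features, os.path.join(outdir, "broken.gff"))
        with open(os.path.join(outdir, "break_report.tsv"), "w") as fh:
            fh.write(f"# seed={seed} level={level} n_selected={len(entries)}\n")
            fh.write("\t".join(REPORT_HEADER) + "\n")
            for e in entries:
                fh.write(
                    "\t".join(
                        [e.locus_tag, e.kind, e.contig, str(e.position), e.detail]
                    )
                    + "\n"
                )
    return mutated_genome, entries


def invert_entry(gene_seq: str, entry: ReportEntry) -> str:
    """Undo one reported mutation on a coding-strand gene sequence."""
    detail = entry.detail.split(",")[0]
    tag, _, payload = detail.partition(":")
    p = entry.position
    if entry.kind == "nonsense":
        old, _, _new = payload.partition(">")
        return gene_seq[: p - 1] + old + gene_seq[p + 2 :]
    if entry.kind == "frameshift_insertion":
        return gene_seq[: p - 1] + gene_seq[p - 1 + len(payload) :]
    if entry.kind == "frameshift_deletion":
        return gene_seq[: p - 1] + payload + gene_seq[p - 1 :]
    if entry.kind == "start_loss":
        old, _, _new = payload.partition(">")
        return old + gene_seq[3:]
    if entry.kind == "truncation":
        return gene_seq[: p - 1] + payload + gene_seq[p - 1 :]
    raise BreakError(f"cannot invert kind {entry.kind!r}")


def revert_genome(mutated: GenomeRecord, entries: list) -> GenomeRecord:
    """Apply the inverse of every reported mutation; restores the original."""
    by_locus = {f.locus_tag: f for f in mutated.cds_features()}
    edits = {}
    for entry in entries:
        feat = by_locus[entry.locus_tag]
        gene_seq = feature_nt(mutated, feat)
        restored = invert_entry(gene_seq, entry)
        forward = (
            reverse_complement(restored) if feat.interval.strand == "-" else restored
        )
        edits[entry.locus_tag] = (feat.interval, forward)
    return _splice(mutated, edits)
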