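"""Genome, feature and sequence I/O.

Every coordinate inside the package is 0-based, half-open, on the forward
strand of its contig. GenBank and GFF3 locations (1-based, inclusive) are
converted at the I/O boundary and nowhere else. Compound (``join``) GenBank
locations are collapsed to their enclosing span and flagged with a
``compound`` qualifier: downstream pseudogene logic operates on genomic
spans, not exon structure.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = set("ACGTN")
STRANDS = ("+", "-")

# columns of the per-call evidence table, fixed so downstream parsing is stable
EVIDENCE_HEADER = [
    "call_id", "contig", "start", "end", "strand",
    "members", "reasons", "evidence",
]


class GenomeIOError(ValueError):
    """Raised for malformed genome/feature input."""


@dataclass(frozen=True)
class Interval:
    """A genomic span: 0-based start, exclusive end, explicit strand."""

    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in STRANDS:
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Feature:
    """An annotated feature (gene, CDS, pseudogene or other)."""

    kind: str
    interval: Interval
    locus_tag: str
    qualifiers: dict = field(default_factory=dict)

    @property
    def is_partial(self) -> bool:
        return self.qualifiers.get("partial") == "true"

    @property
    def is_compound(self) -> bool:
        return self.qualifiers.get("compound") == "true"


@dataclass
class GenomeRecord:
    """A genome: ordered contigs plus a flat feature list."""

    contigs: dict  # contig_id -> uppercase A/C/G/T/N string
    features: list  # of Feature
    translation_table: int = 11

    def cds_features(self) -> list:
        return [f for f in self.features if f.kind == "CDS"]

    def validate(self) -> None:
        for contig_id, seq in self.contigs.items():
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise GenomeIOError(
                    f"contig {contig_id} contains unsupported characters: "
                    f"{sorted(bad)} (only A/C/G/T/N accepted)"
                )
        seen: dict = {}
        for f in self.features:
            if not f.locus_tag:
                raise GenomeIOError("feature with empty locus_tag")
            key = (f.kind, f.locus_tag)
            if key in seen:
                raise GenomeIOError(
                    f"duplicate locus_tag {f.locus_tag!r} for kind {f.kind}"
                )
            seen[key] = f
            if f.interval.contig_id not in self.contigs:
                raise GenomeIOError(
                    f"feature {f.locus_tag} on unknown contig {f.interval.contig_id}"
                )
            if f.interval.end > len(self.contigs[f.interval.contig_id]):
                raise GenomeIOError(
                    f"feature {f.locus_tag} extends past end of contig"
                )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for cid in sorted(self.contigs):
            h.update(cid.encode())
            h.update(self.contigs[cid].encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# reading


def _feature_kind(gb_type: str) -> str:
    if gb_type in ("gene", "CDS", "pseudogene"):
        return gb_type
    return "other"


def read_genbank(path: str) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    Requires at least one CDS feature; ``complement`` becomes strand ``-``
    and ``join`` locations are collapsed to the enclosing span with a
    ``compound`` flag.
    """
    contigs: dict = {}
    features: list = []
    table = 11
    n_auto = 0
    for rec in SeqIO.parse(path, "genbank"):
        contigs[rec.id] = str(rec.seq).upper()
        for gbf in rec.features:
            kind = _feature_kind(gbf.type)
            if kind == "other" and gbf.type == "source":
                continue
            loc = gbf.location
            if loc is None:
                raise GenomeIOError(
                    f"unparseable location for feature in {rec.id} "
                    f"(locus {gbf.qualifiers.get('locus_tag', ['?'])[0]})"
                )
            quals = {k: v[0] for k, v in gbf.qualifiers.items() if v}
            locus = quals.get("locus_tag") or quals.get("gene")
            if not locus:
                n_auto += 1
                locus = f"feature_{n_auto:05d}"
            # Biopython locations are already 0-based half-open
            start, end = int(loc.start), int(loc.end)
            strand = "-" if loc.strand == -1 else "+"
            if len(getattr(loc, "parts", [loc])) > 1:
                quals["compound"] = "true"
            if kind == "CDS":
                if "transl_table" in quals:
                    table = int(quals["transl_table"])
                if (end - start) % 3 != 0:
                    quals["partial"] = "true"
            features.append(
                Feature(kind, Interval(rec.id, start, end, strand), locus, quals)
            )
    genome = GenomeRecord(contigs, features, translation_table=table)
    genome.validate()
    if not genome.cds_features():
        raise GenomeIOError("no coding features: input has no CDS features")
    return genome


def _parse_gff_attributes(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_fasta_gff(fasta_path: str, gff_path: str) -> GenomeRecord:
    """Load a genome from a FASTA + GFF3 pair.

    All GFF seqids must exist in the FASTA; coordinates are normalised to
    the internal 0-based half-open convention.
    """
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
    }
    if not contigs:
        raise GenomeIOError(f"no sequences in {fasta_path}")
    features: list = []
    orphans = set()
    n_auto = 0
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(
                    f"{gff_path}: line {lineno}: expected 9 columns, got {len(cols)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if seqid not in contigs:
                orphans.add(seqid)
                continue
            qual = _parse_gff_attributes(attrs)
            locus = qual.get("locus_tag") or qual.get("ID")
            if not locus:
                n_auto += 1
                locus = f"feature_{n_auto:05d}"
            kind = _feature_kind(ftype)
            iv = Interval(seqid, int(start) - 1, int(end), "-" if strand == "-" else "+")
            if kind == "CDS" and len(iv) % 3 != 0:
                qual["partial"] = "true"
            features.append(Feature(kind, iv, locus, qual))
    if orphans:
        raise GenomeIOError(
            f"GFF seqids missing from FASTA: {', '.join(sorted(orphans))}"
        )
    genome = GenomeRecord(contigs, features)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# sequence extraction


def translate(nt: str, table: int = 11) -> str:
    """Frame-0 translation keeping internal stops as ``*``; trailing stop kept."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate(table=table))


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def feature_nt(genome: GenomeRecord, feature: Feature) -> str:
    """Strand-aware nucleotide sequence of a feature."""
    iv = feature.interval
    seq = genome.contigs[iv.contig_id][iv.start:iv.end]
    return reverse_complement(seq) if iv.strand == "-" else seq


def extract_coding_regions(genome: GenomeRecord):
    """Yield ``(Feature, nucleotide, protein)`` for every CDS.

    The protein is the frame-0 translation with the trailing stop removed;
    internal stops are retained as ``*`` and the feature is marked
    ``internal_stop`` rather than raising.
    """
    if not genome.cds_features():
        raise GenomeIOError("no coding features: genome has no CDS features")
    out = []
    for f in genome.cds_features():
        nt = feature_nt(genome, f)
        prot = translate(nt, genome.translation_table)
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            f.qualifiers["internal_stop"] = "true"
        out.append((f, nt, prot))
    return out


def extract_intergenic_regions(genome: GenomeRecord, min_length: int = 1):
    """Complement of the union of gene/CDS intervals, per contig.

    Regions shorter than ``min_length`` are dropped; all regions are
    reported on the forward strand (downstream six-frame search handles
    orientation).
    """
    if min_length < 1:
        raise GenomeIOError("min_length must be >= 1")
    out = []
    genic = [f for f in genome.features if f.kind in ("gene", "CDS", "pseudogene")]
    for contig_id, seq in genome.contigs.items():
        spans = sorted(
            (f.interval.start, f.interval.end)
            for f in genic
            if f.interval.contig_id == contig_id
        )
        merged: list = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        for s, e in merged + [[len(seq), len(seq)]]:
            if s - cursor >= min_length:
                iv = Interval(contig_id, cursor, s, "+")
                out.append((iv, seq[cursor:s]))
            cursor = max(cursor, e)
    return out


# ---------------------------------------------------------------------------
# writing


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(records: Iterable, path: str) -> None:
    """Write ``(id, sequence)`` pairs as 70-column wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{_wrap(seq)}\n")


def read_fasta(path: str) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _gff_escape(text: str) -> str:
    return text.replace(";", "%3B").replace("=", "%3D").replace("\t", " ")


def write_gff(features: Iterable, path: str, source: str = "pseudoscan") -> None:
    """Write features as GFF3 (1-based inclusive, version pragma emitted)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = [f"ID={_gff_escape(f.locus_tag)}"]
            for k, v in sorted(f.qualifiers.items()):
                attrs.append(f"{_gff_escape(k)}={_gff_escape(str(v))}")
            fh.write(
                "\t".join(
                    [
                        iv.contig_id,
                        source,
                        f.kind,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_genbank(genome: GenomeRecord, path: str) -> None:
    """Emit the genome as a GenBank flat file (round-trippable subset)."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    records = []
    for cid, seq in genome.contigs.items():
        rec = SeqRecord(
            Seq(seq), id=cid, name=cid[:16], description="synthetic genome",
            annotations={"molecule_type": "DNA"},
        )
        for f in genome.features:
            if f.interval.contig_id != cid:
                continue
            loc = SimpleLocation(
                f.interval.start, f.interval.end,
                strand=1 if f.interval.strand == "+" else -1,
            )
            sf = SeqFeature(loc, type=f.kind)
            sf.qualifiers["locus_tag"] = [f.locus_tag]
            if f.kind == "CDS":
                sf.qualifiers["transl_table"] = [str(genome.translation_table)]
            for k, v in f.qualifiers.items():
                sf.qualifiers.setdefault(k, [str(v)])
            rec.features.append(sf)
        records.append(rec)
    SeqIO.write(records, path, "genbank")


def write_outputs(calls, genome: GenomeRecord, outdir: str) -> dict:
    """Write the standard result bundle for a set of pseudogene calls.

    Emits pseudogene calls as GFF3 (with reason flags in the attributes),
    pseudogene nucleotide FASTA, intact-gene protein FASTA and a
    tab-separated per-call evidence table. Returns the paths written.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gff": os.path.join(outdir, "pseudogenes.gff"),
        "pseudogene_fasta": os.path.join(outdir, "pseudogenes.fna"),
        "intact_fasta": os.path.join(outdir, "intact_proteins.faa"),
        "evidence": os.path.join(outdir, "evidence.tsv"),
    }
    call_features = []
    call_seqs = []
    rows = []
    for i, call in enumerate(calls, 1):
        call_id = f"pseudo_{i:05d}"
        reasons = ",".join(sorted(call.reasons))
        quals = {"reasons": reasons}
        if call.member_locus_tags:
            quals["members"] = ",".join(call.member_locus_tags)
        call_features.append(
            Feature("pseudogene", call.interval, call_id, quals)
        )
        iv = call.interval
        seq = genome.contigs[iv.contig_id][iv.start:iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        call_seqs.append((call_id, seq))
        evidence = ",".join(
            f"{k}:{call.evidence[k]}" for k in sorted(call.evidence)
        )
        rows.append(
            [
                call_id,
                iv.contig_id,
                str(iv.start + 1),
                str(iv.end),
                iv.strand,
                ",".join(call.member_locus_tags) or ".",
                reasons,
                evidence or ".",
            ]
        )
    write_gff(call_features, paths["gff"])
    write_fasta(call_seqs, paths["pseudogene_fasta"])

    called = set()
    for call in calls:
        called.update(call.member_locus_tags)
    intact = [
        (f.locus_tag, prot)
        for f, _nt, prot in extract_coding_regions(genome)
        if f.locus_tag not in called
    ]
    write_fasta(intact, paths["intact_fasta"])
    with open(paths["evidence"], "w") as fh:
        fh.write("\t".join(EVIDENCE_HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return paths


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
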