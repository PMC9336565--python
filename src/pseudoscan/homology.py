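"""Protein and six-frame translated homology search.

One engine contract serves both the gene-vs-database and the
intergenic-vs-database searches: an engine is a callable
``engine(queries: dict[id, protein], db: dict[id, protein]) -> list[HomologyHit]``
returning raw (unranked) hits. The built-in engine pairs an exact 5-mer
candidate prescreen with full Smith–Waterman alignment (affine gaps,
BLOSUM62) so the whole pipeline runs deterministically with no external
binaries; adapters for external search tools can be plugged in through the
same contract.

Bit scores use the published gapped BLOSUM62 (open 11, extend 1)
Karlin–Altschul constants (lambda = 0.267, K = 0.041); E-values are
``m * n * 2**-bitscore`` with *n* the total database length.
"""

from __future__ import annotations

import math
import statistics
import subprocess
import tempfile
from dataclasses import dataclass, field, replace

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import reverse_complement, translate, write_fasta

KA_LAMBDA = 0.267
KA_K = 0.041
DEFAULT_EVALUE = 1e-4
DEFAULT_MAX_HITS = 15
MIN_WORD = 10  # residues; translated search needs >= 3*MIN_WORD nt

TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "slen", "frame",
]


class SearchError(RuntimeError):
    """Engine or search-input failure."""


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int
    s_end: int
    subject_length: int
    reading_frame: int = 0  # 0 for protein queries, +/-1..3 for translated

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise SearchError("q_start > q_end")
        if self.bitscore <= 0 or self.evalue < 0 or self.subject_length <= 0:
            raise SearchError("invalid hit statistics")


@dataclass
class HitSet:
    query_id: str
    hits: list = field(default_factory=list)

    def sort(self) -> "HitSet":
        self.hits.sort(key=lambda h: (-h.bitscore, h.subject_id))
        return self

    def subject_ids(self, top_n: int = DEFAULT_MAX_HITS):
        seen, out = set(), []
        for h in self.hits[:top_n]:
            if h.subject_id not in seen:
                seen.add(h.subject_id)
                out.append(h.subject_id)
        return out


# ---------------------------------------------------------------------------
# built-in aligner


def _make_aligner(mode: str, gap_open: float, gap_extend: float,
                  matrix_name: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST convention: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float  # percent over aligned columns
    alignment_length: int
    q_start: int  # 1-based inclusive spans
    q_end: int
    s_start: int
    s_end: int


def builtin_align(query: str, subject: str, gap_open: float = 11.0,
                  gap_extend: float = 1.0,
                  matrix_name: str = "BLOSUM62") -> AlignmentResult:
    """Deterministic Smith–Waterman local alignment with affine gaps."""
    if not query or not subject:
        raise SearchError("empty sequence in builtin_align")
    aligner = _make_aligner("local", gap_open, gap_extend, matrix_name)
    alignments = aligner.align(query, subject)
    aln = alignments[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    q_blocks, s_blocks = aln.aligned
    return AlignmentResult(
        score=aln.score,
        identity=100.0 * counts.identities / length if length else 0.0,
        alignment_length=length,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
    )


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def _kmers(seq: str, k: int = 5):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class BuiltinEngine:
    """Exhaustive pairwise search over a protein database.

    A shared exact 5-mer prescreen skips subject proteins with no plausible
    similarity before running the full dynamic program; the prescreen is a
    deterministic candidate filter (candidates are aligned exactly, never
    scored heuristically).
    """

    identifier = "builtin"

    def __init__(self, gap_open: float = 11.0, gap_extend: float = 1.0,
                 min_shared_kmers: int = 3, min_raw_score: float = 25.0):
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.min_shared_kmers = min_shared_kmers
        self.min_raw_score = min_raw_score
        self._index_cache: dict = {}

    def _db_index(self, db: dict):
        key = id(db)
        cached = self._index_cache.get(key)
        if cached is not None and cached[0] is db:
            return cached[1]
        index: dict = {}
        for sid, seq in db.items():
            for kmer in _kmers(seq):
                index.setdefault(kmer, set()).add(sid)
        self._index_cache = {key: (db, index)}
        return index

    def __call__(self, queries: dict, db: dict):
        if not db:
            raise SearchError("empty protein database")
        index = self._db_index(db)
        total_db = sum(len(s) for s in db.values())
        hits = []
        for qid, qseq in queries.items():
            if not qseq:
                continue
            counts: dict = {}
            qk = _kmers(qseq)
            for kmer in qk:
                for sid in index.get(kmer, ()):
                    counts[sid] = counts.get(sid, 0) + 1
            threshold = self.min_shared_kmers if len(qk) >= 20 else 1
            for sid in sorted(s for s, c in counts.items() if c >= threshold):
                res = builtin_align(qseq, db[sid], self.gap_open, self.gap_extend)
                if res.score < self.min_raw_score:
                    continue
                bits = bit_score(res.score)
                evalue = len(qseq) * total_db * 2.0 ** (-bits)
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        percent_identity=round(res.identity, 2),
                        alignment_length=res.alignment_length,
                        evalue=evalue,
                        bitscore=round(bits, 2),
                        q_start=res.q_start,
                        q_end=res.q_end,
                        s_start=res.s_start,
                        s_end=res.s_end,
                        subject_length=len(db[sid]),
                    )
                )
        return hits


class ExternalEngine:
    """Adapter running an external search tool through a command template.

    The template receives ``{query}``, ``{db}`` and ``{out}`` placeholders
    and must write standard 12-column tabular output to ``{out}``.
    """

    def __init__(self, command_template: str, identifier: str = "external"):
        self.command_template = command_template
        self.identifier = identifier

    def __call__(self, queries: dict, db: dict):
        if not db:
            raise SearchError("empty protein database")
        with tempfile.TemporaryDirectory() as tmp:
            qpath = f"{tmp}/queries.faa"
            dpath = f"{tmp}/db.faa"
            opath = f"{tmp}/hits.tsv"
            write_fasta(queries.items(), qpath)
            write_fasta(db.items(), dpath)
            cmd = self.command_template.format(query=qpath, db=dpath, out=opath)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise SearchError(
                    f"external engine failed ({cmd}): {proc.stderr.strip()}"
                )
            hits = []
            with open(opath) as fh:
                for lineno, line in enumerate(fh, 1):
                    if not line.strip() or line.startswith("#"):
                        continue
                    cols = line.rstrip("\n").split("\t")
                    if len(cols) < 12:
                        raise SearchError(
                            f"{opath}: line {lineno}: expected >=12 columns"
                        )
                    sid = cols[1]
                    hits.append(
                        HomologyHit(
                            query_id=cols[0], subject_id=sid,
                            percent_identity=float(cols[2]),
                            alignment_length=int(cols[3]),
                            evalue=float(cols[10]), bitscore=float(cols[11]),
                            q_start=int(cols[6]), q_end=int(cols[7]),
                            s_start=int(cols[8]), s_end=int(cols[9]),
                            subject_length=len(db.get(sid, "")) or int(cols[3]),
                        )
                    )
            return hits


# ---------------------------------------------------------------------------
# search drivers


def search_proteins(queries: dict, db: dict, evalue_cutoff: float = DEFAULT_EVALUE,
                    max_hits: int = DEFAULT_MAX_HITS, engine=None) -> dict:
    """Search each query protein against the database.

    Returns every query id (queries with no passing hit map to an empty
    :class:`HitSet`); hits are sorted by descending bitscore with ties
    broken by ascending subject id, then capped at ``max_hits``.
    """
    if not db:
        raise SearchError("empty protein database")
    if evalue_cutoff <= 0 or max_hits < 1:
        raise SearchError("evalue_cutoff must be > 0 and max_hits >= 1")
    engine = engine or BuiltinEngine()
    raw = engine(queries, db)
    by_query: dict = {qid: HitSet(qid) for qid in queries}
    for hit in raw:
        if hit.evalue <= evalue_cutoff:
            by_query[hit.query_id].hits.append(hit)
    for hs in by_query.values():
        hs.sort()
        del hs.hits[max_hits:]
    return by_query


def _six_frames(nt: str):
    """Yield (frame, translation, nt_offset_on_that_strand)."""
    rc = reverse_complement(nt)
    for off in range(3):
        yield off + 1, translate(nt[off:]), off
        yield -(off + 1), translate(rc[off:]), off


def search_translated(region_seq: str, db: dict,
                      evalue_cutoff: float = DEFAULT_EVALUE,
                      engine=None, region_id: str = "region",
                      max_hits: int = DEFAULT_MAX_HITS) -> HitSet:
    """Six-frame translated search of a nucleotide region against proteins.

    Hit coordinates are reported in forward-strand nucleotide space of the
    region (1-based inclusive, start < end); the frame sign carries the
    strand. Mapping to genome coordinates is the caller's job.
    """
    if len(region_seq) < 3 * MIN_WORD:
        raise SearchError(f"region shorter than {3 * MIN_WORD} nt")
    engine = engine or BuiltinEngine()
    L = len(region_seq)
    pooled = HitSet(region_id)
    for frame, prot, off in _six_frames(region_seq):
        if len(prot) < MIN_WORD:
            continue
        for hit in engine({region_id: prot}, db):
            if hit.evalue > evalue_cutoff:
                continue
            strand_start = off + 3 * (hit.q_start - 1) + 1
            strand_end = off + 3 * hit.q_end
            if frame > 0:
                nt_start, nt_end = strand_start, strand_end
            else:
                nt_start, nt_end = L - strand_end + 1, L - strand_start + 1
            pooled.hits.append(
                replace(hit, q_start=nt_start, q_end=nt_end, reading_frame=frame)
            )
    pooled.sort()
    del pooled.hits[max_hits:]
    return pooled


def hit_length_stats(hitset: HitSet, top_n: int = DEFAULT_MAX_HITS):
    """Mean and population sd of subject lengths over the top hits.

    Returns ``(mean, sd, n_used)``; mean and sd are ``None`` when the hit
    set is empty — callers must check ``n_used`` before using them.
    """
    if top_n < 1:
        raise SearchError("top_n must be >= 1")
    lengths = [h.subject_length for h in hitset.hits[:top_n]]
    if not lengths:
        return None, None, 0
    return (
        statistics.fmean(lengths),
        statistics.pstdev(lengths),
        len(lengths),
    )


# ---------------------------------------------------------------------------
# tabular cache format (12 standard columns + subject_length + frame)


def write_tabular_hits(hitsets: dict, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(TABULAR_COLUMNS) + "\n")
        for qid in sorted(hitsets):
            for h in hitsets[qid].hits:
                fh.write(
                    "\t".join(
                        [
                            h.query_id, h.subject_id,
                            f"{h.percent_identity:.17g}", str(h.alignment_length),
                            "0", "0",
                            str(h.q_start), str(h.q_end),
                            str(h.s_start), str(h.s_end),
                            f"{h.evalue:.17g}", f"{h.bitscore:.17g}",
                            str(h.subject_length), str(h.reading_frame),
                        ]
                    )
                    + "\n"
                )


def parse_tabular_hits(path: str) -> dict:
    """Lossless inverse of :func:`write_tabular_hits` (sorting re-applied)."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 14:
                raise SearchError(
                    f"{path}: line {lineno}: expected >=14 tab-separated "
                    f"columns, got {len(cols)}"
                )
            hit = HomologyHit(
                query_id=cols[0], subject_id=cols[1],
                percent_identity=float(cols[2]), alignment_length=int(cols[3]),
                q_start=int(cols[6]), q_end=int(cols[7]),
                s_start=int(cols[8]), s_end=int(cols[9]),
                evalue=float(cols[10]), bitscore=float(cols[11]),
                subject_length=int(cols[12]), reading_frame=int(cols[13]),
            )
            out.setdefault(hit.query_id, HitSet(hit.query_id)).hits.append(hit)
    for hs in out.values():
        hs.sort()
    return out
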