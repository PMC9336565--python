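"""Pairwise reference-guided gene analysis.

Given a closely related reference genome's CDS, each reference gene is
located on the query genome by translated search, realigned, and examined
for inactivating lesions: indels (frameshifting when their length is not a
multiple of three), nonsense substitutions (including stops that only
appear when the query is re-read in the frame implied by an upstream
indel), loss of the start codon, loss of the stop codon, the fraction of
the protein rendered out-of-frame by frameshifts, and relaxed selection.

dN/dS is estimated by Nei–Gojobori (1986) counting: per-codon synonymous
site fractions from exhaustive single-nucleotide neighbor enumeration,
pathway-averaged synonymous/nonsynonymous difference counts, and a
Jukes–Cantor correction of the resulting proportions. Interpretation is
gated to a trustworthy synonymous-divergence window (default
0.01 < dS < 3): outside it, dN/dS never flags a gene.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .config import Thresholds
from .genome_io import GenomeRecord, Interval, reverse_complement, translate
from .homology import BuiltinEngine, bit_score, builtin_align

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODONS = {"ATG", "GTG", "TTG"}  # bacterial alternative starts
GAP_CODON = "---"
BASES = "ACGT"

_table11 = CodonTable.unambiguous_dna_by_id[11]
SENSE_CODONS = sorted(_table11.forward_table)
AA = dict(_table11.forward_table)
for _stop in STOP_CODONS:
    AA[_stop] = "*"


class SleuthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NG86 counting machinery


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str):
    """(S, N) site counts for one sense codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous; changes creating a stop codon count as
    nonsynonymous. S + N = 3 for every sense codon.
    """
    if codon not in AA or AA[codon] == "*":
        raise SleuthError(f"not a sense codon: {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if AA.get(alt) == AA[codon]:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str):
    """Pathway-averaged (Sd, Nd) between two sense codons.

    All orderings of the differing positions are enumerated; each
    single-step change is synonymous iff it preserves the amino acid
    (intermediate stop codons count their steps as nonsynonymous).
    Sd + Nd equals the number of differing positions.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if AA.get(cur) == AA.get(nxt) and AA.get(nxt) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


def jukes_cantor(p: float):
    """JC69-corrected distance; None when p >= 3/4 (saturation)."""
    if p < 0:
        raise SleuthError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DndsResult:
    dN: float | None
    dS: float | None
    omega: float | None
    S_sites: float
    N_sites: float
    n_codons: int
    gated: bool

    def to_dict(self) -> dict:
        return {
            "dN": self.dN, "dS": self.dS, "omega": self.omega,
            "S_sites": self.S_sites, "N_sites": self.N_sites,
            "n_codons": self.n_codons, "gated": self.gated,
        }


@dataclass
class CodonAlignment:
    """Equal-length codon rows; gap cells are ``---``."""

    ref_codons: list
    query_codons: list

    def __post_init__(self):
        if len(self.ref_codons) != len(self.query_codons):
            raise SleuthError("codon rows differ in length")
        for row in (self.ref_codons, self.query_codons):
            for cell in row:
                if cell != GAP_CODON and len(cell) != 3:
                    raise SleuthError(f"bad codon cell {cell!r}")

    def ungapped(self, row: str) -> str:
        cells = self.ref_codons if row == "ref" else self.query_codons
        return "".join(c for c in cells if c != GAP_CODON)


def compute_dnds(codon_aln: CodonAlignment, ds_min: float = 0.01,
                 ds_max: float = 3.0) -> DndsResult:
    """NG86 dN/dS over the comparable codon pairs of a codon alignment.

    Comparable pairs are gapless, N-free, and sense in both rows. Raises
    when no codon pair is comparable; saturation (p >= 3/4) marks the
    affected distance None rather than raising. ``gated`` is True whenever
    dS is undefined or outside the (ds_min, ds_max) window.
    """
    S = N = Sd = Nd = 0.0
    n = 0
    for rc, qc in zip(codon_aln.ref_codons, codon_aln.query_codons):
        if rc == GAP_CODON or qc == GAP_CODON:
            continue
        if "N" in rc or "N" in qc:
            continue
        if AA.get(rc, "*") == "*" or AA.get(qc, "*") == "*":
            continue
        s1, n1 = syn_nonsyn_sites(rc)
        s2, n2 = syn_nonsyn_sites(qc)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = pathway_differences(rc, qc)
        Sd += sd
        Nd += nd
        n += 1
    if n == 0:
        raise SleuthError("no comparable codon pairs for dN/dS")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    gated = dS is None or not (ds_min < dS < ds_max)
    return DndsResult(dN, dS, omega, S, N, n, gated)


# ---------------------------------------------------------------------------
# pairwise alignment


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def _nt_aligner(free_end_gaps: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -2.0
    if free_end_gaps:
        for kind in ("insertion", "deletion"):
            for side in ("left", "right"):
                setattr(aligner, f"open_{side}_{kind}_score", 0.0)
                setattr(aligner, f"extend_{side}_{kind}_score", 0.0)
    return aligner


def _rows(alignment):
    return str(alignment[0]), str(alignment[1])


def align_pair(ref_cds: str, query_region: str):
    """Global protein and nucleotide alignments for a reference/query pair.

    Returns ``((ref_prot_row, query_prot_row), (ref_nt_row, query_nt_row))``
    as gapped strings. The protein alignment uses the frame-0 translations
    (trailing stops trimmed); both alignments are deterministic.
    """
    if len(ref_cds) < 30 or len(query_region) < 30:
        raise SleuthError("sequences must be >= 30 nt")
    ref_prot = translate(ref_cds).rstrip("*")
    query_prot = translate(query_region).rstrip("*")
    if not query_prot.strip("X"):
        raise SleuthError("query translates to no usable residues")
    prot_aln = _rows(_protein_aligner().align(ref_prot, query_prot)[0])
    nt_aln = _rows(_nt_aligner(free_end_gaps=False).align(ref_cds, query_region)[0])
    return prot_aln, nt_aln


def align_semiglobal_nt(ref_cds: str, query_region: str):
    """Nucleotide alignment with cost-free end gaps (region overhangs)."""
    return _rows(_nt_aligner(free_end_gaps=True).align(ref_cds, query_region)[0])


def codon_align(protein_alignment, ref_cds: str, query_cds: str) -> CodonAlignment:
    """Thread CDS codons through a protein alignment (pal2nal-style).

    Each aligned residue is replaced by its source codon and each protein
    gap by ``---``; errors out (naming the first offending residue) when a
    protein row disagrees with the translation of its CDS.
    """
    ref_row, query_row = protein_alignment
    out = {"ref": [], "query": []}
    for name, row, cds in (("ref", ref_row, ref_cds), ("query", query_row, query_cds)):
        prot = translate(cds).rstrip("*")
        i = 0
        for col, residue in enumerate(row):
            if residue == "-":
                out[name].append(GAP_CODON)
                continue
            if i >= len(prot) or prot[i] != residue:
                raise SleuthError(
                    f"{name} protein row disagrees with CDS translation at "
                    f"residue {i + 1} (row has {residue!r})"
                )
            out[name].append(cds[3 * i : 3 * i + 3])
            i += 1
        if i != len(prot):
            raise SleuthError(f"{name} protein row shorter than CDS translation")
    return CodonAlignment(out["ref"], out["query"])


# ---------------------------------------------------------------------------
# mutation typing


@dataclass(frozen=True)
class MutationEvent:
    kind: str  # insertion | deletion | nonsense | start_lost | stop_lost
    position: int  # codon index in the reference frame (0-based)
    length_nt: int = 0
    frameshifting: bool = False


def _alignment_walk(nt_aln):
    """Per-column (ref_index, query_index) pairs; None marks a gap.

    Indices refer to the ungapped sequences; terminal columns where either
    row is a gap are flagged so callers can skip overhangs.
    """
    ref_row, query_row = nt_aln
    first = last = None
    for col, (r, q) in enumerate(zip(ref_row, query_row)):
        if r != "-" and q != "-":
            if first is None:
                first = col
            last = col
    ri = qi = 0
    out = []
    for col, (r, q) in enumerate(zip(ref_row, query_row)):
        internal = first is not None and first <= col <= last
        out.append((
            ri if r != "-" else None,
            qi if q != "-" else None,
            internal,
        ))
        if r != "-":
            ri += 1
        if q != "-":
            qi += 1
    return out


def _indel_events(nt_aln):
    events = []
    walk = _alignment_walk(nt_aln)
    run_kind = None
    run_len = 0
    run_ref = 0
    for ri, qi, internal in walk:
        if not internal:
            kind = None
        elif ri is None:
            kind = "insertion"
        elif qi is None:
            kind = "deletion"
        else:
            kind = None
        if kind == run_kind and kind is not None:
            run_len += 1
        else:
            if run_kind is not None:
                events.append(
                    MutationEvent(run_kind, run_ref // 3, run_len,
                                  frameshifting=(run_len % 3 != 0))
                )
            run_kind = kind
            run_len = 1 if kind else 0
            if kind is not None:
                run_ref = ri if ri is not None else _last_ref(walk, qi)
    if run_kind is not None:
        events.append(
            MutationEvent(run_kind, run_ref // 3, run_len,
                          frameshifting=(run_len % 3 != 0))
        )
    return events


def _last_ref(walk, qi_target):
    ref = 0
    for ri, qi, _ in walk:
        if qi is not None and qi == qi_target:
            return ref
        if ri is not None:
            ref = ri
    return ref


def _ref_to_query_map(nt_aln):
    """ref nt index -> query nt index (first query base at/after it)."""
    mapping = {}
    pending = []
    for ri, qi, internal in _alignment_walk(nt_aln):
        if ri is not None:
            pending.append(ri)
        if qi is not None:
            for r in pending:
                mapping[r] = qi
            pending = []
    return mapping


def _query_to_ref_map(nt_aln):
    """query nt index -> last reference nt index matched at/before it."""
    mapping = {}
    last_ref = None
    for ri, qi, _internal in _alignment_walk(nt_aln):
        if ri is not None and qi is not None:
            last_ref = ri
        if qi is not None:
            mapping[qi] = last_ref
    return mapping


def detect_mutations(codon_aln, nt_aln) -> list:
    """Type inactivating lesions from the nucleotide alignment.

    Indels are maximal internal gap runs (frameshifting when their length
    is not a multiple of 3). Stop-related lesions follow the ribosome:
    the query is read in contiguous triplets from the position aligned to
    the reference start, so the reading frame downstream of an indel is
    the shifted one. The first stop triplet is classified by the
    reference codon it falls in — ``nonsense`` when that codon is sense,
    nothing when it is the reference's own terminal stop; reaching or
    passing the terminal stop without any stop triplet is ``stop_lost``.
    Start loss requires the query's first codon outside {ATG, GTG, TTG}.
    ``codon_aln`` may be None; all typing derives from ``nt_aln``.
    """
    ref_row, query_row = nt_aln
    ref_seq = ref_row.replace("-", "")
    query_seq = query_row.replace("-", "")
    events = _indel_events(nt_aln)
    n_codons = len(ref_seq) // 3
    if n_codons == 0:
        return events
    r2q = _ref_to_query_map(nt_aln)
    q2r = _query_to_ref_map(nt_aln)
    q0 = r2q.get(0)
    if q0 is None:
        return events
    ref_start = ref_seq[0:3]
    first_triplet = query_seq[q0 : q0 + 3]
    if (
        ref_start in START_CODONS
        and len(first_triplet) == 3
        and first_triplet not in START_CODONS
    ):
        events.append(MutationEvent("start_lost", 0))
    terminal_is_stop = ref_seq[3 * (n_codons - 1) : 3 * n_codons] in STOP_CODONS
    last_ci = n_codons - 1
    terminal_q = r2q.get(3 * last_ci)
    normal_stop = False
    early_stop = False
    j = 0
    while True:
        q = q0 + 3 * j
        triplet = query_seq[q : q + 3]
        if len(triplet) < 3:
            break
        ref_nt = q2r.get(q)
        ci = min(ref_nt // 3, last_ci) if ref_nt is not None else 0
        if triplet in STOP_CODONS:
            if terminal_is_stop and q == terminal_q:
                normal_stop = True  # the reference's own stop, read in frame
            elif ci < last_ci:
                events.append(MutationEvent("nonsense", ci))
                early_stop = True
            break
        if ci >= last_ci and (terminal_q is None or q > terminal_q):
            break  # read past the reference stop without terminating
        j += 1
    if terminal_is_stop and not normal_stop and not early_stop:
        events.append(MutationEvent("stop_lost", last_ci))
    return events


def frameshift_impact(ref_cds: str, query_region: str, nt_aln,
                      codon_aln=None) -> float:
    """Fraction of reference codons read out-of-frame in the query.

    For every reference codon, the query's reading frame at that codon is
    the cumulative indel offset (query minus reference nucleotides
    consumed) at the codon's first base; the codon counts as impacted when
    that offset is not a multiple of 3. In-frame indels therefore
    contribute nothing. Codons outside the aligned span are not counted as
    impacted. Denominator: all reference codons.
    """
    ref_len = len(ref_cds) - len(ref_cds) % 3
    n_codons = ref_len // 3
    if n_codons == 0:
        raise SleuthError("reference has no codons")
    walk = _alignment_walk(nt_aln)
    offset_at_ref = {}
    delta = 0
    for ri, qi, internal in walk:
        if ri is not None:
            offset_at_ref[ri] = delta
        if internal:
            if ri is None:
                delta += 1  # insertion in query
            elif qi is None:
                delta -= 1  # deletion from query
    r2q = _ref_to_query_map(nt_aln)
    impacted = 0
    for ci in range(n_codons):
        pos = 3 * ci
        if pos not in offset_at_ref or r2q.get(pos) is None:
            continue
        if offset_at_ref[pos] % 3 != 0:
            impacted += 1
    return impacted / n_codons


def codon_pairs_from_nt(nt_aln) -> CodonAlignment:
    """Codon alignment of the gapless, in-frame reference codons.

    Used for dN/dS on pairs that may carry frameshifts: only reference
    codons whose three bases align gaplessly to three contiguous query
    bases at a net offset divisible by 3 are paired.
    """
    ref_row, query_row = nt_aln
    ref_seq = ref_row.replace("-", "")
    query_seq = query_row.replace("-", "")
    walk = _alignment_walk(nt_aln)
    # per-ref-base query index only for match columns
    match_q = {}
    delta = 0
    offset_at_ref = {}
    for ri, qi, internal in walk:
        if ri is not None:
            offset_at_ref[ri] = delta
            if qi is not None:
                match_q[ri] = qi
        if internal:
            if ri is None:
                delta += 1
            elif qi is None:
                delta -= 1
    ref_codons, query_codons = [], []
    for ci in range(len(ref_seq) // 3):
        pos = 3 * ci
        qs = [match_q.get(pos + k) for k in range(3)]
        if None in qs or qs[1] != qs[0] + 1 or qs[2] != qs[0] + 2:
            continue
        if offset_at_ref.get(pos, 1) % 3 != 0:
            continue
        ref_codons.append(ref_seq[pos : pos + 3])
        query_codons.append(query_seq[qs[0] : qs[0] + 3])
    return CodonAlignment(ref_codons, query_codons)


# ---------------------------------------------------------------------------
# mapping reference CDS onto the genome


@dataclass
class _FrameHit:
    contig_id: str
    frame: int
    score: float
    start: int  # genomic 0-based
    end: int


def _frame_translations(genome: GenomeRecord):
    frames = {}
    for cid, seq in genome.contigs.items():
        rc = reverse_complement(seq)
        for off in range(3):
            frames[(cid, off + 1)] = translate(seq[off:])
            frames[(cid, -(off + 1))] = translate(rc[off:])
    return frames


def _aa_to_genomic(contig_len: int, frame: int, aa_start: int, aa_end: int):
    """aa span (0-based half-open on the frame translation) -> genomic span."""
    off = abs(frame) - 1
    s = off + 3 * aa_start
    e = off + 3 * aa_end
    if frame > 0:
        return s, e
    return contig_len - e, contig_len - s


def _locate_protein(prot: str, frames: dict, kmer_index: dict, contig_lens: dict,
                    total_aa: int, evalue_cutoff: float = 1e-3):
    """Candidate genomic loci for one protein via seeded windowed alignment."""
    qk = {}
    k = 5
    for i in range(len(prot) - k + 1):
        qk.setdefault(prot[i : i + k], []).append(i)
    buckets: dict = {}
    for kmer, qpos_list in qk.items():
        for (cid, frame, tpos) in kmer_index.get(kmer, ()):
            for qpos in qpos_list:
                key = (cid, frame, (tpos - qpos) // 24)
                buckets.setdefault(key, []).append(tpos)
    threshold = 3 if len(qk) >= 20 else 1
    # merge neighboring diagonal buckets into windows per (contig, frame)
    windows: dict = {}
    for (cid, frame, band), tpos_list in buckets.items():
        if len(tpos_list) < 1:
            continue
        windows.setdefault((cid, frame), []).extend(
            (band, len(tpos_list), min(tpos_list), max(tpos_list))
        )
    hits = []
    for (cid, frame), flat in windows.items():
        bands = sorted(
            (flat[i], flat[i + 1], flat[i + 2], flat[i + 3])
            for i in range(0, len(flat), 4)
        )
        merged = []
        for band, cnt, lo, hi in bands:
            if merged and band - merged[-1][0] <= 2:
                merged[-1] = (band, merged[-1][1] + cnt,
                              min(merged[-1][2], lo), max(merged[-1][3], hi))
            else:
                merged.append((band, cnt, lo, hi))
        trans = frames[(cid, frame)]
        for _band, cnt, lo, hi in merged:
            if cnt < threshold:
                continue
            w0 = max(0, lo - len(prot))
            w1 = min(len(trans), hi + 2 * len(prot))
            if w1 - w0 < 5:
                continue
            res = builtin_align(prot, trans[w0:w1])
            bits = bit_score(res.score)
            if len(prot) * total_aa * 2.0 ** (-bits) > evalue_cutoff:
                continue
            g0, g1 = _aa_to_genomic(
                contig_lens[cid], frame, w0 + res.s_start - 1, w0 + res.s_end
            )
            hits.append(_FrameHit(cid, frame, res.score, g0, g1))
    return hits


def _cluster_hits(hits: list, chain_distance: int) -> list:
    """Group HSPs into candidate loci: same contig/strand, nearby spans.

    A mid-gene frameshift splits one gene's homology across two reading
    frames; chaining nearby same-strand spans keeps them one locus.
    Returns ``[(contig_id, strand_sign, start, end, protein_score), ...]``.
    """
    keyed: dict = {}
    for h in hits:
        keyed.setdefault((h.contig_id, 1 if h.frame > 0 else -1), []).append(h)
    loci = []
    for (cid, sign), group in keyed.items():
        group.sort(key=lambda h: h.start)
        cur = [group[0]]
        for h in group[1:]:
            if h.start <= max(x.end for x in cur) + chain_distance:
                cur.append(h)
            else:
                loci.append(
                    (cid, sign, min(x.start for x in cur),
                     max(x.end for x in cur), max(x.score for x in cur))
                )
                cur = [h]
        loci.append(
            (cid, sign, min(x.start for x in cur),
             max(x.end for x in cur), max(x.score for x in cur))
        )
    return loci


def map_reference_cds(ref_cds: dict, genome: GenomeRecord, engine=None,
                      flank: int = 60, chain_distance: int = 100):
    """Locate each reference CDS on the query genome by translated search.

    Returns ``(mapped, unmapped)`` where ``mapped`` is a list of
    ``(reference_id, Interval)``. Candidate loci come from six-frame
    protein-level alignment; the winning locus per reference CDS is the
    candidate with the best nucleotide-level alignment score of the
    reference CDS against the candidate region, which separates a gene's
    true (near-identical) locus from paralogous copies that look alike in
    protein space. Ties break to the leftmost genomic start. The locus is
    the chained union of same-strand HSP spans, extended by ``flank`` nt
    and clipped to the contig.
    """
    frames = _frame_translations(genome)
    contig_lens = {cid: len(seq) for cid, seq in genome.contigs.items()}
    kmer_index: dict = {}
    k = 5
    for (cid, frame), trans in frames.items():
        for i in range(len(trans) - k + 1):
            kmer_index.setdefault(trans[i : i + k], []).append((cid, frame, i))
    total_aa = sum(len(t) for t in frames.values())
    nt_scorer = _nt_aligner(free_end_gaps=True)
    mapped, unmapped = [], []
    for rid in sorted(ref_cds):
        prot = translate(ref_cds[rid]).rstrip("*")
        if not prot:
            unmapped.append(rid)
            continue
        hits = _locate_protein(prot, frames, kmer_index, contig_lens, total_aa)
        if not hits:
            unmapped.append(rid)
            continue
        loci = _cluster_hits(hits, chain_distance)
        scored = []
        for cid, sign, lo, hi, _pscore in loci:
            rlo = max(0, lo - flank)
            rhi = min(contig_lens[cid], hi + flank)
            region = genome.contigs[cid][rlo:rhi]
            if sign < 0:
                region = reverse_complement(region)
            nt_score = nt_scorer.score(ref_cds[rid], region)
            scored.append((nt_score, cid, sign, rlo, rhi))
        nt_score, cid, sign, rlo, rhi = min(
            scored, key=lambda x: (-x[0], x[3], x[1])
        )
        mapped.append(
            (rid, Interval(cid, rlo, rhi, "+" if sign > 0 else "-"))
        )
    return mapped, unmapped


# ---------------------------------------------------------------------------
# per-gene report


VERDICT_FLAGS = ("high_dnds", "frameshift", "nonsense", "start_lost", "stop_lost")


@dataclass
class SleuthGeneReport:
    reference_id: str
    interval: Interval | None
    events: list = field(default_factory=list)
    frameshift_impact: float = 0.0
    dnds: DndsResult | None = None
    flags: dict = field(default_factory=dict)
    absent: bool = False

    def flagged_reasons(self):
        return {k for k, v in self.flags.items() if v}


def _verdicts(events, impact, dnds, t: Thresholds) -> dict:
    kinds = {e.kind for e in events}
    omega_flag = (
        dnds is not None
        and not dnds.gated
        and dnds.omega is not None
        and dnds.omega > t.dnds_max
    )
    return {
        "high_dnds": omega_flag,
        "frameshift": impact > t.frameshift_impact_max,
        "nonsense": "nonsense" in kinds,
        "start_lost": "start_lost" in kinds,
        "stop_lost": "stop_lost" in kinds,
    }


def sleuth_gene(reference_id: str, ref_cds: str, genome: GenomeRecord,
                t: Thresholds | None = None, engine=None,
                _premapped: Interval | None = None) -> SleuthGeneReport:
    """Run the full reference-guided chain for one reference CDS."""
    t = t or Thresholds()
    if _premapped is not None:
        interval = _premapped
    else:
        mapped, _ = map_reference_cds({reference_id: ref_cds}, genome, engine)
        if not mapped:
            return SleuthGeneReport(reference_id, None, absent=True)
        interval = mapped[0][1]
    region = genome.contigs[interval.contig_id][interval.start:interval.end]
    if interval.strand == "-":
        region = reverse_complement(region)
    nt_aln = align_semiglobal_nt(ref_cds, region)
    events = detect_mutations(None, nt_aln)
    impact = frameshift_impact(ref_cds, region, nt_aln)
    try:
        # comparable pairs come straight off the nucleotide alignment:
        # only gapless, in-frame reference codons enter the dN/dS count
        pairs = codon_pairs_from_nt(nt_aln)
        dnds = compute_dnds(pairs, t.ds_min, t.ds_max)
    except SleuthError:
        dnds = None
    flags = _verdicts(events, impact, dnds, t)
    return SleuthGeneReport(reference_id, interval, events, impact, dnds, flags)


def sleuth_genome(ref_cds: dict, genome: GenomeRecord,
                  t: Thresholds | None = None, engine=None) -> list:
    """Reports for every reference CDS (absent ones included)."""
    t = t or Thresholds()
    mapped, unmapped = map_reference_cds(ref_cds, genome, engine)
    reports = []
    for rid, interval in mapped:
        reports.append(
            sleuth_gene(rid, ref_cds[rid], genome, t, engine, _premapped=interval)
        )
    for rid in unmapped:
        reports.append(SleuthGeneReport(rid, None, absent=True))
    reports.sort(key=lambda r: r.reference_id)
    return reports


def write_sleuth_tsv(reports: list, path: str) -> None:
    header = [
        "reference_id", "contig", "start", "end", "strand", "dN", "dS",
        "omega", "gated", "impact", "events", "verdicts",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in reports:
            if r.absent:
                fh.write("\t".join([r.reference_id] + ["absent"] * 11) + "\n")
                continue
            d = r.dnds
            fmt = lambda x: "NA" if x is None else f"{x:.6g}"
            events = ",".join(
                f"{e.kind}@{e.position}" + (f":{e.length_nt}nt" if e.length_nt else "")
                for e in r.events
            ) or "."
            verdicts = ",".join(sorted(r.flagged_reasons())) or "."
            fh.write(
                "\t".join(
                    [
                        r.reference_id, r.interval.contig_id,
                        str(r.interval.start + 1), str(r.interval.end),
                        r.interval.strand,
                        fmt(d.dN if d else None), fmt(d.dS if d else None),
                        fmt(d.omega if d else None),
                        str(d.gated if d else True),
                        f"{r.frameshift_impact:.4f}", events, verdicts,
                    ]
                )
                + "\n"
            )
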