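"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a different route than the package
(explicit dynamic programming tables, exhaustive enumeration of
substitution orderings, direct offset arithmetic) so agreement is
meaningful.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

BLOSUM62 = substitution_matrices.load("BLOSUM62")
STOPS = {"TAA", "TAG", "TGA"}


def sw_score(a: str, b: str, gap_open: float = 11.0,
             gap_extend: float = 1.0) -> float:
    """Textbook Smith–Waterman with affine gaps (gap of k costs open+k*ext)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - (gap_open + gap_extend), E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - (gap_open + gap_extend), F[i - 1][j] - gap_extend)
            s = H[i - 1][j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_nt_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                gap_open: float = 5.0, gap_extend: float = 2.0) -> float:
    """Global affine-gap nucleotide alignment score (gap of k costs open+k*ext)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + gap_extend * j)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + gap_extend * i)
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            s = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i][j] = max(s, E[i][j], F[i][j])
    return H[n][m]


def _aa(codon: str) -> str:
    return "*" if codon in STOPS else str(Seq(codon).translate(table=11))


def ng86_sites(codon: str):
    """(S, N) by enumerating all 9 single-nucleotide substitutions."""
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def ng86_path_counts(c1: str, c2: str):
    """(Sd, Nd) averaged over every ordering of the differing positions."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) != "*" and _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        totals.append((sd, nd))
    n = len(totals)
    return sum(t[0] for t in totals) / n, sum(t[1] for t in totals) / n


def out_of_frame_fraction(n_codons: int, indels: list) -> float:
    """Direct offset arithmetic: fraction of codons read out of frame.

    ``indels`` is a list of ``(ref_nt_position, signed_length)`` where a
    positive length is an insertion placed immediately after that
    reference base and a negative length a deletion starting there.
    """
    impacted = 0
    for ci in range(n_codons):
        pos = 3 * ci
        offset = 0
        for p, ln in indels:
            if ln > 0 and p <= pos:
                offset += ln
            elif ln < 0 and p + (-ln) <= pos:
                offset += ln
        if offset % 3 != 0:
            impacted += 1
    return impacted / n_codons


def alignment_from_indels(ref: str, indels: list):
    """Build (ref_row, query_row) gapped strings realizing planted indels.

    Insertion ``(p, +k)``: k random-free bases (copies of 'A') enter the
    query after reference base index p-1...  here, after the first ``p``
    reference bases. Deletion ``(p, -k)``: reference bases [p, p+k) have
    no query partner.
    """
    events = sorted(indels)
    ref_row, query_row = [], []
    cursor = 0
    for p, ln in events:
        ref_row.append(ref[cursor:p])
        query_row.append(ref[cursor:p])
        if ln > 0:
            ref_row.append("-" * ln)
            query_row.append("A" * ln)
            cursor = p
        else:
            k = -ln
            ref_row.append(ref[p : p + k])
            query_row.append("-" * k)
            cursor = p + k
    ref_row.append(ref[cursor:])
    query_row.append(ref[cursor:])
    return "".join(ref_row), "".join(query_row)
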