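"""Synthetic test data: protein families, genomes, divergence, remnants.

Everything every other module consumes can be generated here from a seed:
a toy protein database organised as families (one seed protein plus two
homologs at 80–95% identity, so homolog length statistics are meaningful
and the minimum-evidence rule is satisfiable), genomes whose genes are
exact back-translations of family seed proteins, reference CDS diverged
at a controlled dS and omega, and degraded gene remnants planted into
intergenic DNA with a recorded truth interval.

All outputs are bit-reproducible from (spec, seed). Genomes are laid out
so that two copies of the same family are never adjacent: adjacency plus
shared homologs is exactly the fragment signal, which must not occur in
an undecayed genome.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from Bio.Data import CodonTable

from .genome_io import Feature, GenomeRecord, Interval, reverse_complement

_table11 = CodonTable.unambiguous_dna_by_id[11]
CODONS_FOR = {}
for _codon, _aa in _table11.forward_table.items():
    CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR:
    CODONS_FOR[_aa].sort()
AA_OF = dict(_table11.forward_table)
STOPS = ("TAA", "TAG", "TGA")

# approximate background amino-acid frequencies in bacterial proteomes
AA_BACKGROUND = {
    "A": 8.9, "R": 5.5, "N": 3.9, "D": 5.4, "C": 1.2, "Q": 3.8, "E": 6.2,
    "G": 7.4, "H": 2.2, "I": 6.0, "L": 10.2, "K": 4.7, "M": 2.3, "F": 3.9,
    "P": 4.4, "S": 6.3, "T": 5.4, "W": 1.3, "Y": 2.9, "V": 7.0,
}
_AA_LIST = sorted(AA_BACKGROUND)
_AA_WEIGHTS = [AA_BACKGROUND[a] for a in _AA_LIST]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    n_proteins: int = 60
    protein_length_range: tuple = (80, 200)
    n_genes: int = 200
    intergenic_length_range: tuple = (60, 240)
    seed: int = 0
    divergence: tuple | None = None  # (target_dS, target_omega)

    def __post_init__(self):
        lo, hi = self.protein_length_range
        ilo, ihi = self.intergenic_length_range
        if min(self.n_proteins, self.n_genes, lo, hi, ilo, ihi) <= 0 or lo > hi or ilo > ihi:
            raise FixtureError("invalid fixture specification")


def _random_protein(rng: random.Random, length: int) -> str:
    body = rng.choices(_AA_LIST, weights=_AA_WEIGHTS, k=length - 1)
    return "M" + "".join(body)


def make_protein_db(spec: FixtureSpec) -> dict:
    """Seeded toy database: per family a seed protein plus two homologs.

    Homologs carry an exact number of substitutions putting pairwise
    identity to the family seed in [0.82, 0.94]; lengths are preserved so
    intact genes sit at a length ratio of exactly 1.
    """
    rng = random.Random(spec.seed)
    lo, hi = spec.protein_length_range
    db = {}
    for i in range(spec.n_proteins):
        fam = f"fam{i:03d}"
        seed_prot = _random_protein(rng, rng.randint(lo, hi))
        db[f"{fam}_a"] = seed_prot
        for suffix in ("b", "c"):
            frac = rng.uniform(0.06, 0.18)
            k = max(1, round(frac * len(seed_prot)))
            positions = rng.sample(range(1, len(seed_prot)), k)
            mutant = list(seed_prot)
            for p in positions:
                choices = [a for a in _AA_LIST if a != mutant[p]]
                mutant[p] = rng.choice(choices)
            db[f"{fam}_{suffix}"] = "".join(mutant)
    return db


def back_translate(protein: str, rng: random.Random) -> str:
    """Random synonymous back-translation (table 11), no terminal stop."""
    return "".join(rng.choice(CODONS_FOR[aa]) for aa in protein)


def _spread_families(order: list, rng: random.Random) -> list:
    """Shuffle so no two adjacent entries share a family."""
    order = list(order)
    rng.shuffle(order)
    for _sweep in range(50):
        clashes = [
            i for i in range(1, len(order)) if order[i] == order[i - 1]
        ]
        if not clashes:
            return order
        for i in clashes:
            for j in range(len(order)):
                left = order[j - 1] if j > 0 else None
                right = order[j + 1] if j < len(order) - 1 else None
                if (
                    order[j] != order[i]
                    and order[i] not in (left, right)
                    and (
                        (j < i and order[j] != order[i - 1])
                        or (j > i and order[j] != order[i - 1])
                    )
                ):
                    order[i], order[j] = order[j], order[i]
                    break
    return order


def make_genome(db: dict, spec: FixtureSpec, contig_id: str = "contig_1"):
    """Build a genome of back-translated family seed genes.

    Genes start with ATG (M is forced at every family seed's first
    residue), end with TAA, sit on random strands and are separated by
    seeded random intergenic spacers. Returns
    ``(GenomeRecord, assignments)`` with assignments mapping locus_tag to
    the source protein id.
    """
    rng = random.Random(spec.seed + 1)
    families = sorted(pid for pid in db if pid.endswith("_a"))
    if not families:
        raise FixtureError("database has no family seed proteins")
    order = [families[i % len(families)] for i in range(spec.n_genes)]
    order = _spread_families(order, rng)
    ilo, ihi = spec.intergenic_length_range
    parts = []
    features = []
    assignments = {}
    cursor = 0

    def spacer():
        nonlocal cursor
        n = rng.randint(ilo, ihi)
        parts.append("".join(rng.choice("ACGT") for _ in range(n)))
        cursor += n

    spacer()
    for i, pid in enumerate(order):
        locus = f"gene_{i + 1:04d}"
        cds = back_translate(db[pid], rng) + "TAA"
        strand = rng.choice("+-")
        forward = reverse_complement(cds) if strand == "-" else cds
        iv = Interval(contig_id, cursor, cursor + len(cds), strand)
        parts.append(forward)
        cursor += len(cds)
        features.append(Feature("gene", iv, locus))
        features.append(Feature("CDS", iv, locus))
        assignments[locus] = pid
        spacer()
    genome = GenomeRecord({contig_id: "".join(parts)}, features)
    genome.validate()
    return genome, assignments


# ---------------------------------------------------------------------------
# controlled divergence


def _substitution_probability(d: float) -> float:
    """Invert the Jukes–Cantor correction: planted difference proportion."""
    if d < 0:
        raise FixtureError("negative divergence")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def diverge_cds(cds: str, target_dS: float, target_omega: float,
                seed: int) -> str:
    """Evolve a CDS to a target synonymous divergence and omega.

    Codon-by-codon, position-by-position: each position is substituted
    synonymously with probability p_S times its synonymous-neighbor
    fraction and nonsynonymously with p_N times its nonsynonymous
    fraction, where p_S and p_N are the Jukes–Cantor-inverted difference
    proportions for the target dS and dN = omega * dS. Stop codons are
    never introduced; the start codon and terminal stop are untouched.
    """
    if len(cds) % 3 != 0:
        raise FixtureError("CDS length not a multiple of 3")
    if target_dS == 0:
        return cds
    p_s = _substitution_probability(target_dS)
    p_n = _substitution_probability(target_omega * target_dS)
    rng = random.Random(seed)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    out = [codons[0]]
    for codon in codons[1:]:
        if codon in STOPS or codon not in AA_OF:
            out.append(codon)
            continue
        current = codon
        for pos in range(3):
            syn_alts, nonsyn_alts = [], []
            for base in "ACGT":
                if base == current[pos]:
                    continue
                alt = current[:pos] + base + current[pos + 1 :]
                if alt in STOPS:
                    continue
                (syn_alts if AA_OF[alt] == AA_OF[current] else nonsyn_alts).append(alt)
            f_s = len(syn_alts) / 3.0
            f_n = len(nonsyn_alts) / 3.0
            u = rng.random()
            if u < p_s * f_s and syn_alts:
                current = rng.choice(syn_alts)
            elif u < p_s * f_s + p_n * f_n and nonsyn_alts:
                current = rng.choice(nonsyn_alts)
        out.append(current)
    return "".join(out)


def diverge_reference(genome: GenomeRecord, target_dS: float,
                      target_omega: float, seed: int) -> dict:
    """Diverged copy of every CDS, keyed by locus_tag (reference fixture)."""
    from .genome_io import feature_nt

    out = {}
    for i, feat in enumerate(genome.cds_features()):
        out[feat.locus_tag] = diverge_cds(
            feature_nt(genome, feat), target_dS, target_omega, seed + i
        )
    return out


# ---------------------------------------------------------------------------
# planted remnants


def plant_remnant(genome: GenomeRecord, protein: str, corruption: float,
                  seed: int, strand: str = "+"):
    """Insert a degraded back-translated copy of a protein between genes.

    A ``corruption`` fraction of codons is randomized and two internal
    codons are set to stops; the copy is inserted into the middle of the
    first intergenic region with room, shifting downstream features.
    Returns ``(new_genome, truth_interval)``.
    """
    from .genome_io import extract_intergenic_regions

    rng = random.Random(seed)
    remnant = back_translate(protein, rng)
    ncod = len(remnant) // 3
    k = round(corruption * ncod)
    corrupt_at = rng.sample(range(ncod), k) if k else []
    cells = [remnant[3 * i : 3 * i + 3] for i in range(ncod)]
    for ci in corrupt_at:
        cells[ci] = "".join(rng.choice("ACGT") for _ in range(3))
    for ci in rng.sample(range(1, ncod - 1), 2):
        cells[ci] = rng.choice(STOPS)
    remnant = "".join(cells)
    if strand == "-":
        remnant = reverse_complement(remnant)

    # insertion expands the host region, so only a small margin is needed
    regions = extract_intergenic_regions(genome, min_length=20)
    if not regions:
        raise FixtureError("no intergenic region can host the remnant")
    region_iv, _seq = max(regions, key=lambda r: len(r[0]))
    insert_at = region_iv.start + len(region_iv) // 2
    contig = genome.contigs[region_iv.contig_id]
    new_seq = contig[:insert_at] + remnant + contig[insert_at:]
    new_features = []
    for f in genome.features:
        iv = f.interval
        if iv.start >= insert_at:
            iv = Interval(
                iv.contig_id, iv.start + len(remnant), iv.end + len(remnant), iv.strand
            )
        elif iv.end > insert_at:
            raise FixtureError("insertion point inside a feature")
        nf = Feature(f.kind, iv, f.locus_tag, dict(f.qualifiers))
        new_features.append(nf)
    contigs = dict(genome.contigs)
    contigs[region_iv.contig_id] = new_seq
    new_genome = GenomeRecord(contigs, new_features, genome.translation_table)
    new_genome.validate()
    truth = Interval(region_iv.contig_id, insert_at, insert_at + len(remnant), strand)
    return new_genome, truth


# ---------------------------------------------------------------------------
# the standard benchmarking fixture


@dataclass
class Fixture:
    spec: FixtureSpec
    db: dict
    genome: GenomeRecord
    assignments: dict


def build_fixture(spec: FixtureSpec) -> Fixture:
    db = make_protein_db(spec)
    genome, assignments = make_genome(db, spec)
    return Fixture(spec, db, genome, assignments)


def fixture_200(seed: int = 0) -> Fixture:
    """The standard 200-gene / 60-family benchmarking fixture."""
    return build_fixture(FixtureSpec(n_proteins=60, n_genes=200, seed=seed))


def small_fixture(seed: int = 0, n_genes: int = 24, n_proteins: int = 12) -> Fixture:
    return build_fixture(
        FixtureSpec(n_proteins=n_proteins, n_genes=n_genes, seed=seed)
    )
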