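"""Homeologous triplet construction from pairwise alignment evidence.

Cross-subgenome gene pairs are screened by BLAST-style thresholds (e-value
<= 1e-10, coverage >= 75% of the shorter sequence, identity >= 90%); the
passing pairs form a graph whose connected components are retained as
triplets only when they contain exactly one A, one B and one D gene, with
chromosome-group agreement when annotated.  Columns of the triplet alignment
with two or three distinct alleles are the subgenome-diagnostic SNP sites
used for read classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align

SUBGENOMES = ("A", "B", "D")

DEFAULT_EVALUE = 1e-10
DEFAULT_COVERAGE = 75.0
DEFAULT_IDENTITY = 90.0


@dataclass
class GeneRecord:
    gene_id: str
    subgenome: str
    sequence: str
    chromosome_group: int | None = None
    first_exon_start: int | None = None  # 1-based
    has_start_codon: bool = False

    def __post_init__(self):
        if self.subgenome not in SUBGENOMES:
            raise ValueError(f"unknown subgenome {self.subgenome!r}")
        if not self.sequence:
            raise ValueError("empty sequence")


@dataclass
class PairAlignment:
    query_id: str
    subject_id: str
    identity_pct: float
    coverage_pct: float
    e_value: float
    aligned_length: int = 0

    def passes(self, evalue=DEFAULT_EVALUE, coverage=DEFAULT_COVERAGE,
               identity=DEFAULT_IDENTITY) -> bool:
        return (self.e_value <= evalue
                and self.coverage_pct >= coverage
                and self.identity_pct >= identity)


@dataclass
class DiagnosticSite:
    """Alignment column distinguishing at least one subgenome copy.

    ``pattern`` is the partition of {A, B, D} induced by the alleles, as a
    sorted tuple of sorted tuples, e.g. ``(("A", "B"), ("D",))`` for a site
    where D carries the minority allele.  ``coords`` maps each subgenome to
    the 0-based ungapped position of the column within that copy.
    """

    column: int
    alleles: dict[str, str]
    pattern: tuple[tuple[str, ...], ...]
    coords: dict[str, int]

    @property
    def all_distinct(self) -> bool:
        return len(self.pattern) == 3


@dataclass
class HomeologTriplet:
    triplet_id: str
    members: dict[str, str]            # subgenome -> gene_id
    alignment: dict[str, str]          # subgenome -> gapped row, equal length
    diagnostic_sites: list[DiagnosticSite] = field(default_factory=list)

    def __post_init__(self):
        if set(self.members) != set(SUBGENOMES):
            raise ValueError("triplet needs exactly one member per subgenome")
        lens = {len(v) for v in self.alignment.values()}
        if len(lens) != 1:
            raise ValueError("alignment rows must have equal length")


def make_aligner() -> Align.PairwiseAligner:
    """Global DNA aligner with EMBOSS-needle-like scoring, for desk scale."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    return aligner


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1, k)}


def kmer_jaccard(seq1: str, seq2: str, k: int = 8) -> float:
    """Cheap similarity screen before full alignment (non-overlapping k-mers)."""
    a, b = _kmer_set(seq1, k), _kmer_set(seq2, k)
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def compute_alignment_stats(seq1: str, seq2: str,
                            query_id: str = "query",
                            subject_id: str = "subject",
                            aligner: Align.PairwiseAligner | None = None,
                            ) -> PairAlignment:
    """Globally align two sequences and report identity and coverage.

    Identity is matched columns over all alignment columns; coverage is the
    aligned (both-base) length over the shorter sequence length.  Both are
    symmetric in the two sequences.  An internal aligner stands in for an
    external search engine at desk scale, so no e-value is computed here
    (it is reported as 0, i.e. passing).
    """
    if not seq1 or not seq2:
        return PairAlignment(query_id, subject_id, 0.0, 0.0, 0.0, 0)
    aligner = aligner or make_aligner()
    aln = aligner.align(seq1.upper(), seq2.upper())[0]
    counts = aln.counts()
    identities, mismatches = counts.identities, counts.mismatches
    columns = counts.gaps + identities + mismatches
    aligned = identities + mismatches
    identity = 100.0 * identities / columns if columns else 0.0
    coverage = 100.0 * aligned / min(len(seq1), len(seq2))
    return PairAlignment(query_id, subject_id, identity, coverage, 0.0,
                         aligned)


def pairwise_screen(genes: list[GeneRecord],
                    aligner: Align.PairwiseAligner | None = None,
                    jaccard_min: float = 0.05) -> list[PairAlignment]:
    """All cross-subgenome pairwise stats, with a k-mer pre-screen.

    Pairs sharing almost no 8-mers cannot reach 90% identity and are skipped
    without a full alignment.
    """
    aligner = aligner or make_aligner()
    out = []
    by_sub: dict[str, list[GeneRecord]] = {s: [] for s in SUBGENOMES}
    for g in genes:
        by_sub[g.subgenome].append(g)
    for s1, s2 in (("A", "B"), ("A", "D"), ("B", "D")):
        for g1 in by_sub[s1]:
            for g2 in by_sub[s2]:
                if kmer_jaccard(g1.sequence, g2.sequence) < jaccard_min:
                    continue
                out.append(compute_alignment_stats(
                    g1.sequence, g2.sequence, g1.gene_id, g2.gene_id,
                    aligner))
    return out


def cluster_triplets(alignments: list[PairAlignment],
                     genes: dict[str, GeneRecord],
                     evalue: float = DEFAULT_EVALUE,
                     coverage: float = DEFAULT_COVERAGE,
                     identity: float = DEFAULT_IDENTITY,
                     aligner: Align.PairwiseAligner | None = None,
                     ) -> tuple[list[HomeologTriplet], list[dict]]:
    """Cluster pass-filter pairs; keep 1A+1B+1D components as triplets.

    Returns the triplets (with alignment and diagnostic sites attached) and a
    rejection log, one record per discarded component or unplaced gene, with
    the reason (composition, chromosome-group disagreement, or singleton).
    """
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for aln in alignments:
        if aln.query_id == aln.subject_id:
            continue
        if aln.passes(evalue, coverage, identity):
            graph.add_edge(aln.query_id, aln.subject_id)
    triplets, rejected = [], []
    n_emitted = 0
    for comp in sorted(nx.connected_components(graph), key=min):
        members = sorted(comp)
        subs = [genes[m].subgenome for m in members]
        counts = {s: subs.count(s) for s in SUBGENOMES}
        if len(members) == 1:
            rejected.append({"members": members, "reason": "singleton"})
            continue
        if any(c != 1 for c in counts.values()):
            rejected.append({"members": members,
                             "reason": "composition "
                                       + "/".join(f"{counts[s]}{s}"
                                                  for s in SUBGENOMES)})
            continue
        by_sub = {genes[m].subgenome: genes[m] for m in members}
        groups = {g.chromosome_group for g in by_sub.values()}
        if None not in groups and len(groups) > 1:
            rejected.append({"members": members,
                             "reason": "chromosome-group disagreement"})
            continue
        n_emitted += 1
        trip = build_triplet(f"TRP{n_emitted:04d}", by_sub, aligner=aligner)
        triplets.append(trip)
    return triplets, rejected


def triplet_msa(seq_a: str, seq_b: str, seq_d: str,
                aligner: Align.PairwiseAligner | None = None,
                ) -> dict[str, str]:
    """Column-wise alignment of the three copies.

    Equal-length inputs (the no-indel synthetic regime) are stacked directly;
    otherwise B and D are each aligned to A and merged progressively on A
    coordinates.
    """
    if len(seq_a) == len(seq_b) == len(seq_d):
        return {"A": seq_a, "B": seq_b, "D": seq_d}
    aligner = aligner or make_aligner()
    rows_ab = _pair_rows(aligner, seq_a, seq_b)
    rows_ad = _pair_rows(aligner, seq_a, seq_d)
    return _merge_on_anchor(rows_ab, rows_ad)


def _pair_rows(aligner, anchor: str, other: str) -> tuple[str, str]:
    aln = aligner.align(anchor.upper(), other.upper())[0]
    return str(aln[0]), str(aln[1])


def _merge_on_anchor(rows_ab: tuple[str, str],
                     rows_ad: tuple[str, str]) -> dict[str, str]:
    a1, b = rows_ab
    a2, d = rows_ad
    out_a, out_b, out_d = [], [], []
    i = j = 0
    while i < len(a1) or j < len(a2):
        c1 = a1[i] if i < len(a1) else None
        c2 = a2[j] if j < len(a2) else None
        if c1 == "-" and i < len(a1):
            out_a.append("-"); out_b.append(b[i]); out_d.append("-")
            i += 1
        elif c2 == "-" and j < len(a2):
            out_a.append("-"); out_b.append("-"); out_d.append(d[j])
            j += 1
        else:
            out_a.append(c1 or "-")
            out_b.append(b[i] if i < len(a1) else "-")
            out_d.append(d[j] if j < len(a2) else "-")
            i += 1
            j += 1
    return {"A": "".join(out_a), "B": "".join(out_b), "D": "".join(out_d)}


def call_diagnostic_sites(alignment: dict[str, str]) -> list[DiagnosticSite]:
    """Emit every gap-free, N-free column with >= 2 distinct alleles."""
    rows = {s: alignment[s].upper() for s in SUBGENOMES}
    ncol = len(rows["A"])
    sites = []
    coords = {s: 0 for s in SUBGENOMES}
    for col in range(ncol):
        alleles = {s: rows[s][col] for s in SUBGENOMES}
        usable = all(a in "ACGT" for a in alleles.values())
        if usable and len(set(alleles.values())) >= 2:
            groups: dict[str, list[str]] = {}
            for s, a in alleles.items():
                groups.setdefault(a, []).append(s)
            pattern = tuple(sorted(tuple(sorted(v)) for v in groups.values()))
            sites.append(DiagnosticSite(col, alleles, pattern,
                                        dict(coords)))
        for s in SUBGENOMES:
            if rows[s][col] != "-":
                coords[s] += 1
    return sites


def build_triplet(triplet_id: str, by_sub: dict[str, GeneRecord],
                  aligner: Align.PairwiseAligner | None = None,
                  ) -> HomeologTriplet:
    alignment = triplet_msa(by_sub["A"].sequence, by_sub["B"].sequence,
                            by_sub["D"].sequence, aligner=aligner)
    trip = HomeologTriplet(
        triplet_id=triplet_id,
        members={s: by_sub[s].gene_id for s in SUBGENOMES},
        alignment=alignment,
    )
    trip.diagnostic_sites = call_diagnostic_sites(alignment)
    return trip
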