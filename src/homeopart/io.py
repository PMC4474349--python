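"""Readers and writers for the formats the pipeline touches.

Tabular alignments are the standard 12-column BLAST format (query, subject,
identity, length, mismatches, gap opens, qstart, qend, sstart, send, evalue,
bitscore).  All internal coordinates are 0-based half-open; GFF3 I/O converts
to and from the format's 1-based closed convention.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .motifs import GeneModel
from .triplets import GeneRecord, PairAlignment

ALIGNMENT_COLUMNS = ("query", "subject", "identity", "length", "mismatches",
                     "gap_opens", "qstart", "qend", "sstart", "send",
                     "evalue", "bitscore")

SUBGENOME_PATTERN = re.compile(r"([1-7])([ABD])")


def one_to_zero(start1: int, end1: int) -> tuple[int, int]:
    """1-based closed interval -> 0-based half-open."""
    return start1 - 1, end1


def zero_to_one(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based closed."""
    return start0 + 1, end0


def parse_alignment_table(path,
                          lengths: dict[str, int] | None = None
                          ) -> list[PairAlignment]:
    """Parse a 12-column tabular alignment file.

    Coverage (aligned length over the shorter sequence) is computed when
    ``lengths`` supplies sequence lengths, otherwise left as ``nan``.
    Malformed rows raise with their line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(parts)}")
            try:
                query, subject = parts[0], parts[1]
                identity = float(parts[2])
                length = int(parts[3])
                evalue = float(parts[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            coverage = float("nan")
            if lengths and query in lengths and subject in lengths:
                coverage = 100.0 * length / min(lengths[query],
                                                lengths[subject])
            out.append(PairAlignment(query, subject, identity, coverage,
                                     evalue, length))
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def subgenome_of(chrom: str,
                 pattern: re.Pattern = SUBGENOME_PATTERN
                 ) -> tuple[int | None, str | None]:
    """(chromosome group, subgenome) parsed from a chromosome name."""
    m = pattern.search(chrom)
    if not m:
        return None, None
    return int(m.group(1)), m.group(2)


def load_gene_models(gff3_path, fasta_path,
                     pattern: re.Pattern = SUBGENOME_PATTERN
                     ) -> tuple[list[GeneRecord], list[GeneModel]]:
    """Gene records (spliced sequence) and gene models from GFF3 + FASTA.

    ``has_start_codon`` is true iff the gene has an annotated CDS.  The
    subgenome and chromosome group are parsed from the chromosome name; an
    unparsable name leaves them unknown and such genes are skipped from
    triplet building (they keep a gene model for promoter work).
    """
    import gffutils

    contigs = read_fasta(fasta_path)
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    records, models = [], []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in contigs:
            raise KeyError(f"contig {gene.seqid!r} of gene {gene.id} "
                           "missing from FASTA")
        exons = sorted(db.children(gene, featuretype="exon"),
                       key=lambda f: f.start)
        has_cds = any(True for _ in db.children(gene, featuretype="CDS"))
        if not exons:
            continue
        seq = "".join(contigs[gene.seqid][f.start - 1:f.end] for f in exons)
        if gene.strand == "-":
            from .simulate import revcomp
            seq = revcomp(seq)
        first = exons[0] if gene.strand == "+" else exons[-1]
        group, sub = subgenome_of(gene.seqid, pattern)
        models.append(GeneModel(gene.id, gene.seqid, gene.strand,
                                first.start, first.end, has_cds))
        if sub is not None:
            records.append(GeneRecord(gene.id, sub, seq,
                                      chromosome_group=group,
                                      first_exon_start=first.start,
                                      has_start_codon=has_cds))
    return records, models


def write_gff3(models: list[GeneModel], path) -> None:
    """Toy gene models: one gene + one exon feature each (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            fh.write(f"{m.contig}\thomeopart\tgene\t{m.first_exon_start}\t"
                     f"{m.first_exon_end}\t.\t{m.strand}\t.\t{attrs}\n")
            fh.write(f"{m.contig}\thomeopart\texon\t{m.first_exon_start}\t"
                     f"{m.first_exon_end}\t.\t{m.strand}\t.\t"
                     f"Parent={m.gene_id}\n")
            if m.has_start_codon:
                fh.write(f"{m.contig}\thomeopart\tCDS\t{m.first_exon_start}\t"
                         f"{m.first_exon_end}\t.\t{m.strand}\t0\t"
                         f"Parent={m.gene_id}\n")


def write_table(df: pd.DataFrame, path, config_hash: str | None = None
                ) -> None:
    """TSV with an optional config-hash header comment."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t")


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     index_col=["triplet_id", "subgenome"])
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    """Every knob of the pipeline, defaulting to the published thresholds."""

    # synthetic design
    rng_seed: int = 0
    n_triplets: int = 60
    n_decoys: int = 10
    gene_length: int = 1500
    divergence_rate: float = 0.02
    read_length: int = 100
    insert_size: int = 200
    seq_error_rate: float = 0.001
    depth_mean: float = 150.0
    frac_uct: float = 0.5
    uct_ratio: float = 2.0
    frac_partitioned: float = 0.3
    partition_fc: float = 4.0
    # thresholds (paper defaults)
    min_identity: float = 90.0
    min_coverage: float = 75.0
    max_evalue: float = 1e-10
    balance_p: float = 0.01
    balance_ratio: float = 1.5
    de_fold_change: float = 2.0
    de_fdr: float = 0.01
    partition_ratio: float = 2.0
    trend_log2fc: float = 1.0
    # design decision flags
    balance_method: str = "binomial"     # or "fisher2x2"
    scan_reverse_complement: bool = False
    count_dist: str = "poisson"
    write_fastq: bool = False

    def hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Flat key-value YAML with a strict schema: unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
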