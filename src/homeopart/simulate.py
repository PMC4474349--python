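"""Synthetic data with ground truth for the homeolog-partitioning pipeline.

Emulates the structure of a hexaploid wheat stress transcriptome experiment:
homeologous triplets (one gene copy per subgenome A/B/D) diverged by point
substitutions, 100-bp paired-end reads with known copy of origin, per-sample
raw counts over a 7-condition x 2-replicate design (control plus drought,
heat, and combined stress at 1 h and 6 h), and 2-kb promoters with planted
heat-shock (HSE) and dehydration-responsive (DRE) elements.

Randomness is split from one seed through ``numpy.random.SeedSequence`` with
a fixed spawn key per stage (0 triplets, 1 counts, 2 reads, 3 promoters), so
each stage is independently reproducible from the same config.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("CK", "DS-1h", "DS-6h", "HS-1h", "HS-6h", "HD-1h", "HD-6h")
STRESS_FAMILIES = ("DS", "HS", "HD")
# response patterns planted on responding homeologs: single-stress responses
# plus the drought+combined and heat+combined patterns characteristic of
# DREB- and HSF-regulated genes
RESPONSE_PATTERNS = ("DS", "HS", "HD", "DS/HD", "HS/HD")
SUBGENOMES = ("A", "B", "D")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65, 78: 78}


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate({65: "T", 67: "G", 71: "C", 84: "A", 78: "N",
                          97: "t", 99: "g", 103: "c", 116: "a", 110: "n"})[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for all synthetic stages.

    Defaults mirror the emulated experiment: 1.5-kb genes at 2% pairwise
    subgenome divergence, 100-bp paired-end reads on ~200-bp fragments, two
    replicates of the 7-condition design, a planted unequal-contribution
    ratio of 2 and a planted stress fold change of 4 on the responding
    homeolog.
    """

    n_triplets: int = 100
    gene_length: int = 1500
    divergence_rate: float = 0.02
    read_length: int = 100
    insert_size: int = 200
    seq_error_rate: float = 0.001
    conditions: tuple[str, ...] = CONDITIONS
    n_replicates: int = 2
    control: str = "CK"
    depth_mean: float = 300.0
    frac_uct: float = 0.5
    uct_ratio: float = 2.0
    frac_partitioned: float = 0.3
    partition_fc: float = 4.0
    frac_coordinated: float = 0.2
    coordinated_fc: float = 3.0
    count_dist: str = "poisson"
    nb_dispersion: float = 0.1
    n_decoys: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("divergence_rate", "seq_error_rate", "frac_uct",
                     "frac_partitioned", "frac_coordinated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_partitioned + self.frac_coordinated > 1.0:
            raise ValueError("frac_partitioned + frac_coordinated > 1")
        if self.n_triplets < 0:
            raise ValueError("n_triplets must be >= 0")
        if self.gene_length <= self.read_length:
            raise ValueError("gene_length must exceed read_length")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")
        if self.insert_size > self.gene_length:
            raise ValueError("insert_size must fit inside the gene")
        if self.control not in self.conditions:
            raise ValueError("design must contain the control condition")
        if self.uct_ratio < 1.5:
            raise ValueError("uct_ratio below the 1.5 bias threshold")
        if self.partition_fc < 2.0:
            raise ValueError("partition_fc below the 2-fold ratio threshold")
        if self.count_dist not in ("poisson", "nb"):
            raise ValueError("count_dist must be 'poisson' or 'nb'")

    @property
    def samples(self) -> list[str]:
        return [f"{c}_r{i + 1}" for c in self.conditions
                for i in range(self.n_replicates)]

    def sample_condition(self, sample: str) -> str:
        return sample.rsplit("_r", 1)[0]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=(stage,)))


@dataclass
class SimTriplet:
    triplet_id: str
    seqs: dict[str, str]
    variant_positions: np.ndarray  # 0-based positions where not all copies agree

    def gene_id(self, subgenome: str) -> str:
        return f"{self.triplet_id}_{subgenome}"


@dataclass
class TripletSet:
    triplets: list[SimTriplet]
    decoys: list[tuple[str, str, str]]  # (gene_id, subgenome, sequence)
    config: SimConfig

    @property
    def sites(self) -> pd.DataFrame:
        rows = []
        for t in self.triplets:
            for p in t.variant_positions:
                rows.append((t.triplet_id, int(p),
                             *(t.seqs[s][p] for s in SUBGENOMES)))
        return pd.DataFrame(rows, columns=["triplet_id", "pos",
                                           "allele_A", "allele_B", "allele_D"])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.triplets:
                for s in SUBGENOMES:
                    fh.write(f">{t.gene_id(s)}\n{t.seqs[s]}\n")
            for gid, _sub, seq in self.decoys:
                fh.write(f">{gid}\n{seq}\n")


def _per_copy_rate(divergence: float) -> float:
    """Per-copy substitution rate giving the target pairwise divergence.

    Each copy mutates independently from a shared ancestor; two copies differ
    at a site with probability 2m - (4/3)m^2, solved for m.
    """
    if divergence == 0:
        return 0.0
    return 0.75 * (1.0 - math.sqrt(1.0 - 4.0 * divergence / 3.0))


def simulate_triplets(config: SimConfig) -> TripletSet:
    """Draw homeologous triplet sequences with recorded variant positions."""
    rng = config.rng(0)
    if config.divergence_rate == 0 and config.n_triplets > 0:
        warnings.warn("divergence_rate is 0: triplets carry no diagnostic "
                      "sites and every read will be three-way ambiguous",
                      stacklevel=2)
    m = _per_copy_rate(config.divergence_rate)
    L = config.gene_length
    triplets = []
    for i in range(config.n_triplets):
        ancestral = _BASES[rng.integers(0, 4, L)]
        copies = {}
        for s in SUBGENOMES:
            seq = ancestral.copy()
            mask = rng.random(L) < m
            n_mut = int(mask.sum())
            if n_mut:
                # substitute to one of the three other bases, uniformly
                shift = rng.integers(1, 4, n_mut).astype(np.uint8)
                idx = np.searchsorted(_BASES, seq[mask])
                seq[mask] = _BASES[(idx + shift) % 4]
            copies[s] = seq
        stacked = np.vstack([copies[s] for s in SUBGENOMES])
        variant = np.where((stacked != stacked[0]).any(axis=0))[0]
        triplets.append(SimTriplet(
            triplet_id=f"T{i:04d}",
            seqs={s: _to_str(copies[s]) for s in SUBGENOMES},
            variant_positions=variant,
        ))
    decoys = []
    for j in range(config.n_decoys):
        sub = SUBGENOMES[j % 3]
        seq = _to_str(_BASES[rng.integers(0, 4, L)])
        decoys.append((f"X{j:04d}_{sub}", sub, seq))
    return TripletSet(triplets, decoys, config)


@dataclass
class CountSim:
    """Raw per-homeolog counts plus the generating truth."""

    counts: pd.DataFrame          # index (triplet_id, subgenome) x samples
    true_fc: pd.DataFrame         # index (triplet_id, subgenome) x conditions
    truth: pd.DataFrame           # per-triplet labels and flags
    lib_factors: pd.Series
    config: SimConfig

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def simulate_counts(config: SimConfig,
                    triplet_ids: list[str] | None = None) -> CountSim:
    """Draw raw counts encoding planted bias and stress-response structure.

    Per triplet, control means are ``depth_mean`` per homeolog, multiplied by
    ``uct_ratio`` on one random homeolog for planted unequal-contribution
    triplets; stress means are additionally multiplied by the planted fold
    change on responding homeologs.  Counts are Poisson (or gamma-Poisson for
    the negative-binomial stress test) around mean x per-sample library
    factor.
    """
    rng = config.rng(1)
    if triplet_ids is None:
        triplet_ids = [f"T{i:04d}" for i in range(config.n_triplets)]
    n = len(triplet_ids)
    samples = config.samples
    conditions = list(config.conditions)
    stress_conditions = [c for c in conditions if c != config.control]

    lib = pd.Series(rng.uniform(0.85, 1.15, len(samples)), index=samples)

    bias = np.ones((n, 3))
    is_uct = rng.random(n) < config.frac_uct
    dominant = rng.integers(0, 3, n)
    bias[np.arange(n)[is_uct], dominant[is_uct]] = config.uct_ratio

    fc = np.ones((n, 3, len(conditions)))
    u = rng.random(n)
    is_part = u < config.frac_partitioned
    is_coord = (~is_part) & (u < config.frac_partitioned
                             + config.frac_coordinated)
    responder = rng.integers(0, 3, n)
    family = rng.integers(0, len(RESPONSE_PATTERNS), n)
    down = rng.random(n) < 1.0 / 3.0
    for i in range(n):
        fams = RESPONSE_PATTERNS[family[i]].split("/")
        cols = [conditions.index(c) for c in conditions
                if c.split("-")[0] in fams]
        if is_part[i]:
            val = 1.0 / config.partition_fc if down[i] else config.partition_fc
            fc[i, responder[i], cols] = val
        elif is_coord[i]:
            fc[i, :, cols] = config.coordinated_fc

    cond_of = np.array([conditions.index(config.sample_condition(s))
                        for s in samples])
    lam = (config.depth_mean
           * bias[:, :, None]
           * fc[:, :, cond_of]
           * lib.to_numpy()[None, None, :])
    if config.count_dist == "nb":
        shape = 1.0 / config.nb_dispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam)

    index = pd.MultiIndex.from_product([triplet_ids, SUBGENOMES],
                                       names=["triplet_id", "subgenome"])
    counts_df = pd.DataFrame(counts.reshape(n * 3, len(samples)),
                             index=index, columns=samples)
    fc_df = pd.DataFrame(fc.reshape(n * 3, len(conditions)),
                         index=index, columns=conditions)

    ratio = bias.max(axis=1) / bias.min(axis=1)
    part_flags = {}
    for j, c in enumerate(conditions):
        r = fc[:, :, j].max(axis=1) / fc[:, :, j].min(axis=1)
        part_flags[c] = r >= 2.0
    truth = pd.DataFrame({
        "triplet_id": triplet_ids,
        "balance_label": np.where(ratio >= 1.5, "UCT", "ECT"),
        "dominant": np.where(is_uct, np.array(SUBGENOMES)[dominant], ""),
        "responder": np.where(is_part, np.array(SUBGENOMES)[responder], ""),
        "response_pattern": np.where(
            is_part | is_coord, np.array(RESPONSE_PATTERNS)[family], ""),
        "partitioned": is_part,
        "coordinated": is_coord,
    }).set_index("triplet_id")
    for c in stress_conditions:
        truth[f"partitioned_{c}"] = part_flags[c]
    truth["partitioned_any"] = np.column_stack(
        [part_flags[c] for c in stress_conditions]).any(axis=1)
    return CountSim(counts_df, fc_df, truth, lib, config)


@dataclass
class ReadSim:
    """Paired reads with per-read origin truth.

    ``seq2`` is stored on the forward strand of the gene; FASTQ output writes
    its reverse complement, as a sequencer would.
    """

    reads: pd.DataFrame  # read_id, sample, triplet_id, origin, start, seq1, seq2
    config: SimConfig

    def to_fastq(self, outdir, sample: str | None = None) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        qual = "I" * self.config.read_length
        groups = (self.reads.groupby("sample", sort=True)
                  if sample is None
                  else [(sample, self.reads[self.reads["sample"] == sample])])
        for name, df in groups:
            p1 = outdir / f"{name}_1.fastq"
            p2 = outdir / f"{name}_2.fastq"
            with open(p1, "w") as f1, open(p2, "w") as f2:
                for rid, s1, s2 in zip(df["read_id"], df["seq1"], df["seq2"]):
                    f1.write(f"@{rid}/1\n{s1}\n+\n{qual}\n")
                    f2.write(f"@{rid}/2\n{revcomp(s2)}\n+\n{qual}\n")
            written += [p1, p2]
        return written


def _inject_errors(mat: np.ndarray, rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        idx = np.searchsorted(_BASES, mat[mask])
        shift = rng.integers(1, 4, n_err)
        mat[mask] = _BASES[(idx + shift) % 4]
    return mat


def simulate_reads(tripletset: TripletSet, countsim: CountSim,
                   config: SimConfig | None = None,
                   samples: list[str] | None = None) -> ReadSim:
    """Draw paired-end reads; the budget per homeolog x sample is its count.

    Fragments of length ``insert_size`` are placed uniformly on the copy of
    origin; both mates are ``read_length`` long with independent per-base
    substitution errors at ``seq_error_rate``.
    """
    config = config or tripletset.config
    if config.insert_size < config.read_length:
        raise ValueError("insert_size must be >= read_length")
    rl, ins = config.read_length, config.insert_size
    if samples is None:
        samples = list(countsim.counts.columns)
    rng = config.rng(2)
    offs = np.arange(rl)
    records: list[pd.DataFrame] = []
    seq1_all, seq2_all = [], []
    for t in tripletset.triplets:
        L = config.gene_length
        for s in SUBGENOMES:
            seq = np.frombuffer(t.seqs[s].encode(), dtype=np.uint8)
            budgets = countsim.counts.loc[(t.triplet_id, s), samples]
            total = int(budgets.sum())
            if total == 0:
                continue
            starts = rng.integers(0, L - ins + 1, total)
            m1 = seq[starts[:, None] + offs].copy()
            m2 = seq[(starts + ins - rl)[:, None] + offs].copy()
            m1 = _inject_errors(m1, config.seq_error_rate, rng)
            m2 = _inject_errors(m2, config.seq_error_rate, rng)
            sample_col = np.repeat(samples, budgets.to_numpy().astype(int))
            rid = [f"{t.triplet_id}|{s}|{sam}|{i}"
                   for i, sam in enumerate(sample_col)]
            records.append(pd.DataFrame({
                "read_id": rid,
                "sample": sample_col,
                "triplet_id": t.triplet_id,
                "origin": s,
                "start": starts,
            }))
            seq1_all.extend(_to_str(row) for row in m1)
            seq2_all.extend(_to_str(row) for row in m2)
    if records:
        reads = pd.concat(records, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=["read_id", "sample", "triplet_id",
                                      "origin", "start"])
    reads["seq1"] = seq1_all
    reads["seq2"] = seq2_all
    return ReadSim(reads, config)


# ---------------------------------------------------------------------------
# Promoters

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def realize_iupac(pattern: str, rng: np.random.Generator) -> str:
    """One concrete DNA realization of an IUPAC degenerate pattern."""
    out = []
    for ch in pattern.upper():
        choices = _IUPAC.get(ch)
        if choices is None:
            raise ValueError(f"invalid IUPAC code {ch!r} in {pattern!r}")
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


@dataclass
class PromoterSim:
    promoters: dict[str, str]
    truth: pd.DataFrame  # gene_id, pos, motif, realization
    config: SimConfig

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid, seq in self.promoters.items():
                fh.write(f">{gid}\n{seq}\n")


def simulate_promoters(n_genes: int, length: int = 2000,
                       planted: list[tuple[str, str, int]] | None = None,
                       config: SimConfig | None = None,
                       planted_fraction: float = 1.0) -> PromoterSim:
    """Uniform-background promoters with planted motif realizations.

    ``planted`` lists ``(motif_name, iupac_pattern, copies_per_gene)``;
    planted instances never overlap one another, and their identities and
    0-based offsets are recorded in the truth table.  Each motif is planted
    in a given gene with probability ``planted_fraction`` (1 = every gene).
    """
    config = config or SimConfig(n_triplets=0)
    planted = planted or []
    rng = config.rng(3)
    footprint = sum(len(p) * k for _, p, k in planted)
    if footprint > length // 2:
        raise ValueError("planted motifs over-pack the promoter")
    promoters: dict[str, str] = {}
    rows = []
    for g in range(n_genes):
        gid = f"P{g:04d}"
        seq = _BASES[rng.integers(0, 4, length)]
        occupied: list[tuple[int, int]] = []
        for name, pattern, copies in planted:
            if rng.random() >= planted_fraction:
                continue
            w = len(pattern)
            for _ in range(copies):
                for _attempt in range(1000):
                    pos = int(rng.integers(0, length - w + 1))
                    if all(pos + w <= a or pos >= b for a, b in occupied):
                        break
                else:
                    raise ValueError("could not place planted motif "
                                     "without overlap")
                real = realize_iupac(pattern, rng)
                seq[pos:pos + w] = np.frombuffer(real.encode(), np.uint8)
                occupied.append((pos, pos + w))
                rows.append((gid, pos, name, real))
        promoters[gid] = _to_str(seq)
    truth = pd.DataFrame(rows, columns=["gene_id", "pos", "motif",
                                        "realization"])
    return PromoterSim(promoters, truth, config)
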