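"""End-to-end synthetic-mode pipeline.

Runs simulate -> triplet building -> read partitioning -> balance
classification -> stress partitioning -> motif/target prediction, writing
every intermediate as TSV/FASTA under an output directory plus a
deterministic summary report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance as bal
from . import io as hio
from . import motifs as mot
from . import reads as rd
from . import stress as st
from . import triplets as tb
from .simulate import (CONDITIONS, SUBGENOMES, SimConfig, simulate_counts,
                       simulate_promoters, simulate_reads, simulate_triplets)

log = logging.getLogger("homeopart")


def sim_config_from(config: hio.PipelineConfig) -> SimConfig:
    return SimConfig(
        n_triplets=config.n_triplets, n_decoys=config.n_decoys,
        gene_length=config.gene_length,
        divergence_rate=config.divergence_rate,
        read_length=config.read_length, insert_size=config.insert_size,
        seq_error_rate=config.seq_error_rate, depth_mean=config.depth_mean,
        frac_uct=config.frac_uct, uct_ratio=config.uct_ratio,
        frac_partitioned=config.frac_partitioned,
        partition_fc=config.partition_fc, count_dist=config.count_dist,
        rng_seed=config.rng_seed)


@dataclass
class PipelineResult:
    config: hio.PipelineConfig
    triplets: list
    rejections: list
    counts: pd.DataFrame
    balance: pd.DataFrame
    balance_summary: pd.DataFrame
    responses: pd.DataFrame
    partitions: pd.DataFrame
    categories: pd.Series
    partition_summary: pd.DataFrame
    target_report: pd.DataFrame
    summary_text: str


def run_pipeline(config: hio.PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage on synthetic data; write outputs if ``outdir``."""
    cfg = sim_config_from(config)
    chash = config.hash()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        hio.save_config(config, out / "config.yaml")

    log.info("stage simulate: %d triplets, seed %d", cfg.n_triplets,
             cfg.rng_seed)
    tset = simulate_triplets(cfg)
    csim = simulate_counts(cfg)
    rsim = simulate_reads(tset, csim)
    if out:
        tset.to_fasta(out / "genes.fasta")
        hio.write_table(tset.sites.set_index("triplet_id"),
                        out / "truth_sites.tsv", chash)
        hio.write_table(csim.counts, out / "truth_counts.tsv", chash)
        hio.write_table(csim.truth, out / "truth_labels.tsv", chash)
        if config.write_fastq:
            rsim.to_fastq(out / "fastq")

    log.info("stage triplets: clustering %d genes",
             3 * cfg.n_triplets + cfg.n_decoys)
    genes = {}
    for t in tset.triplets:
        for s in SUBGENOMES:
            gid = t.gene_id(s)
            genes[gid] = tb.GeneRecord(gid, s, t.seqs[s])
    for gid, sub, seq in tset.decoys:
        genes[gid] = tb.GeneRecord(gid, sub, seq)
    pairs = tb.pairwise_screen(list(genes.values()))
    built, rejections = tb.cluster_triplets(
        pairs, genes, evalue=config.max_evalue,
        coverage=config.min_coverage, identity=config.min_identity)
    if out:
        members = pd.DataFrame(
            [{"triplet_id": t.triplet_id,
              **{s: t.members[s] for s in SUBGENOMES},
              "n_diagnostic_sites": len(t.diagnostic_sites)}
             for t in built]).set_index("triplet_id")
        hio.write_table(members, out / "triplet_members.tsv", chash)
        site_rows = [{"triplet_id": t.triplet_id, "column": s.column,
                      **{f"allele_{k}": v for k, v in s.alleles.items()}}
                     for t in built for s in t.diagnostic_sites]
        hio.write_table(pd.DataFrame(site_rows).set_index("triplet_id"),
                        out / "diagnostic_sites.tsv", chash)

    log.info("stage partition: classifying %d read pairs", len(rsim.reads))
    # key built triplets back to the simulation ids via their member genes
    sites = {}
    for t in built:
        sim_id = t.members["A"].rsplit("_", 1)[0]
        sites[sim_id] = rd.site_table(t)
    assignments = rd.classify_reads(rsim, sites)
    group_counts = rd.count_groups(assignments)
    counts = rd.allocate_table(group_counts)
    if out:
        hio.write_table(group_counts, out / "read_groups.tsv", chash)
        hio.write_table(counts, out / "homeolog_counts.tsv", chash)

    log.info("stage bias: balance classification")
    control_samples = [s for s in counts.columns
                       if cfg.sample_condition(s) == cfg.control]
    calls = bal.classify_balance_table(
        counts, control_samples, p_threshold=config.balance_p,
        ratio_threshold=config.balance_ratio, method=config.balance_method)
    balance_summary = bal.summarize_balance(calls)
    if out:
        hio.write_table(calls, out / "balance_calls.tsv", chash)
        hio.write_table(balance_summary, out / "balance_summary.tsv", chash)

    log.info("stage stress: DE and partitioning")
    design = {c: [s for s in counts.columns
                  if cfg.sample_condition(s) == c]
              for c in cfg.conditions}
    responses = st.response_table(counts, design, cfg.control,
                                  fc_threshold=config.de_fold_change,
                                  fdr_threshold=config.de_fdr)
    partitions = st.partition_table(responses,
                                    partition_ratio=config.partition_ratio)
    stress_conditions = [c for c in cfg.conditions if c != cfg.control]
    categories = st.categorize_table(responses, partitions,
                                     stress_conditions)
    part_any = (partitions["partitioned"].groupby(level="triplet_id").any())
    part_summary = st.summarize_partitioning(calls["label"], part_any)
    if out:
        hio.write_table(responses, out / "responses.tsv", chash)
        hio.write_table(partitions, out / "partitions.tsv", chash)
        hio.write_table(categories.to_frame(), out / "categories.tsv", chash)
        hio.write_table(part_summary, out / "partition_summary.tsv", chash)

    log.info("stage motifs: promoter scan and target prediction")
    planted = [("HSE", "GAANNTTC", 1), ("DRE", "DRCCGACNW", 1)]
    psim = simulate_promoters(3 * cfg.n_triplets, planted=planted,
                              config=cfg, planted_fraction=0.5)
    # promoter P-ids follow the homeolog gene order (triplet-major, A/B/D)
    gene_order = [t.gene_id(s) for t in tset.triplets for s in SUBGENOMES]
    promoters = {gene_order[i]: seq
                 for i, seq in enumerate(psim.promoters.values())}
    hits = mot.scan_promoters(promoters, mot.HSF_MOTIFS + mot.DREB_MOTIFS,
                              config.scan_reverse_complement)
    gene_l2fc = responses["log2fc"].unstack("condition")
    gene_l2fc.index = [f"{t}_{s}" for t, s in gene_l2fc.index]
    signatures = pd.Series(
        {gid: mot.trend_signature(row[stress_conditions],
                                  config.trend_log2fc)[1]
         for gid, row in gene_l2fc.iterrows()})
    _sets, treport = mot.target_report(hits, signatures)
    if out:
        hio.write_table(hits.set_index("gene_id"), out / "motif_hits.tsv",
                        chash)
        hio.write_table(treport, out / "target_report.tsv", chash)

    summary = _summary_text(config, tset, built, rejections, assignments,
                            balance_summary, part_summary, treport)
    if out:
        (out / "summary.txt").write_text(summary)
    return PipelineResult(config, built, rejections, counts, calls,
                          balance_summary, responses, partitions, categories,
                          part_summary, treport, summary)


def _summary_text(config, tset, built, rejections, assignments,
                  balance_summary, part_summary, treport) -> str:
    lines = [
        "homeopart pipeline summary",
        f"config_hash: {config.hash()}",
        f"seed: {config.rng_seed}",
        f"simulated_triplets: {len(tset.triplets)}",
        f"decoy_genes: {len(tset.decoys)}",
        f"built_triplets: {len(built)}",
        f"rejected_components: {len(rejections)}",
        f"classified_read_pairs: {len(assignments)}",
        "",
        "balance:",
        balance_summary.to_string(),
        "",
        "stress partitioning:",
        part_summary.to_string(),
        "",
        "predicted targets:",
        treport.to_string(),
        "",
    ]
    return "\n".join(lines)
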