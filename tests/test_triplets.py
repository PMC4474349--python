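"""Triplet construction: alignment stats, clustering, diagnostic sites."""

import numpy as np
import pytest

from homeopart.simulate import SUBGENOMES, SimConfig, simulate_triplets
from homeopart.triplets import (DiagnosticSite, GeneRecord, PairAlignment,
                                call_diagnostic_sites, cluster_triplets,
                                compute_alignment_stats, pairwise_screen,
                                triplet_msa)


def test_identical_sequences_full_identity():
    s = "ACGT" * 25
    aln = compute_alignment_stats(s, s)
    assert aln.identity_pct == 100.0
    assert aln.coverage_pct == 100.0


def test_single_mismatch_identity():
    s1 = "ACGT" * 25
    s2 = s1[:50] + ("A" if s1[50] != "A" else "C") + s1[51:]
    aln = compute_alignment_stats(s1, s2)
    assert aln.identity_pct == pytest.approx(99.0)
    assert aln.coverage_pct == pytest.approx(100.0)


def test_stats_symmetric(rng):
    a = "".join(rng.choice(list("ACGT"), 200))
    b = "".join(rng.choice(list("ACGT"), 180))
    x = compute_alignment_stats(a, b)
    y = compute_alignment_stats(b, a)
    assert x.identity_pct == pytest.approx(y.identity_pct)
    assert x.coverage_pct == pytest.approx(y.coverage_pct)


def test_empty_sequence_scores_zero():
    aln = compute_alignment_stats("", "ACGT")
    assert aln.identity_pct == 0.0 and aln.coverage_pct == 0.0


@pytest.mark.parametrize("identity,coverage,keep", [
    (89.9, 100.0, False),
    (90.0, 74.9, False),
    (90.0, 75.0, True),
])
def test_filter_thresholds_are_sharp(identity, coverage, keep):
    aln = PairAlignment("q", "s", identity, coverage, 1e-20)
    assert aln.passes() is keep


def _gene(gid, sub, seq, group=None):
    return GeneRecord(gid, sub, seq, chromosome_group=group)


def test_clean_component_becomes_triplet(rng):
    seq = "".join(rng.choice(list("ACGT"), 200))
    genes = {f"g_{s}": _gene(f"g_{s}", s, seq, group=1) for s in SUBGENOMES}
    pairs = [PairAlignment("g_A", "g_B", 99, 100, 0),
             PairAlignment("g_A", "g_D", 99, 100, 0),
             PairAlignment("g_B", "g_D", 99, 100, 0)]
    triplets, rejected = cluster_triplets(pairs, genes)
    assert len(triplets) == 1 and not rejected
    assert triplets[0].members == {s: f"g_{s}" for s in SUBGENOMES}


def test_duplicated_subgenome_component_rejected(rng):
    seq = "".join(rng.choice(list("ACGT"), 200))
    names = ["a1_A", "a2_A", "b_B", "d_D"]
    genes = {n: _gene(n, n.rsplit("_")[-1], seq) for n in names}
    pairs = [PairAlignment(x, y, 99, 100, 0)
             for x in names for y in names if x < y]
    triplets, rejected = cluster_triplets(pairs, genes)
    assert not triplets
    assert len(rejected) == 1 and "composition" in rejected[0]["reason"]


def test_chromosome_group_disagreement_rejected(rng):
    seq = "".join(rng.choice(list("ACGT"), 200))
    genes = {f"g_{s}": _gene(f"g_{s}", s, seq, group=1 if s != "D" else 2)
             for s in SUBGENOMES}
    pairs = [PairAlignment("g_A", "g_B", 99, 100, 0),
             PairAlignment("g_A", "g_D", 99, 100, 0)]
    _, rejected = cluster_triplets(pairs, genes)
    assert rejected[0]["reason"] == "chromosome-group disagreement"


def _brute_components(edges, nodes):
    """Independent union-find over the pass-filter graph."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((frozenset(c) for c in comps.values()), key=min)


def test_synthetic_families_recovered_exactly():
    """Clustering 20 planted families plus decoys matches brute-force
    component enumeration and the generating truth."""
    cfg = SimConfig(n_triplets=20, gene_length=500, n_decoys=6, rng_seed=21)
    ts = simulate_triplets(cfg)
    genes = {}
    for t in ts.triplets:
        for s in SUBGENOMES:
            genes[t.gene_id(s)] = _gene(t.gene_id(s), s, t.seqs[s])
    for gid, sub, seq in ts.decoys:
        genes[gid] = _gene(gid, sub, seq)
    pairs = pairwise_screen(list(genes.values()))
    triplets, rejected = cluster_triplets(pairs, genes)
    got = {frozenset(t.members.values()) for t in triplets}
    want = {frozenset(t.gene_id(s) for s in SUBGENOMES) for t in ts.triplets}
    assert got == want
    edges = [(p.query_id, p.subject_id) for p in pairs if p.passes()]
    comps = _brute_components(edges, list(genes))
    keep = {c for c in comps
            if sorted(genes[g].subgenome for g in c) == ["A", "B", "D"]}
    assert got == set(keep)


def test_emitted_triplet_edges_all_pass():
    cfg = SimConfig(n_triplets=10, gene_length=500, rng_seed=3)
    ts = simulate_triplets(cfg)
    for t in ts.triplets[:4]:
        for s1, s2 in (("A", "B"), ("A", "D"), ("B", "D")):
            aln = compute_alignment_stats(t.seqs[s1], t.seqs[s2])
            assert aln.passes()


@pytest.mark.parametrize("col,expected_pattern", [
    ({"A": "C", "B": "C", "D": "T"}, (("A", "B"), ("D",))),
    ({"A": "C", "B": "T", "D": "G"}, (("A",), ("B",), ("D",))),
])
def test_diagnostic_site_patterns(col, expected_pattern):
    aln = {s: col[s] * 1 for s in SUBGENOMES}
    sites = call_diagnostic_sites(aln)
    assert len(sites) == 1
    assert sites[0].pattern == tuple(sorted(expected_pattern))
    assert sites[0].all_distinct == (len(expected_pattern) == 3)


def test_monomorphic_and_gapped_columns_skipped():
    aln = {"A": "CC-N", "B": "CC-N", "D": "CTAN"}
    sites = call_diagnostic_sites(aln)
    assert [s.column for s in sites] == [1]


def test_sites_match_truth_on_synthetic_data():
    cfg = SimConfig(n_triplets=10, gene_length=800, rng_seed=17)
    for t in simulate_triplets(cfg).triplets:
        sites = call_diagnostic_sites(t.seqs)
        assert [s.column for s in sites] == list(t.variant_positions)


def test_msa_handles_unequal_lengths():
    a = "ACGTACGTACGTACGTACGT"
    b = "ACGTACGTCGTACGTACGT"   # one deletion
    d = "ACGTACGTACGTACGTACGA"  # one substitution
    msa = triplet_msa(a, b, d)
    lens = {len(v) for v in msa.values()}
    assert len(lens) == 1
    assert msa["A"].replace("-", "") == a
    assert msa["B"].replace("-", "") == b
    assert msa["D"].replace("-", "") == d
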