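"""Read-pair classification, the ten groups, and proportional allocation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from homeopart.reads import (GROUPS, SUPPORT_GROUPS, allocate_counts,
                             allocate_table, build_count_table,
                             classify_read_pair, classify_reads,
                             count_groups, read_sam_assignments,
                             sim_site_tables, site_table_from_sim)
from homeopart.simulate import (SUBGENOMES, SimConfig, simulate_counts,
                                simulate_reads, simulate_triplets)

SITES = {0: {"A": "C", "B": "C", "D": "T"},
         1: {"A": "G", "B": "A", "D": "G"}}


def _pair(obs1, obs2=None):
    return [{s: obs1.get(s, {}) for s in SUBGENOMES},
            {s: (obs2 or {}).get(s, {}) for s in SUBGENOMES}]


def test_specific_read_assigned_to_matching_copy():
    # read shows the D allele at the {D}-vs-{A,B} site
    obs = {s: {0: "T"} for s in SUBGENOMES}
    a = classify_read_pair(_pair(obs), SITES)
    assert a.support == frozenset("D") and a.group == "D"


def test_no_site_overlap_is_three_way_ambiguous():
    a = classify_read_pair(_pair({}), SITES)
    assert a.support == frozenset(SUBGENOMES)
    assert a.group == "ABD0"


def test_two_way_ambiguity():
    obs = {s: {0: "C"} for s in SUBGENOMES}
    a = classify_read_pair(_pair(obs), SITES)
    assert a.support == frozenset({"A", "B"}) and a.group == "AB"


def test_between_mate_conflict_excluded():
    # mate 1 supports only A (site 1, allele G also matches D; add site 0 C
    # -> {A}); mate 2 supports only B
    m1 = {s: {0: "C", 1: "G"} for s in SUBGENOMES}
    m2 = {s: {1: "A"} for s in SUBGENOMES}
    a = classify_read_pair(_pair(m1, m2), SITES)
    assert a.group in ("CONFLICT_BETWEEN", "CONFLICT_WITHIN")
    # here each mate alone is consistent with someone -> between-mate
    assert a.group == "CONFLICT_BETWEEN"
    assert a.support == frozenset()


def test_within_mate_conflict():
    # observed base at site 0 matches nobody
    obs = {s: {0: "A"} for s in SUBGENOMES}
    a = classify_read_pair(_pair(obs), SITES)
    assert a.group == "CONFLICT_WITHIN"


@pytest.mark.parametrize("groups,expected", [
    ({"A": 6, "B": 2, "AB": 4}, {"A": 9, "B": 3, "D": 0}),
    ({"ABD": 9}, {"A": 3, "B": 3, "D": 3}),
    ({"A": 1, "B": 1, "D": 2, "ABD": 4}, {"A": 2, "B": 2, "D": 4}),
    ({}, {"A": 0, "B": 0, "D": 0}),
])
def test_allocation_examples(groups, expected):
    out = allocate_counts(groups)
    for s in SUBGENOMES:
        assert out[s] == pytest.approx(expected[s])


@given(hst.lists(hst.integers(0, 500), min_size=8, max_size=8))
@settings(max_examples=300, derandomize=True)
def test_allocation_conserves_mass(values):
    groups = dict(zip(SUPPORT_GROUPS, values))
    out = allocate_counts(groups)
    assert sum(out.values()) == pytest.approx(sum(values), abs=1e-9)
    assert all(v >= 0 for v in out.values())


def test_conflicts_carry_no_mass():
    out = allocate_counts({"A": 5, "CONFLICT_WITHIN": 7,
                           "CONFLICT_BETWEEN": 3})
    assert sum(out.values()) == 5


@pytest.fixture(scope="module")
def clean_sim():
    cfg = SimConfig(n_triplets=30, gene_length=800, depth_mean=200.0,
                    seq_error_rate=0.0, rng_seed=23)
    ts = simulate_triplets(cfg)
    cs = simulate_counts(cfg)
    rs = simulate_reads(ts, cs, samples=["CK_r1", "CK_r2"])
    return cfg, ts, cs, rs


def test_error_free_support_contains_origin(clean_sim):
    cfg, ts, cs, rs = clean_sim
    assignments = classify_reads(rs, sim_site_tables(ts))
    merged = assignments
    conflict = merged["group"].str.startswith("CONFLICT")
    assert not conflict.any()
    ok = [row.origin in row.group.replace("0", "")
          for row in merged.itertuples()]
    assert all(ok)


def test_allocated_counts_recover_budgets(clean_sim):
    """Allocation is within 5% of the true per-copy budgets for >=95% of
    triplets at 2% divergence and error-free reads."""
    cfg, ts, cs, rs = clean_sim
    table, _ = build_count_table(rs, sim_site_tables(ts))
    samples = ["CK_r1", "CK_r2"]
    good = 0
    for t in ts.triplets:
        truth = cs.counts.loc[t.triplet_id, samples].to_numpy(float)
        got = table.loc[t.triplet_id, samples].to_numpy(float)
        rel = np.abs(got - truth) / np.maximum(truth, 1.0)
        good += bool((rel < 0.05).all())
    assert good >= 0.95 * len(ts.triplets)


def test_vectorized_matches_scalar_classification(clean_sim):
    cfg, ts, cs, rs = clean_sim
    t = ts.triplets[0]
    st = site_table_from_sim(t)
    sub = rs.reads[rs.reads["triplet_id"] == t.triplet_id].head(200)
    fast = classify_reads(
        type(rs)(sub.reset_index(drop=True), cfg), {t.triplet_id: st})
    site_alleles = {i: {s: chr(st.alleles[s][i]) for s in SUBGENOMES}
                    for i in range(st.n_sites)}
    pos = st.coords["A"]
    rl, ins = cfg.read_length, cfg.insert_size
    for row, got in zip(sub.itertuples(), fast["group"]):
        obs_mates = []
        for seq, lo in ((row.seq1, row.start),
                        (row.seq2, row.start + ins - rl)):
            obs = {}
            for i, p in enumerate(pos):
                if lo <= p < lo + rl:
                    obs[i] = seq[p - lo]
            obs_mates.append({s: dict(obs) for s in SUBGENOMES})
        want = classify_read_pair(obs_mates, site_alleles).group
        assert got == want


def test_group_counts_table_has_all_groups(clean_sim):
    cfg, ts, cs, rs = clean_sim
    assignments = classify_reads(rs, sim_site_tables(ts))
    tab = count_groups(assignments)
    assert list(tab.columns) == list(GROUPS)
    assert tab.to_numpy().sum() == len(assignments)


def _write_sam(path, triplet, reads):
    """Tiny hand-built SAM: each read aligned to all three copies."""
    L = len(triplet.seqs["A"])
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for s in SUBGENOMES:
            fh.write(f"@SQ\tSN:{triplet.gene_id(s)}\tLN:{L}\n")
        for rid, seq, pos in reads:
            for s in SUBGENOMES:
                fh.write(f"{rid}\t0\t{triplet.gene_id(s)}\t{pos + 1}\t60\t"
                         f"{len(seq)}M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n")


def test_sam_classification_round_trip(tmp_path, clean_sim):
    cfg, ts, cs, rs = clean_sim
    t = ts.triplets[0]
    p = int(t.variant_positions[0])
    lo = max(0, p - 10)
    reads = [(f"r{s}", t.seqs[s][lo:lo + 50], lo) for s in SUBGENOMES]
    sam = tmp_path / "toy.sam"
    _write_sam(sam, t, reads)
    gene_map = {t.gene_id(s): (t.triplet_id, s) for s in SUBGENOMES}
    sites = {t.triplet_id: site_table_from_sim(t)}
    out = read_sam_assignments(sam, gene_map, sites)
    assert len(out) == 3
    by_id = out.set_index("read_id")
    for s in SUBGENOMES:
        assert s in by_id.loc[f"r{s}", "support"]
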