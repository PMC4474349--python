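"""Read classification at diagnostic SNP sites and proportional allocation.

A read pair mapped to all three homeologs of a triplet is assigned the set of
subgenome copies whose alleles it matches at every diagnostic site it
overlaps, pooling both mates.  Pairs overlapping no site are three-way
ambiguous; pairs matching no copy are conflicts and contribute nothing.
Ambiguous (two- and three-way) counts are then divided proportionally to the
subgenome-specific counts of the same triplet and sample, with an equal split
where no specific reads exist.

The ten read groups are the seven support patterns {A}, {B}, {D}, {A,B},
{A,D}, {B,D}, {A,B,D}, the {A,B,D} subclass that overlapped no diagnostic
site at all (``ABD0``), and two conflict classes (within one mate vs between
mates).  Only the seven support patterns carry count mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ReadSim, SUBGENOMES, TripletSet
from .triplets import HomeologTriplet

GROUPS = ("A", "B", "D", "AB", "AD", "BD", "ABD", "ABD0",
          "CONFLICT_WITHIN", "CONFLICT_BETWEEN")
SUPPORT_GROUPS = GROUPS[:8]
CONFLICT_GROUPS = GROUPS[8:]


@dataclass
class ReadAssignment:
    read_id: str
    support: frozenset[str]
    group: str


@dataclass
class SiteTable:
    """Diagnostic sites of one triplet: per-copy coordinates and alleles."""

    triplet_id: str
    coords: dict[str, np.ndarray]   # subgenome -> 0-based positions, sorted order shared
    alleles: dict[str, np.ndarray]  # subgenome -> allele bytes (uint8)

    @property
    def n_sites(self) -> int:
        return len(self.alleles["A"])


def site_table(triplet: HomeologTriplet) -> SiteTable:
    coords = {s: [] for s in SUBGENOMES}
    alleles = {s: [] for s in SUBGENOMES}
    for site in triplet.diagnostic_sites:
        for s in SUBGENOMES:
            coords[s].append(site.coords[s])
            alleles[s].append(ord(site.alleles[s]))
    return SiteTable(
        triplet.triplet_id,
        {s: np.asarray(coords[s], dtype=np.int64) for s in SUBGENOMES},
        {s: np.asarray(alleles[s], dtype=np.uint8) for s in SUBGENOMES},
    )


def site_table_from_sim(sim_triplet) -> SiteTable:
    """Site table straight from a synthetic triplet's variant truth."""
    pos = np.asarray(sim_triplet.variant_positions, dtype=np.int64)
    coords = {s: pos for s in SUBGENOMES}
    alleles = {
        s: np.frombuffer(sim_triplet.seqs[s].encode(), np.uint8)[pos]
        for s in SUBGENOMES
    }
    return SiteTable(sim_triplet.triplet_id, coords, alleles)


def _group_label(support: frozenset[str], any_overlap: bool) -> str:
    label = "".join(s for s in SUBGENOMES if s in support)
    if label == "ABD" and not any_overlap:
        return "ABD0"
    return label


def classify_read_pair(mate_obs: list[dict[str, dict[int, str]]],
                       site_alleles: dict[int, dict[str, str]],
                       read_id: str = "read") -> ReadAssignment:
    """Classify one pair from per-mate, per-copy observed bases.

    ``mate_obs[m][subgenome]`` maps overlapped site index -> observed base for
    that mate's placement on that copy; ``site_alleles[site index]`` gives the
    reference allele of each copy.  A copy supports the pair iff every
    observed base on it equals its allele, in both mates.
    """
    per_mate_support = []
    any_overlap = False
    for obs in mate_obs:
        sup = set()
        for s in SUBGENOMES:
            seen = obs.get(s, {})
            if seen:
                any_overlap = True
            if all(base == site_alleles[i][s] for i, base in seen.items()):
                sup.add(s)
        per_mate_support.append(sup)
    if any(not sup for sup in per_mate_support):
        return ReadAssignment(read_id, frozenset(), "CONFLICT_WITHIN")
    support = frozenset(set.intersection(*per_mate_support)
                        if per_mate_support else set(SUBGENOMES))
    if not support:
        return ReadAssignment(read_id, frozenset(), "CONFLICT_BETWEEN")
    return ReadAssignment(read_id, support,
                          _group_label(support, any_overlap))


def _mate_matrix(seqs: pd.Series, read_length: int) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), np.uint8).reshape(
        -1, read_length)


def _window_support(arr: np.ndarray, starts: np.ndarray, read_length: int,
                    pos: np.ndarray, alleles: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-copy consistency of one mate with every site (vacuously true
    outside the window).  Returns (consistent[n, 3], overlapped_any[n])."""
    n = len(starts)
    if len(pos) == 0:
        return np.ones((n, 3), dtype=bool), np.zeros(n, dtype=bool)
    inwin = (pos[None, :] >= starts[:, None]) \
        & (pos[None, :] < starts[:, None] + read_length)
    col = np.clip(pos[None, :] - starts[:, None], 0, read_length - 1)
    obs = arr[np.arange(n)[:, None], col]
    consistent = np.empty((n, 3), dtype=bool)
    for j in range(3):
        consistent[:, j] = (~inwin | (obs == alleles[j][None, :])).all(axis=1)
    return consistent, inwin.any(axis=1)


_GROUP_OF_BITS = {
    (1, 0, 0): "A", (0, 1, 0): "B", (0, 0, 1): "D",
    (1, 1, 0): "AB", (1, 0, 1): "AD", (0, 1, 1): "BD",
    (1, 1, 1): "ABD",
}


def classify_reads(readsim: ReadSim, sites: dict[str, SiteTable]
                   ) -> pd.DataFrame:
    """Vectorized classification of simulated reads (shared coordinates).

    Synthetic homeolog copies are ungapped and equal-length, so one shared
    coordinate system applies to all three copies; both mates of a pair carry
    the fragment start in the truth table.
    """
    cfg = readsim.config
    rl, ins = cfg.read_length, cfg.insert_size
    out = []
    for triplet_id, df in readsim.reads.groupby("triplet_id", sort=True):
        st = sites[triplet_id]
        pos = st.coords["A"]
        alleles = np.vstack([st.alleles[s] for s in SUBGENOMES]) \
            if st.n_sites else np.zeros((3, 0), np.uint8)
        starts = df["start"].to_numpy()
        arr1 = _mate_matrix(df["seq1"], rl)
        arr2 = _mate_matrix(df["seq2"], rl)
        c1, o1 = _window_support(arr1, starts, rl, pos, alleles)
        c2, o2 = _window_support(arr2, starts + ins - rl, rl, pos, alleles)
        within = ~c1.any(axis=1) | ~c2.any(axis=1)
        sup = c1 & c2
        between = ~within & ~sup.any(axis=1)
        overlap = o1 | o2
        groups = np.empty(len(df), dtype=object)
        for i in range(len(df)):
            if within[i]:
                groups[i] = "CONFLICT_WITHIN"
            elif between[i]:
                groups[i] = "CONFLICT_BETWEEN"
            else:
                g = _GROUP_OF_BITS[tuple(int(v) for v in sup[i])]
                groups[i] = "ABD0" if g == "ABD" and not overlap[i] else g
        res = df[["read_id", "sample", "triplet_id", "origin"]].copy()
        res["group"] = groups
        out.append(res)
    if not out:
        return pd.DataFrame(columns=["read_id", "sample", "triplet_id",
                                     "origin", "group"])
    return pd.concat(out, ignore_index=True)


def sim_site_tables(tripletset: TripletSet) -> dict[str, SiteTable]:
    return {t.triplet_id: site_table_from_sim(t)
            for t in tripletset.triplets}


def count_groups(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per triplet x sample counts of each of the ten read groups."""
    tab = (assignments.groupby(["triplet_id", "sample", "group"])
           .size().unstack("group", fill_value=0))
    for g in GROUPS:
        if g not in tab.columns:
            tab[g] = 0
    return tab[list(GROUPS)]


def allocate_counts(groups: dict[str, float]) -> dict[str, float]:
    """Divide ambiguous read mass proportionally to the specific counts.

    For copy A: ``A = n_A + n_AB * n_A/(n_A+n_B) + n_AD * n_A/(n_A+n_D)
    + n_ABD * n_A/(n_A+n_B+n_D)`` and symmetrically for B and D; an ambiguity
    class whose specific-count denominator is zero is split equally among its
    member copies.  Conflict reads contribute nothing.
    """
    n = {s: float(groups.get(s, 0)) for s in SUBGENOMES}
    out = dict(n)
    ambiguous = {("A", "B"): groups.get("AB", 0),
                 ("A", "D"): groups.get("AD", 0),
                 ("B", "D"): groups.get("BD", 0),
                 ("A", "B", "D"): (groups.get("ABD", 0)
                                   + groups.get("ABD0", 0))}
    for members, mass in ambiguous.items():
        if mass <= 0:
            continue
        denom = sum(n[s] for s in members)
        for s in members:
            share = n[s] / denom if denom > 0 else 1.0 / len(members)
            out[s] += mass * share
    return out


def allocate_table(group_counts: pd.DataFrame) -> pd.DataFrame:
    """Allocated fractional counts, index (triplet_id, subgenome) x samples."""
    records: dict[tuple[str, str], dict[str, float]] = {}
    for (triplet_id, sample), row in group_counts.iterrows():
        alloc = allocate_counts(row.to_dict())
        for s in SUBGENOMES:
            records.setdefault((triplet_id, s), {})[sample] = alloc[s]
    idx = pd.MultiIndex.from_tuples(records.keys(),
                                    names=["triplet_id", "subgenome"])
    table = pd.DataFrame(list(records.values()), index=idx).fillna(0.0)
    return table.sort_index()


def build_count_table(readsim: ReadSim, sites: dict[str, SiteTable]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify reads and allocate: returns (allocated table, group counts)."""
    assignments = classify_reads(readsim, sites)
    groups = count_groups(assignments)
    return allocate_table(groups), groups


# ---------------------------------------------------------------------------
# SAM input

def read_sam_assignments(path, gene_to_triplet: dict[str, tuple[str, str]],
                         sites: dict[str, SiteTable]) -> pd.DataFrame:
    """Classify pairs from a SAM file of placements on homeolog references.

    Reference names are gene ids mapped to (triplet, subgenome) by
    ``gene_to_triplet``.  Only pairs with placements on all three copies of
    one triplet enter classification; others are dropped (the mapping-filter
    contract).  Returns a read-per-row frame with the group label.
    """
    import pysam

    per_read: dict[tuple[str, int], dict[str, dict[int, str]]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name not in gene_to_triplet:
                continue
            triplet_id, sub = gene_to_triplet[aln.reference_name]
            mate = 1 if aln.is_read2 else 0
            key = (aln.query_name, triplet_id)
            entry = per_read.setdefault(key, {0: {}, 1: {}})
            st = sites[triplet_id]
            refpos_to_q = {rp: qp for qp, rp in
                           aln.get_aligned_pairs(matches_only=True)}
            obs = {}
            qseq = aln.query_sequence or ""
            for i, rp in enumerate(st.coords[sub]):
                qp = refpos_to_q.get(int(rp))
                if qp is not None and qp < len(qseq):
                    obs[i] = qseq[qp]
            entry[mate].setdefault(sub, {}).update(obs)
            entry[mate].setdefault("_placed", set()).add(sub)  # type: ignore
    rows = []
    for (read_id, triplet_id), mates in per_read.items():
        placed = set()
        for m in (0, 1):
            placed |= mates[m].get("_placed", set())
        if placed != set(SUBGENOMES):
            continue
        st = sites[triplet_id]
        site_alleles = {i: {s: chr(st.alleles[s][i]) for s in SUBGENOMES}
                        for i in range(st.n_sites)}
        mate_obs = [{s: mates[m].get(s, {}) for s in SUBGENOMES}
                    for m in (0, 1) if mates[m].get("_placed")]
        assign = classify_read_pair(mate_obs, site_alleles, read_id)
        rows.append({"read_id": read_id, "triplet_id": triplet_id,
                     "group": assign.group,
                     "support": "".join(sorted(assign.support))})
    return pd.DataFrame(rows)
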