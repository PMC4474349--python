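"""Promoter extraction, degenerate motif scanning, and target prediction.

Heat-shock elements (HSE, ``GAANNTTC`` and its reverse orientation
``TTCNNGAA``) and the dehydration-responsive element (DRE,
``(A/G/T)(A/G)CCGACN(A/T)``, IUPAC ``DRCCGACNW``) are scanned over the 2-kb
region upstream of the first exon of genes with an annotated start codon.
Genes carrying a motif hit and matching the inducing expression trend of the
corresponding transcription-factor group (drought/combined-induced for DREBs,
heat/combined-induced for HSFs) are predicted as co-expressed targets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import _IUPAC, revcomp

PROMOTER_LENGTH = 2000
TREND_LOG2FC = 1.0


@dataclass(frozen=True)
class IupacMotif:
    name: str
    pattern: str

    def __post_init__(self):
        if len(self.pattern) < 4:
            raise ValueError("pattern too short")
        for ch in self.pattern.upper():
            if ch not in _IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r}")

    @property
    def regex(self) -> re.Pattern:
        # N in the scanned sequence matches nothing, so classes never list N
        body = "".join(c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]"
                       for c in self.pattern.upper())
        return re.compile(f"(?=({body}))")


HSE_FORWARD = IupacMotif("HSE", "GAANNTTC")
HSE_REVERSE = IupacMotif("HSE_rev", "TTCNNGAA")
DRE = IupacMotif("DRE", "DRCCGACNW")

HSF_MOTIFS = (HSE_FORWARD, HSE_REVERSE)
DREB_MOTIFS = (DRE,)


@dataclass
class MotifHit:
    gene_id: str
    offset: int        # 0-based within the scanned promoter
    motif: str
    strand: str = "+"
    match: str = ""


@dataclass
class GeneModel:
    """Minimal gene coordinates for promoter extraction (1-based, closed)."""

    gene_id: str
    contig: str
    strand: str
    first_exon_start: int
    first_exon_end: int
    has_start_codon: bool = True


def scan_motif(sequence: str, motif: IupacMotif,
               gene_id: str = "seq") -> list[MotifHit]:
    """All (overlapping) occurrences of the motif on the forward strand."""
    seq = sequence.upper()
    hits = []
    for m in motif.regex.finditer(seq):
        hits.append(MotifHit(gene_id, m.start(), motif.name,
                             match=m.group(1)))
    return hits


def scan_promoters(promoters: dict[str, str],
                   motifs: tuple[IupacMotif, ...],
                   scan_reverse_complement: bool = False) -> pd.DataFrame:
    """Hit table over a promoter set; optionally also the reverse strand."""
    rows = []
    for gid, seq in promoters.items():
        for motif in motifs:
            for h in scan_motif(seq, motif, gid):
                rows.append((gid, h.offset, motif.name, "+", h.match))
            if scan_reverse_complement:
                for h in scan_motif(revcomp(seq), motif, gid):
                    rows.append((gid, h.offset, motif.name, "-", h.match))
    return pd.DataFrame(rows, columns=["gene_id", "offset", "motif",
                                       "strand", "match"])


def extract_promoter(gene: GeneModel, contig_seq: str,
                     length: int = PROMOTER_LENGTH) -> str | None:
    """Upstream ``length`` bases of the first exon, strand-aware.

    Plus strand: bases [start - length, start - 1]; minus strand: the
    reverse complement of [end + 1, end + length] (1-based, closed).
    Truncated with a warning at contig boundaries.  Genes without an
    annotated start codon are excluded (returns None).
    """
    if not gene.has_start_codon:
        return None
    L = len(contig_seq)
    if gene.strand == "+":
        hi = gene.first_exon_start - 1          # exclusive, 0-based
        lo = max(0, hi - length)
        if hi - lo < length:
            warnings.warn(f"{gene.gene_id}: promoter truncated to "
                          f"{hi - lo} bp at contig start", stacklevel=2)
        return contig_seq[lo:hi]
    if gene.strand == "-":
        lo = gene.first_exon_end                # 0-based inclusive
        hi = min(L, lo + length)
        if hi - lo < length:
            warnings.warn(f"{gene.gene_id}: promoter truncated to "
                          f"{hi - lo} bp at contig end", stacklevel=2)
        return revcomp(contig_seq[lo:hi])
    raise ValueError(f"bad strand {gene.strand!r}")


def extract_promoters(genes: list[GeneModel], contigs: dict[str, str],
                      length: int = PROMOTER_LENGTH) -> dict[str, str]:
    out = {}
    for g in genes:
        if g.contig not in contigs:
            raise KeyError(f"contig {g.contig!r} missing for {g.gene_id}")
        prom = extract_promoter(g, contigs[g.contig], length)
        if prom is not None:
            out[g.gene_id] = prom
    return out


# ---------------------------------------------------------------------------
# Expression-trend matching

GROUP_TAGS = ("DS/HD-induced", "HS/HD-induced", "other")


def ternary_states(log2fc: pd.Series,
                   threshold: float = TREND_LOG2FC) -> pd.Series:
    """up / flat / down per condition from log2 fold changes vs control."""
    def state(v):
        if not np.isfinite(v):
            return "flat"
        if v >= threshold:
            return "up"
        if v <= -threshold:
            return "down"
        return "flat"
    return log2fc.map(state)


def trend_signature(log2fc: pd.Series,
                    threshold: float = TREND_LOG2FC) -> tuple[pd.Series, str]:
    """Ternary per-condition states and the TF-group tag of a profile.

    ``log2fc`` is indexed by stress condition labels (families DS/HS/HD with
    time suffixes).  DS/HD-induced: up in at least one DS and one HD
    condition while flat or down in every HS condition; HS/HD-induced is the
    mirror image; anything else is "other".
    """
    states = ternary_states(log2fc, threshold)
    fam = {c: c.split("-")[0] for c in states.index}
    def up_in(f): return any(states[c] == "up" for c in states.index
                             if fam[c] == f)
    def none_up(f): return all(states[c] != "up" for c in states.index
                               if fam[c] == f)
    if up_in("DS") and up_in("HD") and none_up("HS"):
        return states, "DS/HD-induced"
    if up_in("HS") and up_in("HD") and none_up("DS"):
        return states, "HS/HD-induced"
    return states, "other"


def trend_correlation(profile_a: pd.Series, profile_b: pd.Series) -> float:
    """Pearson correlation of two expression profiles (alternative trend
    criterion, off by default)."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b.reindex(profile_a.index), dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def predict_targets(group_tag: str,
                    hits: pd.DataFrame,
                    signatures: pd.Series,
                    motif_names: tuple[str, ...]) -> set[str]:
    """Genes with a hit of the group's motif(s) and a matching group tag."""
    with_hit = set(hits.loc[hits["motif"].isin(motif_names), "gene_id"])
    matching = set(signatures.index[signatures == group_tag])
    return with_hit & matching


def target_report(hits: pd.DataFrame, signatures: pd.Series,
                  ) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Predicted target sets of the four TF groups and their overlaps.

    DREB groups use the DRE motif, HSF groups the two HSE orientations;
    group 1 is drought/combined-induced, group 2 heat/combined-induced.
    The report lists each set size and the pairwise intersection of the
    DREB and HSF sets within each group (the commonly-regulated analogue).
    """
    hse = tuple(m.name for m in HSF_MOTIFS)
    dre = tuple(m.name for m in DREB_MOTIFS)
    sets = {
        "DREBs-group1": predict_targets("DS/HD-induced", hits, signatures, dre),
        "HSFs-group1": predict_targets("DS/HD-induced", hits, signatures, hse),
        "DREBs-group2": predict_targets("HS/HD-induced", hits, signatures, dre),
        "HSFs-group2": predict_targets("HS/HD-induced", hits, signatures, hse),
    }
    rows = [{"set": k, "size": len(v)} for k, v in sets.items()]
    rows.append({"set": "group1_common",
                 "size": len(sets["DREBs-group1"] & sets["HSFs-group1"])})
    rows.append({"set": "group2_common",
                 "size": len(sets["DREBs-group2"] & sets["HSFs-group2"])})
    return sets, pd.DataFrame(rows).set_index("set")
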