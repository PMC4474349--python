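"""Per-homeolog differential expression and stress-response partitioning.

Each homeolog copy is tested per stress condition against the control with an
exact conditional count test (pooled treatment count vs pooled total, success
probability set by the library-size split), gated at linear fold change >= 2
and Benjamini-Hochberg FDR < 0.01 per contrast.  A triplet's response is
"partitioned" in a condition when any pairwise ratio of homeolog fold changes
is >= 2 (or <= 1/2); partitioned triplets are assigned one of 12 categories,
the product of response direction (up/down) and the dominant homeolog subset
({A}, {B}, {D}, {A,B}, {A,D}, {B,D}).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exact import exact_count_test, round_half_even
from .simulate import SUBGENOMES

PAIRS = tuple(combinations(SUBGENOMES, 2))

FC_THRESHOLD = 2.0
FDR_THRESHOLD = 0.01
PARTITION_RATIO = 2.0
PSEUDOCOUNT = 0.5

CATEGORIES = tuple(f"{d}-{''.join(s)}" for d in ("up", "down")
                   for s in (("A",), ("B",), ("D",),
                             ("A", "B"), ("A", "D"), ("B", "D")))


def normalize_counts(counts: pd.DataFrame,
                     lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million library reads; columns are samples."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes[counts.columns]
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts / lib_sizes * 1e6


def de_test(treat_counts, ctrl_counts, treat_libs=None, ctrl_libs=None,
            pseudocount: float = PSEUDOCOUNT,
            test: Callable[[int, int, float], float] | None = None,
            ) -> tuple[float, float]:
    """Exact conditional DE test of pooled treatment vs control counts.

    Returns ``(log2FC, p)``: the fold change is the library-size-corrected
    ratio of pooled sums with ``pseudocount`` added to each, and the p-value
    conditions on the pooled total with success probability equal to the
    treatment share of the summed library sizes.  ``test`` may substitute an
    overdispersion-aware test with the same (t, c, p0) signature.

    Both pooled counts zero -> ``(nan, nan)`` (the gene is skipped).
    """
    t = float(np.sum(treat_counts))
    c = float(np.sum(ctrl_counts))
    lt = float(np.sum(treat_libs)) if treat_libs is not None \
        else float(np.size(treat_counts))
    lc = float(np.sum(ctrl_libs)) if ctrl_libs is not None \
        else float(np.size(ctrl_counts))
    if lt <= 0 or lc <= 0:
        raise ValueError("library sizes must be positive")
    if t == 0 and c == 0:
        return float("nan"), float("nan")
    log2fc = float(np.log2(((t + pseudocount) / lt)
                           / ((c + pseudocount) / lc)))
    p0 = lt / (lt + lc)
    if test is None:
        ti, ci = round_half_even(t), round_half_even(c)
        p = exact_count_test(ti, ci, 0.5 if lt == lc else p0)
    else:
        p = test(round_half_even(t), round_half_even(c), p0)
    return log2fc, float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one contrast).

    ``nan`` entries (untestable genes) are passed through unadjusted and do
    not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def response_table(count_table: pd.DataFrame, design: dict[str, list[str]],
                   control: str, lib_sizes: pd.Series | None = None,
                   fc_threshold: float = FC_THRESHOLD,
                   fdr_threshold: float = FDR_THRESHOLD,
                   test: Callable | None = None) -> pd.DataFrame:
    """Per-homeolog DE results for every stress condition vs control.

    ``design`` maps condition label -> sample columns.  Returns a long frame
    indexed by (triplet_id, subgenome, condition) with log2FC, raw and
    BH-adjusted p (adjusted within each contrast across all homeolog genes),
    and the DE flag (|FC| >= ``fc_threshold`` and adjusted p <
    ``fdr_threshold``).
    """
    if lib_sizes is None:
        lib_sizes = count_table.sum(axis=0)
    ctrl_cols = design[control]
    frames = []
    for cond, cols in design.items():
        if cond == control:
            continue
        res = pd.DataFrame(index=count_table.index)
        stats = [de_test(row[cols], row[ctrl_cols],
                         lib_sizes[cols], lib_sizes[ctrl_cols], test=test)
                 for _, row in count_table.iterrows()]
        res["log2fc"] = [s[0] for s in stats]
        res["p"] = [s[1] for s in stats]
        res["padj"] = bh_adjust(res["p"].to_numpy())
        res["de"] = ((np.abs(res["log2fc"]) >= np.log2(fc_threshold))
                     & (res["padj"] < fdr_threshold))
        res["condition"] = cond
        frames.append(res)
    out = pd.concat(frames)
    out = out.set_index("condition", append=True)
    out.index.names = ["triplet_id", "subgenome", "condition"]
    return out


def response_partition(fold_changes,
                       partition_ratio: float = PARTITION_RATIO,
                       ) -> tuple[dict[str, float], bool]:
    """Pairwise fold-change ratios of one triplet in one condition.

    ``fold_changes`` is the linear-scale (pseudocounted) fold change of A, B
    and D.  Returns the three ratios (A/B, A/D, B/D) and the partitioned
    flag: any ratio >= ``partition_ratio`` or <= 1/``partition_ratio``.
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.shape != (3,):
        raise ValueError("expected fold changes for A, B, D")
    if np.any(fc <= 0) or not np.all(np.isfinite(fc)):
        raise ValueError("fold changes must be finite and positive "
                         "(pseudocounted)")
    ratios = {}
    flag = False
    for s1, s2 in PAIRS:
        r = fc[SUBGENOMES.index(s1)] / fc[SUBGENOMES.index(s2)]
        ratios[f"{s1}/{s2}"] = float(r)
        if r >= partition_ratio or r <= 1.0 / partition_ratio:
            flag = True
    return ratios, flag


def partition_table(responses: pd.DataFrame,
                    partition_ratio: float = PARTITION_RATIO) -> pd.DataFrame:
    """Partitioned flag and ratios per triplet x condition.

    Input is the frame from :func:`response_table`.  A triplet is partitioned
    under stress when flagged in at least one condition.
    """
    rows = []
    wide = responses["log2fc"].unstack("subgenome")
    for (triplet_id, cond), row in wide.groupby(level=[0, 1]):
        l2 = row.iloc[0][list(SUBGENOMES)].to_numpy(dtype=float)
        if np.any(~np.isfinite(l2)):
            rows.append({"triplet_id": triplet_id, "condition": cond,
                         "partitioned": False, "max_ratio": np.nan})
            continue
        ratios, flag = response_partition(2.0 ** l2, partition_ratio)
        rmax = max(max(r, 1.0 / r) for r in ratios.values())
        rows.append({"triplet_id": triplet_id, "condition": cond,
                     "partitioned": flag, "max_ratio": rmax,
                     **{f"ratio_{k}": v for k, v in ratios.items()}})
    return pd.DataFrame(rows).set_index(["triplet_id", "condition"])


def categorize_triplet(log2fc: pd.DataFrame, partitions: pd.DataFrame,
                       condition_order: list[str]) -> str:
    """Assign one of the 12 partition categories, or NONE.

    ``log2fc`` is (subgenome x condition) for one triplet, ``partitions`` its
    rows of the partition table.  The category is read off the flagged
    condition with the largest max pairwise ratio (ties: condition order):
    direction is the sign of the dominant deviation, the dominant subset is
    the copies whose \\|log2FC\\| exceeds the rest by >= 1 (one copy if its
    margin over the runner-up is >= 1, else the top pair if its margin over
    the last is >= 1, else the single copy with the largest deviation).
    """
    flagged = partitions[partitions["partitioned"]]
    if len(flagged) == 0:
        return "NONE"
    best_cond, best_ratio = None, -np.inf
    for cond in condition_order:
        if cond in flagged.index and flagged.loc[cond, "max_ratio"] > best_ratio:
            best_cond, best_ratio = cond, flagged.loc[cond, "max_ratio"]
    l2 = np.array([float(log2fc.loc[s, best_cond]) for s in SUBGENOMES])
    absfc = np.abs(l2)
    order = sorted(range(3), key=lambda i: (-absfc[i], SUBGENOMES[i]))
    if absfc[order[0]] - absfc[order[1]] >= 1.0:
        subset = [order[0]]
    elif absfc[order[1]] - absfc[order[2]] >= 1.0:
        subset = sorted(order[:2])
    else:
        subset = [order[0]]
    direction = "up" if l2[order[0]] >= 0 else "down"
    return f"{direction}-{''.join(SUBGENOMES[i] for i in sorted(subset))}"


def categorize_table(responses: pd.DataFrame, partitions: pd.DataFrame,
                     condition_order: list[str]) -> pd.Series:
    wide = responses["log2fc"].unstack("condition")
    cats = {}
    for triplet_id in partitions.index.get_level_values(0).unique():
        cats[triplet_id] = categorize_triplet(
            wide.loc[triplet_id], partitions.loc[triplet_id],
            condition_order)
    return pd.Series(cats, name="category").rename_axis("triplet_id")


def summarize_partitioning(balance_labels: pd.Series,
                           partitioned: pd.Series) -> pd.DataFrame:
    """Partitioned-response proportions stratified by balance label.

    ``balance_labels`` holds ECT/UCT per triplet, ``partitioned`` the
    any-condition partition flag.  Percentages to one decimal, as in the
    headline ECT/UCT partitioning proportions.
    """
    if len(balance_labels) == 0:
        return pd.DataFrame(columns=["count", "total", "percent"])
    df = pd.DataFrame({"label": balance_labels, "partitioned": partitioned})
    df = df[df["label"].isin(["ECT", "UCT"])]
    rows = []
    for stratum, sub in [("ECT", df[df["label"] == "ECT"]),
                         ("UCT", df[df["label"] == "UCT"]),
                         ("overall", df)]:
        n, k = len(sub), int(sub["partitioned"].sum())
        rows.append({"stratum": stratum, "count": k, "total": n,
                     "percent": round(100.0 * k / n, 1) if n else 0.0})
    return pd.DataFrame(rows).set_index("stratum")
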