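"""Equal- vs unequal-contribution classification of triplets in the control.

A triplet is an unequal-contribution triplet (UCT) when, in every control
replicate, at least one of the three pairwise homeolog comparisons (A vs B,
A vs D, B vs D) rejects equal expression at p < 0.01 by an exact test, and
the ratio of the maximum to the minimum homeolog expression (normalized mean
over replicates) is at least 1.5.  Otherwise it is an equal-contribution
triplet (ECT); triplets with no control reads are untested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .exact import exact_count_test, fisher_observed_vs_expected
from .simulate import SUBGENOMES

PAIRS = tuple(combinations(SUBGENOMES, 2))

P_THRESHOLD = 0.01
RATIO_THRESHOLD = 1.5


def pairwise_bias_test(count_x, count_y, method: str = "binomial") -> float:
    """Two-sided exact test of two homeolog counts against a 1:1 null.

    The default reduces the two-count comparison to the exact binomial test
    of ``x`` against ``x + y`` at success probability 1/2 (the doubled-tail /
    minimum-likelihood p-value, identical by symmetry).  ``method=
    "fisher2x2"`` instead builds the 2x2 table against a fabricated
    equal-split expected row.  Fractional counts are rounded half-to-even.
    Returns ``nan`` when both counts are zero.
    """
    if method == "binomial":
        return exact_count_test(count_x, count_y)
    if method == "fisher2x2":
        return fisher_observed_vs_expected(count_x, count_y)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class BalanceCall:
    triplet_id: str
    label: str                       # ECT / UCT / UNTESTED
    significant: bool                # p < 0.01 for some pair in every replicate
    ratio: float                     # Exp_max / Exp_min on normalized means
    pvalues: pd.DataFrame = field(repr=False, default=None)  # replicate x pair


def classify_balance(control_counts, triplet_id: str = "",
                     lib_sizes=None,
                     p_threshold: float = P_THRESHOLD,
                     ratio_threshold: float = RATIO_THRESHOLD,
                     method: str = "binomial") -> BalanceCall:
    """Classify one triplet from its control counts.

    ``control_counts`` is (n_replicates, 3) with columns A, B, D; at least
    two replicates are required.  The significance gate is evaluated per
    replicate on raw counts; the ratio gate on the mean of library-size
    normalized replicates.
    """
    counts = np.asarray(control_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("control_counts must be (replicates, 3)")
    if counts.shape[0] < 2:
        raise ValueError("two control replicates are required")
    if lib_sizes is None:
        lib_sizes = np.ones(counts.shape[0])
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")

    pmat = np.full((counts.shape[0], len(PAIRS)), np.nan)
    for r in range(counts.shape[0]):
        for k, (s1, s2) in enumerate(PAIRS):
            i, j = SUBGENOMES.index(s1), SUBGENOMES.index(s2)
            pmat[r, k] = pairwise_bias_test(counts[r, i], counts[r, j],
                                            method=method)
    pvals = pd.DataFrame(pmat, columns=[f"{a}_vs_{b}" for a, b in PAIRS])

    if counts.sum() == 0:
        return BalanceCall(triplet_id, "UNTESTED", False, np.nan, pvals)

    significant = bool(np.all(np.nansum(pmat < p_threshold, axis=1) > 0))
    norm_mean = (counts / lib_sizes[:, None]).mean(axis=0)
    if norm_mean.min() > 0:
        ratio = float(norm_mean.max() / norm_mean.min())
    else:
        ratio = np.inf if norm_mean.max() > 0 else np.nan
    label = "UCT" if (significant and ratio >= ratio_threshold) else "ECT"
    return BalanceCall(triplet_id, label, significant, ratio, pvals)


def classify_balance_table(count_table: pd.DataFrame,
                           control_samples: list[str],
                           lib_sizes: pd.Series | None = None,
                           **kwargs) -> pd.DataFrame:
    """Balance calls for every triplet in an allocated count table.

    ``count_table`` is indexed by (triplet_id, subgenome).  Library sizes
    default to the per-sample column sums of the table.
    """
    if lib_sizes is None:
        lib_sizes = count_table[control_samples].sum(axis=0)
    rows = []
    for triplet_id, sub in count_table.groupby(level="triplet_id", sort=True):
        mat = sub.droplevel("triplet_id").loc[list(SUBGENOMES),
                                              control_samples]
        call = classify_balance(mat.to_numpy().T, triplet_id,
                                lib_sizes=lib_sizes[control_samples],
                                **kwargs)
        rows.append({"triplet_id": triplet_id, "label": call.label,
                     "significant": call.significant, "ratio": call.ratio,
                     "min_p": np.nanmin(call.pvalues.to_numpy())
                     if call.pvalues.size else np.nan})
    return pd.DataFrame(rows).set_index("triplet_id")


def summarize_balance(calls: pd.DataFrame) -> pd.DataFrame:
    """Proportions of significance-only and significance+ratio triplets.

    Percentages are over tested triplets, printed to one decimal.  Expects
    the frame returned by :func:`classify_balance_table` (columns ``label``
    and ``significant``).
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["count", "total", "percent"])
    tested = calls[calls["label"] != "UNTESTED"]
    n = len(tested)
    n_sig = int(tested["significant"].sum())
    n_uct = int((tested["label"] == "UCT").sum())
    def pct(k): return round(100.0 * k / n, 1) if n else 0.0
    return pd.DataFrame(
        [{"stratum": "significant_both_replicates", "count": n_sig,
          "total": n, "percent": pct(n_sig)},
         {"stratum": "UCT", "count": n_uct, "total": n,
          "percent": pct(n_uct)},
         {"stratum": "ECT", "count": n - n_uct, "total": n,
          "percent": pct(n - n_uct)}]).set_index("stratum")
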