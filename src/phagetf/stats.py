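"""Lifestyle enrichment and GC/genome-size group comparisons.

The two-sample location test is the Wilcoxon rank-sum, implemented from
first principles: an exact mode that enumerates every assignment of
pooled ranks (practical for n_x + n_y <= 12, and the reference for the
permutation null), and a normal approximation on mid-ranks with
tie-corrected variance and continuity correction, matching the defaults
of R's ``wilcox.test``.  P-values map onto the figure-legend ladder
ns / * / ** / *** / ****.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

SIGNIFICANCE_LADDER = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float  # rank sum of group a (mid-ranks)
    p_value: float
    significance_code: str


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the mid-rank sum of ``x`` in the pooled sample.  ``exact`` mode
    enumerates all C(n_x+n_y, n_x) equally likely rank assignments and is
    valid with ties; ``normal`` uses the tie-corrected normal
    approximation with continuity correction.  ``auto`` picks exact for
    n_x + n_y <= 12.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # all values identical across both groups
        ranks = rankdata(pooled)
        return float(ranks[: len(x)].sum()), 1.0
    if mode == "auto":
        mode = "exact" if len(pooled) <= 12 else "normal"
    ranks = rankdata(pooled)  # mid-ranks
    w_obs = float(ranks[: len(x)].sum())
    n_x, n_y = len(x), len(y)
    if mode == "exact":
        sums = np.array(
            [sum(c) for c in itertools.combinations(ranks, n_x)]
        )
        eps = 1e-9
        lo = np.mean(sums <= w_obs + eps)
        hi = np.mean(sums >= w_obs - eps)
        p = min(1.0, 2.0 * min(lo, hi))
        return w_obs, float(p)
    n = n_x + n_y
    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return w_obs, 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return w_obs, p


def significance_code(p: float) -> str:
    """Map a p-value to the ns/*/**/***/**** ladder."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    for cutoff, code in SIGNIFICANCE_LADDER:
        if p < cutoff:
            return code
    return "ns"


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def lifestyle_enrichment(
    carrier_ids: set, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Group-size-normalized carrier proportions per lifestyle.

    Genomes with unknown lifestyle are excluded entirely (numerator and
    denominator).  The output has one row per lifestyle
    (n_total, n_carrying, proportion) plus a "ratio" row giving the
    temperate:virulent proportion ratio (NaN when undefined).
    """
    known = metadata[metadata["lifestyle"].isin(["temperate", "virulent"])]
    rows = []
    props = {}
    for ls in ("temperate", "virulent"):
        sub = known[known["lifestyle"] == ls]
        n = len(sub)
        carrying = int(sub["genome_id"].isin(carrier_ids).sum())
        prop = carrying / n if n else float("nan")
        props[ls] = prop
        rows.append(
            {"lifestyle": ls, "n_total": n, "n_carrying": carrying,
             "proportion": prop}
        )
    ratio = (
        props["temperate"] / props["virulent"]
        if props.get("virulent") not in (0, None) and props["virulent"] == props["virulent"]
        else float("nan")
    )
    rows.append({"lifestyle": "ratio_temperate_virulent", "n_total": None,
                 "n_carrying": None, "proportion": ratio})
    return pd.DataFrame(rows)


def _compare(name_a, name_b, a, b, mode) -> GroupComparison | None:
    if len(a) < 2 or len(b) < 2:
        return None
    w, p = wilcoxon_rank_sum(a, b, mode=mode)
    return GroupComparison(
        group_a=name_a, group_b=name_b, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        statistic=w, p_value=p, significance_code=significance_code(p),
    )


def compare_gc_size(
    genomes: list, carrier_ids: set, mode: str = "normal",
) -> pd.DataFrame:
    """Carrier vs non-carrier Wilcoxon comparisons of GC and genome size,
    within temperate and within virulent phages (four comparisons).

    Degenerate cells (fewer than 2 genomes on either side) are skipped.
    """
    rows = []
    for lifestyle in ("temperate", "virulent"):
        pool = [g for g in genomes if g.lifestyle == lifestyle]
        car = [g for g in pool if g.genome_id in carrier_ids]
        non = [g for g in pool if g.genome_id not in carrier_ids]
        for measure, attr in (("gc", "gc_fraction"), ("size", "length_bp")):
            cmp = _compare(
                f"{lifestyle}_carrier", f"{lifestyle}_noncarrier",
                [getattr(g, attr) for g in car],
                [getattr(g, attr) for g in non],
                mode,
            )
            if cmp is None:
                continue
            rows.append(
                {
                    "measure": measure,
                    "group_a": cmp.group_a, "group_b": cmp.group_b,
                    "n_a": cmp.n_a, "n_b": cmp.n_b,
                    "median_a": cmp.median_a, "median_b": cmp.median_b,
                    "W": cmp.statistic, "p": cmp.p_value,
                    "code": cmp.significance_code,
                }
            )
    columns = ["measure", "group_a", "group_b", "n_a", "n_b",
               "median_a", "median_b", "W", "p", "code"]
    return pd.DataFrame(rows, columns=columns)
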