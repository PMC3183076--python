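"""Summary statistics over called or fixture events.

Covers the descriptive layer of the analysis: class fraction tables with
explicit denominators, two-sided Wilcoxon rank-sum comparisons of tract
lengths (exact enumeration at small n), the per-chromosome event-count
versus chromosome-size regression, and grouped medians of strand-transfer
lengths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "class_fraction_table",
    "wilcoxon_rank_sum",
    "chromosome_size_regression",
    "median_transfer_lengths",
    "RegressionResult",
]


def class_fraction_table(records) -> pd.DataFrame:
    """Occurrence-weighted class counts with both denominators.

    ``records`` is an iterable of (class label, occurrence) pairs — from
    classified events (occurrence 1 each) or fixture rows.  The label
    ``no_transfer``/``none`` marks events without detected strand transfer;
    fractions are reported against all events and against transfer-bearing
    events.  Display percentages are rounded half-up; raw fractions retained.
    """
    counts: dict[str, int] = {}
    for label, occurrence in records:
        counts[label] = counts.get(label, 0) + int(occurrence)
    if not counts:
        return pd.DataFrame(
            columns=["class", "count", "n_all", "n_transfer",
                     "fraction_all", "fraction_transfer", "percent_all",
                     "percent_transfer"]
        )
    n_all = sum(counts.values())
    no_transfer = {"no_transfer", "none"}
    n_transfer = sum(v for k, v in counts.items() if k not in no_transfer)
    rows = []
    for label in sorted(counts, key=lambda k: -counts[k]):
        count = counts[label]
        frac_all = count / n_all
        frac_tr = count / n_transfer if label not in no_transfer and n_transfer else np.nan
        rows.append(
            {
                "class": label,
                "count": count,
                "n_all": n_all,
                "n_transfer": n_transfer,
                "fraction_all": frac_all,
                "fraction_transfer": frac_tr,
                "percent_all": int(np.floor(frac_all * 100 + 0.5)),
                "percent_transfer": (
                    int(np.floor(frac_tr * 100 + 0.5)) if np.isfinite(frac_tr) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def _rank_sum_statistic(pooled_ranks: np.ndarray, idx: tuple) -> float:
    return float(pooled_ranks[list(idx)].sum())


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the rank-sum null distribution (mid-ranks, so ties
    are handled) when the smaller sample has at most 8 observations;
    otherwise the normal approximation with tie correction.  Returns the
    rank-sum statistic of the first sample and the two-sided p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test undefined for an empty sample")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    if min(a.size, b.size) <= 8:
        n = pooled.size
        null = np.array(
            [ranks[list(idx)].sum() for idx in itertools.combinations(range(n), a.size)]
        )
        mean = null.mean()
        p = float(np.mean(np.abs(null - mean) >= abs(w - mean) - 1e-12))
        return w, min(p, 1.0)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float


def chromosome_size_regression(counts, sizes) -> RegressionResult:
    """Least-squares fit of per-chromosome event counts on chromosome size.

    R^2 is the squared Pearson product-moment correlation and the p-value
    tests the hypothesis that it is zero (correlation t-test).
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if counts.size != sizes.size or counts.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(sizes, sizes[0]):
        raise ValueError("degenerate fit: zero variance in chromosome sizes")
    if np.allclose(counts, counts[0]):
        # constant counts: flat fit, no correlation with size
        return RegressionResult(slope=0.0, intercept=float(counts[0]),
                                r_squared=0.0, pvalue=1.0)
    fit = sps.linregress(sizes, counts)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pvalue=float(fit.pvalue),
    )


def median_transfer_lengths(
    events: pd.DataFrame,
    grouping: list[str],
    bin_edges=None,
) -> pd.DataFrame:
    """Medians (and optional binned distributions) of per-event strand-transfer
    lengths.

    ``events`` needs a ``length_bp`` column plus the grouping columns (e.g.
    kind, mode, class).  Transfer-less events (length 0 or NaN) are excluded;
    groups with no events are absent from the output rather than zero.
    """
    df = events.copy()
    df = df[np.isfinite(df["length_bp"]) & (df["length_bp"] > 0)]
    if df.empty:
        return pd.DataFrame(columns=grouping + ["n", "median_bp"])
    out = (
        df.groupby(grouping, dropna=False)["length_bp"]
        .agg(n="count", median_bp="median")
        .reset_index()
    )
    if bin_edges is not None:
        hists = []
        for _, grp in df.groupby(grouping, dropna=False):
            h, _ = np.histogram(grp["length_bp"], bins=bin_edges)
            hists.append(h)
        out["histogram"] = hists
    return out
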