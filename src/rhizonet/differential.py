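"""Fold-change rank-order (FCROS) differential relative abundance.

Pipeline between two sample classes: drop OTUs present in fewer than
3 samples (rare-OTU bias control), variance-stabilize with
log2(x + 1), quantile-normalize columns to damp replicate noise while
preserving between-class structure, then compute the fold-change
rank-order statistic.  For every cross-class sample pair the per-OTU
log fold change is ranked across OTUs; the normalized ranks averaged
over all pairs give r-bar per OTU, and the f-value
Phi((r-bar - mean) / sd) is the probability of over-abundance.  OTUs
with f >= 0.9 (over) or f <= 0.1 (under) at p <= 0.05 are flagged.

Rank statistics are robust to the heavy-tailed, compositional noise
of amplicon counts where per-pair fold changes are unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from rhizonet.data_model import OtuTable


@dataclass(frozen=True)
class DifferentialResult:
    otu_id: str
    f_value: float
    p_value: float
    robust_fold_change: float
    flagged: str  # over | under | none


def variance_stabilize(table: OtuTable, min_samples: int = 3) -> pd.DataFrame:
    """Drop OTUs with < ``min_samples`` positive samples; log2(x + 1).

    The +1 pseudocount keeps zeros at zero and the transform monotone.
    """
    if table.scale != "counts":
        raise ValueError("variance stabilization expects a counts-scale table")
    keep = (table.values > 0).sum(axis=1) >= min_samples
    sub = table.data.loc[keep]
    return np.log2(sub + 1.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-order-statistics distribution.

    Column values are replaced by the reference value at their rank;
    ties receive the mean of the reference values they span.  After
    normalization all columns share identical sorted values.
    """
    if matrix.shape[1] < 2:
        warnings.warn("single column: quantile normalization is the identity", stacklevel=2)
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")  # 1-based, ties averaged
        # average rank k maps to mean of reference[ceil(k)-1], reference[floor(k)-1]
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def fcros_statistic(matrix: pd.DataFrame, class_a, class_b) -> list[DifferentialResult]:
    """Fold-change rank-order statistic on a normalized log-scale matrix.

    ``class_a`` / ``class_b`` are column labels; fold changes are
    (b - a) differences on the log scale, so f near 1 means
    over-abundant in class_b relative to class_a.
    p = 2 * min(f, 1 - f) is the two-sided tail.
    """
    a_cols = list(class_a)
    b_cols = list(class_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("both classes need at least 2 samples")
    m = matrix.shape[0]
    if m < 5:
        raise ValueError("rank statistic degenerate below 5 OTUs")
    av = matrix[a_cols].to_numpy(dtype=float)
    bv = matrix[b_cols].to_numpy(dtype=float)
    rank_sum = np.zeros(m)
    lfc_sum = np.zeros(m)
    n_pairs = 0
    for i in range(len(a_cols)):
        for j in range(len(b_cols)):
            fc = bv[:, j] - av[:, i]
            rank_sum += rankdata(fc, method="average") / (m + 1)
            lfc_sum += fc
            n_pairs += 1
    rbar = rank_sum / n_pairs
    mean_lfc = lfc_sum / n_pairs
    mu, sd = rbar.mean(), rbar.std(ddof=1)
    if sd == 0:
        f = np.full(m, 0.5)
    else:
        f = norm.cdf((rbar - mu) / sd)
    p = 2.0 * np.minimum(f, 1.0 - f)
    return [
        DifferentialResult(otu, float(f[i]), float(p[i]), float(mean_lfc[i]), "none")
        for i, otu in enumerate(matrix.index)
    ]


def select_differential(results: list[DifferentialResult], alpha: float = 0.05,
                        f_threshold: float = 0.9) -> list[DifferentialResult]:
    """Flag over-/under-abundant OTUs.

    over: f >= f_threshold and p <= alpha;
    under: f <= 1 - f_threshold and p <= alpha (mirrored cutoff).
    """
    out = []
    for r in results:
        if r.p_value <= alpha and r.f_value >= f_threshold:
            flag = "over"
        elif r.p_value <= alpha and r.f_value <= 1.0 - f_threshold:
            flag = "under"
        else:
            flag = "none"
        out.append(DifferentialResult(r.otu_id, r.f_value, r.p_value,
                                      r.robust_fold_change, flag))
    return out


def differential_pipeline(table: OtuTable, class_a, class_b,
                          min_samples: int = 3, alpha: float = 0.05,
                          f_threshold: float = 0.9) -> pd.DataFrame:
    """Full stabilize -> quantile-normalize -> FCROS -> select pipeline.

    Restricted to the columns of the two classes; returns a tidy
    result table.
    """
    cols = list(class_a) + list(class_b)
    sub = table.select_samples(cols)
    stab = variance_stabilize(sub, min_samples=min_samples)
    normed = quantile_normalize(stab)
    results = fcros_statistic(normed, class_a, class_b)
    flagged = select_differential(results, alpha=alpha, f_threshold=f_threshold)
    return pd.DataFrame(
        [(r.otu_id, r.f_value, r.p_value, r.robust_fold_change, r.flagged) for r in flagged],
        columns=["otu_id", "f_value", "p_value", "robust_lfc", "flagged"],
    )
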