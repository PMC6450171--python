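"""Dissimilarity, ordination, PERMANOVA/PERMDISP, indicator species,
and OTU-detection chi-square tests.

PERMANOVA partitions the total sum of squared dissimilarities into
between- and within-group parts and tests the pseudo-F by permuting
sample labels; PERMDISP tests homogeneity of multivariate dispersion
(per-sample distance to the group centroid in PCoA space) the same
way.  Indicator analysis scores each OTU for each group (or union of
groups) with IndVal = sqrt(A * B): A is specificity (share of the
OTU's mean abundance concentrated in the target) and B fidelity
(fraction of target samples where the OTU occurs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chisquare, chi2_contingency

from rhizonet.data_model import OtuTable
from rhizonet.enrichment import bh_fdr


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R_squared: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class IndicatorResult:
    otu_id: str
    best_combination: tuple[str, ...]
    stat: float
    A: float
    B: float
    p_value: float
    adjusted_p: float


def bray_curtis_matrix(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    BC(p, q) = sum|p_i - q_i| / sum(p_i + q_i); pairs of all-zero
    samples get distance 0 with a warning.
    """
    vals = table.values.T
    zero = vals.sum(axis=1) == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample(s); distances to them set by convention",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(vals, metric="braycurtis"))
    d = np.where(np.isnan(d), 0.0, d)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def pcoa(distance: pd.DataFrame, k: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates) of a distance matrix.

    Gower double-centering of -d^2/2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue), axes with
    non-positive eigenvalues dropped (all eigenvalues are returned).
    Axis signs are fixed by making each axis's largest-magnitude
    loading positive.
    """
    d = distance.to_numpy(dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    if k is not None and k > int(pos.sum()):
        warnings.warn(f"only {int(pos.sum())} positive eigenvalues; truncating k={k}", stacklevel=2)
    n_axes = int(pos.sum()) if k is None else min(k, int(pos.sum()))
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    for ax in range(n_axes):
        i = int(np.abs(coords[:, ax]).argmax())
        if coords[i, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    cols = [f"PC{i+1}" for i in range(n_axes)]
    return pd.DataFrame(coords, index=distance.index, columns=cols), eigvals


def _group_indices(sample_ids, groups) -> dict[str, list[int]]:
    gi: dict[str, list[int]] = {}
    for i, s in enumerate(sample_ids):
        gi.setdefault(groups[s] if isinstance(groups, dict) else groups[i], []).append(i)
    return gi


def _permanova_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    k = len(uniq)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(distance: pd.DataFrame, groups, n_permutations: int = 9999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` maps sample_id -> group (dict or aligned sequence).
    p = (#{permuted F >= observed} + 1) / (n_permutations + 1).
    """
    ids = list(distance.index)
    gi = _group_indices(ids, groups)
    if len(gi) < 2:
        raise ValueError("need at least 2 groups")
    for g, idx in gi.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    label_of = np.empty(len(ids), dtype=int)
    for gnum, (g, idx) in enumerate(sorted(gi.items())):
        label_of[idx] = gnum
    uniq = np.arange(len(gi))
    d2 = distance.to_numpy(dtype=float) ** 2
    f_obs, r2 = _permanova_f(d2, label_of, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(label_of)
        f_p, _ = _permanova_f(d2, perm, uniq)
        if f_p >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, seed)


def permdisp(distance: pd.DataFrame, groups, n_permutations: int = 9999,
             seed: int = 0) -> tuple[float, float]:
    """Permutation test of multivariate dispersion homogeneity.

    Samples are embedded by PCoA (keeping negative-eigenvalue axes:
    their squared contributions are subtracted, the standard
    imaginary-part handling); each sample's distance to its group
    centroid feeds a one-way ANOVA F, whose null distribution comes
    from permuting group labels.
    """
    ids = list(distance.index)
    gi = _group_indices(ids, groups)
    if len(gi) < 2:
        raise ValueError("need at least 2 groups")
    for g, idx in gi.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    d = distance.to_numpy(dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    pos = eigvals > 1e-10
    neg = eigvals < -1e-10
    pos_coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    neg_coords = eigvecs[:, neg] * np.sqrt(-eigvals[neg])

    groups_list = sorted(gi.items())

    def centroid_distances(assign: dict[str, list[int]]) -> np.ndarray:
        z = np.empty(n)
        for g, idx in assign.items():
            cp = pos_coords[idx].mean(axis=0)
            cn = neg_coords[idx].mean(axis=0)
            d2 = ((pos_coords[idx] - cp) ** 2).sum(axis=1) - ((neg_coords[idx] - cn) ** 2).sum(axis=1)
            z[idx] = np.sqrt(np.maximum(d2, 0.0))
        return z

    def anova_f(z: np.ndarray, assign) -> float:
        grand = z.mean()
        ssb = sum(len(idx) * (z[idx].mean() - grand) ** 2 for _, idx in assign)
        ssw = sum(((z[idx] - z[idx].mean()) ** 2).sum() for _, idx in assign)
        k = len(assign)
        if ssw == 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (k - 1)) / (ssw / (n - k))

    z_obs = centroid_distances(dict(groups_list))
    f_obs = anova_f(z_obs, groups_list)
    rng = np.random.default_rng(seed)
    hits = 0
    labels = np.empty(n, dtype=int)
    for gnum, (_, idx) in enumerate(groups_list):
        labels[idx] = gnum
    names = [g for g, _ in groups_list]
    for _ in range(n_permutations):
        # permute sample labels and recompute centroids/distances: the
        # fitted-centroid constraint biases F when only the observed
        # distances are shuffled
        perm = rng.permutation(labels)
        assign = [(names[gnum], np.where(perm == gnum)[0])
                  for gnum in range(len(names))]
        z_p = centroid_distances(dict(assign))
        if anova_f(z_p, assign) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return float(f_obs), float(p)


def indicator_analysis(table: OtuTable, groups, allow_combinations: bool = False,
                       n_permutations: int = 999, alpha: float = 0.05,
                       seed: int = 0) -> list[IndicatorResult]:
    """IndVal-style taxon-group association with permutation p-values.

    For every OTU and candidate target (each group; optionally every
    non-trivial union of groups), A = target mean abundance / sum of
    per-group mean abundances over the target, B = occurrence fraction
    in target samples, stat = sqrt(A * B); the best target is kept and
    tested by permuting sample labels.  BH FDR across OTUs.
    """
    ids = table.sample_ids
    gi = _group_indices(ids, groups)
    if len(gi) < 2:
        raise ValueError("need at least 2 groups")
    group_names = sorted(gi)
    k = len(group_names)
    targets: list[tuple[str, ...]] = [(g,) for g in group_names]
    if allow_combinations:
        for r in range(2, k):
            targets.extend(combinations(group_names, r))
    vals = table.values
    n = len(ids)
    keep = vals.sum(axis=1) > 0
    v = vals[keep]
    otus = [o for o, k_ in zip(table.otu_ids, keep) for _ in [0] if k_]
    m = v.shape[0]

    # membership matrix per target (n_targets x n_samples); group means
    # come from the singleton rows, specificity A from their ratios
    singleton = np.zeros((k, n))
    for gnum, g in enumerate(group_names):
        singleton[gnum, gi[g]] = 1.0
    target_of = np.zeros((len(targets), k))
    for ti, t in enumerate(targets):
        for g in t:
            target_of[ti, group_names.index(g)] = 1.0
    counts = singleton.sum(axis=1)

    def all_stats(order: np.ndarray) -> np.ndarray:
        """stat matrix (m x n_targets) for a sample ordering."""
        vv = v[:, order]
        gmeans = (vv @ singleton.T) / counts            # m x k
        tsum = gmeans @ target_of.T                     # m x n_targets
        total = gmeans.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(total > 0, tsum / total, 0.0)
        present = (vv > 0) @ singleton.T                # m x k presence counts
        b = (present @ target_of.T) / (counts @ target_of.T)
        return np.sqrt(a * b), a, b

    identity = np.arange(n)
    s_obs, a_obs, b_obs = all_stats(identity)
    best_idx = s_obs.argmax(axis=1)
    best_stat = s_obs[np.arange(m), best_idx]

    rng = np.random.default_rng(seed)
    hits = np.zeros(m)
    for _ in range(n_permutations):
        s_p, _, _ = all_stats(rng.permutation(n))
        hits += s_p.max(axis=1) >= best_stat - 1e-12
    p = (hits + 1) / (n_permutations + 1)
    adj, _ = bh_fdr(p, level=alpha)
    return [
        IndicatorResult(otus[i], targets[best_idx[i]], float(best_stat[i]),
                        float(a_obs[i, best_idx[i]]), float(b_obs[i, best_idx[i]]),
                        float(p[i]), float(adj[i]))
        for i in range(m)
    ]


def chi_square_detection(detected: pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-square on a table of OTU-detection counts per group.

    A 1xk (or kx1) table is tested as goodness-of-fit against
    uniform.  A warning recommends an exact test when any expected
    cell drops below 1.
    """
    obs = np.asarray(detected, dtype=float)
    if obs.ndim == 1 or 1 in obs.shape:
        flat = obs.ravel()
        stat, p = chisquare(flat)
        return float(stat), float(p)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected < 1).any():
        warnings.warn("expected cell below 1; consider an exact test", stacklevel=2)
    stat, p, _, _ = chi2_contingency(obs, correction=False)
    return float(stat), float(p)
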