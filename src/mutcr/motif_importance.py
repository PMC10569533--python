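"""Motif-level interpretation of the context weights.

Per region, the important motifs are selected in two stages: the top 10% of
features by contribution |beta_j * x_j|, then — among those — the top 10% by
|beta_j|.  Each region is then represented by a sparse profile holding beta
at the selected motifs and 0 elsewhere.  Profiles are clustered with K-means
(k from the elbow curve unless forced), small clusters are dropped, and the
cluster mean-weight vectors are merged into a small number of groups by
agglomerative clustering with Manhattan distance and average linkage.
Group-level summaries (mean weights, mutation-density z-scores,
chromatin-state fold changes, mutation-rate profiles around motif sites)
mirror the figures such an analysis is normally read from.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans


# ---------------------------------------------------------------------------
# per-region selection
# ---------------------------------------------------------------------------

def select_important(beta: np.ndarray, x: np.ndarray):
    """Two-stage top-10% selection for one region.

    Stage 1 keeps the ``ceil(0.1*p)`` features with the largest
    ``|beta_j * x_j|`` (contribution); stage 2 keeps the ``ceil(0.1*k1)``
    of those with the largest ``|beta_j|``.  Ties break toward the smaller
    motif index.  Returns ``(profile, selected_idx)`` where ``profile`` has
    beta at the selected indices and 0 elsewhere.
    """
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    p = beta.size
    if p == 0:
        raise ValueError("empty feature vector")
    k1 = ceil(0.1 * p)
    stage1 = np.argsort(-np.abs(beta * x), kind="stable")[:k1]
    stage1 = np.sort(stage1)  # index order so the stable stage-2 sort ties by index
    k2 = ceil(0.1 * k1)
    stage2 = stage1[np.argsort(-np.abs(beta[stage1]), kind="stable")[:k2]]
    profile = np.zeros(p)
    profile[stage2] = beta[stage2]
    return profile, np.sort(stage2)


def importance_profiles(beta_matrix: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise :func:`select_important` over a region x motif matrix."""
    out = np.zeros_like(beta_matrix, dtype=float)
    for i in range(beta_matrix.shape[0]):
        out[i], _ = select_important(beta_matrix[i], X[i])
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray          # cluster id per region, -1 for dropped
    k: int
    inertia_curve: pd.Series    # inertia indexed by k (empty if k forced)


def _elbow_k(ks: np.ndarray, inertias: np.ndarray) -> int:
    """Elbow point: the k whose (k, inertia) point is farthest from the chord
    joining the curve's endpoints (both axes normalised to [0, 1])."""
    x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    y = (inertias - inertias[-1]) / max(inertias[0] - inertias[-1], 1e-12)
    # distance from (x, y) to the line through (0, 1) and (1, 0)
    d = np.abs(x + y - 1.0) / np.sqrt(2.0)
    return int(ks[np.argmax(d)])


def cluster_regions(profiles: np.ndarray, k: int | None = None,
                    k_range: tuple[int, int] = (2, 20), min_size: int = 10,
                    seed: int = 0, n_init: int = 10) -> ClusterResult:
    """K-means over importance profiles with elbow-selected k.

    Clusters with fewer than ``min_size`` regions are dropped (label -1).
    """
    profiles = np.asarray(profiles, dtype=float)
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least 2 profiles")
    curve = pd.Series(dtype=float)
    if k is None:
        # anchor the chord at k=1 (total within-SS) so an elbow at the lower
        # end of the scanned range is still detectable
        ks = np.arange(1, min(k_range[1], n - 1) + 1)
        inertias = np.array([
            float(((profiles - profiles.mean(0)) ** 2).sum()) if kk == 1 else
            KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(profiles).inertia_
            for kk in ks])
        k = max(_elbow_k(ks, inertias), k_range[0])
        curve = pd.Series(inertias, index=ks, name="inertia")
    if k > n:
        raise ValueError("fewer regions than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(profiles)
    labels = km.labels_.astype(np.int64)
    sizes = np.bincount(labels, minlength=k)
    labels[np.isin(labels, np.flatnonzero(sizes < min_size))] = -1
    return ClusterResult(labels=labels, k=k, inertia_curve=curve)


def cluster_mean_weights(profiles: np.ndarray, labels: np.ndarray,
                         motif_ids=None) -> pd.DataFrame:
    """Average profile per retained cluster (rows indexed by cluster id)."""
    kept = labels >= 0
    df = pd.DataFrame(profiles[kept])
    if motif_ids is not None:
        df.columns = motif_ids
    return df.groupby(labels[kept]).mean()


def group_clusters(cluster_means: pd.DataFrame, n_groups: int = 10) -> pd.Series:
    """Merge clusters into groups: agglomerative, Manhattan distance,
    average linkage, cut at ``n_groups``.  Returns group id per cluster."""
    if len(cluster_means) < n_groups:
        raise ValueError("fewer clusters than groups")
    agg = AgglomerativeClustering(n_clusters=n_groups, metric="manhattan",
                                  linkage="average")
    return pd.Series(agg.fit_predict(cluster_means.to_numpy()),
                     index=cluster_means.index, name="group")


def group_summary(labels: np.ndarray, group_of_cluster: pd.Series,
                  profiles: np.ndarray, D1: np.ndarray,
                  motif_ids=None):
    """Group sizes, mean weights and mutation-density z-scores.

    The mutation z-score of a group is the z-score (across groups) of the
    group's mean log2 mutation density.
    """
    group_of_region = np.full(len(labels), -1, dtype=np.int64)
    kept = labels >= 0
    group_of_region[kept] = group_of_cluster.reindex(labels[kept]).to_numpy()

    rows, means, sizes = [], [], []
    for g in sorted(group_of_cluster.unique()):
        mask = group_of_region == g
        rows.append(g)
        sizes.append(int(mask.sum()))
        means.append(float(np.mean(D1[mask])) if mask.any() else np.nan)
    means = np.asarray(means)
    z = (means - np.nanmean(means)) / np.nanstd(means, ddof=1)

    weight_df = pd.DataFrame(profiles[kept])
    if motif_ids is not None:
        weight_df.columns = motif_ids
    group_weights = weight_df.groupby(group_of_region[kept]).mean()
    summary = pd.DataFrame({"group": rows, "n_regions": sizes,
                            "mean_D1": means, "mutation_z": z}).set_index("group")
    return summary, group_weights, group_of_region


def group_important_motifs(group_weights: pd.DataFrame) -> dict:
    """Motifs with a nonzero mean context weight per group."""
    return {g: list(row.index[row != 0]) for g, row in group_weights.iterrows()}


# ---------------------------------------------------------------------------
# enrichment / composition statistics
# ---------------------------------------------------------------------------

def state_fold_change(group_states: pd.Series, all_states: pd.Series) -> pd.Series:
    """Per chromatin state: share in the group over share in all regions.

    States absent from the group map to 0.0; states absent from the whole
    region set are excluded with a warning.
    """
    import warnings

    all_pct = all_states.value_counts(normalize=True)
    group_pct = group_states.value_counts(normalize=True)
    extra = set(group_pct.index) - set(all_pct.index)
    if extra:
        warnings.warn(f"states absent from the reference set excluded: {sorted(extra)}")
    fc = group_pct.reindex(all_pct.index, fill_value=0.0) / all_pct
    return fc.rename("fold_change")


def one_proportion_ztest(count: int, nobs: int, p0: float,
                         alternative: str = "two-sided"):
    """Classic one-proportion z-test with the null proportion in the
    standard error: z = (phat - p0) / sqrt(p0 (1 - p0) / n)."""
    phat = count / nobs
    z = (phat - p0) / np.sqrt(p0 * (1 - p0) / nobs)
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "larger":
        p = stats.norm.sf(z)
    elif alternative == "smaller":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return z, p


# ---------------------------------------------------------------------------
# mutation-rate profiles around motif sites
# ---------------------------------------------------------------------------

def motif_site_profile(sites: pd.DataFrame, mutations: pd.DataFrame,
                       window: int = 1000):
    """Mutation rate per base offset in ``[-window, +window]`` around the
    midpoints of the given motif sites.

    ``sites`` needs chrom/start/stop (1-based inclusive), ``mutations``
    chrom/pos.  Returns ``(offsets, rate, n_sites)`` where ``rate[k]`` is
    the mutation count at that offset over the number of sites.
    """
    if len(sites) == 0:
        raise ValueError("no motif sites supplied")
    counts = np.zeros(2 * window + 1, dtype=np.int64)
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy(np.int64))
                    for c, g in mutations.groupby("chrom")}
    mids = (sites["start"].to_numpy(np.int64) + sites["stop"].to_numpy(np.int64)) // 2
    for chrom, m in zip(sites["chrom"].to_numpy(), mids):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, m - window)
        hi = np.searchsorted(pos, m + window, side="right")
        np.add.at(counts, pos[lo:hi] - m + window, 1)
    offsets = np.arange(-window, window + 1)
    return offsets, counts / len(sites), len(sites)


def site_mean_rates(sites: pd.DataFrame, mutations: pd.DataFrame,
                    flank: int = 50) -> np.ndarray:
    """Per-site mean mutation rate (mutations per bp) within ``+-flank`` of
    each site midpoint — the unit of the positive- vs negative-weight motif
    comparisons."""
    if len(sites) == 0:
        raise ValueError("no motif sites supplied")
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy(np.int64))
                    for c, g in mutations.groupby("chrom")}
    mids = (sites["start"].to_numpy(np.int64) + sites["stop"].to_numpy(np.int64)) // 2
    rates = np.zeros(len(sites))
    span = 2 * flank + 1
    for i, (chrom, m) in enumerate(zip(sites["chrom"].to_numpy(), mids)):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, m - flank)
        hi = np.searchsorted(pos, m + flank, side="right")
        rates[i] = (hi - lo) / span
    return rates


def compare_motif_rates(rates_a: np.ndarray, rates_b: np.ndarray,
                        alternative: str = "greater"):
    """Student's t-test between per-site rate samples of two motif sets."""
    res = stats.ttest_ind(rates_a, rates_b, equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
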