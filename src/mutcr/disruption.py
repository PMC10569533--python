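"""Motif-disruption rates: how often somatic mutations land in binding sites.

For one donor and one region class (cancer-related or cancer-independent),
the disruption rate is C / (M * N): C motif binding sites overlapped by at
least one of the donor's mutations in the class, M total binding sites in
the class, N the donor's mutation count in the class.  A one-sided paired
t-test across donors (related > independent) scores each tumor type, and
significantly disrupted motifs are those in the top 5% by mean rate in
related regions that also reach p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DisruptionRate:
    donor_id: str
    motif_scope: str        # one motif id or "all"
    region_class: str       # "related" or "independent"
    C: int                  # sites overlapped by >= 1 mutation
    M: int                  # sites in the class
    N: int                  # donor mutations in the class
    rate: float | None      # C / (M * N), None when M * N == 0


def disruption_rate(sites: pd.DataFrame, mutations: pd.DataFrame,
                    donor_id: str = "", motif_scope: str = "all",
                    region_class: str = "") -> DisruptionRate:
    """Compute C/(M*N) for sites and mutations already restricted to one
    donor and one region class.

    A mutation overlaps a site when its 1-based position lies within
    ``[start, stop]`` inclusive; a site hit several times still counts once.
    When ``M*N == 0`` the rate is undefined (``None``) and the donor should
    be excluded from paired tests.
    """
    M, N = len(sites), len(mutations)
    if M == 0 or N == 0:
        return DisruptionRate(donor_id, motif_scope, region_class, 0, M, N, None)
    C = 0
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy(np.int64))
                    for c, g in mutations.groupby("chrom")}
    for chrom, grp in sites.groupby("chrom"):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        start = grp["start"].to_numpy(np.int64)
        stop = grp["stop"].to_numpy(np.int64)
        n_in = np.searchsorted(pos, stop, side="right") - np.searchsorted(pos, start, side="left")
        C += int((n_in > 0).sum())
    return DisruptionRate(donor_id, motif_scope, region_class, C, M, N, C / (M * N))


def donor_rates(occurrences: pd.DataFrame, mutations: pd.DataFrame,
                labels: pd.Series, motif_id: str | None = None) -> pd.DataFrame:
    """Per-donor disruption rates in related vs independent regions.

    ``occurrences`` and ``mutations`` must carry a ``region_id`` column (from
    :func:`mutcr.io_formats.assign_mutations` / midpoint assignment);
    ``labels`` maps region_id -> {related, independent, ambiguous}.  Rows
    with an undefined rate carry NaN.
    """
    occ = occurrences if motif_id is None else occurrences[occurrences["motif_id"] == motif_id]
    scope = motif_id or "all"
    lab_occ = labels.reindex(occ["region_id"]).to_numpy()
    lab_mut = labels.reindex(mutations["region_id"]).to_numpy()
    rows = []
    for donor, dmut in mutations.groupby("donor_id"):
        row = {"donor_id": donor, "motif_scope": scope}
        for cls in ("related", "independent"):
            s = occ[lab_occ == cls]
            m = dmut[labels.reindex(dmut["region_id"]).to_numpy() == cls]
            r = disruption_rate(s, m, donor_id=donor, motif_scope=scope, region_class=cls)
            row[cls] = np.nan if r.rate is None else r.rate
        rows.append(row)
    return pd.DataFrame(rows)


def paired_test(rates_related, rates_independent):
    """One-sided paired t-test: disruption higher in related regions.

    Degenerate cases: identical pairs give (0.0, 0.5); a constant nonzero
    difference has zero variance and is reported as t = +-inf with p of 0.0
    or 1.0 according to the sign.  Requires >= 3 pairs.
    """
    a = np.asarray(rates_related, dtype=float)
    b = np.asarray(rates_independent, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 complete donor pairs")
    d = a - b
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 0.5
        return (np.inf, 0.0) if d[0] > 0 else (-np.inf, 1.0)
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def motif_disruption_stats(occurrences: pd.DataFrame, mutations: pd.DataFrame,
                           labels: pd.Series,
                           motif_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-motif disruption summary across donors of one tumor type.

    Columns: mean rate per class (donor-averaged over donors with a defined
    rate), fold change (related / independent), paired t statistic and
    p-value.  Motifs with fewer than 3 complete pairs get NaN statistics.
    """
    if motif_ids is None:
        motif_ids = sorted(occurrences["motif_id"].unique())
    rows = []
    for motif in motif_ids:
        per_donor = donor_rates(occurrences, mutations, labels, motif_id=motif)
        mean_rel = per_donor["related"].mean()
        mean_ind = per_donor["independent"].mean()
        try:
            t, p = paired_test(per_donor["related"], per_donor["independent"])
        except ValueError:
            t, p = np.nan, np.nan
        rows.append({"motif_id": motif, "mean_rate_related": mean_rel,
                     "mean_rate_independent": mean_ind,
                     "fold_change": mean_rel / mean_ind if mean_ind else np.inf,
                     "t": t, "p": p})
    return pd.DataFrame(rows)


def select_disrupted(motif_stats: pd.DataFrame, top_frac: float = 0.05,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Flag motifs in the top ``top_frac`` by mean related-region rate that
    are also significant at ``alpha``.  Ties at the rank boundary break
    toward the smaller row index; exactly ``ceil(top_frac * m)`` motifs make
    the top set."""
    df = motif_stats.reset_index(drop=True).copy()
    k = ceil(top_frac * len(df))
    order = np.argsort(-df["mean_rate_related"].to_numpy(), kind="stable")
    top = np.zeros(len(df), dtype=bool)
    top[order[:k]] = True
    df["selected"] = top & (df["p"].to_numpy() < alpha)
    return df
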