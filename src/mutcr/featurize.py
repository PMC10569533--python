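"""Response and feature construction for regional mutation-rate modelling.

The response is the z-scored log2 mutation density of each segmentation
region:

    D_i   = (C_i / (l_i/1000)) / (T/10^6)        mutations per kb, normalized
                                                 by cohort mutations-per-million
    D1_i  = log2(D_i + 1)
    Y_i   = (D1_i - mean) / std                  mean/std over the training set

Features are per-region motif evidence scores: X_ij = -log10 of the median
FIMO p-value of motif j's occurrences inside region i, 0 when the motif has
no retained occurrence there.  Every transform stores the constants needed
for exact inversion, which the Poisson background test relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import locate_positions


@dataclass
class DensityVector:
    """Density response with the constants required to invert it."""

    D: np.ndarray
    D1: np.ndarray
    Y: np.ndarray
    mean: float
    std: float
    T: int


@dataclass
class FeatureMatrix:
    """Region x motif matrix of -log10(median occurrence p-value) scores."""

    values: np.ndarray
    region_ids: np.ndarray
    motif_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.region_ids, name="region_id"),
                            columns=self.motif_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), list(df.columns))


def mutation_density(counts, lengths, T: float) -> np.ndarray:
    """Per-kb mutation count normalized by the cohort total in millions."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("region lengths must be positive")
    if T <= 0:
        raise ValueError("cohort total T must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return (1000.0 * counts / lengths) / (T / 1e6)


def transform_density(D, mean: float | None = None, std: float | None = None,
                      ddof: int = 1):
    """log2(D+1) then z-score; returns ``(D1, Y, mean, std)``.

    When ``mean``/``std`` are given they are reused (scoring held-out regions
    with training-set constants); otherwise they are computed from ``D``
    with sample standard deviation (``ddof=1``).
    """
    D = np.asarray(D, dtype=float)
    if np.any(~np.isfinite(D)) or np.any(D < 0):
        raise ValueError("densities must be finite and nonnegative")
    D1 = np.log2(D + 1.0)
    if mean is None:
        mean = float(D1.mean())
    if std is None:
        std = float(D1.std(ddof=ddof))
    if std == 0:
        raise ValueError("degenerate response: zero standard deviation")
    Y = (D1 - mean) / std
    return D1, Y, mean, std


def density_response(counts, lengths, T: float, mean: float | None = None,
                     std: float | None = None) -> DensityVector:
    D = mutation_density(counts, lengths, T)
    D1, Y, mean, std = transform_density(D, mean=mean, std=std)
    return DensityVector(D=D, D1=D1, Y=Y, mean=mean, std=std, T=int(T))


def invert_response(Y, mean: float, std: float) -> np.ndarray:
    """Map z-scored response back to density, clamping at zero."""
    D1 = np.asarray(Y, dtype=float) * std + mean
    return np.maximum(np.exp2(D1) - 1.0, 0.0)


def counts_from_density(D, lengths, T: float) -> np.ndarray:
    """Expected mutation count implied by a density (inverse of
    :func:`mutation_density`)."""
    return np.asarray(D, dtype=float) * (np.asarray(lengths, dtype=float) / 1000.0) * (T / 1e6)


def response_weights(counts, lengths, T: float, std: float) -> np.ndarray:
    """Inverse-variance weights for fitting the z-scored density response.

    The Poisson counting noise on ``D1 = log2(D+1)`` is heteroscedastic —
    short or sparsely mutated regions carry far noisier responses than long
    ones.  By the delta method, ``sd(D1) = sqrt(lambda) / (ln2 * (lambda + k))``
    with ``k = (l/1000) * (T/1e6)`` the count corresponding to unit density;
    lambda is estimated by the observed count (floored at 1).  Weights are
    ``1 / var`` on the z scale, normalised to mean 1.  Weighting the squared
    error this way lets the fitted background track precisely measured
    regions tightly instead of spreading one average error over all regions
    — which matters because an error of fixed log2 size inflates the Poisson
    z-statistic of a region by a factor growing with sqrt(lambda).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    k = (lengths / 1000.0) * (T / 1e6)
    lam = np.maximum(counts, 1.0)
    sd_z = np.sqrt(lam) / (np.log(2.0) * (lam + k)) / std
    w = 1.0 / sd_z ** 2
    return w / w.mean()


def motif_features(occurrences: pd.DataFrame, regions: pd.DataFrame,
                   motif_ids: list[str] | None = None) -> FeatureMatrix:
    """Build the region x motif feature matrix from FIMO occurrences.

    An occurrence belongs to the region containing its midpoint (floor of the
    1-based inclusive interval midpoint).  ``X_ij = -log10(median p)`` of the
    assigned occurrences, 0 where the motif is absent.  ``motif_ids`` fixes
    the column order (needed when scoring a new cohort with a trained model);
    by default the sorted motif ids present in ``occurrences`` are used.
    """
    occ = occurrences.copy()
    mid0 = (occ["start"].to_numpy(np.int64) + occ["stop"].to_numpy(np.int64)) // 2 - 1
    occ["region_id"] = locate_positions(occ["chrom"], mid0, regions)
    occ = occ[occ["region_id"] >= 0]

    if motif_ids is None:
        motif_ids = sorted(occ["motif_id"].unique())
    med = (occ.groupby(["region_id", "motif_id"], sort=False)["p_value"]
           .median())
    X = np.zeros((len(regions), len(motif_ids)))
    if len(med):
        row_of = pd.Series(np.arange(len(regions)), index=regions["region_id"])
        col_of = {m: j for j, m in enumerate(motif_ids)}
        for (rid, motif), p in med.items():
            j = col_of.get(motif)
            if j is not None:
                X[row_of[rid], j] = -np.log10(p)
    return FeatureMatrix(values=X, region_ids=regions["region_id"].to_numpy(),
                         motif_ids=list(motif_ids))
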