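"""Poisson excess-mutation tests against the model-predicted background.

For each region the trained CR model supplies a predicted response, which is
inverted to an expected mutation count lambda.  Assuming the background
(cancer-independent) count in a region is Poisson(lambda), upper- and
lower-tail p-values flag regions mutating significantly above or below the
epigenetically expected rate.  An iterative procedure removes the flagged
regions from the training set and retrains, so the background model is fit
on regions that actually behave like background.  Final labels:

* independent:  p_upper > 0.1 and p_lower > 0.1
* related:      BH-adjusted upper-tail FDR < 0.01 (takes precedence)
* ambiguous:    everything else
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from . import cr_model
from .featurize import (counts_from_density, density_response, invert_response,
                        mutation_density, response_weights, transform_density)

LABELS = ("independent", "related", "ambiguous")


def predicted_count(y_pred, mean: float, std: float, lengths, T: float) -> np.ndarray:
    """Invert a predicted z-scored response to an expected count.

    ``D1 = y*std + mean``; ``D = max(2^D1 - 1, 0)`` (the clamp handles
    predictions below the response floor); ``lambda = D * l/1000 * T/1e6``.
    """
    D = invert_response(y_pred, mean, std)
    return counts_from_density(D, lengths, T)


def poisson_tails(observed, lam):
    """Exact Poisson tail probabilities including the observed point.

    Returns ``(p_upper, p_lower)`` with ``p_upper = P(X >= obs)`` and
    ``p_lower = P(X <= obs)``.  For ``lambda == 0`` the distribution is a
    point mass at 0: ``p_upper`` is 1 for ``obs == 0`` and 0 for ``obs > 0``
    (an impossible event was observed — the caller should treat the region
    as flagged rather than divide by these values).
    """
    observed = np.asarray(observed)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be nonnegative")
    obs_int = np.asarray(np.rint(observed), dtype=np.int64)
    if np.any(np.abs(observed - obs_int) > 0) or np.any(obs_int < 0):
        raise ValueError("observed counts must be nonnegative integers")
    p_upper = poisson.sf(obs_int - 1, lam)
    p_lower = poisson.cdf(obs_int, lam)
    return p_upper, p_lower


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def make_verdicts(regions: pd.DataFrame, observed, lam) -> pd.DataFrame:
    """Assemble the per-region verdict table (before labelling)."""
    df = regions[["region_id", "chrom", "start", "end", "state"]].copy()
    df["observed"] = np.asarray(observed)
    df["lambda_hat"] = np.asarray(lam, dtype=float)
    df["p_upper"], df["p_lower"] = poisson_tails(df["observed"], df["lambda_hat"])
    return df


def classify(verdicts: pd.DataFrame, p_threshold: float = 0.1,
             fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Attach BH-FDR and the independent/related/ambiguous label.

    BH is applied to the upper-tail p-values across all regions of the
    cohort.  ``related`` (upper-tail FDR < threshold) takes precedence over
    ``independent`` (both tail p-values above ``p_threshold``); anything
    matching neither rule is ``ambiguous``.
    """
    df = verdicts.copy()
    df["fdr_upper"] = bh_fdr(df["p_upper"].to_numpy())
    independent = (df["p_upper"] > p_threshold) & (df["p_lower"] > p_threshold)
    related = df["fdr_upper"] < fdr_threshold
    label = np.where(related, "related", np.where(independent, "independent", "ambiguous"))
    df["label"] = label
    return df


def recalibrate_lambda(lam: np.ndarray, counts: np.ndarray, flagged: np.ndarray,
                       n_bins: int = 10, trim: float = 0.1) -> np.ndarray:
    """Robust per-stratum recalibration of the expected counts.

    Within each decile of predicted lambda, the trimmed mean of
    ``observed / predicted`` over non-flagged (background-like) regions
    estimates any smooth systematic bias of the fitted background; lambda
    is multiplied by that factor.  A log2 bias of only a few percent is
    irrelevant for prediction but inflates the Poisson z-statistic of a
    deeply covered region by ``~0.7 * bias * sqrt(lambda)``, so removing it
    matters for the validity of the excess-mutation test.  Bins with fewer
    than 20 background regions are left untouched.
    """
    from scipy import stats as _stats

    lam = np.asarray(lam, dtype=float).copy()
    counts = np.asarray(counts, dtype=float)
    edges = np.quantile(lam, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1.0
    edges[-1] += 1.0
    background = ~np.asarray(flagged, dtype=bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        stratum = (lam > lo) & (lam <= hi)
        ref = stratum & background
        if ref.sum() >= 20:
            factor = _stats.trim_mean(counts[ref] / np.maximum(lam[ref], 1e-9), trim)
            lam[stratum] *= factor
    return lam


@dataclass
class RefinementResult:
    model: cr_model.CRModel     # first ensemble member (for persistence)
    models: list                # all ensemble members of the final iteration
    history: pd.DataFrame       # per-iteration test MSE and drop counts
    mean: float                 # response constants of the final iteration
    std: float
    train_mask: np.ndarray      # regions in the final training set
    lambda_hat: np.ndarray      # final expected counts, all regions


def iterate_refinement(X: np.ndarray, counts, lengths, T: float,
                       test_mask: np.ndarray, max_iter: int = 2,
                       removal_p: float = 0.1, plateau_tol: float = 0.01,
                       variance_weighting: bool = True, n_ensemble: int = 1,
                       recalibrate: bool = True, seed: int = 0,
                       architecture=None, **model_kwargs) -> RefinementResult:
    """Iteratively retrain the background model on putatively background regions.

    Each iteration trains on the current training set, predicts all regions,
    converts predictions to Poisson expectations (T held fixed at the
    original cohort total), and removes training regions with either tail
    p-value below ``removal_p`` before the next round.  The removal set is
    recomputed *fresh* against the current model each iteration, so a
    region flagged once can re-enter training if the improved background
    explains it.  Stops after ``max_iter`` trainings or when the held-out
    MSE improves by less than ``plateau_tol`` (relative).

    Numerical choices: the response constants (mean/std of log2 density) are
    recomputed on each iteration's training set so flagged and held-out
    regions never leak into the scaling; fitting uses inverse-variance
    weights (:func:`mutcr.featurize.response_weights`) unless
    ``variance_weighting=False``; ``n_ensemble`` independently seeded
    networks are averaged to stabilise the background; lambda is bias-
    corrected per stratum (:func:`recalibrate_lambda`) unless
    ``recalibrate=False``; and the history's ``test_mse`` is evaluated on
    the held-out regions *not* flagged at the first iteration — a stable,
    background-like evaluation set on which successive iterations are
    comparable (held-out excess-mutation regions would otherwise dominate
    the error of an improving background model).
    """
    X = np.asarray(X, dtype=float)
    counts = np.asarray(counts)
    lengths = np.asarray(lengths, dtype=float)
    test_mask = np.asarray(test_mask, dtype=bool)
    if architecture is None:
        architecture = cr_model.build(X.shape[1])

    base_train = ~test_mask
    train_mask = base_train.copy()
    history = []
    prev_mse = np.inf
    eval_mask = None
    eval_Y = None   # held-out response frozen at iteration-1 constants
    models = []
    mean = std = lam = None
    for iteration in range(1, max_iter + 1):
        if not train_mask.any():
            raise ValueError("all regions removed from the training set")
        dens_train = density_response(counts[train_mask], lengths[train_mask], T)
        mean, std = dens_train.mean, dens_train.std
        _, Y_all, _, _ = transform_density(
            mutation_density(counts, lengths, T), mean=mean, std=std)
        weights = response_weights(counts, lengths, T, std) if variance_weighting else None

        prev_models = models
        models = []
        preds = []
        for j in range(n_ensemble):
            model = cr_model.CRModel(architecture, seed=seed + 100 * iteration + j,
                                     **model_kwargs)
            model.fit(X[train_mask], Y_all[train_mask],
                      sample_weight=None if weights is None else weights[train_mask],
                      init_from=prev_models[j] if prev_models else None)
            models.append(model)
            preds.append(model.predict(X))
        y_pred = np.mean(preds, axis=0)

        lam = predicted_count(y_pred, mean, std, lengths, T)
        p_upper, p_lower = poisson_tails(counts, lam)
        flagged = np.minimum(p_upper, p_lower) < removal_p
        if recalibrate:
            lam = recalibrate_lambda(lam, counts, flagged)
            p_upper, p_lower = poisson_tails(counts, lam)
            flagged = np.minimum(p_upper, p_lower) < removal_p
        if eval_mask is None:
            eval_mask = test_mask & ~flagged
            eval_Y = Y_all
            eval_mean, eval_std = mean, std
        # measure successive models against the same target: iteration-1
        # response constants and the iteration-1 background-like held-out set
        y_pred_eval = (y_pred * std + mean - eval_mean) / eval_std
        test_mse = float(np.mean((y_pred_eval[eval_mask] - eval_Y[eval_mask]) ** 2)) \
            if eval_mask.any() else np.nan
        n_dropped = int((train_mask & flagged).sum())
        history.append({"iteration": iteration, "n_train": int(train_mask.sum()),
                        "test_mse": test_mse, "n_dropped": n_dropped})

        if iteration > 1 and np.isfinite(prev_mse) and np.isfinite(test_mse):
            if (prev_mse - test_mse) / prev_mse < plateau_tol:
                break
        prev_mse = test_mse
        if iteration < max_iter:
            train_mask = base_train & ~flagged

    return RefinementResult(model=models[0], models=models,
                            history=pd.DataFrame(history),
                            mean=mean, std=std, train_mask=train_mask,
                            lambda_hat=lam)
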