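"""High-level pipeline steps shared by the CLI, the tests and the analysis
scripts: featurization of a cohort from its raw tables, background-model
training with iterative refinement, region labelling, and the donor-level
classification experiment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cancer_classifier, cr_model, io_formats, region_classes
from .featurize import DensityVector, FeatureMatrix, density_response, motif_features


@dataclass
class FeaturizeResult:
    features: FeatureMatrix
    regions: pd.DataFrame           # segmentation with a per-region count column
    mutations: pd.DataFrame         # non-blacklisted mutations with region_id
    density: DensityVector
    T: int
    unassigned: int


def featurize_cohort(segmentation: pd.DataFrame, mutations: pd.DataFrame,
                     occurrences: pd.DataFrame,
                     blacklist: pd.DataFrame | None = None,
                     motif_ids: list[str] | None = None) -> FeaturizeResult:
    """Counts, density response and motif features for one cohort."""
    assigned, counts, unassigned, T = io_formats.assign_mutations(
        mutations, segmentation, blacklist)
    regions = segmentation.copy()
    regions["count"] = counts.to_numpy()
    density = density_response(counts.to_numpy(), regions["length_bp"].to_numpy(), T)
    features = motif_features(occurrences, segmentation, motif_ids=motif_ids)
    return FeaturizeResult(features=features, regions=regions, mutations=assigned,
                           density=density, T=T, unassigned=unassigned)


def holdout_mask(regions: pd.DataFrame, holdout_chroms: list[str] | None = None,
                 holdout_fraction: float = 0.1, seed: int = 0) -> np.ndarray:
    """Region- or chromosome-wise held-out test mask."""
    if holdout_chroms:
        return regions["chrom"].isin(holdout_chroms).to_numpy()
    rng = np.random.default_rng(seed)
    n = len(regions)
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=int(round(holdout_fraction * n)), replace=False)] = True
    return mask


def run_region_analysis(features: FeatureMatrix, regions: pd.DataFrame, T: int,
                        test_mask: np.ndarray | None = None, max_iter: int = 2,
                        seed: int = 0, architecture=None,
                        **model_kwargs):
    """Train the refined background model and label every region.

    Returns ``(refinement, verdicts)``; the verdict table carries observed
    counts, lambda, tail p-values, BH-FDR and the final label.
    """
    counts = regions["count"].to_numpy()
    lengths = regions["length_bp"].to_numpy(dtype=float)
    if test_mask is None:
        test_mask = holdout_mask(regions, seed=seed)
    refinement = region_classes.iterate_refinement(
        features.values, counts, lengths, T, test_mask, max_iter=max_iter,
        seed=seed, architecture=architecture, **model_kwargs)
    verdicts = region_classes.make_verdicts(regions, counts, refinement.lambda_hat)
    verdicts = region_classes.classify(verdicts)
    return refinement, verdicts


def score_with_model(model: cr_model.CRModel, features: FeatureMatrix,
                     regions: pd.DataFrame, T: int, mean: float, std: float) -> pd.DataFrame:
    """Label regions with an already-trained background model (single pass)."""
    counts = regions["count"].to_numpy()
    lengths = regions["length_bp"].to_numpy(dtype=float)
    lam = region_classes.predicted_count(model.predict(features.values), mean, std,
                                         lengths, T)
    return region_classes.classify(region_classes.make_verdicts(regions, counts, lam))


def related_region_union(verdicts_by_type: dict[str, pd.DataFrame]) -> list[int]:
    """Union of cancer-related region ids across per-type verdict tables."""
    union: set[int] = set()
    for verdicts in verdicts_by_type.values():
        union |= set(verdicts.loc[verdicts["label"] == "related", "region_id"])
    return sorted(union)


def classification_experiment(mutations: pd.DataFrame, features: FeatureMatrix,
                              segmentation: pd.DataFrame, seed: int = 0,
                              test_fraction: float = 0.2, grid: dict | None = None,
                              max_iter: int = 2, model_kwargs: dict | None = None):
    """End-to-end donor classification with the leakage discipline.

    Donors are split 80/20 per type; cancer-related regions are detected per
    type *from training-donor counts only*; the GBDT is tuned on training
    donors and evaluated on the held-out 20%.  Returns a dict with the union
    size, tuned parameters and train/test evaluation.
    """
    rng = np.random.default_rng(seed)
    model_kwargs = model_kwargs or {}
    donors = mutations[["donor_id", "tumor_type"]].drop_duplicates()
    test_donors: list[str] = []
    for _, grp in donors.groupby("tumor_type"):
        ids = grp["donor_id"].to_numpy()
        n_test = max(1, int(round(test_fraction * len(ids))))
        test_donors.extend(rng.choice(ids, size=n_test, replace=False))
    is_test = mutations["donor_id"].isin(test_donors)
    train_mut = mutations[~is_test]

    lengths = segmentation["length_bp"].to_numpy(dtype=float)
    verdicts_by_type: dict[str, pd.DataFrame] = {}
    for tumor_type, grp in train_mut.groupby("tumor_type"):
        counts = (grp.groupby("region_id").size()
                  .reindex(segmentation["region_id"], fill_value=0))
        regions = segmentation.copy()
        regions["count"] = counts.to_numpy()
        T = int(counts.sum())
        refinement, verdicts = run_region_analysis(
            features, regions, T, max_iter=max_iter, seed=seed, **model_kwargs)
        verdicts_by_type[tumor_type] = verdicts
    union = related_region_union(verdicts_by_type)
    if not union:
        raise ValueError("no cancer-related regions detected; nothing to classify on")

    labels = donors.set_index("donor_id")["tumor_type"]
    X, y = cancer_classifier.build_features(mutations, union, labels)
    test_mask = X.index.isin(test_donors)
    params, report = cancer_classifier.tune(X[~test_mask], y[~test_mask],
                                            grid=grid, seed=seed)
    clf = cancer_classifier.fit(X[~test_mask], y[~test_mask], params, seed=seed)
    evaluation = cancer_classifier.evaluate(clf, X[test_mask], y[test_mask])
    return {
        "union": union,
        "verdicts_by_type": verdicts_by_type,
        "params": params,
        "tuning_report": report,
        "model": clf,
        "features": X,
        "labels": y,
        "test_donors": sorted(test_donors),
        "evaluation": evaluation,
    }
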