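"""Contextual regression: an interpretable neural network for regional rates.

The model is a fully connected embedding network that maps each feature
vector x (length p) to a *context weight* vector beta(x) of the same length;
the prediction is the dot product x . beta(x).  Because the output is, by
construction, a local linear model in the input features, beta(x) directly
quantifies each motif's contribution to the predicted mutation rate of that
region — no post-hoc attribution is needed.

Architecture (p inputs):

    dense(p/2, ReLU) -> dropout(0.01)
    dense(p/d3, ReLU) -> dropout(0.01)       d3 in [10, 20], default 15
    dense(p/d5, ReLU) -> dropout(0.1)        d5 in [5, 30],  default 10
    dense(p, linear)  = context weights beta
    output = dot(x, beta)

Counting dropout layers and the context layer, the stack has seven hidden
layers; three of them carry trainable dense weights.  Training minimises the
mean squared error against the z-scored density response with Adam, inverted
dropout, mini-batches and early stopping on a validation split.  Everything
(init, shuffling, dropout masks, splits) is driven by one seed, so runs are
bit-reproducible.

Two numerical choices matter for optimisation and cost nothing in the
model's semantics:

* The context head is initialised near zero, so training starts from the
  global-linear solution beta(x) ~ b4 with a healthy embedding on top of
  it.  With a conventionally scaled head, the initial dot-product noise is
  large and gradient descent silences it by collapsing the embedding
  activations — after which the contextual part can never recover.
* Features are rescaled internally by their per-column training standard
  deviation (no centering).  Because the rescaling is linear and has no
  offset, it folds exactly into the reported coefficients
  (beta_j = beta_internal_j / s_j), so the prediction remains the literal
  dot product of the *raw* input with the reported context weights.

The implementation is pure NumPy: the network is small (the bottleneck keeps
it to a few times p^2 parameters) and a hand-written forward/backward pass
keeps the dot-product identity and the training procedure fully transparent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CRArchitecture:
    p: int
    hidden_sizes: tuple[int, int, int]
    dropout_rates: tuple[float, float, float] = (0.01, 0.01, 0.1)


@dataclass
class ContextWeights:
    """Per-region coefficient vectors and the dot-product predictions."""

    beta: np.ndarray        # (n, p)
    prediction: np.ndarray  # (n,)


def build(p: int, d3: int = 15, d5: int = 10,
          dropout_rates: tuple[float, float, float] = (0.01, 0.01, 0.1)) -> CRArchitecture:
    """Lay out the network for ``p`` input motifs.

    Widths are ``p/2, p/d3, p/d5`` floored to integers and clamped at 1; the
    context layer always has width ``p``.
    """
    if p < 2:
        raise ValueError("need at least 2 input features")
    sizes = (max(1, p // 2), max(1, p // d3), max(1, p // d5))
    return CRArchitecture(p=p, hidden_sizes=sizes, dropout_rates=tuple(dropout_rates))


def _relu(z):
    return np.maximum(z, 0.0)


class CRModel:
    """Trainable contextual-regression network.

    Parameters
    ----------
    architecture
        From :func:`build`.
    learning_rate, max_epochs, batch_size, patience, val_fraction
        Adam step size, epoch cap, mini-batch size, early-stopping patience
        (epochs without validation-MSE improvement) and the fraction of the
        training rows held aside for that validation signal.
    feature_scaling
        Rescale each feature column by its training-set standard deviation
        (no centering) before the network; folded back into the reported
        context weights so the dot-product identity holds on raw inputs.
    seed
        Governs initialisation, shuffling, dropout masks and the validation
        split.
    """

    def __init__(self, architecture: CRArchitecture, learning_rate: float = 1e-3,
                 max_epochs: int = 200, batch_size: int = 256, patience: int = 10,
                 val_fraction: float = 0.1, feature_scaling: bool = True,
                 seed: int = 0):
        self.architecture = architecture
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.feature_scaling = feature_scaling
        self.seed = seed
        self.params_: dict[str, np.ndarray] | None = None
        self.scale_: np.ndarray | None = None
        self.n_epochs_: int | None = None

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        p = self.architecture.p
        h1, h2, h3 = self.architecture.hidden_sizes
        dims = [(p, h1), (h1, h2), (h2, h3), (h3, p)]
        params = {}
        for k, (fan_in, fan_out) in enumerate(dims, start=1):
            # He init for the ReLU layers; the linear context head starts
            # near zero (see module docstring)
            scale = np.sqrt(2.0 / fan_in) if k < 4 else 0.01 * np.sqrt(1.0 / (fan_in + fan_out))
            params[f"W{k}"] = rng.normal(0.0, scale, size=(fan_in, fan_out))
            params[f"b{k}"] = np.zeros(fan_out)
        return params

    def _scaled(self, X: np.ndarray) -> np.ndarray:
        return X / self.scale_ if self.scale_ is not None else X

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass; dropout is applied only when ``rng`` is given."""
        P = self.params_
        rates = self.architecture.dropout_rates
        cache = {"X": X}
        a = X
        for k in (1, 2, 3):
            z = a @ P[f"W{k}"] + P[f"b{k}"]
            a = _relu(z)
            cache[f"z{k}"] = z
            if rng is not None:
                keep = 1.0 - rates[k - 1]
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
                cache[f"m{k}"] = mask
            cache[f"a{k}"] = a
        beta = a @ P["W4"] + P["b4"]
        cache["beta"] = beta
        cache["yhat"] = np.einsum("ij,ij->i", X, beta)
        return cache

    def _backward(self, cache, y: np.ndarray, w: np.ndarray):
        P = self.params_
        g_yhat = 2.0 * w * (cache["yhat"] - y) / w.sum()
        g_beta = g_yhat[:, None] * cache["X"]
        grads = {"W4": cache["a3"].T @ g_beta, "b4": g_beta.sum(axis=0)}
        g_a = g_beta @ P["W4"].T
        for k in (3, 2, 1):
            if f"m{k}" in cache:
                g_a = g_a * cache[f"m{k}"]
            g_z = g_a * (cache[f"z{k}"] > 0)
            a_prev = cache["X"] if k == 1 else cache[f"a{k-1}"]
            grads[f"W{k}"] = a_prev.T @ g_z
            grads[f"b{k}"] = g_z.sum(axis=0)
            if k > 1:
                g_a = g_z @ P[f"W{k}"].T
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray,
            sample_weight: np.ndarray | None = None,
            X_val: np.ndarray | None = None, Y_val: np.ndarray | None = None,
            init_from: "CRModel | None" = None) -> "CRModel":
        """Train with Adam + early stopping; returns self.

        ``sample_weight`` turns the loss into a weighted MSE (used by the
        pipeline with inverse-variance weights from
        :func:`mutcr.featurize.response_weights`).  If no validation set is
        supplied, ``val_fraction`` of the rows is split off (seeded) to
        drive early stopping.  The parameters giving the best (weighted)
        validation MSE are restored at the end.  ``init_from`` warm-starts
        from another trained model (same architecture) instead of random
        initialisation — used by the iterative refinement so successive
        iterations continue optimisation rather than refit from scratch.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("NaN in training inputs")
        if X.shape[1] != self.architecture.p:
            raise ValueError(f"X has width {X.shape[1]}, expected {self.architecture.p}")
        W = np.ones(len(X)) if sample_weight is None else \
            np.asarray(sample_weight, dtype=float) / np.mean(sample_weight)
        rng = np.random.default_rng(self.seed)
        if init_from is not None:
            self.params_ = {k: v.copy() for k, v in init_from.params_.items()}
            self.scale_ = None if init_from.scale_ is None else init_from.scale_.copy()
        else:
            self.params_ = self._init_params(rng)
            if self.feature_scaling:
                scale = X.std(axis=0)
                scale[scale == 0] = 1.0
                self.scale_ = scale
            else:
                self.scale_ = None
        X = self._scaled(X)
        if X_val is not None:
            X_val = self._scaled(np.asarray(X_val, dtype=float))
            W_val = np.ones(len(X_val))

        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * len(X)))) if len(X) > 10 else 0
            perm = rng.permutation(len(X))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            X_val, Y_val, W_val = X[val_idx], Y[val_idx], W[val_idx]
            X_tr, Y_tr, W_tr = X[train_idx], Y[train_idx], W[train_idx]
        else:
            X_tr, Y_tr, W_tr = X, Y, W

        m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        # score the starting point so a warm start can never be degraded
        has_val0 = len(X_val) > 0
        best_mse = float(np.average(
            (self._forward(X_val if has_val0 else X_tr)["yhat"] -
             (Y_val if has_val0 else Y_tr)) ** 2,
            weights=W_val if has_val0 else W_tr))
        best_params = {k: p.copy() for k, p in self.params_.items()}
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X_tr))
            for start in range(0, len(X_tr), self.batch_size):
                idx = order[start:start + self.batch_size]
                cache = self._forward(X_tr[idx], rng=rng)
                grads = self._backward(cache, Y_tr[idx], W_tr[idx])
                t += 1
                lr_t = self.learning_rate * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
                for k, g in grads.items():
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    self.params_[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
            # monitor inputs are already on the internal scale
            has_val = len(X_val) > 0
            monitor_X = X_val if has_val else X_tr
            monitor_Y = Y_val if has_val else Y_tr
            monitor_W = W_val if has_val else W_tr
            val_mse = float(np.average((self._forward(monitor_X)["yhat"] - monitor_Y) ** 2,
                                       weights=monitor_W))
            if val_mse < best_mse * (1 - 1e-6):
                best_mse = val_mse
                best_params = {k: p.copy() for k, p in self.params_.items()}
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.params_ = best_params
        self.n_epochs_ = epoch + 1
        return self

    # -- inference ----------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.context_weights(X).prediction

    def context_weights(self, X: np.ndarray) -> ContextWeights:
        """Return beta(x) and the dot-product prediction (dropout disabled)."""
        if self.params_ is None:
            raise ValueError("model is not trained")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.architecture.p:
            raise ValueError(f"X has width {X.shape[1] if X.ndim == 2 else 'n/a'}, "
                             f"expected {self.architecture.p}")
        cache = self._forward(self._scaled(X), rng=None)
        beta = cache["beta"] / self.scale_ if self.scale_ is not None else cache["beta"]
        return ContextWeights(beta=beta, prediction=cache["yhat"])

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = dict(self.params_)
        if self.scale_ is not None:
            arrays["_scale"] = self.scale_
        np.savez(d / "weights.npz", **arrays)
        meta = {
            "p": self.architecture.p,
            "hidden_sizes": list(self.architecture.hidden_sizes),
            "dropout_rates": list(self.architecture.dropout_rates),
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "batch_size": self.batch_size,
            "patience": self.patience,
            "val_fraction": self.val_fraction,
            "seed": self.seed,
            "feature_scaling": self.feature_scaling,
            "optimizer": "Adam",
            "n_epochs_trained": self.n_epochs_,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "CRModel":
        from pathlib import Path
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        arch = CRArchitecture(p=meta["p"], hidden_sizes=tuple(meta["hidden_sizes"]),
                              dropout_rates=tuple(meta["dropout_rates"]))
        model = cls(arch, learning_rate=meta["learning_rate"],
                    max_epochs=meta["max_epochs"], batch_size=meta["batch_size"],
                    patience=meta["patience"], val_fraction=meta["val_fraction"],
                    feature_scaling=meta.get("feature_scaling", True),
                    seed=meta["seed"])
        with np.load(d / "weights.npz") as npz:
            model.params_ = {k: npz[k] for k in npz.files if not k.startswith("_")}
            if "_scale" in npz.files:
                model.scale_ = npz["_scale"]
        model.n_epochs_ = meta.get("n_epochs_trained")
        return model


# ---------------------------------------------------------------------------
# convenience training / evaluation
# ---------------------------------------------------------------------------

def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """The four fit metrics: Pearson r, MSE, MAE, Spearman rho."""
    return {
        "pearson_r": float(stats.pearsonr(y_true, y_pred)[0]),
        "mse": float(np.mean((y_true - y_pred) ** 2)),
        "mae": float(np.mean(np.abs(y_true - y_pred))),
        "spearman_r": float(stats.spearmanr(y_true, y_pred)[0]),
    }


def train(X: np.ndarray, Y: np.ndarray, test_mask: np.ndarray, seed: int = 0,
          architecture: CRArchitecture | None = None,
          sample_weight: np.ndarray | None = None, **model_kwargs):
    """Fit a CR model on the rows outside ``test_mask``.

    Returns ``(model, metrics)`` where metrics holds the train/test Pearson r,
    MSE, MAE and Spearman rho.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    test_mask = np.asarray(test_mask, dtype=bool)
    if architecture is None:
        architecture = build(X.shape[1])
    model = CRModel(architecture, seed=seed, **model_kwargs)
    w_tr = None if sample_weight is None else np.asarray(sample_weight)[~test_mask]
    model.fit(X[~test_mask], Y[~test_mask], sample_weight=w_tr)
    metrics = {"train": regression_metrics(Y[~test_mask], model.predict(X[~test_mask]))}
    if test_mask.any():
        metrics["test"] = regression_metrics(Y[test_mask], model.predict(X[test_mask]))
    return model, metrics


def crossvalidate(X: np.ndarray, Y: np.ndarray, folds: int = 10,
                  scheme: str = "region", chromosomes: np.ndarray | None = None,
                  seed: int = 0, **model_kwargs) -> pd.DataFrame:
    """K-fold cross-validation with region- or chromosome-wise folds.

    ``scheme="chromosome"`` leaves whole chromosomes out jointly (so similar
    regions cannot straddle the train/test divide); ``chromosomes`` must then
    give the chromosome of each row.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    if scheme == "region":
        if len(X) < folds:
            raise ValueError("fewer regions than folds")
        fold_groups = np.array_split(rng.permutation(len(X)), folds)
        test_sets = [np.isin(np.arange(len(X)), g) for g in fold_groups]
    elif scheme == "chromosome":
        if chromosomes is None:
            raise ValueError("chromosome scheme needs per-row chromosomes")
        uniq = np.unique(chromosomes)
        if len(uniq) < folds:
            raise ValueError("fewer chromosomes than folds")
        groups = np.array_split(rng.permutation(uniq), folds)
        test_sets = [np.isin(chromosomes, g) for g in groups]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    for i, mask in enumerate(test_sets):
        _, metrics = train(X, Y, mask, seed=seed + i, **model_kwargs)
        rows.append({"fold": i,
                     "n_test": int(mask.sum()),
                     **{f"train_{k}": v for k, v in metrics["train"].items()},
                     **{f"test_{k}": v for k, v in metrics["test"].items()}})
    return pd.DataFrame(rows)
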