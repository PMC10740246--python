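"""Scikit-learn-style regressor predicting ARMSD_bio from a point cloud.

:class:`SchNetRegressor` wraps the numpy network core in the familiar
fit/predict estimator surface.  A sample is a pair ``(atomic_numbers, coords)``
of a heavy-atom conformation; the target is its ARMSD_bio in Å.  Training
minimizes mean squared error with Adam and early-stops on the validation loss
with a configurable patience, keeping the weights of the best validation
epoch.

Two presets are provided: the full-size configuration (128 features, 6
interaction blocks, 50 radial basis functions, cutoff 10 Å, learning rate
1e-5) and a small "desk" configuration for CPU-scale experiments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .conformers import ConformerRecord, LabelledEnsemble
from .errors import ConfrankError
from .nn import SchNetCore, build_graph

__all__ = ["SchNetRegressor", "ensemble_to_samples", "save_checkpoint", "load_checkpoint"]

GraphSample = tuple[np.ndarray, np.ndarray]  # (atomic_numbers, coords)


def ensemble_to_samples(ensemble: LabelledEnsemble) -> list[GraphSample]:
    """(atomic_numbers, coords) pairs for every generated conformer."""
    z = np.array([a.GetAtomicNum() for a in ensemble.mol.GetAtoms()], dtype=np.int64)
    return [(z, c.coords) for c in ensemble.conformers]


class SchNetRegressor(BaseEstimator, RegressorMixin):
    """Distance-only atomistic network regressor with MSE/Adam training.

    Parameters mirror the published SchNet defaults; ``learning_rate`` is the
    Adam step size and ``patience`` the number of consecutive epochs without
    validation improvement tolerated before stopping.
    """

    def __init__(
        self,
        embed_dim: int = 128,
        n_interactions: int = 6,
        n_rbf: int = 50,
        cutoff: float = 10.0,
        readout_hidden: int = 64,
        learning_rate: float = 1e-5,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 5,
        seed: int = 0,
        standardize_targets: bool = False,
    ):
        self.embed_dim = embed_dim
        self.n_interactions = n_interactions
        self.n_rbf = n_rbf
        self.cutoff = cutoff
        self.readout_hidden = readout_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.standardize_targets = standardize_targets

    @classmethod
    def desk(cls, **overrides) -> "SchNetRegressor":
        """Small CPU-scale preset: 64 features, 3 blocks, 20 basis functions."""
        defaults = dict(
            embed_dim=64,
            n_interactions=3,
            n_rbf=20,
            cutoff=5.0,
            readout_hidden=32,
            learning_rate=1e-3,
            max_epochs=60,
        )
        defaults.update(overrides)
        return cls(**defaults)

    # -- training ----------------------------------------------------------

    def _graphs(self, X) -> list:
        return [build_graph(z, coords, self.cutoff) for z, coords in X]

    def _loss_and_grads(self, core, graphs, targets, accumulate: bool):
        targets = np.asarray(targets, dtype=float)
        if accumulate:
            grads = core.zero_grads()
            y, cache = core.forward_batch(graphs, want_cache=True)
            core.backward(cache, 2.0 * (y - targets) / len(graphs), grads)
        else:
            grads = None
            y = core.forward_batch(graphs)
        return float(np.mean((y - targets) ** 2)), grads

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on ``(atomic_numbers, coords)`` samples with targets in Å.

        With a validation set, stops once the validation loss has failed to
        improve for ``patience`` consecutive epochs, restoring the best
        weights; without one, runs ``max_epochs``.
        """
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        y = np.asarray(y, dtype=float)
        vocab_src = list(X) + (list(X_val) if X_val is not None else [])
        vocab = {int(z): i for i, z in enumerate(sorted({int(v) for zz, _ in vocab_src for v in zz}))}
        rng = np.random.default_rng(self.seed)
        core = SchNetCore(
            vocab,
            embed_dim=self.embed_dim,
            n_interactions=self.n_interactions,
            n_rbf=self.n_rbf,
            cutoff=self.cutoff,
            readout_hidden=self.readout_hidden,
            rng=rng,
        )
        self.target_mean_ = float(y.mean()) if self.standardize_targets else 0.0
        self.target_std_ = float(y.std()) or 1.0 if self.standardize_targets else 1.0
        t_train = (y - self.target_mean_) / self.target_std_
        graphs = self._graphs(X)
        val_graphs = self._graphs(X_val) if X_val is not None else None
        t_val = (
            (np.asarray(y_val, dtype=float) - self.target_mean_) / self.target_std_
            if y_val is not None
            else None
        )

        # Adam state
        m = core.zero_grads()
        v = core.zero_grads()
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = []
        best_val = np.inf
        best_epoch = -1
        best_params = {k: p.copy() for k, p in core.params.items()}
        bad_epochs = 0
        idx = np.arange(len(graphs))
        for epoch in range(1, self.max_epochs + 1):
            rng.shuffle(idx)
            epoch_loss = 0.0
            for start in range(0, len(idx), self.batch_size):
                batch = idx[start : start + self.batch_size]
                loss, grads = self._loss_and_grads(
                    core, [graphs[i] for i in batch], t_train[batch], accumulate=True
                )
                if not np.isfinite(loss):
                    raise ConfrankError(
                        f"NaN/inf loss at epoch {epoch}, step {step}; "
                        "reduce the learning rate or standardize targets"
                    )
                epoch_loss += loss * len(batch)
                step += 1
                for k in core.params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    core.params[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            train_loss = epoch_loss / len(idx)
            if val_graphs is not None:
                val_loss, _ = self._loss_and_grads(core, val_graphs, t_val, accumulate=False)
            else:
                val_loss = train_loss
            history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_params = {k: p.copy() for k, p in core.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if val_graphs is not None and bad_epochs >= self.patience:
                    break
        core.params = best_params
        self.core_ = core
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "core_")
        out = np.asarray(self.core_.forward_batch(self._graphs(X)), dtype=float)
        return out * self.target_std_ + self.target_mean_

    def predict_conformer(self, atomic_numbers, conf: ConformerRecord) -> float:
        return float(self.predict([(np.asarray(atomic_numbers), conf.coords)])[0])


def predict_and_rank(ensemble: LabelledEnsemble, model: SchNetRegressor):
    """Rank an ensemble by ascending predicted ARMSD_bio (ties by gen_order)."""
    from .ranking import order_by_scores

    scores = model.predict(ensemble_to_samples(ensemble))
    return order_by_scores(ensemble, scores, "atnn")


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(model: SchNetRegressor, path: str | Path) -> None:
    """Self-describing weight container: config JSON + npz weights."""
    check_is_fitted(model, "core_")
    path = Path(path)
    config = {
        "params": model.get_params(),
        "vocab": {str(k): v for k, v in model.core_.vocab.items()},
        "target_mean": model.target_mean_,
        "target_std": model.target_std_,
        "best_epoch": model.best_epoch_,
    }
    path.with_suffix(".json").write_text(json.dumps(config, indent=1))
    np.savez(path.with_suffix(".npz"), **model.core_.params)


def load_checkpoint(path: str | Path) -> SchNetRegressor:
    path = Path(path)
    config = json.loads(path.with_suffix(".json").read_text())
    model = SchNetRegressor(**config["params"])
    vocab = {int(k): v for k, v in config["vocab"].items()}
    model.core_ = SchNetCore(
        vocab,
        embed_dim=model.embed_dim,
        n_interactions=model.n_interactions,
        n_rbf=model.n_rbf,
        cutoff=model.cutoff,
        readout_hidden=model.readout_hidden,
    )
    with np.load(path.with_suffix(".npz")) as data:
        model.core_.params = {k: data[k] for k in data.files}
    model.target_mean_ = config["target_mean"]
    model.target_std_ = config["target_std"]
    model.best_epoch_ = config["best_epoch"]
    model.history_ = pd.DataFrame()
    return model
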