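"""Scikit-learn style estimator wrapping the CNN-attention-BiLSTM network."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import network
from .network import Adam, ModelConfig
from .seq_data import SequenceDataset


class AttentiveBindingClassifier(BaseEstimator):
    """Multi-task TF binding-site classifier with positional attention.

    A convolutional layer scans one-hot DNA for motif-like patterns, an
    attention layer learns which pooled positions matter, a bidirectional
    LSTM aggregates the scaled feature map, and a dense head emits one
    binding probability per ChIP-seq task.  Trained with Adam on mean
    binary cross-entropy.

    Parameters
    ----------
    kernel_len, n_kernels, pool_window, lstm_hidden, fc_dim
        Architecture dimensions; defaults are the full-scale values
        (kernel length 26, 320 kernels, pool window 13, per-direction LSTM
        width = kernel count, 695 hidden units).  ``lstm_hidden=None``
        means "equal to n_kernels".
    use_attention
        Ablation switch; False removes the attention layer (the activation
        map feeds the BiLSTM unscaled), giving a DanQ-shaped network.
    learning_rate, batch_size, n_epochs
        Adam step size (default 0.001), minibatch size (default 100) and
        number of passes over the training set (default 18).
    random_state
        Seed for parameter initialization and batch shuffling.  Fixed
        seed => bit-identical training runs.

    Attributes
    ----------
    params_ : dict of ndarray
        Trained tensors (kernels ``F``, attention key ``p`` and bias
        ``b_att``, BiLSTM weights, dense weights).
    config_ : ModelConfig
        Resolved architecture (includes the derived pooled length t).
    history_ : DataFrame
        Per-epoch train/validation loss log.
    best_epoch_ : int
        Epoch whose validation loss selected the retained checkpoint
        (last epoch when no validation data was supplied).
    n_tasks_ : int
    """

    def __init__(self, *, kernel_len: int = 26, n_kernels: int = 320,
                 pool_window: int = 13, lstm_hidden: int | None = None,
                 fc_dim: int = 695, use_attention: bool = True,
                 learning_rate: float = 1e-3, batch_size: int = 100,
                 n_epochs: int = 18, random_state: int | None = None,
                 dtype: str = "float32"):
        self.kernel_len = kernel_len
        self.n_kernels = n_kernels
        self.pool_window = pool_window
        self.lstm_hidden = lstm_hidden
        self.fc_dim = fc_dim
        self.use_attention = use_attention
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.random_state = random_state
        self.dtype = dtype

    # -- internals ---------------------------------------------------------

    def _validate_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[2] != 4:
            raise ValueError("X must have shape (n_sequences, seq_length, 4)")
        if fitted and X.shape[1] != self.config_.seq_length:
            raise ValueError(
                f"sequence length {X.shape[1]} != fitted {self.config_.seq_length}")
        return X

    def _epoch_loss(self, X, y, batch: int) -> float:
        total, n = 0.0, 0
        for i in range(0, len(X), batch):
            yh = network.forward(X[i:i + batch], self.params_, self.config_)["y_hat"]
            total += network.bce_loss(yh, y[i:i + batch]) * len(yh)
            n += len(yh)
        return total / n

    # -- estimator API -----------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        """Train on one-hot sequences X (n, S, 4) and binary labels y (n, T).

        When ``validation_data`` is given, validation loss is computed each
        epoch and the best-validation checkpoint is retained; otherwise the
        final-epoch parameters are kept.
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")

        self.config_ = ModelConfig(
            seq_length=X.shape[1], kernel_len=self.kernel_len,
            n_kernels=self.n_kernels, pool_window=self.pool_window,
            lstm_hidden=self.lstm_hidden, fc_dim=self.fc_dim,
            n_tasks=y.shape[1], use_attention=self.use_attention)
        self.n_tasks_ = y.shape[1]
        self.n_features_in_ = X.shape[1] * 4

        rng = np.random.default_rng(self.random_state)
        dt = np.dtype(self.dtype)
        self.params_ = network.init_params(self.config_, rng, dtype=dt)
        opt = Adam(self.params_, lr=self.learning_rate)
        X = X.astype(dt, copy=False)

        val = None
        if validation_data is not None:
            Xv, yv = validation_data
            val = (self._validate_X(Xv, fitted=True).astype(dt, copy=False),
                   np.asarray(yv).reshape(len(Xv), -1))

        log = []
        best_loss, best_params, best_epoch = np.inf, None, 0
        for epoch in range(1, self.n_epochs + 1):
            order = rng.permutation(len(X))
            running, seen = 0.0, 0
            for i in range(0, len(X), self.batch_size):
                idx = order[i:i + self.batch_size]
                out = network.forward(X[idx], self.params_, self.config_,
                                      return_cache=True)
                loss = network.bce_loss(out["y_hat"], y[idx])
                grads = network.backward(y[idx], out["cache"], self.params_,
                                         self.config_)
                opt.step(self.params_, grads)
                running += loss * len(idx)
                seen += len(idx)
            train_loss = running / seen
            if val is not None:
                valid_loss = self._epoch_loss(val[0], val[1], self.batch_size)
                if valid_loss < best_loss:
                    best_loss = valid_loss
                    best_params = {k: v.copy() for k, v in self.params_.items()}
                    best_epoch = epoch
            else:
                valid_loss = np.nan
            log.append({"epoch": epoch, "train_loss": train_loss,
                        "valid_loss": valid_loss})
        # final-epoch parameters are kept alongside the best-validation
        # checkpoint: predictions use the checkpoint, kernel motif
        # harvesting prefers the final state (kernels keep sharpening
        # after the validation optimum)
        self.final_params_ = self.params_
        if best_params is not None:
            self.params_ = best_params
            self.best_epoch_ = best_epoch
        else:
            self.best_epoch_ = self.n_epochs
        self.history_ = pd.DataFrame(log)
        return self

    def predict_proba(self, X: np.ndarray, batch_size: int | None = None
                      ) -> np.ndarray:
        """Per-task binding probabilities, shape (n, n_tasks)."""
        check_is_fitted(self, "params_")
        X = self._validate_X(X, fitted=True)
        bs = batch_size or self.batch_size
        out = [network.forward(X[i:i + bs], self.params_, self.config_)["y_hat"]
               for i in range(0, len(X), bs)]
        return np.concatenate(out) if out else np.empty((0, self.n_tasks_))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Binary per-task calls at the given probability threshold."""
        return (self.predict_proba(X) > threshold).astype(np.uint8)

    def attention_vectors(self, X: np.ndarray, batch_size: int | None = None
                          ) -> np.ndarray:
        """Attention vector per sequence, shape (n, t); rows sum to 1.

        For the no-attention ablation, returns the uniform vector 1/t for
        every sequence (the effective positional weighting).
        """
        check_is_fitted(self, "params_")
        X = self._validate_X(X, fitted=True)
        t = self.config_.pooled_length
        if not self.config_.use_attention:
            return np.full((len(X), t), 1.0 / t)
        bs = batch_size or self.batch_size
        out = [network.forward(X[i:i + bs], self.params_, self.config_)["attention"]
               for i in range(0, len(X), bs)]
        return np.concatenate(out) if out else np.empty((0, t))

    def activation_maps(self, X: np.ndarray) -> np.ndarray:
        """Pooled activation maps C, shape (n, t, h)."""
        check_is_fitted(self, "params_")
        return network.conv_pool_forward(self._validate_X(X, fitted=True),
                                         self.params_, self.config_)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Macro-average AUROC over tasks with both classes present."""
        from .metrics import evaluate_scores
        per_task, macro = evaluate_scores(self.predict_proba(X), np.asarray(y))
        return macro["auroc"]

    # -- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write checkpoint: parameter arrays + JSON config sidecar."""
        check_is_fitted(self, "params_")
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "params.npz", **self.params_)
        final = getattr(self, "final_params_", None)
        if final is not None and final is not self.params_:
            np.savez(out / "final_params.npz", **final)
        cfg = {
            "model_config": {k: getattr(self.config_, k) for k in (
                "seq_length", "kernel_len", "n_kernels", "pool_window",
                "lstm_hidden", "fc_dim", "n_tasks", "use_attention")},
            "hyper": {"learning_rate": self.learning_rate,
                      "batch_size": self.batch_size, "n_epochs": self.n_epochs,
                      "random_state": self.random_state, "dtype": self.dtype},
            "best_epoch": getattr(self, "best_epoch_", None),
        }
        (out / "config.json").write_text(json.dumps(cfg, indent=2))
        if hasattr(self, "history_"):
            self.history_.to_csv(out / "history.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "AttentiveBindingClassifier":
        ind = Path(indir)
        cfg = json.loads((ind / "config.json").read_text())
        mc = cfg["model_config"]
        est = cls(kernel_len=mc["kernel_len"], n_kernels=mc["n_kernels"],
                  pool_window=mc["pool_window"], lstm_hidden=mc["lstm_hidden"],
                  fc_dim=mc["fc_dim"], use_attention=mc["use_attention"],
                  **cfg["hyper"])
        est.config_ = ModelConfig(**mc)
        est.n_tasks_ = mc["n_tasks"]
        est.n_features_in_ = mc["seq_length"] * 4
        with np.load(ind / "params.npz") as npz:
            est.params_ = {k: npz[k] for k in npz.files}
        final = ind / "final_params.npz"
        if final.exists():
            with np.load(final) as npz:
                est.final_params_ = {k: npz[k] for k in npz.files}
        est.best_epoch_ = cfg.get("best_epoch")
        hist = ind / "history.tsv"
        if hist.exists():
            est.history_ = pd.read_csv(hist, sep="\t")
        return est


def train(dataset: SequenceDataset, *, epochs: int = 18, seed: int | None = None,
          use_attention: bool = True, **arch) -> AttentiveBindingClassifier:
    """Train a classifier on a dataset's train split, validating on valid.

    ``arch`` forwards architecture keywords (kernel_len, n_kernels, ...) to
    :class:`AttentiveBindingClassifier`.
    """
    tr = dataset.subset("train")
    if len(tr) == 0:
        raise ValueError("dataset has no train split")
    va = dataset.subset("valid")
    est = AttentiveBindingClassifier(n_epochs=epochs, random_state=seed,
                                     use_attention=use_attention, **arch)
    est.fit(tr.X, tr.y,
            validation_data=(va.X, va.y) if len(va) else None)
    return est
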