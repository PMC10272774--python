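"""Continuous joint-angle regression from synergy activation features.

A stacked bidirectional LSTM (default: five Bi-LSTM layers of 48 hidden
units each, dropout 0.3 after every recurrent layer) maps the r
activation-coefficient time courses to the angle sequence, one output
per timestep.  Training minimizes MSE on standardized features and
angles over sliding windows; the reported accuracy metric downstream is
Pearson CC, which is invariant to the standardization.

The network runs on the in-package numpy Bi-LSTM engine
(:mod:`synergykit._lstm`); training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _lstm
from ._matching import match_columns
from .decompose import SynergyDecomposition
from .errors import ArgumentError
from .kinematics import AngleTrace


@dataclass
class RegressorConfig:
    """Bi-LSTM hyperparameters.

    The architecture constants (5 layers x 48 units, dropout 0.3) are
    the network used throughout; window/stride/epochs/learning rate are
    training-loop choices, see docs/methods.md.
    """

    n_layers: int = 5
    hidden_units: int = 48
    dropout: float = 0.3
    window_length: int = 200
    stride: int = 50
    epochs: int = 40
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ArgumentError("dropout must be in [0, 1)")
        if self.window_length < 1 or self.stride < 1:
            raise ArgumentError("window_length and stride must be positive")
        if self.n_layers < 1 or self.hidden_units < 1:
            raise ArgumentError("n_layers and hidden_units must be positive")


class BiLSTMRegressor(RegressorMixin, BaseEstimator):
    """Sequence-to-sequence Bi-LSTM angle regressor (scikit-learn API).

    ``fit(X, y)`` takes the feature sequence X (n_samples x n_features,
    time-ordered) and the aligned angle y (n_samples,); ``predict(X)``
    returns one angle per input sample, processing the whole sequence in
    one pass (the recurrent network is length-agnostic).  Features and
    targets are standardized internally with training-set statistics.
    Dropout is active only during training; prediction is deterministic.
    """

    def __init__(
        self,
        n_layers: int = 5,
        hidden_units: int = 48,
        dropout: float = 0.3,
        window_length: int = 200,
        stride: int = 50,
        epochs: int = 40,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.window_length = window_length
        self.stride = stride
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _windows(self, n):
        W, s = self.window_length, self.stride
        starts = list(range(0, n - W + 1, s))
        if starts and starts[-1] != n - W:
            starts.append(n - W)  # cover the tail
        return starts

    def _standardize_X(self, X):
        return (X - self.x_mean_) / self.x_std_

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2:
            raise ArgumentError("X must be 2-D (samples x features)")
        if X.shape[0] != y.size:
            raise ArgumentError("X and y must be aligned sample-for-sample")
        n, f = X.shape
        if n < self.window_length:
            raise ArgumentError(
                f"need at least window_length={self.window_length} samples, "
                f"got {n}"
            )
        self.n_features_in_ = f
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0

        Xs = self._standardize_X(X).astype(np.float32)
        ys = ((y - self.y_mean_) / self.y_std_).astype(np.float32)

        starts = self._windows(n)
        W = self.window_length
        Xw = np.stack([Xs[s : s + W] for s in starts])          # (N, W, f)
        yw = np.stack([ys[s : s + W] for s in starts])          # (N, W)

        rng = np.random.default_rng(self.random_state)
        params, out = _lstm.init_bilstm_params(
            f, self.hidden_units, self.n_layers, rng
        )
        optim = _lstm.Adam(lr=self.learning_rate)
        N = Xw.shape[0]
        bs = min(self.batch_size, N)
        log = []
        for _ in range(self.epochs):
            order = rng.permutation(N)
            epoch_loss = 0.0
            for b0 in range(0, N, bs):
                idx = order[b0 : b0 + bs]
                y_pred, hidden, caches = _lstm.bilstm_forward(
                    Xw[idx], params, out,
                    dropout=self.dropout, rng=rng, train=True,
                )
                loss, dy = _lstm.mse_loss_and_grad(y_pred, yw[idx])
                grads, grads_out = _lstm.bilstm_backward(
                    dy.astype(np.float32), hidden, caches, params, out
                )
                optim.step(
                    _lstm.flatten_params(params, out),
                    _lstm.flatten_params(grads, grads_out),
                )
                epoch_loss += loss * idx.size
            log.append(epoch_loss / N)
        self.params_ = params
        self.out_ = out
        self.training_log_ = np.asarray(log)
        self.n_parameters_ = _lstm.count_params(params, out)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ArgumentError(
                f"expected 2-D X with {self.n_features_in_} features"
            )
        Xs = self._standardize_X(X).astype(np.float32)[None]
        y_pred, _, _ = _lstm.bilstm_forward(
            Xs, self.params_, self.out_, train=False
        )
        pred = y_pred[0].astype(np.float64) * self.y_std_ + self.y_mean_
        if not np.all(np.isfinite(pred)):
            raise ArgumentError("non-finite prediction")
        return pred

    # -- persistence -------------------------------------------------------

    def save(self, path):
        """Serialize the fitted model to an .npz archive (bit-exact)."""
        check_is_fitted(self, "params_")
        arrays = {
            f"layer{i}_{k}": v
            for i, lp in enumerate(self.params_)
            for k, v in lp.items()
        }
        arrays["out_Wo"] = self.out_["Wo"]
        arrays["out_bo"] = self.out_["bo"]
        arrays["x_mean"] = self.x_mean_
        arrays["x_std"] = self.x_std_
        arrays["y_stats"] = np.array([self.y_mean_, self.y_std_])
        arrays["training_log"] = self.training_log_
        arrays["config"] = np.array(
            [
                self.n_layers, self.hidden_units, self.dropout,
                self.window_length, self.stride, self.epochs,
                self.learning_rate, self.batch_size, self.random_state,
                self.n_features_in_,
            ],
            dtype=np.float64,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "BiLSTMRegressor":
        data = np.load(path)
        cfg = data["config"]
        model = cls(
            n_layers=int(cfg[0]), hidden_units=int(cfg[1]),
            dropout=float(cfg[2]), window_length=int(cfg[3]),
            stride=int(cfg[4]), epochs=int(cfg[5]),
            learning_rate=float(cfg[6]), batch_size=int(cfg[7]),
            random_state=int(cfg[8]),
        )
        model.n_features_in_ = int(cfg[9])
        model.params_ = [
            {
                k: data[f"layer{i}_{k}"]
                for k in ("Wx_f", "Wh_f", "b_f", "Wx_b", "Wh_b", "b_b")
            }
            for i in range(model.n_layers)
        ]
        model.out_ = {"Wo": data["out_Wo"], "bo": data["out_bo"]}
        model.x_mean_ = data["x_mean"]
        model.x_std_ = data["x_std"]
        model.y_mean_, model.y_std_ = map(float, data["y_stats"])
        model.training_log_ = data["training_log"]
        model.n_parameters_ = _lstm.count_params(model.params_, model.out_)
        return model


# ---------------------------------------------------------------------------
# functional wrappers over the estimator
# ---------------------------------------------------------------------------

def build_features(
    decomp: SynergyDecomposition,
    reference: SynergyDecomposition | None = None,
) -> np.ndarray:
    """Activation-coefficient feature sequence (r x n) from a decomposition.

    When ``reference`` (typically the training-day decomposition) is
    given, rows are reordered by greedy maximum-CC matching of the
    synergy columns so feature k always corresponds to the same synergy
    across sessions — factorization order is otherwise arbitrary.

    The factorization scale split between C and S is also arbitrary
    (C_k, S_k) ~ (C_k / a, a S_k), so each activation row is multiplied
    by the Euclidean norm of its synergy column; the resulting features
    are invariant to that ambiguity and hence comparable across
    sessions.
    """
    S = decomp.S * np.linalg.norm(decomp.C, axis=0)[:, None]
    if reference is not None:
        if reference.r != decomp.r or reference.C.shape != decomp.C.shape:
            raise ArgumentError("reference decomposition shape mismatch")
        perm, _ = match_columns(reference.C, decomp.C)
        S = S[perm]
    return np.asarray(S, dtype=float)


def train(
    features: np.ndarray,
    angles: AngleTrace,
    config: RegressorConfig | None = None,
) -> BiLSTMRegressor:
    """Train the Bi-LSTM on an (r x n) feature sequence and aligned angle."""
    config = config or RegressorConfig()
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ArgumentError("features must be 2-D (r x n)")
    if features.shape[1] != angles.n:
        raise ArgumentError("features and angles must be aligned")
    kwargs = asdict(config)
    kwargs["random_state"] = kwargs.pop("seed")
    model = BiLSTMRegressor(**kwargs)
    model.fit(features.T, angles.theta)
    return model


def predict(model: BiLSTMRegressor, features: np.ndarray,
            sampling_rate: float = 1.0) -> AngleTrace:
    """Predicted angle trace for an (r x n) feature sequence."""
    features = np.asarray(features, dtype=float)
    return AngleTrace(model.predict(features.T), sampling_rate)
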