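"""Velocity decoders for binned neural features.

Two decoders map a stream of normalized 10 ms feature bins to 2-D cursor
velocity:

* an optimal linear estimator (OLE) — ridge regression on a single time
  step's features, with the L2 penalty chosen by 3-fold cross-validation on
  contiguous temporal thirds (shuffling would leak autocorrelated samples
  across folds);
* a recurrent decoder — a single LSTM layer (76 units by default) followed
  by a 2-unit linear readout, trained with mean squared error and Adam.

Decoder output is smoothed with an exponential moving average and scaled by
a gain before it moves the cursor.  For retraining on closed-loop data the
intended velocity is approximated ReFIT-style: point the decoded-magnitude
vector from the cursor at the target, zeroed once the target is reached.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .signal_chain import NormalizerState

__all__ = [
    "OLEWeights",
    "fit_ole",
    "predict_ole",
    "RNNSpec",
    "LSTMDecoder",
    "train_rnn",
    "SmootherConfig",
    "smooth_and_scale",
    "relabel_intent",
    "save_ole",
    "load_ole",
]


# ---------------------------------------------------------------------------
# OLE (ridge regression)
# ---------------------------------------------------------------------------

@dataclass
class OLEWeights:
    """Linear velocity decoder: ``v = W @ z + b`` on normalized features."""

    W: np.ndarray  # 2 x F
    b: np.ndarray  # 2
    lambda_selected: float
    cv_errors: Dict[float, float] = field(default_factory=dict)
    normalizer: Optional[NormalizerState] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).reshape(2)
        if self.W.ndim != 2 or self.W.shape[0] != 2:
            raise ValueError("W must be 2 x F")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite decoder weights")


def _ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float,
                 fit_intercept: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form ridge with an unpenalized intercept (via centering)."""
    if fit_intercept:
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc, Yc = X - x_mean, Y - y_mean
    else:
        x_mean = np.zeros(X.shape[1])
        y_mean = np.zeros(Y.shape[1])
        Xc, Yc = X, Y
    F = X.shape[1]
    A = Xc.T @ Xc + lam * np.eye(F)
    if lam == 0.0 and np.linalg.matrix_rank(A) < F:
        raise np.linalg.LinAlgError("rank-deficient design with lambda = 0")
    coef = np.linalg.solve(A, Xc.T @ Yc)  # F x 2
    W = coef.T
    b = y_mean - W @ x_mean
    return W, b


def _contiguous_folds(n: int, k: int) -> List[np.ndarray]:
    """Index blocks of k contiguous temporal segments (sizes differ by <=1)."""
    edges = np.linspace(0, n, k + 1).round().astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(k)]


def fit_ole(X: np.ndarray, Y: np.ndarray,
            lambda_grid: Optional[Sequence[float]] = None,
            n_folds: int = 3, fit_intercept: bool = True,
            normalizer: Optional[NormalizerState] = None) -> OLEWeights:
    """Fit the OLE by ridge regression with cross-validated regularization.

    For each candidate penalty the mean squared validation error is computed
    over ``n_folds`` contiguous temporal folds; the minimizing penalty is
    selected and the final weights are refit on all data.  ``X`` is expected
    to be pre-normalized (z-scored) features, ``Y`` the N×2 velocities.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or Y.shape[1] != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X must be N x F and Y must be N x 2 with matching N")
    if X.shape[0] < n_folds:
        raise ValueError(f"need at least {n_folds} samples")
    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 3, 10)
    lambda_grid = [float(l) for l in lambda_grid]
    if any(l < 0 for l in lambda_grid):
        raise ValueError("penalties must be non-negative")

    folds = _contiguous_folds(X.shape[0], n_folds)
    cv_errors: Dict[float, float] = {}
    for lam in lambda_grid:
        errs = []
        try:
            for i in range(n_folds):
                val = folds[i]
                train = np.concatenate([folds[j] for j in range(n_folds) if j != i])
                W, b = _ridge_solve(X[train], Y[train], lam, fit_intercept)
                pred = X[val] @ W.T + b
                errs.append(np.mean((pred - Y[val]) ** 2))
        except np.linalg.LinAlgError:
            warnings.warn(f"lambda={lam:g} skipped: rank-deficient design")
            continue
        cv_errors[lam] = float(np.mean(errs))
    if not cv_errors:
        raise ValueError("no usable penalty in the grid")
    lam_best = min(cv_errors, key=lambda l: (cv_errors[l], l))
    W, b = _ridge_solve(X, Y, lam_best, fit_intercept)
    return OLEWeights(W=W, b=b, lambda_selected=lam_best,
                      cv_errors=cv_errors, normalizer=normalizer)


def predict_ole(weights: OLEWeights, features: np.ndarray) -> np.ndarray:
    """``v = W @ z + b`` for one normalized feature vector (or N of them)."""
    z = np.asarray(features, dtype=float)
    if z.shape[-1] != weights.W.shape[1]:
        raise ValueError(f"feature dimension {z.shape[-1]} != {weights.W.shape[1]}")
    return z @ weights.W.T + weights.b


def save_ole(weights: OLEWeights, path: str | Path) -> None:
    """Portable JSON container with shape and version metadata."""
    doc = {
        "format": "neuroloop-ole", "version": 1,
        "shape": list(weights.W.shape),
        "W": weights.W.tolist(), "b": weights.b.tolist(),
        "lambda": weights.lambda_selected,
    }
    if weights.normalizer is not None:
        doc["normalizer"] = {"mean": weights.normalizer.mean.tolist(),
                             "std": weights.normalizer.std.tolist(),
                             "epsilon": weights.normalizer.epsilon}
    Path(path).write_text(json.dumps(doc))


def load_ole(path: str | Path) -> OLEWeights:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "neuroloop-ole":
        raise ValueError("not an OLE decoder file")
    norm = None
    if "normalizer" in doc:
        n = doc["normalizer"]
        norm = NormalizerState(mean=np.array(n["mean"]), std=np.array(n["std"]),
                               epsilon=n["epsilon"])
    return OLEWeights(W=np.array(doc["W"]), b=np.array(doc["b"]),
                      lambda_selected=doc["lambda"], normalizer=norm)


# ---------------------------------------------------------------------------
# Recurrent decoder (LSTM + linear readout)
# ---------------------------------------------------------------------------

@dataclass
class RNNSpec:
    """Architecture and training hyperparameters for the recurrent decoder."""

    input_dim: int = 192
    hidden_units: int = 76
    output_dim: int = 2
    dropout: float = 0.0
    l2: float = 0.0
    seed: int = 0
    learning_rate: float = 3e-3
    max_epochs: int = 50
    plateau_patience: int = 8
    plateau_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.output_dim != 2:
            raise ValueError("output_dim must be 2 (cursor velocity)")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMDecoder:
    """Single-layer LSTM + linear readout, trained by BPTT with Adam.

    Fully deterministic given ``spec.seed``.  Supports both whole-sequence
    (training, offline) and stateful single-step (closed-loop) inference;
    the two are numerically identical on the same input sequence.
    """

    def __init__(self, spec: RNNSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        F, H = spec.input_dim, spec.hidden_units
        s_x, s_h = 1.0 / np.sqrt(F), 1.0 / np.sqrt(H)
        self.params: Dict[str, np.ndarray] = {
            "Wx": rng.uniform(-s_x, s_x, size=(4 * H, F)),
            "Wh": rng.uniform(-s_h, s_h, size=(4 * H, H)),
            "b": np.zeros(4 * H),
            "Wo": rng.uniform(-s_h, s_h, size=(spec.output_dim, H)),
            "bo": np.zeros(spec.output_dim),
        }
        # forget-gate bias of 1 is the usual stabilizer for short sequences
        self.params["b"][H:2 * H] = 1.0
        self._rng = rng
        self.reset_state()
        self.train_losses: List[float] = []

    # -- inference -----------------------------------------------------

    def reset_state(self) -> None:
        H = self.spec.hidden_units
        self._h = np.zeros(H)
        self._c = np.zeros(H)

    def step(self, x: np.ndarray) -> np.ndarray:
        """One 10 ms step; carries (h, c) across calls until reset."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.spec.input_dim,):
            raise ValueError(f"expected input of shape ({self.spec.input_dim},)")
        h, c, _ = self._forward_step(x[None, :], self._h[None, :], self._c[None, :])
        self._h, self._c = h[0], c[0]
        return self.params["Wo"] @ self._h + self.params["bo"]

    def predict_sequence(self, X: np.ndarray) -> np.ndarray:
        """Batch inference over a T×F sequence from a zero initial state."""
        X = np.asarray(X, dtype=float)
        H = self.spec.hidden_units
        h = np.zeros((1, H))
        c = np.zeros((1, H))
        out = np.empty((X.shape[0], self.spec.output_dim))
        for t in range(X.shape[0]):
            h, c, _ = self._forward_step(X[t:t + 1], h, c)
            out[t] = self.params["Wo"] @ h[0] + self.params["bo"]
        return out

    def _forward_step(self, x, h_prev, c_prev):
        H = self.spec.hidden_units
        z = x @ self.params["Wx"].T + h_prev @ self.params["Wh"].T + self.params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return h, c, (i, f, g, o, c_prev)

    # -- training ------------------------------------------------------

    def _forward_backward(self, X: np.ndarray, Y: np.ndarray,
                          dropout_masks: Optional[np.ndarray]) -> Tuple[float, Dict[str, np.ndarray]]:
        """Loss and gradients for a batch of sequences (B×T×F, B×T×2)."""
        p = self.params
        B, T, F = X.shape
        H = self.spec.hidden_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        preds = np.empty((B, T, self.spec.output_dim))
        for t in range(T):
            h_prev, c_prev = h, c
            h, c, gates = self._forward_step(X[:, t], h_prev, c_prev)
            h_out = h * dropout_masks[:, t] if dropout_masks is not None else h
            preds[:, t] = h_out @ p["Wo"].T + p["bo"]
            cache.append((h_prev, c_prev, h, c, h_out, gates))
        err = preds - Y
        n_total = err.size
        loss = float(np.sum(err ** 2) / n_total)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, h_t, c_t, h_out, (i, f, g, o, _) = cache[t]
            dy = 2.0 * err[:, t] / n_total
            grads["Wo"] += dy.T @ h_out
            grads["bo"] += dy.sum(axis=0)
            dh = dy @ p["Wo"]
            if dropout_masks is not None:
                dh = dh * dropout_masks[:, t]
            dh = dh + dh_next
            tanh_c = np.tanh(c_t)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            grads["Wx"] += dz.T @ X[:, t]
            grads["Wh"] += dz.T @ h_prev
            grads["b"] += dz.sum(axis=0)
            dh_next = dz @ p["Wh"]
            dc_next = dc * f
        if self.spec.l2 > 0:
            for k in ("Wx", "Wh", "Wo"):
                grads[k] += 2.0 * self.spec.l2 * p[k]
                loss += self.spec.l2 * float(np.sum(p[k] ** 2))
        return loss, grads

    def fit(self, X: np.ndarray, Y: np.ndarray, verbose: bool = False) -> "LSTMDecoder":
        """Train on sequences (B×T×F vs B×T×2) until plateau or max epochs.

        Inputs are expected to be normalized with the training data's own
        mean and standard deviation.  Aborts on a non-finite loss.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 3 or Y.ndim != 3 or X.shape[:2] != Y.shape[:2]:
            raise ValueError("X must be B x T x F and Y must be B x T x 2")
        spec = self.spec
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best = np.inf
        stale = 0
        for epoch in range(1, spec.max_epochs + 1):
            masks = None
            if spec.dropout > 0:
                keep = 1.0 - spec.dropout
                masks = (self._rng.random((X.shape[0], X.shape[1],
                                           spec.hidden_units)) < keep) / keep
            loss, grads = self._forward_backward(X, Y, masks)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"last finite losses: {self.train_losses[-3:]}")
            self.train_losses.append(loss)
            for k in self.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                m_hat = m[k] / (1 - beta1 ** epoch)
                v_hat = v[k] / (1 - beta2 ** epoch)
                self.params[k] -= spec.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            if verbose:
                print(f"epoch {epoch:3d}  mse {loss:.6f}")
            if loss < best - spec.plateau_tol:
                best = loss
                stale = 0
            else:
                stale += 1
                if stale >= spec.plateau_patience:
                    break
        self.reset_state()
        return self


def train_rnn(spec: RNNSpec, X: np.ndarray, Y: np.ndarray,
              verbose: bool = False) -> LSTMDecoder:
    """Convenience wrapper: build and fit an :class:`LSTMDecoder`."""
    return LSTMDecoder(spec).fit(X, Y, verbose=verbose)


# ---------------------------------------------------------------------------
# Output smoothing and intent relabeling
# ---------------------------------------------------------------------------

@dataclass
class SmootherConfig:
    """Exponential moving average + gain on decoded velocity.

    ``s_t = alpha * v_t + (1 - alpha) * s_{t-1}``, output ``gain * s_t``.
    alpha = 1 disables memory; the state starts at zero velocity.
    """

    alpha: float = 0.3
    gain: float = 1.0
    state: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        self.state = np.asarray(self.state, dtype=float).reshape(2)


def smooth_and_scale(v_raw: np.ndarray, cfg: SmootherConfig) -> np.ndarray:
    """Advance the smoother by one step and return the scaled output."""
    v = np.asarray(v_raw, dtype=float).reshape(2)
    cfg.state = cfg.alpha * v + (1.0 - cfg.alpha) * cfg.state
    return cfg.gain * cfg.state


def relabel_intent(cursor: np.ndarray, target: np.ndarray,
                   decoded: np.ndarray, on_target: bool) -> np.ndarray:
    """ReFIT-style intended velocity for decoder retraining.

    Points from cursor to target with the decoded prediction's magnitude;
    zero once the target is reached (or in the degenerate cursor == target
    case).
    """
    if on_target:
        return np.zeros(2)
    cursor = np.asarray(cursor, dtype=float).reshape(2)
    target = np.asarray(target, dtype=float).reshape(2)
    delta = target - cursor
    dist = np.linalg.norm(delta)
    if dist == 0.0:
        return np.zeros(2)
    return delta / dist * np.linalg.norm(np.asarray(decoded, dtype=float))
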