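"""Single-hidden-layer back-propagation perceptron.

The network used for classification throughout: four hidden units by
default, logistic sigmoid on both layers, trained by classic online
(per-pattern) back-propagation of squared error with momentum. Exposed
statsmodels-style: :class:`Perceptron` is built from data and ``fit()``
returns a :class:`PerceptronResults` carrying the weights, the training
error history and prediction/serialisation methods.

The inner training loop is JIT-compiled with numba when available; a pure
NumPy/Python implementation of the identical update order is the fallback.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@dataclass(frozen=True)
class TrainConfig:
    """Back-propagation hyperparameters.

    Defaults are standard choices for small bounded tabular problems:
    learning rate 0.1, momentum 0.9, 500 epochs, seeded uniform(-0.5, 0.5)
    weight initialisation, per-epoch pattern shuffling. ``early_stop_tol``
    stops training once the epoch-mean squared error falls to or below it
    (0 disables early stopping).
    """

    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 500
    shuffle: bool = True
    seed: int = 0
    early_stop_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


@njit(cache=False)
def _backprop_kernel(X, y, W1, b1, W2, b2arr, perms, lr, mom, tol):
    n, d = X.shape
    h = b1.shape[0]
    vW1 = np.zeros((h, d))
    vb1 = np.zeros(h)
    vW2 = np.zeros(h)
    vb2 = 0.0
    b2 = b2arr[0]
    n_epochs = perms.shape[0]
    errors = np.empty(n_epochs)
    epochs_run = 0
    for e in range(n_epochs):
        sq = 0.0
        for t in range(n):
            i = perms[e, t]
            x = X[i]
            a1 = np.empty(h)
            for j in range(h):
                s = b1[j]
                for k in range(d):
                    s += W1[j, k] * x[k]
                a1[j] = 1.0 / (1.0 + np.exp(-s))
            s2 = b2
            for j in range(h):
                s2 += W2[j] * a1[j]
            out = 1.0 / (1.0 + np.exp(-s2))
            err = y[i] - out
            sq += err * err
            dout = err * out * (1.0 - out)
            # hidden layer first, using the pre-update output weights
            for j in range(h):
                dh = a1[j] * (1.0 - a1[j]) * W2[j] * dout
                vb1[j] = mom * vb1[j] + lr * dh
                b1[j] += vb1[j]
                for k in range(d):
                    vW1[j, k] = mom * vW1[j, k] + lr * dh * x[k]
                    W1[j, k] += vW1[j, k]
            for j in range(h):
                vW2[j] = mom * vW2[j] + lr * dout * a1[j]
                W2[j] += vW2[j]
            vb2 = mom * vb2 + lr * dout
            b2 += vb2
        errors[e] = sq / n
        epochs_run = e + 1
        if errors[e] <= tol:
            break
    b2arr[0] = b2
    return errors[:epochs_run].copy(), epochs_run


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class Perceptron:
    """Model object: a 1-hidden-layer sigmoid MLP bound to (endog, exog).

    Parameters
    ----------
    endog : array (n,)
        Binary target; the case class is coded 1.
    exog : array (n, d)
        Bounded inputs in [0, 1] (one-hot genotype indicators plus the
        scaled micronucleus frequency).
    hidden : int
        Hidden-layer width (default 4).
    """

    def __init__(self, endog, exog, hidden: int = 4):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-D with one row per endog entry")
        if self.exog.min(initial=0.0) < 0 or self.exog.max(initial=0.0) > 1:
            raise ValueError("exog entries must lie in [0, 1]")
        classes = set(np.unique(self.endog))
        if not classes <= {0.0, 1.0}:
            raise ValueError("endog must be binary (0/1)")
        if len(classes) < 2:
            raise ValueError("endog must contain both classes")
        if hidden < 1:
            raise ValueError("hidden size must be >= 1")
        self.hidden = int(hidden)

    def fit(self, cfg: TrainConfig | None = None) -> "PerceptronResults":
        cfg = cfg or TrainConfig()
        n, d = self.exog.shape
        rng = np.random.default_rng(cfg.seed)
        W1 = rng.uniform(-0.5, 0.5, size=(self.hidden, d))
        b1 = rng.uniform(-0.5, 0.5, size=self.hidden)
        W2 = rng.uniform(-0.5, 0.5, size=self.hidden)
        b2 = np.array([rng.uniform(-0.5, 0.5)])
        if cfg.shuffle:
            perms = np.vstack([rng.permutation(n) for _ in range(cfg.max_epochs)])
        else:
            perms = np.tile(np.arange(n), (cfg.max_epochs, 1))
        errors, epochs_run = _backprop_kernel(
            self.exog,
            self.endog,
            W1,
            b1,
            W2,
            b2,
            perms.astype(np.int64),
            cfg.learning_rate,
            cfg.momentum,
            cfg.early_stop_tol,
        )
        return PerceptronResults(
            model=self,
            W1=W1,
            b1=b1,
            W2=W2,
            b2=float(b2[0]),
            error_history=np.asarray(errors),
            epochs_run=int(epochs_run),
            config=cfg,
        )


@dataclass
class PerceptronResults:
    """Trained weights plus diagnostics; the frozen-weight predictor."""

    model: Perceptron | None
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    error_history: np.ndarray
    epochs_run: int
    config: TrainConfig | None = None

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    def predict(self, X) -> np.ndarray:
        """Output scores strictly in (0, 1) for rows of ``X``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"input width {X.shape[1]} does not match training width {self.n_inputs}"
            )
        a1 = _sigmoid(X @ self.W1.T + self.b1)
        return _sigmoid(a1 @ self.W2 + self.b2)

    def summary(self) -> str:
        lines = [
            "Back-propagation perceptron results",
            "===================================",
            f"architecture      : {self.n_inputs} -> {self.hidden} -> 1 (logistic)",
            f"epochs run        : {self.epochs_run}",
            f"initial epoch MSE : {self.error_history[0]:.6f}",
            f"final epoch MSE   : {self.error_history[-1]:.6f}",
        ]
        if self.config is not None:
            lines.append(
                f"training          : lr={self.config.learning_rate}, "
                f"momentum={self.config.momentum}, shuffle={self.config.shuffle}, "
                f"seed={self.config.seed}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        """Plain-text weight file with a versioned header."""
        with open(path, "w") as fh:
            fh.write("folatenet-perceptron v1\n")
            fh.write(f"{self.n_inputs} {self.hidden}\n")
            np.savetxt(fh, self.W1.reshape(1, -1))
            np.savetxt(fh, self.b1.reshape(1, -1))
            np.savetxt(fh, self.W2.reshape(1, -1))
            fh.write(f"{self.b2!r}\n")

    @classmethod
    def load(cls, path) -> "PerceptronResults":
        with open(path) as fh:
            header = fh.readline().strip()
            if header != "folatenet-perceptron v1":
                raise ValueError(f"unrecognised weight file header: {header!r}")
            d, h = map(int, fh.readline().split())
            W1 = np.loadtxt(io.StringIO(fh.readline())).reshape(h, d)
            b1 = np.atleast_1d(np.loadtxt(io.StringIO(fh.readline())))
            W2 = np.atleast_1d(np.loadtxt(io.StringIO(fh.readline())))
            b2 = float(fh.readline())
        return cls(None, W1, b1, W2, b2, np.array([np.nan]), 0, None)


def train_mlp(X, y, cfg: TrainConfig | None = None, hidden: int = 4) -> PerceptronResults:
    """Convenience wrapper: build a :class:`Perceptron` and fit it."""
    return Perceptron(y, X, hidden=hidden).fit(cfg)


def predict_scores(res: PerceptronResults, X) -> np.ndarray:
    return res.predict(X)
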