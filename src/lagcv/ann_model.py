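"""Feed-forward network used to score hyperparameter settings.

The network is a fully connected multilayer perceptron with 1-3 sigmoidal
hidden layers and a single linear output, trained to minimize mean squared
error on the raw death-count scale under a fixed full-batch iteration
budget (default 50,000) with no early stopping, so every hyperparameter
cell gets the same training effort.  Training is delegated to
scikit-learn's ``MLPRegressor``; predictions afterwards use the package's
own forward pass on the extracted weights, which makes saved models
portable and bit-reproducible.

Unstated training details (activation, optimizer, step size) default to a
logistic hidden activation and full-batch Adam with step 3e-4 and a small
L2 penalty (1e-4); all are spec fields recorded on the fitted object.
The step size is chosen so that, at desk-scale budgets, training under a
no-association (permuted-outcome) null stays close to the mean predictor
— the regime the published permuted grids display, where every permuted
cell sits near the outcome variance.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.neural_network import MLPRegressor

from .features import ScalingRecord

HIDDEN_WIDTH_GRID = (6, 12, 24, 36, 48, 60)

_ACTIVATIONS = {
    "logistic": expit,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
    "identity": lambda z: z,
}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training budget of one grid cell."""

    hidden_layout: tuple[int, ...] = (12, 12)
    activation: str = "logistic"
    max_iterations: int = 50_000
    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        layout = tuple(int(w) for w in self.hidden_layout)
        if not 1 <= len(layout) <= 3:
            raise ValueError("1-3 hidden layers supported")
        if any(w < 1 for w in layout):
            raise ValueError("hidden widths must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.max_iterations < 1:
            raise ValueError("training budget must be >= 1")
        object.__setattr__(self, "hidden_layout", layout)

    def replace(self, **kw) -> "NetworkSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class FittedNetwork:
    """Learned weights plus the input-scaling record used at train time."""

    spec: NetworkSpec
    coefs: list[np.ndarray]  # one (fan_in, fan_out) matrix per layer
    intercepts: list[np.ndarray]
    input_names: list[str] | None
    scaling: ScalingRecord | None
    loss_curve: list[float]
    n_iterations: int
    y_offset: float = 0.0  # training-mean outcome; the net fits deviations

    @property
    def input_width(self) -> int:
        return self.coefs[0].shape[0]

    def predict(self, X) -> np.ndarray:
        """Predicted deaths/day, one value per row."""
        if isinstance(X, pd.DataFrame):
            if self.scaling is not None:
                X = self.scaling.apply(X)
            if self.input_names is not None:
                X = X[self.input_names]
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
        if arr.shape[1] != self.input_width:
            raise ValueError(
                f"input width {arr.shape[1]} != expected {self.input_width}"
            )
        act = _ACTIVATIONS[self.spec.activation]
        h = arr
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = act(h @ W + b)
        out = h @ self.coefs[-1] + self.intercepts[-1]
        return out.ravel() + self.y_offset

    def save(self, path: str | Path) -> Path:
        payload = {
            "spec": dataclasses.asdict(self.spec),
            "coefs": [W.tolist() for W in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "input_names": self.input_names,
            "scaling": None
            if self.scaling is None
            else {"center": self.scaling.center, "scale": self.scaling.scale},
            "loss_curve": list(map(float, self.loss_curve)),
            "n_iterations": self.n_iterations,
            "y_offset": self.y_offset,
        }
        Path(path).write_text(json.dumps(payload))
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "FittedNetwork":
        payload = json.loads(Path(path).read_text())
        spec_kw = payload["spec"]
        spec_kw["hidden_layout"] = tuple(spec_kw["hidden_layout"])
        scaling = payload["scaling"]
        return cls(
            spec=NetworkSpec(**spec_kw),
            coefs=[np.asarray(W) for W in payload["coefs"]],
            intercepts=[np.asarray(b) for b in payload["intercepts"]],
            input_names=payload["input_names"],
            scaling=None
            if scaling is None
            else ScalingRecord(center=scaling["center"], scale=scaling["scale"]),
            loss_curve=payload["loss_curve"],
            n_iterations=payload["n_iterations"],
            y_offset=payload.get("y_offset", 0.0),
        )


def train(X, y, spec: NetworkSpec, continuous=None) -> FittedNetwork:
    """Fit the network on (X, y) under the spec's fixed iteration budget.

    If ``X`` is a DataFrame and ``continuous`` names columns, those columns
    are standardized using *these* rows' statistics and the scaling record
    is stored on the returned network, so the same transform is applied at
    prediction time.  Indicator columns pass through untouched.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need at least two training rows")
    input_names = None
    scaling = None
    if isinstance(X, pd.DataFrame):
        input_names = list(X.columns)
        if continuous:
            center, scale = {}, {}
            for col in continuous:
                sd = float(X[col].std(ddof=0))
                if sd > 0:
                    center[col] = float(X[col].mean())
                    scale[col] = sd
            scaling = ScalingRecord(center=center, scale=scale)
            X = scaling.apply(X)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    if arr.shape[0] != len(y):
        raise ValueError("X and y row counts differ")
    if not (np.all(np.isfinite(arr)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")

    model = MLPRegressor(
        hidden_layer_sizes=spec.hidden_layout,
        activation=spec.activation,
        solver="adam",
        alpha=spec.weight_decay,
        batch_size=len(y),  # full batch: one weight update per pass
        learning_rate_init=spec.learning_rate,
        max_iter=spec.max_iterations,
        shuffle=False,
        random_state=spec.seed,
        tol=0.0,
        n_iter_no_change=spec.max_iterations,  # no early stopping
    )
    # Fit deviations from the training mean (equivalent to starting the
    # output bias at the mean level): the fixed budget is then spent on
    # structure, not on climbing to the outcome's scale.  Predictions and
    # MSEs stay on the raw deaths/day scale.
    y_offset = float(y.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # budget exhaustion is intended
        model.fit(arr, y - y_offset)
    return FittedNetwork(
        spec=spec,
        coefs=[np.array(W) for W in model.coefs_],
        intercepts=[np.array(b) for b in model.intercepts_],
        input_names=input_names,
        scaling=scaling,
        loss_curve=list(model.loss_curve_),
        n_iterations=int(model.n_iter_),
        y_offset=y_offset,
    )


def mse(predicted, observed) -> float:
    """Mean squared error, (deaths/day)^2."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must have equal non-zero length")
    return float(np.mean((p - o) ** 2))


def count_parameters(input_width: int, hidden_layout: tuple[int, ...]) -> int:
    """Trainable weights+biases of a dense network with a single output.

    Each dense layer contributes (fan_in + 1) * fan_out including its bias;
    the linear output adds (last_hidden + 1).  An empty layout is the
    linear model with input_width + 1 parameters.
    """
    if input_width < 1:
        raise ValueError("input width must be >= 1")
    widths = [input_width, *hidden_layout, 1]
    return int(sum((widths[i] + 1) * widths[i + 1] for i in range(len(widths) - 1)))
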