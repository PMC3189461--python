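"""Simple recurrent networks for one-step-ahead phoneme prediction.

Three architectures share one state layout:

* ``elman`` — the hidden layer's activations at t-1 are copied into a context
  layer (C1..Cn) that feeds the hidden layer, giving the network short-term
  memory of its own internal state.
* ``jordan`` — the context holds the delayed *output* instead, feeding the
  hidden layer through a single context unit.
* ``elman_jordan`` — the hybrid: Elman hidden-copy context, plus the Jordan
  output-context unit feeding the hidden layer, plus a delayed self-feedback
  connection on the output neuron. The extra feedback paths hand the hidden
  layer the previous prediction directly, which markedly shortens training on
  quasi-periodic signals.

Training is classical truncated gradient descent for simple recurrent
networks: context values are treated as fixed inputs during each weight
update (no backpropagation through time), weights are updated online after
every (x(t) -> x(t+1)) pair, and contexts are reset to zero at the start of
every epoch so window evaluations are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "ARCHITECTURES",
    "NetworkConfig",
    "RecurrentNetState",
    "TrainResult",
    "TrainingDivergenceError",
    "init_network",
    "forward_step",
    "train_on_window",
    "test_on_window",
    "mse",
    "RecurrentOneStepPredictor",
]

ARCHITECTURES = ("elman", "jordan", "elman_jordan")
_ACTIVATIONS = ("logistic", "tanh")


class TrainingDivergenceError(FloatingPointError):
    """Raised when training produces non-finite weights."""


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters of a recurrent one-step-ahead predictor.

    Defaults: 40 hidden units, a 10000-epoch cap, logistic activations on
    both layers (the signals live in [0, 1]), learning rate 0.1 and a
    training-MSE convergence threshold of 1e-3.
    """

    architecture: str = "elman_jordan"
    n_hidden: int = 40
    learning_rate: float = 0.1
    max_epochs: int = 10000
    target_mse: float = 1e-3
    hidden_activation: str = "logistic"
    output_activation: str = "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not self.target_mse > 0:
            raise ValueError("target_mse must be positive")
        for name in (self.hidden_activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation: {name!r}")


@dataclass
class RecurrentNetState:
    """Weights and delayed context values of a recurrent net.

    ``W_ctx`` is absent (None) for the pure Jordan net, ``W_jordan`` is
    absent for the pure Elman net, and ``w_self`` (the delayed output
    self-feedback) exists only in the Elman-Jordan hybrid.
    """

    architecture: str
    W_in: np.ndarray
    W_ctx: np.ndarray | None
    W_jordan: np.ndarray | None
    W_out: np.ndarray
    w_self: float | None
    b_hidden: np.ndarray
    b_out: float
    ctx_hidden: np.ndarray
    ctx_output: float
    hidden_activation: str = "logistic"
    output_activation: str = "logistic"

    @property
    def n_hidden(self) -> int:
        return int(self.W_in.size)

    def reset_context(self) -> None:
        """Zero the delayed values (start of an epoch or a test pass)."""
        self.ctx_hidden = np.zeros(self.n_hidden)
        self.ctx_output = 0.0

    def copy(self) -> "RecurrentNetState":
        return replace(
            self,
            W_in=self.W_in.copy(),
            W_ctx=None if self.W_ctx is None else self.W_ctx.copy(),
            W_jordan=None if self.W_jordan is None else self.W_jordan.copy(),
            W_out=self.W_out.copy(),
            b_hidden=self.b_hidden.copy(),
            ctx_hidden=self.ctx_hidden.copy(),
        )

    def to_json_dict(self) -> dict:
        """Serializable layout: architecture, dimensions, flat weight lists."""
        return {
            "architecture": self.architecture,
            "n_hidden": self.n_hidden,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "W_in": self.W_in.tolist(),
            "W_ctx": None if self.W_ctx is None else self.W_ctx.ravel().tolist(),
            "W_jordan": None if self.W_jordan is None else self.W_jordan.tolist(),
            "W_out": self.W_out.tolist(),
            "w_self": self.w_self,
            "b_hidden": self.b_hidden.tolist(),
            "b_out": self.b_out,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RecurrentNetState":
        n = d["n_hidden"]
        return cls(
            architecture=d["architecture"],
            W_in=np.asarray(d["W_in"], float),
            W_ctx=None
            if d["W_ctx"] is None
            else np.asarray(d["W_ctx"], float).reshape(n, n),
            W_jordan=None
            if d["W_jordan"] is None
            else np.asarray(d["W_jordan"], float),
            W_out=np.asarray(d["W_out"], float),
            w_self=d["w_self"],
            b_hidden=np.asarray(d["b_hidden"], float),
            b_out=float(d["b_out"]),
            ctx_hidden=np.zeros(n),
            ctx_output=0.0,
            hidden_activation=d["hidden_activation"],
            output_activation=d["output_activation"],
        )


@dataclass(frozen=True)
class TrainResult:
    epochs_used: int
    final_train_mse: float
    converged: bool


def init_network(config: NetworkConfig) -> RecurrentNetState:
    """Draw initial weights uniformly from [-0.5, 0.5] and zero the contexts.

    Architecture-specific weights exist exactly when the architecture uses
    them; draws are ordered so that the weights shared by all architectures
    are identical for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_hidden
    u = lambda size=None: rng.uniform(-0.5, 0.5, size)
    W_in = u(n)
    W_out = u(n)
    b_hidden = u(n)
    b_out = float(u())
    W_ctx = u((n, n)) if config.architecture != "jordan" else None
    W_jordan = u(n) if config.architecture != "elman" else None
    w_self = float(u()) if config.architecture == "elman_jordan" else None
    return RecurrentNetState(
        architecture=config.architecture,
        W_in=W_in,
        W_ctx=W_ctx,
        W_jordan=W_jordan,
        W_out=W_out,
        w_self=w_self,
        b_hidden=b_hidden,
        b_out=b_out,
        ctx_hidden=np.zeros(n),
        ctx_output=0.0,
        hidden_activation=config.hidden_activation,
        output_activation=config.output_activation,
    )


def _act(name: str, z: np.ndarray | float):
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    return np.tanh(z)


def forward_step(
    state: RecurrentNetState, x_t: float
) -> tuple[float, RecurrentNetState]:
    """One time step: compute the output and the updated-context state.

    The hidden pre-activation sums the input, the hidden-copy context (Elman
    paths), and the output context (Jordan paths); the output pre-activation
    adds the delayed output self-feedback for the hybrid. The returned state
    stores the hidden activations and the output as the next step's contexts;
    the input state is not modified.
    """
    if not np.isfinite(x_t):
        raise ValueError("input must be finite")
    z_h = state.W_in * x_t + state.b_hidden
    if state.W_ctx is not None:
        z_h = z_h + state.W_ctx @ state.ctx_hidden
    if state.W_jordan is not None:
        z_h = z_h + state.W_jordan * state.ctx_output
    h = _act(state.hidden_activation, z_h)
    z_o = state.W_out @ h + state.b_out
    if state.w_self is not None:
        z_o = z_o + state.w_self * state.ctx_output
    y = float(_act(state.output_activation, z_o))
    if not (np.all(np.isfinite(h)) and np.isfinite(y)):
        raise TrainingDivergenceError("non-finite activations in forward pass")
    new_state = state.copy()
    new_state.ctx_hidden = np.asarray(h, dtype=float)
    new_state.ctx_output = y
    return y, new_state


@njit(cache=True)
def _train_loop(
    x,
    targets,
    W_in,
    W_ctx,
    W_jordan,
    W_out,
    w_self_arr,
    b_hidden,
    b_out_arr,
    use_ctx,
    use_jordan,
    use_self,
    hidden_tanh,
    output_tanh,
    lr,
    target_mse,
    max_epochs,
):  # pragma: no cover - exercised through train_on_window
    n_h = W_in.shape[0]
    n_t = x.shape[0]
    epochs_used = 0
    epoch_mse = np.inf
    for epoch in range(max_epochs):
        ch = np.zeros(n_h)
        co = 0.0
        sse = 0.0
        for i in range(n_t):
            z_h = W_in * x[i] + b_hidden
            if use_ctx:
                z_h = z_h + W_ctx @ ch
            if use_jordan:
                z_h = z_h + W_jordan * co
            if hidden_tanh:
                h = np.tanh(z_h)
                dh_act = 1.0 - h * h
            else:
                h = 1.0 / (1.0 + np.exp(-z_h))
                dh_act = h * (1.0 - h)
            z_o = W_out @ h + b_out_arr[0]
            if use_self:
                z_o = z_o + w_self_arr[0] * co
            if output_tanh:
                y = np.tanh(z_o)
                dy_act = 1.0 - y * y
            else:
                y = 1.0 / (1.0 + np.exp(-z_o))
                dy_act = y * (1.0 - y)
            e = y - targets[i]
            sse += e * e
            d_o = e * dy_act
            d_h = d_o * W_out * dh_act
            W_out -= lr * d_o * h
            b_out_arr[0] -= lr * d_o
            if use_self:
                w_self_arr[0] -= lr * d_o * co
            W_in -= lr * d_h * x[i]
            if use_ctx:
                W_ctx -= lr * np.outer(d_h, ch)
            if use_jordan:
                W_jordan -= lr * d_h * co
            b_hidden -= lr * d_h
            if use_ctx:
                ch = h
            co = y
        epoch_mse = sse / n_t
        epochs_used = epoch + 1
        if not np.isfinite(epoch_mse):
            return epochs_used, epoch_mse, False
        if epoch_mse <= target_mse:
            return epochs_used, epoch_mse, True
    return epochs_used, epoch_mse, False


def train_on_window(
    state: RecurrentNetState,
    window: np.ndarray,
    config: NetworkConfig,
) -> tuple[RecurrentNetState, TrainResult]:
    """Train on one phoneme window by one-step-ahead prediction.

    Every epoch sweeps the pairs (x(t) -> x(t+1)) for t = 1..n-1 with
    contexts reset at the epoch start; training stops when the epoch's
    online MSE reaches ``config.target_mse`` or at ``config.max_epochs``.
    Returns the trained state (the input state is untouched) and a
    TrainResult with the epoch count and final training MSE.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.size < 2:
        raise ValueError("training window must hold at least 2 samples")
    new = state.copy()
    new.reset_context()
    n = new.n_hidden
    use_ctx = new.W_ctx is not None
    use_jordan = new.W_jordan is not None
    use_self = new.w_self is not None
    W_ctx = new.W_ctx if use_ctx else np.zeros((n, n))
    W_jordan = new.W_jordan if use_jordan else np.zeros(n)
    w_self_arr = np.array([new.w_self if use_self else 0.0])
    b_out_arr = np.array([new.b_out])
    epochs_used, final_mse, converged = _train_loop(
        window[:-1],
        window[1:],
        new.W_in,
        W_ctx,
        W_jordan,
        new.W_out,
        w_self_arr,
        new.b_hidden,
        b_out_arr,
        use_ctx,
        use_jordan,
        use_self,
        new.hidden_activation == "tanh",
        new.output_activation == "tanh",
        config.learning_rate,
        config.target_mse,
        config.max_epochs,
    )
    if not np.isfinite(final_mse):
        raise TrainingDivergenceError(
            f"training diverged after {epochs_used} epochs"
        )
    new.b_out = float(b_out_arr[0])
    if use_self:
        new.w_self = float(w_self_arr[0])
    new.reset_context()
    return new, TrainResult(int(epochs_used), float(final_mse), bool(converged))


def test_on_window(state: RecurrentNetState, window: np.ndarray) -> np.ndarray:
    """One forward pass over a window; returns E_i = y(x_i) - z(x_i).

    Contexts are reset first and the persistent weights are unmodified, so
    test passes are order-independent. The error vector has length n - 1:
    one entry per one-step-ahead prediction.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.size < 2:
        raise ValueError("test window must hold at least 2 samples")
    current = state.copy()
    current.reset_context()
    errors = np.empty(window.size - 1)
    for i in range(window.size - 1):
        y, current = forward_step(current, float(window[i]))
        errors[i] = y - window[i + 1]
    return errors


def mse(E: np.ndarray) -> float:
    """Mean squared error of an error vector: (1/n) * sum(E_i^2)."""
    E = np.asarray(E, dtype=np.float64)
    if E.size == 0:
        raise ValueError("error vector must be non-empty")
    return float(np.mean(np.square(E)))


class RecurrentOneStepPredictor:
    """Scikit-learn-style wrapper around the recurrent one-step predictor.

    ``fit(window)`` trains a freshly initialized network on one phoneme
    window; ``predict(window)`` returns the one-step-ahead predictions for
    another window and ``score_window(window)`` their mean squared error
    against the actual next samples.
    """

    def __init__(
        self,
        architecture: str = "elman_jordan",
        n_hidden: int = 40,
        learning_rate: float = 0.1,
        max_epochs: int = 10000,
        target_mse: float = 1e-3,
        hidden_activation: str = "logistic",
        output_activation: str = "logistic",
        seed: int = 0,
    ):
        self.architecture = architecture
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.target_mse = target_mse
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "architecture": self.architecture,
            "n_hidden": self.n_hidden,
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "target_mse": self.target_mse,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "RecurrentOneStepPredictor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter: {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> NetworkConfig:
        return NetworkConfig(**self.get_params())

    def fit(self, window, y=None) -> "RecurrentOneStepPredictor":
        config = self._config()
        state = init_network(config)
        self.state_, self.train_result_ = train_on_window(state, window, config)
        return self

    def predict(self, window) -> np.ndarray:
        errors = test_on_window(self.state_, window)
        return errors + np.asarray(window, dtype=np.float64)[1:]

    def score_window(self, window) -> float:
        return mse(test_on_window(self.state_, window))
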