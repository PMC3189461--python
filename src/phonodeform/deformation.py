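"""Deformation-coefficient scoring of sustained-vowel signals.

Articulation is an individual trait, so a network cannot be trained on
population-level vowel templates; instead, each patient's own recording is
both the training and the testing material. The signal is cut into phoneme
windows, a random subset is selected, and every selected window takes one
turn as the training window while the others are used for testing — a
leave-one-in analogue of cross-validation. A healthy, well-replicated
phonation yields small test errors everywhere; replication disturbances
(elevated jitter/shimmer, irregular cycles) inflate them. The averaged test
MSE is the deformation coefficient.

Each patient is finally described by two such coefficients: ``a1`` from the
normalized signal itself and ``a2`` from its first difference, which exposes
rate-of-change disturbances the raw amplitude path can miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rnn import NetworkConfig, init_network, mse, test_on_window, train_on_window
from .signals import Signal, differentiate, div2win, normalize, sel_win

__all__ = [
    "DeformationResult",
    "PatientFeatures",
    "deformation_coefficient",
    "two_path_results",
    "patient_features",
    "DeformationScorer",
]


@dataclass(frozen=True)
class DeformationResult:
    """Per-repeat test errors and epoch counts for one signal path.

    One repeat = one choice of training window. ``E_bar`` is the arithmetic
    mean of the per-repeat averaged test MSEs, ``n_bar`` the mean number of
    training epochs.
    """

    per_repeat_mse: tuple[float, ...]
    per_repeat_epochs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.per_repeat_mse) != len(self.per_repeat_epochs):
            raise ValueError("per-repeat lists must have equal length")
        if len(self.per_repeat_mse) == 0:
            raise ValueError("at least one repeat is required")
        if min(self.per_repeat_mse) < 0:
            raise ValueError("MSE values must be non-negative")

    @property
    def E_bar(self) -> float:
        return float(np.mean(self.per_repeat_mse))

    @property
    def n_bar(self) -> float:
        return float(np.mean(self.per_repeat_epochs))


@dataclass(frozen=True)
class PatientFeatures:
    """The two-attribute description of one patient.

    ``a1``: average deformation coefficient of the normalized signal;
    ``a2``: the same for the differentiated signal.
    """

    patient_id: str
    a1: float
    a2: float
    n_bar_original: float = float("nan")
    n_bar_derivative: float = float("nan")

    def __post_init__(self) -> None:
        for value in (self.a1, self.a2):
            if not (np.isfinite(value) and value >= 0):
                raise ValueError("attributes must be finite and non-negative")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def deformation_coefficient(
    signal: Signal,
    net_config: NetworkConfig,
    k_windows: int = 4,
    window_length: int = 256,
    seed: int = 0,
    mode: str = "fixed",
    min_distance: int = 32,
) -> DeformationResult:
    """Run the leave-one-in deformation procedure on one signal path.

    The signal is divided into windows, ``k_windows`` of them are selected at
    random, and each selected window in turn trains a freshly initialized
    network (with a seed derived from ``seed`` and the repeat index) that is
    then tested on every other selected window. The per-repeat error is the
    mean of the per-window MSEs, weighting windows equally.
    """
    windows = div2win(
        signal, mode=mode, window_length=window_length, min_distance=min_distance
    )
    sel_seed, *net_seeds = _spawn_seeds(seed, k_windows + 1)
    selected = sel_win(windows, k_windows, sel_seed)
    arrays = selected.slices(signal)
    per_mse: list[float] = []
    per_epochs: list[int] = []
    for i, train_arr in enumerate(arrays):
        config = NetworkConfig(
            **{**_config_dict(net_config), "seed": net_seeds[i]}
        )
        state = init_network(config)
        state, result = train_on_window(state, train_arr, config)
        test_mses = [
            mse(test_on_window(state, arr))
            for j, arr in enumerate(arrays)
            if j != i
        ]
        per_mse.append(float(np.mean(test_mses)))
        per_epochs.append(result.epochs_used)
    return DeformationResult(tuple(per_mse), tuple(per_epochs))


def _config_dict(config: NetworkConfig) -> dict:
    return {
        "architecture": config.architecture,
        "n_hidden": config.n_hidden,
        "learning_rate": config.learning_rate,
        "max_epochs": config.max_epochs,
        "target_mse": config.target_mse,
        "hidden_activation": config.hidden_activation,
        "output_activation": config.output_activation,
        "seed": config.seed,
    }


def two_path_results(
    signal: Signal,
    net_config: NetworkConfig,
    k_windows: int = 4,
    window_length: int = 256,
    seed: int = 0,
    mode: str = "fixed",
    min_distance: int = 32,
) -> tuple[DeformationResult, DeformationResult]:
    """Run the deformation procedure on both analysis paths.

    Path 1 sees the normalized signal, path 2 its re-normalized first
    difference; each path gets an independent seed derived from ``seed``.
    """
    seed_a1, seed_a2 = _spawn_seeds(seed, 2)
    normalized = normalize(signal)
    res1 = deformation_coefficient(
        normalized, net_config, k_windows, window_length, seed_a1,
        mode=mode, min_distance=min_distance,
    )
    res2 = deformation_coefficient(
        differentiate(normalized), net_config, k_windows, window_length, seed_a2,
        mode=mode, min_distance=min_distance,
    )
    return res1, res2


def patient_features(
    signal: Signal,
    net_config: NetworkConfig,
    k_windows: int = 4,
    window_length: int = 256,
    seed: int = 0,
    patient_id: str = "patient",
    mode: str = "fixed",
    min_distance: int = 32,
) -> PatientFeatures:
    """Two-path feature extraction: a1 from the normalized signal, a2 from
    its re-normalized first difference, with independent derived seeds."""
    res1, res2 = two_path_results(
        signal, net_config, k_windows, window_length, seed,
        mode=mode, min_distance=min_distance,
    )
    return PatientFeatures(
        patient_id=patient_id,
        a1=res1.E_bar,
        a2=res2.E_bar,
        n_bar_original=res1.n_bar,
        n_bar_derivative=res2.n_bar,
    )


class DeformationScorer:
    """Transformer mapping signals to (a1, a2) deformation features.

    Stateless in the scikit-learn sense (``fit`` is a no-op); ``transform``
    accepts a sequence of Signal objects and returns an (n_signals, 2) array
    of deformation coefficients. Per-signal seeds are derived from ``seed``
    and the signal's position, so cohorts are reproducible while patients
    remain independent.
    """

    def __init__(
        self,
        architecture: str = "elman_jordan",
        n_hidden: int = 40,
        learning_rate: float = 0.1,
        max_epochs: int = 10000,
        target_mse: float = 1e-3,
        k_windows: int = 4,
        window_length: int = 256,
        seed: int = 0,
    ):
        self.architecture = architecture
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.target_mse = target_mse
        self.k_windows = k_windows
        self.window_length = window_length
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "architecture": self.architecture,
            "n_hidden": self.n_hidden,
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "target_mse": self.target_mse,
            "k_windows": self.k_windows,
            "window_length": self.window_length,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "DeformationScorer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter: {key!r}")
            setattr(self, key, value)
        return self

    def _net_config(self) -> NetworkConfig:
        return NetworkConfig(
            architecture=self.architecture,
            n_hidden=self.n_hidden,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            target_mse=self.target_mse,
        )

    def fit(self, X=None, y=None) -> "DeformationScorer":
        return self

    def transform(self, signals) -> np.ndarray:
        signal_seeds = _spawn_seeds(self.seed, max(len(signals), 1))
        rows = []
        for i, signal in enumerate(signals):
            feats = self.features_for(signal, signal_seeds[i], f"signal_{i}")
            rows.append([feats.a1, feats.a2])
        return np.asarray(rows, dtype=float)

    def fit_transform(self, signals, y=None) -> np.ndarray:
        return self.fit(signals, y).transform(signals)

    def features_for(
        self, signal: Signal, seed: int, patient_id: str
    ) -> PatientFeatures:
        return patient_features(
            signal,
            self._net_config(),
            k_windows=self.k_windows,
            window_length=self.window_length,
            seed=seed,
            patient_id=patient_id,
        )
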