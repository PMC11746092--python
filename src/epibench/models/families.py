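"""The seven classifier families behind one train/predict contract.

Linear and tree families wrap scikit-learn / LightGBM / XGBoost; the
neural families (MLP, CNN, LSTM and the LSTM-CNN hybrid) are built from
the NumPy layers in :mod:`epibench.models.nn` and trained with Adam,
binary cross-entropy, a cosine-annealed learning rate and early stopping.

Genotypes enter every family one-hot encoded: each SNP expands into three
indicator columns (one per 0/1/2 genotype), ordered (snp, level)
lexicographically. The sequence families view the same features as a
3-channel sequence along the SNP axis, preserving per-SNP locality.
"""

from __future__ import annotations

import itertools
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from ..simulate import GenotypeMatrix, rng_for
from .nn import (
    BatchNorm,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    LSTM,
    Network,
    ReLU,
    Reshape3d,
    TrainingProtocol,
    train_network,
)

__all__ = [
    "FAMILIES",
    "NEURAL_FAMILIES",
    "GRID_BOUNDS",
    "ClassifierSpec",
    "FittedClassifier",
    "one_hot_encode",
    "build_classifier",
    "grid_search",
    "default_spec",
    "save_model",
    "load_model",
    "load_spec",
    "save_spec",
]

FAMILIES = (
    "lasso_logistic",
    "random_forest",
    "gradient_boosting",
    "mlp",
    "cnn",
    "rnn",
    "rnn_cnn",
)
NEURAL_FAMILIES = ("mlp", "cnn", "rnn", "rnn_cnn")

#: Documented hyperparameter ranges, enforced when ``strict=True``.
GRID_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "mlp": {"hidden1": (300, 2500), "hidden2": (100, 500), "hidden3": (10, 75),
            "dropout_input": (0.0, 0.95), "dropout_hidden": (0.0, 0.95),
            "bn_momentum": (0.0, 1.0)},
    "cnn": {"channels": (150, 1000), "kernel": (1, 4), "stride": (1, 4),
            "fc_size": (50, 100), "dropout": (0.0, 0.95)},
    "rnn": {"hidden": (50, 300), "dropout": (0.7, 0.9)},
    "rnn_cnn": {"hidden": (50, 300), "channels": (150, 1000), "kernel": (1, 4),
                "stride": (1, 4), "fc_size": (50, 100), "dropout": (0.7, 0.9)},
}

_DEFAULT_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "lasso_logistic": {"C": 1.0},
    "random_forest": {"n_estimators": 500},
    "gradient_boosting": {"n_estimators": 500, "backend": "lightgbm"},
    "mlp": {"hidden1": 300, "hidden2": 100, "hidden3": 10,
            "dropout_input": 0.3, "dropout_hidden": 0.2, "bn_momentum": 0.1},
    "cnn": {"channels": 150, "kernel": 3, "stride": 3, "fc_size": 50,
            "dropout": 0.3},
    "rnn": {"hidden": 50, "dropout": 0.7},
    "rnn_cnn": {"hidden": 50, "channels": 150, "kernel": 3, "stride": 3,
                "fc_size": 50, "dropout": 0.7},
}

_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    # L1 penalty strength, logarithmic
    "lasso_logistic": {"C": [1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [500]},
    "gradient_boosting": {"n_estimators": [500]},
    "mlp": {"hidden1": [300, 1000, 2500], "hidden2": [100, 500],
            "hidden3": [10, 75], "dropout_input": [0.3, 0.5],
            "dropout_hidden": [0.2, 0.4]},
    "cnn": {"channels": [150, 500, 1000], "kernel": [1, 2, 3, 4],
            "stride": [1, 2, 3, 4], "fc_size": [50, 100]},
    "rnn": {"hidden": [50, 150, 300], "dropout": [0.7, 0.8, 0.9]},
    "rnn_cnn": {"hidden": [50, 150], "channels": [150, 500],
                "kernel": [2, 3], "stride": [2, 3], "fc_size": [50, 100],
                "dropout": [0.7, 0.8]},
}


@dataclass
class ClassifierSpec:
    """One model family with its hyperparameter grid and training protocol."""

    family: str
    hyperparameter_grid: dict[str, list] = field(default_factory=dict)
    protocol: TrainingProtocol = field(default_factory=TrainingProtocol)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def is_neural(self) -> bool:
        return self.family in NEURAL_FAMILIES


def default_spec(family: str, grid: dict[str, list] | None = None,
                 protocol: TrainingProtocol | None = None) -> ClassifierSpec:
    """Spec with the family's documented default grid."""
    return ClassifierSpec(
        family=family,
        hyperparameter_grid=grid if grid is not None else
        {k: list(v) for k, v in _DEFAULT_GRIDS[family].items()},
        protocol=protocol or TrainingProtocol(),
    )


def one_hot_encode(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Expand each SNP into three indicator columns, (snp, level) order."""
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else genotypes
    values = np.asarray(values)
    if values.size and not np.isin(values, (0, 1, 2)).all():
        bad = np.argwhere(~np.isin(values, (0, 1, 2)))[0]
        raise ValueError(
            f"cannot one-hot encode genotype {values[tuple(bad)]} at "
            f"row {bad[0]}, column {bad[1]}; entries must be 0, 1 or 2"
        )
    n, m = values.shape
    eye = np.eye(3, dtype=np.float32)
    return eye[values.astype(int)].reshape(n, 3 * m)


def _check_strict(family: str, hyperparameters: dict[str, Any]) -> None:
    bounds = GRID_BOUNDS.get(family, {})
    for name, value in hyperparameters.items():
        if name in bounds:
            lo, hi = bounds[name]
            if not lo <= value <= hi:
                raise ValueError(
                    f"{family} hyperparameter {name}={value} outside the "
                    f"documented range [{lo}, {hi}]"
                )


class _SklearnFamily:
    """Adapter for the linear and tree families."""

    def __init__(self, family: str, hyperparameters: dict[str, Any]):
        self.family = family
        self.hyperparameters = hyperparameters
        self._model = None

    def _make(self, seed: int):
        hp = self.hyperparameters
        if self.family == "lasso_logistic":
            from sklearn.linear_model import LogisticRegression

            # liblinear with pure L1; tol 1e-2 converges to the same AUC
            # as 1e-4 on one-hot genotype data at a fraction of the cost
            return LogisticRegression(
                solver="liblinear", l1_ratio=1.0, C=hp.get("C", 1.0),
                tol=hp.get("tol", 1e-2), max_iter=2000, random_state=seed,
            )
        if self.family == "random_forest":
            from sklearn.ensemble import RandomForestClassifier

            return RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 500),
                random_state=seed, n_jobs=1,
            )
        if self.family == "gradient_boosting":
            backend = hp.get("backend", "lightgbm")
            n_estimators = hp.get("n_estimators", 500)
            if backend == "lightgbm":
                from lightgbm import LGBMClassifier

                return LGBMClassifier(
                    n_estimators=n_estimators, random_state=seed,
                    n_jobs=1, verbose=-1, deterministic=True,
                )
            if backend == "xgboost":
                from xgboost import XGBClassifier

                return XGBClassifier(
                    n_estimators=n_estimators, random_state=seed,
                    n_jobs=1, verbosity=0,
                )
            if backend == "sklearn":
                from sklearn.ensemble import GradientBoostingClassifier

                return GradientBoostingClassifier(
                    n_estimators=n_estimators, random_state=seed,
                )
            raise ValueError(f"unknown boosting backend {backend!r}")
        raise ValueError(f"unknown family {self.family!r}")

    def _prepare(self, x):
        # one-hot features are 1/3 dense; LightGBM's histogram builder and
        # exclusive-feature bundling are faster on CSR input
        if (self.family == "gradient_boosting"
                and self.hyperparameters.get("backend", "lightgbm") == "lightgbm"):
            import scipy.sparse as sp

            return x if sp.issparse(x) else sp.csr_matrix(x)
        return x

    def fit(self, x_train, y_train, x_val=None, y_val=None, seed: int = 0):
        self._model = self._make(seed)
        self._model.fit(self._prepare(x_train), y_train)
        return self

    def predict_proba(self, x) -> np.ndarray:
        return self._model.predict_proba(self._prepare(x))[:, 1]


class _NeuralFamily:
    """Adapter building and training a NumPy network at fit time."""

    def __init__(self, family: str, hyperparameters: dict[str, Any],
                 protocol: TrainingProtocol | None = None,
                 dtype=np.float32):
        self.family = family
        self.hyperparameters = hyperparameters
        self.protocol = protocol or TrainingProtocol()
        self.dtype = dtype
        self._net: Network | None = None
        self.history = None

    def _build(self, n_features: int, rng: np.random.Generator) -> Network:
        hp = self.hyperparameters
        dt = self.dtype
        if n_features % 3:
            raise ValueError("feature count must be 3 * n_snps (one-hot)")
        n_snps = n_features // 3
        if self.family == "mlp":
            h1, h2, h3 = hp["hidden1"], hp["hidden2"], hp["hidden3"]
            p_in, p_h = hp.get("dropout_input", 0.3), hp.get("dropout_hidden", 0.2)
            mom = hp.get("bn_momentum", 0.1)
            return Network([
                Dense(n_features, h1, rng, dt), BatchNorm(h1, mom, dtype=dt),
                ReLU(), Dropout(p_in, rng),
                Dense(h1, h2, rng, dt), BatchNorm(h2, mom, dtype=dt),
                ReLU(), Dropout(p_h, rng),
                Dense(h2, h3, rng, dt), BatchNorm(h3, mom, dtype=dt),
                ReLU(), Dropout(p_h, rng),
                Dense(h3, 1, rng, dt),
            ])
        if self.family == "cnn":
            ch, k, s = hp["channels"], hp["kernel"], hp["stride"]
            fc, p = hp["fc_size"], hp.get("dropout", 0.3)
            conv1 = Conv1d(3, ch, k, s, rng, dt)
            len1 = conv1.out_length(n_snps)
            conv2 = Conv1d(ch, ch, k, s, rng, dt)
            len2 = conv2.out_length(len1)
            if len2 < 1:
                raise ValueError("kernel/stride too large for sequence length")
            return Network([
                Reshape3d(3, n_snps), conv1, ReLU(), conv2, ReLU(), Flatten(),
                Dense(ch * len2, fc, rng, dt), ReLU(), Dropout(p, rng),
                Dense(fc, 1, rng, dt),
            ])
        if self.family == "rnn":
            h, p = hp["hidden"], hp.get("dropout", 0.7)
            return Network([
                Reshape3d(3, n_snps), LSTM(3, h, rng, dtype=dt),
                Dropout(p, rng), Dense(h, 1, rng, dt),
            ])
        if self.family == "rnn_cnn":
            h, ch, k, s = hp["hidden"], hp["channels"], hp["kernel"], hp["stride"]
            fc, p = hp["fc_size"], hp.get("dropout", 0.7)
            conv1 = Conv1d(h, ch, k, s, rng, dt)
            len1 = conv1.out_length(n_snps)
            conv2 = Conv1d(ch, ch, k, s, rng, dt)
            len2 = conv2.out_length(len1)
            if len2 < 1:
                raise ValueError("kernel/stride too large for sequence length")
            return Network([
                Reshape3d(3, n_snps),
                LSTM(3, h, rng, return_sequence=True, dtype=dt),
                conv1, ReLU(), conv2, ReLU(), Flatten(),
                Dense(ch * len2, fc, rng, dt), ReLU(), Dropout(p, rng),
                Dense(fc, 1, rng, dt),
            ])
        raise ValueError(f"unknown neural family {self.family!r}")

    def fit(self, x_train, y_train, x_val=None, y_val=None, seed: int = 0):
        if x_val is None or y_val is None:
            raise ValueError("neural families require a validation set")
        rng = rng_for(seed, "training")
        x_train = np.ascontiguousarray(x_train, dtype=self.dtype)
        x_val = np.ascontiguousarray(x_val, dtype=self.dtype)
        y_train = np.asarray(y_train, dtype=self.dtype)
        y_val = np.asarray(y_val, dtype=self.dtype)
        self._net = self._build(x_train.shape[1], rng)
        self.history = train_network(self._net, x_train, y_train,
                                     x_val, y_val, self.protocol, rng)
        return self

    def predict_proba(self, x) -> np.ndarray:
        if self._net is None:
            raise RuntimeError("classifier is not fitted")
        return self._net.predict_proba(np.ascontiguousarray(x, dtype=self.dtype))


def build_classifier(
    family: str,
    hyperparameters: dict[str, Any] | None = None,
    protocol: TrainingProtocol | None = None,
    strict: bool = False,
):
    """Untrained classifier exposing ``fit`` and ``predict_proba``.

    With ``strict=True`` hyperparameters outside the documented grid
    ranges raise a configuration error.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    hp = {**_DEFAULT_HYPERPARAMS[family], **(hyperparameters or {})}
    if strict:
        _check_strict(family, hp)
    if family in NEURAL_FAMILIES:
        return _NeuralFamily(family, hp, protocol)
    return _SklearnFamily(family, hp)


@dataclass
class FittedClassifier:
    """A trained model with the hyperparameters that produced it."""

    spec: ClassifierSpec
    chosen_hyperparameters: dict[str, Any]
    model: Any
    validation_auc: float | None = None

    def predict_proba(self, x) -> np.ndarray:
        p = np.asarray(self.model.predict_proba(x), dtype=float)
        return np.clip(p, 0.0, 1.0)


def grid_search(
    family: str | ClassifierSpec,
    grid: dict[str, list] | None,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
) -> FittedClassifier:
    """Exhaustive Cartesian grid search selected by validation AUC-ROC.

    Ties are broken by first-in-grid order. Returns the refitted winner
    together with its chosen hyperparameters.
    """
    from sklearn.metrics import roc_auc_score

    spec = family if isinstance(family, ClassifierSpec) else default_spec(
        family, grid)
    grid = grid if grid is not None else spec.hyperparameter_grid
    if not grid:
        grid = {k: [v] for k, v in _DEFAULT_HYPERPARAMS[spec.family].items()}
    names = list(grid)
    best: tuple[float, dict, Any] | None = None
    trials = []
    for combo in itertools.product(*(grid[n] for n in names)):
        hp = dict(zip(names, combo))
        clf = build_classifier(spec.family, hp, spec.protocol)
        clf.fit(x_train, y_train, x_val, y_val, seed=seed)
        auc = roc_auc_score(y_val, clf.predict_proba(x_val))
        trials.append({"hyperparameters": hp, "validation_auc": float(auc)})
        if best is None or auc > best[0]:
            best = (float(auc), hp, clf)
    assert best is not None
    fitted = FittedClassifier(spec=spec, chosen_hyperparameters=best[1],
                              model=best[2], validation_auc=best[0])
    fitted.trials = trials
    return fitted


# -- persistence and configuration ----------------------------------------

def save_model(fitted: FittedClassifier, path: str | Path) -> None:
    """Persist a fitted classifier to a single-file artifact."""
    with Path(path).open("wb") as fh:
        pickle.dump(fitted, fh)


def load_model(path: str | Path) -> FittedClassifier:
    with Path(path).open("rb") as fh:
        return pickle.load(fh)


def save_spec(spec: ClassifierSpec, path: str | Path) -> None:
    """Write a spec as a nested key-value (YAML) configuration file."""
    import yaml

    payload = {
        "family": spec.family,
        "grid": spec.hyperparameter_grid,
        "protocol": {
            "epochs": spec.protocol.epochs,
            "batch_size": spec.protocol.batch_size,
            "lr_max": spec.protocol.lr_max,
            "lr_min": spec.protocol.lr_min,
            "lr_period": spec.protocol.lr_period,
            "patience": spec.protocol.patience,
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_spec(path: str | Path) -> ClassifierSpec:
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    protocol = TrainingProtocol(**payload.get("protocol", {}))
    return ClassifierSpec(family=payload["family"],
                          hyperparameter_grid=payload.get("grid", {}),
                          protocol=protocol)
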