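"""Synergy regression models.

The centrepiece is a feed-forward regression network that maps the
concatenated features of (drug A, drug B, cell line) to a single synergy
score.  Because a combination is an unordered pair, every training sample
is presented twice — once as [a||b||cell] and once as [b||a||cell] — and at
prediction time both orientations are propagated and averaged, which makes
the prediction exactly invariant to drug order.

The network uses ReLU hidden layers (two or three, rectangular or conic),
a linear output, mean-squared-error loss, plain minibatch SGD, optional
inverted dropout, and early stopping that selects the epoch minimizing a
25-epoch moving average of validation MSE.  It is implemented directly in
NumPy: the models here are deliberately small and CPU-sized, and full
control over initialization, dropout and the stopping rule keeps training
runs bit-reproducible for a fixed seed.

Two bespoke baselines accompany it: a median-polish predictor (mean of the
two drug medians and the cell-line median of training synergies) and a
modified MinMax kernel for mixed count/binary/continuous features, used
with an off-the-shelf kernel regressor.  Conventional learners (elastic
net, random forest, gradient boosting, nu-SVR) plug in through the same
thin learner interface via scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NetworkConfig",
    "SampleTriplet",
    "MedianTables",
    "SynergyNetwork",
    "double_training_set",
    "predict_symmetric",
    "median_polish_fit",
    "median_polish_predict",
    "pos_neg_split",
    "minmax_kernel",
    "MedianPolishLearner",
    "NetworkLearner",
    "TabularLearner",
    "KernelSVRLearner",
    "assemble_features",
]

EARLY_STOP_WINDOW_DEFAULT = 25


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the synergy network.

    ``hidden_sizes`` holds two or three positive widths; a conic
    architecture halves the width at each layer, a rectangular one keeps it
    constant.  Dropout rates are keep-nothing probabilities in [0, 1).
    ``early_stop_window`` is the width of the moving average of validation
    MSE whose minimum selects the stopping epoch.
    """

    hidden_sizes: tuple[int, ...] = (64, 32)
    learning_rate: float = 1e-3
    input_dropout: float = 0.0
    hidden_dropout: float = 0.0
    max_epochs: int = 200
    early_stop_window: int = EARLY_STOP_WINDOW_DEFAULT
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.hidden_sizes)
        object.__setattr__(self, "hidden_sizes", sizes)
        if len(sizes) not in (2, 3) or any(s <= 0 for s in sizes):
            raise ValueError(
                f"hidden_sizes must be 2 or 3 positive widths, got {sizes}"
            )
        for name in ("input_dropout", "hidden_dropout"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1 or self.early_stop_window < 1:
            raise ValueError("max_epochs and early_stop_window must be positive")


@dataclass(frozen=True)
class SampleTriplet:
    """One (drug A, drug B, cell line) sample with its synergy target."""

    features_a: np.ndarray
    features_b: np.ndarray
    features_cell: np.ndarray
    target: float

    def __post_init__(self):
        if not np.isfinite(self.target):
            raise ValueError("target must be finite")


def double_training_set(samples) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric doubling: each sample appears as [a||b||c] and [b||a||c].

    Returns a (2n, d) feature matrix and length-2n target vector; rows 2i
    and 2i+1 are the two orientations of sample i.
    """
    if len(samples) == 0:
        return np.zeros((0, 0)), np.zeros(0)
    rows, targets = [], []
    for s in samples:
        rows.append(np.concatenate([s.features_a, s.features_b, s.features_cell]))
        rows.append(np.concatenate([s.features_b, s.features_a, s.features_cell]))
        targets.extend([s.target, s.target])
    return np.vstack(rows), np.asarray(targets, dtype=float)


def double_arrays(xa, xb, xc, y):
    """Array-level symmetric doubling (row 2i = a||b||c, row 2i+1 = b||a||c)."""
    fwd = np.hstack([xa, xb, xc])
    rev = np.hstack([xb, xa, xc])
    out = np.empty((2 * len(fwd), fwd.shape[1]))
    out[0::2] = fwd
    out[1::2] = rev
    yy = np.repeat(np.asarray(y, dtype=float), 2)
    return out, yy


class SynergyNetwork:
    """Feed-forward ReLU regression network trained with plain SGD.

    Weights use variance-scaled uniform initialization (U[-b, b] with
    b = sqrt(6 / fan_in)) drawn from the config seed, so identical
    seed/config give bit-identical training runs in single-threaded use.
    """

    def __init__(self, input_dim: int, config: NetworkConfig):
        self.input_dim = int(input_dim)
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = [self.input_dim, *config.hidden_sizes, 1]
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.log: pd.DataFrame | None = None
        self.best_epoch_: int | None = None

    # -- forward/backward -------------------------------------------------

    def _forward(self, x, rng=None):
        """Forward pass; with ``rng`` applies inverted dropout and returns caches."""
        cfg = self.config
        activations = []
        masks = []
        h = x
        if rng is not None and cfg.input_dropout > 0:
            mask = (rng.random(h.shape) >= cfg.input_dropout) / (1 - cfg.input_dropout)
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        activations.append(h)
        n_hidden = len(self.weights) - 1
        for layer in range(n_hidden):
            h = np.maximum(h @ self.weights[layer] + self.biases[layer], 0.0)
            if rng is not None and cfg.hidden_dropout > 0:
                mask = (rng.random(h.shape) >= cfg.hidden_dropout) / (
                    1 - cfg.hidden_dropout
                )
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            activations.append(h)
        out = (h @ self.weights[-1] + self.biases[-1]).ravel()
        return out, activations, masks

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match the network's "
                f"input dimension {self.input_dim}"
            )
        return self._forward(x)[0]

    def _sgd_step(self, x, y, rng):
        cfg = self.config
        out, acts, masks = self._forward(x, rng=rng)
        n = len(y)
        # d(MSE)/d(out)
        delta = (2.0 / n) * (out - y)[:, None]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        grads_w[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        back = delta @ self.weights[-1].T
        for layer in range(len(self.weights) - 2, -1, -1):
            back = back * (acts[layer + 1] > 0)
            if masks[layer + 1] is not None:
                back = back * masks[layer + 1]
            grads_w[layer] = acts[layer].T @ back
            grads_b[layer] = back.sum(axis=0)
            if layer > 0:
                back = back @ self.weights[layer].T
        for layer in range(len(self.weights)):
            self.weights[layer] -= cfg.learning_rate * grads_w[layer]
            self.biases[layer] -= cfg.learning_rate * grads_b[layer]
        return float(np.mean((out - y) ** 2))

    # -- training ----------------------------------------------------------

    def fit(self, x, y, x_val, y_val) -> "SynergyNetwork":
        """Minibatch SGD with moving-average early stopping.

        Trains for ``max_epochs`` epochs and restores the weights of the
        epoch minimizing the ``early_stop_window``-epoch moving average of
        validation MSE.  The per-epoch log (train/validation MSE and the
        moving average) lands in ``self.log``.
        """
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x_val = np.asarray(x_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(y)
        records = []
        val_history: list[float] = []
        best_ma = np.inf
        best_state = None
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            batch_losses = []
            with np.errstate(invalid="ignore", over="ignore"):
                for start in range(0, n, cfg.batch_size):
                    idx = order[start : start + cfg.batch_size]
                    batch_losses.append(self._sgd_step(x[idx], y[idx], rng))
            train_mse = float(np.mean(batch_losses))
            if not np.isfinite(train_mse):
                raise RuntimeError(
                    f"training diverged (non-finite loss at epoch {epoch}); "
                    f"try a lower learning rate than {cfg.learning_rate:g} "
                    "(small rates such as 1e-5 are often needed)"
                )
            val_mse = float(np.mean((self.predict(x_val) - y_val) ** 2))
            val_history.append(val_mse)
            window = val_history[-cfg.early_stop_window :]
            val_ma = float(np.mean(window))
            records.append(
                {
                    "epoch": epoch,
                    "train_mse": train_mse,
                    "val_mse": val_mse,
                    f"val_mse_ma{cfg.early_stop_window}": val_ma,
                }
            )
            if val_ma < best_ma:
                best_ma = val_ma
                best_state = (
                    [w.copy() for w in self.weights],
                    [b.copy() for b in self.biases],
                    epoch,
                )
        if best_state is not None:
            self.weights, self.biases, self.best_epoch_ = (
                best_state[0],
                best_state[1],
                best_state[2],
            )
        self.log = pd.DataFrame.from_records(records)
        return self

    # -- persistence --------------------------------------------------------

    def save_weights(self, path):
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    def load_weights(self, path):
        data = np.load(path)
        n_layers = len(self.weights)
        self.weights = [data[f"w{i}"] for i in range(n_layers)]
        self.biases = [data[f"b{i}"] for i in range(n_layers)]


def train_network(x, y, config: NetworkConfig, x_val, y_val):
    """Train a :class:`SynergyNetwork` on normalized features; returns (model, log)."""
    model = SynergyNetwork(np.asarray(x).shape[1], config).fit(x, y, x_val, y_val)
    return model, model.log


def predict_symmetric(model, xa, xb, xc, *, symmetric: bool = True) -> np.ndarray:
    """Average predictions over both drug orders: (f(a||b||c) + f(b||a||c)) / 2.

    Exactly invariant to swapping the two drugs.  ``symmetric=False``
    disables the averaging (single forward orientation) for ablations.
    """
    fwd = model.predict(np.hstack([xa, xb, xc]))
    if not symmetric:
        return fwd
    rev = model.predict(np.hstack([xb, xa, xc]))
    return 0.5 * (fwd + rev)


# ---------------------------------------------------------------------------
# Median-polish baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianTables:
    """Training medians per drug and per cell line, with a global fallback."""

    drug_medians: pd.Series
    cell_medians: pd.Series
    global_median: float


def median_polish_fit(quartets: pd.DataFrame) -> MedianTables:
    """Median synergy per drug (either pair position) and per cell line."""
    if quartets.empty:
        raise ValueError("training quartets must be nonempty")
    long = pd.concat(
        [
            quartets[["drug_a", "synergy"]].rename(columns={"drug_a": "drug"}),
            quartets[["drug_b", "synergy"]].rename(columns={"drug_b": "drug"}),
        ]
    )
    return MedianTables(
        drug_medians=long.groupby("drug")["synergy"].median(),
        cell_medians=quartets.groupby("cell_line")["synergy"].median(),
        global_median=float(quartets["synergy"].median()),
    )


def median_polish_predict(tables: MedianTables, quartets: pd.DataFrame) -> np.ndarray:
    """Mean of the two drug medians and the cell-line median; unseen entities
    fall back to the global training median."""
    g = tables.global_median
    ma = quartets["drug_a"].map(tables.drug_medians).fillna(g).to_numpy()
    mb = quartets["drug_b"].map(tables.drug_medians).fillna(g).to_numpy()
    mc = quartets["cell_line"].map(tables.cell_medians).fillna(g).to_numpy()
    return (ma + mb + mc) / 3.0


# ---------------------------------------------------------------------------
# Modified MinMax kernel
# ---------------------------------------------------------------------------

def pos_neg_split(values: pd.DataFrame, kinds: pd.Series) -> pd.DataFrame:
    """Make a mixed feature matrix nonnegative for the MinMax kernel.

    Each continuous column f is replaced by the adjacent pair
    ``f__pos = max(f, 0)`` and ``f__neg = max(-f, 0)``; count and binary
    columns (already nonnegative by contract) pass through unchanged, so
    the original continuous block is recoverable as pos - neg.
    """
    out = {}
    for col in values.columns:
        v = values[col].to_numpy(float)
        if kinds[col] == "continuous":
            out[f"{col}__pos"] = np.maximum(v, 0.0)
            out[f"{col}__neg"] = np.maximum(-v, 0.0)
        else:
            out[col] = v
    return pd.DataFrame(out, index=values.index)


def minmax_kernel(
    x: np.ndarray, z: np.ndarray | None = None, *, empty_support: str = "identical"
) -> np.ndarray:
    """Modified MinMax similarity for nonnegative feature vectors.

    K(x, z) averages min/max ratios over the features active in either
    vector:  K = sum_{p: x_p + z_p > 0} min(x_p, z_p) / max(x_p, z_p),
    divided by the number of such features.  Values lie in [0, 1]; the
    matrix is symmetric and K(x, x) = 1 for any nonzero x.

    ``empty_support`` decides the value for two all-zero vectors:
    ``"identical"`` (default) scores them 1, ``"zero"`` scores them 0.
    """
    x = np.asarray(x, dtype=float)
    z = x if z is None else np.asarray(z, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if z.ndim == 1:
        z = z[None, :]
    if np.any(x < 0) or np.any(z < 0):
        raise ValueError(
            "MinMax kernel requires nonnegative inputs; run pos_neg_split first"
        )
    if empty_support not in ("identical", "zero"):
        raise ValueError("empty_support must be 'identical' or 'zero'")
    empty_value = 1.0 if empty_support == "identical" else 0.0
    K = np.empty((x.shape[0], z.shape[0]))
    for i in range(x.shape[0]):
        mins = np.minimum(x[i], z)
        maxs = np.maximum(x[i], z)
        active = maxs > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(active, mins / np.where(active, maxs, 1.0), 0.0)
        counts = active.sum(axis=1)
        row = np.full(z.shape[0], empty_value)
        nz = counts > 0
        row[nz] = ratios[nz].sum(axis=1) / counts[nz]
        K[i] = row
    return K


# ---------------------------------------------------------------------------
# Learner interface for the evaluation harness
# ---------------------------------------------------------------------------
#
# A learner exposes fit(train_quartets, validation_quartets=None) and
# predict(quartets) -> array of scores; quartet tables carry drug_a, drug_b,
# cell_line and (for fit) synergy columns.


def assemble_features(
    quartets: pd.DataFrame, drug_values: pd.DataFrame, cell_values: pd.DataFrame
):
    """Look up per-sample (drug A, drug B, cell line) feature sub-matrices."""
    xa = drug_values.loc[quartets["drug_a"]].to_numpy(float)
    xb = drug_values.loc[quartets["drug_b"]].to_numpy(float)
    xc = cell_values.loc[quartets["cell_line"]].to_numpy(float)
    return xa, xb, xc


class MedianPolishLearner:
    """Median-polish baseline under the harness's learner interface."""

    def __init__(self):
        self.tables_: MedianTables | None = None

    def fit(self, train: pd.DataFrame, validation: pd.DataFrame | None = None):
        self.tables_ = median_polish_fit(train)
        return self

    def predict(self, quartets: pd.DataFrame) -> np.ndarray:
        return median_polish_predict(self.tables_, quartets)


class NetworkLearner:
    """Synergy network learner: features, normalization, doubling, training.

    The normalizer is fitted on the (doubled) training rows only.  When no
    validation table is supplied, a seeded 25% tail of the training pairs is
    carved off for early stopping.
    """

    def __init__(
        self,
        drug_values: pd.DataFrame,
        cell_values: pd.DataFrame,
        config: NetworkConfig,
        normalization: str = "norm_tanh_norm",
        symmetric_prediction: bool = True,
    ):
        from .preprocess import Normalizer

        self.drug_values = drug_values
        self.cell_values = cell_values
        self.config = config
        self.normalizer = Normalizer(normalization)
        self.symmetric_prediction = symmetric_prediction
        self.model_: SynergyNetwork | None = None

    def _design(self, quartets: pd.DataFrame):
        xa, xb, xc = assemble_features(quartets, self.drug_values, self.cell_values)
        return double_arrays(xa, xb, xc, quartets["synergy"].to_numpy(float))

    def fit(self, train: pd.DataFrame, validation: pd.DataFrame | None = None):
        if validation is None:
            rng = np.random.default_rng(self.config.seed)
            idx = rng.permutation(len(train))
            cut = max(1, len(train) // 4)
            validation = train.iloc[idx[:cut]]
            train = train.iloc[idx[cut:]]
        x, y = self._design(train)
        xv, yv = self._design(validation)
        x = self.normalizer.fit_transform(x)
        xv = self.normalizer.transform(xv)
        self.model_ = SynergyNetwork(x.shape[1], self.config).fit(x, y, xv, yv)
        return self

    def predict(self, quartets: pd.DataFrame) -> np.ndarray:
        xa, xb, xc = assemble_features(quartets, self.drug_values, self.cell_values)
        fwd = self.normalizer.transform(np.hstack([xa, xb, xc]))
        if not self.symmetric_prediction:
            return self.model_.predict(fwd)
        rev = self.normalizer.transform(np.hstack([xb, xa, xc]))
        return 0.5 * (self.model_.predict(fwd) + self.model_.predict(rev))


class TabularLearner:
    """Off-the-shelf regressor over normalized, symmetrically doubled features.

    ``estimator_factory`` returns a scikit-learn style regressor (elastic
    net, random forest, gradient boosting, ...).  Training uses both drug
    orders; prediction averages both orientations.
    """

    def __init__(
        self,
        estimator_factory,
        drug_values: pd.DataFrame,
        cell_values: pd.DataFrame,
        normalization: str = "norm",
    ):
        from .preprocess import Normalizer

        self.estimator_factory = estimator_factory
        self.drug_values = drug_values
        self.cell_values = cell_values
        self.normalizer = Normalizer(normalization)
        self.estimator_ = None

    def fit(self, train: pd.DataFrame, validation: pd.DataFrame | None = None):
        xa, xb, xc = assemble_features(train, self.drug_values, self.cell_values)
        x, y = double_arrays(xa, xb, xc, train["synergy"].to_numpy(float))
        x = self.normalizer.fit_transform(x)
        self.estimator_ = self.estimator_factory()
        self.estimator_.fit(x, y)
        return self

    def predict(self, quartets: pd.DataFrame) -> np.ndarray:
        xa, xb, xc = assemble_features(quartets, self.drug_values, self.cell_values)
        fwd = self.normalizer.transform(np.hstack([xa, xb, xc]))
        rev = self.normalizer.transform(np.hstack([xb, xa, xc]))
        return 0.5 * (self.estimator_.predict(fwd) + self.estimator_.predict(rev))


class KernelSVRLearner:
    """nu-SVR on the precomputed modified MinMax kernel.

    Features are made nonnegative by the positive/negative split before the
    kernel is evaluated; both drug orders enter training and prediction
    averages the two orientations.
    """

    def __init__(
        self,
        drug_values: pd.DataFrame,
        drug_kinds: pd.Series,
        cell_values: pd.DataFrame,
        cell_kinds: pd.Series,
        nu: float = 0.5,
        C: float = 1.0,
        empty_support: str = "identical",
    ):
        self.drug_nonneg = pos_neg_split(drug_values, drug_kinds)
        self.cell_nonneg = pos_neg_split(cell_values, cell_kinds)
        self.nu = nu
        self.C = C
        self.empty_support = empty_support
        self.train_x_: np.ndarray | None = None
        self.svr_ = None

    def _rows(self, quartets: pd.DataFrame):
        xa, xb, xc = assemble_features(quartets, self.drug_nonneg, self.cell_nonneg)
        return np.hstack([xa, xb, xc]), np.hstack([xb, xa, xc])

    def fit(self, train: pd.DataFrame, validation: pd.DataFrame | None = None):
        from sklearn.svm import NuSVR

        fwd, rev = self._rows(train)
        x = np.empty((2 * len(fwd), fwd.shape[1]))
        x[0::2], x[1::2] = fwd, rev
        y = np.repeat(train["synergy"].to_numpy(float), 2)
        self.train_x_ = x
        gram = minmax_kernel(x, empty_support=self.empty_support)
        self.svr_ = NuSVR(kernel="precomputed", nu=self.nu, C=self.C)
        self.svr_.fit(gram, y)
        return self

    def predict(self, quartets: pd.DataFrame) -> np.ndarray:
        fwd, rev = self._rows(quartets)
        kf = minmax_kernel(fwd, self.train_x_, empty_support=self.empty_support)
        kr = minmax_kernel(rev, self.train_x_, empty_support=self.empty_support)
        return 0.5 * (self.svr_.predict(kf) + self.svr_.predict(kr))
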