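"""Recurrent soft-sensor construction, training and application.

The sensor maps a sliding window of process features (measured off-gas
signals plus derived physiological variables) to the concentration of one
soluble compound at the window's final instant.  Inputs are min-max scaled
with parameters fitted on the training split only; the network is the fixed
stack LSTM(23, ReLU) -> dropout(0.2) -> dense(10, ReLU) -> dropout(0.2) ->
dense(1, non-negative kernel/bias), trained with Adam on a modified
mean-square error that keeps sub-unit errors relevant:

    MMSE = mean_i (|A*_i - A_i| + 1)^2

(an alternative linear reading, sum(|e| + 1) / (2n), is available via
``SensorConfig.loss = "mmse_linear"``).  Training holds out ~20% of the
experiments for early stopping; splits are always by experiment so that no
validation window shares history with a training window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, InvalidInputError, TrainingDivergedError
from .nn import Adam, BatchedNets, LSTMNet

__all__ = [
    "SensorConfig", "WindowedDataset", "TrainedSensor", "MinMaxScaler",
    "make_windows", "concat_windows", "fit_scaler", "apply_scaler",
    "invert_scaler", "mmse_loss", "build_sensor", "train_sensor",
    "train_sensors", "predict", "save_sensor", "load_sensor",
]


@dataclass
class SensorConfig:
    """Hyper-parameters of the soft sensor (defaults are the reference stack)."""

    window_steps: int = 23
    lstm_units: int = 23
    dense_units: int = 10
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 1000
    batch_size: int = 16
    patience: int = 50
    train_fraction: float = 0.8
    loss: str = "mmse"            # "mmse" -> mean((|e|+1)^2); "mmse_linear"
    padding: str = "edge"         # or "strict" (drop the first T-1 instants)
    precision: str = "float32"    # network dtype ("float32" or "float64")
    seed: int = 0

    def __post_init__(self):
        if self.window_steps < 1:
            raise InvalidInputError("window_steps must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidInputError("dropout_rate must be in [0, 1)")
        if not 0 < self.train_fraction < 1:
            raise InvalidInputError("train_fraction must be in (0, 1)")
        if self.loss not in ("mmse", "mmse_linear"):
            raise InvalidInputError(f"unknown loss {self.loss!r}")
        if self.padding not in ("edge", "strict"):
            raise InvalidInputError(f"unknown padding {self.padding!r}")
        if self.precision not in ("float32", "float64"):
            raise InvalidInputError(f"unknown precision {self.precision!r}")


# ------------------------------------------------------------------ scaling
@dataclass
class MinMaxScaler:
    """Per-feature affine map to [0, 1] fitted on a training slice.

    Constant features are shifted by their minimum and scaled by 1 (a logged
    convention rather than an error).  Values outside the fitted range map
    outside [0, 1]; no clipping.
    """

    data_min: np.ndarray
    scale: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.data_min) / self.scale

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.data_min


def fit_scaler(matrix: np.ndarray) -> MinMaxScaler:
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    lo = m.min(axis=0)
    hi = m.max(axis=0)
    scale = hi - lo
    scale[scale == 0] = 1.0
    return MinMaxScaler(data_min=lo, scale=scale)


def apply_scaler(scaler: MinMaxScaler, x: np.ndarray) -> np.ndarray:
    return scaler.transform(np.asarray(x, dtype=float))


def invert_scaler(scaler: MinMaxScaler, x: np.ndarray) -> np.ndarray:
    return scaler.inverse_transform(np.asarray(x, dtype=float))


# ------------------------------------------------------------------ windows
@dataclass
class WindowedDataset:
    """Sliding windows with provenance.

    ``X`` has shape (n_windows, window_steps, n_features); ``y`` the target
    at each window's final instant.  Windows never span two experiments.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: List[str]
    exp_ids: np.ndarray      # experiment id per window
    end_times: np.ndarray    # time of the window's final instant

    def __len__(self):
        return self.X.shape[0]


def make_windows(features: np.ndarray, target: np.ndarray, window_steps: int,
                 *, experiment_id: str = "exp0", times: Optional[np.ndarray] = None,
                 at_indices: Optional[Sequence[int]] = None,
                 feature_names: Optional[List[str]] = None,
                 padding: str = "edge") -> WindowedDataset:
    """Build per-instant windows for one experiment.

    With ``padding="edge"`` the first instants are served by replicating the
    first row, so every instant yields a window; ``"strict"`` drops the first
    ``window_steps - 1`` instants.  ``at_indices`` restricts windows to the
    given instants (e.g. the offline assay instants that carry a target).
    """
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if feats.shape[0] == 1 and feats.shape[1] > 1 and np.ndim(features) == 1:
        feats = feats.T
    targ = np.asarray(target, dtype=float).ravel()
    n, F = feats.shape
    if targ.size != n:
        raise InvalidInputError(
            f"features ({n} rows) and target ({targ.size}) are misaligned")
    if times is None:
        times = np.arange(n, dtype=float)
    times = np.asarray(times, dtype=float).ravel()
    T = int(window_steps)
    if padding == "edge":
        pad = np.repeat(feats[:1], T - 1, axis=0)
        padded = np.vstack([pad, feats])
        candidates = np.arange(n)
    else:
        padded = feats
        candidates = np.arange(T - 1, n)
    if at_indices is not None:
        at = np.asarray(at_indices, dtype=int)
        candidates = at[np.isin(at, candidates)]
    windows = np.empty((candidates.size, T, F))
    for k, i in enumerate(candidates):
        start = i if padding == "edge" else i - T + 1
        windows[k] = padded[start:start + T] if padding == "edge" else padded[start:i + 1]
    names = feature_names or [f"f{j}" for j in range(F)]
    return WindowedDataset(X=windows, y=targ[candidates], feature_names=list(names),
                           exp_ids=np.array([experiment_id] * candidates.size),
                           end_times=times[candidates])


def concat_windows(parts: Sequence[WindowedDataset]) -> WindowedDataset:
    if not parts:
        raise InvalidInputError("nothing to concatenate")
    names = parts[0].feature_names
    for p in parts[1:]:
        if p.feature_names != names:
            raise ContractError("feature sets differ between window groups")
    return WindowedDataset(
        X=np.concatenate([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        feature_names=list(names),
        exp_ids=np.concatenate([p.exp_ids for p in parts]),
        end_times=np.concatenate([p.end_times for p in parts]))


# --------------------------------------------------------------------- loss
def mmse_loss(estimates, observations, variant: str = "mmse") -> float:
    """Modified mean-square error; 1.0 at perfect agreement (default variant)."""
    est = np.asarray(estimates, dtype=float).ravel()
    obs = np.asarray(observations, dtype=float).ravel()
    if est.size == 0 or est.size != obs.size:
        raise InvalidInputError("estimates/observations must be equal-length, non-empty")
    e = np.abs(est - obs)
    if variant == "mmse":
        return float(np.mean((e + 1.0) ** 2))
    if variant == "mmse_linear":
        return float(np.sum(e + 1.0) / (2 * e.size))
    raise InvalidInputError(f"unknown loss variant {variant!r}")


def _loss_grad(err_orig: np.ndarray, y_range: float, variant: str) -> np.ndarray:
    """dLoss/d(scaled estimate) for a batch; err_orig in original units."""
    n = err_orig.size
    s = np.sign(err_orig)
    if variant == "mmse":
        return 2.0 * (np.abs(err_orig) + 1.0) * s * y_range / n
    return s * y_range / (2.0 * n)


# ------------------------------------------------------------------- sensor
@dataclass
class TrainedSensor:
    """A trained soft sensor plus everything needed to apply it."""

    net: LSTMNet
    config: SensorConfig
    feature_names: List[str]
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    history: List[dict] = field(default_factory=list)
    val_loss: float = float("nan")
    seed: int = 0
    split: dict = field(default_factory=dict)   # {"train": set, "val": set}

    @property
    def input_group(self) -> tuple:
        return tuple(self.feature_names)


def build_sensor(config: SensorConfig, n_features: int) -> LSTMNet:
    """Instantiate the untrained network for a given input-group width."""
    return LSTMNet(n_features=n_features, lstm_units=config.lstm_units,
                   dense_units=config.dense_units, dropout=config.dropout_rate,
                   seed=config.seed, dtype=np.dtype(config.precision))


def _scale_windows(X: np.ndarray, scaler: MinMaxScaler) -> np.ndarray:
    return (X - scaler.data_min) / scaler.scale


def train_sensor(dataset: WindowedDataset, config: SensorConfig,
                 net: Optional[LSTMNet] = None) -> TrainedSensor:
    """Train a sensor on a windowed dataset with an experiment-level holdout.

    Experiments are shuffled with the config seed; ~``train_fraction`` of
    them update the weights and the rest drive early stopping (patience in
    epochs, best weights restored).  Raises
    :class:`~fermsense.errors.TrainingDivergedError` if the loss leaves the
    finite domain.
    """
    rng = np.random.default_rng(config.seed)
    exps = list(dict.fromkeys(dataset.exp_ids.tolist()))  # stable unique
    if len(exps) < 2:
        raise InvalidInputError("need >= 2 experiments for an experiment-level split")
    order = rng.permutation(len(exps))
    n_train = max(1, int(round(config.train_fraction * len(exps))))
    n_train = min(n_train, len(exps) - 1)
    train_exps = {exps[i] for i in order[:n_train]}
    val_exps = set(exps) - train_exps
    tr_mask = np.isin(dataset.exp_ids, list(train_exps))
    Xtr_raw, ytr_raw = dataset.X[tr_mask], dataset.y[tr_mask]
    Xva_raw, yva_raw = dataset.X[~tr_mask], dataset.y[~tr_mask]

    F = dataset.X.shape[2]
    x_scaler = fit_scaler(Xtr_raw.reshape(-1, F))
    y_scaler = fit_scaler(ytr_raw.reshape(-1, 1))
    y_range = float(y_scaler.scale[0])
    dtype = np.dtype(config.precision)
    Xtr = _scale_windows(Xtr_raw, x_scaler).astype(dtype)
    Xva = _scale_windows(Xva_raw, x_scaler).astype(dtype)
    ytr = (ytr_raw - y_scaler.data_min[0]) / y_range
    yva = yva_raw  # validation loss is evaluated in original units

    if net is None:
        net = build_sensor(config, F)
    opt = Adam(net, lr=config.learning_rate)
    n = Xtr.shape[0]
    best = {"loss": np.inf, "params": None, "epoch": -1}
    history: List[dict] = []
    wait = 0
    for epoch in range(config.max_epochs):
        idx = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            b = idx[start:start + config.batch_size]
            yh, cache = net.forward(Xtr[b], rng=rng, cache=True)
            err = (yh - ytr[b]) * y_range
            ep_loss += mmse_loss(yh * y_range, ytr[b] * y_range, config.loss) * b.size
            grads = net.backward(cache, _loss_grad(err, y_range, config.loss))
            opt.step(grads)
        ep_loss /= n
        yv = net.forward(Xva)
        val_pred = np.clip(invert_scaler(y_scaler, yv.reshape(-1, 1)).ravel(), 0, None)
        val_loss = mmse_loss(val_pred, yva, config.loss)
        if not (np.isfinite(ep_loss) and np.isfinite(val_loss)):
            raise TrainingDivergedError(epoch)
        history.append({"epoch": epoch, "train_loss": ep_loss, "val_loss": val_loss})
        if val_loss < best["loss"] - 1e-12:
            best = {"loss": val_loss,
                    "params": {k: v.copy() for k, v in net.params.items()},
                    "epoch": epoch}
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best["params"] is not None:
        net.params.update(best["params"])
    return TrainedSensor(net=net, config=config,
                         feature_names=list(dataset.feature_names),
                         x_scaler=x_scaler, y_scaler=y_scaler,
                         history=history, val_loss=best["loss"],
                         seed=config.seed,
                         split={"train": train_exps, "val": val_exps})


def train_sensors(dataset: WindowedDataset, configs: Sequence[SensorConfig],
                  columns: Optional[Sequence[Sequence[int]]] = None
                  ) -> List[TrainedSensor]:
    """Train several sensors in lock-step on one windowed dataset.

    Without ``columns`` this trains independent trials of a single input
    group.  With ``columns`` (one equal-length feature-index list per
    config), entry ``e`` sees only its columns of the shared pool windows —
    this is how a whole family of same-size input groups (times their
    trials) is trained in a single stacked pass.  All entries share the
    experiment-level split, the per-feature min-max scaling and the
    minibatch order (derived from ``configs[0].seed``); they differ in
    weight initialization and dropout draws.  Early stopping tracks each
    entry separately, restoring its best weights.
    """
    if not configs:
        raise InvalidInputError("no sensor configs given")
    lead = configs[0]
    rng = np.random.default_rng(lead.seed)
    exps = list(dict.fromkeys(dataset.exp_ids.tolist()))
    if len(exps) < 2:
        raise InvalidInputError("need >= 2 experiments for an experiment-level split")
    order = rng.permutation(len(exps))
    n_train = max(1, int(round(lead.train_fraction * len(exps))))
    n_train = min(n_train, len(exps) - 1)
    train_exps = {exps[i] for i in order[:n_train]}
    val_exps = set(exps) - train_exps
    tr_mask = np.isin(dataset.exp_ids, list(train_exps))
    Xtr_raw, ytr_raw = dataset.X[tr_mask], dataset.y[tr_mask]
    Xva_raw, yva_raw = dataset.X[~tr_mask], dataset.y[~tr_mask]

    F = dataset.X.shape[2]
    pool_scaler = fit_scaler(Xtr_raw.reshape(-1, F))
    y_scaler = fit_scaler(ytr_raw.reshape(-1, 1))
    y_range = float(y_scaler.scale[0])
    dtype = np.dtype(lead.precision)
    Xtr = _scale_windows(Xtr_raw, pool_scaler).astype(dtype)
    Xva = _scale_windows(Xva_raw, pool_scaler).astype(dtype)
    ytr = (ytr_raw - y_scaler.data_min[0]) / y_range

    if columns is not None:
        if len(columns) != len(configs):
            raise InvalidInputError("one column list per config required")
        C = np.asarray(columns, dtype=int)          # (E, k), equal k enforced
        n_feat = C.shape[1]
        # (n, T, F)[..., C] -> (n, T, E, k) -> (E, n, T, k)
        Xva_e = np.ascontiguousarray(Xva[..., C].transpose(2, 0, 1, 3))
        feat_names = [[dataset.feature_names[j] for j in row] for row in C]
        scalers = [MinMaxScaler(data_min=pool_scaler.data_min[row],
                                scale=pool_scaler.scale[row]) for row in C]
    else:
        C = None
        n_feat = F
        Xva_e = Xva
        feat_names = [list(dataset.feature_names)] * len(configs)
        scalers = [pool_scaler] * len(configs)

    nets = [build_sensor(cfg, n_feat) for cfg in configs]
    stack = BatchedNets(nets)
    opt = Adam(stack, lr=lead.learning_rate)
    E = len(configs)
    n = Xtr.shape[0]
    best_loss = np.full(E, np.inf)
    best_params = [None] * E
    best_epoch = np.full(E, -1)
    waits = np.zeros(E, dtype=int)
    histories: List[List[dict]] = [[] for _ in range(E)]
    for epoch in range(lead.max_epochs):
        idx = rng.permutation(n)
        ep_loss = np.zeros(E)
        for start in range(0, n, lead.batch_size):
            b = idx[start:start + lead.batch_size]
            if C is None:
                Xb = Xtr[b]
            else:
                Xb = np.ascontiguousarray(Xtr[b][..., C].transpose(2, 0, 1, 3))
            yh, cache = stack.forward(Xb, rng=rng, cache=True)
            err = (yh - ytr[b]) * y_range                      # (E, |b|)
            if lead.loss == "mmse":
                ep_loss += ((np.abs(err) + 1.0) ** 2).sum(axis=1)
                dy = 2.0 * (np.abs(err) + 1.0) * np.sign(err) * y_range / b.size
            else:
                ep_loss += ((np.abs(err) + 1.0) / 2.0).sum(axis=1)
                dy = np.sign(err) * y_range / (2.0 * b.size)
            grads = stack.backward(cache, dy)
            opt.step(grads)
        ep_loss /= n
        yv = stack.forward(Xva_e)                              # (E, n_val)
        val_pred = np.clip(yv * y_range + y_scaler.data_min[0], 0, None)
        verr = np.abs(val_pred - yva_raw)
        if lead.loss == "mmse":
            val_loss = ((verr + 1.0) ** 2).mean(axis=1)
        else:
            val_loss = ((verr + 1.0) / 2.0).mean(axis=1)
        if not (np.all(np.isfinite(ep_loss)) and np.all(np.isfinite(val_loss))):
            raise TrainingDivergedError(epoch)
        for e in range(E):
            histories[e].append({"epoch": epoch, "train_loss": float(ep_loss[e]),
                                 "val_loss": float(val_loss[e])})
            if val_loss[e] < best_loss[e] - 1e-12:
                best_loss[e] = val_loss[e]
                best_params[e] = {k: v[e].copy() for k, v in stack.params.items()}
                best_epoch[e] = epoch
                waits[e] = 0
            else:
                waits[e] += 1
        if np.all(waits >= lead.patience):
            break
    for e in range(E):
        if best_params[e] is not None:
            for k in stack.params:
                stack.params[k][e] = best_params[e][k]
    nets = stack.unstack()
    return [TrainedSensor(net=nets[e], config=configs[e],
                          feature_names=feat_names[e],
                          x_scaler=scalers[e], y_scaler=y_scaler,
                          history=histories[e], val_loss=float(best_loss[e]),
                          seed=configs[e].seed,
                          split={"train": train_exps, "val": val_exps})
            for e in range(E)]


def predict(trained: TrainedSensor, dataset: WindowedDataset) -> np.ndarray:
    """Apply a trained sensor; returns non-negative estimates in g/L."""
    if list(dataset.feature_names) != list(trained.feature_names):
        raise ContractError(
            f"dataset features {dataset.feature_names} do not match the sensor's "
            f"input group {trained.feature_names}")
    X = _scale_windows(dataset.X, trained.x_scaler)
    yh = trained.net.forward(X)
    out = invert_scaler(trained.y_scaler, yh.reshape(-1, 1)).ravel()
    return np.clip(out, 0.0, None)


# ------------------------------------------------------------------ persist
def save_sensor(trained: TrainedSensor, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arch = {
        "config": dataclasses.asdict(trained.config),
        "feature_names": list(trained.feature_names),
        "n_features": trained.net.n_features,
        "val_loss": float(trained.val_loss),
        "seed": trained.seed,
    }
    (d / "architecture.yaml").write_text(yaml.safe_dump(arch))
    np.savez(d / "weights.npz", **trained.net.params)
    pd.DataFrame({
        "feature": trained.feature_names + ["__target__"],
        "data_min": np.append(trained.x_scaler.data_min, trained.y_scaler.data_min),
        "scale": np.append(trained.x_scaler.scale, trained.y_scaler.scale),
    }).to_csv(d / "scaler.csv", index=False)
    pd.DataFrame(trained.history).to_csv(d / "history.csv", index=False)


def load_sensor(directory) -> TrainedSensor:
    d = Path(directory)
    arch = yaml.safe_load((d / "architecture.yaml").read_text())
    config = SensorConfig(**arch["config"])
    net = build_sensor(config, arch["n_features"])
    with np.load(d / "weights.npz") as w:
        net.params.update({k: w[k] for k in w.files})
    sc = pd.read_csv(d / "scaler.csv")
    x_scaler = MinMaxScaler(data_min=sc["data_min"].to_numpy()[:-1],
                            scale=sc["scale"].to_numpy()[:-1])
    y_scaler = MinMaxScaler(data_min=sc["data_min"].to_numpy()[-1:],
                            scale=sc["scale"].to_numpy()[-1:])
    hist = pd.read_csv(d / "history.csv") if (d / "history.csv").stat().st_size else None
    history = hist.to_dict("records") if hist is not None else []
    return TrainedSensor(net=net, config=config, feature_names=arch["feature_names"],
                         x_scaler=x_scaler, y_scaler=y_scaler, history=history,
                         val_loss=arch["val_loss"], seed=arch["seed"])
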