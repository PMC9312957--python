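"""The multi-label chromatin-accessibility classifier.

Architecture (for input length L, kernel k, pool width p):

    conv -> ReLU -> conv -> ReLU -> maxpool -> dropout
    -> conv -> ReLU -> conv -> ReLU -> maxpool -> dropout
    -> flatten -> dense -> ReLU -> dropout -> dense -> sigmoid

With the defaults (L=1000, k=9, p=4) the spatial length of the last
convolutional feature map is floor((floor((L-2(k-1))/p) - 2(k-1))/p) = 57
(1000 -> 992 -> 984 -> 246 -> 238 -> 230 -> 57), and the first dense layer
has 925 units. The final dense layer has one unit per cell type; sigmoid
outputs are per-cell-type accessibility probabilities.

Training minimizes mean binary cross-entropy with Adam (lr 5e-4, batch 64).
Both strands of every window are independent training examples; evaluation
takes the element-wise max of the forward- and reverse-strand probabilities.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import nn
from .seqdata import DatasetSplit, EncodedExample, reverse_complement_codes

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    n_cell_types: int
    input_length: int = 1000
    conv_channels: tuple[int, int, int, int] = (160, 160, 320, 320)
    kernel_width: int = 9
    pool_width: int = 4
    dense1_units: int = 925
    dropout_rates: tuple[float, float, float] = (0.2, 0.2, 0.5)
    learning_rate: float = 5e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1:
            raise ValueError("need at least one cell type")
        if self.dense1_units <= self.n_cell_types:
            raise ValueError("dense1_units must exceed the number of cell types")
        if len(self.conv_channels) != 4:
            raise ValueError("conv_channels must list four layer widths")
        if len(self.dropout_rates) != 3:
            raise ValueError("dropout_rates must list three rates")
        z = self.feature_map_length
        if z < 1:
            raise ValueError(
                f"input_length {self.input_length} with kernel {self.kernel_width} "
                f"and pool {self.pool_width} yields feature-map length {z} < 1"
            )

    @property
    def feature_map_length(self) -> int:
        """Spatial length Z of the last conv feature map after both pools."""
        k, p = self.kernel_width, self.pool_width
        length = (self.input_length - 2 * (k - 1)) // p
        return (length - 2 * (k - 1)) // p


class ClassifierModel:
    """The trained (or trainable) network plus its configuration and history."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.training_history: list[dict[str, float]] = []
        rng = np.random.default_rng([config.seed, 3])
        c1, c2, c3, c4 = config.conv_channels
        k, p = config.kernel_width, config.pool_width
        d1, d2, d3 = config.dropout_rates
        self._conv = {
            "conv1": nn.Conv1D(4, c1, k, rng),
            "conv2": nn.Conv1D(c1, c2, k, rng),
            "conv3": nn.Conv1D(c2, c3, k, rng),
            "conv4": nn.Conv1D(c3, c4, k, rng),
        }
        self.features = nn.Sequential([
            self._conv["conv1"], nn.ReLU(),
            self._conv["conv2"], nn.ReLU(),
            nn.MaxPool1D(p), nn.Dropout(d1),
            self._conv["conv3"], nn.ReLU(),
            self._conv["conv4"], nn.ReLU(),
            nn.MaxPool1D(p),
        ])
        z = config.feature_map_length
        self._dense = {
            "dense1": nn.Dense(c4 * z, config.dense1_units, rng),
            "dense2": nn.Dense(config.dense1_units, config.n_cell_types, rng),
        }
        self.head = nn.Sequential([
            nn.Dropout(d2), nn.Flatten(),
            self._dense["dense1"], nn.ReLU(), nn.Dropout(d3),
            self._dense["dense2"],
        ])

    # -- parameter access ---------------------------------------------------

    def _param_layers(self) -> dict[str, nn.Layer]:
        return {**self._conv, **self._dense}

    def param_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{key}": arr
            for name, layer in self._param_layers().items()
            for key, arr in layer.params().items()
        }

    def grad_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{key}": arr
            for name, layer in self._param_layers().items()
            for key, arr in layer.grads().items()
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.param_arrays().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.param_arrays()
        for k, v in state.items():
            params[k][...] = v

    # -- forward passes -----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != 4 or x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected input of shape (n, 4, {self.config.input_length}), "
                f"got {x.shape}"
            )
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None,
                       cache: bool = False) -> np.ndarray:
        a = self.features.forward(self._check_input(x), train=train, rng=rng, cache=cache)
        return self.head.forward(a, train=train, rng=rng, cache=cache)

    def forward_feature_map(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Last conv feature map A (n, K, Z) in evaluation mode."""
        return self.features.forward(self._check_input(x), cache=cache)

    def head_logits(self, feature_map: np.ndarray, cache: bool = False) -> np.ndarray:
        return self.head.forward(feature_map, cache=cache)

    def head_input_grad(self, d_logits: np.ndarray) -> np.ndarray:
        """d(logits . d_logits)/d(feature map); requires a cached head forward."""
        return self.head.backward(d_logits.astype(nn.DTYPE))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-strand sigmoid probabilities in evaluation mode (deterministic)."""
        x = self._check_input(x)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(nn.sigmoid(self.forward_logits(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig) -> ClassifierModel:
    """Instantiate the untrained network (uniform fan-in init under config.seed)."""
    return ClassifierModel(config)


# ---------------------------------------------------------------------------
# Batching


def batch_one_hot(codes: np.ndarray) -> np.ndarray:
    """(n, L) base codes -> (n, 4, L) one-hot float32; code 4 (N) -> zero column."""
    codes = np.asarray(codes)
    n, length = codes.shape
    out = np.zeros((n, 4, length), dtype=nn.DTYPE)
    rows, cols = np.nonzero(codes < 4)
    out[rows, codes[rows, cols], cols] = 1.0
    return out


def _stacked_codes(examples: Sequence[EncodedExample]) -> np.ndarray:
    return np.stack([ex.codes for ex in examples])


def _both_strand_codes(examples: Sequence[EncodedExample]) -> tuple[np.ndarray, np.ndarray]:
    fwd = _stacked_codes(examples)
    return fwd, _rc_codes(fwd)


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    comp = np.where(codes < 4, 3 - codes.astype(np.int16), 4)
    return np.ascontiguousarray(comp.astype(np.uint8)[:, ::-1])


# ---------------------------------------------------------------------------
# Training


def _epoch_loss(model: ClassifierModel, codes: np.ndarray, labels: np.ndarray,
                batch_size: int) -> float:
    total, count = 0.0, 0
    for i in range(0, codes.shape[0], batch_size):
        x = batch_one_hot(codes[i : i + batch_size])
        logits = model.forward_logits(x)
        loss, _ = nn.bce_with_logits(logits, labels[i : i + batch_size])
        total += loss * x.shape[0]
        count += x.shape[0]
    return total / count


def train(
    model: ClassifierModel,
    split: DatasetSplit,
    max_epochs: int | None = None,
    patience: int | None = None,
    verbose: bool = False,
) -> tuple[ClassifierModel, list[dict[str, float]]]:
    """Fit with Adam on binary cross-entropy; keep the best-validation snapshot.

    Both strands of every training and validation window enter as independent
    examples. Training stops after `patience` epochs without validation
    improvement or at `max_epochs`; the returned model carries the parameter
    snapshot with the lowest validation loss. Deterministic per config.seed.
    """
    if not split.train or not split.validation:
        raise ValueError("training requires non-empty train and validation sets")
    cfg = model.config
    max_epochs = cfg.max_epochs if max_epochs is None else max_epochs
    patience = cfg.patience if patience is None else patience

    fwd, rev = _both_strand_codes(split.train)
    train_codes = np.concatenate([fwd, rev], axis=0)
    train_labels = np.concatenate(
        [np.stack([ex.labels for ex in split.train])] * 2, axis=0
    ).astype(nn.DTYPE)
    vfwd, vrev = _both_strand_codes(split.validation)
    val_codes = np.concatenate([vfwd, vrev], axis=0)
    val_labels = np.concatenate(
        [np.stack([ex.labels for ex in split.validation])] * 2, axis=0
    ).astype(nn.DTYPE)

    rng = np.random.default_rng([cfg.seed, 7])
    params = model.param_arrays()
    optimizer = nn.Adam(params, lr=cfg.learning_rate)

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    history: list[dict[str, float]] = []

    n = train_codes.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        running, seen = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            x = batch_one_hot(train_codes[idx])
            y = train_labels[idx]
            logits = model.forward_logits(x, train=True, rng=rng, cache=True)
            loss, dlogits = nn.bce_with_logits(logits, y)
            da = model.head.backward(dlogits)
            model.features.backward(da)
            optimizer.step(model.grad_arrays())
            running += loss * x.shape[0]
            seen += x.shape[0]
        val_loss = _epoch_loss(model, val_codes, val_labels, cfg.batch_size * 4)
        entry = {"epoch": epoch, "train_loss": running / seen, "val_loss": val_loss}
        history.append(entry)
        if verbose:
            print(f"epoch {epoch}: train {entry['train_loss']:.4f} val {val_loss:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= patience:
            break

    model.load_state_dict(best_state)
    model.training_history = history
    return model, history


# ---------------------------------------------------------------------------
# Prediction (strand-max)


def predict(
    model: ClassifierModel,
    examples: Sequence[EncodedExample] | np.ndarray,
    batch_size: int = 256,
) -> np.ndarray:
    """Per-window probabilities: element-wise max over forward and reverse strand."""
    if isinstance(examples, np.ndarray):
        codes = examples if examples.ndim == 2 else examples[None]
    else:
        codes = _stacked_codes(examples)
    if codes.shape[1] != model.config.input_length:
        raise ValueError(
            f"window length {codes.shape[1]} != configured input length "
            f"{model.config.input_length}"
        )
    rev = _rc_codes(codes)
    p_fwd = model.predict_proba(batch_one_hot(codes), batch_size)
    p_rev = model.predict_proba(batch_one_hot(rev), batch_size)
    return np.maximum(p_fwd, p_rev)


def predict_strands(
    model: ClassifierModel, example: EncodedExample
) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse) probability vectors for one window."""
    p_fwd = model.predict_proba(example.forward[None])[0]
    p_rev = model.predict_proba(
        batch_one_hot(reverse_complement_codes(example.codes)[None])
    )[0]
    return p_fwd, p_rev


# ---------------------------------------------------------------------------
# Checkpoints and transfer-learning warm start


def save_checkpoint(model: ClassifierModel, path: str | os.PathLike) -> None:
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.config)}
    with open(path, "wb") as fh:
        np.savez(
            fh,
            __meta__=np.array(json.dumps(meta)),
            **model.param_arrays(),
        )


def _load_npz(path: str | os.PathLike) -> tuple[dict, dict[str, np.ndarray]]:
    try:
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
    except Exception as exc:
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {meta.get('version')} != supported {CHECKPOINT_VERSION}"
        )
    return meta, arrays


def load_checkpoint(path: str | os.PathLike) -> ClassifierModel:
    """Round-trip load: rebuild the model from the embedded config and weights."""
    meta, arrays = _load_npz(path)
    cfg_dict = meta["config"]
    cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
    cfg_dict["dropout_rates"] = tuple(cfg_dict["dropout_rates"])
    model = ClassifierModel(ModelConfig(**cfg_dict))
    params = model.param_arrays()
    if set(params) != set(arrays):
        raise ValueError(f"checkpoint {path} parameter names do not match architecture")
    for k in params:
        if params[k].shape != arrays[k].shape:
            raise ValueError(
                f"checkpoint {path}: shape mismatch for {k}: "
                f"{arrays[k].shape} vs {params[k].shape}"
            )
        params[k][...] = arrays[k]
    return model


def warm_start(model: ClassifierModel, checkpoint_path: str | os.PathLike) -> dict:
    """Transfer-learning initialization from a checkpoint trained elsewhere.

    All layers whose shapes match are loaded; a final dense layer with a
    different cell-type count stays freshly initialized. Any other mismatch
    (the conv stack or the first dense layer) is an error naming the first
    offending parameter. Returns a manifest of loaded vs. reinitialized
    parameters; the model is untouched on error.
    """
    _meta, arrays = _load_npz(checkpoint_path)
    params = model.param_arrays()
    loaded, reinitialized = [], []
    staged: dict[str, np.ndarray] = {}
    for name in sorted(params):
        if name not in arrays:
            raise ValueError(f"checkpoint missing parameter {name}")
        if params[name].shape == arrays[name].shape:
            staged[name] = arrays[name]
            loaded.append(name)
        elif name.startswith("dense2."):
            reinitialized.append(name)
        else:
            raise ValueError(
                f"incompatible checkpoint: shape mismatch at {name}: "
                f"{arrays[name].shape} vs {params[name].shape}"
            )
    for name, arr in staged.items():
        params[name][...] = arr
    return {"loaded": loaded, "reinitialized": reinitialized}
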