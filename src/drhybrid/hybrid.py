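"""Ensemble fusion of basic-model probability outputs.

Three fusers:

* ``Hybrid-a`` — elementwise average of the M probability vectors.
* ``Hybrid-f`` — a 2048-unit hidden layer then a 5-unit softmax layer on the
  vertically stacked (5*M)-vector.
* ``Hybrid-c`` — three 256-filter 3x3 convolutions (padding 1, 1, 0) on the
  horizontally stacked 5xMx1 matrix, flattened into the Hybrid-f stack.

Hybrid-f/c are order-sensitive in the models, so the model order used at
training time is persisted with the fuser and enforced at prediction time.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .backbones import DEFAULT_MODEL_ORDER, read_outputs_csv
from .losses import LossConfig, batch_loss_and_grad, predicted_grade, validate_probability_vector

__all__ = [
    "BaseOutputs",
    "HybridSpec",
    "Fuser",
    "ModelOrderMismatchError",
    "stack_vertical",
    "stack_horizontal",
    "fuse_average",
    "build_hybrid_f",
    "build_hybrid_c",
    "train_hybrid",
    "predict_hybrid",
    "save_fuser",
    "load_fuser",
    "outputs_frame_to_dataset",
]

N_GRADES = 5


class ModelOrderMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class BaseOutputs:
    """M x 5 matrix of per-model probability vectors for one image."""

    matrix: np.ndarray
    model_order: tuple[str, ...]

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != N_GRADES:
            raise ValueError(f"expected (M, {N_GRADES}) matrix, got {matrix.shape}")
        if matrix.shape[0] < 1:
            raise ValueError("need at least one model row")
        order = tuple(self.model_order)
        if len(order) != matrix.shape[0]:
            raise ValueError("model_order length must match row count")
        if len(set(order)) != len(order):
            raise ValueError("model_order has duplicates")
        for row in matrix:
            validate_probability_vector(row)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "model_order", order)

    @property
    def n_models(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class HybridSpec:
    kind: str  # a | f | c
    n_models: int = 5
    n_grades: int = N_GRADES
    hidden_units: int = 2048
    conv_filters: int = 256
    conv_kernel: int = 3

    def __post_init__(self):
        if self.kind not in ("a", "f", "c"):
            raise ValueError(f"kind must be one of a/f/c, got {self.kind!r}")
        if self.hidden_units <= 0 or self.n_models < 1:
            raise ValueError("hidden_units and n_models must be positive")


def stack_vertical(outputs: BaseOutputs) -> np.ndarray:
    """Concatenate model rows into a (5*M)-vector (Hybrid-f input)."""
    return outputs.matrix.reshape(-1)


def stack_horizontal(outputs: BaseOutputs) -> np.ndarray:
    """Column-per-model 5 x M x 1 matrix (Hybrid-c input)."""
    return outputs.matrix.T[:, :, None]


def fuse_average(outputs: BaseOutputs) -> np.ndarray:
    """Elementwise mean over the M model rows."""
    return outputs.matrix.mean(axis=0)


class Fuser:
    """A trainable fusion network tied to a fixed base-model order."""

    def __init__(self, spec: HybridSpec, net: _nn.Sequential,
                 model_order: tuple[str, ...] | None = None):
        self.spec = spec
        self.net = net
        self.model_order = tuple(model_order) if model_order else None

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def _prepare(self, batch: np.ndarray) -> np.ndarray:
        """(B, M, 5) probability stacks -> network input layout."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 3 or batch.shape[2] != N_GRADES:
            raise ValueError(f"expected (B, M, {N_GRADES}) batch, got {batch.shape}")
        if batch.shape[1] != self.spec.n_models:
            raise ValueError(
                f"fuser built for M={self.spec.n_models}, got M={batch.shape[1]}"
            )
        if self.spec.kind == "f":
            return batch.reshape(batch.shape[0], -1)
        return np.ascontiguousarray(batch.transpose(0, 2, 1))[:, :, :, None]

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._prepare(batch), train=train)


def build_hybrid_f(spec: HybridSpec, seed: int = 0) -> Fuser:
    if spec.kind != "f":
        raise ValueError("spec.kind must be 'f'")
    rng = np.random.default_rng(seed)
    net = _nn.Sequential([
        _nn.Dense(spec.n_grades * spec.n_models, spec.hidden_units, rng=rng),
        _nn.ReLU(),
        _nn.Dense(spec.hidden_units, spec.n_grades, rng=rng),
        _nn.Softmax(),
    ])
    return Fuser(spec, net)


def build_hybrid_c(spec: HybridSpec, seed: int = 0) -> Fuser:
    """Conv(pad 1) -> conv(pad 1) -> conv(pad 0) -> flatten -> dense stack."""
    if spec.kind != "c":
        raise ValueError("spec.kind must be 'c'")
    if spec.n_models < 3:
        raise ValueError(
            "Hybrid-c needs M >= 3: the unpadded third convolution shrinks "
            "each spatial dimension by 2"
        )
    rng = np.random.default_rng(seed)
    k, f = spec.conv_kernel, spec.conv_filters
    flat = (spec.n_grades - 2) * (spec.n_models - 2) * f
    net = _nn.Sequential([
        _nn.Conv2D(1, f, kernel=k, padding=1, rng=rng),
        _nn.ReLU(),
        _nn.Conv2D(f, f, kernel=k, padding=1, rng=rng),
        _nn.ReLU(),
        _nn.Conv2D(f, f, kernel=k, padding=0, rng=rng),
        _nn.ReLU(),
        _nn.Flatten(),
        _nn.Dense(flat, spec.hidden_units, rng=rng),
        _nn.ReLU(),
        _nn.Dense(spec.hidden_units, spec.n_grades, rng=rng),
        _nn.Softmax(),
    ])
    return Fuser(spec, net)


def trace_shapes(fuser: Fuser) -> list[tuple[int, ...]]:
    """Per-layer output shapes (batch axis dropped) for one forward pass."""
    x = np.zeros((1, fuser.spec.n_models, N_GRADES), dtype=np.float32)
    x = fuser._prepare(x)
    shapes = []
    for layer in fuser.net.layers:
        x = layer.forward(x, train=False)
        shapes.append(tuple(x.shape[1:]))
    return shapes


@dataclass(frozen=True)
class FusionTrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0


def train_hybrid(fuser: Fuser, stacks: np.ndarray, grades: np.ndarray,
                 cfg: FusionTrainConfig | None = None,
                 model_order: tuple[str, ...] | None = None) -> tuple[Fuser, list[dict]]:
    """Adam + cross-entropy training of a Hybrid-f/c fuser.

    ``stacks`` is (B, M, 5); ``model_order`` (or ``DEFAULT_MODEL_ORDER``
    truncated to M) is stamped onto the fuser for prediction-time checking.
    """
    cfg = cfg or FusionTrainConfig()
    stacks = np.asarray(stacks, dtype=np.float32)
    grades = np.asarray(grades, dtype=np.int64)
    if len(stacks) == 0:
        raise ValueError("empty fusion training set")
    if len(stacks) != len(grades):
        raise ValueError("stacks and grades length mismatch")
    if grades.min() < 0 or grades.max() >= N_GRADES:
        raise ValueError("grades must lie in 0-4")

    if model_order is None:
        model_order = tuple(DEFAULT_MODEL_ORDER[:fuser.spec.n_models])
        if len(model_order) < fuser.spec.n_models:
            model_order = tuple(f"model{i}" for i in range(fuser.spec.n_models))
    fuser.model_order = tuple(model_order)

    rng = np.random.default_rng(cfg.seed)
    opt = _nn.Adam(fuser.net.params(), lr=cfg.learning_rate)
    loss_cfg = LossConfig()
    n = len(grades)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_loss = tot_correct = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs = fuser.forward(stacks[idx], train=True)
            loss, _, grad = batch_loss_and_grad(grades[idx], probs, "ce", loss_cfg)
            fuser.net.zero_grad()
            fuser.net.backward(grad.astype(np.float32))
            opt.step()
            tot_loss += loss * len(idx)
            tot_correct += (probs.argmax(axis=1) == grades[idx]).sum()
        history.append({
            "epoch": epoch + 1,
            "loss": tot_loss / n,
            "accuracy": tot_correct / n,
        })
    return fuser, history


def predict_hybrid(fuser: Fuser | str, outputs: BaseOutputs) -> tuple[np.ndarray, int]:
    """Fused probabilities and their argmax grade (ties toward lowest grade).

    Pass the string ``"a"`` (or a Fuser) — the averaging rule has no
    trainable state.
    """
    if isinstance(fuser, str):
        if fuser != "a":
            raise ValueError("string fuser must be 'a' (averaging)")
        fused = fuse_average(outputs)
        return fused, predicted_grade(fused)
    if fuser.model_order is not None and outputs.model_order != fuser.model_order:
        raise ModelOrderMismatchError(
            f"fuser was trained with model order {fuser.model_order}, "
            f"got {outputs.model_order}"
        )
    fused = fuser.forward(outputs.matrix[None, :, :], train=False)[0].astype(float)
    return fused, predicted_grade(fused)


def predict_hybrid_batch(fuser: Fuser | str, stacks: np.ndarray,
                         batch_size: int = 256) -> np.ndarray:
    """(B, M, 5) -> (B, 5) fused probabilities."""
    stacks = np.asarray(stacks, dtype=np.float32)
    if isinstance(fuser, str):
        if fuser != "a":
            raise ValueError("string fuser must be 'a' (averaging)")
        return stacks.mean(axis=1).astype(float)
    out = [fuser.forward(stacks[i:i + batch_size], train=False)
           for i in range(0, len(stacks), batch_size)]
    return np.concatenate(out, axis=0).astype(float)


# ---------------------------------------------------------------------------
# persistence and cached-output plumbing

def save_fuser(fuser: Fuser, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({
        "kind": fuser.spec.kind,
        "n_models": fuser.spec.n_models,
        "hidden_units": fuser.spec.hidden_units,
        "conv_filters": fuser.spec.conv_filters,
        "conv_kernel": fuser.spec.conv_kernel,
        "model_order": list(fuser.model_order) if fuser.model_order else None,
    })
    weights = {f"w{i}": w for i, w in enumerate(fuser.net.get_weights())}
    np.savez(path, meta=np.array(meta), **weights)


def load_fuser(path: str | Path) -> Fuser:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        weights = [archive[f"w{i}"] for i in range(len(archive.files) - 1)]
    spec = HybridSpec(kind=meta["kind"], n_models=meta["n_models"],
                      hidden_units=meta["hidden_units"],
                      conv_filters=meta["conv_filters"],
                      conv_kernel=meta["conv_kernel"])
    fuser = build_hybrid_f(spec) if spec.kind == "f" else build_hybrid_c(spec)
    fuser.net.set_weights(weights)
    if meta["model_order"]:
        fuser.model_order = tuple(meta["model_order"])
    return fuser


def outputs_frame_to_dataset(df: pd.DataFrame | str | Path,
                             model_order: list[str] | None = None
                             ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], list]:
    """Cached outputs table -> ((B, M, 5) stacks, grades, model order, image ids).

    The table holds one row per (image, model); every image must have one row
    for every model in ``model_order`` (default: the order the models appear).
    """
    if not isinstance(df, pd.DataFrame):
        df = read_outputs_csv(df)
    if model_order is None:
        model_order = list(dict.fromkeys(df["model_name"]))
    prob_cols = [f"p{g}" for g in range(N_GRADES)]
    wide = df.pivot_table(index=["image_id", "grade"], columns="model_name",
                          values=prob_cols, sort=False)
    if wide.isna().any().any():
        raise ValueError("every image needs an output row for every model")
    image_ids = [i for i, _ in wide.index]
    grades = np.array([g for _, g in wide.index], dtype=np.int64)
    stacks = np.empty((len(wide), len(model_order), N_GRADES))
    for m, name in enumerate(model_order):
        for g, col in enumerate(prob_cols):
            stacks[:, m, g] = wide[(col, name)].to_numpy()
    return stacks, grades, tuple(model_order), image_ids
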