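"""Basic classifier models behind a name registry.

Each registered model maps an SxSx3 uint8 batch to 5-grade probability
vectors via a convolutional trunk and a classifier head (dropout + 5-unit
softmax dense layer; the InceptionResNetV2 entry replaces only the final
dense layer, so its head has no dropout).

No GPU deep-learning framework is available in this environment, so the
named large backbones are registered with their published input sizes,
batch sizes and head wiring, but their trunks are small CPU stand-ins built
on the bundled numpy engine; ``pretrained=True`` is therefore always an
explicit error, never a silent random initialization.  ``TinyCNN`` is the
desk-scale backbone the test-suite trains for real.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .imageprep import AugmentConfig, GradedImage, augment_image
from .losses import LossConfig, batch_loss_and_grad

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "BasicModel",
    "PretrainedWeightsUnavailableError",
    "REGISTRY",
    "DEFAULT_MODEL_ORDER",
    "get_backbone_spec",
    "build_basic_model",
    "train_basic_model",
    "predict_probabilities",
    "save_model",
    "load_model",
    "write_outputs_csv",
    "read_outputs_csv",
]

N_GRADES = 5


class PretrainedWeightsUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_size: int
    batch_size: int
    dropout_rate: float = 0.4
    n_outputs: int = N_GRADES
    pretrained: bool = False

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_outputs != N_GRADES:
            raise ValueError(f"n_outputs must be {N_GRADES}")


#: published input/batch sizes; InceptionResNetV2 keeps its original head
#: minus the 1000-unit layer, hence no added dropout.
REGISTRY: dict[str, BackboneSpec] = {
    "EfficientNetB4": BackboneSpec("EfficientNetB4", input_size=380, batch_size=32),
    "EfficientNetB5": BackboneSpec("EfficientNetB5", input_size=299, batch_size=40),
    "NASNetLarge": BackboneSpec("NASNetLarge", input_size=331, batch_size=64),
    "Xception": BackboneSpec("Xception", input_size=299, batch_size=64),
    "InceptionResNetV2": BackboneSpec("InceptionResNetV2", input_size=299,
                                      batch_size=32, dropout_rate=0.0),
    "TinyCNN": BackboneSpec("TinyCNN", input_size=64, batch_size=32, dropout_rate=0.1),
}

#: canonical row order for ensemble fusion inputs
DEFAULT_MODEL_ORDER = ["EfficientNetB4", "EfficientNetB5", "NASNetLarge",
                       "InceptionResNetV2", "Xception"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer_name: str = "radam"
    initial_learning_rate: float = 8e-4
    epochs: int = 50
    loss_name: str = "ce"  # ce | ece
    penalty_mode: str = "hard"
    batch_size: int | None = None  # None -> backbone's registered batch size
    seed: int = 0
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    min_learning_rate: float = 1e-6

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.loss_name not in ("ce", "ece"):
            raise ValueError(f"unknown loss {self.loss_name!r}")
        if self.optimizer_name.lower() not in ("adam", "radam"):
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")


def get_backbone_spec(model_name: str) -> BackboneSpec:
    try:
        return REGISTRY[model_name]
    except KeyError:
        raise KeyError(
            f"unknown model {model_name!r}; registered: {sorted(REGISTRY)}"
        ) from None


class BasicModel:
    """A trunk + head classifier with strict input-shape checking."""

    def __init__(self, spec: BackboneSpec, net: _nn.Sequential):
        self.spec = spec
        self.net = net

    def _validate_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        s = self.spec.input_size
        if batch.ndim != 4 or batch.shape[1:] != (s, s, 3):
            raise ValueError(
                f"{self.spec.name} expects batches of shape (B, {s}, {s}, 3), "
                f"got {batch.shape}"
            )
        return batch

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._validate_batch(batch), train=train)

    @property
    def n_params(self) -> int:
        return self.net.n_params


def _tiny_cnn(spec: BackboneSpec, rng: np.random.Generator) -> list[_nn.Layer]:
    return [
        _nn.Scale(1.0 / 255.0),
        _nn.Conv2D(3, 8, kernel=3, stride=2, padding=1, rng=rng),
        _nn.ReLU(),
        _nn.Conv2D(8, 16, kernel=3, stride=2, padding=1, rng=rng),
        _nn.ReLU(),
        _nn.Flatten(),
        _nn.Dense((spec.input_size // 4) ** 2 * 16, 64, rng=rng),
        _nn.ReLU(),
    ]


def _standin_trunk(rng: np.random.Generator) -> list[_nn.Layer]:
    # input-size agnostic: strided convs + global average pooling
    return [
        _nn.Scale(1.0 / 255.0),
        _nn.Conv2D(3, 16, kernel=5, stride=4, rng=rng),
        _nn.ReLU(),
        _nn.Conv2D(16, 32, kernel=3, stride=4, rng=rng),
        _nn.ReLU(),
        _nn.GlobalAvgPool(),
    ]


def build_basic_model(spec: BackboneSpec, seed: int = 0) -> BasicModel:
    """Trunk + (dropout, 5-unit softmax) head per the registered spec."""
    get_backbone_spec(spec.name)  # must be a registered name
    if spec.pretrained:
        raise PretrainedWeightsUnavailableError(
            f"no pretrained weights are available for {spec.name} in this "
            "environment; build with pretrained=False"
        )
    rng = np.random.default_rng(seed)
    if spec.name == "TinyCNN":
        layers = _tiny_cnn(spec, rng)
        feat = 64
    else:
        layers = _standin_trunk(rng)
        feat = 32
    if spec.dropout_rate > 0:
        layers.append(_nn.Dropout(spec.dropout_rate, rng=rng))
    layers += [_nn.Dense(feat, spec.n_outputs, rng=rng), _nn.Softmax()]
    return BasicModel(spec, _nn.Sequential(layers))


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    """Sequence of GradedImage -> (pixel batch, grade vector)."""
    if len(data) == 0:
        raise ValueError("empty training data")
    pixels = np.stack([im.pixels for im in data])
    grades = np.array([im.grade for im in data], dtype=np.int64)
    return pixels, grades


def train_basic_model(model: BasicModel, data: list[GradedImage], train_cfg: TrainConfig,
                      aug_cfg: AugmentConfig | None = None) -> tuple[BasicModel, list[dict]]:
    """Minibatch training; returns the model and a per-epoch history.

    History entries carry ``epoch, loss, ce, accuracy, lr``; for the E-CE
    loss, ``loss`` includes the ordinal penalty while ``ce`` is the plain
    cross-entropy component recorded alongside it.
    """
    pixels, grades = _as_arrays(data)
    model._validate_batch(pixels[:1])
    rng = np.random.default_rng(train_cfg.seed)
    batch_size = train_cfg.batch_size or model.spec.batch_size
    loss_cfg = LossConfig(penalty_mode=train_cfg.penalty_mode)

    opt_cls = _nn.RAdam if train_cfg.optimizer_name.lower() == "radam" else _nn.Adam
    opt = opt_cls(model.net.params(), lr=train_cfg.initial_learning_rate)
    schedule = _nn.ReduceLROnPlateau(opt, factor=train_cfg.plateau_factor,
                                     patience=train_cfg.plateau_patience,
                                     min_lr=train_cfg.min_learning_rate)

    n = len(grades)
    history: list[dict] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        tot_loss = tot_ce = tot_correct = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = pixels[idx]
            if aug_cfg is not None:
                batch = np.stack([augment_image(im, aug_cfg, rng) for im in batch])
            probs = model.forward(batch, train=True)
            loss, ce, grad = batch_loss_and_grad(grades[idx], probs,
                                                 train_cfg.loss_name, loss_cfg)
            model.net.zero_grad()
            model.net.backward(grad.astype(np.float32))
            opt.step()
            tot_loss += loss * len(idx)
            tot_ce += ce * len(idx)
            tot_correct += (probs.argmax(axis=1) == grades[idx]).sum()
        epoch_loss = tot_loss / n
        history.append({
            "epoch": epoch + 1,
            "loss": epoch_loss,
            "ce": tot_ce / n,
            "accuracy": tot_correct / n,
            "lr": opt.lr,
        })
        schedule.step(epoch_loss)
    return model, history


def predict_probabilities(model: BasicModel, images, batch_size: int = 64) -> list[np.ndarray]:
    """Inference-mode probabilities, one vector per image (dropout inactive)."""
    if len(images) == 0:
        return []
    if isinstance(images[0], GradedImage):
        pixels = np.stack([im.pixels for im in images])
    else:
        pixels = np.asarray(images)
    out = []
    for start in range(0, len(pixels), batch_size):
        out.append(model.forward(pixels[start:start + batch_size], train=False))
    return list(np.concatenate(out, axis=0).astype(float))


# ---------------------------------------------------------------------------
# persistence

def save_model(model: BasicModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({
        "name": model.spec.name,
        "input_size": model.spec.input_size,
        "batch_size": model.spec.batch_size,
        "dropout_rate": model.spec.dropout_rate,
    })
    weights = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    np.savez(path, meta=np.array(meta), **weights)


def load_model(path: str | Path, seed: int = 0) -> BasicModel:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        weights = [archive[f"w{i}"] for i in range(len(archive.files) - 1)]
    spec = replace(get_backbone_spec(meta["name"]), dropout_rate=meta["dropout_rate"])
    model = build_basic_model(spec, seed=seed)
    model.net.set_weights(weights)
    return model


def write_history_csv(history: list[dict], path: str | Path) -> None:
    pd.DataFrame(history).to_csv(path, index=False)


# cached per-image model outputs: image_id,grade,p0..p4,model_name
_PROB_COLS = [f"p{g}" for g in range(N_GRADES)]


def write_outputs_csv(rows: pd.DataFrame, path: str | Path) -> None:
    expected = ["image_id", "grade", *_PROB_COLS, "model_name"]
    missing = set(expected) - set(rows.columns)
    if missing:
        raise ValueError(f"outputs frame lacks columns: {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows[expected].to_csv(path, index=False)


def read_outputs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"image_id", "grade", "model_name", *_PROB_COLS} - set(df.columns)
    if missing:
        raise ValueError(f"outputs file {path} lacks columns: {sorted(missing)}")
    return df
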