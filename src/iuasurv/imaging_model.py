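"""Image survival models: backbones, Cox head, training and complexity.

A model maps a preprocessed hysteroscopic image to a scalar log-hazard of
conception.  The trainable path uses the ``tiny_test`` convolutional
backbone (a small seeded CNN suited to desk-scale synthetic cohorts and the
package's own NumPy layer engine) or a ``tabular`` identity backbone that
feeds clinical covariates straight into the head.  The four published
transfer-learning backbones are available as analytic architecture tapes
for parameter/FLOP accounting (see ``_architectures``); they are not
instantiated with weights here.

Training minimizes the per-event negative log Cox partial likelihood with an
L2 weight penalty.  Risk sets are formed within each minibatch (batches are
sorted by follow-up time), the only consistent reading of Cox training with
small batches; a full-batch mode is available for head fine-tuning.
"""

from __future__ import annotations

import time as _time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from PIL import Image

from . import _nn
from ._architectures import KNOWN_ARCHITECTURES, Tape, architecture_tape
from .survival_core import CohortTable, RiskScore, cox_loss_and_score_gradient

__all__ = [
    "BackboneSpec",
    "SurvivalHeadSpec",
    "TrainConfig",
    "ComplexityReport",
    "DeepSurvModel",
    "preprocess_image",
    "build_model",
    "train",
    "predict_patient",
    "count_parameters",
    "count_flops",
    "measure_inference_time",
    "complexity_report",
]

FLOP_CONVENTION = "multiply-accumulate = 2 FLOPs; batch-norm folded (2/elem)"


@dataclass
class BackboneSpec:
    """Which feature extractor to use and at what input size.

    ``tiny_test`` is a small configurable CNN for desk-scale work; the four
    named ImageNet architectures are analytic tapes (complexity only);
    ``tabular`` feeds covariate vectors directly to the survival head.
    """

    name: str = "tiny_test"
    input_size: int = 336
    feature_dim: int = 32
    pretrained: bool = False
    channels: Sequence[int] = (8, 16, 32)  # tiny_test conv widths
    min_resolution: Optional[int] = None

    _FEATURE_DIMS = {
        "inception_v3": 2048,
        "resnet50": 2048,
        "inception_resnet_v2": 1536,
        "vgg19": 512,
    }

    def __post_init__(self) -> None:
        known = set(KNOWN_ARCHITECTURES) | {"tiny_test", "tabular"}
        if self.name not in known:
            raise ValueError(f"unknown backbone {self.name!r}; known: {sorted(known)}")
        if self.name in self._FEATURE_DIMS:
            self.feature_dim = self._FEATURE_DIMS[self.name]
            if self.min_resolution is None:
                self.min_resolution = 300
        elif self.name == "tiny_test":
            self.feature_dim = int(self.channels[-1])


@dataclass
class SurvivalHeadSpec:
    """The Cox regression head: SELU MLP ending in one linear node."""

    hidden_layers: int = 2
    nodes_per_layer: int = 8
    activation: str = "selu"
    dropout: float = 0.5
    batch_norm: bool = True


@dataclass
class TrainConfig:
    """Training hyperparameters; the defaults are the grid-search optimum
    reported for the clinical model (learning rate 0.154, weight decay
    0.00567, momentum 0.887, Nadam, batch 16).  Small desk-scale CNNs are
    normally trained with a smaller learning rate passed explicitly."""

    learning_rate: float = 0.154
    weight_decay: float = 0.00567
    momentum: float = 0.887
    optimizer: str = "nadam"  # or "sgd_nesterov"
    batch_size: int = 16
    epochs: int = 300
    gradient_clip: float = 5.0
    lr_decay: float = 1.0  # multiplicative per-epoch schedule
    seed: int = 0
    aggregation: str = "mean"  # patient-level pooling of image scores
    dropout_transfer: float = 0.2  # after pooled backbone features


@dataclass
class ComplexityReport:
    model_id: str
    param_count: int
    flops: int
    avg_inference_seconds: Optional[float]
    flop_convention: str = FLOP_CONVENTION

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess_image(
    image: Union[str, Image.Image, np.ndarray],
    spec: Optional[BackboneSpec] = None,
) -> np.ndarray:
    """Load, validate, resize and scale an image to a model input tensor.

    Images below the minimum acquisition resolution (300 px on either side
    for the clinical backbones) are rejected; non-RGB inputs are converted
    with a warning.  Bilinear resize to ``spec.input_size`` square, then
    scaled to [-1, 1].  Deterministic: the same file always yields the same
    tensor.
    """
    spec = spec or BackboneSpec()
    if isinstance(image, str):
        img = Image.open(image)
    elif isinstance(image, np.ndarray):
        arr = image
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        img = Image.fromarray(arr)
    else:
        img = image
    if img.mode != "RGB":
        warnings.warn(f"image mode {img.mode} converted to RGB")
        img = img.convert("RGB")
    w, h = img.size
    if spec.min_resolution is not None and (
        w < spec.min_resolution or h < spec.min_resolution
    ):
        raise ValueError(
            f"below-min-resolution: {w}x{h} < {spec.min_resolution} required"
        )
    img = img.resize((spec.input_size, spec.input_size), Image.BILINEAR)
    x = np.asarray(img, dtype=np.float64) / 255.0
    return x * 2.0 - 1.0


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------


class DeepSurvModel:
    """A backbone + survival head producing one log-hazard per input."""

    def __init__(
        self,
        backbone: BackboneSpec,
        head: SurvivalHeadSpec,
        net: _nn.Sequential,
        conv_layer_indices: List[int],
        seed: int,
    ):
        self.backbone = backbone
        self.head = head
        self.net = net
        self.conv_layer_indices = conv_layer_indices
        self.seed = seed

    def forward_scores(
        self, x: np.ndarray, train: bool = False, keep_activations: bool = False
    ) -> np.ndarray:
        out = self.net.forward(x, train=train, keep_activations=keep_activations)
        return out[:, 0]

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def _build_head(layers: List[_nn.Layer], in_dim: int, head: SurvivalHeadSpec, rng,
                dropout_transfer: float) -> None:
    if dropout_transfer > 0:
        layers.append(_nn.Dropout(dropout_transfer, rng))
    dim = in_dim
    for _ in range(head.hidden_layers):
        layers.append(_nn.Dense(dim, head.nodes_per_layer, rng))
        if head.batch_norm:
            layers.append(_nn.BatchNorm(head.nodes_per_layer))
        if head.activation == "selu":
            layers.append(_nn.SELU())
        elif head.activation != "linear":
            raise ValueError(f"unsupported activation {head.activation!r}")
        if head.dropout > 0:
            layers.append(_nn.Dropout(head.dropout, rng))
        dim = head.nodes_per_layer
    layers.append(_nn.Dense(dim, 1, rng))


def build_model(
    backbone: BackboneSpec,
    head: Optional[SurvivalHeadSpec] = None,
    seed: int = 0,
    dropout_transfer: float = 0.2,
) -> DeepSurvModel:
    """Assemble a trainable model: backbone -> GAP -> head -> log-hazard.

    Only ``tiny_test`` and ``tabular`` backbones are trainable in this
    package; the named ImageNet architectures raise (use
    ``complexity_report`` for their accounting).
    """
    head = head or SurvivalHeadSpec()
    rng = np.random.default_rng(seed)
    layers: List[_nn.Layer] = []
    conv_idx: List[int] = []
    if backbone.name == "tiny_test":
        c_in = 3
        for i, c_out in enumerate(backbone.channels):
            layers.append(_nn.Conv2D(c_in, c_out, 3, rng))
            conv_idx.append(len(layers) - 1)
            layers.append(_nn.BatchNorm(c_out))
            layers.append(_nn.SELU())
            if i < len(backbone.channels) - 1:
                layers.append(_nn.MaxPool2D())
            c_in = c_out
        layers.append(_nn.GlobalAvgPool())
        feat = backbone.feature_dim
    elif backbone.name == "tabular":
        feat = backbone.feature_dim
    else:
        raise ValueError(
            f"backbone {backbone.name!r} is an analytic architecture tape; "
            "it cannot be instantiated with weights here"
        )
    _build_head(layers, feat, head, rng, dropout_transfer)
    return DeepSurvModel(backbone, head, _nn.Sequential(layers), conv_idx, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _stack_images(
    cohort: CohortTable, images: Dict[str, List[np.ndarray]]
) -> tuple:
    """Flatten per-patient image lists into (X, times, events, patient_idx)."""
    xs, ts, es, pid = [], [], [], []
    for i, rec in enumerate(cohort.records):
        imgs = images.get(rec.patient_id, [])
        for im in imgs:
            xs.append(im)
            ts.append(rec.time)
            es.append(rec.event)
            pid.append(i)
    if not xs:
        raise ValueError("no images for any patient in cohort")
    return np.stack(xs), np.asarray(ts), np.asarray(es, int), np.asarray(pid)


def train(
    model: DeepSurvModel,
    cohort: CohortTable,
    images: Optional[Dict[str, List[np.ndarray]]],
    config: TrainConfig,
    val_cohort: Optional[CohortTable] = None,
    val_images: Optional[Dict[str, List[np.ndarray]]] = None,
    covariates: bool = False,
) -> dict:
    """Minibatch Cox training; returns a history dict.

    Each image carries its patient's follow-up time and event flag; a batch
    is sorted by time and contributes the Breslow partial likelihood over
    its own risk sets.  Batches without any event are skipped (counted in
    the history).  Fully reproducible given ``config.seed``.
    """
    if cohort.events.sum() < 2:
        raise ValueError("need at least 2 events to train")
    if covariates:
        X = cohort.covariate_matrix
        times, events = cohort.times, cohort.events
    else:
        X, times, events, _ = _stack_images(cohort, images)

    rng = np.random.default_rng(config.seed)
    net = model.net
    if config.optimizer == "nadam":
        opt = _nn.Nadam(net, lr=config.learning_rate)
    elif config.optimizer == "sgd_nesterov":
        opt = _nn.SGDNesterov(net, lr=config.learning_rate, momentum=config.momentum)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    n = X.shape[0]
    bs = min(config.batch_size, n)
    history = {"train_loss": [], "val_loss": [], "skipped_batches": 0, "epochs": 0}
    lam = config.weight_decay
    lr0 = config.learning_rate
    for epoch in range(config.epochs):
        opt.lr = lr0 * (config.lr_decay ** epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            if events[idx].sum() == 0:
                history["skipped_batches"] += 1
                continue
            # sort the batch by time so risk sets are contiguous
            idx = idx[np.argsort(times[idx], kind="stable")]
            net.zero_grad()
            scores = model.forward_scores(X[idx], train=True)
            loss, dscores = cox_loss_and_score_gradient(scores, times[idx], events[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: scores "
                    f"range [{scores.min():.3g}, {scores.max():.3g}]"
                )
            net.backward(dscores[:, None])
            if lam > 0:
                for p in net.parameters():
                    if p[3]:
                        p[2] += 2.0 * lam * p[1]
            _nn.clip_gradients(net, config.gradient_clip)
            opt.step()
            losses.append(loss + lam * net.weight_sq_norm())
        history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        if val_cohort is not None:
            if covariates:
                vs = model.forward_scores(val_cohort.covariate_matrix, train=False)
                vt, ve = val_cohort.times, val_cohort.events
            else:
                vX, vt, ve, _ = _stack_images(val_cohort, val_images)
                vs = model.forward_scores(vX, train=False)
            vloss, _ = cox_loss_and_score_gradient(vs, vt, ve)
            history["val_loss"].append(float(vloss))
        history["epochs"] = epoch + 1
    return history


def predict_patient(
    model: DeepSurvModel,
    images: List[np.ndarray],
    aggregation: str = "mean",
    patient_id: str = "",
) -> RiskScore:
    """Aggregate per-image log-hazards into one patient score."""
    if len(images) == 0:
        raise ValueError(f"no images for patient {patient_id!r}")
    scores = model.forward_scores(np.stack(images), train=False)
    if aggregation == "mean":
        agg = float(scores.mean())
    elif aggregation == "max":
        agg = float(scores.max())
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return RiskScore(patient_id=patient_id, log_hazard=agg)


def predict_cohort(
    model: DeepSurvModel,
    cohort: CohortTable,
    images: Dict[str, List[np.ndarray]],
    aggregation: str = "mean",
) -> np.ndarray:
    """Patient-level log-hazards in cohort record order."""
    return np.array(
        [
            predict_patient(model, images[r.patient_id], aggregation, r.patient_id).log_hazard
            for r in cohort.records
        ]
    )


# ---------------------------------------------------------------------------
# Complexity accounting
# ---------------------------------------------------------------------------


def _tiny_tape(channels: Sequence[int], input_size: int) -> Tape:
    t = Tape(input_size, input_size, 3)
    for i, c_out in enumerate(channels):
        t.conv(c_out, 3, bias=True, bn="scale", name=f"tiny_conv{i + 1}")
        if i < len(channels) - 1:
            t.pool(2, 2)
    return t


def count_parameters(model_or_name: Union[str, DeepSurvModel, BackboneSpec]) -> int:
    """Total weight count, trainable plus batch-norm statistics.

    For a named ImageNet architecture this is the headless backbone total
    (the published accounting); for a built model it includes the head.
    """
    if isinstance(model_or_name, str):
        return architecture_tape(model_or_name).n_params
    if isinstance(model_or_name, BackboneSpec):
        name = model_or_name.name
        if name in KNOWN_ARCHITECTURES:
            return architecture_tape(name, model_or_name.input_size).n_params
        if name == "tiny_test":
            return _tiny_tape(model_or_name.channels, model_or_name.input_size).n_params
        raise ValueError(f"no parameter accounting for backbone {name!r}")
    return model_or_name.n_parameters()


def count_flops(
    model_or_name: Union[str, DeepSurvModel, BackboneSpec], input_size: Optional[int] = None
) -> int:
    """Forward-pass FLOPs at the given input size (MAC = 2 convention)."""
    if isinstance(model_or_name, str):
        return architecture_tape(model_or_name, input_size or 336).flops
    if isinstance(model_or_name, BackboneSpec):
        spec = model_or_name
        size = input_size or spec.input_size
        if spec.name in KNOWN_ARCHITECTURES:
            return architecture_tape(spec.name, size).flops
        if spec.name == "tiny_test":
            return _tiny_tape(spec.channels, size).flops
        raise ValueError(f"no FLOP accounting for backbone {spec.name!r}")
    model = model_or_name
    size = input_size or model.backbone.input_size
    flops = 0
    if model.backbone.name == "tiny_test":
        flops += _tiny_tape(model.backbone.channels, size).flops
    # head: dense layers, 2 FLOPs per weight
    for layer in model.net.layers:
        if isinstance(layer, _nn.Dense):
            w = layer.params[0][1]
            flops += 2 * w.size + w.shape[1]
    return flops


def measure_inference_time(
    model: DeepSurvModel, n_images: int = 8, repeats: int = 5, seed: int = 0
) -> float:
    """Mean wall-clock seconds for a single-image prediction (after warm-up)."""
    rng = np.random.default_rng(seed)
    size = model.backbone.input_size
    if model.backbone.name == "tabular":
        x = rng.normal(size=(1, model.backbone.feature_dim))
    else:
        x = rng.normal(size=(1, size, size, 3))
    model.forward_scores(x)  # warm-up
    timings = []
    for _ in range(repeats):
        t0 = _time.perf_counter()
        for _ in range(n_images):
            model.forward_scores(x)
        timings.append((_time.perf_counter() - t0) / n_images)
    return float(np.mean(timings))


def complexity_report(
    model_or_name: Union[str, DeepSurvModel],
    input_size: int = 336,
    measure_time: bool = False,
) -> ComplexityReport:
    """Parameter, FLOP and (optionally) timing summary for one model."""
    if isinstance(model_or_name, str):
        return ComplexityReport(
            model_id=model_or_name,
            param_count=count_parameters(model_or_name),
            flops=count_flops(model_or_name, input_size),
            avg_inference_seconds=None,
        )
    model = model_or_name
    avg = measure_inference_time(model) if measure_time else None
    return ComplexityReport(
        model_id=model.backbone.name,
        param_count=count_parameters(model),
        flops=count_flops(model, input_size=model.backbone.input_size),
        avg_inference_seconds=avg,
    )
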