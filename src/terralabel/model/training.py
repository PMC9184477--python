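"""Dual-pathway training of the labeling model and its synthesis replica.

The labeling model maps a 9-band normalized stack to a per-pixel distribution
over the 9 land-cover classes.  The synthesis model is a replica of the same
architecture that maps the estimated probabilities back to the input
reflectances — a reverse classifier whose reconstruction error acts as weak
supervision.  Gradient routing is asymmetric: the labeling model is optimized
with respect to both the classification and the synthesis losses (the latter
reaching it through the synthesis model's input), while the synthesis model
is optimized only with respect to the synthesis loss.

Pixels annotated as cloud (annotation class 9) and pixels under the
cloud/shadow mask are excluded from the classification term; the synthesis
term runs over all clear pixels, labeled or not.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..io_core import CLOUD_CLASS, N_CLASSES
from ..training_prep import TrainingExample
from . import nn

ALGORITHM_VERSION = "terralabel-model-0.1.0"


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    in_bands: int = 9
    out_classes: int = N_CLASSES
    base_channels: int = 32
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    lambda_synth: float = 1.0
    learning_rate: float = 5e-3
    epochs: int = 20
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_bands != 9 or self.out_classes != N_CLASSES:
            raise TrainingError("model is defined for 9 input bands and 9 classes")
        if self.lambda_synth < 0:
            raise TrainingError("lambda_synth must be >= 0")


@dataclass
class LossReport:
    classification: list[float] = field(default_factory=list)
    synthesis: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    final_validation_accuracy: float | None = None


def build_models(config: ModelConfig) -> tuple[nn.FCN, nn.FCN]:
    """Labeling model (9 bands -> 9-class distribution) and synthesis replica
    (9-class distribution -> 9-band reflectance estimate)."""
    labeling = nn.FCN(config.in_bands, config.out_classes, config.base_channels,
                      config.dilations, seed=config.seed)
    synthesis = nn.FCN(config.out_classes, config.in_bands, config.base_channels,
                       config.dilations, seed=config.seed + 1)
    return labeling, synthesis


def classification_targets(example: TrainingExample) -> tuple[np.ndarray, np.ndarray]:
    """9-class targets (cloud column dropped, renormalized) and the validity
    mask (labeled, clear, and not annotated as cloud)."""
    targets = example.targets
    labeled_class = targets.argmax(axis=0)
    valid = example.labeled & example.clear & (labeled_class != CLOUD_CLASS)
    t9 = targets[:N_CLASSES].astype(np.float64)
    s = t9.sum(axis=0)
    t9 = np.divide(t9, s, out=np.zeros_like(t9), where=s > 0)
    return t9.astype(np.float32), valid


def compute_losses(pred_probs: np.ndarray, example: TrainingExample,
                   synth_pred: np.ndarray | None,
                   config: ModelConfig) -> tuple[float, float, np.ndarray, np.ndarray | None]:
    """Losses plus their gradients with respect to the model outputs.

    Returns ``(loss_cls, loss_syn, dprobs_cls, dsynth)``; ``dsynth`` is the
    gradient w.r.t. the synthesis output (None when the pathway is off).
    """
    t9, valid = classification_targets(example)
    w = example.class_weight * valid
    wsum = float(w.sum())
    p = np.clip(pred_probs, 1e-12, None)
    if wsum > 0:
        ce = -(t9 * np.log(p)).sum(axis=0)
        loss_cls = float((w * ce).sum() / wsum)
        dprobs_cls = -(w / wsum) * t9 / p
    else:
        warnings.warn("no pixels contribute to the classification loss")
        loss_cls, dprobs_cls = 0.0, np.zeros_like(pred_probs)

    loss_syn, dsynth = 0.0, None
    if synth_pred is not None:
        ws = example.synth_weight * example.clear
        ws_sum = float(ws.sum())
        if ws_sum > 0:
            resid = synth_pred - example.inputs
            n_bands = synth_pred.shape[0]
            loss_syn = float((ws * (resid ** 2).mean(axis=0)).sum() / ws_sum)
            dsynth = (2.0 / n_bands) * ws * resid / ws_sum
        else:
            warnings.warn("no pixels contribute to the synthesis loss")
            dsynth = np.zeros_like(synth_pred)
    return loss_cls, loss_syn, dprobs_cls.astype(np.float32), \
        None if dsynth is None else dsynth.astype(np.float32)


def predict_probs(labeling: nn.FCN, inputs: np.ndarray) -> np.ndarray:
    """Per-pixel class distribution for a normalized (9, H, W) stack."""
    return nn.softmax_channels(labeling.forward(np.asarray(inputs, np.float32)))


def pixel_accuracy(labeling: nn.FCN, examples: list[TrainingExample],
                   truth: list[np.ndarray]) -> float:
    """Fraction of clear pixels whose Top-1 prediction matches the truth grid."""
    hits = total = 0
    for ex, t in zip(examples, truth):
        pred = predict_probs(labeling, ex.inputs).argmax(axis=0)
        m = ex.clear
        hits += int((pred[m] == t[m]).sum())
        total += int(m.sum())
    return hits / max(total, 1)


def train(examples: list[TrainingExample], config: ModelConfig | None = None,
          validation: tuple[list[TrainingExample], list[np.ndarray]] | None = None,
          ) -> tuple[tuple[nn.FCN, nn.FCN], LossReport]:
    """Mini-batch Adam optimization of the dual-pathway objective.

    ``classification + lambda_synth * synthesis``, with the asymmetric
    gradient routing described in the module docstring.  Deterministic given
    ``config.seed`` (ordering, initialisation) up to BLAS reduction order.
    """
    if not examples:
        raise TrainingError("need at least one training example")
    config = config or ModelConfig()
    labeling, synthesis = build_models(config)
    use_synth = config.lambda_synth > 0
    nets = [labeling, synthesis] if use_synth else [labeling]
    opt = nn.Adam(nets, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    report = LossReport()

    for epoch in range(config.epochs):
        order = rng.permutation(len(examples))
        ep_cls = ep_syn = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            for net in nets:
                net.zero_grad()
            for idx in batch:
                ex = examples[idx]
                logits = labeling.forward(ex.inputs.astype(np.float32))
                probs = nn.softmax_channels(logits)
                synth_out = None
                if use_synth:
                    synth_logits = synthesis.forward(probs)
                    synth_out = nn.sigmoid(synth_logits)
                l_cls, l_syn, dprobs, dsynth = compute_losses(probs, ex, synth_out, config)
                if not (np.isfinite(l_cls) and np.isfinite(l_syn)):
                    raise TrainingError(f"divergence at epoch {epoch}: non-finite loss")
                ep_cls += l_cls
                ep_syn += l_syn
                if use_synth:
                    dsl = nn.sigmoid_backward(synth_out, config.lambda_synth * dsynth)
                    dprobs = dprobs + synthesis.backward(dsl)
                labeling.backward(nn.softmax_backward(probs, dprobs))
            opt.step()
        report.classification.append(ep_cls / len(examples))
        report.synthesis.append(ep_syn / len(examples))
        report.total.append((ep_cls + config.lambda_synth * ep_syn) / len(examples))

    if validation is not None:
        report.final_validation_accuracy = pixel_accuracy(labeling, *validation)
    return (labeling, synthesis), report


# ---------------------------------------------------------------------------
# Checkpointing

def save_checkpoint(path: Path | str, labeling: nn.FCN, synthesis: nn.FCN | None,
                    config: ModelConfig) -> None:
    blob = {
        "algorithm_version": ALGORITHM_VERSION,
        "config": config,
        "labeling": labeling.state(),
        "synthesis": synthesis.state() if synthesis is not None else None,
    }
    Path(path).write_bytes(pickle.dumps(blob))


def load_checkpoint(path: Path | str) -> tuple[nn.FCN, nn.FCN | None, ModelConfig]:
    blob = pickle.loads(Path(path).read_bytes())
    config: ModelConfig = blob["config"]
    labeling, synthesis = build_models(config)
    labeling.load_state(blob["labeling"])
    if blob["synthesis"] is None:
        synthesis = None
    else:
        synthesis.load_state(blob["synthesis"])
    return labeling, synthesis, config
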