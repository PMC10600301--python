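"""Pretraining, weight transfer, fine-tuning, grid search and ablations.

Two training phases mirror the method's transfer recipe:

* **WFP pretraining** — the encoder plus projection head is trained with
  the subject-aware contrastive loss (or the SupCon baseline) on composed
  batches, plain SGD at a fixed learning rate.
* **WFC fine-tuning** — the pretrained weights (CNN bank, attention,
  encoder dense) are copied into a fresh classifier network whose 2-node
  head is newly initialized; the whole network is fine-tuned with Adam and
  cross-entropy on un-augmented spectrograms.

Per-class "accuracy" is reported as the recall of that class (the only
reading under which the two classes can score differently on a shared
test set); overall accuracy is trace(confusion) / total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, recall_score

from . import nn
from .contrastive import (AugmentConfig, BatchCompositionSpec, DatasetIndex,
                          build_view_batch, compose_batch, sac_loss,
                          supcon_loss)
from .model import WaveFusionNet
from .preprocess import TensorDataset


@dataclass(frozen=True)
class WfpConfig:
    """Contrastive pretraining phase."""

    epochs: int = 25
    learning_rate: float = 0.05
    optimizer: str = "sgd"
    tau_sac: float = 0.25
    loss: str = "sac"                     # "sac" or "supcon"
    composition: BatchCompositionSpec = field(
        default_factory=lambda: BatchCompositionSpec(0.5, 0.0, 0.5, 500))
    augment: AugmentConfig = field(default_factory=AugmentConfig)


@dataclass(frozen=True)
class WfcConfig:
    """Supervised fine-tuning phase."""

    epochs: int = 150
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    weight_decay: float = 7e-3
    batch_size: int = 32


@dataclass(frozen=True)
class TrainConfig:
    wfp: WfpConfig = field(default_factory=WfpConfig)
    wfc: WfcConfig = field(default_factory=WfcConfig)
    seed: int = 0


@dataclass
class EvalReport:
    """Per-class F1 and recall, overall accuracy, confusion matrix."""

    f1: dict[int, float]
    recall: dict[int, float]
    overall_accuracy: float
    confusion: np.ndarray
    config_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "f1": {str(k): v for k, v in self.f1.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "overall_accuracy": self.overall_accuracy,
            "confusion": np.asarray(self.confusion).tolist(),
            "config_fingerprint": self.config_fingerprint,
        }


def evaluate(predictions, labels, config_fingerprint: str = "") -> EvalReport:
    """Score binary predictions against labels."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    if len(labels) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    cm = confusion_matrix(labels, predictions, labels=[0, 1])
    f1 = f1_score(labels, predictions, labels=[0, 1], average=None,
                  zero_division=0.0)
    rec = recall_score(labels, predictions, labels=[0, 1], average=None,
                       zero_division=0.0)
    return EvalReport(
        f1={0: float(f1[0]), 1: float(f1[1])},
        recall={0: float(rec[0]), 1: float(rec[1])},
        overall_accuracy=float(np.trace(cm) / cm.sum()),
        confusion=cm,
        config_fingerprint=config_fingerprint,
    )


# ---------------------------------------------------------------------- #
# splits and prediction


def stratified_split(dataset: TensorDataset, first_frac: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Index split stratified by (subject, class)."""
    rng = np.random.default_rng(seed)
    first, second = [], []
    for subj in np.unique(dataset.y2):
        for cls in (0, 1):
            idx = np.flatnonzero((dataset.y2 == subj) & (dataset.y1 == cls))
            idx = rng.permutation(idx)
            k = int(round(first_frac * len(idx)))
            first.append(idx[:k])
            second.append(idx[k:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def predict(net: WaveFusionNet, X: np.ndarray, batch_size: int = 256
            ) -> np.ndarray:
    """Class predictions in eval mode."""
    out = []
    for i in range(0, len(X), batch_size):
        logits, _ = net.forward_logits(X[i:i + batch_size], train=False)
        out.append(logits.argmax(axis=1))
    return np.concatenate(out)


# ---------------------------------------------------------------------- #
# WFP pretraining


def pretrain_wfp(dataset: TensorDataset, net: WaveFusionNet,
                 cfg: WfpConfig = WfpConfig(), seed: int = 0
                 ) -> list[float]:
    """Contrastive pretraining; returns the mean per-view loss per epoch.

    Each epoch cycles every (subject, class) key: the key's samples are
    shuffled and consumed in chunks of the composition's positive count,
    so every training sample appears in the positive role once per epoch;
    negatives are drawn fresh for each batch.
    """
    rng = np.random.default_rng(seed)
    index = DatasetIndex(dataset)
    counts = cfg.composition.role_counts()
    n_pos = counts["positive"]
    if n_pos < 1:
        raise ValueError("composition must include at least one positive")
    if cfg.optimizer != "sgd":
        raise ValueError(f"unsupported pretraining optimizer {cfg.optimizer}")
    opt = nn.SGD(
        net.layers_for(("features", "sen", "encoder", "projection")),
        lr=cfg.learning_rate,
    )
    trace: list[float] = []
    for _ in range(cfg.epochs):
        epoch_losses: list[float] = []
        for key in index.keys():
            pool = rng.permutation(index.pool(*key))
            for start in range(0, len(pool) - n_pos + 1, n_pos):
                positives = pool[start:start + n_pos]
                rest = compose_batch(index, key, cfg.composition, rng)
                batch_idx = np.concatenate([positives, rest[n_pos:]])
                views = build_view_batch(dataset, batch_idx, cfg.augment, rng)
                Z, cache = net.forward_embedding(views.views, train=True)
                if cfg.loss == "sac":
                    loss, grad = sac_loss(Z, views.y1, views.y2,
                                          cfg.tau_sac, return_grad=True)
                elif cfg.loss == "supcon":
                    loss, grad = supcon_loss(Z, views.y1, cfg.tau_sac,
                                             return_grad=True)
                else:
                    raise ValueError(f"unknown pretraining loss {cfg.loss}")
                opt.zero_grad()
                # the loss is a sum over anchors; step on the per-view mean
                # so the learning rate is batch-size independent
                net.backward_from_embedding(grad / len(views), cache)
                opt.step()
                epoch_losses.append(loss / len(views))
        if not epoch_losses:
            raise ValueError("no batch could be formed; dataset too small "
                             "for the composition spec")
        trace.append(float(np.mean(epoch_losses)))
    return trace


def transfer_weights(wfp_net: WaveFusionNet, seed: int = 0) -> WaveFusionNet:
    """Copy CNN bank, attention and encoder weights into a fresh
    classifier network; projection head dropped, 2-node head re-drawn."""
    wfc = WaveFusionNet(wfp_net.config, seed=seed, dtype=wfp_net.dtype)
    if wfc.config.fingerprint() != wfp_net.config.fingerprint():
        raise ValueError("architecture fingerprints do not match")
    src = wfp_net.named_parameters()
    keep = {k: v for k, v in src.items()
            if k.split(".")[0] in ("features", "sen", "encoder")}
    dst = wfc.named_parameters()
    dst.update({k: v.copy() for k, v in keep.items()})
    wfc.load_parameters(dst)
    return wfc


# ---------------------------------------------------------------------- #
# WFC fine-tuning


def finetune_wfc(train_set: TensorDataset, test_set: TensorDataset,
                 net: WaveFusionNet, cfg: WfcConfig = WfcConfig(),
                 seed: int = 0) -> tuple[WaveFusionNet, EvalReport]:
    """Supervised fine-tuning with Adam and cross-entropy; spectrograms
    are fed without augmentation.  Returns the net and the held-out
    report."""
    if len(np.unique(train_set.y1)) < 2:
        raise ValueError("fine-tuning requires both classes in the "
                         "training set")
    rng = np.random.default_rng(seed)
    if cfg.optimizer == "adam":
        opt = nn.Adam(net.layers_for(("features", "sen", "encoder",
                                      "classifier")),
                      lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    elif cfg.optimizer == "sgd":
        opt = nn.SGD(net.layers_for(("features", "sen", "encoder",
                                     "classifier")),
                     lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unsupported optimizer {cfg.optimizer}")
    n = len(train_set)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs more than one sample
            logits, cache = net.forward_logits(train_set.X[idx], train=True)
            _, dlogits = nn.cross_entropy(logits, train_set.y1[idx])
            opt.zero_grad()
            net.backward_from_logits(dlogits, cache)
            opt.step()
    preds = predict(net, test_set.X)
    report = evaluate(preds, test_set.y1, net.config.fingerprint())
    return net, report


# ---------------------------------------------------------------------- #
# grid search and ablations


@dataclass
class GridPoint:
    weight_decay: float
    val_accuracy: float
    report: EvalReport


def grid_search(train_set: TensorDataset, val_set: TensorDataset,
                wfp_net: WaveFusionNet, weight_decays: list[float],
                cfg: WfcConfig = WfcConfig(), seed: int = 0
                ) -> tuple[GridPoint, list[GridPoint]]:
    """Fine-tune one transferred model per weight-decay value and return
    the best by validation accuracy (ties go to the smallest decay)."""
    if not weight_decays:
        raise ValueError("grid must contain at least one point")
    rows: list[GridPoint] = []
    for wd in weight_decays:
        run_cfg = replace(cfg, weight_decay=wd)
        wfc = transfer_weights(wfp_net, seed=seed)
        _, report = finetune_wfc(train_set, val_set, wfc, run_cfg, seed=seed)
        rows.append(GridPoint(wd, report.overall_accuracy, report))
    best = max(rows, key=lambda r: (r.val_accuracy, -r.weight_decay))
    return best, rows


#: Rows of the component ablation: (pretraining, SEN enabled).
ABLATION_MATRIX: tuple[tuple[str, bool], ...] = (
    ("supcon", True),
    ("none", True),
    ("sac", False),
    ("none", False),
    ("sac", True),
)


def run_ablation(train_set: TensorDataset, test_set: TensorDataset,
                 base_net_config, train_cfg: TrainConfig,
                 matrix=ABLATION_MATRIX, dtype=np.float32) -> list[dict]:
    """Train one configuration per (pretraining, SEN) cell.

    ``pretraining`` in {"sac", "supcon", "none"}; SEN off replaces the
    attention vector with ones.  Returns one row per cell with the
    held-out report.  Training runs in single precision by default.
    """
    rows = []
    for pretraining, use_sen in matrix:
        config = replace(base_net_config, use_sen=use_sen)
        net = WaveFusionNet(config, seed=train_cfg.seed, dtype=dtype)
        if pretraining != "none":
            wfp_cfg = replace(train_cfg.wfp, loss=pretraining)
            pretrain_wfp(train_set, net, wfp_cfg, seed=train_cfg.seed)
            net = transfer_weights(net, seed=train_cfg.seed + 1)
        _, report = finetune_wfc(train_set, test_set, net, train_cfg.wfc,
                                 seed=train_cfg.seed)
        rows.append({
            "pretraining": pretraining,
            "sen": use_sen,
            "report": report,
        })
    return rows
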