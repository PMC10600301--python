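"""End-to-end run configuration and staged pipeline execution.

A :class:`RunConfig` nests the per-module configurations (generator,
preprocessing, model, contrastive, training) and a master seed.  The
pipeline runs any subset of the stages ``simulate -> preprocess ->
pretrain -> finetune -> evaluate -> explain``; each stage writes its
artifacts under the run directory and later stages reload them, so a run
can be resumed stage by stage.  Every run emits a resolved-config snapshot
and a summary with content checksums of all artifacts.

Presets
-------
``tiny``
    2 subjects x 20 samples, a couple of epochs: a smoke-test scale that
    completes in well under two minutes.
``easy``
    10 subjects x 40 samples with a strong (x6 band power) class effect on
    the P7/P6 leads and mild noise, reduced epochs: the scale used for the
    directional synthetic-data experiments.
``paper-scale``
    10 subjects x 1000 bootstrap-averaged samples, batch 500, 25 + 150
    epochs: the full protocol (minutes to hours on CPU).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .model import WaveFusionConfig, WaveFusionNet, load_checkpoint, \
    save_checkpoint
from .montage import POSTERIOR_17, default_montage
from .preprocess import StftConfig, TensorDataset, \
    bootstrap_average_classes, preprocess_recording
from .recording import load_recording, save_recording
from .synthetic import SyntheticDatasetSpec, generate_dataset, make_profiles
from .train import TrainConfig, evaluate, \
    finetune_wfc, predict, pretrain_wfp, stratified_split, transfer_weights
from . import interpret

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "pretrain", "finetune", "evaluate",
          "explain")


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-data block: dataset shape plus profile parameters."""

    n_subjects: int = 10
    trials_per_class: int = 100
    n_leads: int = 63
    sampling_rate: float = 500.0
    epoch_length: float = 2.0
    class_effect: float = 3.0
    noise_scale: float = 1.0
    heterogeneity: float = 0.4
    effect_leads: tuple[str, ...] | None = None   # None: posterior leads


@dataclass(frozen=True)
class PreprocessConfig:
    n_select: int = 25
    n_out: int = 500
    start_s: float = 0.0
    duration_s: float = 1.0
    target_rate: float = 100.0
    stft: StftConfig = field(default_factory=StftConfig)
    posterior_set: tuple[str, ...] = POSTERIOR_17
    zscore: bool = False


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: WaveFusionConfig = field(default_factory=WaveFusionConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    weight_decay_grid: tuple[float, ...] = (7e-3,)
    train_frac: float = 0.5       # remainder split 50/50 into val / test
    seed: int = 0

    def resolved(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=list))


def _nested_replace(obj, overrides: dict):
    """Recursively apply dict overrides onto (frozen) dataclasses."""
    kwargs = {}
    for key, val in overrides.items():
        current = getattr(obj, key)
        if isinstance(val, dict) and hasattr(current, "__dataclass_fields__"):
            kwargs[key] = _nested_replace(current, val)
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return replace(obj, **kwargs)


def config_from_dict(overrides: dict) -> RunConfig:
    return _nested_replace(RunConfig(), overrides or {})


def load_config(path) -> RunConfig:
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f) or {})


PRESETS: dict[str, dict] = {
    "tiny": {
        "generator": {"n_subjects": 2, "trials_per_class": 12,
                      "n_leads": 17, "sampling_rate": 200.0,
                      "epoch_length": 1.2, "class_effect": 6.0,
                      "noise_scale": 0.5},
        "preprocess": {"n_select": 5, "n_out": 10},
        "training": {
            "wfp": {"epochs": 2,
                    "composition": {"batch_size": 4}},
            "wfc": {"epochs": 5, "batch_size": 8},
        },
    },
    "easy": {
        "generator": {"n_subjects": 10, "trials_per_class": 30,
                      "n_leads": 17, "sampling_rate": 200.0,
                      "epoch_length": 1.2, "class_effect": 6.0,
                      "noise_scale": 0.5,
                      "effect_leads": ["P7", "P6"]},
        "preprocess": {"n_select": 5, "n_out": 20},
        "training": {
            "wfp": {"epochs": 5,
                    "composition": {"batch_size": 8}},
            "wfc": {"epochs": 40, "learning_rate": 5e-4, "batch_size": 32},
        },
    },
    "paper-scale": {},
}


def preset_config(name: str, seed: int = 0) -> RunConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = config_from_dict(dict(PRESETS[name]))
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------- #
# dataset construction helper


def make_tensor_dataset(cfg: RunConfig) -> TensorDataset:
    """Generator -> bootstrap averaging -> spectrogram tensors."""
    g = cfg.generator
    posterior = tuple(n for n in cfg.preprocess.posterior_set)
    lead_names = (default_montage().lead_names[: g.n_leads]
                  if g.n_leads != len(posterior) else posterior)
    spec = SyntheticDatasetSpec(
        n_subjects=g.n_subjects, trials_per_class=g.trials_per_class,
        n_leads=g.n_leads, sampling_rate=g.sampling_rate,
        epoch_length=g.epoch_length, seed=cfg.seed, lead_names=lead_names,
    )
    profiles = make_profiles(
        spec, class_effect=g.class_effect, noise_scale=g.noise_scale,
        heterogeneity=g.heterogeneity, effect_leads=g.effect_leads,
    )
    recordings = generate_dataset(spec, profiles)
    parts = []
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    for rec in recordings:
        avg = bootstrap_average_classes(rec, cfg.preprocess.n_select,
                                        cfg.preprocess.n_out, rng)
        parts.append(preprocess_recording(
            avg, cfg.preprocess.stft, cfg.preprocess.posterior_set,
            cfg.preprocess.start_s, cfg.preprocess.duration_s,
            cfg.preprocess.target_rate, cfg.preprocess.zscore,
        ))
    return TensorDataset.concatenate(parts)


# ---------------------------------------------------------------------- #
# staged pipeline


def _digest(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()[:16]


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name}; run the "
            f"'{stage}' stage first"
        )
    return path


def run_pipeline(cfg: RunConfig, stages, out_dir) -> dict:
    """Execute the requested stages and return the summary dict."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in set(stages)]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "summary.json"
    summary = (json.loads(summary_path.read_text())
               if summary_path.exists() else {})
    summary.setdefault("seed", cfg.seed)
    summary.setdefault("checksums", {})
    summary["config"] = cfg.resolved()

    if "simulate" in stages:
        g = cfg.generator
        posterior = cfg.preprocess.posterior_set
        lead_names = (default_montage().lead_names[: g.n_leads]
                      if g.n_leads != len(posterior) else tuple(posterior))
        spec = SyntheticDatasetSpec(
            n_subjects=g.n_subjects, trials_per_class=g.trials_per_class,
            n_leads=g.n_leads, sampling_rate=g.sampling_rate,
            epoch_length=g.epoch_length, seed=cfg.seed,
            lead_names=lead_names,
        )
        profiles = make_profiles(
            spec, class_effect=g.class_effect, noise_scale=g.noise_scale,
            heterogeneity=g.heterogeneity, effect_leads=g.effect_leads,
        )
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in generate_dataset(spec, profiles):
            save_recording(rec, rec_dir / f"subject_{rec.subject_id:02d}")
            summary["checksums"][f"subject_{rec.subject_id:02d}"] = \
                _digest({"data": rec.data, "y1": rec.y1})
        logger.info("simulate: wrote %d subjects to %s",
                    spec.n_subjects, rec_dir)

    if "preprocess" in stages:
        rec_dir = _require(out / "recordings", "simulate", "preprocess")
        parts = []
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(2)[1])
        for path in sorted(rec_dir.glob("subject_*.npz")):
            rec = load_recording(path)
            avg = bootstrap_average_classes(rec, cfg.preprocess.n_select,
                                            cfg.preprocess.n_out, rng)
            parts.append(preprocess_recording(
                avg, cfg.preprocess.stft, cfg.preprocess.posterior_set,
                cfg.preprocess.start_s, cfg.preprocess.duration_s,
                cfg.preprocess.target_rate, cfg.preprocess.zscore,
            ))
        ds = TensorDataset.concatenate(parts)
        ds.save(out / "tensors.npz")
        summary["checksums"]["tensors"] = _digest(
            {"X": ds.X, "y1": ds.y1, "y2": ds.y2})
        logger.info("preprocess: %d tensors of shape %s", len(ds),
                    ds.X.shape[1:])

    if "pretrain" in stages:
        ds = TensorDataset.load(
            _require(out / "tensors.npz", "preprocess", "pretrain"))
        train_idx, _ = stratified_split(ds, cfg.train_frac, cfg.seed)
        net = WaveFusionNet(cfg.model, seed=cfg.seed, dtype=np.float32)
        trace = pretrain_wfp(ds.subset(train_idx), net, cfg.training.wfp,
                             seed=cfg.seed)
        save_checkpoint(net, out / "wfp.npz")
        (out / "wfp_loss_trace.json").write_text(json.dumps(trace))
        summary["checksums"]["wfp"] = _digest(net.named_parameters())
        logger.info("pretrain: per-view loss %0.4f -> %0.4f",
                    trace[0], trace[-1])

    if "finetune" in stages:
        ds = TensorDataset.load(
            _require(out / "tensors.npz", "preprocess", "finetune"))
        wfp = load_checkpoint(
            _require(out / "wfp.npz", "pretrain", "finetune"),
            expect_fingerprint=cfg.model.fingerprint())
        train_idx, rest = stratified_split(ds, cfg.train_frac, cfg.seed)
        val_idx, test_idx = _split_half(rest, ds, cfg.seed + 1)
        best = None
        rows = []
        for wd in cfg.weight_decay_grid:
            wfc = transfer_weights(wfp, seed=cfg.seed + 1)
            run_cfg = replace(cfg.training.wfc, weight_decay=wd)
            wfc, report = finetune_wfc(ds.subset(train_idx),
                                       ds.subset(val_idx), wfc, run_cfg,
                                       seed=cfg.seed)
            rows.append({"weight_decay": wd,
                         "val_accuracy": report.overall_accuracy})
            if best is None or report.overall_accuracy > best[1] or (
                    report.overall_accuracy == best[1] and wd < best[0]):
                best = (wd, report.overall_accuracy, wfc)
        save_checkpoint(best[2], out / "wfc.npz")
        (out / "grid_search.json").write_text(json.dumps(
            {"rows": rows, "best_weight_decay": best[0]}, indent=1))
        summary["checksums"]["wfc"] = _digest(best[2].named_parameters())
        logger.info("finetune: best weight decay %g (val acc %0.3f)",
                    best[0], best[1])

    if "evaluate" in stages:
        ds = TensorDataset.load(
            _require(out / "tensors.npz", "preprocess", "evaluate"))
        wfc = load_checkpoint(
            _require(out / "wfc.npz", "finetune", "evaluate"),
            expect_fingerprint=cfg.model.fingerprint())
        _, rest = stratified_split(ds, cfg.train_frac, cfg.seed)
        _, test_idx = _split_half(rest, ds, cfg.seed + 1)
        test = ds.subset(test_idx)
        report = evaluate(predict(wfc, test.X), test.y1,
                          cfg.model.fingerprint())
        (out / "metrics.json").write_text(json.dumps(report.to_dict(),
                                                     indent=1))
        _metrics_csv(report, out / "metrics.csv")
        summary["metrics"] = report.to_dict()
        logger.info("evaluate: overall accuracy %0.3f",
                    report.overall_accuracy)

    if "explain" in stages:
        ds = TensorDataset.load(
            _require(out / "tensors.npz", "preprocess", "explain"))
        wfc = load_checkpoint(
            _require(out / "wfc.npz", "finetune", "explain"),
            expect_fingerprint=cfg.model.fingerprint())
        montage = default_montage().subset(ds.lead_names)
        for cls in (0, 1):
            i = int(np.flatnonzero(ds.y1 == cls)[0])
            pi = interpret.extract_attention(wfc, ds.X[i], ds.lead_names)
            topo = interpret.interpolate_topomap(pi, montage)
            interpret.save_topomap_figure(
                topo, out / f"topomap_class{cls}.png",
                title=f"class {cls} attention")
            interpret.export_attention_csv(
                pi, out / f"attention_class{cls}.csv")
            cams = [interpret.class_activation_map(
                        wfc, ds.X[i], lead, cls, ds.lead_names)
                    for lead in ("P7", "P6", "POz", "Oz")
                    if lead in ds.lead_names]
            interpret.save_cam_figure(cams, out / f"cam_class{cls}.png",
                                      ds.freq_centers, ds.time_centers)
            interpret.export_cam_arrays(cams, out / f"cam_class{cls}.npz")
        logger.info("explain: wrote topomaps and class activation maps")

    (out / "config_snapshot.yaml").write_text(yaml.safe_dump(cfg.resolved()))
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _split_half(rest: np.ndarray, ds: TensorDataset, seed: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Split held-out indices 50/50 into validation and test, stratified."""
    sub = ds.subset(rest)
    first, second = stratified_split(sub, 0.5, seed)
    return rest[first], rest[second]


def _metrics_csv(report, path) -> None:
    import pandas as pd
    pd.DataFrame([
        {"class": c, "f1": report.f1[c], "recall": report.recall[c]}
        for c in (0, 1)
    ]).assign(overall_accuracy=report.overall_accuracy).to_csv(
        path, index=False)
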