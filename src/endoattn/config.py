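"""Run configuration: YAML loading, validation, and pipeline orchestration.

One YAML file describes a whole run (synth -> preprocess -> train -> eval).
Defaults reproduce the study's stated settings: V=80 / S=90 preprocessing
thresholds, attention behind blocks 2, 3 and 12, learning rate 0.02, batch
size 8, and the 109/69 benign/malignant case split.  Unknown keys are
rejected with the offending key named; all randomness derives from the
single run seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .model import (AttentionConfig, BackboneConfig, ChannelPlan, XceptionRA,
                    assemble_xception_ra)
from .preprocess import PreprocessConfig, preprocess_frame
from .synthetic import (DatasetManifest, FrameSpec, ManifestRecord,
                        generate_dataset, load_manifest)
from .training import TrainConfig, patient_split, train

__all__ = [
    "ConfigError", "RunConfig", "SynthSection", "BackboneSection",
    "AttentionSection", "EvalSection", "load_config", "dump_config",
    "run_pipeline", "build_network", "save_checkpoint", "load_checkpoint",
]

log = logging.getLogger("endoattn")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthSection:
    n_benign: int = 109
    n_malignant: int = 69
    width: int = 256
    height: int = 256
    border_columns_left: int = 28
    border_columns_right: int = 28
    border_rows_top: int = 0
    border_rows_bottom: int = 0

    def frame_template(self) -> FrameSpec:
        return FrameSpec(width=self.width, height=self.height,
                         border_columns_left=self.border_columns_left,
                         border_columns_right=self.border_columns_right,
                         border_rows_top=self.border_rows_top,
                         border_rows_bottom=self.border_rows_bottom)


@dataclass(frozen=True)
class BackboneSection:
    input_side: int = 441
    flow_blocks: tuple[int, int, int] = (4, 8, 2)
    channel_plan: str = "full"  # "full" or "small"
    num_classes: int = 2

    def to_config(self) -> BackboneConfig:
        if self.channel_plan not in ("full", "small"):
            raise ConfigError("backbone.channel_plan must be 'full' or 'small'")
        plan = ChannelPlan() if self.channel_plan == "full" \
            else ChannelPlan.small()
        return BackboneConfig(input_side=self.input_side,
                              flow_blocks=tuple(self.flow_blocks),
                              channel_plan=plan, num_classes=self.num_classes)


@dataclass(frozen=True)
class AttentionSection:
    positions: tuple[int, ...] = (2, 3, 12)
    downsample_counts: tuple[int, ...] | None = None

    def to_config(self) -> AttentionConfig:
        counts = None if self.downsample_counts is None \
            else tuple(self.downsample_counts)
        return AttentionConfig(positions=tuple(self.positions),
                               downsample_counts=counts)


@dataclass(frozen=True)
class EvalSection:
    positive_class: int = 1
    patient_level: bool = False


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/run"
    log_level: str = "INFO"
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    backbone: BackboneSection = field(default_factory=BackboneSection)
    attention: AttentionSection = field(default_factory=AttentionSection)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalSection = field(default_factory=EvalSection)


_SECTIONS = {
    "synth": SynthSection, "preprocess": PreprocessConfig,
    "backbone": BackboneSection, "attention": AttentionSection,
    "train": TrainConfig, "eval": EvalSection,
}


def _tupleize(value):
    return tuple(value) if isinstance(value, list) else value


def _build_section(cls, data: dict, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigError(f"unknown key {path}.{unknown[0]}")
    kwargs = {k: _tupleize(v) for k, v in data.items()}
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        key = next(iter(kwargs), "")
        raise ConfigError(f"invalid value in section {path!r} "
                          f"(keys {sorted(kwargs)}): {exc}") from exc


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    top_names = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - top_names)
    if unknown:
        raise ConfigError(f"unknown key {unknown[0]}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data.pop(name), name)
    for name, value in data.items():
        kwargs[name] = value
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Parse and validate a run-configuration YAML file.

    An empty file yields the all-defaults configuration.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return config_from_dict(raw)


def dump_config(cfg: RunConfig) -> str:
    """Serialise a RunConfig back to YAML (round-trips through load)."""
    return yaml.safe_dump(json.loads(json.dumps(dataclasses.asdict(cfg))),
                          sort_keys=False)


# ---------------------------------------------------------------------------
# checkpointing


def build_network(cfg: RunConfig, seed: int | None = None) -> XceptionRA:
    return assemble_xception_ra(cfg.backbone.to_config(),
                                cfg.attention.to_config(),
                                seed=cfg.seed if seed is None else seed)


def save_checkpoint(network: XceptionRA, path) -> None:
    meta = {
        "backbone": dataclasses.asdict(network.cfg),
        "attention": dataclasses.asdict(network.attn_cfg),
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **network.state_dict())


def load_checkpoint(path) -> XceptionRA:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    bb = meta["backbone"]
    bb["channel_plan"] = ChannelPlan(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in bb["channel_plan"].items()})
    bb["flow_blocks"] = tuple(bb["flow_blocks"])
    at = meta["attention"]
    at["positions"] = tuple(at["positions"])
    if at["downsample_counts"] is not None:
        at["downsample_counts"] = tuple(at["downsample_counts"])
    from .model import XceptionBackbone
    net = XceptionRA(XceptionBackbone(BackboneConfig(**bb)),
                     AttentionConfig(**at))
    net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return net


# ---------------------------------------------------------------------------
# pipeline


def _stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    ss = np.random.SeedSequence([run_seed, sum(map(ord, stage))])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _preprocess_dataset(manifest: DatasetManifest, cfg: PreprocessConfig,
                        out_dir: Path, save_masks: bool = False
                        ) -> DatasetManifest:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for rec in manifest.records:
        img = iio.imread(manifest.resolve(rec.image_path))
        crop, masks = preprocess_frame(img, cfg)
        stem = Path(rec.image_path).stem
        iio.imwrite(out_dir / f"{stem}.png", crop.pixels)
        dark_path = refl_path = ""
        if save_masks:
            dark_path, refl_path = f"{stem}_dark.png", f"{stem}_refl.png"
            iio.imwrite(out_dir / dark_path,
                        masks.dark.astype(np.uint8) * 255)
            iio.imwrite(out_dir / refl_path,
                        masks.reflective.astype(np.uint8) * 255)
        records.append(ManifestRecord(
            image_path=f"{stem}.png", dark_mask_path=dark_path,
            reflective_mask_path=refl_path, class_label=rec.class_label,
            patient_id=rec.patient_id))
    result = DatasetManifest(records=tuple(records),
                             class_counts=dict(manifest.class_counts),
                             root=str(out_dir))
    result.save(out_dir / "manifest.json")
    return result


def run_pipeline(cfg: RunConfig, stages=("synth", "preprocess", "train",
                                         "eval"),
                 checkpoint=None) -> int:
    """Execute the configured stages; returns 0 on success, 1 on failure.

    Every run directory receives the resolved configuration, the seed, a
    version stamp and a log file; artifacts of completed stages survive a
    later failure.  Re-running an identical configuration reproduces the
    metrics exactly.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        (out / "config.yaml").write_text(dump_config(cfg))
        (out / "run.json").write_text(json.dumps({
            "seed": cfg.seed, "version": __version__,
            "stages": list(stages), "started": time.strftime("%F %T")}))
        manifest = None
        network = None
        if "synth" in stages:
            seed = _stage_seed(cfg.seed, "synth")
            log.info("synth: %d/%d frames, seed %d", cfg.synth.n_benign,
                     cfg.synth.n_malignant, seed)
            manifest = generate_dataset(
                (cfg.synth.n_benign, cfg.synth.n_malignant),
                cfg.synth.frame_template(), seed=seed, out_dir=out / "raw")
        if "preprocess" in stages:
            if manifest is None:
                manifest = load_manifest(out / "raw" / "manifest.json")
            log.info("preprocess: %d frames (V<%g, S<%g)",
                     len(manifest.records), cfg.preprocess.value_threshold,
                     cfg.preprocess.saturation_threshold)
            manifest = _preprocess_dataset(manifest, cfg.preprocess,
                                           out / "processed")
        if "train" in stages:
            if manifest is None:
                manifest = load_manifest(out / "processed" / "manifest.json")
            seed = _stage_seed(cfg.seed, "train")
            train_cfg = dataclasses.replace(cfg.train, seed=seed)
            log.info("train: lr %g, batch %d, epochs %d, seed %d",
                     train_cfg.learning_rate, train_cfg.batch_size,
                     train_cfg.epochs, seed)
            network = build_network(cfg, seed=seed)
            network, history = train(network, manifest, train_cfg)
            save_checkpoint(network, out / "checkpoint.npz")
            (out / "history.json").write_text(json.dumps(history, indent=1))
        if "eval" in stages:
            from .evaluation import evaluate

            if manifest is None:
                manifest = load_manifest(out / "processed" / "manifest.json")
            if network is None:
                path = checkpoint or out / "checkpoint.npz"
                log.info("eval: loading checkpoint %s", path)
                network = load_checkpoint(path)
            indices = None
            if cfg.train.patient_level_split[0] < 1.0 - 1e-12:
                split = patient_split(manifest, cfg.train.patient_level_split,
                                      _stage_seed(cfg.seed, "train"))
                test = split.get("test")
                indices = test if test is not None and len(test) else None
            metrics, rows = evaluate(
                network, manifest, indices=indices,
                positive_class=cfg.eval.positive_class,
                patient_level=cfg.eval.patient_level)
            (out / "metrics.json").write_text(
                json.dumps(metrics.as_dict(), indent=1))
            with open(out / "predictions.csv", "w") as fh:
                fh.write("image_path,actual,predicted,error\n")
                for r in rows:
                    fh.write(f"{r['image_path']},{r['actual']},"
                             f"{r['predicted']},{r['error'] or ''}\n")
            log.info("eval: %s", metrics.as_dict())
        return 0
    except Exception:
        log.exception("pipeline stage failed")
        return 1
    finally:
        log.removeHandler(handler)
        handler.close()
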