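"""End-to-end workflows tying the pipeline stages together.

Each ``run_*`` function is a thin orchestration over the library — generate
phantoms, preprocess to patch stacks, train, predict, evaluate — that writes
its outputs under a run directory together with a JSON snapshot of the fully
resolved configuration and every seed used, so a run can be reproduced from
its directory alone. The functions return the same objects the library
returns; there is no separate code path to drift from.

:class:`RunConfig` merges the phantom / model / training configurations and
validates strictly: unknown keys are rejected with the offending field named.
YAML is accepted via :meth:`RunConfig.from_yaml`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io_nifti import IntensityVolume, LabelVolume, read_volume, write_volume
from .model import ModelConfig, SegmentationNetwork
from .phantom import PhantomSpec, generate_dataset, save_dataset
from .preprocess import (extract_patches, load_patch_stack, normalize_intensity,
                         remap_labels, remove_empty_slices, save_patch_stack,
                         split_dataset)
from .training import TrainConfig, evaluate, predict_volume, train

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_phantom", "run_preprocess", "run_train",
           "run_predict", "run_evaluate"]


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}' config: {sorted(unknown)}")
    for key in ("shape", "input_shape", "encoder_channels", "decoder_channels",
                "intensity_means"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Merged phantom + model + training configuration for a pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = {"phantom", "model", "train", "log_level"}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        return cls(
            phantom=_build_section(PhantomSpec, dict(data.get("phantom", {})), "phantom"),
            model=_build_section(ModelConfig, dict(data.get("model", {})), "model"),
            train=_build_section(TrainConfig, dict(data.get("train", {})), "train"),
            log_level=data.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = {"phantom": asdict(self.phantom), "model": asdict(self.model),
             "train": asdict(self.train), "log_level": self.log_level}
        return json.loads(json.dumps(d, default=list))


def _start_run(out_dir, config: dict, stage: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snapshot = {"stage": stage, "config": config}
    (out_dir / "run_config.json").write_text(json.dumps(snapshot, indent=2,
                                                        default=list))
    logger.info("%s run in %s: %s", stage, out_dir, json.dumps(config, default=list))
    return out_dir


def run_phantom(out_dir, spec: PhantomSpec | None = None, n_volumes: int = 4,
                seed: int | None = None) -> Path:
    """Generate a phantom dataset and write paired NIfTI files + manifest."""
    spec = spec or PhantomSpec()
    out_dir = _start_run(out_dir, {"spec": asdict(spec), "n_volumes": n_volumes,
                                   "seed": seed}, "phantom")
    pairs = generate_dataset(spec, n_volumes, seed=seed)
    return save_dataset(pairs, out_dir, spec=spec)


def load_manifest_pairs(data_dir) -> list[tuple[IntensityVolume, LabelVolume]]:
    """Read the (image, label) pairs listed by a dataset manifest."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    pairs = []
    for entry in manifest["pairs"]:
        img = read_volume(data_dir / entry["image"], kind="intensity")
        lab = read_volume(data_dir / entry["label"], kind="label")
        pairs.append((img, lab))
    return pairs


def run_preprocess(in_dir, out_dir, patch_size: int = 64,
                   mapping: dict[int, int] | None = None,
                   normalize: bool = True, crop_empty: bool = True,
                   nbins: int = 256) -> Path:
    """Preprocess every manifest pair to an HDF5 patch stack.

    Applies, in order: label remapping (when a mapping is given), histogram
    equalization + min-max normalisation, boundary empty-slice removal, and
    nonoverlapping patch extraction.
    """
    out_dir = _start_run(out_dir, {"in_dir": str(in_dir), "patch_size": patch_size,
                                   "mapping": mapping, "normalize": normalize,
                                   "crop_empty": crop_empty, "nbins": nbins},
                         "preprocess")
    pairs = load_manifest_pairs(in_dir)
    entries = []
    for i, (img, lab) in enumerate(pairs):
        if mapping is not None:
            lab = remap_labels(lab, mapping)
        if normalize:
            img = normalize_intensity(img, nbins=nbins)
        if crop_empty:
            img, lab = remove_empty_slices(img, lab)
        stack = extract_patches(img, lab, patch_size=patch_size)
        name = f"stack_{i:03d}.h5"
        save_patch_stack(stack, out_dir / name)
        entries.append({"stack": name, "n_patches": len(stack)})
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"stacks": entries}, indent=2))
    return manifest_path


def run_train(data_dir, out_dir, model_cfg: ModelConfig, train_cfg: TrainConfig,
              ratio: tuple[int, int] = (8, 2), max_steps: int | None = None,
              progress: bool = False):
    """Split preprocessed stacks 8:2, train, and checkpoint the best model.

    Training patches come from the training-split stacks; validation scores
    whole reassembled volumes from the held-out stacks. Class weights are
    computed on the training split only.
    """
    data_dir = Path(data_dir)
    out_dir = _start_run(out_dir, {"data_dir": str(data_dir),
                                   "model": asdict(model_cfg),
                                   "train": asdict(train_cfg),
                                   "ratio": list(ratio),
                                   "max_steps": max_steps}, "train")
    manifest = json.loads((data_dir / "manifest.json").read_text())
    stacks = [load_patch_stack(data_dir / e["stack"]) for e in manifest["stacks"]]
    if len(stacks) == 1:
        train_stacks, val_stacks = stacks, []
    else:
        train_stacks, val_stacks = split_dataset(stacks, ratio=ratio,
                                                 seed=train_cfg.seed)
    train_patches = [pair for s in train_stacks for pair in s.patches]
    from .preprocess import reassemble_patches
    val_pairs = [reassemble_patches(s) for s in val_stacks] or None
    net, history = train(model_cfg, train_cfg, train_patches, val_data=val_pairs,
                         out_dir=out_dir, max_steps=max_steps, progress=progress)
    return net, history


def run_predict(checkpoint, in_path, out_path, normalize: bool = True) -> Path:
    """Segment one NIfTI volume with a trained checkpoint."""
    in_path, out_path = Path(in_path), Path(out_path)
    net = checkpoint if isinstance(checkpoint, SegmentationNetwork) \
        else SegmentationNetwork.load(checkpoint)
    vol = read_volume(in_path, kind="intensity")
    if normalize:
        vol = normalize_intensity(vol)
    pred = predict_volume(net, vol)
    write_volume(pred, out_path)
    return out_path


def run_evaluate(checkpoint, data_dir, out_dir, normalize: bool = True):
    """Evaluate a checkpoint against a phantom dataset directory; writes the
    per-structure report as TSV + JSON and returns it."""
    net = checkpoint if isinstance(checkpoint, SegmentationNetwork) \
        else SegmentationNetwork.load(checkpoint)
    out_dir = _start_run(out_dir, {"data_dir": str(data_dir),
                                   "normalize": normalize}, "evaluate")
    pairs = load_manifest_pairs(data_dir)
    if normalize:
        pairs = [(normalize_intensity(img), lab) for img, lab in pairs]
    rep = evaluate(net, pairs)
    rep.save(out_dir / "report")
    return rep
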