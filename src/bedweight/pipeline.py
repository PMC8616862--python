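"""End-to-end orchestration: simulate -> preprocess -> voxelize -> train
-> evaluate, with YAML-serializable configuration and per-stage seeds.

The preprocessing chain mirrors the acquisition protocol: depth frames
are back-projected to clouds, the bed+patient region is isolated by
depth thresholding and lattice clustering, clouds are mean-centered and
voxelized into the fixed cuboid grid.  Uncovering targets are built
from the *uncovered* frame of each pair by segmenting the patient from
the bed plane; a target is shifted by its paired covered cloud's
centroid so input and target occupy the same grid frame (at inference
only the covered centroid is available).

A run is fully reproducible from its :class:`RunConfig`: the global
seed derives per-stage seeds by fixed offsets, and every stage writes a
manifest of inputs, seeds and artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import models
from .depth_io import extract_bed_region, mean_center, segment_patient_from_bed
from .metrics import EvalCase, evaluate
from .scene_sim import PairedSample, SceneParams, generate_dataset, write_dataset
from .voxel import GridSpec, voxelize

__all__ = ["RunConfig", "DependencyError", "prepare_grids", "run_pipeline", "COMMANDS"]

logger = logging.getLogger("bedweight")

# fixed per-stage seed offsets (stage-level reproducibility, no collisions)
_SEED_SIMULATE = 0
_SEED_UNET = 1
_SEED_REGRESSOR = 2
_SEED_CLASSIFIER = 3
_SEED_EVAL = 10

COMMANDS = (
    "simulate",
    "preprocess",
    "train-uncover",
    "train-weight",
    "train-classifier",
    "evaluate",
    "predict",
)


class DependencyError(RuntimeError):
    """A pipeline stage is missing an artifact a previous stage produces."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    The reduced preset shrinks the grid to (24, 48, 16), the network
    widths (U-Net base 8; regressor channels (8, 12, 16, 24), head 64,
    dropout 0.5) and the schedules (U-Net 10 epochs at lr 2e-3 with
    batch 4 and a decay at epoch 8 — more, larger steps to offset the
    much smaller dataset — regressor 30 epochs) so a full chain runs on
    a single desktop CPU.
    """

    scene: SceneParams = field(default_factory=SceneParams)
    grid: GridSpec = field(default_factory=GridSpec)
    n_train: int = 240
    n_test: int = 60
    n_unet_train: int | None = None  # default: all training pairs
    unet_base_channels: int = 32
    unet_epochs: int = 50
    unet_milestones: tuple[int, ...] = (30,)
    unet_batch_size: int = 16
    unet_learning_rate: float = 1e-3
    regressor_schedule: tuple[int, ...] = (16, 24, 32, 48, 64)
    head_width: int = 128
    dropout: float = 0.8
    regressor_epochs: int = 120
    regressor_milestones: tuple[int, ...] = (60, 100)
    classifier_epochs: int = 10
    classifier_milestones: tuple[int, ...] = (5, 8)
    repetitions: int = 5
    seed: int = 0
    out_dir: str = "runs/default"

    @classmethod
    def reduced(cls, seed: int = 0, out_dir: str = "runs/reduced",
                n_train: int = 240, n_test: int = 60) -> "RunConfig":
        return cls(
            grid=GridSpec(resolution=(24, 48, 16)),
            n_train=n_train,
            n_test=n_test,
            n_unet_train=min(160, n_train),
            unet_base_channels=8,
            unet_epochs=10,
            unet_milestones=(8,),
            unet_batch_size=4,
            unet_learning_rate=2e-3,
            regressor_schedule=(8, 12, 16, 24),
            head_width=64,
            dropout=0.5,
            regressor_epochs=30,
            regressor_milestones=(20,),
            repetitions=3,
            seed=seed,
            out_dir=out_dir,
        )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["scene"] = self.scene.to_dict()
        d["grid"] = self.grid.to_dict()
        for key in ("unet_milestones", "regressor_milestones", "classifier_milestones", "regressor_schedule"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["scene"] = SceneParams.from_dict(d["scene"])
        d["grid"] = GridSpec.from_dict(d["grid"])
        for key in ("unet_milestones", "regressor_milestones", "classifier_milestones", "regressor_schedule"):
            d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def depth_interval(scene: SceneParams) -> tuple[float, float]:
    """Depth band that keeps bed + patient and rejects the floor."""
    return (scene.camera_height - 0.9, scene.camera_height + 0.05)


def prepare_grids(samples: list[PairedSample], scene: SceneParams, grid: GridSpec,
                  seed: int = 0) -> dict:
    """Run the preprocessing chain on paired samples and voxelize.

    Returns arrays keyed ``covered`` (bed+patient inputs), ``uncovered``
    (bed+patient, plain-regression inputs), ``target`` (patient-only
    uncovering targets, aligned to the covered centroid), ``weight``,
    ``position``, ``cover`` and the out-of-cuboid discard tally.
    """
    interval = depth_interval(scene)
    covered, uncovered, targets = [], [], []
    weights, positions, covers = [], [], []
    discarded = 0
    for k, s in enumerate(samples):
        bed_cov = extract_bed_region(s.covered, interval)
        bed_unc = extract_bed_region(s.uncovered, interval)
        cov_centered = mean_center(bed_cov)
        cov_centroid = np.asarray(cov_centered.metadata["center_offset"])
        patient = segment_patient_from_bed(bed_unc, seed=seed + 7 * k)
        target = mean_center(patient, center=cov_centroid)
        unc_centered = mean_center(bed_unc)

        g_cov = voxelize(cov_centered, grid)
        g_tar = voxelize(target, grid)
        g_unc = voxelize(unc_centered, grid)
        discarded += g_cov.n_discarded + g_tar.n_discarded + g_unc.n_discarded
        covered.append(g_cov.occupancy)
        targets.append(g_tar.occupancy)
        uncovered.append(g_unc.occupancy)
        weights.append(s.weight)
        positions.append(s.meta["position"])
        covers.append(s.meta["cover"])
    return {
        "covered": np.stack(covered).astype(np.float32),
        "uncovered": np.stack(uncovered).astype(np.float32),
        "target": np.stack(targets).astype(np.float32),
        "weight": np.asarray(weights, dtype=np.float64),
        "position": np.asarray(positions),
        "cover": np.asarray(covers),
        "n_discarded": discarded,
    }


# ---------------------------------------------------------------------------
# Stage runner
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, seeds: dict, artifacts: list[Path],
                    extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "seeds": seeds,
        "artifacts": {p.name: _sha256(p) for p in artifacts if p.exists()},
    }
    if extra:
        manifest.update(extra)
    with open(out / f"{stage}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path} — run the '{produced_by}' stage first"
        )
    return path


def _load_grids(out: Path) -> dict:
    path = _require(out / "grids.npz", "preprocess")
    with np.load(path, allow_pickle=False) as data:
        return {k: data[k] for k in data.files}


def _write_log_csv(model, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "loss", "lr"])
        writer.writerows(model.train_log)


def run_pipeline(config: RunConfig, command: str) -> Path:
    """Execute one pipeline stage; returns the output directory.

    Stages read their inputs from ``config.out_dir`` artifacts written
    by earlier stages and raise :class:`DependencyError` naming the
    missing artifact otherwise.
    """
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    scene = SceneParams(**{**config.scene.__dict__, "seed": config.seed + _SEED_SIMULATE})

    if command == "simulate":
        logger.info("simulating %d train + %d test scenes", config.n_train, config.n_test)
        samples = generate_dataset(config.n_train + config.n_test, scene, keep_frames=True)
        manifest = write_dataset(samples, out / "dataset", scene)
        _write_manifest(out, "simulate", {"scene_seed": scene.seed},
                        [out / "dataset" / "manifest.json"],
                        extra={"n_samples": len(manifest["samples"])})
        return out

    if command == "preprocess":
        _require(out / "dataset" / "manifest.json", "simulate")
        samples = generate_dataset(config.n_train + config.n_test, scene)
        grids = prepare_grids(samples, scene, config.grid, seed=config.seed)
        np.savez_compressed(out / "grids.npz", **{k: v for k, v in grids.items() if k != "n_discarded"})
        _write_manifest(out, "preprocess", {"seed": config.seed}, [out / "grids.npz"],
                        extra={"n_discarded_points": int(grids["n_discarded"])})
        return out

    grids = None
    if command in ("train-uncover", "train-weight", "train-classifier", "evaluate"):
        grids = _load_grids(out)
    tr = slice(0, config.n_train)
    te = slice(config.n_train, config.n_train + config.n_test)

    if command == "train-uncover":
        n_unet = config.n_unet_train or config.n_train
        cfg = models.TrainConfig.unet(seed=config.seed + _SEED_UNET, epochs=config.unet_epochs,
                                      milestones=config.unet_milestones,
                                      batch_size=config.unet_batch_size,
                                      learning_rate=config.unet_learning_rate)
        unet = models.train_uncover(grids["covered"][tr][:n_unet], grids["target"][tr][:n_unet],
                                    config=cfg, base_channels=config.unet_base_channels)
        models.save_checkpoint(unet, out / "unet.npz", cfg)
        _write_log_csv(unet, out / "unet_log.csv")
        _write_manifest(out, "train-uncover", {"seed": cfg.seed}, [out / "unet.npz"])
        return out

    if command == "train-weight":
        cfg = models.TrainConfig.regressor(seed=config.seed + _SEED_REGRESSOR,
                                           epochs=config.regressor_epochs,
                                           milestones=config.regressor_milestones)
        arch = dict(channel_schedule=config.regressor_schedule, head_width=config.head_width,
                    dropout=config.dropout)
        unet = models.load_checkpoint(_require(out / "unet.npz", "train-uncover"))
        two_stage = models.train_weight(grids["covered"][tr], grids["weight"][tr],
                                        mode="two-stage", uncover_model=unet, config=cfg, **arch)
        models.save_checkpoint(two_stage, out / "regressor_two_stage.npz", cfg)
        plain = models.train_weight(grids["uncovered"][tr], grids["weight"][tr],
                                    mode="plain", config=cfg, **arch)
        models.save_checkpoint(plain, out / "regressor_plain.npz", cfg)
        _write_log_csv(two_stage, out / "regressor_log.csv")
        _write_manifest(out, "train-weight", {"seed": cfg.seed},
                        [out / "regressor_two_stage.npz", out / "regressor_plain.npz"])
        return out

    if command == "train-classifier":
        cfg = models.TrainConfig.classifier(seed=config.seed + _SEED_CLASSIFIER,
                                            epochs=config.classifier_epochs,
                                            milestones=config.classifier_milestones)
        x = np.concatenate([grids["covered"][tr], grids["uncovered"][tr]])
        labels = np.concatenate([np.ones(config.n_train), np.zeros(config.n_train)])
        clf = models.train_cover_classifier(x, labels, config=cfg,
                                            channel_schedule=config.regressor_schedule,
                                            head_width=config.head_width, dropout=config.dropout)
        models.save_checkpoint(clf, out / "classifier.npz", cfg)
        _write_manifest(out, "train-classifier", {"seed": cfg.seed}, [out / "classifier.npz"])
        return out

    if command == "evaluate":
        unet = models.load_checkpoint(_require(out / "unet.npz", "train-uncover"))
        arch = dict(channel_schedule=config.regressor_schedule, head_width=config.head_width,
                    dropout=config.dropout)
        cases = [
            EvalCase(x=grids["covered"][te][i], weight=float(grids["weight"][te][i]),
                     cover=str(grids["cover"][te][i]), position=str(grids["position"][te][i]),
                     target=grids["target"][te][i] > 0.5)
            for i in range(config.n_test)
        ]

        def fit(seed: int):
            cfg = models.TrainConfig.regressor(seed=seed, epochs=config.regressor_epochs,
                                               milestones=config.regressor_milestones)
            reg = models.train_weight(grids["covered"][tr], grids["weight"][tr],
                                      mode="two-stage", uncover_model=unet, config=cfg, **arch)

            def predictor(x):
                return models.predict_weight(x, unet, reg)

            return predictor

        report = evaluate(fit, cases, repetitions=config.repetitions,
                          base_seed=config.seed + _SEED_EVAL,
                          voxel_size=tuple(config.grid.voxel_size))
        report.to_json(out / "eval_report.json")
        report.to_csv(out / "eval_report.csv")
        np.savetxt(out / "cumulative_error_curve.csv", report.curve,
                   delimiter=",", header="abs_error_kg,fraction", comments="")
        _write_manifest(out, "evaluate", {"base_seed": config.seed + _SEED_EVAL},
                        [out / "eval_report.json"])
        return out

    if command == "predict":
        unet = models.load_checkpoint(_require(out / "unet.npz", "train-uncover"))
        reg = models.load_checkpoint(_require(out / "regressor_two_stage.npz", "train-weight"))
        grids = _load_grids(out)
        preds = []
        for x in grids["covered"][te]:
            w, _ = models.predict_weight(x, unet, reg)
            preds.append(w)
        with open(out / "predictions.json", "w") as fh:
            json.dump({"weights_kg": preds}, fh, indent=1)
        _write_manifest(out, "predict", {}, [out / "predictions.json"])
        return out

    raise AssertionError("unreachable")  # pragma: no cover
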