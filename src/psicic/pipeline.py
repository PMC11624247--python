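"""End-to-end orchestration: simulate -> train -> segment -> detect ->
annotate -> classify -> evaluate, with per-stage artifacts in a run directory.

Each stage reads its inputs from the run directory and writes its outputs
there, so runs are resumable stage by stage. An "oracle" segmentation mode
feeds the ground-truth class masks directly into detection and annotation,
decoupling the geometric annotation algorithm from network training.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify_eval, colonysim, masks, platedetect, sectorannot, segnet

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "train", "segment", "detect", "annotate", "classify", "evaluate")

_PROFILES = {
    "full": dict(
        image_size=1024,
        n_colonies=100,
        radius_range=(18.0, 28.0),
        encoder_depth=4,
        base_channels=64,
        epochs=24,
        batch_size=2,
        learning_rate=1e-4,
        n_images=200,
        n_train=150,
    ),
    "desk": dict(
        image_size=128,
        n_colonies=6,
        radius_range=(10.0, 14.0),
        encoder_depth=2,
        base_channels=8,
        epochs=100,
        batch_size=2,
        learning_rate=3e-3,
        n_images=30,
        n_train=24,
    ),
}


@dataclass
class RunConfig:
    out_dir: str = "run"
    profile: str = "desk"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    segmentation: str = "model"  # "model" or "oracle" (ground-truth masks)
    # None fields are filled from the profile
    image_size: int | None = None
    n_images: int | None = None
    n_train: int | None = None
    n_colonies: int | None = None
    sectors_per_colony: int = 1
    radius_range: tuple[float, float] | None = None
    encoder_depth: int | None = None
    base_channels: int | None = None
    epochs: int | None = None
    batch_size: int | None = None
    learning_rate: float | None = None
    border_margin: int | None = None
    pad_factor: float = 1.5
    noise_enabled: bool = True
    _resolved: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        prof = _PROFILES[self.profile]
        for key, value in prof.items():
            if getattr(self, key, None) is None:
                setattr(self, key, value)
        if self.border_margin is None:
            self.border_margin = platedetect.scaled_border_margin(self.image_size)
        if self.segmentation not in ("model", "oracle"):
            raise ValueError("segmentation must be 'model' or 'oracle'")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "radius_range" in data and data["radius_range"] is not None:
            data["radius_range"] = tuple(data["radius_range"])
        return cls(**data)

    def plate_spec(self) -> colonysim.PlateSpec:
        return colonysim.PlateSpec(
            image_size=self.image_size,
            n_colonies=self.n_colonies,
            radius_range=tuple(self.radius_range),
            sectors_per_colony=self.sectors_per_colony,
            noise_enabled=self.noise_enabled,
            rng_seed=self.seed,
        )


def _plates_dir(cfg: RunConfig) -> Path:
    return Path(cfg.out_dir) / "plates"


def _load_plate(cfg: RunConfig, i: int):
    d = _plates_dir(cfg)
    return (
        masks.load_image(d / f"plate_{i}.png"),
        masks.load_mask(d / f"plate_{i}_class.png"),
        colonysim.load_layout(d / f"plate_{i}_layout.json"),
    )


def stage_simulate(cfg: RunConfig) -> int:
    spec = cfg.plate_spec()
    plates = colonysim.generate_plates(spec, cfg.n_images)
    for i, plate in enumerate(plates):
        colonysim.write_plate(_plates_dir(cfg), i, plate)
    return len(plates)


def stage_train(cfg: RunConfig) -> dict:
    data = [_load_plate(cfg, i)[:2] for i in range(cfg.n_images)]
    train_set, val_set = data[: cfg.n_train], data[cfg.n_train :]
    model = segnet.build_model(
        segnet.SegModelConfig(
            input_size=cfg.image_size,
            encoder_depth=cfg.encoder_depth,
            base_channels=cfg.base_channels,
            rng_seed=cfg.seed,
        )
    )
    model, report = segnet.train_model(
        model,
        train_set,
        val_set,
        segnet.TrainConfig(
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            rng_seed=cfg.seed,
        ),
    )
    segnet.save_weights(Path(cfg.out_dir) / "model.npz", model, report)
    return {
        "epochs": cfg.epochs,
        "final_val_accuracy": report.val_accuracy[-1] if report.val_accuracy else None,
    }


def stage_segment(cfg: RunConfig) -> int:
    out = Path(cfg.out_dir) / "pred_masks"
    out.mkdir(parents=True, exist_ok=True)
    model = segnet.load_weights(Path(cfg.out_dir) / "model.npz")
    for i in range(cfg.n_images):
        image, _, _ = _load_plate(cfg, i)
        masks.save_mask(out / f"plate_{i}_pred.png", segnet.predict_mask(model, image))
    return cfg.n_images


def _mask_for_detection(cfg: RunConfig, i: int) -> np.ndarray:
    if cfg.segmentation == "oracle":
        return _load_plate(cfg, i)[1]
    return masks.load_mask(Path(cfg.out_dir) / "pred_masks" / f"plate_{i}_pred.png")


def stage_detect(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    rmin, rmax = cfg.radius_range
    for i in range(cfg.n_images):
        mask = _mask_for_detection(cfg, i)
        dets = platedetect.detect_colonies(mask, (rmin, rmax))
        kept, excluded = platedetect.exclude_border(dets, cfg.image_size, cfg.border_margin)
        kept_set = {id(d) for d in kept}
        for j, d in enumerate(dets):
            rows.append(
                {
                    "plate_id": i,
                    "colony_id": f"{i}:{j}",
                    "center_row": d.center[0],
                    "center_col": d.center[1],
                    "radius": d.radius,
                    "score": d.score,
                    "kept": id(d) in kept_set,
                    "excluded_reason": "" if id(d) in kept_set else "border",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "plate_id", "colony_id", "center_row", "center_col",
            "radius", "score", "kept", "excluded_reason",
        ],
    )
    df.to_csv(Path(cfg.out_dir) / "detections.csv", index=False)
    return df


def stage_annotate(cfg: RunConfig) -> list[dict]:
    df = pd.read_csv(Path(cfg.out_dir) / "detections.csv")
    records = []
    for plate_id, group in df[df.kept].groupby("plate_id"):
        image, _, _ = _load_plate(cfg, int(plate_id))
        mask = _mask_for_detection(cfg, int(plate_id))
        for _, row in group.iterrows():
            circle = platedetect.CircleDetection(
                center=(int(row.center_row), int(row.center_col)),
                radius=float(row.radius),
                score=float(row.score),
            )
            try:
                crop = platedetect.crop_colony(image, mask, circle, cfg.pad_factor)
                ann = sectorannot.annotate_colony(crop.mask)
            except ValueError:
                ann = sectorannot.ColonyAnnotation(status="unquantifiable", reason="crop_out_of_bounds")
            rec = {"colony_id": row.colony_id, "plate_id": int(plate_id)}
            rec.update(ann.to_dict())
            records.append(rec)
    path = Path(cfg.out_dir) / "annotations.jsonl"
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return records


def stage_classify(cfg: RunConfig) -> pd.DataFrame:
    df = pd.read_csv(Path(cfg.out_dir) / "detections.csv").set_index("colony_id")
    rows = []
    with open(Path(cfg.out_dir) / "annotations.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            det = df.loc[rec["colony_id"]]
            entry = {
                "plate_id": rec["plate_id"],
                "colony_id": rec["colony_id"],
                "center_row": det.center_row,
                "center_col": det.center_col,
                "radius": det.radius,
                "status": rec["status"],
                "p_w": rec["weighted_purity"],
                "class": "",
                "sector_count": 0,
            }
            if rec["status"] == "ok":
                ann = sectorannot.ColonyAnnotation(
                    a=rec["a"], b=rec["b"], weighted_purity=rec["weighted_purity"]
                )
                call = classify_eval.assign_class(ann)
                entry["class"] = call.label
                entry["sector_count"] = call.sector_count
            rows.append(entry)
    out = pd.DataFrame(rows)
    out.to_csv(Path(cfg.out_dir) / "per_colony_calls.csv", index=False)
    return out


def stage_evaluate(cfg: RunConfig) -> dict:
    calls_df = pd.read_csv(Path(cfg.out_dir) / "per_colony_calls.csv")
    calls, truths = {}, {}
    det_tp = det_fn = det_fp = 0
    n_unquantifiable = 0
    for plate_id in sorted(calls_df.plate_id.unique()):
        layout = colonysim.load_layout(
            _plates_dir(cfg) / f"plate_{int(plate_id)}_layout.json"
        )
        sub = calls_df[calls_df.plate_id == plate_id].reset_index()
        dets = [
            platedetect.CircleDetection(
                center=(int(r.center_row), int(r.center_col)),
                radius=float(r.radius),
                score=0.0,
            )
            for r in sub.itertuples()
        ]
        # only truths away from the border can be matched by kept detections
        margin = cfg.border_margin
        eligible = [
            (ti, t)
            for ti, t in enumerate(layout)
            if min(
                t.center[0], t.center[1],
                cfg.image_size - 1 - t.center[0], cfg.image_size - 1 - t.center[1],
            )
            >= margin
        ]
        pairs = platedetect.greedy_matches(dets, [t for _, t in eligible])
        det_tp += len(pairs)
        det_fn += len(eligible) - len(pairs)
        det_fp += len(dets) - len(pairs)
        for di, ti in pairs:
            row = sub.iloc[di]
            if row.status != "ok":
                n_unquantifiable += 1
                continue
            cid = row.colony_id
            calls[cid] = str(row["class"])
            truths[cid] = colonysim.layout_truth_label(eligible[ti][1])
    report = classify_eval.evaluate(calls, truths)
    metrics = report.to_dict()
    metrics["detection"] = {
        "tp": det_tp,
        "fn": det_fn,
        "fp": det_fp,
        "precision": classify_eval.precision_recall_f1(det_tp, det_fp, det_fn)[0],
        "recall": classify_eval.precision_recall_f1(det_tp, det_fp, det_fn)[1],
    }
    metrics["n_unquantifiable"] = n_unquantifiable
    (Path(cfg.out_dir) / "metrics.json").write_text(json.dumps(metrics, indent=1))
    return metrics


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "train": stage_train,
    "segment": stage_segment,
    "detect": stage_detect,
    "annotate": stage_annotate,
    "classify": stage_classify,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Writes a manifest with the config snapshot, seed, and per-stage summary
    counts. Unquantifiable colonies never abort a run.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items() if not k.startswith("_")
        },
        "stages": {},
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        if cfg.segmentation == "oracle" and stage in ("train", "segment"):
            manifest["stages"][stage] = "skipped (oracle segmentation)"
            continue
        result = _STAGE_FUNCS[stage](cfg)
        if isinstance(result, pd.DataFrame):
            manifest["stages"][stage] = {"rows": int(len(result))}
        elif isinstance(result, list):
            manifest["stages"][stage] = {"records": len(result)}
        elif isinstance(result, dict):
            manifest["stages"][stage] = {
                k: v for k, v in result.items() if np.isscalar(v) or v is None
            }
        else:
            manifest["stages"][stage] = result
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
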