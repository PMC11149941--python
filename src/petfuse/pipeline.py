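"""One-shot resumable pipeline: phantom → preprocess → t-map → radiomics →
selection → training → evaluation, with per-stage completion markers.

Every stage writes its artifacts under the run directory and drops a
``<stage>.done`` marker with timing and the stage seed; a rerun skips
completed stages. Per-stage seeds derive from the global seed by stable
hashing so stages are independent yet reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import build_report
from .models import CohortData, ModelConfig, TrainingConfig, build_model, predict, save_model, train
from .phantom import PhantomConfig, generate_cohort
from .preprocess import preprocess_volume
from .radiomics import RadiomicsConfig, extract_cohort
from .select import select_features
from .volume import load_volume, save_volume
from .voxelstats import single_subject_tmap, threshold_and_cluster

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("petfuse")

STAGES = ("simulate", "preprocess", "tmap", "extract", "select", "train", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of ``seed:stage``, below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Nested configuration of every stage plus the run directory."""

    run_dir: str = "petfuse_run"
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_control: int = 20
    n_demented: int = 20
    n_test_control: int = 10
    n_test_demented: int = 10
    fwhm_mm: float = 8.0
    p_threshold: float = 0.01
    min_cluster_size: int = 100
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    select_fraction: float = 0.10
    r_threshold: float = 0.30
    model_kinds: tuple[str, ...] = ("feature_only", "cnn", "combined")
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def validate(self) -> None:
        if self.n_control < 0 or self.n_demented < 0:
            raise ValueError("cohort sizes must be non-negative")
        for k in self.model_kinds:
            ModelConfig(kind=k, image_shape=self.phantom.grid_shape, n_features=1)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = (
            yaml.safe_load(path.read_text())
            if path.suffix in (".yaml", ".yml")
            else json.loads(path.read_text())
        )
        if "phantom" in raw:
            ph = raw["phantom"]
            for key in ("grid_shape", "voxel_size_mm", "age_range_control", "age_range_demented"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            raw["phantom"] = PhantomConfig(**ph)
        if "radiomics" in raw:
            raw["radiomics"] = RadiomicsConfig(**raw["radiomics"])
        if "training" in raw:
            raw["training"] = TrainingConfig(**raw["training"])
        if "model_kinds" in raw:
            raw["model_kinds"] = tuple(raw["model_kinds"])
        return cls(**raw)


class _Run:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.dir = Path(config.run_dir)
        self.dir.mkdir(parents=True, exist_ok=True)

    def marker(self, stage: str) -> Path:
        return self.dir / f"{stage}.done"

    def done(self, stage: str) -> bool:
        return self.marker(stage).exists()

    def finish(self, stage: str, t0: float, seed: int, outputs: list[str]) -> None:
        self.marker(stage).write_text(
            json.dumps(
                {"stage": stage, "seconds": round(time.time() - t0, 3), "seed": seed, "outputs": outputs},
                indent=2,
            )
        )
        log.info("stage %s finished in %.2fs (seed %d)", stage, time.time() - t0, seed)


def _manifest(run: _Run, split: str) -> pd.DataFrame:
    return pd.read_csv(run.dir / split / "manifest.csv", keep_default_na=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute (or resume) all stages; returns the run directory.

    A stage failure aborts with the failing stage named; artifacts of
    completed stages are preserved.
    """
    config.validate()
    run = _Run(config)
    handler = logging.StreamHandler()
    if not log.handlers:
        log.addHandler(handler)
        log.setLevel(logging.INFO)

    try:
        for stage in STAGES:
            if run.done(stage):
                log.info("stage %s already complete; skipping", stage)
                continue
            t0 = time.time()
            seed = stage_seed(config.seed, stage)
            globals()[f"_stage_{stage}"](run, seed)
            # each stage writes its own marker via run.finish inside
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage with error: {exc}") from exc
    return run.dir


def _stage_simulate(run: _Run, seed: int) -> None:
    t0 = time.time()
    cfg = run.cfg
    generate_cohort(cfg.phantom, cfg.n_control, cfg.n_demented, run.dir / "train", seed)
    generate_cohort(
        cfg.phantom, cfg.n_test_control, cfg.n_test_demented, run.dir / "test", seed + 1
    )
    run.finish("simulate", t0, seed, ["train/manifest.csv", "test/manifest.csv"])


def _stage_preprocess(run: _Run, seed: int) -> None:
    t0 = time.time()
    cfg = run.cfg
    outputs = []
    for split in ("train", "test"):
        man = _manifest(run, split)
        out_dir = run.dir / f"{split}_preproc"
        out_dir.mkdir(exist_ok=True)
        new_paths = []
        for _, rec in man.iterrows():
            vol = load_volume(rec["path"])
            pre = preprocess_volume(vol, fwhm_mm=cfg.fwhm_mm)
            p = out_dir / Path(rec["path"]).name
            save_volume(pre, p)
            new_paths.append(str(p))
        man["path"] = new_paths
        man.to_csv(out_dir / "manifest.csv", index=False)
        outputs.append(f"{split}_preproc/manifest.csv")
    run.finish("preprocess", t0, seed, outputs)


def _stage_tmap(run: _Run, seed: int) -> None:
    t0 = time.time()
    cfg = run.cfg
    train_man = pd.read_csv(run.dir / "train_preproc" / "manifest.csv", keep_default_na=False)
    test_man = pd.read_csv(run.dir / "test_preproc" / "manifest.csv", keep_default_na=False)
    controls_rows = train_man[train_man["label"] == "control"]
    controls = [load_volume(p) for p in controls_rows["path"]]
    control_ages = list(controls_rows["age"].astype(float))
    out_dir = run.dir / "tmaps"
    out_dir.mkdir(exist_ok=True)
    outputs = []
    min_size = cfg.min_cluster_size
    for _, rec in test_man[test_man["label"] == "demented"].iterrows():
        subj = load_volume(rec["path"])
        tmap = single_subject_tmap(subj, controls, float(rec["age"]), control_ages)
        clusters = threshold_and_cluster(tmap, cfg.p_threshold, min_size)
        tpath = out_dir / f"{rec['id']}_tmap.nii.gz"
        save_volume(subj.copy(data=tmap.t), tpath)
        clusters.save_table(out_dir / f"{rec['id']}_clusters.csv")
        outputs += [tpath.name, f"{rec['id']}_clusters.csv"]
    run.finish("tmap", t0, seed, outputs)


def _stage_extract(run: _Run, seed: int) -> None:
    t0 = time.time()
    cfg = run.cfg
    outputs = []
    for split in ("train", "test"):
        man = pd.read_csv(run.dir / f"{split}_preproc" / "manifest.csv", keep_default_na=False)
        table = extract_cohort(man, cfg.radiomics)
        p = run.dir / f"features_{split}.csv"
        table.to_csv(p)
        outputs.append(p.name)
    run.finish("extract", t0, seed, outputs)


def _stage_select(run: _Run, seed: int) -> None:
    t0 = time.time()
    cfg = run.cfg
    table = pd.read_csv(run.dir / "features_train.csv", index_col="id")
    result = select_features(
        table, fraction=cfg.select_fraction, r_threshold=cfg.r_threshold
    )
    result.to_json(run.dir / "selection.json")
    table[result.final_features].to_csv(run.dir / "features_selected.csv")
    run.finish("select", t0, seed, ["selection.json", "features_selected.csv"])


def _load_cohort(run: _Run, split: str, selected: list[str]) -> CohortData:
    man = pd.read_csv(run.dir / f"{split}_preproc" / "manifest.csv", keep_default_na=False)
    feats = pd.read_csv(run.dir / f"features_{split}.csv", index_col="id")
    images = np.stack([load_volume(p).data for p in man["path"]])
    features = feats.loc[man["id"], selected].to_numpy(dtype=np.float64)
    return CohortData.from_labels(man["id"], man["label"], images, features)


def _stage_train(run: _Run, seed: int) -> None:
    t0 = time.time()
    cfg = run.cfg
    selection = json.loads((run.dir / "selection.json").read_text())
    selected = selection["final_features"]
    cohort = _load_cohort(run, "train", selected)
    outputs = []
    for kind in cfg.model_kinds:
        mcfg = ModelConfig(
            kind=kind, image_shape=cfg.phantom.grid_shape, n_features=max(len(selected), 1)
        )
        tcfg = TrainingConfig(**{**asdict(cfg.training), "seed": seed})
        net = build_model(mcfg, seed=seed)
        model = train(net, cohort, tcfg)
        p = run.dir / f"model_{kind}.npz"
        save_model(model, p)
        outputs.append(p.name)
        log.info("trained %s: validation accuracy %.1f%%", kind, model.val_accuracy)
    run.finish("train", t0, seed, outputs)


def _stage_evaluate(run: _Run, seed: int) -> None:
    from .models import load_model

    t0 = time.time()
    cfg = run.cfg
    selection = json.loads((run.dir / "selection.json").read_text())
    selected = selection["final_features"]
    test = _load_cohort(run, "test", selected)
    man = pd.read_csv(run.dir / "test_preproc" / "manifest.csv", keep_default_na=False)
    preds = {}
    for kind in cfg.model_kinds:
        model = load_model(run.dir / f"model_{kind}.npz")
        preds[kind] = [
            predict(
                model,
                image=test.images[i] if model.config.kind != "feature_only" else None,
                features=test.features[i] if model.config.kind != "cnn" else None,
                subject_id=test.ids[i],
            )
            for i in range(len(test))
        ]
    report = build_report(man, preds)
    report.to_csv(run.dir / "report.csv")
    report.to_json(run.dir / "report.json")
    run.finish("evaluate", t0, seed, ["report.csv", "report.json"])
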