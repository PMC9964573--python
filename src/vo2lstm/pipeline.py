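"""End-to-end orchestration: simulate -> preprocess -> features -> train -> evaluate.

Each stage reads the previous stage's CSV outputs from disk and writes its
own under ``<output_dir>/<stage>/``, so any prefix of the pipeline can be
re-run or swapped for real data at the CSV boundary.  A run manifest
records the seeds, package version and SHA-256 of every file written.
Every stage seed derives deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import evaluation, features, model as model_mod, preprocessing, synthetic
from .synthetic import ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed", "STAGES"]

STAGES = ("simulate", "preprocess", "features", "train", "evaluate")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SimulationSection:
    walk_speeds: tuple[float, float] = (1.3, 1.8)
    run_speeds: tuple[float, float] = (2.5, 3.5)
    stage_duration: float = 180.0
    rest_duration: float = 120.0
    motion_sample_rate: float = 100.0
    vo2_rate: float = 0.2
    hr_rate: float = 1.0
    vo2_noise_sd_abs: float = 125.0
    hr_noise_sd: float = 2.0
    offsets: tuple[float, float, float] = (0.0, 2.0, -1.5)
    jump_time: float = 10.0
    subject: dict[str, Any] | None = None  # overrides for SubjectProfile


@dataclass(frozen=True)
class FeatureSection:
    min_period: float = 0.2
    min_prominence: float = 0.03
    target_anchor: str = "end"  # start | mid | end


@dataclass(frozen=True)
class PipelineConfig:
    """One structured, serializable config covering every stage."""

    master_seed: int = 42
    output_dir: str = "runs/default"
    stages: tuple[str, ...] = STAGES
    simulation: SimulationSection = field(default_factory=SimulationSection)
    preprocess: preprocessing.PreprocessConfig = field(
        default_factory=preprocessing.PreprocessConfig
    )
    features: FeatureSection = field(default_factory=FeatureSection)
    model: model_mod.ModelConfig = field(
        default_factory=lambda: model_mod.ModelConfig(epochs=300)
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["model"]["features"] = list(self.model.features)
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)

        def _section(key, factory):
            sub = raw.pop(key, {})
            if isinstance(sub, dict):
                allowed = {f.name for f in dataclasses.fields(factory)}
                unknown = set(sub) - allowed
                if unknown:
                    raise ValidationError(
                        f"unknown config fields in {key!r}: {sorted(unknown)}"
                    )
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                return factory(**sub)
            return sub

        sim = _section("simulation", SimulationSection)
        pre = _section("preprocess", preprocessing.PreprocessConfig)
        feat = _section("features", FeatureSection)
        mdl = _section("model", model_mod.ModelConfig)
        allowed = {"master_seed", "output_dir", "stages"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, preprocess=pre, features=feat, model=mdl, **raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the requested stages in order and return the run manifest.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    written before the failure are left on disk.
    """
    out_root = Path(config.output_dir)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "seeds": {s: stage_seed(config.master_seed, s) for s in STAGES},
        "version": __import__("vo2lstm").__version__,
        "files": {},
    }

    def _record(stage: str, paths: dict[str, Path]) -> None:
        manifest["files"][stage] = {
            name: _sha256(p) for name, p in sorted(paths.items())
        }

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _record(stage, _run_stage(stage, config, out_root, manifest["seeds"][stage]))
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    mp = out_root / "manifest.json"
    out_root.mkdir(parents=True, exist_ok=True)
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(
    stage: str, config: PipelineConfig, out_root: Path, seed: int
) -> dict[str, Path]:
    import pandas as pd

    sim_dir = out_root / "simulate"
    pre_dir = out_root / "preprocess"
    feat_dir = out_root / "features"
    train_dir = out_root / "train"
    eval_dir = out_root / "evaluate"

    if stage == "simulate":
        sec = config.simulation
        subject = synthetic.sample_subject(seed)
        if sec.subject:
            subject = dataclasses.replace(subject, **sec.subject)
        protocol = synthetic.generate_protocol(
            sec.walk_speeds, sec.run_speeds, sec.stage_duration, sec.rest_duration
        )
        motion, step_times = synthetic.simulate_steps(
            protocol, subject, seed + 1, sample_rate=sec.motion_sample_rate
        )
        physio = synthetic.simulate_physiology(
            protocol,
            subject,
            seed + 2,
            vo2_rate=sec.vo2_rate,
            hr_rate=sec.hr_rate,
            vo2_noise_sd_abs=sec.vo2_noise_sd_abs,
            hr_noise_sd=sec.hr_noise_sd,
        )
        synced = synthetic.inject_sync_artifacts(
            motion, physio.vo2, physio.hr, sec.offsets, sec.jump_time, seed=seed + 3
        )
        physio_out = synthetic.SimulatedPhysiology(
            vo2=synced.vo2, hr=synced.hr,
            latent_vo2=physio.latent_vo2, latent_hr=physio.latent_hr,
        )
        return synthetic.write_simulation(
            sim_dir, synced.motion, physio_out, step_times, subject, protocol,
            seeds={"stage_seed": seed}, true_offsets=synced.true_offsets,
        )

    if stage == "preprocess":
        sidecar = json.loads((sim_dir / "sidecar.json").read_text())
        motion = synthetic.read_motion_csv(
            sim_dir / "motion.csv", sidecar["motion_sample_rate_hz"]
        )
        vo2 = synthetic.read_physio_csv(
            sim_dir / "vo2.csv", "vo2", sidecar["vo2_rate_hz"],
            bookmark_time=sidecar["vo2_bookmark_time_s"],
        )
        hr = synthetic.read_physio_csv(
            sim_dir / "hr.csv", "hr", sidecar["hr_rate_hz"],
            bookmark_time=sidecar["hr_bookmark_time_s"],
        )
        motion_a, vo2_a, hr_a, shifts = preprocessing.align_streams(
            motion, vo2, hr, config=config.preprocess
        )
        vo2_c = preprocessing.remove_outliers(vo2_a, config.preprocess)
        vo2_s = preprocessing.smooth_vo2(vo2_c, config.preprocess)
        hr_s = preprocessing.smooth_vo2(hr_a, config.preprocess)
        pre_dir.mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}
        pd.DataFrame({
            "time_s": motion_a.time, "speed_mps": motion_a.speed,
            "vertical_position_m": motion_a.vertical_position,
            "vertical_acceleration_mps2": motion_a.vertical_acceleration,
        }).to_csv(pre_dir / "motion.csv", index=False, float_format="%.6f")
        files["motion.csv"] = pre_dir / "motion.csv"
        pd.DataFrame({"time_s": vo2_s.time, "vo2_mlkgmin": vo2_s.values}).to_csv(
            pre_dir / "vo2.csv", index=False, float_format="%.6f")
        files["vo2.csv"] = pre_dir / "vo2.csv"
        pd.DataFrame({"time_s": hr_s.time, "hr_bpm": hr_s.values}).to_csv(
            pre_dir / "hr.csv", index=False, float_format="%.6f")
        files["hr.csv"] = pre_dir / "hr.csv"
        meta = {"aligned": True, "applied_shifts_s": shifts,
                "motion_sample_rate_hz": sidecar["motion_sample_rate_hz"],
                "vo2_rate_hz": sidecar["vo2_rate_hz"],
                "hr_rate_hz": sidecar["hr_rate_hz"]}
        (pre_dir / "sidecar.json").write_text(json.dumps(meta, indent=2))
        files["sidecar.json"] = pre_dir / "sidecar.json"
        return files

    if stage == "features":
        meta = json.loads((pre_dir / "sidecar.json").read_text())
        motion = synthetic.read_motion_csv(
            pre_dir / "motion.csv", meta["motion_sample_rate_hz"]
        )
        vo2 = synthetic.read_physio_csv(pre_dir / "vo2.csv", "vo2", meta["vo2_rate_hz"])
        hr = synthetic.read_physio_csv(pre_dir / "hr.csv", "hr", meta["hr_rate_hz"])
        segs = features.segment_steps(
            motion, config.features.min_period, config.features.min_prominence
        )
        steps = features.compute_step_metrics(motion, segs)
        steps = features.attach_physiology(
            steps, vo2, hr, anchor=config.features.target_anchor
        )
        feat_dir.mkdir(parents=True, exist_ok=True)
        files = {}
        features.write_steps_csv(feat_dir / "steps.csv", steps)
        files["steps.csv"] = feat_dir / "steps.csv"
        corr = features.correlations(steps)
        corr.feature_feature.to_csv(feat_dir / "correlation_matrix.csv",
                                    float_format="%.4f")
        files["correlation_matrix.csv"] = feat_dir / "correlation_matrix.csv"
        (feat_dir / "correlation_target.json").write_text(
            json.dumps({k: (None if pd.isna(v) else round(float(v), 4))
                        for k, v in corr.feature_target.items()}, indent=2))
        files["correlation_target.json"] = feat_dir / "correlation_target.json"
        return files

    if stage == "train":
        steps = features.read_steps_csv(feat_dir / "steps.csv")
        cfg = dataclasses.replace(config.model, seed=seed)
        dataset = model_mod.build_sequences(steps, cfg)
        train_set, test_set = model_mod.split_dataset(dataset, cfg)
        trained = model_mod.train(train_set, cfg)
        model_mod.save_model(trained, train_dir)
        pred = model_mod.predict(trained, test_set)
        files = {"model.json": train_dir / "model.json"}
        pd.DataFrame({
            "end_step_index": test_set.end_step_indices,
            "subject_id": test_set.subject_ids,
            "measured": test_set.targets,
            "predicted": pred,
        }).sort_values("end_step_index").to_csv(
            train_dir / "predictions.csv", index=False, float_format="%.6f")
        files["predictions.csv"] = train_dir / "predictions.csv"
        return files

    if stage == "evaluate":
        df = pd.read_csv(train_dir / "predictions.csv")
        rep = evaluation.report(
            df["measured"], df["predicted"], df["subject_id"],
        )
        return evaluation.write_report(rep, eval_dir)

    raise ValidationError(f"unknown stage {stage!r}")
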