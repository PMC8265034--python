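"""End-to-end experiment orchestration.

A run: generate seeded phantoms -> simulate noisy baseline stacks -> MPPCA
denoise -> dictionary-match quantitative maps (training targets) -> train a
network variant -> predict on held-out phantoms -> evaluate.  Every stage
derives its seed from the global seed, logs its wall time, writes its
outputs under the run directory, and is skipped when a config-hash marker
shows its outputs are already current (the phantoms and the dictionary are
reused when several variants are trained on one dataset).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .denoise import mppca_denoise
from .dictionary import (
    Dictionary,
    build_dictionary,
    default_grid,
    load_dictionary,
    reconstruct_maps,
    save_dictionary,
)
from .io import load_phantom, read_nifti, save_phantom, write_nifti, write_stack
from .metrics import (
    binarize,
    dice,
    lesion_detection_rate,
    mean_relative_deviation,
    per_lesion_stats,
    threshold_sweep,
)
from .nn import (
    TrainingCase,
    TrainingConfig,
    build_training_set,
    get_variant,
    make_targets,
    normalize_inputs,
    predict,
    save_checkpoint,
    train,
)
from .phantom import PhantomConfig, generate_phantom
from .schedule import default_schedule
from .signal import add_rician_noise, simulate_baseline_stack

__all__ = ["ExperimentConfig", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    output_dir: str = "run"
    seed: int = 0
    n_train: int = 4
    n_val: int = 1
    n_test: int = 1
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    snr: float = 40.0
    denoise_window: int = 5
    denoise: bool = True
    dictionary_rel_step: float = 0.05
    targets_from: str = "dictionary"  # or "phantom" (ground-truth maps)
    variant: str = "MSE-5"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    lesion_threshold: float = 0.33
    tissue_threshold: float = 0.8

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            pk = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["phantom"].items()
            }
            kwargs["phantom"] = PhantomConfig(**pk)
        if "training" in kwargs and isinstance(kwargs["training"], dict):
            kwargs["training"] = TrainingConfig(**kwargs["training"])
        return cls(**kwargs)


def _stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage seed: SeedSequence(global_seed) spawned by stage key."""
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(key, index))
    return int(ss.generate_state(1)[0] % (2**31))


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=list).encode()).hexdigest()[:16]


class _Stage:
    """Content-hash cached stage: skipped when its marker matches."""

    def __init__(self, run_dir: Path, name: str, config_obj):
        self.dir = run_dir / name
        self.name = name
        self.marker = self.dir / ".stage.json"
        self.hash = _config_hash(config_obj)

    def is_cached(self) -> bool:
        if not self.marker.exists():
            return False
        try:
            return json.loads(self.marker.read_text())["hash"] == self.hash
        except (KeyError, json.JSONDecodeError):
            return False

    def start(self) -> Path:
        self.dir.mkdir(parents=True, exist_ok=True)
        self._t0 = time.time()
        logger.info("stage %s: started", self.name)
        return self.dir

    def done(self) -> None:
        self.marker.write_text(
            json.dumps({"hash": self.hash, "wall_s": round(time.time() - self._t0, 2)})
        )
        logger.info("stage %s: done in %.1fs", self.name, time.time() - self._t0)


def run_experiment(config: ExperimentConfig) -> Path:
    """Run (or resume) a full experiment; returns the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    schedule = default_schedule()
    n_total = config.n_train + config.n_val + config.n_test
    variant = get_variant(config.variant)

    # ---- phantoms + stacks -------------------------------------------------
    sim_cfg = {"phantom": config.phantom.__dict__, "snr": config.snr,
               "n": n_total, "seed": config.seed}
    sim = _Stage(run_dir, "simulate", sim_cfg)
    if not sim.is_cached():
        d = sim.start()
        for i in range(n_total):
            pdir = d / f"case{i:02d}"
            phantom = generate_phantom(config.phantom, seed=_stage_seed(config.seed, "phantom", i))
            save_phantom(phantom, pdir)
            stack = simulate_baseline_stack(phantom, schedule)
            noisy = add_rician_noise(stack, config.snr, seed=_stage_seed(config.seed, "noise", i))
            write_stack(noisy, pdir / "stack.nii.gz")
        sim.done()

    cases = [run_dir / "simulate" / f"case{i:02d}" for i in range(n_total)]

    # ---- denoise -----------------------------------------------------------
    den = _Stage(run_dir, "denoise", {"window": config.denoise_window,
                                      "on": config.denoise, "sim": sim.hash})
    if not den.is_cached():
        d = den.start()
        from .io import read_stack

        for i, cdir in enumerate(cases):
            stack = read_stack(cdir / "stack.nii.gz", schedule)
            if config.denoise:
                result = mppca_denoise(stack, window=config.denoise_window)
                out = result.denoised
                write_nifti(result.sigma_map, out.voxel_size, d / f"case{i:02d}_sigma.nii.gz")
            else:
                out = stack
            write_stack(out, d / f"case{i:02d}.nii.gz")
        den.done()

    # ---- dictionary --------------------------------------------------------
    dic = _Stage(run_dir, "dictionary", {"rel_step": config.dictionary_rel_step})
    dict_path = dic.dir / "dictionary.npz"
    if not dic.is_cached():
        d = dic.start()
        dictionary = build_dictionary(schedule, default_grid(config.dictionary_rel_step))
        save_dictionary(dictionary, dict_path)
        dic.done()
    else:
        dictionary = load_dictionary(dict_path)

    # ---- reconstruct (training targets) ------------------------------------
    rec = _Stage(run_dir, "reconstruct", {"dict": dic.hash, "den": den.hash,
                                          "targets_from": config.targets_from})
    if not rec.is_cached():
        d = rec.start()
        from .io import read_stack

        for i, cdir in enumerate(cases):
            stack = read_stack(run_dir / "denoise" / f"case{i:02d}.nii.gz", schedule)
            phantom = load_phantom(cdir)
            qm = reconstruct_maps(stack, dictionary, phantom.brain_mask)
            for name in ("t1_ms", "t2s_ms", "b1_scale", "m0", "correlation"):
                write_nifti(getattr(qm, name), stack.voxel_size,
                            d / f"case{i:02d}_{name}.nii.gz")
        rec.done()

    # ---- train -------------------------------------------------------------
    trn = _Stage(run_dir, "train", {"variant": config.variant,
                                    "training": config.training.__dict__,
                                    "rec": rec.hash})
    ckpt_path = trn.dir / "model.npz"
    if not trn.is_cached():
        d = trn.start()
        from .io import read_stack

        def build_case(i: int) -> TrainingCase:
            phantom = load_phantom(cases[i])
            stack = read_stack(run_dir / "denoise" / f"case{i:02d}.nii.gz", schedule)
            if config.targets_from == "dictionary":
                t1, _ = read_nifti(run_dir / "reconstruct" / f"case{i:02d}_t1_ms.nii.gz")
                t2s, _ = read_nifti(run_dir / "reconstruct" / f"case{i:02d}_t2s_ms.nii.gz")
            else:
                t1, t2s = phantom.t1_map, phantom.t2s_map
            if variant.n_inputs == 2:  # reference network: quantitative maps in
                from .nn.training import T1_SCALE_MS, T2S_SCALE_MS

                inputs = np.stack([t1 / T1_SCALE_MS, t2s / T2S_SCALE_MS], axis=-1).astype(np.float32)
            else:
                inputs = normalize_inputs(stack.data)
            targets, _ = make_targets(variant, np.asarray(t1, np.float32),
                                      np.asarray(t2s, np.float32),
                                      phantom.prob_nawm, phantom.prob_gm,
                                      phantom.lesion_mask)
            return TrainingCase(inputs=inputs, targets=targets,
                                lesion_mask=phantom.lesion_mask,
                                voxel_size=phantom.voxel_size)

        train_cases = [build_case(i) for i in range(config.n_train)]
        val_cases = [build_case(i) for i in
                     range(config.n_train, config.n_train + config.n_val)]
        sampler = build_training_set(train_cases, config.training)
        result = train(variant, sampler, config.training, val_cases=val_cases)
        save_checkpoint(result, ckpt_path)
        pd.DataFrame(result.history).to_csv(d / "history.csv", index=False)
        if result.collapsed:
            logger.warning("%s", result.collapse_message)
        (d / "flags.json").write_text(json.dumps(
            {"collapsed": result.collapsed, "message": result.collapse_message}))
        trn.done()

    # ---- predict + evaluate -------------------------------------------------
    ev = _Stage(run_dir, "evaluate", {"train": trn.hash,
                                      "lesion_threshold": config.lesion_threshold,
                                      "tissue_threshold": config.tissue_threshold})
    if not ev.is_cached():
        d = ev.start()
        from .io import read_stack
        from .nn import load_checkpoint
        from .nn.training import T1_SCALE_MS, T2S_SCALE_MS

        result = load_checkpoint(ckpt_path)
        rows = []
        test_ids = range(config.n_train + config.n_val, n_total)
        for i in test_ids:
            phantom = load_phantom(cases[i])
            stack = read_stack(run_dir / "denoise" / f"case{i:02d}.nii.gz", schedule)
            if variant.n_inputs == 2:
                t1r, _ = read_nifti(run_dir / "reconstruct" / f"case{i:02d}_t1_ms.nii.gz")
                t2r, _ = read_nifti(run_dir / "reconstruct" / f"case{i:02d}_t2s_ms.nii.gz")
                inputs = np.stack([np.asarray(t1r) / T1_SCALE_MS,
                                   np.asarray(t2r) / T2S_SCALE_MS], axis=-1).astype(np.float32)
            else:
                inputs = normalize_inputs(stack.data)
            out = predict(result.model, inputs, variant)
            lesion_prob = out.channels[..., -1]
            write_nifti(lesion_prob, phantom.voxel_size, d / f"case{i:02d}_lesion_prob.nii.gz")
            pred_mask = binarize(lesion_prob, config.lesion_threshold)
            row = {
                "case": i,
                "dice": dice(pred_mask, phantom.lesion_mask),
                "detection_rate": lesion_detection_rate(phantom.lesion_mask, pred_mask),
                "gt_lesion_voxels": int(phantom.lesion_mask.sum()),
                "pred_lesion_voxels": int(pred_mask.sum()),
            }
            if variant.n_outputs == 5:
                t1p, t2p = out.quantitative()
                brain = phantom.brain_mask
                row["t1_mean_rel_dev"] = mean_relative_deviation(t1p, phantom.t1_map, brain)
                row["t2s_mean_rel_dev"] = mean_relative_deviation(t2p, phantom.t2s_map, brain)
                row["dice_nawm"] = dice(binarize(out.probability("prob_nawm"), config.tissue_threshold),
                                        phantom.prob_nawm >= config.tissue_threshold)
                row["dice_gm"] = dice(binarize(out.probability("prob_gm"), config.tissue_threshold),
                                      phantom.prob_gm >= config.tissue_threshold)
            rows.append(row)
            per_lesion_stats(phantom.lesion_mask, pred_mask, phantom.voxel_size).to_csv(
                d / f"case{i:02d}_lesions.csv", index=False)
            sweep = threshold_sweep(np.clip(lesion_prob, 0, 1), phantom.lesion_mask,
                                    np.linspace(0.05, 0.95, 19))
            sweep.to_frame().to_csv(d / f"case{i:02d}_sweep.csv", index=False)
        pd.DataFrame(rows).to_csv(d / "per_case.csv", index=False)
        flags = json.loads((trn.dir / "flags.json").read_text())
        summary = {
            "variant": config.variant,
            "collapsed": flags["collapsed"],
            "collapse_message": flags["message"],
            "mean_dice": float(np.mean([r["dice"] for r in rows])) if rows else None,
            "mean_detection_rate": float(np.mean([r["detection_rate"] for r in rows])) if rows else None,
        }
        (d / "summary.json").write_text(json.dumps(summary, indent=2))
        ev.done()
    return run_dir
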