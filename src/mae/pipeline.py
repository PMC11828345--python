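"""Run orchestration: prepare -> train -> evaluate, beta sweeps, ablations.

Every run writes a self-contained directory under ``config.out_dir`` holding
the config echo, the manifest, a JSON report with all weight vectors and test
metrics, and a checkpoint from which ``evaluate`` reproduces the report's
test metrics exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from mae.classes import derive_seed
from mae.config import RunConfig
from mae.data import AugmentationPolicy, expand_training_set, load_manifest, save_manifest, stratified_split
from mae.ensemble import (
    BaseModelSpec,
    build_model,
    fuse_probs,
    load_split_arrays,
    normalize_images,
    train_mae,
)
from mae.metrics import build_confusion, metrics_from_confusion
from mae.synth import generate_dataset
from mae.voting import WeightVector, mixed_combine

logger = logging.getLogger("mae")

__all__ = ["run_from_config", "beta_sweep", "ablation_grid", "evaluate_checkpoint", "run_id"]


def run_id(config: RunConfig) -> str:
    """Deterministic run identifier: short hash of the canonical config."""
    blob = json.dumps(config.as_dict(), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


def _specs_from_config(config: RunConfig) -> list[BaseModelSpec]:
    return [
        BaseModelSpec(
            name=f"{bb}-{i}",
            backbone=bb,
            use_csae=config.use_csae,
            csae_kernel=config.csae_kernel,
            rescale_attention=config.rescale_attention,
        )
        for i, bb in enumerate(config.backbones)
    ]


def _prepare_manifest(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    if config.manifest:
        manifest = load_manifest(config.manifest)
    elif config.synth_n_per_class > 0:
        manifest = generate_dataset(
            config.synth_n_per_class,
            seed=derive_seed(config.seed, "synth"),
            out_dir=run_dir / "data",
            image_size=config.image_size,
            noise_level=config.noise_level,
        )
    else:
        raise ValueError(
            "no dataset: set 'manifest' to an existing manifest CSV or "
            "'synth_n_per_class' > 0 to generate synthetic images"
        )
    if (manifest["split"].astype(str) == "").all():
        manifest = stratified_split(manifest, seed=derive_seed(config.seed, "split"))
    if config.augment:
        policy = AugmentationPolicy(
            copies_per_image=config.copies_per_image,
            seed=derive_seed(config.seed, "augment"),
        )
        manifest = expand_training_set(manifest, policy)
    return manifest


def run_from_config(config: RunConfig | str | Path) -> dict:
    """Execute prepare -> train -> evaluate and write the versioned report."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    rid = run_id(config)
    run_dir = Path(config.out_dir) / f"run-{rid}"
    run_dir.mkdir(parents=True, exist_ok=True)

    manifest = _prepare_manifest(config, run_dir)
    save_manifest(manifest, run_dir / "manifest.csv")
    specs = _specs_from_config(config)
    result = train_mae(manifest, specs, config)
    report = result["report"]
    report["run_id"] = rid
    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _save_checkpoint(run_dir / "checkpoint.npz", result, config)
    _metrics_csv(report, run_dir / "metrics.csv")
    logger.info("run %s: test accuracy %.4f", rid, report["test_accuracy"])
    result["run_dir"] = run_dir
    return result


def _metrics_csv(report: dict, path: Path) -> None:
    m = report["metrics"]
    rows = [dict(metric="accuracy", value=m["accuracy"]), dict(metric="error_rate", value=m["error_rate"])]
    for agg in ("micro", "macro", "weighted"):
        for k, v in m[agg].items():
            rows.append(dict(metric=f"{agg}_{k}", value=v))
    pd.DataFrame(rows).to_csv(path, index=False)


def _save_checkpoint(path: Path, result: dict, config: RunConfig) -> None:
    arrays = {}
    for i, model in enumerate(result["models"]):
        for j, arr in enumerate(model.state_dict()):
            arrays[f"model{i}_p{j}"] = arr
    arrays["w_final"] = np.asarray(result["report"]["w_final"])
    meta = dict(
        config=config.as_dict(),
        specs=[dataclasses.asdict(m.spec) for m in result["models"]],
    )
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def evaluate_checkpoint(checkpoint_path, manifest_path) -> dict:
    """Reload a trained ensemble and recompute test metrics from scratch."""
    with np.load(checkpoint_path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        config = RunConfig.from_dict(meta["config"])
        models = []
        for i, spec_d in enumerate(meta["specs"]):
            spec = BaseModelSpec(**spec_d)
            model = build_model(spec)
            state = []
            j = 0
            while f"model{i}_p{j}" in data:
                state.append(data[f"model{i}_p{j}"])
                j += 1
            model.load_state_dict(state)
            models.append(model)
        w = WeightVector(data["w_final"])
    manifest = load_manifest(manifest_path)
    x_te, y_te = load_split_arrays(manifest, "test", config.image_size)
    x_te = normalize_images(x_te)
    test_probs = np.stack([m.predict_proba(x_te) for m in models])
    pred = fuse_probs(test_probs, w).argmax(axis=1)
    cm = build_confusion(y_te, pred, models[0].spec.num_classes)
    rep = metrics_from_confusion(cm)
    return {
        "test_accuracy": rep.accuracy,
        "confusion_matrix": cm.counts.tolist(),
        "metrics": rep.as_dict(),
        "w_final": w.w.tolist(),
    }


def beta_sweep(result: dict, beta_values) -> pd.DataFrame:
    """Evaluate the mixed blend over a list of beta1 values.

    Uses the cached frozen per-model test probabilities from a finished run —
    no retraining.  Row beta1 = 0 equals the pure individual-voting ensemble,
    beta1 = 1 the pure group-voting ensemble.
    """
    betas = list(beta_values)
    if not betas:
        raise ValueError("beta_values is empty")
    report = result["report"]
    w_i = WeightVector(np.asarray(report["w_individual"]))
    w_g = WeightVector(np.asarray(report["w_group"]))
    test_probs, y_te = result["test_probs"], result["y_test"]
    rows = []
    for b in betas:
        w = mixed_combine(w_g, w_i, b)
        pred = fuse_probs(test_probs, w).argmax(axis=1)
        cm = build_confusion(y_te, pred, test_probs.shape[2])
        m = metrics_from_confusion(cm)
        rows.append(
            dict(
                beta1=b,
                accuracy=m.accuracy,
                macro_precision=m.macro["precision"],
                macro_recall=m.macro["recall"],
                macro_f1=m.macro["f1"],
                weights=w.w.tolist(),
            )
        )
    return pd.DataFrame(rows)


def ablation_grid(
    config: RunConfig,
    voting_modes=("average", "standard", "individual", "group", "mixed"),
    csae_options=(False, True),
) -> pd.DataFrame:
    """Run the voting-mode x CSAE grid and tabulate test metrics."""
    rows = []
    for use_csae in csae_options:
        for mode in voting_modes:
            cfg = dataclasses.replace(config, voting_mode=mode, use_csae=use_csae)
            result = run_from_config(cfg)
            rep = result["report"]
            rows.append(
                dict(
                    voting_mode=mode,
                    use_csae=use_csae,
                    accuracy=rep["test_accuracy"],
                    macro_f1=rep["metrics"]["macro"]["f1"],
                )
            )
    return pd.DataFrame(rows)
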