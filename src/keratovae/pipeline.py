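"""End-to-end experiment orchestration.

``run_experiment`` drives the full study from one YAML config: synthesize a
cohort of topography maps, preprocess them (segment, denoise, ordered
grayscale), train the VAE, expand the dataset to a balanced per-class
target, train the customized CNN twice — on originals only and on the
augmented set — and evaluate both on the same originals-only test set,
emitting the original-vs-synthesized comparison table.

Two scales are built in: ``paper`` (978/780 originals, target 2000/class,
full epoch counts) and ``demo`` (100/100, target 200/class, short epochs),
the latter sized to complete end-to-end on a single CPU.  Every stochastic
stage receives a seed derived deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify, evalmetrics, preprocess, synthmap, vae_core

__all__ = [
    "ExperimentConfig", "ConfigError", "validate_config", "run_experiment",
    "generate_processed_cohort", "ProcessedSample", "augmentation_comparison",
]


class ConfigError(ValueError):
    """Configuration schema violation, naming the offending key(s)."""


SCALES = {
    "paper": {"n_normal": 978, "n_kcn": 780, "per_class_target": 2000,
              "vae_epochs": 50, "cnn_epochs": 15},
    "demo": {"n_normal": 100, "n_kcn": 100, "per_class_target": 200,
             "vae_epochs": 3, "cnn_epochs": 6},
}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "runs/experiment",
    "scale": "demo",
    "synthmap": {"n_normal": None, "n_kcn": None, "canvas": 300,
                 "noise_amplitude": 40, "noise_period": 9, "impulse_density": 0.01},
    "preprocess": {"gray_size": 104, "cnn_size": 50},
    "vae": {"epochs": None, "batch_size": 32, "latent_dim": 1,
            "learning_rate": 1e-4, "input_size": 104, "augment": False},
    "classify": {"epochs": None, "batch_size": 32, "learning_rate": 1e-4,
                 "per_class_target": None},
    "evaluate": {"prevalence": 0.44, "threshold": 0.5},
}


@dataclasses.dataclass
class ExperimentConfig:
    raw: dict[str, Any]
    warnings: list[str]

    def __getitem__(self, key: str):
        return self.raw[key]


def _merge_defaults(user: dict, defaults: dict, path: str,
                    warnings: list[str]) -> dict:
    out = {}
    for key, val in defaults.items():
        if isinstance(val, dict):
            out[key] = _merge_defaults(user.get(key, {}) or {}, val,
                                       f"{path}{key}.", warnings)
        else:
            out[key] = user.get(key, val)
    for key in user:
        if key not in defaults:
            warnings.append(f"unknown key ignored: {path}{key}")
    return out


def validate_config(path_or_dict: str | Path | dict) -> ExperimentConfig:
    """Load, default-fill and cross-check an experiment config.

    Scale presets fill any unset counts/epochs; inconsistent blocks (e.g. a
    VAE input size different from the preprocessing grayscale size) raise
    :class:`ConfigError` naming the offending keys; unknown keys are ignored
    with a recorded warning.
    """
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    warnings: list[str] = []
    cfg = _merge_defaults(user, _DEFAULTS, "", warnings)
    if cfg["scale"] not in SCALES:
        raise ConfigError(f"scale must be one of {sorted(SCALES)}, got {cfg['scale']!r}")
    preset = SCALES[cfg["scale"]]
    if cfg["synthmap"]["n_normal"] is None:
        cfg["synthmap"]["n_normal"] = preset["n_normal"]
    if cfg["synthmap"]["n_kcn"] is None:
        cfg["synthmap"]["n_kcn"] = preset["n_kcn"]
    if cfg["vae"]["epochs"] is None:
        cfg["vae"]["epochs"] = preset["vae_epochs"]
    if cfg["classify"]["epochs"] is None:
        cfg["classify"]["epochs"] = preset["cnn_epochs"]
    if cfg["classify"]["per_class_target"] is None:
        cfg["classify"]["per_class_target"] = preset["per_class_target"]
    if cfg["vae"]["input_size"] != cfg["preprocess"]["gray_size"]:
        raise ConfigError(
            "vae.input_size and preprocess.gray_size must agree "
            f"({cfg['vae']['input_size']} != {cfg['preprocess']['gray_size']})")
    n_min = min(cfg["synthmap"]["n_normal"], cfg["synthmap"]["n_kcn"])
    if cfg["classify"]["per_class_target"] < n_min:
        raise ConfigError("classify.per_class_target below synthmap class counts")
    return ExperimentConfig(raw=cfg, warnings=warnings)


@dataclasses.dataclass
class ProcessedSample:
    params: synthmap.MapParams
    gray: np.ndarray  # (S, S, 1) float32 in [0, 1], VAE-ready
    color: np.ndarray  # (s, s, 3) float32 in [0, 1], classifier-ready


def _stage_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


def generate_processed_cohort(n_normal: int, n_kcn: int, seed: int,
                              gray_size: int = 104, cnn_size: int = 50,
                              canvas_size: int = 300,
                              noise_cfg: synthmap.NoiseConfig | None = None,
                              scale: synthmap.ColorScale | None = None
                              ) -> list[ProcessedSample]:
    """Synthesize, contaminate and fully preprocess a labelled cohort."""
    scale = scale or synthmap.default_color_scale()
    noise_cfg = noise_cfg if noise_cfg is not None else synthmap.NoiseConfig()
    cohort = synthmap.sample_cohort(n_normal, n_kcn, seed)
    canvas = synthmap.CanvasConfig(size=(canvas_size, canvas_size),
                                   annotation_seed=seed)
    side = int(round(2 * canvas.radius_frac * canvas_size))
    out: list[ProcessedSample] = []
    for i, params in enumerate(cohort):
        field, mask = synthmap.curvature_field(params, (side, side))
        rendered = synthmap.render_map(field, mask, scale, canvas)
        noisy = synthmap.add_acquisition_noise(rendered.image, noise_cfg,
                                               seed=seed + 7919 * (i + 1))
        crop = preprocess.segment_cornea(noisy).image
        clean = preprocess.remove_regular_noise(crop)
        gray = preprocess.ordered_grayscale(clean, scale,
                                            size=(gray_size, gray_size))
        color = preprocess.prepare_input(clean, "custom_cnn",
                                         size_override=cnn_size)
        out.append(ProcessedSample(params=params,
                                   gray=gray.values[..., None].astype(np.float32),
                                   color=color))
    return out


def _clf_records(samples: list[ProcessedSample]) -> list[vae_core.LabeledImage]:
    return [vae_core.LabeledImage(image=s.color, label=s.params.label)
            for s in samples]


def _vae_records(samples: list[ProcessedSample]) -> list[vae_core.LabeledImage]:
    return [vae_core.LabeledImage(image=s.gray, label=s.params.label)
            for s in samples]


def _synth_to_clf(rec: vae_core.LabeledImage, scale: synthmap.ColorScale,
                  cnn_size: int) -> vae_core.LabeledImage:
    rgb = preprocess.grayscale_to_color(rec.image[..., 0], scale)
    color = preprocess.prepare_input(rgb, "custom_cnn", size_override=cnn_size)
    return vae_core.LabeledImage(image=color, label=rec.label,
                                 origin="synthesized", source_id=rec.source_id)


def train_vae_and_augment(samples: list[ProcessedSample], seed: int, *,
                          per_class_target: int, vae_epochs: int,
                          batch_size: int = 32, cnn_size: int = 50,
                          scale: synthmap.ColorScale | None = None) -> dict:
    """Train the VAE on the cohort's grayscale maps and expand the
    classifier dataset to ``per_class_target`` images per class."""
    scale = scale or synthmap.default_color_scale()
    seeds = _stage_seeds(seed, 6)
    vae_cfg = vae_core.VaeConfig(epochs=vae_epochs, batch_size=batch_size,
                                 augment=False)
    vae, history = vae_core.train_vae(_vae_records(samples), vae_cfg,
                                      seed=seeds[0])
    augmented_gray = vae_core.synthesize_to_target(
        _vae_records(samples), vae, per_class_target, seed=seeds[1])
    clf_dataset = _clf_records(samples) + [
        _synth_to_clf(r, scale, cnn_size)
        for r in augmented_gray if r.origin == "synthesized"]
    return {"vae": vae, "vae_history": history, "clf_dataset": clf_dataset}


def paired_classifier_comparison(clf_dataset: list[vae_core.LabeledImage],
                                 seed: int, *, cnn_epochs: int,
                                 batch_size: int = 32,
                                 learning_rate: float = 1e-4,
                                 threshold: float = 0.5,
                                 prevalence: float | None = None) -> dict:
    """Train the custom CNN on originals-only vs the full augmented set.

    Both conditions share the identical originals-only test set, making the
    comparison paired.
    """
    seeds = _stage_seeds(seed, 6)
    split = classify.split_dataset(clf_dataset, classify.SplitSpec(seed=seeds[2]))
    originals_train = [r for r in split.train if r.origin == "original"]
    x_te = np.stack([r.image for r in split.test])
    y_te = np.array([1 if r.label == classify.POSITIVE_LABEL else 0
                     for r in split.test])

    cnn_cfg = classify.CustomCnnConfig(epochs=cnn_epochs, batch_size=batch_size,
                                       learning_rate=learning_rate)
    results: dict[str, Any] = {"n_augmented": len(clf_dataset),
                               "n_test": len(split.test)}
    for cond, train_set in (("original", originals_train),
                            ("synthesized", split.train)):
        model = classify.build_custom_cnn(cnn_cfg, seed=seeds[3])
        x_tr = np.stack([r.image for r in train_set])
        y_tr = np.array([[1.0 if r.label == classify.POSITIVE_LABEL else 0.0]
                         for r in train_set], dtype=np.float32)
        hist, _ = classify.fit_binary(
            model, x_tr, y_tr, epochs=cnn_cfg.epochs,
            learning_rate=cnn_cfg.learning_rate, optimizer=cnn_cfg.optimizer,
            batch_size=cnn_cfg.batch_size, seed=seeds[4])
        scores = classify.predict_scores(model, x_te)
        rep = evalmetrics.report_from_scores(scores, y_te, threshold=threshold,
                                             prevalence=prevalence)
        results[cond] = {"report": rep, "scores": scores, "labels": y_te,
                         "history": hist, "n_train": len(train_set),
                         "model": model}
    return results


def augmentation_comparison(samples: list[ProcessedSample], seed: int, *,
                            per_class_target: int, vae_epochs: int,
                            cnn_epochs: int, batch_size: int = 32,
                            learning_rate: float = 1e-4, cnn_size: int = 50,
                            threshold: float = 0.5,
                            prevalence: float | None = None,
                            scale: synthmap.ColorScale | None = None) -> dict:
    """Full originals-vs-augmented experiment: VAE training, dataset
    expansion, then the paired custom-CNN comparison."""
    aug = train_vae_and_augment(samples, seed,
                                per_class_target=per_class_target,
                                vae_epochs=vae_epochs, batch_size=batch_size,
                                cnn_size=cnn_size, scale=scale)
    results = paired_classifier_comparison(
        aug["clf_dataset"], seed, cnn_epochs=cnn_epochs,
        batch_size=batch_size, learning_rate=learning_rate,
        threshold=threshold, prevalence=prevalence)
    results["vae_history"] = aug["vae_history"]
    results["vae"] = aug["vae"]
    return results


def run_experiment(config: ExperimentConfig | str | Path | dict) -> dict:
    """Execute the six pipeline stages and write a run manifest.

    Returns the manifest dict; artifacts (CSVs, weights, manifest JSON) are
    written under ``out_dir``.
    """
    if not isinstance(config, ExperimentConfig):
        config = validate_config(config)
    cfg = config.raw
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    manifest: dict[str, Any] = {"config_hash": cfg_hash, "seed": cfg["seed"],
                                "warnings": config.warnings, "stages": []}
    seeds = _stage_seeds(cfg["seed"], 8)

    def stage(name: str):
        manifest["stages"].append({"name": name, "t0": time.time()})
        return manifest["stages"][-1]

    def done(rec: dict, **info):
        rec["wall_s"] = round(time.time() - rec.pop("t0"), 3)
        rec.update(info)
        rec["status"] = "complete"

    try:
        s = stage("synth_cohort")
        noise_cfg = synthmap.NoiseConfig(
            row_period=cfg["synthmap"]["noise_period"],
            col_period=cfg["synthmap"]["noise_period"],
            amplitude=cfg["synthmap"]["noise_amplitude"],
            impulse_density=cfg["synthmap"]["impulse_density"])
        samples = generate_processed_cohort(
            cfg["synthmap"]["n_normal"], cfg["synthmap"]["n_kcn"], seeds[0],
            gray_size=cfg["preprocess"]["gray_size"],
            cnn_size=cfg["preprocess"]["cnn_size"],
            canvas_size=cfg["synthmap"]["canvas"], noise_cfg=noise_cfg)
        man = synthmap.cohort_manifest([x.params for x in samples])
        man.to_csv(out_dir / "cohort.csv", index=False)
        done(s, n_images=len(samples), manifest_csv=str(out_dir / "cohort.csv"))

        s = stage("preprocess")  # folded into cohort generation; record sizes
        done(s, gray_size=cfg["preprocess"]["gray_size"],
             cnn_size=cfg["preprocess"]["cnn_size"])

        s = stage("train_vae_and_augment")
        aug = train_vae_and_augment(
            samples, cfg["seed"],
            per_class_target=cfg["classify"]["per_class_target"],
            vae_epochs=cfg["vae"]["epochs"],
            batch_size=cfg["vae"]["batch_size"],
            cnn_size=cfg["preprocess"]["cnn_size"])
        pd.DataFrame([dataclasses.asdict(h) for h in aug["vae_history"]]
                     ).to_csv(out_dir / "vae_loss_history.csv", index=False)
        done(s, n_augmented=len(aug["clf_dataset"]))

        s = stage("train_classifiers")
        comparison = paired_classifier_comparison(
            aug["clf_dataset"], cfg["seed"],
            cnn_epochs=cfg["classify"]["epochs"],
            batch_size=cfg["classify"]["batch_size"],
            learning_rate=cfg["classify"]["learning_rate"],
            threshold=cfg["evaluate"]["threshold"],
            prevalence=cfg["evaluate"]["prevalence"])
        for cond in ("original", "synthesized"):
            pd.DataFrame({"epoch": range(1, len(comparison[cond]["history"]) + 1),
                          "loss": comparison[cond]["history"]}
                         ).to_csv(out_dir / f"cnn_{cond}_history.csv", index=False)
            pd.DataFrame({"score": comparison[cond]["scores"],
                          "label": comparison[cond]["labels"]}
                         ).to_csv(out_dir / f"predictions_{cond}.csv", index=False)
        done(s, n_test=comparison["n_test"])

        s = stage("evaluate")
        table = evalmetrics.compare_experiments(
            {"custom_cnn": {c: comparison[c]["report"]
                            for c in ("original", "synthesized")}})
        table.to_csv(out_dir / "comparison.csv", index=False)
        done(s, comparison_csv=str(out_dir / "comparison.csv"))

        s = stage("report")
        manifest["metrics"] = {
            c: {k: (None if v != v else round(float(v), 6))
                for k, v in comparison[c]["report"].as_dict().items()}
            for c in ("original", "synthesized")}
        done(s)
    except Exception as exc:  # record the failing stage, keep partial output
        manifest["stages"][-1]["status"] = "failed"
        manifest["stages"][-1]["error"] = repr(exc)
        manifest["stages"][-1].pop("t0", None)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
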