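"""End-to-end orchestration: denoise -> tune -> train extractor -> extract
features -> train DBN -> evaluate.

The flow mirrors the four-stage design: Wiener pre-processing, the MAFNet
extractor whose training hyperparameters (learning rate, batch size, epochs,
dropout) are tuned by HGSO on an inner validation split using the
misclassification-rate fitness, and a DBN classifier on the extracted
features, evaluated with per-class and macro accuracy / sensitivity /
specificity / F-score / MCC on a stratified 70/30 split.

Hyperparameter fitness evaluations run a down-scaled extractor (epochs
capped, lighter DBN schedule) to keep tuning tractable on one CPU; the final
model retrains at the winning settings' full budget.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time

import numpy as np
import pandas as pd
from scipy import ndimage

from . import hgso as hg
from .dbn import DBNClassifier, DBNConfig
from .mafnet import (MAFNetConfig, TrainSettings, build_mafnet,
                     extract_features, save_checkpoint, train_mafnet)
from .metrics import EvaluationReport, confusion, macro_report, stratified_split
from .preprocess import WienerConfig, wiener_denoise
from .synthetic import ImageSample, SyntheticDatasetConfig, generate_dataset, \
    load_dataset

__all__ = ["PipelineConfig", "PipelineResult", "REFERENCE_SETTINGS",
           "FitnessEvaluationError", "run_pipeline", "run_ablation"]

#: Reference trainer settings (learning rate 0.01, dropout 0.5, batch size 5,
#: 50 epochs) used verbatim when tuning is skipped.
REFERENCE_SETTINGS = TrainSettings(lr0=0.01, batch_size=5, epochs=50,
                                   dropout=0.5)


class FitnessEvaluationError(RuntimeError):
    """A hyperparameter evaluation failed; carries the offending settings."""

    def __init__(self, settings: dict, cause: Exception):
        super().__init__(f"fitness evaluation failed for {settings}: {cause}")
        self.settings = settings


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    wiener: WienerConfig = WienerConfig()
    mafnet: MAFNetConfig = MAFNetConfig(n_classes=3)
    hgso: hg.HGSOConfig = hg.HGSOConfig(population_size=6, n_clusters=2,
                                        max_iter=5)
    dbn: DBNConfig = DBNConfig()
    split_seed: int = 0
    train_fraction: float = 0.70
    skip_wiener: bool = False
    skip_hgso: bool = False
    proxy_epochs: int = 3       # epoch cap inside fitness evaluations
    out_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class PipelineResult:
    report: EvaluationReport          # held-out 30% split
    train_report: EvaluationReport    # 70% split
    settings: TrainSettings           # extractor settings actually used
    tuned: bool
    loss_history: np.ndarray
    hgso_history: np.ndarray | None
    out_dir: pathlib.Path | None


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    h, w, _ = image.shape
    if h == size and w == size:
        return image
    out = ndimage.zoom(image, (size / h, size / w, 1.0), order=1,
                       mode="nearest", grid_mode=True)
    return np.clip(out, 0.0, 1.0)


def _load_samples(data) -> list[ImageSample]:
    if isinstance(data, SyntheticDatasetConfig):
        samples, _ = generate_dataset(data)
        return samples
    if isinstance(data, (str, pathlib.Path)):
        return load_dataset(data)
    return list(data)


def _prepare(data, config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """Resize to the extractor's input size, then Wiener-denoise."""
    samples = _load_samples(data)
    images = np.stack([_resize(s.image, config.mafnet.input_size)
                       for s in samples])
    labels = np.array([s.label for s in samples], dtype=int)
    if not config.skip_wiener:
        images = np.stack([wiener_denoise(im, config.wiener) for im in images])
    return images, labels


def _train_and_classify(images_train, labels_train, images_eval,
                        config: PipelineConfig, settings: TrainSettings,
                        dbn_config: DBNConfig
                        ) -> tuple[np.ndarray, np.ndarray, DBNClassifier, object]:
    """Train extractor + DBN on the training fold; predict the eval fold."""
    network = build_mafnet(config.mafnet, seed=settings.seed)
    loss_history = train_mafnet(network, images_train, labels_train, settings)
    feats_train = extract_features(network, images_train)
    feats_eval = extract_features(network, images_eval)
    model = DBNClassifier(dbn_config).fit(feats_train, labels_train)
    return model.predict(feats_eval), loss_history, model, network


def _tune(images, labels, config: PipelineConfig
          ) -> tuple[TrainSettings, np.ndarray]:
    """HGSO search over the extractor hyperparameters.

    Each fitness evaluation trains a down-scaled extractor (epochs capped at
    proxy_epochs, light DBN schedule) on an inner 70/30 split of the
    training fold and returns the validation misclassification percentage.
    """
    space = hg.default_hyperparameter_space()
    inner_train, inner_val = stratified_split(labels, config.train_fraction,
                                              seed=config.split_seed + 1)
    proxy_dbn = dataclasses.replace(config.dbn, rbm_epochs=10,
                                    finetune_epochs=20)

    def objective(position: np.ndarray) -> float:
        decoded = space.decode(position)
        try:
            settings = TrainSettings(
                lr0=decoded["lr0"], batch_size=decoded["batch_size"],
                epochs=min(decoded["epochs"], config.proxy_epochs),
                dropout=decoded["dropout"], seed=config.split_seed)
            preds, _, _, _ = _train_and_classify(
                images[inner_train], labels[inner_train], images[inner_val],
                config, settings, proxy_dbn)
        except (ValueError, FloatingPointError, RuntimeError) as exc:
            raise FitnessEvaluationError(decoded, exc) from exc
        return hg.misclassification_rate(labels[inner_val], preds)

    result = hg.hgso_minimize(objective, space.bounds, config.hgso)
    best = space.decode(result.best_position)
    settings = TrainSettings(lr0=best["lr0"], batch_size=best["batch_size"],
                             epochs=best["epochs"], dropout=best["dropout"],
                             seed=config.split_seed)
    return settings, result.history


def run_pipeline(data, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full flow and evaluate on the held-out 30% split.

    `data` may be a SyntheticDatasetConfig, a directory with a
    ``filename,label`` manifest, or a list of ImageSample.  All artifacts
    (tuned settings, extractor checkpoint, features, DBN model, report,
    run manifest with every seed and the config hash) are persisted when
    `config.out_dir` is set.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    stage = "load-and-preprocess"
    try:
        images, labels = _prepare(data, config)
        n_classes = config.mafnet.n_classes
        if labels.max() >= n_classes:
            raise ValueError("labels exceed the configured class count")

        stage = "split"
        train_idx, test_idx = stratified_split(labels, config.train_fraction,
                                               seed=config.split_seed)

        stage = "hgso-tuning"
        hgso_history = None
        if config.skip_hgso:
            settings = dataclasses.replace(REFERENCE_SETTINGS,
                                           seed=config.split_seed)
        else:
            settings, hgso_history = _tune(images[train_idx],
                                           labels[train_idx], config)

        stage = "train-and-classify"
        preds_test, loss_history, model, network = _train_and_classify(
            images[train_idx], labels[train_idx], images[test_idx],
            config, settings, config.dbn)
        preds_train = model.predict(
            extract_features(network, images[train_idx]))

        stage = "evaluate"
        report = macro_report(
            confusion(labels[test_idx], preds_test, n_classes))
        train_report = macro_report(
            confusion(labels[train_idx], preds_train, n_classes))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    out_dir = None
    if config.out_dir is not None:
        out_dir = pathlib.Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(network, out_dir / "extractor")
        model.save(out_dir / "dbn_model")
        feats = extract_features(network, images)
        pd.DataFrame(feats, columns=[f"f{i}" for i in range(feats.shape[1])]
                     ).assign(label=labels).to_csv(out_dir / "features.csv",
                                                   index=False)
        report.to_csv(out_dir / "report_test.csv")
        train_report.to_csv(out_dir / "report_train.csv")
        (out_dir / "best_settings.json").write_text(
            json.dumps(dataclasses.asdict(settings), indent=2))
        manifest = {
            "config": _as_jsonable(config),
            "config_hash": config.config_hash(),
            "seeds": {"split": config.split_seed,
                      "hgso": config.hgso.seed,
                      "dbn": config.dbn.seed,
                      "trainer": settings.seed},
            "n_samples": int(labels.size),
            "runtime_seconds": round(time.time() - t0, 2),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(report=report, train_report=train_report,
                          settings=settings, tuned=not config.skip_hgso,
                          loss_history=loss_history,
                          hgso_history=hgso_history, out_dir=out_dir)


def run_ablation(data, config: PipelineConfig | None = None,
                 toggles: tuple[str, ...] = ("skip_wiener", "skip_hgso",
                                             "plain_conv")) -> pd.DataFrame:
    """Run the pipeline and one variant per toggle under a shared seed.

    Variants: `skip_wiener` drops the denoising stage, `skip_hgso` trains at
    the reference settings, `plain_conv` swaps CoT attention for plain 3x3
    convolutions.  Returns one macro-metric row per variant (0-100 scale).
    """
    config = config or PipelineConfig()
    valid = {"skip_wiener", "skip_hgso", "plain_conv"}
    if not set(toggles) <= valid:
        raise ValueError(f"toggles must be within {sorted(valid)}")
    variants: dict[str, PipelineConfig] = {"full": config}
    for toggle in toggles:
        if toggle == "plain_conv":
            variants[toggle] = dataclasses.replace(
                config, mafnet=dataclasses.replace(config.mafnet,
                                                   use_cot=False))
        else:
            variants[toggle] = dataclasses.replace(config, **{toggle: True})
    rows = []
    for name, cfg in variants.items():
        res = run_pipeline(data, dataclasses.replace(cfg, out_dir=None))
        rows.append({"variant": name,
                     **{k: round(100 * v, 2) for k, v in res.report.macro.items()}})
    return pd.DataFrame(rows)
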