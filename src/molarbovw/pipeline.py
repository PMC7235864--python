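"""End-to-end pipeline orchestration: configured, seeded, logged runs.

One :class:`PipelineConfig` snapshot plus an image manifest fully
determines a run: preprocessing -> ROI masking -> keypoint extraction ->
vocabulary building -> BoVW encoding -> paired cross-validation of the
benchmark classifiers.  A single ``global_seed`` fans out to every
stochastic stage through a documented derivation (stage-name hash XOR
global seed), so one integer reproduces a whole run.

By default one vocabulary is built from all images before
cross-validation (the default protocol); ``strict_cv=True`` instead
rebuilds the vocabulary inside each fold from training descriptors only,
closing the information leak of the global variant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bovw import (
    BovwHistogram,
    Vocabulary,
    build_vocabulary,
    encode,
    ensure_compatible,
)
from .classify import (
    CLASSIFIER_NAMES,
    CvResult,
    cross_validate,
    make_folds,
    results_to_frame,
    train_classifier,
)
from .errors import ConfigurationError
from .features import (
    DescriptorMatrix,
    ExtractorConfig,
    batch_extract,
    extract_features,
)
from .preprocess import FilterParams, preprocess_chain, to_grayscale
from .roi import RoiSpec, make_roi_mask
from .synthetic import read_manifest

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "run_pipeline",
    "predict_image",
    "synthetic_preset",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256(stage) XOR global seed, mod 2^31."""
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    return (int.from_bytes(digest[:4], "big") ^ int(global_seed)) % (2**31)


@dataclass
class PipelineConfig:
    """Every tunable of a run, with the reference constants as defaults."""

    filter_params: FilterParams = field(default_factory=FilterParams)
    roi_spec: RoiSpec = field(default_factory=RoiSpec)
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    vocab_k: int = 2800
    normalize_histograms: bool = True
    n_folds: int = 10
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    global_seed: int = 0
    strict_cv: bool = False
    use_edge_image: bool = True

    def validate(self) -> None:
        self.filter_params.validate()
        self.roi_spec.validate()
        self.extractor.validate()
        if self.vocab_k < 1:
            raise ConfigurationError(f"vocab_k must be >= 1, got {self.vocab_k}")
        if self.n_folds < 2:
            raise ConfigurationError(f"n_folds must be >= 2, got {self.n_folds}")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ConfigurationError(
                f"unknown classifiers {sorted(unknown)}; valid: {list(CLASSIFIER_NAMES)}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "filter_params": FilterParams,
            "roi_spec": RoiSpec,
            "extractor": ExtractorConfig,
        }
        kwargs: dict = {}
        for name, typ in sections.items():
            if name in data:
                sub = data.pop(name)
                valid = {f.name for f in dataclasses.fields(typ)}
                unknown = set(sub) - valid
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys {sorted(unknown)} in section {name!r}"
                    )
                for key in ("class_proportions", "tilt_range"):
                    if key in sub and isinstance(sub[key], list):
                        sub[key] = tuple(sub[key])
                kwargs[name] = typ(**sub)
        valid_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid_top
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        if "classifiers" in data:
            data["classifiers"] = tuple(data["classifiers"])
        kwargs.update(data)
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def synthetic_preset(
    n_images: int = 150, vocab_k: int = 200, global_seed: int = 42
) -> PipelineConfig:
    """Desk-scale preset used with the synthetic generator (K=200)."""
    return PipelineConfig(vocab_k=vocab_k, global_seed=global_seed)


def _encode_all(
    matrices: list[DescriptorMatrix], vocab: Vocabulary, normalize: bool
) -> np.ndarray:
    rows = [encode(m.descriptors, vocab, normalize=normalize).counts for m in matrices]
    return np.vstack([np.asarray(r, dtype=np.float64) for r in rows])


def _strict_cv(
    matrices: list[DescriptorMatrix],
    y: np.ndarray,
    config: PipelineConfig,
) -> list[CvResult]:
    """Leak-free variant: per-fold vocabulary from training descriptors only."""
    assignment = make_folds(
        y, n_folds=config.n_folds, seed=stage_seed(config.global_seed, "folds")
    )
    per_clf: dict[str, list[float]] = {name: [] for name in config.classifiers}
    for fold in range(config.n_folds):
        test = assignment == fold
        pool = np.vstack(
            [m.descriptors for m, t in zip(matrices, test) if not t and m.n > 0]
        )
        vocab = build_vocabulary(
            pool,
            k=config.vocab_k,
            seed=stage_seed(config.global_seed, "vocabulary"),
            method=config.extractor.method.upper(),
        )
        X = _encode_all(matrices, vocab, config.normalize_histograms)
        for name in config.classifiers:
            model = train_classifier(
                name,
                X[~test],
                y[~test],
                seed=stage_seed(config.global_seed, "classifier"),
            )
            acc = float(np.mean(model.predict(X[test]) == y[test]))
            per_clf[name].append(acc)
    return [
        CvResult(
            classifier_name=name,
            fold_accuracies=accs,
            fold_assignment=assignment,
            seed=stage_seed(config.global_seed, "folds"),
        )
        for name, accs in per_clf.items()
    ]


def run_pipeline(
    config: PipelineConfig, manifest_path: str | Path, out_dir: str | Path
) -> dict:
    """Execute the full pipeline on a manifest; write report + run record.

    Returns a dict with the report payload, the CvResults, and output
    paths.  Re-running with identical config and inputs reproduces a
    byte-identical ``report.json`` (the run record holds the timings).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    y = np.asarray([label for _, label in manifest])
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    matrices, log = batch_extract(
        manifest,
        config.filter_params,
        config.roi_spec,
        config.extractor,
        use_edge_image=config.use_edge_image,
    )
    timings["extract"] = time.perf_counter() - t0

    pooled_count = int(sum(m.n for m in matrices))
    if pooled_count < config.vocab_k:
        raise ConfigurationError(
            f"vocabulary stage: only {pooled_count} pooled descriptors for "
            f"vocab_k={config.vocab_k}; lower vocab_k (synthetic preset uses 200) "
            f"or supply more/larger images"
        )

    t0 = time.perf_counter()
    if config.strict_cv:
        results = _strict_cv(matrices, y, config)
        vocab = None
    else:
        pool = np.vstack([m.descriptors for m in matrices if m.n > 0])
        vocab = build_vocabulary(
            pool,
            k=config.vocab_k,
            seed=stage_seed(config.global_seed, "vocabulary"),
            method=config.extractor.method.upper(),
        )
        X = _encode_all(matrices, vocab, config.normalize_histograms)
        timings["vocabulary"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        results = cross_validate(
            X,
            y,
            names=config.classifiers,
            n_folds=config.n_folds,
            seed=stage_seed(config.global_seed, "folds"),
        )
    timings["classify"] = time.perf_counter() - t0

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_images": len(manifest),
        "extraction_warnings": log,
        "results": [
            {
                "classifier": r.classifier_name,
                "fold_accuracies": r.fold_accuracies,
                "mean_accuracy": r.mean_accuracy,
                "std_accuracy": r.std_accuracy,
                "failed_folds": r.failed_folds,
            }
            for r in results
        ],
    }
    report_json = out_dir / "report.json"
    report_json.write_text(json.dumps(report, indent=2, sort_keys=True))
    table = results_to_frame({config.extractor.method.upper(): results})
    report_csv = out_dir / "report.csv"
    table.to_csv(report_csv)
    if vocab is not None:
        from .bovw import save_vocabulary

        save_vocabulary(vocab, out_dir / "vocabulary.bovw")

    record = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "manifest": str(Path(manifest_path).resolve()),
        "manifest_sha256": hashlib.sha256(
            Path(manifest_path).read_bytes()
        ).hexdigest(),
        "software_version": __version__,
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
        "warnings": log,
        "outputs": [str(report_json), str(report_csv)],
    }
    (out_dir / "run_record.json").write_text(json.dumps(record, indent=2, sort_keys=True))
    return {"report": report, "results": results, "table": table, "out_dir": out_dir}


def predict_image(
    model,
    vocab: Vocabulary,
    image: str | Path | np.ndarray,
    filter_params: FilterParams | None = None,
    roi_spec: RoiSpec | None = None,
    extractor: ExtractorConfig | None = None,
    normalize: bool = True,
    use_edge_image: bool = True,
) -> dict:
    """Run the full chain on one radiograph and classify it.

    Compatibility between extractor method and vocabulary is checked
    before any computation.  A blank image (zero keypoints) still gets a
    prediction, flagged ``low_evidence``.
    """
    import imageio.v3 as iio

    extractor = extractor or ExtractorConfig()
    filter_params = filter_params or FilterParams()
    roi_spec = roi_spec or RoiSpec()
    from .features import DESCRIPTOR_DIMENSIONS

    ensure_compatible(vocab, extractor.method, DESCRIPTOR_DIMENSIONS[extractor.method.upper()])

    raw = image if isinstance(image, np.ndarray) else iio.imread(image)
    gray = to_grayscale(raw)
    stage = preprocess_chain(gray, filter_params) if use_edge_image else gray
    mask = make_roi_mask(*stage.shape, roi_spec)
    keypoints, matrix = extract_features(stage, mask, extractor)
    hist: BovwHistogram = encode(matrix.descriptors, vocab, normalize=normalize)
    label = model.predict(np.asarray(hist.counts, dtype=np.float64)[None, :])[0]
    return {
        "label": str(label),
        "histogram": hist,
        "n_keypoints": len(keypoints),
        "low_evidence": len(keypoints) == 0,
    }
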