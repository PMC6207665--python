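"""End-to-end orchestration: simulate -> preprocess -> extract -> LOO
evaluate -> report.

One master seed fixes everything downstream (image synthesis, classifier
seeds, bootstrap resampling), so a rerun with the same config reproduces
the report files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import DICHOTOMIES, evaluation_report
from .io import (feature_columns, feature_manifest, write_feature_table)
from .models import ClassifierSpec
from .morphology import (dataset_thresholds, morph_features, segment_fibers)
from .preprocess import PreprocessConfig, preprocess_pipeline
from .synthetic import SyntheticDataset, default_stage_table, generate_dataset
from .texture import TextureConfig, combine_features, texture_feature_vector

log = logging.getLogger("fibrostage")

__all__ = ["PipelineConfig", "extract_feature_table", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs; JSON-serializable.

    Unknown keys are rejected on load so silent typos cannot change a run.
    """

    seed: int = 0
    n_per_stage: int = 20
    image_size: int = 512
    feature_sets: tuple[str, ...] = ("morph",)
    models: tuple[str, ...] = ("ann", "mlr", "svm", "rf")
    ann_hidden_layers: tuple[int, ...] = (20,)
    n_boot: int = 200
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "texture" in d and isinstance(d["texture"], dict):
            t = dict(d["texture"])
            for k in ("glcm_distances", "gabor_orientations"):
                if k in t:
                    t[k] = tuple(t[k])
            d["texture"] = TextureConfig(**t)
        for k in ("feature_sets", "models", "ann_hidden_layers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         default=str))


def classifier_specs(cfg: PipelineConfig) -> dict[str, ClassifierSpec]:
    specs = {}
    for fam in cfg.models:
        if fam == "ann":
            specs[fam] = ClassifierSpec(
                family="ann", hidden_layers=cfg.ann_hidden_layers,
                seed=cfg.seed)
        else:
            specs[fam] = ClassifierSpec(family=fam, seed=cfg.seed)
    return specs


def extract_feature_table(dataset: SyntheticDataset,
                          cfg: PipelineConfig | None = None,
                          blocks: str = "all") -> pd.DataFrame:
    """Preprocess every image and compute its feature vector.

    ``blocks``: "morph" (21 columns), "texture" (109) or "all" (130).  The
    long/short and thick/thin cuts are the pooled per-fiber median length
    and width over the whole dataset.
    """
    cfg = cfg or PipelineConfig()
    procs, fiber_sets = [], []
    for i, img in enumerate(dataset.images):
        proc = preprocess_pipeline(img, cfg.preprocess)
        procs.append(proc)
        fiber_sets.append(segment_fibers(proc))
        if (i + 1) % 25 == 0:
            log.info("preprocessed %d/%d images", i + 1, len(dataset))
    thresholds = dataset_thresholds(fiber_sets)
    log.info("fiber cuts: length %.1f px, width %.2f px",
             thresholds.length_cut, thresholds.width_cut)
    rows = []
    for i, (proc, fs) in enumerate(zip(procs, fiber_sets)):
        parts = []
        if blocks in ("morph", "all"):
            parts.append(morph_features(fs, proc, thresholds))
        if blocks in ("texture", "all"):
            parts.append(texture_feature_vector(proc, cfg.texture))
        vec = (combine_features(*parts) if blocks == "all"
               else parts[0])
        rows.append(vec)
    X = np.vstack(rows)
    n_feat = X.shape[1]
    if blocks == "texture":
        cols = [f"f{i:03d}" for i in range(22, 131)]
    else:
        cols = feature_columns(n_feat)
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "stage", dataset.labels)
    df.insert(0, "image_id", [f"img_{i:04d}" for i in range(len(dataset))])
    return df


def run_pipeline(cfg: PipelineConfig | None = None,
                 outdir: str | Path | None = None):
    """Full run on a freshly simulated dataset; returns
    ``(report_table, comparisons, feature_table)`` and optionally writes
    ``features.csv``, ``report.csv``, ``report.json``, ``manifest.json``.
    """
    cfg = cfg or PipelineConfig()
    log.info("simulating %d images (seed %d)", 5 * cfg.n_per_stage, cfg.seed)
    dataset = generate_dataset(default_stage_table(), cfg.n_per_stage,
                               cfg.seed, shape=(cfg.image_size,
                                                cfg.image_size))
    needs_texture = any(fs in ("texture", "all") for fs in cfg.feature_sets)
    blocks = "all" if needs_texture else "morph"
    features = extract_feature_table(dataset, cfg, blocks=blocks)
    fcols = [c for c in features.columns if c.startswith("f")]
    X = features[fcols].to_numpy()
    if blocks == "morph":  # pad so FEATURE_SETS slices still apply
        feature_sets = tuple(fs for fs in cfg.feature_sets if fs == "morph")
    else:
        feature_sets = cfg.feature_sets
    specs = classifier_specs(cfg)
    log.info("evaluating %s on %s (LOO)", list(specs), feature_sets)
    table, comparisons = evaluation_report(
        X, np.asarray(dataset.labels), specs,
        feature_sets=feature_sets, n_boot=cfg.n_boot, seed=cfg.seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(features, outdir / "features.csv",
                            seed=cfg.seed, config=cfg.to_dict())
        table.to_csv(outdir / "report.csv", index=False,
                     float_format="%.6g")
        comp_json = {
            f"{fset}|{dname}": {
                "kw_statistic": c.kw_statistic, "kw_p": c.kw_p,
                "critical_p": c.critical_p,
                "pairwise_p": {f"{a} vs {b}": p
                               for (a, b), p in c.pairwise_p.items()},
                "significant": {f"{a} vs {b}": bool(s)
                                for (a, b), s in c.significant.items()},
            } for (fset, dname), c in comparisons.items()}
        report = {
            "config": cfg.to_dict(),
            "dichotomies": [d.name for d in DICHOTOMIES],
            "results": table.to_dict(orient="records"),
            "comparisons": comp_json,
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=str))
        (outdir / "manifest.json").write_text(
            json.dumps(feature_manifest(), indent=2))
        cfg.to_json(outdir / "config.json")
        log.info("report written to %s", outdir)
    return table, comparisons, features
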