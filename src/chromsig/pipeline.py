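"""End-to-end experiment orchestration.

Three experiments mirror the study design the package targets:

* **type** — leave-one-out cross-validation of the binary SVM separating
  MLL-fusion from wild-type samples;
* **subtype** — the same harness restricted to fusion samples, labelled by
  fusion partner (one-vs-one voting if more than two subtypes are present);
* **de novo** — a single model trained on a full training panel and applied
  to an independent test panel whose features are projected onto the
  training feature index.

Every run is deterministic given a config and seed; reports are plain
dicts serializable to JSON and carry the config hash and seed used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .classifier import SVMConfig, fit_binary, predict, predict_multiclass, train_multiclass
from .data_model import (
    SamplePanel,
    build_feature_index,
    panel_feature_matrix,
    vectorize,
)
from .errors import DegenerateDataError, ValidationError
from .evaluation import (
    ConfusionMatrix,
    CVResult,
    SVMTrainer,
    TreeTrainer,
    accuracy,
    loocv,
    mcc,
)
from .normalization import NormalizationConfig, normalize_panel
from .synthetic import SimulationDesign, PlantedEffect, simulate_panel

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    label_field: str = "mll_status"
    classifier: str = "svm"  # svm | tree
    alpha: float = 0.01
    normalize: bool = True
    log_level: str = "INFO"
    svm: SVMConfig = field(default_factory=SVMConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    simulation: SimulationDesign = field(default_factory=SimulationDesign)

    def __post_init__(self) -> None:
        if self.classifier not in ("svm", "tree"):
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        doc = dict(doc)
        kwargs: dict[str, Any] = {}
        for name, sub_cls in (
            ("svm", SVMConfig),
            ("normalization", NormalizationConfig),
            ("simulation", SimulationDesign),
        ):
            if name in doc:
                sub = dict(doc.pop(name))
                if name == "simulation" and "planted_effects" in sub:
                    sub["planted_effects"] = tuple(
                        PlantedEffect(
                            pair=tuple(e["pair"]),
                            fold_change=float(e["fold_change"]),
                            class_label=str(e["class_label"]),
                        )
                        for e in sub["planted_effects"]
                    )
                if name == "simulation" and "class_sizes" in sub:
                    cs = sub["class_sizes"]
                    if isinstance(cs, dict):
                        sub["class_sizes"] = tuple(sorted(cs.items()))
                    else:
                        sub["class_sizes"] = tuple((str(a), int(b)) for a, b in cs)
                if name == "simulation" and "array_scale_range" in sub:
                    sub["array_scale_range"] = tuple(sub["array_scale_range"])
                _check_keys(sub, sub_cls)
                kwargs[name] = sub_cls(**sub)
        _check_keys(doc, cls)
        kwargs.update(doc)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return enc(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(doc: dict, cls) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")


def _trainer(cfg: PipelineConfig):
    if cfg.classifier == "tree":
        return TreeTrainer()
    return SVMTrainer(cfg.svm)


def _prepare_panel(cfg: PipelineConfig, panel: SamplePanel | None) -> SamplePanel:
    if panel is None:
        design = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        panel, _ = simulate_panel(design)
    if cfg.normalize:
        panel, _ = normalize_panel(panel, cfg.normalization)
    return panel


def _report_header(cfg: PipelineConfig, experiment: str) -> dict[str, Any]:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "experiment": experiment,
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
    }


def run_type_experiment(
    cfg: PipelineConfig, panel: SamplePanel | None = None
) -> dict[str, Any]:
    """LOOCV of the binary fusion-vs-wild-type classifier."""
    panel = _prepare_panel(cfg, panel)
    result = loocv(panel, "mll_status", trainer=_trainer(cfg))
    report = _report_header(cfg, "type")
    report.update(result.to_dict())
    return report


def run_subtype_experiment(
    cfg: PipelineConfig, panel: SamplePanel | None = None
) -> dict[str, Any]:
    """LOOCV over fusion subtypes, restricted to fusion samples."""
    panel = _prepare_panel(cfg, panel)
    fusion = panel.subset(mll_status="fusion")
    subtypes = set(fusion.labels("subtype"))
    if len(subtypes) < 2:
        raise DegenerateDataError(f"need >= 2 fusion subtypes, got {sorted(subtypes)}")
    result = loocv(fusion, "subtype", trainer=_trainer(cfg))
    report = _report_header(cfg, "subtype")
    report.update(result.to_dict())
    report["n_pairwise_models"] = len(subtypes) * (len(subtypes) - 1) // 2
    return report


def run_denovo(
    cfg: PipelineConfig,
    train_panel: SamplePanel,
    test_panel: SamplePanel,
    label_field: str | None = None,
) -> dict[str, Any]:
    """Train once on the full training panel, predict an independent panel.

    Test matrices are projected onto the training feature index; cells the
    test sample lacks are imputed from training feature means.  An empty
    test panel yields an empty report with a warning rather than an error.
    """
    label_field = label_field or cfg.label_field
    overlap = set(train_panel.sample_ids()) & set(test_panel.sample_ids())
    if overlap:
        raise ValidationError(f"train/test sample ids overlap: {sorted(overlap)}")
    report = _report_header(cfg, "denovo")
    if len(test_panel) == 0:
        logger.warning("empty test panel; nothing to predict")
        report.update({"per_sample": [], "confusion": None, "accuracy": None, "mcc": None})
        return report
    if cfg.normalize:
        train_panel, _ = normalize_panel(train_panel, cfg.normalization)
        test_panel, _ = normalize_panel(test_panel, cfg.normalization)
    if train_panel.n_fragments != test_panel.n_fragments:
        raise ValidationError("train and test panels use different fragment maps")

    idx = build_feature_index(train_panel)
    X = panel_feature_matrix(train_panel, idx).to_numpy()
    train_labels = train_panel.labels(label_field)
    classes = sorted(set(train_labels))
    trainer = _trainer(cfg)
    model = trainer.fit(X, train_labels)
    impute = X.mean(axis=0)

    rows = []
    true, pred = [], []
    for s in test_panel:
        vec = vectorize(
            s.matrix, idx, missing_policy="impute_row_mean",
            impute_values=impute, sample_id=s.sample_id,
        )
        lab, val = trainer.predict_one(model, vec.values)
        rows.append(
            {
                "sample_id": s.sample_id,
                "true": s.label(label_field),
                "predicted": lab,
                "decision_value": val,
            }
        )
        true.append(s.label(label_field))
        pred.append(lab)
    cm = ConfusionMatrix.from_predictions(true, pred, labels=classes)
    report["per_sample"] = rows
    report["confusion"] = cm.to_dict()
    report["accuracy"] = accuracy(cm)
    report["mcc"] = mcc(cm) if len(classes) == 2 else None
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
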