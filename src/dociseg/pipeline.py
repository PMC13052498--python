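"""End-to-end orchestration: preprocessing, gate fitting and regional calls,
gated segmentation training, threshold selection, evaluation and ablation.

This module glues the building blocks into the study workflow: every voxel
tensor is min-max normalized to [0, 1]; the pixel gate is fit on training
slides and regional majority voting produces specimen calls, confusion
matrices and patient-level bootstrap CIs; per tumor target, gated slides form
the training set for an SE-UNet whose operating threshold is swept on the
validation split; metrics mirror the Dice (non-empty) / empty penalty /
balanced Dice triple.
"""

from __future__ import annotations

import json
from copy import copy
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gate import PixelGate
from .metrics import MetricsReport, evaluate_split, select_threshold
from .phantom import PhantomConfig, generate_cohort, read_cohort
from .regional import (
    GateConfig,
    SpecimenCall,
    bootstrap_accuracy_ci,
    confusion_and_accuracy,
    gate_specimen,
)
from .segmodel import SegModelConfig
from .trainer import (
    AugmentConfig,
    SegItem,
    SEUNetSegmenter,
    TrainConfig,
    assemble_gated_dataset,
)
from .voxelio import minmax_normalize


def normalize_cohort(specimens):
    """Min-max normalize every specimen's voxel tensor to [0, 1]."""
    out = []
    for spec in specimens:
        new = copy(spec)
        new.voxels = minmax_normalize(spec.voxels)
        out.append(new)
    return out


def split_specimens(specimens) -> dict[str, list]:
    groups = {"train": [], "val": [], "test": []}
    for s in specimens:
        groups.setdefault(s.split, []).append(s)
    return groups


def gate_cohort(
    gate: PixelGate, specimens, gate_config: GateConfig | None = None
) -> dict[str, SpecimenCall]:
    """Regional slide-level call for every specimen."""
    calls = {}
    for spec in specimens:
        maps = gate.predict_proba_maps(spec)
        calls[spec.specimen_id] = gate_specimen(maps, spec.tissue_mask, gate_config)
    return calls


def gate_split_report(
    specimens, calls: dict[str, SpecimenCall], n_reps: int = 2000, seed: int = 0
) -> dict:
    """Confusion matrix, accuracy and patient-level bootstrap CI for one
    split (atypical slides are excluded, as in the gate's evaluation)."""
    evald = [s for s in specimens if s.true_class != "atypical"]
    if not evald:
        return {"n_slides": 0}
    preds = [calls[s.specimen_id].predicted_class for s in evald]
    truths = [s.true_class for s in evald]
    cm, acc = confusion_and_accuracy(preds, truths)
    by_patient: dict[str, list[bool]] = {}
    for s, p, t in zip(evald, preds, truths):
        by_patient.setdefault(s.patient_id, []).append(p == t)
    ci = bootstrap_accuracy_ci(list(by_patient.values()), n_reps=n_reps, seed=seed)
    return {
        "n_slides": len(evald),
        "confusion": cm,
        "accuracy": acc,
        "bootstrap_ci": ci,
    }


def eval_items(specimens, target: str) -> list[SegItem]:
    """Evaluation items for one target model: slides of the target class
    (pathology mask as truth) plus normal slides (empty truth)."""
    items = []
    for s in specimens:
        if s.true_class == target:
            mask = s.tumor_mask.data
        elif s.true_class == "normal":
            mask = np.zeros(s.tumor_mask.shape, dtype=np.uint8)
        else:
            continue
        items.append(
            SegItem(s.specimen_id, s.voxels.data, mask, s.tissue_mask.data)
        )
    return items


def _default_model_config(h: int, w: int, c: int) -> SegModelConfig:
    return SegModelConfig(input=(h, w, c))


def train_target_segmenter(
    splits: dict[str, list],
    gate_calls: dict[str, SpecimenCall],
    target: str,
    model_config_factory=None,
    augment: AugmentConfig | None = None,
    train: TrainConfig | None = None,
    include_atypical_if_gated: bool = False,
    seed: int = 0,
) -> dict:
    """Train one tumor-targeted segmenter on gate-retained slides and report
    threshold-swept metrics on validation and test splits."""
    factory = model_config_factory or _default_model_config
    call_labels = {sid: c.predicted_class for sid, c in gate_calls.items()}
    dataset = assemble_gated_dataset(
        splits["train"], call_labels, target, include_atypical_if_gated
    )
    h, w, c = dataset[0].voxels.shape
    aug = augment or AugmentConfig(output_size=h, seed=seed)
    seg = SEUNetSegmenter(
        model_config=factory(h, w, c),
        augment=aug,
        train=train or TrainConfig(seed=seed),
        random_state=seed,
    )
    X = np.stack([i.voxels for i in dataset])
    y = np.stack([i.tumor_mask for i in dataset])
    tis = np.stack([i.tissue_mask for i in dataset])
    val_items = eval_items(splits["val"], target)
    test_items = eval_items(splits["test"], target)
    Xv = np.stack([i.voxels for i in val_items])
    yv = np.stack([i.tumor_mask for i in val_items])
    seg.fit(X, y, X_val=Xv, y_val=yv, tissue=tis)

    val_probs = seg.predict_proba(Xv)
    op = select_threshold(list(val_probs), [i.tumor_mask for i in val_items])
    seg.set_operating_threshold(op.t_star)
    reports: dict[str, MetricsReport] = {}
    for name, items in (("val", val_items), ("test", test_items)):
        if not items:
            continue
        probs = seg.predict_proba(np.stack([i.voxels for i in items]))
        reports[name] = evaluate_split(
            list(probs),
            [i.tumor_mask for i in items],
            op.t_star,
            [i.tissue_mask for i in items],
        )
    return {
        "segmenter": seg,
        "t_star": op.t_star,
        "operating_point": op,
        "reports": reports,
        "val_items": val_items,
        "test_items": test_items,
        "n_train_slides": len(dataset),
    }


def run_analysis(
    specimens,
    targets: tuple[str, ...] = ("papillary", "follicular"),
    gate_params: dict | None = None,
    gate_config: GateConfig | None = None,
    model_config_factory=None,
    augment: AugmentConfig | None = None,
    train: TrainConfig | None = None,
    include_atypical_if_gated: bool = False,
    n_bootstrap: int = 2000,
    seed: int = 0,
    normalize: bool = True,
) -> dict:
    """Gate fitting + regional calls + per-target segmentation training.

    Returns a dict with the fitted gate, per-split gate reports, per-target
    segmentation results and the normalized specimens keyed by split.
    """
    if normalize:
        specimens = normalize_cohort(specimens)
    splits = split_specimens(specimens)
    gate = PixelGate(random_state=seed, **(gate_params or {}))
    gate.fit(splits["train"])
    calls = gate_cohort(gate, specimens, gate_config)
    gate_reports = {
        name: gate_split_report(group, calls, n_reps=n_bootstrap, seed=seed)
        for name, group in splits.items()
        if group
    }
    seg_results = {}
    for target in targets:
        seg_results[target] = train_target_segmenter(
            splits,
            calls,
            target,
            model_config_factory=model_config_factory,
            augment=augment,
            train=train,
            include_atypical_if_gated=include_atypical_if_gated,
            seed=seed,
        )
    return {
        "gate": gate,
        "gate_calls": calls,
        "gate_reports": gate_reports,
        "segmentation": seg_results,
        "splits": splits,
    }


# ---------------------------------------------------------------------------
# Full pipeline with manifest (CLI entry)


@dataclass
class PipelineConfig:
    mode: str = "phantom"                  # 'phantom' or 'real'
    data_dir: str | None = None            # cohort directory in real mode
    out_dir: str = "run"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    gate_config: GateConfig = field(default_factory=GateConfig)
    targets: tuple[str, ...] = ("papillary", "follicular")
    run_ablation: bool = True
    ablation_top_k: int = 6
    include_atypical_if_gated: bool = False
    encoder_filters: tuple[int, ...] | None = None
    bottleneck_filters: int | None = None
    se_min_channels: int | None = None
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    n_bootstrap: int = 2000
    seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            batch_size=self.batch_size,
            seed=self.seed,
        )


def _report_to_json(result: dict) -> dict:
    out = {"gate": {}, "segmentation": {}}
    for split, rep in result["gate_reports"].items():
        if rep.get("n_slides", 0) == 0:
            continue
        ci = rep["bootstrap_ci"]
        out["gate"][split] = {
            "n_slides": rep["n_slides"],
            "accuracy": rep["accuracy"],
            "confusion": rep["confusion"].tolist(),
            "ci_lower": ci.lower,
            "ci_upper": ci.upper,
        }
    for target, res in result["segmentation"].items():
        out["segmentation"][target] = {
            "t_star": res["t_star"],
            "n_train_slides": res["n_train_slides"],
            **{k: v.to_dict() for k, v in res["reports"].items()},
        }
    return out


def _model_config_factory_from(cfg: PipelineConfig):
    def factory(h, w, c):
        kwargs = {"input": (h, w, c)}
        if cfg.encoder_filters is not None:
            kwargs["encoder_filters"] = tuple(cfg.encoder_filters)
        if cfg.bottleneck_filters is not None:
            kwargs["bottleneck_filters"] = cfg.bottleneck_filters
        if cfg.se_min_channels is not None:
            kwargs["se_min_channels"] = cfg.se_min_channels
        return SegModelConfig(**kwargs)

    return factory


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole workflow and write reports plus a manifest.

    Stages: cohort ingest/generation → normalization → gate fit/calls →
    bootstrap reports → gated segmentation training per target → threshold
    selection and test metrics → channel ablation → reduced-channel retrain.
    """
    from .ablation import channel_importance, retrain_reduced, select_reduced_subset

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mode == "phantom":
        specimens = generate_cohort(config.phantom)
    else:
        if not config.data_dir or not Path(config.data_dir).exists():
            raise FileNotFoundError(
                f"cohort directory {config.data_dir!r} not found"
            )
        specimens = read_cohort(config.data_dir)

    result = run_analysis(
        specimens,
        targets=config.targets,
        gate_config=config.gate_config,
        model_config_factory=_model_config_factory_from(config),
        train=config.train_config(),
        include_atypical_if_gated=config.include_atypical_if_gated,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
    )
    report = {"full": _report_to_json(result)}

    if config.run_ablation:
        importances = {}
        for target, res in result["segmentation"].items():
            importances[target] = channel_importance(
                res["segmenter"].model_,
                res["val_items"],
                res["t_star"],
                seed=config.seed,
            )
        subset = select_reduced_subset(importances, k=config.ablation_top_k)
        reduced = retrain_reduced(
            specimens,
            subset,
            targets=config.targets,
            gate_config=config.gate_config,
            model_config_factory=_model_config_factory_from(config),
            train=config.train_config(),
            include_atypical_if_gated=config.include_atypical_if_gated,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
        )
        report["ablation"] = {
            t: {
                "delta_dice": imp.delta_dice.tolist(),
                "delta_iou": imp.delta_iou.tolist(),
                "baseline_dice": imp.baseline_dice,
                "ranking": imp.ranking.tolist(),
            }
            for t, imp in importances.items()
        }
        report["reduced_subset"] = subset.channels
        report["reduced"] = _report_to_json(reduced)

    manifest = {
        "dociseg_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return {"result": result, "report": report, "out_dir": str(out)}
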