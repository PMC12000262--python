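"""End-to-end orchestration: simulate -> assemble -> train -> evaluate.

A single :class:`RunConfig` drives a reproducible run: one master seed fans
out to per-stage seeds, every artifact (manifest, fold assignments, selection
log, metrics tables, run report) is written under the output directory, and
re-running the same config reproduces the non-training artifacts bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assembly, evaluate, model as model_mod, phantom
from .augment import AugmentParams

_STAGES = ("simulate", "select", "split", "train", "evaluate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Fan one master seed out to a stage seed (counter-based, < 2**31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([master_seed, idx]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Structured configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    # phantom
    n_per_class: int = 100
    image_side: int = 128
    speckle_scale: float = 1.0
    artifact_rate: float = 0.0
    # assembly
    time_limits: list[str] = field(default_factory=lambda: ["B-10m"])
    folds: int = 10
    folds_to_run: list[int] = field(default_factory=lambda: [0])
    input_side: int = 64
    # model / training (desk-scale defaults)
    backbone: str = "small-cnn"
    branch_fc_width: int = 64
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 3e-3
    augment: bool = False
    # evaluation
    washout_delta: float = 0.10
    write_images: bool = True

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# dataset preparation
# ---------------------------------------------------------------------------

def build_case_stack(case: phantom.CaseRecord, time_limit: str, input_side: int,
                     rule_seed: int) -> tuple[np.ndarray, assembly.PhaseSelection]:
    """ROI-crop, resize and pack one case into its (3, S, S, 3) stack
    (intensities scaled to [0, 1])."""
    geo = case.geometry
    selection = assembly.select_phases(phantom.PHASE_IDS, time_limit, rule_seed)
    resized = {}
    for slot in set(selection.slots):
        roi = assembly.extract_roi(case.images[slot], geo.lesion_center,
                                   geo.lesion_diameter, geo.roi_margin_factor)
        resized[slot] = assembly.resize_to_input(roi, input_side) / 255.0
    stack = assembly.pack_stack(selection, resized)
    return stack.data.astype(np.float64), selection


def prepare_dataset(cases: list[phantom.CaseRecord], time_limit: str,
                    input_side: int, seed: int):
    """Stacks, integer labels and per-case selection log for a cohort."""
    xs, ys, log = [], [], []
    for i, case in enumerate(cases):
        rule_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        data, sel = build_case_stack(case, time_limit, input_side, rule_seed)
        xs.append(data)
        ys.append(phantom.CLASS_LABELS.index(case.label))
        log.append({"case_id": case.case_id, "time_limit": time_limit,
                    "slots": "|".join(sel.slots),
                    "excluded": "|".join(sel.excluded), "seed": rule_seed})
    return np.stack(xs), np.array(ys), pd.DataFrame(log)


def prepare_reference_dataset(cases: list[phantom.CaseRecord], input_side: int):
    """B-mode-only pseudo-RGB inputs (the single frame on all three channels)
    for the reference model."""
    xs, ys = [], []
    for case in cases:
        geo = case.geometry
        roi = assembly.extract_roi(case.images["B"], geo.lesion_center,
                                   geo.lesion_diameter, geo.roi_margin_factor)
        img = assembly.resize_to_input(roi, input_side) / 255.0
        xs.append(np.repeat(img[:, :, None], 3, axis=2))
        ys.append(phantom.CLASS_LABELS.index(case.label))
    return np.stack(xs), np.array(ys)


def make_folds(cases: list[phantom.CaseRecord], x: np.ndarray, y: np.ndarray,
               split: assembly.SplitSpec, folds_to_run) -> tuple[list[dict], pd.DataFrame]:
    manifest = pd.DataFrame({"case_id": [c.case_id for c in cases],
                             "label": [c.label for c in cases]})
    assignment = assembly.split_dataset(manifest, split)
    index = {cid: i for i, cid in enumerate(manifest.case_id)}
    fold_data = []
    for fold in folds_to_run:
        sub = assignment[assignment.fold == fold]
        part = {role: np.array([index[cid] for cid in sub[sub.role == role].case_id])
                for role in ("train", "val", "test")}
        fold_data.append({
            "x_train": x[part["train"]], "y_train": y[part["train"]],
            "x_val": x[part["val"]], "y_val": y[part["val"]],
            "x_test": x[part["test"]], "y_test": y[part["test"]],
            "test_case_ids": [cases[i].case_id for i in part["test"]],
        })
    return fold_data, assignment


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_experiment(cases: list[phantom.CaseRecord], time_limit: str, *,
                   input_side: int = 64, branch_fc_width: int = 64,
                   epochs: int = 40, batch_size: int = 32,
                   learning_rate: float = 3e-3, folds: int = 10,
                   folds_to_run=(0,), seed: int = 0,
                   augment_params: AugmentParams | None = None,
                   reference: bool = False) -> dict:
    """Train and evaluate one condition (one time limit, one model arity).

    ``reference=True`` trains the single-input B-mode-only model instead of
    the nine-input model.  Returns per-fold results plus pooled held-out
    predictions, accuracy and confusion matrix.
    """
    if reference:
        x, y = prepare_reference_dataset(cases, input_side)
        selections = pd.DataFrame()
        cfg = model_mod.ModelConfig(n_branches=1, input_side=input_side,
                                    branch_fc_width=branch_fc_width)
    else:
        x, y, selections = prepare_dataset(cases, time_limit, input_side,
                                           stage_seed(seed, "select"))
        cfg = model_mod.ModelConfig(n_branches=3, input_side=input_side,
                                    branch_fc_width=branch_fc_width)
    split = assembly.SplitSpec(folds=folds, seed=stage_seed(seed, "split"))
    fold_data, assignment = make_folds(cases, x, y, split, folds_to_run)
    tc = model_mod.TrainConfig(batch_size=batch_size, epochs=epochs,
                               learning_rate=learning_rate, folds=folds,
                               seed=stage_seed(seed, "train"))
    results = model_mod.train(cfg, fold_data, tc, aug=augment_params)

    rows = []
    for fold, res in zip(fold_data, results):
        preds = res.test_probabilities.argmax(axis=1)
        for cid, t, p, probs in zip(fold["test_case_ids"], res.test_labels,
                                    preds, res.test_probabilities):
            rows.append({"case_id": cid,
                         "truth": phantom.CLASS_LABELS[int(t)],
                         "pred": phantom.CLASS_LABELS[int(p)],
                         "prob0": probs[0], "prob1": probs[1], "prob2": probs[2],
                         "fold": res.fold})
    predictions = pd.DataFrame(rows)
    accuracy = float((predictions.truth == predictions.pred).mean())
    cm = evaluate.confusion_matrix(predictions.truth, predictions.pred)
    return {
        "time_limit": "B" if reference else time_limit,
        "reference": reference,
        "accuracy": accuracy,
        "per_fold_accuracy": [r.test_accuracy for r in results],
        "confusion_matrix": cm,
        "predictions": predictions,
        "assignment": assignment,
        "selections": selections,
        "fold_results": results,
        "n_test": int(len(predictions)),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage of one configured run and write its artifacts."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    cfg.to_yaml(os.path.join(cfg.out_dir, "config.yaml"))

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # simulate
    def _simulate():
        cases = phantom.sample_cohort(
            cfg.n_per_class, stage_seed(cfg.seed, "simulate"),
            image_side=cfg.image_side, speckle_scale=cfg.speckle_scale,
            artifact_rate=cfg.artifact_rate)
        if cfg.write_images:
            phantom.write_cohort(cases, os.path.join(cfg.out_dir, "cohort"))
        return cases
    cases = _stage("simulate", _simulate)
    report["stages"]["simulate"] = {"n_cases": len(cases)}

    aug = AugmentParams() if cfg.augment else None
    summary = {}
    for limit in cfg.time_limits:
        result = _stage(f"train[{limit}]", lambda limit=limit: run_experiment(
            cases, limit, input_side=cfg.input_side,
            branch_fc_width=cfg.branch_fc_width, epochs=cfg.epochs,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            folds=cfg.folds, folds_to_run=cfg.folds_to_run, seed=cfg.seed,
            augment_params=aug))
        tag = limit.replace("-", "_")
        result["predictions"].to_csv(
            os.path.join(cfg.out_dir, f"predictions_{tag}.csv"), index=False)
        result["assignment"].to_csv(
            os.path.join(cfg.out_dir, f"folds_{tag}.csv"), index=False)
        if len(result["selections"]):
            result["selections"].to_csv(
                os.path.join(cfg.out_dir, f"selections_{tag}.csv"), index=False)
        summary[limit] = evaluate.metrics_column(result["predictions"].truth,
                                                 result["predictions"].pred)
        report["stages"][f"train[{limit}]"] = {
            "accuracy": result["accuracy"],
            "per_fold_accuracy": result["per_fold_accuracy"],
            "n_test": result["n_test"],
        }

    def _evaluate():
        table = evaluate.write_metrics_table(
            summary, os.path.join(cfg.out_dir, "summary.csv"))
        wtable = evaluate.washout_table(cases, delta=cfg.washout_delta)
        wtable.to_csv(os.path.join(cfg.out_dir, "washout_table.csv"))
        return table
    _stage("evaluate", _evaluate)

    with open(os.path.join(cfg.out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
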