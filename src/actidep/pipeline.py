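"""Configuration-driven orchestration of the full analysis pipeline.

Stages run in order: ingest (or simulate) -> window -> feature extraction ->
cross-validated model evaluation (scale -> ADASYN -> train -> score inside
each fold) -> significance protocol -> explanation layer. Every stochastic
stage derives its randomness from the single run seed, and a JSON manifest
records the configuration, seed, library versions and per-stage row counts
so a run directory is self-describing.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import AdasynConfig
from .cohort_io import Cohort, read_cohort_dir, ValidationError
from .explain import (
    PermutationShapleyExplainer,
    compare_model_explanations,
    global_importance,
    lime_explain,
)
from .features import FeatureConfig, FeatureMatrix, FeatureScaler, build_feature_matrix
from .model_eval import (
    MODEL_NAMES,
    metric_suite,
    repeated_stratified_cv,
    significance_protocol,
    train_classifier,
)
from .synthetic_cohort import SyntheticCohortConfig

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated run description; exactly one input source.

    ``task`` is ``binary`` (depressed vs not) or ``severity`` (three MADRS
    bands). ``models`` defaults to the full five-model roster with
    ``gradient_boosting`` as the significance baseline.
    """

    task: str = "binary"
    data_dir: Optional[str] = None
    synthetic: Optional[dict] = None
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    adasyn: AdasynConfig = field(default_factory=AdasynConfig)
    models: tuple[str, ...] = MODEL_NAMES
    hyperparams: dict = field(default_factory=dict)
    cv_repeats: int = 3
    cv_folds: int = 10
    alpha: float = 0.05
    baseline_model: str = "gradient_boosting"
    explain_models: tuple[str, ...] = ("gradient_boosting",)
    n_explain_instances: int = 20
    shapley_permutations: int = 50
    background_size: int = 50
    lime_samples: int = 2000
    seed: int = 0
    out_dir: str = "run"

    def validate(self) -> None:
        if self.task not in ("binary", "severity"):
            raise ValidationError(f"unknown task {self.task!r}")
        if (self.data_dir is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one input source required: data_dir XOR synthetic"
            )
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValidationError(f"unknown model(s): {sorted(unknown)}")
        if self.baseline_model not in self.models:
            raise ValidationError("baseline_model must be in models")
        if not set(self.explain_models) <= set(self.models):
            raise ValidationError("explain_models must be a subset of models")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file plus keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    feature = FeatureConfig(**raw.pop("feature", {}))
    adasyn = AdasynConfig(**raw.pop("adasyn", {}))
    for key in ("models", "explain_models"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(feature=feature, adasyn=adasyn, **raw)
    cfg.validate()
    return cfg


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _library_versions() -> dict:
    import scipy
    import sklearn
    import xgboost

    return {
        "actidep": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def _load_or_simulate(config: RunConfig, out: Path) -> Cohort:
    if config.data_dir is not None:
        return read_cohort_dir(config.data_dir)
    from .synthetic_cohort import generate_cohort

    syn = dict(config.synthetic or {})
    syn.setdefault("seed", config.seed)
    return generate_cohort(SyntheticCohortConfig.from_dict(syn))


def extract_stage(cohort: Cohort, config: RunConfig) -> FeatureMatrix:
    fm = build_feature_matrix(cohort, config.feature, task=config.task)
    present = set(fm.labels.tolist())
    expected = {0, 1} if config.task == "binary" else {0, 1, 2}
    missing = expected - present
    if missing:
        names = {0: "normal/control", 1: "mild/condition", 2: "moderate"}
        raise ValidationError(
            "cohort lacks class(es): "
            + ", ".join(f"{m} ({names.get(m, '?')})" for m in sorted(missing))
        )
    return fm


def evaluate_stage(fm: FeatureMatrix, config: RunConfig) -> dict:
    cv = repeated_stratified_cv(
        list(config.models), fm.frame, fm.labels, fm.participant_ids,
        repeats=config.cv_repeats, k=config.cv_folds, seed=config.seed,
        adasyn=config.adasyn, hyperparams=config.hyperparams,
    )
    averaging = "binary" if config.task == "binary" else "weighted"
    metrics = {
        name: {
            "cv_f1_mean": res.mean,
            "cv_f1_sd": res.sd,
            "fold_scores": res.fold_scores.tolist(),
            "pooled": metric_suite(res.pooled_confusion, averaging).to_dict(),
        }
        for name, res in cv.items()
    }
    sig = (
        significance_protocol(cv, baseline=config.baseline_model,
                              alpha=config.alpha).to_records()
        if len(cv) > 1 else []
    )
    return {"cv": cv, "metrics": metrics, "significance": sig}


def explain_stage(fm: FeatureMatrix, config: RunConfig) -> dict:
    """Train each explanation model on the full standardized matrix and
    attribute a seeded subsample of instances."""
    scaler = FeatureScaler().fit(fm.frame)
    Xz = scaler.transform(fm.frame).to_numpy()
    rng = np.random.default_rng(config.seed)
    n_inst = min(config.n_explain_instances, len(Xz))
    inst_idx = rng.choice(len(Xz), size=n_inst, replace=False)
    rankings = {}
    lime_examples = {}
    all_explanations = {}
    for name in config.explain_models:
        model = train_classifier(
            name, Xz, fm.labels, config.hyperparams.get(name),
            seed=config.seed,
        )

        def score_fn(data: np.ndarray) -> np.ndarray:
            return model.predict_proba(np.asarray(data))[:, 1]

        explainer = PermutationShapleyExplainer(
            score_fn, n_permutations=config.shapley_permutations,
            seed=config.seed,
        ).fit(
            np.asarray(Xz)[
                rng.choice(len(Xz),
                           size=min(config.background_size, len(Xz)),
                           replace=False)
            ],
            feature_names=fm.feature_names,
        )
        explanations = [
            explainer.explain(Xz[i], instance_id=str(fm.participant_ids[i]))
            for i in inst_idx
        ]
        all_explanations[name] = explanations
        rankings[name] = global_importance(explanations, model_tag=name)
        lime_examples[name] = lime_explain(
            score_fn, Xz[inst_idx[0]], Xz, feature_names=fm.feature_names,
            n_samples=config.lime_samples, seed=config.seed,
            instance_id=str(fm.participant_ids[inst_idx[0]]),
        )
    comparison = None
    if len(rankings) > 1:
        tags = list(rankings)
        comparison = compare_model_explanations(rankings[tags[0]],
                                                rankings[tags[1]])
    return {"rankings": rankings, "lime": lime_examples,
            "explanations": all_explanations, "comparison": comparison}


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write the run directory; returns its path."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "config": {k: str(v) for k, v in sorted(vars(config).items())},
        "seed": config.seed,
        "task": config.task,
        "versions": _library_versions(),
        "stages": {},
    }

    def fail(stage: str, err: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise err

    try:
        cohort = _load_or_simulate(config, out)
        manifest["stages"]["ingest"] = {"participants": len(cohort)}
    except Exception as e:  # noqa: BLE001
        fail("ingest", e)
    try:
        fm = extract_stage(cohort, config)
        manifest["stages"]["features"] = {
            "rows": len(fm), "dropped": len(fm.drop_log),
        }
        fm.frame.assign(
            label=fm.labels, participant_id=fm.participant_ids
        ).to_csv(out / "features.csv", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_scaler = FeatureScaler().fit(fm.frame)
        (out / "scaler.json").write_text(
            json.dumps(full_scaler.params_.to_dict(), indent=2)
        )
        with open(out / "drop_log.jsonl", "w") as fh:
            for entry in fm.drop_log:
                fh.write(json.dumps(entry) + "\n")
    except Exception as e:  # noqa: BLE001
        fail("features", e)
    try:
        ev = evaluate_stage(fm, config)
        manifest["stages"]["evaluate"] = {
            "folds": config.cv_repeats * config.cv_folds,
            "models": list(config.models),
        }
        (out / "metrics.json").write_text(json.dumps(ev["metrics"], indent=2))
        (out / "significance.json").write_text(
            json.dumps(ev["significance"], indent=2)
        )
        pd.DataFrame(
            {name: res.fold_scores for name, res in ev["cv"].items()}
        ).to_csv(out / "fold_scores.csv", index=False)
    except Exception as e:  # noqa: BLE001
        fail("evaluate", e)
    try:
        ex = explain_stage(fm, config)
        manifest["stages"]["explain"] = {
            "models": list(config.explain_models),
            "instances": min(config.n_explain_instances, len(fm)),
        }
        for name, ranking in ex["rankings"].items():
            ranking.to_frame().to_csv(
                out / f"importance_{name}.csv", index=False
            )
            (out / f"shapley_{name}.json").write_text(json.dumps(
                [e.to_dict() for e in ex["explanations"][name]], indent=2
            ))
        (out / "lime.json").write_text(
            json.dumps({n: e.to_dict() for n, e in ex["lime"].items()},
                       indent=2)
        )
        if ex["comparison"] is not None:
            (out / "explanation_comparison.json").write_text(
                json.dumps(ex["comparison"], indent=2)
            )
    except Exception as e:  # noqa: BLE001
        fail("explain", e)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
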