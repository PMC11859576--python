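"""End-to-end pipeline: simulate/load → resample → select features →
GA-optimized stacking → evaluate on a held-out split.

Every stage seed is derived deterministically from the single global seed,
so a rerun with the same configuration reproduces the same report.  Stage
outputs (resampled data, feature scores, chromosome, metrics) are plain
CSV/JSON so any stage can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from imbga.core_data import Dataset, compute_ur, minmax_normalize, read_dataset, write_dataset
from imbga.feature_selection import rank_features, wrapper_select
from imbga.ga_ensemble import (
    GAConfig,
    StackFitness,
    default_pool,
    fit_stack,
    ga_optimize,
    predict,
)
from imbga.metrics import EvalReport, classification_report
from imbga.sampling import AmomConfig, amom_dums
from imbga.synthetic import ScenarioConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``scenario`` (synthetic generation) or ``input_path`` (CSV/TSV)
    must be provided.  Per-stage seeds are spawned from ``rng_seed``.
    """

    scenario: ScenarioConfig | None = None
    input_path: str | None = None
    label_column: str = "label"
    test_fraction: float = 0.3
    sampler: AmomConfig = field(default_factory=AmomConfig)
    fs_variant: str = "improved"
    fs_max_dim: int | None = None
    fs_folds: int = 5
    fs_classifier: str = "adaboost"
    fs_mode: str = "rank"  # "rank" (filter only, k = fs_max_dim) or "wrapper"
    ga: GAConfig = field(default_factory=GAConfig)
    stack_folds: int = 5
    rng_seed: int = 0
    report_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("scenario"):
            d["scenario"] = ScenarioConfig(**d["scenario"])
        if d.get("sampler"):
            d["sampler"] = AmomConfig(**d["sampler"])
        if d.get("ga"):
            d["ga"] = GAConfig(**d["ga"])
        return cls(**d)


def stage_seeds(global_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2^31 derived from one seed."""
    return [int(s) for s in np.random.SeedSequence(global_seed).generate_state(n) % (2**31)]


def single_svm_baseline(train: Dataset, test: Dataset, rng_seed: int = 0) -> EvalReport:
    """RBF-SVM trained on the raw (unsampled, all-features) training data —
    the single-model reference the stacked pipeline is compared against."""
    svm = SVC(kernel="rbf", probability=True, random_state=rng_seed)
    svm.fit(train.X, train.y)
    score0 = svm.predict_proba(test.X)[:, list(svm.classes_).index(0)]
    return classification_report(test.y, score0, positive_label=0)


def benchmark_against_svm(
    scenario: ScenarioConfig, rng_seed: int, **config_overrides
) -> dict:
    """Run the full pipeline on one scenario draw and evaluate a raw-data
    RBF-SVM on the identical train/test split.

    Returns {"stack": EvalReport, "svm": EvalReport, "details": dict}.  The
    SVM sees the normalized but unsampled, unselected training data — the
    single-model reference the stacked pipeline is compared against.
    """
    config = PipelineConfig(scenario=scenario, rng_seed=rng_seed, **config_overrides)
    report, details = run_pipeline(config, return_details=True)

    seeds = stage_seeds(rng_seed)
    data = generate(dataclasses.replace(scenario, rng_seed=seeds[0]))
    X_tr, X_te, y_tr, y_te = train_test_split(
        data.X,
        data.y,
        test_size=config.test_fraction,
        stratify=data.y,
        random_state=seeds[1],
    )
    train = Dataset(X_tr, y_tr, list(data.feature_names))
    test = Dataset(X_te, y_te, list(data.feature_names))
    train, params = minmax_normalize(train)
    test = Dataset(params.transform(test.X), test.y, list(test.feature_names))
    baseline = single_svm_baseline(train, test, seeds[5])
    return {"stack": report, "svm": baseline, "details": details}


def run_pipeline(config: PipelineConfig, return_details: bool = False):
    """Execute the full pipeline; returns the held-out :class:`EvalReport`
    (and, with ``return_details=True``, a dict of stage artifacts)."""
    seeds = stage_seeds(config.rng_seed)
    details: dict = {"seed": config.rng_seed, "stage_seeds": seeds}

    # ---- stage 0: data ----------------------------------------------------
    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, rng_seed=seeds[0])
        data = generate(scenario)
        details["scenario"] = scenario.to_dict()
    elif config.input_path:
        data = read_dataset(config.input_path, label_column=config.label_column)
        details["input_path"] = str(config.input_path)
    else:
        raise ValueError("pipeline needs either a scenario or an input_path")
    details["ur_input"] = compute_ur(data)

    X_tr, X_te, y_tr, y_te = train_test_split(
        data.X,
        data.y,
        test_size=config.test_fraction,
        stratify=data.y,
        random_state=seeds[1],
    )
    train = Dataset(X_tr, y_tr, list(data.feature_names))
    test = Dataset(X_te, y_te, list(data.feature_names))

    train, norm_params = minmax_normalize(train)
    test = Dataset(norm_params.transform(test.X), test.y, list(test.feature_names))

    # ---- stage 1: hybrid resampling ---------------------------------------
    sampler = dataclasses.replace(config.sampler, rng_seed=seeds[2])
    sampled = amom_dums(train, sampler)
    details["sampling"] = {
        "counts_before": train.class_counts(),
        "counts_after": sampled.dataset.class_counts(),
        "ur_before": compute_ur(train),
        "ur_after": compute_ur(sampled.dataset),
        "n_synthetic": int(sampled.synthetic_mask.sum()),
        "n_deleted": len(sampled.deleted_indices),
        "iterations": sampled.iterations,
    }
    balanced = sampled.dataset

    # ---- stage 2: feature selection ---------------------------------------
    if config.fs_mode == "wrapper":
        wres = wrapper_select(
            balanced,
            classifier_spec=config.fs_classifier,
            max_dim=config.fs_max_dim,
            cv_folds=config.fs_folds,
            rng_seed=seeds[3],
            variant=config.fs_variant,
        )
        selected = wres.selected_features
        details["selection"] = {
            "mode": "wrapper",
            "best_dimension": wres.best_dimension,
            "auc_by_dimension": wres.auc_by_dimension,
            "baseline_auc_no_fs": wres.baseline_auc_no_fs,
            "selected_features": selected,
        }
    else:
        scores = rank_features(balanced, variant=config.fs_variant)
        k = config.fs_max_dim or max(1, balanced.n_features // 2)
        selected = [s.feature_name for s in scores[:k]]
        details["selection"] = {
            "mode": "rank",
            "k": k,
            "selected_features": selected,
            "scores": [dataclasses.asdict(s) for s in scores],
        }
    cols = [balanced.feature_names.index(f) for f in selected]
    train_sel = Dataset(
        balanced.X[:, cols], balanced.y, selected, balanced.provenance, balanced.groups
    )
    test_sel = Dataset(test.X[:, cols], test.y, selected)

    # ---- stage 3: GA-optimized stacking ------------------------------------
    pool = default_pool()
    ga = dataclasses.replace(config.ga, rng_seed=seeds[4])
    fitness = StackFitness(train_sel, pool, config.stack_folds, seeds[4], ga.fitness_metric)
    best_chrom, history = ga_optimize(train_sel, pool, ga, config.stack_folds, fitness)
    model = fit_stack(train_sel, best_chrom, pool, config.stack_folds, seeds[4])
    details["ga"] = {
        "chromosome": best_chrom.bits.tolist(),
        "selected_members": model.member_names,
        "best_fitness": history["best_ever"][-1],
        "history_best": history["best"],
        "history_mean": history["mean"],
        "n_evaluated": history["n_evaluated"],
    }

    # ---- stage 4: held-out evaluation --------------------------------------
    score0 = predict(model, test_sel.X)
    report = classification_report(test_sel.y, score0, positive_label=0)
    details["evaluation"] = report.to_dict()

    if config.report_dir:
        outdir = Path(config.report_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(balanced, outdir / "sampled.csv")
        serializable = {k: v for k, v in details.items()}
        (outdir / "report.json").write_text(json.dumps(serializable, indent=2, default=str))
        logger.info("pipeline report written to %s", outdir / "report.json")

    if return_details:
        return report, details
    return report
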