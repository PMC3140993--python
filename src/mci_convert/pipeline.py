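"""End-to-end study orchestration.

Simulate (or load) a cohort, select features per modality on the NC/AD
training groups, train RBF-SVM classifiers for each requested modality
combination, predict decision values for the MCI test groups, evaluate,
and analyse decision values by conversion time. Every stochastic stage
derives its seed from the single pipeline seed, so a (config, seed)
pair reproduces the whole run bit-for-bit. MCI subjects are never
touched by scaling, ranking, selection or hyperparameter search.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classification import (
    MetricsReport,
    SvmConfig,
    evaluate,
    predict_cohort,
    records_to_frame,
    train_svm,
)
from .conversion import compare_conversion_groups, summarize_by_month
from .feature_selection import apply_frequency_threshold, nm_dual_filter, wrapper_select
from .stats import bonferroni, two_sample_t
from .synthetic_cohort import Cohort, CohortConfig, generate_cohort, read_cohort, write_cohort

__all__ = ["MODALITIES", "DEFAULT_COMBOS", "SelectionParams", "PipelineConfig", "run_pipeline"]

log = logging.getLogger("mci_convert")

MODALITIES = ("NM", "CSF", "MRI")
# The seven non-empty modality combinations, strongest-first ordering.
DEFAULT_COMBOS = (
    ("NM", "CSF", "MRI"),
    ("NM", "CSF"),
    ("NM", "MRI"),
    ("NM",),
    ("MRI", "CSF"),
    ("MRI",),
    ("CSF",),
)


@dataclass
class SelectionParams:
    repeats: int = 20
    folds: int = 10
    frequency_threshold: float = 0.50
    relevance_threshold: float = 0.3
    auc_threshold: float = 0.95
    max_subset_size: int = 30
    scheme: str = "MID"


@dataclass
class PipelineConfig:
    """Source cohort, requested modality combinations and stage settings."""

    cohort: CohortConfig | str | Cohort = field(default_factory=CohortConfig)
    combos: tuple = DEFAULT_COMBOS
    selection: SelectionParams = field(default_factory=SelectionParams)
    svm: SvmConfig = field(default_factory=SvmConfig)
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.combos:
            raise ValueError("at least one modality combination is required")
        for combo in self.combos:
            if not combo or any(m not in MODALITIES for m in combo):
                raise ValueError(f"invalid modality combination {combo!r}")


def _child_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def _select_modality(modality, cohort, train_X, train_y, params, seed):
    """Run the modality-appropriate selection procedure; returns
    (selected feature names, serialisable detail dict)."""
    feats = cohort.modality_features(modality)
    X = train_X.loc[:, feats]
    if modality == "NM":
        result = nm_dual_filter(
            X,
            train_y,
            rel_threshold=params.relevance_threshold,
            auc_threshold=params.auc_threshold,
            repeats=params.repeats,
            folds=params.folds,
            seed=seed,
        )
        return result.selected, result.to_dict()
    result = wrapper_select(
        X,
        train_y,
        repeats=params.repeats,
        folds=params.folds,
        max_subset_size=min(params.max_subset_size, len(feats)),
        scheme=params.scheme,
        seed=seed,
    )
    chosen = apply_frequency_threshold(result, params.frequency_threshold)
    detail = result.to_dict()
    detail["selected"] = chosen
    detail["frequency_threshold"] = params.frequency_threshold
    return chosen, detail


def _feature_stats_table(cohort, features, m):
    """Tables 4/5/7 analogue: per selected feature, NC-vs-AD and
    MCInc-vs-MCIc t-tests with Bonferroni correction over m features."""
    rows = []
    df = cohort.data
    for name in features:
        by = {g: df.loc[df["group"] == g, name].to_numpy() for g in ("NC", "AD", "MCInc", "MCIc")}
        t_train = two_sample_t(by["NC"], by["AD"])
        t_test = two_sample_t(by["MCInc"], by["MCIc"])
        rows.append(
            {
                "feature": name,
                "nc_vs_ad_p": t_train.p_value,
                "nc_vs_ad_p_corr": bonferroni(t_train.p_value, m),
                "mcinc_vs_mcic_p": t_test.p_value,
                "mcinc_vs_mcic_p_corr": bonferroni(t_test.p_value, m),
            }
        )
    return rows


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute every stage and return the JSON-serialisable report."""
    config = config or PipelineConfig()
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    cohort_seed, mri_seed, csf_seed, nm_seed, svm_seed = _child_seeds(config.seed, 5)

    with _stage("cohort"):
        if isinstance(config.cohort, Cohort):
            cohort = config.cohort
        elif isinstance(config.cohort, (str, Path)):
            cohort = read_cohort(config.cohort)
        else:
            cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
            cohort = generate_cohort(cohort_cfg)
        if out_dir:
            write_cohort(cohort, out_dir / "cohort.csv")

    train = cohort.subset(["NC", "AD"])
    train_X = train.data
    train_y = train.labels()

    modality_seeds = {"MRI": mri_seed, "CSF": csf_seed, "NM": nm_seed}
    needed = sorted({m for combo in config.combos for m in combo})
    selected = {}
    selection_detail = {}
    for modality in needed:
        with _stage(f"select[{modality}]"):
            chosen, detail = _select_modality(
                modality, cohort, train_X, train_y, config.selection, modality_seeds[modality]
            )
            selected[modality] = chosen
            selection_detail[modality] = detail
            log.info("selected %s features for %s: %s", len(chosen), modality, chosen)
            if out_dir:
                with open(out_dir / f"selection_{modality.lower()}.json", "w") as fh:
                    json.dump(_jsonify(detail), fh, indent=1)

    stats_tables = {
        m: _feature_stats_table(cohort, selected[m], max(len(selected[m]), 1)) for m in needed
    }

    combo_reports = {}
    for i, combo in enumerate(config.combos):
        key = "+".join(combo)
        with _stage(f"classify[{key}]"):
            features = [f for m in combo for f in selected[m]]
            if not features:
                log.warning("no features selected for combination %s; skipping", key)
                combo_reports[key] = {"features": [], "error": "no features selected"}
                continue
            svm_cfg = dataclasses.replace(config.svm, seed=(svm_seed + i) % 2**31)
            model = train_svm(train_X.loc[:, features], train_y, svm_cfg)
            records = predict_cohort(model, cohort)
            metrics = evaluate(records)
            summary = summarize_by_month(records)
            early, late = summary.group_values()
            if early.size >= 2 and late.size >= 2:
                conv_test = compare_conversion_groups(summary).to_dict()
            else:
                conv_test = None
            combo_reports[key] = {
                "features": features,
                "C": model.C,
                "gamma": model.gamma,
                "train_cv_auc": model.cv_auc,
                "metrics": metrics.to_dict(),
                "conversion": summary.to_dict(),
                "conversion_test": conv_test,
            }
            if out_dir:
                records_to_frame(records).to_csv(
                    out_dir / f"predictions_{key.replace('+', '_')}.csv", index=False
                )

    report = {
        "seed": config.seed,
        "group_sizes": {g: int((cohort.data["group"] == g).sum()) for g in ("NC", "AD", "MCInc", "MCIc")},
        "selection": {m: selected[m] for m in needed},
        "selection_detail": selection_detail,
        "stats_tables": stats_tables,
        "combos": combo_reports,
    }
    report = _jsonify(report)
    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report
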