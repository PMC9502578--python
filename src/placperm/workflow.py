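"""End-to-end orchestration: filter → normalize → select → fit → applicability domain.

:func:`run_train` executes the full training pipeline on a descriptor table
with observed CI and writes every artifact (filter report, normalization
parameters, selection trace, model, AD model, evaluation reports) as JSON
so a run is fully reproducible from its config and seed.  :func:`run_predict`
and :func:`run_evaluate` compose the module operations for new tables; the
evaluated table's CI is only ever read inside :func:`run_evaluate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .domain import ADModel, TreeConfig, apply_ad, derive_ad
from .metrics import EvaluationReport, evaluate, mae, pearson_r
from .models import FittedModel, ModelSpec, fit, loocv, predict, save_model
from .preprocess import (
    FilterConfig,
    FilterReport,
    NormalizationParams,
    apply_normalizer,
    fit_normalizer,
    remove_useless_features,
)
from .selection import SelectionTrace, sequential_forward_select
from .tables import DescriptorTable, PredictionRecord

__all__ = ["RunConfig", "TrainingArtifacts", "run_train", "run_predict", "run_evaluate", "split_table"]


@dataclass
class RunConfig:
    model: ModelSpec
    filters: FilterConfig = field(default_factory=FilterConfig)
    selection_threshold: float = 0.01
    selection_mode: str = "absolute"
    max_features: int | None = None
    ad_threshold: float = 0.01
    tree: TreeConfig = field(default_factory=TreeConfig)
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.selection_threshold <= 0 or self.ad_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class TrainingArtifacts:
    filter_report: FilterReport
    normalization: NormalizationParams
    trace: SelectionTrace
    model: FittedModel
    ad: ADModel
    loocv_predictions: np.ndarray
    eval_fit: EvaluationReport
    eval_loocv: dict
    eval_fit_in_ad: dict
    eval_loocv_in_ad: dict


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_train(table: DescriptorTable, config: RunConfig) -> TrainingArtifacts:
    """Train the full pipeline on ``table`` (raw descriptor values with CI).

    Stages run in order: prune useless features, z-score on the training
    table, sequential forward selection by LOOCV r, final fit, AD rule
    derivation from the final model's LOOCV errors.  If
    ``config.output_dir`` is set, six JSON artifacts are written there.
    """
    if table.ci is None:
        raise ValueError("training requires target column (CI)")

    try:
        filtered, report = remove_useless_features(table, config.filters)
    except ValueError as e:
        raise RuntimeError(f"stage 'filter' failed: {e}") from e

    try:
        params = fit_normalizer(filtered)
        normalized = apply_normalizer(filtered, params)
    except ValueError as e:
        raise RuntimeError(f"stage 'normalize' failed: {e}") from e

    try:
        trace = sequential_forward_select(
            normalized,
            config.model,
            threshold=config.selection_threshold,
            max_features=config.max_features,
            mode=config.selection_mode,  # type: ignore[arg-type]
        )
    except Exception as e:
        raise RuntimeError(f"stage 'select' failed: {e}") from e
    selected = trace.selected

    try:
        model = fit(normalized, selected, config.model, normalization=params)
        loocv_preds = loocv(normalized, selected, config.model)
    except Exception as e:
        raise RuntimeError(f"stage 'fit' failed: {e}") from e

    try:
        ad = derive_ad(
            normalized,
            selected,
            loocv_preds,
            threshold=config.ad_threshold,
            tree_config=config.tree,
        )
        ad.normalization = params.to_dict()
    except Exception as e:
        raise RuntimeError(f"stage 'ad' failed: {e}") from e

    eval_fit = evaluate(model, normalized, against="ci")
    eval_loocv = {
        "pearson_r": pearson_r(normalized.ci, loocv_preds),
        "mae": mae(normalized.ci, loocv_preds),
        "n": normalized.n_chemicals,
    }
    in_ad, _, _ = apply_ad(ad, normalized)
    if in_ad.sum() >= 3 and np.ptp(normalized.ci[in_ad]) > 0:
        fit_preds = predict(model, normalized)
        eval_fit_in_ad = {
            "pearson_r": pearson_r(normalized.ci[in_ad], fit_preds[in_ad]),
            "mae": mae(normalized.ci[in_ad], fit_preds[in_ad]),
            "n": int(in_ad.sum()),
        }
        eval_loocv_in_ad = {
            "pearson_r": pearson_r(normalized.ci[in_ad], loocv_preds[in_ad]),
            "mae": mae(normalized.ci[in_ad], loocv_preds[in_ad]),
            "n": int(in_ad.sum()),
        }
    else:  # degenerate within-AD set
        eval_fit_in_ad = eval_loocv_in_ad = {"pearson_r": None, "mae": None, "n": int(in_ad.sum())}

    artifacts = TrainingArtifacts(
        filter_report=report,
        normalization=params,
        trace=trace,
        model=model,
        ad=ad,
        loocv_predictions=loocv_preds,
        eval_fit=eval_fit,
        eval_loocv=eval_loocv,
        eval_fit_in_ad=eval_fit_in_ad,
        eval_loocv_in_ad=eval_loocv_in_ad,
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _json_dump(report.to_dict(), out / "filter_report.json")
        _json_dump(params.to_dict(), out / "normalization.json")
        _json_dump(trace.to_dict(), out / "selection_trace.json")
        save_model(model, out / "model.json")
        ad.save(out / "ad_model.json")
        _json_dump(
            {
                "fit": eval_fit.to_dict(),
                "loocv": eval_loocv,
                "fit_in_ad": eval_fit_in_ad,
                "loocv_in_ad": eval_loocv_in_ad,
                "loocv_predictions": {
                    cid: float(p)
                    for cid, p in zip(normalized.chemical_ids, loocv_preds)
                },
            },
            out / "evaluation.json",
        )
    return artifacts


def run_predict(
    model: FittedModel,
    table: DescriptorTable,
    ad: ADModel | None = None,
    auto_normalize: bool = True,
) -> list[PredictionRecord]:
    """Predict CI for a new table and (optionally) flag AD membership.

    Only descriptor values are read from ``table``; any observed CI it
    carries is ignored here.
    """
    work = table
    if auto_normalize and not table.normalized:
        if model.normalization is None:
            raise ValueError("model stores no normalization parameters")
        covered = [f for f in table.feature_names if f in model.normalization.feature_names]
        work = apply_normalizer(table.select_features(covered), model.normalization)
    preds = predict(model, work)
    if ad is not None:
        in_ad, matched, _ = apply_ad(ad, work)
        return [
            PredictionRecord(cid, float(p), bool(f), list(m))
            for cid, p, f, m in zip(table.chemical_ids, preds, in_ad, matched)
        ]
    return [
        PredictionRecord(cid, float(p)) for cid, p in zip(table.chemical_ids, preds)
    ]


def run_evaluate(
    records: list[PredictionRecord],
    table: DescriptorTable,
    against: str = "ci",
) -> dict:
    """Score prediction records against a target column, overall and within-AD."""
    observed = getattr(table, against)
    if observed is None:
        raise ValueError(f"table has no {against} column")
    by_id = dict(zip(table.chemical_ids, observed))
    obs = np.array([by_id[r.chemical_id] for r in records])
    preds = np.array([r.predicted_ci for r in records])
    out = {
        "all": {
            "pearson_r": pearson_r(obs, preds),
            "mae": mae(obs, preds),
            "n": len(records),
        }
    }
    assessed = [r.in_ad != "unassessed" for r in records]
    if any(assessed):
        mask = np.array([r.in_ad is True for r in records])
        if mask.sum() >= 3 and np.ptp(obs[mask]) > 0:
            out["in_ad"] = {
                "pearson_r": pearson_r(obs[mask], preds[mask]),
                "mae": mae(obs[mask], preds[mask]),
                "n": int(mask.sum()),
            }
        else:
            out["in_ad"] = {"pearson_r": None, "mae": None, "n": int(mask.sum())}
    return out


def split_table(
    table: DescriptorTable, n_test: int, seed: int
) -> tuple[DescriptorTable, DescriptorTable]:
    """Random train/test split by chemicals (the split is the user's choice)."""
    n = table.n_chemicals
    if not 0 < n_test < n:
        raise ValueError("n_test must be between 1 and n−1")
    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True

    def subset(mask: np.ndarray) -> DescriptorTable:
        rows = np.flatnonzero(mask)
        return replace(
            table,
            chemical_ids=[table.chemical_ids[i] for i in rows],
            values=table.values[mask],
            ci=table.ci[mask] if table.ci is not None else None,
            ci_min=table.ci_min[mask] if table.ci_min is not None else None,
            ci_variation=(
                table.ci_variation[mask] if table.ci_variation is not None else None
            ),
            names=[table.names[i] for i in rows] if table.names else None,
            smiles=[table.smiles[i] for i in rows] if table.smiles else None,
        )

    return subset(~test_mask), subset(test_mask)
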