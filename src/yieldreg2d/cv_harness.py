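"""Leave-one-year-out experiment orchestration.

For each fold of a multi-year field dataset and each requested method
(Hyper3DNetReg with N = 5/3/1, and the MLR baseline) the harness fits the
normalization on the training years only, extracts and splits patches,
trains, generates the predicted map on the held-out year, computes the map
metrics and tabulates everything as one tidy results table. No test-year
value ever reaches normalization or training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import compare_maps
from .hyper3dnetreg import ModelConfig, build_model
from .map_generation import predict_field
from .patch_sampling import (SplitPlan, build_loyo_splits, extract_patches,
                             split_train_val)
from .raster_core import CHANNELS, FieldYear, fit_minmax
from .training import TrainConfig, fit_mlr, predict_mlr, train

__all__ = ["run_loyo", "representativeness_report", "METHODS"]

#: Method labels understood by :func:`run_loyo`.
METHODS = ("Hyper3DNetReg-N5", "Hyper3DNetReg-N3", "Hyper3DNetReg-N1", "MLR")

_METRIC_COLS = ("RMSE", "RMedSE", "r", "SSIM3*", "SSIM11*")


def _mlr_cells(fys: list[FieldYear], params) -> tuple[np.ndarray, np.ndarray]:
    from .raster_core import apply_minmax

    X, y = [], []
    for fy in fys:
        cov = apply_minmax(fy.covariates, params)
        X.append(cov[fy.mask])
        y.append(fy.yield_map[fy.mask])
    return np.concatenate(X), np.concatenate(y)


def _predict_mlr_map(coef, fy: FieldYear, params) -> np.ndarray:
    from .raster_core import apply_minmax

    cov = apply_minmax(fy.covariates, params)
    P = np.full(fy.shape, np.nan)
    P[fy.mask] = predict_mlr(coef, cov[fy.mask])
    return P


def run_loyo(dataset: list[FieldYear],
             methods: tuple[str, ...] = METHODS,
             train_cfg: TrainConfig | None = None,
             stride: int = 2,
             min_valid_fraction: float = 1.0,
             val_fraction: float = 0.1,
             seed: int = 0,
             model_seed: int = 0,
             model_kwargs: dict | None = None,
             return_maps: bool = False):
    """Run the full leave-one-year-out experiment on one field.

    Returns a tidy DataFrame with one row per (fold, method) carrying RMSE,
    RMedSE, r, SSIM3* and SSIM11* on the held-out year. A fold/method whose
    training fails (e.g. no valid patches) is recorded as a failure row and
    the run continues. ``model_kwargs`` forwards extra ModelConfig fields
    (e.g. reduced layer widths for quick experiments); with
    ``return_maps=True`` also returns a dict
    ``(fold_label, method) -> predicted map``.
    """
    train_cfg = train_cfg or TrainConfig()
    plan: SplitPlan = build_loyo_splits(dataset, val_fraction=val_fraction)
    by_year = {fy.year: fy for fy in dataset}
    rows, maps = [], {}

    for label, (train_years, test_year) in zip(plan.labels, plan.folds):
        train_fys = [by_year[y] for y in train_years]
        test_fy = by_year[test_year]
        params = fit_minmax(train_fys, fitted_on=f"fold {label}")

        for method in methods:
            row = {"field": plan.field_id, "fold": label,
                   "train_years": ",".join(map(str, train_years)),
                   "test_year": test_year, "method": method}
            try:
                if method == "MLR":
                    X, y = _mlr_cells(train_fys, params)
                    coef = fit_mlr(X, y)
                    P = _predict_mlr_map(coef, test_fy, params)
                else:
                    N = int(method.rsplit("N", 1)[1])
                    samples = []
                    for fy in train_fys:
                        samples.extend(extract_patches(
                            fy, N=N, stride=stride,
                            min_valid_fraction=min_valid_fraction,
                            params=params))
                    tr, va = split_train_val(samples, val_fraction, seed=seed)
                    model = build_model(ModelConfig(N=N, seed=model_seed,
                                                    **(model_kwargs or {})))
                    model, _ = train(model, tr, va, train_cfg)
                    P = predict_field(model, test_fy, params)
                cmp_ = compare_maps(test_fy.yield_map, P, test_fy.mask)
                row.update({k: cmp_.metrics[k] for k in _METRIC_COLS})
                row["status"] = "ok"
                if return_maps:
                    maps[(label, method)] = P
            except (ValueError, np.linalg.LinAlgError) as exc:
                row.update({k: np.nan for k in _METRIC_COLS})
                row["status"] = f"failed: {exc}"
            rows.append(row)

    table = pd.DataFrame(rows)
    return (table, maps) if return_maps else table


def representativeness_report(dataset: list[FieldYear],
                              fold: tuple[tuple[int, ...], int],
                              flag_threshold: float = 0.05) -> pd.DataFrame:
    """Train-vs-test covariate range overlap for one fold.

    For every covariate channel, reports the training min/max, test min/max
    and the fraction of test field cells whose value falls outside the
    training range; channels whose fraction exceeds ``flag_threshold`` are
    flagged. A flagged precipitation channel reproduces the classic failure
    mode: a test year wetter or drier than every training year, on which
    models trained with in-range precipitation cannot generalize.
    """
    train_years, test_year = fold
    by_year = {fy.year: fy for fy in dataset}
    train_fys = [by_year[y] for y in train_years]
    test_fy = by_year[test_year]
    params = fit_minmax(train_fys, fitted_on=f"test={test_year}")

    rows = []
    test_vals = test_fy.covariates[test_fy.mask]
    for c, (name, unit) in enumerate(CHANNELS[:test_fy.n_channels]):
        v = test_vals[:, c]
        v = v[np.isfinite(v)]
        outside = float(np.mean((v < params.mins[c]) | (v > params.maxs[c]))) \
            if v.size else np.nan
        rows.append({
            "channel": name, "unit": unit,
            "train_min": params.mins[c], "train_max": params.maxs[c],
            "test_min": v.min() if v.size else np.nan,
            "test_max": v.max() if v.size else np.nan,
            "frac_outside": outside,
            "flagged": bool(outside > flag_threshold),
        })
    return pd.DataFrame(rows)
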