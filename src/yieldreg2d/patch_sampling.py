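"""Training-patch extraction, train/validation splitting and
leave-one-year-out fold construction.

Training patches are W x W covariate windows (W = 5 by default) with an
N x N centered yield target. Extraction uses a stride of 2, which caps the
overlap of adjacent same-row windows at 15 shared pixels — within the
19-pixel overlap budget that keeps neighboring training samples from being
near-duplicates while still harvesting enough samples from a single field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import (CovariatePatch, FieldYear, NormalizationParams,
                          YieldPatch, apply_minmax)

__all__ = [
    "SplitPlan",
    "extract_patches",
    "make_target",
    "split_train_val",
    "build_loyo_splits",
    "write_split_manifest",
]


@dataclass(frozen=True)
class SplitPlan:
    """Leave-one-year-out fold plan for one field.

    ``folds`` is a list of ``(train_years, test_year)``; every observed year
    appears as the test year of exactly one fold. Folds are labeled
    A, B, C, ... with the most recent year held out first.
    """

    field_id: str
    folds: tuple[tuple[tuple[int, ...], int], ...]
    val_fraction: float = 0.1

    def __post_init__(self):
        test_years = [t for _, t in self.folds]
        if len(set(test_years)) != len(test_years):
            raise ValueError("duplicate test year across folds")
        for train, test in self.folds:
            if test in train:
                raise ValueError("train and test years must be disjoint")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")

    @property
    def labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(len(self.folds))]


def make_target(yield_window: np.ndarray, N: int,
                valid_window: np.ndarray | None = None,
                center: tuple[int, int] = (0, 0)) -> YieldPatch:
    """Centered N x N crop of a W x W yield window.

    The (i, j)-th target pixel maps to window pixel
    (i + (W-N)/2, j + (W-N)/2); N = 1 returns the center pixel. W - N must
    be even so the crop is exactly centered.
    """
    yield_window = np.asarray(yield_window, dtype=np.float64)
    W = yield_window.shape[0]
    if yield_window.shape != (W, W):
        raise ValueError("yield window must be square")
    if N not in (5, 3, 1):
        raise ValueError(f"output size N must be 5, 3 or 1, got {N}")
    if N > W or (W - N) % 2:
        raise ValueError(f"W - N must be even and nonnegative (W={W}, N={N})")
    o = (W - N) // 2
    data = yield_window[o:o + N, o:o + N]
    if valid_window is None:
        valid = np.isfinite(data)
    else:
        valid = np.asarray(valid_window, dtype=bool)[o:o + N, o:o + N]
    return YieldPatch(data=data.copy(), valid=valid.copy(), center=center)


def extract_patches(fy: FieldYear, N: int = 5, window: int = 5, stride: int = 2,
                    min_valid_fraction: float = 1.0,
                    params: NormalizationParams | None = None,
                    ) -> list[tuple[CovariatePatch, YieldPatch]]:
    """Extract (covariate patch, yield target) training pairs from one
    field-year.

    Windows sit at top-left corners (r, c) with r, c multiples of ``stride``,
    fully inside the raster. A window is kept iff at least
    ``min_valid_fraction`` of its yield pixels are masked-true. When
    ``params`` is given, covariates are min-max normalized and NoData
    covariate cells zero-filled; yield NoData pixels stay NaN and are
    flagged invalid in the target for loss masking.
    """
    H, W_r = fy.shape
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if window > H or window > W_r:
        raise ValueError(f"window {window} exceeds raster dims {H}x{W_r}")

    cov = apply_minmax(fy.covariates, params) if params is not None \
        else fy.covariates
    half = window // 2
    out: list[tuple[CovariatePatch, YieldPatch]] = []
    for r in range(0, H - window + 1, stride):
        for c in range(0, W_r - window + 1, stride):
            m = fy.mask[r:r + window, c:c + window]
            if m.mean() < min_valid_fraction:
                continue
            center = (r + half, c + half)
            x = CovariatePatch(data=cov[r:r + window, c:c + window].copy(),
                               center=center)
            y = make_target(fy.yield_map[r:r + window, c:c + window], N,
                            valid_window=m, center=center)
            out.append((x, y))
    if not out:
        raise ValueError("no patch satisfied the validity filter")
    return out


def split_train_val(samples: list, val_fraction: float = 0.1,
                    seed: int | np.random.Generator = 0) -> tuple[list, list]:
    """Random train/validation partition of a sample list (90/10 default).

    The validation size rounds to the nearest integer but is never smaller
    than 1; the partition is reproducible from the seed.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_val = max(1, round(n * val_fraction))
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [samples[i] for i in sorted(val_idx)]
    return train, val


def build_loyo_splits(dataset: list[FieldYear],
                      val_fraction: float = 0.1) -> SplitPlan:
    """Build the leave-one-year-out fold plan from a multi-year dataset.

    One fold per observed year, each year serving once as the independent
    test set; fold A holds out the most recent year, B the next, and so on.
    """
    years = [fy.year for fy in dataset]
    if len(set(years)) != len(years):
        raise ValueError("duplicate year labels in dataset")
    if len(years) < 2:
        raise ValueError("leave-one-year-out needs at least 2 years")
    field_ids = {fy.field_id for fy in dataset}
    if len(field_ids) != 1:
        raise ValueError("dataset mixes multiple fields")
    folds = tuple(
        (tuple(sorted(y for y in years if y != test)), test)
        for test in sorted(years, reverse=True))
    return SplitPlan(field_id=field_ids.pop(), folds=folds,
                     val_fraction=val_fraction)


def write_split_manifest(plan: SplitPlan, path) -> None:
    """Write the fold plan as a small CSV manifest (fold, year, role) so a
    run's train/test assignment is reproducible from disk."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["field", "fold", "year", "role"])
        for label, (train_years, test_year) in zip(plan.labels, plan.folds):
            for y in train_years:
                writer.writerow([plan.field_id, label, y, "train"])
            writer.writerow([plan.field_id, label, test_year, "test"])
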