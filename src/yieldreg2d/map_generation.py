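"""Whole-field predicted-yield-map generation.

The trained network sees a 5 x 5 neighborhood and predicts an N x N yield
window centered on it. To predict the whole field, the window slides over
*every* field cell (stride 1), so for N > 1 consecutive predictions
overlap: a cell can receive up to N^2 predicted values (25 for N = 5), one
from each window that covers it. The aggregated map is the per-cell average
of all contributions — which is what smooths the N = 5 maps relative to the
single-prediction N = 1 maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hyper3dnetreg import Hyper3DNetReg
from .raster_core import FieldYear, NormalizationParams, apply_minmax

__all__ = [
    "PredictionAccumulator",
    "coverage_count",
    "predict_field",
]


@dataclass
class PredictionAccumulator:
    """Running per-cell sum and count of overlapping window predictions.

    The final map is ``sum / count`` where ``count > 0``; cells never
    covered stay NoData.
    """

    sum: np.ndarray
    count: np.ndarray

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "PredictionAccumulator":
        return cls(np.zeros(shape), np.zeros(shape, dtype=np.int64))

    def add(self, window: np.ndarray, top_left: tuple[int, int],
            mask: np.ndarray) -> None:
        """Accumulate an N x N prediction window at an absolute position,
        discarding pixels that fall outside the raster or the field set."""
        N = window.shape[0]
        H, W = self.sum.shape
        r0, c0 = top_left
        for dr in range(N):
            for dc in range(N):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < H and 0 <= c < W and mask[r, c]:
                    self.sum[r, c] += window[dr, dc]
                    self.count[r, c] += 1

    def resolve(self) -> np.ndarray:
        out = np.full(self.sum.shape, np.nan)
        covered = self.count > 0
        out[covered] = self.sum[covered] / self.count[covered]
        return out


def coverage_count(mask: np.ndarray, N: int) -> np.ndarray:
    """Number of prediction windows contributing to each field cell.

    With stride-1 window centers on every masked-true cell, a cell is
    covered by the windows of all centers within Chebyshev distance
    (N-1)/2 — up to N^2 of them (25 for N = 5) in the field interior.
    Cells outside the field receive no contribution.
    """
    if N not in (5, 3, 1):
        raise ValueError(f"output size N must be 5, 3 or 1, got {N}")
    mask = np.asarray(mask, dtype=bool)
    counts = ndimage.uniform_filter(
        mask.astype(np.float64), size=N, mode="constant", cval=0.0) * N * N
    counts = np.rint(counts).astype(np.int64)
    counts[~mask] = 0
    return counts


def predict_field(model: Hyper3DNetReg, fy: FieldYear,
                  params: NormalizationParams, batch_size: int = 256,
                  return_count: bool = False) -> np.ndarray:
    """Generate the predicted yield map for one field-year.

    For every masked-true cell the 5 x 5 covariate neighborhood is taken
    from the normalized stack — with zeros outside the raster and at
    out-of-field or NoData cells, mirroring the zero-valued pixels beyond
    the field border — and pushed through the network in evaluation mode.
    Each N x N output window is accumulated at its absolute position; the
    returned map is the per-cell average, NaN outside the field set.
    """
    if not fy.mask.any():
        raise ValueError("field-year has an empty mask")
    cfg = model.config
    W = cfg.W
    half = W // 2
    H, W_r = fy.shape

    cov = apply_minmax(fy.covariates, params)
    cov[~fy.mask] = 0.0                       # zero-fill outside the field set
    pad = np.pad(cov, ((half, half), (half, half), (0, 0)))

    centers = np.argwhere(fy.mask)
    patches = np.empty((len(centers), W, W, cfg.n), dtype=np.float32)
    for k, (r, c) in enumerate(centers):
        patches[k] = pad[r:r + W, c:c + W]

    acc = PredictionAccumulator.zeros((H, W_r))
    off = (W - cfg.N) // 2                    # window top-left: center - (N-1)/2
    for i in range(0, len(centers), batch_size):
        preds = model.forward(patches[i:i + batch_size], train=False)
        if cfg.N == 1:
            preds = preds.reshape(-1, 1, 1)
        for k, (r, c) in enumerate(centers[i:i + batch_size]):
            acc.add(preds[k], (r - half + off, c - half + off), fy.mask)

    result = acc.resolve()
    return (result, acc.count) if return_count else result
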