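"""Map-level evaluation metrics.

An observed yield map M and a predicted map P are compared over the field
cell set F with four metrics: RMSE, root *median* squared error (RMedSE,
robust to yield-monitor outliers), Pearson correlation r, and structural
similarity. SSIM treats the two yield maps as images: a w x w window slides
over every pixel to produce an SSIM quality map of the same dimensions, and
SSIM3 / SSIM11 (w = 3, 11) are the means of that map over F, reported x100
as SSIM3* / SSIM11*.

Cells outside F are set to zero in both maps before windowing and the
raster edge is zero-padded. This is deliberate: windows near the field
border then contain zero-valued pixels at identical locations in M and P,
which makes them structurally similar and inflates the SSIM index along the
border — a known artifact of the procedure that the tests pin down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MapComparison",
    "rmse",
    "rmedse",
    "pearson_r",
    "ssim_index",
    "ssim_map",
    "ssim_mean",
    "square_error_map",
    "dynamic_range",
    "total_variation",
    "compare_maps",
]


def _check(M, P, F):
    M = np.asarray(M, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    F = np.asarray(F, dtype=bool)
    if M.shape != P.shape or M.shape != F.shape:
        raise ValueError("M, P and F must share dimensions")
    if not F.any():
        raise ValueError("empty field cell set F")
    return M, P, F


def rmse(M, P, F) -> float:
    """Root mean squared error over F (bu/ac)."""
    M, P, F = _check(M, P, F)
    d = M[F] - P[F]
    return float(np.sqrt(np.mean(d * d)))


def rmedse(M, P, F) -> float:
    """Root median squared error over F (bu/ac) — the median absolute
    deviation between the maps, insensitive to isolated outliers."""
    M, P, F = _check(M, P, F)
    d = M[F] - P[F]
    return float(np.sqrt(np.median(d * d)))


def pearson_r(M, P, F) -> float:
    """Pearson correlation of M and P over F.

    A constant map has no defined correlation; that case returns NaN with a
    warning rather than a silent 0.
    """
    M, P, F = _check(M, P, F)
    m, p = M[F], P[F]
    if np.ptp(m) == 0 or np.ptp(p) == 0:
        warnings.warn("Pearson r undefined: a map is constant over F",
                      stacklevel=2)
        return float("nan")
    mc, pc = m - m.mean(), p - p.mean()
    return float((mc * pc).sum() /
                 np.sqrt((mc * mc).sum() * (pc * pc).sum()))


def square_error_map(M, P, F) -> np.ndarray:
    """Elementwise (M - P)^2 on F, NaN elsewhere; its mean over F is
    exactly RMSE^2."""
    M, P, F = _check(M, P, F)
    out = np.full(M.shape, np.nan)
    out[F] = (M[F] - P[F]) ** 2
    return out


# ---------------------------------------------------------------------------
# SSIM


def ssim_index(a: np.ndarray, b: np.ndarray, L: float,
               K1: float = 0.01, K2: float = 0.03) -> float:
    """SSIM index between two equal-size local windows.

    ((2*mu_a*mu_b + C1) * (2*sigma_ab + C2)) /
    ((mu_a^2 + mu_b^2 + C1) * (sigma_a^2 + sigma_b^2 + C2))

    with C1 = (K1*L)^2, C2 = (K2*L)^2 and unweighted (uniform) window
    statistics; L is the dynamic range of the reference map. 1 means the
    windows are identical, -1 perfect anti-correlation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("windows must have equal size")
    if L <= 0:
        raise ValueError("dynamic range L must be positive")
    C1, C2 = (K1 * L) ** 2, (K2 * L) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(((2 * mu_a * mu_b + C1) * (2 * cov + C2)) /
                 ((mu_a ** 2 + mu_b ** 2 + C1) * (var_a + var_b + C2)))


def dynamic_range(M, F) -> float:
    """Dynamic range L of the observed (reference) map over F."""
    M = np.asarray(M, dtype=np.float64)
    vals = M[np.asarray(F, dtype=bool)]
    return float(vals.max() - vals.min())


def ssim_map(M, P, F, w: int, L: float | None = None,
             K1: float = 0.01, K2: float = 0.03) -> np.ndarray:
    """Per-pixel SSIM quality map between M and P with a w x w window.

    Non-F cells are zeroed in both maps before windowing and the raster
    edge is zero-padded, so the output has the same dimensions as the yield
    maps. L defaults to the dynamic range of M over F.
    """
    M, P, F = _check(M, P, F)
    if w % 2 == 0 or w < 1:
        raise ValueError("window size w must be odd and positive")
    if L is None:
        L = dynamic_range(M, F)
    if L <= 0:
        raise ValueError("dynamic range L must be positive")
    a = np.where(F, M, 0.0)
    b = np.where(F, P, 0.0)

    def um(x):                              # uniform window mean, zero-padded
        return ndimage.uniform_filter(x, size=w, mode="constant", cval=0.0)

    mu_a, mu_b = um(a), um(b)
    var_a = um(a * a) - mu_a ** 2
    var_b = um(b * b) - mu_b ** 2
    cov = um(a * b) - mu_a * mu_b
    C1, C2 = (K1 * L) ** 2, (K2 * L) ** 2
    return (((2 * mu_a * mu_b + C1) * (2 * cov + C2)) /
            ((mu_a ** 2 + mu_b ** 2 + C1) * (var_a + var_b + C2)))


def ssim_mean(smap: np.ndarray, F: np.ndarray) -> float:
    """Mean of an SSIM quality map over the field cell set F."""
    F = np.asarray(F, dtype=bool)
    if not F.any():
        raise ValueError("empty field cell set F")
    return float(np.asarray(smap, dtype=np.float64)[F].mean())


def total_variation(P: np.ndarray, F: np.ndarray) -> float:
    """Total variation of a map over F: summed absolute differences between
    horizontally and vertically adjacent field cells. Lower values mean a
    smoother map."""
    P = np.asarray(P, dtype=np.float64)
    F = np.asarray(F, dtype=bool)
    tv = 0.0
    dh = np.abs(np.diff(P, axis=1))
    tv += float(dh[(F[:, 1:] & F[:, :-1])].sum())
    dv = np.abs(np.diff(P, axis=0))
    tv += float(dv[(F[1:, :] & F[:-1, :])].sum())
    return tv


# ---------------------------------------------------------------------------
# bundled comparison


@dataclass
class MapComparison:
    """Observed map M, predicted map P, field set F and derived metrics."""

    M: np.ndarray
    P: np.ndarray
    F: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)


def compare_maps(M, P, F, L: float | None = None) -> MapComparison:
    """Compute the full metric set for one (observed, predicted) map pair.

    Returns RMSE, RMedSE, r, SSIM3, SSIM11 and the x100-scaled SSIM3*,
    SSIM11* used for reporting.
    """
    M, P, F = _check(M, P, F)
    s3 = ssim_mean(ssim_map(M, P, F, 3, L=L), F)
    s11 = ssim_mean(ssim_map(M, P, F, 11, L=L), F)
    metrics = {
        "RMSE": rmse(M, P, F),
        "RMedSE": rmedse(M, P, F),
        "r": pearson_r(M, P, F),
        "SSIM3": s3,
        "SSIM11": s11,
        "SSIM3*": 100.0 * s3,
        "SSIM11*": 100.0 * s11,
    }
    return MapComparison(M=M, P=P, F=F, metrics=metrics)
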