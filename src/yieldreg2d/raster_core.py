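"""Field-raster domain types, masking/NoData semantics, min-max
normalization and raster I/O.

A field-year is an 8-channel covariate stack at 10 m resolution co-registered
with an observed yield raster (bu/ac) and a boolean validity mask. The mask
defines the field cell set F: cells that belong to the field and carry a
valid yield observation. NoData is represented internally as NaN; yield
cells outside F always hold the NoData sentinel.

Channel order is fixed package-wide (see :data:`CHANNELS`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CHANNELS",
    "FieldYear",
    "NormalizationParams",
    "CovariatePatch",
    "YieldPatch",
    "fit_minmax",
    "apply_minmax",
    "read_field_year",
    "write_field_year",
]

#: Fixed covariate channel order: names and units.
CHANNELS = (
    ("nitrogen", "lbs/ac"),
    ("precipitation", "mm"),
    ("slope", "degrees"),
    ("elevation", "m"),
    ("tpi", "dimensionless"),
    ("aspect", "radians"),
    ("vv", "dB"),
    ("vh", "dB"),
)


@dataclass
class FieldYear:
    """One field-year: covariates, observed yield and validity mask.

    Attributes
    ----------
    field_id : str
        Field identifier.
    year : int
        Calendar year of observation.
    covariates : ndarray, shape (H, W, n)
        Covariate stack in the fixed channel order of :data:`CHANNELS`.
    yield_map : ndarray, shape (H, W)
        Observed yield in bu/ac; NaN outside the field set F.
    mask : ndarray of bool, shape (H, W)
        True where the cell belongs to F (valid yield).
    """

    field_id: str
    year: int
    covariates: np.ndarray
    yield_map: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.covariates = np.asarray(self.covariates, dtype=np.float64)
        self.yield_map = np.asarray(self.yield_map, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.covariates.ndim != 3:
            raise ValueError("covariates must be (H, W, n)")
        if self.covariates.shape[:2] != self.yield_map.shape or \
                self.yield_map.shape != self.mask.shape:
            raise ValueError("covariates, yield_map and mask must share H x W")
        if self.covariates.shape[2] < 1:
            raise ValueError("need at least one covariate channel")
        if not self.mask.any():
            raise ValueError("mask has no valid cell")
        # enforce the NoData sentinel outside F
        self.yield_map = np.where(self.mask, self.yield_map, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.yield_map.shape

    @property
    def n_channels(self) -> int:
        return self.covariates.shape[2]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel (min, max) fitted on masked training cells only."""

    mins: np.ndarray
    maxs: np.ndarray
    fitted_on: str = ""

    def __post_init__(self):
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=np.float64))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=np.float64))
        if self.mins.shape != self.maxs.shape:
            raise ValueError("mins and maxs must have equal length")
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in normalization parameters")

    @property
    def n_channels(self) -> int:
        return self.mins.size


@dataclass(frozen=True)
class CovariatePatch:
    """A W x W x n covariate window centered at raster cell (row, col)."""

    data: np.ndarray            # (W, W, n)
    center: tuple[int, int]


@dataclass(frozen=True)
class YieldPatch:
    """The centered N x N yield target of a covariate patch.

    ``valid`` flags target pixels inside F; invalid pixels are excluded from
    the training loss.
    """

    data: np.ndarray            # (N, N)
    valid: np.ndarray           # (N, N) bool
    center: tuple[int, int]


def fit_minmax(field_years: list[FieldYear] | FieldYear,
               fitted_on: str = "train") -> NormalizationParams:
    """Fit per-channel min-max statistics over masked-true cells of the
    training field-years only.

    Raises
    ------
    ValueError
        If any channel has no finite value on the masked cells (the error
        names the offending channel).
    """
    if isinstance(field_years, FieldYear):
        field_years = [field_years]
    if not field_years:
        raise ValueError("no training field-years given")
    n = field_years[0].n_channels
    mins = np.full(n, np.inf)
    maxs = np.full(n, -np.inf)
    for fy in field_years:
        if fy.n_channels != n:
            raise ValueError("channel count differs across field-years")
        vals = fy.covariates[fy.mask]            # (cells, n)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channel
            mins = np.fmin(mins, np.nanmin(vals, axis=0))
            maxs = np.fmax(maxs, np.nanmax(vals, axis=0))
    for c in range(n):
        if not (np.isfinite(mins[c]) and np.isfinite(maxs[c])):
            name = CHANNELS[c][0] if c < len(CHANNELS) else f"channel {c}"
            raise ValueError(f"channel '{name}' has no finite training value")
    return NormalizationParams(mins, maxs, fitted_on=fitted_on)


def apply_minmax(stack: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Scale a covariate stack with previously fitted min-max statistics.

    ``x' = (x - min_c) / (max_c - min_c)`` per channel. Values are *not*
    clipped, so data outside the training range map outside [0, 1] — the
    model is allowed to see, e.g., a test-year precipitation below anything
    in the training years. Degenerate channels (max == min) map to 0
    everywhere, and NoData (NaN) cells become 0 after scaling.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.shape[-1] != params.n_channels:
        raise ValueError(
            f"stack has {stack.shape[-1]} channels, params expect {params.n_channels}")
    span = params.maxs - params.mins
    out = np.zeros_like(stack)
    ok = span > 0
    with np.errstate(invalid="ignore"):
        out[..., ok] = (stack[..., ok] - params.mins[ok]) / span[ok]
    out[~np.isfinite(out)] = 0.0
    out[np.isnan(stack)] = 0.0
    return out


# ---------------------------------------------------------------------------
# I/O: .npz archive (lossless) and multi-band TIFF


def write_field_year(fy: FieldYear, path: str | Path,
                     layout: str | None = None) -> Path:
    """Write a field-year container.

    Layouts
    -------
    ``"npz"``
        Compressed numpy archive with named arrays; lossless round-trip of
        grids, mask and metadata.
    ``"tiff"``
        Multi-band TIFF: bands 1..n covariates in the fixed channel order,
        band n+1 yield, band n+2 mask; field metadata as a JSON
        ImageDescription tag.

    The layout is inferred from the file suffix when not given.
    """
    path = Path(path)
    layout = layout or _infer_layout(path)
    if layout == "npz":
        np.savez_compressed(
            path,
            covariates=fy.covariates,
            yield_map=fy.yield_map,
            mask=fy.mask,
            meta=np.bytes_(json.dumps(
                {"field_id": fy.field_id, "year": fy.year, **fy.meta}
            ).encode()),
        )
    elif layout == "tiff":
        import tifffile

        n = fy.n_channels
        bands = np.concatenate(
            [np.moveaxis(fy.covariates, 2, 0),
             fy.yield_map[None],
             fy.mask[None].astype(np.float64)], axis=0)
        desc = json.dumps({
            "field_id": fy.field_id, "year": fy.year, "n_channels": n,
            "channels": [c for c, _ in CHANNELS[:n]], **fy.meta})
        tifffile.imwrite(path, bands.astype(np.float32), description=desc)
    else:
        raise ValueError(f"unknown layout '{layout}'")
    return path


def read_field_year(path: str | Path, layout: str | None = None) -> FieldYear:
    """Read a field-year container written by :func:`write_field_year`.

    For either layout the mask is reconstructed exactly; the NaN NoData
    sentinel in the yield band round-trips through both containers.
    """
    path = Path(path)
    layout = layout or _infer_layout(path)
    if layout == "npz":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            return FieldYear(
                field_id=meta.pop("field_id"), year=int(meta.pop("year")),
                covariates=z["covariates"], yield_map=z["yield_map"],
                mask=z["mask"], meta=meta)
    if layout == "tiff":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            bands = tf.asarray().astype(np.float64)
            desc = tf.pages[0].description
        meta = json.loads(desc)
        n = int(meta.pop("n_channels"))
        meta.pop("channels", None)
        if bands.shape[0] != n + 2:
            raise ValueError(
                f"expected {n + 2} bands ({n} covariates + yield + mask), "
                f"found {bands.shape[0]}")
        return FieldYear(
            field_id=meta.pop("field_id"), year=int(meta.pop("year")),
            covariates=np.moveaxis(bands[:n], 0, 2), yield_map=bands[n],
            mask=bands[n + 1] > 0.5, meta=meta)
    raise ValueError(f"unknown layout '{layout}'")


def _infer_layout(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return "npz"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer container layout from suffix '{suffix}'")
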