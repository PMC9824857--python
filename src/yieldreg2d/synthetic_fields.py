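"""Synthetic multi-year field generator.

Emulates the statistical structure of an on-farm precision-experimentation
(OFPE) dataset: a smooth terrain surface with derived slope/aspect/TPI,
spatially blocked experimental nitrogen rates, one precipitation scalar per
year broadcast to the raster, moisture-correlated SAR backscatter channels
(VV/VH), and a nonlinear, noisy yield response. The real farm data this
mirrors cannot be shared, so the simulator is the package's test bed: it
reproduces the *shapes* of the problem (covariate ranges, spatial blocking,
year-to-year precipitation shifts, terrain-yield interaction), not the
agronomy of any particular field.

Default precipitation years follow the wet/dry alternation reported for
dryland winter-wheat fields in Montana (86/130/101 mm), which makes one
leave-one-year-out fold train on wet years and test on a dry one — the data
representativeness failure mode the evaluation harness must surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster_core import CHANNELS, FieldYear

__all__ = [
    "SimConfig",
    "generate_dem",
    "compute_slope",
    "compute_aspect",
    "compute_tpi",
    "generate_nitrogen_map",
    "generate_sar_channels",
    "yield_response",
    "generate_field_years",
]

#: Grid cell size in meters (10 m resolution throughout).
CELL_SIZE = 10.0


@dataclass
class SimConfig:
    """Configuration of the synthetic field simulator.

    Parameters with units:

    * ``years`` — list of ``(year, precipitation mm)`` pairs; precipitation
      is a single scalar per field-year broadcast to the raster.
    * ``dem_smoothness`` — Gaussian sigma (cells) of the terrain filter.
    * ``dem_relief`` — total elevation range (m); ``dem_base`` the floor (m).
    * ``n_rates`` — experimental nitrogen levels (lbs/ac), applied in
      ``block_size`` x ``block_size`` blocks.
    * yield response: ``ymax0`` (bu/ac) asymptotic yield, ``n_halfsat``
      (lbs/ac) nitrogen half-saturation, ``precip_coeff`` (per mm) linear
      precipitation effect around ``precip_ref`` (mm), ``tpi_coeff`` ridge
      penalty per standardized-TPI unit, ``noise_sd`` (bu/ac) additive
      Gaussian noise.
    * ``mask_fraction`` — target fraction of the raster covered by the
      irregular field boundary blob.
    """

    height: int = 40
    width: int = 40
    years: list[tuple[int, float]] = field(
        default_factory=lambda: [(2016, 86.0), (2018, 130.0), (2020, 101.0)])
    dem_smoothness: float = 5.0
    dem_relief: float = 20.0
    dem_base: float = 1000.0
    n_rates: list[float] = field(
        default_factory=lambda: [0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
    block_size: int = 5
    ymax0: float = 110.0
    n_halfsat: float = 40.0
    precip_coeff: float = 0.006
    precip_ref: float = 100.0
    tpi_coeff: float = 0.15
    noise_sd: float = 5.0
    mask_fraction: float = 0.85
    field_id: str = "SYN1"
    seed: int = 0

    def __post_init__(self):
        if self.height < 15 or self.width < 15:
            raise ValueError("field must be at least 15 x 15 cells")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(r < 0 for r in self.n_rates):
            raise ValueError("nitrogen rates must be nonnegative")
        if len(self.years) < 2:
            raise ValueError("need at least two years for leave-one-year-out use")


# ---------------------------------------------------------------------------
# terrain


def generate_dem(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Smooth random elevation surface: Gaussian-filtered white noise
    rescaled to ``[dem_base, dem_base + dem_relief]``."""
    rng = rng or np.random.default_rng(cfg.seed)
    z = ndimage.gaussian_filter(
        rng.standard_normal((cfg.height, cfg.width)), cfg.dem_smoothness,
        mode="nearest")
    lo, hi = z.min(), z.max()
    if hi > lo and cfg.dem_relief > 0:
        z = (z - lo) / (hi - lo) * cfg.dem_relief
    else:
        z = np.zeros_like(z)
    return z + cfg.dem_base


def _horn_gradients(dem: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horn (1981) third-order finite differences with replicated borders.

    Returns (gx, gy): eastward and northward elevation change per meter on
    the 10 m grid (row 0 is the northern edge).
    """
    dem = np.asarray(dem, dtype=np.float64)
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3 x 3")
    zp = np.pad(dem, 1, mode="edge")
    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    g, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * CELL_SIZE)
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * CELL_SIZE)
    return gx, gy


def compute_slope(dem: np.ndarray) -> np.ndarray:
    """Terrain slope in degrees (Horn's method)."""
    gx, gy = _horn_gradients(dem)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def compute_aspect(dem: np.ndarray) -> np.ndarray:
    """Downslope direction in radians, wrapped to [0, 2*pi)."""
    gx, gy = _horn_gradients(dem)
    return np.mod(np.arctan2(gy, -gx), 2 * np.pi)


def compute_tpi(dem: np.ndarray) -> np.ndarray:
    """Topographic position index: cell elevation minus the mean of its
    eight 3x3 neighbors (center excluded), replicated borders.

    Positive on ridges, negative in depressions, zero on flat or uniformly
    sloping ground.
    """
    dem = np.asarray(dem, dtype=np.float64)
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3 x 3")
    kernel = np.ones((3, 3)) / 8.0
    kernel[1, 1] = 0.0
    return dem - ndimage.convolve(dem, kernel, mode="nearest")


# ---------------------------------------------------------------------------
# management and weather covariates


def generate_nitrogen_map(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Blocked experimental nitrogen-rate map (lbs/ac).

    The field is tiled into ``block_size`` blocks; each block draws one rate
    uniformly from ``cfg.n_rates`` — the spatially distributed rate design
    of an on-farm experiment.
    """
    if not cfg.n_rates:
        raise ValueError("n_rates is empty")
    nb_r = -(-cfg.height // cfg.block_size)
    nb_c = -(-cfg.width // cfg.block_size)
    rates = rng.choice(np.asarray(cfg.n_rates, dtype=np.float64), size=(nb_r, nb_c))
    grid = np.kron(rates, np.ones((cfg.block_size, cfg.block_size)))
    return grid[:cfg.height, :cfg.width]


def generate_sar_channels(dem: np.ndarray, tpi: np.ndarray, precipitation: float,
                          rng: np.random.Generator, cfg: SimConfig,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """VV and VH backscatter (dB) driven by a latent soil-moisture field.

    Moisture rises with the year's precipitation and falls on ridges
    (positive TPI sheds water); backscatter is affine in moisture with a
    weaker VH response, plus smooth spatial texture and speckle-like noise.
    """
    precs = np.array([p for _, p in cfg.years], dtype=np.float64)
    p_mu, p_sd = precs.mean(), precs.std() or 1.0
    precip_z = (precipitation - p_mu) / p_sd
    t_sd = tpi.std() or 1.0
    tpi_z = (tpi - tpi.mean()) / t_sd
    texture = ndimage.gaussian_filter(
        rng.standard_normal(dem.shape), 2.0, mode="nearest")
    moisture = 1.0 / (1.0 + np.exp(-(1.5 * precip_z - 1.0 * tpi_z + 0.5 * texture)))
    vv = -17.0 + 10.0 * moisture + 0.3 * rng.standard_normal(dem.shape)
    vh = -24.0 + 6.0 * moisture + 0.3 * rng.standard_normal(dem.shape)
    return vv, vh


def yield_response(covariates: np.ndarray, cfg: SimConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Nonlinear noisy yield response (bu/ac) to the covariate stack.

    yield = ymax0 * N/(N + n_halfsat)
            * max(0, 1 + precip_coeff * (precip - precip_ref))
            * max(0, 1 - tpi_coeff * TPI_z)
            + Gaussian(0, noise_sd),  truncated at 0.

    A Mitscherlich-type saturating nitrogen response: monotone nondecreasing
    in applied nitrogen with everything else fixed, boosted by wetter years
    and penalized on water-shedding ridges (standardized TPI).
    """
    nitrogen = covariates[..., 0]
    precip = covariates[..., 1]
    tpi = covariates[..., 4]
    t_sd = tpi.std()
    tpi_z = (tpi - tpi.mean()) / t_sd if t_sd > 0 else np.zeros_like(tpi)
    base = cfg.ymax0 * nitrogen / (nitrogen + cfg.n_halfsat)
    wet = np.maximum(0.0, 1.0 + cfg.precip_coeff * (precip - cfg.precip_ref))
    topo = np.maximum(0.0, 1.0 - cfg.tpi_coeff * tpi_z)
    y = base * wet * topo
    if rng is not None and cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.shape)
    return np.maximum(y, 0.0)


def _generate_mask(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Irregular field-boundary blob covering ~mask_fraction of the raster."""
    blob = ndimage.gaussian_filter(
        rng.standard_normal((cfg.height, cfg.width)), cfg.dem_smoothness,
        mode="nearest")
    thresh = np.quantile(blob, 1.0 - cfg.mask_fraction)
    mask = blob >= thresh
    # keep the largest connected component so the field is one piece
    labels, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(mask, labels, index=range(1, nlab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if not mask.any():
        mask[cfg.height // 2, cfg.width // 2] = True
    return mask


def generate_field_years(cfg: SimConfig) -> list[FieldYear]:
    """Generate the full multi-year dataset for one synthetic field.

    Terrain (and hence slope/aspect/TPI) and the boundary mask are shared
    across years; nitrogen assignment, precipitation, backscatter and the
    yield realization vary per year. A single seeded generator is threaded
    through every draw, so a fixed ``cfg.seed`` reproduces the dataset
    byte for byte.
    """
    rng = np.random.default_rng(cfg.seed)
    dem = generate_dem(cfg, rng)
    slope = compute_slope(dem)
    aspect = compute_aspect(dem)
    tpi = compute_tpi(dem)
    mask = _generate_mask(cfg, rng)

    out = []
    n = len(CHANNELS)
    for year, precip in cfg.years:
        cov = np.empty((cfg.height, cfg.width, n))
        cov[..., 0] = generate_nitrogen_map(cfg, rng)
        cov[..., 1] = precip
        cov[..., 2] = slope
        cov[..., 3] = dem
        cov[..., 4] = tpi
        cov[..., 5] = aspect
        cov[..., 6], cov[..., 7] = generate_sar_channels(dem, tpi, precip, rng, cfg)
        ymap = yield_response(cov, cfg, rng)
        out.append(FieldYear(
            field_id=cfg.field_id, year=year, covariates=cov,
            yield_map=ymap, mask=mask,
            meta={"precipitation_mm": precip}))
    return out
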