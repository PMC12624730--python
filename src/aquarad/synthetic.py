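"""Synthetic multi-site field campaigns for exercising the processing chain.

Real paired device/reference radiometry is rarely shareable, so this module
fabricates campaigns end to end: bloom-parameterised R_rs scenes, analytic
sky and panel radiances, the exact inverse of the reflectance equation to get
water-leaving radiance, and an instrument forward model producing raw pixel
counts with dark offset, multiplicative noise, and saturation clipping.

Scene model
-----------
R_rs is a smooth positive baseline (green-peaked, as in turbid productive
waters) modified by three bloom features: a phycocyanin absorption dip at
620 nm (Gaussian, sigma 15 nm, driven by ``pc_level``), a chlorophyll-a
absorption dip at 665 nm (sigma 15 nm) and the associated red-edge
reflectance peak at 708 nm (sigma 12 nm), both driven by ``chl_level``.  A
small seeded low-frequency modulation makes stations distinguishable without
breaking positivity or the monotone response of the indices to their pigment
parameters.

Ground-truth convention
-----------------------
The reference instrument is defined to report the exact linear radiometric
model applied to the piecewise-linear interpolant of the device's noiseless
pixel-sampled counts.  Both instruments therefore observe the *same*
band-limited field, and with zero noise the whole chain (calibrate on other
sites, apply, compute R_rs) reproduces the reference to machine precision —
which is exactly what makes the generator useful for isolating estimation
error.  Bandwidth mismatch between real instruments is deliberately not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .calibration import (
    DEFAULT_N_PIXELS,
    DEFAULT_SATURATION_CEILING,
    PixelSpectrum,
    StationRecord,
    WavelengthPolynomial,
    pixel_to_wavelength,
)
from .errors import ConfigurationError, GridRangeError
from .reflectance import ReflectanceParams
from .spectra import DEFAULT_GRID, Spectrum, Unit, WavelengthGrid

__all__ = [
    "SceneParams",
    "InstrumentParams",
    "EnvironmentModels",
    "default_instrument",
    "rrs_model",
    "generate_rrs",
    "sky_radiance",
    "panel_radiance",
    "forward_model_station",
    "generate_campaign",
]

#: Default factory pixel->wavelength polynomial: 288 pixels spanning
#: ~313-889 nm with a slight quadratic term, matching the device's range.
DEFAULT_WAVELENGTH_POLY = WavelengthPolynomial((313.0, 1.95, 2.0e-4, 0.0, 0.0, 0.0))

_SCENE_RANGE = (313.0, 890.0)


@dataclass(frozen=True)
class SceneParams:
    """Bloom scene controls, all dimensionless.

    chl_level, pc_level in [0, 1] scale the chlorophyll-a (665 nm dip +
    708 nm peak) and phycocyanin (620 nm dip) features; backscatter_level
    (sr^-1) sets the baseline R_rs magnitude (default 0.01 sr^-1, a turbid
    inland-water magnitude); seed drives the per-scene smooth modulation.
    """

    chl_level: float = 0.5
    pc_level: float = 0.5
    backscatter_level: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chl_level", "pc_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not self.backscatter_level > 0:
            raise ConfigurationError("backscatter_level must be positive")


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def rrs_model(wavelengths, params: SceneParams) -> np.ndarray:
    """Scene R_rs evaluated at arbitrary wavelengths within 313-890 nm."""
    wl = np.asarray(wavelengths, dtype=float)
    bs = params.backscatter_level
    # green-high, NIR-low baseline; the sigmoid is near-linear across the
    # 560-665 nm window, so with no bloom the baseline-subtraction indices
    # sit close to zero
    base = bs * (0.25 + 0.9 / (1.0 + np.exp((wl - 645.0) / 60.0)))
    values = (
        base
        - params.pc_level * 0.35 * bs * _gauss(wl, 620.0, 15.0)
        - params.chl_level * 0.35 * bs * _gauss(wl, 665.0, 15.0)
        + params.chl_level * 0.50 * bs * _gauss(wl, 708.0, 12.0)
    )
    # seeded smooth station-to-station variability (~1% of baseline)
    rng = np.random.default_rng(params.seed)
    amp = rng.uniform(0.002, 0.01, size=3) * bs
    period = rng.uniform(150.0, 450.0, size=3)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
    for a, L, ph in zip(amp, period, phase):
        values = values + a * np.cos(2.0 * np.pi * (wl - 390.0) / L + ph)
    return values


def generate_rrs(params: SceneParams, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Scene R_rs sampled on an analysis grid (within 390-880 nm)."""
    wl = grid.wavelengths()
    if wl[0] < DEFAULT_GRID.start or wl[-1] > DEFAULT_GRID.stop:
        raise GridRangeError("scene grids must lie within 390-880 nm")
    return Spectrum(wl, rrs_model(wl, params), Unit.RRS_PER_SR)


def sky_radiance(wavelengths) -> np.ndarray:
    """Analytic positive sky radiance: Rayleigh-like blue rise over a floor."""
    wl = np.asarray(wavelengths, dtype=float)
    return 5.0 * (400.0 / wl) ** 4 + 1.0


def panel_radiance(wavelengths) -> np.ndarray:
    """Analytic positive panel radiance: broad solar-like hump over a floor."""
    wl = np.asarray(wavelengths, dtype=float)
    return 18.0 * np.exp(-0.5 * ((wl - 560.0) / 260.0) ** 2) + 4.0


@dataclass
class EnvironmentModels:
    """Sky and panel radiance models plus a per-station brightness factor
    (illumination variability: sun elevation, haze, thin cloud)."""

    sky: Callable = sky_radiance
    panel: Callable = panel_radiance
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if not self.brightness > 0:
            raise ConfigurationError("brightness must be positive")


def _default_gain(wl: np.ndarray) -> np.ndarray:
    return 1.0e-3 * (0.8 + 0.4 * np.exp(-0.5 * ((wl - 600.0) / 200.0) ** 2))


def _default_offset(wl: np.ndarray) -> np.ndarray:
    return 0.005 * (1.0 + 0.2 * np.exp(-0.5 * ((wl - 500.0) / 300.0) ** 2))


@dataclass
class InstrumentParams:
    """Device truth: per-wavelength linear response, dark level, noise, ceiling.

    ``gain`` (radiance per AU) and ``offset`` (radiance) are tabulated on
    ``wavelength_table`` (default 313-889 nm at 1 nm) and interpolated
    linearly in between.  ``noise_sd_fraction`` is the standard deviation of
    multiplicative Gaussian count noise; ``dark_counts`` is added to every
    pixel; counts clip at ``saturation_ceiling``.
    """

    wavelength_table: np.ndarray = None
    gain: np.ndarray = None
    offset: np.ndarray = None
    noise_sd_fraction: float = 0.01
    dark_counts: float = 120.0
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING
    wavelength_poly: WavelengthPolynomial = DEFAULT_WAVELENGTH_POLY
    n_pixels: int = DEFAULT_N_PIXELS
    integration_time_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.wavelength_table is None:
            self.wavelength_table = np.arange(313.0, 890.0)
        self.wavelength_table = np.asarray(self.wavelength_table, dtype=float)
        if self.gain is None:
            self.gain = _default_gain(self.wavelength_table)
        if self.offset is None:
            self.offset = _default_offset(self.wavelength_table)
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.gain.shape != self.wavelength_table.shape:
            raise ConfigurationError("gain is not on the wavelength table")
        if self.offset.shape != self.wavelength_table.shape:
            raise ConfigurationError("offset is not on the wavelength table")
        if np.any(self.gain == 0.0):
            raise ConfigurationError("true gain must be nonzero everywhere")
        if self.noise_sd_fraction < 0:
            raise ConfigurationError("noise_sd_fraction must be >= 0")
        if not self.saturation_ceiling > self.dark_counts:
            raise ConfigurationError("saturation ceiling must exceed dark counts")
        self.wavelength_poly.check_monotone(self.n_pixels)

    def gain_at(self, wavelengths) -> np.ndarray:
        return np.interp(wavelengths, self.wavelength_table, self.gain)

    def offset_at(self, wavelengths) -> np.ndarray:
        return np.interp(wavelengths, self.wavelength_table, self.offset)


def default_instrument(noise_sd_fraction: float = 0.01, **kwargs) -> InstrumentParams:
    return InstrumentParams(noise_sd_fraction=noise_sd_fraction, **kwargs)


def forward_model_station(
    scene: Union[SceneParams, Callable],
    inst: InstrumentParams,
    env: Optional[EnvironmentModels] = None,
    site_id: str = "site",
    timestamp: str = "2024-07-01T16:00:00Z",
    params: ReflectanceParams = ReflectanceParams(),
    rng: Optional[np.random.Generator] = None,
) -> StationRecord:
    """Simulate one station: device pixel scans plus reference radiances.

    ``scene`` is either :class:`SceneParams` or a callable wavelength->R_rs.
    The noiseless radiances (on the instrument's wavelength table restricted
    to the detector span) form the reference triplet; device counts get dark
    offset, multiplicative noise, and saturation clipping, with saturated
    pixels masked.
    """
    env = env or EnvironmentModels()
    if rng is None:
        rng = np.random.default_rng(0)
    rrs_fn = (lambda wl: rrs_model(wl, scene)) if isinstance(scene, SceneParams) else scene

    wl_px = inst.wavelength_poly(np.arange(inst.n_pixels))
    lsky = env.brightness * np.asarray(env.sky(wl_px), dtype=float)
    lc = env.brightness * np.asarray(env.panel(wl_px), dtype=float)
    rrs = np.asarray(rrs_fn(wl_px), dtype=float)
    lw = (
        rrs * np.pi * params.panel_correction * lc / params.panel_reflectance
        + params.rho * lsky
    )

    gain_px = inst.gain_at(wl_px)
    off_px = inst.offset_at(wl_px)
    table = inst.wavelength_table
    in_span = (table >= wl_px[0]) & (table <= wl_px[-1])
    table = table[in_span]

    device, reference = {}, {}
    for comp, radiance in (("Lw", lw), ("Lsky", lsky), ("Lc", lc)):
        counts_true = (radiance - off_px) / gain_px + inst.dark_counts
        if np.any(counts_true < 0):
            raise ConfigurationError(
                f"{comp}: negative noiseless counts — offset/dark configuration "
                "inconsistent with the scene"
            )
        counts = counts_true
        if inst.noise_sd_fraction > 0:
            counts = counts * (
                1.0 + inst.noise_sd_fraction * rng.standard_normal(counts.size)
            )
        counts = np.clip(counts, 0.0, inst.saturation_ceiling)
        px = PixelSpectrum(
            counts,
            integration_time_ms=inst.integration_time_ms,
            saturation_ceiling=inst.saturation_ceiling,
        )
        dev = pixel_to_wavelength(px, inst.wavelength_poly)
        dev.meta.update(site=site_id, timestamp=timestamp, component=comp)
        device[comp] = dev

        # reference = exact linear model applied to the interpolated
        # noiseless dark-corrected counts (see module docstring)
        c_hat = np.interp(table, wl_px, counts_true)
        l_ref = inst.gain_at(table) * (c_hat - inst.dark_counts) + inst.offset_at(table)
        reference[comp] = Spectrum(
            table.copy(), l_ref, Unit.RADIANCE,
            meta={"site": site_id, "timestamp": timestamp, "component": comp},
        )

    return StationRecord(
        site_id=site_id, timestamp=timestamp, device=device, reference=reference
    )


def _station_counts(n_sites: int, n_stations: int) -> list:
    base, extra = divmod(n_stations, n_sites)
    return [base + (1 if i < extra else 0) for i in range(n_sites)]


def generate_campaign(
    n_sites: int = 6,
    n_stations: int = 31,
    seed: int = 0,
    inst: Optional[InstrumentParams] = None,
    params: ReflectanceParams = ReflectanceParams(),
    backscatter_level: float = 0.01,
) -> list:
    """Deterministic multi-site campaign (default: 31 stations over 6 sites).

    Each site draws its own bloom levels (chlorophyll and phycocyanin);
    stations within a site jitter those levels slightly and vary in overall
    illumination brightness.  Identical seeds give bit-identical campaigns.
    """
    if n_sites < 2:
        raise ConfigurationError("a campaign needs at least 2 sites")
    if n_stations < n_sites:
        raise ConfigurationError("need at least one station per site")
    inst = inst or default_instrument()
    rng = np.random.default_rng(seed)

    records = []
    counts = _station_counts(n_sites, n_stations)
    for s in range(n_sites):
        site_id = f"site{s + 1}"
        chl_site = rng.uniform(0.1, 0.9)
        pc_site = rng.uniform(0.1, 0.9)
        for k in range(counts[s]):
            scene = SceneParams(
                chl_level=float(np.clip(chl_site + rng.normal(0.0, 0.05), 0.0, 1.0)),
                pc_level=float(np.clip(pc_site + rng.normal(0.0, 0.05), 0.0, 1.0)),
                backscatter_level=backscatter_level,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            env = EnvironmentModels(brightness=float(rng.uniform(0.7, 1.3)))
            timestamp = f"2024-07-{(s % 28) + 1:02d}T{10 + (k % 8):02d}:00:00Z"
            records.append(
                forward_model_station(
                    scene, inst, env,
                    site_id=site_id, timestamp=timestamp, params=params, rng=rng,
                )
            )
    return records
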