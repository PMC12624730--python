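"""Radiometric cross-calibration of a low-cost spectrometer against a reference.

The device records raw intensity in arbitrary units (AU) over a pixel axis; a
factory-provided polynomial maps pixel index to wavelength.  Because the
detector response is assumed linear, converting counts to physical radiance
amounts to a wavelength-dependent linear map fitted against a co-located
reference spectroradiometer: at every wavelength of the analysis grid,
ordinary least squares of reference radiance on device counts across stations
gives a gain (radiance per AU) and an offset (radiance), one calibration per
radiance component (L_w, L_sky, L_c).

Transferability is assessed by leave-one-location-out cross-validation:
calibrations are fit on all but one site and evaluated on the held-out site's
stations, both component-by-component and on the derived remote-sensing
reflectance.

The per-wavelength regression is exposed as a scikit-learn style estimator
(:class:`PerWavelengthLinearCalibrator`); the domain-level helpers
(:func:`fit_calibration`, :func:`apply_calibration`,
:func:`leave_one_location_out`) wrap it with Spectrum/StationRecord plumbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyFitError,
    GridMismatchError,
    UnitError,
)
from .metrics import EvaluationReport, evaluate_vectors
from .reflectance import RadianceTriplet, ReflectanceParams, compute_rrs
from .spectra import DEFAULT_GRID, Spectrum, Unit, WavelengthGrid, resample

__all__ = [
    "COMPONENTS",
    "PixelSpectrum",
    "WavelengthPolynomial",
    "pixel_to_wavelength",
    "PerWavelengthLinearCalibrator",
    "RadiometricCalibration",
    "StationRecord",
    "Geometry",
    "fit_calibration",
    "apply_calibration",
    "LocationReport",
    "leave_one_location_out",
]

#: Radiance component tags: water-leaving, sky, and reference-panel radiance.
COMPONENTS = ("Lw", "Lsky", "Lc")

#: Default detector length and 16-bit saturation ceiling (datasheet convention).
DEFAULT_N_PIXELS = 288
DEFAULT_SATURATION_CEILING = 65535.0


@dataclass(frozen=True)
class WavelengthPolynomial:
    """Pixel-index -> wavelength map, lambda(p) = sum_k a_k p^k.

    Factory calibrations for miniature spectrometers conventionally ship six
    coefficients (degree 5); any length >= 2 is accepted.
    """

    coefficients: tuple

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if len(coeffs) < 2:
            raise ConfigurationError("wavelength polynomial needs >= 2 coefficients")

    def __call__(self, pixels) -> np.ndarray:
        p = np.asarray(pixels, dtype=float)
        return np.polynomial.polynomial.polyval(p, np.asarray(self.coefficients))

    def check_monotone(self, n_pixels: int) -> None:
        wl = self(np.arange(n_pixels))
        if np.any(np.diff(wl) <= 0):
            raise ConfigurationError(
                "wavelength polynomial is not strictly increasing over the pixel range"
            )


@dataclass
class PixelSpectrum:
    """Raw device scan: counts (AU) over pixel indices 0..N-1.

    Pixels at or above ``saturation_ceiling`` are flagged saturated and will
    be masked once mapped into the wavelength domain.
    """

    counts: np.ndarray
    integration_time_ms: float = 10.0
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise DegenerateInputError("counts must be a 1-D vector of >= 2 pixels")
        if np.any(self.counts < 0):
            raise ConfigurationError("raw counts must be non-negative")
        if not self.integration_time_ms > 0:
            raise ConfigurationError("integration time must be positive")

    @property
    def n_pixels(self) -> int:
        return self.counts.size

    @property
    def pixel_indices(self) -> np.ndarray:
        return np.arange(self.n_pixels)

    @property
    def saturated(self) -> np.ndarray:
        return self.counts >= self.saturation_ceiling


def pixel_to_wavelength(px: PixelSpectrum, poly: WavelengthPolynomial) -> Spectrum:
    """Map a raw pixel scan into the wavelength domain.

    Returns a counts_AU Spectrum on the (non-uniform) factory wavelength axis,
    with saturated pixels masked.  Raises ConfigurationError if the polynomial
    is not monotone over the pixel range.
    """
    poly.check_monotone(px.n_pixels)
    wl = poly(px.pixel_indices)
    sat = px.saturated
    return Spectrum(
        wl,
        px.counts.copy(),
        Unit.COUNTS_AU,
        mask=sat if sat.any() else None,
        meta={
            "integration_time_ms": px.integration_time_ms,
            "saturation_ceiling": px.saturation_ceiling,
        },
    )


class PerWavelengthLinearCalibrator(RegressorMixin, BaseEstimator):
    """Independent ordinary-least-squares line per wavelength column.

    Fits ``y[:, j] ~ gain_[j] * X[:, j] + offset_[j]`` column by column, where
    rows are stations and columns are wavelengths.  NaN entries (masked
    samples) are excluded pairwise; columns with fewer than two usable pairs
    or zero count variance are left NaN and reported in ``invalid_columns_``.

    Attributes (after fit)
    ----------------------
    gain_ : ndarray, slope per column (radiance per AU)
    offset_ : ndarray, intercept per column (radiance)
    r2_ : ndarray, squared Pearson correlation per column
    n_used_ : ndarray, usable pairs per column
    invalid_columns_ : boolean ndarray, columns without a valid fit
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != X.shape:
            raise DegenerateInputError(
                "X and y must be 2-D arrays of identical shape (stations x wavelengths)"
            )
        if X.shape[0] < 2:
            raise DegenerateInputError("need at least 2 stations to fit a line")

        valid = np.isfinite(X) & np.isfinite(y)
        n = valid.sum(axis=0)
        Xv = np.where(valid, X, 0.0)
        yv = np.where(valid, y, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            n_safe = np.where(n > 0, n, 1)
            xm = Xv.sum(axis=0) / n_safe
            ym = yv.sum(axis=0) / n_safe
            dx = np.where(valid, X - xm, 0.0)
            dy = np.where(valid, y - ym, 0.0)
            sxx = (dx * dx).sum(axis=0)
            syy = (dy * dy).sum(axis=0)
            sxy = (dx * dy).sum(axis=0)
            if self.fit_intercept:
                gain = sxy / sxx
                offset = ym - gain * xm
            else:
                raw_sxx = (np.where(valid, X, 0.0) ** 2).sum(axis=0)
                raw_sxy = (Xv * yv).sum(axis=0)
                gain = raw_sxy / raw_sxx
                offset = np.zeros_like(gain)
            r2 = np.where(syy > 0, sxy**2 / (sxx * syy), np.nan)

        bad = (n < 2) | (sxx <= 0) | ~np.isfinite(gain)
        gain = np.where(bad, np.nan, gain)
        offset = np.where(bad, np.nan, offset)
        r2 = np.where(bad, np.nan, np.clip(r2, 0.0, 1.0))
        if bad.all():
            raise EmptyFitError("no wavelength has >= 2 usable, varying count pairs")

        self.gain_ = gain
        self.offset_ = offset
        self.r2_ = r2
        self.n_used_ = n
        self.invalid_columns_ = bad
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "gain_"):
            raise DegenerateInputError("calibrator is not fitted")
        if X.shape[-1] != self.n_features_in_:
            raise GridMismatchError(
                f"X has {X.shape[-1]} wavelengths, calibrator was fit on "
                f"{self.n_features_in_}"
            )
        return self.gain_ * X + self.offset_


@dataclass
class RadiometricCalibration:
    """Fitted per-wavelength linear counts->radiance map for one component."""

    component: str
    grid: WavelengthGrid
    gain: np.ndarray
    offset: np.ndarray
    fit_r2: np.ndarray
    n_samples: int
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ConfigurationError(
                f"component must be one of {COMPONENTS}, got {self.component!r}"
            )
        npts = self.grid.n_points
        for name, v in (
            ("gain", self.gain),
            ("offset", self.offset),
            ("fit_r2", self.fit_r2),
        ):
            arr = np.asarray(v, dtype=float)
            if arr.shape != (npts,):
                raise GridMismatchError(f"{name} is not on the calibration grid")
            setattr(self, name, arr)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                self.mask = None

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.zeros(self.grid.n_points, dtype=bool)
        return self.mask


@dataclass(frozen=True)
class Geometry:
    """Viewing geometry of a station; the glint-avoidance default is
    40 deg off-nadir looking 135 deg away from the sun."""

    sensor_zenith_deg: float = 40.0
    sensor_azimuth_deg: float = 135.0


@dataclass
class StationRecord:
    """One sampling event: paired device (counts) and reference (radiance)
    triplets for the three radiance components at a site."""

    site_id: str
    timestamp: str
    device: dict
    reference: dict
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        for name, triplet, unit in (
            ("device", self.device, Unit.COUNTS_AU),
            ("reference", self.reference, Unit.RADIANCE),
        ):
            if set(triplet) != set(COMPONENTS):
                raise ConfigurationError(
                    f"{name} triplet must contain exactly {COMPONENTS}"
                )
            for comp, s in triplet.items():
                if s.unit is not unit:
                    raise UnitError(
                        f"{name}[{comp}] must be {unit.value}, got {s.unit.value}"
                    )


def _common_integration_time(records: Sequence[StationRecord], component: str):
    times = [
        r.device[component].meta.get("integration_time_ms") for r in records
    ]
    known = [t for t in times if t is not None]
    if not known or len(set(known)) == 1:
        return None  # nothing to normalise
    return float(np.median(known))


def fit_calibration(
    records: Sequence[StationRecord],
    component: str,
    grid: WavelengthGrid = DEFAULT_GRID,
    dark: Optional[Spectrum] = None,
) -> RadiometricCalibration:
    """Fit the per-wavelength linear calibration for one radiance component.

    Device and reference spectra are resampled to ``grid`` (masks propagate);
    at each wavelength an OLS line of reference radiance on device counts is
    fitted across stations using only unmasked pairs.  Wavelengths with fewer
    than two usable pairs are masked in the output.

    If ``dark`` is given (a counts_AU spectrum), it is subtracted from every
    device spectrum before fitting.  If integration times differ across
    records, counts are linearly rescaled to the median integration time
    (linear-detector assumption).
    """
    records = list(records)
    if component not in COMPONENTS:
        raise ConfigurationError(f"unknown component {component!r}")
    if len(records) < 2:
        raise DegenerateInputError("need >= 2 station records to fit a calibration")

    t_common = _common_integration_time(records, component)
    dark_on_grid = None
    if dark is not None:
        if dark.unit is not Unit.COUNTS_AU:
            raise UnitError("dark spectrum must be in counts_AU")
        dark_on_grid = resample(dark, grid).values

    X = np.empty((len(records), grid.n_points))
    Y = np.empty_like(X)
    for i, rec in enumerate(records):
        dev = resample(rec.device[component], grid)
        ref = resample(rec.reference[component], grid)
        x = dev.masked_values()
        if dark_on_grid is not None:
            x = x - dark_on_grid
        if t_common is not None:
            t_i = dev.meta.get("integration_time_ms")
            if t_i:
                x = x * (t_common / float(t_i))
        X[i] = x
        Y[i] = ref.masked_values()

    est = PerWavelengthLinearCalibrator().fit(X, Y)
    return RadiometricCalibration(
        component=component,
        grid=grid,
        gain=est.gain_,
        offset=est.offset_,
        fit_r2=np.where(est.invalid_columns_, np.nan, est.r2_),
        n_samples=len(records),
        mask=est.invalid_columns_,
    )


def apply_calibration(s: Spectrum, cal: RadiometricCalibration) -> Spectrum:
    """Convert a counts spectrum on the calibration grid to radiance."""
    if s.unit is not Unit.COUNTS_AU:
        raise UnitError(f"expected counts_AU input, got {s.unit.value}")
    if not np.array_equal(s.wavelengths, cal.grid.wavelengths()):
        raise GridMismatchError("spectrum is not on the calibration grid")
    values = cal.gain * s.values + cal.offset
    mask = s.effective_mask() | cal.effective_mask()
    meta = dict(s.meta)
    meta["component"] = cal.component
    return Spectrum(
        s.wavelengths.copy(),
        values,
        Unit.RADIANCE,
        mask=mask if mask.any() else None,
        meta=meta,
    )


@dataclass
class LocationReport:
    """Held-out evaluation for one site: one report per radiance component
    plus one for the derived remote-sensing reflectance."""

    site_id: str
    n_stations: int
    reports: dict  # component or "Rrs" -> EvaluationReport


def _calibrated_triplet(
    record: StationRecord,
    cals: dict,
    grid: WavelengthGrid,
    params: ReflectanceParams,
) -> tuple[RadianceTriplet, RadianceTriplet]:
    """Device (calibrated) and reference radiance triplets on the grid."""
    dev, ref = {}, {}
    for comp in COMPONENTS:
        d = resample(record.device[comp], grid)
        dev[comp] = apply_calibration(d, cals[comp])
        ref[comp] = resample(record.reference[comp], grid)
    return (
        RadianceTriplet(dev["Lw"], dev["Lsky"], dev["Lc"], params),
        RadianceTriplet(ref["Lw"], ref["Lsky"], ref["Lc"], params),
    )


def leave_one_location_out(
    records: Sequence[StationRecord],
    grid: WavelengthGrid = DEFAULT_GRID,
    params: ReflectanceParams = ReflectanceParams(),
) -> dict:
    """Leave-one-location-out cross-validation of the full processing chain.

    For each site, the three component calibrations are fitted on every other
    site's stations and applied to the held-out site's device spectra; the
    calibrated radiances and the derived R_rs are compared against the
    reference instrument.  Values are pooled over the held-out site's stations
    and unmasked wavelengths before computing the agreement metrics.

    Returns a mapping site_id -> :class:`LocationReport`.
    """
    records = list(records)
    sites: list[str] = []
    for r in records:
        if r.site_id not in sites:
            sites.append(r.site_id)
    if len(sites) < 2:
        raise DegenerateInputError(
            "leave-one-location-out needs at least 2 distinct sites"
        )

    out: dict[str, LocationReport] = {}
    for site in sites:
        train = [r for r in records if r.site_id != site]
        test = [r for r in records if r.site_id == site]
        if not test:  # pragma: no cover - defensive
            warnings.warn(f"site {site!r} has no records; skipped")
            continue
        cals = {c: fit_calibration(train, c, grid) for c in COMPONENTS}

        pooled_est = {key: [] for key in (*COMPONENTS, "Rrs")}
        pooled_ref = {key: [] for key in (*COMPONENTS, "Rrs")}
        for rec in test:
            dev_t, ref_t = _calibrated_triplet(rec, cals, grid, params)
            pairs = {
                "Lw": (dev_t.Lw, ref_t.Lw),
                "Lsky": (dev_t.Lsky, ref_t.Lsky),
                "Lc": (dev_t.Lc, ref_t.Lc),
                "Rrs": (compute_rrs(dev_t), compute_rrs(ref_t)),
            }
            for key, (d, r) in pairs.items():
                keep = ~(d.effective_mask() | r.effective_mask())
                pooled_est[key].append(d.values[keep])
                pooled_ref[key].append(r.values[keep])

        reports = {}
        for key in (*COMPONENTS, "Rrs"):
            est = np.concatenate(pooled_est[key])
            ref = np.concatenate(pooled_ref[key])
            reports[key] = evaluate_vectors(est, ref, scope="per_spectrum_pair")
        out[site] = LocationReport(site_id=site, n_stations=len(test), reports=reports)
    return out
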