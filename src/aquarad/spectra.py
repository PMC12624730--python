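"""Spectral containers and wavelength-grid resampling.

A :class:`Spectrum` is a strictly increasing wavelength axis (nm) with values,
a physical unit tag, and an optional boolean mask flagging invalid samples
(saturated pixels, detector edge artifacts).  All downstream stages — radiance
calibration, reflectance, band convolution — operate on spectra aligned to a
common :class:`WavelengthGrid`; the default analysis grid is 390–880 nm at
1 nm (491 points), the overlap region of the field instruments involved and
the range typical for aquatic remote sensing.

Resampling is piecewise linear only (no splines, no smoothing) and never
extrapolates: wavelengths outside a spectrum's support are an error, not a
NaN fill, because spectrometer edge regions are a known artifact zone.  Masks
propagate pessimistically — an output sample is masked whenever its linear
interpolation stencil touches a masked input sample — so that saturated or
otherwise invalid raw samples can never leak into a calibration fit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, GridRangeError, UnitError

__all__ = [
    "Unit",
    "WavelengthGrid",
    "DEFAULT_GRID",
    "Spectrum",
    "resample",
    "align_pair",
]


class Unit(str, enum.Enum):
    """Physical unit of a spectrum's values."""

    COUNTS_AU = "counts_AU"      # raw detector counts, arbitrary units
    RADIANCE = "radiance"        # at-sensor radiance (e.g. mW cm-2 um-1 sr-1)
    RRS_PER_SR = "rrs_per_sr"    # remote-sensing reflectance, sr^-1

    @classmethod
    def coerce(cls, value: "Unit | str") -> "Unit":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError as exc:
            raise UnitError(f"unknown unit {value!r}") from exc


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid, closed at both ends.

    The default covers 390–880 nm at 1 nm steps (491 points), including both
    endpoints.
    """

    start: float = 390.0
    stop: float = 880.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise GridRangeError(f"grid step must be > 0, got {self.step}")
        if not self.stop > self.start:
            raise GridRangeError(
                f"grid stop must exceed start, got [{self.start}, {self.stop}]"
            )
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise GridRangeError(
                "grid stop must be start + integer multiple of step; "
                f"got start={self.start}, stop={self.stop}, step={self.step}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


DEFAULT_GRID = WavelengthGrid(390.0, 880.0, 1.0)


@dataclass
class Spectrum:
    """A sampled spectrum: wavelengths (nm), values, unit, optional mask.

    ``mask[i] == True`` marks sample *i* invalid.  ``meta`` carries free-form
    provenance (site, timestamp, component tag, integration time) and does not
    participate in numerical operations.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    unit: Unit
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.unit = Unit.coerce(self.unit)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise DegenerateInputError(
                "a spectrum needs a 1-D wavelength axis with at least 2 samples"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise GridRangeError("wavelengths must be strictly increasing")
        if self.values.shape != self.wavelengths.shape:
            raise DegenerateInputError(
                "values must have the same length as wavelengths"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.wavelengths.shape:
                raise DegenerateInputError(
                    "mask must have the same length as wavelengths"
                )
            if not self.mask.any():
                self.mask = None

    # -- convenience ------------------------------------------------------

    @property
    def n(self) -> int:
        return self.wavelengths.size

    def effective_mask(self) -> np.ndarray:
        """Boolean mask (False = valid), always materialised."""
        if self.mask is None:
            return np.zeros(self.n, dtype=bool)
        return self.mask

    def masked_values(self) -> np.ndarray:
        """Values with masked samples replaced by NaN."""
        out = self.values.copy()
        if self.mask is not None:
            out[self.mask] = np.nan
        return out

    def replace(self, **kwargs) -> "Spectrum":
        fields = dict(
            wavelengths=self.wavelengths,
            values=self.values,
            unit=self.unit,
            mask=self.mask,
            meta=dict(self.meta),
        )
        fields.update(kwargs)
        return Spectrum(**fields)

    def allclose(self, other: "Spectrum", rtol: float = 1e-12, atol: float = 0.0) -> bool:
        return (
            self.unit is other.unit
            and self.n == other.n
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
            and np.array_equal(self.effective_mask(), other.effective_mask())
        )


def resample(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly resample a spectrum onto a uniform grid.

    The grid must lie entirely within the spectrum's support (no
    extrapolation).  Output samples whose two-point interpolation stencil
    touches a masked input sample are masked; a grid point that coincides
    exactly with an input wavelength inherits only that sample's mask.
    """
    wl = grid.wavelengths()
    if wl[0] < spectrum.wavelengths[0] or wl[-1] > spectrum.wavelengths[-1]:
        raise GridRangeError(
            f"grid [{wl[0]}, {wl[-1]}] nm outside spectrum support "
            f"[{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}] nm"
        )
    n_valid = spectrum.n - int(spectrum.effective_mask().sum())
    if n_valid < 2:
        raise DegenerateInputError(
            f"fewer than 2 unmasked samples ({n_valid}) — cannot interpolate"
        )
    values = np.interp(wl, spectrum.wavelengths, spectrum.values)

    mask = None
    if spectrum.mask is not None:
        src = spectrum.mask
        idx = np.searchsorted(spectrum.wavelengths, wl, side="left")
        idx = np.clip(idx, 0, spectrum.n - 1)
        exact = spectrum.wavelengths[idx] == wl
        mask = np.zeros(wl.size, dtype=bool)
        mask[exact] = src[idx[exact]]
        interior = ~exact
        mask[interior] = src[idx[interior] - 1] | src[idx[interior]]

    return Spectrum(wl, values, spectrum.unit, mask=mask, meta=dict(spectrum.meta))


def align_pair(
    a: Spectrum, b: Spectrum, grid: WavelengthGrid = DEFAULT_GRID
) -> tuple[Spectrum, Spectrum]:
    """Resample two same-unit spectra onto one grid and union their masks.

    This is the instrument-alignment step: e.g. a device covering 313–889 nm
    and a reference covering 331–2500 nm are both reduced to the common
    390–880 nm analysis grid before comparison.
    """
    if a.unit is not b.unit:
        raise UnitError(f"cannot align {a.unit.value} with {b.unit.value}")
    ra = resample(a, grid)
    rb = resample(b, grid)
    union = ra.effective_mask() | rb.effective_mask()
    if union.any():
        ra = ra.replace(mask=union.copy())
        rb = rb.replace(mask=union.copy())
    return ra, rb
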