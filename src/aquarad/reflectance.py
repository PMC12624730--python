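"""Remote-sensing reflectance from above-water radiometry.

The above-water (Mobley-style) protocol records three radiances with the same
fore-optics: upwelling water radiance L_w, downwelling sky radiance L_sky, and
the radiance L_c leaving a near-Lambertian reference panel of known
irradiance reflectance R_ref.  Remote-sensing reflectance is then

    R_rs(lambda) = (L_w - rho * L_sky) * R_ref / (pi * c_panel * L_c)

where rho (default 0.02) removes surface-reflected skylight and c_panel
(default 1.01) is a small panel non-ideality correction; the panel converts
measured radiance to downwelling irradiance as E_d = pi * c_panel * L_c / R_ref.
Defaults correspond to a 99 % white Spectralon panel viewed at 40 deg zenith /
135 deg relative azimuth; an 18 % gray card is expressed by R_ref ~ 0.18.

`invert_rrs` is the exact algebraic inverse used by the synthetic campaign's
forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GridMismatchError, UnitError
from .spectra import Spectrum, Unit

__all__ = ["ReflectanceParams", "RadianceTriplet", "compute_rrs", "invert_rrs"]


@dataclass(frozen=True)
class ReflectanceParams:
    """Scalar parameters of the reflectance equation.

    rho : sky-glint (surface reflectance) factor, dimensionless, >= 0.
    panel_correction : multiplicative panel non-ideality factor, > 0.
    panel_reflectance : irradiance reflectance R_ref of the panel, in (0, 1].
    """

    rho: float = 0.02
    panel_correction: float = 1.01
    panel_reflectance: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.panel_reflectance <= 1.0):
            raise ConfigurationError(
                f"panel reflectance must be in (0, 1], got {self.panel_reflectance}"
            )
        if self.rho < 0.0:
            raise ConfigurationError(f"rho must be >= 0, got {self.rho}")
        if not self.panel_correction > 0.0:
            raise ConfigurationError(
                f"panel correction must be > 0, got {self.panel_correction}"
            )


def _check_same_grid(*spectra: Spectrum) -> None:
    ref = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.n != spectra[0].n or not np.array_equal(s.wavelengths, ref):
            raise GridMismatchError("radiance spectra are not on identical grids")


@dataclass
class RadianceTriplet:
    """Co-registered L_w, L_sky, L_c spectra plus the reflectance parameters."""

    Lw: Spectrum
    Lsky: Spectrum
    Lc: Spectrum
    params: ReflectanceParams = field(default_factory=ReflectanceParams)

    def __post_init__(self) -> None:
        for name, s in (("Lw", self.Lw), ("Lsky", self.Lsky), ("Lc", self.Lc)):
            if s.unit is not Unit.RADIANCE:
                raise UnitError(f"{name} must be in radiance units, got {s.unit.value}")
        _check_same_grid(self.Lw, self.Lsky, self.Lc)


def compute_rrs(triplet: RadianceTriplet) -> Spectrum:
    """Remote-sensing reflectance of a radiance triplet, in sr^-1.

    Masks of the three inputs are unioned; wavelengths where L_c <= 0 are
    additionally masked (the panel signal there carries no usable irradiance
    information).
    """
    p = triplet.params
    lw, lsky, lc = triplet.Lw.values, triplet.Lsky.values, triplet.Lc.values
    with np.errstate(divide="ignore", invalid="ignore"):
        rrs = (lw - p.rho * lsky) * p.panel_reflectance / (
            math.pi * p.panel_correction * lc
        )
    mask = (
        triplet.Lw.effective_mask()
        | triplet.Lsky.effective_mask()
        | triplet.Lc.effective_mask()
        | (lc <= 0.0)
    )
    rrs = np.where(lc <= 0.0, np.nan, rrs)
    return Spectrum(
        triplet.Lw.wavelengths.copy(),
        rrs,
        Unit.RRS_PER_SR,
        mask=mask if mask.any() else None,
        meta=dict(triplet.Lw.meta),
    )


def invert_rrs(
    rrs: Spectrum,
    Lsky: Spectrum,
    Lc: Spectrum,
    params: ReflectanceParams = ReflectanceParams(),
) -> Spectrum:
    """Water-leaving radiance L_w that reproduces ``rrs`` exactly.

    The algebraic inverse of :func:`compute_rrs`:
    L_w = rrs * pi * c_panel * L_c / R_ref + rho * L_sky.
    Used as the forward model when synthesising campaigns.
    """
    _check_same_grid(rrs, Lsky, Lc)
    if rrs.unit is not Unit.RRS_PER_SR:
        raise UnitError(f"rrs must be in sr^-1, got {rrs.unit.value}")
    lw = (
        rrs.values * math.pi * params.panel_correction * Lc.values
        / params.panel_reflectance
        + params.rho * Lsky.values
    )
    mask = rrs.effective_mask() | Lsky.effective_mask() | Lc.effective_mask()
    return Spectrum(
        rrs.wavelengths.copy(),
        lw,
        Unit.RADIANCE,
        mask=mask if mask.any() else None,
        meta=dict(rrs.meta),
    )
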