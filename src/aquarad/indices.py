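"""Cyanobacteria bloom spectral indices on satellite band spectra.

Four widely used chlorophyll-a / phycocyanin proxies are expressed through
three generic primitives:

* normalized difference:  (R+ - R-) / (R+ + R-)
    NDCI = ND(708, 665) — the red-edge chlorophyll proxy, in [-1, 1].
* reciprocal three-band:  sign * (1/R(l1) - 1/R(l2)) * R(l3)
    PC3 with (620, 665, 708) targets phycocyanin absorption at 620 nm.  The
    default sign is -1 so that denser blooms (deeper 620 nm absorption) give
    LOWER PC3, matching the direction reported alongside NDCI/CI/PCI in field
    comparisons; the raw published form and sign are configurable.
* spectral shape (baseline subtraction):
    SS(l; l-, l+) = R(l) - R(l-) - (R(l+) - R(l-)) * (l - l-)/(l+ - l-)
    CI  = -SS(681; 665, 708): the Cyanobacteria Index around the 681 nm trough.
    PCI = -SS(620; 560, 665): the Phycocyanin Index around the 620 nm dip;
    sign -1 makes deeper absorption -> larger index.

All band roles and signs are configurable via :class:`IndexDefinition`; the
wavelengths entering the baseline term are the *actual* centers of the bands
matched to each role (e.g. 681.25 / 708.75 nm for OLCI).  Undefined values
(zero denominators, masked bands) propagate as NaN, never exceptions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError
from .bands import BandSpectrum

__all__ = [
    "IndexDefinition",
    "default_index_definitions",
    "normalized_difference",
    "reciprocal_three_band",
    "spectral_shape",
    "compute_all_indices",
    "SpectralIndexTransformer",
    "fit_index_recalibration",
    "apply_index_recalibration",
]

#: Nearest-band matching tolerance in nm (681 matches Oa10 at 681.25, etc.)
BAND_MATCH_TOL = 3.0


def normalized_difference(b: BandSpectrum, plus: float, minus: float) -> float:
    """(R(plus) - R(minus)) / (R(plus) + R(minus)); NaN on zero denominator."""
    rp = b.value_at(plus, BAND_MATCH_TOL)
    rm = b.value_at(minus, BAND_MATCH_TOL)
    denom = rp + rm
    if not math.isfinite(rp) or not math.isfinite(rm) or denom == 0.0:
        return float("nan")
    return (rp - rm) / denom


def reciprocal_three_band(
    b: BandSpectrum, lambda1: float, lambda2: float, lambda3: float, sign: float = 1.0
) -> float:
    """sign * (1/R(lambda1) - 1/R(lambda2)) * R(lambda3); NaN on zero bands."""
    r1 = b.value_at(lambda1, BAND_MATCH_TOL)
    r2 = b.value_at(lambda2, BAND_MATCH_TOL)
    r3 = b.value_at(lambda3, BAND_MATCH_TOL)
    if not all(map(math.isfinite, (r1, r2, r3))) or r1 == 0.0 or r2 == 0.0:
        return float("nan")
    return sign * (1.0 / r1 - 1.0 / r2) * r3


def spectral_shape(
    b: BandSpectrum,
    center: float,
    left: float,
    right: float,
    sign: float = 1.0,
) -> float:
    """Baseline-subtracted band height at ``center`` between ``left``/``right``.

    SS = R(c) - R(l) - (R(r) - R(l)) * (c - l)/(r - l), multiplied by ``sign``;
    the wavelengths are the matched bands' actual centers.
    """
    lc = b.center_at(center, BAND_MATCH_TOL)
    ll = b.center_at(left, BAND_MATCH_TOL)
    lr = b.center_at(right, BAND_MATCH_TOL)
    if lr == ll:
        raise ConfigurationError("spectral_shape flanking bands coincide")
    if not (ll < lc < lr):
        raise ConfigurationError(
            f"spectral_shape needs left < center < right, got {ll}, {lc}, {lr}"
        )
    rc = b.value_at(center, BAND_MATCH_TOL)
    rl = b.value_at(left, BAND_MATCH_TOL)
    rr = b.value_at(right, BAND_MATCH_TOL)
    if not all(map(math.isfinite, (rc, rl, rr))):
        return float("nan")
    return sign * (rc - rl - (rr - rl) * (lc - ll) / (lr - ll))


@dataclass(frozen=True)
class IndexDefinition:
    """A named index: a primitive form, band roles (role -> center nm), a sign."""

    name: str
    form: str  # "normalized_difference" | "reciprocal_three_band" | "spectral_shape"
    bands: dict = field(default_factory=dict)
    sign: float = 1.0

    _ROLES = {
        "normalized_difference": ("plus", "minus"),
        "reciprocal_three_band": ("lambda1", "lambda2", "lambda3"),
        "spectral_shape": ("center", "left", "right"),
    }

    def __post_init__(self) -> None:
        if self.form not in self._ROLES:
            raise ConfigurationError(f"unknown index form {self.form!r}")
        missing = set(self._ROLES[self.form]) - set(self.bands)
        if missing:
            raise ConfigurationError(
                f"index {self.name!r} missing band roles {sorted(missing)}"
            )
        if self.sign not in (-1.0, 1.0, -1, 1):
            raise ConfigurationError("index sign must be +1 or -1")

    def compute(self, b: BandSpectrum) -> float:
        if self.form == "normalized_difference":
            return self.sign * normalized_difference(
                b, self.bands["plus"], self.bands["minus"]
            )
        if self.form == "reciprocal_three_band":
            return reciprocal_three_band(
                b,
                self.bands["lambda1"],
                self.bands["lambda2"],
                self.bands["lambda3"],
                sign=self.sign,
            )
        return spectral_shape(
            b,
            self.bands["center"],
            self.bands["left"],
            self.bands["right"],
            sign=self.sign,
        )


def default_index_definitions() -> list:
    """NDCI, PC3, CI, PCI with their default band roles and signs."""
    return [
        IndexDefinition("NDCI", "normalized_difference",
                        {"plus": 708.0, "minus": 665.0}, sign=1.0),
        IndexDefinition("PC3", "reciprocal_three_band",
                        {"lambda1": 620.0, "lambda2": 665.0, "lambda3": 708.0},
                        sign=-1.0),
        IndexDefinition("CI", "spectral_shape",
                        {"center": 681.0, "left": 665.0, "right": 708.0}, sign=-1.0),
        IndexDefinition("PCI", "spectral_shape",
                        {"center": 620.0, "left": 560.0, "right": 665.0}, sign=-1.0),
    ]


def compute_all_indices(b: BandSpectrum, definitions=None) -> dict:
    """Evaluate each definition; a definition whose bands are missing from the
    band spectrum yields NaN with a warning instead of failing the rest."""
    if definitions is None:
        definitions = default_index_definitions()
    out = {}
    for d in definitions:
        try:
            out[d.name] = d.compute(b)
        except ConfigurationError as exc:
            warnings.warn(f"index {d.name}: {exc}")
            out[d.name] = float("nan")
    return out


class SpectralIndexTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: band-value rows -> index values.

    Parameters
    ----------
    band_centers : array-like
        Centers (nm) of the input columns, strictly increasing.
    band_labels : sequence of str, optional
    sensor_name : str
    definitions : list of IndexDefinition, optional (defaults to NDCI/PC3/CI/PCI)
    """

    def __init__(self, band_centers=None, band_labels=None,
                 sensor_name="bands", definitions=None):
        self.band_centers = band_centers
        self.band_labels = band_labels
        self.sensor_name = sensor_name
        self.definitions = definitions

    def fit(self, X=None, y=None):
        if self.band_centers is None:
            raise ConfigurationError("SpectralIndexTransformer needs band centers")
        centers = np.asarray(self.band_centers, dtype=float)
        labels = (
            list(self.band_labels)
            if self.band_labels is not None
            else [f"{c:g}" for c in centers]
        )
        if len(labels) != centers.size:
            raise ConfigurationError("band labels/centers length mismatch")
        self.centers_ = centers
        self.labels_ = labels
        self.definitions_ = (
            list(self.definitions) if self.definitions is not None
            else default_index_definitions()
        )
        self.n_features_in_ = centers.size
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ConfigurationError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        out = np.empty((X.shape[0], len(self.definitions_)))
        for i, row in enumerate(X):
            mask = ~np.isfinite(row)
            b = BandSpectrum(
                sensor_name=self.sensor_name,
                band_labels=self.labels_,
                centers=self.centers_,
                values=np.nan_to_num(row),
                unit="rrs_per_sr",
                mask=mask if mask.any() else None,
            )
            vals = compute_all_indices(b, self.definitions_)
            out[i] = [vals[d.name] for d in self.definitions_]
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array([d.name for d in self.definitions_])


def fit_index_recalibration(estimates, references) -> tuple[float, float]:
    """Optional vicarious recalibration: OLS (slope, intercept) mapping
    device-derived index values onto reference-derived ones."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    keep = np.isfinite(est) & np.isfinite(ref)
    if keep.sum() < 2:
        raise ConfigurationError("need >= 2 finite pairs to recalibrate an index")
    slope, intercept = np.polyfit(est[keep], ref[keep], 1)
    return float(slope), float(intercept)


def apply_index_recalibration(values, slope: float, intercept: float) -> np.ndarray:
    return slope * np.asarray(values, dtype=float) + intercept
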