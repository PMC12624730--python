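"""Agreement metrics between estimated and reference spectra.

Magnitude metrics (asymmetric in their arguments; the second argument is the
reference):

* R^2 — squared Pearson correlation.
* %NRMSE — RMSE normalised by the reference range (max - min), in percent.
  Mean normalisation is available via ``nrmse_norm="mean"``.
* MAPE — mean absolute percentage error over reference values != 0.
* beta — signed symmetric percentage bias: with Z the median of
  log10(estimate/reference) over strictly positive pairs,
  beta = 100 * sign(Z) * (10^|Z| - 1).  A systematic overestimate gives
  beta > 0; estimate = 2*reference gives exactly +100 %.

Shape metrics (magnitude-blind or distance-like):

* SAM — spectral angle, arccos of the normalised inner product, radians;
  invariant to positive rescaling of either spectrum.
* SID — spectral information divergence, the symmetrised Kullback–Leibler
  divergence between the two spectra normalised to unit sum (values are
  clipped to a small positive epsilon first, since reflectance can touch
  zero at the red/NIR edge); also scale-invariant.
* SED — plain spectral Euclidean distance, scale-*dependent* by design.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "EvaluationReport",
    "magnitude_metrics",
    "shape_metrics",
    "evaluate_vectors",
    "per_wavelength_profile",
]


@dataclass
class EvaluationReport:
    """Bundle of magnitude and shape agreement metrics."""

    scope: str  # "per_wavelength" | "per_spectrum_pair" | "per_index"
    r2: float
    nrmse_pct: float
    mape_pct: float
    beta_pct: float
    sam_rad: Optional[float] = None
    sid: Optional[float] = None
    sed: Optional[float] = None
    n: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _clean_pair(estimate, reference) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimate, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if est.shape != ref.shape:
        raise DegenerateInputError("estimate and reference lengths differ")
    keep = np.isfinite(est) & np.isfinite(ref)
    return est[keep], ref[keep]


def magnitude_metrics(
    estimate,
    reference,
    nrmse_norm: str = "range",
) -> tuple[float, float, float, float]:
    """(r2, nrmse_pct, mape_pct, beta_pct) of estimate against reference.

    NaN entries are dropped pairwise; at least two pairs must remain.
    Undefined quantities (degenerate reference range for NRMSE, no positive
    pairs for beta, zero variance for r2) come back as NaN.
    """
    est, ref = _clean_pair(estimate, reference)
    if est.size < 2:
        raise DegenerateInputError("need >= 2 finite pairs for magnitude metrics")

    de = est - est.mean()
    dr = ref - ref.mean()
    denom = np.sqrt((de**2).sum() * (dr**2).sum())
    r2 = float((de * dr).sum() ** 2 / denom**2) if denom > 0 else float("nan")

    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    if nrmse_norm == "range":
        norm = float(ref.max() - ref.min())
    elif nrmse_norm == "mean":
        norm = float(abs(ref.mean()))
    else:
        raise DegenerateInputError(f"unknown NRMSE normalisation {nrmse_norm!r}")
    nrmse_pct = 100.0 * rmse / norm if norm > 0 else float("nan")

    nz = ref != 0.0
    mape_pct = (
        float(100.0 * np.mean(np.abs(est[nz] - ref[nz]) / np.abs(ref[nz])))
        if nz.any()
        else float("nan")
    )

    pos = (est > 0.0) & (ref > 0.0)
    if pos.any():
        z = float(np.median(np.log10(est[pos] / ref[pos])))
        beta_pct = float(100.0 * np.sign(z) * (10.0 ** abs(z) - 1.0))
    else:
        beta_pct = float("nan")

    return r2, nrmse_pct, mape_pct, beta_pct


def shape_metrics(
    estimate,
    reference,
    sid_eps: float = 1e-8,
) -> tuple[float, float, float]:
    """(sam_rad, sid, sed) between two spectra treated as vectors.

    SAM needs both vectors to have positive norm (otherwise NaN).  For SID
    the spectra are clipped to ``sid_eps`` and normalised to unit sum.
    """
    est, ref = _clean_pair(estimate, reference)
    if est.size < 1:
        raise DegenerateInputError("need >= 1 finite pair for shape metrics")

    ne, nr = np.linalg.norm(est), np.linalg.norm(ref)
    if ne > 0 and nr > 0:
        # chord form 2*arcsin(|u - v|/2): equivalent to arccos of the
        # normalised inner product but exact at identity and stable for
        # near-parallel spectra
        chord = np.linalg.norm(est / ne - ref / nr)
        sam = float(2.0 * np.arcsin(min(1.0, 0.5 * chord)))
    else:
        sam = float("nan")

    p = np.clip(est, sid_eps, None)
    q = np.clip(ref, sid_eps, None)
    p = p / p.sum()
    q = q / q.sum()
    sid = float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))

    sed = float(np.linalg.norm(est - ref))
    return sam, sid, sed


def evaluate_vectors(
    estimate,
    reference,
    scope: str = "per_spectrum_pair",
    nrmse_norm: str = "range",
    sid_eps: float = 1e-8,
) -> EvaluationReport:
    """Full magnitude + shape report for one pair of aligned value vectors."""
    est, ref = _clean_pair(estimate, reference)
    r2, nrmse, mape, beta = magnitude_metrics(est, ref, nrmse_norm=nrmse_norm)
    sam, sid, sed = shape_metrics(est, ref, sid_eps=sid_eps)
    return EvaluationReport(
        scope=scope,
        r2=r2,
        nrmse_pct=nrmse,
        mape_pct=mape,
        beta_pct=beta,
        sam_rad=sam,
        sid=sid,
        sed=sed,
        n=int(est.size),
    )


def per_wavelength_profile(
    estimates: np.ndarray,
    references: np.ndarray,
    wavelengths: np.ndarray,
    nrmse_norm: str = "range",
) -> pd.DataFrame:
    """Magnitude metrics at each wavelength across a stack of spectrum pairs.

    ``estimates`` and ``references`` are (n_pairs, n_wavelengths) arrays with
    NaN marking masked samples; metrics are computed independently per column
    (wavelength), mirroring error-versus-wavelength validation plots.
    Wavelengths with fewer than two usable pairs come back as NaN rows.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if est.shape != ref.shape or est.ndim != 2 or est.shape[1] != wl.size:
        raise DegenerateInputError(
            "expected matching (n_pairs, n_wavelengths) stacks and a wavelength axis"
        )
    if est.shape[0] < 2:
        raise DegenerateInputError("need >= 2 spectrum pairs for a profile")

    rows = []
    for j in range(wl.size):
        keep = np.isfinite(est[:, j]) & np.isfinite(ref[:, j])
        if keep.sum() < 2:
            rows.append((np.nan, np.nan, np.nan, np.nan, int(keep.sum())))
            continue
        r2, nrmse, mape, beta = magnitude_metrics(
            est[keep, j], ref[keep, j], nrmse_norm=nrmse_norm
        )
        rows.append((r2, nrmse, mape, beta, int(keep.sum())))
    return pd.DataFrame(
        rows,
        columns=["r2", "nrmse_pct", "mape_pct", "beta_pct", "n"],
        index=pd.Index(wl, name="wavelength_nm"),
    )
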