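"""Delimited-text and JSON readers/writers for all pipeline artifacts.

Spectra travel as plain text: ``#``-prefixed ``key: value`` header lines
(``unit`` is mandatory; ``domain`` distinguishes wavelength-indexed from raw
pixel-indexed files — never guessed) followed by two or three whitespace
separated columns (wavelength_nm or pixel, value, optional mask 0/1).
Numeric values are written with 17 significant digits, so files round-trip
bit-exactly and identical runs produce identical artifacts.

Campaigns are a ``stations.json`` manifest plus one spectrum file per
component per instrument; calibrations are five-column text files
(wavelength, gain, offset, r2, mask).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .bands import BandSet, RSRTable
from .calibration import (
    COMPONENTS,
    Geometry,
    PixelSpectrum,
    RadiometricCalibration,
    StationRecord,
)
from .errors import ConfigurationError
from .spectra import Spectrum, Unit, WavelengthGrid

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_pixel_spectrum",
    "read_any_spectrum",
    "write_calibration",
    "read_calibration",
    "write_campaign",
    "read_campaign",
    "read_rsr_file",
    "read_band_set_manifest",
]

_FMT = "%.17g"


def _write_table(path: Path, header: dict, columns: Sequence[np.ndarray],
                 names: Sequence[str]) -> None:
    lines = [f"# {k}: {v}" for k, v in header.items()]
    lines.append("# columns: " + " ".join(names))
    data = np.column_stack(columns)
    body = "\n".join(" ".join(_FMT % v for v in row) for row in data)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _read_table(path: Path) -> tuple[dict, np.ndarray]:
    header: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
            continue
        rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ConfigurationError(f"{path}: no data rows")
    return header, np.asarray(rows, dtype=float)


def write_spectrum(path: Union[str, Path], s: Spectrum) -> None:
    """Write a wavelength-indexed spectrum (unit + meta in the header)."""
    path = Path(path)
    header = {"domain": "wavelength", "unit": s.unit.value}
    header.update({k: v for k, v in s.meta.items() if v is not None})
    cols = [s.wavelengths, s.values]
    names = ["wavelength_nm", "value"]
    if s.mask is not None:
        cols.append(s.mask.astype(float))
        names.append("mask")
    _write_table(path, header, cols, names)


def read_spectrum(path: Union[str, Path]) -> Spectrum:
    header, data = _read_table(Path(path))
    if header.get("domain", "wavelength") != "wavelength":
        raise ConfigurationError(
            f"{path}: not a wavelength-indexed spectrum (domain="
            f"{header.get('domain')!r}); use read_any_spectrum"
        )
    if "unit" not in header:
        raise ConfigurationError(f"{path}: missing required 'unit' header")
    mask = data[:, 2].astype(bool) if data.shape[1] >= 3 else None
    meta = {
        k: v for k, v in header.items()
        if k not in {"domain", "unit", "columns"}
    }
    if "integration_time_ms" in meta:
        meta["integration_time_ms"] = float(meta["integration_time_ms"])
    if "saturation_ceiling" in meta:
        meta["saturation_ceiling"] = float(meta["saturation_ceiling"])
    return Spectrum(data[:, 0], data[:, 1], header["unit"], mask=mask, meta=meta)


def write_pixel_spectrum(path: Union[str, Path], px: PixelSpectrum,
                         meta: Optional[dict] = None) -> None:
    """Write a raw pixel-indexed scan (domain: pixel)."""
    header = {
        "domain": "pixel",
        "unit": Unit.COUNTS_AU.value,
        "integration_time_ms": px.integration_time_ms,
        "saturation_ceiling": px.saturation_ceiling,
    }
    if meta:
        header.update(meta)
    _write_table(Path(path), header,
                 [px.pixel_indices.astype(float), px.counts],
                 ["pixel", "counts_AU"])


def read_any_spectrum(path: Union[str, Path]):
    """Read either a wavelength-indexed Spectrum or a pixel-indexed
    PixelSpectrum, decided by the ``domain`` header."""
    header, data = _read_table(Path(path))
    domain = header.get("domain")
    if domain == "pixel":
        return PixelSpectrum(
            data[:, 1],
            integration_time_ms=float(header.get("integration_time_ms", 10.0)),
            saturation_ceiling=float(header.get("saturation_ceiling", 65535.0)),
        )
    if domain == "wavelength":
        return read_spectrum(path)
    raise ConfigurationError(
        f"{path}: header must declare 'domain: wavelength' or 'domain: pixel'"
    )


def write_calibration(path: Union[str, Path], cal: RadiometricCalibration,
                      created: Optional[str] = None) -> None:
    header = {
        "component": cal.component,
        "n_samples": cal.n_samples,
        "grid": f"{cal.grid.start} {cal.grid.stop} {cal.grid.step}",
    }
    if created is not None:
        header["created"] = created
    wl = cal.grid.wavelengths()
    mask = cal.effective_mask().astype(float)
    gain = np.where(np.isfinite(cal.gain), cal.gain, 0.0)
    offset = np.where(np.isfinite(cal.offset), cal.offset, 0.0)
    r2 = np.where(np.isfinite(cal.fit_r2), cal.fit_r2, 0.0)
    _write_table(Path(path), header, [wl, gain, offset, r2, mask],
                 ["wavelength_nm", "gain", "offset", "r2", "mask"])


def read_calibration(path: Union[str, Path]) -> RadiometricCalibration:
    header, data = _read_table(Path(path))
    try:
        start, stop, step = (float(t) for t in header["grid"].split())
        component = header["component"]
        n_samples = int(header["n_samples"])
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing calibration header {exc}") from exc
    grid = WavelengthGrid(start, stop, step)
    mask = data[:, 4].astype(bool)
    gain = np.where(mask, np.nan, data[:, 1])
    offset = np.where(mask, np.nan, data[:, 2])
    r2 = np.where(mask, np.nan, data[:, 3])
    return RadiometricCalibration(
        component=component, grid=grid, gain=gain, offset=offset,
        fit_r2=r2, n_samples=n_samples, mask=mask if mask.any() else None,
    )


def write_campaign(records: Sequence[StationRecord], out_dir: Union[str, Path]) -> Path:
    """Write a campaign directory: spectra/ files plus stations.json manifest."""
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rec in enumerate(records):
        entry = {
            "site_id": rec.site_id,
            "timestamp": rec.timestamp,
            "geometry": {
                "sensor_zenith_deg": rec.geometry.sensor_zenith_deg,
                "sensor_azimuth_deg": rec.geometry.sensor_azimuth_deg,
            },
            "files": {"device": {}, "reference": {}},
        }
        for kind, triplet in (("device", rec.device), ("reference", rec.reference)):
            for comp in COMPONENTS:
                fname = f"{rec.site_id}_st{i:03d}_{kind}_{comp}.txt"
                s = triplet[comp]
                s = s.replace(meta={**s.meta, "site": rec.site_id,
                                    "timestamp": rec.timestamp, "component": comp})
                write_spectrum(spectra_dir / fname, s)
                entry["files"][kind][comp] = f"spectra/{fname}"
        manifest.append(entry)
    (out_dir / "stations.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out_dir


def read_campaign(campaign_dir: Union[str, Path]) -> list:
    campaign_dir = Path(campaign_dir)
    manifest_path = campaign_dir / "stations.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no stations.json manifest in {campaign_dir}")
    manifest = json.loads(manifest_path.read_text())
    records = []
    for entry in manifest:
        device = {c: read_spectrum(campaign_dir / entry["files"]["device"][c])
                  for c in COMPONENTS}
        reference = {c: read_spectrum(campaign_dir / entry["files"]["reference"][c])
                     for c in COMPONENTS}
        geo = entry.get("geometry", {})
        records.append(StationRecord(
            site_id=entry["site_id"],
            timestamp=entry["timestamp"],
            device=device,
            reference=reference,
            geometry=Geometry(
                sensor_zenith_deg=float(geo.get("sensor_zenith_deg", 40.0)),
                sensor_azimuth_deg=float(geo.get("sensor_azimuth_deg", 135.0)),
            ),
        ))
    return records


def read_rsr_file(path: Union[str, Path], band_label: Optional[str] = None,
                  center: Optional[float] = None) -> RSRTable:
    """Read a single-band RSR file: columns (wavelength_nm, response);
    band-label and center may come from the header or the arguments."""
    header, data = _read_table(Path(path))
    label = band_label or header.get("band", Path(path).stem)
    wl, resp = data[:, 0], data[:, 1]
    if center is None:
        c = header.get("center")
        center = float(c) if c is not None else float(wl[np.argmax(resp)])
    return RSRTable(label, center, wl, resp)


def read_band_set_manifest(path: Union[str, Path]) -> BandSet:
    """Build a BandSet from a JSON manifest: {"sensor_name": ..., "bands":
    [{"label": ..., "center": ..., "file": relative path}, ...]}."""
    path = Path(path)
    spec = json.loads(path.read_text())
    bands = [
        read_rsr_file(path.parent / b["file"], band_label=b.get("label"),
                      center=b.get("center"))
        for b in spec["bands"]
    ]
    return BandSet(
        sensor_name=spec.get("sensor_name", path.stem),
        bands=bands,
        excluded_regions=[tuple(r) for r in spec.get("excluded_regions", [])],
    )
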