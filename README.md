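# aquarad

Radiometric processing for low-cost in-situ hyperspectral water radiometry,
aimed at cyanobacterial harmful algal bloom (CyanoHAB) monitoring and ocean
color satellite validation.

Low-cost field spectrometers record raw intensity in arbitrary units over a
pixel axis. To make such an instrument scientifically useful it must be
cross-calibrated against a trusted reference spectroradiometer, its data
reduced to remote-sensing reflectance, and the result connected to the band
space of the satellites that bloom-monitoring algorithms actually run on.
`aquarad` implements that whole chain:

1. **Spectral handling** — wavelength-tagged spectra with saturation masks,
   strictly linear resampling onto a common 390–880 nm, 1 nm analysis grid
   (the aquatic-remote-sensing overlap window of typical device/reference
   pairs), no extrapolation ever.
2. **Radiometric calibration** — a factory polynomial maps pixel index to
   wavelength; then, per wavelength, ordinary least squares of reference
   radiance on device counts across stations yields a gain/offset pair for
   each radiance component (water `L_w`, sky `L_sky`, panel `L_c`).
   Transferability is assessed by leave-one-location-out cross-validation.
3. **Reflectance** — the above-water (Mobley-style) estimate

   `R_rs(λ) = (L_w − ρ·L_sky) · R_ref / (π · c_panel · L_c)`,

   with sky-glint factor ρ = 0.02, panel reflectance R_ref = 0.99 (white
   Spectralon; ≈ 0.18 for a gray card) and panel correction c_panel = 1.01,
   all configurable.
4. **Satellite band simulation** — relative-spectral-response-weighted band
   averaging for a hyperspectral ocean-color sensor's 560/620/665/681/708 nm
   channels and Sentinel-3 OLCI bands Oa06–Oa11 (Gaussian built-ins; official
   RSR tables load from files).
5. **Bloom indices** — NDCI, PC3, CI and PCI through three configurable
   primitives (normalized difference, reciprocal three-band, spectral-shape
   baseline subtraction).
6. **Agreement metrics** — magnitude (R², %NRMSE, MAPE, signed symmetric
   bias β) and spectral shape (SAM, SID, SED), pooled or per wavelength.
7. **Synthetic campaigns** — a generator producing bloom-parameterised
   scenes, forward-modeled radiances and raw device counts (dark offset,
   multiplicative noise, saturation clipping), so every stage is testable
   without field data.

The fittable pieces follow scikit-learn conventions
(`PerWavelengthLinearCalibrator`, `BandConvolver`,
`SpectralIndexTransformer`) and compose in sklearn pipelines; the
domain-level functions wrap them.

## Worked example

Generate a 6-site, 31-station synthetic campaign with 1 % multiplicative
count noise, run leave-one-location-out validation, and compute bloom
indices for one scene:

```python
from aquarad import (generate_campaign, default_instrument,
                     leave_one_location_out, generate_rrs, SceneParams,
                     builtin_band_set, to_band_spectrum, compute_all_indices)

records = generate_campaign(n_sites=6, n_stations=31, seed=7,
                            inst=default_instrument(noise_sd_fraction=0.01))
for site, rep in leave_one_location_out(records).items():
    r = rep.reports["Rrs"]
    print(f"{site}: R2={r.r2:.3f}  NRMSE={r.nrmse_pct:.2f}%  "
          f"beta={r.beta_pct:+.2f}%  SAM={r.sam_rad:.4f} rad")

scene = SceneParams(chl_level=0.8, pc_level=0.8, seed=1)
bands = to_band_spectrum(generate_rrs(scene), builtin_band_set("olci"))
for name, value in compute_all_indices(bands).items():
    print(f"{name:>4}: {value:+.4f}")
```

prints

```
site1: R2=0.999  NRMSE=1.26%  beta=-0.02%  SAM=0.0145 rad
site2: R2=0.999  NRMSE=1.24%  beta=-0.09%  SAM=0.0140 rad
site3: R2=0.999  NRMSE=1.28%  beta=+0.04%  SAM=0.0145 rad
site4: R2=0.999  NRMSE=1.23%  beta=-0.04%  SAM=0.0139 rad
site5: R2=0.999  NRMSE=1.30%  beta=+0.07%  SAM=0.0146 rad
site6: R2=0.999  NRMSE=1.34%  beta=+0.16%  SAM=0.0151 rad
NDCI: +0.4312
 PC3: +0.8518
  CI: +0.0009
 PCI: +0.0011
```

Each held-out site's device-derived R_rs agrees with the reference to ~1 %
normalized RMSE with negligible bias at this noise level — the calibration
transfers across sites. For the strong-bloom scene, the red-edge chlorophyll
proxy NDCI and both baseline-subtraction indices (CI at 681 nm, PCI at the
620 nm phycocyanin dip) are clearly positive; PC3 decreases as phycocyanin
absorption deepens (its default sign is chosen so denser blooms give lower
PC3).

A command-line interface exposes the same chain on file artifacts:

```sh
aquarad run-all --out run/ --seed 7          # synth → calibrate → rrs →
                                             # bands → indices → evaluate → lolo
aquarad synth --out campaign/ --seed 1       # just the synthetic campaign
```

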