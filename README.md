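# jetcurve

Diagnostics of Northern Hemisphere westerly-jet geometry and its imprint on
surface fields such as terrestrial gross primary productivity (GPP).

Upper-level westerlies do not flow zonally: they bend into northward ridges
and southward troughs whose position and intensity organise surface
temperature, precipitation, and hence vegetation productivity over whole
longitudinal sectors. `jetcurve` provides the full chain of tools needed to
quantify that geometry from gridded wind fields and to connect it to surface
impacts:

- **Axis detection** (`jetcurve.jetdetect`) — grayscale morphological
  *closing* then *opening* of daily 200 hPa zonal-wind fields sharpens the
  westerly core and removes isolated high-wind anomalies; the jet axis is
  the latitude of maximum filtered wind at each longitude (0–90°N),
  smoothed with a longitude-periodic ~1000 km running mean.
- **Curvature metrics** (`jetcurve.curvametrics`) — for the axis polyline
  y(x) the signed streamline curvature

      κ(x) = − y″ / (1 + y′²)^{3/2}     [degree⁻¹]

  computed by central differences on the periodic longitude circle, with the
  ridge-positive convention: a northward bulge has κ > 0, a southward trough
  κ < 0. Derived metrics: |κ| (bending regardless of direction), the overall
  curvature √(Σκᵢ²/N) (a hemispheric waviness index), JJA seasonal means,
  and means over eight longitudinal sectors (WE, EE, CA, EA, PA, WN, CN, EN).
- **Statistical layer** (`jetcurve.diagnostics`) — OLS trends with 95%
  confidence intervals (optional AR(1) correction), epoch-mean anomalies for
  reversal detection, detrended Pearson correlation and regression maps of
  gridded fields onto a curvature index with per-cell significance masks,
  managed-vs-natural land-use stratification of |r|, and binned response
  curves with a continuous two-segment (hinge) fit for thresholds such as
  the GPP–Tmax plateau.
- **Attribution** (`jetcurve.attribution`) — single-forcing large-ensemble
  differencing: the contribution of forcing F to a change C is
  ΔC_F = (C_ALL − C_XF)/C_ALL × 100%, with member-level bootstrap 95%
  confidence intervals. Percentages are signed and unclamped.
- **Synthetic truth** (`jetcurve.synthio`) — generators for wind fields with
  a prescribed meandering axis, productivity fields with a known
  coupled-cell mask, and additive forcing ensembles with prescribed
  GHG/AER/BMB responses, so every stage can be verified against ground
  truth without external archives.

Real inputs (ERA5/NCEP/JRA-style winds, gridded GPP and climate fields,
scenario-labelled ensembles) are read from CF-style NetCDF through
`jetcurve.interface.read_gridded`; no data are bundled.

## Worked example

Detect the axis of a synthetic meandering jet (SNR 5, spurious high-wind
patches) over a 92-day season, compute curvature metrics, and attribute a
prescribed 70:20:10 forcing split from synthetic ensembles:

```python
import numpy as np
from jetcurve import synthio, jetdetect, curvametrics, attribution

axis_spec = synthio.JetAxisSpec(base_latitude=45.0,
                                harmonics=((8.0, 2, 0.3), (3.0, 5, 1.2)))
wind_spec = synthio.WindFieldSpec(jet_peak_speed=40.0, jet_width=5.0,
                                  noise_sd=8.0, spurious_patch_rate=2.0,
                                  grid_step=1.0, n_time=92, seed=0)
wind = synthio.generate_wind_field(axis_spec, wind_spec)

axis = jetdetect.detect_axis(wind.u)          # close, open, extract, smooth
profile = curvametrics.pointwise_curvature(axis.mean("time"))
overall = curvametrics.overall_curvature(profile)
sectors = curvametrics.sector_mean(profile)

print(f"overall curvature (RMS kappa): {float(overall.value):.4e} deg^-1")
for name in ("WE", "EE", "CA", "EA"):
    print(f"sector mean kappa {name}: {float(sectors[name]):+.4e} deg^-1")

years = tuple(range(2000, 2080))
t = np.linspace(0.0, 1.0, len(years))
ens = synthio.generate_ensemble(synthio.EnsembleSpec(
    years, {"GHG": 7.0 * t, "AER": 2.0 * t, "BMB": 1.0 * t},
    internal_sd=0.3, seed=0))
res = attribution.attribute_forcings(ens, n_boot=2000, seed=0)
for f in ("GHG", "AER", "BMB"):
    print(f"{f}: {res.contribution[f]:5.1f}% "
          f"[{res.ci_low[f]:5.1f}, {res.ci_high[f]:5.1f}]")
```

Output:

```
overall curvature (RMS kappa): 1.6744e-02 deg^-1
sector mean kappa WE: +2.0210e-03 deg^-1
sector mean kappa EE: -1.2956e-03 deg^-1
sector mean kappa CA: +9.7752e-03 deg^-1
sector mean kappa EA: -1.0213e-02 deg^-1
GHG:  69.9% [ 69.5,  70.4]
AER:  19.9% [ 19.2,  20.5]
BMB:  10.1% [  9.3,  11.0]
```

The season-mean axis bends northward over some sectors (positive sector-mean
κ, e.g. CA here) and southward over others (negative, e.g. EA), reflecting
the prescribed two-harmonic meander; the overall curvature is the RMS
waviness of the whole axis. The attribution recovers the generator's
prescribed 70/20/10 percentage split within the bootstrap intervals.

A command-line interface exposes the same pipeline as subcommands
(`jetcurve simulate | detect | curvature | trend | correlate | attribute`);
each writes NetCDF/CSV/JSON outputs plus a copy of its configuration. Run
`jetcurve <subcommand> --help` for options.

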