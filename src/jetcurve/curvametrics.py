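"""Curvature metrics of the westerly jet axis.

Given the detected axis polyline y(x) — latitude as a function of
longitude, both in degrees — the signed pointwise curvature is

    kappa(x) = - y'' / (1 + y'^2)^(3/2)     [degree^-1]

with derivatives taken by central differences on the periodic longitude
circle.  The leading minus sign is the package's ridge-positive
convention: a northward crest of the axis (y'' < 0) has positive
curvature, a southward trough negative.  The raw differential-geometry
sign (no flip) is available via ``convention="raw"``.

Derived metrics: absolute curvature |kappa| (bending regardless of
direction), the hemispheric overall curvature (root mean square of kappa
over all longitudes — a waviness index), JJA seasonal means, and
longitudinal sector means over a configurable sector scheme.

Coordinates are treated as planar longitude-latitude degrees with no
cos-latitude metric scaling; the curvature is a property of the polyline
in that plane, not a great-circle curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "SectorScheme",
    "PAPER_SECTORS",
    "default_sectors",
    "pointwise_curvature",
    "absolute_curvature",
    "overall_curvature",
    "seasonal_mean",
    "sector_mean",
]

#: Eight-sector longitudinal decomposition of the Northern Hemisphere
#: (west, east) bounds in degrees east on [0, 360); intervals half-open
#: [west, east) and wrapping across 0.
PAPER_SECTORS: dict[str, tuple[float, float]] = {
    "WE": (325.0, 16.5),     # Western Europe, 35W-16.5E
    "EE": (16.5, 47.0),      # Eastern Europe
    "CA": (47.0, 80.25),     # Central Asia
    "EA": (80.25, 120.5),    # Eastern Asia
    "PA": (120.5, 218.25),   # Pacific, 120.5E-141.75W
    "WN": (218.25, 253.25),  # Western North America, 141.75W-106.75W
    "CN": (253.25, 288.25),  # Central North America, 106.75W-71.75W
    "EN": (288.25, 325.0),   # Eastern North America, 71.75W-35W
}


def _norm_lon(x: float) -> float:
    return float(np.mod(x, 360.0))


@dataclass(frozen=True)
class SectorScheme:
    """Named longitudinal sectors tiling the full circle without overlap."""

    sectors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PAPER_SECTORS)
    )

    def __post_init__(self) -> None:
        norm = {
            name: (_norm_lon(w), _norm_lon(e))
            for name, (w, e) in self.sectors.items()
        }
        object.__setattr__(self, "sectors", norm)
        width = sum(self.width(name) for name in norm)
        if not np.isclose(width, 360.0):
            raise ValueError(
                f"sectors must tile the full circle; total width {width:.4f} deg"
            )
        # pairwise-disjoint check at sector midpoints and quarter points
        for name, (w, e) in norm.items():
            for frac in (0.25, 0.5, 0.75):
                probe = _norm_lon(w + frac * self.width(name))
                owners = [n for n in norm if self.contains(n, probe)]
                if owners != [name]:
                    raise ValueError(
                        f"sectors overlap or leave gaps near {probe:.2f} deg E: "
                        f"{owners}"
                    )

    def width(self, name: str) -> float:
        w, e = self.sectors[name]
        return (e - w) % 360.0 if e != w else 360.0

    def contains(self, name: str, lon) -> np.ndarray:
        """Membership of longitude(s) in the half-open interval [west, east)."""
        w, e = self.sectors[name]
        lon = np.mod(np.asarray(lon, dtype=float), 360.0)
        if w < e:
            return (lon >= w) & (lon < e)
        return (lon >= w) | (lon < e)  # wraps through 0


def default_sectors() -> SectorScheme:
    return SectorScheme()


def _require_regular_lon(axis: xr.DataArray) -> float:
    lon = axis.lon.values
    steps = np.diff(lon)
    if not np.allclose(steps, steps[0]):
        raise ValueError("axis longitudes must be uniformly spaced")
    return float(steps[0])


def pointwise_curvature(axis: xr.DataArray,
                        convention: str = "ridge_positive") -> xr.Dataset:
    """Signed curvature kappa and |kappa| per longitude (degree^-1).

    Central differences with periodic wrap at the endpoints (the
    hemisphere is zonally periodic).  Expects the already-smoothed axis on
    a regular longitude grid; kappa itself is not re-smoothed.
    """
    if convention not in ("ridge_positive", "raw"):
        raise ValueError(f"unknown sign convention {convention!r}")
    h = _require_regular_lon(axis)
    y = axis.values
    yp = np.roll(y, -1, axis=-1)
    ym = np.roll(y, 1, axis=-1)
    dy = (yp - ym) / (2.0 * h)
    d2y = (yp - 2.0 * y + ym) / h**2
    kappa = d2y / (1.0 + dy**2) ** 1.5
    if convention == "ridge_positive":
        kappa = -kappa

    coords = dict(axis.coords)
    ds = xr.Dataset(
        {
            "kappa": (axis.dims, kappa,
                      {"units": "degree-1", "sign_convention": convention,
                       "long_name": "signed westerly curvature"}),
            "abs_kappa": (axis.dims, np.abs(kappa),
                          {"units": "degree-1",
                           "long_name": "absolute westerly curvature"}),
        },
        coords=coords,
    )
    return ds


def absolute_curvature(profile: xr.Dataset | xr.DataArray) -> xr.DataArray:
    """Elementwise |kappa|: degree of bending regardless of direction."""
    kappa = profile["kappa"] if isinstance(profile, xr.Dataset) else profile
    out = np.abs(kappa)
    out.name = "abs_kappa"
    out.attrs = {**kappa.attrs, "long_name": "absolute westerly curvature"}
    return out


def overall_curvature(profile: xr.Dataset | xr.DataArray,
                      base_period: tuple | None = None) -> xr.Dataset:
    """Hemispheric overall curvature: RMS of kappa over all longitudes.

    Returns per-time ``value`` = sqrt(mean(kappa^2)) and ``anomaly``
    relative to the mean over ``base_period`` (a (start, stop) time-label
    pair; default the full record).
    """
    kappa = profile["kappa"] if isinstance(profile, xr.Dataset) else profile
    if kappa.sizes.get("lon", 0) < 2:
        raise ValueError("overall curvature needs at least 2 longitude points")
    value = np.sqrt((kappa**2).mean("lon"))
    value.name = "overall_curvature"
    value.attrs = {"units": "degree-1",
                   "long_name": "RMS westerly curvature (waviness index)"}
    if "time" in value.dims:
        base = (value.sel(time=slice(*base_period)) if base_period is not None
                else value)
        clim = base.mean("time")
    else:
        clim = value
    anomaly = value - clim
    anomaly.name = "overall_curvature_anomaly"
    anomaly.attrs = dict(value.attrs)
    return xr.Dataset({"value": value, "anomaly": anomaly})


def seasonal_mean(daily: xr.DataArray, season: str = "JJA",
                  min_coverage: float = 0.8) -> xr.DataArray:
    """Per-year mean of a daily series/profile over a season (default JJA).

    The mean is taken over the daily values within June 1 - August 31 of
    each year (so mean(|kappa|) and |mean(kappa)| stay distinct — the
    caller chooses what to average).  Years covering less than
    ``min_coverage`` of the season's 92 days are set to NaN.
    """
    if season != "JJA":
        raise NotImplementedError("only the JJA season is supported")
    t = pd.DatetimeIndex(daily.time.values)
    sel = daily.sel(time=t.month.isin([6, 7, 8]))
    grouped = sel.groupby("time.year")
    mean = grouped.mean("time")
    counts = grouped.count("time")
    out = mean.where(counts >= min_coverage * 92)
    if out.sizes.get("year", 0) == 0:
        raise ValueError("no JJA days found in the record")
    out.attrs = dict(daily.attrs)
    return out


def sector_mean(profile: xr.Dataset | xr.DataArray,
                scheme: SectorScheme | None = None) -> xr.Dataset:
    """Mean over longitudes within each sector's half-open [west, east).

    Works on any array with a ``lon`` dimension (kappa profiles,
    |kappa| profiles, trend maps); sectors crossing the 0-degree wrap
    (e.g. Western Europe) aggregate across the wrap.
    """
    scheme = scheme or SectorScheme()
    kappa = profile["kappa"] if isinstance(profile, xr.Dataset) else profile
    lon = kappa.lon.values
    out = {}
    for name in scheme.sectors:
        inside = scheme.contains(name, lon)
        if not inside.any():
            raise ValueError(f"sector {name!r} contains no longitude points")
        out[name] = kappa.isel(lon=np.flatnonzero(inside)).mean("lon")
    ds = xr.Dataset(out)
    ds.attrs["sector_bounds_deg_east"] = str(scheme.sectors)
    return ds
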