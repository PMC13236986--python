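"""Morphological filtering of zonal-wind fields and jet-axis extraction.

The westerly jet axis is detected in three stages, mirroring how an image
analyst would clean a noisy intensity field before ridge extraction:

1. grayscale morphological *closing* (dilation then erosion) sharpens the
   coherent high-wind channel by filling narrow weak gaps inside it;
2. grayscale morphological *opening* (erosion then dilation) removes
   isolated high-wind anomalies smaller than the structuring element;
3. the axis is the latitude of maximum filtered zonal wind at each
   longitude — rank filters leave flat plateaus around maxima, so the
   plateau centre is taken by default — followed by a longitude-periodic
   running-mean smoothing over a ~1000 km window.

All operations treat longitude as periodic; latitude edges are handled by
edge replication.  Detection is restricted to the Northern Hemisphere
(0-90 degrees N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "NoDistinctJetError",
    "morphological_close",
    "morphological_open",
    "extract_axis",
    "smooth_axis",
    "detect_axis",
    "smoothing_window_cells",
]

# metres per degree of longitude at the 45N mid-latitude of the jet belt
_KM_PER_DEG_LON_45N = 111.32 * np.cos(np.deg2rad(45.0))


class NoDistinctJetError(ValueError):
    """Raised when a wind column has no distinct maximum (degenerate jet)."""


@dataclass(frozen=True)
class StructuringElement:
    """Centred structuring element: rectangle or disk, spans in grid cells."""

    shape: str = "rectangle"
    span: tuple[int, int] = (5, 5)  # (lat cells, lon cells)

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "disk"):
            raise ValueError(f"unknown element shape {self.shape!r}")
        for s in self.span:
            if s < 1 or s % 2 == 0:
                raise ValueError(f"element spans must be odd and >= 1, got {self.span}")

    def footprint(self) -> np.ndarray:
        ny, nx = self.span
        if self.shape == "rectangle":
            return np.ones((ny, nx), dtype=bool)
        yy, xx = np.mgrid[-(ny // 2): ny // 2 + 1, -(nx // 2): nx // 2 + 1]
        return (yy / max(ny // 2, 1)) ** 2 + (xx / max(nx // 2, 1)) ** 2 <= 1.0


def _apply_morphology(values: np.ndarray, elem: StructuringElement,
                      op) -> np.ndarray:
    """Apply a grayscale morphology op with lon-wrap / lat-edge padding.

    Padding is twice the half-span so that both passes of the compound
    operation (e.g. the erosion following a dilation) see correct
    neighbourhoods everywhere in the cropped interior.
    """
    fp = elem.footprint()
    py, px = 2 * (fp.shape[0] // 2), 2 * (fp.shape[1] // 2)
    if fp.shape[0] > values.shape[-2] or fp.shape[1] > values.shape[-1]:
        raise ValueError(
            f"structuring element {fp.shape} larger than domain {values.shape[-2:]}"
        )
    squeeze = values.ndim == 2
    v = values[None] if squeeze else values
    pad = np.pad(v, ((0, 0), (py, py), (0, 0)), mode="edge")
    pad = np.pad(pad, ((0, 0), (0, 0), (px, px)), mode="wrap")
    out = op(pad, footprint=fp[None])  # time slices filtered independently
    out = out[:, py: py + v.shape[1], px: px + v.shape[2]]
    return out[0] if squeeze else out


def _wrap_field(field: xr.DataArray, values: np.ndarray) -> xr.DataArray:
    out = field.copy(data=values)
    return out


def _check_field(field: xr.DataArray) -> None:
    if np.isnan(field.values).any():
        raise ValueError("missing values inside the detection domain")


def morphological_close(field: xr.DataArray,
                        elem: StructuringElement = StructuringElement()
                        ) -> xr.DataArray:
    """Grayscale closing (dilation then erosion) of a wind field.

    Extensive (``close(f) >= f``) and idempotent; fills narrow low-wind
    gaps inside the westerly channel, sharpening the core structure.
    """
    _check_field(field)
    return _wrap_field(
        field, _apply_morphology(field.values, elem, ndimage.grey_closing)
    )


def morphological_open(field: xr.DataArray,
                       elem: StructuringElement = StructuringElement()
                       ) -> xr.DataArray:
    """Grayscale opening (erosion then dilation) of a wind field.

    Anti-extensive (``open(f) <= f``) and idempotent; removes isolated
    high-wind patches smaller than the structuring element.
    """
    _check_field(field)
    return _wrap_field(
        field, _apply_morphology(field.values, elem, ndimage.grey_opening)
    )


def extract_axis(field: xr.DataArray, *, tie_tol: float = 1e-6,
                 tie_break: str = "midpoint",
                 start_latitude: float = 45.0) -> xr.DataArray:
    """Latitude of maximum zonal wind per longitude column, 0-90 N.

    The field should already be filtered (closing then opening).  Rank
    filters leave exactly-flat plateaus around maxima, so within each
    column all values within ``tie_tol`` of the column maximum count as
    tied.  ``tie_break`` resolves them:

    * ``"midpoint"`` (default): the centre latitude of the contiguous
      tied plateau containing the argmax — the unbiased reading of
      "latitude of maximum" when the maximum is a plateau;
    * ``"continuity"``: the tied latitude closest to the previous
      column's choice (westernmost column: ``start_latitude``), which
      keeps the axis continuous but tends to stick to plateau edges.

    A column where more than half the latitudes tie with the maximum has
    no distinct jet and raises :class:`NoDistinctJetError`.
    """
    if tie_break not in ("midpoint", "continuity"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    f = field.where((field.lat >= 0) & (field.lat <= 90), drop=True)
    lat = f.lat.values
    vals = f.transpose(..., "lat", "lon").values
    squeeze = vals.ndim == 2
    if squeeze:
        vals = vals[None]
    n_time, n_lat, n_lon = vals.shape

    col_max = vals.max(axis=1)
    near = vals >= col_max[:, None, :] - tie_tol
    counts = near.sum(axis=1)
    bad = counts > 0.5 * n_lat
    if bad.any():
        t, j = map(int, np.argwhere(bad)[0])
        raise NoDistinctJetError(
            f"no distinct jet at time index {t}: {counts[t, j]} of {n_lat} "
            f"latitudes tie with the maximum at longitude column {j}"
        )

    if tie_break == "midpoint":
        am = vals.argmax(axis=1)  # (time, lon)
        ii = np.arange(n_lat)[None, :, None]
        # last non-tied index below each row / first above, per column
        below = np.maximum.accumulate(np.where(~near, ii, -1), axis=1)
        above = np.flip(np.minimum.accumulate(
            np.flip(np.where(~near, ii, n_lat), axis=1), axis=1), axis=1)
        ti, tj = np.ogrid[:n_time, :n_lon]
        lo = below[ti, am, tj] + 1
        hi = above[ti, am, tj] - 1
        axis = 0.5 * (lat[lo] + lat[hi])
    else:
        axis = np.empty((n_time, n_lon))
        for t in range(n_time):
            prev = start_latitude
            for j in range(n_lon):
                cand = lat[near[t, :, j]]
                prev = cand[np.argmin(np.abs(cand - prev))]
                axis[t, j] = prev

    out = xr.DataArray(
        axis if not squeeze else axis[0],
        dims=("time", "lon") if not squeeze else ("lon",),
        coords={"lon": f.lon, **({"time": f.time} if not squeeze else {})},
        name="axis_latitude",
        attrs={"units": "degrees_north", "long_name": "westerly jet axis latitude"},
    )
    return out


def smoothing_window_cells(window_km: float, grid_step: float) -> int:
    """Boxcar width in grid columns for a window of ``window_km``.

    Kilometres are converted to degrees of longitude at the 45N reference
    latitude of the jet belt and rounded to the nearest odd integer, so
    the running mean is centred.
    """
    if window_km <= 0:
        raise ValueError("window_km must be > 0")
    w_cells = window_km / (_KM_PER_DEG_LON_45N * grid_step)
    w = int(2 * round((w_cells - 1) / 2) + 1)
    return max(w, 1)


def smooth_axis(axis: xr.DataArray, window_km: float = 1000.0) -> xr.DataArray:
    """Longitude-periodic running mean of the axis over ``window_km``.

    Removes mesoscale wiggles before curvature is computed; the default
    ~1000 km window suppresses features narrower than a synoptic ridge
    or trough while leaving planetary-scale meanders nearly intact.
    """
    lon = axis.lon.values
    grid_step = float(lon[1] - lon[0])
    w = smoothing_window_cells(window_km, grid_step)
    if w * grid_step > 180.0:
        raise ValueError(
            f"smoothing window {window_km} km spans {w * grid_step:.0f} deg "
            "of longitude (> 180 deg)"
        )
    smoothed = ndimage.uniform_filter1d(axis.values, size=w, axis=-1, mode="wrap")
    out = axis.copy(data=smoothed)
    out.attrs["smoothing_window_km"] = window_km
    out.attrs["smoothing_window_cells"] = w
    return out


def detect_axis(field: xr.DataArray,
                elem: StructuringElement = StructuringElement(),
                window_km: float = 1000.0, *,
                tie_tol: float = 1e-6,
                tie_break: str = "midpoint") -> xr.DataArray:
    """Full detection chain: close, open, extract, smooth."""
    filtered = morphological_open(morphological_close(field, elem), elem)
    axis = extract_axis(filtered, tie_tol=tie_tol, tie_break=tie_break)
    return smooth_axis(axis, window_km)
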