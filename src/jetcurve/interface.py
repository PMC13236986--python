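"""I/O and configuration scaffolding for the pipeline.

Gridded fields travel as CF-style NetCDF read into :class:`xarray`
objects, normalised on read to ascending latitude and [0, 360) longitude;
scalar/sector series travel as CSV with a commented metadata header;
attribution tables as JSON.  A :class:`RunConfig` collects every knob of
a pipeline run, validates it up front, and is serialised next to the
outputs so a run can be reproduced from its own artefacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from jetcurve.curvametrics import PAPER_SECTORS, SectorScheme

__all__ = ["RunConfig", "read_gridded", "write_outputs"]


def _check_regular(coord: np.ndarray, name: str) -> None:
    if coord.size < 2:
        return
    steps = np.diff(coord)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-8):
        raise ValueError(
            f"irregular {name} grid: spacing varies from "
            f"{steps.min():.6g} to {steps.max():.6g} degrees"
        )


def read_gridded(path, variable: str, level=None,
                 time_range: tuple | None = None) -> xr.DataArray:
    """Read one variable from a lat-lon NetCDF file, normalising the grid.

    Latitude is returned strictly ascending; longitudes on [-180, 180)
    are remapped to [0, 360) with the values permuted consistently.
    ``level`` selects a vertical level by coordinate label when the
    variable has one; ``time_range`` slices the time axis by label.
    Raises ``KeyError`` listing the available variables when ``variable``
    is absent, and ``ValueError`` on an irregular grid.
    """
    ds = xr.open_dataset(path)
    if variable not in ds:
        raise KeyError(
            f"variable {variable!r} not in {path}; available: "
            f"{sorted(ds.data_vars)}"
        )
    da = ds[variable]
    for cand in ("level", "lev", "plev", "pressure_level"):
        if cand in da.dims:
            if level is None:
                raise ValueError(
                    f"variable has a {cand!r} dimension; pass level="
                )
            da = da.sel({cand: level})
            break
    if time_range is not None and "time" in da.dims:
        da = da.sel(time=slice(*time_range))

    lat_name = "lat" if "lat" in da.dims else "latitude"
    lon_name = "lon" if "lon" in da.dims else "longitude"
    da = da.rename({lat_name: "lat", lon_name: "lon"})
    if da.lat.values[0] > da.lat.values[-1]:
        da = da.isel(lat=slice(None, None, -1))
    lon = np.mod(da.lon.values, 360.0)
    da = da.assign_coords(lon=lon).sortby("lon")
    _check_regular(da.lat.values, "latitude")
    _check_regular(da.lon.values, "longitude")
    if "units" not in da.attrs:
        da.attrs["units"] = "unknown"
    da = da.load()
    ds.close()
    return da


def _csv_header(obj) -> str:
    lines = [f"# jetcurve output",
             f"# convention: ridge-positive curvature, degree^-1"]
    units = getattr(obj, "attrs", {}).get("units")
    if units:
        lines.append(f"# units: {units}")
    return "\n".join(lines) + "\n"


def write_outputs(objects: dict, out_dir) -> list[Path]:
    """Write a dict of named results to ``out_dir`` with stable ordering.

    Dispatch by type: xarray objects -> CF-style NetCDF, pandas objects
    -> CSV with a commented metadata header, dicts/dataclasses -> JSON.
    Returns the written paths, sorted by name so reruns are byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(objects):
        obj = objects[name]
        if isinstance(obj, (xr.Dataset, xr.DataArray)):
            path = out / f"{name}.nc"
            obj.to_netcdf(path, engine="scipy")
        elif isinstance(obj, (pd.DataFrame, pd.Series)):
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(_csv_header(obj))
                obj.to_csv(fh)
        elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            path = out / f"{name}.json"
            payload = _jsonable(dataclasses.asdict(obj))
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        elif isinstance(obj, dict):
            path = out / f"{name}.json"
            path.write_text(json.dumps(_jsonable(obj), indent=2,
                                       sort_keys=True))
        else:
            raise TypeError(f"cannot serialise output {name!r}: {type(obj)}")
        written.append(path)
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunConfig:
    """Validated settings of one pipeline run.

    Conventions baked in here and stamped on outputs: sectors are
    half-open [west, east) intervals on the normalised [0, 360) circle;
    grid indexing is 0-based.
    """

    wind_path: str = ""
    wind_variable: str = "u"
    level: float | None = None
    season: str = "JJA"
    sectors: dict = field(default_factory=lambda: dict(PAPER_SECTORS))
    element_shape: str = "rectangle"
    element_span: tuple = (5, 5)
    window_km: float = 1000.0
    detrend: bool = True
    ar1_adjust: bool = False
    fdr: bool = False
    epochs: tuple = ((1979, 1999), (2000, 2023))
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        SectorScheme(self.sectors)  # raises on overlap/gap
        for s in self.element_span:
            if s < 1 or s % 2 == 0:
                raise ValueError(
                    f"element spans must be odd and >= 1, got {self.element_span}"
                )
        if self.window_km <= 0:
            raise ValueError("window_km must be > 0")
        if self.season != "JJA":
            raise ValueError("only the JJA season is supported")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sectors" in raw:
            raw["sectors"] = {k: tuple(v) for k, v in raw["sectors"].items()}
        if "epochs" in raw:
            raw["epochs"] = tuple(tuple(e) for e in raw["epochs"])
        if "element_span" in raw:
            raw["element_span"] = tuple(raw["element_span"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = _jsonable(dataclasses.asdict(self))
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
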