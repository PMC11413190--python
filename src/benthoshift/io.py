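"""NetCDF and CSV I/O helpers.

NetCDF goes through xarray's scipy backend (classic NetCDF3), which cannot
hold 64-bit integers or booleans — variables are downcast on write. CSV
output uses a fixed float format so identical runs produce byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

FLOAT_FORMAT = "%.10g"


def _netcdf3_safe(ds: xr.Dataset) -> xr.Dataset:
    out = ds.copy()
    for name, var in out.variables.items():
        if var.dtype == np.int64:
            out[name] = var.astype(np.int32)
        elif var.dtype == bool:
            out[name] = var.astype(np.int8)
    for key, val in list(out.attrs.items()):
        if isinstance(val, bool):
            out.attrs[key] = int(val)
    return out


def save_netcdf(obj: xr.Dataset | xr.DataArray, path: str | Path) -> Path:
    path = Path(path)
    ds = obj.to_dataset(name=obj.name or "value") if isinstance(obj, xr.DataArray) else obj
    _netcdf3_safe(ds).to_netcdf(path, engine="scipy")
    return path


def load_netcdf(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def save_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path
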