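"""TIFF raster persistence with sidecar-free georeferencing metadata.

Rasters are written as plain (multiband) TIFFs via :mod:`tifffile`; the
geotransform, nodata value and band names travel as a JSON document in the
ImageDescription tag, so a written raster round-trips through
:func:`read_raster` without auxiliary files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

# GDAL-style geotransform: (x_origin, pixel_w, 0, y_origin, 0, -pixel_h)
DEFAULT_GEOTRANSFORM = (0.0, 30.0, 0.0, 0.0, 0.0, -30.0)


def write_raster(
    path: str | Path,
    data: np.ndarray,
    *,
    geotransform: tuple[float, ...] = DEFAULT_GEOTRANSFORM,
    nodata: float | int | None = None,
    band_names: list[str] | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a (bands, rows, cols) or (rows, cols) array as a TIFF.

    Metadata is serialized to JSON in the ImageDescription tag.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D array, got ndim={data.ndim}")
    meta = {
        "geotransform": list(geotransform),
        "nodata": nodata,
        "band_names": band_names,
    }
    if extra:
        meta.update(extra)
    kwargs = {"photometric": "minisblack"}
    if data.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(path, data, description=json.dumps(meta), **kwargs)
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_raster`.

    Returns ``(data, meta)`` with ``data`` always (bands, rows, cols).
    Plain TIFFs without the JSON tag yield default metadata.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    meta.setdefault("geotransform", list(DEFAULT_GEOTRANSFORM))
    meta.setdefault("nodata", None)
    meta.setdefault("band_names", None)
    if data.ndim == 2:
        data = data[None]
    return data, meta
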