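"""Multiband TIFF raster I/O.

Images are written band-first with the sensor model, band roles, image kind
and panel coordinates serialized as JSON in the TIFF ImageDescription tag,
so a round trip rebuilds the full in-memory object.  Reflectance and
abundance are stored as float32 (computation stays float64); DN images keep
their integer dtype bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .images import AbundanceImage, DNImage, PanelRegion, ReflectanceImage
from .spectra import SensorModel


class RasterFormatError(ValueError):
    """The file's metadata does not describe a raster this package wrote."""


def write_raster(image: ReflectanceImage | DNImage | AbundanceImage, path: str | Path) -> None:
    """Write an image as a multiband TIFF with JSON metadata."""
    if isinstance(image, ReflectanceImage):
        desc = {
            "kind": "reflectance",
            "sensor": image.sensor.to_dict(),
            "meta": image.meta,
        }
        data = image.values.astype(np.float32)
        extra = {"mask": image.mask}
    elif isinstance(image, DNImage):
        desc = {
            "kind": "dn",
            "sensor": image.sensor.to_dict(),
            "bit_depth": image.bit_depth,
            "panels": [
                {"reflectance": p.reflectance, "row0": p.row0, "row1": p.row1,
                 "col0": p.col0, "col1": p.col1}
                for p in image.panels
            ],
            "meta": image.meta,
        }
        data = image.values
        extra = {}
    elif isinstance(image, AbundanceImage):
        desc = {
            "kind": "abundance",
            "endmember_names": list(image.endmember_names),
            "meta": image.meta,
        }
        data = np.concatenate(
            [image.values, image.residual[None]], axis=0
        ).astype(np.float32)
        extra = {"mask": image.mask}
    else:
        raise TypeError(f"cannot write {type(image).__name__}")
    if extra.get("mask") is not None and not np.all(extra["mask"]):
        desc["mask_rows"] = np.flatnonzero(~extra["mask"].ravel()).tolist()
    tifffile.imwrite(path, data, description=json.dumps(desc), photometric="minisblack")


def read_raster(path: str | Path) -> ReflectanceImage | DNImage | AbundanceImage:
    """Read back a raster written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc_raw = tif.pages[0].description
    try:
        desc = json.loads(desc_raw)
    except (TypeError, json.JSONDecodeError):
        raise RasterFormatError(f"{path}: missing or invalid raster metadata") from None
    if data.ndim == 2:
        data = data[None]
    kind = desc.get("kind")
    mask = None
    if "mask_rows" in desc:
        mask = np.ones(data.shape[1] * data.shape[2], dtype=bool)
        mask[np.asarray(desc["mask_rows"], dtype=int)] = False
        mask = mask.reshape(data.shape[1:])
    if kind == "reflectance":
        sensor = SensorModel.from_dict(desc["sensor"])
        return ReflectanceImage(
            values=data.astype(float), sensor=sensor, mask=mask, meta=desc.get("meta", {})
        )
    if kind == "dn":
        sensor = SensorModel.from_dict(desc["sensor"])
        panels = tuple(
            PanelRegion(p["reflectance"], p["row0"], p["row1"], p["col0"], p["col1"])
            for p in desc.get("panels", [])
        )
        return DNImage(
            values=data, sensor=sensor, bit_depth=desc.get("bit_depth", 8),
            panels=panels, meta=desc.get("meta", {}),
        )
    if kind == "abundance":
        names = tuple(desc.get("endmember_names", ("FL", "LF", "SL")))
        return AbundanceImage(
            values=data[: len(names)].astype(float),
            residual=data[len(names)].astype(float),
            mask=mask, endmember_names=names, meta=desc.get("meta", {}),
        )
    raise RasterFormatError(f"{path}: unknown raster kind {kind!r}")
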