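"""Raster and table I/O: TIFF stacks, graph export, stamped outputs.

All rasters are TIFF (labels as integer pages, intensities as 32-bit
float); tables are CSV and summaries JSON.  Conventions recorded in
every output: 0-based pixel indices, pixel-centered coordinates,
half-open regions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .graph import JunctionGraph

CONVENTIONS = ("coordinates: um, x=ML axis; pixels 0-based, centers at "
               "(i+0.5)*pixel_size; regions half-open [origin, origin+size)")


def write_image(path, array: np.ndarray, pixel_size_um: float | None = None,
                as_labels: bool = False) -> None:
    """Write a (T)YX image or movie as (multi-page) TIFF."""
    arr = np.asarray(array)
    if as_labels:
        if arr.max() >= 2**16 or arr.min() < 0:
            raise ValueError("labels out of uint16 range")
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.float32)
    meta = {}
    if pixel_size_um is not None:
        meta = {"resolution": (1.0 / pixel_size_um, 1.0 / pixel_size_um),
                "metadata": {"spacing": pixel_size_um, "unit": "um"}}
    tifffile.imwrite(path, arr, **meta)


def read_image_stack(path, pixel_size_um: float | None = None,
                     expect_labels: bool = False):
    """Read a TIFF (single or multi-page) as (T)YX array plus pixel size.

    Pixel size comes from TIFF resolution metadata unless overridden;
    missing both is an error.  Float-typed files are rejected when a
    label image is expected.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        px = pixel_size_um
        if px is None:
            try:
                res = tf.pages[0].tags["XResolution"].value
                px = res[1] / res[0]
                if px == 1.0:
                    # tifffile's default placeholder resolution; a true
                    # 1 um/px must be passed explicitly
                    px = None
            except (KeyError, ZeroDivisionError, TypeError):
                px = None
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata and no override")
    if expect_labels:
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"{path}: label image must be integer-typed, "
                            f"got {arr.dtype}")
        arr = arr.astype(np.int32)
    else:
        arr = arr.astype(np.float64)
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: expected (T)YX data, got shape {arr.shape}")
    return arr, float(px)


def graph_to_json(graph: JunctionGraph, path) -> None:
    doc = {
        "conventions": CONVENTIONS,
        "pixel_size_um": graph.pixel_size_um,
        "ml_axis": graph.ml_axis,
        "vertices": graph.vertices.to_dict(orient="records"),
        "edges": graph.edges.replace({np.nan: None}).to_dict(orient="records"),
        "cells": graph.cells.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def edge_table_csv(graph: JunctionGraph, path) -> None:
    cols = ["id", "v1", "v2", "cell1", "cell2", "length_um", "angle_deg"]
    graph.edges[cols].to_csv(path, index=False)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stamp(doc: dict, config: dict, seed: int | None) -> dict:
    from . import __version__
    doc = dict(doc)
    doc["provenance"] = {
        "software": f"junctionscope {__version__}",
        "config_hash": config_hash(config),
        "seed": seed,
        "conventions": CONVENTIONS,
    }
    return doc


def write_json(doc: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    Path(path).write_text(json.dumps(doc, indent=1, default=default))
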