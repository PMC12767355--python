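"""Intensity statistics on junction graphs.

Implements the classic junctional quantifications: cytoplasmic
background estimation from circular ROIs, planar-polarity ratios
(mediolateral 0-15 deg vs anterior-posterior 75-90 deg edge bins),
tricellular-junction (TCJ) enrichment ratios, perpendicular line
profiles, mitotic index, and hierarchical region -> embryo -> cohort
aggregation in which each embryo contributes a single value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import RegionSpec, disk_pixel_indices
from .graph import JunctionGraph, skeleton_mask

ML_MAX_DEG = 15.0
AP_MIN_DEG = 75.0


@dataclass
class BackgroundEstimate:
    value: float
    n_rois: int
    roi_radius_um: float


@dataclass
class PolarityResult:
    ml_mean: float          # background-subtracted
    ap_mean: float
    ratio: float
    n_ml: int
    n_ap: int


@dataclass
class TcjMeasurement:
    vertex_id: int
    tcj_mean: float
    edge_means: tuple[float, float, float]
    ratio: float


def estimate_background(image: np.ndarray, graph: JunctionGraph,
                        roi_radius_um: float = 0.5, n_rois: int = 30,
                        seed: int = 0) -> BackgroundEstimate:
    """Mean of per-ROI mean intensities in circular cytoplasmic regions.

    One ROI per sampled cell, placed at the cell-interior point farthest
    from the junctional skeleton (the distance-transform maximum), which
    emulates hand-drawn cytoplasmic ROIs.  ``n_rois`` is clamped to the
    20-40 range used in practice; fewer eligible cells produce a warning
    and a smaller n.
    """
    if graph.label_image is None:
        raise ValueError("graph must carry its label image")
    px = graph.pixel_size_um
    n_rois = int(np.clip(n_rois, 20, 40))
    sk = skeleton_mask(graph.label_image)
    edt = ndimage.distance_transform_edt(~sk) * px
    labs = graph.cells["label"].to_numpy()
    pos = ndimage.maximum_position(edt, labels=graph.label_image, index=labs)
    depth = ndimage.maximum(edt, labels=graph.label_image, index=labs)
    ok = np.asarray(depth) >= roi_radius_um + px
    eligible = [(int(l), p) for l, p, o in zip(labs, pos, ok) if o]
    if len(eligible) < 20:
        warnings.warn(f"only {len(eligible)} cells can host a background ROI")
    rng = np.random.default_rng(seed)
    take = min(n_rois, len(eligible))
    if take == 0:
        raise ValueError("no cell can host a background ROI")
    idx = rng.choice(len(eligible), size=take, replace=False)
    means = []
    for k in idx:
        _, (i, j) = eligible[k]
        center = ((j + 0.5) * px, (i + 0.5) * px)
        rr, cc = disk_pixel_indices(center, roi_radius_um, px, image.shape)
        means.append(float(image[rr, cc].mean()))
    return BackgroundEstimate(value=float(np.mean(means)), n_rois=take,
                              roi_radius_um=roi_radius_um)


def edge_mean_intensity(image: np.ndarray, polyline_um: np.ndarray,
                        pixel_size_um: float, line_width_um: float = 0.9,
                        skeleton: np.ndarray | None = None,
                        exclusion_disks=()) -> float:
    """Mean intensity over pixels within ``line_width_um / 2`` of the edge
    polyline, optionally restricted to the junctional skeleton and with
    circular exclusion zones (e.g. around vertices) removed."""
    px = pixel_size_um
    poly = np.asarray(polyline_um, dtype=float)
    half = max(line_width_um / 2.0, 0.75 * px)
    x0, y0 = poly.min(axis=0) - half - px
    x1, y1 = poly.max(axis=0) + half + px
    j0 = max(int(x0 / px - 0.5), 0)
    j1 = min(int(np.ceil(x1 / px - 0.5)) + 1, image.shape[1])
    i0 = max(int(y0 / px - 0.5), 0)
    i1 = min(int(np.ceil(y1 / px - 0.5)) + 1, image.shape[0])
    if i0 >= i1 or j0 >= j1:
        raise ValueError("edge lies outside the image")
    ii, jj = np.mgrid[i0:i1, j0:j1]
    centers = np.column_stack([(jj.ravel() + 0.5) * px, (ii.ravel() + 0.5) * px])
    d, _ = cKDTree(poly).query(centers)
    sel = d <= half
    if skeleton is not None:
        sel &= skeleton[ii.ravel(), jj.ravel()]
    for c, r in exclusion_disks:
        sel &= np.hypot(centers[:, 0] - c[0], centers[:, 1] - c[1]) > r
    if not sel.any():
        return np.nan
    return float(image[ii.ravel()[sel], jj.ravel()[sel]].mean())


def _edge_vertex_exclusions(graph, row, exclusion_um):
    out = []
    for v in (row.v1, row.v2):
        if v > 0:
            vr = graph.vertices.loc[graph.vertices["id"] == v].iloc[0]
            out.append(((vr.x_um, vr.y_um), exclusion_um))
    return out


def edge_intensity_table(image: np.ndarray, graph: JunctionGraph,
                         line_width_um: float = 0.9,
                         vertex_exclusion_um: float = 1.0) -> pd.DataFrame:
    """Per-edge mean intensity (vertex-proximal 1 um excluded, sampled on
    the junctional skeleton)."""
    sk = skeleton_mask(graph.label_image)
    rows = []
    for row in graph.edges.itertuples():
        mean = edge_mean_intensity(
            image, graph.edge_polylines[row.id], graph.pixel_size_um,
            line_width_um=line_width_um, skeleton=sk,
            exclusion_disks=_edge_vertex_exclusions(graph, row,
                                                    vertex_exclusion_um))
        rows.append((row.id, row.angle_deg, row.length_um, mean))
    return pd.DataFrame(rows, columns=["id", "angle_deg", "length_um", "mean"])


def planar_polarity(image: np.ndarray, graph: JunctionGraph,
                    region: RegionSpec | None, background: float,
                    line_width_um: float = 0.9,
                    vertex_exclusion_um: float = 1.0) -> PolarityResult:
    """ML/AP planar-polarity ratio of junctional intensity.

    Edge bins are closed: [0, 15] deg is mediolateral, [75, 90] deg is
    anterior-posterior; intermediate edges are excluded.  Per-edge means
    are averaged within each bin and the background is subtracted before
    taking the ratio.
    """
    sk = skeleton_mask(graph.label_image)
    ml, ap = [], []
    for row in graph.edges.itertuples():
        if not np.isfinite(row.angle_deg):
            continue
        if row.angle_deg > ML_MAX_DEG and row.angle_deg < AP_MIN_DEG:
            continue
        poly = graph.edge_polylines[row.id]
        if region is not None:
            mid = poly[len(poly) // 2]
            if not region.contains(mid[None, :])[0]:
                continue
        mean = edge_mean_intensity(
            image, poly, graph.pixel_size_um, line_width_um=line_width_um,
            skeleton=sk,
            exclusion_disks=_edge_vertex_exclusions(graph, row,
                                                    vertex_exclusion_um))
        if not np.isfinite(mean):
            continue
        (ml if row.angle_deg <= ML_MAX_DEG else ap).append(mean)
    if not ml or not ap:
        raise ValueError("planar polarity undefined: an angle bin is empty")
    ml_mean = float(np.mean(ml)) - background
    ap_mean = float(np.mean(ap)) - background
    return PolarityResult(ml_mean=ml_mean, ap_mean=ap_mean,
                          ratio=ml_mean / ap_mean, n_ml=len(ml), n_ap=len(ap))


def tcj_ratio(image: np.ndarray, graph: JunctionGraph, vertex_id: int,
              background: float, disk_radius_um: float = 0.5,
              line_width_um: float = 0.9,
              vertex_exclusion_um: float = 1.0) -> TcjMeasurement:
    """Tricellular-junction enrichment ratio.

    ``(TCJ disk mean - bg) / mean(incident bicellular edge means - bg)``
    for an order-3 vertex; edge sampling excludes a zone around vertices
    so the vertex enrichment itself does not contaminate the edge means.
    """
    v = graph.vertices.loc[graph.vertices["id"] == vertex_id]
    if not len(v):
        raise KeyError(f"no vertex {vertex_id}")
    v = v.iloc[0]
    if int(v.order) != 3:
        raise ValueError("tcj_ratio is defined for tricellular (order-3) "
                         f"vertices; vertex {vertex_id} has order {int(v.order)}")
    e = graph.edges[(graph.edges["v1"] == vertex_id)
                    | (graph.edges["v2"] == vertex_id)]
    if len(e) != 3:
        raise ValueError(f"vertex {vertex_id} has {len(e)} resolvable incident "
                         "edges; need exactly 3")
    px = graph.pixel_size_um
    rr, cc = disk_pixel_indices((v.x_um, v.y_um), disk_radius_um, px, image.shape)
    tcj_mean = float(image[rr, cc].mean())
    sk = skeleton_mask(graph.label_image)
    edge_means = []
    for row in e.itertuples():
        m = edge_mean_intensity(
            image, graph.edge_polylines[row.id], px,
            line_width_um=line_width_um, skeleton=sk,
            exclusion_disks=_edge_vertex_exclusions(graph, row,
                                                    vertex_exclusion_um))
        if not np.isfinite(m):
            raise ValueError(f"incident edge {row.id} has no sampleable pixels")
        edge_means.append(m)
    denom = float(np.mean(edge_means)) - background
    return TcjMeasurement(
        vertex_id=int(vertex_id), tcj_mean=tcj_mean,
        edge_means=tuple(edge_means),
        ratio=(tcj_mean - background) / denom,
    )


def line_profile(image: np.ndarray, anchor_um, direction,
                 length_um: float = 3.0, n_samples: int = 31,
                 pixel_size_um: float = 1.0, background: float = 0.0) -> dict:
    """Background-subtracted, max-normalized intensity profile along a
    line of ``length_um`` centered on ``anchor_um``.

    ``direction`` is a (dx, dy) vector or an angle in degrees.  Sampling
    is bilinear.  An all-background line is flagged and returned
    unnormalized.
    """
    if np.isscalar(direction):
        th = np.radians(float(direction))
        d = np.array([np.cos(th), np.sin(th)])
    else:
        d = np.asarray(direction, dtype=float)
        d = d / np.hypot(*d)
    a = np.asarray(anchor_um, dtype=float)
    offs = np.linspace(-length_um / 2, length_um / 2, n_samples)
    pts = a[None, :] + offs[:, None] * d[None, :]
    cols = pts[:, 0] / pixel_size_um - 0.5
    rows = pts[:, 1] / pixel_size_um - 0.5
    if (rows.min() < 0 or cols.min() < 0 or rows.max() > image.shape[0] - 1
            or cols.max() > image.shape[1] - 1):
        raise ValueError("profile line extends outside the image")
    vals = ndimage.map_coordinates(image.astype(float), [rows, cols], order=1)
    vals = vals - background
    peak = vals.max()
    normalized = peak > 0
    if normalized:
        vals = vals / peak
    else:
        warnings.warn("all-background line profile; returned unnormalized")
    return {"offset_um": offs, "profile": vals, "normalized": normalized}


def mitotic_index(ph3_centroids_um: np.ndarray, graph: JunctionGraph,
                  region: RegionSpec) -> float:
    """Fraction of cells in the region with a phospho-histone-H3-positive
    nucleus: n(pH3 centroids in region) / n(cells in region)."""
    cells = graph.cells
    in_region = region.contains(cells[["x_um", "y_um"]].to_numpy())
    n_cells = int(in_region.sum())
    if n_cells == 0:
        raise ValueError("no cells in region; mitotic index undefined")
    pts = np.atleast_2d(np.asarray(ph3_centroids_um, dtype=float)) \
        if np.size(ph3_centroids_um) else np.empty((0, 2))
    n_pos = int(region.contains(pts).sum()) if len(pts) else 0
    return n_pos / n_cells


def cohort_summary(values_by_embryo: dict[str, np.ndarray],
                   dispersion: str = "sem") -> dict:
    """Two-level aggregation: region values -> one mean per embryo ->
    cohort mean with SEM (default) or SD between embryos."""
    if dispersion not in ("sem", "sd"):
        raise ValueError("dispersion must be 'sem' or 'sd'")
    per_embryo = {}
    for embryo, vals in values_by_embryo.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"embryo {embryo!r} has no values; excluded")
            continue
        per_embryo[embryo] = float(np.mean(vals))
    if not per_embryo:
        raise ValueError("no embryo has any values")
    arr = np.array(list(per_embryo.values()))
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    disp = sd / np.sqrt(len(arr)) if dispersion == "sem" else sd
    return {
        "per_embryo_means": per_embryo,
        "cohort_mean": float(np.mean(arr)),
        "dispersion": float(disp),
        "dispersion_type": dispersion,
        "n_embryos": len(arr),
    }
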