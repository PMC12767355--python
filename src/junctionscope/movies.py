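"""Synthetic time-lapse generator: label/intensity movies with scripted
divisions, rosette formation, junctional-gap fates and uniform apical
constriction.

Frames are rendered at a fixed 6-minute interval.  The tissue constricts
uniformly (coordinates scale about the field center so that total apical
area follows the configured checkpoints, linearly interpolated).
Scheduled events, all logged to a truth table:

* divisions -- a parent cell splits across its short axis one frame
  after furrow onset (t0); the daughter interface acquires junctional
  signal after a configurable delay, or never (probability
  ``p_no_new_interface``); with probability ``p_neighbor_gap`` one
  parent-neighbor contact loses junctional signal from t0 on.
* rosettes -- a two-edge internal path contracts to a point, creating a
  5-cell vertex; with probability ``p_rosette_gap`` the vertex carries a
  central gap whose fate (repaired / persistent / expanding) is drawn
  from ``rosette_fate_probs``.

Only divisions beginning in the first 90 minutes are scheduled, matching
the scoring window of the downstream tracker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon
from shapely.ops import split as shapely_split
from skimage.draw import line as draw_line

from .graph import extract_graph
from .mesh import (MeshTopology, contract_short_edges, make_mesh,
                   plan_contractions, rasterize_polygons)
from .synth import GeneratorConfig, render_channels

REPAIRED_GAP_FRAMES = 3          # frames a "repaired" rosette gap persists
EXPANDING_GROWTH_UM_PER_FRAME = 0.25
ROSETTE_GAP_RADIUS_UM = 0.7
MAX_GAP_RADIUS_UM = 3.0


@dataclass
class SyntheticMovie:
    labels: np.ndarray                   # (T, H, W) int32
    channels: dict[str, np.ndarray]      # name -> (T, H, W) float
    times_min: np.ndarray
    truth: pd.DataFrame
    config: GeneratorConfig
    pixel_size_um: float
    graphs: list | None = None           # per-frame junction graphs


def _area_scale(config: GeneratorConfig, t_min: float) -> float:
    """Remaining area fraction at time t (1 at t=0), linear between the
    configured constriction checkpoints."""
    pts = sorted(config.constriction_fraction_at.items())
    if not pts:
        return 1.0
    ts = [0.0] + [p[0] for p in pts]
    fs = [1.0] + [1.0 - p[1] for p in pts]
    return float(np.interp(t_min, ts, fs))


def _split_cell(points: np.ndarray, ring: list[int],
                clearance_um: float = 1.0) -> tuple[np.ndarray, np.ndarray] | None:
    """Split a cell polygon through the centroid, preferring the short
    axis (the cleavage plane runs perpendicular to the cell's long axis).

    The cut is rotated away from orientations whose interface endpoints
    fall within ``clearance_um`` of an existing mesh vertex, which would
    create an artifactual high-order vertex at the new interface end.
    """
    coords = points[ring]
    poly = Polygon(coords)
    if not poly.is_valid or poly.area <= 0:
        return None
    c = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    minor = vecs[:, 0]
    centroid = np.array(poly.centroid.coords[0])
    span = 4.0 * np.sqrt(poly.area)
    base_angle = np.arctan2(minor[1], minor[0])
    for delta_deg in (0, 10, -10, 20, -20, 30, -30, 45, -45, 60, -60, 75, -75, 90):
        th = base_angle + np.radians(delta_deg)
        d = np.array([np.cos(th), np.sin(th)])
        cut = LineString([centroid - span * d, centroid + span * d])
        try:
            parts = shapely_split(poly, cut)
        except Exception:
            continue
        geoms = [g for g in parts.geoms if isinstance(g, Polygon) and g.area > 0]
        if len(geoms) != 2:
            continue
        boundary = poly.exterior.intersection(cut)
        ends = np.array([[p.x, p.y] for p in getattr(boundary, "geoms", [boundary])
                         if p.geom_type == "Point"])
        if len(ends) >= 2:
            dmin = np.min(np.hypot(ends[:, 0][:, None] - coords[:, 0][None, :],
                                   ends[:, 1][:, None] - coords[:, 1][None, :]))
            if dmin < clearance_um:
                continue
        return tuple(np.array(g.exterior.coords)[:-1] for g in geoms)
    return None


def make_timelapse(config: GeneratorConfig, seed: int | None = None,
                   channels: tuple[str, ...] = ("aj",)) -> SyntheticMovie:
    """Generate a fully seeded synthetic movie with event ground truth."""
    n_frames = int(round(config.movie_duration_min / config.frame_interval_min)) + 1
    if n_frames < 2:
        raise ValueError("movie must have at least 2 frames")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    px = config.pixel_size_um
    w, h = config.field_um
    shape = (int(round(h / px)), int(round(w / px)))
    center = np.array([w / 2.0, h / 2.0])

    def order5_free(topology):
        """True when no 5+ vertex reads out at frame 0 or, constriction
        being a pure shrink, at the fully-constricted final frame."""
        for t_min in (0.0, config.movie_duration_min):
            s = np.sqrt(_area_scale(config, t_min))
            polys = [center + s * (topology.points[ring] - center)
                     for ring in topology.rings]
            lab = _rasterize_tissue(polys, [int(l) for l in topology.labels],
                                    shape, px, center, s, config.field_um)
            if (extract_graph(lab, px).vertices["order"] >= 5).any():
                return False
        return True

    topo = None
    for _ in range(8):
        cand = make_mesh(config.n_cells, config.field_um,
                         seed=int(rng.integers(2**31)),
                         relaxation_steps=config.relaxation_steps,
                         pixel_size_um=px, n_order4=config.n_order4,
                         n_order5=config.n_order5)
        cand_topo = cand.topology
        if config.n_order5 == 0:
            # scheduled rosettes must be the only 5+ vertices, so the
            # event truth is complete: collapse sub-resolution edges
            # (close vertex pairs read as one 5-cell vertex once the
            # tissue constricts) and reject the rare mesh that still
            # shows an accidental 5+ vertex
            cand_topo = contract_short_edges(cand_topo, max_len_um=1.0)
            if not order5_free(cand_topo):
                continue
        topo = cand_topo
        break
    if topo is None:
        topo = cand_topo

    # --- schedule rosettes -------------------------------------------------
    _, rosette_groups = plan_contractions(topo, 0, config.rosette_count, rng)
    if len(rosette_groups) < config.rosette_count:
        import warnings
        warnings.warn(f"only {len(rosette_groups)} of {config.rosette_count} "
                      "rosettes could be placed")
    vc = topo.vertex_cells()
    rosette_cells = {c for g in rosette_groups for v in g for c in vc[v]}
    rosettes = []
    fates = list(config.rosette_fate_probs)
    fate_p = np.array([config.rosette_fate_probs[f] for f in fates])
    last_formation = n_frames - 1 - (REPAIRED_GAP_FRAMES + 2)
    for g in rosette_groups:
        t_f = int(rng.integers(2, max(3, last_formation)))
        gapped = rng.random() < config.p_rosette_gap
        fate = fates[int(rng.choice(len(fates), p=fate_p))] if gapped else "no_gap"
        rosettes.append({"group": g, "frame": t_f, "gapped": gapped,
                         "fate": fate,
                         "center": topo.points[list(g)].mean(axis=0)})

    # --- schedule divisions ------------------------------------------------
    border = set(topo.boundary_vertices().tolist())
    eligible = [ci for ci, ring in enumerate(topo.rings)
                if not (set(ring) & border) and ci not in rosette_cells]
    window_h = min(90.0, config.movie_duration_min) / 60.0
    p_div = min(1.0, config.division_rate_per_hour * window_h)
    chosen = [ci for ci in eligible if rng.random() < p_div]
    adjacency: dict[int, set[int]] = {}
    for (a, b), cells in topo.edges().items():
        if len(cells) == 2:
            adjacency.setdefault(cells[0], set()).add(cells[1])
            adjacency.setdefault(cells[1], set()).add(cells[0])
    # neighbor contacts eligible for a scored gap must be substantial
    # boundaries (>= 1.5 um), not sub-pixel slivers
    contact_len: dict[tuple[int, int], float] = {}
    for (a, b), cells in topo.edges().items():
        if len(cells) == 2:
            key = tuple(sorted(cells))
            contact_len[key] = contact_len.get(key, 0.0) + float(
                np.hypot(*(topo.points[a] - topo.points[b])))
    next_label = int(topo.labels.max()) + 1
    divisions = []
    t0_max = int(min(90.0, config.movie_duration_min - config.frame_interval_min)
                 / config.frame_interval_min)
    for ci in chosen:
        parts = _split_cell(topo.points, topo.rings[ci])
        if parts is None:
            continue
        t0 = int(rng.integers(1, t0_max + 1))
        failed = rng.random() < config.p_no_new_interface
        nbr_gap = rng.random() < config.p_neighbor_gap
        nbrs = sorted(n for n in adjacency.get(ci, set())
                      if contact_len.get(tuple(sorted((ci, n))), 0.0) >= 1.5)
        nbr = int(topo.labels[nbrs[int(rng.integers(len(nbrs)))]]) \
            if (nbr_gap and nbrs) else -1
        delay_min = float(np.clip(rng.exponential(config.completion_delay_mean_min),
                                  config.frame_interval_min, 84.0))
        delay_frames = max(1, int(round(delay_min / config.frame_interval_min)))
        divisions.append({
            "cell": ci, "label": int(topo.labels[ci]), "t0": t0,
            "d1": next_label, "d2": next_label + 1,
            "poly1": parts[0], "poly2": parts[1],
            "failed": failed, "neighbor_gap": nbr_gap and nbr > 0,
            "neighbor": nbr,
            "completion_frame": None if failed else t0 + delay_frames,
        })
        next_label += 2

    # --- truth table -------------------------------------------------------
    rows = []
    for r in rosettes:
        rows.append(dict(event="rosette", frame=r["frame"],
                         x_um=r["center"][0], y_um=r["center"][1],
                         label=-1, gapped=r["gapped"], fate=r["fate"],
                         failed=False, neighbor_gap=False, neighbor=-1,
                         daughter1=-1, daughter2=-1, completion_frame=-1))
    for d in divisions:
        rows.append(dict(event="division", frame=d["t0"],
                         x_um=np.mean(d["poly1"][:, 0]),
                         y_um=np.mean(d["poly1"][:, 1]),
                         label=d["label"], gapped=False, fate="",
                         failed=d["failed"], neighbor_gap=d["neighbor_gap"],
                         neighbor=d["neighbor"],
                         daughter1=d["d1"], daughter2=d["d2"],
                         completion_frame=(-1 if d["completion_frame"] is None
                                           else d["completion_frame"])))
    truth = pd.DataFrame(rows)

    # --- render frames -----------------------------------------------------
    times = np.arange(n_frames) * config.frame_interval_min
    labels_mov = np.zeros((n_frames,) + shape, dtype=np.int32)
    chan_mov = {ch: np.zeros((n_frames,) + shape, dtype=np.float32)
                for ch in channels}
    graphs = []

    for f in range(n_frames):
        t_min = times[f]
        scale = np.sqrt(_area_scale(config, t_min))
        active = [r["group"] for r in rosettes if f >= r["frame"]]
        topo_f = topo.contracted(active) if active else topo
        polys, labs = [], []
        divided = {d["cell"]: d for d in divisions if f >= d["t0"] + 1}
        for ci, ring in enumerate(topo_f.rings):
            if ci in divided:
                d = divided[ci]
                polys.extend([d["poly1"], d["poly2"]])
                labs.extend([d["d1"], d["d2"]])
            else:
                polys.append(topo_f.points[ring])
                labs.append(int(topo_f.labels[ci]))
        polys = [center + scale * (p - center) for p in polys]
        lab = _rasterize_tissue(polys, labs, shape, px, center, scale,
                                config.field_um)
        labels_mov[f] = lab

        suppressed = set()
        for d in divisions:
            if f >= d["t0"] + 1:
                cf = d["completion_frame"]
                if cf is None or f < cf:
                    suppressed.add((d["d1"], d["d2"]))
            if d["neighbor_gap"] and f >= d["t0"]:
                suppressed.update({(d["label"], d["neighbor"]),
                                   (d["d1"], d["neighbor"]),
                                   (d["d2"], d["neighbor"])})
        voids = []
        for r in rosettes:
            if not r["gapped"] or f < r["frame"]:
                continue
            age = f - r["frame"]
            if r["fate"] == "repaired" and age >= REPAIRED_GAP_FRAMES:
                continue
            radius = ROSETTE_GAP_RADIUS_UM
            if r["fate"] == "expanding":
                radius = min(MAX_GAP_RADIUS_UM,
                             radius + EXPANDING_GROWTH_UM_PER_FRAME * age)
            pos = center + scale * (r["center"] - center)
            voids.append(((float(pos[0]), float(pos[1])), float(radius)))

        graph_f = extract_graph(lab, px)
        graphs.append(graph_f)
        imgs = render_channels(lab, config, graph=graph_f, channels=channels,
                               suppressed_pairs=suppressed, voids=voids,
                               add_noise=False)
        # furrow onset: draw the cleavage chord (figure-8 outline) at t0
        for d in divisions:
            if f == d["t0"]:
                chord = _interface_chord(d, center, scale)
                _paint_segment(imgs, chord, px,
                               config.background_level + config.edge_intensity_base)
        for ch in channels:
            img = imgs[ch]
            if config.noise_sd > 0:
                img = np.clip(img + rng.normal(0.0, config.noise_sd, img.shape),
                              0.0, None)
            chan_mov[ch][f] = img

    return SyntheticMovie(labels=labels_mov, channels=chan_mov,
                          times_min=times.astype(float), truth=truth,
                          config=config, pixel_size_um=px, graphs=graphs)


def _rasterize_tissue(polys, labs, shape, px, center, scale, field_um):
    """Rasterize scaled polygons; gap-filling is restricted to the scaled
    tissue box so the border band stays 0 (outside the tissue)."""
    lab = rasterize_polygons(polys, labs, shape, px)
    w, h = field_um
    x0, x1 = center[0] - scale * w / 2, center[0] + scale * w / 2
    y0, y1 = center[1] - scale * h / 2, center[1] + scale * h / 2
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    inside = (((jj + 0.5) * px >= x0) & ((jj + 0.5) * px < x1)
              & ((ii + 0.5) * px >= y0) & ((ii + 0.5) * px < y1))
    lab[~inside] = 0
    return lab


def _interface_chord(division, center, scale):
    """Endpoints of the daughter interface (shared boundary of the two
    split polygons), in image coordinates."""
    p1 = division["poly1"]
    p2 = division["poly2"]
    from scipy.spatial import cKDTree
    d, idx = cKDTree(p2).query(p1)
    shared = p1[d < 1e-6]
    if len(shared) < 2:
        return None
    dd = np.hypot(shared[:, 0][:, None] - shared[:, 0][None, :],
                  shared[:, 1][:, None] - shared[:, 1][None, :])
    i, j = np.unravel_index(np.argmax(dd), dd.shape)
    a, b = shared[i], shared[j]
    return (center + scale * (a - center), center + scale * (b - center))


def _paint_segment(imgs, chord, px, value):
    if chord is None:
        return
    a, b = chord
    shape = next(iter(imgs.values())).shape
    r0, c0 = int(a[1] / px - 0.5), int(a[0] / px - 0.5)
    r1, c1 = int(b[1] / px - 0.5), int(b[0] / px - 0.5)
    r0, c0 = np.clip(r0, 0, shape[0] - 1), np.clip(c0, 0, shape[1] - 1)
    r1, c1 = np.clip(r1, 0, shape[0] - 1), np.clip(c1, 0, shape[1] - 1)
    rr, cc = draw_line(r0, c0, r1, c1)
    for img in imgs.values():
        img[rr, cc] = value
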