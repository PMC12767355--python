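"""Polygonal cell meshes: Lloyd-relaxed Voronoi tilings with optional
higher-order (4-cell and 5+-cell) vertices created by edge contraction.

The mesh is the geometric ground truth behind every synthetic image.
``make_mesh`` produces a ``CellMesh`` whose label image is a full tiling
(labels >= 1 meet each other directly; 0 is reserved for "outside the
tissue" in time-lapse rendering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

DEFAULT_PIXEL_SIZE_UM = 0.3


@dataclass
class MeshTopology:
    """Index-based half-edge-free mesh: vertex coordinates plus one
    counter-clockwise vertex ring per cell."""

    points: np.ndarray              # (V, 2) um
    rings: list[list[int]]          # per cell, ordered vertex indices
    labels: np.ndarray              # (C,) int cell labels >= 1
    field_um: tuple[float, float] = (0.0, 0.0)

    def vertex_cells(self) -> dict[int, list[int]]:
        """vertex index -> list of cell positions using it."""
        out: dict[int, list[int]] = {}
        for ci, ring in enumerate(self.rings):
            for v in ring:
                out.setdefault(v, []).append(ci)
        return out

    def edges(self) -> dict[tuple[int, int], list[int]]:
        """undirected vertex-pair edge -> list of cell positions sharing it."""
        out: dict[tuple[int, int], list[int]] = {}
        for ci, ring in enumerate(self.rings):
            n = len(ring)
            for k in range(n):
                a, b = ring[k], ring[(k + 1) % n]
                key = (a, b) if a < b else (b, a)
                out.setdefault(key, []).append(ci)
        return out

    def boundary_vertices(self, tol: float = 1e-6) -> np.ndarray:
        w, h = self.field_um
        p = self.points
        return np.where(
            (p[:, 0] < tol) | (p[:, 0] > w - tol)
            | (p[:, 1] < tol) | (p[:, 1] > h - tol)
        )[0]

    def contracted(self, groups: list[list[int]]) -> "MeshTopology":
        """Merge each vertex group to its centroid; rings are remapped and
        consecutive duplicates removed."""
        mapping = np.arange(len(self.points))
        new_points = self.points.copy()
        for g in groups:
            tgt = min(g)
            new_points[tgt] = self.points[list(g)].mean(axis=0)
            for v in g:
                mapping[v] = tgt
        rings = []
        for ring in self.rings:
            m = [int(mapping[v]) for v in ring]
            dedup = [v for k, v in enumerate(m) if v != m[k - 1]]
            rings.append(dedup)
        return MeshTopology(new_points, rings, self.labels.copy(), self.field_um)

    def polygons(self) -> dict[int, Polygon]:
        return {
            int(lab): Polygon(self.points[ring])
            for lab, ring in zip(self.labels, self.rings)
            if len(ring) >= 3
        }


@dataclass
class CellMesh:
    """Rasterized tiling plus its generating topology.

    ``label_image`` is a full tiling of integer labels >= 1; the
    junctional skeleton is implicit as the inter-label boundary.
    """

    label_image: np.ndarray
    pixel_size_um: float
    field_um: tuple[float, float]
    cell_polygons: dict[int, Polygon]
    topology: MeshTopology | None = field(default=None, repr=False)

    @property
    def shape(self):
        return self.label_image.shape


def _lloyd_points(n_cells, field_um, rng, steps):
    """Lloyd relaxation on a coarse raster: seeds move to the centroid of
    their nearest-seed region, yielding near-centroidal packing."""
    w, h = field_um
    pts = np.column_stack([rng.uniform(0, w, n_cells), rng.uniform(0, h, n_cells)])
    # coarse grid: ~2 samples per expected cell diameter is enough
    res = max(64, int(4 * np.sqrt(n_cells)))
    gx = (np.arange(res) + 0.5) * (w / res)
    gy = (np.arange(res) + 0.5) * (h / res)
    gxx, gyy = np.meshgrid(gx, gy)
    grid = np.column_stack([gxx.ravel(), gyy.ravel()])
    from scipy.spatial import cKDTree
    for _ in range(steps):
        _, owner = cKDTree(pts).query(grid)
        cnt = np.bincount(owner, minlength=n_cells).astype(float)
        sx = np.bincount(owner, weights=grid[:, 0], minlength=n_cells)
        sy = np.bincount(owner, weights=grid[:, 1], minlength=n_cells)
        nz = cnt > 0
        pts[nz, 0] = sx[nz] / cnt[nz]
        pts[nz, 1] = sy[nz] / cnt[nz]
    return pts


def _clipped_voronoi(points, field_um):
    """Voronoi diagram clipped exactly to the field box via mirroring."""
    w, h = field_um
    p = points
    mirrored = np.vstack([
        p,
        np.column_stack([-p[:, 0], p[:, 1]]),
        np.column_stack([2 * w - p[:, 0], p[:, 1]]),
        np.column_stack([p[:, 0], -p[:, 1]]),
        np.column_stack([p[:, 0], 2 * h - p[:, 1]]),
    ])
    vor = Voronoi(mirrored)
    rings = []
    for i in range(len(p)):
        region = vor.regions[vor.point_region[i]]
        assert -1 not in region and len(region) >= 3
        rings.append(list(region))
    # compact vertex array to the used subset
    used = sorted({v for ring in rings for v in ring})
    remap = {v: k for k, v in enumerate(used)}
    pts = vor.vertices[used]
    pts[:, 0] = np.clip(pts[:, 0], 0.0, w)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, h)
    rings = [[remap[v] for v in ring] for ring in rings]
    # enforce ccw orientation
    for ring in rings:
        poly = pts[ring]
        area2 = np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                       - np.roll(poly[:, 0], -1) * poly[:, 1])
        if area2 < 0:
            ring.reverse()
    labels = np.arange(1, len(rings) + 1)
    return MeshTopology(pts, rings, labels, (float(w), float(h)))


def _eligible_order4_edges(topo: MeshTopology):
    """Internal edges between two internal 3-cell vertices whose flanking
    cells keep >= 4 vertices after contraction."""
    vc = topo.vertex_cells()
    border = set(topo.boundary_vertices().tolist())
    ring_len = [len(r) for r in topo.rings]
    out = []
    for (a, b), cells in topo.edges().items():
        if len(cells) != 2 or a in border or b in border:
            continue
        if len(vc.get(a, [])) != 3 or len(vc.get(b, [])) != 3:
            continue
        if min(ring_len[c] for c in cells) < 4:
            continue
        length = float(np.hypot(*(topo.points[a] - topo.points[b])))
        out.append(((a, b), length))
    return out


def plan_contractions(topo: MeshTopology, n_order4: int, n_order5: int,
                      rng: np.random.Generator):
    """Choose disjoint vertex groups whose contraction yields the requested
    numbers of 4-cell vertices (one edge collapsed) and 5+-cell vertices
    (a two-edge path collapsed).  Short edges are preferred, mimicking
    T1-like configurations."""
    edges = topo.edges()
    vc = topo.vertex_cells()
    ring_len = [len(r) for r in topo.rings]
    elig = _eligible_order4_edges(topo)
    elig.sort(key=lambda t: t[1])
    # mild randomization of the shortest-first order
    idx = np.arange(len(elig))
    jitter = rng.normal(0, max(2.0, len(elig) * 0.05), size=len(elig))
    order = np.argsort(idx + jitter)

    used: set[int] = set()
    adjacency: dict[int, set[int]] = {}
    for (a, b) in edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    groups4: list[list[int]] = []
    groups5: list[list[int]] = []

    # order-5: collapse a path a-m-b of two eligible edges
    border = set(topo.boundary_vertices().tolist())
    pool5 = [elig[i][0] for i in order]
    for (a, m) in pool5:
        if len(groups5) >= n_order5:
            break
        if a in used or m in used:
            continue
        # find third vertex b adjacent to m, internal, 3-cell, unused
        cands = [b for b in adjacency[m]
                 if b not in (a,) and b not in used
                 and len(vc.get(b, [])) == 3
                 and b not in border]
        ok = None
        for b in cands:
            key2 = (m, b) if m < b else (b, m)
            cells2 = edges.get(key2, [])
            if len(cells2) != 2:
                continue
            trio = {a, m, b}
            if (adjacency[a] | adjacency[m] | adjacency[b]) & used:
                continue
            # every incident cell must survive losing the collapsed vertices
            bad = False
            for c in set(vc[a] + vc[m] + vc[b]):
                lost = len(trio & set(topo.rings[c]))
                if ring_len[c] - (lost - 1) < 3:
                    bad = True
                    break
            if not bad:
                ok = b
                break
        if ok is not None:
            groups5.append([a, m, ok])
            used.update((a, m, ok))

    # order-4: collapse single edges
    for i in order:
        if len(groups4) >= n_order4:
            break
        a, b = elig[i][0]
        if a in used or b in used:
            continue
        if (adjacency[a] | adjacency[b]) & used:
            continue
        cells = edges[(a, b)]
        if min(ring_len[c] for c in cells) < 4:
            continue
        groups4.append([a, b])
        used.update((a, b))

    return groups4, groups5


def contract_short_edges(topo: MeshTopology, max_len_um: float) -> MeshTopology:
    """Contract every isolated short internal edge into a 4-cell vertex.

    Sub-resolution edges read ambiguously once rasterized (two 3-cell
    vertices under one sampling disk look like a 5-cell vertex), so
    movies collapse them up front.  Only edges whose endpoints are
    3-cell internal vertices are touched, and never two adjacent ones,
    so no vertex of order > 4 can be created.
    """
    elig = [(pair, ln) for pair, ln in _eligible_order4_edges(topo)
            if ln < max_len_um]
    elig.sort(key=lambda t: t[1])
    used: set[int] = set()
    adjacency: dict[int, set[int]] = {}
    for (a, b) in topo.edges():
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    groups = []
    for (a, b), _ in elig:
        if a in used or b in used:
            continue
        if (adjacency[a] | adjacency[b]) & used:
            continue
        groups.append([a, b])
        used.update((a, b))
    return topo.contracted(groups) if groups else topo


def rasterize_polygons(polys: list[np.ndarray], labels, shape, pixel_size_um):
    """Fill each polygon's pixels (centers inside); unassigned boundary
    pixels are claimed by the nearest labeled pixel so the tiling is
    complete."""
    lab = np.zeros(shape, dtype=np.int32)
    px = pixel_size_um
    for coords, label in zip(polys, labels):
        rr, cc = draw_polygon(coords[:, 1] / px - 0.5, coords[:, 0] / px - 0.5,
                              shape=shape)
        lab[rr, cc] = label
    if (lab == 0).any():
        _, (ir, ic) = ndimage.distance_transform_edt(lab == 0, return_indices=True)
        lab = lab[ir, ic]
    return clean_label_image(lab)


def clean_label_image(lab: np.ndarray) -> np.ndarray:
    """Make the tiling a proper planar partition: every label one
    4-connected region and no checkerboard point contacts."""
    from skimage.measure import label as cc_label
    for _ in range(8):
        lab = resolve_checkerboards(lab)
        # one global 4-connected labeling; a cell is fragmented when two
        # components share its label -- keep only the largest per label
        comp = cc_label(lab, connectivity=1, background=0)
        nc = comp.max()
        if nc == 0:
            break
        comp_sizes = np.bincount(comp.ravel(), minlength=nc + 1)
        flat_pos = np.flatnonzero(comp.ravel())
        comp_lab = np.zeros(nc + 1, dtype=lab.dtype)
        comp_lab[comp.ravel()[flat_pos]] = lab.ravel()[flat_pos]
        order = np.lexsort((comp_sizes[1:], comp_lab[1:]))
        keep = np.zeros(nc + 1, dtype=bool)
        # the last entry per label in lexsort order is its largest component
        labs_sorted = comp_lab[1:][order]
        last = np.r_[labs_sorted[1:] != labs_sorted[:-1], True]
        keep[1 + order[last]] = True
        stray = ~keep[comp] & (comp > 0)
        if not stray.any():
            break
        lab = lab.copy()
        lab[stray] = 0
        _, (ir, ic) = ndimage.distance_transform_edt(lab == 0,
                                                     return_indices=True)
        lab = lab[ir, ic]
    return lab


def resolve_checkerboards(lab: np.ndarray) -> np.ndarray:
    """Break checkerboard (diagonal point-contact) pixel corners.

    A 2x2 window [[a, b], [b, a]] leaves the planar topology ambiguous
    (both diagonals "cross"); flipping one pixel decides the contact and
    makes the tiling a proper planar subdivision.  Iterates until clean.
    """
    lab = lab.copy()
    for _ in range(8):
        a = lab[:-1, :-1]
        b = lab[:-1, 1:]
        c = lab[1:, :-1]
        d = lab[1:, 1:]
        chk = (a == d) & (b == c) & (a != b)
        ii, jj = np.nonzero(chk)
        if not len(ii):
            break
        lab[ii, jj + 1] = lab[ii, jj]     # top-right joins the main diagonal
    return lab


def rasterize_topology(topo: MeshTopology, pixel_size_um: float) -> np.ndarray:
    w, h = topo.field_um
    shape = (int(round(h / pixel_size_um)), int(round(w / pixel_size_um)))
    polys = [topo.points[ring] for ring in topo.rings]
    return rasterize_polygons(polys, topo.labels, shape, pixel_size_um)


def make_mesh(n_cells: int, field_um, seed: int, relaxation_steps: int = 3,
              pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
              n_order4: int = 0, n_order5: int = 0) -> CellMesh:
    """Generate a Lloyd-relaxed Voronoi tiling of ``n_cells`` cells.

    ``n_order4``/``n_order5`` request that many higher-order vertices,
    created by contracting short internal edges (one edge -> a 4-cell
    vertex; a two-edge path -> a 5-cell vertex).  Deterministic for a
    fixed seed.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    field_um = (float(field_um[0]), float(field_um[1]))
    shape = (int(round(field_um[1] / pixel_size_um)),
             int(round(field_um[0] / pixel_size_um)))
    if min(shape) < 3:
        raise ValueError("degenerate field: each dimension must be >= 3 px")
    mean_diam = 2.0 * np.sqrt(field_um[0] * field_um[1] / n_cells / np.pi)
    if min(field_um) < 3 * mean_diam / 2:
        raise ValueError("field too small relative to cell size")
    rng = np.random.default_rng(seed)
    pts = _lloyd_points(n_cells, field_um, rng, relaxation_steps)
    topo = _clipped_voronoi(pts, field_um)
    if n_order4 or n_order5:
        g4, g5 = plan_contractions(topo, n_order4, n_order5, rng)
        topo = topo.contracted(g4 + g5)
    label_image = rasterize_topology(topo, pixel_size_um)
    return CellMesh(
        label_image=label_image,
        pixel_size_um=pixel_size_um,
        field_um=field_um,
        cell_polygons=topo.polygons(),
        topology=topo,
    )
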