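"""Synthetic epithelium generator: ground-truthed label images and
junctional intensity channels.

The generator emulates the statistical structure of confocal images of
an apical epithelial surface: a polygonal cell tiling, a junctional
marker (adherens-junction channel, "aj") drawn along cell-cell
boundaries with a configurable mediolateral/anterior-posterior polarity
factor and tricellular-vertex enrichment over a cytoplasmic background,
an optional tight-junction channel ("tj"), vertex-order-dependent
circular gaps in junctional signal, and additive Gaussian noise.

Rendering rules (noise-free) are exactly invertible by the analysis
modules, which is what the parameter-recovery tests exploit:

* a boundary pixel of an edge with folded angle <= 15 deg (an ML edge)
  has value ``background + polarity_factor * edge_intensity_base``;
  every other boundary pixel has ``background + edge_intensity_base``;
* a vertex disk (radius ``vertex_disk_radius_um``) has value
  ``background + tcj_enrichment * mean(incident edge values - background)``;
* a gap voids a disk back to ``background``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .graph import JunctionGraph, extract_graph
from .mesh import CellMesh, make_mesh
from .geometry import disk_pixel_indices

ML_BIN_DEG = 15.0


@dataclass
class RecoilParams:
    """Kelvin-Voigt recoil trace parameters: d(t) = L0 + A(1 - e^(-t/tau))."""

    L0_um: float = 10.0
    A_um: float = 1.2
    tau_s: float = 4.0
    dt_s: float = 2.0
    T_s: float = 8.0
    noise_sd_um: float = 0.05

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.dt_s <= 0 or self.T_s < self.dt_s:
            raise ValueError("need dt_s > 0 and T_s >= dt_s")


@dataclass
class GeneratorConfig:
    """Named parameter set for the synthetic epithelium.

    Probabilities are per event (per vertex of the matching order, per
    division, per rosette); intensities are in arbitrary units; lengths
    in micrometers; the movie frame interval is fixed at 6 minutes by
    the acquisition design it emulates.
    """

    preset_name: str = "custom"
    n_cells: int = 118
    field_um: tuple[float, float] = (60.0, 60.0)
    pixel_size_um: float = 0.3
    seed: int = 0
    # mesh composition: higher-order vertices made by edge contraction
    n_order4: int = 28
    n_order5: int = 9
    relaxation_steps: int = 3
    # intensity model
    polarity_factor: float = 1.5
    tcj_enrichment: float = 1.5
    edge_intensity_base: float = 100.0
    background_level: float = 50.0
    noise_sd: float = 5.0
    vertex_disk_radius_um: float = 0.5
    blur_sigma_um: float = 0.0
    # gap injection
    gap_prob_by_order: dict[int, float] = field(default_factory=dict)
    gap_prob_bicellular: float = 0.0
    p_tj_given_aj: float = 0.0
    gap_radius_um: tuple[float, float] = (0.6, 0.2)
    gap_radius_min_um: float = 0.2
    tj_radius_scale: float = 0.5
    gaps_per_region_target: float | None = None
    # time-lapse dynamics
    frame_interval_min: float = 6.0
    movie_duration_min: float = 180.0
    division_rate_per_hour: float = 0.02
    p_neighbor_gap: float = 0.0
    p_no_new_interface: float = 0.0
    completion_delay_mean_min: float = 18.0
    rosette_count: int = 0
    p_rosette_gap: float = 0.0
    rosette_fate_probs: dict[str, float] = field(
        default_factory=lambda: {"repaired": 0.6, "persistent": 0.25,
                                 "expanding": 0.15})
    constriction_fraction_at: dict[float, float] = field(default_factory=dict)
    # laser ablation
    recoil: RecoilParams = field(default_factory=RecoilParams)

    def __post_init__(self):
        for p in list(self.gap_prob_by_order.values()) + [
            self.gap_prob_bicellular, self.p_tj_given_aj, self.p_neighbor_gap,
            self.p_no_new_interface, self.p_rosette_gap,
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.rosette_fate_probs:
            s = sum(self.rosette_fate_probs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError("rosette_fate_probs must sum to 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    def to_json(self, path):
        d = asdict(self)
        d["gap_prob_by_order"] = {str(k): v for k, v in self.gap_prob_by_order.items()}
        d["constriction_fraction_at"] = {
            str(k): v for k, v in self.constriction_fraction_at.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        d["gap_prob_by_order"] = {int(k): v for k, v in d["gap_prob_by_order"].items()}
        d["constriction_fraction_at"] = {
            float(k): v for k, v in d["constriction_fraction_at"].items()}
        d["recoil"] = RecoilParams(**d["recoil"])
        d["field_um"] = tuple(d["field_um"])
        d["gap_radius_um"] = tuple(d["gap_radius_um"])
        return cls(**d)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------
# The default mesh composition (n_cells / n_order4 / n_order5 for a
# 60x60 um field) is calibrated so a 50x50 um region carries on the
# order of 90-100 tricellular, ~25 4-cell and ~8 5+-cell vertices,
# matching the censuses reported for the tissue this emulates; with the
# late-stage mutant per-order gap probabilities this yields ~35 expected
# gaps per region, making the per-region count and the per-order
# fractions mutually consistent.  Early-stage presets print no per-order
# probabilities, so theirs are the late-stage profile scaled to the
# per-region count target.

_MUTANT_LATE_P = {3: 0.18, 4: 0.49, 5: 0.78}
_CONTROL_LATE_P = {3: 0.05, 4: 0.14, 5: 0.32}


def _scale_probs(p, f):
    return {k: min(1.0, v * f) for k, v in p.items()}


_STATIC_COMMON = dict(
    n_cells=118, field_um=(60.0, 60.0), n_order4=28, n_order5=9,
    polarity_factor=1.5, tcj_enrichment=1.5,
)
_MOVIE_COMMON = dict(
    n_cells=430, field_um=(110.0, 110.0), n_order4=20, n_order5=0,
    polarity_factor=1.2, tcj_enrichment=1.5,
    constriction_fraction_at={90.0: 0.17, 180.0: 0.22},
    division_rate_per_hour=0.02, rosette_count=10,
)

_PRESETS: dict[str, dict] = {
    "mutant_late": dict(
        _STATIC_COMMON,
        gap_prob_by_order=dict(_MUTANT_LATE_P),
        gaps_per_region_target=35.0,
        p_tj_given_aj=56 / 498,
    ),
    "control_late": dict(
        _STATIC_COMMON,
        gap_prob_by_order=dict(_CONTROL_LATE_P),
        gaps_per_region_target=18.0,
        p_tj_given_aj=9 / 150,
    ),
    # early-stage probabilities: late profile scaled to the 12 (mutant)
    # and 4 (control) expected gaps/region given the calibrated census
    "mutant_early": dict(
        _STATIC_COMMON,
        gap_prob_by_order=_scale_probs(_MUTANT_LATE_P, 12.0 / 35.0),
        gaps_per_region_target=12.0,
        p_tj_given_aj=0.05,
    ),
    "control_early": dict(
        _STATIC_COMMON,
        gap_prob_by_order=_scale_probs(_CONTROL_LATE_P, 4.0 / 11.0),
        gaps_per_region_target=4.0,
        p_tj_given_aj=0.05,
    ),
    "control_movie": dict(
        _MOVIE_COMMON,
        p_no_new_interface=0.01, p_neighbor_gap=0.08, p_rosette_gap=0.11,
        rosette_fate_probs={"repaired": 0.2, "persistent": 0.8, "expanding": 0.0},
        completion_delay_mean_min=18.0,
    ),
    "mutant_movie": dict(
        _MOVIE_COMMON,
        p_no_new_interface=0.49, p_neighbor_gap=0.73, p_rosette_gap=0.71,
        rosette_fate_probs={"repaired": 20 / 33, "persistent": 7 / 33,
                           "expanding": 6 / 33},
        completion_delay_mean_min=36.0,
    ),
    # Rho-kinase-inhibition analogue: myosin planar polarity and vertex
    # enrichment abolished
    "zero_polarity": dict(
        _STATIC_COMMON, polarity_factor=1.0, tcj_enrichment=1.0,
    ),
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """Return a named, fully populated generator configuration."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return GeneratorConfig(preset_name=name, **kw)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def edge_render_value(angle_deg: float, config: GeneratorConfig) -> float:
    """Boundary-pixel value for an edge of the given folded angle."""
    pf = config.polarity_factor if (np.isfinite(angle_deg)
                                    and angle_deg <= ML_BIN_DEG) else 1.0
    return config.background_level + pf * config.edge_intensity_base


def render_channels(mesh_or_label, config: GeneratorConfig,
                    graph: JunctionGraph | None = None,
                    channels: tuple[str, ...] = ("aj",),
                    suppressed_pairs: set[tuple[int, int]] | None = None,
                    voids: list[tuple[tuple[float, float], float]] | None = None,
                    rng: np.random.Generator | None = None,
                    add_noise: bool = True):
    """Render junctional intensity channels for a label image.

    ``suppressed_pairs`` are cell-label pairs whose shared boundary is
    left at background (used for failed new interfaces and neighbor-
    contact gaps in movies); ``voids`` are (center_um, radius_um) disks
    reset to background after drawing (rosette gaps).  Negative values
    after noise are clipped at 0.
    """
    if isinstance(mesh_or_label, CellMesh):
        label = mesh_or_label.label_image
        px = mesh_or_label.pixel_size_um
    else:
        label = np.asarray(mesh_or_label)
        px = config.pixel_size_um
    if graph is None:
        graph = extract_graph(label, px)
    sup = {tuple(sorted(p)) for p in (suppressed_pairs or set())}

    base = np.full(label.shape, config.background_level, dtype=np.float64)
    edge_value = {}
    for row in graph.edges.itertuples():
        pair = (row.cell1, row.cell2)
        val = edge_render_value(row.angle_deg, config)
        edge_value[row.id] = val
        if pair in sup:
            continue
        poly = graph.edge_polylines[row.id]
        # corner (i, j) touches pixels (i, j)..(i+1, j+1); corner indices
        # are interior so no bounds clipping is needed
        jj = np.round(poly[:, 0] / px - 1.0).astype(np.intp)
        ii = np.round(poly[:, 1] / px - 1.0).astype(np.intp)
        base[ii, jj] = val
        base[ii, jj + 1] = val
        base[ii + 1, jj] = val
        base[ii + 1, jj + 1] = val

    # vertex disks: enrichment over the mean of incident (drawn) edges
    incid: dict[int, list[float]] = {}
    for row in graph.edges.itertuples():
        if tuple(sorted((row.cell1, row.cell2))) in sup:
            continue
        for v in (row.v1, row.v2):
            if v > 0:
                incid.setdefault(v, []).append(edge_value[row.id])
    for row in graph.vertices.itertuples():
        vals = incid.get(row.id, [])
        if not vals:
            continue
        net = float(np.mean(vals)) - config.background_level
        disk_val = config.background_level + config.tcj_enrichment * net
        rr, cc = disk_pixel_indices((row.x_um, row.y_um),
                                    config.vertex_disk_radius_um, px, label.shape)
        base[rr, cc] = disk_val

    for center, radius in (voids or []):
        rr, cc = disk_pixel_indices(center, radius, px, label.shape)
        base[rr, cc] = config.background_level

    out = {}
    for k, ch in enumerate(channels):
        img = base.copy()
        if config.blur_sigma_um > 0:
            from scipy.ndimage import gaussian_filter
            img = gaussian_filter(img, config.blur_sigma_um / px)
        if add_noise and config.noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(config.seed)
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
            np.clip(img, 0.0, None, out=img)
        out[ch] = img
    return out


# ---------------------------------------------------------------------------
# gap injection
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["event", "frame", "x_um", "y_um", "radius_um",
                 "junction_order", "channel", "label", "value"]


def _sample_gap_radius(config, rng):
    mean, sd = config.gap_radius_um
    for _ in range(100):
        r = rng.normal(mean, sd)
        if r >= config.gap_radius_min_um:
            return float(r)
    return config.gap_radius_min_um


def inject_gaps(graph: JunctionGraph, channel_images: dict[str, np.ndarray],
                config: GeneratorConfig, rng: np.random.Generator):
    """Void junctional signal at vertices, Bernoulli per vertex order.

    Tight-junction gaps (channel "tj", when rendered) occur only at
    adherens-junction gap sites, with probability ``p_tj_given_aj`` and
    radius ``tj_radius_scale`` times the colocated AJ radius.  Returns a
    truth table (one row per injected gap).
    """
    if not set(config.gap_prob_by_order) <= {3, 4, 5}:
        raise ValueError("gap_prob_by_order keys must be within {3, 4, 5}")
    px = graph.pixel_size_um
    bg = config.background_level
    rows = []
    aj = channel_images.get("aj")
    tj = channel_images.get("tj")
    for row in graph.vertices.itertuples():
        k = min(int(row.order), 5)
        p = config.gap_prob_by_order.get(k, 0.0)
        if p <= 0 or rng.random() >= p:
            continue
        r = _sample_gap_radius(config, rng)
        # void at least one pixel: a sub-pixel gap still erases signal at
        # the junction point itself
        r_eff = max(r, 0.8 * px)
        if aj is not None:
            rr, cc = disk_pixel_indices((row.x_um, row.y_um), r_eff, px, aj.shape)
            aj[rr, cc] = bg
        rows.append(("gap", -1, row.x_um, row.y_um, r, int(row.order), "aj",
                     int(row.id), np.nan))
        if tj is not None and rng.random() < config.p_tj_given_aj:
            rt = r * config.tj_radius_scale
            rr, cc = disk_pixel_indices((row.x_um, row.y_um),
                                        max(rt, 0.8 * px), px, tj.shape)
            tj[rr, cc] = bg
            rows.append(("gap", -1, row.x_um, row.y_um, rt, int(row.order),
                         "tj", int(row.id), np.nan))
    if config.gap_prob_bicellular > 0:
        for row in graph.edges.itertuples():
            if rng.random() >= config.gap_prob_bicellular:
                continue
            poly = graph.edge_polylines[row.id]
            mid = poly[len(poly) // 2]
            r = _sample_gap_radius(config, rng)
            if aj is not None:
                rr, cc = disk_pixel_indices(mid, r, px, aj.shape)
                aj[rr, cc] = bg
            rows.append(("gap", -1, float(mid[0]), float(mid[1]), r, 2, "aj",
                         int(row.id), np.nan))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Serialize a truth table (gaps or time-lapse events) as CSV."""
    df = truth if len(truth) else pd.DataFrame(columns=TRUTH_COLUMNS)
    df.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# static-field convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticField:
    mesh: CellMesh
    graph: JunctionGraph
    channels: dict[str, np.ndarray]
    truth: pd.DataFrame
    config: GeneratorConfig


def generate_field(config: GeneratorConfig, seed: int | None = None,
                   channels: tuple[str, ...] = ("aj",)) -> SyntheticField:
    """Mesh -> render -> inject gaps -> add noise, fully seeded."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mesh_seed = int(rng.integers(2**31))
    mesh = make_mesh(config.n_cells, config.field_um, seed=mesh_seed,
                     relaxation_steps=config.relaxation_steps,
                     pixel_size_um=config.pixel_size_um,
                     n_order4=config.n_order4, n_order5=config.n_order5)
    graph = extract_graph(mesh.label_image, mesh.pixel_size_um)
    imgs = render_channels(mesh, config, graph=graph, channels=channels,
                           add_noise=False)
    truth = inject_gaps(graph, imgs, config, rng)
    if config.noise_sd > 0:
        for ch in imgs:
            imgs[ch] = np.clip(
                imgs[ch] + rng.normal(0.0, config.noise_sd, imgs[ch].shape),
                0.0, None)
    return SyntheticField(mesh=mesh, graph=graph, channels=imgs,
                          truth=truth, config=config)


def simulate_recoil_trace(params: RecoilParams, seed: int = 0):
    """Kelvin-Voigt vertex-separation trace sampled at the acquisition
    grid t in {0 (pre-cut), dt, 2dt, ..., T} with additive Gaussian
    noise on the distances."""
    from .recoil import RecoilTrace

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.T_s + params.dt_s / 2, params.dt_s)
    d = params.L0_um + params.A_um * (1.0 - np.exp(-t / params.tau_s))
    if params.noise_sd_um > 0:
        d = d + rng.normal(0.0, params.noise_sd_um, size=d.shape)
    return RecoilTrace(times_s=t, distances_um=d)
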