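"""Scoring of dynamic cell behaviors in junction-labeled movies:
rosette tracking and gap-fate classification, division adhesion
outcomes, cumulative new-interface timing, and apical-area trajectories.

All intensity criteria reuse the gap threshold convention: a contact or
vertex is "junction-positive" when its background-subtracted signal
exceeds ``threshold_fraction`` times the frame's median junctional
(skeleton) intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaps import DEFAULT_THRESHOLD_FRACTION, _grow_radius
from .geometry import RegionSpec, disk_pixel_indices
from .graph import JunctionGraph, extract_graph, skeleton_mask
from .intensity import edge_mean_intensity

SCORING_WINDOW_MIN = 90.0
MAX_LINK_STEP_UM = 2.0
MIN_EXPANSION_STEP_UM = 0.1


@dataclass
class FrameContext:
    """Per-frame quantities shared by the trackers."""
    graph: JunctionGraph
    skeleton: np.ndarray
    background: float
    cutoff: float           # absolute (background-subtracted) threshold


def build_frame_contexts(label_movie: np.ndarray, channel_movie: np.ndarray,
                         pixel_size_um: float,
                         threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                         graphs: list | None = None) -> list[FrameContext]:
    """Extract per-frame graphs, backgrounds (median cytoplasmic pixel)
    and junctional reference levels for a movie.

    ``graphs`` may supply precomputed per-frame junction graphs (graph
    extraction is deterministic, so recomputing them is pure cost).
    """
    out = []
    for f in range(label_movie.shape[0]):
        lab = label_movie[f]
        g = graphs[f] if graphs is not None else extract_graph(lab, pixel_size_um)
        sk = skeleton_mask(lab)
        tissue = lab > 0
        interior = tissue & ~sk
        img = channel_movie[f]
        bg = float(np.median(img[interior])) if interior.any() else 0.0
        ref = float(np.median(img[sk & tissue])) - bg if (sk & tissue).any() else 0.0
        out.append(FrameContext(graph=g, skeleton=sk, background=bg,
                                cutoff=threshold_fraction * max(ref, 0.0)))
    return out


# ---------------------------------------------------------------------------
# rosettes
# ---------------------------------------------------------------------------

@dataclass
class RosetteTrack:
    id: int
    frames: list[int]
    centers_um: list[tuple[float, float]]
    max_order: int
    formation_mode: str = "undetermined"   # rearrangement | preexisting | undetermined
    gap_fate: str = "no_gap"               # no_gap | repaired | persistent | expanding
    gap_radii_um: list[float] = field(default_factory=list)


def track_rosettes(contexts: list[FrameContext],
                   tight_radius_um: float = 0.4,
                   min_tight_fraction: float = 0.3) -> list[RosetteTrack]:
    """Detect and link 5+-order vertices across frames.

    Linking is nearest-neighbor with a maximum step of 2 um/frame (the
    tissue moves slowly at 6-min sampling); ties go to the lower track
    id.  A track must read as a *compact* 5-cell point -- order >= 5
    within ``tight_radius_um`` -- in at least ``min_tight_fraction`` of
    its frames: two merely close lower-order vertices drifting under the
    standard order disk rarely do, while a true rosette center does.
    Formation mode: "preexisting" when the rosette is present at frame
    0, "rearrangement" when at least one pair of its constituent cells
    was not yet adjacent at movie start.
    """
    from .graph import _order_from_disk
    tracks: list[RosetteTrack] = []
    open_tracks: list[RosetteTrack] = []
    for f, ctx in enumerate(contexts):
        v = ctx.graph.vertices
        cand = v[v["order"] >= 5]
        used = set()
        assigned = {}
        for tr in sorted(open_tracks, key=lambda t: t.id):
            if not len(cand):
                continue
            last = np.array(tr.centers_um[-1])
            d = np.hypot(cand["x_um"].to_numpy() - last[0],
                         cand["y_um"].to_numpy() - last[1])
            order_d = np.argsort(d, kind="stable")
            for k in order_d:
                if d[k] > MAX_LINK_STEP_UM:
                    break
                rid = int(cand["id"].iloc[int(k)])
                if rid in used:
                    continue
                used.add(rid)
                assigned[rid] = tr
                row = cand.iloc[int(k)]
                tr.frames.append(f)
                tr.centers_um.append((float(row.x_um), float(row.y_um)))
                tr.max_order = max(tr.max_order, int(row.order))
                break
        for row in cand.itertuples():
            if int(row.id) in used:
                continue
            # a rasterized rosette core can split into two 5+ vertices for
            # a frame; don't spawn a second track on top of an existing one
            if any(np.hypot(tr.centers_um[-1][0] - row.x_um,
                            tr.centers_um[-1][1] - row.y_um) <= 1.2
                   for tr in open_tracks):
                continue
            tr = RosetteTrack(id=len(tracks) + 1, frames=[f],
                              centers_um=[(float(row.x_um), float(row.y_um))],
                              max_order=int(row.order))
            tracks.append(tr)
            open_tracks.append(tr)
    # compactness filter
    px0 = contexts[0].graph.pixel_size_um
    kept = []
    for tr in tracks:
        frac = np.mean([
            _order_from_disk(contexts[f].graph.label_image, x, y,
                             tight_radius_um, px0) >= 5
            for f, (x, y) in zip(tr.frames, tr.centers_um)])
        if frac >= min_tight_fraction:
            kept.append(tr)
    tracks = kept
    # formation mode
    g0 = contexts[0].graph
    adj0 = {tuple(sorted((r.cell1, r.cell2))) for r in g0.edges.itertuples()}
    lab0 = g0.label_image
    px = g0.pixel_size_um
    for tr in tracks:
        if tr.frames[0] == 0:
            tr.formation_mode = "preexisting"
            continue
        cx, cy = tr.centers_um[0]
        lab_f = contexts[tr.frames[0]].graph.label_image
        rr, cc = disk_pixel_indices((cx, cy), 1.5, px, lab_f.shape)
        labs = np.unique(lab_f[rr, cc])
        labs = labs[labs > 0]
        if len(labs) < 2:
            tr.formation_mode = "undetermined"
            continue
        pairs = [(int(a), int(b)) for i, a in enumerate(labs)
                 for b in labs[i + 1:]]
        tr.formation_mode = ("rearrangement"
                             if any(p not in adj0 for p in pairs)
                             else "undetermined")
    return tracks


def gap_radius_series(track: RosetteTrack, contexts: list[FrameContext],
                      channel_movie: np.ndarray,
                      seed_radius_um: float = 0.5) -> list[float]:
    """Gap radius (0 when no gap) at the rosette center for every tracked
    frame, measured with the same dimmest-pixel seed rule and radial
    growth as static gap detection."""
    px = contexts[0].graph.pixel_size_um
    radii = []
    for f, center in zip(track.frames, track.centers_um):
        ctx = contexts[f]
        img = channel_movie[f]
        rr, cc = disk_pixel_indices(center, seed_radius_um, px, img.shape)
        on = ctx.skeleton[rr, cc]
        if not on.any():
            radii.append(0.0)
            continue
        if (img[rr[on], cc[on]].min() - ctx.background) >= ctx.cutoff:
            radii.append(0.0)
            continue
        radii.append(_grow_radius(img, ctx.skeleton, center, px,
                                  ctx.background, ctx.cutoff))
    return radii


def classify_rosette_fate(track: RosetteTrack,
                          gap_radii: list[float] | None = None,
                          contexts: list[FrameContext] | None = None,
                          channel_movie: np.ndarray | None = None) -> str:
    """Mutually exclusive gap fates for a rosette track.

    * ``no_gap`` -- no central gap at any tracked frame;
    * ``repaired`` -- the gap disappears and stays absent for >= 2
      consecutive tracked frames;
    * ``expanding`` -- the radius strictly increases over >= 2
      consecutive frame steps (beyond sampling jitter);
    * ``persistent`` -- everything else.
    """
    if gap_radii is None:
        gap_radii = gap_radius_series(track, contexts, channel_movie)
    r = np.asarray(gap_radii, dtype=float)
    track.gap_radii_um = [float(x) for x in r]
    present = r > 0
    if not present.any():
        track.gap_fate = "no_gap"
        return track.gap_fate
    first = int(np.argmax(present))
    seg = r[first:]
    inc = np.diff(seg)
    expanding = any(inc[k] >= MIN_EXPANSION_STEP_UM
                    and inc[k + 1] >= MIN_EXPANSION_STEP_UM
                    for k in range(len(inc) - 1))
    if expanding:
        track.gap_fate = "expanding"
        return track.gap_fate
    absent = seg == 0
    run = 0
    repaired = False
    for a in absent:
        run = run + 1 if a else 0
        if run >= 2:
            repaired = True
    if repaired and absent[-1]:
        track.gap_fate = "repaired"
    else:
        track.gap_fate = "persistent"
    return track.gap_fate


# ---------------------------------------------------------------------------
# divisions
# ---------------------------------------------------------------------------

@dataclass
class DivisionTrack:
    cell_label: int
    t0_frame: int
    completed: bool
    completion_time_min: float | None     # multiple of the frame interval
    censored_at_90: bool
    neighbor_gap: bool
    excluded: bool = False                # left the field / untrackable


def _pair_contact_mean(ctx: FrameContext, image, a, b, exclusion_um=1.0):
    """Mean junctional intensity along the boundary between labels a and
    b, vertex-proximal zones excluded (falls back to a smaller exclusion
    for very short contacts).  NaN when the labels share no boundary."""
    e = ctx.graph.edges
    sel = e[((e["cell1"] == a) & (e["cell2"] == b))
            | ((e["cell1"] == b) & (e["cell2"] == a))]
    if not len(sel):
        return np.nan
    from .intensity import _edge_vertex_exclusions
    means = []
    for row in sel.itertuples():
        for excl in (exclusion_um, 0.5, 0.0):
            m = edge_mean_intensity(
                image, ctx.graph.edge_polylines[row.id],
                ctx.graph.pixel_size_um, skeleton=ctx.skeleton,
                exclusion_disks=_edge_vertex_exclusions(ctx.graph, row, excl))
            if np.isfinite(m):
                means.append(m)
                break
    return float(np.mean(means)) if means else np.nan


def track_division(label_movie: np.ndarray, contexts: list[FrameContext],
                   channel_movie: np.ndarray, parent_label: int,
                   t0_frame: int, frame_interval_min: float = 6.0) -> DivisionTrack:
    """Score one division for adhesion outcomes.

    The daughters are the labels that occupy the parent's footprint at
    t0+1.  The division is *completed* at the first frame the daughter
    interface is junction-positive; if that never happens within 90 min
    of furrow onset it is censored (scored as a failure to form a new
    interface).  ``neighbor_gap`` is scored when any contact with a
    neighboring cell loses signal (>= 2 consecutive frames) and is not
    restored by the end of the 90-min window.
    """
    n_frames = label_movie.shape[0]
    window = int(round(SCORING_WINDOW_MIN / frame_interval_min))
    end = min(t0_frame + window, n_frames - 1)
    if t0_frame + 1 >= n_frames:
        return DivisionTrack(parent_label, t0_frame, False, None, False,
                             False, excluded=True)
    mask = label_movie[t0_frame] == parent_label
    if not mask.any():
        return DivisionTrack(parent_label, t0_frame, False, None, False,
                             False, excluded=True)
    after = label_movie[t0_frame + 1][mask]
    labs, counts = np.unique(after[after > 0], return_counts=True)
    keep = labs[counts > 0.05 * mask.sum()]
    new = [int(l) for l in keep if l != parent_label]
    if len(new) < 2:
        return DivisionTrack(parent_label, t0_frame, False, None, False,
                             False, excluded=True)
    new.sort(key=lambda l: -counts[list(labs).index(l)])
    d1, d2 = new[0], new[1]

    # neighbors of the parent immediately before ingression
    e0 = contexts[t0_frame].graph.edges
    nbrs = set(e0.loc[e0["cell1"] == parent_label, "cell2"]) \
        | set(e0.loc[e0["cell2"] == parent_label, "cell1"])
    nbrs = {int(n) for n in nbrs if n > 0}

    completion_frame = None
    for f in range(t0_frame + 1, end + 1):
        m = _pair_contact_mean(contexts[f], channel_movie[f], d1, d2)
        if np.isfinite(m) and (m - contexts[f].background) >= contexts[f].cutoff:
            completion_frame = f
            break

    neighbor_gap = False
    for nbr in sorted(nbrs):
        low_run = 0
        tail_low = False
        for f in range(t0_frame, end + 1):
            pairs = [(parent_label, nbr)] if f <= t0_frame else \
                [(d1, nbr), (d2, nbr), (parent_label, nbr)]
            vals = [_pair_contact_mean(contexts[f], channel_movie[f], a, b)
                    for a, b in pairs]
            vals = [v for v in vals if np.isfinite(v)]
            if not vals:
                continue
            low = (min(vals) - contexts[f].background) < contexts[f].cutoff
            low_run = low_run + 1 if low else 0
            tail_low = low
        if low_run >= 2 and tail_low:
            neighbor_gap = True
            break

    completed = completion_frame is not None
    return DivisionTrack(
        cell_label=int(parent_label), t0_frame=int(t0_frame),
        completed=completed,
        completion_time_min=(None if not completed
                             else (completion_frame - t0_frame) * frame_interval_min),
        censored_at_90=not completed,
        neighbor_gap=neighbor_gap)


def cumulative_new_interface(tracks: list[DivisionTrack],
                             times_min: np.ndarray | None = None,
                             frame_interval_min: float = 6.0,
                             denominator: str = "completed") -> pd.DataFrame:
    """Cumulative fraction of divisions with a junction-positive new
    vertex/interface by each time on the frame grid.

    ``denominator`` is "completed" (the figure convention) or "all".
    """
    usable = [t for t in tracks if not t.excluded]
    if not usable:
        raise ValueError("no tracks")
    if times_min is None:
        times_min = np.arange(0.0, SCORING_WINDOW_MIN + frame_interval_min,
                              frame_interval_min)
    comp = [t.completion_time_min for t in usable if t.completed]
    denom = len(comp) if denominator == "completed" else len(usable)
    frac = [(np.sum(np.asarray(comp) <= t) / denom if denom else np.nan)
            for t in times_min]
    return pd.DataFrame({"t_min": times_min, "cumulative_fraction": frac})


def division_summary(tracks: list[DivisionTrack]) -> dict:
    usable = [t for t in tracks if not t.excluded]
    n = len(usable)
    return {
        "n_divisions": n,
        "n_excluded": len(tracks) - n,
        "failure_fraction": (sum(t.censored_at_90 for t in usable) / n
                             if n else np.nan),
        "neighbor_gap_fraction": (sum(t.neighbor_gap for t in usable) / n
                                  if n else np.nan),
        "median_completion_min": float(np.median(
            [t.completion_time_min for t in usable if t.completed]))
        if any(t.completed for t in usable) else np.nan,
    }


# ---------------------------------------------------------------------------
# apical area trajectory
# ---------------------------------------------------------------------------

def area_trajectory(label_movie: np.ndarray, pixel_size_um: float,
                    region: RegionSpec, checkpoint_min: tuple[float, ...] = (90.0, 180.0),
                    frame_interval_min: float = 6.0) -> dict:
    """Percent decrease of tracked apical cell area at checkpoints.

    Cells present in the region at frame 0 (not touching the image
    border) are tracked by label; cells lost by a checkpoint (division,
    field exit) are excluded pairwise.  The statistic is the mean of
    per-cell area ratios, which is exact under uniform constriction.
    """
    lab0 = label_movie[0]
    px = pixel_size_um
    n_lab = int(label_movie.max()) + 1
    a0 = np.bincount(lab0.ravel(), minlength=n_lab).astype(float)
    from scipy import ndimage as ndi
    labs = np.unique(lab0[lab0 > 0])
    com = ndi.center_of_mass(np.ones_like(lab0, float), lab0, index=labs)
    xy = np.array([[(c[1] + 0.5) * px, (c[0] + 0.5) * px] for c in com])
    inside = region.contains(xy)
    sl = ndi.find_objects(lab0)
    border = np.array([
        sl[int(l) - 1] is None
        or sl[int(l) - 1][0].start == 0 or sl[int(l) - 1][1].start == 0
        or sl[int(l) - 1][0].stop == lab0.shape[0]
        or sl[int(l) - 1][1].stop == lab0.shape[1]
        for l in labs])
    tracked = labs[inside & ~border]
    results = {"n_initial": int(len(tracked))}
    pct = {}
    for t in checkpoint_min:
        f = int(round(t / frame_interval_min))
        f = min(f, label_movie.shape[0] - 1)
        at = np.bincount(label_movie[f].ravel(), minlength=n_lab).astype(float)
        keep = tracked[at[tracked] > 0]
        if len(keep) == 0:
            pct[t] = np.nan
            continue
        ratios = at[keep] / a0[keep]
        pct[t] = float(100.0 * (1.0 - np.mean(ratios)))
        results[f"n_tracked_{t:g}"] = int(len(keep))
    results["percent_decrease"] = pct
    results["unreliable"] = any(
        results.get(f"n_tracked_{t:g}", 0) < 0.5 * max(len(tracked), 1)
        for t in checkpoint_min)
    return results
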